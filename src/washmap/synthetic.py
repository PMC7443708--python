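"""Synthetic continent generator.

Builds a reproducible world with the statistical structure the analysis
assumes: a gridded population surface, spatially correlated covariates, a
nested country/admin1/admin2 partition, true access surfaces generated on the
continuation-ratio scale (linear covariate effects + a separable
spatiotemporal Gaussian field + country-specific year trends), and survey
simulators producing geolocated cluster (point) data, areal admin aggregates,
and nationally representative annual series.

The world is an abstract planar grid (row-major, origin top-left, unit cell
size); admin units are rectangular partitions for testability.  Gaussian
fields use a dense Cholesky factor of a Matérn ν=3/2 covariance on cell
centres — exact at desk-scale grid sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from washmap._rng import child_rng
from washmap.admin import AdminHierarchy
from washmap.grids import RasterGrid
from washmap.ordinal import recombine
from washmap.records import SurveyRecord

DEFAULT_YEARS = tuple(range(2000, 2018))


# --------------------------------------------------------------------------
# covariance kernels


def matern32(dist: np.ndarray, rho: float) -> np.ndarray:
    a = np.sqrt(3.0) * dist / rho
    return (1.0 + a) * np.exp(-a)


def exponential(dist: np.ndarray, rho: float) -> np.ndarray:
    return np.exp(-dist / rho)


KERNELS = {"matern32": matern32, "exponential": exponential}


def spatial_chol(coords: np.ndarray, rho: float, kernel: str = "matern32",
                 jitter: float = 1e-8) -> np.ndarray:
    """Lower Cholesky factor of the unit-variance spatial covariance."""
    K = KERNELS[kernel](cdist(coords, coords), rho)
    K[np.diag_indices_from(K)] += jitter
    return np.linalg.cholesky(K)


def ar1_chol(n: int, ar: float) -> np.ndarray:
    """Lower Cholesky factor of a unit-variance AR1 correlation matrix."""
    idx = np.arange(n)
    K = ar ** np.abs(idx[:, None] - idx[None, :])
    K[np.diag_indices_from(K)] += 1e-10
    return np.linalg.cholesky(K)


# --------------------------------------------------------------------------
# configuration and world


@dataclass
class WorldConfig:
    """Generator settings; the defaults are the package's desk-scale study
    conditions (grid and admin sizes chosen so the full pipeline runs on one
    CPU in minutes, survey density 20 clusters of 25 households per country
    and year, study period 2000-2017, seven covariates)."""

    n_rows: int = 16
    n_cols: int = 16
    n_countries: int = 4
    admin1_per_country: int = 2
    admin2_per_admin1: int = 2
    years: tuple[int, ...] = DEFAULT_YEARS
    n_covariates: int = 7
    spatial_range: float = 6.0
    spatial_sd: float = 1.0
    temporal_ar: float = 0.9
    total_population: float = 1_000_000.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.years = tuple(int(y) for y in self.years)
        if any(b <= a for a, b in zip(self.years, self.years[1:])):
            raise ValueError("years must be strictly increasing")
        for name in (
            "n_rows",
            "n_cols",
            "n_countries",
            "admin1_per_country",
            "admin2_per_admin1",
            "n_covariates",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if not (-1.0 < self.temporal_ar < 1.0):
            raise ValueError("temporal_ar must lie in (-1, 1)")
        if self.spatial_range <= 0 or self.spatial_sd <= 0:
            raise ValueError("spatial_range and spatial_sd must be positive")
        if self.total_population <= 0:
            raise ValueError("total_population must be positive")

    @property
    def n_years(self) -> int:
        return len(self.years)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols


@dataclass
class World:
    """A generated synthetic continent, including the generating truth."""

    config: WorldConfig
    population: RasterGrid
    covariates: RasterGrid  # (n_covariates, n_rows, n_cols), constant in time
    admin: AdminHierarchy
    true_conditional: np.ndarray  # (3, n_cells, n_years)
    true_category: np.ndarray  # (4, n_cells, n_years)

    @property
    def years(self) -> tuple[int, ...]:
        return self.config.years

    def year_index(self, year: int) -> int:
        try:
            return self.config.years.index(int(year))
        except ValueError:
            raise ValueError(f"year {year} not in study period") from None

    def covariates_for_year(self, year: int) -> list[RasterGrid]:
        """Per-year covariate rasters (time-constant in this generator)."""
        self.year_index(year)
        return [
            RasterGrid(self.covariates.values[j], name=f"cov{j}")
            for j in range(self.config.n_covariates)
        ]


# --------------------------------------------------------------------------
# admin tiling


def _split(n_items: int, n_parts: int) -> list[tuple[int, int]]:
    """Contiguous near-equal partition of range(n_items) into n_parts."""
    edges = np.linspace(0, n_items, n_parts + 1).round().astype(int)
    return [(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:])]


def _country_blocks(cfg: WorldConfig) -> list[tuple[int, int, int, int]]:
    """Tile the grid into n_countries contiguous rectangles (r0,r1,c0,c1)."""
    best = None
    for br in range(1, cfg.n_countries + 1):
        if cfg.n_countries % br:
            continue
        bc = cfg.n_countries // br
        if br <= cfg.n_rows and bc <= cfg.n_cols:
            score = abs(cfg.n_rows / br - cfg.n_cols / bc)
            if best is None or score < best[0]:
                best = (score, br, bc)
    if best is None:
        raise ValueError("grid too small to tile into the requested countries")
    _, br, bc = best
    blocks = []
    for r0, r1 in _split(cfg.n_rows, br):
        for c0, c1 in _split(cfg.n_cols, bc):
            blocks.append((r0, r1, c0, c1))
    return blocks


def _build_admin(cfg: WorldConfig, population: np.ndarray) -> AdminHierarchy:
    country = np.empty(cfg.n_cells, dtype=int)
    admin1 = np.empty(cfg.n_cells, dtype=int)
    admin2 = np.empty(cfg.n_cells, dtype=int)
    grid_idx = np.arange(cfg.n_cells).reshape(cfg.n_rows, cfg.n_cols)
    for ci, (r0, r1, c0, c1) in enumerate(_country_blocks(cfg)):
        # admin1: strips along the block's longer axis; admin2: the other axis
        tall = (r1 - r0) >= (c1 - c0)
        a1_splits = _split(r1 - r0 if tall else c1 - c0, cfg.admin1_per_country)
        for ai, (a0, a1) in enumerate(a1_splits):
            if a1 <= a0:
                raise ValueError("an admin1 unit would own zero cells")
            a2_splits = _split(c1 - c0 if tall else r1 - r0, cfg.admin2_per_admin1)
            for si, (s0, s1) in enumerate(a2_splits):
                if s1 <= s0:
                    raise ValueError("an admin2 unit would own zero cells")
                if tall:
                    cells = grid_idx[r0 + a0 : r0 + a1, c0 + s0 : c0 + s1]
                else:
                    cells = grid_idx[r0 + s0 : r0 + s1, c0 + a0 : c0 + a1]
                country[cells] = ci
                admin1[cells] = ai
                admin2[cells] = si
    return AdminHierarchy(
        country=country, admin1=admin1, admin2=admin2, population=population
    )


# --------------------------------------------------------------------------
# world generation

# Intercepts for the three conditional logits: chosen so the generated worlds
# sit in a realistic LMIC regime (safest category a minority but growing,
# residual no-facility mass present everywhere).
_LEVEL_INTERCEPTS = (-0.8, 0.3, 0.2)
_COVARIATE_EFFECT_SD = 0.25
_TREND_SD = 0.06
_POP_LOGFIELD_SD = 0.8


def generate_world(config: WorldConfig) -> World:
    """Generate a seeded synthetic world; same config + seed is bitwise
    reproducible."""
    cfg = config
    grid = RasterGrid(np.zeros((cfg.n_rows, cfg.n_cols)))
    coords = grid.cell_centers()
    Ls = spatial_chol(coords, cfg.spatial_range)
    Lt = ar1_chol(cfg.n_years, cfg.temporal_ar)

    # population: log-Gaussian field scaled to the configured total
    rng = child_rng(cfg.seed, "world.population")
    pop_field = Ls @ rng.standard_normal(cfg.n_cells)
    population = np.exp(_POP_LOGFIELD_SD * pop_field)
    population *= cfg.total_population / population.sum()

    admin = _build_admin(cfg, population)

    # covariates: independent stationary Gaussian fields, constant in time
    rng = child_rng(cfg.seed, "world.covariates")
    covs = (Ls @ rng.standard_normal((cfg.n_cells, cfg.n_covariates))).T
    covariates = RasterGrid(
        covs.reshape(cfg.n_covariates, cfg.n_rows, cfg.n_cols), name="covariates"
    )

    # true conditional logit surfaces
    rng = child_rng(cfg.seed, "world.truth")
    betas = rng.normal(0.0, _COVARIATE_EFFECT_SD, size=(3, cfg.n_covariates))
    trends = rng.normal(0.0, _TREND_SD, size=(3, cfg.n_countries))
    year_c = np.asarray(cfg.years, float) - np.mean(cfg.years)
    logits = np.empty((3, cfg.n_cells, cfg.n_years))
    for k in range(3):
        st = cfg.spatial_sd * (Ls @ rng.standard_normal((cfg.n_cells, cfg.n_years)) @ Lt.T)
        fixed = _LEVEL_INTERCEPTS[k] + covs.T @ betas[k]
        trend = trends[k][admin.country][:, None] * year_c[None, :]
        logits[k] = fixed[:, None] + trend + st
    if not np.all(np.isfinite(logits)):
        raise FloatingPointError("non-finite truth logits")
    true_conditional = 1.0 / (1.0 + np.exp(-logits))
    true_category = recombine(true_conditional)

    return World(
        config=cfg,
        population=RasterGrid(
            population.reshape(cfg.n_rows, cfg.n_cols), name="population"
        ),
        covariates=covariates,
        admin=admin,
        true_conditional=true_conditional,
        true_category=true_category,
    )


# --------------------------------------------------------------------------
# survey simulators


def _country_cells(world: World, country_id: str) -> np.ndarray:
    return world.admin.cells_of(country_id)


def simulate_point_survey(
    world: World,
    country_id: str,
    year: int,
    n_clusters: int,
    households_per_cluster: int = 25,
    seed: int = 0,
) -> list[SurveyRecord]:
    """Cluster survey: cells sampled with probability proportional to
    population within the country; per cluster, multinomial household counts
    from the true category probabilities at that cell and year."""
    yi = world.year_index(year)
    cells = _country_cells(world, country_id)
    pop = world.admin.population[cells]
    if pop.sum() <= 0:
        raise ValueError(f"country {country_id} has zero population")
    if n_clusters == 0:
        return []
    rng = child_rng(seed, f"survey.point.{country_id}.{year}")
    chosen = rng.choice(cells, size=n_clusters, replace=True, p=pop / pop.sum())
    records = []
    for j, cell in enumerate(chosen):
        probs = world.true_category[:, cell, yi]
        counts = rng.multinomial(households_per_cluster, probs)
        records.append(
            SurveyRecord(
                record_id=f"pt-{country_id}-{year}-{j}",
                source_type="point",
                country=country_id,
                admin1=world.admin.unit_id("admin1", int(cell)),
                admin2=world.admin.unit_id("admin2", int(cell)),
                cell=int(cell),
                year=int(year),
                N=households_per_cluster,
                counts=counts,
            )
        )
    return records


def _areal_record(
    world: World, unit: str, year: int, n_households: int, rng: np.random.Generator,
    record_id: str
) -> SurveyRecord:
    yi = world.year_index(year)
    cells = world.admin.cells_of(unit)
    pop = world.admin.population[cells]
    if pop.sum() <= 0:
        raise ValueError(f"unit {unit} has zero population")
    probs = (world.true_category[:, cells, yi] * pop).sum(axis=1) / pop.sum()
    counts = rng.multinomial(n_households, probs)
    level = world.admin.level_of(unit)
    country = unit if level == "country" else f"C{AdminHierarchy._parse(unit)[1][0]}"
    return SurveyRecord(
        record_id=record_id,
        source_type="areal",
        country=country,
        admin1=unit if level == "admin1" else None,
        admin2=unit if level == "admin2" else None,
        polygon=unit,
        year=int(year),
        N=n_households,
        counts=counts,
    )


def simulate_areal_survey(
    world: World,
    country_id: str,
    year: int,
    admin_level: str = "admin1",
    n_households_per_unit: int = 500,
    seed: int = 0,
) -> list[SurveyRecord]:
    """Areal survey: per admin unit, counts drawn from the population-weighted
    mean of the true category probabilities over the unit's cells."""
    rng = child_rng(seed, f"survey.areal.{country_id}.{year}.{admin_level}")
    units = [
        u
        for u in world.admin.units(admin_level)
        if world.admin._parse(u)[1][0] == world.admin._parse(country_id)[1][0]
    ]
    if not units:
        raise KeyError(f"no {admin_level} units in {country_id}")
    return [
        _areal_record(
            world, u, year, n_households_per_unit, rng,
            f"ar-{u}-{year}",
        )
        for u in units
    ]


def simulate_national_series(
    world: World,
    country_id: str,
    seed: int = 0,
    n_households: int = 4000,
) -> list[SurveyRecord]:
    """Nationally representative series: one large areal record per study
    year over the whole country, for fitting the national trend model."""
    rng = child_rng(seed, f"survey.national.{country_id}")
    return [
        _areal_record(world, country_id, y, n_households, rng, f"nat-{country_id}-{y}")
        for y in world.years
    ]
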