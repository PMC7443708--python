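"""Model validation: five-fold cross-validation and truth recovery.

Clusters (not households) are assigned to folds, either at random stratified
by country or in spatial blocks by admin1.  Out-of-sample metrics follow the
usual small-area-estimation trio: RMSE and bias of the mean prediction
against held-out observed proportions, and 95% coverage — the share of
held-out observed proportions inside the central 95% posterior-predictive
interval.  Predictive intervals include binomial sampling noise (a draw of
k/N per posterior draw), which is what makes nominal coverage attainable for
small cluster sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from washmap._rng import child_rng

FOLD_SCHEMES = ("random_by_cluster", "spatial_blocks")


@dataclass
class CVReport:
    rmse: float
    bias: float
    coverage95: float
    n_heldout: int
    per_fold: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.n_heldout > 0 and self.rmse + 1e-12 < abs(self.bias):
            raise ValueError("rmse cannot be smaller than |bias|")


def make_folds(
    cluster_ids: np.ndarray,
    k: int = 5,
    seed: int = 0,
    scheme: str = "random_by_cluster",
    strata: np.ndarray | None = None,
) -> np.ndarray:
    """Fold label per record; whole clusters stay together.

    ``strata`` gives the stratification key per record: country for the
    random scheme, admin1 for spatial blocks (all clusters of an admin1 land
    in one fold).
    """
    if scheme not in FOLD_SCHEMES:
        raise ValueError(f"scheme must be one of {FOLD_SCHEMES}")
    cluster_ids = np.asarray(cluster_ids)
    uniq = pd.unique(cluster_ids)
    if len(uniq) < k:
        raise ValueError(f"need >= {k} clusters, got {len(uniq)}")
    rng = child_rng(seed, f"cv.folds.{scheme}")
    if scheme == "spatial_blocks":
        if strata is None:
            raise ValueError("spatial_blocks needs admin1 strata")
        blocks = pd.unique(np.asarray(strata))
        perm = rng.permutation(blocks)
        fold_of_block = {b: i % k for i, b in enumerate(perm)}
        return np.array([fold_of_block[s] for s in strata])
    # random by cluster, stratified so each stratum spreads over folds
    strata = np.zeros(len(cluster_ids)) if strata is None else np.asarray(strata)
    first_stratum = {}
    for cid, s in zip(cluster_ids, strata):
        first_stratum.setdefault(cid, s)
    fold_of: dict = {}
    for s in pd.unique(strata):
        members = [c for c in pd.unique(cluster_ids) if first_stratum[c] == s]
        perm = rng.permutation(members)
        for i, c in enumerate(perm):
            fold_of[c] = i % k
    return np.array([fold_of[c] for c in cluster_ids])


def cv_metrics(
    observed: np.ndarray,
    trials: np.ndarray,
    predictive_probs: np.ndarray,
    seed: int = 0,
    fold_labels: np.ndarray | None = None,
) -> CVReport:
    """Out-of-sample RMSE, bias, and 95% posterior-predictive coverage.

    ``observed`` are held-out proportions; ``predictive_probs`` is
    (n_heldout, n_draws) latent probability draws per record.  Binomial noise
    with ``trials`` households is added per draw to form the predictive
    distribution of the observed proportion.
    """
    observed = np.asarray(observed, float)
    if observed.size == 0:
        raise ValueError("empty held-out set")
    probs = np.asarray(predictive_probs, float)
    trials = np.asarray(trials, int)
    rng = child_rng(seed, "cv.predictive")
    counts = rng.binomial(trials[:, None], probs)
    pred_prop = counts / trials[:, None]
    mean_pred = probs.mean(axis=1)
    lo = np.percentile(pred_prop, 2.5, axis=1)
    hi = np.percentile(pred_prop, 97.5, axis=1)

    def _metrics(mask):
        err = mean_pred[mask] - observed[mask]
        return (
            float(np.sqrt(np.mean(err**2))),
            float(np.mean(err)),
            float(np.mean((observed[mask] >= lo[mask]) & (observed[mask] <= hi[mask]))),
            int(mask.sum()),
        )

    rmse, bias, cov, n = _metrics(np.ones(len(observed), bool))
    per_fold = None
    if fold_labels is not None:
        fold_rows = []
        for f in sorted(set(fold_labels)):
            fr, fb, fc, fn = _metrics(np.asarray(fold_labels) == f)
            fold_rows.append(
                {"fold": f, "rmse": fr, "bias": fb, "coverage95": fc, "n_heldout": fn}
            )
        per_fold = pd.DataFrame(fold_rows)
    return CVReport(rmse=rmse, bias=bias, coverage95=cov, n_heldout=n, per_fold=per_fold)
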