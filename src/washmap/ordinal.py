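"""Continuation-ratio decomposition of the four ordered access categories.

The four facility categories (safest first: piped / sewer-septic, other
improved, unimproved, surface water / open defecation) are modelled through
three conditional probabilities:

* ``p1`` — probability of category 1,
* ``q2`` — probability of category 2 given not category 1,
* ``q3`` — probability of category 3 given neither 1 nor 2,

with category 4 taking the residual mass.  Recombination::

    p2 = (1 - p1) * q2
    p3 = (1 - p1) * (1 - q2) * q3
    p4 = (1 - p1) * (1 - q2) * (1 - q3)

guarantees the four categories are mutually exclusive and sum to one — in
every posterior draw, so downstream uncertainty inherits the structure.  The
safest-first conditioning order is part of the public contract.

All functions are vectorised: conditional components stack on axis 0 with
shape ``(3, ...)`` and category vectors with shape ``(4, ...)``.
"""

from __future__ import annotations

import numpy as np

from washmap.records import SurveyRecord

N_CATEGORIES = 4
N_LEVELS = 3


def recombine(conditional: np.ndarray) -> np.ndarray:
    """Category probabilities ``(4, ...)`` from conditionals ``(3, ...)``.

    Total on ``[0, 1]^3``; output sums to 1 along axis 0 up to float drift
    (<= 1e-12).
    """
    c = np.asarray(conditional, dtype=float)
    if c.shape[0] != N_LEVELS:
        raise ValueError("conditional probabilities must stack 3 levels on axis 0")
    if np.any(c < 0) or np.any(c > 1):
        raise ValueError("conditional probabilities must lie in [0, 1]")
    p1, q2, q3 = c[0], c[1], c[2]
    r1 = 1.0 - p1
    r2 = r1 * (1.0 - q2)
    return np.stack([p1, r1 * q2, r2 * q3, r2 * (1.0 - q3)])


def conditional_from_category(category: np.ndarray) -> np.ndarray:
    """Inverse of :func:`recombine`; 0/0 conditionals are defined as 0.

    Needed to turn national category targets into continuation-ratio raking
    targets.  ``recombine(conditional_from_category(p))`` reproduces ``p`` to
    machine precision on the open simplex.
    """
    p = np.asarray(category, dtype=float)
    if p.shape[0] != N_CATEGORIES:
        raise ValueError("category probabilities must stack 4 categories on axis 0")
    r1 = 1.0 - p[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        q2 = np.where(r1 > 0, p[1] / np.where(r1 > 0, r1, 1.0), 0.0)
        r2 = r1 * (1.0 - q2)
        q3 = np.where(r2 > 0, p[2] / np.where(r2 > 0, r2, 1.0), 0.0)
    return np.stack([p[0], np.clip(q2, 0.0, 1.0), np.clip(q3, 0.0, 1.0)])


def to_conditional_observations(
    record: SurveyRecord,
) -> list[tuple[int, int, int]]:
    """Binomial observations ``(level, successes, trials)`` for one record.

    Level 1 uses all N households; level 2 conditions on not category 1;
    level 3 on neither 1 nor 2.  Levels whose conditional denominator is zero
    are omitted — such records carry no information about those models.
    """
    n1, n2, n3, _ = (int(v) for v in record.counts)
    out = [(1, n1, record.N)]
    d2 = record.N - n1
    if d2 > 0:
        out.append((2, n2, d2))
        d3 = d2 - n2
        if d3 > 0:
            out.append((3, n3, d3))
    return out
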