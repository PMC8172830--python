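"""Motif displacement (MD) scores.

The MD-Score is the fraction of best motif hits falling within a small
radius (default 150 bp) of ROI centers among hits within a larger radius
(default 1500 bp).  Unlike the rank-weighted enrichment statistic it
ignores the ROI ordering entirely; the differential variant (MDD) compares
MD-Scores between differentially transcribed and unchanged ROI sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .ranking import DifferentialRecord

__all__ = ["MDScore", "md_score", "MDDResult", "mdd_score"]


@dataclass(frozen=True)
class MDScore:
    motif: str
    h_small: float
    h_large: float
    n_small: int
    n_large: int

    @property
    def score(self) -> float | None:
        """n_small / n_large, or None when no hit lies within h_large."""
        if self.n_large == 0:
            return None
        return self.n_small / self.n_large


def md_score(
    distances: Sequence[float],
    motif: str = "",
    h_small: float = 150.0,
    h_large: float = 1500.0,
) -> MDScore:
    """MD-Score from per-ROI best-hit distances (NaN = no hit).

    Both radii are inclusive; ``h_small <= h_large`` is required, and
    setting them equal forces a score of 1.
    """
    if h_small > h_large:
        raise ValueError("h_small must be <= h_large")
    d = np.asarray(distances, dtype=float)
    finite = d[np.isfinite(d)]
    n_large = int((finite <= h_large).sum())
    n_small = int((finite <= h_small).sum())
    return MDScore(motif, h_small, h_large, n_small, n_large)


@dataclass(frozen=True)
class MDDResult:
    md_changed: MDScore
    md_unchanged: MDScore
    p_threshold: float
    lfc_threshold: float
    z: float | None = None
    p: float | None = None

    @property
    def difference(self) -> float | None:
        a, b = self.md_changed.score, self.md_unchanged.score
        if a is None or b is None:
            return None
        return a - b


def mdd_score(
    records: Sequence[DifferentialRecord],
    distances: Sequence[float],
    p_threshold: float = 0.05,
    lfc_threshold: float = 0.0,
    motif: str = "",
    h_small: float = 150.0,
    h_large: float = 1500.0,
    test: bool = False,
) -> MDDResult:
    """Differential MD-Score between changed and unchanged ROI sets.

    An ROI counts as "changed" when its differential p-value is below
    ``p_threshold`` and |LFC| >= ``lfc_threshold`` (thresholds are
    empirical, dataset-dependent choices; they are echoed in the result).
    A two-proportion z-test is available behind ``test=True`` but off by
    default.
    """
    if len(records) != len(distances):
        raise ValueError("records and distances must align")
    changed_d, unchanged_d = [], []
    for rec, d in zip(records, distances):
        is_changed = (
            rec.p_value < p_threshold
            and abs(rec.log_fold_change) >= lfc_threshold
        )
        (changed_d if is_changed else unchanged_d).append(d)
    md_c = md_score(changed_d, motif, h_small, h_large)
    md_u = md_score(unchanged_d, motif, h_small, h_large)
    z = p = None
    if test and md_c.n_large > 0 and md_u.n_large > 0:
        pooled = (md_c.n_small + md_u.n_small) / (md_c.n_large + md_u.n_large)
        se = np.sqrt(
            pooled * (1 - pooled) * (1 / md_c.n_large + 1 / md_u.n_large)
        )
        if se > 0:
            z = (md_c.score - md_u.score) / se
            p = float(2 * stats.norm.sf(abs(z)))
            z = float(z)
    return MDDResult(md_c, md_u, p_threshold, lfc_threshold, z, p)
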