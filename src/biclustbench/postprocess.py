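"""Thresholding of loading matrices into sparse bicluster memberships.

Many factorisation algorithms return dense loadings in which almost every
sample and gene has a non-zero weight in every factor, making the raw
"biclusters" highly redundant.  Thresholding masks the small entries:
sample ``i`` belongs to factor ``k`` iff ``|X[i, k]|`` exceeds a fraction
``theta`` (default 0.01) of the factor's largest absolute sample loading,
and likewise for genes.  Scaling per factor makes the rule invariant to the
arbitrary column rescalings that differ between algorithms; the scaling
rule is pluggable.  Binary membership matrices (all entries 0/1) are passed
through unchanged, since thresholding is meaningless for them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import Bicluster, Biclustering, Factorisation
from .metrics import clustering_error, mbr, nre

__all__ = [
    "ThresholdConfig",
    "SCALING_RULES",
    "threshold_factorisation",
    "drop_empty_and_count",
    "threshold_sweep",
]


def _scale_column_max(M: np.ndarray) -> np.ndarray:
    """Per-factor scale: the largest absolute loading in each column."""
    return np.abs(M).max(axis=0, initial=0.0)


def _scale_matrix_max(M: np.ndarray) -> np.ndarray:
    scale = np.abs(M).max(initial=0.0)
    return np.full(M.shape[1], scale)


def _scale_unit_norm(M: np.ndarray) -> np.ndarray:
    return np.linalg.norm(M, axis=0)


SCALING_RULES = {
    "column-max": _scale_column_max,
    "matrix-max": _scale_matrix_max,
    "column-norm": _scale_unit_norm,
}


@dataclass(frozen=True)
class ThresholdConfig:
    """Threshold fraction theta (>= 0; 0 keeps every non-zero entry) and the
    per-factor scaling rule applied before comparison."""

    theta: float = 0.01
    scaling: str = "column-max"

    def __post_init__(self):
        if self.theta < 0:
            raise ValueError("threshold theta must be >= 0")
        if self.scaling not in SCALING_RULES:
            raise ValueError(
                f"unknown scaling rule {self.scaling!r}; "
                f"valid: {', '.join(SCALING_RULES)}"
            )


def _member_mask(M: np.ndarray, cfg: ThresholdConfig) -> np.ndarray:
    scale = SCALING_RULES[cfg.scaling](M)
    return np.abs(M) > cfg.theta * scale


def _is_binary(M: np.ndarray) -> bool:
    return bool(np.isin(M, (0.0, 1.0)).all())


def threshold_factorisation(
    f: Factorisation, cfg: ThresholdConfig = ThresholdConfig()
) -> Biclustering:
    """Convert loading matrices into one bicluster per factor.

    Membership requires the absolute loading to exceed ``theta`` times the
    factor's scale on the respective side; all-zero columns give empty
    biclusters.  If both loading matrices are binary (algorithms that
    return membership indicators rather than raw loadings) the non-zero
    pattern is returned unchanged.
    """
    if _is_binary(f.X) and _is_binary(f.B):
        xmask = f.X > 0
        bmask = f.B > 0
    else:
        xmask = _member_mask(f.X, cfg)
        bmask = _member_mask(f.B, cfg)
    biclusters = [
        Bicluster(np.flatnonzero(xmask[:, k]), np.flatnonzero(bmask[:, k]))
        for k in range(f.K)
    ]
    return Biclustering(biclusters, n=f.n, p=f.p)


def drop_empty_and_count(bc: Biclustering) -> tuple[Biclustering, int]:
    """Remove zero-cell biclusters; the count remaining is the recovered K."""
    kept = bc.drop_empty()
    return kept, kept.K


def threshold_sweep(
    f: Factorisation,
    thresholds: Sequence[float],
    Y: Optional[np.ndarray] = None,
    truth: Optional[Biclustering] = None,
    scaling: str = "column-max",
) -> pd.DataFrame:
    """Evaluate thresholding across a grid of theta values.

    For each theta: the memberships' mean bicluster redundancy, the
    recovered K, the reconstruction error of the masked loadings (entries
    below threshold zeroed) when ``Y`` is given, and the clustering error
    against ``truth`` when given.  Used to choose an operating threshold
    from measures available even without ground truth.
    """
    thresholds = list(thresholds)
    if not thresholds:
        raise ValueError("thresholds must be non-empty")
    if any(b < a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be ascending")
    rows = []
    for theta in thresholds:
        cfg = ThresholdConfig(theta=theta, scaling=scaling)
        bc = threshold_factorisation(f, cfg)
        _, k_rec = drop_empty_and_count(bc)
        row = {"theta": theta, "mbr": mbr(bc), "k_recovered": k_rec}
        if Y is not None:
            xmask = _member_mask(f.X, cfg)
            bmask = _member_mask(f.B, cfg)
            row["nre"] = nre(Y, np.where(xmask, f.X, 0.0),
                             np.where(bmask, f.B, 0.0))
        if truth is not None:
            row["ce"] = clustering_error(truth, bc).ce
        rows.append(row)
    return pd.DataFrame(rows)
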