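"""Similarity and accuracy metrics for biclusterings.

Clustering error (CE) scores the agreement of two biclusterings as
``d_max / |U|``: ``d_max`` is the largest total cell-intersection
achievable by a one-to-one pairing of biclusters (an optimal assignment
problem, solved by the Hungarian method), and ``|U|`` is the overlap-aware
union size — the per-cell maximum of the two coverage multiplicities,
summed over the grid — so duplicated biclusters inflate ``|U|`` without
inflating ``d_max`` and are penalised.  CE = 1 means identical
biclusterings; 0 means no agreement.

The normalised reconstruction error (NRE) and mean bicluster redundancy
(MBR) need no ground truth: NRE compares a factorisation's reconstruction
to the data matrix through Frobenius norms, and MBR averages pairwise
Jaccard indices between the biclusters of one run.  Recovery/relevance
scores, trait F1 matching, run-to-run CE similarity and Pearson robustness
correlations complete the suite.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.stats import pearsonr

from .core import Bicluster, Biclustering, TraitAnnotation

__all__ = [
    "CEDecomposition",
    "jaccard",
    "mbr",
    "nre",
    "clustering_error",
    "ce_brute_force",
    "f1_trait",
    "trait_clustering_ability",
    "recovery_relevance",
    "run_similarity",
    "robustness_correlation",
]


# ---------------------------------------------------------------------------
# Jaccard index and mean bicluster redundancy
# ---------------------------------------------------------------------------

def _pair_intersection(b1: Bicluster, b2: Bicluster) -> int:
    # Both cell sets are Cartesian products, so the intersection is the
    # product of the axis-wise intersections.
    s = len(b1.sample_set() & b2.sample_set())
    if s == 0:
        return 0
    g = len(b1.gene_set() & b2.gene_set())
    return s * g


def jaccard(b1: Bicluster, b2: Bicluster) -> float:
    """Jaccard index between the cell sets of two biclusters; 0 when both
    are empty."""
    inter = _pair_intersection(b1, b2)
    union = b1.n_cells + b2.n_cells - inter
    if union == 0:
        return 0.0
    return inter / union


def mbr(bc: Biclustering) -> float:
    """Mean bicluster redundancy: mean pairwise Jaccard index within a run.

    0 means no two biclusters overlap; 1 means all biclusters are
    identical.  Undefined (NaN) for fewer than two biclusters.
    """
    K = bc.K
    if K < 2:
        return math.nan
    total = 0.0
    for k in range(K - 1):
        for l in range(k + 1, K):
            total += jaccard(bc[k], bc[l])
    return 2.0 * total / (K * (K - 1))


# ---------------------------------------------------------------------------
# Normalised reconstruction error
# ---------------------------------------------------------------------------

def nre(Y: np.ndarray, X: np.ndarray, B: np.ndarray) -> float:
    """Normalised reconstruction error ||Y - XBᵀ||_F / (||Y||_F + ||XBᵀ||_F).

    0 is perfect reconstruction; the maximum of 1 is attained e.g. when the
    reconstruction is the negated matrix.  Undefined when Y and the
    reconstruction are both all-zero.
    """
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    B = np.asarray(B, dtype=float)
    if X.shape[1] != B.shape[1]:
        raise ValueError("X and B must have the same number of factors")
    if Y.shape != (X.shape[0], B.shape[0]):
        raise ValueError(
            f"Y has shape {Y.shape} but the reconstruction has shape "
            f"({X.shape[0]}, {B.shape[0]})"
        )
    Yhat = X @ B.T
    ny, nyhat = np.linalg.norm(Y), np.linalg.norm(Yhat)
    if ny == 0.0 and nyhat == 0.0:
        raise ValueError("NRE undefined: Y and the reconstruction are both zero")
    return float(np.linalg.norm(Y - Yhat) / (ny + nyhat))


# ---------------------------------------------------------------------------
# Clustering error
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CEDecomposition:
    """Components of the clustering-error score.

    ``intersections[k, l]`` is the cell overlap between bicluster ``k`` of
    the first biclustering and ``l`` of the second; ``d_max`` the optimal
    injective matching value; ``u_size`` the overlap-aware union size.
    """

    intersections: np.ndarray
    d_max: int
    u_size: int

    @property
    def ce(self) -> float:
        if self.u_size == 0:
            # Both biclusterings cover no cells: identical, perfect score.
            return 1.0
        return self.d_max / self.u_size


def _union_size(a: Biclustering, r: Biclustering) -> int:
    return int(np.maximum(a.coverage_counts(), r.coverage_counts()).sum())


def _intersection_matrix(a: Biclustering, r: Biclustering) -> np.ndarray:
    out = np.zeros((a.K, r.K), dtype=np.int64)
    for k, bk in enumerate(a):
        for l, bl in enumerate(r):
            out[k, l] = _pair_intersection(bk, bl)
    return out


def clustering_error(A: Biclustering, R: Biclustering) -> CEDecomposition:
    """Clustering error between two biclusterings on a common grid.

    The optimal one-to-one pairing of biclusters maximising the summed
    cell intersections is found by the Hungarian algorithm on the
    (rectangular) intersection matrix.
    """
    if not A.same_grid(R):
        raise ValueError(
            f"grid mismatch: {A.n} x {A.p} versus {R.n} x {R.p}"
        )
    inter = _intersection_matrix(A, R)
    if inter.size:
        rows, cols = linear_sum_assignment(inter, maximize=True)
        d_max = int(inter[rows, cols].sum())
    else:
        d_max = 0
    return CEDecomposition(inter, d_max, _union_size(A, R))


def ce_brute_force(A: Biclustering, R: Biclustering) -> float:
    """Clustering error by exhaustive enumeration of injective matchings.

    A test oracle, independent of the assignment solver; guarded to small
    instances (at most 6 biclusters per side).
    """
    if not A.same_grid(R):
        raise ValueError("grid mismatch")
    if A.K > 6 or R.K > 6:
        raise ValueError("brute-force oracle limited to <= 6 biclusters per side")
    u_size = _union_size(A, R)
    if u_size == 0:
        return 1.0
    small, large = (A, R) if A.K <= R.K else (R, A)
    d_max = 0
    for perm in itertools.permutations(range(large.K), small.K):
        d = sum(
            _pair_intersection(small[k], large[perm[k]])
            for k in range(small.K)
        )
        d_max = max(d_max, d)
    return d_max / u_size


# ---------------------------------------------------------------------------
# Trait matching
# ---------------------------------------------------------------------------

def f1_trait(trait_samples, bicluster_samples) -> float:
    """F1 score between a trait's sample set S and a bicluster's sample set F.

    Precision = |S ∩ F| / |F|, recall = |S ∩ F| / |S|; returns 0 when the
    bicluster's sample set is empty or disjoint from the trait.
    """
    S = frozenset(trait_samples)
    F = frozenset(bicluster_samples)
    if not S:
        raise ValueError("trait sample set must be non-empty")
    overlap = len(S & F)
    if overlap == 0:
        return 0.0
    precision = overlap / len(F)
    recall = overlap / len(S)
    return 2.0 * precision * recall / (precision + recall)


def trait_clustering_ability(
    bc: Biclustering, traits: list[TraitAnnotation]
) -> tuple[float, pd.DataFrame]:
    """Mean over traits of the best F1 score achieved by any bicluster.

    Applied to tissue traits only this is the tissue clustering ability;
    to genotype traits only, the genotype clustering ability.  Returns the
    mean and a per-trait table (trait, best F1, best bicluster index).
    """
    if not traits:
        raise ValueError("at least one trait is required")
    rows = []
    for trait in traits:
        best, best_k = 0.0, -1
        for k, b in enumerate(bc):
            score = f1_trait(trait.samples, b.samples) if b.samples else 0.0
            if score > best:
                best, best_k = score, k
        rows.append({"trait": trait.name, "best_f1": best,
                     "best_bicluster": best_k})
    table = pd.DataFrame(rows, columns=["trait", "best_f1", "best_bicluster"])
    return float(table["best_f1"].mean()), table


# ---------------------------------------------------------------------------
# Recovery and relevance
# ---------------------------------------------------------------------------

def recovery_relevance(
    truth: Biclustering, recovered: Biclustering
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-bicluster best-Jaccard scores in both directions.

    Recovery: for each true bicluster, the best Jaccard index over
    recovered biclusters (how well it was found).  Relevance: for each
    recovered bicluster, the best Jaccard over true biclusters (how closely
    it matches anything real).
    """
    if not truth.same_grid(recovered):
        raise ValueError("grid mismatch")
    J = np.zeros((truth.K, recovered.K))
    for k, bk in enumerate(truth):
        for l, bl in enumerate(recovered):
            J[k, l] = jaccard(bk, bl)
    recovery = pd.DataFrame({
        "bicluster": np.arange(truth.K),
        "recovery": J.max(axis=1) if recovered.K else np.zeros(truth.K),
    })
    relevance = pd.DataFrame({
        "bicluster": np.arange(recovered.K),
        "relevance": J.max(axis=0) if truth.K else np.zeros(recovered.K),
    })
    return recovery, relevance


# ---------------------------------------------------------------------------
# Run-to-run similarity and robustness correlations
# ---------------------------------------------------------------------------

def run_similarity(runs: list[Biclustering]) -> tuple[pd.DataFrame, float, float]:
    """CE between every unordered pair of runs; returns (table, mean, median).

    High values indicate that re-runs recover similar biclusters, a sign of
    a robust decomposition.
    """
    if len(runs) < 2:
        raise ValueError("at least two runs are required")
    rows = []
    for i, j in itertools.combinations(range(len(runs)), 2):
        rows.append({"run_a": i, "run_b": j,
                     "ce": clustering_error(runs[i], runs[j]).ce})
    table = pd.DataFrame(rows)
    return table, float(table["ce"].mean()), float(table["ce"].median())


def robustness_correlation(x, y) -> float:
    """Pearson correlation between two numeric sequences (e.g. the initial
    K and the CE achieved).  Constant input is signalled as not computable.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be 1-d sequences of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation not computable for constant input")
    return float(pearsonr(x, y).statistic)
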