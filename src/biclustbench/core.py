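"""Shared domain types for biclustering benchmarks.

A *bicluster* is a subset of samples together with a subset of genes; its
cells are the Cartesian product of the two index sets.  A *biclustering* is
an ordered collection of biclusters over a common ``n x p`` expression grid
— overlaps and exact duplicates are permitted, since evaluation metrics must
be able to penalise redundant output.  A *factorisation* holds the sample
and gene loading matrices ``X`` (n x K) and ``B`` (p x K) whose product
``X @ B.T`` approximates the expression matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Bicluster",
    "Biclustering",
    "Factorisation",
    "TraitAnnotation",
    "PathwayDatabase",
    "ValidationReport",
    "cells_of",
    "validate_biclustering",
]


def _as_index_tuple(indices: Iterable[int]) -> tuple[int, ...]:
    """Deduplicate and sort indices into a canonical ordered tuple."""
    return tuple(sorted({int(i) for i in indices}))


@dataclass(frozen=True)
class Bicluster:
    """A set of sample indices and a set of gene indices (both 0-based).

    Index sets are stored as sorted tuples so equality and hashing behave
    like set equality.  A bicluster with either set empty covers zero cells
    and is treated as empty throughout.
    """

    samples: tuple[int, ...]
    genes: tuple[int, ...]

    def __init__(self, samples: Iterable[int], genes: Iterable[int]):
        object.__setattr__(self, "samples", _as_index_tuple(samples))
        object.__setattr__(self, "genes", _as_index_tuple(genes))

    @property
    def n_cells(self) -> int:
        return len(self.samples) * len(self.genes)

    @property
    def is_empty(self) -> bool:
        return self.n_cells == 0

    def sample_set(self) -> frozenset[int]:
        return frozenset(self.samples)

    def gene_set(self) -> frozenset[int]:
        return frozenset(self.genes)


@dataclass(frozen=True)
class Biclustering:
    """An ordered collection of biclusters over a common ``n x p`` grid."""

    biclusters: tuple[Bicluster, ...]
    n: int
    p: int

    def __init__(self, biclusters: Sequence[Bicluster], n: int, p: int):
        object.__setattr__(self, "biclusters", tuple(biclusters))
        object.__setattr__(self, "n", int(n))
        object.__setattr__(self, "p", int(p))
        if self.n < 0 or self.p < 0:
            raise ValueError("grid dimensions must be non-negative")
        validate_biclustering(self, raise_on_bounds=True)

    @property
    def K(self) -> int:
        return len(self.biclusters)

    def __len__(self) -> int:
        return len(self.biclusters)

    def __iter__(self):
        return iter(self.biclusters)

    def __getitem__(self, k: int) -> Bicluster:
        return self.biclusters[k]

    def same_grid(self, other: "Biclustering") -> bool:
        return self.n == other.n and self.p == other.p

    def coverage_counts(self) -> np.ndarray:
        """Per-cell multiplicity: how many member biclusters cover each cell."""
        counts = np.zeros((self.n, self.p), dtype=np.int64)
        for b in self.biclusters:
            if not b.is_empty:
                counts[np.ix_(b.samples, b.genes)] += 1
        return counts

    def drop_empty(self) -> "Biclustering":
        return Biclustering(
            [b for b in self.biclusters if not b.is_empty], self.n, self.p
        )


@dataclass(frozen=True)
class Factorisation:
    """Loading matrices of the factorisation Y ≈ X Bᵀ.

    ``X`` has shape (n, K) (sample loadings) and ``B`` has shape (p, K)
    (gene loadings); the reconstruction ``X @ B.T`` has shape (n, p).
    """

    X: np.ndarray
    B: np.ndarray

    def __post_init__(self):
        X = np.asarray(self.X, dtype=float)
        B = np.asarray(self.B, dtype=float)
        if X.ndim != 2 or B.ndim != 2:
            raise ValueError("loading matrices must be 2-dimensional")
        if X.shape[1] != B.shape[1]:
            raise ValueError(
                f"X has {X.shape[1]} factors but B has {B.shape[1]}"
            )
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "B", B)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.B.shape[0]

    @property
    def K(self) -> int:
        return self.X.shape[1]

    def reconstruction(self) -> np.ndarray:
        return self.X @ self.B.T


@dataclass(frozen=True)
class TraitAnnotation:
    """A named sample trait: the set S of samples carrying the trait."""

    name: str
    samples: tuple[int, ...]

    def __init__(self, name: str, samples: Iterable[int]):
        object.__setattr__(self, "name", str(name))
        object.__setattr__(self, "samples", _as_index_tuple(samples))

    def sample_set(self) -> frozenset[int]:
        return frozenset(self.samples)


@dataclass(frozen=True)
class PathwayDatabase:
    """Map from pathway identifier to member gene indices, with a universe size.

    The gene universe is the full set of genes in the analysed matrix;
    pathways may overlap but must be non-empty, and every member gene must
    lie inside the universe.
    """

    pathways: Mapping[str, frozenset[int]]
    universe_size: int

    def __init__(self, pathways: Mapping[str, Iterable[int]], universe_size: int):
        universe_size = int(universe_size)
        cleaned: dict[str, frozenset[int]] = {}
        for pid, genes in pathways.items():
            gset = frozenset(int(g) for g in genes)
            if not gset:
                raise ValueError(f"pathway {pid!r} is empty")
            bad = [g for g in gset if g < 0 or g >= universe_size]
            if bad:
                raise ValueError(
                    f"pathway {pid!r} has gene indices outside the universe "
                    f"of size {universe_size}: {sorted(bad)[:5]}"
                )
            cleaned[pid] = gset
        object.__setattr__(self, "pathways", cleaned)
        object.__setattr__(self, "universe_size", universe_size)

    def __len__(self) -> int:
        return len(self.pathways)

    def items(self):
        return self.pathways.items()


@dataclass
class ValidationReport:
    """Findings from validating a biclustering: nothing here is fatal except
    out-of-bounds indices, which `validate_biclustering` raises on."""

    out_of_bounds: list[tuple[int, str]] = field(default_factory=list)
    duplicate_pairs: list[tuple[int, int]] = field(default_factory=list)
    empty_biclusters: list[int] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.out_of_bounds


def cells_of(bicluster: Bicluster) -> set[tuple[int, int]]:
    """Materialise a bicluster as its set of (sample, gene) cells.

    Returns the Cartesian product of the two index sets; empty if either
    set is empty.
    """
    return {(i, j) for i in bicluster.samples for j in bicluster.genes}


def validate_biclustering(
    bc: Biclustering, raise_on_bounds: bool = True
) -> ValidationReport:
    """Check a biclustering for out-of-bounds indices, duplicates, empties.

    Out-of-bounds indices are rejected (raised) because no metric is defined
    for them; duplicates and empty biclusters are legitimate algorithm
    output and are merely reported.
    """
    report = ValidationReport()
    for k, b in enumerate(bc.biclusters):
        if b.samples and (b.samples[0] < 0 or b.samples[-1] >= bc.n):
            report.out_of_bounds.append((k, "samples"))
        if b.genes and (b.genes[0] < 0 or b.genes[-1] >= bc.p):
            report.out_of_bounds.append((k, "genes"))
        if b.is_empty:
            report.empty_biclusters.append(k)
    seen: dict[Bicluster, int] = {}
    for k, b in enumerate(bc.biclusters):
        if b in seen:
            report.duplicate_pairs.append((seen[b], k))
        else:
            seen[b] = k
    if raise_on_bounds and report.out_of_bounds:
        k, which = report.out_of_bounds[0]
        raise ValueError(
            f"bicluster {k} has {which} indices outside the "
            f"{bc.n} x {bc.p} grid"
        )
    return report
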