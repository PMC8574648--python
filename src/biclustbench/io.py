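"""File formats, normalisation helpers and run manifests.

Everything on disk is plain tab- or space-separated text so artifacts stay
inspectable and portable: expression and loading matrices as labelled TSV,
bicluster memberships in a three-line-per-bicluster record format with an
``n=<n> p=<p>`` header, pathway databases / trait tables / knockout maps as
two-column TSV, and dataset configurations as flat YAML.  Indices are
0-based both in memory and on disk.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm, rankdata

from .core import Bicluster, Biclustering, PathwayDatabase, TraitAnnotation
from .simulate import DatasetConfig, NoiseSpec

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_memberships",
    "write_memberships",
    "read_pathway_db",
    "write_pathway_db",
    "read_traits",
    "write_traits",
    "read_knockout_map",
    "write_knockout_map",
    "read_config",
    "write_config",
    "log_transform",
    "quantile_normalise",
    "RunManifest",
]


# ---------------------------------------------------------------------------
# Matrices
# ---------------------------------------------------------------------------

def read_matrix(path) -> pd.DataFrame:
    """Read a labelled numeric matrix from tab-separated text.

    First row holds column labels, first column row labels.  Non-numeric or
    missing cells are rejected with their coordinates; empty matrices and
    duplicate labels are rejected.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(header) != len(set(header)):
        raise ValueError(f"{path}: duplicate row or column labels")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"{path}: matrix is empty")
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise ValueError(f"{path}: duplicate row or column labels")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric value at row {df.index[i]!r}, "
            f"column {df.columns[j]!r}"
        )
    return numeric


def write_matrix(M, path, row_labels=None, col_labels=None) -> None:
    """Write a matrix as labelled tab-separated text (default labels
    sample0.., gene0..)."""
    M = np.asarray(M)
    if row_labels is None:
        row_labels = [f"sample{i}" for i in range(M.shape[0])]
    if col_labels is None:
        col_labels = [f"gene{j}" for j in range(M.shape[1])]
    pd.DataFrame(M, index=row_labels, columns=col_labels).to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Membership files
# ---------------------------------------------------------------------------

def write_memberships(bc: Biclustering, path) -> None:
    """Write a biclustering in the membership format.

    Header line ``n=<n> p=<p>``; then, per bicluster, a ``bicluster <k>``
    line followed by one line of space-separated sample indices and one of
    gene indices (blank lines for empty index sets).  Round-trips exactly,
    including empty biclusters and an empty biclustering.
    """
    lines = [f"n={bc.n} p={bc.p}"]
    for k, b in enumerate(bc):
        lines.append(f"bicluster {k}")
        lines.append(" ".join(map(str, b.samples)))
        lines.append(" ".join(map(str, b.genes)))
    Path(path).write_text("\n".join(lines) + "\n")


def read_memberships(path) -> Biclustering:
    """Read a membership file back into a Biclustering (with bounds checks)."""
    text = Path(path).read_text().splitlines()
    if not text or not text[0].startswith("n="):
        raise ValueError(f"{path}: missing 'n=<n> p=<p>' header")
    try:
        nfield, pfield = text[0].split()
        n = int(nfield.removeprefix("n="))
        p = int(pfield.removeprefix("p="))
    except Exception as exc:
        raise ValueError(f"{path}: malformed header {text[0]!r}") from exc
    body = text[1:]
    if len(body) % 3 != 0:
        raise ValueError(f"{path}: truncated bicluster record")
    biclusters = []
    for at in range(0, len(body), 3):
        label, samples_line, genes_line = body[at:at + 3]
        if not label.startswith("bicluster"):
            raise ValueError(f"{path}: expected 'bicluster <k>', got {label!r}")
        samples = [int(x) for x in samples_line.split()]
        genes = [int(x) for x in genes_line.split()]
        biclusters.append(Bicluster(samples, genes))
    return Biclustering(biclusters, n=n, p=p)  # raises on out-of-bounds


# ---------------------------------------------------------------------------
# Pathways, traits, knockout maps
# ---------------------------------------------------------------------------

def _read_two_column(path, what: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] != 2:
        raise ValueError(f"{path}: expected two tab-separated {what} columns")
    return df


def write_pathway_db(db: PathwayDatabase, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# universe={db.universe_size}\n")
        for pid in sorted(db.pathways):
            for g in sorted(db.pathways[pid]):
                fh.write(f"{pid}\t{g}\n")


def read_pathway_db(path, universe_size: Optional[int] = None) -> PathwayDatabase:
    """Read a two-column (pathway_id, gene_index) file.  The universe size
    comes from a ``# universe=<p>`` comment line unless given explicitly."""
    if universe_size is None:
        for line in Path(path).read_text().splitlines():
            if line.startswith("# universe="):
                universe_size = int(line.removeprefix("# universe="))
                break
        else:
            raise ValueError(
                f"{path}: universe size not given and no '# universe=' header")
    df = _read_two_column(path, "(pathway_id, gene_index)")
    pathways: dict[str, set[int]] = {}
    for pid, gene in df.itertuples(index=False):
        pathways.setdefault(pid, set()).add(int(gene))
    return PathwayDatabase(pathways, universe_size=universe_size)


def write_traits(traits, path) -> None:
    with open(path, "w") as fh:
        for trait in traits:
            for s in trait.samples:
                fh.write(f"{trait.name}\t{s}\n")


def read_traits(path) -> list[TraitAnnotation]:
    """Read a two-column (trait_id, sample_index) file."""
    df = _read_two_column(path, "(trait_id, sample_index)")
    grouped: dict[str, set[int]] = {}
    for name, sample in df.itertuples(index=False):
        grouped.setdefault(name, set()).add(int(sample))
    return [TraitAnnotation(name, samples) for name, samples in grouped.items()]


def write_knockout_map(mapping: dict, path) -> None:
    with open(path, "w") as fh:
        for ko in sorted(mapping):
            for pid in sorted(mapping[ko]):
                fh.write(f"{ko}\t{pid}\n")


def read_knockout_map(path) -> dict[str, frozenset[str]]:
    """Read a two-column (knockout_id, pathway_id) file."""
    df = _read_two_column(path, "(knockout_id, pathway_id)")
    grouped: dict[str, set[str]] = {}
    for ko, pid in df.itertuples(index=False):
        grouped.setdefault(ko, set()).add(pid)
    return {ko: frozenset(pids) for ko, pids in grouped.items()}


# ---------------------------------------------------------------------------
# Dataset configuration files
# ---------------------------------------------------------------------------

def write_config(config: DatasetConfig, path) -> None:
    """Write a DatasetConfig as flat YAML key-value pairs."""
    flat = {
        "name": config.name, "m": config.m, "t": config.t, "p": config.p,
        "K": config.K, "size_regime": config.size_regime,
        "noise_family": config.noise.family,
        "noise_p_negbin": config.noise.p_negbin,
        "noise_sigma": config.noise.sigma,
        "variant": config.variant, "seed": config.seed,
    }
    Path(path).write_text(yaml.safe_dump(flat, sort_keys=False))


def read_config(path) -> DatasetConfig:
    flat = yaml.safe_load(Path(path).read_text())
    return DatasetConfig(
        m=flat["m"], t=flat["t"], p=flat["p"], K=flat["K"],
        size_regime=flat["size_regime"],
        noise=NoiseSpec(flat["noise_family"], flat["noise_p_negbin"],
                        flat["noise_sigma"]),
        seed=flat["seed"], variant=flat.get("variant"),
        name=flat.get("name", ""),
    )


# ---------------------------------------------------------------------------
# Normalisation helpers
# ---------------------------------------------------------------------------

def log_transform(Y: np.ndarray) -> np.ndarray:
    """The log transform x -> log(x + 1) commonly applied to counts."""
    return np.log1p(np.asarray(Y, dtype=float))


def quantile_normalise(Y: np.ndarray) -> np.ndarray:
    """Per-gene Gaussian quantile normalisation.

    Each gene's values are replaced by standard-normal quantiles of their
    ranks (average ranks for ties, Blom-style offset rank/(n+1)) so every
    gene has an approximate N(0, 1) distribution.
    """
    Y = np.asarray(Y, dtype=float)
    ranks = np.apply_along_axis(rankdata, 0, Y)  # average ties
    return norm.ppf(ranks / (Y.shape[0] + 1))


# ---------------------------------------------------------------------------
# Run manifests
# ---------------------------------------------------------------------------

@dataclass
class RunManifest:
    """Record of one CLI invocation, written beside its outputs so any run
    can be reproduced from the manifest alone."""

    command: str
    parameters: dict = field(default_factory=dict)
    seed: Optional[int] = None
    inputs: list = field(default_factory=list)
    outputs: list = field(default_factory=list)
    version: str = ""
    timestamp: str = ""

    def write(self, path) -> None:
        record = asdict(self)
        if not record["timestamp"]:
            record["timestamp"] = datetime.datetime.now(
                datetime.timezone.utc).isoformat()
        Path(path).write_text(json.dumps(record, indent=2, default=str) + "\n")
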