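"""Synthetic gene-expression datasets with implanted, overlapping biclusters.

The base generative model builds an ``m x t x p`` tensor (individuals x
tissues x genes).  Each of ``K`` biclusters occupies a contiguous block of
individuals, a contiguous run of tissues and a contiguous block of genes;
its cell values are negative-binomial counts with a bicluster-specific mean
``mu_k ~ Gamma(2, rate 1/600)`` and shared success parameter ``p`` (so that
``NegBin(n_k, p)`` with ``n_k = mu_k * p / (1 - p)`` has mean ``mu_k`` and
variance ``mu_k / p``).  Bicluster contributions are summed, background
``NegBin(1, p)`` noise is added, and the tensor is flattened to an
``n x p`` matrix with samples listed tissue by tissue (sample index
``tissue * m + individual``).

Variants: Gaussian cell values ``N(mu_k, sigma^2)`` with Gaussian background
(clipped at zero), noiseless (cell value = ``mu_k``, no background), and the
shift-scale family where cell values follow ``alpha_j * pi_il + beta_j``
with exponential parameter draws and no background noise.

A knockout-design fixture emulates a multi-tissue knockout RNA-seq study:
each knockout genotype perturbs the genes of its assigned pathway across all
of its samples, and each tissue contributes a dense main-effect bicluster,
so that trait-matching and enrichment metrics can be exercised end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .core import Bicluster, Biclustering, PathwayDatabase, TraitAnnotation

__all__ = [
    "NoiseSpec",
    "DatasetConfig",
    "BiclusterSpec",
    "ShiftScaleParams",
    "SimulatedDataset",
    "KnockoutFixture",
    "PRESETS",
    "SHIFT_SCALE_VARIANTS",
    "make_preset_config",
    "preset_names",
    "sample_bicluster_shape",
    "sample_bicluster_mean",
    "negbin_dispersion",
    "sample_negbin",
    "simulate_dataset",
    "simulate_shift_scale_dataset",
    "flatten_tensor",
    "sample_maps",
    "simulate_knockout_fixture",
    "ideal_knockout_biclustering",
]

# Gamma prior on bicluster means: shape 2, rate 1/600 -> mean 1200, sd ~849.
MEAN_GAMMA_SHAPE = 2.0
MEAN_GAMMA_RATE = 1.0 / 600.0

# Candidate bicluster sizes, as fractions of the axis length.  Lists keep
# duplicates after rounding so the uniform draw weights values as listed.
SIZE_FRACTIONS = {
    "mixed": (1 / 100, 1 / 10, 1 / 5, 1 / 2, 1.0),
    "sparse": (1 / 20, 2 / 20, 3 / 20),
    "dense": (3 / 10, 5 / 10, 9 / 10),
}

SIZE_REGIMES = ("mixed", "sparse", "dense", "sparse-square", "dense-square")
SHIFT_SCALE_VARIANTS = ("shift-scale", "shift", "scale", "constant-samples")


@dataclass(frozen=True)
class NoiseSpec:
    """Noise model: negative-binomial (success parameter ``p_negbin``),
    Gaussian (standard deviation ``sigma``), or none."""

    family: str = "negbin"
    p_negbin: float = 0.3
    sigma: float = 0.0

    def __post_init__(self):
        if self.family not in ("negbin", "gaussian", "none"):
            raise ValueError(f"unknown noise family {self.family!r}")
        if self.family == "negbin" and not (0.0 < self.p_negbin < 1.0):
            raise ValueError("negative-binomial success parameter must be in (0, 1)")
        if self.family == "gaussian" and self.sigma <= 0:
            raise ValueError("gaussian noise requires sigma > 0")


@dataclass(frozen=True)
class DatasetConfig:
    """Dimensions and generation settings for one simulated dataset.

    ``m`` individuals, ``t`` tissues and ``p`` genes give an ``n = m * t``
    sample by ``p`` gene matrix with ``K`` implanted biclusters.
    """

    m: int
    t: int
    p: int
    K: int
    size_regime: str = "mixed"
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    seed: int = 0
    variant: Optional[str] = None  # shift-scale family member, if any
    name: str = ""

    def __post_init__(self):
        for label, v in (("m", self.m), ("t", self.t), ("p", self.p)):
            if v < 1:
                raise ValueError(f"{label} must be >= 1")
        if self.K < 0:
            raise ValueError("K must be >= 0")
        if self.size_regime not in SIZE_REGIMES:
            raise ValueError(
                f"unknown size regime {self.size_regime!r}; "
                f"valid: {', '.join(SIZE_REGIMES)}"
            )
        if self.variant is not None and self.variant not in SHIFT_SCALE_VARIANTS:
            raise ValueError(
                f"unknown shift-scale variant {self.variant!r}; "
                f"valid: {', '.join(SHIFT_SCALE_VARIANTS)}"
            )

    @property
    def n(self) -> int:
        return self.m * self.t


@dataclass(frozen=True)
class ShiftScaleParams:
    """Per-bicluster shift-scale parameters: base values ``pi`` per member
    (individual, tissue) pair and per-member-gene scale ``alpha`` / shift
    ``beta``."""

    pi: np.ndarray       # (m_k, t_k)
    alpha: np.ndarray    # (g_k,)
    beta: np.ndarray     # (g_k,)
    variant: str


@dataclass(frozen=True)
class BiclusterSpec:
    """Size, placement and value parameters of one implanted bicluster."""

    g_k: int
    m_k: int
    t_k: int
    gene_start: int
    individual_start: int
    tissue_start: int
    mu_k: Optional[float] = None
    n_k: Optional[float] = None
    shift_scale: Optional[ShiftScaleParams] = None

    @property
    def genes(self) -> range:
        return range(self.gene_start, self.gene_start + self.g_k)

    @property
    def individuals(self) -> range:
        return range(self.individual_start, self.individual_start + self.m_k)

    @property
    def tissues(self) -> range:
        return range(self.tissue_start, self.tissue_start + self.t_k)


@dataclass(frozen=True)
class SimulatedDataset:
    """A generated expression matrix together with its ground truth."""

    Y: np.ndarray                       # (m*t, p)
    truth: Biclustering
    specs: tuple[BiclusterSpec, ...]
    tissue_of_sample: np.ndarray        # (n,)
    individual_of_sample: np.ndarray    # (n,)
    config: DatasetConfig

    @property
    def n(self) -> int:
        return self.Y.shape[0]

    @property
    def p(self) -> int:
        return self.Y.shape[1]


# ---------------------------------------------------------------------------
# Presets (the catalogue of named simulated-dataset configurations)
# ---------------------------------------------------------------------------

def _preset(name, m=10, t=10, p=1000, K=20, regime="mixed",
            noise=NoiseSpec("negbin", 0.3), variant=None):
    return DatasetConfig(m=m, t=t, p=p, K=K, size_regime=regime,
                         noise=noise, variant=variant, name=name)


_NB = NoiseSpec("negbin", 0.3)
_NONE = NoiseSpec("none")

PRESETS: dict[str, DatasetConfig] = {
    c.name: c
    for c in [
        _preset("base"),
        _preset("N50-T2", m=50, t=2),
        _preset("N10-T20", t=20),
        _preset("N100-T10", m=100),
        _preset("N500-T10", m=500),
        _preset("G100", p=100),
        _preset("G5000", p=5000),
        _preset("Large-K20", m=300, t=20, p=10000),
        _preset("Negbin-medium", noise=NoiseSpec("negbin", 0.1)),
        _preset("Negbin-high", noise=NoiseSpec("negbin", 0.01)),
        _preset("Gaussian", noise=NoiseSpec("gaussian", sigma=20.0)),
        _preset("Gaussian-medium", noise=NoiseSpec("gaussian", sigma=100.0)),
        _preset("Gaussian-high", noise=NoiseSpec("gaussian", sigma=300.0)),
        _preset("Noiseless", noise=_NONE),
        _preset("Sparse", regime="sparse"),
        _preset("Dense", regime="dense"),
        _preset("Sparse-square", regime="sparse-square"),
        _preset("Dense-square", regime="dense-square"),
        _preset("K5", K=5),
        _preset("K10", K=10),
        _preset("K50", K=50),
        _preset("K70", K=70),
        _preset("Large-K100", m=300, t=20, p=10000, K=100),
        _preset("Large-K400", m=300, t=20, p=10000, K=400),
    ]
}
# Shift-scale family: base dimensions, no background noise.
for _v in SHIFT_SCALE_VARIANTS:
    PRESETS[_v] = _preset(_v, noise=_NONE, variant=_v)

_PRESETS_LOWER = {k.lower(): k for k in PRESETS}


def preset_names() -> list[str]:
    return list(PRESETS)


def make_preset_config(name: str, seed: int = 0) -> DatasetConfig:
    """Look up a named dataset preset (case-insensitive) and attach a seed."""
    key = _PRESETS_LOWER.get(name.lower())
    if key is None:
        raise ValueError(
            f"unknown preset {name!r}; valid presets: {', '.join(PRESETS)}"
        )
    return replace(PRESETS[key], seed=int(seed))


# ---------------------------------------------------------------------------
# Elementary sampling steps
# ---------------------------------------------------------------------------

def _candidate_sizes(length: int, fractions) -> list[int]:
    """Candidate counts: fraction * length rounded to nearest (half-even),
    floored at 1 so no bicluster is degenerate."""
    return [max(1, int(np.rint(f * length))) for f in fractions]


def sample_bicluster_shape(
    config: DatasetConfig, rng: np.random.Generator
) -> BiclusterSpec:
    """Draw bicluster sizes and contiguous block placements.

    Gene and individual counts come uniformly from the regime's candidate
    set; the tissue count is uniform on {1..t}.  In square regimes a single
    fraction is drawn and applied to both genes and individuals.  Blocks
    (and the tissue run) are contiguous with uniformly drawn starts.
    """
    regime = config.size_regime
    if regime.endswith("-square"):
        fractions = SIZE_FRACTIONS[regime[: -len("-square")]]
        f = fractions[rng.integers(len(fractions))]
        g_k = max(1, int(np.rint(f * config.p)))
        m_k = max(1, int(np.rint(f * config.m)))
    else:
        g_cands = _candidate_sizes(config.p, SIZE_FRACTIONS[regime])
        m_cands = _candidate_sizes(config.m, SIZE_FRACTIONS[regime])
        g_k = g_cands[rng.integers(len(g_cands))]
        m_k = m_cands[rng.integers(len(m_cands))]
    t_k = int(rng.integers(1, config.t + 1))
    gene_start = int(rng.integers(0, config.p - g_k + 1))
    individual_start = int(rng.integers(0, config.m - m_k + 1))
    tissue_start = int(rng.integers(0, config.t - t_k + 1))
    return BiclusterSpec(
        g_k=g_k, m_k=m_k, t_k=t_k,
        gene_start=gene_start,
        individual_start=individual_start,
        tissue_start=tissue_start,
    )


def sample_bicluster_mean(
    alpha: float, beta: float, rng: np.random.Generator, size=None
):
    """Gamma(shape ``alpha``, rate ``beta``) draw of the bicluster mean;
    mean alpha/beta, standard deviation sqrt(alpha)/beta."""
    if alpha <= 0 or beta <= 0:
        raise ValueError("Gamma shape and rate must be positive")
    return rng.gamma(shape=alpha, scale=1.0 / beta, size=size)


def negbin_dispersion(mu: float, p: float) -> float:
    """Dispersion ``n_k = mu * p / (1 - p)`` so that NegBin(n_k, p) has mean
    ``mu`` and variance ``mu / p``."""
    if not (0.0 < p < 1.0):
        raise ValueError("success parameter must be in (0, 1)")
    if mu < 0:
        raise ValueError("mean must be non-negative")
    return mu * p / (1.0 - p)


def sample_negbin(n, p: float, size, rng: np.random.Generator) -> np.ndarray:
    """Negative-binomial draws (failures before the n-th success).

    Real-valued ``n`` is handled through the Gamma–Poisson mixture:
    lambda ~ Gamma(shape n, scale (1-p)/p), draw Poisson(lambda).  Mean
    n(1-p)/p, variance n(1-p)/p^2; n = 0 yields all-zero draws.
    """
    if not (0.0 < p < 1.0):
        raise ValueError("success parameter must be in (0, 1)")
    if np.any(np.asarray(n) < 0):
        raise ValueError("dispersion n must be non-negative")
    lam = rng.gamma(shape=n, scale=(1.0 - p) / p, size=size)
    return rng.poisson(lam)


# ---------------------------------------------------------------------------
# Tensor flattening
# ---------------------------------------------------------------------------

def sample_maps(m: int, t: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample tissue and individual indices under tissue-major ordering
    (sample index = tissue * m + individual)."""
    samples = np.arange(m * t)
    return samples // m, samples % m


def flatten_tensor(tensor: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Flatten an (m, t, p) tensor to an (m*t, p) matrix, listing the
    samples from each tissue in turn with individuals in the same order
    within each tissue.  Returns (matrix, tissue_of_sample,
    individual_of_sample)."""
    m, t, p = tensor.shape
    Y = np.ascontiguousarray(np.transpose(tensor, (1, 0, 2)).reshape(m * t, p))
    tissue_of, individual_of = sample_maps(m, t)
    return Y, tissue_of, individual_of


def _flat_samples(spec: BiclusterSpec, m: int) -> list[int]:
    return [l * m + i for l in spec.tissues for i in spec.individuals]


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------

def _spawn_streams(config: DatasetConfig):
    """One master seed; an independent sub-stream for the background noise
    and one per bicluster (itself split into shape/mean/value streams) so
    that adding biclusters does not perturb earlier draws."""
    children = np.random.SeedSequence(config.seed).spawn(config.K + 1)
    noise_rng = np.random.default_rng(children[0])
    bicluster_streams = []
    for k in range(config.K):
        shape_ss, mean_ss, value_ss = children[k + 1].spawn(3)
        bicluster_streams.append(
            (np.random.default_rng(shape_ss),
             np.random.default_rng(mean_ss),
             np.random.default_rng(value_ss))
        )
    return noise_rng, bicluster_streams


def _assemble(config: DatasetConfig, tensor: np.ndarray,
              specs: list[BiclusterSpec]) -> SimulatedDataset:
    Y, tissue_of, individual_of = flatten_tensor(tensor)
    truth = Biclustering(
        [Bicluster(_flat_samples(s, config.m), s.genes) for s in specs],
        n=config.n, p=config.p,
    )
    return SimulatedDataset(
        Y=Y, truth=truth, specs=tuple(specs),
        tissue_of_sample=tissue_of, individual_of_sample=individual_of,
        config=config,
    )


def simulate_dataset(config: DatasetConfig) -> SimulatedDataset:
    """Generate a dataset under the base count model or its noise variants.

    Each bicluster's cell values are drawn i.i.d. (negative binomial,
    Gaussian, or the constant ``mu_k`` when noiseless), summed across
    biclusters, and background noise is added (NegBin(1, p) counts, or
    N(0, sigma^2) for Gaussian datasets, or none).  Gaussian datasets are
    clipped at zero so count-oriented consumers still function.
    """
    if config.variant is not None:
        return simulate_shift_scale_dataset(config, config.variant)
    noise = config.noise
    noise_rng, streams = _spawn_streams(config)
    tensor = np.zeros((config.m, config.t, config.p), dtype=float)
    specs: list[BiclusterSpec] = []
    for shape_rng, mean_rng, value_rng in streams:
        spec = sample_bicluster_shape(config, shape_rng)
        mu_k = float(sample_bicluster_mean(
            MEAN_GAMMA_SHAPE, MEAN_GAMMA_RATE, mean_rng))
        block = np.ix_(spec.individuals, spec.tissues, spec.genes)
        shape3 = (spec.m_k, spec.t_k, spec.g_k)
        if noise.family == "negbin":
            n_k = negbin_dispersion(mu_k, noise.p_negbin)
            tensor[block] += sample_negbin(n_k, noise.p_negbin, shape3, value_rng)
        elif noise.family == "gaussian":
            n_k = None
            tensor[block] += value_rng.normal(mu_k, noise.sigma, size=shape3)
        else:  # noiseless: constant bicluster value
            n_k = None
            tensor[block] += mu_k
        specs.append(replace(spec, mu_k=mu_k, n_k=n_k))
    if noise.family == "negbin":
        tensor += sample_negbin(
            1.0, noise.p_negbin, tensor.shape, noise_rng)
    elif noise.family == "gaussian":
        tensor += noise_rng.normal(0.0, noise.sigma, size=tensor.shape)
        np.clip(tensor, 0.0, None, out=tensor)
    return _assemble(config, tensor, specs)


def simulate_shift_scale_dataset(
    config: DatasetConfig, variant: str
) -> SimulatedDataset:
    """Generate a dataset whose bicluster cells follow the shift-scale
    pattern ``alpha_j * pi_il + beta_j`` with no background noise.

    Base values ``pi ~ Exponential(1)``; gene scales
    ``alpha ~ Exponential(rate 2) + 1/2`` (mean 1, mode 1/2) and gene shifts
    ``beta ~ Exponential(1)``, drawn independently per bicluster.  The
    "shift" variant fixes alpha = 1, "scale" fixes beta = 0 and
    "constant-samples" fixes both.
    """
    if variant not in SHIFT_SCALE_VARIANTS:
        raise ValueError(
            f"unknown shift-scale variant {variant!r}; "
            f"valid: {', '.join(SHIFT_SCALE_VARIANTS)}"
        )
    _, streams = _spawn_streams(config)
    tensor = np.zeros((config.m, config.t, config.p), dtype=float)
    specs: list[BiclusterSpec] = []
    for shape_rng, _mean_rng, value_rng in streams:
        spec = sample_bicluster_shape(config, shape_rng)
        pi = value_rng.exponential(1.0, size=(spec.m_k, spec.t_k))
        if variant in ("shift", "constant-samples"):
            alpha = np.ones(spec.g_k)
        else:
            alpha = value_rng.exponential(0.5, size=spec.g_k) + 0.5
        if variant in ("scale", "constant-samples"):
            beta = np.zeros(spec.g_k)
        else:
            beta = value_rng.exponential(1.0, size=spec.g_k)
        # E[i, l, j] = alpha_j * pi_il + beta_j
        tensor[np.ix_(spec.individuals, spec.tissues, spec.genes)] += (
            pi[:, :, None] * alpha[None, None, :] + beta[None, None, :]
        )
        specs.append(replace(
            spec, shift_scale=ShiftScaleParams(pi, alpha, beta, variant)))
    return _assemble(config, tensor, specs)


# ---------------------------------------------------------------------------
# Knockout-design fixture
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KnockoutFixture:
    """A synthetic multi-tissue knockout study.

    Samples are laid out tissue-major with ``replicates`` samples per
    (genotype, tissue) pair.  Each knockout genotype carries an additive
    count perturbation on its assigned pathway's genes in every one of its
    samples; each tissue carries a dense main-effect bicluster over all
    genes.  Ground-truth traits and pathway membership make trait-matching
    and enrichment metrics testable with no external data.
    """

    Y: np.ndarray
    truth: Biclustering
    genotype_traits: tuple[TraitAnnotation, ...]
    tissue_traits: tuple[TraitAnnotation, ...]
    pathway_db: PathwayDatabase
    knockout_pathways: dict[str, frozenset[str]]  # genotype trait -> pathways

    @property
    def n(self) -> int:
        return self.Y.shape[0]

    @property
    def p(self) -> int:
        return self.Y.shape[1]


def simulate_knockout_fixture(
    n_genotypes: int,
    n_tissues: int,
    replicates: int,
    n_pathways: int,
    genes_per_pathway: int,
    effect_mean: float = 1200.0,
    tissue_effect_mean: float = 1200.0,
    background_p: float = 0.3,
    seed: int = 0,
) -> KnockoutFixture:
    """Generate the knockout-design fixture.

    The gene universe has ``p = n_pathways * genes_per_pathway`` genes,
    partitioned into consecutive pathways; knockout genotype ``g`` is
    assigned pathway ``g mod n_pathways``.  Additive effects are
    negative-binomial with the given means; the background is NegBin(1,
    ``background_p``) everywhere.
    """
    for label, v in (("n_genotypes", n_genotypes), ("n_tissues", n_tissues),
                     ("replicates", replicates), ("n_pathways", n_pathways),
                     ("genes_per_pathway", genes_per_pathway)):
        if v < 1:
            raise ValueError(f"{label} must be >= 1")
    if effect_mean < 0:
        raise ValueError("effect_mean must be non-negative")
    G, T, R = n_genotypes, n_tissues, replicates
    p = n_pathways * genes_per_pathway
    n = G * T * R
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    # Sample layout: tissue-major, replicates nested inside genotype.
    def samples_of_genotype(g):
        return [l * G * R + g * R + r for l in range(T) for r in range(R)]

    def samples_of_tissue(l):
        return list(range(l * G * R, (l + 1) * G * R))

    pathway_genes = {
        f"pathway{q}": range(q * genes_per_pathway, (q + 1) * genes_per_pathway)
        for q in range(n_pathways)
    }
    db = PathwayDatabase(pathway_genes, universe_size=p)

    Y = sample_negbin(1.0, background_p, (n, p), rng).astype(float)

    biclusters: list[Bicluster] = []
    genotype_traits: list[TraitAnnotation] = []
    knockout_pathways: dict[str, frozenset[str]] = {}
    for g in range(G):
        pid = f"pathway{g % n_pathways}"
        genes = list(pathway_genes[pid])
        samples = samples_of_genotype(g)
        if effect_mean > 0:
            n_eff = negbin_dispersion(effect_mean, background_p)
            Y[np.ix_(samples, genes)] += sample_negbin(
                n_eff, background_p, (len(samples), len(genes)), rng)
        biclusters.append(Bicluster(samples, genes))
        name = f"knockout{g}"
        genotype_traits.append(TraitAnnotation(name, samples))
        knockout_pathways[name] = frozenset({pid})

    tissue_traits: list[TraitAnnotation] = []
    for l in range(T):
        samples = samples_of_tissue(l)
        mu_l = float(sample_bicluster_mean(
            MEAN_GAMMA_SHAPE, MEAN_GAMMA_RATE, rng))
        if tissue_effect_mean > 0:
            n_eff = negbin_dispersion(mu_l, background_p)
            Y[samples, :] += sample_negbin(
                n_eff, background_p, (len(samples), p), rng)
        biclusters.append(Bicluster(samples, range(p)))
        tissue_traits.append(TraitAnnotation(f"tissue{l}", samples))

    truth = Biclustering(biclusters, n=n, p=p)
    return KnockoutFixture(
        Y=Y, truth=truth,
        genotype_traits=tuple(genotype_traits),
        tissue_traits=tuple(tissue_traits),
        pathway_db=db,
        knockout_pathways=knockout_pathways,
    )


def ideal_knockout_biclustering(fixture: KnockoutFixture) -> Biclustering:
    """The biclustering a perfect algorithm would recover on the fixture:
    one bicluster per knockout genotype, covering exactly its samples and
    its pathway's genes."""
    biclusters = []
    for trait in fixture.genotype_traits:
        genes: set[int] = set()
        for pid in fixture.knockout_pathways[trait.name]:
            genes |= fixture.pathway_db.pathways[pid]
        biclusters.append(Bicluster(trait.samples, genes))
    return Biclustering(biclusters, n=fixture.n, p=fixture.p)
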