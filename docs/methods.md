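# Methods

## Generative model for simulated datasets

Expression is generated on an `m × t × p` tensor (individuals × tissues ×
genes) and flattened to an `n × p` matrix with `n = m·t`, listing the
samples from each tissue in turn with individuals in the same order within
each tissue (sample index = `tissue·m + individual`).  Every implanted
bicluster is a *tricluster* — a contiguous block of individuals, a
contiguous run of tissues, and a contiguous block of genes — so flattened
biclusters are detectable by both matrix- and tensor-factorisation
algorithms.  Contiguity loses no generality for metric evaluation (metrics
depend only on set membership) and makes datasets easy to visualise.

For each bicluster `k`:

1. Gene count `g_k` uniform from the regime's candidate set, as fractions
   of `p` — mixed `{1/100, 1/10, 1/5, 1/2, 1}`, sparse
   `{1/20, 2/20, 3/20}`, dense `{3/10, 5/10, 9/10}` — and individual
   count `m_k` from the same fractions of `m`.  In the square regimes one
   fraction is drawn and applied to both axes.  Tissue count `t_k` uniform
   on `{1..t}`.  Block starts uniform over the admissible range.
2. Bicluster mean `μ_k ~ Gamma(shape 2, rate 1/600)` (mean 1200,
   sd ≈ 849) — a range wide enough to mix easy, well-separated biclusters
   with hard, similar-mean ones.
3. Cell values `E ~ NegBin(n_k, p)` with `n_k = μ_k p/(1−p)` and shared
   success parameter `p` (default 0.3), giving mean `μ_k` and
   sd `√(μ_k/p)` (≈ 63.2 at μ = 1200).

Contributions are summed over biclusters; background `NegBin(1, p)` noise
is added everywhere.  Variants: Gaussian cell values `N(μ_k, σ²)` with
σ ∈ {20, 100, 300}, and noiseless (`E = μ_k`, no background).  The
shift-scale family replaces the count draw by `E_ijl = α_j·π_il + β_j`
with `π ~ Exp(1)`, `α ~ Exp(rate 2) + 1/2` (mean 1, mode 1/2, bounded away
from zero so the signal is never flattened), `β ~ Exp(1)`, no background;
"shift" fixes `α = 1`, "scale" fixes `β = 0`, "constant-samples" fixes
both.  Exponential draws keep all values non-negative so NMF-style
algorithms remain applicable.

### Numerical choices

- **Fractional candidate sizes** are rounded half-to-even (`np.rint`) and
  floored at 1, so e.g. `m = 10` under the sparse regime yields candidates
  `{1, 1, 2}` (duplicates retained, weighting the uniform draw).
- **Real-valued dispersion** `n_k` is sampled via the Gamma–Poisson
  mixture (`λ ~ Gamma(n_k, (1−p)/p)`, then `Poisson(λ)`), the standard
  continuous extension of the negative binomial; `n_k = 0` yields zeros.
- **Gaussian background** is `N(0, σ²)` and the final matrix is clipped at
  zero.  The background distribution for Gaussian datasets is genuinely
  open — only the cell-value distribution is pinned down — so this choice
  is isolated in the noise configuration; clipping keeps count-oriented
  consumers (log transform, NMF) functional.
- **Shift-scale parameters are drawn independently per bicluster.**
  Sharing `α_j, β_j` across biclusters is the other defensible reading;
  per-bicluster draws preserve the identifiability of each bicluster and
  were chosen for that reason.
- **Seeding**: one master seed per dataset spawns one sub-stream for
  background noise and one per bicluster (split again into
  shape/mean/value streams), so raising `K` extends the bicluster list
  without perturbing earlier draws, and identical seeds give bit-identical
  datasets.
- **Noiseless and Gaussian datasets are real-valued** (bicluster means are
  Gamma draws); only the count models produce integer matrices.

### Knockout-design fixture

The fixture emulates the structure of a multi-tissue knockout RNA-seq
study without any download: `G` knockout genotypes × `T` tissues × `R`
replicates, a gene universe of `n_pathways × genes_per_pathway` genes
partitioned into consecutive pathways, knockout `g` assigned pathway
`g mod n_pathways`.  Each knockout adds a negative-binomial effect
(default mean 1200, matching the simulator's average bicluster mean) on
its pathway's genes in all of its samples; each tissue adds a dense
main-effect bicluster over all genes with a Gamma-drawn mean, reproducing
the tissue-dominance structure seen in real multi-tissue data.  Ground
truth (trait tables, pathway database, knockout→pathway map) is returned
so that trait-F1, enrichment and the knockout biclustering score can be
exercised end to end.

What the fixture does *not* emulate: library-size variation between
samples, gene-specific baseline expression, correlated (co-regulated)
noise, and partially overlapping pathway annotations.  Passing scores on
the fixture therefore demonstrate the *metrics'* correctness and the
pipeline's closure, not algorithm performance on real data.

## Evaluation metrics

- **Clustering error** `CE(A, Â) = d_max / |U|`.  `d_max` is the maximum,
  over injective pairings of biclusters, of the summed cell intersections,
  computed by the Hungarian algorithm on the (rectangular) intersection
  matrix — intersections of Cartesian-product biclusters factor into
  axis-wise intersections, so no cell sets are materialised.  `|U|` is the
  per-cell maximum of the two coverage multiplicities, summed over the
  grid.  This union definition is the one for overlapping biclusterings in
  the clustering-error literature; it makes CE symmetric and strictly
  penalises duplicate, merged or omitted biclusters (properties verified
  in the test suite against a brute-force matching oracle).
  Conventions for degenerate input: two biclusterings covering no cells
  are identical (CE = 1); exactly one empty side scores 0.
- **NRE** `= ‖Y − XBᵀ‖_F / (‖Y‖_F + ‖XBᵀ‖_F)`: 0 at perfect
  reconstruction, at most 1, with equality e.g. at `Ŷ = −Y`; undefined
  (signalled) when both norms vanish.  Invariant to simultaneously
  rescaling `Y` and the reconstruction.
- **MBR**: mean off-diagonal pairwise Jaccard index between the cell sets
  of one run's biclusters; 0 = no overlap, 1 = all identical; undefined
  (NaN) for fewer than two biclusters rather than silently 0.
- **Trait F1**: for a trait's sample set `S` and a bicluster's sample set
  `F`, the harmonic mean of precision `|S∩F|/|F|` and recall `|S∩F|/|S|`;
  an empty or disjoint `F` scores 0 so the max over biclusters is always
  defined.  The clustering ability for a trait family is the mean over
  traits of the best F1 over biclusters.
- **Recovery / relevance**: per-true-bicluster best Jaccard over recovered
  biclusters, and per-recovered-bicluster best Jaccard over true ones.
- **Run similarity**: CE over every unordered pair of runs; both the mean
  and the median are reported, since either summary is defensible.
- **Robustness correlations** are Pearson (the conventional default when
  the correlation type is unspecified); constant input is signalled as not
  computable rather than returned as 0.

## Enrichment

Gene-set enrichment uses the one-tailed hypergeometric upper tail
`P(X ≥ overlap)` with the analysed matrix's full gene set as universe, and
the Benjamini–Yekutieli adjustment (step-up with harmonic-number inflation
`c_m = Σ 1/i`), which controls FDR under arbitrary dependence between
overlapping pathways.  Adjustment families: the *enrichment proportion*
adjusts jointly across all (bicluster, pathway) tests of one call; the
*knockout biclustering score* adjusts within each knockout's own pathway
family, the narrower family matching the per-knockout question being
asked.  Significance thresholds are always caller-supplied (common
choices: 0.01 for the enrichment proportion, 0.05 for the knockout
score).  Ties — best-F1 bicluster, most-enriched pathway — break to the
lowest index / lexicographically first identifier for determinism.

## Thresholding

Membership of sample `i` in factor `k` requires
`|X_ik| > θ · s_k(X)` where `s_k` is the factor's scale (likewise genes on
`B`).  The default scale is the per-column maximum absolute loading, which
is invariant to the arbitrary per-factor rescalings that differ between
algorithms; per-matrix max and per-column Euclidean norm are available as
alternative rules, since the exact normalisation applied before
thresholding is a reconstruction rather than a pinned-down prescription.
Absolute values are compared, so negative loadings count as membership by
magnitude.  θ = 0 reduces to the non-zero pattern; raising θ can only
remove members (monotone support).  Loading matrices whose entries are all
0/1 are membership indicators already and pass through unthresholded.
`θ = 0.01` is the default operating point; `threshold_sweep` evaluates
MBR, masked-loading NRE, recovered K and (when truth is available) CE over
a threshold grid so the operating point can be chosen from measures that
exist for real data.

## Problem sizes in tests

The test and acceptance suites run at desk scale: distributional checks
use 10⁶ Monte-Carlo draws (assertions at 3 standard errors of the
estimator); CE is validated against the brute-force oracle on 200 random
instances with ≤ 4 biclusters per side on grids up to 8 × 8; end-to-end
recovery uses the noiseless base-dimension preset (100 × 1000, K = 20);
the knockout fixture uses 5 genotypes × 3 tissues × 3 replicates with
5 pathways of 20 genes, with the null-rate check averaged over 20 random
biclusterings.  Large presets (up to 6000 × 10000, K = 400) are exercised
only for configuration correctness, not simulated in tests.

## Known limitations

- The simulator's contiguous-block placement means bicluster overlap is
  driven by block collisions; overlap frequency rises with K but is not
  directly controllable.
- The enrichment universe is the full analysed gene set; restricting the
  universe to pathway-annotated genes is the caller's responsibility (the
  knockout fixture's universe is already pathway-restricted by
  construction).
- Normalisation helpers cover `log(x+1)` and per-gene Gaussian quantile
  transformation (average-rank ties); library-size (median-of-ratios)
  normalisation is out of scope.
- No wrappers for external biclustering algorithms are provided: recovered
  factorisations and memberships enter only as files.
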