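"""Pathway-enrichment evaluation of gene clustering, and the knockout score.

A bicluster's gene set is tested against each pathway with the one-tailed
hypergeometric (Fisher) test, and p-values are adjusted with the
Benjamini–Yekutieli correction, which controls the false discovery rate
under arbitrary dependence between tests.  Two summary scores follow:

* the proportion of biclusters enriched for at least one pathway (a gene
  clustering score), with the distinct count of top pathways guarding
  against many biclusters re-discovering the same pathway; and
* the knockout biclustering score: for each knockout genotype, the
  bicluster best matching its samples (by F1) is tested for enrichment of
  the pathways containing the knocked-out gene — a simultaneous test of
  sample clustering, gene clustering and the link between the two.

Adjustment families: the enrichment proportion adjusts jointly across all
(bicluster, pathway) tests of one call; the knockout score adjusts within
each knockout's own (typically small) family of pathways.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .core import Biclustering, PathwayDatabase, TraitAnnotation
from .metrics import f1_trait

__all__ = [
    "EnrichmentResult",
    "hypergeom_pvalue",
    "benjamini_yekutieli",
    "enrichment_table",
    "pathway_enrichment_proportion",
    "distinct_enriched_count",
    "knockout_biclustering_score",
]


@dataclass(frozen=True)
class EnrichmentResult:
    """One (bicluster, pathway) test with raw and adjusted significance."""

    bicluster: int
    pathway: str
    overlap: int
    bicluster_genes: int
    pathway_genes: int
    universe: int
    p_value: float
    q_value: float


def hypergeom_pvalue(
    overlap: int, bicluster_size: int, pathway_size: int, universe_size: int
) -> float:
    """Upper-tail hypergeometric probability P(X >= overlap).

    X counts pathway genes in a random draw of ``bicluster_size`` genes
    from a universe of ``universe_size`` containing ``pathway_size``
    pathway genes.
    """
    if not (0 <= overlap <= min(bicluster_size, pathway_size)):
        raise ValueError("overlap exceeds bicluster or pathway size")
    if max(bicluster_size, pathway_size) > universe_size:
        raise ValueError("set sizes exceed the universe")
    return float(hypergeom.sf(overlap - 1, universe_size, pathway_size,
                              bicluster_size))


def benjamini_yekutieli(pvalues) -> np.ndarray:
    """Benjamini–Yekutieli adjusted q-values, in input order.

    The BY step-up procedure inflates each Benjamini–Hochberg adjustment by
    the harmonic factor c_m = sum_{i=1..m} 1/i, giving FDR control under
    arbitrary dependence; q-values are capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("p-values must be a 1-d sequence")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_by")[1]


def enrichment_table(
    bc: Biclustering, db: PathwayDatabase
) -> pd.DataFrame:
    """Test every (non-empty bicluster, pathway) pair; BY-adjust jointly.

    Returns one row per test with raw p and adjusted q.  Empty biclusters
    are skipped (they carry no genes to test).
    """
    if len(db) == 0:
        raise ValueError("pathway database is empty")
    rows = []
    for k, b in enumerate(bc):
        if b.is_empty:
            continue
        genes = b.gene_set()
        for pid, pgenes in db.items():
            rows.append({
                "bicluster": k,
                "pathway": pid,
                "overlap": len(genes & pgenes),
                "bicluster_genes": len(genes),
                "pathway_genes": len(pgenes),
                "universe": db.universe_size,
            })
    table = pd.DataFrame(
        rows, columns=["bicluster", "pathway", "overlap", "bicluster_genes",
                       "pathway_genes", "universe"])
    if table.empty:
        table["p_value"] = pd.Series(dtype=float)
        table["q_value"] = pd.Series(dtype=float)
        return table
    table["p_value"] = [
        hypergeom_pvalue(r.overlap, r.bicluster_genes, r.pathway_genes,
                         r.universe)
        for r in table.itertuples()
    ]
    table["q_value"] = benjamini_yekutieli(table["p_value"].to_numpy())
    return table


def pathway_enrichment_proportion(
    bc: Biclustering, db: PathwayDatabase, q_threshold: float
) -> tuple[float, pd.DataFrame]:
    """Fraction of (non-empty) biclusters enriched for at least one pathway.

    A bicluster counts as enriched if any of its BY-adjusted q-values falls
    below ``q_threshold``.  The threshold is caller-supplied: different
    analyses legitimately use different significance levels.
    """
    kept = bc.drop_empty()
    if kept.K == 0:
        raise ValueError("no non-empty biclusters to evaluate")
    table = enrichment_table(kept, db)
    enriched = table[table["q_value"] < q_threshold]["bicluster"].nunique()
    return enriched / kept.K, table


def distinct_enriched_count(results: pd.DataFrame) -> int:
    """Number of distinct pathways that were some bicluster's top hit.

    Per bicluster the pathway with the smallest q-value wins (ties broken
    by pathway identifier); the count of distinct winners measures how many
    different pathways the run actually discovered.
    """
    if results.empty:
        raise ValueError("results table is empty")
    ordered = results.sort_values(["bicluster", "q_value", "pathway"])
    top = ordered.groupby("bicluster", sort=False).first()
    return int(top["pathway"].nunique())


def knockout_biclustering_score(
    bc: Biclustering,
    knockout_traits: list[TraitAnnotation],
    gene_pathways: dict[str, frozenset[str]],
    db: PathwayDatabase,
    q_threshold: float,
) -> tuple[float, pd.DataFrame]:
    """Proportion of knockouts whose best-matching bicluster is enriched
    for a pathway containing the knocked-out gene.

    For each knockout trait, the bicluster with the highest F1 score
    against the knockout's samples is selected (ties to the lowest
    bicluster index); its gene set is then tested only against that
    knockout's own pathways, BY-adjusted within that per-knockout family.
    """
    detail_rows = []
    hits = 0
    for trait in knockout_traits:
        if not trait.samples:
            raise ValueError(f"knockout {trait.name!r} has no samples")
        pids = sorted(gene_pathways.get(trait.name, ()))
        if not pids:
            raise ValueError(f"knockout {trait.name!r} has no assigned pathways")
        best_f1, best_k = 0.0, -1
        for k, b in enumerate(bc):
            score = f1_trait(trait.samples, b.samples) if b.samples else 0.0
            if score > best_f1:
                best_f1, best_k = score, k
        enriched = False
        min_q = math.nan
        if best_k >= 0:
            genes = bc[best_k].gene_set()
            pvals = [
                hypergeom_pvalue(
                    len(genes & db.pathways[pid]), len(genes),
                    len(db.pathways[pid]), db.universe_size)
                for pid in pids
            ]
            qvals = benjamini_yekutieli(pvals)
            min_q = float(qvals.min())
            enriched = bool(min_q < q_threshold)
        hits += enriched
        detail_rows.append({
            "knockout": trait.name, "best_bicluster": best_k,
            "best_f1": best_f1, "min_q": min_q, "enriched": enriched,
        })
    if not detail_rows:
        raise ValueError("at least one knockout trait is required")
    detail = pd.DataFrame(detail_rows)
    return hits / len(detail_rows), detail
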