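"""Nearest-gene mapping of causal variants and hypergeometric gene-set
over-representation with Benjamini-Hochberg adjustment.

Each causal variant is assigned the single gene minimizing the distance
to its position (distance 0 inside the gene body, BED half-open
coordinates); the deduplicated gene list is then tested against each
supplied gene set with the hypergeometric upper tail

    p = P(X >= overlap),  X ~ Hypergeom(universe, set_size, query_size)

where the universe is all genes in the annotation.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CortMRError
from .gwas_io import GeneSet

logger = logging.getLogger(__name__)


def nearest_gene(chrom: str, pos: int, genes: pd.DataFrame) -> str | None:
    """The gene nearest a 1-based variant position.

    Distance is the gap between the variant position and the gene's
    nearest boundary coordinate, 0 inside the gene body; ties break by
    smallest distance then lexicographic gene ID.  ``None`` when the
    chromosome has no annotated gene.
    """
    sub = genes.loc[genes["chrom"].astype(str) == str(chrom)]
    if len(sub) == 0:
        logger.warning("no gene annotation on chromosome %s", chrom)
        return None
    p = int(pos)
    start = sub["start"].to_numpy()
    end = sub["end"].to_numpy()
    dist = np.maximum(np.maximum(start - p, p - end), 0)
    best = sorted(zip(dist, sub["gene_id"]))[0]
    return str(best[1])


def map_variants_to_genes(snps: pd.DataFrame, genes: pd.DataFrame) -> list[str]:
    """Nearest gene per variant, deduplicated, order-preserving."""
    hits = []
    for _, row in snps.iterrows():
        g = nearest_gene(row["chrom"], row["pos"], genes)
        if g is not None:
            hits.append(g)
    return list(dict.fromkeys(hits))


@dataclass(frozen=True)
class EnrichmentResult:
    set_id: str
    overlap: int
    set_size: int
    query_size: int
    universe_size: int
    pval: float
    pval_adj: float
    genes: tuple[str, ...]


def _bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    m = len(pvals)
    order = np.argsort(pvals, kind="mergesort")
    ranked = pvals[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


def overrepresentation(query, gene_sets, universe) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of a gene list in each gene set.

    ``query`` must be a subset of ``universe``; each set is intersected
    with the universe before testing.  Results are BH-adjusted across
    all tested sets and sorted by (p, set_id).
    """
    query = list(dict.fromkeys(query))
    universe = set(universe)
    if not query:
        raise CortMRError("empty query gene list")
    stray = [g for g in query if g not in universe]
    if stray:
        raise CortMRError(
            f"query genes outside the universe: {', '.join(sorted(stray)[:5])}")
    M = len(universe)
    N = len(query)
    qset = set(query)
    raw = []
    for gs in gene_sets:
        members = sorted(set(gs.members) & universe)
        n = len(members)
        hit = sorted(qset & set(members))
        k = len(hit)
        # upper tail P(X >= k); sf(k-1) by the survival-function convention
        p = float(stats.hypergeom.sf(k - 1, M, n, N)) if n else 1.0
        raw.append((gs.set_id, k, n, p, tuple(hit)))
    padj = _bh_adjust(np.array([r[3] for r in raw])) if raw else np.array([])
    results = [EnrichmentResult(sid, k, n, N, M, p, float(pa), hit)
               for (sid, k, n, p, hit), pa in zip(raw, padj)]
    results.sort(key=lambda r: (r.pval, r.set_id))
    return results


def results_frame(results) -> pd.DataFrame:
    return pd.DataFrame([{
        "set_id": r.set_id, "overlap": r.overlap, "set_size": r.set_size,
        "query_size": r.query_size, "universe_size": r.universe_size,
        "pval": r.pval, "pval_adj": r.pval_adj,
        "genes": ";".join(r.genes),
    } for r in results])
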