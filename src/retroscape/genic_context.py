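"""TE-to-gene annotation, enriched gene sets, repeat matrices and enrichment.

A TE is assigned to exactly one genomic feature by its midpoint, testing
features in a fixed priority: Promoter > 5UTR > 3UTR > Exon > Intron >
Downstream > Intergenic. Gene-set enrichment uses the hypergeometric
upper tail with Benjamini-Hochberg adjustment, and query-vs-random
p-value distributions are compared with a two-sided rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from statsmodels.stats.multitest import multipletests

from .io_formats import GeneModel, TECopy

__all__ = [
    "FeatureAnnotation",
    "EnrichmentResult",
    "FEATURE_LABELS",
    "annotate_te",
    "annotate_all",
    "enriched_genes",
    "genic_overlap_fraction",
    "repeat_percent_matrix",
    "quantile_normalize",
    "hierarchical_cluster",
    "term_enrichment",
    "cdc_compare",
]

FEATURE_LABELS = (
    "Promoter", "5UTR", "3UTR", "Exon", "Intron", "Downstream", "Intergenic",
)


@dataclass(frozen=True)
class FeatureAnnotation:
    copy_id: str
    label: str
    nearest_gene_id: str | None
    distance_bp: int


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    N: int
    K: int
    n: int
    k: int
    p_hyper: float
    p_adjusted: float
    significant: bool


def _in_any(pos: int, intervals: list[tuple[int, int]]) -> bool:
    return any(s <= pos < e for s, e in intervals)


def _utrs(gene: GeneModel) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Exonic sub-intervals upstream/downstream of the CDS (strand-aware)."""
    if not gene.cds:
        return [], []
    cds_lo = min(s for s, _ in gene.cds)
    cds_hi = max(e for _, e in gene.cds)
    left = [(max(s, gene.tx_start), min(e, cds_lo)) for s, e in gene.exons if s < cds_lo]
    right = [(max(s, cds_hi), e) for s, e in gene.exons if e > cds_hi]
    left = [(s, e) for s, e in left if s < e]
    right = [(s, e) for s, e in right if s < e]
    return (left, right) if gene.strand == "+" else (right, left)


def annotate_te(
    te: TECopy,
    genes: list[GeneModel],
    promoter_flank: int = 3000,
    downstream_flank: int = 3000,
) -> FeatureAnnotation:
    """Assign one feature label to a TE by midpoint, in priority order.

    Promoter = [TSS-flank, TSS+flank) strand-aware; Downstream = flank bp
    past the transcript end. Distance is signed bp to the nearest gene
    body (0 when overlapping; negative when upstream of the TSS).
    """
    mid = te.midpoint
    same_chrom = [g for g in genes if g.chrom == te.chrom]

    def hit(label: str) -> GeneModel | None:
        for g in same_chrom:
            if label == "Promoter":
                tss = g.tss
                if tss - promoter_flank <= mid < tss + promoter_flank:
                    return g
            elif label in ("5UTR", "3UTR"):
                utr5, utr3 = _utrs(g)
                if _in_any(mid, utr5 if label == "5UTR" else utr3):
                    return g
            elif label == "Exon":
                if _in_any(mid, g.exons):
                    return g
            elif label == "Intron":
                if g.tx_start <= mid < g.tx_end and not _in_any(mid, g.exons):
                    return g
            elif label == "Downstream":
                if g.strand == "+":
                    if g.tx_end <= mid < g.tx_end + downstream_flank:
                        return g
                else:
                    if g.tx_start - downstream_flank <= mid < g.tx_start:
                        return g
        return None

    for label in FEATURE_LABELS[:-1]:
        g = hit(label)
        if g is not None:
            return FeatureAnnotation(te.copy_id, label, g.gene_id, _signed_distance(mid, g))

    nearest, dist = None, None
    for g in same_chrom:
        d = _signed_distance(mid, g)
        if dist is None or abs(d) < abs(dist):
            nearest, dist = g, d
    return FeatureAnnotation(
        te.copy_id, "Intergenic",
        nearest.gene_id if nearest else None,
        dist if dist is not None else np.iinfo(np.int32).max,
    )


def _signed_distance(pos: int, gene: GeneModel) -> int:
    """0 inside the gene body; negative upstream of the TSS, positive past it."""
    if gene.tx_start <= pos < gene.tx_end:
        return 0
    if pos < gene.tx_start:
        d = gene.tx_start - pos
        return -d if gene.strand == "+" else d
    d = pos - gene.tx_end + 1
    return d if gene.strand == "+" else -d


def annotate_all(
    tes: list[TECopy], genes: list[GeneModel], **kwargs
) -> list[FeatureAnnotation]:
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    return [annotate_te(te, by_chrom.get(te.chrom, []), **kwargs) for te in tes]


def enriched_genes(
    tes: list[TECopy],
    genes: list[GeneModel],
    flank: int = 5000,
    te_classes: tuple[str, ...] = ("LINE", "SINE"),
) -> dict[str, set[str]]:
    """Per-class enriched gene sets and their class-specific differences.

    A gene is class-enriched iff any element of that class overlaps
    [tx_start - flank, tx_end + flank). ``<class>_specific`` removes genes
    also enriched for any other class.
    """
    enr: dict[str, set[str]] = {c: set() for c in te_classes}
    by_chrom: dict[str, list[TECopy]] = {}
    for te in tes:
        if te.te_class in enr:
            by_chrom.setdefault(te.chrom, []).append(te)
    for g in genes:
        lo, hi = g.tx_start - flank, g.tx_end + flank
        for te in by_chrom.get(g.chrom, []):
            if te.start < hi and te.end > lo:
                enr[te.te_class].add(g.gene_id)
    out = {f"{c}_enriched": s for c, s in enr.items()}
    for c in te_classes:
        others = set().union(*(enr[o] for o in te_classes if o != c))
        out[f"{c}_specific"] = enr[c] - others
    return out


def genic_overlap_fraction(
    tes: list[TECopy], genes: list[GeneModel], flank: int = 3000
) -> tuple[float, float]:
    """(fraction of TEs within flank of a gene, fraction of genes hit)."""
    if not tes or not genes:
        return 0.0, 0.0
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    te_hit = 0
    genes_hit: set[str] = set()
    for te in tes:
        hit = False
        for g in by_chrom.get(te.chrom, []):
            if te.start < g.tx_end + flank and te.end > g.tx_start - flank:
                hit = True
                genes_hit.add(g.gene_id)
        te_hit += hit
    return te_hit / len(tes), len(genes_hit) / len(genes)


def repeat_percent_matrix(
    tes: list[TECopy], genes: list[GeneModel], flank: int = 3000
) -> pd.DataFrame:
    """Genes x families matrix of percent of flanked gene span covered.

    The gene span includes the +-flank; same-family intervals are merged
    before measuring coverage so entries stay within [0, 100].
    """
    families = sorted({te.family for te in tes})
    by_chrom: dict[str, list[TECopy]] = {}
    for te in tes:
        by_chrom.setdefault(te.chrom, []).append(te)
    mat = np.zeros((len(genes), len(families)))
    fam_idx = {f: i for i, f in enumerate(families)}
    for gi, g in enumerate(genes):
        lo, hi = max(0, g.tx_start - flank), g.tx_end + flank
        span = hi - lo
        per_fam: dict[str, list[tuple[int, int]]] = {}
        for te in by_chrom.get(g.chrom, []):
            s, e = max(te.start, lo), min(te.end, hi)
            if s < e:
                per_fam.setdefault(te.family, []).append((s, e))
        for fam, ivs in per_fam.items():
            ivs.sort()
            covered, cur_s, cur_e = 0, *ivs[0]
            for s, e in ivs[1:]:
                if s > cur_e:
                    covered += cur_e - cur_s
                    cur_s, cur_e = s, e
                else:
                    cur_e = max(cur_e, e)
            covered += cur_e - cur_s
            mat[gi, fam_idx[fam]] = 100.0 * covered / span
    return pd.DataFrame(mat, index=[g.gene_id for g in genes], columns=families)


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Replace each column's sorted values by the across-column row means.

    Ties within a column receive the average of the means they span, so
    normalized columns are exact permutations of one another when
    tie-free.
    """
    values = matrix.to_numpy(dtype=float)
    ref = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        ranks = stats.rankdata(values[:, j], method="average") - 1.0
        lo = np.floor(ranks).astype(int)
        hi = np.ceil(ranks).astype(int)
        out[:, j] = (ref[lo] + ref[hi]) / 2.0
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def hierarchical_cluster(
    matrix: pd.DataFrame, k: int = 2, method: str = "average"
) -> tuple[np.ndarray, np.ndarray]:
    """Average-linkage agglomeration on Euclidean distance between rows.

    Returns (cluster labels 1..k, scipy linkage matrix).
    """
    Z = linkage(matrix.to_numpy(dtype=float), method=method, metric="euclidean")
    return fcluster(Z, t=k, criterion="maxclust"), Z


def term_enrichment(
    query_genes: set[str],
    term_membership: dict[str, set[str]],
    universe: set[str],
    alpha: float = 0.01,
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of each term in the query set.

    p = P(X >= k) with X ~ Hypergeometric(N, K, n); Benjamini-Hochberg
    adjustment across terms; significant iff adjusted p <= alpha.
    """
    if not query_genes <= universe:
        raise ValueError("query genes must be a subset of the universe")
    N, n = len(universe), len(query_genes)
    rows = []
    for term, members in term_membership.items():
        members = members & universe
        K = len(members)
        k = len(members & query_genes)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((term, N, K, n, k, min(p, 1.0)))
    pvals = np.array([r[5] for r in rows]) if rows else np.array([])
    if len(pvals):
        _, padj, _, _ = multipletests(pvals, method="fdr_bh")
    else:
        padj = pvals
    return [
        EnrichmentResult(*r, p_adjusted=float(q), significant=bool(q <= alpha))
        for r, q in zip(rows, padj)
    ]


def cdc_compare(
    pvals_query: np.ndarray, pvals_random_sets: list[np.ndarray]
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum of query p-values vs pooled random-set p-values."""
    pooled = np.concatenate([np.asarray(p, dtype=float) for p in pvals_random_sets])
    stat, p = stats.ranksums(np.asarray(pvals_query, dtype=float), pooled)
    return float(stat), float(p)
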