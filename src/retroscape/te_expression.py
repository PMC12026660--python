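"""Post-quantification TE expression analytics.

Counts for individual TE copies and genes (quantified upstream) are
converted to TPM, filtered for high-confidence expression, and screened
for tissue x developmental-stage differential expression with a global
F-test of a degree-2 polynomial time-course model; selected profiles are
clustered with average linkage on correlation distance, the cluster
count chosen by mean silhouette, and selected intergenic TEs are linked
to their nearest differentially expressed gene by expression
correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.metrics import silhouette_score
from statsmodels.stats.multitest import multipletests

from .io_formats import CountMatrix, GeneModel, TECopy

__all__ = [
    "DEResult",
    "ClusterAssignment",
    "TEGeneLink",
    "classify_te_location",
    "tpm",
    "filter_expressed",
    "timecourse_de",
    "cluster_profiles",
    "te_gene_links",
]


@dataclass(frozen=True)
class DEResult:
    feature_id: str
    F_stat: float
    p: float
    p_adjusted: float
    R_squared: float
    selected: bool


@dataclass
class ClusterAssignment:
    labels: dict[str, int]
    k: int
    silhouette_by_k: dict[int, float]
    degenerate: bool = False


@dataclass(frozen=True)
class TEGeneLink:
    te_id: str
    gene_id: str
    gene_label: str | None
    distance_bp: int
    pearson_r: float


def classify_te_location(
    tes: list[TECopy],
    genes: list[GeneModel],
    intergenic_min_bp: int = 5000,
) -> dict[str, str]:
    """Label each TE intergenic / intronic / exonic / proximal by midpoint.

    Exonic if the midpoint falls in an exon, intronic if inside a gene
    but not an exon, intergenic iff farther than ``intergenic_min_bp``
    from every gene; TEs outside genes but within that distance are
    "proximal" and excluded from the three analysis classes.
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    out: dict[str, str] = {}
    for te in tes:
        mid = te.midpoint
        label = "intergenic"
        min_dist = None
        for g in by_chrom.get(te.chrom, []):
            if g.tx_start <= mid < g.tx_end:
                label = "exonic" if any(s <= mid < e for s, e in g.exons) else "intronic"
                min_dist = 0
                break
            d = g.tx_start - mid if mid < g.tx_start else mid - g.tx_end + 1
            min_dist = d if min_dist is None else min(min_dist, d)
        else:
            if min_dist is not None and min_dist <= intergenic_min_bp:
                label = "proximal"
        out[te.copy_id] = label
    return out


def tpm(counts: CountMatrix) -> pd.DataFrame:
    """Transcripts-per-million: length-normalized rates scaled to 1e6 per sample."""
    c = counts.counts.astype(float)
    if (c.sum(axis=0) == 0).any():
        empty = [s for s, tot in zip(counts.sample_ids, c.sum(axis=0)) if tot == 0]
        raise ValueError(f"empty library: {empty}")
    rate = c / (counts.feature_lengths[:, None] / 1000.0)
    out = rate / rate.sum(axis=0)[None, :] * 1.0e6
    return pd.DataFrame(out, index=counts.feature_ids, columns=counts.sample_ids)


def filter_expressed(
    counts: CountMatrix,
    groups: np.ndarray | list,
    min_count: float = 10.0,
    min_total: float = 15.0,
) -> list[str]:
    """Keep features expressed at a CPM cutoff in at least the smallest group.

    The cutoff is ``min_count / median(library size) * 1e6`` CPM; a
    feature is kept iff its CPM reaches the cutoff in at least n*
    samples, where n* is the size of the smallest experimental group, and
    its total count across samples is >= ``min_total``.
    """
    lib = counts.counts.sum(axis=0).astype(float)
    cutoff = min_count / np.median(lib) * 1.0e6
    cpm = counts.counts / lib[None, :] * 1.0e6
    _, group_sizes = np.unique(np.asarray(groups), return_counts=True)
    n_star = int(group_sizes.min())
    keep = ((cpm >= cutoff).sum(axis=1) >= n_star) & (
        counts.counts.sum(axis=1) >= min_total
    )
    return [f for f, k in zip(counts.feature_ids, keep) if k]


def _design_matrix(stage_idx: np.ndarray, tissue_bin: np.ndarray) -> np.ndarray:
    t = stage_idx.astype(float)
    g = tissue_bin.astype(float)
    X = np.column_stack([np.ones_like(t), t, t**2, g, g * t, g * t**2])
    return X


def timecourse_de(
    expr: pd.DataFrame,
    design: pd.DataFrame,
    alpha: float = 0.05,
    r2_min: float = 0.6,
) -> list[DEResult]:
    """Per-feature global F-test of the tissue x stage polynomial model.

    The response is log2(TPM+1); the model is
    y ~ 1 + t + t^2 + g + g.t + g.t^2 with stages coded 0,1,2 and tissue
    g in {0,1}. The F statistic compares the full fit to the
    intercept-only model; p-values are Benjamini-Hochberg adjusted across
    features, and a feature is selected iff adjusted p <= ``alpha`` and
    R^2 >= ``r2_min``.
    """
    stages = sorted(design["stage"].unique())
    tissues = sorted(design["tissue"].unique())
    if len(stages) < 2 or len(tissues) < 2:
        raise ValueError("design needs >= 2 stages and >= 2 tissues")
    stage_idx = design["stage"].map({s: i for i, s in enumerate(stages)}).to_numpy()
    tissue_bin = (design["tissue"] == tissues[0]).to_numpy().astype(float)
    X = _design_matrix(stage_idx, tissue_bin)
    n, p = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        raise ValueError(
            "rank-deficient design: stage/tissue interaction terms are aliased"
        )
    if n - p <= 0:
        raise ValueError("not enough samples for the model's degrees of freedom")

    Y = np.log2(expr.loc[:, design.index].to_numpy(dtype=float) + 1.0)  # features x samples
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    fitted = (X @ beta).T
    resid = Y - fitted
    rss = (resid**2).sum(axis=1)
    tss = ((Y - Y.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    df_model, df_resid = p - 1, n - p
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ((tss - rss) / df_model) / (rss / df_resid)
        r2 = np.where(tss > 0, 1.0 - rss / tss, 0.0)
    F = np.where(np.isfinite(F), F, np.inf)
    pvals = stats.f.sf(F, df_model, df_resid)
    pvals = np.where(np.isfinite(pvals), pvals, 0.0)
    _, padj, _, _ = multipletests(pvals, method="fdr_bh")
    return [
        DEResult(
            feature_id=fid,
            F_stat=float(F[i]),
            p=float(pvals[i]),
            p_adjusted=float(padj[i]),
            R_squared=float(r2[i]),
            selected=bool(padj[i] <= alpha and r2[i] >= r2_min),
        )
        for i, fid in enumerate(expr.index)
    ]


def cluster_profiles(
    expr: pd.DataFrame,
    k_range: range = range(2, 16),
    method: str = "average",
) -> ClusterAssignment:
    """Cluster standardized profiles; pick k by maximum mean silhouette.

    Rows are z-scored, distances are correlation distance (1 - r),
    linkage is average; the silhouette is evaluated on the same distance.
    Identical profiles (zero distance everywhere) give a degenerate
    assignment with all features in one cluster.
    """
    X = expr.to_numpy(dtype=float)
    sd = X.std(axis=1, keepdims=True)
    if (sd == 0).any():
        raise ValueError("constant profiles cannot be standardized")
    Z = (X - X.mean(axis=1, keepdims=True)) / sd
    n = Z.shape[0]
    corr = np.corrcoef(Z)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    if np.allclose(dist, 0.0):
        return ClusterAssignment(
            labels={f: 1 for f in expr.index}, k=1, silhouette_by_k={}, degenerate=True
        )
    from scipy.spatial.distance import squareform

    condensed = squareform(dist, checks=False)
    link = linkage(condensed, method=method)
    sil: dict[int, float] = {}
    best_labels: dict[int, np.ndarray] = {}
    for k in k_range:
        if k >= n:
            break
        lab = fcluster(link, t=k, criterion="maxclust")
        if len(np.unique(lab)) < 2:
            continue
        sil[k] = float(silhouette_score(dist, lab, metric="precomputed"))
        best_labels[k] = lab
    if not sil:
        return ClusterAssignment(
            labels={f: 1 for f in expr.index}, k=1, silhouette_by_k={}, degenerate=True
        )
    k_best = max(sil, key=sil.get)
    return ClusterAssignment(
        labels={f: int(c) for f, c in zip(expr.index, best_labels[k_best])},
        k=k_best,
        silhouette_by_k=sil,
    )


def te_gene_links(
    selected_tes: list[TECopy],
    deg_genes: list[GeneModel],
    expr: pd.DataFrame,
    min_distance_bp: int = 5000,
) -> list[TEGeneLink]:
    """Link each selected TE to its nearest DEG beyond ``min_distance_bp``.

    Distance is the gap between the TE span and the gene body on the same
    chromosome; the link records the Pearson correlation of log2(TPM+1)
    profiles across all samples. TEs with no eligible gene, or TE/gene
    ids missing from ``expr``, yield no link.
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in deg_genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    links: list[TEGeneLink] = []
    logx = np.log2(expr.to_numpy(dtype=float) + 1.0)
    log_expr = pd.DataFrame(logx, index=expr.index, columns=expr.columns)
    for te in selected_tes:
        if te.copy_id not in log_expr.index:
            continue
        best: tuple[int, GeneModel] | None = None
        for g in by_chrom.get(te.chrom, []):
            if g.gene_id not in log_expr.index:
                continue
            if te.end <= g.tx_start:
                d = g.tx_start - te.end
            elif g.tx_end <= te.start:
                d = te.start - g.tx_end
            else:
                d = 0
            if d <= min_distance_bp:
                continue
            if best is None or d < best[0]:
                best = (d, g)
        if best is None:
            continue
        d, g = best
        x = log_expr.loc[te.copy_id].to_numpy()
        y = log_expr.loc[g.gene_id].to_numpy()
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            r = np.nan
        else:
            r = float(np.corrcoef(x, y)[0, 1])
        links.append(
            TEGeneLink(
                te_id=te.copy_id,
                gene_id=g.gene_id,
                gene_label=g.annotation_label,
                distance_bp=d,
                pearson_r=r,
            )
        )
    return links
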