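"""GC-content association and CpG-methylation aggregation over TEs.

Window-level GC is compared with per-window TE occupancy per class
(Pearson), element GC with insertion age, and per-CpG methylated-read
fractions are aggregated to per-element and per-subfamily summaries so
the age-methylation relationship can be measured.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .io_formats import GeneModel, MethylSite, TECopy

__all__ = [
    "CorrResult",
    "TEMethylSummary",
    "gc_content",
    "window_gc_track",
    "te_gc_association",
    "gc_vs_age",
    "methylation_summary",
    "methylation_vs_age",
    "pearson",
]


@dataclass(frozen=True)
class CorrResult:
    r: float
    n: int
    t_stat: float
    p: float
    flagged: bool = False  # undefined (constant input or df <= 0)


@dataclass(frozen=True)
class TEMethylSummary:
    copy_id: str
    n_sites: int
    mean_fraction: float
    is_methylated: bool


def pearson(x, y) -> CorrResult:
    """Pearson r with its t statistic; degenerate inputs are flagged, not raised."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y):
        raise ValueError("length mismatch")
    if n < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrResult(np.nan, n, np.nan, np.nan, flagged=True)
    r, p = stats.pearsonr(x, y)
    t = r * np.sqrt((n - 2) / (1 - r**2)) if abs(r) < 1 else np.inf
    return CorrResult(float(r), n, float(t), float(p))


def gc_content(seq: str) -> float:
    """(G+C)/(A+C+G+T); N and other symbols excluded from the denominator."""
    arr = np.frombuffer(seq.upper().encode(), dtype="S1")
    gc = int(((arr == b"G") | (arr == b"C")).sum())
    at = int(((arr == b"A") | (arr == b"T")).sum())
    if gc + at == 0:
        return np.nan
    return gc / (gc + at)


def window_gc_track(
    genome: dict[str, str], window: int = 250_000
) -> pd.DataFrame:
    """Non-overlapping window GC fractions across the genome."""
    rows = []
    for chrom, seq in genome.items():
        n_win = -(-len(seq) // window)
        for w in range(n_win):
            lo, hi = w * window, min((w + 1) * window, len(seq))
            rows.append((chrom, lo, hi, gc_content(seq[lo:hi])))
    return pd.DataFrame(rows, columns=["chrom", "window_start", "window_end", "gc"])


def te_gc_association(
    te_copies: list[TECopy],
    genome: dict[str, str],
    window: int = 250_000,
    te_classes: tuple[str, ...] = ("LINE", "SINE"),
) -> tuple[pd.DataFrame, dict[str, CorrResult]]:
    """Per-window TE GC/bp per class and the window-GC vs TE-bp correlation.

    TE GC is measured over TE-covered bases only; the per-class ratio
    log10(TE GC / window GC) is defined where both are positive. Windows
    with no TE of any requested class are dropped from the correlations;
    an all-free genome is an error.
    """
    track = window_gc_track(genome, window)
    n = len(track)
    key = {
        (r.chrom, r.window_start // window): i
        for i, r in enumerate(track.itertuples(index=False))
    }
    bp = {c: np.zeros(n) for c in te_classes}
    gc_num = {c: np.zeros(n) for c in te_classes}  # G+C bases inside TEs
    at_num = {c: np.zeros(n) for c in te_classes}
    for te in te_copies:
        if te.te_class not in bp:
            continue
        seq = genome[te.chrom]
        w_lo, w_hi = te.start // window, (te.end - 1) // window
        for w in range(w_lo, w_hi + 1):
            lo = max(te.start, w * window)
            hi = min(te.end, (w + 1) * window)
            i = key[(te.chrom, w)]
            sub = np.frombuffer(seq[lo:hi].upper().encode(), dtype="S1")
            g = int(((sub == b"G") | (sub == b"C")).sum())
            a = int(((sub == b"A") | (sub == b"T")).sum())
            bp[te.te_class][i] += hi - lo
            gc_num[te.te_class][i] += g
            at_num[te.te_class][i] += a
    for c in te_classes:
        track[f"{c}_bp"] = bp[c]
        denom = gc_num[c] + at_num[c]
        with np.errstate(invalid="ignore", divide="ignore"):
            te_gc = np.where(denom > 0, gc_num[c] / np.maximum(denom, 1), np.nan)
            track[f"{c}_gc"] = te_gc
            track[f"{c}_log10_ratio"] = np.where(
                (te_gc > 0) & (track["gc"] > 0), np.log10(te_gc / track["gc"]), np.nan
            )
    occupied = track[[f"{c}_bp" for c in te_classes]].sum(axis=1) > 0
    if not occupied.any():
        raise ValueError("no data: no window contains a TE of the requested classes")
    corr = {
        c: pearson(track.loc[occupied, "gc"], track.loc[occupied, f"{c}_bp"])
        for c in te_classes
    }
    return track, corr


def gc_vs_age(gc_fracs, ages_my) -> CorrResult:
    """Correlation between element GC content and insertion age (My)."""
    return pearson(gc_fracs, ages_my)


def methylation_summary(
    te_copies: list[TECopy],
    sites: list[MethylSite],
    genes: list[GeneModel] | None = None,
    near_gene_bp: int = 5000,
    min_sites_methylated: int = 1,
) -> tuple[list[TEMethylSummary], pd.DataFrame]:
    """Assign CpG sites to TEs (half-open) and aggregate per element and class.

    A site inside overlapping copies contributes to each copy's mean but
    is counted once per class for the site-share statistic. Class
    aggregates report the share of all sites in each class, the share of
    elements with >= ``min_sites_methylated`` sites, the mean fraction,
    and (when genes are given) mean fractions near (<= ``near_gene_bp``)
    vs distal to genes.
    """
    trees: dict[str, IntervalTree] = {}
    for idx, te in enumerate(te_copies):
        trees.setdefault(te.chrom, IntervalTree()).addi(te.start, te.end, idx)
    per_te_fracs: dict[int, list[float]] = {i: [] for i in range(len(te_copies))}
    class_sites: dict[str, set[int]] = {}
    for si, site in enumerate(sites):
        tree = trees.get(site.chrom)
        if tree is None:
            continue
        for iv in tree.at(site.pos):
            idx = iv.data
            per_te_fracs[idx].append(site.methyl_fraction)
            class_sites.setdefault(te_copies[idx].te_class, set()).add(si)

    near_gene: dict[int, bool] = {}
    if genes is not None:
        by_chrom: dict[str, list[GeneModel]] = {}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append(g)
        for idx, te in enumerate(te_copies):
            near_gene[idx] = any(
                te.start < g.tx_end + near_gene_bp and te.end > g.tx_start - near_gene_bp
                for g in by_chrom.get(te.chrom, [])
            )

    summaries = [
        TEMethylSummary(
            copy_id=te.copy_id,
            n_sites=len(per_te_fracs[i]),
            mean_fraction=float(np.mean(per_te_fracs[i])) if per_te_fracs[i] else np.nan,
            is_methylated=len(per_te_fracs[i]) >= min_sites_methylated,
        )
        for i, te in enumerate(te_copies)
    ]

    rows = []
    total_sites = len(sites)
    for cls in sorted({te.te_class for te in te_copies}):
        idxs = [i for i, te in enumerate(te_copies) if te.te_class == cls]
        fracs = [f for i in idxs for f in per_te_fracs[i]]
        n_class_sites = len(class_sites.get(cls, set()))
        row = {
            "te_class": cls,
            "n_sites": n_class_sites,
            "site_share": n_class_sites / total_sites if total_sites else np.nan,
            "element_methylated_share": float(
                np.mean([summaries[i].is_methylated for i in idxs])
            ),
            "mean_fraction": float(np.mean(fracs)) if fracs else np.nan,
        }
        if genes is not None:
            near = [
                f for i in idxs if near_gene.get(i) for f in per_te_fracs[i]
            ]
            far = [
                f for i in idxs if not near_gene.get(i) for f in per_te_fracs[i]
            ]
            row["mean_fraction_near_gene"] = float(np.mean(near)) if near else np.nan
            row["mean_fraction_distal"] = float(np.mean(far)) if far else np.nan
        rows.append(row)
    return summaries, pd.DataFrame(rows)


def methylation_vs_age(
    subfamily_mean_age_my, subfamily_mean_methylation
) -> CorrResult:
    """Correlation of subfamily mean insertion age with mean methylation fraction."""
    x = np.asarray(subfamily_mean_age_my, dtype=float)
    if len(x) < 2:
        raise ValueError("need >= 2 subfamilies")
    return pearson(x, subfamily_mean_methylation)
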