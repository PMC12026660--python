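"""Compartment calling, TAD-separation boundaries and TE-composition analytics.

Compartments: each chromosome's contact map is distance-normalized
(observed/expected by per-diagonal mean), converted to a Pearson
correlation matrix over bins, and the leading eigenvector (PC1) is
oriented so that it correlates non-negatively with bin GC; A = positive
PC1. TAD boundaries come from a multi-scale separation score: for each
bin the mean contact frequency in d x d squares bridging the bin is
z-scored per scale and averaged; boundaries are significant local minima.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import ContactMatrix, IntervalSet

__all__ = [
    "CompartmentTrack",
    "TadBoundarySet",
    "BinClassTrack",
    "HomotypicStats",
    "oe_normalize",
    "correlation_matrix",
    "compartments",
    "compartment_te_association",
    "tad_separation",
    "classify_bins",
    "homotypic_stats",
    "feature_overlap",
]


@dataclass
class CompartmentTrack:
    pc1: np.ndarray
    labels: np.ndarray  # 'A', 'B' or 'masked'
    sign_anchor_r: float
    weak: bool = False  # anchor correlation indistinguishable from 0


@dataclass
class TadBoundarySet:
    boundaries: list[int]
    score: np.ndarray
    delta: float
    qvalues: dict[int, float]


@dataclass
class BinClassTrack:
    labels: np.ndarray  # 'LINE-rich', 'SINE-rich', 'neutral'
    line_fraction: np.ndarray
    sine_fraction: np.ndarray


@dataclass(frozen=True)
class HomotypicStats:
    pair_type: str
    n_pairs: int
    fraction_positive: float
    mean_correlation: float


def _masked_bins(values: np.ndarray) -> np.ndarray:
    return values.sum(axis=0) == 0


def oe_normalize(m: ContactMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Observed/expected: divide each entry by its diagonal's mean.

    Diagonal means are taken over entries not touching masked (zero
    marginal) bins; zero-mean diagonals map to 0. Returns (O/E matrix,
    boolean mask of excluded bins).
    """
    v = m.values
    n = m.n_bins
    mask = _masked_bins(v)
    keep = ~mask
    oe = np.zeros_like(v, dtype=float)
    for d in range(n):
        idx = np.arange(n - d)
        valid = keep[idx] & keep[idx + d]
        diag = v[idx, idx + d]
        mean = diag[valid].mean() if valid.any() else 0.0
        if mean > 0:
            oe[idx, idx + d] = diag / mean
            oe[idx + d, idx] = oe[idx, idx + d]
    oe[mask, :] = 0.0
    oe[:, mask] = 0.0
    return oe, mask


def correlation_matrix(oe: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Pearson correlation of O/E rows over unmasked bins."""
    keep = ~mask
    sub = oe[np.ix_(keep, keep)]
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(sub)
    return np.nan_to_num(corr)


def _power_iteration(a: np.ndarray, tol: float = 1e-10, max_iter: int = 10_000) -> np.ndarray:
    """Leading eigenvector by power iteration with a deterministic start."""
    n = a.shape[0]
    v = np.ones(n) / np.sqrt(n)
    # shift to make the dominant eigenvalue of (a + cI) the largest-magnitude
    # one even when a has a large negative eigenvalue
    shift = float(np.abs(a).sum(axis=1).max())
    m = a + shift * np.eye(n)
    for _ in range(max_iter):
        w = m @ v
        norm = np.linalg.norm(w)
        if norm == 0:
            raise ValueError("degenerate (rank-0) matrix")
        w /= norm
        if np.linalg.norm(w - v) < tol or np.linalg.norm(w + v) < tol:
            v = w
            break
        v = w
    return v


def compartments(
    m: ContactMatrix, gc_track: np.ndarray, weak_r_threshold: float = 0.1
) -> CompartmentTrack:
    """A/B compartments from PC1 of the O/E Pearson correlation matrix.

    PC1 is the leading eigenvector (power iteration, tolerance 1e-10,
    deterministic all-ones start), sign-flipped so corr(PC1, GC) >= 0;
    A = positive PC1. Bins with zero contact marginal are masked. A weak
    GC anchor (|r| below ``weak_r_threshold``) flags the track as weakly
    compartmentalized, where the orientation is unreliable.
    """
    gc_track = np.asarray(gc_track, dtype=float)
    if len(gc_track) != m.n_bins:
        raise ValueError("gc_track length must equal n_bins")
    oe, mask = oe_normalize(m)
    keep = ~mask
    if keep.sum() < 10:
        raise ValueError("need >= 10 unmasked bins")
    corr = correlation_matrix(oe, mask)
    if not np.any(corr):
        raise ValueError("degenerate (rank-0) matrix")
    v = _power_iteration(corr)
    pc1 = np.full(m.n_bins, np.nan)
    pc1[keep] = v
    gc_sub = gc_track[keep]
    if np.ptp(gc_sub) > 0 and np.ptp(v) > 0:
        r = float(np.corrcoef(v, gc_sub)[0, 1])
    else:
        r = 0.0
    if r < 0:
        pc1 = -pc1
        r = -r
    labels = np.where(mask, "masked", np.where(pc1 > 0, "A", "B")).astype(object)
    return CompartmentTrack(
        pc1=pc1, labels=labels, sign_anchor_r=r, weak=bool(r < weak_r_threshold)
    )


def compartment_te_association(
    track: CompartmentTrack, te_fraction_by_bin: dict[str, np.ndarray]
) -> pd.DataFrame:
    """A-vs-B per-class mean TE fraction with a two-sided rank-sum p-value."""
    labels = track.labels
    in_a, in_b = labels == "A", labels == "B"
    if not in_a.any() or not in_b.any():
        raise ValueError("single compartment: cannot compare A vs B")
    rows = []
    for cls, frac in te_fraction_by_bin.items():
        frac = np.asarray(frac, dtype=float)
        a_vals, b_vals = frac[in_a], frac[in_b]
        stat, p = stats.ranksums(a_vals, b_vals)
        rows.append(
            (cls, float(a_vals.mean()), float(b_vals.mean()), float(stat), float(p))
        )
    return pd.DataFrame(rows, columns=["te_class", "mean_A", "mean_B", "z", "p"])


def tad_separation(
    m: ContactMatrix,
    min_depth_bp: int = 300_000,
    max_depth_bp: int = 800_000,
    step_bp: int = 100_000,
    delta: float = 0.01,
    fdr: float = 0.05,
) -> TadBoundarySet:
    """Multi-scale TAD-separation boundaries from diamond means.

    For each bin b and depth d (bins), the score is the mean of the d x d
    square of contacts bridging b (rows b-d..b-1, columns b..b+d-1),
    z-scored per depth and averaged over depths. A boundary is a local
    minimum whose mean drop below the neighboring local maxima is >=
    ``delta`` and whose bridging values are significantly lower than the
    flanking intra-domain values (one-sided rank-sum, Benjamini-Hochberg
    at ``fdr``). Depths are rounded up to at least one bin. The score is
    invariant to global scaling of the matrix.
    """
    import warnings

    v = m.values.astype(float)
    n = m.n_bins
    res = m.resolution
    oe, _ = oe_normalize(m)  # distance-normalized values for the boundary test
    depths = sorted(
        {max(1, -(-d // res)) for d in range(min_depth_bp, max_depth_bp + 1, step_bp)}
    )
    max_d = max(depths)
    score_by_d = np.full((len(depths), n), np.nan)
    for di, d in enumerate(depths):
        for b in range(d, n - d + 1):
            if b + d > n:
                continue
            score_by_d[di, b] = v[b - d : b, b : b + d].mean()
    # z-transform per depth (scale invariance); constant scores -> zeros
    z = np.full_like(score_by_d, np.nan)
    for di in range(len(depths)):
        row = score_by_d[di]
        finite = np.isfinite(row)
        if finite.sum() == 0:
            continue
        sd = row[finite].std()
        if sd == 0:
            z[di, finite] = 0.0
        else:
            z[di, finite] = (row[finite] - row[finite].mean()) / sd
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        score = np.nanmean(z, axis=0)

    valid = np.isfinite(score)
    idx = np.where(valid)[0]
    if len(idx) < 3:
        return TadBoundarySet([], score, delta, {})
    s = score[idx]
    minima = [
        i for i in range(1, len(s) - 1) if s[i] <= s[i - 1] and s[i] <= s[i + 1]
        and (s[i] < s[i - 1] or s[i] < s[i + 1])
    ]
    maxima = [
        i for i in range(1, len(s) - 1) if s[i] >= s[i - 1] and s[i] >= s[i + 1]
        and (s[i] > s[i - 1] or s[i] > s[i + 1])
    ]
    candidates = []
    for i in minima:
        left_m = [j for j in maxima if j < i]
        right_m = [j for j in maxima if j > i]
        lmax = s[left_m[-1]] if left_m else s[0]
        rmax = s[right_m[0]] if right_m else s[-1]
        depth_drop = (lmax - s[i] + rmax - s[i]) / 2.0
        if depth_drop >= delta:
            candidates.append(idx[i])
    # Significance: distance-normalized (O/E) diamond values vs flanking
    # intra-domain values, so the decay profile cancels and only a genuine
    # depletion across the bin registers.
    pvals = []
    for b in candidates:
        d = min(max_d, b, n - b)
        diamond = oe[b - d : b, b : b + d].ravel()
        intra = np.concatenate(
            [
                oe[b - d : b, b - d : b][np.triu_indices(d, 1)],
                oe[b : b + d, b : b + d][np.triu_indices(d, 1)],
            ]
        )
        pooled = np.concatenate([diamond, intra])
        if len(diamond) == 0 or len(intra) == 0 or np.ptp(pooled) == 0:
            pvals.append(1.0)
            continue
        stat, p = stats.mannwhitneyu(diamond, intra, alternative="less")
        pvals.append(float(p))
    if candidates:
        _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    else:
        qvals = []
    kept = [(b, q) for b, q in zip(candidates, qvals) if q <= fdr]
    # merge boundaries closer than the smallest depth, keeping the deeper minimum
    kept.sort()
    boundaries: list[int] = []
    for b, _q in kept:
        if boundaries and b - boundaries[-1] < min(depths):
            if score[b] < score[boundaries[-1]]:
                boundaries[-1] = b
        else:
            boundaries.append(b)
    return TadBoundarySet(
        boundaries=[int(b) for b in boundaries],
        score=score,
        delta=delta,
        qvalues={int(b): float(q) for b, q in zip(candidates, qvals)},
    )


def classify_bins(
    line_fraction: np.ndarray,
    sine_fraction: np.ndarray,
    quantile: float = 0.75,
) -> BinClassTrack:
    """Label bins LINE-rich / SINE-rich / neutral by class quantile and dominance.

    A bin is LINE-rich iff its LINE bp fraction reaches the genome-wide
    LINE quantile and strictly exceeds its SINE fraction (symmetrically
    for SINE); everything else, including exact ties, is neutral.
    """
    lf = np.asarray(line_fraction, dtype=float)
    sf = np.asarray(sine_fraction, dtype=float)
    lq = np.quantile(lf, quantile)
    sq = np.quantile(sf, quantile)
    labels = np.full(len(lf), "neutral", dtype=object)
    labels[(lf >= lq) & (lf > sf)] = "LINE-rich"
    labels[(sf >= sq) & (sf > lf)] = "SINE-rich"
    return BinClassTrack(labels=labels, line_fraction=lf, sine_fraction=sf)


def homotypic_stats(
    corr: np.ndarray, track: BinClassTrack, mask: np.ndarray | None = None
) -> dict[str, HomotypicStats]:
    """Sign and magnitude of correlations between class-labeled bin pairs.

    Off-diagonal unmasked pairs are grouped as LINE-LINE, SINE-SINE and
    LINE-SINE; each group reports its pair count, fraction of positive
    correlations and mean correlation.
    """
    n = corr.shape[0]
    if mask is None:
        mask = np.zeros(n, dtype=bool)
    labels = track.labels
    groups = {"LINE-LINE": [], "SINE-SINE": [], "LINE-SINE": []}
    rich = {"LINE-rich": "LINE", "SINE-rich": "SINE"}
    for i in range(n):
        if mask[i] or labels[i] not in rich:
            continue
        for j in range(i + 1, n):
            if mask[j] or labels[j] not in rich:
                continue
            pair = sorted((rich[labels[i]], rich[labels[j]]))
            groups[f"{pair[0]}-{pair[1]}"].append(corr[i, j])
    out = {}
    for name, vals in groups.items():
        arr = np.asarray(vals, dtype=float)
        out[name] = HomotypicStats(
            pair_type=name,
            n_pairs=len(arr),
            fraction_positive=float((arr > 0).mean()) if len(arr) else np.nan,
            mean_correlation=float(arr.mean()) if len(arr) else np.nan,
        )
    return out


def feature_overlap(
    features: IntervalSet,
    track: BinClassTrack,
    resolution: int,
    chrom: str | None = None,
) -> pd.DataFrame:
    """Fractions of TADs/loops falling in LINE-rich vs SINE-rich bins.

    A span feature is assigned by the majority of its bp over labeled
    bins (exact tie -> "mixed"); a loop is assigned by its two anchors'
    bin labels (both LINE-rich -> LINE-rich etc., otherwise mixed).
    """
    counts = {"LINE-rich": 0, "SINE-rich": 0, "neutral": 0, "mixed": 0}
    n_bins = len(track.labels)

    def bp_by_label(c, s, e):
        acc = {"LINE-rich": 0, "SINE-rich": 0, "neutral": 0}
        for b in range(s // resolution, min((e - 1) // resolution + 1, n_bins)):
            ov = min(e, (b + 1) * resolution) - max(s, b * resolution)
            acc[track.labels[b]] += ov
        return acc

    n_features = 0
    if features.anchor_pairs:
        for (c1, s1, e1), (c2, s2, e2) in features.anchor_pairs:
            if chrom is not None and (c1 != chrom or c2 != chrom):
                continue
            b1 = min((s1 + e1) // 2 // resolution, n_bins - 1)
            b2 = min((s2 + e2) // 2 // resolution, n_bins - 1)
            l1, l2 = track.labels[b1], track.labels[b2]
            counts[l1 if l1 == l2 else "mixed"] += 1
            n_features += 1
    else:
        for c, s, e in features.intervals:
            if chrom is not None and c != chrom:
                continue
            acc = bp_by_label(c, s, e)
            rich = {k: acc[k] for k in ("LINE-rich", "SINE-rich")}
            best = max(rich.values())
            if best == 0:
                counts["neutral"] += 1
            elif rich["LINE-rich"] == rich["SINE-rich"]:
                counts["mixed"] += 1
            else:
                counts[max(rich, key=rich.get)] += 1
            n_features += 1
    rows = [
        (lbl, cnt, cnt / n_features if n_features else 0.0)
        for lbl, cnt in counts.items()
    ]
    return pd.DataFrame(rows, columns=["label", "n_features", "proportion"])
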