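"""Windowed TE distribution statistics, randomness tests and block detection.

Per-window occupancy apportions each element's length to the windows it
intersects; element *counts* go to the window holding the midpoint, so the
two views answer "how much sequence" and "how many elements" separately.
Spatial randomness along a chromosome is assessed with the Wald-Wolfowitz
runs test on a median-split binarization of window counts, and dense
same-class clusters are reported as blocks (runs of >=5 elements with all
consecutive gaps <=1 kb).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GenomeIndex, TECopy

__all__ = [
    "RunsTestResult",
    "Block",
    "window_stats",
    "runs_test",
    "randomness_by_chromosome",
    "proximity_distribution",
    "detect_blocks",
    "dispersion_summary",
    "chromosome_proportion_test",
]


@dataclass(frozen=True)
class RunsTestResult:
    R: int
    n1: int
    n2: int
    mu_R: float
    sigma_R: float
    z: float
    p_two_sided: float
    degenerate: bool = False


@dataclass(frozen=True)
class Block:
    chrom: str
    start: int
    end: int
    te_class: str
    n_elements: int


def window_stats(
    tes: list[TECopy],
    genome: GenomeIndex,
    window_bp: int = 250_000,
    te_classes: tuple[str, ...] = ("LINE", "SINE"),
) -> pd.DataFrame:
    """Per-window element counts, occupied bp and window fraction per class.

    Element bp is split across overlapping windows by intersection length
    (conserving total TE bp); the count goes to the midpoint's window.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    rows = []
    for chrom in genome.chroms:
        length = genome[chrom]
        n_win = -(-length // window_bp)
        for w in range(n_win):
            rows.append((chrom, w * window_bp, min((w + 1) * window_bp, length)))
    df = pd.DataFrame(rows, columns=["chrom", "window_start", "window_end"])
    key = {(r.chrom, r.window_start // window_bp): i for i, r in df.iterrows()}

    counts = {c: np.zeros(len(df), dtype=int) for c in te_classes}
    bps = {c: np.zeros(len(df), dtype=float) for c in te_classes}
    for te in tes:
        if te.chrom not in genome:
            raise ValueError(f"TE {te.copy_id} on unknown chromosome {te.chrom!r}")
        if te.te_class not in counts:
            continue
        w_lo, w_hi = te.start // window_bp, (te.end - 1) // window_bp
        for w in range(w_lo, w_hi + 1):
            ov = min(te.end, (w + 1) * window_bp) - max(te.start, w * window_bp)
            bps[te.te_class][key[(te.chrom, w)]] += ov
        counts[te.te_class][key[(te.chrom, te.midpoint // window_bp)]] += 1

    for c in te_classes:
        df[f"{c}_count"] = counts[c]
        df[f"{c}_bp"] = bps[c]
        df[f"{c}_fraction"] = bps[c] / (df["window_end"] - df["window_start"])
    return df


def runs_test(binary_sequence) -> RunsTestResult:
    """Wald-Wolfowitz runs test with the normal approximation.

    z = (R - mu_R)/sigma_R with mu_R = 2 n1 n2/(n1+n2) + 1 and
    sigma_R^2 = 2 n1 n2 (2 n1 n2 - n1 - n2) / ((n1+n2)^2 (n1+n2-1)).
    """
    seq = list(binary_sequence)
    symbols = sorted(set(seq))
    if len(symbols) != 2:
        raise ValueError(
            f"runs test needs exactly two symbols with n1,n2 > 0; got {symbols}"
        )
    n1 = sum(1 for s in seq if s == symbols[0])
    n2 = len(seq) - n1
    R = 1 + sum(1 for a, b in zip(seq, seq[1:]) if a != b)
    n = n1 + n2
    mu = 2.0 * n1 * n2 / n + 1.0
    var = 2.0 * n1 * n2 * (2.0 * n1 * n2 - n) / (n**2 * (n - 1.0))
    sigma = np.sqrt(var)
    z = (R - mu) / sigma
    p = 2.0 * stats.norm.sf(abs(z))
    return RunsTestResult(R, n1, n2, mu, sigma, float(z), float(p))


def randomness_by_chromosome(
    wstats: pd.DataFrame, te_class: str
) -> dict[str, RunsTestResult]:
    """Per-chromosome runs test on window counts split at the chrom median.

    Windows above the chromosome's median count code 1, ties and below
    code 0. A chromosome whose binarization is single-valued (all counts
    equal) yields a degenerate result rather than a p-value.
    """
    col = f"{te_class}_count"
    out: dict[str, RunsTestResult] = {}
    for chrom, sub in wstats.groupby("chrom", sort=False):
        counts = sub.sort_values("window_start")[col].to_numpy()
        if len(counts) < 2:
            raise ValueError(f"{chrom}: need >= 2 windows")
        binar = (counts > np.median(counts)).astype(int)
        if binar.min() == binar.max():
            out[chrom] = RunsTestResult(
                R=1, n1=len(binar), n2=0, mu_R=np.nan, sigma_R=np.nan,
                z=np.nan, p_two_sided=np.nan, degenerate=True,
            )
        else:
            out[chrom] = runs_test(binar)
    return out


def proximity_distribution(
    tes: list[TECopy],
    te_class: str,
    bins: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-chromosome proportions of gaps between consecutive same-class TEs.

    Gap = next.start - current.end, clamped at 0 for overlaps. Bins are
    half-open [lo, hi) with a final open-ended bin; proportions sum to 1
    per chromosome.
    """
    if bins is None:
        bins = np.arange(0, 2001, 200)
    edges = np.append(np.asarray(bins, dtype=float), np.inf)
    rows = []
    by_chrom: dict[str, list[TECopy]] = {}
    for te in tes:
        if te.te_class == te_class:
            by_chrom.setdefault(te.chrom, []).append(te)
    for chrom, elems in by_chrom.items():
        elems.sort(key=lambda t: (t.start, t.end))
        gaps = np.array(
            [max(0, b.start - a.end) for a, b in zip(elems, elems[1:])], dtype=float
        )
        if len(gaps) == 0:
            continue
        hist, _ = np.histogram(gaps, bins=edges)
        props = hist / hist.sum()
        for lo, p in zip(edges[:-1], props):
            rows.append((chrom, lo, p))
    return pd.DataFrame(rows, columns=["chrom", "bin_start", "proportion"])


def detect_blocks(
    tes: list[TECopy],
    te_class: str,
    max_gap: int = 1000,
    min_elements: int = 5,
) -> list[Block]:
    """Maximal runs of same-class elements with gaps <= max_gap, length >= min_elements.

    A block spans from the first member's start to the last member's end.
    Input order is irrelevant; elements are sorted per chromosome.
    """
    by_chrom: dict[str, list[TECopy]] = {}
    for te in tes:
        if te.te_class == te_class:
            by_chrom.setdefault(te.chrom, []).append(te)
    blocks: list[Block] = []
    for chrom in sorted(by_chrom):
        elems = sorted(by_chrom[chrom], key=lambda t: (t.start, t.end))
        run_start = 0
        for i in range(1, len(elems) + 1):
            gap_break = i == len(elems) or max(
                0, elems[i].start - elems[i - 1].end
            ) > max_gap
            if gap_break:
                run = elems[run_start:i]
                if len(run) >= min_elements:
                    blocks.append(
                        Block(
                            chrom=chrom,
                            start=run[0].start,
                            end=max(t.end for t in run),
                            te_class=te_class,
                            n_elements=len(run),
                        )
                    )
                run_start = i
    return blocks


def dispersion_summary(
    wstats: pd.DataFrame, te_classes: tuple[str, ...] = ("LINE", "SINE")
) -> pd.DataFrame:
    """Per-chromosome sample SD (ddof=1) of window counts and bp per class."""
    rows = []
    for chrom, sub in wstats.groupby("chrom", sort=False):
        for c in te_classes:
            rows.append(
                (
                    chrom,
                    c,
                    float(sub[f"{c}_count"].std(ddof=1)),
                    float(sub[f"{c}_bp"].std(ddof=1)),
                )
            )
    return pd.DataFrame(rows, columns=["chrom", "te_class", "sd_count", "sd_bp"])


def chromosome_proportion_test(
    proportions: np.ndarray, uniform_value: float | None = None
) -> tuple[float, float]:
    """One-sample t-test of per-chromosome TE proportions against a uniform value.

    ``uniform_value`` is the proportion a perfectly uniform genome would
    show on every chromosome — normally the genome-wide (length-weighted)
    TE proportion. When omitted the unweighted mean is used, which reduces
    the test to its degenerate t=0 center. Zero variance gives t=0, p=1.
    """
    x = np.asarray(proportions, dtype=float)
    if len(x) < 2:
        raise ValueError("need >= 2 chromosomes")
    if np.ptp(x) == 0:
        return 0.0, 1.0
    popmean = float(x.mean()) if uniform_value is None else float(uniform_value)
    t, p = stats.ttest_1samp(x, popmean=popmean)
    return float(t), float(p)
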