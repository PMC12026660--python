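"""Consensus building, Kimura 2-parameter distances and insertion ages.

A copy's divergence from its subfamily consensus is summarized as
K = -1/2 ln((1 - 2P - Q) sqrt(1 - 2Q)), with P and Q the transition and
transversion fractions over comparable (non-gap, non-N) columns, then
converted to years as T = K / mu with a default neutral rate of
mu = 2.2e-9 substitutions/site/year — the consensus is treated as the
ancestral active element so divergence accrues along a single lineage.
Subfamilies with a copy younger than 15 My and more than 10 copies are
flagged putatively active.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import TECopy

__all__ = [
    "AlignedPair",
    "K2PResult",
    "AgeModel",
    "majority_consensus",
    "k2p",
    "age_from_divergence",
    "divergence_landscape",
    "classify_putatively_active",
]

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}
_GAPLIKE = {"-", "N"}


@dataclass(frozen=True)
class AlignedPair:
    copy_seq: str
    cons_seq: str

    def __post_init__(self) -> None:
        if len(self.copy_seq) != len(self.cons_seq):
            raise ValueError("aligned sequences must have equal length")


@dataclass(frozen=True)
class K2PResult:
    P: float
    Q: float
    K: float  # nan when saturated
    n_sites: int
    saturated: bool = False


@dataclass(frozen=True)
class AgeModel:
    mu: float = 2.2e-9  # substitutions/site/year
    active_age_cutoff_my: float = 15.0
    active_min_copies: int = 10

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError("mu must be positive")


def majority_consensus(aligned_copies: list[str]) -> str:
    """Majority-rule column consensus over equal-length aligned copies.

    Columns with gap fraction > 0.5 are dropped; among non-gap bases the
    most frequent wins, ties resolved by the fixed order A < C < G < T.
    """
    if len(aligned_copies) < 2:
        raise ValueError("need >= 2 aligned sequences")
    length = len(aligned_copies[0])
    if any(len(s) != length for s in aligned_copies):
        raise ValueError("aligned sequences must have equal length")
    out = []
    for col in zip(*(s.upper() for s in aligned_copies)):
        gaps = sum(1 for b in col if b == "-")
        if gaps / len(col) > 0.5:
            continue
        counts = {b: 0 for b in "ACGT"}
        for b in col:
            if b in counts:
                counts[b] += 1
        if sum(counts.values()) == 0:
            continue
        best = max("ACGT", key=lambda b: (counts[b], ))  # ties: first in ACGT order
        # max() keeps the first maximum in iteration order A,C,G,T
        out.append(best)
    return "".join(out)


def k2p(pair: AlignedPair, exclude_cpg: bool = False) -> K2PResult:
    """Kimura 2-parameter distance between an aligned copy and its consensus.

    When ``exclude_cpg`` is set, both positions of every CpG dinucleotide
    in the consensus are ignored (hypermutable sites). The distance is
    flagged saturated (K = nan) when 1-2P-Q <= 0 or 1-2Q <= 0.
    """
    a, b = pair.copy_seq.upper(), pair.cons_seq.upper()
    skip = set()
    if exclude_cpg:
        for i in range(len(b) - 1):
            if b[i] == "C" and b[i + 1] == "G":
                skip.update((i, i + 1))
    n = ts = tv = 0
    for i, (x, y) in enumerate(zip(a, b)):
        if i in skip or x in _GAPLIKE or y in _GAPLIKE:
            continue
        n += 1
        if x == y:
            continue
        if (x in PURINES) == (y in PURINES):
            ts += 1
        else:
            tv += 1
    if n == 0:
        raise ValueError("no comparable columns")
    P, Q = ts / n, tv / n
    w1, w2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        return K2PResult(P, Q, math.nan, n, saturated=True)
    return K2PResult(P, Q, -0.5 * math.log(w1 * math.sqrt(w2)), n)


def age_from_divergence(K: float, model: AgeModel = AgeModel()) -> float:
    """Insertion age in years, T = K / mu."""
    if K < 0:
        raise ValueError("K must be >= 0")
    return K / model.mu


def divergence_landscape(
    tes_with_k: list[tuple[TECopy, float]],
    bin_width_pct: float = 5.0,
) -> pd.DataFrame:
    """Genome bp per family in half-open percent-divergence bins [0,5), [5,10)...

    Saturated (nan) distances are excluded and reported in the
    ``saturated_bp`` attribute of the returned frame.
    """
    finite = [(te, k) for te, k in tes_with_k if np.isfinite(k)]
    saturated_bp = sum(te.length for te, k in tes_with_k if not np.isfinite(k))
    max_pct = max((100.0 * k for _, k in finite), default=0.0)
    n_bins = max(1, int(math.floor(max_pct / bin_width_pct)) + 1)
    families = sorted({te.family for te, _ in finite})
    mat = np.zeros((n_bins, len(families)))
    fam_idx = {f: i for i, f in enumerate(families)}
    for te, k in finite:
        b = min(int(100.0 * k // bin_width_pct), n_bins - 1)
        mat[b, fam_idx[te.family]] += te.length
    df = pd.DataFrame(
        mat,
        index=[bin_width_pct * i for i in range(n_bins)],
        columns=families,
    )
    df.index.name = "bin_start_pct"
    df.attrs["saturated_bp"] = saturated_bp
    return df


def classify_putatively_active(
    min_age_my: float, n_copies: int, model: AgeModel = AgeModel()
) -> bool:
    """Active iff the youngest copy is under the age cutoff and copy count > minimum."""
    return (min_age_my < model.active_age_cutoff_my) and (
        n_copies > model.active_min_copies
    )
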