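"""Synthetic genomes, TE landscapes, contact maps, methylation and counts.

Each generator emulates the statistical structure the downstream analysis
assumes — windowed GC heterogeneity, Kimura-model copy divergence,
GC-biased insertion placement, plaid compartments with block TADs,
age-dependent CpG methylation and negative-binomial time-course counts —
with the planted ground truth returned alongside, so every analysis stage
can be tested against a known answer. All generators are deterministic
given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import ContactMatrix, CountMatrix, GenomeIndex, MethylSite, TECopy

__all__ = [
    "MutationConfig",
    "PlaidConfig",
    "ExprSimConfig",
    "FamilySpec",
    "simulate_genome",
    "mutate_consensus",
    "plant_te_landscape",
    "simulate_contact_matrix",
    "simulate_methylation",
    "simulate_counts",
]

BASES = np.array(list("ACGT"))
# Kimura-model substitution partners: index by base, [transition, tv1, tv2]
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


@dataclass
class MutationConfig:
    """Kimura-style divergence: expected substitutions/site and ts/tv ratio."""

    target_K: float
    kappa: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_K < 0:
            raise ValueError("target_K must be >= 0")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")


@dataclass
class PlaidConfig:
    """Plaid compartment + block-TAD contact-matrix generator settings."""

    n_bins: int
    compartments: np.ndarray  # a_i in {+1, -1}
    plaid_strength: float = 0.2  # rho
    decay_exponent: float = 1.0  # gamma
    tad_boundaries: list[int] = field(default_factory=list)
    tad_boost: float = 1.0
    noise_mean_scale: float = 1000.0  # adjacent-bin contact depth typical of 100 kb maps
    seed: int = 0

    def __post_init__(self) -> None:
        self.compartments = np.asarray(self.compartments)
        if len(self.compartments) != self.n_bins:
            raise ValueError("compartment vector length must equal n_bins")
        if not set(np.unique(self.compartments)) <= {-1, 1}:
            raise ValueError("compartments must be +1/-1")
        if not (0 <= self.plaid_strength < 1):
            raise ValueError("plaid_strength must be in [0,1)")
        if self.decay_exponent <= 0:
            raise ValueError("decay_exponent must be > 0")
        if self.tad_boost < 1:
            raise ValueError("tad_boost must be >= 1")
        if sorted(self.tad_boundaries) != list(self.tad_boundaries) or any(
            not (0 < b < self.n_bins) for b in self.tad_boundaries
        ):
            raise ValueError("tad_boundaries must be sorted, within (0, n_bins)")


@dataclass
class ExprSimConfig:
    """Negative-binomial count simulator for a tissue x stage x replicate design."""

    n_features: int = 2000
    n_planted: int = 100
    tissues: tuple[str, ...] = ("dorsal", "abdominal")
    stages: tuple[str, ...] = ("I", "II", "III")
    n_replicates: int = 3
    effect_log2fc: float = 1.0  # tissue effect at the first stage, decaying linearly
    nb_dispersion: float = 0.1
    lib_size: float = 1.0e6
    base_mean: float = 100.0
    feature_length_bp: tuple[int, int] = (300, 3000)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_planted > self.n_features:
            raise ValueError("planted ids must be a subset of features")


@dataclass
class FamilySpec:
    """One planted TE family: a consensus, copy count, age and GC placement bias."""

    name: str
    te_class: str  # LINE or SINE
    consensus: str
    n_copies: int
    age_my: float
    gc_bias_sign: int = 0  # +1 toward GC-rich windows, -1 toward AT-rich, 0 uniform
    gc_bias_strength: float = 20.0  # softmax inverse temperature on window GC


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=n, p=p)


def simulate_genome(
    chrom_lengths: dict[str, int],
    gc_profile: dict[str, np.ndarray] | float,
    window: int = 10_000,
    seed: int = 0,
) -> tuple[dict[str, str], GenomeIndex]:
    """I.i.d. bases per window with a per-window target GC fraction.

    ``gc_profile`` is either a single GC fraction or a per-chromosome array
    of one target per window (last window may be partial).
    """
    rng = np.random.default_rng(seed)
    seqs: dict[str, str] = {}
    for chrom, length in chrom_lengths.items():
        n_windows = -(-length // window)
        if isinstance(gc_profile, dict):
            targets = np.asarray(gc_profile[chrom], dtype=float)
            if len(targets) != n_windows:
                raise ValueError(
                    f"{chrom}: gc_profile has {len(targets)} windows, need {n_windows}"
                )
        else:
            targets = np.full(n_windows, float(gc_profile))
        if ((targets <= 0) | (targets >= 1)).any():
            raise ValueError("target GC must lie strictly inside (0,1)")
        codes = np.empty(length, dtype=int)
        for w in range(n_windows):
            lo, hi = w * window, min((w + 1) * window, length)
            codes[lo:hi] = _random_seq(rng, hi - lo, targets[w])
        seqs[chrom] = "".join(BASES[codes])
    return seqs, GenomeIndex.from_sequences(seqs)


# ---------------------------------------------------------------------------
# Divergence / mutation
# ---------------------------------------------------------------------------

def mutate_consensus(consensus_seq: str, cfg: MutationConfig) -> str:
    """Diverge a copy from its consensus under the two-parameter model.

    Each site receives a Poisson(``target_K``) number of substitution
    events; each event is a transition with probability kappa/(kappa+2) and
    each of the two transversions with probability 1/(kappa+2). Multiple
    hits at a site are allowed, so distance estimators must genuinely
    correct for them.
    """
    rng = np.random.default_rng(cfg.seed)
    seq = list(consensus_seq.upper())
    n_events = rng.poisson(cfg.target_K, size=len(seq))
    p_ts = cfg.kappa / (cfg.kappa + 2.0) if np.isfinite(cfg.kappa) else 1.0
    for i, k in enumerate(n_events):
        base = seq[i]
        if base not in _TRANSITION:
            continue
        for _ in range(k):
            u = rng.random()
            if u < p_ts:
                base = _TRANSITION[base]
            else:
                tv = _TRANSVERSIONS[base]
                base = tv[0] if (u - p_ts) < (1 - p_ts) / 2 else tv[1]
        seq[i] = base
    return "".join(seq)


# ---------------------------------------------------------------------------
# TE landscape planting
# ---------------------------------------------------------------------------

def _window_gc(seq: str, window: int) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype="S1")
    is_gc = (arr == b"G") | (arr == b"C")
    n = len(seq)
    n_windows = -(-n // window)
    gc = np.empty(n_windows)
    for w in range(n_windows):
        lo, hi = w * window, min((w + 1) * window, n)
        gc[w] = is_gc[lo:hi].mean()
    return gc


def plant_te_landscape(
    genome: dict[str, str],
    family_specs: list[FamilySpec],
    mu: float = 2.2e-9,
    window: int = 10_000,
    seed: int = 0,
) -> tuple[dict[str, str], list[TECopy]]:
    """Insert diverged TE copies into a genome with GC-biased placement.

    Copies of each family are mutated away from the family consensus to
    ``target_K = age_my * 1e6 * mu`` and written over genome windows chosen
    by a softmax over window GC (sign and strength from the family spec), so
    coordinates of unrelated features stay fixed. Returns the modified
    genome and the ground-truth annotation; ``divergence_pct`` holds the
    planted target divergence (x100).
    """
    rng = np.random.default_rng(seed)
    seqs = {c: list(s) for c, s in genome.items()}
    chroms = list(genome)
    win_gc = {c: _window_gc(genome[c], window) for c in chroms}
    # flat window table: (chrom index, window index, gc, free cursor)
    flat = [
        (ci, wi, win_gc[c][wi])
        for ci, c in enumerate(chroms)
        for wi in range(len(win_gc[c]))
    ]
    gc_arr = np.array([g for _, _, g in flat])
    cursors = np.array(
        [flat_wi * window for _, flat_wi, _ in flat], dtype=int
    )  # next free position within each window (absolute)
    limits = np.array(
        [
            min((wi + 1) * window, len(genome[chroms[ci]]))
            for ci, wi, _ in flat
        ],
        dtype=int,
    )

    tes: list[TECopy] = []
    counter = 0
    for spec in family_specs:
        target_k = spec.age_my * 1e6 * mu
        if spec.gc_bias_sign == 0:
            logits = np.zeros(len(flat))
        else:
            logits = spec.gc_bias_sign * spec.gc_bias_strength * gc_arr
        copy_len = len(spec.consensus)
        for _ in range(spec.n_copies):
            free = (limits - cursors) >= copy_len + 1
            if not free.any():
                raise ValueError("genome too small for requested copies")
            w = np.exp(logits - logits[free].max())
            w[~free] = 0.0
            idx = rng.choice(len(flat), p=w / w.sum())
            ci = flat[idx][0]
            chrom = chroms[ci]
            pos = int(cursors[idx])
            cursors[idx] = pos + copy_len + 1  # 1 bp spacer between copies
            copy_seq = mutate_consensus(
                spec.consensus,
                MutationConfig(target_k, seed=int(rng.integers(2**31))),
            )
            strand = "+" if rng.random() < 0.5 else "-"
            seqs[chrom][pos : pos + copy_len] = list(copy_seq)
            counter += 1
            tes.append(
                TECopy(
                    copy_id=f"{spec.te_class}_{counter}",
                    chrom=chrom,
                    start=pos,
                    end=pos + copy_len,
                    strand=strand,
                    te_class=spec.te_class,
                    family=spec.name,
                    consensus_id=spec.name,
                    divergence_pct=min(100.0, 100.0 * target_k),
                )
            )
    return {c: "".join(s) for c, s in seqs.items()}, tes


# ---------------------------------------------------------------------------
# Hi-C
# ---------------------------------------------------------------------------

def expected_plaid_matrix(cfg: PlaidConfig) -> np.ndarray:
    """Noise-free expectation of the plaid/TAD contact model."""
    n = cfg.n_bins
    i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    decay = (1.0 + np.abs(i - j)) ** (-cfg.decay_exponent)
    plaid = 1.0 + cfg.plaid_strength * np.outer(cfg.compartments, cfg.compartments)
    edges = [0, *cfg.tad_boundaries, n]
    domain = np.zeros(n, dtype=int)
    for d, (lo, hi) in enumerate(zip(edges, edges[1:])):
        domain[lo:hi] = d
    same_tad = (domain[:, None] == domain[None, :]).astype(float)
    boost = cfg.tad_boost**same_tad
    return cfg.noise_mean_scale * decay * plaid * boost


def simulate_contact_matrix(cfg: PlaidConfig) -> ContactMatrix:
    """Poisson-sampled symmetric contact matrix from the plaid/TAD model."""
    rng = np.random.default_rng(cfg.seed)
    mean = expected_plaid_matrix(cfg)
    upper = rng.poisson(np.triu(mean))
    values = np.triu(upper) + np.triu(upper, 1).T
    return ContactMatrix(chrom="chrS", resolution=100_000, values=values.astype(float))


# ---------------------------------------------------------------------------
# Methylation
# ---------------------------------------------------------------------------

def simulate_methylation(
    te_copies: list[TECopy],
    ages_my: np.ndarray,
    base_level: float = 0.9,
    age_slope: float = 0.008,  # methylation lost per My of age
    noise_sd: float = 0.05,
    site_spacing: int = 50,
    genome_index: GenomeIndex | None = None,
    n_background: int = 0,
    background_means: tuple[float, float] = (0.1, 0.9),
    background_weights: tuple[float, float] = (0.5, 0.5),
    background_sd: float = 0.05,
    coverage: int = 20,
    seed: int = 0,
) -> list[MethylSite]:
    """Age-dependent CpG methylation over TEs plus a bimodal background.

    Each TE gets one site every ``site_spacing`` bp with fraction
    ``clamp(base_level - age_slope * age_my + N(0, noise_sd), 0, 1)``;
    background sites are drawn from a two-component normal mixture,
    mimicking the genome-wide low/high methylation bimodality.
    """
    if len(ages_my) != len(te_copies):
        raise ValueError("ages_my must align with te_copies")
    rng = np.random.default_rng(seed)
    sites: list[MethylSite] = []
    for te, age in zip(te_copies, ages_my):
        positions = range(te.start, te.end, site_spacing)
        for pos in positions:
            frac = base_level - age_slope * age + rng.normal(0.0, noise_sd)
            sites.append(
                MethylSite(te.chrom, pos, coverage, float(np.clip(frac, 0.0, 1.0)))
            )
    if n_background and genome_index is not None:
        te_spans: dict[str, list[tuple[int, int]]] = {}
        for te in te_copies:
            te_spans.setdefault(te.chrom, []).append((te.start, te.end))
        chroms = genome_index.chroms
        lens = np.array([genome_index[c] for c in chroms], dtype=float)
        for _ in range(n_background):
            ci = rng.choice(len(chroms), p=lens / lens.sum())
            chrom = chroms[ci]
            pos = int(rng.integers(genome_index[chrom]))
            if any(s <= pos < e for s, e in te_spans.get(chrom, [])):
                continue
            comp = rng.random() >= background_weights[0]
            frac = rng.normal(background_means[int(comp)], background_sd)
            sites.append(MethylSite(chrom, pos, coverage, float(np.clip(frac, 0, 1))))
    return sites


# ---------------------------------------------------------------------------
# Counts
# ---------------------------------------------------------------------------

def simulate_counts(cfg: ExprSimConfig) -> tuple[CountMatrix, list[str]]:
    """Negative-binomial counts for a tissue x stage x replicate design.

    The first ``n_planted`` features carry a tissue x stage interaction on
    the log scale: a tissue effect of ``effect_log2fc`` log2-units at the
    first stage, decaying linearly to zero by the last stage. All other
    features are flat (library-size differences only). Returns the count
    matrix and the list of planted feature ids.
    """
    rng = np.random.default_rng(cfg.seed)
    samples = []
    meta_rows = []
    for tissue in cfg.tissues:
        for s_idx, stage in enumerate(cfg.stages):
            for rep in range(1, cfg.n_replicates + 1):
                samples.append(f"{tissue}_{stage}_r{rep}")
                meta_rows.append((tissue, stage, rep, s_idx))
    import pandas as pd

    meta = pd.DataFrame(
        meta_rows, columns=["tissue", "stage", "replicate", "stage_idx"], index=samples
    )
    n_s = len(samples)
    feature_ids = [f"TE_{i:05d}" for i in range(cfg.n_features)]
    planted = feature_ids[: cfg.n_planted]
    lengths = rng.integers(*cfg.feature_length_bp, size=cfg.n_features)

    base = rng.lognormal(mean=np.log(cfg.base_mean), sigma=0.5, size=cfg.n_features)
    t = meta["stage_idx"].to_numpy()
    g = (meta["tissue"] == cfg.tissues[0]).to_numpy().astype(float)
    n_stages = len(cfg.stages)
    # planted profile: a degree-2 stage trajectory shared by both tissues plus
    # a tissue effect of effect_log2fc at the first stage decaying to zero by
    # the last, both on the log2 scale
    ts = t / max(n_stages - 1, 1)  # stage scaled to [0,1]
    stage_curve = 1.0 - 1.5 * ts - 0.5 * ts**2  # 1, 0.125, -1 at stages I..III
    decay = 1.0 - ts
    log2fc = np.zeros((cfg.n_features, n_s))
    log2fc[: cfg.n_planted] = cfg.effect_log2fc * (stage_curve + g * decay)[None, :]
    mean = (cfg.lib_size / 1.0e6) * base[:, None] * 2.0**log2fc

    if cfg.nb_dispersion <= 0:
        counts = rng.poisson(mean)
    else:
        shape = 1.0 / cfg.nb_dispersion
        lam = rng.gamma(shape, mean / shape)
        counts = rng.poisson(lam)
    return (
        CountMatrix(
            feature_ids=feature_ids,
            feature_lengths=lengths,
            sample_ids=samples,
            counts=counts,
            sample_meta=meta,
        ),
        planted,
    )
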