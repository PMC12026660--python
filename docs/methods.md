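# Methods

## Scope and data model

All coordinates are 0-based, half-open, converted at the I/O boundary
from the 1-based inclusive conventions of RepeatMasker `.out` and GFF3.
RepeatMasker strand `C` maps to `-`; records whose class is not LINE or
SINE (including "Unknown") carry `te_class="other"` and are excluded
from LINE/SINE statistics unless a user-supplied map reassigns them.
Gene models keep the longest transcript per gene. Contact matrices are
symmetric per-chromosome bin matrices with `n_bins = ceil(length /
resolution)`; methylation input is one record per CpG with coverage and
methylated-read fraction in [0, 1].

## Divergence dating

The Kimura 2-parameter distance is computed over comparable columns
(both bases in {A,C,G,T}): K = −½ ln[(1−2P−Q)√(1−2Q)]. Distances with
1−2P−Q ≤ 0 or 1−2Q ≤ 0 are flagged saturated and excluded from
landscapes and age summaries (reported separately as bp). Age is T =
K/μ, μ = 2.2 × 10⁻⁹ substitutions/site/year by default: the consensus is
treated as the ancestral sequence, so divergence accrues along one
lineage. Whether dating should instead use K/(2μ) is a modeling choice
exposed only through μ itself; K/μ is the standard TE-dating convention
and the default. Optional CpG exclusion drops both positions of every
consensus CpG; it is off by default. Majority-rule consensus keeps
columns with gap fraction ≤ 0.5 and breaks ties in the fixed order
A < C < G < T, making the operation deterministic. A subfamily is
putatively active iff its youngest copy is < 15 My old and it has
strictly more than 10 copies.

## Landscape statistics

Window statistics apportion each element's bp to overlapping windows by
intersection length (bp is conserved exactly); the element count goes to
the midpoint's window. The runs test binarizes window counts at the
per-chromosome median (ties → 0) — the binarization is not prescribed by
the procedure this reimplements, and a median split is the standard
construction — and uses the normal approximation, appropriate for the
tens-to-hundreds of windows per chromosome. A chromosome with a
single-valued binarization is reported degenerate rather than tested.
Gaps between consecutive same-class elements are measured end-to-start
and clamped at 0 for overlaps. Blocks are maximal same-class runs with
all gaps ≤ 1 kb (inclusive) and ≥ 5 elements, computed per chromosome
without window clipping so results are invariant to window offsets; the
implementation is checked against an independent quadratic scan oracle.
The chromosome-uniformity check is a one-sample t-test of per-chromosome
proportions against an explicit uniform value (normally the genome-wide,
length-weighted proportion).

## Genic context

TEs are assigned by midpoint so feature labels partition the annotation;
the priority Promoter > 5′UTR > 3′UTR > Exon > Intron > Downstream >
Intergenic is fixed (the category list is standard; the order is a
design choice mirroring peak-annotation tools). Promoter = [TSS−3 kb,
TSS+3 kb) strand-aware, Downstream = 3 kb past the transcript end. A
gene is class-enriched iff any element of that class overlaps its ±5 kb
flanked span; class-specific sets subtract genes enriched for the other
class. Repeat-percentage matrices measure family coverage of the ±3 kb
flanked gene span with same-family intervals merged first, so entries
stay in [0, 100]. Quantile normalization maps each column's sorted
values to across-column row means, averaging tied ranks. Enrichment uses
the hypergeometric upper tail P(X ≥ k) with Benjamini–Hochberg control
at α = 0.01 by default; p-value distributions of enriched vs random gene
sets are compared with the two-sided Wilcoxon rank-sum test.

## 3D genome

O/E normalization divides each entry by its diagonal's mean over bins
with non-zero marginals; masked bins propagate through all downstream
statistics. Compartments are the leading eigenvector of the Pearson
correlation matrix of O/E rows, found by power iteration (tolerance
1e-10, deterministic all-ones start, with a diagonal shift so the
dominant eigenvalue is the largest in magnitude); the result is verified
against full eigendecomposition in tests. The sign is anchored so
corr(PC1, bin GC) ≥ 0 and A = positive — the standard orientation
convention. When the anchor correlation is weak (|r| < 0.1) the track is
flagged weakly compartmentalized. The TAD-separation score averages
per-depth z-scores of d × d diamond means across depths; published
parameter sets for this score quote depths in bp that fall below one
bin at 100 kb resolution, so depths are rounded up to ≥ 1 bin and the
100 kb defaults span 3–8 bins (300–800 kb, step 100 kb). Boundaries are
local minima whose mean drop below the neighboring local maxima is ≥
delta (0.01) and whose O/E diamond values are significantly lower than
the flanking intra-domain values (one-sided rank-sum, BH at FDR 0.05);
the test runs on O/E rather than raw counts so the distance-decay
profile cancels instead of making every diamond look depleted.
Boundaries closer than the smallest depth are merged, keeping the deeper
minimum. Bin classification is quantile-based (default 0.75) with strict
dominance, ties neutral. Homotypic statistics group off-diagonal
correlation entries by bin-label pair. Matrix balancing and loop calling
are out of scope; loops are consumed as anchor-pair intervals.

## GC and methylation

GC content excludes N from the denominator. Windows are non-overlapping
tiles (the common "sliding window" phrasing with window-sized steps).
The GC association correlates window GC with per-window inserted bp per
class over windows containing at least one TE. Methylation sites are
assigned to TEs half-open; a site inside overlapping copies counts for
each copy's mean but once for the class site-share. An element is
"methylated" when it contains ≥ 1 called site (an optional fraction
cutoff exists because element-level definitions vary). The near-gene
context uses ≤ 5 kb, matching the enriched-gene flank. The age trend is
the Pearson correlation between subfamily mean age and subfamily mean
methylated fraction.

## Expression

TPM divides counts by length in kb and rescales each sample to 1e6
(conservation is asserted to 1e-6). Expression filtering follows the
edgeR `filterByExpr` logic: CPM cutoff 10/median(lib)×1e6, required in
at least the smallest group's worth of samples, plus a total-count floor
of 15. Time-course selection fits y ~ 1 + t + t² + g + g·t + g·t² per
feature on log₂(TPM+1) with stages coded 0, 1, 2 and tissue g ∈ {0,1},
and tests the full model against the intercept with a global F-test, BH
across features; selection requires adjusted p ≤ 0.05 and R² ≥ 0.6. This
replaces a two-step fit-then-prune regression with a single global test
under identical selection criteria — a deliberate simplification that
makes the selection fully specifiable and exactly testable; the F-test
is verified against statsmodels OLS to 1e-10. Profile clustering uses
average linkage on correlation distance of row-standardized profiles,
with k chosen by maximum mean silhouette over 2–15. TE–gene links pair
each selected intergenic TE with the nearest DEG more than 5 kb away and
report Pearson r on log₂(TPM+1) across all samples (no maximum distance
is imposed; the distance is reported so users can filter). The linked
values are correlation coefficients r, not r² — they can be negative.

## Synthetic data: what it emulates and what it does not

Generators are deterministic given their seed.

- **Genome**: i.i.d. bases per window with a target GC profile. It
  reproduces windowed GC heterogeneity but no k-mer structure, repeats
  other than the planted ones, or assembly gaps.
- **Copy divergence**: per-site Poisson(K) substitution events with
  transition probability κ/(κ+2) per event (κ = 2 by default, the
  mammalian transition bias). Multiple hits occur, so the K2P
  multiple-hit correction is genuinely exercised. No indels — alignment
  is the identity — so alignment error is not modeled.
- **TE planting**: copies are written over genome windows chosen by a
  softmax over window GC with sign and strength per family; one knob
  reproduces the direction of GC insertion bias. Insertions replace
  sequence rather than lengthening it, keeping window coordinates fixed.
  Planted divergence is K = age × 1e6 × μ.
- **Contact maps**: mean = scale × (1+|i−j|)^(−γ) × (1 + ρ·aᵢaⱼ) ×
  boost^[same TAD], Poisson-sampled and symmetrized. The default scale
  (1000 expected contacts at the first off-diagonal) represents a
  deeply sequenced 100 kb map; plaid strength ρ = 0.2 and γ = 1 are
  typical of mammalian maps. Real maps add balancing artifacts,
  translocations and copy-number effects that are not modeled.
- **Methylation**: TE sites every 50 bp with fraction base − slope·age +
  noise (defaults 0.9, 0.008/My, sd 0.05), clamped to [0,1]; background
  CpGs from a 50/50 normal mixture at 0.1/0.9, mimicking genome-wide
  bimodality. Real CpG density varies with sequence; coverage is
  constant here.
- **Counts**: negative-binomial (gamma–Poisson) with dispersion 0.1 and
  base mean 100; planted features carry a degree-2 stage trajectory
  plus a tissue effect of one log₂ unit at stage I decaying to zero by
  stage III — the profile shape a time-course screen is designed to
  catch. Null features are flat, so type-I calibration is measurable.

Passing tests on these generators demonstrates the statistics recover
known structure under the stated noise models; they do not certify
behavior under alignment artifacts, mappability bias, or batch effects
present in real data.

## Problem sizes

Defaults used by the test suite and the acceptance script: 500 copies of
a 300 bp consensus for divergence recovery; 200-bin compartment and
90-bin TAD matrices; 1000 random block instances (n ≤ 200); 2000
runs-test replicates over 100 windows; 2100 features × 18 samples for
the expression pipeline; 60 × 10 kb windows for the GC association and
30 subfamilies for the methylation–age trend. These sizes give stable
statistics while keeping the full suite under a minute of compute.
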