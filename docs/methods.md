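# Methods

## Study design assumed throughout

Two reference RNA pools, `Ref1` and `Ref2`, chosen so that a large
fraction of miRNAs differ in abundance between them, are measured on
several microarray platforms and on a TaqMan-style qRT-PCR array.
One-color platforms hybridize 2 independent replicates of each pool
(4 arrays); two-color platforms co-hybridize both pools on each array,
twice plus two dye swaps (4 arrays). All agreement analyses operate on
the per-miRNA log2(Ref1/Ref2) ratio — the only quantity the platforms
share — never on absolute intensities.

## Probe matching

Platforms annotate probes against different miRBase releases, so names
alone are unreliable. Matching proceeds name-first, sequence-final:

1. sequences are canonicalized (uppercase, U→T, alphabet {A,C,G,T});
2. candidate groups are formed by exact miRNA-name equality across
   platforms and kept only if every cross-platform pair of member
   sequences matches — equal, or the shorter contained as a contiguous
   substring of the longer (short capture probes are embedded in longer
   chemistries);
3. groups under discordant names whose sequences match are merged,
   provided the merged group still passes the pairwise check (this
   covers both identical sequences under renamed miRNAs and nested
   probe windows of different lengths); if a containment link connects
   groups that cannot be merged consistently, all of them are dropped
   and logged — ambiguity must not silently inflate concordance.

The matcher is deterministic (lexicographic key order) and invariant to
input row/platform order. Mismatch-tolerant (alignment-based) matching
is out of scope.

## Normalization

All normalization operates on log2 intensities, preserves matrix shape
and NaN positions, and never imputes.

**Cyclic lowess (one-color).** For every unordered array pair (i, j) a
lowess curve of M = x_i − x_j on A = (x_i + x_j)/2 is fitted; column i
accumulates +fit/2, column j −fit/2; each column's summed corrections
are scaled by 2/n (n = number of arrays sharing finite values in that
row) and subtracted; the cycle repeats for a fixed number of passes.
The 2/n scaling removes a constant array offset exactly in one pass —
the behavior of the widely used cyclic-loess implementations — whereas
averaging over the n−1 pairs would shrink offsets by only a factor
1 − n/(2(n−1)) per pass (≈ 1/3 at n = 4) and never reach approximate
idempotence at the default pass count. Smoothing constants (unstated in
most method descriptions) default to span 0.4, 3 robustifying
iterations, 3 cyclic passes; they are exposed as `LowessParams`. The
method assumes roughly balanced up/down regulation between the pools;
the synthetic truth honors this by construction.

**Dye-swap + lowess (two-color).** Per array,
M = log2(Ref1 channel) − log2(Ref2 channel) — the sign is fixed by
*sample*, not dye, so swap arrays are orientation-corrected
automatically and averaging a swap pair cancels additive dye bias —
and M is lowess-normalized against A = mean log2 channel. Non-positive
intensities become NaN (flooring would fabricate signal).

**Quantile** (alternative): columns share the mean order-statistic
distribution; ties receive the mean of the tied quantiles; columns with
missing values are mapped through scaled mid-ranks.

`normalization.method: none` is a supported pass-through for data that
are already normalized — and it defines the noise-free closure check:
a lowess fit is estimated from finite data, so even on noise-free input
it perturbs values at fit-residual (≈1e-2), not floating-point,
magnitude; with the identity normalization, zero-noise synthetic data
recover every agreement statistic as exactly 1.0.

## Detection calls

**Negative-control rule** (one- and two-color raw signal): per array
the threshold is the trimmed mean + 3 × trimmed SD of the
negative-control intensities; the trim removes ⌊0.05·n⌋ values from
each tail and the SD is the ddof=1 standard deviation of the survivors
(a Winsorized SD was considered and rejected for simplicity). A spot is
absent iff strictly below the threshold (equality → present); NaN →
absent. At least 5 finite controls per array are required.

**Background-SD rule** (background-subtracted platforms): a spot passes
iff signal > 3 × spot background SD and (replicate SD)/signal < 0.5; a
miRNA is present iff ≥ 50% of its spots pass. Both rules' constants
live in `DetectionRuleParams`.

**qRT-PCR**: ΔCt = Ct(miRNA) − Ct(U6) per well; log2 normalized
expression is −ΔCt (sign exposed as a parameter; the default makes high
expression ↔ large values, consistent with flipping Ct-scale
differences by −1 when correlating with array ratios). Ct > 35 or
undetermined ⇒ undetected; a miRNA counts as qPCR-detected only when
every well is determined and ≤ 35. Undetermined wells are NaN
throughout (the pre-threshold treatment is not standardized anywhere;
NaN → absent is the conservative choice).

## Collapsing and presence

Technical-replicate spots collapse to the median per (miRNA, column),
NaN excluded; an even count takes the mean of the two central values.
Flags propagate by rule: any contributing absent spot makes the
collapsed value absent (negative-control rule), or a < 50% pass
fraction does (background-SD rule). A miRNA is *present on a platform*
only when present in every column — conservative, and symmetric across
color modes (both channels of every two-color array must pass).
`common_all` denotes the all-platform present ∩ qPCR-detected set.

## Agreement statistics

- Spearman = Pearson of mid-ranks (average ties); pairwise NaN removal;
  n ≥ 3 enforced. Backed by `scipy.stats.spearmanr`; the test suite
  checks it against an independently coded rank-then-Pearson oracle.
- Within-platform: (ρ(r11, r22) + ρ(r12, r21))/2 — each term pairs
  disjoint hybridizations so replicate noise never appears on both
  sides. Raw ρ values are averaged (no Fisher-z), and the statistic is
  deliberately restricted to the 2×2 replicate design.
- Between-platform and vs-qPCR: Spearman of mean log ratios (all
  pairings averaged, NaN-aware) over the chosen probe set.
- Lin's CCC with population (1/n) moments; 95% CI by Fisher
  z-transform with Lin's corrected asymptotic variance; the reported SE
  is the delta-method back-transform. Degenerate inputs (both vectors
  constant) are errors; a perfect CCC collapses the CI to a point.
- Bootstrap: the resampling unit is the miRNA (the only exchangeable
  unit); indices are drawn jointly across all vectors/pairings;
  B = 2000 default, percentile CI, SE = SD of the bootstrap
  distribution; degenerate resamples are skipped and logged, > 20%
  skips is an error; fully seed-deterministic.
- Permutation test for ρ(P1, ref) − ρ(P2, ref): under the null the two
  platform labels are exchangeable per miRNA, so each of the 5000
  permutations swaps (P1, P2) values independently with probability ½;
  p = (1 + #{|d*| ≥ |d|})/(n_perm + 1) (add-one avoids zero p).
  The permuted-correlation computation is vectorized (row-wise ranks)
  and verified against a per-permutation loop in the tests. Family-wise
  correction across platform contrasts is Holm step-down.
- All CIs are clipped to [−1, 1]; every estimate records n and its
  probe set.

## The synthetic generator

`generate_truth` draws per-miRNA baseline log2 abundances
N(9, 2.5²) — clearly above the negative-control background
N(6, 1²) for most miRNAs — and gives a configurable fraction of miRNAs
half-normal(2.0 log2) shifts in Ref1, split evenly up/down (the
cyclic-lowess balance assumption; when the differential count is odd
the extra miRNA goes down). Non-differential miRNAs are identical in
both pools. Each miRNA also gets a fixed 60-nt precursor-like context
with its 22-nt mature core centered; platform probes are
length-L windows centered on the core, so windows of different lengths
nest and the containment rule holds pairwise across platforms by
construction (per-platform random flanks were rejected: two long-probe
platforms would then never match each other).

`simulate_platform` models log2 spot signal as
platform offset + per-probe affinity + true abundance + curvature
distortion + dye bias (two-color, channel-additive) + N(0, noise_sd),
exponentiated to intensities; technical replicates get independent
noise; negative controls draw log2-normal background (strictly
positive, right-skewed like scanner background). The curvature term is
a saturating cubic in centered abundance, scaled linearly from
−curvature to +curvature across columns so that it is a *between-array*
distortion cyclic lowess can remove. Each platform retains a
`content_fraction` of the catalogue (exercising Venn logic) and may
rename a fraction of miRNAs with a "-5p"-style suffix (exercising
sequence-authoritative matching).

`simulate_qpcr` maps abundance to Ct = 33 − abundance + N(0, 0.15)
(slope −1 ⇒ 100% efficiency; the intercept places array-present miRNAs
at Ct ≤ 25, well inside the detection range, while the limit sits at
35), with a constant U6 row at Ct 20.

The default four-platform scenario (`paper_like_scenario`) combines two
one-color platforms (one using the background-SD detection rule, with a
background matrix), two two-color platforms with dye-swap pairs,
partially overlapping catalogues (85–92%), probe lengths from exactly
22 nt up to 30–40 nt windows, and a differential fraction of 0.8
(reference pools are chosen to maximize content differences). These
defaults were fixed once so that the all-platform present ∩
qPCR-detected set lands in the few-dozen range typical of this design
(the tests require 30–80 at 260 miRNAs) and concordance sits in the
high-agreement regime real platform comparisons report.

What the generator does **not** emulate: cross-hybridization between
related miRNAs (family members differing by 1–2 nt), spatial/print-tip
effects, saturation, image-level artifacts, or probe thermodynamics.
Passing tests therefore demonstrate correctness of the statistical
machinery under the design's stochastic structure — not robustness to
those real-data failure modes.

## Pipeline determinism and problem sizes

Every bootstrap/permutation seed derives from the run seed in a fixed
iteration order; identical config + seed give byte-identical report
TSVs (statistics written to six decimals). The test suite runs the
full scenario at 260 miRNAs and 4 platforms, bootstrap calibration at
1000 simulations (n = 100, B = 500), permutation calibration at 200
datasets (n = 50, n_perm = 1000), and noise-recovery sweeps at 200
miRNAs × 20 seeds per noise level — sizes chosen as the smallest at
which the Monte-Carlo tolerances are meaningful.

## Known limitations

- The within-platform statistic supports only the 2×2 replicate
  design; other designs raise rather than silently generalizing.
- Presence-by-all-columns is strict; platforms with one bad array lose
  borderline miRNAs from `common_all`.
- The CCC confidence interval is the asymptotic one; no U-statistic or
  bootstrap variant.
- The permutation scheme (per-miRNA label swap) is one defensible
  choice among several for comparing dependent correlations; it is
  configurable only in its seed and count.
- Vendor-format ingestion (GPR, Feature Extraction, GEO SOFT) is out of
  scope; inputs are the documented TSV/YAML interchange formats.
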