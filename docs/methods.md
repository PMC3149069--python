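# Methods

`cnastats` implements a genome-wide somatic copy-number alteration (CNA)
analysis for cohorts profiled on a dense, ordered probe map (a SNP array),
together with a synthetic cohort generator used to validate every stage.
This note records the statistical models, the defaults and why they were
chosen, the numerical decisions, and the limits of what the synthetic
benchmarks demonstrate.

## Calling model

Raw copy number at probe *i* of sample *s* is the reference-scaled signal
`2 · signal(s,i) / mean reference signal(i)`, where the reference set is
diploid material (blood / non-involved tissue). Inferred copy numbers are
obtained by a centered running median of 11 probes, applied per sample and
strictly within chromosomes; at chromosome ends the window shrinks to the
available probes, so output length equals input length and no information
crosses a chromosome boundary. Ternary calls use inclusive thresholds

* gain: CN ≥ 2.7,
* loss: CN ≤ 1.3.

These encode detection of true CN ≥ 3 / ≤ 1 under up to 30% contamination
by normal diploid cells: a 70/30 tumor/normal mixture maps CN 3 to
0.7·3 + 0.3·2 = 2.7 and CN 1 to 1.3. Note that 30% is the *boundary* of
tolerance, not a point with margin: at exactly 30% contamination the
noise-free mixed signal of a single-copy gain sits exactly on the
threshold, so with any symmetric noise roughly half of such probes fall
on either side. The calling benchmark therefore checks exact recovery at
the design point with zero noise, and ≥99% per-probe accuracy at the
generator default of zero contamination with noise sd 0.2 (where the
margin is 0.3 and the 11-probe median leaves ≈4 sd of headroom).

## Per-locus prevalence tests

At each probe, the number of patients carrying the event is modelled as
Binomial(n, π₀) with an *empirical* null probability

π₀ = (total event probe-cells over the analysis subset) / (probes × samples),

i.e. the genome-wide average event rate, estimated separately per event
type and per analysis subset. Exact upper-tail p-values P(X ≥ k) are
evaluated through the regularized incomplete beta function
(`scipy.stats.binom.sf`), which is stable far below 1e-300 in log
magnitude; an independent log-space summation oracle in the test suite
confirms 1e-12 relative agreement for n ≤ 50 and deep-tail stability.
Benjamini–Hochberg q-values control the FDR across the genome (Storey's
q with λ = 0.5 is available behind a flag; BH is the default because it
is deterministic and parameter-free). Gene-level results assign a probe
to a gene when its position lies in the gene interval extended by a 2 kb
flank (inclusive bounds, 1-based coordinates); a probe overlapping
several extended genes counts for each of them, and each gene is
represented by its maximum-prevalence probe (equivalently minimum p),
ties broken by smaller genomic position.

The upper tail is used for both gains and losses, each against its own
π₀; this orientation reproduces the worked-example p-values of the
published 301-patient cohort to <0.2% relative (see
`scripts/acceptance.py`). For those examples the patient counts are
recovered from printed percentages as k = round(pct·301), and the null
probabilities are the unrounded empirical rates (mean event probes per
genome divided by the 256,554 autosomal probes); the commonly quoted
0.076/0.010 are rounded displays of the same quantities and are too
coarse to reproduce the extreme tails.

## Global test for genome-wide pattern differences

For two groups with sizes n₁, n₂, each locus contributes the standardized
difference of stabilized proportions

d_i = (p₁ᵢ − p₂ᵢ) / √( p₁ᵢ(1−p₁ᵢ)/n₁ + p₂ᵢ(1−p₂ᵢ)/n₂ ),  p_ji = (x_ji + 0.5)/n_j,

with the edge case x = n using (x + 0.5)/(n + 1) so the proportion stays
inside (0,1) and the variance stays positive. The global statistic is
D = Σᵢ d_i²; its null distribution is obtained by permuting group
membership among the pooled samples with group sizes preserved (10,000
permutations by default), and the one-sided p-value uses the add-one rule
p = (1 + #{D_null ≥ D_obs})/(1 + B), so p is never zero. Because entire
samples are permuted, the spatial correlation of copy numbers along the
genome and the multiplicity over loci are accounted for automatically.
All loci are retained, including event-free ones (whose d_i is nonzero
only through the stabilizer when n₁ ≠ n₂). Design choices left open by
the verbal definition: the unpooled variance is the default (a pooled
variant sits behind a flag), and the test is one-sided upper since D is a
non-negative omnibus distance. An exact mode enumerates all C(n₁+n₂, n₁)
reassignments (or all 2^m within-pair swaps for the paired test) and is
used by the tests to verify the permutation machinery on small cohorts.

The matched-pairs variant computes the same D between pair members and
permutes by independently swapping the two members of each pair with
probability ½, preserving the pairing. Late-stage tumors are matched to
early-stage tumors by closest smoking pack-years, greedily in descending
order of late-stage pack-years with seeded tie-breaks; the greedy total
|Δ pack-years| is not guaranteed optimal (a test documents this against
brute-force optimal matching), but is deterministic and mirrors
one-at-a-time clinical matching.

## Positional selection: TP, GP and the G/T ratio

Per sample, TP counts event probes and GP the subset inside extended
genes; under random placement E[GP/TP] equals the array's in-gene probe
fraction (104,256/256,554 = 40.64% on the 250K array). The vs-null test
is a two-sided one-sample t test on the per-sample ratios (samples with
TP = 0 are excluded as their ratio is undefined); a pooled exact binomial
variant is available behind a flag. Group comparisons of TP, GP or G/T
use Welch's unequal-variance two-sided t test. The one-sample t was
chosen for symmetry with the Welch comparisons; the pooled binomial
alternative weights samples by their event counts instead.

## CNA gene-set enrichment

Genes are ranked by CNA prevalence (ties broken by gene id for
determinism) and scored with the weighted Kolmogorov–Smirnov running-sum
enrichment statistic: hit increments |score|^w normalized over the set's
members, miss increments 1/(N − N_H), ES = the running sum's maximal
signed deviation from zero. The weight exponent defaults to 1 (standard
GSEA weighting; 0 gives the classic KS statistic). If every member score
is zero the hit weights fall back to uniform so the statistic remains
defined. Because a single group is profiled, the null permutes *gene
labels*: a null ES for a set of m genes is the ES of a uniformly random
m-subset of the universe against the fixed ranking (20,000 draws by
default; sets below 15 members in the universe are excluded). Null draws
are shared across sets of equal size — the null law depends on a set only
through its size, so this is exact, not an approximation. p-values are
one-sided for positive enrichment with the add-one rule. Reported sets
must be significant (strictly p < 0.05) in a seeded random
discovery/validation split of the tumors (sizes ⌈n/2⌉ and ⌊n/2⌋) and in
any further strata supplied (e.g. early- and late-stage subgroups, each
using its own subgroup ranking). No cross-set FDR is applied on top of
the two-stage filter.

## Synthetic cohort generator

The generator emulates the study design the analysis targets: a germline →
early tumor → late tumor progression in which event burden rises sharply
with stage and events avoid genes to a configurable degree.

* **Axis:** evenly spaced probes (5 kb default) on up to 22 autosomes;
  genes tile the axis in blocks (default: one gene of ~10 probes per
  25-probe block, matching the real array's ~9 in-gene probes per gene)
  with cumulative rounding so the realized in-gene probe fraction hits
  the target (default 40.64%) to within one probe per block. Gene bounds
  are placed so that the ±2 kb flank covers exactly the intended probes.
* **Cohort structure (defaults):** 63 blood + 50 non-involved references
  paired to tumor patients, 246 early-stage and 25 late-stage tumors.
* **Events:** per sample, segment counts ~ Poisson(group rate), lengths
  geometric (mean 50 probes), truncated at chromosome ends. Default
  rates (gains 1.1/1.1/22/71, losses 1.5/1.5/3.8/6.9 segments per genome
  for blood/non-involved/early/late) are calibrated so the expected
  altered fraction of the 20,000-probe axis matches the study's mean
  event-probe fractions per group. Gains set true CN to 3 (4 with
  probability 0.1), losses to 1 (0 with probability 0.05).
* **Selection:** a candidate segment start falling on an in-gene probe is
  accepted with probability 1/s (selection strength s, default 1.5 —
  chosen because start-rejection at s = 1.5 yields an in-gene start
  fraction ≈ 31%, the germline G/T level the method is meant to detect).
  Selection acts at placement, not per probe, respecting the segmental
  nature of CNAs; as a consequence its imprint on the G/T ratio weakens
  when segments are much longer than the gene/intergenic alternation.
* **Observation model:** observed = truth + c·(2 − truth) + N(0, σ²),
  floored at 0, with contamination c (default 0, 0.3 reproduces the
  threshold design point exactly — the mixing is written in this form so
  the design point lands on the representable 2.7/1.3 doubles) and noise
  σ = 0.2 by default.
* **Planted enrichment:** chosen gene sets get their member genes forced
  to gain in an extra boost-fraction of target samples (sampled per gene
  among samples currently event-free over the gene, so the per-gene
  prevalence rises by exactly the boost); size-matched decoy sets are
  drawn from the remaining genes.

All draws flow through one `numpy` Generator seeded from the config, so
every artifact is reproducible bit-for-bit.

### Benchmark configurations and problem sizes

The validation suite scales the study down to desk size; the configurations
are part of the package's benchmark definitions:

* **Global-test calibration:** 500 null cohorts of 10 + 10 samples over
  200 probes, B = 200 permutations; rejection at α = 0.05 must stay in
  the 95% binomial band [0.032, 0.071].
* **GSEA:** gene-dense axis (4,000 probes, ~160 genes), 100 tumors;
  decoy-set p-values uniform (KS at 0.01, 200 sets, B = 2,000); a
  planted 20-gene set with +0.3 prevalence boost detected at p < 0.05 in
  ≥90% of 50 replicates (B = 2,000, scaled down from 20,000).
* **Selection:** large gene blocks (one gene per 150-probe block) and
  short segments (mean 20) so start-placement selection shifts the
  per-sample G/T ratio measurably; strengths {1, 2, 4} with 20 tumors,
  25 replicates each: neutral placement reproduces the in-gene fraction,
  the mean ratio decreases strictly in s, and power exceeds 0.8 for s ≥ 2.

### What the synthetic benchmarks do not show

The generator has no linkage-disequilibrium structure between probes, no
allele-specific copy number, no subclonal heterogeneity beyond a single
contamination mixture, and gene/segment geometries far more regular than
a real genome. Passing benchmarks therefore demonstrates the statistics
are implemented correctly and are calibrated/powered under the assumed
model — not that the model captures every property of real array data.
Cohort-level published results (total event-probe counts, which specific
gene sets validate) depend on the real cohort and the curated gene-set
database, neither of which is packaged, and are deliberately not
benchmark targets.

## Numerical and degenerate-input decisions

* Coordinates are 1-based inclusive throughout; BED input converts at the
  reader boundary. Sex chromosomes are rejected at read time — the
  analysis is defined on autosomes.
* Missing copy-number cells are an error (the smoothed matrix is
  complete by construction); missing pack-years are allowed and excluded
  from matching.
* Both groups constant and equal in Welch's test returns p = 1 rather
  than NaN; fewer than two defined G/T ratios is an error.
* Permutation p-values always include the observed statistic (add-one
  rule); exact enumeration modes include the identity relabelling, so
  their tail fraction is likewise never zero.
* Thresholding is monotone and boundary-inclusive; enumeration-mode tail
  comparisons use a 1e-12 absolute guard against floating-point ties.
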