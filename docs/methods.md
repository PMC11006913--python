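# Methods

## Scope and data model

`pbmeta` analyzes universal protein-binding microarray (PBM) experiments
in which the chambers of one slide assay an *allelic series* — a
reference transcription-factor DNA-binding domain plus variants — and
the same series is repeated on further slides (*allelic replicates*).
The unit of inference is the RC-collapsed k-mer: a k-mer and its reverse
complement are one feature because double-stranded probes cannot
distinguish orientation; the canonical representative is the
lexicographically smaller string. For the order-10 universal design the
features are the 32,896 RC-collapsed 8-mers; the pipeline is generic in
k = order − 2, and the package's own validation studies run on the
order-8 design (2080 RC-collapsed 6-mers, 4096 probes of 23-nt variable
region) so that a complete calibrated analysis takes seconds.

## Array design

`make_debruijn_design` builds the cyclic de Bruijn sequence of a given
order by the Duval/FKM Lyndon-word concatenation (lexicographically
least sequence for seed 0; other seeds relabel the alphabet and rotate,
preserving the de Bruijn property without putting RNG into the
construction). The sequence is cut into probes overlapping by order−1
nt, so every order-mer occurs in exactly one probe variable region; when
the probe step does not divide 4^order the last probe wraps cyclically
and a warning is recorded. Each (order−2)-mer then occurs 16 times per
orientation in the cycle — 32 combined-strand occurrences per
non-palindromic RC-collapsed feature, 16 per palindromic one. The k-mer
index records, per probe and canonical k-mer, the occurrence nearest the
free (distal) probe end; a probe contributes at most once per feature
because observations within one probe are not independent.

## Preprocessing

Per chamber, the optimal PMT scan minimizes the summed proportions of
over-saturated (foreground > 2^15.5) and under-saturated (< 2^5)
probes, with ties going to the lower gain. Probes still over-saturated
in the chosen scan are excluded — as a union across the chambers of a
slide, because dropping a clipped probe from only the brighter allele of
a comparison would bias every k-mer on that probe. Background is
subtracted (probes with foreground ≤ background are excluded), smooth
spatial bias is divided out as the local 15×15 window median over the
global median (windows truncate at array edges; the window size is a
package choice — the operation, not its parameters, is dictated by the
upstream convention), and the protein channel is normalized by the Cy3
double-stranding channel against a pooled empirical reference (per-probe
median across the run's chambers; ≥2 chambers required). Probes with
|log2 observed/expected Cy3| strictly greater than 1 are excluded; the
boundary is kept. Masking is monotone: no step unmasks a probe, and each
masked probe carries its first reason.

## Normalization

Within a replicate, each non-anchor sample receives an additive log2
shift from the trimmed mean of M-values against the anchor (trim 30% of
extreme M and 5% of extreme A values, the original TMM defaults; the
approach, not the fractions, is inherited). Because the bulk of
universal-array probes carry little specific signal, TMM anchors the
background while preserving genuine uniform affinity changes in the
bound minority. Across replicates, the per-probe log-scale mean of the
anchor samples defines a reference; each replicate gets an additive
factor (median difference vs the reference) and a multiplicative factor
(median ratio of rank-ordered, median-centered values — the slope of the
log-scale QQ plot), averaged when multiple anchor alleles are used, and
all samples of the replicate are transformed identically. Replicates
whose reference sample's upper-tail width (99th − 90th percentile) falls
below 25% of the maximum across replicates (50% for stripped arrays) are
dropped; the filter runs on within-normalized values *before* the
across-replicate pass, which would otherwise equalize the very widths it
judges, and across-replicate normalization is then (re)run on the
survivors.

## k-mer scoring

Probe-level means and variances across replicates are moderated with a
scaled-inverse-chi-square prior fitted by moment matching on log sample
variances (d0 from a trigamma inversion; in the underdispersed
degenerate branch the prior variance is the geometric mean, so identical
sample variances are a fixed point). Alleles observed in a single
replicate borrow the prior — and per-probe moderated variances — from
the anchor allele's fit.

A per-offset, per-strand position-bias profile (median over occurrences
of probe mean minus the k-mer's median probe mean, median-centered) is
subtracted from each probe contribution. On composite probes this
profile is strongly attenuated — most occurrences at a given offset
belong to k-mers whose probe means carry no positional information — so
it is a partial correction; it is exact in the regime where a single
occurrence drives a probe's signal, which is where the correction
matters.

Each k-mer is then scored by the two-step DerSimonian–Laird
(DerSimonian–Kacker) estimator across its probes: a first moment
estimate of the between-probe variance τ² with inverse-variance weights,
one re-estimation with updated weights via the generalized moment
equation, then the weighted mean, SE = (Σw)^(−1/2), with single-probe
k-mers falling back to τ² = 0 and the probe SE.

Because both alleles of a contrast are scored on the same probes, their
estimates covary. The covariance per k-mer is derived from the weighted
paired-difference variance V of the per-probe differences (probe effects
shared by the alleles cancel in the differences):
cov = (SE²_a + SE²_b − V)/2, clipped to ±SE_a·SE_b, so that the contrast
variance SE²_a + SE²_b − 2·cov equals the directly calibrated paired
estimator. An earlier formulation that shrank the empirical
cross-covariance toward min(τ²_a, τ²_b) systematically under-estimated
the shared component (null contrast z-scores had sd ≈ 0.86 and failed a
Kolmogorov–Smirnov normality check); the paired-derived form gives null
z-scores with sd 0.92–1.00 and mean KS p ≈ 0.15 across seeds.

## Per-k-mer tests

**Preferential affinity.** The across-k-mer score distribution is
modeled as Normal(μ, σ²) + Exponential(mean α), fitted by maximum
likelihood over (μ, log σ, log α) with Nelder–Mead from several
moment-based starts (the normexp likelihood is fragile; failures raise,
never silently fall back). The p-value is the one-sided upper tail of
the score under the fitted normal component; the reported effect size is
the closed-form posterior mean E[S|X=x] (the centered score x − μ is
also available). At least 1000 finite k-mers are required for the fit.

**Contrast.** d = variant − reference exactly; Var(d) as above, floored
at 1e−12 (negative values before flooring are logged); two-sided normal
p-value.

**Specificity.** The contrast-vs-reference-score plot is split into 20
equal-width bins; in each bin a two-component univariate normal mixture
is fitted by EM (means initialized at the 25th/75th percentiles, 100
iterations or relative tolerance 1e−8, variances floored; bins with
under 20 points weight both components fully). Upper/lower components
are grouped across bins by mean, and two cubic B-spline weighted
regressions (5 interior knots at x-quantiles) are fitted with the
membership probabilities as weights. The trend minimizing the mean
absolute residual over the 50% of k-mers with highest reference score is
selected; residuals from it are tested two-sided with the contrast
variance (the trend is treated as fixed — no trend-uncertainty term —
matching the reported normal-approximation p-value). Points outside the
fitted support are linearly extrapolated and flagged.

All three p-value families are Benjamini–Hochberg adjusted across
k-mers.

## Variant classification

The affinity rule: among reference-preferential k-mers
(affinityQ < 1e−6), if the fraction that is differential
(contrastQ < 1e−6) in one direction strictly exceeds 0.15, the variant
is called loss or gain by the larger direction. The primary specificity
rule: ≥10 k-mers preferential in the reference *or* the variant with
specificityQ < 1e−6 (the OR makes gained recognition countable). The
edit-distance rule: per residual sign, the k-mer with the maximal
|contrastResidual| seeds a neighbourhood; for each panel combination
(distance < 2 or < 3, specificityQ < 0.05 or < 0.01) the count of other
same-sign k-mers within the cutoff — the seed itself is not counted, so
a lone significant k-mer is never its own cluster — must exceed a
threshold for every combination. Thresholds are the smallest counts
exceeded by ≤5% of empirical null comparisons: all balanced
relabelings of the reference's replicates into pseudo-reference and
pseudo-variant halves (1 comparison for duplicates, 6 for
quadruplicates), run through the full test stack with probe variances
pooled from all replicates when a side has only one.

## Synthetic data generator

The generator is the package's stand-in for real scanner output and
defines its study conditions. Ground truth: a position-specific energy
matrix of width k−1 with steep penalties (3.5–5 natural-log units) at
specific positions and mild ones (0.2–0.9) at three degenerate
positions, giving tens of strongly bound k-mers within an order of
magnitude of the optimum — the shape of real TF motifs — plus a
heavy-tailed per-k-mer baseline affinity (log-normal, median 3e−4,
log-sd 1.5, capped at 0.3) for non-motif binding. Planted effects
multiply affinities uniformly (affinity loss/gain), on an IUPAC-core
subset (specificity change; the standard scenario derives the core from
the motif consensus with one intolerant substitution, since gained sites
resemble the canonical site), or swap the motif.

Per chamber, probe foreground is a normal background draw (mean 300,
sd 40 counts) plus a gain-scaled signal: the occurrence sum of affinity
× exponential position decay (0.02/nt from the free end), times a smooth
spatial bias field (±10%), a per-probe dsDNA amount shared with the Cy3
channel (log-sd 0.10), a fixed per-probe multiplicative bias (log-sd
1.2, clipped to [0.25, 4]; identical in every chamber, so it cancels in
contrasts while spreading the across-k-mer score distribution the way
real probe effects do), and heteroscedastic measurement noise (log-sd
0.15 scaled per probe by a fixed log-sd-0.5 factor — the regime variance
moderation exists for). Values are clipped to the 2^16 scanner ceiling
and written at three PMT gains (0.5×/1×/2×). The Cy3 channel carries
sequence-dependent expected values with occasional outliers, so the
empirical Cy3 normalization has real structure to remove. A fixed
(seed, config) reproduces every file byte-for-byte.

What the generator does not emulate: probe secondary structure,
position-dependent double-stranding failure, spatial gradients that
correlate with sequence, protein concentration series, and chamber
cross-talk. Passing recovery tests therefore demonstrates the
statistical machinery under a faithful noise budget, not robustness to
every laboratory artifact.

### Standard study conditions

Desk-scale validation uses the order-8 design, four allelic replicates
(series are assayed at least in duplicate and nulls in quadruplicate),
planted uniform loss at 0.5× and subset gain at 4×. Under these
conditions: reference-vs-reference comparisons yield essentially no
false variant calls (0 of 120 in the standard study) and calibrated
contrast z-scores; uniform-loss recovery is ≈95% of seeds with no
accompanying specificity call; subset-gain recovery is ≈100% with the
seed k-mer containing the planted core in ≥90% of seeds. The residual
failure mode — an edit-distance cluster of trend-misfit k-mers under a
strong global affinity change — mirrors the known brittleness of
B-spline trend fits on such contrasts.

## Numerical choices and limitations

- Scan-choice tie-break: lowest PMT gain (least saturation risk).
- fg = bg probes are excluded (log-undefined downstream).
- Cy3 outlier boundary (|log2 ratio| = 1) is kept; exclusion is strict.
- The normexp MLE refuses to fall back silently; degenerate α → 0 fits
  (pure noise) are representable and tested.
- BH adjustment propagates NaN p-values as NaN Q-values.
- Rank-matching across replicates uses shared probes only; no
  interpolation.
- Threshold panels calibrated from few null comparisons (6 for one
  quadruplicate reference) are coarse; the implementation warns below 10
  comparisons. Pooling references, as the upstream study design does, is
  supported through `build_null_comparisons`.
- The positional-bias profile under-corrects on composite probes (see
  above); the residual positional variance is absorbed into τ².
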