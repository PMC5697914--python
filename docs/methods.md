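# Methods

This note documents the models, estimators and numerical choices that
dendroscale implements, the reasoning behind defaults where the design was
genuinely open, and what the synthetic-data generators do and do not
emulate.

## Two-layer dendritic model

The model neuron has `Nbr = 20` dendritic branches with `Nsyn = 15`
synapses each. For an input pattern `x_ij` (uniform on [0.5, 1.5]) the
somatic output is

    y = f_n( (1/Nbr) Σ_i w_ib · f_b( (1/Nsyn) Σ_j w_ij · x_ij ) ),
    f(x) = 1 / (1 + exp(-β (x - μ)))

with branch nonlinearity β_b = 0.7, μ_b = 33 a.u. and somatic nonlinearity
β_n = 5, μ_n = 0.5. Branch weights `w_ib` default to 1 (no distribution is
specified for them; the term is retained for fidelity to the equation).

**Weight distribution.** Weights are lognormal, rejection-resampled into
[20, 150] a.u. The distribution is parameterized by its *scale* (median):
`exp(μ_log) = 30`, `σ_log = 0.3`, giving a truncated sample mean of ≈ 32.7
(within 10% of 30; the tested tolerance). This choice is deliberate: it
places the per-branch operating point `Σ w·x̄ / Nsyn ≈ 32.7` at the
midpoint of the branch sigmoid (μ_b = 33), the regime in which the model's
mechanism operates — pattern-driven input fluctuations traverse the
sigmoid's linear range, global up-scaling pushes intact branches toward the
high plateau while under-compensated deprived branches fall toward the low
plateau, and branch-specific scaling returns every branch to the linear
range. Parameterizing instead so the *truncated mean* equals 30 puts the
operating point ~3 a.u. below the midpoint, where global scaling *helps*
most branches (moves them toward maximal gain) and the information
difference reverses sign. Since the mechanism requires the
midpoint operating regime, the median-30 parameterization is used.

**Active inputs.** The fraction of simultaneously active synapses per
branch is a free parameter (`active_fraction`, default 1.0). Under the
printed 1/Nsyn normalization, small active fractions push all branch sums
deep into the lower sigmoid plateau (at 0.5 the output is constant and the
mutual information is identically zero), so the default activates all
inputs and uses the equation verbatim. For subset-active regimes the
`normalize_by_active` option divides by the active count instead, which
keeps the operating point fixed; `sweep_active_fraction` re-runs the
comparison across fractions under that convention (the branch > global
direction holds for fractions 0.4–1.0, t ≈ +7 to +10).

**Deprivation and rescaling.** Exactly `round(0.5 · Nbr)` branches are
deprived (deterministic count so "half the branches" is exact); each of
their synapses is zeroed independently with probability 0.1. Rescaling:

* *branch-specific* — each deprived branch's surviving weights are
  multiplied by (its own pre-loss total) / (post-loss total); intact
  branches are returned bit-identical. An alternative normalization to a
  common per-branch total is available behind `common_branch_target`
  (default off). A branch losing all 15 synapses (probability 0.1^15 at
  defaults) raises an explicit error.
* *global* — every surviving weight is multiplied by (pre-loss cell
  total) / (post-loss cell total).

Both conditions conserve the cell total to floating tolerance and zeros
stay zero.

**Mutual information.** The input→output map is deterministic and the 1000
input patterns are almost surely distinct, so MI(stimulus; binned output)
equals the entropy of the binned-output distribution. Outputs are binned
into 10 equal-width bins on [0, 1] — the codomain of the somatic sigmoid —
which is parameter-free and respects the output range. Binning over the
*observed* output range was evaluated and rejected: it is scale-free and
nearly blind to saturation-induced output collapse, washing out the
difference between conditions. MI is reported in bits and is bounded by
log2(10) and log2(n_patterns).

**Statistics.** Per repetition the weights, the loss pattern and the 1000
patterns are shared between the two conditions; 100 repetitions yield two
MI samples compared with an unpaired Welch t test by default (a paired
variant is available since the loss patterns are shared; the unpaired test
is the conservative default when the pairing is not documented).

## Spine census statistics

Sizes are integrated brightness, background-subtracted and normalized by
the adjacent dendrite (`size_from_intensity`), then normalized per spine to
the mean of its baseline timepoints (−24 h and 0 h by default). A `log10`
flag produces the transformed column used for parametric statistics on
normalized sizes.

A branch is **increasing** when its surviving-spine mean normalized size is
≥ 1.1 *and* strictly more than 45% of its spines individually exceed 1.1
(the joint criterion guards against a single large outlier). Ties exactly
at the size threshold count as not increased (strict inequality). Branches
failing the increasing criterion are *decreasing* when their mean falls
below 0.9 and *same* otherwise — including the rare residual case of a
high mean driven by one outlier, which is "not increasing, not decreasing"
rather than decreasing. Both thresholds are re-derivable from a control
dataset as 90th percentiles (`derive_thresholds`); with fewer than 10
control spines the derivation is refused, and a degenerate control (90th
percentile ≤ 1) yields a warning.

**Chance level.** 100 simulated datasets of 30 branches × 25 spines are
resampled with replacement from the pooled deprived population; the
fraction of simulated branches meeting the increasing criteria gives the
chance mean ± SD. The estimator is unbiased; with 3000 simulated branches
its own Monte-Carlo SE is ~0.6 percentage points, which the tests average
out over repeated runs before comparing with a 10⁶-draw enumeration.

**Cluster analysis.** Distances are measured along the dendrite between
attachment points (spines directly opposite are 0 μm apart, which the
half-open binning [k·w, (k+1)·w) honors). For each seed spine Sp0 of a
chosen class, neighbors on the same branch are binned by distance (default
4 μm, matching the mean interspine interval) and the fraction exceeding the
size threshold is pooled across branches; Sp0 is excluded from its own
bins. Nulls: (1) a position-shuffle that permutes which spine occupies
which position within the branch — preserving the position multiset, the
spine count and the branch-level increase rate exactly — repeated 1000
times by default; (2) a different-branch (DB) probability, 10 resamples
with replacement of single spines on other branches of the same cell per
Sp0, averaged per Sp0 before averaging across spines. Branches with fewer
than 2 measured spines are skipped with a log entry. The shuffled pooled
fraction is a ratio-of-counts estimator and is slightly biased in sparsely
populated far bins; band-coverage checks are therefore restricted to bins
with adequate neighbor counts.

**Lost spines.** Nearest-neighbor distances among lost spines are pooled
over branches with ≥ 2 losses; the null re-draws which positions (among
all spines of the branch) are lost.

**Density vs. size.** Per branch, spine density at the evaluation
timepoint relative to baseline against the branch mean normalized size;
association by Spearman rank correlation. Fewer than 3 branches, or
constant values, are reported as undefined with a warning.

**Co-localization.** GluA2/GRIP1 intensities are read at the GFP peak of
each spine's line profile; background mean and SD come from the 90°-rotated
profile (flat backgrounds are rejected). A spine co-localizes when both
channels exceed background mean + 2 SD; normalized intensity is peak /
background mean, and the GluA2-per-size ratio divides it by the spine's
integrated brightness. Dendrite summaries average over co-localized spines
only.

## mEPSC scaling fits

Events are kept when amplitude > 5 pA and 20–80% rise time < 1 ms; 30–50
events per cell are expected (a warning flags samples outside that range —
pooled multi-cell samples trigger it deliberately). The multiplicative fit
scans factors 1.00–2.00 in steps of 0.01, covering the effect sizes
homeostatic scaling produces (both grid and α = 0.05 are configurable), scaling either 100% of the control
distribution (deterministic elementwise multiplication) or 50% (half the
output drawn with replacement from the empirical control distribution and
scaled, half drawn unscaled; the empirical distribution is used because the
underlying distribution is non-parametric). Each candidate is compared with
the deprived sample by a two-sample K-S test; the best factor is the one
with the highest non-significant p (p > α), or "no fit" if none clears α.
Because the 50% construction is stochastic, its p per factor is the median
over 100 resampled constructions by default (mean available); a single
draw would make the fit seed-dependent. `compare_fraction_models` runs
both modes and prefers the one with the higher best p; model selection
between a uniform shift and a half-scaled mixture is reliable at pooled
sample sizes (~200 events) but near chance at single-cell sizes (~40
events), where the two hypotheses are statistically indistinguishable.

## Calcium analysis

Raw traces are detrended by subtracting the rolling 8th percentile of a
±15 s window (truncated at the edges) and dividing by it:
`100·(F − F0)/F0`. Division by the same rolling baseline is adopted — the
subtraction alone would leave the signal in raw units rather than %ΔF/F0.
Note the estimator's intrinsic behavior: a low percentile sits below the
local mean, so noise and curvature leave a small positive offset in the
detrended signal; a constant trace detrends to exactly 0%.

Activity is the rectangle-rule time integral of %ΔF/F0 (optionally
normalized to branch 1 of a pair). Pair similarity is Pearson correlation
plus plug-in mutual information from a 10×10 joint histogram over each
signal's observed range (matching the model's discretization granularity;
the plug-in estimator's upward bias at finite samples is small at
trace-length n).

Events are contiguous excursions ≥ 15% ΔF/F0; the offset rule — first
frame below half the threshold after the peak — is this package's choice.
An event is **branch-specific** when the partner branch has no
supra-threshold frame within ±0.5 s of the event span; the 0.5 s overlap
window is likewise a package default, chosen to span the rise time of
typical GCaMP6f transients at these frame rates. Per branch, the branch-specific
fraction is the summed branch-specific event integral as a percentage of
the branch's total activity integral; the pair difference is
|BS₁ − BS₂| as a percentage of the mean of the two branches' total
integrals. Event-count monotonicity in the threshold holds for isolated
transients but can be violated by multi-peaked excursions that split at
higher thresholds.

## Synthetic generators

The generators produce data with the statistical structure the analyses
assume; they start at quantified measurements (sizes, amplitudes, traces,
profiles) and render no images.

* **Spine censuses** — positions accumulate shifted-exponential gaps
  (minimum 0.5 μm, mean 4.0 μm: matches the reported mean spacing without
  asserting a distribution); baseline sizes are lognormal (scale 10 a.u.,
  σ = 0.5). Deprivation happens between 0 h and the next timepoint on a
  Bernoulli(0.5) subset of branches; loss is independent per spine
  (probability 0.15), i.e. spatially unclustered, matching the negative
  clustering finding the null calibration relies on. Survivors on a branch
  with fractional loss L are multiplied by (1 + coupling·L), coupling = 1,
  which produces the negative density-size correlation across branches.
  Measurement noise is lognormal with a per-spine CV of 0.05 and a
  per-branch per-session CV of 0.05; combined they give a normalized-ratio
  SD of ≈ 0.078, so ≈ 10% of control spines exceed 1.1 — the calibration
  the 1.1/45% thresholds presuppose — and the branch-level component
  supplies the overdispersion that pushes the derived fraction threshold
  toward the 0.3–0.5 range. An `excitatory` preset uses denser spines
  (16 per branch, 3.5 μm spacing) and sub-day timepoints; the machinery is
  identical. Ground truth (per-branch loss fraction and size factor, spine
  fates) is always returned.
* **mEPSC samples** — control amplitudes are 5 pA + lognormal (scale 7 pA,
  σ = 0.4; all events pass the filters), rise times normal (0.6 ± 0.15 ms,
  clipped below 1 ms); the deprived sample multiplies a known fraction of
  control-distributed draws by a known factor.
* **Calcium pairs** — 240 s at 10 Hz around a baseline of 100 a.u.; shared
  events (1.5/min) injected into branch1/branch2/within-branch with ±10%
  amplitude jitter, branch-specific events (0.5/min) into exactly one
  branch, independent events into the different-cell trace; kernels rise
  over 2 frames and decay with τ = 1 s; slow sinusoidal drift (amplitude 5
  a.u., period 120 s) and Gaussian noise (SD 2 a.u.). The event log carries
  each event's analytic kernel integral.
* **Intensity profiles** — 21-point profiles, background 100 ± 10; GFP has
  a clear central peak; co-localizing spines carry GluA2/GRIP1 peaks
  `snr`·SD above background at the GFP peak.

What the generators do *not* emulate: imaging artifacts (registration
error, saturation, bleaching), spine birth/death dynamics beyond a single
loss epoch, non-multiplicative amplitude changes, bursting or correlated
event timing, and any anatomical structure beyond linear branches. Tests
passing on these data validate the estimators' correctness and calibration
under the stated statistical assumptions, not their robustness to real
imaging pathology.

## Problem sizes and runtimes

The default experiment (100 repetitions × 1000 patterns) runs in ~1 s.
Test-suite calibration runs use 100 synthetic censuses of 30 branches with
300-shuffle permutation bands, 50 mEPSC model-selection replicates at 200
pooled events with 20 resampled constructions per factor, and five
fixed-seed calcium pairs; the full suite completes in under two minutes on
one CPU.

## Known limitations

* The MI estimator reads the deterministic-map entropy; if outputs were
  instead compared against discretized input values the estimate would
  change, though not the direction of the comparison.
* The 50%-scaling fit's resampled construction means its best factor has
  sampling variability of about one grid step at realistic sample sizes.
* The cluster-profile permutation band is a pooled ratio estimator;
  per-bin coverage is nominal only where neighbor counts are adequate.
* `chance_increasing_fraction` inherits ~0.6 pp Monte-Carlo SE at the
  canonical 100 × 30 procedure size.
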