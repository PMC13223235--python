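# Methods

This note documents the models, parameter choices, and numerical decisions
behind `feargen`, and what the synthetic-data validation does and does not
establish about real data.

## Imaging model and ΔF/F quantification

Each trial is a 20-s acquisition at 50 Hz, segmented 225 pre-odor / 350
odor / 425 post-odor frames. Per ROI, ΔF/F_t = (F_t − B)/B where B is the
mean ROI fluorescence over the final second (50 frames) of the pre-odor
period. ΔF/F is invariant to multiplicative rescaling of F but not to
additive offsets; camera bias must be removed upstream. The odor-evoked
peak is the maximum ΔF/F between odor onset and odor offset + 0.5 s (a lag
allowance for indicator kinetics; configurable). Ties break to the earliest
frame. Before peak detection, the pipeline applies a 100-ms boxcar to the
ΔF/F trace: a raw maximum over ~400 noisy frames is upward-biased by
E[max of noise], which cancels in neither numerator nor denominator of the
percent-change ratio; smoothing suppresses that bias while leaving a
noise-free plateau response untouched (set `smooth_frames=1` to disable).

The drug effect per ROI×odor is 100 × (post-drug mean peak − pre-drug mean
peak)/(pre-drug mean peak), with peaks averaged across recorded trials
within each phase *before* the ratio (one dependent variable per ROI; the
alternative — averaging per-trial ratios — is more variable and was not
used). Mock trials (2% odor strength, first four of each 8-trial block) are
flagged at generation and must be excluded before effect computation; the
table-level API refuses unflagged mixing.

Temporal profiles take the maximum ΔF/F in four consecutive 2-s intervals
from odor onset. The four intervals span 8 s while the odor lasts 7 s, so
the final interval includes 1 s of the post-odor period — the only
consistent reading of four equal 2-s bins.

Cumulative percentile curves use the ≤-empirical CDF (percentile of x =
fraction of values ≤ x); midpoint plotting positions (i − 0.5)/n are
available as an option.

ROI curation: real experiments select ROIs manually per animal and odor.
The automated stand-in keeps ROIs whose trial-averaged peak exceeds 3× the
baseline-ΔF/F SD; explicit per-odor ROI lists (as the synthetic ground
truth provides) override it.

## Spatial analysis

Overlap and proximity are computed center-to-center on µm-calibrated ROI
positions (pixel centers × µm-per-pixel; default calibration 10 µm/pixel,
a required input in principle since rig calibrations vary). A CS− ROI
overlaps the CS+ representation when its center lies within 70 µm (one
small-glomerulus width) of any CS+ ROI center; proximity categorizes ROIs
at 400 µm (~four glomerular widths) from the maximally responsive pre-drug
CS+ ROI. Both cuts are boundary-inclusive ("within"), fixed so tests are
deterministic; on continuous data the boundary has measure zero. Mask-level
overlap (intersection of ROI areas) is deliberately not used: the operative
definition is a distance threshold equal to a glomerulus size.

## Behavioral metrics

The open field is an 18 × 18 unit box (unit-agnostic; all zone math is
invariant to rescaling) partitioned into 9 equal square zones with
half-open boundaries (left/bottom inclusive). Odors hang in the corners,
MV and BA adjacent. Dwell time accrues by left-Riemann rule — each
inter-sample interval belongs to the zone of its starting sample — which
converges at the 25 Hz sampling used here. Corner distances are
time-weighted means to the exact arena corners.

Freezing sessions last 120 s per odor; the first 30 s are excluded as
acclimation and immobility is the percentage of the remaining 90 s spent
in bouts with centroid speed < 2 units/s sustained ≥ 1 s (both
configurable; tracking-software internals differ, so these are standard
freezing proxies rather than a reimplementation of any product).
Conditioned animals are retained only if CS+ immobility exceeds the
highest other-odor immobility by ≥ 5 percentage points (boundary
inclusive).

The habituation/dishabituation assay is a 14-trial series (mineral oil,
then 4 trials each of three odors, then a return to the first odor, each
≤ 50 s of investigation). The summary aligns trials by within-odor
position and reports dishabituation contrasts: switch-trial investigation
minus the preceding fourth habituation trial.

## Occupancy models and AIC

The four hypotheses are minimal parameterizations of verbal models. A zone
with avoidance weight a ≥ 0 gets unnormalized mass e^(−a), others 1:

| model              | weights                              | k |
|--------------------|--------------------------------------|---|
| no_fear            | none (uniform 1/9)                   | 0 |
| cs_specific        | a_MV                                 | 1 |
| gradient           | a_MV ≥ a_BA ≥ 0 (HEX at baseline)    | 2 |
| overgeneralization | one shared a on MV, BA, HEX          | 1 |

The gradient's ordering constraint is enforced by reparameterization
(a_BA = b, a_MV = b + d, b,d ≥ 0).

The likelihood is a multinomial counts kernel Σ_z c_z ln p_z over zone
dwell counts pooled across mice (fixed-effect pooling; per-mouse random
effects are out of scope), with the multinomial coefficient omitted
consistently across models so it cancels from every comparison. Dwell
times are converted to counts at one effective observation per 5 s
(largest-remainder rounding, so totals are exact) to blunt the serial
autocorrelation of a continuous path. This likelihood is a documented
stand-in construction: it is the simplest model consistent with scoring
"relative likelihood given the avoidance data", not a reconstruction of
any particular study's unpublished likelihood — printed AIC magnitudes are
therefore not comparable, while the AIC → evidence-ratio arithmetic
(exp(ΔAIC/2)) is exact and is validated against published figures.

Fitting uses a deterministic coarse grid over the constrained weights
(61 points on [0, 6] for one-parameter models, 25² for the gradient)
followed by local refinement (bounded scalar minimization / L-BFGS-B);
with ≤ 2 parameters and a smooth concave-like objective no stochastic
optimizer is warranted. A weight of 6 corresponds to a corner probability
of ~3×10⁻⁴ — effectively complete avoidance. Zero-probability zones with
observed counts return −∞ explicitly. AIC ties break toward fewer
parameters. AICc is available nowhere by design (cohort-level counts are
large relative to k).

A known property of this selection procedure: when the generating model is
nested inside a competitor (no_fear inside everything; cs_specific inside
gradient), the probability of selecting the true smaller model is bounded
by the chi-bar-squared boundary distribution of the likelihood-ratio
statistic against the +2-per-parameter AIC penalty — about 0.92 per
nesting competitor, independent of sample size. Recovery rates for
nested-true scenarios therefore plateau near 92% (cs_specific) and 89%
(no_fear against three competitors) no matter how much data is simulated;
the validation study reports the measured rates.

## Synthetic-data generator

**Imaging.** Glomeruli are isotropic 2-D Gaussians (σ = radius/2, radius
35 µm) placed by rejection sampling with 70 µm minimum spacing on a 640 µm
field at 20 µm/pixel (32 glomeruli, 12 responders per odor by default).
The temporal kernel ramps to plateau within 0.5 s of onset and decays
exponentially (τ = 1 s) after offset, so the peak is well defined inside
the odor window. Odor tuning fixes joint-responder counts exactly: by
default 4/12 of MV responders also respond to BA but only 1/12 to HEX,
mirroring the greater representational overlap of similar odors.
Amplitudes are gamma-distributed nominal center values (mean 0.30,
floor 0.12 ΔF/F); averaging a Gaussian footprint over its ROI disc
attenuates them by (1 − e⁻²)/2 ≈ 0.43, so effective ROI responses span
the ~5–15% ΔF/F typical of curated glomerular responders. Baseline
fluorescence is 100 counts with additive Gaussian frame noise of 1 count
(~1% shot noise) — inter-trial variability magnitudes are free parameters
here, chosen once for realism. Post-infusion trials scale the evoked
signal by an odor-specific multiplier times a 0.95 rundown factor
(the ~5% nonspecific decline seen under vehicle): conditioned sessions
use (MV 1.10, BA 1.25, HEX 1.40) — blockade affects the threat-predictive
odor least — and control sessions use 1.40 for all odors. With zero
noise the measured drug effect equals 100·(multiplier·rundown − 1)
exactly, giving the pipeline a closed-form oracle.

**Behavior.** The zone sequence is a Metropolis–Hastings random walk on
the 3×3 zone grid (uniform proposal over 4-neighbours, update every 2 s);
detailed balance makes its stationary distribution exactly the model's
zone-probability vector, and because two grid-adjacent zones form a convex
union, straight-line crossings never clip a third zone. Within a zone the
mouse walks toward a random interior target at 18 units/s and jitters
around it (per-step SD 0.5). The 2-s hold makes the zone process
decorrelate on the ~5-s scale the counts likelihood assumes (measured
count variance inflation 0.76 vs multinomial, i.e. slightly conservative);
residual dwell-fraction bias is ≤ 0.002 absolute. The default "moderate"
avoidance weight is 1.5 (CS+ corner occupancy ~0.03 vs 0.13 uniform),
comparable to strong conditioned avoidance; the gradient model sets BA at
half the MV weight. Cohorts derive per-mouse seeds deterministically from
one master seed (`SeedSequence([master·10007 + i])`-style counters), so
every fixture is exactly reproducible.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: respiration-coupled and hemodynamic signal
components, photobleaching beyond the constant rundown factor, correlated
(shared-source) noise across glomeruli, anesthesia-state drift, wall-following
(thigmotaxis) and grooming bouts in the arena, and inter-animal
heterogeneity in avoidance strength (cohorts share one occupancy vector).
Recovery results certify the *analysis code*, not robustness to these
real-data features.

## Statistics

ANOVA implementations are direct balanced-design sums-of-squares
decompositions (split-plot error terms for the mixed design); unbalanced
or incomplete tables are rejected rather than imputed. Effect size is the
classical η² = SS_effect/SS_total, not partial η². Greenhouse–Geisser ε is
computed from the double-centered covariance of within-subject conditions,
clipped to [1/(k−1), 1]; it equals 1 under compound symmetry and always at
k = 2. Pearson correlation reports df = n − 2 with the two-sided p.
Holm–Bonferroni adjustment delegates to the standard step-down
implementation and is cross-checked against brute-force enumeration in the
tests. p-values are reported to machine precision; comparisons against
"p < .001"-style statements are bound checks only. Under iid-normal null
simulations all three tests are exact, and the validation study verifies
5% rejection within Monte-Carlo error.

## Problem sizes and numerical choices

The validation studies use: one 144-trial session (72 recorded) per seed
on a 32×32-pixel field; 100 conditioned + 100 control sessions for the
effect-ordering study; 200 cohorts × 4 generating models × 10 mice × 5 min
for model recovery; 2000 replicates per test for null calibration. These
sizes put every study's Monte-Carlo error well inside the margins being
asserted while keeping a full run in minutes on one CPU. Noisy imaging
frames are rendered in float32 (the noise floor dwarfs float32 rounding);
noise-free renders stay float64 so closed-form identities hold to machine
precision. Trials render lazily from per-trial seeds, so a session never
needs to hold all frame stacks in memory.

## Known limitations

- The occupancy likelihood ignores within-mouse autocorrelation beyond the
  5-s thinning and between-mouse heterogeneity; AIC values are
  cohort-level and not comparable across likelihood constructions.
- The exclusion rule, immobility proxy, and ROI-inclusion rule are
  reproducible operationalizations of procedures that were manual or
  tool-specific in the original workflow.
- Overlap is center-distance-based; ROI masks with irregular shapes would
  need a mask-intersection variant.
- The arena generator produces occupancy-faithful but kinematically
  simplified paths; speed distributions are not matched to real mice.
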