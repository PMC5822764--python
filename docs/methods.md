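# Methods

## Curve model and extraction

A pixel's fluorescence after an ICG bolus is modeled as a baseline *b*,
a smooth rise to *b + A* over the rise time *Tr* (half-cosine ramp
starting at the arrival time *t0*), and an exponential washout with time
constant *τ* towards a recirculation plateau *ρ·A*:

    I(t) = b                                             t < t0
    I(t) = b + A/2 · (1 − cos π(t−t0)/Tr)                t0 ≤ t ≤ t0+Tr
    I(t) = b + A · (ρ + (1−ρ) e^−(t−t0−Tr)/τ)           t > t0+Tr

ICG binds plasma proteins and recirculates, so curves do not return to
baseline within the 10-min window; the plateau term represents that.
This family was preferred over a gamma-variate because *A* and *Tr* map
one-to-one onto I_max and the rise, so generator ground truth is exact
rather than fitted (a gamma-variate is kept as an alternative family for
robustness checks; it decays to baseline and under-represents
recirculation).

Extraction from a sampled curve proceeds in one deterministic pass:

1. **Baseline.** A provisional onset is the first sample exceeding
   `min + 0.10·range` of the raw curve; the basal intensity is the
   *median* of all samples strictly before it. The median is used
   because the window inevitably contains the sub-threshold early-ramp
   samples; a mean absorbs them and acquires a bias of order 0.5 % of
   amplitude at dense sampling, while the median is exact whenever the
   flat pre-bolus segment outnumbers the early ramp. Curves without such
   a segment (arrival within seconds, rise over minutes) have no
   identifiable baseline from the curve alone — a documented limitation;
   the slow-rise diabetic group lives near this regime.
2. **Net curve.** Intensities minus baseline, clipped at 0 (noise below
   baseline must not create negative area or mass).
3. **Landmarks.** A centered 3-frame moving average (truncated at the
   array ends) is used *only* to locate the peak (earliest sample
   attaining the smoothed maximum) and the onset (earliest sample with
   smoothed net ≥ 10 % of the smoothed peak). Parameter values are never
   read off the smoothed curve, preserving the printed definitions of
   I_max and AUC on raw data.
4. **Parameters.** I_max = max of the raw net curve (earliest tie);
   T_rising = peak − onset; BFI = I_max/T_rising; AUC = trapezoidal
   integral of the net curve over the acquisition; MTT = trapezoid-
   weighted first temporal moment, measured from acquisition start
   (configurable to onset-relative). AUC and MTT are window-limited: no
   tail extrapolation is attempted beyond the last frame, a known
   truncation bias shared by any per-protocol analysis.
5. **Validity.** A curve is invalid with a reason code if constant, if
   onset equals peak (degenerate rise), if the net mass is zero, or if
   I_max falls below 5× the pre-onset noise SD (successive-difference
   robust SD when no usable pre-onset window exists). The 5-SD floor
   suppresses most, not all, background pixels: the maximum of 120 noise
   samples sits near 4–5 SD, so isolated speckle can survive; invalid
   map pixels carry NaN, never 0, to keep map statistics unbiased.

## Regions, QC, stimulation, statistics

**Regions.** The limb is divided into digits (peripheral arterial
input) and dorsum (microvascular circulation) via 8-bit label images
(0/1/2). The canonical region value extracts parameters from the
per-frame spatial mean curve — one vector per region per limb, matching
one value per region in the published tables; per-pixel dispersion
summaries are computed alongside since parameter maps are also of
interest. No automatic segmentation is attempted; masks are inputs (the
generator always emits ground-truth labels).

**Motion QC.** Rigid drift is the integer-pixel translation maximizing
cross-correlation of Sobel gradient-magnitude images (gradients suppress
the global bolus intensity ramp). Frames with less than 5 % of the
stack's maximum gradient energy — pre-arrival frames, which are
featureless — are assigned zero displacement, and the reference is the
earliest structured frame rather than frame 0, whose gradients are pure
noise before the dye arrives; drift completed before any dye structure
exists is undetectable in principle. An acquisition is excluded iff the
drift magnitude (Euclidean norm × pixel size) strictly exceeds 1 cm at
any frame within the first 180 s; integer-pixel resolution suffices
since 1 cm ≈ 20 px at the default 0.5 mm/px.

**Stimulation.** Rest and post-cuff acquisitions are paired per
(subject, limb, side, region); responses are absolute differences of
digit-region BFI, I_max and T_rising, plus the perpendicular distance
|post−pre|/√2 from the y = x line of the pre-vs-post scatter. Hands only
by default: the cuff compresses the brachial artery and no response is
expected distally in the legs.

**Statistics.** Classical equal-variance one-way ANOVA (the published
tables name plain ANOVA despite their large SD disparities — noted, not
"fixed"), pooled-variance pairwise t tests with Bonferroni multiplier
equal to the number of pairs, and Pearson chi-square without continuity
correction for categorical demographics. Each limb is one observation;
n is always reported explicitly.

## Synthetic cohorts and calibration

The generator emulates the acquisition (120 frames / 5 s / 0.5 mm px;
default desk-scale geometry 96 × 64, a 1:8 scaling of 768 × 512 chosen
so full-cohort analyses run in minutes; full size is available) and a
cohort of 14/11/16 subjects (C/D/M) × 2 limbs × rest/post conditions.

Per group × region, the mean curve parameters are *calibrated by
inverting the extraction*: A and Tr are matched so the extracted I_max
and BFI (rise quantized to the 5-s grid) hit the published foot-table
means; (t0, τ, ρ) are then fitted — first with closed-form moments,
then against the actual sampled extraction — so the emergent
window-limited MTT and AUC land on the published values, with residuals
scaled by the published SDs. Two published combinations are not exactly
attainable under any single-peak family: the dorsum-D cell's BFI
(10.6 A.U./s at I_max 2907) forces a ~345-s rise, after which its AUC
and MTT cannot both be reached in a 595-s window; the SD-weighted fit
leaves AUC ≈ 1.3 SD low with MTT within 0.4 SD. All other cells close
within ~1 % except toe-D AUC (−8 %, −0.24 SD).

Between-limb variability draws mean-preserving lognormal multipliers
for amplitude and BFI with sigmas from the published coefficients of
variation, correlated at 0.8 (high-volume limbs also fill fast); the
rise time is derived as Tr·(amp factor)/(BFI factor) so the *ratio*
statistic BFI keeps its published arithmetic mean. Without the
correlation, all BFI spread becomes rise-time spread and the emergent
MTT SDs overshoot the published ones several-fold; with it they track
the published column. The published joint spread (BFI CV up to ~100 %,
MTT CV ~5–10 %) is still not exactly reproducible under any single-bolus
family, since BFI spread must move the first moment. 90 % of the
variance is a subject-level effect shared by both limbs. Arrival jitter
(SD 12 s), washout and plateau jitter use fixed realistic scales — the
published text does not constrain them.

Within a stack, per-pixel amplitude (±6 %) and arrival (±2 s) vary as
spatially smooth Gaussian-filtered fields; noise is additive Gaussian
with shot-like variance σ = ν·√I, ν = 2 by default (unconstrained by the
text; stated as config, not claimed as faithful). Everything is
bit-for-bit reproducible from (config, seed); cohort items are
regenerated on demand from per-item seeds recorded in the manifest.

Hands have no published kinetic table. All groups' hands borrow the
control foot kinetics — peripheral diabetic disease manifests distally,
and the groups separate through the stimulation response, consistent
with similar pre-stimulus BFI ranges across groups in the published
scatter. Responder post/pre BFI ratios: C ~ N(2.0, 0.5) truncated to
[1.2, 3.2]; D ~ N(1.0, 0.6) on [0.3, 2.2] (mixed increases and
decreases); M ~ N(1.0, 0.05) on [0.85, 1.15]. The post condition scales
digit amplitude by √ratio and divides the rise by √ratio, so BFI scales
by the ratio while I_max and T_rising each respond, matching the
qualitative pattern that all three deltas are smallest in the M group.

## What the synthetic data does and does not show

The generator reproduces the acquisition geometry/timing, the published
group kinetics with realistic between-limb spread, shot-like noise,
rigid drift, and the group response structure. It does not model optical
physics (depth-dependent attenuation, scattering), vessel-tree texture,
non-rigid motion, arrhythmic arrival, or inter-protocol variation — so
green tests demonstrate correctness of the algorithms under the stated
study conditions, not robustness to every property of clinical images.

A measurement property worth knowing: at 5-s sampling with 3-frame
landmark smoothing, rises shorter than ~15 s cannot be resolved, so the
group-mean BFI of fast-rise draws saturates low; the correlated
variability model keeps this bias small at the published parameter
levels.

Parameter recovery under noise is limited by the raw-maximum I_max
estimator the definitions prescribe: with peak-amplitude SNR 20
(σ = I_max/20), the maximum over the handful of near-apex samples is
biased upward by ~0.75 σ and spreads ~0.8 σ, so only ~40 % of draws land
within 5 % of truth and ~55 % of rise times within one sample; ≈95 %
rates would require SNR ≈ 50. The acceptance suite states this check at
SNR 20 and it fails by design of the estimator; smoothing the peak
estimate would trade this variance for bias on the printed definitions
and is deliberately not done.

## Numerical choices

- Peak and onset ties resolve to the earliest sample; no sub-sample
  interpolation anywhere (deterministic at 5-s resolution).
- Moving-average windows truncate at the array ends (no padding values
  invented).
- MTT reference is acquisition start by default — matching the published
  279–345 s magnitudes over a 600-s window — with an onset-relative
  option.
- Degenerate inputs (constant curves, zero-variance ANOVA groups, zero
  chi-square marginals, empty masks) are flagged or rejected explicitly,
  never silently coerced.
- The problem sizes used by the test suite and the acceptance script
  (96 × 64 geometry, 100 cohort replicates for ordering frequencies,
  1000 draws for recovery rates) were chosen so a full run completes in
  minutes on a single CPU while keeping Monte-Carlo error well below the
  margins being tested.
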