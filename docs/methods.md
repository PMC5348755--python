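# Methods

## Scope and data model

The package analyses long-format paired measurements from a
method-comparison study of cardiac output (CO, L/min) and stroke volume
(SV, mL): one reference method (`td`, transpulmonary thermodilution,
calibration state `na`) and one or more pulse-contour test channels
(e.g. `pR` radial, `pF` femoral), each observed `precal` (before) and
`postcal` (after) the device's on-demand auto-calibration. Timepoints are
ordered categorical labels (default T0–T7); elapsed time is not modelled.

Thermodilution values arrive as triplicates with paired global
end-diastolic volume (GEDV) readings. A triplicate is reduced to its mean
CO when the GEDV relative range (max − min)/mean is ≤ 10 %; a wider
spread marks the set unreliable and requires a fourth dilution, after
which the GEDV-extreme reading (largest |GEDV − median GEDV|) is dropped
and the remaining three averaged. Ties are broken by CO deviation from
the CO median, then by larger GEDV and CO value, so the rule depends only
on the values, never on reading order. The 10 % criterion is interpreted
as relative range because no finer definition is standard; both the
threshold and the spread rule are parameters.

## Repeated-measures Bland-Altman

Differences are d = reference − test by default (a negative bias means
the test device over-reads); the convention is switchable. Because the
true CO genuinely changes between timepoints, the variance of d is
estimated with the variance-components approach for multiple observations
per individual: a one-way random-effects ANOVA of d on subject gives

    within_var  = MSW
    between_var = max(0, (MSB − MSW) / m0),   m0 = (N − Σmᵢ²/N)/(n − 1)

for n subjects contributing mᵢ differences (N = Σmᵢ), and

    sd_diff = sqrt(within_var + between_var),  LoA = bias ± 1.96·sd_diff.

A negative moment estimate of the between component is clamped to zero
and flagged. When every subject contributes exactly one pair the
decomposition is undefined and the ordinary single-measurement SD is used
(flagged `simple_fallback`); with this fallback the repeated-measures
analysis coincides exactly with the classic Bland-Altman. The
implementation is verified against a longhand sums-of-squares oracle on
all replicate patterns of 2–5 subjects × ≤4 pairs to 1e-10.

Percentage error is PE = 1.96·sd_diff / ((mean_ref + mean_test)/2) × 100,
with the two method means taken over the same aligned pairs. PE is
scale-invariant. No confidence intervals on the LoA are computed.

## Trending analysis

Per subject, changes are taken between consecutive *observed* timepoints
of a single calibration state (both interval ends precal, or both
postcal). A missing intermediate timepoint is bridged and the step gap
recorded, so catheter failures reduce precision rather than discarding
subjects.

Four-quadrant concordance: a change pair is concordant iff
Δref·Δtest > 0. Pairs with a zero change in either method lie on an axis
and are dropped from the denominator. The central exclusion zone removes
pairs with (|Δref| + |Δtest|)/2 < zone (default 0.75 L/min; `either` and
`both` membership rules are available); rates are reported with and
without the zone, and an empty denominator yields an explicit
"undefined" (None), never 0 %.

Polar transform: for the vector (Δref, Δtest), θ is its angle from the
reference axis; vectors with negative mean change are reflected by 180°
into the right half-plane; the reported angle is θ − 45°, i.e. relative
to the line of identity, and the radius is |Δref + Δtest|/2 — the mean CO
change, in the same units as the 0.5 L/min polar exclusion zone. The
radius definition follows the "mean CO change" reading; the alternative
reading (mean CO level) is noted but not implemented. Angular bias is the
arithmetic mean of the included angles (reflection keeps angles near 0, so
a circular mean is unnecessary; this is a documented approximation), and
polar concordance is the percentage of included points with |angle| ≤ 30°
(inclusive; zone exclusion is strict `radius < zone`).

## Fluid responsiveness

ΔSV % = 100·(SV_post − SV_pre)/SV_pre across the study's fluid-challenge
interval (default T4→T5); a responder has ΔSV % strictly greater than
10 %. The test device's pre-bolus SV is always the auto-calibrated value;
the post-bolus SV is taken either auto-calibrated (`postcal-postcal`) or
uncalibrated (`postcal-precal`), and both pairings are reported by the
pipeline. Agreement is the count of subjects with matching responder
flags. Spearman's ρ (average ranks for ties) compares the two ΔSV %
series; its two-sided p-value uses the t approximation for n ≥ 10 and
exact enumeration of all rank permutations below that. Correlation
coefficients are compared with the Fisher z transform,
z = (atanh r₁ − atanh r₂)/√(1/(n₁−3) + 1/(n₂−3)), which assumes
independent correlations; when the two correlations share the reference
arm (radial vs femoral against the same thermodilution series) this is an
approximation, reported as printed in the field's practice.

## Descriptive summaries and baseline contrasts

Each variable/timepoint cell is summarised as mean (SD) when a
Shapiro-Wilk test at α = 0.05 is non-significant and as median (25th–75th
percentile, linear-interpolation convention) otherwise. Every
post-baseline timepoint is compared against baseline with a paired
contrast — paired t when the paired *differences* pass Shapiro-Wilk,
Wilcoxon signed-rank (zeros dropped, Wilcoxon's convention) otherwise —
flagged significant at α/m with m = 7 by default (seven post-baseline
timepoints). The normality decision is made per contrast.

## Synthetic study generator

The generator emulates the design of a cardiac-surgery validation study:

- **Subjects/schedule**: 25 subjects, timepoints T0–T7; population CO
  means (4.3, 6.8, 6.2, 5.9, 5.5, 5.9, 5.8, 5.9) L/min with SDs
  1.2–1.7 L/min — low at baseline, elevated after bypass, ≈5.9 L/min
  overall. 80 % of the variance is a shared per-subject effect, the rest
  independent per-timepoint jitter. Heart rate follows the same scheme
  (≈59 bpm at baseline, ≈80 after bypass); SV = CO/HR × 1000.
- **Fluid bolus**: between T4 and T5 the true SV changes by a drawn
  ΔSV %: responders (fraction 7/22) draw N(20, 6) %, non-responders
  N(2, 5) %. T5's true CO is recomputed from the overridden SV.
- **Thermodilution**: triplicate readings = true CO + N(0, 0.3) L/min;
  GEDV readings around a per-subject mean (N(1500, 200) mL) with 2 % CV.
  If the GEDV spread exceeds 10 % (or an optional outlier is injected), a
  fourth reading is drawn and the standard reduction rule applied.
- **Devices**: test = scale·true + bias + subject_offset + drift·step
  + N(0, noise_sd). The per-subject offset (SD 1.4/1.3 L/min radial/
  femoral) models the demographic compliance estimate of an uncalibrated
  monitor; additive biases (+0.31/+0.56 L/min) make the device over-read
  site-specifically. The auto-calibration state removes accumulated drift
  and redraws an independent residual, but keeps the subject offset
  (auto-calibration does not improve accuracy, only trending). Drift
  defaults (0.2/0.15 L/min per step) are illustrative: no quantitative
  drift magnitude is established for these devices.
- **Determinism**: all draws come from one seeded generator in a fixed,
  documented order; identical (config, seed) gives byte-identical output.

What the generator does **not** emulate: arterial waveforms, Windkessel
physiology, the reversed central-to-radial pressure gradient mechanism,
non-Gaussian error tails, or informative missingness (catheter failures
must be imposed by deleting records). A single white-noise term also
cannot jointly reproduce every published study-level statistic: the
defaults land the percentage error near 45–50 % and a fluid-challenge
ΔSV correlation near 0.5, but then four-quadrant concordance sits in the
90s rather than the 70–85 % range reported for real devices, whose
trend-tracking errors are evidently not white. Passing parameter-recovery
tests therefore demonstrates correctness of the statistics under this
generative model, not device realism.

## Numerical and design choices

- Exclusion-zone membership uses strict `<`; concordance limits use
  inclusive `≤`.
- Undefined statistics (empty denominators, all points excluded,
  constant correlation input) are reported as None/null, never as 0, and
  degenerate inputs raise typed errors (CLI exit code 3; validation
  errors exit 2).
- The mean of identical triplicate readings is returned exactly (no
  floating-point averaging), so a noise-free generator yields an exactly
  zero Bland-Altman bias.
- CSV values are parsed with exact string→double conversion so that
  write/read round-trips preserve every record bit for bit.
- Problem sizes in the test suite (e.g. 100 replicates × 500 subjects for
  bias recovery, 10,000 constructed deltas for concordance recovery) were
  chosen so Monte-Carlo error is several times smaller than the asserted
  tolerances.
- Pipeline bundles contain no timestamps and serialize JSON with sorted
  keys, making re-runs byte-identical and diff-able.
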