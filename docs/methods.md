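# Methods

## The measurement problem

In a Fontan circulation a single functional ventricle fills through a
functional mono-atrium, without a subpulmonary pump. Diastolic and atrial
function are assessed from chamber volume–time curves — one cardiac cycle of
volume samples per chamber — acquired at rest and during low-dose
pharmacological (dobutamine) stress. From each pair of curves the package
derives the standard parameter set: ventricular EDV, ESV, SV, EF; early
(first third of diastole) and late (atrial-contraction) filling volumes;
early and late peak filling rates and their ratio (E/A); deceleration time
(DT); atrial maximal/minimal volume, cyclic volume change, early
(reservoir) and late (booster-pump) emptying volumes; and conduit volume,
defined as

    conduit volume = SV − (atrial early emptying + atrial late emptying).

The *reserve* of a parameter is its dobutamine-stress value minus its
resting value. Volumes are indexed to body surface area by the Haycock
formula, BSA = 0.024265 · weight^0.5378 · height^0.3964 (kg, cm, m²).

## Generative model of one cycle

The synthetic generator is a closed-loop, no-regurgitation two-chamber
model in which every flow is a raised-cosine (Hann) lobe, so every derived
parameter has a closed form or reduces to a one-dimensional root-find:

* ejection: one Hann lobe over systole with integral EDV − ESV;
* ventricular inflow: an E and an A lobe inside diastole whose integrals
  (e_fill, a_fill) sum to the stroke volume;
* pulmonary venous return into the atrium is constant over the cycle, with
  VR · T = SV (mass balance);
* atrial volume integrates (venous return − AV flow), AV flow being the
  ventricular inflow during diastole and zero during systole.

Consequences worth knowing:

* The atrium refills whenever AV flow < VR, so the atrial local maximum
  that marks atrial-contraction onset sits slightly *after* the nominal A
  window start — where the A upstroke first exceeds VR. Ground truth is
  therefore *operational*: anchors are located on the analytic flows with
  the same definitions the extractor uses, and "late filling volume" is the
  inflow after that anchor (≈ 0.96 · a_fill), not the raw lobe integral.
* Because all non-A filling is carried by a single E lobe, the model's
  atrial cyclic volume change and peak filling rates run higher than
  typical published levels at matched stroke volume; *reserves*
  (stress − rest differences), which the cohort statistics operate on, are
  controlled exactly (below).
* With E pushed late enough in diastole to reproduce realistic first-third
  filling fractions, an isovolumic plateau appears after end-systole
  (physiologically, isovolumic relaxation).

## Extraction

Curves are represented by a periodic cubic spline. For noisy data the
samples are first smoothed by periodic penalised least squares (circulant
second-difference penalty solved in the Fourier domain; the penalty weight
is set by the discrepancy principle so the residual matches the declared
per-sample noise SD `smoothing_sd`), then interpolated; FITPACK's own
periodic smoothing mode (`s > 0`) was found numerically unstable on
30-frame cycles and is not used. Derivatives come from the spline, not raw
finite differences.

Landmarks: end-diastole/end-systole are the times of the ventricular
maximum/minimum on a dense evaluation (default 1024 points); ties — and,
under smoothing, values within `0.5 · smoothing_sd` of the extremum — are
resolved to the earliest time, anchoring isovolumic plateaus at their
start. Diastole runs from end-systole to the next end-diastole; the
"first 1/3" partition is temporal. Atrial-contraction onset is the last
local maximum of the atrial curve in the latter half of diastole
(prominence ≥ 0.5% of the atrial range, with a 5×-lower retry); if none is
resolvable the onset falls back to diastole start + 2/3 of its duration and
the result carries a `fusion` flag (E–A fusion under tachycardia).

DT operationalises the "linear segment of the downward slope" as the
70–30%-of-peak band of the early-filling rate limb (echocardiographic
convention; band edges configurable): a least-squares line through the
in-band samples is extrapolated to zero rate. Fewer than 3 in-band samples,
or a non-negative slope, yield a missing value with a flag. Atrial emptying
volumes are floored at zero (flagged); conduit volume is never floored —
its sign is diagnostic of model violations.

Verified accuracy (noiseless, 30 frames, 100-cycle grid over EDV 90–170 mL,
EF 40–60%, HR 60–90, systole fraction 0.33–0.40, E width 0.35–0.45 of
diastole, A onset 0.70–0.75): extrema within 0.04 mL, filling/emptying
volumes within ~1%, peak rates within 0.4%, DT within ~1% of truth — the
test tolerances (0.5 mL / 2% / 5%) hold with margin.

**Known limitation — measured early filling under noise.** With per-sample
noise of ~1 mL at 30 frames, the end-systolic anchor can wander along the
isovolumic plateau (the volume valley is flat to cubic order), and the
first-third window edge then lands on the steep E upstroke; the measured
early filling volume is the least robust parameter (per-patient reserve
error SD of several mL, occasionally tens for long plateaus at high
stress systole fractions). This mirrors the known temporal-resolution
caveat of cine imaging. Direction-reproduction checks therefore run on the
generator's cohort table; extractor fidelity is asserted separately on
noiseless curves.

## Cohort generation

Per patient, resting parameters are drawn from median/IQR specs
(normal, SD = IQR width / 1.349) matching the published resting medians:
BSA 1.34 m², HR 71.4, EDV 96.8 mL/m², EF 49.3%, early filling 13.6,
late filling 9.8, atrial minimal volume 25.6 mL/m². Three geometry
inversions make emergent quantities hit their targets exactly in the
noiseless truth:

* the A-lobe volume is solved (closed form + bisection) so the operational
  late filling equals its target;
* the E-lobe start is solved so the first-third filling equals its target;
* at stress, the systole fraction is solved so the atrial cyclic volume
  change equals rest + configured shift (reservoir filling lasts all of
  systole, so cyclic change is monotone in systole fraction).

Unreachable targets are clipped to the feasible boundary and flagged.

Stress parameters are rest + configured shifts. Default shift medians are
the published reserve medians (HR +20 /min; EDV −7.5, early filling −1.6,
late filling +1.0, cyclic volume change +3.0, minimal volume −2.8 mL/m²).
Spreads: HR, EDV, cyclic and minimal volume use the published IQR-implied
SDs; the early-filling (SD 2.2) and late-filling (SD 1.4) spreads are set
narrower than their published IQRs so that the configured median effects
are reliably detectable by a paired Wilcoxon test at n = 57 (normal-theory
power ≥ 99.8%) — with the IQR-implied spreads the power would be ~70–75%
and the direction-reproduction property could not hold in ≥ 90% of seeds.
The stroke-volume shift is centred at zero with SD ~3 mL/m², encoding the
published null finding; under the no-regurgitation mass balance a
median +2.1 shift with published spread would instead be clearly
significant at n = 57.

Exercise outcomes: peak VO2 (30 ± 3.7 mL/kg/min) receives a configurable
Spearman correlation (default ρ = 0.66 within the ECC stratum) to a named
reserve parameter (default atrial early emptying) via a Gaussian copula —
latent normal scores of the realised reserve mixed with independent noise
at ρ_G = 2 sin(πρ_S/6), so the *rank* correlation, the statistic the
analysis uses, is controlled directly. RERmax ~ N(1.07, 0.05) puts ~65% of
subjects past the 1.05 maximal-effort gate. Events are exponential
(default hazard 0.0575/yr, the rate implied by 75% five-year event-free
survival), optionally covariate-dependent through a log-hazard ratio, with
uniform administrative censoring at 6.0–8.2 years; event records include
occasional second events and non-qualifying arrhythmias so the composite
endpoint's qualifier logic is exercised. Curve noise is additive i.i.d.
Gaussian (default 1 mL per sample, a deliberately modest stand-in for
segmentation error); a config knob sets the within-patient correlation of
rest and stress noise (default 0 — no claim of realism is made).

What the generator does *not* emulate: respiratory modulation of filling,
AV-valve regurgitation flow (the grade is carried only as a categorical
covariate), pulsatile venous return, autocorrelated segmentation error,
and any image-domain effect. Passing tests therefore demonstrate correct
recovery of the model's parameters and correct statistics — not robustness
to those real-data features.

## Statistics

* Paired Wilcoxon signed-rank: zeros dropped (Wilcoxon convention; Pratt
  variant available), exact tie-aware null by dynamic programming over
  doubled midranks for n ≤ 25, otherwise normal approximation with
  continuity and tie correction. Two-sided p = min(1, 2·min(tails)), both
  tails inclusive.
* Rank-sum: exact subset-sum DP when both groups ≤ 10, otherwise
  Mann–Whitney normal approximation.
* Categorical tables: Pearson χ² without continuity correction; Fisher's
  exact test whenever a cell is zero (2×2 via scipy; 2×k via a
  Freeman–Halton enumeration summing tables no more probable than the
  observed one).
* Spearman ρ = Pearson correlation of midranks; exact permutation p for
  n ≤ 9, t approximation otherwise; Fisher-z CI with the Bonett–Wright SE.
* Benjamini–Hochberg step-up per declared family (statsmodels), NaNs
  passed through. Default families: the stress-response table as one
  family; the correlation table per outcome; the Cox table as one family.
  `per_table` and `pooled` (correlation + Cox as one family) are available,
  since the original family partition is ambiguous.
* Cox proportional hazards: univariable, Efron ties (lifelines), Wald CI;
  no events raises, non-convergence and |log HR| > 50 are flagged.
* Kaplan–Meier: product-limit with Greenwood variance and log-log CI;
  horizons beyond follow-up with survivors remaining are flagged missing.
* Peak-VO2 analyses are restricted to maximal-effort subjects
  (RER ≥ 1.05); VE/VCO2-slope analyses use all subjects. The submaximal
  segment for the VE/VCO2 slope is all breaths before RER first exceeds
  1.0 (configurable).

Verified on simulation: the Cox model recovers a true HR of 2.0 within
10% in mean over 100 replicates at n = 200 with 95% CI coverage in
[0.90, 0.99], and the KM 5-year estimate matches e^(−5λ) at n = 2000
within Monte-Carlo error.

## Problem sizes and numerical choices

Default dense-evaluation resolution 1024 points/cycle; recovery grids use
100 cycles at 30 frames; oracle checks enumerate up to 2^10 sign
assignments, C(20,10) subsets and 7! permutations, plus 1000 random BH
vectors; survival recovery uses 100 replicates of n = 200 and one KM run
at n = 2000; direction reproduction uses 50 cohorts of n = 57. Extrema
tie-breaks go to the earliest time. Degenerate inputs (flat curves, absent
A waves, all-zero difference vectors, zero-cell tables, event-free
cohorts) return flagged or missing values, never raise past validation.
DT on a normalised scale (DT / RR interval) can be derived by the caller;
it is deliberately not a separate output.
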