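# Methods

This note documents the models, numerical choices and limitations
behind `aquajump`: a simulation-backed implementation of accelerometer
based prediction of vertical ground reaction force (GRF) during
countermovement jumps (CMJ) in water.

## The measurement problem

During continuous jumping in chest-deep water a force plate measures
the vertical GRF; triaxial accelerometers at the seventh cervical
vertebra (C7), fifth lumbar vertebra (L5) and above the tibial
malleolus (TA) measure segment accelerations. Forces in water are
normalised by the subject's *land* body weight (`GRF_V_L_BW`, BW
units) so that buoyancy does not contaminate the normaliser; the quiet
standing force in water (*water body weight*) is reduced below land
weight by buoyancy and only serves as the contact-detection reference.
The analysis unit is one landing: its peak normalised force and the
peak three-axis resultant acceleration of each wear-position inside
the landing contact.

## Intensity protocol

Exercise intensity is prescribed by heart-rate reserve (HRR) with a
water adjustment:

- predicted maximum: `MHR_pred = 206.9 − 0.67·age`;
- immersion adjustment: `MHR_water = MHR_pred − (RHR_land − RHR_water)`;
- Karvonen target at fraction f: `(MHR_water − RHR_water)·f + RHR_water`,
  with f ∈ {0.50, 0.65, 0.80} by default (configurable).

Cadence starts at 80 jumps/min and rises 5 jumps/min every 20 s until
the heart rate reaches the phase target; five further jumps are then
performed at frozen cadence. Labelling rule: the first 1 Hz heart-rate
sample at or above the target opens the terminal window; because the
true crossing is only localised to the sampling interval ending at
that sample, landings from `t_cross − 1/fs_hr` onward are candidates
and the first five receive the phase label. The simulator labels its
own output through this same function, so there is exactly one
labelling rule in the package.

## Session simulator

No public recordings of this protocol exist, so all validation rests
on synthetic sessions with known truth.

**Force template.** Each jump period (60/cadence s) is piecewise
smooth: quiet stance at the apparent weight `w = 1 − buoyancy_fraction`
(BW), a cosine countermovement dip to `0.5·w`, a sinusoidal push-off,
a zero-force flight (20% of the period), and a landing impulse
(quarter-sine rise, cosine fall; 120 ms, capped at a quarter period)
whose apex sample is set exactly to the drawn peak so ground truth is
exact on the sample grid. Landing peaks are drawn per intensity from
N(0.64, 0.088), N(0.67, 0.075) and N(0.73, 0.099) BW at 50/65/80% HRR,
floored at `w + 0.05` BW so every landing is the maximum of its
contact. The push-off peak is capped at `w + 0.04` BW for the same
reason: a landing contact runs through the next jump's push-off, and
an uncapped push-off would outgrow a weak landing in roughly a third
of stochastic draws.

**Buoyancy.** `buoyancy_fraction` defaults to 0.55 (apparent weight
0.45 BW), consistent with chest-deep immersion for a ~158 cm adult in
1 m of water. A markedly smaller value would push the quiet-stance
force into the lower tail of the 50%-intensity landing-peak
distribution and force heavy truncation of the draws.

**Acceleration link.** Per jump and wear-position, the true peak
resultant is `a = α0 + α1·grf + subject_offset + N(0, σ_a)`. Intercept
and slope are solved from the per-intensity mean accelerations at the
50% and 80% mean peak forces (C7: 1.51→1.61 g, L5: 1.47→1.55 g, TA:
1.55→1.65 g over 0.64→0.73 BW), so simulated marginal means reproduce
the published per-intensity values and L5 < C7 < TA ordering by
construction. σ_a defaults to 0.08 g: with the per-intensity force
spread this puts the within-intensity acceleration–force Pearson r
near 0.77, inside the 0.69–0.78 band reported for the upper-back
positions, and yields pooled adjusted R² ≈ 0.6 and CCC ≈ 0.74
downstream — the agreement regime the method actually operates in. A
per-subject sensor offset (SD 0.04 g) adds realistic within-subject
clustering. The resultant profile (1 g grounded, ≈0 g in flight,
landing bump to the drawn peak, small push-off bump) is decomposed
onto three axes through a slowly wandering tilt, so the Euclidean norm
reconstructs it exactly before white axis noise (SD 0.01 g) is added.

**Heart rate.** First-order relaxation toward an asymptote a few bpm
above the phase target (so the target is crossed in finite time), with
per-phase time constants 8.4/16.0/16.4 s. These were calibrated so the
default cadence ramp yields about 34/45/53 jumps at the three
intensities for a typical subject — the study-scale session — giving
≈1580–1600 jumps for a 12-subject cohort. Between phases the heart
rate decays toward rest (τ = 30 s) until it falls back to the 50%
target, mimicking the walk-to-recover rule. A single published HR time
constant would not reproduce those per-phase jump counts; kinetics are
otherwise inconsequential downstream because only the labelling rule
consumes the trace.

**Cohort.** Subjects are drawn from N(23.6, 1.83) y, N(158.2, 5.33) cm,
N(53.1, 7.50) kg (truncated to 18–45 y, 140–185 cm, 35–90 kg by
redraw). The study reports no resting heart rates; defaults are
RHR_land ~ N(70, 6) bpm with an immersion drop ΔHR ~ N(8, 3) bpm
(immersion bradycardia; the sign is not assumed). All randomness
derives from one `numpy` seed sequence; identical (config, seed) give
byte-identical outputs.

## Signal processing

- **Filter.** Butterworth low-pass, order 6, 50 Hz cut-off, applied
  forward–backward (`sosfiltfilt`) to every channel. Zero-phase
  filtering preserves peak timing at the cost of squaring the
  magnitude response; at 1000 Hz the squared response leaves a 5 Hz
  tone intact to <1% and attenuates 200 Hz below 1e-3.
- **Order of operations.** Each acceleration axis is filtered first,
  then the resultant is formed. The two orders do not commute (the
  norm is nonlinear); the choice is fixed and exposed as a flag.
- **Segmentation.** Contacts are maximal runs of filtered force above
  10% of the water body weight (mean force over a ≥0.5 s quiet-standing
  window). Sub-threshold gaps shorter than 80 ms are merged as
  chatter; contacts shorter than 50 ms are dropped; only contacts
  preceded by a flight-length gap count as jump landings, which
  excludes the initial stance. Intervals are 0-based half-open.
- **Per-jump scalar.** The maximum inside the landing contact, for
  both force and accelerations — impact loading is the construct of
  interest, and the landing cap on the push-off template guarantees
  the maximum is the landing impulse.

## Equation development and validation

Per-jump records are split at the record level (not subject level)
into development and validation sets by a seeded uniform permutation,
`floor(ratio·n)` to development (ratio 2/3); subject-stratified
splitting is available since records cluster within subjects. Backward
elimination starts from the full OLS model over {C7ACC, PWDH, age,
weight} and repeatedly removes the highest-p term while its p-value
exceeds `alpha_remove = 0.10` (a common statistical-package default;
no criterion is published). Exact p-ties remove the later column; NaN
p-values from zero-residual fits count as 0 (never removed); the
intercept is never removed. The estimator follows the scikit-learn
protocol (`fit`/`predict`, `coef_`, `get_params`) and composes with
sklearn tooling.

PWDH enters in percent (0–100): with the published coefficient 0.016
only the percent scale reproduces the published mean prediction of
0.679 BW, so fraction-scale inputs trigger a unit warning.

Agreement statistics are implemented from their formulas: Lin's CCC
uses biased (divide-by-n) moments, per the original concordance
estimator — the n−1 variant differs noticeably at small n; Bland–Altman
limits default to bias ± 1.96·SD (sample SD) with strictly-outside
counting, k configurable; the bias percentage is defined as
mean(measured − predicted)/mean(measured) × 100 (the source material
prints several inconsistent values without a formula, so the
definition is fixed here rather than inferred); the one-way
repeated-measures ANOVA uses the standard subject/condition/error SS
decomposition with no sphericity correction, with Bonferroni paired
post-hocs.

## What the simulator does and does not establish

Passing tests show the chain is *internally correct*: segmentation
recovers every simulated landing across noise levels, noiseless peaks
match truth to <1e-3 BW, backward elimination recovers generating
coefficients within sampling error and rejects null predictors at the
nominal 10% rate, and the agreement statistics match brute-force
oracles. The simulator reproduces the published marginal means,
per-intensity correlations and downstream agreement magnitudes, but it
is not biofidelic: no hydrodynamic drag, no 3-D kinematics, no
inter-jump force variation in waveform shape, a linear
acceleration–force link, and sessions without protocol deviations.
Real-data quantities (the published CCC of 0.7453, adjusted R² of
0.592, bias percentages) therefore guide simulator defaults but are
not asserted by any test; reproducing them exactly would require the
original recordings, which are not public.

## Problem sizes

The default test suite and the acceptance script use a 12-subject
cohort (~1580–1600 jumps, ≈2 minutes of 1000 Hz waveform per subject),
50-seed segmentation sweeps on single-phase sessions, and 100–200-seed
regression-rate experiments on records generated directly from the
reference equation — sizes chosen to mirror the study scale while
keeping a full run in tens of seconds on one CPU.
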