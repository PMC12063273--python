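# Methods

This note documents the models, the numerical choices, and the design of
the synthetic-data generator, in the spirit of the model documentation of
packages like statsmodels or msprime.  It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Signal pipeline

**Conditioning.**  Each gait-speed condition loses its first 10 s and last
5 s (treadmill start/stop transients), then force and marker streams are
low-passed with a 2nd-order Butterworth at 15 Hz applied forward and
backward (`scipy.signal.filtfilt`), then force is polyphase-decimated from
1000 Hz to the 100 Hz motion-capture rate.  "Second-order zero-phase" is
read as a 2nd-order *design* applied in both directions — the standard
biomechanics reading — so the effective magnitude response is 4th-order
and the group delay is zero.  Trimming precedes filtering so start/stop
transients never enter the filter; filter edge effects are confined to
well under 1 s of each boundary while at least 5 s are always trimmed, so
the alternative order would change no extracted metric (asserted by a
commutation test).  No separate anti-alias filter is applied before
decimation: the 15 Hz low-pass already suppresses everything near the
50 Hz output Nyquist.

**Stance detection.**  Initial contact (IC) is the local forward extremum
of the heel (calcaneus) marker relative to the pelvis reference, terminal
contact (TC) the local backward extremum of the toe (second metatarsal)
marker, the standard kinematic event definitions for treadmill walking.
Pelvis-relative coordinates make detection translation invariant.  The
minimum peak separation is 0.4 × the expected stride time, obtained from a
linear cadence model (steps/min = 60 + 40 × speed; configurable).  Stance
intervals are half-open `[ic, tc)` with 0-based indices at 100 Hz; a
physiological guard discards candidate stances shorter than 0.2 s or
longer than 2.5 s; partial cycles at the window edges are dropped and
full stances touching the boundary are flagged `edge`-invalid rather than
truncated.

**Crossover steps.**  A stance is excluded when, at any sample during it,
the contralateral heel or toe mediolateral coordinate lies on (boundary
inclusive) or beyond the belt midline — per-leg force attribution is then
unreliable.  The criterion uses foot placement (markers), not force
heuristics, because the exclusion is about which plate the foot is on; the
midline is configuration (default 0, left belt negative).

**Propulsion metrics.**  The peak is the global maximum of the positive
part of the stance AP-GRF (ties broken to the latest index; propulsion is
a late-stance event).  The propulsion window runs from the last
negative-to-positive crossing before the peak, forward across any interior
negative dip that is followed by another positive lobe (each bridged dip
is counted and its area subtracts), ending at the final
positive-to-negative crossing, so trailing negative lobes are excluded.
Zero-crossings are sign changes between adjacent samples, with the
crossing index at the first sample of the new sign — deterministic on
discrete data; sub-sample interpolation is unnecessary because the 100 Hz
trapezoidal integral already matches closed-form lobe areas within 0.5 %
(tested).  The integration support includes the bounding crossing samples
so the lobe area up to the sign change is captured.  "Corrected for body
weight" is division by mass in kg: the published units (N/kg) identify
mass, not weight in newtons.

**Exclusion rules.**  A condition needs ≥ 23 valid steps per leg
(boundary inclusive); a participant is dropped entirely when two or more
conditions fail, otherwise only the failing conditions are dropped.
Steps invalid for events (crossover, edge) and steps with no positive
lobe both reduce the count — the validity filter is applied *before*
counting, the stricter of the two possible readings.

## Mixed models

All models are fitted by REML with participant as the grouping factor,
using `statsmodels.MixedLM`:

- **Symmetry (stroke):** `sym ~ speed + s0 + speed:s0` with correlated
  random intercept + speed slope.  The response is a fraction (0–1) and
  speed is in m/s, uncentered; `s0` is the *observed* symmetry at the CWS
  condition (not a model-based estimate), constant within participant.
  Its main effect is estimated for correct adjustment but marked
  not-reported.  Participants whose CWS condition was excluded drop out
  of these fits with a logged reason.
- **Symmetry (control):** `sym ~ speed`, random intercept + slope.
- **Per-leg (stroke):** `value ~ speed * leg` with leg coded
  non-paretic = 0 / paretic = 1 (the published negative paretic effects
  fix this reference) and independent random components for intercept,
  speed, leg and speed × leg.  Independent (diagonal) components are used
  instead of a full 4 × 4 covariance: at 15 participants the unstructured
  fit is routinely singular, the generator draws the latents
  independently, and the fixed effects — the quantities of interest — are
  insensitive to this choice.
- **Post-hoc per leg / control propulsion:** `value ~ speed`, random
  intercept + slope; post-hoc fits run only when the speed × leg
  interaction is significant at α = 0.05.  No multiple-testing correction
  is applied anywhere (none is part of the analysis).

**Degrees of freedom.**  Kenward–Roger is not available in the Python
stack used here, so the default is a Satterthwaite approximation computed
directly from the REML surface: for each fixed-effect coefficient,
`df = 2·Vβ² / Var(Vβ)`, with the gradient of `Vβ(θ)` w.r.t. the variance
parameters and the observed REML information both obtained by central
finite differences on a self-contained block-wise REML log-likelihood.
On the study-sized cohorts this yields df ≈ 13–15, the same range a
Kenward–Roger correction produces for these designs.  A between-within
fallback (`n_participants − p`) covers numerical failure and is also
available as an explicit `df_method`.  Estimates and SEs are identical
across df methods (tested); only df and p change.  The published
fixed-effect SEs that anchor the acceptance tolerances are unaffected.
Fixed-effect agreement with an independent REML implementation (lme4 via
Rscript) is asserted to ~1e-3 in the test suite.

**Diagnostics.**  Conditional residuals feed the three standard plots
(normal Q-Q, residual histogram, residual vs fitted) plus a Shapiro–Wilk
statistic as a numeric summary.

## Synthetic cohorts

No raw recordings for this protocol are public, so validation is by
parameter recovery: generate cohorts whose *generative* coefficients are
the published estimates, run the pipeline, and check the fitted
coefficients come back.  The generator therefore defines the study
conditions; its defaults live in `src/gaitprop/data/params_paper.yaml`
with a provenance tag per value.

**Cohorts.**  15 PwCS (CWS ~ N(0.71, 0.18²) m/s truncated to
[0.5, 1.1] and snapped to the 0.05 m/s treadmill grid; mass ~ N(82, 10²)
kg; paretic side 50/50) and 16 controls (CWS ~ N(1.25, 0.15²); mass ~
N(74, 12²)).  Schedules follow the protocol: PwCS walk 0.2 m/s up to and
including CWS in 0.2 m/s increments (randomized), then +0.1 m/s per
condition up to CWS + 0.3; controls walk the randomized 0.4–1.6 m/s grid
plus a CWS condition.  Conditions ≤ 0.4 m/s last 180 s, faster ones
120 s.  The randomized order is recorded but the analysis is
order-invariant (tested).

**Generative model.**  Per metric (peak, impulse) the per-leg condition
means are parameterized as (total, share): the paretic *share* follows
the symmetry mixed model exactly,

```
share_i(v) = s0_i + (β1 + β3·s0_i + u_i) · (v − cws_i)
```

with the published β1/β3 and random-slope SD for `u_i`, and s0_i ~
N(0.40, 0.10²) truncated to [0.10, 0.60] (the cohort-level asymmetry at
CWS; not published, chosen to match the reported asymmetric cohort);
*total* propulsion (sum of both legs) is linear in speed,
`T_i(v) = T0 + kT·v` plus participant deviations.  Per-leg means are
`share × total` and `(1 − share) × total`, so symmetry covariates always
derive from generated legs and the symmetry-model coefficients are
recovered unbiasedly by construction.  Controls use
`share = 0.5 + b0_i + (β1 + u_i)·v` with the left leg as numerator, so
the symmetry intercept is 0.5 by construction.

The total-propulsion parameters are closed-form combinations of published
per-leg quantities rather than free knobs:

- `kT` is the sum of the per-leg speed slopes (peak: 1.6 + 1.2 = 2.8
  N/kg per m/s; impulse: 0.12 + (0.12 + 0.026) = 0.266 N/kg·s per m/s;
  controls: twice the published single slope).
- `T0` makes the expected leg difference at speed zero equal the
  published leg effect: `T0·(2·E[share(0)] − 1) = β_leg`, giving
  T0 = 0.727 N/kg (peak) and 0.345 N/kg·s (impulse) at the 0.40 mean
  CWS share.
- Total slope SDs reproduce the published per-leg slope SDs through
  `var(leg slope) ≈ (1−s̄)²·σ_kT² + T̄²·σ_u²`.

Because `share × total` is mildly nonlinear in speed, the per-leg linear
mixed models see a slightly curved truth; the recovery harness (not
algebra) is the arbiter that the published per-leg coefficients re-emerge
within their published SEs, and the acceptance suite asserts exactly
that.

**Steps.**  Step counts come from the cadence model and the usable
(trimmed) duration — e.g. 120 s at 1.0 m/s gives 87 analysable steps,
~43 per leg, comfortably above the 23-step rule, while deliberate
starvation below it is available for exclusion tests.  Per-step values
are the condition mean times `1 + N(0, 0.10²)` (a 10 % step-to-step CV;
within-condition variability is not published).  Peak and impulse share a
participant-level factor (ρ = 0.8) and a step-level factor (ρ = 0.7): a
leg weak in peak is weak in impulse, and a vigorous step raises both.
The correlations leave every per-metric marginal — and hence every
recovery target — unchanged; they keep the impulse-to-peak ratio, which
sets the push-off duration, physiological.  Shares and totals are floored
(0.05 / 0.02 N·kg⁻¹-scale) with a logged count; floors bind only for
extreme latent draws at speeds far below CWS.

**Waveform mode.**  Each stance is rendered on its leg's plate as a
negative braking half-sine followed by a propulsive lobe whose amplitude
and duration solve the step's target peak and impulse exactly
(half-sine: area = 2AT/π, so T = π·impulse/(2·peak)); when that duration
exceeds 0.75 × stance — slow gait with large impulse at low peak — a
flat-topped lobe (quarter-sine ramps around a plateau) holds the same
peak and area in the available time, the shape slow push-off takes.  The
lobe ends slightly (4 % of stance) before TC so that ±2-sample event
jitter cannot clip it, and a gap before the propulsion window keeps the
filter transition of the braking lobe out of it.  Heel and toe AP
trajectories are cosines phased so every IC is a heel forward extremum
and every TC a toe backward extremum; ML coordinates place feet at
±0.10 m, with injected crossover steps excursing the contralateral foot
0.02 m past the midline.  Round-trip recovery of injected per-step
metrics through the full pipeline is within 2 % (tested; the loss is
filter attenuation of lobe shoulders), and the waveform-route observation
table matches the metrics-route table within 2 % per cell.

**What the generator does not emulate.**  Constant cadence within a
condition (no step-time variability), no double-support force exchange or
vertical-force dynamics, no marker dropout or soft-tissue artifact, no
within-condition fatigue drift, and two-lobe AP-GRF shapes only (atypical
multi-lobe curves are injectable in tests but not generated by default).
Passing recovery therefore demonstrates that the pipeline and models are
correct and unbiased under the stated generative assumptions — not that
the published coefficients are right, nor how the pipeline behaves under
real-world artifacts.

## Problem sizes and determinism

The acceptance script and tests use 50 replicates at the study's cohort
sizes (15/16 participants) for Monte-Carlo means, 6 replicates at 200
participants for the consistency check, and 100 replicates for the
type-I calibration of the post-hoc rule — sizes at which the Monte-Carlo
error of each mean is several times smaller than its acceptance
tolerance.  All randomness flows from explicit seeds (NumPy
`SeedSequence` spawning per participant), so every cohort, table and fit
is bit-reproducible.

## Known limitations

- The stance-estimation literature the protocol references is not fully
  specified there; the pelvis-relative extremum detector implemented here
  is the standard treadmill method but may differ in detail.
- Whether the 23-step rule counts steps before or after
  propulsion-validity filtering is ambiguous; the stricter (after)
  reading is implemented.
- The symmetry-at-CWS covariate uses the observed CWS-condition symmetry;
  a BLUP-based estimate is a defensible alternative and would slightly
  shrink the covariate's spread.
- Symmetry-model covariates are uncentered; centering would change the
  interpretation of main effects but not the fits.
- Two published inconsistencies are carried, not resolved: the control
  impulse model's SE (0.0076) is incompatible with its t (11) — the
  generator uses the β and the separately published SD — and the
  peak-symmetry interaction's SE/t pair is likewise inconsistent.
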