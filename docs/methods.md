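# Methods

## Respirometry model and estimators

Oxygen consumption is inferred from the linear decline of % air
saturation during the sealed phase of an intermittent-closed
respirometer, ṀO₂ = s · (V_loop − V_fish) · α / M. Slopes are fitted by
ordinary least squares over each window and stored as magnitudes
(oxygen declines; a rising fit is clamped to zero and flagged). The
mean fish-free background slope from three trailing cycles is
subtracted on the slope scale — background is measured in the same
chamber on the same %-saturation scale, so correcting before the
volume/solubility conversion keeps the fish-specific V_resp out of the
background term. Corrected slopes that would be negative are clamped to
zero, flagged, and excluded from the SMR pool.

Cycles begin with the closed phase at t = 0: exercised fish enter the
sealed chamber immediately after exhaustion, so the MMR window sits at
the start of the record. Phase intervals are half-open [start, end) and
time is seconds from trial start.

Estimator conventions, all configurable in `AnalysisParams`:

- **MMR**: 60-s windows at 0, 30, 60, … s of *accumulated closed time*
  within the first 15 min of closed time; windows never span a flush
  (slopes are undefined across a re-oxygenation). Ties go to the
  earliest window, with a 1e-9 relative tolerance so fit round-off
  cannot flip the rule.
- **SMR**: lowest ceil(0.10·n) of the whole-cycle values (120-s leading
  / 60-s trailing trims), one pass of 2-SD exclusion about the subset
  mean (sample SD), mean of the survivors. The cycle containing the MMR
  window is excluded from the pool so the post-exercise peak cannot
  contaminate the lowest-10% subset; fewer than 10 cycles triggers a
  warning and uses all values.
- **Recovery series**: sequential 60-s sub-windows inside each trimmed
  closed phase for 4 h post-MMR, then one 3-min window at the start of
  a trimmed closed phase no sooner than 45 min after the previous one.
  Within a trial, fine time points lacking a value for every fish
  (fish enter their chambers at different moments of a cycle) are
  dropped for all fish, matched within a 30-s tolerance.
- **Recovery time**: time of the first sample of the earliest run of 3
  consecutive values inside SMR ± 10%; series exhausted without such a
  run returns the trace end flagged not-recovered.
- **EPOC**: trapezoid of max(ṀO₂ − SMR, 0) on the irregular grid from
  the MMR time (MMR point prepended) to the recovery time.

α (oxygen solubility per % air saturation) is taken from configuration
when supplied, else computed from the Benson & Krause (1984)
equilibrium fit with salinity correction; outputs carry the α used and
its provenance (`alpha`, `alpha_source` columns).

## Kinematics

Umax and Amax are measured over a fixed 75-ms window after the
annotated C-start onset (roughly stage 1 + stage 2 of the reflex).
Speed is the norm of the first derivative of the calibrated (x, y)
path; acceleration is the derivative of speed (tangential magnitude).
Both derivatives use `numpy.gradient` with second-order edges: centered
differences in the interior and second-order one-sided stencils at the
window boundaries. The edge treatment matters — first-order edges bias
Umax low by a·Δt (≈5% of the closed-form value at 240 fps over 75 ms
for a constant-acceleration burst), whereas the second-order stencil is
exact for constant-acceleration motion. No smoothing is applied by
default; a centered moving average over the pixel coordinates is
available for noisy tracking (the pipeline uses none; tracking-software
filtering varies between tools, a comparability caveat for absolute
Amax values). Onset is an input annotation, not auto-detected.

Per fish, the attempt with the highest Umax supplies both reported
values (its Amax is used even when another attempt accelerated harder);
ties go to the earliest attempt. Responsiveness counts pre-contact
C-starts over all attempts; contact-triggered C-starts are
non-responses, so the metric reflects visual/mechanoacoustic rather
than tactile sensing. Attempts without usable kinematics still count in
the denominator.

## Thermal sensitivity

Each fish is tested at one temperature, so interval Q10 =
(R₂/R₁)^(10/(T₂−T₁)) uses arithmetic group-mean rates at the endpoint
temperatures — one value per metric × treatment × interval, not a mean
of per-pair values. Percent change is signed in the cooling direction
(loss on cooling is negative) and is the thermal-sensitivity measure
for non-rate metrics (chase duration, recovery time, responsiveness),
for which Q10 is dimensionally inappropriate. Omnibus summaries average
the per-metric values within an interval × treatment (Q10 over rate
metrics; percent change over all metrics), always excluding SMR, which
is a maintenance cost rather than performance; dispersion is reported
as SD, s.e.m. and quartiles. Q10 is undefined and excluded for
non-positive mean rates. Temperatures stay in °C throughout — Q10
depends only on Celsius differences.

## Inference

Two-way ANOVAs (temperature × acclimation status and interaction) use
type-II sums of squares, which tolerate the mild imbalance of field
sample sizes; one-way ANOVAs cover the wider acute range. Tukey HSD
(α = 0.05) runs on group labels (cell labels for the two-way design).
Degenerate all-equal inputs report F = 0, p = 1 rather than 0/0.
Levene's test uses mean-centered absolute deviations. The
effort–EPOC comparison fits OLS per treatment on group means (one
point per temperature) and tests slope equality via the
effort × treatment interaction of the pooled model. Normality is left
to diagnostic inspection; no automatic transformation and no
multiple-testing layer beyond Tukey.

## Synthetic-study generator

The generator produces every raw input with known truth, emulating the
study design it is meant to exercise: acute exposure (after 3 °C h⁻¹
change) of warm-acclimated fish to 26–2 °C and acclimation to 14–2 °C
in 3 °C steps, bracketing a winter-dormancy threshold near 8 °C.

- **O2 traces**: flushes re-equilibrate instantly to 100% saturation
  (the protocol's flush "ensures full re-oxygenation"); the closed-phase
  decline integrates ṀO₂(t) = SMR + (MMR − SMR)·e^(−t/τ) exactly —
  mono-exponential recovery was chosen because the reference recovery
  curves are not parameterised and the form yields closed-form EPOC
  (= (MMR−SMR)·τ·(1−e^(−t_r/τ))) and recovery time
  (t_r = τ·ln[(MMR−SMR)/(0.1·SMR)]) for oracle tests. Background
  respiration is constant in time (measured once post-trial); probe
  noise is pointwise Gaussian, SD 0.05 %sat (optical-probe scale);
  default τ = 1 h gives recovery times of ~3–4 h, within the observed
  overnight range. Defaults are plausible-trace choices, not estimates
  of any measured animal.
- **Burst trajectories**: straight constant-acceleration paths sampled
  at 240 fps with optional pixel jitter; truth Umax = v0 + a·Δt,
  Amax = a.
- **Performance datasets**: group means follow a piecewise-Q10 model —
  Q10_above (default 2, the passive expectation) at and above the
  threshold, Q10_below (default 5, a modeled constraint) below it, and
  a compensation multiplier (default 1.7) on acclimated groups below
  the threshold, which lowers the recovered acclimated cold-interval
  Q10 to 5/1.7^(10/6) ≈ 2.06. Individuals are lognormal (rates are
  positive) at CV 0.15, n = 12 per group.
- **Full study**: per-metric reference values at 14 °C (Umax 50 cm s⁻¹,
  U_chase 2.5 BL s⁻¹, chase duration 300 s, SMR 60 and MMR 250
  mg O₂ h⁻¹ kg⁻¹, responsiveness 0.85) with metric-specific shape
  parameters; mass from a cubic condition factor on lognormal body
  length (mean 8.8 cm).

What the generator does *not* emulate — and hence what passing tests do
not show about real data: no thermal-optimum plateau or decline above
17 °C (the model is monotone in temperature); Amax is tied to Umax by
the constant-acceleration paths, so its thermal sensitivity mirrors
Umax's; EPOC and recovery emerge from (SMR, MMR, τ) and are not coupled
to chase effort, so the effort-vs-EPOC regression on synthetic data is
flat-ish and its treatment slopes need not differ, unlike animal data
where effort drives EPOC; no probe drift, partial flushes, activity
bouts during recovery, or multi-fish interactions.

## Problem sizes and numerical choices

The default full study simulates 14 groups (9 acute + 5 acclimated),
8 respirometry fish (14-h traces at 1 Hz) and 12 burst fish (5 attempts
each) per group — a complete overnight protocol at realistic sampling
density that runs in well under a minute. Test fixtures use 3
temperatures, 2–3 fish per group and 6–8-h traces; the Monte-Carlo
calibration suite uses 1000 null replicates per test (2000 for the
two-way ANOVA terms, where three term-wise checks share each dataset)
and the parameter-recovery suite 200 replicates. Window selection uses
1e-9 time tolerances so grid points landing exactly on sample times are
included regardless of float representation; slope fits require ≥2
samples (cycles failing this are skipped with a warning); all RNG flows
from explicit integer seeds, making every pipeline run bit-reproducible.

## Known limitations

Besides the generator gaps above: the package consumes tracked
coordinates and does not do video tracking or C-start stage
decomposition; Pcrit/closed respirometry and Ucrit protocols are out of
scope; enzyme pathlength must be supplied (plate-reader geometry is
operator-calculated); continuous thermal-performance-curve fitting
(Topt estimation, Arrhenius parameterisations) is deliberately not
included — the sensitivity layer is interval-based by design.
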