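# Methods

`neoloop` simulates randomised feasibility trials of closed-loop glucose
control in extremely preterm infants. This note records the models, the
parameters that matter, the deliberately open design choices, and what the
simulations can and cannot say about real wards.

## Virtual patient

The physiology module implements a Hovorka-family two-compartment glucose
model with remote insulin action, adapted to neonatal intensive care:
insulin is intravenous (one plasma compartment, first-order elimination,
t½ = 10 min) rather than subcutaneous, and glucose arrives as a continuous
infusion flux rather than meals. The published equations of the controller
family this descends from are not reproduced anywhere for the neonatal
setting, so the structure here is the package's own and every parameter is
a documented, configurable default — not a fitted value.

Two glucose-dependent loss terms depart from the minimal textbook form and
deserve justification. Insulin-independent uptake saturates below
4.5 mmol/L (`f01 * min(1, G/4.5)`), the standard way to keep uptake from
exceeding supply in hypoglycaemia. Renal spill above 9 mmol/L
(`renal_cl * (Q1 - Q1(9 mmol/L))`, threshold low as in glycosuric preterm
infants) bounds the insulin-free system: without it an infant on
8.4 mg/kg/min of dextrose with immature insulin secretion diverges without
limit, and a guideline-managed comparator arm cannot be simulated at all.
Untreated virtual infants therefore plateau in the mid-teens mmol/L, which
matches the clinical picture of severe but bounded neonatal
hyperglycaemia.

Key defaults (all per kg, configurable in `PatientParams`):

| parameter | value | units | rationale |
|---|---|---|---|
| `v_g` | 4.5 | dL/kg | neonatal glucose space ~0.45 L/kg; an adult-sized 1.6 dL/kg makes the pool turn over in ~20 min, so glucose would swing ~3 mmol/L per 15-min control cycle — uncontrollable at any clinically reported performance and far faster than published neonatal traces |
| `f01` | 2.5 | mg/kg/min | non-insulin-mediated uptake, dominated by brain |
| `egp0` | 4.0 | mg/kg/min | endogenous production at zero insulin action |
| `s_base` | 2.2e-4 | (1/min)/(mU/L) | cohort median; chosen so the basal insulin holding 6 mmol/L under default nutrition is ~0.04 U/kg/h, the median closed-loop rate reported clinically — roughly 4% of adult sensitivity, consistent with marked prematurity-related resistance |
| `k_a` | 1/40 | 1/min | insulin-action lag, the dominant control delay |
| `k_e` | ln2/10 | 1/min | IV insulin half-life 10 min |
| `tau_isf` | 10 | min | plasma→interstitium CGM lag |
| `x_egp` | 0.05 | 1/min | effective action fully suppressing EGP |

Insulin sensitivity varies at two levels. Between infants the baseline
`s_base` is log-normal (CV 50%). Within an infant a dimensionless
multiplier follows a log-Ornstein–Uhlenbeck process with stationary median
1, stationary CV 0.30 and reversion time 12 h — "strongly time-varying"
without being untrackable; the exact OU discretisation makes the update
valid for any step size and the stationary CV testable against closed-form
moments. There are no counter-regulatory hormones, no endogenous insulin
secretion, and no mechanistic inotrope effects; an inotrope episode can
only be represented as a sensitivity excursion.

## Sensing

CGM readings are interstitial glucose times a sensor gain, a linear drift
since the last calibration (±2%/h, fixed per sensor), and multiplicative
log-normal noise of CV 7%, quantised to the 0.1 mmol/L display step. No
accuracy statistics were published for this population, so these are
typical values for the sensor generation, not fitted ones. Calibration
against a blood-glucose (BG) reference rescales the gain exactly (folded
drift included) and restarts the drift clock; gains clamp to [0.5, 2.0].
The BG meter has unbiased Gaussian error (SD 0.3 mmol/L). Sensor dropout
episodes arrive as a Poisson process (one per 72 h) with uniform lengths
capped at 210 min, the longest signal loss the closed-loop protocol is
specified to ride out on hourly BG values.

## Closed-loop controller

The controller sees only CGM/BG readings and the infant's weight —
nutrition is deliberately withheld, as in the clinical protocol. Its
internal model is the nominal virtual patient; individualisation happens
through two adaptive quantities updated at each 15-min cycle from the
innovation `e = reading − model prediction`:

* `d_fast` (mg/kg/min): an integrating flux correction with ~30 min time
  constant, expressed as a residual around a built-in turnover prior of
  8.4 mg/kg/min (a population constant, not patient data). The dt-aware
  gain `(1−exp(−Δt/τ))·e·18.016·V_G/Δt` stays stable when readings arrive
  hourly in BG-fallback mode.
* `b_slow` (U/kg/h): a low-pass of the delivered insulin plus an
  error-implied increment (κ = 0.05 U/kg/h per mmol/L), time constant 2 h.
  Each cycle the model's sensitivity multiplier is re-derived in closed
  form so the model's steady-state basal at the 6.0 mmol/L reference
  equals `b_slow` — this is how the dose-response gain is learned. Two
  hours is deliberately faster than a naive "slow" constant: an infant
  entering the 24 h window with a mis-scaled gain must be captured within
  a few hours, and the fast/slow separation (30 min vs 2 h) is preserved.
  Keeping `d_fast` out of the gain calibration matters: calibrating
  against the instantaneous flux makes the controller read its own flux
  corrections as sensitivity changes and under-dose resistant infants.

The glucose state is re-anchored to each accepted reading; `q2`, plasma
insulin and action propagate through the model between cycles.

Insulin is the argmin over the pump-achievable grid (0 to 0.5 U/kg/h in
0.01 steps at the 5 U/kg/50 mL closed-loop dilution) of
`Σ w(g)(g − 6.0)²` along the predicted 90-min trajectory at 5-min
resolution, with `w = 4` below 4.0 mmol/L; ties take the lower rate. Grid
search keeps the optimisation exact and oracle-testable. Three guards
shape the dose: increases are ramp-limited to 0.05 U/kg/h per cycle
(cuts are not), insulin is zeroed whenever the 40-min predicted minimum at
the chosen rate falls below 4.0 mmol/L, and whenever the predicted minimum
over minutes 30–40 falls below 3.5 mmol/L the controller instead commands
the smallest 20% dextrose rate (0.01 steps, cap 1.0 mL/kg/h) lifting that
minimum above 4.0 — insulin and rescue dextrose are never simultaneous.
Prediction integration uses RK4 with stiffness-aware substepping (the
insulin-clearance eigenvalue `s_i·x` can exceed the plain 5-min stability
limit when the learned gain is high).

With sensor data lost, hourly BG values inform the controller for up to
4 h ("bg_fallback"); beyond that it holds the last rates and raises an
alarm rather than dosing blind. Hold behaviour on expiry is a package
decision — the clinical protocol is silent past 4 h.

## Ward guideline comparator

The nurse-executed titration table the control arm follows exists only as
an unpublished supplement, so the shipped table
(`neoloop/data/guideline_rules.yaml`) is an explicit reconstruction:
start 0.02 U/kg/h when SG ≥ 10 (unless already falling >1 mmol/L/h),
±50% steps using the trailing-hour least-squares trend, stop below 4.0,
stop plus dextrose review below 3.5. Evaluations are hourly plus
threshold-crossing alarms; delivered rates quantise to the ward pump grid
(0.05 U/kg/h at 25 U/kg/50 mL — the dilution difference between arms is
exactly the 5× dosing-resolution gap). The nurse response to a dextrose
review starts 0.5 mL/kg/h of 20% dextrose and escalates by 0.5 per
re-review (cap 2.0) until SG recovers past 4.0. The comparator's
*qualitative* sluggishness (late starts, hourly cadence, coarse steps) is
the modelled phenomenon; its absolute percentages are a reconstruction and
are not treated as validated numbers. Users holding the actual supplement
can transcribe it into the YAML.

## Trial protocol and synthetic cohort

The full protocol monitors each infant 0–160 h from birth with guideline
management everywhere except the prespecified half-open window
[48 h, 72 h), where the closed-loop arm switches to MPC (first action at
48:00, last at 71:45 — exactly 96 cycles). Calibrations run 12-hourly on
the ward and 6-hourly during closed loop; clinical BG checks arrive so the
expected total is 5.5/day including calibrations. Arms are assigned by
Pocock–Simon minimisation over gestational-age ({<26, 26–28, >28} wk) and
birth-weight ({<750, 750–1000, ≥1000} g) categories — conventional strata,
as the study's actual cut-points are unreported — with deterministic
assignment to the minimising arm and seeded coin flips on ties. A hard
"≤1 imbalance per category" cannot be guaranteed by any online rule (an
arriving infant whose two categories are imbalanced in opposite directions
forces one of them to two either way); measured over many seeds the rule
keeps mean maximum imbalance ~1.4 versus ~4.3 for coin-flip allocation.

Cohorts default to the demographics of the emulated study arm: GA
N(27.0, 2.4) wk truncated to [22, 34], BW N(962, 164) g resampled below
1200 g, maintenance dextrose N(8.4, 1.5) mg/kg/min, 40% of infants on
trophic feeds (0.3 mg/kg/min, nutritionally minor). The window-only
surrogate (`run_window`) draws entry glucose log-normally around
8.0 mmol/L (σ_log 0.25, clipped to [4, 15]) — matching the reported
baseline — and starts each infant at the steady state sustained by the
ward-quantised basal insulin, since nearly all such infants were already
on insulin at 48 h.

All randomness flows from one integer seed through spawned generator
streams (sensitivity, sensor, meter, dropout, schedule), so any run is
bit-reproducible and arms sharing a seed are paired: same infants, same
sensitivity trajectories, same sensor noise, differing only in titration.

What the generator does *not* emulate: real CGM artefacts (pressure,
warm-up, insertion failures), nurse reaction-time variability, nutrition
protocol changes (a config-gated fluid-change perturbation exists but
defaults off), death/transfer censoring, endogenous insulin secretion and
counter-regulation. Passing the simulated-trial tests therefore shows the
controller masters the modelled variability — sensitivity swings, sensor
error, dropout — not that it would achieve the same percentages in a real
unit.

## Numerical choices

Physiology integrates with classical RK4 at 1-min steps (4th-order
convergence is asserted against a 10× finer reference, <1e-4 mmol/L over
24 h); any negative state clamps to zero with a logged warning rather than
aborting a long trial. Steady states are closed-form (the flux balance is
linear in effective action on each EGP branch), giving an analytic oracle
for controller tests. Glucose unit conversion uses 18.016 mg/dL per
mmol/L. Display quantisation rounds half-up to 0.1 mmol/L. Time-in-band
metrics weight each 5-min reading equally (sample-hold, the clinical
%-of-readings convention) with target band inclusive [4.0, 8.0], wide band
[2.6, 10.0], hyper strict >10.0, hypo strict <2.6; hypoglycaemia episodes
require two consecutive sub-threshold readings (≥10 min) to suppress
single-sample noise. Quartiles use linear interpolation (type 7).
Mann-Whitney p-values are exact by enumeration when min(n) ≤ 8 without
ties, otherwise normally approximated with tie and continuity corrections;
the t test uses the pooled-variance form. No multiplicity adjustment is
applied, matching the analysis convention of small feasibility studies.

Simulation sizes in the shipped tests and the results script — 10 infants
per arm, the 24 h window, five replicates — mirror the emulated study's
own scale; the full 160 h protocol is exercised at smaller n.

## Known limitations

The controller gains, cost weights and caps were tuned in silico against
this same virtual cohort (as the original clinical controller was against
its simulator); they are not transferable claims. The comparator table is
a reconstruction. Insulin requirements scale with the chosen sensitivity
median, so absolute doses track the clinical range by construction, not by
independent validation. Percentages below ~0.5% of a 24 h window (one or
two CGM readings) sit at the quantisation floor of the metrics and should
not be over-interpreted.
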