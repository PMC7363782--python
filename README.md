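# neoloop

In-silico randomised trials of closed-loop glucose control in extremely
preterm infants.

Infants born under ~1200 g are prone to both hyperglycaemia and
hypoglycaemia: endogenous insulin secretion is immature, glycogen stores are
absent, and insulin sensitivity swings widely with illness, inotropes and
parenteral nutrition. Ward practice titrates an insulin infusion by hand
from intermittent glucose values; a closed-loop system instead feeds
continuous glucose monitoring (CGM) readings to a model-predictive
controller that adjusts insulin — and, at low glucose, a 20% dextrose rescue
infusion — every 15 minutes. `neoloop` provides the full simulation stack
needed to study that comparison: a virtual-patient cohort, a CGM error
model, the adaptive controller, a nurse-executed guideline comparator,
trial orchestration and the glycaemic outcome statistics. It is aimed at
researchers prototyping neonatal glucose-control algorithms and trial
designs before touching a ward.

## Model

Each virtual infant follows a Hovorka-family compartment model (per kg,
minutes). With accessible/non-accessible glucose masses $Q_1, Q_2$
(mg/kg), plasma insulin $I$ (mU/L), remote insulin action $x$ (min⁻¹)
and interstitial glucose $G_{isf}$:

$$\dot Q_1 = F_{in} + EGP_0\,\max(0,\,1 - s_I x/x_{egp}) - F_{01}^c - s_I x Q_1 - R - k_{21}Q_1 + k_{12}Q_2$$
$$\dot Q_2 = k_{21}Q_1 - k_{12}Q_2,\qquad \dot I = u(t)/V_I - k_e I,\qquad \dot x = k_a(s_b I - x)$$
$$\dot G_{isf} = (G - G_{isf})/\tau_{isf},\qquad G = Q_1/(V_G \cdot 18.016)$$

where $F_{in}$ bundles parenteral dextrose, enteral carbohydrate and any
20% dextrose rescue; $F_{01}^c$ is insulin-independent uptake (saturable
below 4.5 mmol/L), $R$ renal spill above 9 mmol/L, and the insulin
sensitivity $s_b \cdot s_I(t)$ combines a log-normal between-infant baseline
with a log-Ornstein–Uhlenbeck process in time — the "extremely variable
insulin sensitivity" that makes these infants hard to manage.

The controller is initialised from weight alone and adapts two parameters
online: a fast glucose-flux correction (τ ≈ 30 min) absorbing prediction
errors, and a slow basal-insulin estimate (τ ≈ 2 h) that recalibrates the
internal model's insulin gain. Insulin is chosen by exhaustive grid search
(pump resolution 0.01 U/kg/h at the 5 U/kg per 50 mL closed-loop dilution)
minimising an asymmetric quadratic cost around 6.0 mmol/L over a 1.5 h
horizon; a 30–40 min look-ahead triggers the minimal 20% dextrose rate that
averts predicted hypoglycaemia, and hourly blood-glucose values keep the
loop informed for up to 4 h of sensor loss.

Outcomes mirror the clinical convention: percentage of CGM readings in
4.0–8.0 mmol/L (primary), in 2.6–10.0, above 10.0, below 2.6; mean and SD
of sensor glucose; hypoglycaemia episodes; Mann-Whitney U (exact for small
tie-free samples) and pooled t tests between arms; medians with IQR.

## Worked example

Simulate a small trial (two infants per arm, 80 h protocol with the
48–72 h intervention window) and compare the arms over the window:

```
$ neoloop simulate --n-per-arm 2 --seed 3 --out demo/
simulated 4 infants (2 closed loop, 2 control) -> demo/

$ neoloop analyze demo/ --period intervention
outcome                                             closed loop                control       p
Time 4.0-8.0 mmol/L (%)                        93.9 (92.1-95.7)       56.1 (47.1-65.0)   0.333
Time 2.6-10.0 mmol/L (%)                       99.7 (99.5-99.8)       85.2 (78.4-92.1)   0.333
Time >10.0 mmol/L (%)                             0.3 (0.2-0.5)        14.6 (7.8-21.4)   0.333
Time <2.6 mmol/L (%)                              0.0 (0.0-0.0)          0.2 (0.1-0.3)   0.617
Baseline sensor glucose (mmol/L)                  8.4 (7.8-8.9)          8.2 (8.1-8.3)   1.000
Mean sensor glucose (mmol/L)                      6.0 (6.0-6.0)          7.6 (7.3-7.8)   0.333
SD of sensor glucose (mmol/L)                     1.0 (1.0-1.1)          2.1 (1.7-2.5)   0.333
Insulin (U/kg/hour)                               0.0 (0.0-0.0)          0.1 (0.1-0.1)   0.333
Dextrose (mg/kg/min)                           10.8 (10.6-11.0)          8.9 (8.8-9.0)   0.333
```

Both arms enter the window around 8 mmol/L. The closed-loop infants spend
~94% of the day in the 4–8 mmol/L target with mean glucose pinned at the
6.0 mmol/L reference and no time below 2.6; the guideline-managed infants
drift hyperglycaemic (15% of the day above 10 mmol/L) because the ward
table only starts insulin above 10 and re-evaluates hourly. At n=2/arm no
contrast is statistically significant — run `--n-per-arm 10` for the
study-scale version. `neoloop report demo/` writes the tables for the
intervention and post-intervention periods plus a summary figure
(median ± IQR glucose and insulin over time with the window marked).

The same machinery is importable directly: `cohort.sample_cohort` →
`trial.run_trial` / `trial.run_window` → `outcomes.outcome_table`.

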