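# Methods

This note documents the models, numerical choices and limitations behind
`ventadvisor`: a decision-theoretic advisory engine for mechanical
ventilation that simulates a patient, scores the six competing goals of
ventilation as penalties, searches for the penalty-minimal settings, emits
step-capped advice and visualizes the decision space as hexagon glyphs.

## Forward physiological model

The engine needs a forward model only rich enough to reproduce the
qualitative dependences the preference functions read: how PaCO2, pH,
saturations, tidal volume, frequency and pressures respond to the
ventilator settings.  We use a deliberately minimal, hand-checkable
composition of textbook relations rather than a full multi-compartment
gas-exchange model:

- **CO2.** Alveolar ventilation VA = f (VT − Vd) / 1000 L/min; PaCO2[mmHg]
  = 0.863 VCO2 / VA, converted to kPa.  Vd is a fixed serial dead space;
  there is no high-V/Q (alveolar dead space) term.
- **pH.** Henderson–Hasselbalch, pH = 6.1 + log10(HCO3 / (0.225 ·
  PaCO2[kPa])), with HCO3 = 24.4 + BE mmol/L (a one-line Van Slyke
  simplification).  Anchored at pH 7.40 for PaCO2 5.33 kPa, BE 0.
- **O2.** Alveolar gas equation PAO2 = FiO2 (Pb − PH2O) − PaCO2/RQ with
  Pb = 101.3 kPa, PH2O = 6.3 kPa, RQ = VCO2/VO2; an optional fixed
  additional drop ΔPO2 models low-V/Q regions.  End-capillary saturation
  follows the Severinghaus (1979) closed form S = 1/(1 + 23400/(P³ + 150P)),
  P in mmHg.  Venous admixture uses a single shunt compartment closed with
  the Fick relation.  Neglecting dissolved O2, the arterial/venous fixed
  point has the closed form Sa = Sc − fs/(1−fs)·dS, Sv = Sa − dS with
  dS = VO2/(10·CO·1.34·Hb); substituting back reproduces the mixing and
  Fick equations exactly (machine precision), which the tests verify.
- **Mechanics.** Linear single-compartment mechanics: driving pressure
  dP = VT/C; volume control delivers the set VT, pressure control delivers
  VT = C·Pinsp.  Peak pressure is PEEP + dP in control modes and PEEP + PS
  in support mode; no resistive term is modelled.

### Spontaneous breathing (pressure support)

Breathing pattern is the equilibrium of a chemoreflex drive model.  With
excess e = PaCO2 − Tc (Tc the patient's central drive threshold):

    Pmus = clamp(g_p · e, 0, Pmus_max)
    f    = clamp(f_base + g_f · e − k_ps · PS, f_min, f_max)
    VT   = C · (PS + Pmus)

Defaults: f_base 14 /min, k_ps 0.5 /min per cmH2O, f bounds [6, 45] /min,
g_p 4 cmH2O/kPa; g_f (patient `drive_gain`), Tc and Pmus_max are patient
parameters.  Raising PS deepens and slows breathing (lower f, higher VT,
lower f/VT), which is the behaviour the over/under-support patterns
require; the direction is property-tested.

The equilibrium PaCO2 solves p = PaCO2(VA(p)).  Because VA is
non-decreasing in p, the residual p − PaCO2(VA(p)) is strictly increasing
and the root is unique wherever one exists.  We solve it by 80 bisection
steps on the bracket [0.2, 80] kPa — deterministic, array-vectorizable
across a settings grid, and free of the divergence a plain fixed-point
iteration exhibits at realistic drive gains (the iteration map's slope
exceeds 1 in magnitude).  If even maximal drive cannot produce positive
alveolar ventilation the settings are reported infeasible.

Units are centralized: pressures cmH2O, tensions kPa, FiO2 percent at the
API and fraction internally.

## Preference (penalty) functions

Each of the six goals carries a penalty in [0, 1].  Every axis is a
piecewise-linear ramp from a zero-penalty anchor; axes that read several
variables combine per-variable ramps with a **maximum**, which preserves
monotonicity and keeps each anchor independently calibratable.  Defaults:

| axis | variables | zero anchor | reaches 1 at |
|---|---|---|---|
| oxygen toxicity | FiO2 | 21 % (ramp kinked: 1/3 at 50 %) | 100 % |
| low oxygenation | SaO2, SvO2 | 0.97 / 0.70 | 0.85 / 0.40 |
| lung trauma | VT/PBW, dP, f | 6 ml/kg, 10 cmH2O, 20 /min | 15 ml/kg, 40 cmH2O, 50 /min |
| acidosis | pH | 7.35 | 7.05 |
| muscle atrophy | f (+ VT floor) | 14 /min; floor from 10 ml/kg | 5 /min; 15 ml/kg |
| respiratory stress | f/(VT/PBW) | index 2.5 | index 7.0 |

PBW is the ARDSNet-style predicted body weight (50/45.5 + 0.91·(h−152.4)).
The stress index is the rapid-shallow-breathing index adjusted to PBW; the
red region (index ≳ 5.5) corresponds to a classic f/VT of roughly
80–100 /min/L for a 70 kg adult.  The atrophy VT floor encodes that very
large supported breaths unload the muscles even at preserved frequency.

The total penalty is the plain **unweighted sum** of the active axes — no
weights, no renormalization by the number of active axes.  In control modes
the muscle axes (atrophy, stress) are inactive and excluded; the mask is
keyed to the ventilator mode.

**Severity bands** split the unit scale into three equal parts, *closed on
the low side*: green for max ≤ 1/3, yellow to 2/3, red above.  The closed
boundary is a deliberate calibration: with the driving-pressure ramp
(dP − 10)/30, a peak pressure of exactly 25 cmH2O at PEEP 5 (dP 20) scores
exactly 1/3 and is still green, so the trauma axis leaves the green band
precisely when peak pressure exceeds 25 cmH2O.  A half-open convention
would move the anchor to 24.

`evaluate` clips the simulated pH into the acidosis domain [6.5, 8.0]
before the axis call (the penalty saturates at 1 from pH 7.05 down), so
extreme candidates inside a settings search evaluate instead of erroring;
direct out-of-range calls still raise.

## Advisor

`find_optimum` enumerates a finite grid of candidates (defaults: FiO2 21 %
then 25–100 % in 5 % steps; PEEP 2–16 and inspiratory pressures in 1 cmH2O
steps; VT 300–700 ml in 25 ml steps; frequency 10–30 in 1/min steps; the
current settings always included) and returns the least-total-penalty
point.  The evaluation is one vectorized pass of the forward model over
the whole grid (~10^5 points in well under a second); the unit tests check
it against an independent scalar brute-force enumeration.  Ties within
1e-9 are broken by least total settings change from the current settings
(per-setting |Δ| normalized by its step cap), then lexicographically —
needed for determinism, and it keeps penalty-neutral settings (e.g. PEEP,
which the minimal model ties across) at their current values.

`step_advice` moves every setting toward its optimum by min(cap, gap):
FiO2 5 percentage points; pressures 2 cmH2O, except 3 cmH2O for a PEEP
increase while current PEEP < 10 cmH2O; VT 50 ml; frequency 3 /min.  All
settings may step simultaneously in one advice.  An optimum 5 cmH2O of
pressure support below the current value is therefore delivered as three
steps of 2, 2 and 1 cmH2O.

`advise_loop` iterates simulate → evaluate → optimize → step until the
advice is null.  The optimum is recomputed each step; with a static
patient this reproduces the fixed stepping schedule exactly.  The
configured waiting period between advices (default 5 min, allowed range
5–20 min) is recorded as inter-step time metadata only — no real-time
sleeping.  The default grid is built once from the initial settings;
intermediate stepped settings need not lie on it.

## Hexagon glyphs

Axes are vertical at three columns, x ∈ {−1, 0, +1}: left = support axes
(atrophy up, stress down), center = ventilation axes (trauma up, acidosis
down), right = oxygenation axes (toxicity up, low oxygenation down).  "Up"
always means "too much" harms.  Control modes deactivate the left column,
so the symbol occupies the right-hand side only.  A vertex sits at
base + direction·(0.08 + penalty·scale); the 0.08 minimum offset keeps
zero-penalty shapes visible as a small ring.  The scale depends on the
severity band of the current vector: green 3.0, yellow 1.5, red 0.7.  The
red factor is chosen < 1 so that compression is real: a 0.2 penalty drawn
under green magnification (0.68 units) is longer than a 0.8 penalty under
red compression (0.64 units).  Both polygons of a scene (current blue,
advised/simulated grey) share one scale.  The hexagon outline itself is
fixed and decorative; only the symbols deform.  SVG output is generated by
a small deterministic writer (fixed six-decimal formatting), so identical
scenes are byte-identical documents; geometry is exactly invertible back
to penalties, which is property-tested to 1e-9.

## Pattern classification

A decision list over the penalty vector, in priority order (combined
patterns before single spikes):

1. **Over-support triad** — atrophy, trauma and toxicity all elevated
   (> 1/3): quadrilateral above the three upward axes.
2. **Over-ventilation with hypoxia** — trauma and low oxygenation both
   elevated.
3. **Single spike** — the maximum axis elevated and ≥ 2.0× the next
   highest; the axis fixes the label (trauma→over-ventilation,
   acidosis→under-ventilation, atrophy→over-support, stress→under-support,
   toxicity→over-oxygenation, low-oxygenation→under-oxygenation).
4. **Balanced ventilation trade-off** — exactly the two center axes
   elevated, neither dominating the other: the permissive-hypercapnia
   optimum, where the pressure/pH balance is achieved at abnormal values
   of both.  Classified as the optimal family for the mode, typically with
   a yellow or red background.
5. **Optimal shapes** — nothing elevated: control → optimal control;
   support → bow tie if the center is pinched relative to visible wings
   (max(center) < 0.5·min(wing extents), wings = per-side maxima, both
   ≥ 0.15), else round.
6. Otherwise **unclassified**.

Dominance is relative, so uniformly shrinking a vector never converts one
spike into a different spike.  The wing-visibility floor (0.15) exists
because piecewise-linear ramps put many near-normal support patients at
exactly zero on several axes; without the floor every near-perfect shape
would count as a bow tie.  All thresholds live in `PatternConfig`.

## Scenario fixtures

`scenario_suite()` provides 14 synthetic (patient, settings) pairs whose
simulated vectors classify to every pattern label: optimal volume/pressure
control, permissive hypercapnia, round optimal support at low and moderate
PS, bow-tie optimal support, over-ventilation (± hypoxia),
under-ventilation, over-support, the over-support triad, under-support,
over- and under-oxygenation.  Parameter values are invented to realize the
qualitative clinical pictures with comfortable classification margins —
e.g. the under-support patient combines weak muscles (Pmus_max 4 cmH2O),
preserved drive and partial metabolic compensation (BE +3) so the stress
spike dominates the secondary acidosis; the over-support and bow-tie
scenarios share one patient, two cmH2O of pressure support apart, which
also realizes the simulated-reduction narrative (PS 8 → 6 turns the
over-support spike into a bow tie).  `perturb` applies seeded ±10 %
multiplicative jitter to the continuous patient parameters; the
over-ventilation scenario retains its label in ≥ 95/100 jitters.

What the generator does *not* emulate: measurement noise, sensor tuning of
model parameters to data, cardiovascular dynamics, time-varying patient
state, alveolar dead space, shifted dissociation curves.  Passing tests
therefore demonstrate the engine's internal consistency and its agreement
with the documented constants and patterns — not predictive accuracy on
real patients.

## Numerical choices and degenerate inputs

- Support-mode equilibrium: 80 bisection iterations on [0.2, 80] kPa
  (bracket width shrinks below 1e-10 kPa); infeasibility is reported when
  the top of the bracket cannot clear CO2.
- Settings with VT ≤ dead space raise an infeasible-settings error in
  scalar simulation and are masked to +inf total penalty in grid searches.
- Severity band boundaries carry a 1e-12 tolerance so exact-anchor values
  land on the intended side of the boundary.
- Optimizer ties: 1e-9 absolute window, then minimal normalized change,
  then lexicographic order over (FiO2, PEEP, PS, Pinsp, VT, f).
- All stochastic elements (fixture jitter only) run through
  `numpy.random.default_rng` with caller-supplied seeds.

## Problem sizes

Default grids are exhaustive at desk scale: ~1.1·10^5 candidates in volume
control, ~1.6·10^5 in pressure control, ~5·10^3 in pressure support, each
evaluated in one vectorized pass.  Oracle comparisons in the tests use
scalar enumeration on grids of ≤ 200 points; robustness checks use 100
jittered replicates.  The full test suite runs in well under a minute on
one CPU.

## Known limitations

- The physiological model is a minimal substitute: no EELV/recruitment,
  no CO2 dissociation or CSF buffering, no 2,3-DPG-shifted dissociation
  curve, no cardiovascular interaction, no airway resistance (peak
  pressure is plateau-like).  PEEP consequently has no physiological
  effect in this model and is optimized only through tie-breaking.
- Penalty curves are package defaults calibrated to one printed anchor
  (peak 25 cmH2O green boundary) plus standard clinical reference ranges;
  they are not the proprietary preference functions of any commercial
  device.
- The drive model's interaction between the central threshold and pressure
  support is a declared substitute; the literature the engine emulates
  does not specify it.
- Pattern thresholds (elevated 1/3, dominance 2.0, bow-tie 0.5/0.15) are
  design choices that reproduce the documented example shapes; clinical
  data could motivate different values, and all are configurable.
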