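# ventadvisor

A decision-theoretic advisory engine for mechanical ventilation, with
hexagon "decision space" glyphs.

Choosing ventilator settings is a balancing act between competing harms:
too much inspired oxygen risks oxygen toxicity, too little causes
hypoxaemia; high pressures, volumes or frequencies injure the lung, low
minute ventilation causes respiratory acidosis; for spontaneously breathing
patients, too much pressure support wastes the respiratory muscles while
too little produces stressful rapid shallow breathing.  `ventadvisor`
implements this trade-off explicitly:

- a **forward physiological model** predicts, for an individualized patient,
  the outcome of any candidate settings (alveolar ventilation equation,
  alveolar gas equation, Severinghaus dissociation curve, single-shunt
  venous admixture closed with the Fick relation, Henderson–Hasselbalch pH,
  and a chemoreflex drive model for pressure-support breathing);
- **preference functions** score the six competing goals as penalties in
  [0, 1]; the net harm of a strategy is the total, unweighted sum
  `J = Σ_a p_a` over the active axes;
- the **advisor** searches a discrete settings grid for argmin J and steps
  toward it under fixed caps (FiO2 5 %; pressures 2 cmH2O, 3 cmH2O for PEEP
  increases below 10 cmH2O; VT 50 ml; frequency 3 /min), waiting a
  configured 5–20 min between advices — so an optimum 5 cmH2O of pressure
  support below the current value is delivered as steps of 2, 2 and 1;
- the **hexagon** module renders current (blue) and advised (grey) penalty
  polygons on the six-axis glyph with green/yellow/red severity background
  and band-dependent axis rescaling;
- the **patterns** module classifies glyph shapes into the clinical
  taxonomy (optimal control, round/bow-tie optimal support, directional
  spikes for over/under ventilation, support and oxygenation, the
  over-support triad, over-ventilation with hypoxia).

The target audience is researchers and educators studying transparent
clinical decision support for ventilation; it is not a medical device.

## Worked example

Describe a patient and their current settings (YAML or JSON):

```yaml
# oversupported.yaml
patient:
  shunt_fraction: 0.06
  dead_space_ml: 150
  compliance_ml_per_cmH2O: 50
  vo2_ml_per_min: 160
  vco2_ml_per_min: 130
  hb_g_per_dl: 13
  cardiac_output_l_per_min: 5
  drive_threshold_kpa: 5.3
  drive_gain: 3.0
  height_cm: 175
  sex: male
  spontaneous: true
settings:
  mode: pressure_support
  fio2_pct: 35
  peep_cmH2O: 5
  ps_cmH2O: 8
```

```text
$ ventadvisor simulate --config oversupported.yaml
sao2 = 0.985351
svo2 = 0.801654
paco2_kpa = 5.39672
ph = 7.40308
vt_ml = 419.343
freq_per_min = 10.2901
driving_pressure_cmH2O = 8.38686
peak_pressure_cmH2O = 13
fio2_pct = 35
penalty[muscle_atrophy] = 0.412206
penalty[lung_trauma] = 0
penalty[oxygen_toxicity] = 0.16092
penalty[low_oxygenation] = 0
penalty[acidosis] = 0
penalty[respiratory_stress] = 0
total_penalty = 0.573125
severity = yellow
```

Gas exchange and pH are fine, but the support has suppressed the drive:
the patient breathes at only 10.3 /min, so the muscle-atrophy axis carries
0.41 and the background is yellow.  The classifier reads the shape as a
left-upward spike:

```text
$ ventadvisor classify --config oversupported.yaml
label = OVERSUPPORT
dominant_axes = muscle_atrophy
confidence = 0.0903668
```

The advisory loop steps toward the penalty minimum under the caps:

```text
$ ventadvisor advise --config oversupported.yaml --out-dir out
3 records -> out/trajectory.csv (converged=True)

$ cat out/advise.log
t=0 min: advise fio2_pct -5, ps_cmH2O -2
t=5 min: advise fio2_pct -5, ps_cmH2O -2
t=10 min: settings optimal, no advice
```

Two advices (each −2 cmH2O of support and −5 % oxygen, the per-step caps)
reach the optimum at PS 4 / FiO2 25 %; the trajectory CSV holds the
simulated outcome, all six penalties and the advice deltas per step.
`ventadvisor render --config … --out glyph.svg` draws the hexagon
(`--show-values` adds the per-axis physiological readouts at the corners);
`ventadvisor demo --out-dir demo` runs the full 14-scenario suite and
writes labels, penalties and glyphs; `ventadvisor schema` prints the JSON
Schema of the configuration document.

The same functionality is available as a library:

```python
from ventadvisor import scenario_by_name, advise_loop, classify_trajectory
sc = scenario_by_name("over_support")
traj = advise_loop(sc.patient, sc.settings)
print([c.label.value for c in classify_trajectory(traj)])
# ['OVERSUPPORT', 'OPTIMAL_SUPPORT_ROUND', 'OPTIMAL_SUPPORT_ROUND']
```

See `docs/methods.md` for the model equations, penalty anchors, numerical
choices and known limitations.

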