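"""Synthetic clinical scenarios covering every hexagon pattern.

Each scenario is a (patient, settings) pair whose simulated penalty vector
classifies to a known pattern: optimal control in volume and pressure
control, a permissive-hypercapnia optimum balancing injurious pressure
against acidosis, round and bow-tie optimal support at low and moderate
pressure support, directional spikes for over/under ventilation, over/under
support and over/under oxygenation, the over-support triad, and
over-ventilation combined with hypoxia.  Parameter values are invented to
realize these qualitative pictures with comfortable classification margins;
the under-oxygenation pattern is included even though it is the one shape
predicted rather than observed clinically.

All scenarios are generated programmatically; ``perturb`` adds seeded
multiplicative jitter to the continuous patient parameters for robustness
testing.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .patterns import PatternLabel
from .physiology import Mode, PatientState, Sex, VentSettings


@dataclass(frozen=True)
class Scenario:
    name: str
    patient: PatientState
    settings: VentSettings
    expected_label: PatternLabel
    notes: str


def _patient(**kw) -> PatientState:
    base = dict(
        shunt_fraction=0.05, dead_space_ml=150.0, compliance_ml_per_cmH2O=50.0,
        vo2_ml_per_min=250.0, vco2_ml_per_min=200.0, hb_g_per_dl=14.0,
        base_excess_mmol_per_l=0.0, cardiac_output_l_per_min=5.0,
        drive_threshold_kpa=4.5, drive_gain=6.0, muscle_pressure_max_cmH2O=10.0,
        spontaneous=False, height_cm=175.0, sex=Sex.MALE, dpo2_kpa=0.0,
    )
    base.update(kw)
    return PatientState(**base)


def scenario_suite() -> list[Scenario]:
    """The full scenario suite (every pattern label except UNCLASSIFIED)."""
    s = []

    s.append(Scenario(
        "optimal_volume_control",
        _patient(),
        VentSettings(Mode.VOLUME_CONTROL, fio2_pct=30, peep_cmH2O=5,
                     vt_ml=450, freq_per_min=14),
        PatternLabel.OPTIMAL_CONTROL,
        "Sedated patient with near-normal lungs: adequate pressures, pH and "
        "oxygenation; small square on the right half of the hexagon."))

    s.append(Scenario(
        "optimal_pressure_control",
        _patient(),
        VentSettings(Mode.PRESSURE_CONTROL, fio2_pct=30, peep_cmH2O=5,
                     pinsp_cmH2O=9, freq_per_min=14),
        PatternLabel.OPTIMAL_CONTROL,
        "Same balance delivered by pressure control (identical tidal volume)."))

    s.append(Scenario(
        "permissive_hypercapnia",
        _patient(shunt_fraction=0.12, dead_space_ml=300.0,
                 compliance_ml_per_cmH2O=20.0, vo2_ml_per_min=280.0,
                 vco2_ml_per_min=350.0, hb_g_per_dl=12.0,
                 cardiac_output_l_per_min=6.0),
        VentSettings(Mode.PRESSURE_CONTROL, fio2_pct=45, peep_cmH2O=8,
                     pinsp_cmH2O=24, freq_per_min=26),
        PatternLabel.OPTIMAL_CONTROL,
        "Extreme illness: high pressures traded against a deliberately low pH; "
        "both ventilation axes elevated but balanced, hence optimal despite a "
        "yellow/red background."))

    s.append(Scenario(
        "optimal_support_round_low_ps",
        _patient(spontaneous=True, drive_gain=6.0, drive_threshold_kpa=4.5),
        VentSettings(Mode.PRESSURE_SUPPORT, fio2_pct=30, peep_cmH2O=5, ps_cmH2O=4),
        PatternLabel.OPTIMAL_SUPPORT_ROUND,
        "Strong drive, low support: relaxed breathing, all penalties small; "
        "near-circular ring."))

    s.append(Scenario(
        "optimal_support_round_moderate_ps",
        _patient(spontaneous=True, compliance_ml_per_cmH2O=45.0,
                 vco2_ml_per_min=220.0, drive_gain=5.0, drive_threshold_kpa=4.8),
        VentSettings(Mode.PRESSURE_SUPPORT, fio2_pct=30, peep_cmH2O=5, ps_cmH2O=8),
        PatternLabel.OPTIMAL_SUPPORT_ROUND,
        "The same round optimum at a moderate support level: the correct "
        "balance is patient-specific."))

    s.append(Scenario(
        "optimal_support_bowtie",
        _patient(spontaneous=True, shunt_fraction=0.06,
                 vo2_ml_per_min=160.0, vco2_ml_per_min=130.0,
                 hb_g_per_dl=13.0, drive_threshold_kpa=5.3, drive_gain=3.0),
        VentSettings(Mode.PRESSURE_SUPPORT, fio2_pct=35, peep_cmH2O=5, ps_cmH2O=6),
        PatternLabel.OPTIMAL_SUPPORT_BOWTIE,
        "Support balanced between mild atrophy risk and mild oxygen-toxicity "
        "risk with a pinched center: bow tie."))

    s.append(Scenario(
        "over_ventilation",
        _patient(compliance_ml_per_cmH2O=22.0),
        VentSettings(Mode.VOLUME_CONTROL, fio2_pct=30, peep_cmH2O=5,
                     vt_ml=550, freq_per_min=24),
        PatternLabel.OVERVENTILATION,
        "Stiff lungs driven hard: driving pressure 25 cmH2O dominates as an "
        "upward trauma spike (peak pressure 30, yellow)."))

    s.append(Scenario(
        "over_ventilation_with_hypoxia",
        _patient(compliance_ml_per_cmH2O=22.0, shunt_fraction=0.28,
                 vo2_ml_per_min=260.0, hb_g_per_dl=12.0),
        VentSettings(Mode.VOLUME_CONTROL, fio2_pct=40, peep_cmH2O=8,
                     vt_ml=550, freq_per_min=24),
        PatternLabel.OVERVENTILATION_WITH_HYPOXIA,
        "High shunt adds arterial desaturation: spikes upward and to the "
        "lower right."))

    s.append(Scenario(
        "under_ventilation",
        _patient(compliance_ml_per_cmH2O=40.0, vco2_ml_per_min=220.0),
        VentSettings(Mode.VOLUME_CONTROL, fio2_pct=35, peep_cmH2O=5,
                     vt_ml=350, freq_per_min=9),
        PatternLabel.UNDERVENTILATION,
        "Minute ventilation far too low: severe respiratory acidosis, a red "
        "downward spike."))

    s.append(Scenario(
        "over_support",
        _patient(spontaneous=True, vo2_ml_per_min=160.0, vco2_ml_per_min=130.0,
                 hb_g_per_dl=13.0, drive_threshold_kpa=5.3, drive_gain=3.0,
                 shunt_fraction=0.06),
        VentSettings(Mode.PRESSURE_SUPPORT, fio2_pct=35, peep_cmH2O=5, ps_cmH2O=8),
        PatternLabel.OVERSUPPORT,
        "Two cmH2O more support than the bow-tie patient needs suppresses the "
        "drive: left-upward atrophy spike.  Simulated reduction of PS 8 -> 6 "
        "restores the bow tie."))

    s.append(Scenario(
        "over_support_triad",
        _patient(spontaneous=True, compliance_ml_per_cmH2O=55.0,
                 vco2_ml_per_min=170.0, vo2_ml_per_min=210.0,
                 drive_threshold_kpa=5.5, drive_gain=4.0),
        VentSettings(Mode.PRESSURE_SUPPORT, fio2_pct=60, peep_cmH2O=6, ps_cmH2O=14),
        PatternLabel.OVERSUPPORT_TRIAD,
        "Over support with elevated pressure and over oxygenation: a "
        "quadrilateral above the three upward axes."))

    s.append(Scenario(
        "under_support",
        _patient(spontaneous=True, compliance_ml_per_cmH2O=35.0,
                 dead_space_ml=140.0, muscle_pressure_max_cmH2O=4.0,
                 vo2_ml_per_min=190.0, vco2_ml_per_min=150.0,
                 base_excess_mmol_per_l=3.0,
                 drive_gain=4.0, drive_threshold_kpa=4.6),
        VentSettings(Mode.PRESSURE_SUPPORT, fio2_pct=30, peep_cmH2O=5, ps_cmH2O=2),
        PatternLabel.UNDERSUPPORT,
        "Weak muscles and high drive on minimal support with partial "
        "metabolic compensation: rapid shallow breathing, a left-downward "
        "stress spike."))

    s.append(Scenario(
        "over_oxygenation",
        _patient(shunt_fraction=0.03),
        VentSettings(Mode.VOLUME_CONTROL, fio2_pct=70, peep_cmH2O=5,
                     vt_ml=450, freq_per_min=14),
        PatternLabel.OVEROXYGENATION,
        "Healthy lungs on far too much oxygen: right-upward toxicity spike; "
        "the optimum has a much lower FiO2."))

    s.append(Scenario(
        "under_oxygenation",
        _patient(shunt_fraction=0.22),
        VentSettings(Mode.VOLUME_CONTROL, fio2_pct=25, peep_cmH2O=5,
                     vt_ml=450, freq_per_min=14),
        PatternLabel.UNDEROXYGENATION,
        "Shunt with near-room-air oxygen and no other problem: the predicted "
        "right-downward spike (not typically observed clinically)."))

    return s


def scenario_by_name(name: str) -> Scenario:
    for sc in scenario_suite():
        if sc.name == name:
            return sc
    raise KeyError(name)


#: continuous patient fields receiving multiplicative jitter
_JITTER_FIELDS = (
    "shunt_fraction", "dead_space_ml", "compliance_ml_per_cmH2O",
    "vo2_ml_per_min", "vco2_ml_per_min", "hb_g_per_dl",
    "cardiac_output_l_per_min", "drive_threshold_kpa", "drive_gain",
    "muscle_pressure_max_cmH2O",
)


def perturb(scenario: Scenario, seed: int, rel: float = 0.10) -> Scenario:
    """Seeded +-``rel`` multiplicative jitter of the patient parameters.

    Deterministic per seed; settings and expected label are preserved (the
    scenarios are built with margins that tolerate the default jitter).
    """
    rng = np.random.default_rng(seed)
    factors = rng.uniform(1.0 - rel, 1.0 + rel, size=len(_JITTER_FIELDS))
    updates = {}
    for name, f in zip(_JITTER_FIELDS, factors):
        value = getattr(scenario.patient, name) * f
        if name == "shunt_fraction":
            value = min(value, 0.95)
        updates[name] = value
    return replace(scenario, patient=replace(scenario.patient, **updates))
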