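"""Clinical preference (penalty) functions for the six competing goals.

Each axis of the decision hexagon carries a penalty in [0, 1] computed from
the simulated outcome: oxygen toxicity, low oxygenation, lung trauma,
acidosis, respiratory muscle atrophy and respiratory stress.  Every axis is a
piecewise-linear ramp from a zero-penalty anchor; multi-variable axes combine
per-variable ramps with a maximum, which preserves monotonicity and keeps
each anchor independently calibratable.  The net detrimental effect of a
strategy is the plain unweighted sum of the active penalties.

Severity bands divide the unit penalty scale into three equal parts, closed
on the low side: green for max penalty <= 1/3, yellow up to 2/3, red above.
With the default driving-pressure ramp this places the green/yellow boundary
of the trauma axis exactly at a peak pressure of 25 cmH2O when PEEP is 5.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .errors import DomainError
from .physiology import CONTROL_MODES, Mode, Outcome, PatientState, VentSettings

# Canonical axis order = hexagon vertex order:
# left-up, center-up, right-up, right-down, center-down, left-down.
AXES = (
    "muscle_atrophy",
    "lung_trauma",
    "oxygen_toxicity",
    "low_oxygenation",
    "acidosis",
    "respiratory_stress",
)

#: axes shown only for spontaneously supported patients (the left column)
SUPPORT_ONLY_AXES = frozenset({"muscle_atrophy", "respiratory_stress"})


class SeverityBand(str, Enum):
    GREEN = "green"
    YELLOW = "yellow"
    RED = "red"


@dataclass(frozen=True)
class PenaltyConfig:
    """All penalty anchors and band thresholds, overridable in one block."""

    # oxygen toxicity: 0 at room air, green/yellow boundary at the FiO2 anchor,
    # penalty 1 at 100 %
    fio2_zero_pct: float = 21.0
    fio2_yellow_pct: float = 50.0
    # low oxygenation: decreasing ramps in each saturation
    sao2_zero: float = 0.97
    sao2_span: float = 0.12
    svo2_zero: float = 0.70
    svo2_span: float = 0.30
    # lung trauma: increasing ramps in VT/PBW, driving pressure, frequency
    vt_per_kg_zero: float = 6.0
    vt_per_kg_span: float = 9.0
    dp_zero_cmH2O: float = 10.0
    dp_span_cmH2O: float = 30.0
    freq_zero_per_min: float = 20.0
    freq_span_per_min: float = 30.0
    # acidosis: 0 at pH >= 7.35; red boundary (penalty 2/3) at pH 7.15
    ph_zero: float = 7.35
    ph_span: float = 0.30
    ph_domain: tuple = (6.5, 8.0)
    # muscle atrophy: low-frequency ramp plus a high-VT floor
    atrophy_freq_zero_per_min: float = 14.0
    atrophy_freq_span_per_min: float = 9.0
    atrophy_vt_floor_start_per_kg: float = 10.0
    atrophy_vt_floor_span_per_kg: float = 5.0
    # respiratory stress: ramp in the PBW-adjusted rapid-shallow-breathing
    # index freq / (VT per kg PBW)
    stress_index_zero: float = 2.5
    stress_index_span: float = 4.5
    # severity bands, closed on the low side
    green_max: float = 1.0 / 3.0
    yellow_max: float = 2.0 / 3.0


DEFAULT_PENALTY_CONFIG = PenaltyConfig()

_BAND_EPS = 1e-12


def _ramp_up(x, zero, span):
    return np.clip((np.asarray(x, dtype=float) - zero) / span, 0.0, 1.0)


def _ramp_down(x, zero, span):
    return np.clip((zero - np.asarray(x, dtype=float)) / span, 0.0, 1.0)


def _maybe_scalar(value, *inputs):
    return float(value) if all(np.isscalar(i) for i in inputs) else value


def penalty_oxygen_toxicity(fio2_pct, config: PenaltyConfig = DEFAULT_PENALTY_CONFIG):
    """Penalty for elevated inspired oxygen: 0 at 21 %, 1/3 at the yellow
    anchor (default 50 %), 1.0 at 100 %."""
    f = np.asarray(fio2_pct, dtype=float)
    if np.any((f < 21.0) | (f > 100.0)):
        raise DomainError("fio2_pct outside [21, 100]")
    low = (f - config.fio2_zero_pct) / (config.fio2_yellow_pct - config.fio2_zero_pct) / 3.0
    high = 1.0 / 3.0 + (f - config.fio2_yellow_pct) / (100.0 - config.fio2_yellow_pct) * (2.0 / 3.0)
    p = np.clip(np.where(f <= config.fio2_yellow_pct, low, high), 0.0, 1.0)
    return _maybe_scalar(p, fio2_pct)


def penalty_low_oxygenation(sao2, svo2, config: PenaltyConfig = DEFAULT_PENALTY_CONFIG):
    """Penalty for arterial and mixed-venous desaturation (max of two ramps);
    the venous term represents systemic oxygen deprivation."""
    sa, sv = np.asarray(sao2, dtype=float), np.asarray(svo2, dtype=float)
    if np.any((sa <= 0) | (sa > 1) | (sv <= 0) | (sv > 1)):
        raise DomainError("saturations must lie in (0, 1]")
    p = np.maximum(_ramp_down(sa, config.sao2_zero, config.sao2_span),
                   _ramp_down(sv, config.svo2_zero, config.svo2_span))
    return _maybe_scalar(p, sao2, svo2)


def penalty_lung_trauma(vt_ml, driving_pressure_cmH2O, freq_per_min, pbw_kg,
                        config: PenaltyConfig = DEFAULT_PENALTY_CONFIG):
    """Penalty for injurious ventilation: max of ramps in VT/PBW, driving
    pressure and frequency (all raise mechanical power)."""
    vt = np.asarray(vt_ml, dtype=float)
    dp = np.asarray(driving_pressure_cmH2O, dtype=float)
    fr = np.asarray(freq_per_min, dtype=float)
    if np.any(vt <= 0) or np.any(dp <= 0) or np.any(fr <= 0) or pbw_kg <= 0:
        raise DomainError("trauma-axis inputs must be strictly positive")
    p = np.maximum.reduce([
        _ramp_up(vt / pbw_kg, config.vt_per_kg_zero, config.vt_per_kg_span),
        _ramp_up(dp, config.dp_zero_cmH2O, config.dp_span_cmH2O),
        _ramp_up(fr, config.freq_zero_per_min, config.freq_span_per_min),
    ])
    return _maybe_scalar(p, vt_ml, driving_pressure_cmH2O, freq_per_min)


def penalty_acidosis(ph, config: PenaltyConfig = DEFAULT_PENALTY_CONFIG):
    """Penalty for acidaemia: 0 at pH >= 7.35, 2/3 (red boundary) at 7.15,
    saturating at 1 for pH <= 7.05."""
    p_in = np.asarray(ph, dtype=float)
    lo, hi = config.ph_domain
    if np.any((p_in < lo) | (p_in > hi)):
        raise DomainError(f"ph outside physiologic range [{lo}, {hi}]")
    p = _ramp_down(p_in, config.ph_zero, config.ph_span)
    return _maybe_scalar(p, ph)


def penalty_muscle_atrophy(freq_per_min, vt_ml, pbw_kg, spontaneous,
                           config: PenaltyConfig = DEFAULT_PENALTY_CONFIG):
    """Penalty for disuse atrophy under excessive support: rises as
    spontaneous frequency falls, with a floor for very large supported
    breaths (VT > 10 ml/kg PBW) which unload the muscles even at preserved
    frequency."""
    if not spontaneous:
        raise DomainError("atrophy penalty is defined only for spontaneous patients")
    fr = np.asarray(freq_per_min, dtype=float)
    vt = np.asarray(vt_ml, dtype=float)
    if np.any(fr <= 0) or np.any(vt <= 0) or pbw_kg <= 0:
        raise DomainError("atrophy-axis inputs must be strictly positive")
    p = np.maximum(
        _ramp_down(fr, config.atrophy_freq_zero_per_min, config.atrophy_freq_span_per_min),
        _ramp_up(vt / pbw_kg, config.atrophy_vt_floor_start_per_kg,
                 config.atrophy_vt_floor_span_per_kg),
    )
    return _maybe_scalar(p, freq_per_min, vt_ml)


def penalty_respiratory_stress(freq_per_min, vt_ml, pbw_kg, spontaneous,
                               config: PenaltyConfig = DEFAULT_PENALTY_CONFIG):
    """Penalty for stressful rapid shallow breathing, from the PBW-adjusted
    frequency-to-tidal-volume index freq / (VT/PBW)."""
    if not spontaneous:
        raise DomainError("stress penalty is defined only for spontaneous patients")
    fr = np.asarray(freq_per_min, dtype=float)
    vt = np.asarray(vt_ml, dtype=float)
    if np.any(fr <= 0) or np.any(vt <= 0) or pbw_kg <= 0:
        raise DomainError("stress-axis inputs must be strictly positive")
    index = fr / (vt / pbw_kg)
    p = _ramp_up(index, config.stress_index_zero, config.stress_index_span)
    return _maybe_scalar(p, freq_per_min, vt_ml)


@dataclass(frozen=True)
class PenaltyVector:
    """The six axis penalties plus the mode-dependent active-axis mask."""

    values: dict        # axis name -> penalty in [0, 1]
    active: dict        # axis name -> bool
    mode: Mode

    def __post_init__(self):
        if set(self.values) != set(AXES) or set(self.active) != set(AXES):
            raise DomainError("penalty vector must carry all six axes")
        for axis in AXES:
            v = self.values[axis]
            if self.active[axis] and not 0.0 <= v <= 1.0:
                raise DomainError(f"active penalty {axis}={v} outside [0, 1]")

    def __getitem__(self, axis: str) -> float:
        return self.values[axis]

    def active_axes(self) -> tuple[str, ...]:
        return tuple(a for a in AXES if self.active[a])

    def active_values(self) -> dict:
        return {a: self.values[a] for a in self.active_axes()}

    @property
    def max_active(self) -> float:
        return max(self.values[a] for a in self.active_axes())

    @property
    def total(self) -> float:
        return float(sum(self.values[a] for a in self.active_axes()))

    def as_csv_row(self) -> dict:
        row = {a: (self.values[a] if self.active[a] else float("nan")) for a in AXES}
        row["total"] = self.total
        row["mode"] = self.mode.value
        return row


def active_mask_for_mode(mode: Mode) -> dict:
    """Support mode shows all six goals; control modes mask the muscle axes."""
    mode = Mode(mode)
    return {a: (mode not in CONTROL_MODES or a not in SUPPORT_ONLY_AXES) for a in AXES}


def evaluate(outcome: Outcome, settings: VentSettings, patient: PatientState,
             config: PenaltyConfig = DEFAULT_PENALTY_CONFIG) -> PenaltyVector:
    """Map a simulated outcome to the six-axis penalty vector.

    The simulated pH is clipped into the acidosis domain before the axis call
    (the penalty saturates at 1 well inside it), so extreme candidate
    settings still evaluate rather than erroring out of a settings search.
    """
    pbw = patient.pbw_kg
    spont = settings.mode is Mode.PRESSURE_SUPPORT
    lo, hi = config.ph_domain
    values = {
        "oxygen_toxicity": penalty_oxygen_toxicity(outcome.fio2_pct, config),
        "low_oxygenation": penalty_low_oxygenation(outcome.sao2, outcome.svo2, config),
        "lung_trauma": penalty_lung_trauma(
            outcome.vt_ml, outcome.driving_pressure_cmH2O,
            outcome.freq_per_min, pbw, config),
        "acidosis": penalty_acidosis(min(max(outcome.ph, lo), hi), config),
        "muscle_atrophy": (
            penalty_muscle_atrophy(outcome.freq_per_min, outcome.vt_ml, pbw, True, config)
            if spont else 0.0),
        "respiratory_stress": (
            penalty_respiratory_stress(outcome.freq_per_min, outcome.vt_ml, pbw, True, config)
            if spont else 0.0),
    }
    return PenaltyVector(values=values, active=active_mask_for_mode(settings.mode),
                         mode=settings.mode)


def total_penalty(pv: PenaltyVector) -> float:
    """The total, unweighted sum of the active penalties."""
    return pv.total


def severity(pv: PenaltyVector, config: PenaltyConfig = DEFAULT_PENALTY_CONFIG) -> SeverityBand:
    """Background band from the maximum active penalty (bands closed on the
    low side: a penalty of exactly 1/3 is still green)."""
    m = pv.max_active
    if m <= config.green_max + _BAND_EPS:
        return SeverityBand.GREEN
    if m <= config.yellow_max + _BAND_EPS:
        return SeverityBand.YELLOW
    return SeverityBand.RED
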