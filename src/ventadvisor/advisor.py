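"""Penalty-minimal settings search and step-capped advice generation.

The advisor enumerates a discrete grid of candidate ventilator settings,
simulates every candidate with the forward model, sums the active penalties,
and returns the candidate with the least total penalty.  Advice then steps
the current settings toward that optimum under fixed per-step caps (inspired
oxygen 5 percentage points; pressures 2 cmH2O, except 3 cmH2O for a PEEP
increase while PEEP is below 10 cmH2O; tidal volume 50 ml; frequency
3 breaths/min), and the advice loop iterates simulate -> evaluate ->
optimize -> step until the current settings are optimal.  A configured
waiting period (5-20 min) between advices is recorded as metadata only.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Optional

import numpy as np

from .errors import DomainError, InfeasibleSettingsError
from .physiology import (CONTROL_MODES, DEFAULT_DRIVE, DriveConfig, Mode,
                         Outcome, PatientState, VentSettings, predict_grid,
                         simulate)
from .preferences import (DEFAULT_PENALTY_CONFIG, PenaltyConfig, PenaltyVector,
                          evaluate, penalty_acidosis, penalty_low_oxygenation,
                          penalty_lung_trauma, penalty_muscle_atrophy,
                          penalty_oxygen_toxicity, penalty_respiratory_stress,
                          total_penalty)


@dataclass(frozen=True)
class StepCaps:
    """Maximum advised change per step, per setting."""

    fio2_pct: float = 5.0
    pressure_cmH2O: float = 2.0
    peep_increase_low_cmH2O: float = 3.0   # PEEP increase while PEEP < threshold
    peep_low_threshold_cmH2O: float = 10.0
    vt_ml: float = 50.0
    freq_per_min: float = 3.0

    def cap_for(self, name: str, current: VentSettings, delta_sign: float) -> float:
        if name == "fio2_pct":
            return self.fio2_pct
        if name == "vt_ml":
            return self.vt_ml
        if name == "freq_per_min":
            return self.freq_per_min
        if name == "peep_cmH2O":
            if delta_sign > 0 and current.peep_cmH2O < self.peep_low_threshold_cmH2O:
                return self.peep_increase_low_cmH2O
            return self.pressure_cmH2O
        return self.pressure_cmH2O  # ps_cmH2O / pinsp_cmH2O


DEFAULT_CAPS = StepCaps()

# lexicographic tie-break order over setting fields
_FIELD_ORDER = ("fio2_pct", "peep_cmH2O", "ps_cmH2O", "pinsp_cmH2O", "vt_ml",
                "freq_per_min")


def _steps(lo: float, hi: float, step: float) -> tuple[float, ...]:
    n = int(round((hi - lo) / step))
    return tuple(lo + i * step for i in range(n + 1))


@dataclass(frozen=True)
class SettingsGrid:
    """Per-setting discrete candidate values for one ventilation mode."""

    mode: Mode
    fio2_pct: tuple
    peep_cmH2O: tuple
    ps_cmH2O: tuple = ()
    pinsp_cmH2O: tuple = ()
    vt_ml: tuple = ()
    freq_per_min: tuple = ()

    def __post_init__(self):
        object.__setattr__(self, "mode", Mode(self.mode))
        for name in self.axis_names():
            vals = getattr(self, name)
            if not vals:
                raise DomainError(f"grid axis {name} is empty")
            object.__setattr__(self, name, tuple(sorted(set(float(v) for v in vals))))

    def axis_names(self) -> tuple[str, ...]:
        base = ("fio2_pct", "peep_cmH2O")
        extra = {
            Mode.VOLUME_CONTROL: ("vt_ml", "freq_per_min"),
            Mode.PRESSURE_CONTROL: ("pinsp_cmH2O", "freq_per_min"),
            Mode.PRESSURE_SUPPORT: ("ps_cmH2O",),
        }[self.mode]
        return base + extra

    @property
    def size(self) -> int:
        return math.prod(len(getattr(self, n)) for n in self.axis_names())

    def points(self) -> Iterator[VentSettings]:
        names = self.axis_names()
        for combo in itertools.product(*(getattr(self, n) for n in names)):
            yield VentSettings(mode=self.mode, **dict(zip(names, combo)))

    def contains(self, settings: VentSettings) -> bool:
        return settings.mode is self.mode and all(
            getattr(settings, n) in getattr(self, n) for n in self.axis_names())

    @classmethod
    def default_for(cls, current: VentSettings) -> "SettingsGrid":
        """Clinically bounded grid at the standard resolutions (FiO2 5 %,
        pressures 1 cmH2O, VT 25 ml, frequency 1/min), always containing the
        current settings."""
        fio2 = (21.0,) + _steps(25, 100, 5) + (current.fio2_pct,)
        peep = _steps(2, 16, 1) + (current.peep_cmH2O,)
        if current.mode is Mode.VOLUME_CONTROL:
            return cls(mode=current.mode, fio2_pct=fio2, peep_cmH2O=peep,
                       vt_ml=_steps(300, 700, 25) + (current.vt_ml,),
                       freq_per_min=_steps(10, 30, 1) + (current.freq_per_min,))
        if current.mode is Mode.PRESSURE_CONTROL:
            return cls(mode=current.mode, fio2_pct=fio2, peep_cmH2O=peep,
                       pinsp_cmH2O=_steps(5, 30, 1) + (current.pinsp_cmH2O,),
                       freq_per_min=_steps(10, 30, 1) + (current.freq_per_min,))
        return cls(mode=current.mode, fio2_pct=fio2, peep_cmH2O=peep,
                   ps_cmH2O=_steps(0, 20, 1) + (current.ps_cmH2O,))


@dataclass(frozen=True)
class Advice:
    """One step of advice toward the penalty-minimal settings."""

    target: VentSettings            # the next step, not the optimum
    optimum: VentSettings
    deltas: dict                    # setting name -> signed change this step
    predicted: Optional[PenaltyVector]
    is_null: bool


@dataclass(frozen=True)
class TrajectoryStep:
    index: int
    time_min: float
    settings: VentSettings
    outcome: Outcome
    penalties: PenaltyVector
    advice: Advice


@dataclass(frozen=True)
class Trajectory:
    """Ordered advisory records with inter-step waiting-time metadata."""

    steps: tuple
    converged: bool
    wait_min: float

    def __len__(self) -> int:
        return len(self.steps)

    def to_rows(self) -> list[dict]:
        rows = []
        for s in self.steps:
            row = {"step": s.index, "time_min": s.time_min, "mode": s.settings.mode.value}
            row.update({f"set_{k}": v for k, v in s.settings.as_dict().items()
                        if k != "mode"})
            row.update(s.outcome.as_csv_row())
            pv = s.penalties.as_csv_row()
            pv.pop("mode")
            row.update({f"penalty_{k}" if k != "total" else "penalty_total": v
                        for k, v in pv.items()})
            row["advice_null"] = s.advice.is_null
            for k, v in s.advice.deltas.items():
                row[f"delta_{k}"] = v
            rows.append(row)
        return rows


def _grid_penalties(patient: PatientState, grid: SettingsGrid,
                    config: PenaltyConfig, drive: DriveConfig):
    """Vectorized total penalty over the full grid.

    Returns (names, value-columns, totals) with infeasible points at +inf.
    """
    names = grid.axis_names()
    mesh = np.meshgrid(*(np.asarray(getattr(grid, n)) for n in names), indexing="ij")
    cols = {n: m.ravel() for n, m in zip(names, mesh)}
    out = predict_grid(
        patient, grid.mode,
        fio2_pct=cols["fio2_pct"], peep_cmH2O=cols["peep_cmH2O"],
        vt_ml=cols.get("vt_ml"), freq_per_min=cols.get("freq_per_min"),
        pinsp_cmH2O=cols.get("pinsp_cmH2O"), ps_cmH2O=cols.get("ps_cmH2O"),
        drive=drive)
    feas = out["feasible"]
    pbw = patient.pbw_kg
    # clip outcome arrays into the penalty domains at infeasible points so the
    # vectorized axis calls never raise; those points are masked to +inf below
    ph = np.clip(np.nan_to_num(out["ph"], nan=7.4), *config.ph_domain)
    sao2 = np.clip(np.nan_to_num(out["sao2"], nan=1.0), 1e-9, 1.0)
    svo2 = np.clip(np.nan_to_num(out["svo2"], nan=1.0), 1e-9, 1.0)
    vt = np.clip(out["vt_ml"], 1e-9, None)
    dp = np.clip(out["driving_pressure_cmH2O"], 1e-9, None)
    freq = np.clip(out["freq_per_min"], 1e-9, None)
    total = (penalty_oxygen_toxicity(out["fio2_pct"], config)
             + penalty_low_oxygenation(sao2, svo2, config)
             + penalty_lung_trauma(vt, dp, freq, pbw, config)
             + penalty_acidosis(ph, config))
    if grid.mode is Mode.PRESSURE_SUPPORT:
        total = (total
                 + penalty_muscle_atrophy(freq, vt, pbw, True, config)
                 + penalty_respiratory_stress(freq, vt, pbw, True, config))
    total = np.where(feas, total, np.inf)
    return names, cols, total


def find_optimum(patient: PatientState, current: VentSettings,
                 grid: Optional[SettingsGrid] = None,
                 config: PenaltyConfig = DEFAULT_PENALTY_CONFIG,
                 drive: DriveConfig = DEFAULT_DRIVE,
                 caps: StepCaps = DEFAULT_CAPS) -> VentSettings:
    """Exhaustive search for the grid point with least total penalty.

    Ties (within 1e-9) are broken by least total settings change from the
    current settings (per-setting |delta| normalized by its step cap), then
    lexicographically over the setting values.
    """
    grid = grid if grid is not None else SettingsGrid.default_for(current)
    if grid.mode is not current.mode:
        raise DomainError("grid mode does not match current settings mode")
    names, cols, total = _grid_penalties(patient, grid, config, drive)
    best = float(np.min(total))
    if not np.isfinite(best):
        raise InfeasibleSettingsError("every grid point is infeasible for this patient")
    tie_idx = np.flatnonzero(total <= best + 1e-9)

    def sort_key(i):
        change = sum(
            abs(cols[n][i] - getattr(current, n)) / caps.cap_for(n, current,
                np.sign(cols[n][i] - getattr(current, n)))
            for n in names)
        lex = tuple(cols[n][i] for n in _FIELD_ORDER if n in names)
        return (change, lex)

    pick = min(tie_idx, key=sort_key)
    return VentSettings(mode=grid.mode, **{n: float(cols[n][pick]) for n in names})


def step_advice(current: VentSettings, optimum: VentSettings,
                caps: StepCaps = DEFAULT_CAPS,
                patient: Optional[PatientState] = None,
                config: PenaltyConfig = DEFAULT_PENALTY_CONFIG,
                drive: DriveConfig = DEFAULT_DRIVE) -> Advice:
    """One capped step from the current settings toward the optimum.

    Every setting moves toward its optimal value by min(cap, remaining gap);
    a PEEP increase may step 3 cmH2O while PEEP is below 10 cmH2O, all other
    pressure changes are capped at 2 cmH2O.  When a patient is supplied the
    advice carries the predicted penalty vector at the target settings.
    """
    if current.mode is not optimum.mode:
        raise DomainError("current and optimum settings must share a mode")
    deltas = {}
    new_values = {}
    for name in current.active_fields():
        if name == "mode":
            continue
        gap = getattr(optimum, name) - getattr(current, name)
        cap = caps.cap_for(name, current, np.sign(gap))
        delta = float(np.sign(gap) * min(abs(gap), cap))
        deltas[name] = delta
        new_values[name] = getattr(current, name) + delta
    is_null = all(d == 0.0 for d in deltas.values())
    target = current if is_null else VentSettings(mode=current.mode, **new_values)
    predicted = None
    if patient is not None:
        predicted = evaluate(simulate(patient, target, drive), target, patient, config)
    return Advice(target=target, optimum=optimum, deltas=deltas,
                  predicted=predicted, is_null=is_null)


def simulate_settings(patient: PatientState, candidate: VentSettings,
                      config: PenaltyConfig = DEFAULT_PENALTY_CONFIG,
                      drive: DriveConfig = DEFAULT_DRIVE):
    """Pure what-if: (Outcome, PenaltyVector) for any candidate settings."""
    outcome = simulate(patient, candidate, drive)
    return outcome, evaluate(outcome, candidate, patient, config)


def advise_loop(patient: PatientState, initial: VentSettings,
                grid: Optional[SettingsGrid] = None, max_steps: int = 25,
                wait_min: float = 5.0,
                config: PenaltyConfig = DEFAULT_PENALTY_CONFIG,
                drive: DriveConfig = DEFAULT_DRIVE,
                caps: StepCaps = DEFAULT_CAPS) -> Trajectory:
    """Iterate simulate -> evaluate -> optimize -> step until optimal.

    The optimum is recomputed each step (the patient model is static, so this
    reproduces the fixed stepping schedule).  ``wait_min`` is the configured
    waiting period between advices, recorded as inter-step time metadata; it
    must lie in [5, 20] minutes.
    """
    if not 5.0 <= wait_min <= 20.0:
        raise DomainError(f"wait_min={wait_min} outside the allowed range [5, 20]")
    grid = grid if grid is not None else SettingsGrid.default_for(initial)
    steps = []
    current = initial
    t = 0.0
    converged = False
    for index in range(max_steps + 1):
        outcome, pv = simulate_settings(patient, current, config, drive)
        optimum = find_optimum(patient, current, grid, config, drive, caps)
        advice = step_advice(current, optimum, caps, patient, config, drive)
        if advice.is_null:
            advice = replace(advice, predicted=pv)
        steps.append(TrajectoryStep(index=index, time_min=t, settings=current,
                                    outcome=outcome, penalties=pv, advice=advice))
        if advice.is_null:
            converged = True
            break
        current = advice.target
        t += wait_min
    return Trajectory(steps=tuple(steps), converged=converged, wait_min=wait_min)
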