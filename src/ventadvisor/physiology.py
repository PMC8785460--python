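"""Forward model of pulmonary gas exchange under mechanical ventilation.

Predicts the physiological consequence (saturations, PaCO2, pH, delivered
volume/frequency/pressures) of any candidate ventilator settings for an
individualized patient, in control or support mode.

The model is a documented minimal composition of textbook relations:

* alveolar ventilation equation  PaCO2[mmHg] = 0.863 * VCO2 / VA,
  VA = f * (VT - Vd);
* alveolar gas equation  PAO2 = FiO2 * (Pb - PH2O) - PaCO2 / RQ with
  barometric pressure 101.3 kPa, water vapour 6.3 kPa, RQ = VCO2/VO2;
* a Severinghaus-form oxygen dissociation curve;
* single-compartment venous admixture (shunt) closed with the Fick relation
  for mixed venous content, which has a closed-form fixed point in the
  saturations when dissolved oxygen is neglected;
* Henderson-Hasselbalch pH with bicarbonate 24.4 + BE mmol/L (simplified
  Van Slyke) and CO2 solubility 0.225 mmol/L/kPa.

In pressure-support mode the breathing pattern is the equilibrium of a
chemoreflex drive model (see :class:`DriveConfig`): inspiratory muscle
pressure and respiratory frequency both rise with PaCO2 above the patient's
central drive threshold, and the equilibrium PaCO2 is found by bisection on
the strictly increasing residual p - PaCO2(VA(p)).

All numerical kernels are numpy-array aware so that the advisor can evaluate
whole settings grids in one vectorized pass.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional

import numpy as np

from .errors import ConvergenceError, DomainError, InfeasibleSettingsError
from .units import fio2_pct_to_frac, kpa_to_mmhg, mmhg_to_kpa

# Physical / physiological constants (see docs/methods.md for provenance).
PB_KPA = 101.3           # barometric pressure
PH2O_KPA = 6.3           # saturated water vapour pressure at 37 C
HB_O2_CAPACITY = 1.34    # ml O2 bound per g haemoglobin
HCO3_NORMAL = 24.4       # plasma bicarbonate at base excess 0, mmol/L
CO2_SOLUBILITY = 0.225   # mmol/L per kPa (0.03 mmol/L/mmHg)
PK_CARBONIC = 6.1
PACO2_FACTOR = 0.863     # mmHg per (ml/min CO2) / (L/min alveolar ventilation)


class Mode(str, Enum):
    VOLUME_CONTROL = "volume_control"
    PRESSURE_CONTROL = "pressure_control"
    PRESSURE_SUPPORT = "pressure_support"


CONTROL_MODES = frozenset({Mode.VOLUME_CONTROL, Mode.PRESSURE_CONTROL})


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"


@dataclass(frozen=True)
class DriveConfig:
    """Constants of the spontaneous chemoreflex drive model.

    freq = clamp(f_base + drive_gain*(PaCO2 - Tc) - k_ps*PS, f_min, f_max)
    Pmus = clamp(pmus_gain*(PaCO2 - Tc), 0, muscle_pressure_max)

    ``drive_gain``, ``Tc`` and ``muscle_pressure_max`` are patient properties;
    the remaining constants below are model defaults shared across patients.
    """

    f_base_per_min: float = 14.0      # frequency at PaCO2 == Tc, no support
    k_ps_per_cmH2O: float = 0.5       # direct frequency relief per cmH2O of PS
    f_min_per_min: float = 6.0
    f_max_per_min: float = 45.0
    pmus_gain_cmH2O_per_kpa: float = 4.0
    paco2_lo_kpa: float = 0.2         # bisection bracket
    paco2_hi_kpa: float = 80.0
    bisect_iters: int = 80


DEFAULT_DRIVE = DriveConfig()


def predicted_body_weight(height_cm: float, sex: Sex | str) -> float:
    """ARDSNet-style predicted body weight in kg.

    male: 50 + 0.91*(height - 152.4); female: 45.5 + 0.91*(height - 152.4).
    """
    if not 100.0 <= height_cm <= 250.0:
        raise DomainError(f"height_cm={height_cm!r} outside plausible range [100, 250]")
    sex = Sex(sex)
    intercept = 50.0 if sex is Sex.MALE else 45.5
    return intercept + 0.91 * (height_cm - 152.4)


@dataclass(frozen=True)
class PatientState:
    """Physiological parameters of one patient.

    Units: volumes ml, pressures cmH2O, tensions kPa, flows L/min (cardiac
    output) or ml/min (VO2, VCO2), haemoglobin g/dl, base excess mmol/L.
    """

    shunt_fraction: float
    dead_space_ml: float
    compliance_ml_per_cmH2O: float
    vo2_ml_per_min: float
    vco2_ml_per_min: float
    hb_g_per_dl: float
    base_excess_mmol_per_l: float
    cardiac_output_l_per_min: float
    drive_threshold_kpa: float
    drive_gain: float                  # breaths/min per kPa above threshold
    muscle_pressure_max_cmH2O: float
    spontaneous: bool
    height_cm: float
    sex: Sex
    dpo2_kpa: float = 0.0              # extra alveolar-arterial O2 drop

    def __post_init__(self):
        if not 0.0 <= self.shunt_fraction < 1.0:
            raise DomainError(f"shunt_fraction={self.shunt_fraction} not in [0, 1)")
        positive = {
            "dead_space_ml": self.dead_space_ml,
            "compliance_ml_per_cmH2O": self.compliance_ml_per_cmH2O,
            "vo2_ml_per_min": self.vo2_ml_per_min,
            "vco2_ml_per_min": self.vco2_ml_per_min,
            "hb_g_per_dl": self.hb_g_per_dl,
            "cardiac_output_l_per_min": self.cardiac_output_l_per_min,
            "drive_threshold_kpa": self.drive_threshold_kpa,
            "drive_gain": self.drive_gain,
            "muscle_pressure_max_cmH2O": self.muscle_pressure_max_cmH2O,
        }
        for name, value in positive.items():
            if not value > 0:
                raise DomainError(f"{name}={value} must be strictly positive")
        if self.dpo2_kpa < 0:
            raise DomainError("dpo2_kpa must be non-negative")
        object.__setattr__(self, "sex", Sex(self.sex))
        predicted_body_weight(self.height_cm, self.sex)  # range check

    @property
    def pbw_kg(self) -> float:
        return predicted_body_weight(self.height_cm, self.sex)


@dataclass(frozen=True)
class VentSettings:
    """Ventilator mode plus exactly the setting values that mode uses."""

    mode: Mode
    fio2_pct: float
    peep_cmH2O: float
    ps_cmH2O: Optional[float] = None      # pressure support above PEEP
    pinsp_cmH2O: Optional[float] = None   # inspiratory pressure above PEEP
    vt_ml: Optional[float] = None
    freq_per_min: Optional[float] = None

    _REQUIRED = {
        Mode.VOLUME_CONTROL: ("vt_ml", "freq_per_min"),
        Mode.PRESSURE_CONTROL: ("pinsp_cmH2O", "freq_per_min"),
        Mode.PRESSURE_SUPPORT: ("ps_cmH2O",),
    }

    def __post_init__(self):
        object.__setattr__(self, "mode", Mode(self.mode))
        if not 21.0 <= self.fio2_pct <= 100.0:
            raise DomainError(f"fio2_pct={self.fio2_pct} outside [21, 100]")
        if self.peep_cmH2O < 0:
            raise DomainError("peep_cmH2O must be >= 0")
        required = self._REQUIRED[self.mode]
        optional_fields = ("ps_cmH2O", "pinsp_cmH2O", "vt_ml", "freq_per_min")
        for name in optional_fields:
            value = getattr(self, name)
            if name in required:
                if value is None:
                    raise DomainError(f"mode {self.mode.value} requires {name}")
                if value < 0:
                    raise DomainError(f"{name}={value} must be >= 0")
            elif value is not None:
                raise DomainError(f"{name} is not a setting of mode {self.mode.value}")

    def active_fields(self) -> tuple[str, ...]:
        return ("fio2_pct", "peep_cmH2O") + self._REQUIRED[self.mode]

    def as_dict(self) -> dict:
        d = {"mode": self.mode.value}
        for name in self.active_fields():
            d[name] = getattr(self, name)
        return d


@dataclass(frozen=True)
class Outcome:
    """Simulated physiological consequence of one settings choice."""

    sao2: float
    svo2: float
    paco2_kpa: float
    ph: float
    vt_ml: float
    freq_per_min: float
    driving_pressure_cmH2O: float
    peak_pressure_cmH2O: float
    fio2_pct: float

    def __post_init__(self):
        if not (0.0 < self.sao2 <= 1.0 and 0.0 < self.svo2 <= 1.0):
            raise DomainError("saturations must lie in (0, 1]")
        if self.paco2_kpa <= 0:
            raise DomainError("paco2_kpa must be positive")

    def as_csv_row(self) -> dict:
        return {
            "sao2": self.sao2,
            "svo2": self.svo2,
            "paco2_kpa": self.paco2_kpa,
            "ph": self.ph,
            "vt_ml": self.vt_ml,
            "freq_per_min": self.freq_per_min,
            "driving_pressure_cmH2O": self.driving_pressure_cmH2O,
            "peak_pressure_cmH2O": self.peak_pressure_cmH2O,
            "fio2_pct": self.fio2_pct,
        }


def odc_saturation(po2_kpa):
    """Oxygen saturation from tension via the Severinghaus 1979 closed form.

    S = 1 / (1 + 23400 / (P^3 + 150 P)) with P in mmHg.  Strictly increasing,
    S(26.8 mmHg) ~ 0.50, S -> 1 at high tension.
    """
    po2 = np.asarray(po2_kpa, dtype=float)
    if np.any(po2 <= 0):
        raise DomainError("oxygen tension must be strictly positive")
    p_mmhg = kpa_to_mmhg(po2)
    sat = 1.0 / (1.0 + 23400.0 / (p_mmhg**3 + 150.0 * p_mmhg))
    return float(sat) if np.isscalar(po2_kpa) else sat


def acid_base_ph(paco2_kpa, base_excess):
    """Arterial pH from PaCO2 and base excess (Henderson-Hasselbalch).

    pH = 6.1 + log10((24.4 + BE) / (0.225 * PaCO2[kPa])).  Strictly decreasing
    in PaCO2 and increasing in BE; anchored at pH 7.40 for PaCO2 5.33 kPa, BE 0.
    """
    paco2 = np.asarray(paco2_kpa, dtype=float)
    be = np.asarray(base_excess, dtype=float)
    if np.any(paco2 <= 0):
        raise DomainError("paco2_kpa must be strictly positive")
    hco3 = HCO3_NORMAL + be
    if np.any(hco3 <= 0):
        raise DomainError("base excess implies non-positive bicarbonate")
    ph = PK_CARBONIC + np.log10(hco3 / (CO2_SOLUBILITY * paco2))
    if np.isscalar(paco2_kpa) and np.isscalar(base_excess):
        return float(ph)
    return ph


def _paco2_from_va(patient: PatientState, va_l_min):
    """Alveolar ventilation equation; +inf where VA <= 0."""
    va = np.asarray(va_l_min, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_mmhg = np.where(va > 0, PACO2_FACTOR * patient.vco2_ml_per_min / va, np.inf)
    return mmhg_to_kpa(p_mmhg)


def _oxygenation(patient: PatientState, fio2_frac, paco2_kpa):
    """End-capillary -> arterial -> venous saturations.

    Returns (sao2, svo2, valid).  The shunt/Fick fixed point has the closed
    form  Sa = Sc - fs/(1-fs) * dS,  Sv = Sa - dS  with
    dS = VO2 / (10 * CO * 1.34 * Hb); substituting back reproduces both the
    mixing and Fick equations exactly.
    """
    rq = patient.vco2_ml_per_min / patient.vo2_ml_per_min
    pao2 = np.asarray(fio2_frac) * (PB_KPA - PH2O_KPA) - np.asarray(paco2_kpa) / rq
    pc_o2 = pao2 - patient.dpo2_kpa
    valid = pc_o2 > 0
    sc = np.where(valid, 1.0 / (1.0 + 23400.0 /
                                (kpa_to_mmhg(np.clip(pc_o2, 1e-9, None))**3 +
                                 150.0 * kpa_to_mmhg(np.clip(pc_o2, 1e-9, None)))),
                  np.nan)
    ds = patient.vo2_ml_per_min / (
        10.0 * patient.cardiac_output_l_per_min * HB_O2_CAPACITY * patient.hb_g_per_dl
    )
    fs = patient.shunt_fraction
    sa = sc - fs / (1.0 - fs) * ds
    sv = sa - ds
    valid = valid & (sv > 0) & (sa > 0)
    return sa, sv, valid


def o2_content_ml_per_dl(patient: PatientState, saturation) -> float:
    """Oxygen content bound to haemoglobin (dissolved O2 neglected)."""
    return HB_O2_CAPACITY * patient.hb_g_per_dl * np.asarray(saturation)


def _support_pattern(patient: PatientState, ps_cmH2O, paco2_kpa, drive: DriveConfig):
    """Breathing pattern (pmus, vt, freq, va) at a hypothesized PaCO2."""
    p = np.asarray(paco2_kpa, dtype=float)
    ps = np.asarray(ps_cmH2O, dtype=float)
    excess = p - patient.drive_threshold_kpa
    pmus = np.clip(drive.pmus_gain_cmH2O_per_kpa * excess,
                   0.0, patient.muscle_pressure_max_cmH2O)
    vt = patient.compliance_ml_per_cmH2O * (ps + pmus)
    freq = np.clip(
        drive.f_base_per_min + patient.drive_gain * excess - drive.k_ps_per_cmH2O * ps,
        drive.f_min_per_min, drive.f_max_per_min,
    )
    va = freq * (vt - patient.dead_space_ml) / 1000.0
    return pmus, vt, freq, va


def solve_support_paco2(patient: PatientState, ps_cmH2O, drive: DriveConfig = DEFAULT_DRIVE):
    """Equilibrium PaCO2 (kPa) of the drive model, by bisection.

    The residual r(p) = p - PaCO2(VA(p)) is strictly increasing (higher PaCO2
    recruits more muscle pressure and frequency, hence more ventilation), so
    the equilibrium is unique whenever one exists.  Array-aware over PS.
    Returns (paco2, feasible).
    """
    if not patient.spontaneous:
        raise DomainError("support-mode simulation requires a spontaneous patient")
    ps = np.asarray(ps_cmH2O, dtype=float)
    lo = np.full(ps.shape, drive.paco2_lo_kpa)
    hi = np.full(ps.shape, drive.paco2_hi_kpa)

    def residual(p):
        _, _, _, va = _support_pattern(patient, ps, p, drive)
        return p - _paco2_from_va(patient, va)

    r_hi = residual(hi)
    feasible = r_hi > 0  # at the bracket top the patient can clear CO2
    for _ in range(drive.bisect_iters):
        mid = 0.5 * (lo + hi)
        r_mid = residual(mid)
        take_lower = r_mid > 0
        hi = np.where(take_lower, mid, hi)
        lo = np.where(take_lower, lo, mid)
    paco2 = 0.5 * (lo + hi)
    if np.any(feasible & (hi - lo > 1e-6)):
        raise ConvergenceError("support-mode bisection failed to tighten bracket",
                               {"ps": ps, "bracket": (lo, hi)})
    if np.isscalar(ps_cmH2O):
        return float(paco2), bool(feasible)
    return paco2, feasible


def predict_grid(patient: PatientState, mode: Mode, fio2_pct, peep_cmH2O,
                 vt_ml=None, freq_per_min=None, pinsp_cmH2O=None, ps_cmH2O=None,
                 drive: DriveConfig = DEFAULT_DRIVE) -> dict:
    """Vectorized forward model over broadcastable setting arrays.

    Returns a dict of outcome arrays plus a boolean ``feasible`` mask (no
    exceptions are raised for individually infeasible points).
    """
    mode = Mode(mode)
    fio2_frac = fio2_pct_to_frac(np.asarray(fio2_pct, dtype=float))
    peep = np.asarray(peep_cmH2O, dtype=float)
    comp = patient.compliance_ml_per_cmH2O

    if mode is Mode.VOLUME_CONTROL:
        vt = np.asarray(vt_ml, dtype=float)
        freq = np.asarray(freq_per_min, dtype=float)
        dp = vt / comp
        peak = peep + dp
        va = freq * (vt - patient.dead_space_ml) / 1000.0
        feasible = va > 0
        paco2 = _paco2_from_va(patient, va)
    elif mode is Mode.PRESSURE_CONTROL:
        pinsp = np.asarray(pinsp_cmH2O, dtype=float)
        freq = np.asarray(freq_per_min, dtype=float)
        vt = comp * pinsp
        dp = pinsp
        peak = peep + pinsp
        va = freq * (vt - patient.dead_space_ml) / 1000.0
        feasible = va > 0
        paco2 = _paco2_from_va(patient, va)
    else:
        ps = np.asarray(ps_cmH2O, dtype=float)
        paco2, feasible = solve_support_paco2(patient, ps, drive)
        paco2 = np.asarray(paco2)
        feasible = np.asarray(feasible)
        pmus, vt, freq, va = _support_pattern(patient, ps, paco2, drive)
        dp = vt / comp
        peak = peep + ps

    paco2 = np.where(feasible, paco2, np.nan)
    ph = PK_CARBONIC + np.log10(
        (HCO3_NORMAL + patient.base_excess_mmol_per_l)
        / (CO2_SOLUBILITY * np.where(feasible, paco2, 1.0))
    )
    sao2, svo2, ox_valid = _oxygenation(patient, fio2_frac, np.where(feasible, paco2, 5.0))
    feasible = feasible & ox_valid
    return {
        "sao2": sao2, "svo2": svo2, "paco2_kpa": paco2, "ph": ph,
        "vt_ml": vt + 0.0 * peep, "freq_per_min": freq + 0.0 * peep,
        "driving_pressure_cmH2O": dp + 0.0 * peep,
        "peak_pressure_cmH2O": peak,
        "fio2_pct": np.asarray(fio2_pct, dtype=float) + 0.0 * peep,
        "feasible": feasible & np.ones_like(peep, dtype=bool),
    }


def simulate(patient: PatientState, settings: VentSettings,
             drive: DriveConfig = DEFAULT_DRIVE) -> Outcome:
    """Simulate one patient under one set of ventilator settings."""
    if settings.mode is Mode.PRESSURE_SUPPORT and not patient.spontaneous:
        raise DomainError("pressure support requires patient.spontaneous")
    if settings.mode in CONTROL_MODES:
        vt = settings.vt_ml if settings.mode is Mode.VOLUME_CONTROL \
            else patient.compliance_ml_per_cmH2O * settings.pinsp_cmH2O
        if vt <= patient.dead_space_ml:
            raise InfeasibleSettingsError(
                f"tidal volume {vt:.0f} ml does not exceed dead space "
                f"{patient.dead_space_ml:.0f} ml: no alveolar ventilation")
    out = predict_grid(
        patient, settings.mode,
        fio2_pct=settings.fio2_pct, peep_cmH2O=settings.peep_cmH2O,
        vt_ml=settings.vt_ml, freq_per_min=settings.freq_per_min,
        pinsp_cmH2O=settings.pinsp_cmH2O, ps_cmH2O=settings.ps_cmH2O,
        drive=drive,
    )
    if not bool(np.asarray(out["feasible"])):
        raise InfeasibleSettingsError(
            "settings are infeasible for this patient (no gas-exchange "
            "equilibrium); inputs: " + repr(settings.as_dict()))
    return Outcome(
        sao2=float(out["sao2"]), svo2=float(out["svo2"]),
        paco2_kpa=float(out["paco2_kpa"]), ph=float(out["ph"]),
        vt_ml=float(out["vt_ml"]), freq_per_min=float(out["freq_per_min"]),
        driving_pressure_cmH2O=float(out["driving_pressure_cmH2O"]),
        peak_pressure_cmH2O=float(out["peak_pressure_cmH2O"]),
        fio2_pct=float(out["fio2_pct"]),
    )
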