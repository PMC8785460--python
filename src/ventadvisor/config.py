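"""Configuration documents: reading, validation and round-tripping.

Patients and ventilator settings are described by JSON or YAML documents
validated against a pydantic schema (unknown keys rejected, violations
reported per field).  The JSON Schema is generated from the same models via
:func:`config_schema`, so validator and schema cannot drift apart.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .errors import ConfigError
from .physiology import Mode, PatientState, Sex, VentSettings


class PatientDoc(BaseModel):
    model_config = ConfigDict(extra="forbid")

    shunt_fraction: float = Field(ge=0.0, lt=1.0)
    dead_space_ml: float = Field(gt=0)
    compliance_ml_per_cmH2O: float = Field(gt=0)
    vo2_ml_per_min: float = Field(gt=0)
    vco2_ml_per_min: float = Field(gt=0)
    hb_g_per_dl: float = Field(gt=0)
    base_excess_mmol_per_l: float = 0.0
    cardiac_output_l_per_min: float = Field(gt=0)
    drive_threshold_kpa: float = Field(default=4.5, gt=0)
    drive_gain: float = Field(default=6.0, gt=0)
    muscle_pressure_max_cmH2O: float = Field(default=10.0, gt=0)
    spontaneous: bool = False
    height_cm: float = Field(ge=100, le=250)
    sex: Sex
    dpo2_kpa: float = Field(default=0.0, ge=0)

    def to_state(self) -> PatientState:
        return PatientState(**self.model_dump())


class SettingsDoc(BaseModel):
    model_config = ConfigDict(extra="forbid")

    mode: Mode
    fio2_pct: float = Field(ge=21, le=100)
    peep_cmH2O: float = Field(ge=0)
    ps_cmH2O: Optional[float] = Field(default=None, ge=0)
    pinsp_cmH2O: Optional[float] = Field(default=None, ge=0)
    vt_ml: Optional[float] = Field(default=None, gt=0)
    freq_per_min: Optional[float] = Field(default=None, gt=0)

    def to_settings(self) -> VentSettings:
        return VentSettings(**self.model_dump())


class RunConfig(BaseModel):
    """Top-level run document: patient + settings + engine overrides."""

    model_config = ConfigDict(extra="forbid")

    patient: PatientDoc
    settings: SettingsDoc
    grid: Optional[dict] = None            # per-setting candidate lists
    preferences: Optional[dict] = None     # PenaltyConfig field overrides
    max_steps: int = Field(default=25, ge=1)
    wait_min: float = Field(default=5.0, ge=5.0, le=20.0)
    seed: int = 0
    output_dir: Optional[str] = None
    verbosity: int = Field(default=1, ge=0, le=2)


def load_config(path) -> RunConfig:
    """Load and validate a JSON/YAML run configuration.

    Raises :class:`ConfigError` naming every offending field.
    """
    text = Path(path).read_text(encoding="utf-8")
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: not valid YAML/JSON: {exc}") from exc
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    try:
        cfg = RunConfig.model_validate(doc)
    except ValidationError as exc:
        failures = "; ".join(
            f"{'.'.join(str(p) for p in e['loc'])}: {e['msg']}" for e in exc.errors())
        raise ConfigError(f"{path}: invalid configuration: {failures}") from exc
    # cross-field mode/setting consistency via the domain type itself
    try:
        cfg.settings.to_settings()
    except Exception as exc:
        raise ConfigError(f"{path}: invalid settings: {exc}") from exc
    return cfg


def save_config(cfg: RunConfig, path) -> None:
    """Write a normalized (defaults applied, keys sorted) JSON document."""
    Path(path).write_text(
        json.dumps(cfg.model_dump(mode="json"), indent=2, sort_keys=True) + "\n",
        encoding="utf-8")


def normalize(cfg: RunConfig) -> dict:
    return cfg.model_dump(mode="json")


def config_hash(cfg: RunConfig) -> str:
    payload = json.dumps(cfg.model_dump(mode="json"), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()


def config_schema() -> dict:
    """JSON Schema of the run configuration document."""
    return RunConfig.model_json_schema()
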