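import pytest

from ventadvisor import Mode, PatientState, Sex, VentSettings


@pytest.fixture
def normal_patient() -> PatientState:
    """Near-normal sedated adult used across tests."""
    return PatientState(
        shunt_fraction=0.05, dead_space_ml=150.0, compliance_ml_per_cmH2O=50.0,
        vo2_ml_per_min=250.0, vco2_ml_per_min=200.0, hb_g_per_dl=14.0,
        base_excess_mmol_per_l=0.0, cardiac_output_l_per_min=5.0,
        drive_threshold_kpa=4.5, drive_gain=6.0, muscle_pressure_max_cmH2O=10.0,
        spontaneous=False, height_cm=175.0, sex=Sex.MALE)


@pytest.fixture
def spont_patient(normal_patient) -> PatientState:
    from dataclasses import replace
    return replace(normal_patient, spontaneous=True)


@pytest.fixture
def vc_settings() -> VentSettings:
    return VentSettings(Mode.VOLUME_CONTROL, fio2_pct=30, peep_cmH2O=5,
                        vt_ml=450, freq_per_min=14)


@pytest.fixture
def ps_settings() -> VentSettings:
    return VentSettings(Mode.PRESSURE_SUPPORT, fio2_pct=30, peep_cmH2O=5,
                        ps_cmH2O=8)
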