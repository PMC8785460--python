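"""Penalty axes: anchors, monotonicity, severity bands, composition."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ventadvisor import (AXES, DomainError, Mode, PenaltyVector, SeverityBand,
                         VentSettings, evaluate, penalty_acidosis,
                         penalty_low_oxygenation, penalty_lung_trauma,
                         penalty_muscle_atrophy, penalty_oxygen_toxicity,
                         penalty_respiratory_stress, severity, simulate,
                         total_penalty)
from ventadvisor.preferences import active_mask_for_mode

PBW = 70.0


def make_pv(mode=Mode.PRESSURE_SUPPORT, **overrides) -> PenaltyVector:
    values = {a: 0.0 for a in AXES}
    values.update(overrides)
    return PenaltyVector(values=values, active=active_mask_for_mode(mode), mode=mode)


def bisect_crossing(f, lo, hi, level, tol=1e-9):
    """x where the monotone curve f crosses `level`, by bisection."""
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if f(mid) > level:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


class TestOxygenToxicity:
    def test_room_air_anchor(self):
        assert penalty_oxygen_toxicity(21.0) == 0.0

    def test_monotone(self):
        assert penalty_oxygen_toxicity(60.0) >= penalty_oxygen_toxicity(40.0)

    def test_green_yellow_crossing_at_default_anchor(self):
        crossing = bisect_crossing(penalty_oxygen_toxicity, 21, 100, 1.0 / 3.0)
        assert crossing == pytest.approx(50.0, abs=1e-6)

    def test_red_band_by_full_oxygen(self):
        assert penalty_oxygen_toxicity(100.0) > 2.0 / 3.0

    def test_domain(self):
        with pytest.raises(DomainError):
            penalty_oxygen_toxicity(15.0)


class TestLowOxygenation:
    def test_healthy_anchor(self):
        assert penalty_low_oxygenation(0.99, 0.75) == 0.0

    def test_arterial_desaturation_monotone(self):
        assert (penalty_low_oxygenation(0.85, 0.75)
                > penalty_low_oxygenation(0.95, 0.75))

    def test_equal_penalty_contour_through_single_variable_anchors(self):
        """The zero contour leaves through the SaO2 0.97 and SvO2 0.70
        anchors found by root-finding on each slice."""
        sa = bisect_crossing(lambda s: penalty_low_oxygenation(1 - s + 1e-12, 0.99),
                             0.0, 0.5, 0.0)
        assert 1 - sa == pytest.approx(0.97, abs=1e-6)
        sv = bisect_crossing(lambda s: penalty_low_oxygenation(0.99, 1 - s + 1e-12),
                             0.0, 0.5, 0.0)
        assert 1 - sv == pytest.approx(0.70, abs=1e-6)


class TestLungTrauma:
    def test_safe_region_anchor(self):
        assert penalty_lung_trauma(6 * PBW, 8.0, 14.0, PBW) == 0.0

    def test_driving_pressure_monotone(self):
        assert (penalty_lung_trauma(6 * PBW, 24.0, 14.0, PBW)
                >= penalty_lung_trauma(6 * PBW, 12.0, 14.0, PBW))

    def test_green_boundary_at_peak_25_with_peep_5(self):
        """The trauma axis leaves green exactly when peak pressure exceeds
        25 cmH2O (driving pressure 20 at PEEP 5)."""
        def band_of(peak):
            pv = make_pv(mode=Mode.VOLUME_CONTROL,
                         lung_trauma=penalty_lung_trauma(6 * PBW, peak - 5.0, 14.0, PBW))
            return severity(pv)
        assert band_of(25.0) is SeverityBand.GREEN
        assert band_of(25.0 + 1e-6) is SeverityBand.YELLOW


class TestAcidosis:
    def test_normal_anchor(self):
        assert penalty_acidosis(7.40) == 0.0

    def test_monotone(self):
        assert penalty_acidosis(7.20) > penalty_acidosis(7.30)

    def test_red_boundary_at_configured_anchor(self):
        crossing = bisect_crossing(lambda ph: penalty_acidosis(7.35 - ph),
                                   0.0, 0.5, 2.0 / 3.0)
        assert 7.35 - crossing == pytest.approx(7.15, abs=1e-6)

    def test_domain(self):
        with pytest.raises(DomainError):
            penalty_acidosis(6.2)


class TestMuscleAxes:
    def test_atrophy_normal_frequency_anchor(self):
        assert penalty_muscle_atrophy(18.0, 7 * PBW / 10, PBW, True) == 0.0

    def test_atrophy_monotone_in_low_frequency(self):
        assert (penalty_muscle_atrophy(6.0, 400, PBW, True)
                > penalty_muscle_atrophy(12.0, 400, PBW, True))

    def test_high_vt_modification_never_relieves(self):
        assert (penalty_muscle_atrophy(8.0, 12 * PBW, PBW, True)
                >= penalty_muscle_atrophy(8.0, 7 * PBW, PBW, True))

    def test_inactive_when_not_spontaneous(self):
        with pytest.raises(DomainError):
            penalty_muscle_atrophy(10.0, 400, PBW, False)

    def test_stress_relaxed_anchor(self):
        assert penalty_respiratory_stress(14.0, 8 * PBW, PBW, True) == 0.0

    def test_stress_rapid_shallow_red(self):
        assert penalty_respiratory_stress(35.0, 4 * PBW, PBW, True) > 2.0 / 3.0

    def test_stress_depends_only_on_index(self):
        a = penalty_respiratory_stress(25.0, 300.0, 60.0, True)
        b = penalty_respiratory_stress(25.0, 450.0, 90.0, True)
        assert a == pytest.approx(b, abs=1e-12)


@settings(derandomize=True, max_examples=200)
@given(st.floats(21, 100), st.floats(0.5, 1.0), st.floats(0.2, 1.0),
       st.floats(100, 900), st.floats(1, 45), st.floats(5, 40),
       st.floats(6.5, 8.0))
def test_all_axes_bounded_unit_interval(fio2, sa, sv, vt, freq, dp, ph):
    vals = [
        penalty_oxygen_toxicity(fio2),
        penalty_low_oxygenation(sa, sv),
        penalty_lung_trauma(vt, dp, freq, PBW),
        penalty_acidosis(ph),
        penalty_muscle_atrophy(freq, vt, PBW, True),
        penalty_respiratory_stress(freq, vt, PBW, True),
    ]
    assert all(0.0 <= v <= 1.0 for v in vals)


class TestEvaluateAndSeverity:
    def test_control_mode_masks_muscle_axes(self, normal_patient, vc_settings):
        pv = evaluate(simulate(normal_patient, vc_settings), vc_settings,
                      normal_patient)
        assert pv.active_axes() == ("lung_trauma", "oxygen_toxicity",
                                    "low_oxygenation", "acidosis")

    def test_support_mode_has_six_axes(self, spont_patient, ps_settings):
        pv = evaluate(simulate(spont_patient, ps_settings), ps_settings,
                      spont_patient)
        assert len(pv.active_axes()) == 6

    def test_axis_entries_equal_axis_functions(self, spont_patient, ps_settings):
        out = simulate(spont_patient, ps_settings)
        pv = evaluate(out, ps_settings, spont_patient)
        pbw = spont_patient.pbw_kg
        assert pv["oxygen_toxicity"] == penalty_oxygen_toxicity(out.fio2_pct)
        assert pv["low_oxygenation"] == penalty_low_oxygenation(out.sao2, out.svo2)
        assert pv["lung_trauma"] == penalty_lung_trauma(
            out.vt_ml, out.driving_pressure_cmH2O, out.freq_per_min, pbw)
        assert pv["acidosis"] == penalty_acidosis(out.ph)
        assert pv["muscle_atrophy"] == penalty_muscle_atrophy(
            out.freq_per_min, out.vt_ml, pbw, True)
        assert pv["respiratory_stress"] == penalty_respiratory_stress(
            out.freq_per_min, out.vt_ml, pbw, True)

    def test_evaluate_is_deterministic(self, spont_patient, ps_settings):
        a = evaluate(simulate(spont_patient, ps_settings), ps_settings, spont_patient)
        b = evaluate(simulate(spont_patient, ps_settings), ps_settings, spont_patient)
        assert a.values == b.values

    def test_total_is_sum_of_active(self):
        pv = make_pv(mode=Mode.VOLUME_CONTROL, oxygen_toxicity=0.2,
                     low_oxygenation=0.1, lung_trauma=0.3,
                     muscle_atrophy=0.9, respiratory_stress=0.9)
        assert total_penalty(pv) == pytest.approx(0.6)  # masked axes excluded

    def test_severity_bands(self):
        assert severity(make_pv(lung_trauma=0.1)) is SeverityBand.GREEN
        assert severity(make_pv(acidosis=0.5)) is SeverityBand.YELLOW
        assert severity(make_pv(acidosis=0.9)) is SeverityBand.RED

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.floats(0, 1), min_size=6, max_size=6), st.integers(0, 5))
    def test_severity_depends_only_on_max(self, vals, rot):
        pv1 = make_pv(**dict(zip(AXES, vals)))
        rotated = vals[rot:] + vals[:rot]
        pv2 = make_pv(**dict(zip(AXES, rotated)))
        assert severity(pv1) is severity(pv2)
        assert total_penalty(pv1) == pytest.approx(total_penalty(pv2))
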