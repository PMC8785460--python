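"""Settings search, step caps and the advisory loop."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings as hsettings, strategies as st

from ventadvisor import (DomainError, Mode, SettingsGrid, StepCaps,
                         VentSettings, advise_loop, find_optimum,
                         scenario_by_name, simulate_settings, step_advice,
                         total_penalty)


def brute_force_optimum(patient, grid):
    """Independent oracle: plain scalar enumeration of the grid."""
    best = None
    for cand in grid.points():
        try:
            _, pv = simulate_settings(patient, cand)
        except Exception:
            continue
        total = total_penalty(pv)
        if best is None or total < best[0] - 1e-15:
            best = (total, cand)
    return best


SMALL_GRIDS = {
    "support": lambda cur: SettingsGrid(
        mode=Mode.PRESSURE_SUPPORT, fio2_pct=(25, 30, 35, 40),
        peep_cmH2O=(cur.peep_cmH2O,), ps_cmH2O=tuple(range(0, 15))),
    "volume": lambda cur: SettingsGrid(
        mode=Mode.VOLUME_CONTROL, fio2_pct=(25, 30, 40),
        peep_cmH2O=(cur.peep_cmH2O,), vt_ml=(350, 400, 450, 500, 550),
        freq_per_min=(10, 14, 18, 22)),
}


class TestFindOptimum:
    def test_singleton_grid_returns_that_point(self, spont_patient, ps_settings):
        grid = SettingsGrid(mode=Mode.PRESSURE_SUPPORT,
                            fio2_pct=(30,), peep_cmH2O=(5,), ps_cmH2O=(8,))
        assert find_optimum(spont_patient, ps_settings, grid) == ps_settings

    @pytest.mark.parametrize("scenario,kind", [
        ("over_support", "support"),
        ("under_support", "support"),
        ("over_oxygenation", "volume"),
        ("over_ventilation", "volume"),
    ])
    def test_matches_exhaustive_oracle(self, scenario, kind):
        sc = scenario_by_name(scenario)
        grid = SMALL_GRIDS[kind](sc.settings)
        oracle_total, _ = brute_force_optimum(sc.patient, grid)
        opt = find_optimum(sc.patient, sc.settings, grid)
        _, pv = simulate_settings(sc.patient, opt)
        assert total_penalty(pv) == pytest.approx(oracle_total, abs=1e-9)

    def test_overoxygenated_patient_gets_lower_fio2(self):
        sc = scenario_by_name("over_oxygenation")
        start = replace(sc.settings, fio2_pct=80.0)
        opt = find_optimum(sc.patient, start)
        assert opt.fio2_pct < 80.0

    def test_tie_break_prefers_current_settings(self, spont_patient, ps_settings):
        # PEEP does not enter the penalties in support mode, so all PEEP
        # candidates tie; minimal-change tie-breaking must keep the current one
        grid = SettingsGrid(mode=Mode.PRESSURE_SUPPORT, fio2_pct=(30,),
                            peep_cmH2O=(2, 5, 8, 11), ps_cmH2O=(8,))
        opt = find_optimum(spont_patient, ps_settings, grid)
        assert opt.peep_cmH2O == ps_settings.peep_cmH2O

    def test_default_grid_contains_current(self, ps_settings):
        grid = SettingsGrid.default_for(replace(ps_settings, fio2_pct=33.0,
                                                ps_cmH2O=7.5))
        assert grid.contains(replace(ps_settings, fio2_pct=33.0, ps_cmH2O=7.5))


class TestStepAdvice:
    def test_null_at_optimum(self, ps_settings):
        advice = step_advice(ps_settings, ps_settings)
        assert advice.is_null and all(d == 0 for d in advice.deltas.values())

    def test_pressure_support_2_2_1_schedule(self, ps_settings):
        current = replace(ps_settings, ps_cmH2O=11.0)
        optimum = replace(ps_settings, ps_cmH2O=6.0)
        deltas = []
        while True:
            advice = step_advice(current, optimum)
            if advice.is_null:
                break
            deltas.append(advice.deltas["ps_cmH2O"])
            current = advice.target
        assert deltas == [-2.0, -2.0, -1.0]

    def test_peep_increase_cap_depends_on_current_level(self, ps_settings):
        lo = step_advice(replace(ps_settings, peep_cmH2O=6.0),
                         replace(ps_settings, peep_cmH2O=14.0))
        hi = step_advice(replace(ps_settings, peep_cmH2O=12.0),
                         replace(ps_settings, peep_cmH2O=16.0))
        down = step_advice(replace(ps_settings, peep_cmH2O=8.0),
                           replace(ps_settings, peep_cmH2O=2.0))
        assert lo.deltas["peep_cmH2O"] == 3.0
        assert hi.deltas["peep_cmH2O"] == 2.0
        assert down.deltas["peep_cmH2O"] == -2.0

    def test_mode_mismatch_rejected(self, ps_settings, vc_settings):
        with pytest.raises(DomainError):
            step_advice(ps_settings, vc_settings)

    @hsettings(derandomize=True, max_examples=150)
    @given(st.floats(21, 100), st.floats(21, 100), st.floats(0, 18),
           st.floats(0, 18), st.floats(0, 20), st.floats(0, 20))
    def test_caps_never_exceeded(self, f0, f1, p0, p1, s0, s1):
        caps = StepCaps()
        current = VentSettings(Mode.PRESSURE_SUPPORT, fio2_pct=f0,
                               peep_cmH2O=p0, ps_cmH2O=s0)
        optimum = VentSettings(Mode.PRESSURE_SUPPORT, fio2_pct=f1,
                               peep_cmH2O=p1, ps_cmH2O=s1)
        advice = step_advice(current, optimum)
        assert abs(advice.deltas["fio2_pct"]) <= caps.fio2_pct + 1e-12
        assert abs(advice.deltas["ps_cmH2O"]) <= caps.pressure_cmH2O + 1e-12
        peep_cap = (caps.peep_increase_low_cmH2O
                    if advice.deltas["peep_cmH2O"] > 0 and p0 < 10
                    else caps.pressure_cmH2O)
        assert abs(advice.deltas["peep_cmH2O"]) <= peep_cap + 1e-12
        # each setting moves toward its optimum, never past it
        for name in ("fio2_pct", "peep_cmH2O", "ps_cmH2O"):
            gap = getattr(optimum, name) - getattr(current, name)
            d = advice.deltas[name]
            assert d * gap >= 0 and abs(d) <= abs(gap) + 1e-12


class TestAdviseLoop:
    def test_start_at_optimum_yields_single_null_record(self, spont_patient,
                                                        ps_settings):
        opt = find_optimum(spont_patient, ps_settings)
        traj = advise_loop(spont_patient, opt)
        assert len(traj) == 1 and traj.steps[0].advice.is_null and traj.converged

    def test_five_above_optimum_takes_three_steps(self, spont_patient):
        """A pressure-support start exactly 5 cmH2O above the optimum is
        closed in steps of 2, 2 and 1."""
        base = VentSettings(Mode.PRESSURE_SUPPORT, fio2_pct=30, peep_cmH2O=5,
                            ps_cmH2O=8)
        opt = find_optimum(spont_patient, base)
        start = replace(opt, ps_cmH2O=opt.ps_cmH2O + 5.0)
        traj = advise_loop(spont_patient, start)
        ps_deltas = [s.advice.deltas["ps_cmH2O"] for s in traj.steps
                     if not s.advice.is_null]
        assert ps_deltas == [-2.0, -2.0, -1.0]
        assert len(traj) == 4 and traj.converged

    def test_total_penalty_non_increasing_along_trajectory(self):
        for name in ("over_oxygenation", "over_support", "over_ventilation"):
            sc = scenario_by_name(name)
            traj = advise_loop(sc.patient, sc.settings)
            totals = [total_penalty(s.penalties) for s in traj.steps]
            assert all(a >= b - 1e-9 for a, b in zip(totals, totals[1:])), name
            assert traj.converged, name

    def test_termination_bound(self):
        """Convergence within ceil(max gap / cap) + 1 records for a static
        optimum."""
        sc = scenario_by_name("over_support")
        opt = find_optimum(sc.patient, sc.settings)
        traj = advise_loop(sc.patient, sc.settings)
        caps = StepCaps()
        bound = 1 + max(
            math.ceil(abs(getattr(opt, n) - getattr(sc.settings, n))
                      / caps.cap_for(n, sc.settings,
                                     getattr(opt, n) - getattr(sc.settings, n)))
            for n in ("fio2_pct", "peep_cmH2O", "ps_cmH2O"))
        assert len(traj) <= bound + 1  # + final null record

    def test_consecutive_settings_differ_by_emitted_deltas(self):
        sc = scenario_by_name("over_oxygenation")
        traj = advise_loop(sc.patient, sc.settings)
        for a, b in zip(traj.steps, traj.steps[1:]):
            for name, delta in a.advice.deltas.items():
                assert getattr(b.settings, name) == pytest.approx(
                    getattr(a.settings, name) + delta)

    def test_wait_metadata_recorded_and_bounded(self, spont_patient, ps_settings):
        traj = advise_loop(spont_patient, ps_settings, wait_min=10.0)
        times = [s.time_min for s in traj.steps]
        assert times == [10.0 * i for i in range(len(times))]
        with pytest.raises(DomainError):
            advise_loop(spont_patient, ps_settings, wait_min=4.0)
        with pytest.raises(DomainError):
            advise_loop(spont_patient, ps_settings, wait_min=25.0)


class TestSimulateSettings:
    def test_pure_composition(self, spont_patient, ps_settings):
        out1, pv1 = simulate_settings(spont_patient, ps_settings)
        out2, pv2 = simulate_settings(spont_patient, ps_settings)
        assert out1 == out2 and pv1.values == pv2.values

    def test_fio2_increase_never_raises_hypoxia_penalty(self, normal_patient,
                                                        vc_settings):
        patient = replace(normal_patient, shunt_fraction=0.25)
        penalties = [simulate_settings(patient, replace(vc_settings, fio2_pct=f)
                                       )[1]["low_oxygenation"]
                     for f in range(25, 101, 5)]
        assert all(a >= b - 1e-12 for a, b in zip(penalties, penalties[1:]))
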