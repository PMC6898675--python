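"""Integrator and pacing-engine behavior on the toy model."""

import numpy as np
import pytest

from cardioprofile.engine import (
    PacingProtocol,
    StepController,
    euler_integrate,
    pace,
    step,
    sweep_cl,
    write_trace,
)
from cardioprofile.synthetic_fixtures import TOY_MODEL, make_toy_cell


class TestStepController:
    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            StepController(dt_min=0.01, dt_max=0.001)
        with pytest.raises(ValueError):
            StepController(dt_min=0.003, dt_max=0.01)

    def test_slow_phase_uses_dt_max(self, toy_cell):
        params, state = toy_cell
        ctrl = StepController()
        _, dt = step(state, params, 0.0, ctrl, TOY_MODEL)
        assert dt == ctrl.dt_max  # resting cell: |dV/dt| far below threshold

    def test_stimulus_forces_dt_min(self, toy_cell):
        params, state = toy_cell
        ctrl = StepController()
        _, dt = step(state, params, -90.0, ctrl, TOY_MODEL, stim_active=True)
        assert dt == ctrl.dt_min

    def test_fast_upstroke_forces_dt_min(self, toy_cell):
        params, state = toy_cell
        ctrl = StepController()
        s = state.copy()
        s.v = -30.0  # inside the activation window: large dV/dt
        _, dt = step(s, params, 0.0, ctrl, TOY_MODEL)
        assert dt == ctrl.dt_min

    def test_stimulus_enters_linearly(self, toy_cell):
        from cardioprofile.model_core import rhs
        params, state = toy_cell
        d1 = rhs(state, params, i_stim=-10.0, model=TOY_MODEL)
        d2 = rhs(state, params, i_stim=-20.0, model=TOY_MODEL)
        assert d2["v"] - d1["v"] == pytest.approx(10.0)
        for gate in ("f", "x", "w"):
            assert d1[gate] == d2[gate]


class TestEulerOracle:
    def test_exponential_decay(self):
        y = euler_integrate(lambda t, y: -y, np.array([1.0]), 0.001, 1.0)
        assert abs(y[0] - np.exp(-1.0)) / np.exp(-1.0) < 1e-3


class TestPace:
    def test_max_beats_one_gives_one_trace(self, toy_cell):
        params, state = toy_cell
        res = pace(TOY_MODEL, params, PacingProtocol(cl=1000.0, max_beats=1))
        assert len(res.beats) == 1
        assert res.n_beats == 1

    def test_trace_grid(self, toy_paced):
        tr = toy_paced.beats[-1]
        assert tr.t[0] == 0.0
        assert tr.t[-1] == pytest.approx(tr.cl)
        assert np.all(np.diff(tr.t) > 0)

    def test_converges_within_tolerance(self, toy_paced):
        assert toy_paced.converged
        a = toy_paced.apd90_series
        assert abs(a[-1] - a[-2]) < 0.1

    def test_determinism_bit_identical(self, toy_cell):
        params, state = toy_cell
        proto = PacingProtocol(cl=1000.0, max_beats=20, ss_window=6)
        r1 = pace(TOY_MODEL, params, proto)
        r2 = pace(TOY_MODEL, params, proto)
        assert np.array_equal(r1.apd90_series, r2.apd90_series)
        assert np.array_equal(r1.beats[-1].v, r2.beats[-1].v)

    def test_dt_halving_changes_apd_under_1ms(self, toy_cell):
        params, state = toy_cell
        proto = PacingProtocol(cl=1000.0, max_beats=30, ss_window=6)
        coarse = pace(TOY_MODEL, params, proto, StepController())
        fine = pace(TOY_MODEL, params, proto,
                    StepController(dt_min=0.001, dt_max=0.005))
        assert abs(coarse.apd90 - fine.apd90) < 1.0

    def test_gates_stay_bounded(self, toy_paced):
        final = toy_paced.final_state
        for name, x in final.gates.items():
            assert 0.0 <= x <= 1.0, name
        assert toy_paced.max_gate_excursion < 1e-6

    def test_invalid_protocol_rejected(self):
        with pytest.raises(ValueError):
            PacingProtocol(cl=100.0, stim_duration=200.0)
        with pytest.raises(ValueError):
            PacingProtocol(cl=1000.0, max_beats=0)

    def test_full_schedule_bound_is_60_minutes(self):
        assert PacingProtocol(cl=1000.0).resolved_max_beats() == 3600
        assert PacingProtocol(cl=700.0).resolved_max_beats() == 5143


class TestSweep:
    def test_single_entry_equals_pace(self, toy_cell):
        params, state = toy_cell
        proto = PacingProtocol(cl=1000.0, max_beats=20, ss_window=6)
        solo = pace(TOY_MODEL, params, proto)
        swept = sweep_cl(TOY_MODEL, params, [1000.0],
                         protocol_factory=lambda cl: PacingProtocol(
                             cl=cl, max_beats=20, ss_window=6))
        assert swept[1000.0].apd90 == solo.apd90

    def test_each_cl_from_fresh_state(self, toy_cell):
        params, state = toy_cell
        factory = lambda cl: PacingProtocol(cl=cl, max_beats=15, ss_window=6)
        res = sweep_cl(TOY_MODEL, params, [800.0, 1200.0],
                       protocol_factory=factory)
        again = sweep_cl(TOY_MODEL, params, [1200.0], protocol_factory=factory)
        assert res[1200.0].apd90 == again[1200.0].apd90


class TestTraceIO:
    def test_write_trace_round_trip(self, toy_paced, tmp_path):
        import pandas as pd
        tr = toy_paced.beats[-1]
        path = tmp_path / "beat.tsv"
        write_trace(tr, path)
        df = pd.read_csv(path, sep="\t")
        assert "t_ms" in df.columns and "V_mV" in df.columns
        assert len(df) == len(tr.t)
        np.testing.assert_allclose(df["V_mV"], tr.v, rtol=1e-4, atol=1e-3)
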