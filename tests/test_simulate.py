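"""Integration, burst detection, and cycle-metric tests."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from lrcpg import (
    CenterParams,
    ConvergenceOptions,
    NetworkConfig,
    NetworkState,
    SolverOptions,
    Trajectory,
    alt_seed,
    cycle_metrics,
    detect_bursts,
    integrate,
    integrate_center,
    steady_state_metrics,
)
from lrcpg.model_core import single_center_rhs
from lrcpg.simulate import BurstEvent, cold_start


class TestDetectBursts:
    def test_constant_zero_activity(self):
        t = np.arange(0, 1000.0, 1.0)
        traj = Trajectory(t, np.full((4, t.size), -60.0), np.full((4, t.size), 0.5),
                          np.zeros((4, t.size)))
        assert detect_bursts(traj, 1) == []

    def test_square_pulse_single_event(self, fixtures):
        events = detect_bursts(fixtures["square_pulse"], 1, theta_on=0.05)
        assert len(events) == 1
        ev = events[0]
        assert ev.t_onset == pytest.approx(100.0, abs=1.5)
        assert ev.t_offset == pytest.approx(600.0, abs=1.5)
        assert ev.peak_activity == 1.0

    def test_nearby_events_merged(self):
        t = np.arange(0, 2000.0, 1.0)
        a = np.zeros((4, t.size))
        a[0, (t >= 100) & (t < 300)] = 1.0
        a[0, (t >= 330) & (t < 600)] = 1.0   # 30 ms gap < min_gap
        traj = Trajectory(t, -60 + 60 * a, np.full_like(a, 0.5), a)
        events = detect_bursts(traj, 1, min_gap=50.0)
        assert len(events) == 1
        assert events[0].t_offset - events[0].t_onset > 400

    def test_partial_bursts_dropped(self):
        t = np.arange(0, 1000.0, 1.0)
        a = np.zeros((4, t.size))
        a[0, t < 200] = 1.0          # in progress at t=0
        a[0, t >= 800] = 1.0         # no offset before the record ends
        traj = Trajectory(t, -60 + 60 * a, np.full_like(a, 0.5), a)
        assert detect_bursts(traj, 1) == []

    def test_threshold_ordering_enforced(self, fixtures):
        with pytest.raises(ValueError):
            detect_bursts(fixtures["square_pulse"], 1, theta_on=0.02, theta_off=0.05)


class TestCycleMetrics:
    def _ev(self, cid, on, off):
        return BurstEvent(cid, on, off, 1.0)

    @pytest.mark.parametrize("rf_onset,expected", [(500.0, 0.5), (200.0, 0.2)])
    def test_phase_difference_from_onset_lag(self, rf_onset, expected):
        lf = [self._ev(1, 0.0, 100.0), self._ev(1, 1000.0, 1100.0)]
        rf = [self._ev(3, rf_onset, rf_onset + 100.0)]
        m = cycle_metrics(lf, rf)[0]
        assert m.dphi_LF_RF == pytest.approx(expected)
        assert m.period == pytest.approx(1000.0)
        assert m.frequency == pytest.approx(1.0)

    def test_extensor_duration_is_complement(self):
        lf = [self._ev(1, 0.0, 300.0), self._ev(1, 1000.0, 1300.0)]
        m = cycle_metrics(lf, [self._ev(3, 500.0, 800.0)])[0]
        assert m.dur_flexor == pytest.approx(300.0)
        assert m.dur_extensor == pytest.approx(700.0)
        assert m.duty_cycle_flexor == pytest.approx(0.3)

    def test_missing_contralateral_onset_flagged(self):
        lf = [self._ev(1, 0.0, 100.0), self._ev(1, 1000.0, 1100.0)]
        m = cycle_metrics(lf, [])[0]
        assert math.isnan(m.dphi_LF_RF)

    def test_two_cycle_fixture(self, fixtures):
        tr = fixtures["two_cycle"]
        m = cycle_metrics(detect_bursts(tr, 1), detect_bursts(tr, 3),
                          detect_bursts(tr, 2))[0]
        assert m.period == pytest.approx(1000.0, abs=2)
        assert m.dphi_LF_RF == pytest.approx(0.5, abs=5e-3)
        assert m.dphi_F_E == pytest.approx(0.3, abs=5e-3)

    def test_requires_two_lf_bursts(self):
        with pytest.raises(ValueError):
            cycle_metrics([self._ev(1, 0.0, 1.0)], [])


class TestIntegration:
    def test_mirrored_initial_conditions_give_mirrored_trajectory(self, params, cfg):
        s = NetworkState(V=np.array([-40.0, -60.0, -55.0, -58.0]),
                         h=np.array([0.7, 0.6, 0.5, 0.55]))
        t1 = integrate(s, 0.8, params, cfg, duration=5000.0)
        t2 = integrate(s.mirrored(), 0.8, params, cfg, duration=5000.0)
        idx = [2, 3, 0, 1]
        np.testing.assert_allclose(t2.V, t1.V[idx], atol=1e-9)
        np.testing.assert_allclose(t2.h, t1.h[idx], atol=1e-12)

    def test_h_stays_in_unit_box(self, params, cfg, rng):
        for _ in range(3):
            s = NetworkState(V=rng.uniform(-70, -20, 4), h=rng.uniform(0, 1, 4))
            tr = integrate(s, 0.9, params, cfg, duration=20000.0)
            assert tr.h.min() >= 0.0 and tr.h.max() <= 1.0

    def test_uncoupled_center_matches_independent_2d_integration(self, params):
        """Oracle: the network kernel with zero weights must reproduce a
        separate 2-D integration of the single-center equations by SciPy."""
        E_L = -60.0
        tr = integrate_center(E_L, p=params, initial=(-58.0, 0.55), duration=20000.0)

        def rhs(_t, y):
            return single_center_rhs(y[0], y[1], E_L, params)

        sol = solve_ivp(rhs, (0, 20000.0), [-58.0, 0.55], t_eval=tr.t,
                        rtol=1e-10, atol=1e-12, max_step=1.0)
        np.testing.assert_allclose(tr.V[0], sol.y[0], atol=0.02)
        np.testing.assert_allclose(tr.h[0], sol.y[1], atol=1e-4)

    def test_fixed_and_adaptive_solvers_agree(self, params, cfg):
        s = alt_seed()
        a = integrate(s, 0.8, params, cfg, duration=10000.0)
        b = integrate(s, 0.8, params, cfg, duration=10000.0,
                      solver=SolverOptions(method="rk45"))
        np.testing.assert_allclose(a.V, b.V, atol=0.15)

    def test_noise_requires_seed(self, params, cfg):
        with pytest.raises(ValueError, match="seed"):
            integrate(alt_seed(), 0.8, params, cfg, duration=100.0,
                      solver=SolverOptions(noise_amp=5.0))

    def test_noise_is_reproducible_given_seed(self, params, cfg):
        so = SolverOptions(noise_amp=5.0, noise_seed=42)
        a = integrate(alt_seed(), 0.8, params, cfg, duration=2000.0, solver=so)
        b = integrate(alt_seed(), 0.8, params, cfg, duration=2000.0, solver=so)
        np.testing.assert_array_equal(a.V, b.V)


class TestSteadyState:
    def test_all_weights_zero_low_drive_relaxes_to_rest(self, params):
        cfg = NetworkConfig(E_LF0=-70.0, E_LE0=-70.0, a_30=0.0, a_V0=0.0,
                            a_D=0.0, b_1=0.0, b_2=0.0)
        r = steady_state_metrics(cold_start(), 0.0, params, cfg)
        assert r.converged and not r.oscillatory
        assert np.all(r.final_state.V < -60.0)

    def test_intact_alternation_at_high_alpha(self, params, cfg):
        r = steady_state_metrics(alt_seed(), 0.8, params, cfg)
        assert r.converged and r.oscillatory
        assert r.metrics.dphi_LF_RF == pytest.approx(0.5, abs=0.01)

    def test_burst_spacing_matches_reported_period(self, params, cfg):
        """Cross-check: LF burst spacing on a fresh trajectory equals the
        converged cycle period."""
        r = steady_state_metrics(alt_seed(), 0.8, params, cfg)
        tr = integrate(r.final_state, 0.8, params, cfg, duration=20000.0)
        onsets = [b.t_onset for b in detect_bursts(tr, 1)]
        spacing = np.diff(onsets)
        assert np.allclose(spacing, r.metrics.period, rtol=0.01)

    def test_phase_insensitive_to_halving_the_step(self, params, cfg):
        r1 = steady_state_metrics(alt_seed(), 0.8, params, cfg,
                                  solver=SolverOptions(dt=0.1))
        r2 = steady_state_metrics(alt_seed(), 0.8, params, cfg,
                                  solver=SolverOptions(dt=0.05))
        assert abs(r1.metrics.dphi_LF_RF - r2.metrics.dphi_LF_RF) < 1e-3
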