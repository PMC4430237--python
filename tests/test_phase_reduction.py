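"""Weak-coupling phase model: coupling function, potential, fixed points."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from lrcpg import (
    PhaseReductionParams,
    coupling_G,
    effective_coupling_A,
    fixed_points,
    potential_P,
    reduced_bifurcation_diagram,
)


class TestEffectiveCoupling:
    def test_intact_baseline(self):
        assert effective_coupling_A(0.0) == pytest.approx(7.0)   # -4 + 0 + 11

    def test_both_v0_deleted_always_negative(self):
        for a in np.linspace(0, 10, 21):
            A = effective_coupling_A(a, knockout="dV0")
            assert A == pytest.approx(-4.0 - 2.0 * a)
            assert A < 0

    def test_v0d_deleted_baseline(self):
        assert effective_coupling_A(0.0, knockout="dV0D") == pytest.approx(-4.0)

    def test_intact_alternation_stable_for_all_alpha(self):
        p = PhaseReductionParams()
        for a in np.linspace(0, 8, 17):
            assert effective_coupling_A(a, p) > 2 * p.B   # only pi stable


class TestCouplingAndPotential:
    def test_zeros_at_sync_and_antiphase(self):
        assert coupling_G(0.0, 3.0, 1.5) == pytest.approx(0.0)
        assert coupling_G(math.pi, 3.0, 1.5) == pytest.approx(0.0, abs=1e-12)

    def test_example_value(self):
        assert coupling_G(math.pi / 2, 2.0, 1.0) == pytest.approx(2.0)

    def test_odd_and_periodic(self, rng):
        phi = rng.uniform(0, 2 * math.pi, 50)
        np.testing.assert_allclose(coupling_G(-phi, 1.3, 0.7),
                                   -coupling_G(phi, 1.3, 0.7), atol=1e-12)
        np.testing.assert_allclose(coupling_G(phi + 2 * math.pi, 1.3, 0.7),
                                   coupling_G(phi, 1.3, 0.7), atol=1e-12)

    def test_potential_gradient_is_minus_G(self):
        phi = np.linspace(0, 2 * math.pi, 2001)
        P = potential_P(phi, 1.7, 0.9)
        dP = np.gradient(P, phi)
        np.testing.assert_allclose(dP[5:-5], -coupling_G(phi, 1.7, 0.9)[5:-5],
                                   atol=1e-4)

    def test_zero_coupling_flat_potential(self):
        assert np.all(potential_P(np.linspace(0, 7, 20), 0.0, 0.0) == 0.0)

    def test_stable_points_are_potential_minima(self):
        A, B = 0.8, 1.0
        phi = np.linspace(0, 2 * math.pi, 20001)
        P = potential_P(phi, A, B)
        for fp in fixed_points(A, B):
            i = np.argmin(np.abs(phi - fp.phi))
            if 10 < i < len(phi) - 10:
                is_min = P[i] < P[i - 10] and P[i] < P[i + 10]
                assert is_min == (fp.stability == "stable")


class TestFixedPoints:
    def test_alternation_only(self):
        fps = {round(f.phi, 6): f.stability for f in fixed_points(3.0, 1.0)}
        assert fps[0.0] == "unstable"
        assert fps[round(math.pi, 6)] == "stable"
        assert len(fps) == 2

    def test_synchronization_only(self):
        fps = {round(f.phi, 6): f.stability for f in fixed_points(-3.0, 1.0)}
        assert fps[0.0] == "stable"
        assert fps[round(math.pi, 6)] == "unstable"

    def test_bistable_with_interior_separatrices(self):
        fps = fixed_points(0.0, 1.0)
        stab = {round(f.phi, 4): f.stability for f in fps}
        assert stab[0.0] == "stable" and stab[round(math.pi, 4)] == "stable"
        assert stab[round(math.pi / 2, 4)] == "unstable"
        assert stab[round(3 * math.pi / 2, 4)] == "unstable"

    def test_interior_points_exist_iff_bistable_window(self, rng):
        for _ in range(50):
            B = rng.uniform(0.1, 3.0)
            A = rng.uniform(-4 * B, 4 * B)
            fps = fixed_points(A, B)
            interior = [f for f in fps if f.phi not in (0.0, math.pi)]
            if abs(A) < 2 * B:
                assert len(interior) == 2
                assert all(f.stability == "unstable" for f in interior)
            elif abs(A) > 2 * B:
                assert interior == []

    def test_degenerate_boundary_flagged(self):
        fps = {f.phi: f.stability for f in fixed_points(2.0, 1.0)}
        assert fps[0.0] == "degenerate"

    def test_no_bistability_without_positive_B(self, rng):
        """With B <= 0 the sync and alternation states are never
        simultaneously stable."""
        for B in (-1.0, 0.0):
            for A in rng.uniform(-3, 3, 20):
                stable = {f.phi for f in fixed_points(A, B) if f.stability == "stable"}
                assert not ({0.0, math.pi} <= stable)

    def test_attractors_match_integrated_dynamics(self, rng):
        """Oracle: integrate dphi/dt = G(phi) from uniform initial phases;
        the set of limits must equal the stable fixed points."""
        for _ in range(10):
            B = rng.uniform(0.2, 2.0)
            A = rng.uniform(-3 * B, 3 * B)
            if min(abs(A - 2 * B), abs(A + 2 * B)) < 0.05:
                continue  # skip near-degenerate boundaries
            stable = sorted(f.phi for f in fixed_points(A, B) if f.stability == "stable")
            phis0 = np.linspace(0.05, 2 * math.pi - 0.05, 24)
            sol = solve_ivp(lambda t, y: coupling_G(y, A, B), (0, 400.0), phis0,
                            rtol=1e-9, atol=1e-11)
            limits = np.sort(np.unique(np.round(np.mod(sol.y[:, -1], 2 * math.pi), 2)))
            merged = {0.0 if min(l, 2 * math.pi - l) < 0.05 else l for l in limits}
            for l in merged:
                assert any(abs(l - s) < 0.05 for s in stable)


class TestReducedDiagram:
    def test_scenario_topologies(self):
        grid = np.linspace(0, 8, 81)
        intact = reduced_bifurcation_diagram(knockout="intact", alpha_grid=grid)
        pi_rows = intact[np.isclose(intact.phi, math.pi)]
        assert (pi_rows.stability == "stable").all()

        dv0 = reduced_bifurcation_diagram(knockout="dV0", alpha_grid=grid)
        assert (dv0[np.isclose(dv0.phi, math.pi)].stability == "unstable").all()
        assert (dv0[np.isclose(dv0.phi, 0.0)].stability == "stable").all()

    def test_v0v_deleted_supercritical_pitchfork(self):
        """Interior separatrix branches appear when sync stabilizes and merge
        into pi where alternation destabilizes."""
        grid = np.linspace(0, 8, 161)
        df = reduced_bifurcation_diagram(knockout="dV0V", alpha_grid=grid)
        interior = df[~np.isclose(df.phi, 0.0) & ~np.isclose(df.phi, math.pi)
                      & ~np.isclose(df.phi, 2 * math.pi)]
        assert not interior.empty
        # A(alpha) = 7 - 2 alpha: sync stabilizes at alpha=2.5, pi destabilizes at 4.5
        assert interior.alpha.min() == pytest.approx(2.5, abs=0.1)
        assert interior.alpha.max() == pytest.approx(4.5, abs=0.1)
        sync = df[np.isclose(df.phi, 0.0) & (df.stability != "degenerate")].sort_values("alpha")
        flips = sync.stability.ne(sync.stability.shift()).iloc[1:].sum()
        assert flips == 1    # unstable -> stable exactly once (supercritical pitchfork)

    def test_v0d_deleted_is_reverse_scenario(self):
        grid = np.linspace(0, 8, 161)
        df = reduced_bifurcation_diagram(knockout="dV0D", alpha_grid=grid)
        lo = df[(df.alpha < 1.5) & np.isclose(df.phi, 0.0)]
        hi = df[(df.alpha > 6.5) & np.isclose(df.phi, math.pi)]
        assert (lo.stability == "stable").all()
        assert (hi.stability == "stable").all()
        assert (df[(df.alpha > 6.5) & np.isclose(df.phi, 0.0)].stability == "unstable").all()
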