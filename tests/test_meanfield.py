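"""Mean-field ODE: drives, regimes, event-driven integration, manifolds."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from affectpol import (
    ModelParams,
    StateVector,
    classify_regime,
    consensus_reachable,
    drives,
    effective_params,
    integrate,
    limiting_state,
    rhs,
    switching_manifolds,
)
from affectpol.meanfield import FULLY_CONNECTED, SBM, MeanFieldConfig
from conftest import euler_integrate, random_case1_config


def cfg_of(alpha, beta, r, delta=0.0, rho=0.5, mode=FULLY_CONNECTED):
    return MeanFieldConfig(ModelParams(alpha, beta, delta, rho), r, mode=mode)


class TestEffectiveParams:
    def test_sbm_rescaling(self):
        assert effective_params(ModelParams(0.8, 0.7, rho=0.5), SBM) == (0.4, 0.35)
        ae, be = effective_params(ModelParams(0.8, 0.7, rho=0.7), SBM)
        assert (ae, be) == (pytest.approx(0.56), pytest.approx(0.21))

    def test_fully_connected_passthrough(self):
        assert effective_params(ModelParams(0.8, 0.7, rho=0.9), FULLY_CONNECTED) == (0.8, 0.7)

    def test_high_homophily_suppresses_out_group(self):
        _, be = effective_params(ModelParams(0.8, 0.7, rho=0.999), SBM)
        assert be == pytest.approx(0.0, abs=1e-3)


class TestDrives:
    def test_centered_state_is_neutral(self):
        assert drives((0.5, 0.5), cfg_of(0.7, 0.3, 0.4)) == (0.0, 0.0)

    def test_hand_arithmetic(self):
        gb, gr = drives((0.8, 0.8), cfg_of(0.6, 0.5, 0.65))
        assert gb == pytest.approx(0.6 * 0.35 * 0.6 - 0.5 * 0.65 * 0.6)  # -0.069
        assert gr == pytest.approx(0.6 * 0.65 * 0.6 - 0.5 * 0.35 * 0.6)  # +0.129

    def test_diagonal_sign_reproduces_case_boundary(self, rng):
        """On the diagonal the blue drive's sign is that of
        (2 theta - 1) * (alpha(1-r) - beta r), i.e. the case-1/case-2
        phase boundary alpha/beta = r/(1-r)."""
        for _ in range(50):
            a, b = rng.uniform(0.01, 1, 2)
            r = rng.uniform(0.1, 0.9)
            th = rng.uniform(0, 1)
            gb, _ = drives((th, th), cfg_of(a, b, r))
            expected = (2 * th - 1) * (a * (1 - r) - b * r)
            assert np.sign(gb) == np.sign(expected)

    def test_printed_red_drive_variant(self):
        cfg = MeanFieldConfig(ModelParams(0.6, 0.5), 0.65, red_drive="printed")
        _, gr = drives((0.8, 0.8), cfg)
        assert gr == pytest.approx(0.6 * 0.6 - 0.5 * 0.35 * 0.6)


class TestRhs:
    def test_growth_rates(self):
        # strong in-group conformity, both drives positive at (0.8, 0.8)
        rates = rhs((0.8, 0.8), cfg_of(0.8, 0.1, 0.5))
        assert rates == (pytest.approx(0.2), pytest.approx(0.2))

    def test_frozen_inside_inertia_band(self):
        rates = rhs((0.55, 0.55), cfg_of(0.8, 0.1, 0.5, delta=0.5))
        assert rates == (0.0, 0.0)

    def test_absorbing_corner(self):
        assert rhs((1.0, 1.0), cfg_of(0.8, 0.1, 0.5)) == (0.0, 0.0)


class TestClassifyRegime:
    def test_examples(self):
        assert classify_regime(cfg_of(0.8, 0.4, 0.5)).case_id == 1
        assert classify_regime(cfg_of(0.6, 0.5, 0.65)).case_id == 2
        assert classify_regime(cfg_of(0.6, 0.5, 0.35)).case_id == 3
        assert classify_regime(cfg_of(0.3, 0.9, 0.5)).case_id == 4

    def test_homophily_rescaled_classification(self):
        # neutral mixing turns a love-dominated pair into a partisan regime
        assert classify_regime(cfg_of(0.8, 0.7, 0.65, rho=0.5, mode=SBM)).case_id == 2
        assert classify_regime(cfg_of(0.8, 0.7, 0.65, rho=0.7, mode=SBM)).case_id == 1

    def test_no_hate_is_always_consensus(self, rng):
        for _ in range(20):
            a = rng.uniform(0.05, 1)
            r = rng.uniform(0.1, 0.9)
            assert classify_regime(cfg_of(a, 0.0, r)).case_id == 1

    def test_boundary_detected(self):
        assert classify_regime(cfg_of(0.5, 0.5, 0.5)).case_id == "boundary"

    def test_degenerate_parameters_raise(self):
        with pytest.raises(ValueError):
            classify_regime(cfg_of(0.0, 0.0, 0.5))


class TestIntegrate:
    def test_case1_closed_form(self):
        """In the consensus regime from (0.8, 0.8) both components follow
        1 - 0.2 exp(-t) all the way to the (1,1) corner."""
        traj = integrate((0.8, 0.8), cfg_of(0.8, 0.4, 0.5), horizon=10)
        expected = 1.0 - 0.2 * np.exp(-traj.times)
        assert np.abs(traj.thetas - expected[:, None]).max() < 1e-12
        assert traj.final.thetaB == pytest.approx(1.0, abs=1e-4)

    def test_center_is_stationary(self):
        traj = integrate((0.5, 0.5), cfg_of(0.8, 0.4, 0.5), horizon=5)
        assert np.all(traj.thetas == 0.5)
        assert traj.events == []

    def test_case4_reaches_half_half_and_freezes(self):
        """With hate dominating love, a diagonal start decays toward the
        half-half split and freezes exactly there in finite time."""
        traj = integrate((0.8, 0.8), cfg_of(0.3, 0.9, 0.5), horizon=40)
        assert traj.final.thetaB == pytest.approx(0.5, abs=1e-12)
        assert traj.final.thetaR == pytest.approx(0.5, abs=1e-12)
        # before the freeze the components decay as 0.8 exp(-t)
        t_freeze = np.log(1.6)
        early = traj.times < t_freeze - 1e-9
        assert np.allclose(traj.thetas[early, 0], 0.8 * np.exp(-traj.times[early]),
                           atol=1e-12)

    def test_agrees_with_fixed_step_euler(self, rng):
        """Event-driven integration matches naive Euler (step 1e-4)
        within sup-norm 1e-3 on 100 random configurations."""
        t_eval = np.linspace(0, 8, 33)
        worst = 0.0
        for _ in range(100):
            a, b = rng.uniform(0.02, 1, 2)
            r = rng.uniform(0.1, 0.9)
            delta = float(rng.choice([0.0, 0.0, 0.05]))
            theta0 = tuple(rng.uniform(0.02, 0.98, 2))
            cfg = cfg_of(a, b, r, delta=delta)
            exact = integrate(theta0, cfg, horizon=8, t_eval=t_eval)
            approx = euler_integrate(theta0, cfg, horizon=8, t_eval=t_eval)
            idx = np.searchsorted(exact.times, t_eval)
            worst = max(worst, np.abs(exact.thetas[idx] - approx).max())
        assert worst < 1e-3

    def test_limit_matches_regime_prediction(self, rng):
        """The integrated limit from diagonal starts reproduces the
        case-by-case asymptotic states for 500 random parameter draws
        (phase-boundary band excluded)."""
        n_done = 0
        while n_done < 500:
            a, b = rng.uniform(0.02, 1, 2)
            r = rng.uniform(0.1, 0.9)
            p = a * (1 - r) - b * r
            q = a * r - b * (1 - r)
            if abs(p) < 1e-3 or abs(q) < 1e-3:
                continue
            th0 = float(rng.choice([0.2, 0.8]))
            cfg = cfg_of(a, b, r)
            predicted = limiting_state((th0, th0), cfg)
            got = integrate((th0, th0), cfg, horizon=40).final
            assert got.thetaB == pytest.approx(predicted.thetaB, abs=1e-6)
            assert got.thetaR == pytest.approx(predicted.thetaR, abs=1e-6)
            n_done += 1

    def test_case4_center_is_unstable(self):
        """A 1e-3 off-center perturbation under hate-dominated parameters
        polarizes the population along party lines."""
        cfg = cfg_of(0.3, 0.9, 0.5)
        traj = integrate((0.5 + 1e-3, 0.5), cfg, horizon=40)
        assert abs(traj.final.thetaB - traj.final.thetaR) >= 0.99
        center = integrate((0.5, 0.5), cfg, horizon=40)
        assert np.all(center.thetas == 0.5)

    def test_neutral_homophily_equals_fully_connected(self, rng):
        """At rho=0.5 and delta=0 the block-model trajectory is
        bit-identical to the fully connected one."""
        for _ in range(20):
            a, b = rng.uniform(0.02, 1, 2)
            r = rng.uniform(0.1, 0.9)
            theta0 = tuple(rng.uniform(0, 1, 2))
            fc = integrate(theta0, cfg_of(a, b, r), horizon=12)
            sbm = integrate(theta0, cfg_of(a, b, r, rho=0.5, mode=SBM), horizon=12)
            assert np.array_equal(fc.times, sbm.times)
            assert np.array_equal(fc.thetas, sbm.thetas)

    def test_group_swap_symmetry(self, rng):
        """Relabeling the parties, (thetaB, thetaR, r) -> (thetaR, thetaB,
        1-r), commutes exactly with the integration (r drawn dyadic so
        1-r is exact in floating point)."""
        for _ in range(20):
            a, b = rng.uniform(0.02, 1, 2)
            r = float(rng.integers(1, 64)) / 64.0
            theta0 = tuple(rng.uniform(0, 1, 2))
            fwd = integrate(theta0, cfg_of(a, b, r), horizon=12)
            mirrored = integrate((theta0[1], theta0[0]), cfg_of(a, b, 1.0 - r), horizon=12)
            assert np.array_equal(fwd.times, mirrored.times)
            assert np.array_equal(fwd.thetas, mirrored.thetas[:, ::-1])


class TestTrajectoryInvariants:
    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        alpha=st.floats(0.01, 1.0),
        beta=st.floats(0.0, 1.0),
        r=st.floats(0.05, 0.95),
        delta=st.sampled_from([0.0, 0.05, 0.2]),
        tb=st.floats(0.0, 1.0),
        tr=st.floats(0.0, 1.0),
    )
    def test_trajectory_stays_in_unit_square(self, alpha, beta, r, delta, tb, tr):
        """Rates vanish at the faces of the unit square, so trajectories
        never leave it and times are nondecreasing."""
        traj = integrate((tb, tr), cfg_of(alpha, beta, r, delta=delta), horizon=20)
        assert np.all(traj.thetas >= 0.0) and np.all(traj.thetas <= 1.0)
        assert np.all(np.diff(traj.times) >= 0)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        alpha=st.floats(0.01, 1.0),
        beta=st.floats(0.01, 1.0),
        r=st.floats(0.05, 0.95),
    )
    def test_regime_sign_convention(self, alpha, beta, r):
        """The classifier's case matches the signs of the corner drives
        computed independently from the drive function."""
        cfg = cfg_of(alpha, beta, r)
        regime = classify_regime(cfg)
        gb, gr = drives((1.0, 1.0), cfg)
        if regime.case_id == "boundary":
            return
        expected = {(True, True): 1, (False, True): 2,
                    (True, False): 3, (False, False): 4}[(gb > 0, gr > 0)]
        assert regime.case_id == expected


class TestLimitingState:
    @pytest.mark.parametrize(
        "params,theta0,expected",
        [
            ((0.8, 0.4, 0.5), (0.8, 0.8), (1.0, 1.0)),
            ((0.8, 0.4, 0.5), (0.2, 0.2), (0.0, 0.0)),
            ((0.6, 0.5, 0.65), (0.8, 0.8), (0.0, 1.0)),
            ((0.6, 0.5, 0.65), (0.2, 0.2), (1.0, 0.0)),
            ((0.6, 0.5, 0.35), (0.8, 0.8), (1.0, 0.0)),
            ((0.3, 0.9, 0.5), (0.8, 0.8), (0.5, 0.5)),
        ],
    )
    def test_theorem_limits(self, params, theta0, expected):
        got = limiting_state(theta0, cfg_of(*params))
        assert (got.thetaB, got.thetaR) == pytest.approx(expected, abs=1e-9)

    def test_off_diagonal_falls_back_to_integration(self):
        # inside the consensus cone: both drives positive at (0.9, 0.75)
        got = limiting_state((0.9, 0.75), cfg_of(0.8, 0.4, 0.5))
        assert (got.thetaB, got.thetaR) == pytest.approx((1.0, 1.0), abs=1e-6)
        # outside the cone the same parameters polarize
        got = limiting_state((0.9, 0.6), cfg_of(0.8, 0.4, 0.5))
        assert (got.thetaB, got.thetaR) == pytest.approx((1.0, 0.0), abs=1e-6)


class TestConsensusReachable:
    def test_diagonal_case1_start(self):
        res = consensus_reachable((0.8, 0.8), cfg_of(0.8, 0.4, 0.5))
        assert res.reachable and res.corner == StateVector(1.0, 1.0)

    def test_partisan_regime_never_consensus(self):
        res = consensus_reachable((0.8, 0.8), cfg_of(0.6, 0.5, 0.65))
        assert not res.reachable
        assert "case 1" in res.reason

    def test_center_is_fixed_point(self):
        res = consensus_reachable((0.5, 0.5), cfg_of(0.8, 0.4, 0.5))
        assert not res.reachable
        assert "fixed point" in res.reason

    def test_agrees_with_integration_oracle(self, rng):
        """Checker vs integrate-to-convergence oracle on a grid of
        initial states for random consensus-regime configurations."""
        grid = np.linspace(0, 1, 11)
        for _ in range(5):
            cfg = random_case1_config(rng)
            for tb in grid:
                for tr in grid:
                    gb, gr = drives((tb, tr), cfg)
                    if abs(gb) < 1e-3 or abs(gr) < 1e-3:
                        continue
                    predicted = consensus_reachable((tb, tr), cfg).reachable
                    final = integrate((tb, tr), cfg, horizon=60, n_samples=2).final
                    arr = np.array([final.thetaB, final.thetaR])
                    oracle = (np.abs(arr - 1).max() < 1e-6) or (np.abs(arr).max() < 1e-6)
                    assert predicted == oracle

    def test_requires_zero_inertia(self):
        with pytest.raises(ValueError):
            consensus_reachable((0.8, 0.8), cfg_of(0.8, 0.4, 0.5, delta=0.1))


class TestSwitchingManifolds:
    def test_zero_inertia_lines_pass_through_center(self):
        m = switching_manifolds(cfg_of(0.8, 0.4, 0.5))
        for line in m.lines:
            assert line.residual((0.5, 0.5)) == pytest.approx(0.0, abs=1e-15)

    def test_blue_manifold_slope(self):
        cfg = cfg_of(0.8, 0.4, 0.3)
        a, b, _, _ = cfg.coefficients()
        line = switching_manifolds(cfg).line("B", 1)
        t1 = line.theta_R_at(0.5)
        t2 = line.theta_R_at(0.6)
        assert (t2 - t1) / 0.1 == pytest.approx(a / b)

    def test_trajectory_events_lie_on_manifolds(self):
        """A trend-reversal trajectory's red-group region switch occurs
        exactly on the red switching manifold."""
        cfg = cfg_of(0.5, 0.8, 0.35)  # majority-blue mirror of the hate showcase
        traj = integrate((0.75, 0.85), cfg, horizon=20)
        red_events = [e for e in traj.events if e.group == "R"]
        assert red_events
        m = switching_manifolds(cfg)
        for ev in red_events:
            k = np.searchsorted(traj.times, ev.time)
            state = traj.thetas[k]
            res = min(abs(m.line("R", 1).residual(state)),
                      abs(m.line("R", -1).residual(state)))
            assert res < 1e-9
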