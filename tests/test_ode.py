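"""Mean-field model: initial condition, right-hand side, Euler integration,
vote counting and quorum detection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from antnest import (
    IntegrationError,
    ModelParams,
    OdeState,
    ParameterError,
    integrate_euler,
    make_initial_state,
    ode_quorum_time,
    ode_rhs,
    votes,
)

# Earliest time the good-site vote reaches 0.5 at the baseline parameters,
# from a fine-step (dt=1e-5) forward-Euler integration; used as a regression
# anchor for the reference dt=0.001 integrator.
T_QUORUM_FINE_STEP = 14.02236


def rhs_by_equations(s: OdeState, p: ModelParams) -> np.ndarray:
    """Direct transcription of the nine balance equations (independent of
    the channel-based implementation)."""
    rec_total = s.x_lprec + s.x_lgrec + s.x_hgrec
    rec_good = s.x_lgrec + s.x_hgrec
    al = p.alpha_leak
    return np.array([
        -rec_total * s.x_lc
        + al * (s.x_lpcom + s.x_lprec + s.x_lgcom + s.x_lgrec),       # lc
        -rec_total * s.x_hc + al * (s.x_hpvis + s.x_hgcom + s.x_hgrec),  # hc
        s.x_lprec * s.x_lc - p.alpha_p * s.x_lpcom - al * s.x_lpcom,  # lpcom
        s.x_lprec * s.x_hc - p.alpha_s * s.x_hpvis - al * s.x_hpvis,  # hpvis
        rec_good * s.x_lc - p.alpha_g * s.x_lgcom - al * s.x_lgcom,   # lgcom
        rec_good * s.x_hc + p.alpha_s * s.x_hpvis
        - p.alpha_g * s.x_hgcom - al * s.x_hgcom,                     # hgcom
        p.alpha_p * s.x_lpcom - al * s.x_lprec,                       # lprec
        p.alpha_g * s.x_lgcom - al * s.x_lgrec,                       # lgrec
        p.alpha_g * s.x_hgcom - al * s.x_hgrec,                       # hgrec
    ])


def random_state(rng: np.random.Generator, H: float) -> OdeState:
    """A valid state: random split of L over low and H over high compartments."""
    low = rng.dirichlet(np.ones(5)) * (1 - H)
    high = rng.dirichlet(np.ones(4)) * H
    return OdeState(
        x_lc=low[0], x_lpcom=low[1], x_lgcom=low[2], x_lprec=low[3],
        x_lgrec=low[4], x_hc=high[0], x_hpvis=high[1], x_hgcom=high[2],
        x_hgrec=high[3],
    )


class TestInitialState:
    def test_scouts_split_equally(self):
        s = make_initial_state(ModelParams(H=0.2, z=0.3))
        assert s.x_lc == pytest.approx(0.56)
        assert s.x_lpcom == s.x_lgcom == pytest.approx(0.12)
        assert s.x_hc == pytest.approx(0.14)
        assert s.x_hpvis == s.x_hgcom == pytest.approx(0.03)
        assert s.x_lprec == s.x_lgrec == s.x_hgrec == 0.0

    def test_no_scouts_no_high_threshold(self):
        s = make_initial_state(ModelParams(H=0.0, z=0.0))
        assert s.x_lc == 1.0
        assert sum(s.to_array()) == 1.0
        assert np.count_nonzero(s.to_array()) == 1

    def test_all_high_threshold(self):
        s = make_initial_state(ModelParams(H=1.0, z=0.3))
        assert s.x_hc == pytest.approx(0.7)
        assert s.x_hpvis == s.x_hgcom == pytest.approx(0.15)
        assert s.x_lc == s.x_lpcom == s.x_lgcom == 0.0

    @given(H=st.floats(0, 1), z=st.floats(0, 0.99))
    @settings(max_examples=50, derandomize=True)
    def test_class_sums_and_total_mass(self, H, z):
        s = make_initial_state(ModelParams(H=H, z=z))
        assert s.low_sum == pytest.approx(1 - H, abs=1e-12)
        assert s.high_sum == pytest.approx(H, abs=1e-12)
        assert s.to_array().sum() == pytest.approx(1.0, abs=1e-12)


class TestRhs:
    def test_hand_derived_example(self, baseline):
        d = ode_rhs(make_initial_state(baseline), baseline)
        expected = np.array([0.012, 0.003, -0.018, -0.0045, -0.018,
                             -0.0015, 0.012, 0.012, 0.003])
        np.testing.assert_allclose(d, expected, atol=1e-15)
        assert d.sum() == pytest.approx(0.0, abs=1e-15)

    def test_all_home_is_absorbing(self, baseline):
        s = OdeState(0.8, 0.2, 0, 0, 0, 0, 0, 0, 0)
        np.testing.assert_array_equal(ode_rhs(s, baseline), np.zeros(9))

    @given(seed=st.integers(0, 10_000), H=st.floats(0, 1))
    @settings(max_examples=50, derandomize=True)
    def test_matches_direct_equations_and_conserves_classes(self, seed, H):
        rng = np.random.default_rng(seed)
        s = random_state(rng, H)
        p = ModelParams(H=H, alpha_p=0.07, alpha_g=0.13, alpha_s=0.4,
                        alpha_leak=0.05)
        d = ode_rhs(s, p)
        np.testing.assert_allclose(d, rhs_by_equations(s, p), atol=1e-14)
        # per-class derivative sums vanish (the two conservation laws)
        assert d[[0, 2, 4, 6, 7]].sum() == pytest.approx(0.0, abs=1e-14)
        assert d[[1, 3, 5, 8]].sum() == pytest.approx(0.0, abs=1e-14)


class TestVotes:
    def test_initial_state_split(self):
        v = votes(make_initial_state(ModelParams(H=0.4, z=0.3)))
        assert v.v_good == pytest.approx(0.15)
        assert v.v_poor == pytest.approx(0.15)

    def test_all_home_zero(self):
        assert votes(OdeState(0.8, 0.2, 0, 0, 0, 0, 0, 0, 0)) == (0.0, 0.0)

    def test_component_sum(self):
        s = OdeState(x_lc=0.65, x_hc=0.0, x_lpcom=0.0, x_hpvis=0.05,
                     x_lgcom=0.1, x_hgcom=0.0, x_lprec=0.0, x_lgrec=0.0,
                     x_hgrec=0.2)
        v = votes(s)
        assert v.v_good == pytest.approx(0.3)
        assert v.v_poor == pytest.approx(0.05)


class TestEulerIntegration:
    def test_quorum_time_matches_fine_step_regression(self, baseline):
        traj = integrate_euler(baseline, dt=0.001, t_max=20)
        assert traj.quorum_site == "good"
        assert traj.quorum_time == pytest.approx(T_QUORUM_FINE_STEP, abs=5e-3)

    def test_step_halving_convergence(self, baseline):
        a = integrate_euler(baseline, dt=1e-3, t_max=100, stride=100)
        b = integrate_euler(baseline, dt=1e-4, t_max=100, stride=1000)
        np.testing.assert_allclose(a.times, b.times, atol=1e-9)
        assert np.abs(a.states - b.states).max() < 1e-3

    def test_good_vote_dominates_at_baseline(self, baseline):
        traj = integrate_euler(baseline, dt=0.001, t_max=100)
        assert np.all(traj.v_good[1:] > traj.v_poor[1:])

    def test_two_sites_symmetric_without_high_threshold_ants(self):
        p = ModelParams(H=0.0, alpha_s=0.0)
        traj = integrate_euler(p, dt=0.001, t_max=50, quorum_fraction=0.9)
        np.testing.assert_array_equal(traj.v_good, traj.v_poor)

    def test_conservation_along_trajectory(self, baseline):
        traj = integrate_euler(baseline, dt=0.001, t_max=200)
        low = traj.states[:, [0, 2, 4, 6, 7]].sum(axis=1)
        high = traj.states[:, [1, 3, 5, 8]].sum(axis=1)
        assert np.abs(low - baseline.L).max() < 1e-6
        assert np.abs(high - baseline.H).max() < 1e-6

    def test_oversized_step_is_rejected(self):
        p = ModelParams(alpha=10.0)
        with pytest.raises(IntegrationError):
            integrate_euler(p, dt=0.5, t_max=10)

    def test_bad_grid_arguments(self, baseline):
        with pytest.raises(ValueError):
            integrate_euler(baseline, dt=0.0)
        with pytest.raises(ValueError):
            integrate_euler(baseline, dt=1.0, t_max=0.5)


class TestQuorumDetection:
    def test_unreachable_quorum_with_leakage(self, baseline):
        traj = integrate_euler(baseline, dt=0.01, t_max=50,
                               quorum_fraction=1.0)
        assert traj.quorum_time is None
        assert ode_quorum_time(traj, 1.0) is None

    def test_low_threshold_reached_at_good_site_first(self, baseline):
        # just above the initial z/2 vote of each site
        traj = integrate_euler(baseline, dt=0.001, t_max=50,
                               quorum_fraction=0.16)
        assert traj.quorum_site == "good"
        t, site = ode_quorum_time(traj, 0.16)
        assert site == "good"

    def test_quorum_already_met_at_start_is_rejected(self, baseline):
        with pytest.raises(ParameterError, match="already met"):
            integrate_euler(baseline, dt=0.01, t_max=10,
                            quorum_fraction=0.1)  # z/2 = 0.15 >= 0.1
        traj = integrate_euler(baseline, dt=0.01, t_max=10)
        with pytest.raises(ParameterError, match="already met"):
            ode_quorum_time(traj, 0.1)
        t, site = ode_quorum_time(traj, 0.1, allow_initial=True)
        assert t == 0.0
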