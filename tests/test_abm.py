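"""Finite-population stochastic model: initial counts, event channels,
the exact event-driven engine and the fixed-step cross-validation engine."""

import numpy as np
import pytest

from antnest import (
    ModelParams,
    ParameterError,
    discrete_time_run,
    event_rates,
    gillespie_run,
    gillespie_run_logged,
    make_initial_counts,
)
from antnest.abm import COUNT_FIELDS, integer_votes


class TestInitialCounts:
    def test_baseline_counts(self, baseline):
        c = make_initial_counts(baseline)
        assert (c.n_lc, c.n_lpcom, c.n_lgcom) == (56, 12, 12)
        assert (c.n_hc, c.n_hpvis, c.n_hgcom) == (14, 3, 3)
        assert c.n_lprec == c.n_lgrec == c.n_hgrec == 0
        assert c.total == 100

    def test_small_colony_all_low_threshold(self):
        c = make_initial_counts(ModelParams(N=10, H=0.0, z=0.2))
        assert (c.n_lc, c.n_lpcom, c.n_lgcom) == (8, 1, 1)
        assert c.total == 10

    def test_non_integer_split_rejected(self):
        with pytest.raises(ParameterError, match="not integers"):
            make_initial_counts(ModelParams(N=100, H=0.1, z=0.3))

    def test_largest_remainder_mode_apportions_all_ants(self):
        p = ModelParams(N=100, H=0.1, z=0.3)
        c = make_initial_counts(p, rounding="largest_remainder")
        assert c.total == 100
        assert c.n_lpcom + c.n_lgcom + c.n_hpvis + c.n_hgcom == 30


class TestEventRates:
    def test_hand_summed_initial_rates(self, baseline):
        channels = event_rates(make_initial_counts(baseline), baseline)
        assert len(channels) == 15
        rates = {ch.name: ch.rate for ch in channels}
        # no recruiters yet: all four recruitment channels silent
        assert all(rates[n] == 0.0 for n in rates if n.startswith("recruit"))
        assert rates["convert:lpcom->lprec"] == pytest.approx(1.2)
        assert rates["convert:lgcom->lgrec"] == pytest.approx(1.2)
        assert rates["convert:hgcom->hgrec"] == pytest.approx(0.3)
        assert rates["switch:hpvis->hgcom"] == pytest.approx(0.3)
        assert rates["leak:lpcom->lc"] == rates["leak:lgcom->lc"] == pytest.approx(0.6)
        assert rates["leak:hpvis->hc"] == rates["leak:hgcom->hc"] == pytest.approx(0.15)
        assert sum(rates.values()) == pytest.approx(4.5)

    def test_all_home_is_absorbing(self, baseline):
        from antnest import AbmCounts
        c = AbmCounts(80, 20, 0, 0, 0, 0, 0, 0, 0)
        assert all(ch.rate == 0.0 for ch in event_rates(c, baseline))

    def test_each_channel_moves_one_ant(self, baseline):
        for ch in event_rates(make_initial_counts(baseline), baseline):
            assert ch.source in COUNT_FIELDS and ch.dest in COUNT_FIELDS
            assert ch.source != ch.dest


class TestGillespieEngine:
    def test_seeded_determinism(self, baseline):
        a = gillespie_run(baseline, seed=42)
        b = gillespie_run(baseline, seed=42)
        assert a == b

    @pytest.mark.parametrize("seed", [1, 2, 999, 123456])
    def test_compiled_and_python_engines_bit_identical(self, baseline, seed):
        fast = gillespie_run(baseline, seed=seed)
        slow, log = gillespie_run_logged(baseline, seed=seed)
        assert (fast.result, fast.t_event, fast.n_events) == \
            (slow.result, slow.t_event, slow.n_events)
        assert len(log) == fast.n_events

    def test_counts_conserved_after_every_event(self, baseline):
        _, log = gillespie_run_logged(baseline, seed=7)
        counts = log[list(COUNT_FIELDS)].to_numpy()
        assert (counts >= 0).all()
        np.testing.assert_array_equal(counts.sum(axis=1), 100)
        low = counts[:, [0, 2, 4, 6, 7]].sum(axis=1)
        high = counts[:, [1, 3, 5, 8]].sum(axis=1)
        np.testing.assert_array_equal(low, 80)
        np.testing.assert_array_equal(high, 20)

    def test_event_times_strictly_increase(self, baseline):
        _, log = gillespie_run_logged(baseline, seed=11)
        assert (np.diff(log["time"].to_numpy()) > 0).all()

    def test_no_unsuccessful_runs_without_leakage(self):
        p = ModelParams(alpha_leak=0.0)
        results = {gillespie_run(p, seed=s).result for s in range(200)}
        assert "unsuccessful" not in results

    def test_no_scouts_is_immediately_unsuccessful(self):
        out = gillespie_run(ModelParams(z=0.0), seed=3)
        assert out.result == "unsuccessful"
        assert out.n_events == 0
        assert out.t_event == 0.0

    def test_tiny_horizon_censors(self, baseline):
        out = gillespie_run(baseline, seed=5, t_max=1e-6)
        assert out.result == "censored"
        assert out.t_event == 1e-6

    def test_quorum_met_at_start_rejected(self):
        with pytest.raises(ParameterError, match="already met"):
            gillespie_run(ModelParams(quorum_fraction=0.15), seed=1)

    def test_integer_votes_definition(self, baseline):
        c = make_initial_counts(baseline)
        assert integer_votes(c) == (15, 15)


class TestDiscreteTimeEngine:
    def test_oversized_step_rejected(self, baseline):
        with pytest.raises(ValueError, match="per-ant step probability"):
            discrete_time_run(baseline, dt=0.15, seed=1)

    def test_seeded_determinism(self, baseline):
        a = discrete_time_run(baseline, dt=0.01, seed=9)
        b = discrete_time_run(baseline, dt=0.01, seed=9)
        assert a == b

    def test_no_scouts_never_fires(self):
        out = discrete_time_run(ModelParams(z=0.0), dt=0.01, seed=2, t_max=10)
        assert out.result == "unsuccessful"

    def test_reaches_quorum_at_baseline(self, baseline):
        out = discrete_time_run(baseline, dt=0.01, seed=17)
        assert out.result in ("good_quorum", "poor_quorum")
        assert out.t_event > 0
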