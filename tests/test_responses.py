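"""PETH construction, response tests, latencies and population summaries."""

import numpy as np
import pytest

from vpetypes import (compare_group_fractions, compare_outcome_conditions,
                      compute_peth, response_combination_table, response_latency,
                      zscore_peth)
from vpetypes import test_event_response as event_response_test
from vpetypes.exceptions import (DegenerateDataError, InsufficientDataError,
                                 ParameterError)
from vpetypes.responses import ResponseResult, classify_response
from vpetypes.simulate import ResponseKernel

from conftest import as_train, poisson_train


def regular_events(n, spacing=3.0, start=5.0):
    return start + spacing * np.arange(n)


def unit_with_kernel(rng, events, baseline_hz, kernel, T=None):
    """Poisson unit with one multiplicative event kernel, built by thinning."""
    from vpetypes.simulate import UnitSpec, simulate_unit
    import pandas as pd
    from vpetypes import TrialTable
    T = T if T is not None else events[-1] + 5.0
    rows = [{"trial_id": i, "cue": "likely_reward", "outcome": "reward",
             "t_cue_on_s": e - 1.0, "t_cue_off_s": e - 0.5, "t_reinforcement_s": e}
            for i, e in enumerate(events)]
    trials = TrialTable(pd.DataFrame(rows))
    spec = UnitSpec("u", etype="poisson", baseline_hz=baseline_hz,
                    responses=[kernel])
    st, _ = simulate_unit(spec, trials, T, rng=rng)
    return st


class TestPeth:
    def test_spike_at_each_event_gives_single_bin_peak(self):
        events = regular_events(50)
        peth = compute_peth(as_train(events + 0.001), events, window=(-0.5, 0.5))
        assert peth.rate.max() == pytest.approx(1 / 0.02)
        assert (peth.rate > 0).sum() == 1

    def test_zero_spikes_gives_zero_peth(self):
        peth = compute_peth(as_train([]), regular_events(5))
        assert np.all(peth.rate == 0)

    def test_poisson_rate_recovered_flat(self):
        g = np.random.default_rng(2)
        events = regular_events(200)
        t = poisson_train(10.0, events[-1] + 5, g)
        peth = compute_peth(as_train(t), events)
        assert peth.rate.mean() == pytest.approx(10.0, rel=0.1)
        assert peth.rate.std() < 5.0

    def test_rate_integrates_to_mean_spike_count(self, rng):
        events = regular_events(30)
        t = poisson_train(15.0, events[-1] + 5, rng)
        peth = compute_peth(as_train(t), events, window=(-1.0, 1.0), bin_s=0.02)
        total = sum(((t >= e - 1.0) & (t < e + 1.0)).sum() for e in events)
        assert peth.rate.sum() * 0.02 == pytest.approx(total / len(events))

    def test_no_events_rejected(self):
        with pytest.raises(InsufficientDataError):
            compute_peth(as_train([1.0]), [])


class TestZscore:
    def test_baseline_bins_standardized(self, rng):
        events = regular_events(100)
        t = poisson_train(20.0, events[-1] + 5, rng)
        zp = zscore_peth(compute_peth(as_train(t), events))
        mask = (zp.bin_centers >= -0.5) & (zp.bin_centers < 0.0)
        assert zp.z[mask].mean() == pytest.approx(0.0, abs=1e-9)
        assert zp.z[mask].std() == pytest.approx(1.0, abs=1e-9)

    def test_constant_peth_is_degenerate(self):
        events = regular_events(10)
        peth = compute_peth(as_train([]), events)
        with pytest.raises(DegenerateDataError):
            zscore_peth(peth)


class TestResponseTest:
    def test_response_copy_of_baseline_is_none(self, rng):
        t = poisson_train(10.0, 400.0, rng)
        events = regular_events(60)
        res = event_response_test(as_train(t), events,
                                  baseline_win=(-0.5, 0.0), response_win=(-0.5, 0.0))
        assert res.direction == "none"
        assert res.p_value == pytest.approx(1.0)

    def test_type_one_error_near_nominal(self):
        flagged = 0
        n_units = 300
        for seed in range(n_units):
            g = np.random.default_rng(40_000 + seed)
            events = regular_events(40)
            t = poisson_train(10.0, events[-1] + 5, g)
            res = event_response_test(as_train(t), events, alpha=0.05)
            flagged += res.direction != "none"
        # 95% binomial interval around 0.05 with n=300: [8, 23]
        assert 5 <= flagged <= 26

    def test_inhibited_unit_detected(self):
        hits = 0
        for seed in range(10):
            g = np.random.default_rng(seed)
            events = regular_events(60)
            st = unit_with_kernel(g, events, baseline_hz=20.0,
                                  kernel=ResponseKernel(event="reward", amplitude=-0.85,
                                                        latency_s=0.02, tau_s=0.1))
            res = event_response_test(st, events, alpha=0.001)
            hits += res.direction == "inhibited"
        assert hits >= 9

    def test_too_few_events_rejected(self):
        with pytest.raises(InsufficientDataError):
            event_response_test(as_train([1.0]), [5.0])

    def test_global_time_shift_invariance(self, rng):
        events = regular_events(40)
        t = poisson_train(12.0, events[-1] + 5, rng)
        r0 = event_response_test(as_train(t), events)
        r1 = event_response_test(as_train(t + 1000.0), events + 1000.0)
        assert r0.p_value == pytest.approx(r1.p_value)
        assert r0.direction == r1.direction


class TestLatency:
    def test_symmetric_peak_is_exact(self):
        events = regular_events(50)
        # one spike 90 ms after every event, on sparse background noise so
        # the baseline SD is nonzero -> z extremum at the 80-100 ms bin
        bg = poisson_train(2.0, events[-1] + 5, np.random.default_rng(0))
        t = np.sort(np.concatenate([events + 0.09, bg]))
        res = classify_response(as_train(t), events, alpha=0.05)
        assert res.direction == "activated"
        assert res.latency_s == pytest.approx(0.09, abs=0.01)

    def test_injected_kernel_latency_recovered(self):
        errs = []
        for seed in range(8):
            g = np.random.default_rng(100 + seed)
            events = regular_events(60)
            st = unit_with_kernel(g, events, baseline_hz=10.0,
                                  kernel=ResponseKernel(event="reward", amplitude=2.5,
                                                        latency_s=0.04, tau_s=0.04))
            res = classify_response(st, events)
            assert res.direction == "activated"
            errs.append(abs(res.latency_s - 0.08))
        assert np.median(errs) <= 0.02

    def test_latency_requires_direction(self):
        events = regular_events(10)
        peth = compute_peth(as_train(poisson_train(5, 40, np.random.default_rng(0))), events)
        zp = zscore_peth(peth)
        with pytest.raises(ParameterError):
            response_latency(zp, "none")


class TestOutcomeComparison:
    def test_unit_with_too_few_trials_excluded(self, rng):
        from vpetypes.responses import response_count_delta
        t = poisson_train(10.0, 100.0, rng)
        # 4 trials in condition b -> excluded per the 5-trial rule
        assert response_count_delta(as_train(t), regular_events(10),
                                    regular_events(4)) is None
        with pytest.raises(InsufficientDataError):
            compare_outcome_conditions([as_train(t, "a")],
                                       regular_events(10), regular_events(4))

    def test_null_deltas_center_on_zero(self):
        ps = []
        for seed in range(15):
            g = np.random.default_rng(900 + seed)
            units = [as_train(poisson_train(8.0, 200.0, g), f"u{i}") for i in range(30)]
            ev_a, ev_b = regular_events(30, start=5.0), regular_events(30, start=6.5)
            cmp = compare_outcome_conditions(units, ev_a, ev_b)
            ps.append(cmp.p_value)
        assert np.mean(np.asarray(ps) < 0.05) <= 0.3
        assert abs(np.median([compare_outcome_conditions(
            [as_train(poisson_train(8.0, 200.0, np.random.default_rng(1)), "u")],
            regular_events(30), regular_events(30, start=5.7)).median_delta])) < 2.0

    def test_selective_population_detected(self):
        g = np.random.default_rng(3)
        units = []
        ev_a, ev_b = regular_events(30, start=5.0), regular_events(30, start=6.5)
        for i in range(50):
            base = poisson_train(8.0, 110.0, g)
            extra = np.concatenate([e + np.sort(g.uniform(0, 0.5, g.poisson(1.5)))
                                    for e in ev_a])
            units.append(as_train(np.sort(np.concatenate([base, extra])), f"u{i}"))
        cmp = compare_outcome_conditions(units, ev_a, ev_b)
        assert cmp.median_delta > 0
        assert cmp.p_value < 0.05


class TestCombinationTable:
    def _res(self, sign):
        d = {1: "activated", -1: "inhibited", 0: "none"}[sign]
        return ResponseResult("u", "e", d, 0.0001 if sign else 0.5, 1.0)

    def test_all_unresponsive_mass_in_zero_cell(self):
        results = {f"u{i}": {"cue": self._res(0), "reward": self._res(0),
                             "punishment": self._res(0)} for i in range(7)}
        df = response_combination_table(results)
        zero = df[(df["cue"] == "0") & (df["reward"] == "0") & (df["punishment"] == "0")]
        assert int(zero["n_units"].iloc[0]) == 7
        assert df["n_units"].sum() == 7

    def test_salience_cohort_concentrates_in_triple_plus(self):
        results = {f"u{i}": {"cue": self._res(1), "reward": self._res(1),
                             "punishment": self._res(1)} for i in range(10)}
        results["u_none"] = {"cue": self._res(0), "reward": self._res(1),
                             "punishment": self._res(0)}
        df = response_combination_table(results)
        triple = df[(df["cue"] == "+") & (df["reward"] == "+") & (df["punishment"] == "+")]
        assert int(triple["n_units"].iloc[0]) == 10

    def test_marginals_match_per_event_counts(self):
        rng = np.random.default_rng(0)
        results = {}
        for i in range(40):
            results[f"u{i}"] = {ev: self._res(int(rng.integers(-1, 2)))
                                for ev in ("cue", "reward", "punishment")}
        df = response_combination_table(results)
        for ev in ("cue", "reward", "punishment"):
            marg = df.loc[df[ev] == "+", "n_units"].sum()
            direct = sum(results[u][ev].sign == 1 for u in results)
            assert marg == direct

    def test_incomplete_unit_dropped_with_warning(self):
        results = {"u0": {"cue": self._res(1)}}
        with pytest.warns(UserWarning, match="u0"):
            df = response_combination_table(results)
        assert df["n_units"].sum() == 0


class TestGroupFractions:
    def test_closed_form_example(self):
        chi2, p = compare_group_fractions(30, 100, 10, 100)
        assert chi2 == pytest.approx(12.5)
        assert p < 0.001

    def test_identical_proportions_give_zero(self):
        chi2, p = compare_group_fractions(25, 100, 25, 100)
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_degenerate_table_rejected(self):
        with pytest.raises(DegenerateDataError):
            compare_group_fractions(0, 10, 0, 10)

    def test_power_at_stated_effect(self):
        # responsive fractions 0.6 vs 0.3 at n=300 per group
        hits = 0
        for seed in range(20):
            g = np.random.default_rng(seed)
            a = int(g.binomial(300, 0.6))
            b = int(g.binomial(300, 0.3))
            hits += compare_group_fractions(a, 300, b, 300)[1] < 0.001
        assert hits >= 19
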