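"""Generator correctness: contingencies, delays, determinism, bookkeeping."""

import numpy as np
import pytest
from scipy import stats

from vpetypes import (SimConfig, UnitSpec, parse_bursts, simulate_session,
                      simulate_trials, simulate_unit, validate_session)
from vpetypes.exceptions import ConfigError
from vpetypes.session import sessions_equal
from vpetypes.simulate import DEFAULT_CONTINGENCIES, LickSpec, simulate_licks

from conftest import as_train


def outcome_fraction(trials, cue, outcome):
    df = trials.df
    sel = df[df["cue"] == cue]
    return (sel["outcome"] == outcome).mean(), len(sel)


class TestTrials:
    def test_contingencies_within_binomial_ci(self):
        trials = simulate_trials(SimConfig(seed=5, n_trials=4000))
        for cue, (p_r, p_p, p_o) in DEFAULT_CONTINGENCIES.items():
            for outcome, p in zip(("reward", "punishment", "omission"), (p_r, p_p, p_o)):
                frac, n = outcome_fraction(trials, cue, outcome)
                lo, hi = stats.binom.interval(0.99, n, p)
                assert lo / n <= frac <= hi / n, (cue, outcome)

    def test_all_delays_within_printed_bounds(self):
        trials = simulate_trials(SimConfig(seed=6, n_trials=2000))
        df = trials.df
        d = df["t_reinforcement_s"] - df["t_cue_off_s"]
        ok = ~np.isnan(d)
        assert np.all((d[ok] >= 0.4) & (d[ok] <= 0.6))
        # absent exactly on omission trials
        assert (np.isnan(d) == (df["outcome"] == "omission")).all()

    def test_same_seed_identical_table(self):
        t1 = simulate_trials(SimConfig(seed=7, n_trials=200))
        t2 = simulate_trials(SimConfig(seed=7, n_trials=200))
        assert t1.df.equals(t2.df)

    def test_bad_contingency_rejected(self):
        cfg = SimConfig(seed=0, contingencies={"likely_reward": (0.5, 0.2, 0.2),
                                               "likely_punishment": (0.25, 0.65, 0.10)})
        with pytest.raises(ConfigError):
            simulate_trials(cfg)


class TestUnits:
    def test_same_seed_identical_train(self):
        a, _ = simulate_unit(UnitSpec("u", etype="bursting"), None, 200.0, seed=9)
        b, _ = simulate_unit(UnitSpec("u", etype="bursting"), None, 200.0, seed=9)
        np.testing.assert_array_equal(a.times, b.times)

    def test_burst_fraction_matches_generative_bookkeeping(self):
        spec = UnitSpec("u", etype="bursting", baseline_hz=2.0, burst_rate_hz=2.0,
                        burst_extra_mean=2.0)
        fracs = []
        for seed in range(5):
            st, gt = simulate_unit(spec, None, 1200.0, seed=seed)
            p = parse_bursts(st)
            fracs.append(p.n_burst_spikes / st.n_spikes)
        expected = gt["expected_burst_spike_fraction"]
        assert abs(np.mean(fracs) - expected) <= 0.1

    def test_rhythmic_acg_peak_at_period(self):
        from vpetypes import autocorrelogram, smooth_correlogram
        st, _ = simulate_unit(UnitSpec("u", etype="rhythmic", baseline_hz=12.0,
                                       rhythm_freq_hz=40.0, rhythm_depth=0.8),
                              None, 600.0, seed=3)
        acg = smooth_correlogram(autocorrelogram(st), 1.0)
        mask = (acg.lags >= 10) & (acg.lags <= 40)
        peak = acg.lags[mask][np.argmax(acg.counts[mask])]
        assert abs(peak - 25.0) <= 2.5

    def test_zero_amplitude_kernel_behaves_as_null(self):
        from vpetypes import test_event_response as ert
        from vpetypes.simulate import ResponseKernel
        nones = 0
        for seed in range(10):
            cfg = SimConfig(seed=seed, n_trials=60,
                            units=[UnitSpec("u", etype="poisson", baseline_hz=10.0,
                                            responses=[ResponseKernel("reward", 0.0)])])
            session, _ = simulate_session(cfg)
            events = session.trials.events("reward")
            res = ert(session.spike_trains[0], events, alpha=0.001)
            nones += res.direction == "none"
        assert nones >= 9

    def test_invalid_specs_rejected(self):
        with pytest.raises(ConfigError):
            simulate_unit(UnitSpec("u", etype="rhythmic", rhythm_depth=1.5), None, 10.0, seed=0)
        with pytest.raises(ConfigError):
            simulate_unit(UnitSpec("u", baseline_hz=-1.0), None, 10.0, seed=0)
        with pytest.raises(ConfigError):
            simulate_unit(UnitSpec("u", etype="weird"), None, 10.0, seed=0)


class TestLicks:
    def test_zero_rates_give_empty_train(self):
        trials = simulate_trials(SimConfig(seed=1, n_trials=20))
        licks = simulate_licks(trials, LickSpec(0.0, 0.0, 0.0, 0.0), 200.0, seed=0)
        assert licks.n_licks == 0

    def test_same_seed_identical(self):
        trials = simulate_trials(SimConfig(seed=1, n_trials=30))
        l1 = simulate_licks(trials, LickSpec(), 300.0, seed=4)
        l2 = simulate_licks(trials, LickSpec(), 300.0, seed=4)
        np.testing.assert_array_equal(l1.times, l2.times)


class TestSession:
    def test_demo_session_validates_clean(self, small_session):
        session, gt, _ = small_session
        assert validate_session(session) == []
        assert len(gt["units"]) == len(session.spike_trains)

    def test_same_config_seed_byte_identical_bundles(self, tmp_path):
        from vpetypes import demo_config
        cfg = demo_config(seed=13, n_trials=30)
        simulate_session(cfg, out_dir=tmp_path / "a")
        simulate_session(cfg, out_dir=tmp_path / "b")
        for name in ("spikes.csv", "trials.csv", "licks.csv", "units.csv",
                     "meta.json", "ground_truth.json"):
            assert (tmp_path / "a" / name).read_bytes() == \
                (tmp_path / "b" / name).read_bytes(), name

    def test_unknown_coupling_unit_rejected(self):
        from vpetypes import PairSpec
        cfg = SimConfig(seed=0, n_trials=10,
                        units=[UnitSpec("u0")],
                        pairs=[PairSpec("synaptic", "u0", "nope")])
        with pytest.raises(ConfigError):
            simulate_session(cfg)

    def test_contingency_convergence_with_n(self):
        # mean absolute deviation from the configured probability shrinks
        # with n (averaged over seeds to damp single-draw noise)
        errs = []
        for n in (300, 6000):
            e = [abs(outcome_fraction(
                simulate_trials(SimConfig(seed=s, n_trials=n)),
                "likely_reward", "reward")[0] - 0.8) for s in range(10)]
            errs.append(np.mean(e))
        assert errs[1] < errs[0]
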