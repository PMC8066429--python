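"""Jitter-surrogate bands, pair classification and assembly graphs."""

import numpy as np
import pytest

from vpetypes import (SpikeTrain, analyze_pair, build_assembly_graph,
                      classify_pair, compare_sync_responsiveness,
                      jitter_surrogate_ci)
from vpetypes.exceptions import DegenerateDataError, ParameterError
from vpetypes.responses import ResponseResult
from vpetypes.simulate import (AssemblySpec, PairSpec, SimConfig, demo_config,
                               simulate_pair, simulate_session)
from vpetypes.synchrony import PairResult, pairs_table

from conftest import as_train, poisson_train


def indep_pair(seed, rate=5.0, T=300.0):
    g = np.random.default_rng(seed)
    return (as_train(poisson_train(rate, T, g), "a"),
            as_train(poisson_train(rate, T, g), "b"))


class TestSurrogates:
    def test_zero_jitter_bands_collapse_on_observed(self):
        a, b = indep_pair(0)
        ccg = jitter_surrogate_ci(a, b, jitter_ms=0.0, n_surrogates=100, seed=1)
        np.testing.assert_array_equal(ccg.ci_lower, ccg.counts)
        np.testing.assert_array_equal(ccg.ci_upper, ccg.counts)

    def test_same_seed_identical_bands(self):
        a, b = indep_pair(1)
        c1 = jitter_surrogate_ci(a, b, n_surrogates=150, seed=42)
        c2 = jitter_surrogate_ci(a, b, n_surrogates=150, seed=42)
        np.testing.assert_array_equal(c1.ci_upper, c2.ci_upper)
        np.testing.assert_array_equal(c1.ci_lower, c2.ci_lower)

    def test_pointwise_exceedance_calibrated(self):
        # observed counts of an independent pair should exceed the upper band
        # in roughly (1-ci)/2 of bins, and well under 10%
        total = above = 0
        for seed in range(10):
            a, b = indep_pair(seed, rate=8.0, T=300.0)
            ccg = jitter_surrogate_ci(a, b, n_surrogates=400, seed=seed)
            above += int((ccg.counts > ccg.ci_upper).sum())
            total += ccg.n_bins
        assert above / total < 0.10

    def test_too_few_surrogates_rejected(self):
        a, b = indep_pair(2)
        with pytest.raises(ParameterError):
            jitter_surrogate_ci(a, b, n_surrogates=10)

    def test_empty_train_degenerate_bands_with_warning(self):
        a = as_train([], "a")
        b = as_train([1.0, 2.0], "b")
        with pytest.warns(UserWarning):
            ccg = jitter_surrogate_ci(a, b, n_surrogates=100, seed=0)
        assert np.all(ccg.ci_upper == 0)


class TestPairClassification:
    def test_narrow_sync_detected(self):
        hits = 0
        for i in range(5):
            a, b, _ = simulate_pair(PairSpec("common_input", "a", "b", rate_hz=2.0,
                                             copy_prob=0.3, copy_jitter_sd_ms=0.5),
                                    1200.0, seed=i)
            hits += "narrow_sync" in analyze_pair(a, b, seed=i).classes
        assert hits >= 4

    def test_broad_sync_detected(self):
        hits = 0
        for i in range(5):
            a, b, _ = simulate_pair(PairSpec("common_input", "a", "b", rate_hz=4.0,
                                             copy_prob=0.4, copy_jitter_sd_ms=3.0),
                                    1200.0, seed=10 + i)
            hits += "broad_sync" in analyze_pair(a, b, seed=i).classes
        assert hits >= 4

    def test_mono_excitation_detected_with_correct_center(self):
        hits = 0
        for i in range(5):
            a, b, _ = simulate_pair(PairSpec("synaptic", "a", "b", p_syn=0.15,
                                             delay_ms=2.0), 1200.0, seed=20 + i)
            pr = analyze_pair(a, b, seed=i)
            mono = [f for f in pr.features if f.feature_class == "mono_excitation"]
            hits += bool(mono) and 1.0 <= abs(mono[0].center_ms) <= 4.0
        assert hits >= 4

    def test_null_pairs_rarely_sync(self):
        fp = 0
        for i in range(25):
            a, b = indep_pair(5000 + i)
            fp += analyze_pair(a, b, n_surrogates=200, seed=i).any_sync
        assert fp <= 2

    def test_sync_label_symmetric_mono_center_flips(self):
        a, b, _ = simulate_pair(PairSpec("common_input", "a", "b", rate_hz=2.0,
                                         copy_prob=0.3, copy_jitter_sd_ms=0.5),
                                1200.0, seed=7)
        ab = analyze_pair(a, b, seed=1)
        ba = analyze_pair(b, a, seed=2)
        assert (ab.classes & {"narrow_sync", "broad_sync"}) == \
            (ba.classes & {"narrow_sync", "broad_sync"})
        a, b, _ = simulate_pair(PairSpec("synaptic", "a", "b", p_syn=0.2,
                                         delay_ms=2.0), 1200.0, seed=8)
        mono_ab = [f for f in analyze_pair(a, b, seed=3).features
                   if f.feature_class == "mono_excitation"]
        mono_ba = [f for f in analyze_pair(b, a, seed=4).features
                   if f.feature_class == "mono_excitation"]
        assert mono_ab and mono_ba
        assert np.sign(mono_ab[0].center_ms) == -np.sign(mono_ba[0].center_ms)

    def test_missing_bands_rejected(self):
        from vpetypes import crosscorrelogram
        a, b = indep_pair(3)
        with pytest.raises(ParameterError):
            classify_pair(crosscorrelogram(a, b))


class TestAssemblyGraph:
    def _pr(self, a, b, cls):
        from vpetypes.synchrony import CcgFeature
        feats = [] if cls is None else [CcgFeature(-0.75, 0.75, 1.5, 1.5, 0.0, 10.0, cls)]
        return PairResult(unit_a=a, unit_b=b, ccg=None, features=feats)

    def test_no_significant_pairs_all_asynchronous(self):
        g = build_assembly_graph([self._pr("a", "b", None)], ["a", "b", "c"])
        assert g.assemblies == []
        assert set(g.membership.values()) == {"asynchronous"}

    def test_chain_forms_single_assembly(self):
        g = build_assembly_graph([self._pr("a", "b", "narrow_sync"),
                                  self._pr("b", "c", "broad_sync"),
                                  self._pr("c", "d", None)],
                                 ["a", "b", "c", "d"])
        assert g.assemblies == [{"a", "b", "c"}]
        assert g.membership["d"] == "asynchronous"
        assert g.synchronous_units() == {"a", "b", "c"}

    def test_mono_edges_do_not_make_sync(self):
        g = build_assembly_graph([self._pr("a", "b", "mono_excitation")], ["a", "b"])
        assert g.assemblies == []

    def test_common_drive_group_recovered_from_session(self):
        cfg = SimConfig(
            seed=21, n_trials=150,
            units=[__import__("vpetypes").UnitSpec(unit_id=f"u{i:02d}",
                                                   etype="poisson", baseline_hz=5.0)
                   for i in range(12)],
            assemblies=[AssemblySpec(unit_ids=[f"u{i:02d}" for i in range(5)],
                                     rate_hz=2.0, copy_prob=0.35,
                                     copy_jitter_sd_ms=0.5)])
        session, _ = simulate_session(cfg)
        trains = session.spike_trains
        prs = []
        for i in range(len(trains)):
            for j in range(i + 1, len(trains)):
                prs.append(analyze_pair(trains[i], trains[j], n_surrogates=200,
                                        seed=1000 + 13 * i + j))
        g = build_assembly_graph(prs, trains)
        target = {f"u{i:02d}" for i in range(5)}
        best = max(g.assemblies, key=len, default=set())
        assert len(best & target) >= 4
        assert len(best - target) <= 1


class TestSyncResponsiveness:
    def _results(self, units, responsive):
        return {u: {"reward": ResponseResult(u, "reward",
                                             "activated" if u in responsive else "none",
                                             0.0001 if u in responsive else 0.5, 1.0)}
                for u in units}

    def test_fraction_table_and_chi_square(self):
        units = [f"u{i}" for i in range(40)]
        membership = {u: ("synchronous" if i < 10 else "asynchronous")
                      for i, u in enumerate(units)}
        responsive = set(units[:9]) | set(units[10:13])
        df = compare_sync_responsiveness(membership, self._results(units, responsive),
                                         events=("reward",))
        row = df.iloc[0]
        assert row["frac_sync"] > row["frac_async"]
        assert row["p"] < 0.001

    def test_all_async_is_degenerate(self):
        membership = {"a": "asynchronous", "b": "asynchronous"}
        with pytest.raises(DegenerateDataError):
            compare_sync_responsiveness(membership, self._results(["a", "b"], set()),
                                        events=("reward",))


def test_pairs_table_lists_all_pairs():
    pr_empty = PairResult(unit_a="a", unit_b="b", ccg=None, features=[])
    df = pairs_table([pr_empty])
    assert list(df["feature_class"]) == ["none"]
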