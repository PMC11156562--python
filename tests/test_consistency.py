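"""Event-aligned responses and self-consistency: oracles and invariants."""

import numpy as np
import pandas as pd
import pytest

import gazerf as gz
from gazerf.consistency import BinSpec


class TestEventResponses:
    def test_count_over_duration(self):
        s = _spike_session(spikes=np.array([10.0, 50.0, 150.0]))
        r = gz.event_responses(s, np.array([0.0]), (0.0, 200.0))
        assert np.isclose(r[0, 0], 3 / 0.2)  # 3 spikes in 200 ms -> 15 spikes/s

    def test_empty_window_is_zero(self):
        s = _spike_session(spikes=np.array([500.0]))
        r = gz.event_responses(s, np.array([0.0]), (0.0, 200.0))
        assert r[0, 0] == 0.0

    def test_event_beyond_recording_is_nan_not_error(self):
        s = _spike_session(spikes=np.array([10.0]))
        r = gz.event_responses(s, np.array([1e6]), (0.0, 200.0))
        assert np.isnan(r[0, 0])

    def test_matches_naive_per_spike_scan(self, rng):
        spikes = np.sort(rng.uniform(0, 60_000, 5000))
        s = _spike_session(spikes=spikes)
        anchors = rng.uniform(0, 59_000, 1000)
        got = gz.event_responses(s, anchors, (-50.0, 150.0))[0]
        naive = np.array([
            np.sum((spikes >= a - 50.0) & (spikes < a + 150.0)) / 0.2 for a in anchors
        ])
        assert np.allclose(got, naive)

    def test_rate_trace_window_mean(self):
        s = _spike_session(spikes=None)
        s.rates = {"u": np.concatenate([np.zeros(500), np.full(500, 10.0),
                                        np.zeros(len(s.eye_t) - 1000)])}
        r = gz.event_responses(s, np.array([500.0]), (0.0, 500.0))
        assert np.isclose(r[0, 0], 10.0)


def _spike_session(spikes):
    t = np.arange(60_000.0)
    return gz.Session(
        eye_t=t, eye_x=np.zeros_like(t), eye_y=np.zeros_like(t),
        spikes={"u": spikes if spikes is not None else np.empty(0)},
        schedule=pd.DataFrame([[0, "im", 0.0, 60_000.0, 0.0, 0.0, 16.0, 16.0, 0]],
                              columns=gz.core.SCHEDULE_COLUMNS),
        images={"im": np.zeros((128, 128))},
        units=pd.DataFrame([["u", "e", "b", "a", "CIT", "M1"]],
                           columns=gz.core.UNIT_COLUMNS),
    )


class TestSelfConsistency:
    def test_identity_responses_give_r_one(self):
        a = np.array([1.0, 3.0, 2.0, 5.0])
        res = gz.self_consistency(a, a.copy())
        assert np.isclose(res.r, 1.0)

    def test_single_pair_invalid(self):
        res = gz.self_consistency([1.0], [1.0])
        assert not res.valid and np.isnan(res.r)

    def test_zero_variance_invalid(self):
        res = gz.self_consistency([1.0, 1.0, 1.0], [0.5, 0.7, 0.9])
        assert not res.valid

    def test_textbook_pearson_on_hand_built_pairs(self):
        # hand-computed: a=[1,2,3,4,5], b=[2,1,4,3,7] -> r = 0.8232...
        a = np.array([1, 2, 3, 4, 5.0])
        b = np.array([2, 1, 4, 3, 7.0])
        expect = (np.sum((a - 3) * (b - b.mean()))
                  / np.sqrt(np.sum((a - 3) ** 2) * np.sum((b - b.mean()) ** 2)))
        res = gz.self_consistency(a, b)
        assert np.isclose(res.r, expect)

    def test_affine_rescaling_invariance(self, rng):
        a = rng.standard_normal(40)
        b = 0.8 * a + rng.standard_normal(40) * 0.3
        r1 = gz.self_consistency(a, b).r
        r2 = gz.self_consistency(3.0 * a + 7.0, 3.0 * b + 7.0).r
        assert np.isclose(r1, r2)


class TestTimecourses:
    def test_noiseless_postfixation_bins_near_one(self, bench):
        """Current-return self-consistency ~1 in bins inside the fixation (lag 0)."""
        fx = bench.fixations
        ps = gz.build_pairs(fx, "current_return", 0.25)
        bins = BinSpec()
        u = bench.session.unit_ids[0]
        binned = bench.source.binned(u, fx["onset"].to_numpy(), bins)
        tc = gz.sc_timecourse(ps, binned, fx, bins)
        # bins fully inside the guaranteed 100-ms fixation duration
        inside = (tc.centers >= 25) & (tc.centers <= 75)
        assert np.all(tc.r[inside] >= 0.9)

    def test_previous_return_prefixation_exceeds_postfixation(self, bench):
        fx = bench.fixations
        pp = gz.build_pairs(fx, "previous_return", 1.0)
        bins = BinSpec()
        u = bench.session.unit_ids[0]
        binned = bench.source.binned(u, fx["onset"].to_numpy(), bins)
        tc = gz.sc_timecourse(pp, binned, fx, bins)
        pre = (tc.centers >= -150) & (tc.centers <= -50)
        post = (tc.centers >= 100) & (tc.centers <= 250)
        assert np.nanmean(tc.r[pre]) > np.nanmean(tc.r[post])

    def test_jitter_to_zero_limit(self):
        """With zero return jitter, return self-consistency approaches 1."""
        import gazerf.synthetic as syn
        from helpers import ProcessedSession
        params = syn.GazeParams(p_return=0.6, return_jitter_sd=0.0, seed=8)
        synth = gz.make_benchmark_session(
            "noiseless-retinotopic", seed=8, n_images=6, n_presentations=30,
            n_units=2, params=params,
        )
        fix, _ = gz.detect_session(synth.session)
        fix = gz.attach_images(gz.select_fixations(fix, synth.session.schedule),
                               synth.session.schedule)
        ps = gz.build_pairs(fix, "current_return", 0.1)
        src = gz.ResponseSource(synth.session)
        resp = src.window_rates(synth.session.unit_ids[0],
                                fix["onset"].to_numpy(), 25.0, 100.0)
        res = gz.pair_self_consistency(ps, resp, fix)
        assert res.n_pairs >= 10
        assert res.r >= 0.99

    def test_shuffled_pairs_destroy_consistency(self, bench, rng):
        fx = bench.fixations
        ps = gz.build_pairs(fx, "current_return", 1.0)
        shuffled = ps.pairs.copy()
        shuffled[:, 1] = rng.permutation(shuffled[:, 1])
        ps_sh = gz.PairSet("current_return", 1.0, shuffled)
        bins = BinSpec()
        u = bench.session.unit_ids[0]
        binned = bench.source.binned(u, fx["onset"].to_numpy(), bins)
        tc = gz.sc_timecourse(ps_sh, binned, fx, bins)
        # 95% of bins inside the null band ~ +/- 2.6/sqrt(n)
        band = 2.6 / np.sqrt(np.maximum(tc.n, 1))
        assert np.mean(np.abs(tc.r) <= band) >= 0.8


class TestDistanceProfile:
    def test_decreases_with_threshold(self, bench):
        fx = bench.fixations
        u = bench.session.unit_ids[0]
        resp = bench.source.window_rates(u, fx["onset"].to_numpy(), 40.0, 190.0)
        prof = gz.distance_profile(fx, resp, np.array([0.25, 0.5, 1, 2, 4, 8]))
        r = prof["r"].to_numpy()
        assert r[0] > r[-1]
        # overall monotone trend: Spearman of r against threshold is negative
        from scipy.stats import spearmanr
        assert spearmanr(prof["threshold"], r).statistic < -0.8

    def test_single_threshold_equals_direct_call(self, bench):
        fx = bench.fixations
        u = bench.session.unit_ids[0]
        resp = bench.source.window_rates(u, fx["onset"].to_numpy(), 40.0, 190.0)
        prof = gz.distance_profile(fx, resp, np.array([1.0]))
        ps = gz.build_pairs(fx, "current_return", 1.0)
        direct = gz.pair_self_consistency(ps, resp, fx)
        assert np.isclose(prof.loc[0, "r"], direct.r)

    def test_unsorted_thresholds_rejected(self, bench):
        fx = bench.fixations
        u = bench.session.unit_ids[0]
        resp = bench.source.window_rates(u, fx["onset"].to_numpy(), 40.0, 190.0)
        with pytest.raises(ValueError):
            gz.distance_profile(fx, resp, np.array([2.0, 1.0]))


class TestPresentationTimecourse:
    def test_rule_ordering_under_retinotopy(self, bench):
        """Return > same-image > distant self-consistency throughout the trial."""
        fx = bench.fixations
        u = bench.session.unit_ids[0]
        pt = gz.presentation_timecourse(fx, bench.source, u, bench.session.schedule)
        piv = pt.pivot_table(index="center", columns="rule", values="r")
        means = piv.mean()
        assert means["return"] > means["same_image"] > means["distant"]
        # bin-wise ordering holds for the vast majority of bins
        ok = (piv["return"] >= piv["same_image"]) & (piv["same_image"] >= piv["distant"])
        assert ok.mean() >= 0.7


class TestSelectivityScreen:
    def test_screen_combines_effect_size_and_significance(self):
        assert gz.visual_selectivity_screen(0.3, 0.001)
        assert not gz.visual_selectivity_screen(0.05, 0.001)  # r below 0.1
        assert not gz.visual_selectivity_screen(0.3, 0.02)  # p above 0.01
        assert not gz.visual_selectivity_screen(float("nan"), 0.001)


class TestOracleEquivalence:
    def test_pairing_and_correlation_reproduced_by_brute_force(self, bench, rng):
        """Independent end-to-end recomputation on a <= 100-fixation subset."""
        fx = bench.fixations.iloc[:100]
        u = bench.session.unit_ids[1]
        resp = bench.source.window_rates(u, fx["onset"].to_numpy(), 40.0, 190.0)
        ps = gz.build_pairs(fx, "current_return", 1.0)
        got = gz.pair_self_consistency(ps, resp, fx)
        # brute force, written independently of the package internals
        rows = fx.reset_index(drop=True)
        rmap = dict(zip(rows["fixation"], resp))
        xs, ys = [], []
        for i in range(len(rows)):
            for j in range(i + 1, len(rows)):
                a, b = rows.iloc[i], rows.iloc[j]
                if a["image_id"] != b["image_id"] or not (a["valid"] and b["valid"]):
                    continue
                if np.hypot(a["x"] - b["x"], a["y"] - b["y"]) > 1.0:
                    continue
                first, second = (a, b) if a["onset"] <= b["onset"] else (b, a)
                xs.append(rmap[first["fixation"]])
                ys.append(rmap[second["fixation"]])
        assert len(xs) == got.n_pairs
        expect = np.corrcoef(xs, ys)[0, 1]
        assert np.isclose(got.r, expect)
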