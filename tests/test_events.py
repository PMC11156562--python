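"""Event detection, fixation selection, pairing rules, matching: oracle checks."""

import numpy as np
import pandas as pd
import pytest

import gazerf as gz
from gazerf.core import Presentation, Session
from gazerf.events import PairSet, match_saccades


def toy_fixation_table(rng, n=50, n_images=3, n_pres=6, spread=8.0):
    rows = []
    t = 0.0
    for i in range(n):
        pres = int(rng.integers(0, n_pres))
        rows.append((i, pres, 0, t, t + 200.0, float(rng.uniform(-spread, spread)),
                     float(rng.uniform(-spread, spread)), True))
        t += 300.0
    fx = pd.DataFrame(rows, columns=["fixation", "presentation", "ordinal",
                                     "onset", "offset", "x", "y", "valid"])
    # consistent ordinals within presentation
    fx["ordinal"] = fx.groupby("presentation").cumcount()
    fx["image_id"] = [f"im{p % n_images}" for p in fx["presentation"]]
    return fx


def brute_force_pairs(fx, rule, threshold=1.0, distant=8.0):
    """O(n^2) literal enumeration of the pairing rules."""
    out = []
    v = fx[fx["valid"]]
    prev = {}
    for _, r in fx.iterrows():
        prev[(r["presentation"], r["ordinal"])] = r
    for i, a in v.iterrows():
        for j, b in v.iterrows():
            if a["fixation"] >= b["fixation"]:
                continue
            first, second = (a, b) if a["onset"] <= b["onset"] else (b, a)
            if a["image_id"] != b["image_id"]:
                continue
            d = np.hypot(a["x"] - b["x"], a["y"] - b["y"])
            if rule == "current_return" and d <= threshold:
                out.append((first["fixation"], second["fixation"]))
            elif rule == "same_image":
                out.append((first["fixation"], second["fixation"]))
            elif rule == "distant" and d > distant:
                out.append((first["fixation"], second["fixation"]))
            elif rule == "previous_return":
                pa = prev.get((a["presentation"], a["ordinal"] - 1))
                pb = prev.get((b["presentation"], b["ordinal"] - 1))
                if pa is None or pb is None or pa["image_id"] != pb["image_id"]:
                    continue
                dp = np.hypot(pa["x"] - pb["x"], pa["y"] - pb["y"])
                if dp <= threshold:
                    out.append((first["fixation"], second["fixation"]))
    return set(out)


class TestDetection:
    def test_recovers_ground_truth_fixations(self, bench):
        """>= 90% of true fixations found with onset error <= one 30-Hz frame."""
        truth = bench.synth.true_fixations
        truth = truth[~truth["truncated"]]
        fx = bench.fixations
        hits = 0
        for _, tr in truth.iterrows():
            cand = fx[fx["presentation"] == tr["presentation"]]
            if len(cand) and np.abs(cand["onset"] - tr["onset"]).min() <= 33.0:
                hits += 1
        assert hits / len(truth) >= 0.9

    def test_still_gaze_is_one_fixation(self):
        t = np.arange(2000.0)
        s = Session(
            eye_t=t, eye_x=np.full(2000, 1.0), eye_y=np.full(2000, -2.0),
            spikes={}, schedule=pd.DataFrame(
                [[0, "im", 0.0, 2000.0, 0.0, 0.0, 16.0, 16.0, 0]],
                columns=gz.core.SCHEDULE_COLUMNS),
            images={"im": np.zeros((128, 128))},
            units=pd.DataFrame(columns=gz.core.UNIT_COLUMNS),
        )
        fix, sacc = gz.detect_events(s, s.presentation(0))
        assert len(fix) == 1 and len(sacc) == 0
        assert fix.loc[0, "offset"] - fix.loc[0, "onset"] >= 1900

    def test_two_fixations_one_saccade(self):
        t = np.arange(1500.0)
        x = np.concatenate([np.zeros(700), np.linspace(0, 5, 50), np.full(750, 5.0)])
        s = Session(
            eye_t=t, eye_x=x, eye_y=np.zeros(1500),
            spikes={}, schedule=pd.DataFrame(
                [[0, "im", 0.0, 1500.0, 0.0, 0.0, 16.0, 16.0, 0]],
                columns=gz.core.SCHEDULE_COLUMNS),
            images={"im": np.zeros((128, 128))},
            units=pd.DataFrame(columns=gz.core.UNIT_COLUMNS),
        )
        fix, sacc = gz.detect_events(s, s.presentation(0))
        assert len(fix) == 2 and len(sacc) == 1
        assert np.isclose(sacc.loc[0, "amplitude"], 5.0, atol=0.3)

    def test_short_trace_warns_and_returns_empty(self):
        t = np.arange(100.0)
        s = Session(
            eye_t=t, eye_x=np.zeros(100), eye_y=np.zeros(100), spikes={},
            schedule=pd.DataFrame([[0, "im", 0.0, 100.0, 0.0, 0.0, 16.0, 16.0, 0]],
                                  columns=gz.core.SCHEDULE_COLUMNS),
            images={"im": np.zeros((128, 128))},
            units=pd.DataFrame(columns=gz.core.UNIT_COLUMNS),
        )
        with pytest.warns(UserWarning, match="too short"):
            fix, sacc = gz.detect_events(s, s.presentation(0))
        assert fix.empty and sacc.empty


class TestSelection:
    @pytest.mark.parametrize(
        "duration,x,expected",
        [(99.0, 0.0, False), (100.0, 0.0, True), (150.0, 8.1, False), (150.0, 8.0, True)],
    )
    def test_duration_and_image_bounds(self, duration, x, expected):
        fx = pd.DataFrame(
            [[0, 0, 0, 0.0, duration, x, 0.0, True]],
            columns=["fixation", "presentation", "ordinal", "onset", "offset", "x", "y", "valid"],
        )
        sched = pd.DataFrame([[0, "im", 0.0, 1500.0, 0.0, 0.0, 16.0, 16.0, 0]],
                             columns=gz.core.SCHEDULE_COLUMNS)
        out = gz.select_fixations(fx, sched)
        assert bool(out.loc[0, "valid"]) is expected

    def test_all_valid_is_identity(self, bench):
        v = bench.valid_fixations
        again = gz.select_fixations(v, bench.session.schedule)
        assert again["valid"].all()


class TestPairs:
    @pytest.mark.parametrize("rule", ["current_return", "previous_return", "same_image", "distant"])
    def test_matches_brute_force(self, rule, rng):
        fx = toy_fixation_table(rng, n=60)
        ps = gz.build_pairs(fx, rule, threshold_dva=1.5)
        got = {tuple(p) for p in ps.pairs}
        assert got == brute_force_pairs(fx, rule, threshold=1.5)

    def test_three_colocated_fixations_give_three_pairs(self):
        fx = pd.DataFrame(
            [[i, i, 0, i * 1000.0, i * 1000.0 + 200, 1.0, 1.0, True] for i in range(3)],
            columns=["fixation", "presentation", "ordinal", "onset", "offset", "x", "y", "valid"],
        )
        fx["image_id"] = "im"
        ps = gz.build_pairs(fx, "current_return", 1.0)
        assert len(ps) == 3

    def test_different_images_never_pair(self):
        fx = pd.DataFrame(
            [[0, 0, 0, 0.0, 200.0, 0.0, 0.0, True],
             [1, 1, 0, 1000.0, 1200.0, 0.0, 0.0, True]],
            columns=["fixation", "presentation", "ordinal", "onset", "offset", "x", "y", "valid"],
        )
        fx["image_id"] = ["a", "b"]
        for rule in ("current_return", "same_image", "distant", "previous_return"):
            assert len(gz.build_pairs(fx, rule)) == 0

    def test_threshold_edges(self):
        def table(d):
            fx = pd.DataFrame(
                [[0, 0, 0, 0.0, 200.0, 0.0, 0.0, True],
                 [1, 1, 0, 1000.0, 1200.0, d, 0.0, True]],
                columns=["fixation", "presentation", "ordinal", "onset", "offset", "x", "y", "valid"],
            )
            fx["image_id"] = "im"
            return fx
        assert len(gz.build_pairs(table(1.01), "current_return", 1.0)) == 0
        assert len(gz.build_pairs(table(1.00), "current_return", 1.0)) == 1
        assert len(gz.build_pairs(table(8.01), "distant")) == 1
        assert len(gz.build_pairs(table(8.00), "distant")) == 0

    def test_cardinality_monotone_in_threshold(self, rng):
        fx = toy_fixation_table(rng, n=80)
        sizes = [len(gz.build_pairs(fx, "current_return", th))
                 for th in (0.5, 1.0, 2.0, 4.0, 8.0)]
        assert sizes == sorted(sizes)

    def test_scope_partitions_same_image_pairs(self, rng):
        fx = toy_fixation_table(rng, n=60)
        both = gz.build_pairs(fx, "same_image", scope="both")
        within = gz.build_pairs(fx, "same_image", scope="within")
        between = gz.build_pairs(fx, "same_image", scope="between")
        assert len(within) + len(between) == len(both)
        w = {tuple(p) for p in within.pairs}
        b = {tuple(p) for p in between.pairs}
        assert not (w & b)
        pres = fx.set_index("fixation")["presentation"]
        assert all(pres[a] == pres[b_] for a, b_ in w)
        assert all(pres[a] != pres[b_] for a, b_ in b)

    def test_unknown_rule_rejected(self, rng):
        with pytest.raises(ValueError):
            gz.build_pairs(toy_fixation_table(rng), "nearest")


class TestDecorrelation:
    def test_matches_brute_force_and_only_removes(self, rng):
        fx = toy_fixation_table(rng, n=50, spread=4.0)
        ps = gz.build_pairs(fx, "current_return", 2.0)
        out = gz.decorrelate_pairs(ps, fx, limit_dva=4.0)
        assert len(out.pairs) == len(ps.pairs)
        assert out.decorrelated.sum() <= len(ps)
        prev = {(r["presentation"], r["ordinal"]): r for _, r in fx.iterrows()}
        pos = fx.set_index("fixation")
        for (a, b), kept in zip(out.pairs, out.decorrelated):
            ra, rb = pos.loc[a], pos.loc[b]
            pa = prev.get((ra["presentation"], ra["ordinal"] - 1))
            pb = prev.get((rb["presentation"], rb["ordinal"] - 1))
            if pa is None or pb is None or pa["image_id"] != pb["image_id"]:
                expect = True  # zeroth fixations have no preceding fixation
            else:
                expect = np.hypot(pa["x"] - pb["x"], pa["y"] - pb["y"]) > 4.0
            assert kept == expect

    def test_far_previous_fixations_kept(self):
        fx = pd.DataFrame(
            [[0, 0, 0, 0.0, 200.0, -5.0, -5.0, True],
             [1, 0, 1, 300.0, 500.0, 0.0, 0.0, True],
             [2, 1, 0, 2000.0, 2200.0, 5.0, 5.0, True],
             [3, 1, 1, 2300.0, 2500.0, 0.1, 0.0, True]],
            columns=["fixation", "presentation", "ordinal", "onset", "offset", "x", "y", "valid"],
        )
        fx["image_id"] = "im"
        ps = gz.build_pairs(fx, "current_return", 1.0)
        out = gz.decorrelate_pairs(ps, fx)
        kept = {tuple(p) for p, k in zip(out.pairs, out.decorrelated) if k}
        assert (1, 3) in kept  # previous fixations 14 dva apart

    def test_near_previous_fixations_removed(self):
        fx = pd.DataFrame(
            [[0, 0, 0, 0.0, 200.0, -5.0, -5.0, True],
             [1, 0, 1, 300.0, 500.0, 0.0, 0.0, True],
             [2, 1, 0, 2000.0, 2200.0, -4.0, -3.0, True],  # 2.2 dva from fix 0
             [3, 1, 1, 2300.0, 2500.0, 0.1, 0.0, True]],
            columns=["fixation", "presentation", "ordinal", "onset", "offset", "x", "y", "valid"],
        )
        fx["image_id"] = "im"
        ps = gz.build_pairs(fx, "current_return", 1.0)
        out = gz.decorrelate_pairs(ps, fx)
        flags = {tuple(p): k for p, k in zip(out.pairs, out.decorrelated)}
        assert flags[(1, 3)] == False  # noqa: E712

    def test_wrong_rule_rejected(self, rng):
        fx = toy_fixation_table(rng)
        ps = gz.build_pairs(fx, "same_image")
        with pytest.raises(ValueError):
            gz.decorrelate_pairs(ps, fx)


class TestMatching:
    def _sacc(self, rows):
        return pd.DataFrame(
            rows, columns=["saccade", "image_id", "onset", "x1", "y1", "x2", "y2"]
        )

    def test_basic_rules(self):
        T = self._sacc([[0, "im", 0.0, 0.0, 0.0, 5.0, 0.0]])
        C = self._sacc([[1, "im", 10.0, 0.5, 0.0, 5.0, 5.0],  # ok: start 0.5, div 5
                        [2, "im", 20.0, 0.2, 0.0, 5.0, 2.0]])  # div 2 < 4: fails
        out = gz.match_saccades(T, C)
        m = out["matches"]
        assert list(m["match"]) == [1]

    def test_divergence_rule_leaves_unmatched(self):
        T = self._sacc([[0, "im", 0.0, 0.0, 0.0, 5.0, 0.0]])
        C = self._sacc([[1, "im", 10.0, 0.5, 0.0, 5.0, 2.0]])
        out = gz.match_saccades(T, C)
        assert out["matches"].empty and out["unmatched"] == [0]

    def test_empty_candidates(self):
        T = self._sacc([[0, "im", 0.0, 0.0, 0.0, 5.0, 0.0]])
        out = gz.match_saccades(T, T.iloc[0:0])
        assert out["matches"].empty and out["unmatched"] == [0]

    def test_greedy_start_distances_bounded_by_optimal(self, rng):
        """Each greedy assignment takes the best start distance still available."""
        rows_t = [[i, "im", float(i), *rng.uniform(-1, 1, 2), *rng.uniform(4, 8, 2)]
                  for i in range(5)]
        rows_c = [[100 + i, "im", float(i), *rng.uniform(-1.5, 1.5, 2), *rng.uniform(-8, -4, 2)]
                  for i in range(10)]
        T = self._sacc(rows_t)
        C = self._sacc(rows_c)
        out = gz.match_saccades(T, C)
        used = set()
        for _, r in out["matches"].iterrows():
            t = T.set_index("saccade").loc[r["template"]]
            d = np.hypot(C["x1"] - t["x1"], C["y1"] - t["y1"])
            div = np.hypot(C["x2"] - t["x2"], C["y2"] - t["y2"])
            ok = (d <= 1.0) & (div >= 4.0) & (~C["saccade"].isin(used))
            assert np.isclose(r["start_distance"], d[ok].min())
            used.add(r["match"])
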