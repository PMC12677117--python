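"""Feature shuffling, TFCE statistics, ROI selection, paired tests."""

from itertools import product

import numpy as np
import pandas as pd
import pytest

from speechtrack.acoustic import EventStream, FeatureMatrix
from speechtrack.inference import (
    ShufflePlan,
    compare_conditions,
    select_roi,
    shuffle_event_values,
    shuffle_features,
    shuffle_trial_labels,
    tfce_scores,
    tfce_test,
)
from speechtrack.layout import ChannelGraph
from speechtrack.trf import FitScores


def brute_force_tfce(t_values, edges, E, H, dh):
    """Independent threshold-sweep enumeration with BFS components."""
    t_abs = np.abs(np.asarray(t_values, float))
    n = t_abs.size
    adj = {i: set() for i in range(n)}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    scores = np.zeros(n)
    for k in range(1, int(np.floor(t_abs.max() / dh + 1e-9)) + 1):
        h = k * dh
        above = set(np.nonzero(t_abs >= h - 1e-9)[0])
        seen = set()
        for start in sorted(above):
            if start in seen:
                continue
            comp = {start}
            frontier = [start]
            while frontier:
                x = frontier.pop()
                for y in adj[x]:
                    if y in above and y not in comp:
                        comp.add(y)
                        frontier.append(y)
            seen |= comp
            for c in comp:
                scores[c] += len(comp) ** E * h**H * dh
    return scores


class TestShuffles:
    def _streams(self, rng):
        out = {}
        for tid in range(4):
            times = np.sort(rng.uniform(0, 2, 6))
            out[tid] = {
                "word_surprisal": EventStream(times, rng.uniform(1, 5, 6), "word_surprisal"),
                "cohort_entropy": EventStream(times + 0.01, rng.uniform(0, 2, 6), "cohort_entropy"),
            }
        return out

    def test_value_shuffle_preserves_multiset_and_onsets(self, rng):
        streams = self._streams(rng)
        plan = ShufflePlan("word_linguistic", shuffled_features=["word_surprisal"], seed=4)
        shuffled = shuffle_features(streams, plan, iteration=0)
        before = np.sort(np.concatenate([s["word_surprisal"].values for s in streams.values()]))
        after = np.sort(np.concatenate([s["word_surprisal"].values for s in shuffled.values()]))
        np.testing.assert_allclose(before, after)
        for tid in streams:
            np.testing.assert_array_equal(
                streams[tid]["word_surprisal"].times, shuffled[tid]["word_surprisal"].times
            )
            # untouched feature is identical
            np.testing.assert_array_equal(
                streams[tid]["cohort_entropy"].values, shuffled[tid]["cohort_entropy"].values
            )

    def test_value_shuffle_moves_values_across_trials(self, rng):
        streams = self._streams(rng)
        plan = ShufflePlan("word_linguistic", shuffled_features=["word_surprisal"], seed=1)
        shuffled = shuffle_features(streams, plan, iteration=0)
        moved = any(
            not np.allclose(streams[t]["word_surprisal"].values, shuffled[t]["word_surprisal"].values)
            for t in streams
        )
        assert moved

    def test_deterministic_per_seed_iteration(self, rng):
        streams = self._streams(rng)
        plan = ShufflePlan("phoneme_linguistic", shuffled_features=["cohort_entropy"], seed=9)
        a = shuffle_features(streams, plan, 3)
        b = shuffle_features(streams, plan, 3)
        c = shuffle_features(streams, plan, 4)
        for t in streams:
            np.testing.assert_array_equal(
                a[t]["cohort_entropy"].values, b[t]["cohort_entropy"].values
            )
        assert any(
            not np.allclose(a[t]["cohort_entropy"].values, c[t]["cohort_entropy"].values)
            for t in streams
        )

    def test_trial_label_shuffle_single_trial_identity(self, rng):
        fm = FeatureMatrix(rng.random((50, 2)), ["envelope", "acoustic_onsets"], 128.0)
        out = shuffle_trial_labels({0: fm}, ["envelope"], np.random.default_rng(0))
        np.testing.assert_array_equal(out[0].data, fm.data)

    def test_trial_label_shuffle_moves_only_group_columns(self, rng):
        feats = {
            t: FeatureMatrix(rng.random((40, 2)), ["envelope", "word_onsets"], 128.0)
            for t in range(5)
        }
        out = shuffle_trial_labels(feats, ["envelope"], np.random.default_rng(3))
        for t in feats:
            np.testing.assert_array_equal(out[t].column("word_onsets"), feats[t].column("word_onsets"))
        assert any(
            not np.allclose(out[t].column("envelope"), feats[t].column("envelope"))
            for t in feats
        )

    def test_stream_suffix_applied(self):
        plan = ShufflePlan("acoustic", stream="target")
        assert plan.shuffled_features == ["envelope_target", "acoustic_onsets_target"]


class TestTFCE:
    def _path_graph(self, n):
        return ChannelGraph([f"c{i}" for i in range(n)], [(i, i + 1) for i in range(n - 1)])

    def test_matches_brute_force_on_path_graph(self):
        t = np.array([0.3, 2.1, 1.7, -2.5, 0.0])
        g = self._path_graph(5)
        got = tfce_scores(t, g, E=0.5, H=2.0, dh=0.1)
        want = brute_force_tfce(t, g.edges, 0.5, 2.0, 0.1)
        np.testing.assert_allclose(got, want, atol=1e-9)

    def test_matches_brute_force_random_graphs(self, rng):
        for trial in range(8):
            n = int(rng.integers(5, 11))
            edges = [
                (int(a), int(b))
                for a, b in rng.integers(0, n, (2 * n, 2))
                if a != b
            ]
            g = ChannelGraph([f"c{i}" for i in range(n)], edges or [(0, 1)])
            t = rng.standard_normal(n) * 3
            np.testing.assert_allclose(
                tfce_scores(t, g, 0.5, 2.0, 0.1),
                brute_force_tfce(t, g.edges, 0.5, 2.0, 0.1),
                atol=1e-9,
            )

    def test_isolated_channel_closed_form(self):
        # extent 1 throughout: TFCE = sum over h <= |t| of h^H * dh
        g = ChannelGraph(["a", "b"], [])
        t = np.array([1.35, 0.0])
        got = tfce_scores(t, g, E=0.5, H=2.0, dh=0.1)
        hs = np.arange(1, 14) * 0.1  # h = 0.1 .. 1.3
        assert got[0] == pytest.approx((hs**2 * 0.1).sum(), abs=1e-12)
        assert got[1] == 0.0

    def test_monotone_in_t(self, rng):
        g = self._path_graph(6)
        t = rng.standard_normal(6)
        base = tfce_scores(t, g)
        t2 = t.copy()
        t2[2] = np.sign(t2[2] or 1) * (abs(t2[2]) + 1.0)
        bumped = tfce_scores(t2, g)
        assert np.all(bumped >= base - 1e-12)


class TestTfceTest:
    def _graph(self, n):
        return ChannelGraph([f"c{i}" for i in range(n)], [(i, i + 1) for i in range(n - 1)])

    def test_all_zero_deltas_give_p_one(self):
        g = self._graph(4)
        stat = tfce_test(np.zeros((6, 4)), g, n_signflips=64, seed=0)
        assert np.all(stat.frame["p"] == 1.0)

    def test_signflip_enumeration_matches_independent_oracle(self, rng):
        # tiny N: full enumeration must equal a brute-force recomputation
        deltas = rng.standard_normal((6, 5)) + 0.4
        g = self._graph(5)
        stat = tfce_test(deltas, g, n_signflips="all", seed=0)
        tf_obs = stat.frame["tfce"].to_numpy()
        maxima = []
        for signs in product([1.0, -1.0], repeat=6):
            d = deltas * np.array(signs)[:, None]
            m, sd = d.mean(0), d.std(0, ddof=1)
            t = np.where(sd > 0, m / (sd / np.sqrt(6)), 0.0)
            maxima.append(brute_force_tfce(t, g.edges, 0.5, 2.0, 0.1).max())
        maxima = np.array(maxima)
        p_oracle = (maxima[None, :] >= tf_obs[:, None]).mean(axis=1)
        np.testing.assert_allclose(stat.frame["p"].to_numpy(), p_oracle, atol=1e-12)

    def test_strong_effect_detected(self, rng):
        deltas = 0.5 + 0.1 * rng.standard_normal((12, 6))
        stat = tfce_test(deltas, self._graph(6), n_signflips=512, seed=1)
        assert (stat.frame["p"] < 0.05).all()

    def test_two_participants_minimum(self):
        with pytest.raises(ValueError):
            tfce_test(np.zeros((1, 3)), self._graph(3))

    def test_dataframe_input_keeps_channel_names(self, rng):
        df = pd.DataFrame(rng.standard_normal((5, 3)), columns=["Fz", "Cz", "Pz"])
        stat = tfce_test(df, ChannelGraph(["Fz", "Cz", "Pz"], [(0, 1), (1, 2)]), n_signflips=32)
        assert list(stat.frame["channel"]) == ["Fz", "Cz", "Pz"]


def _fit_scores(scores, participants, variants=None):
    n = scores.shape[0]
    frame = pd.DataFrame(
        {
            "participant": participants,
            "trial": range(n),
            "variant": variants or ["correct"] * n,
            "n_folds": 1,
        }
    )
    ch = [f"c{i}" for i in range(scores.shape[1])]
    return FitScores(frame, scores, ch)


class TestSelectROI:
    def test_single_candidate_returned(self, rng):
        fs = _fit_scores(rng.random((6, 4)), list("aabbcc"))
        name, table = select_roi(fs, {"only": ["c0", "c1"]})
        assert name == "only"

    def test_highest_fit_cluster_wins(self, rng):
        scores = rng.random((6, 4)) * 0.01
        scores[:, 2:] += 0.5  # posterior channels fit best
        fs = _fit_scores(scores, list("aabbcc"))
        name, _ = select_roi(fs, {"front": ["c0", "c1"], "post": ["c2", "c3"]})
        assert name == "post"

    def test_tie_warns_and_keeps_first(self, rng):
        scores = np.tile(rng.random((6, 1)), (1, 4))
        fs = _fit_scores(scores, list("aabbcc"))
        with pytest.warns(UserWarning, match="tie"):
            name, _ = select_roi(fs, {"one": ["c0", "c1"], "two": ["c2", "c3"]})
        assert name == "one"

    def test_empty_cluster_rejected(self, rng):
        fs = _fit_scores(rng.random((2, 2)), list("ab"))
        with pytest.raises(ValueError):
            select_roi(fs, {"bad": []})


class TestCompareConditions:
    def _table(self, diff, n=10, seed=0):
        rng = np.random.default_rng(seed)
        base = rng.random(n)
        return pd.DataFrame(
            {
                "feature": "acoustic",
                "stream": "target",
                "participant": [f"P{i}" for i in range(n)],
                "fit_correct": base + diff + 0.02 * rng.standard_normal(n),
                "fit_incorrect": base,
            }
        )

    def test_identical_inputs(self):
        tbl = self._table(0.0)
        tbl["fit_correct"] = tbl["fit_incorrect"]
        out = compare_conditions(tbl)
        assert out["t"].iloc[0] == 0.0 and out["p"].iloc[0] == 1.0 and out["cohens_d"].iloc[0] == 0.0

    def test_constant_nonzero_difference_refused(self):
        tbl = self._table(0.0)
        tbl["fit_correct"] = tbl["fit_incorrect"] + 0.3
        with pytest.raises(ValueError, match="constant"):
            compare_conditions(tbl)

    def test_too_few_participants_refused(self):
        with pytest.raises(ValueError, match="participants"):
            compare_conditions(self._table(0.1, n=2))

    def test_rejection_rate_matches_analytic_power(self):
        # paired t-test, d = 0.8, N = 43, alpha = .05 two-sided:
        # power = P(|T'| > t_crit) with ncp = d * sqrt(N)
        from scipy import stats

        N, d = 43, 0.8
        ncp = d * np.sqrt(N)
        tcrit = stats.t.ppf(0.975, N - 1)
        power = 1 - stats.nct.cdf(tcrit, N - 1, ncp) + stats.nct.cdf(-tcrit, N - 1, ncp)
        rng = np.random.default_rng(7)
        hits = 0
        reps = 400
        for _ in range(reps):
            diffs = rng.standard_normal(N) + d
            t, p = stats.ttest_1samp(diffs, 0.0)
            hits += p < 0.05
        assert hits / reps == pytest.approx(power, abs=0.05)

    def test_fdr_monotone_in_p(self, rng):
        rows = []
        for i, (f, s) in enumerate(product(["a", "b", "c"], ["t", "d"])):
            base = rng.random(8)
            rows.append(
                pd.DataFrame(
                    {
                        "feature": f,
                        "stream": s,
                        "participant": [f"P{j}" for j in range(8)],
                        "fit_correct": base + 0.05 * i + 0.1 * rng.standard_normal(8),
                        "fit_incorrect": base,
                    }
                )
            )
        out = compare_conditions(pd.concat(rows))
        order = out.sort_values("p")
        assert order["p_fdr"].is_monotonic_increasing
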