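"""Synthetic stimuli, forward-model EEG, behavior, and the staircase."""

import numpy as np
import pytest

from speechtrack.acoustic import FeatureMatrix
from speechtrack.lexicon import make_lexicon
from speechtrack.simulate import (
    PAPER_COEFFS,
    PsychometricListener,
    make_ground_truth_kernels,
    pink_noise,
    simulate_behavior,
    simulate_behavior_dataset,
    simulate_eeg,
    simulate_staircase,
    simulate_stimuli,
)


@pytest.fixture(scope="module")
def lexicon():
    return make_lexicon(150, seed=11)


@pytest.fixture(scope="module")
def stim(lexicon):
    return simulate_stimuli(lexicon, n_trials=12, seed=21)


class TestStimuli:
    def test_stream_timing_invariants(self, stim):
        for t in stim.trials:
            assert t.target_onset == pytest.approx(0.5)  # distractor head start
            assert 5 <= len(t.target_tokens) <= 7
            assert 7 <= len(t.distractor_tokens) <= 10
            tdur = t.target_offset - t.target_onset
            ddur = t.distractor_words[-1].offset - t.distractor_words[0].onset
            assert 2.0 - 1e-9 <= tdur <= 4.0 + 1e-9
            assert ddur <= 5.0 + 1e-9
            assert t.distractor_words[-1].offset >= t.target_offset + 0.3 - 1e-9

    def test_onsets_strictly_increasing(self, stim):
        for t in stim.trials:
            for words in (t.target_words, t.distractor_words):
                onsets = [iv.onset for iv in words]
                assert np.all(np.diff(onsets) > 0)

    def test_phonemes_nested_in_words(self, stim):
        t = stim.trials[0]
        for iv, phons in zip(t.target_words, t.target_phonemes):
            assert phons[0].onset == pytest.approx(iv.onset)
            assert phons[-1].offset == pytest.approx(iv.offset)

    def test_seed_determinism(self, lexicon):
        a = simulate_stimuli(lexicon, n_trials=4, seed=5)
        b = simulate_stimuli(lexicon, n_trials=4, seed=5)
        for ta, tb in zip(a.trials, b.trials):
            assert ta.target_tokens == tb.target_tokens
            np.testing.assert_array_equal(ta.target_spec.levels, tb.target_spec.levels)

    def test_td_condition_sets_level_difference(self, lexicon):
        stim10 = simulate_stimuli(lexicon, n_trials=6, td_conditions=(10.0,), seed=3)
        for t in stim10.trials:
            frames = np.arange(t.target_spec.n_frames) / t.target_spec.frame_rate

            def in_word_mean(spec, words):
                sel = np.zeros(frames.size, bool)
                for iv in words:
                    sel |= (frames >= iv.onset) & (frames < iv.offset)
                return spec.levels[:, sel].mean()

            diff = in_word_mean(t.target_spec, t.target_words) - in_word_mean(
                t.distractor_spec, t.distractor_words
            )
            assert diff == pytest.approx(10.0, abs=4.0)

    def test_control_condition_flagged(self, lexicon):
        s = simulate_stimuli(lexicon, n_trials=12, td_conditions=(0.0, 10.0), seed=7)
        flags = [t.is_control for t in s.trials]
        tds = [t.td_db for t in s.trials]
        assert all((td == 10.0) == f for td, f in zip(tds, flags))
        assert any(flags) and not all(flags)

    def test_240_trials(self, lexicon):
        s = simulate_stimuli(lexicon, n_trials=240, seed=1)
        assert len(s) == 240


class TestForwardModel:
    def test_delta_kernel_reproduces_impulse_train(self):
        # kernel = delta at lag 0 -> EEG equals the feature itself
        from speechtrack.simulate import GroundTruthKernels
        from speechtrack.trf import lag_samples

        lags = lag_samples((-100, 800), 128.0)
        K = np.zeros((lags.size, 1, 1))
        K[list(lags).index(0), 0, 0] = 1.0
        kern = GroundTruthKernels(K, ["x"], (-100, 800), 128.0)
        F = np.zeros((200, 1))
        F[[10, 50, 130], 0] = 1.0
        ds = simulate_eeg({0: FeatureMatrix(F, ["x"], 128.0)}, kern, noise_sd=0.0)
        np.testing.assert_allclose(ds.epochs[0][0], F[:, 0], atol=1e-12)

    def test_zero_kernels_give_pure_noise_at_requested_sd(self, rng):
        names = ["x"]
        kern = make_ground_truth_kernels(names, 4, scale=0.0, seed=0)
        F = (rng.random((2000, 1)) < 0.05).astype(float)
        ds = simulate_eeg({0: FeatureMatrix(F, names, 128.0)}, kern, noise_sd=2.0, seed=1)
        assert ds.epochs[0].std(axis=1) == pytest.approx(2.0, rel=0.05)

    def test_noise_free_output_is_exact_convolution(self, rng):
        # conservation: regenerating with the same seed and subtracting
        # the noiseless output leaves exactly the scaled noise
        names = ["x", "y"]
        kern = make_ground_truth_kernels(names, 3, seed=5)
        F = rng.standard_normal((300, 2))
        feats = {0: FeatureMatrix(F, names, 128.0)}
        clean = simulate_eeg(feats, kern, noise_sd=0.0, seed=7)
        noisy = simulate_eeg(feats, kern, noise_sd=1.0, seed=7)
        resid = noisy.epochs[0] - clean.epochs[0]
        assert resid.std() == pytest.approx(1.0, rel=0.05)

    def test_predictor_mismatch_rejected(self, rng):
        kern = make_ground_truth_kernels(["x"], 2, seed=0)
        feats = {0: FeatureMatrix(rng.random((50, 1)), ["other"], 128.0)}
        with pytest.raises(ValueError):
            simulate_eeg(feats, kern, noise_sd=0.0)

    def test_pink_noise_band_limited(self):
        x = pink_noise(4096, 2, 128.0, rng=np.random.default_rng(0))
        f = np.fft.rfftfreq(4096, 1 / 128.0)
        P = np.abs(np.fft.rfft(x, axis=1)) ** 2
        out_band = P[:, (f > 20) | ((f < 0.3) & (f > 0))].mean()
        in_band = P[:, (f > 1) & (f < 10)].mean()
        assert out_band < 1e-20 * in_band


class TestBehavior:
    def test_null_coefficients_give_half_accuracy(self):
        coeffs = {k: 0.0 for k in PAPER_COEFFS}
        tbl = simulate_behavior_dataset(30, 80, 4, coeffs, re_sd=(0.0, 0.0), seed=2)
        assert tbl["accuracy"].mean() == pytest.approx(0.5, abs=0.02)

    def test_accuracy_monotone_in_audibility(self):
        coeffs = {k: 0.0 for k in PAPER_COEFFS}
        coeffs["audibility"] = 3.0
        tbl = simulate_behavior_dataset(20, 100, 4, coeffs, re_sd=(0.0, 0.0), seed=3)
        deciles = tbl.groupby(np.digitize(tbl["audibility"], np.quantile(tbl["audibility"], np.linspace(0.1, 0.9, 9))))["accuracy"].mean()
        assert deciles.is_monotonic_increasing

    def test_binned_accuracy_matches_inverse_logit(self):
        tbl = simulate_behavior_dataset(30, 100, 4, "paper", seed=4)
        lp = tbl["linear_predictor"].to_numpy()
        acc = tbl["accuracy"].to_numpy()
        bins = np.quantile(lp, np.linspace(0, 1, 9))
        for lo, hi in zip(bins, bins[1:]):
            sel = (lp >= lo) & (lp < hi)
            if sel.sum() < 200:
                continue
            expected = (1 / (1 + np.exp(-lp[sel]))).mean()
            se = np.sqrt(expected * (1 - expected) / sel.sum())
            assert acc[sel].mean() == pytest.approx(expected, abs=4 * se + 0.01)

    def test_seed_determinism(self):
        a = simulate_behavior_dataset(5, 20, 3, "paper", seed=9)
        b = simulate_behavior_dataset(5, 20, 3, "paper", seed=9)
        assert a.equals(b)

    def test_negative_re_sd_rejected(self):
        import pandas as pd

        wt = pd.DataFrame(
            {"sentence_id": [0, 0], "word_index": [0, 1], "audibility": [0.0, 1.0],
             "surprisal": [0.0, 1.0], "td_condition": [0.0, 0.0]}
        )
        with pytest.raises(ValueError):
            simulate_behavior(wt, "paper", re_sd=(-1.0, 1.0))


class TestStaircase:
    def test_step_sizes_decay_geometrically(self):
        listener = PsychometricListener(srt_true=-8.0, slope=np.inf)
        srt, trace = simulate_staircase(listener, seed=0, return_trace=True)
        # step after k reversals = 6 * 0.85^k
        steps = np.unique(trace["steps"])[::-1]
        k = len(trace["reversal_levels"])
        expected = 6.0 * 0.85 ** np.arange(k + 1)
        got = sorted(set(np.round(trace["steps"], 10)), reverse=True)
        np.testing.assert_allclose(got, expected[: len(got)], rtol=1e-9)

    def test_deterministic_listener_recovers_srt(self):
        # brute-force trace: with a step-function listener the staircase
        # brackets the true 50% point within the final step size
        listener = PsychometricListener(srt_true=-8.16, slope=np.inf)
        srt, trace = simulate_staircase(listener, seed=1, return_trace=True)
        final_step = trace["steps"][-1]
        assert abs(srt - listener.srt_true) <= final_step

    def test_steep_slope_mean_estimate_near_midpoint(self):
        listener = PsychometricListener(srt_true=-5.0, slope=8.0)
        ests = [simulate_staircase(listener, seed=s) for s in range(40)]
        assert np.mean(ests) == pytest.approx(-5.0, abs=0.5)

    def test_invalid_step_factor(self):
        with pytest.raises(ValueError):
            simulate_staircase(PsychometricListener(0.0, 1.0), step_factor=1.5)

    def test_nonconvergence_warns(self):
        listener = PsychometricListener(srt_true=0.0, slope=np.inf)
        with pytest.warns(UserWarning, match="turning points"):
            simulate_staircase(listener, start_td=500.0, max_trials=5, seed=0)
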