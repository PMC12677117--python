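"""Synthetic two-talker stimuli, EEG, behavior, and staircase.

Everything downstream assumes the statistical structure generated
here: two overlapping sentence streams (the to-be-attended target and
a to-be-ignored distractor that starts 0.5 s earlier and outlasts the
target), spectrogram/envelope representations whose per-word level
difference realizes the trial's target-to-distractor ratio (T/D),
EEG built by convolving ground-truth kernels with the stimulus
features plus band-limited 1/f noise, word-level comprehension
accuracies drawn from a logistic model with crossed random intercepts,
and a 1-down/1-up adaptive staircase estimating the 50% speech
reception threshold.

Synthetic "audio" is generated directly as spectrograms and envelopes;
no waveform is synthesized, because the analysis consumes features,
not sound.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .acoustic import ANALYSIS_RATE, ContinuousSeries, FeatureMatrix, Interval, Spectrogram
from .dataset import EEGDataset
from .lexicon import Lexicon
from .trf import lag_samples, DEFAULT_LAG_RANGE_MS

__all__ = [
    "TD_CONDITIONS_DB",
    "CONTROL_TD_DB",
    "PAPER_COEFFS",
    "PAPER_RE_SD",
    "StimulusTrial",
    "StimulusSet",
    "GroundTruthKernels",
    "PsychometricListener",
    "simulate_stimuli",
    "make_ground_truth_kernels",
    "simulate_eeg",
    "pink_noise",
    "simulate_behavior",
    "simulate_behavior_dataset",
    "simulate_staircase",
]

#: T/D conditions relative to the individual SRT; 10 dB is the control
TD_CONDITIONS_DB = (-2.0, -1.0, 0.0, 1.0, 2.0, 10.0)
CONTROL_TD_DB = 10.0

#: Fixed-effect preset for the behavioral generator: the published
#: log-odds coefficients of the comprehension model on standardized
#: predictors (intercept unpublished, set to 1.0).
PAPER_COEFFS: dict[str, float] = {
    "intercept": 1.0,
    "audibility": 0.39,
    "surprisal": -0.39,
    "audibility:surprisal": 0.12,
    "fit_acoustic_target": -0.03,
    "fit_onsets_target": 0.07,
    "fit_word_linguistic_target": 0.06,
    "fit_phoneme_linguistic_target": 0.03,
    "fit_acoustic_distractor": 0.05,
    "fit_onsets_distractor": -0.02,
    "fit_word_linguistic_distractor": -0.04,
    "fit_phoneme_linguistic_distractor": 0.00,
    "td_condition": 0.49,
    "word_frequency": -0.07,
    "word_order": -0.07,
    "sentence_length": -0.15,
    "control_accuracy": 0.21,
    "srt": 0.28,
}

#: Random-intercept SDs (subject, sentence) back-derived from the
#: published variance-explained figures (15.9% fixed-only vs 50.8%
#: total on the latent logistic scale), split equally between the two
#: crossed intercepts.
PAPER_RE_SD: tuple[float, float] = (1.0803, 1.0803)


# ---------------------------------------------------------------------------
# stimuli


@dataclass
class StimulusTrial:
    """One two-talker trial on a common clock (0 = distractor onset)."""

    trial_id: int
    td_db: float
    is_control: bool
    target_tokens: list[str]
    distractor_tokens: list[str]
    target_words: list[Interval]
    distractor_words: list[Interval]
    target_phonemes: list[list[Interval]]  # nested per word
    distractor_phonemes: list[list[Interval]]
    target_spec: Spectrogram
    distractor_spec: Spectrogram
    f0_target: ContinuousSeries
    f0_distractor: ContinuousSeries

    @property
    def target_onset(self) -> float:
        return self.target_words[0].onset

    @property
    def target_offset(self) -> float:
        return self.target_words[-1].offset

    @property
    def span(self) -> float:
        return self.distractor_words[-1].offset

    def envelope(self, stream: str) -> ContinuousSeries:
        spec = self.target_spec if stream == "target" else self.distractor_spec
        return ContinuousSeries(spec.levels.mean(axis=0), spec.frame_rate, "envelope", stream)


@dataclass
class StimulusSet:
    trials: list[StimulusTrial]
    lexicon: Lexicon
    seed: int

    def __len__(self) -> int:
        return len(self.trials)


def _draw_sentence(
    rng: np.random.Generator,
    lexicon: Lexicon,
    n_words: int,
    duration_range: tuple[float, float],
    mean_word_s: float,
    start: float,
    min_duration: float = 0.0,
) -> tuple[list[str], list[Interval], list[list[Interval]]]:
    freqs = np.array([e.frequency for e in lexicon.entries])
    p = freqs / freqs.sum()
    idx = rng.choice(len(lexicon.entries), size=n_words, p=p)
    tokens = [lexicon.entries[i].word for i in idx]
    durs = rng.lognormal(np.log(mean_word_s), 0.25, n_words)
    lo, hi = duration_range
    lo = max(lo, min_duration)
    total = durs.sum()
    if total < lo:
        durs *= lo / total
    elif total > hi:
        durs *= hi / total
    words, phon_nested = [], []
    t = start
    for tok, d in zip(tokens, durs):
        words.append(Interval(tok, t, t + d))
        n_ph = len(lexicon[tok].phonemes)
        parts = rng.lognormal(0.0, 0.2, n_ph)
        parts = parts / parts.sum() * d
        edges = t + np.concatenate([[0.0], np.cumsum(parts)])
        phon_nested.append(
            [
                Interval(ph, edges[i], edges[i + 1])
                for i, ph in enumerate(lexicon[tok].phonemes)
            ]
        )
        t += d
    return tokens, words, phon_nested


def _smooth_noise(rng: np.random.Generator, shape: tuple[int, int], sigma_t: float) -> np.ndarray:
    """Temporally smoothed Gaussian field (simple moving-average blur)."""
    x = rng.standard_normal(shape)
    k = max(int(sigma_t), 1)
    kernel = np.hanning(2 * k + 1)
    kernel /= kernel.sum()
    return np.apply_along_axis(lambda v: np.convolve(v, kernel, mode="same"), 1, x)


def _stream_spectrogram(
    rng: np.random.Generator,
    words: list[Interval],
    span: float,
    base_level_db: float,
    word_jitter_db: float,
    n_bands: int,
    frame_rate: float,
    floor_db: float = -40.0,
) -> Spectrogram:
    n_frames = int(round(span * frame_rate))
    t = np.arange(n_frames) / frame_rate
    levels = np.full((n_bands, n_frames), floor_db)
    band_idx = np.arange(n_bands)
    formant_center = rng.uniform(0.25, 0.75) * n_bands
    band_profile = 6.0 * np.exp(-0.5 * ((band_idx - formant_center) / (0.25 * n_bands)) ** 2)
    for iv in words:
        sel = (t >= iv.onset) & (t < iv.offset)
        if not sel.any():
            continue
        jitter = rng.normal(0.0, word_jitter_db)
        # raised-cosine temporal envelope over the word
        phase = (t[sel] - iv.onset) / max(iv.offset - iv.onset, 1e-6)
        temporal = 3.0 * np.sin(np.pi * phase)
        levels[:, sel] = (
            base_level_db + jitter + temporal[None, :] + band_profile[:, None]
        )
    levels += 1.0 * _smooth_noise(rng, levels.shape, frame_rate * 0.05)
    centers = np.geomspace(80.0, 8000.0, n_bands)
    return Spectrogram(levels, centers, frame_rate, "dB")


def _f0_track(
    rng: np.random.Generator,
    base_hz: float,
    onset: float,
    offset: float,
    span: float,
    frame_rate: float,
) -> ContinuousSeries:
    n = int(round(span * frame_rate))
    t = np.arange(n) / frame_rate
    f0 = base_hz + 8.0 * np.sin(2 * np.pi * 0.7 * t + rng.uniform(0, 2 * np.pi))
    f0 += np.cumsum(rng.normal(0, 0.3, n))  # slow drift
    voiced = (t >= onset) & (t < offset)
    return ContinuousSeries(np.where(voiced, f0, 0.0), frame_rate, "f0")


def simulate_stimuli(
    lexicon: Lexicon,
    n_trials: int = 240,
    td_conditions: tuple[float, ...] = TD_CONDITIONS_DB,
    word_jitter_db: float = 2.0,
    n_bands: int = 32,
    frame_rate: float = ANALYSIS_RATE,
    head_start_s: float = 0.5,
    min_tail_s: float = 0.3,
    seed: int = 0,
) -> StimulusSet:
    """Generate a two-talker stimulus set.

    Target sentences have 5-7 words and last 2-4 s; distractor
    sentences have 7-10 words, last 3-5 s, start ``head_start_s``
    before the target and outlast it by at least ``min_tail_s``. T/D
    conditions cycle through ``td_conditions`` (balanced); the 10 dB
    condition is flagged as the control condition and excluded from the
    main fits downstream. Per-word stream levels differ by the trial's
    T/D plus Gaussian word-level jitter (``word_jitter_db`` SD),
    emulating moment-to-moment masking fluctuation.
    """
    if not td_conditions:
        raise ValueError("td_conditions must be non-empty")
    rng = np.random.default_rng(seed)
    trials = []
    td_cycle = np.tile(td_conditions, int(np.ceil(n_trials / len(td_conditions))))[:n_trials]
    rng.shuffle(td_cycle)
    for i in range(n_trials):
        td = float(td_cycle[i])
        n_tw = int(rng.integers(5, 8))
        t_tokens, t_words, t_phon = _draw_sentence(
            rng, lexicon, n_tw, (2.0, 4.0), 0.45, start=head_start_s
        )
        target_dur = t_words[-1].offset - t_words[0].onset
        n_dw = int(rng.integers(7, 11))
        d_tokens, d_words, d_phon = _draw_sentence(
            rng,
            lexicon,
            n_dw,
            (3.0, 5.0),
            0.42,
            start=0.0,
            min_duration=head_start_s + target_dur + min_tail_s,
        )
        span = d_words[-1].offset
        t_spec = _stream_spectrogram(rng, t_words, span, td, word_jitter_db, n_bands, frame_rate)
        d_spec = _stream_spectrogram(rng, d_words, span, 0.0, word_jitter_db, n_bands, frame_rate)
        f0_t = _f0_track(rng, 120.0, t_words[0].onset, t_words[-1].offset, span, frame_rate)
        f0_d = _f0_track(rng, 210.0, 0.0, span, span, frame_rate)
        trials.append(
            StimulusTrial(
                trial_id=i,
                td_db=td,
                is_control=(td == CONTROL_TD_DB),
                target_tokens=t_tokens,
                distractor_tokens=d_tokens,
                target_words=t_words,
                distractor_words=d_words,
                target_phonemes=t_phon,
                distractor_phonemes=d_phon,
                target_spec=t_spec,
                distractor_spec=d_spec,
                f0_target=f0_t,
                f0_distractor=f0_d,
            )
        )
    return StimulusSet(trials, lexicon, seed)


# ---------------------------------------------------------------------------
# EEG forward model


@dataclass
class GroundTruthKernels:
    """Known forward-model kernels for recovery tests."""

    kernels: np.ndarray  # (n_lags, n_predictors, n_channels)
    predictor_names: list[str]
    lag_range_ms: tuple[float, float]
    sampling_rate: float

    def __post_init__(self):
        self.kernels = np.asarray(self.kernels, float)
        lags = lag_samples(self.lag_range_ms, self.sampling_rate)
        if self.kernels.shape[0] != lags.size:
            raise ValueError("kernel lag axis does not match the lag grid")
        if self.kernels.shape[1] != len(self.predictor_names):
            raise ValueError("kernel predictor axis mismatch")
        if not np.all(np.isfinite(self.kernels)):
            raise ValueError("kernels must be finite")

    @property
    def lags(self) -> np.ndarray:
        return lag_samples(self.lag_range_ms, self.sampling_rate)


def make_ground_truth_kernels(
    predictor_names: list[str],
    n_channels: int,
    lag_range_ms: tuple[float, float] = DEFAULT_LAG_RANGE_MS,
    rate: float = ANALYSIS_RATE,
    scale: float | dict[str, float] = 1.0,
    seed: int = 0,
) -> GroundTruthKernels:
    """Smooth Gabor-shaped kernels with random channel topographies.

    Kernel energy is concentrated at positive (causal) lags 50-400 ms.
    ``scale`` may be a per-predictor dict to silence some predictors
    (scale 0) in null simulations.
    """
    rng = np.random.default_rng(seed)
    lags = lag_samples(lag_range_ms, rate)
    tau = lags / rate
    P = len(predictor_names)
    K = np.zeros((lags.size, P, n_channels))
    for p, name in enumerate(predictor_names):
        s = scale[name] if isinstance(scale, dict) else scale
        if s == 0:
            continue
        for _ in range(2):
            t0 = rng.uniform(0.05, 0.4)
            width = rng.uniform(0.03, 0.12)
            freq = rng.uniform(1.0, 4.0)
            shape = np.exp(-0.5 * ((tau - t0) / width) ** 2) * np.cos(
                2 * np.pi * freq * (tau - t0)
            )
            topo = rng.standard_normal(n_channels)
            topo /= np.abs(topo).max()
            K[:, p, :] += s * np.outer(shape, topo)
    return GroundTruthKernels(K, list(predictor_names), tuple(lag_range_ms), rate)


def pink_noise(
    n_samples: int,
    n_channels: int,
    rate: float,
    exponent: float = 1.0,
    band: tuple[float, float] = (0.5, 15.0),
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Band-limited 1/f^exponent noise with unit sample SD per channel.

    Generated in the frequency domain and restricted to ``band`` to
    mirror the band-pass applied to real recordings.
    """
    rng = np.random.default_rng() if rng is None else rng
    freqs = np.fft.rfftfreq(n_samples, 1.0 / rate)
    amp = np.zeros_like(freqs)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    amp[sel] = freqs[sel] ** (-exponent / 2.0)
    spec = amp[None, :] * (
        rng.standard_normal((n_channels, freqs.size))
        + 1j * rng.standard_normal((n_channels, freqs.size))
    )
    x = np.fft.irfft(spec, n=n_samples, axis=1)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _convolve_features(features: FeatureMatrix, kernels: GroundTruthKernels) -> np.ndarray:
    """Direct convolution of features with kernels (independent of the
    lagged-design construction used by the estimator)."""
    if features.names != kernels.predictor_names:
        raise ValueError("feature columns do not match kernel predictors")
    T = features.n_samples
    lags = kernels.lags
    l0 = int(lags[0])
    C = kernels.kernels.shape[2]
    out = np.zeros((C, T))
    for p in range(len(features.names)):
        f = features.data[:, p]
        for c in range(C):
            full = np.convolve(f, kernels.kernels[:, p, c])
            # full[m] = sum_j f[m-j] k[j]; response[t] = full[t - l0]
            idx = np.arange(T) - l0
            valid = (idx >= 0) & (idx < full.size)
            out[c, valid] += full[idx[valid]]
    return out


def simulate_eeg(
    features: dict[int, FeatureMatrix],
    kernels: GroundTruthKernels,
    noise_sd: float = 1.0,
    noise_exponent: float = 1.0,
    n_channels: int | None = None,
    condition_labels: dict[int, str] | None = None,
    participant: str = "sim01",
    ch_names: list[str] | None = None,
    positions: np.ndarray | None = None,
    seed: int = 0,
) -> EEGDataset:
    """EEG epochs from the forward model: feature * kernel + 1/f noise.

    ``features`` maps trial id to the epoch-spanning feature matrix
    (target-sentence onset to offset). With ``noise_sd=0`` the output is
    exactly the convolution of features and kernels.
    """
    rng = np.random.default_rng(seed)
    C = kernels.kernels.shape[2] if n_channels is None else n_channels
    if kernels.kernels.shape[2] != C:
        raise ValueError("n_channels does not match the kernels")
    if ch_names is None:
        ch_names = [f"CH{i:02d}" for i in range(C)]
    epochs, tids, labels = [], [], []
    for tid, fm in features.items():
        clean = _convolve_features(fm, kernels)
        if noise_sd > 0:
            clean = clean + noise_sd * pink_noise(
                clean.shape[1], C, fm.sfreq, noise_exponent, rng=rng
            )
        epochs.append(clean)
        tids.append(tid)
        if condition_labels is not None:
            labels.append(condition_labels[tid])
        else:
            labels.append("correct" if rng.random() < 0.5 else "incorrect")
    return EEGDataset(
        participant,
        epochs,
        tids,
        ch_names,
        kernels.sampling_rate,
        labels,
        positions,
    )


# ---------------------------------------------------------------------------
# behavior


def simulate_behavior(
    word_table: pd.DataFrame,
    coeffs: dict[str, float] | str = "paper",
    re_sd: tuple[float, float] = PAPER_RE_SD,
    n_subjects: int = 40,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw word-level accuracies from the logistic mixed model.

    ``word_table`` has one row per (sentence_id, word_index) with the
    word-level predictor columns; every subject is crossed with every
    sentence. Accuracy is Bernoulli(logit^-1(X beta + u_subject +
    u_sentence)) with independent Gaussian random intercepts. Predictor
    columns named in ``coeffs`` that are missing from ``word_table``
    (e.g. the standardized TRF fit columns, or subject-level controls)
    are drawn as standard normals at the appropriate level.
    """
    if isinstance(coeffs, str):
        if coeffs != "paper":
            raise ValueError(f"unknown preset {coeffs!r}")
        coeffs = PAPER_COEFFS
    required = {"intercept", "audibility", "surprisal", "audibility:surprisal", "td_condition"}
    if not required <= set(coeffs):
        raise ValueError(f"coeffs must include {sorted(required)}")
    if re_sd[0] < 0 or re_sd[1] < 0:
        raise ValueError("random-effect SDs must be >= 0")
    rng = np.random.default_rng(seed)
    word_table = word_table.reset_index(drop=True)
    sent_ids = word_table["sentence_id"].to_numpy()
    uniq_sent = np.unique(sent_ids)
    n_sent = uniq_sent.size

    subject_level = {"control_accuracy", "srt"}
    trial_wise = [k for k in coeffs if k.startswith("fit_")]

    rows = []
    u_subj = rng.normal(0, re_sd[0], n_subjects)
    u_sent = rng.normal(0, re_sd[1], n_sent)
    sent_pos = {s: i for i, s in enumerate(uniq_sent)}
    for s in range(n_subjects):
        df = word_table.copy()
        df.insert(0, "subject", f"S{s:03d}")
        for name in subject_level & set(coeffs):
            if name not in df.columns:
                df[name] = rng.standard_normal()
        # trial-wise standardized fits vary per (subject, sentence)
        fit_draws = {
            name: rng.standard_normal(n_sent) for name in trial_wise if name not in df.columns
        }
        for name, draws in fit_draws.items():
            df[name] = draws[[sent_pos[x] for x in df["sentence_id"]]]
        rows.append(df)
    table = pd.concat(rows, ignore_index=True)

    lp = np.full(len(table), coeffs["intercept"], float)
    for name, beta in coeffs.items():
        if name == "intercept" or beta == 0:
            continue
        if name == "audibility:surprisal":
            x = table["audibility"].to_numpy() * table["surprisal"].to_numpy()
        else:
            if name not in table.columns:
                table[name] = 0.0
            x = table[name].to_numpy(float)
        lp += beta * x
    subj_idx = table["subject"].str.slice(1).astype(int).to_numpy()
    lp += u_subj[subj_idx] + u_sent[[sent_pos[x] for x in table["sentence_id"]]]
    table["linear_predictor"] = lp
    table["accuracy"] = (rng.random(len(table)) < 1.0 / (1.0 + np.exp(-lp))).astype(int)
    return table


def simulate_behavior_dataset(
    n_subjects: int = 40,
    n_sentences: int = 200,
    words_per_sentence: int = 4,
    coeffs: dict[str, float] | str = "paper",
    re_sd: tuple[float, float] = PAPER_RE_SD,
    seed: int = 0,
) -> pd.DataFrame:
    """Self-contained behavioral dataset at recovery-harness scale.

    Word-level predictors (audibility, surprisal, frequency, order,
    sentence length) are drawn standardized; the T/D condition is drawn
    from the five experimental levels and standardized. One row per
    (subject, sentence, scored word).
    """
    rng = np.random.default_rng(seed)
    n_rows = n_sentences * words_per_sentence
    sent = np.repeat(np.arange(n_sentences), words_per_sentence)
    td_levels = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
    td_sent = rng.choice(td_levels, n_sentences)
    td = (td_sent - td_sent.mean()) / td_sent.std()
    slen_sent = rng.integers(5, 8, n_sentences).astype(float)
    slen = (slen_sent - slen_sent.mean()) / slen_sent.std()
    word_order = np.tile(np.arange(words_per_sentence, dtype=float), n_sentences)
    word_order = (word_order - word_order.mean()) / word_order.std()
    tbl = pd.DataFrame(
        {
            "sentence_id": sent,
            "word_index": np.tile(np.arange(words_per_sentence), n_sentences),
            "audibility": rng.standard_normal(n_rows),
            "surprisal": rng.standard_normal(n_rows),
            "word_frequency": rng.standard_normal(n_rows),
            "word_order": word_order,
            "sentence_length": slen[sent],
            "td_condition": td[sent],
        }
    )
    return simulate_behavior(tbl, coeffs, re_sd, n_subjects, seed=seed + 1)


# ---------------------------------------------------------------------------
# adaptive staircase


@dataclass
class PsychometricListener:
    """Logistic listener: P(correct | td) = logit^-1(slope * (td - srt))."""

    srt_true: float
    slope: float = 2.0

    def __post_init__(self):
        if self.slope <= 0:
            raise ValueError("slope must be > 0")

    def respond(self, td: float, rng: np.random.Generator) -> bool:
        if np.isinf(self.slope):
            return td > self.srt_true
        p = 1.0 / (1.0 + np.exp(-self.slope * (td - self.srt_true)))
        return bool(rng.random() < p)


def simulate_staircase(
    listener: PsychometricListener,
    start_td: float = 5.0,
    start_step: float = 6.0,
    step_factor: float = 0.85,
    n_turnpoints_for_srt: int = 5,
    n_turnpoints_total: int = 14,
    max_trials: int = 60,
    seed: int = 0,
    return_trace: bool = False,
):
    """1-down/1-up adaptive SRT estimation.

    T/D decreases after a fully-correct response and increases after
    any error; the step size shrinks geometrically by ``step_factor``
    after every turning point. The SRT estimate is the mean of the T/D
    ratios presented at the final ``n_turnpoints_for_srt`` turning
    points. If ``max_trials`` is reached first, a warning is emitted
    and the best available estimate returned.
    """
    if not 0 < step_factor < 1:
        raise ValueError("step_factor must be in (0, 1)")
    rng = np.random.default_rng(seed)
    td = float(start_td)
    step = float(start_step)
    levels: list[float] = []
    reversal_levels: list[float] = []
    step_trace: list[float] = []
    prev_dir = 0
    for _ in range(max_trials):
        levels.append(td)
        step_trace.append(step)
        correct = listener.respond(td, rng)
        direction = -1 if correct else 1
        if prev_dir != 0 and direction != prev_dir:
            reversal_levels.append(td)
            step *= step_factor
            if len(reversal_levels) >= n_turnpoints_total:
                prev_dir = direction
                break
        prev_dir = direction
        td += direction * step
    else:
        warnings.warn(
            f"staircase did not reach {n_turnpoints_total} turning points "
            f"within {max_trials} trials; using available reversals",
            stacklevel=2,
        )
    tail = reversal_levels[-n_turnpoints_for_srt:]
    if not tail:
        tail = levels[-n_turnpoints_for_srt:]
    srt = float(np.mean(tail))
    if return_trace:
        return srt, {
            "levels": np.array(levels),
            "reversal_levels": np.array(reversal_levels),
            "steps": np.array(step_trace),
        }
    return srt
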