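"""Acoustic predictors for lagged encoding models.

Auditory-style spectrograms (log-spaced constant-Q filterbank with
compressive nonlinearity), broadband envelopes, half-wave-rectified
envelope derivatives ("acoustic onsets"), and word/phoneme onset
impulse trains, assembled into min-max normalized feature matrices at
the analysis rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "ANALYSIS_RATE",
    "Spectrogram",
    "EventStream",
    "ContinuousSeries",
    "FeatureMatrix",
    "Interval",
    "compute_spectrogram",
    "compute_envelope",
    "compute_acoustic_onsets",
    "make_onset_trains",
    "assemble_feature_matrix",
    "assemble_trials",
    "event_index",
]

#: EEG/feature analysis sampling rate in Hz
ANALYSIS_RATE = 128.0


@dataclass(frozen=True)
class Interval:
    """One aligned unit (word or phoneme): ``[onset, offset)`` seconds."""

    label: str
    onset: float
    offset: float

    def __post_init__(self):
        if self.offset < self.onset:
            raise ValueError(f"interval {self.label!r} has negative duration")


@dataclass
class Spectrogram:
    """Band x frame auditory spectrogram.

    ``levels`` are on the scale named by ``scale``: ``"dB"`` or
    ``"compressed-power"`` (power raised to the compression exponent).
    """

    levels: np.ndarray  # (n_bands, n_frames)
    center_frequencies: np.ndarray  # Hz, ascending
    frame_rate: float
    scale: str = "dB"
    compression: float = 0.3

    def __post_init__(self):
        self.levels = np.asarray(self.levels, float)
        self.center_frequencies = np.asarray(self.center_frequencies, float)
        if self.levels.shape[0] != self.center_frequencies.size:
            raise ValueError("band count mismatch")
        if np.any(np.diff(self.center_frequencies) <= 0):
            raise ValueError("bands must be ordered by frequency")

    @property
    def n_frames(self) -> int:
        return self.levels.shape[1]

    def to_db(self) -> "Spectrogram":
        """Return a dB-scale view (10*log10 of the underlying power)."""
        if self.scale == "dB":
            return self
        with np.errstate(divide="ignore"):
            db = (10.0 / self.compression) * np.log10(self.levels)
        db = np.where(np.isfinite(db), db, -200.0)
        return Spectrogram(db, self.center_frequencies, self.frame_rate, "dB", self.compression)


@dataclass
class EventStream:
    """Timestamped impulses for one predictor of one stream."""

    times: np.ndarray  # seconds, strictly increasing
    values: np.ndarray  # per-event magnitudes
    label: str
    stream: str = "target"  # target | distractor

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        self.values = np.asarray(self.values, float)
        if self.times.shape != self.values.shape:
            raise ValueError("times/values length mismatch")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError(f"{self.label}: event times must be strictly increasing")
        if self.times.size and not np.all(np.isfinite(self.values)):
            raise ValueError(f"{self.label}: event values must be finite")

    def __len__(self) -> int:
        return self.times.size


@dataclass
class ContinuousSeries:
    """A regularly sampled predictor time series (e.g. an envelope)."""

    values: np.ndarray
    sfreq: float
    label: str
    stream: str = "target"

    def __post_init__(self):
        self.values = np.asarray(self.values, float)


@dataclass
class FeatureMatrix:
    """Time x predictor matrix at the analysis rate.

    ``normalization`` records the per-predictor (min, max) actually
    applied; after normalization all values lie in [0, 1].
    """

    data: np.ndarray  # (n_samples, n_predictors)
    names: list[str]
    sfreq: float
    normalization: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, float))
        if self.data.shape[1] != len(self.names):
            raise ValueError("column/name count mismatch")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate predictor names")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.data[:, self.names.index(name)]


def _constant_q_bank(freqs: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Triangular constant-Q weights (bands x fft bins), unit row sums."""
    bank = np.zeros((centers.size, freqs.size))
    for b, fc in enumerate(centers):
        bw = fc / 4.0  # Q = 4 half-bandwidth
        w = np.clip(1.0 - np.abs(freqs - fc) / bw, 0.0, None)
        s = w.sum()
        if s > 0:
            bank[b] = w / s
    return bank


def compute_spectrogram(
    audio: np.ndarray,
    rate: float,
    n_bands: int = 128,
    f_range: tuple[float, float] = (80.0, 8000.0),
    compression: float = 0.3,
    frame_rate: float = ANALYSIS_RATE,
) -> Spectrogram:
    """Auditory spectrogram of a waveform.

    STFT power is pooled into ``n_bands`` logarithmically spaced
    constant-Q bands and passed through a power-law compressive
    nonlinearity (exponent ``compression``) standing in for hair-cell
    transduction, then linearly interpolated to ``frame_rate``.
    """
    audio = np.asarray(audio, float)
    if audio.size == 0:
        raise ValueError("empty audio")
    lo, hi = f_range
    if hi > rate / 2:
        raise ValueError("f_range exceeds Nyquist")
    nper = max(int(round(rate * 0.025)), 16)
    hop = max(int(round(rate / max(frame_rate, 100.0))), 1)
    f, t, Z = sps.stft(audio, fs=rate, nperseg=nper, noverlap=nper - hop, boundary=None)
    power = np.abs(Z) ** 2
    centers = np.geomspace(lo, hi, n_bands)
    bank = _constant_q_bank(f, centers)
    band_power = bank @ power
    floor = 1e-12
    compressed = np.maximum(band_power, floor) ** compression
    # resample frames to the analysis rate
    n_out = max(int(round(audio.size / rate * frame_rate)), 1)
    t_out = np.arange(n_out) / frame_rate
    levels = np.empty((n_bands, n_out))
    for b in range(n_bands):
        levels[b] = np.interp(t_out, t, compressed[b])
    return Spectrogram(levels, centers, frame_rate, "compressed-power", compression)


def compute_envelope(spec: Spectrogram, subtract_floor: bool = False) -> ContinuousSeries:
    """Broadband envelope: the mean across all spectrogram channels."""
    env = spec.levels.mean(axis=0)
    if subtract_floor:
        env = env - env.min()
    return ContinuousSeries(env, spec.frame_rate, "envelope")


def compute_acoustic_onsets(envelope: np.ndarray | ContinuousSeries, rate: float | None = None) -> ContinuousSeries:
    """Half-wave rectified derivative of the envelope.

    ``o[t] = max(0, (e[t] - e[t-1]) * rate)``; the first sample is 0.
    """
    if isinstance(envelope, ContinuousSeries):
        values, rate, stream = envelope.values, envelope.sfreq, envelope.stream
    else:
        values = np.asarray(envelope, float)
        stream = "target"
        if rate is None:
            raise ValueError("rate required for a bare array")
    if values.size < 2:
        raise ValueError("envelope must have at least 2 samples")
    d = np.diff(values) * rate
    out = np.concatenate([[0.0], np.maximum(d, 0.0)])
    return ContinuousSeries(out, rate, "acoustic_onsets", stream)


def _validate_tier(intervals: list[Interval], name: str) -> None:
    for a, b in zip(intervals, intervals[1:]):
        if b.onset < a.offset - 1e-9:
            raise ValueError(f"overlapping intervals in {name} tier at {b.onset:.3f}s")


def make_onset_trains(
    words: list[Interval],
    phonemes: list[Interval],
    stream: str = "target",
    sentence_span: tuple[float, float] | None = None,
) -> dict[str, EventStream]:
    """Unit-impulse onset trains for words and phonemes.

    The sentence-initial onset (the first word onset, coincident with
    the first phoneme onset) is moved to a separate ``initial_onset``
    predictor so the evoked sentence-onset response does not contaminate
    the word/phoneme onset kernels. Word-initial phonemes otherwise
    remain in the phoneme train — the linguistic exclusion of
    word-initial phonemes applies to valued linguistic events only.
    """
    words = sorted(words, key=lambda iv: iv.onset)
    phonemes = sorted(phonemes, key=lambda iv: iv.onset)
    _validate_tier(words, "word")
    _validate_tier(phonemes, "phoneme")
    if sentence_span is not None:
        t0, t1 = sentence_span
        for iv in list(words) + list(phonemes):
            if iv.onset < t0 - 1e-9 or iv.offset > t1 + 1e-9:
                raise ValueError(f"interval {iv.label!r} outside sentence span")
    out: dict[str, EventStream] = {}
    if words:
        first = words[0].onset
        out["initial_onset"] = EventStream(np.array([first]), np.array([1.0]), "initial_onset", stream)
        rest = np.array([iv.onset for iv in words[1:]])
        out["word_onsets"] = EventStream(rest, np.ones(rest.size), "word_onsets", stream)
        ph = np.array([iv.onset for iv in phonemes if abs(iv.onset - first) > 1e-9])
        out["phoneme_onsets"] = EventStream(ph, np.ones(ph.size), "phoneme_onsets", stream)
    else:
        out["initial_onset"] = EventStream(np.array([]), np.array([]), "initial_onset", stream)
        out["word_onsets"] = EventStream(np.array([]), np.array([]), "word_onsets", stream)
        ph = np.array([iv.onset for iv in phonemes])
        out["phoneme_onsets"] = EventStream(ph, np.ones(ph.size), "phoneme_onsets", stream)
    return out


def event_index(time_s: float, rate: float) -> int:
    """Sample index for an event: round to nearest, ties up."""
    return int(np.floor(time_s * rate + 0.5))


def _rasterize(stream: EventStream, rate: float, n_samples: int) -> np.ndarray:
    col = np.zeros(n_samples)
    for t, v in zip(stream.times, stream.values):
        i = event_index(t, rate)
        if 0 <= i < n_samples:
            col[i] += v
    return col


def _resample_series(series: ContinuousSeries, rate: float, n_samples: int) -> np.ndarray:
    t_out = np.arange(n_samples) / rate
    t_in = np.arange(series.values.size) / series.sfreq
    if series.values.size == 0:
        return np.zeros(n_samples)
    return np.interp(t_out, t_in, series.values)


def _minmax(col: np.ndarray, bounds: tuple[float, float] | None) -> tuple[np.ndarray, tuple[float, float]]:
    if bounds is None:
        bounds = (float(col.min()), float(col.max()))
    lo, hi = bounds
    if hi <= lo:
        return np.zeros_like(col), (lo, hi)  # constant column convention
    return np.clip((col - lo) / (hi - lo), 0.0, 1.0), (lo, hi)


def assemble_feature_matrix(
    items: dict[str, EventStream | ContinuousSeries],
    rate: float = ANALYSIS_RATE,
    span: float | None = None,
    normalization: str | dict[str, tuple[float, float]] | None = "per_trial",
) -> FeatureMatrix:
    """Rasterize/resample predictors onto a shared time base.

    Event streams become impulse columns (impulses scaled by event
    values); continuous series are linearly interpolated to ``rate``.
    Min-max normalization maps every column into [0, 1]; ``normalization``
    may be ``"per_trial"``, ``None``, or an explicit per-predictor
    ``{name: (min, max)}`` dict (the *global* scope, computed across a
    stimulus set by :func:`assemble_trials`). Constant columns map to 0.
    """
    if span is None:
        ends = []
        for it in items.values():
            if isinstance(it, EventStream):
                if len(it):
                    ends.append(it.times.max() + 1.0 / rate)
            else:
                ends.append(it.values.size / it.sfreq)
        span = max(ends) if ends else 1.0 / rate
    n_samples = max(int(round(span * rate)), 1)
    names = list(items)
    cols, norm = [], {}
    for name in names:
        it = items[name]
        raw = (
            _rasterize(it, rate, n_samples)
            if isinstance(it, EventStream)
            else _resample_series(it, rate, n_samples)
        )
        if normalization is None:
            cols.append(raw)
            continue
        bounds = None if normalization == "per_trial" else normalization.get(name)
        scaled, used = _minmax(raw, bounds)
        cols.append(scaled)
        norm[name] = used
    return FeatureMatrix(np.column_stack(cols), names, rate, norm)


def assemble_trials(
    trial_items: list[dict[str, EventStream | ContinuousSeries]],
    rate: float = ANALYSIS_RATE,
    spans: list[float] | None = None,
    scope: str = "global",
) -> list[FeatureMatrix]:
    """Assemble per-trial feature matrices with a shared normalization.

    With ``scope="global"`` (the default) the min-max bounds for each
    predictor are computed across all trials, keeping magnitudes
    comparable across the stimulus set; ``scope="per_trial"`` normalizes
    each trial independently.
    """
    if spans is None:
        spans = [None] * len(trial_items)
    if scope == "per_trial":
        return [
            assemble_feature_matrix(it, rate, sp, "per_trial")
            for it, sp in zip(trial_items, spans)
        ]
    if scope != "global":
        raise ValueError("scope must be 'global' or 'per_trial'")
    raw = [
        assemble_feature_matrix(it, rate, sp, None)
        for it, sp in zip(trial_items, spans)
    ]
    names = raw[0].names
    for fm in raw:
        if fm.names != names:
            raise ValueError("trials must share predictor names for global scope")
    bounds = {
        name: (
            float(min(fm.column(name).min() for fm in raw)),
            float(max(fm.column(name).max() for fm in raw)),
        )
        for name in names
    }
    return [
        assemble_feature_matrix(it, rate, sp, bounds)
        for it, sp in zip(trial_items, spans)
    ]
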