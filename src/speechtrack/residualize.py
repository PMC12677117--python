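"""Acoustic/nuisance residualization of EEG.

Higher-level linguistic predictors covary strongly with acoustics, so
linguistic encoding models are fitted on *residualized* EEG: a nuisance
TRF (envelope, acoustic onsets, word/phoneme/initial onsets, F0 track,
and constant speaker-characteristic regressors placed at word onsets,
per stream) is fitted on all trials without cross-validation, its
predictions are subtracted from the observed EEG, and all linguistic
analyses run on the difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .acoustic import EventStream, FeatureMatrix
from .dataset import EEGDataset
from .trf import DEFAULT_LAG_RANGE_MS, TRFResults, TemporalResponseModel

__all__ = ["NuisanceSpec", "speaker_characteristic_streams", "fit_nuisance_trf", "residualize_eeg"]


@dataclass
class NuisanceSpec:
    """Which predictors the nuisance model removes, and how."""

    predictors: list[str] = field(
        default_factory=lambda: [
            "envelope",
            "acoustic_onsets",
            "word_onsets",
            "phoneme_onsets",
            "initial_onset",
            "f0",
        ]
    )
    alpha: float = 0.1
    lag_range_ms: tuple[float, float] = DEFAULT_LAG_RANGE_MS

    def __post_init__(self):
        if len(set(self.predictors)) != len(self.predictors):
            raise ValueError("nuisance predictor names must be unique")


def speaker_characteristic_streams(
    word_onsets: np.ndarray | list[float],
    ratings: dict[str, float],
    stream: str,
) -> dict[str, EventStream]:
    """Constant speaker-rating regressors at each word onset.

    Each perceptual characteristic that differs between the talkers
    (e.g. age, dominance, attractiveness) becomes one regressor per
    stream holding the speaker's mean rating at every word onset.
    """
    t = np.asarray(word_onsets, float)
    return {
        f"speaker_{name}_{stream}": EventStream(
            t, np.full(t.size, float(val)), f"speaker_{name}_{stream}", stream
        )
        for name, val in ratings.items()
    }


def fit_nuisance_trf(
    features: dict[int, FeatureMatrix],
    eeg: EEGDataset | dict[str, EEGDataset],
    alpha: float = 0.1,
    lag_range_ms: tuple[float, float] = DEFAULT_LAG_RANGE_MS,
) -> TRFResults:
    """One ridge TRF over all trials (and participants), no CV."""
    datasets = {eeg.participant: eeg} if isinstance(eeg, EEGDataset) else eeg
    fms, resps = [], []
    for ds in datasets.values():
        for tid, ep in zip(ds.trial_ids, ds.epochs):
            fms.append(features[tid])
            resps.append(ep)
    res = TemporalResponseModel(resps, fms, lag_range_ms).fit(alpha)
    res.variant = "nuisance"
    return res


def residualize_eeg(
    eeg: EEGDataset,
    model: TRFResults,
    features: dict[int, FeatureMatrix],
) -> EEGDataset:
    """Observed minus nuisance-predicted EEG, per trial and channel."""
    residuals = []
    for tid, ep in zip(eeg.trial_ids, eeg.epochs):
        pred = model.predict(features[tid])
        T = min(ep.shape[1], pred.shape[1])
        if pred.shape[0] != ep.shape[0]:
            raise ValueError("channel count mismatch between model and EEG")
        residuals.append(ep[:, :T] - pred[:, :T])
    return EEGDataset(
        eeg.participant,
        residuals,
        list(eeg.trial_ids),
        eeg.ch_names,
        eeg.sfreq,
        list(eeg.condition_labels),
        eeg.positions,
        residualized=True,
    )
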