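"""Epoched EEG container and array serialization.

EEG enters the encoding analysis as per-trial epochs spanning the
target sentence (onset to offset), at the analysis rate, with channel
names and sensor positions carried along for cluster statistics.
Serialization is a ``.npz`` archive of the arrays plus a JSON sidecar
for the metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["EEGDataset", "save_eeg", "load_eeg"]


@dataclass
class EEGDataset:
    """Per-participant epoched EEG (trial x channel x sample).

    Epochs may differ in length across trials (sentences differ in
    duration), so they are stored as a list of 2-D arrays. Each trial
    carries a condition label (``correct`` / ``incorrect`` / ``control``)
    and a stimulus id linking it to its feature matrices.
    """

    participant: str
    epochs: list[np.ndarray]  # each (n_channels, n_samples)
    trial_ids: list[int]
    ch_names: list[str]
    sfreq: float
    condition_labels: list[str]
    positions: np.ndarray | None = None  # (n_channels, 2 or 3)
    residualized: bool = False

    def __post_init__(self):
        self.epochs = [np.atleast_2d(np.asarray(e, float)) for e in self.epochs]
        n_ch = len(self.ch_names)
        for e in self.epochs:
            if e.shape[0] != n_ch:
                raise ValueError("epoch channel count does not match ch_names")
        if not (len(self.epochs) == len(self.trial_ids) == len(self.condition_labels)):
            raise ValueError("epochs, trial_ids and condition_labels must align")
        if self.positions is not None:
            self.positions = np.asarray(self.positions, float)

    @property
    def n_trials(self) -> int:
        return len(self.epochs)

    @property
    def n_channels(self) -> int:
        return len(self.ch_names)

    def select(self, labels: set[str] | list[str]) -> "EEGDataset":
        """Subset trials by condition label."""
        keep = [i for i, lab in enumerate(self.condition_labels) if lab in set(labels)]
        return EEGDataset(
            self.participant,
            [self.epochs[i] for i in keep],
            [self.trial_ids[i] for i in keep],
            self.ch_names,
            self.sfreq,
            [self.condition_labels[i] for i in keep],
            self.positions,
            self.residualized,
        )


def save_eeg(ds: EEGDataset, path: str | Path) -> None:
    """Write a dataset as ``<path>.npz`` + ``<path>.json`` sidecar."""
    path = Path(path)
    arrays = {f"epoch_{i}": e for i, e in enumerate(ds.epochs)}
    if ds.positions is not None:
        arrays["positions"] = ds.positions
    np.savez_compressed(path.with_suffix(".npz"), **arrays)
    meta = {
        "participant": ds.participant,
        "trial_ids": list(map(int, ds.trial_ids)),
        "ch_names": ds.ch_names,
        "sfreq": ds.sfreq,
        "condition_labels": ds.condition_labels,
        "residualized": ds.residualized,
        "n_trials": ds.n_trials,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_eeg(path: str | Path) -> EEGDataset:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    with np.load(path.with_suffix(".npz")) as arc:
        epochs = [arc[f"epoch_{i}"] for i in range(meta["n_trials"])]
        positions = arc["positions"] if "positions" in arc.files else None
    return EEGDataset(
        meta["participant"],
        epochs,
        meta["trial_ids"],
        meta["ch_names"],
        meta["sfreq"],
        meta["condition_labels"],
        positions,
        meta["residualized"],
    )
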