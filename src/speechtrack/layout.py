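"""Sensor layout: positions, adjacency graph, and ROI candidates.

Cluster-based sensor statistics need a neighbor relation between
channels; it is built from Delaunay triangulation of the 2-D projected
sensor positions (or from an explicit edge list for full
reproducibility). Candidate regions of interest are name-defined
electrode sets for the standard 63-channel 10-20 layout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "STANDARD_63",
    "DEFAULT_CLUSTERS",
    "standard_positions",
    "ChannelGraph",
    "delaunay_adjacency",
]

#: 63 scalp electrodes of the extended 10-20 layout (mastoids excluded)
STANDARD_63 = [
    "Fp1", "Fpz", "Fp2",
    "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8",
    "O1", "Oz", "O2",
    "P9", "P10",
]

#: candidate ROI clusters (declared order breaks ties)
DEFAULT_CLUSTERS: dict[str, list[str]] = {
    "frontocentral": [
        "F1", "Fz", "F2", "FC1", "FCz", "FC2", "C1", "Cz", "C2", "F3", "F4", "FC3", "FC4",
    ],
    "temporal": [
        "FT7", "T7", "TP7", "C5", "CP5", "FT8", "T8", "TP8", "C6", "CP6",
    ],
    "centroparietal": [
        "CP1", "CPz", "CP2", "P1", "Pz", "P2", "CP3", "CP4", "P3", "P4", "POz",
    ],
}


def standard_positions(ch_names: list[str] | None = None) -> tuple[list[str], np.ndarray]:
    """2-D projected sensor positions from the standard 10-20 montage."""
    import mne

    try:
        montage = mne.channels.make_standard_montage("colin27_1005")
    except ValueError:  # older mne releases use the previous name
        montage = mne.channels.make_standard_montage("standard_1005")
    pos3 = montage.get_positions()["ch_pos"]
    names = STANDARD_63 if ch_names is None else ch_names
    missing = [n for n in names if n not in pos3]
    if missing:
        raise KeyError(f"channels not in montage: {missing}")
    xyz = np.array([pos3[n] for n in names])
    # azimuthal-style projection to 2-D: x stays lateral, y anterior
    return list(names), xyz[:, :2]


@dataclass
class ChannelGraph:
    """Symmetric channel neighbor relation without self-edges."""

    ch_names: list[str]
    edges: list[tuple[int, int]]

    def __post_init__(self):
        clean = set()
        for a, b in self.edges:
            if a == b:
                raise ValueError("self-edges are not allowed")
            clean.add((min(a, b), max(a, b)))
        self.edges = sorted(clean)

    @property
    def n_channels(self) -> int:
        return len(self.ch_names)

    def neighbors(self) -> list[list[int]]:
        adj: list[list[int]] = [[] for _ in self.ch_names]
        for a, b in self.edges:
            adj[a].append(b)
            adj[b].append(a)
        return adj

    @classmethod
    def from_positions(cls, ch_names: list[str], positions: np.ndarray) -> "ChannelGraph":
        return cls(ch_names, delaunay_adjacency(np.asarray(positions, float)))

    @classmethod
    def standard(cls) -> "ChannelGraph":
        names, pos = standard_positions()
        return cls.from_positions(names, pos)


def delaunay_adjacency(positions: np.ndarray) -> list[tuple[int, int]]:
    """Delaunay-neighbor edges from 2-D sensor positions."""
    from scipy.spatial import Delaunay

    if positions.shape[1] != 2:
        positions = positions[:, :2]
    tri = Delaunay(positions)
    edges = set()
    for simplex in tri.simplices:
        for i in range(3):
            a, b = int(simplex[i]), int(simplex[(i + 1) % 3])
            edges.add((min(a, b), max(a, b)))
    return sorted(edges)
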