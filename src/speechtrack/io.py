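"""Readers and writers for the pipeline's on-disk formats.

Word/phoneme alignments arrive as Praat TextGrids (long format) or
plain TSV (``tier<TAB>label<TAB>onset_s<TAB>offset_s``); audio as WAV;
feature matrices and fitted scores as ``.npz`` archives with JSON
sidecars. Lexicon TSV round-trips live on :class:`~speechtrack.lexicon.Lexicon`.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np

from .acoustic import FeatureMatrix, Interval

__all__ = [
    "load_alignment",
    "write_alignment_tsv",
    "read_textgrid",
    "read_wav",
    "save_feature_matrix",
    "load_feature_matrix",
]


def _validate_tiers(tiers: dict[str, list[Interval]], source: str) -> dict[str, list[Interval]]:
    for name, ivs in tiers.items():
        ivs.sort(key=lambda iv: iv.onset)
        for iv in ivs:
            if iv.onset < 0:
                raise ValueError(f"{source}: negative time in tier {name!r} ({iv.label!r})")
        for a, b in zip(ivs, ivs[1:]):
            if b.onset < a.offset - 1e-9:
                raise ValueError(
                    f"{source}: overlapping intervals in tier {name!r} at {b.onset:.3f}s"
                )
    return tiers


def load_alignment(path: str | Path) -> dict[str, list[Interval]]:
    """Load word/phoneme interval tiers from TextGrid or TSV."""
    path = Path(path)
    if path.suffix.lower() == ".textgrid":
        return read_textgrid(path)
    tiers: dict[str, list[Interval]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 tab-separated fields")
            tier, label, onset, offset = parts
            if lineno == 1 and tier.lower() == "tier":
                continue  # header row
            try:
                iv = Interval(label, float(onset), float(offset))
            except ValueError as err:
                raise ValueError(f"{path}:{lineno}: {err}") from None
            tiers.setdefault(tier, []).append(iv)
    return _validate_tiers(tiers, str(path))


def write_alignment_tsv(tiers: dict[str, list[Interval]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("tier\tlabel\tonset_s\toffset_s\n")
        for name, ivs in tiers.items():
            for iv in ivs:
                fh.write(f"{name}\t{iv.label}\t{iv.onset:.10g}\t{iv.offset:.10g}\n")


_TG_FLOAT = re.compile(r"(xmin|xmax)\s*=\s*([-\d.eE+]+)")
_TG_TEXT = re.compile(r'text\s*=\s*"(.*)"')
_TG_NAME = re.compile(r'name\s*=\s*"(.*)"')


def read_textgrid(path: str | Path) -> dict[str, list[Interval]]:
    """Minimal long-format Praat TextGrid reader (interval tiers only).

    Empty-text intervals (silences) are skipped.
    """
    tiers: dict[str, list[Interval]] = {}
    current: str | None = None
    xmin = xmax = None
    in_item = False
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            s = line.strip()
            if s.startswith("item ["):
                in_item = True
                current = None
                continue
            m = _TG_NAME.search(s)
            if m and in_item:
                current = m.group(1)
                tiers.setdefault(current, [])
                continue
            m = _TG_FLOAT.search(s)
            if m and current is not None:
                if m.group(1) == "xmin":
                    xmin = float(m.group(2))
                else:
                    xmax = float(m.group(2))
                continue
            m = _TG_TEXT.search(s)
            if m and current is not None:
                text = m.group(1).strip()
                if text:
                    if xmin is None or xmax is None:
                        raise ValueError(f"{path}:{lineno}: text before interval bounds")
                    tiers[current].append(Interval(text, xmin, xmax))
                xmin = xmax = None
    if not tiers:
        raise ValueError(f"{path}: no interval tiers found")
    return _validate_tiers(tiers, str(path))


def read_wav(path: str | Path) -> tuple[np.ndarray, float]:
    """Read a WAV file as float64 mono in [-1, 1]."""
    from scipy.io import wavfile

    rate, data = wavfile.read(path)
    data = np.asarray(data)
    if data.ndim == 2:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data / float(np.iinfo(data.dtype).max)
    return data.astype(float), float(rate)


def save_feature_matrix(fm: FeatureMatrix, path: str | Path) -> None:
    path = Path(path)
    np.savez_compressed(path.with_suffix(".npz"), data=fm.data)
    meta = {
        "names": fm.names,
        "sfreq": fm.sfreq,
        "normalization": {k: list(v) for k, v in fm.normalization.items()},
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_feature_matrix(path: str | Path) -> FeatureMatrix:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    with np.load(path.with_suffix(".npz")) as arc:
        data = arc["data"]
    return FeatureMatrix(
        data,
        meta["names"],
        meta["sfreq"],
        {k: tuple(v) for k, v in meta["normalization"].items()},
    )
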