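"""Glimpse-rate word audibility and audibility-split model evaluation.

In competing speech the masking of the target fluctuates moment to
moment; "glimpses" are spectrotemporal cells where the target's local
level exceeds the distractor's by more than a threshold. The glimpse
rate of a word — the fraction of (band, frame) cells in its interval
that are glimpsed at the -5 dB local T/D threshold — is a word-level
audibility proxy. The combined audibility score adds the trial's T/D
condition to the standardized glimpse rate. Splitting evaluation
samples at the median combined audibility (within condition) probes
whether encoding-model fits depend on speech clarity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .acoustic import Interval, Spectrogram
from .trf import score as _score

__all__ = [
    "GLIMPSE_THRESHOLD_DB",
    "GlimpseMap",
    "glimpse_rate",
    "combined_audibility",
    "split_fit_by_audibility",
    "compare_audibility_halves",
]

#: local T/D threshold above which a spectrotemporal cell is "glimpsed"
GLIMPSE_THRESHOLD_DB = -5.0


@dataclass
class GlimpseMap:
    """Per (trial, word) glimpse rates with the threshold used."""

    table: pd.DataFrame  # columns: trial, word_index, glimpse_rate [, combined_audibility]
    threshold_db: float


def glimpse_rate(
    target_spec: Spectrogram,
    distractor_spec: Spectrogram,
    word_intervals: list[Interval],
    threshold_db: float = GLIMPSE_THRESHOLD_DB,
    trial: int = 0,
) -> GlimpseMap:
    """Fraction of glimpsed cells per target word.

    A cell (band, frame) inside a word's interval counts as glimpsed
    when ``target_dB - distractor_dB > threshold_db``. All cells in the
    interval enter the denominator (no energy floor gate).
    """
    t_db = target_spec.to_db()
    d_db = distractor_spec.to_db()
    if t_db.levels.shape != d_db.levels.shape or t_db.frame_rate != d_db.frame_rate:
        raise ValueError("target and distractor spectrograms must share band/frame grids")
    diff = t_db.levels - d_db.levels
    t = np.arange(t_db.n_frames) / t_db.frame_rate
    rows = []
    for w, iv in enumerate(word_intervals):
        sel = (t >= iv.onset) & (t < iv.offset)
        if not sel.any():
            rows.append((trial, w, np.nan))
            continue
        cells = diff[:, sel]
        rows.append((trial, w, float((cells > threshold_db).mean())))
    table = pd.DataFrame(rows, columns=["trial", "word_index", "glimpse_rate"])
    return GlimpseMap(table, threshold_db)


def combined_audibility(glimpse: GlimpseMap, td_by_trial: dict[int, float]) -> GlimpseMap:
    """Standardized glimpse rate plus the trial's T/D condition.

    Glimpse rates are z-scored across *all* words of the map, then the
    T/D value of each word's trial is added. Zero variance in the
    glimpse rates yields z = 0 with a warning.
    """
    tbl = glimpse.table.copy()
    g = tbl["glimpse_rate"].to_numpy(float)
    sd = np.nanstd(g)
    if sd == 0:
        warnings.warn("glimpse rates have zero variance; z-scores set to 0", stacklevel=2)
        z = np.zeros_like(g)
    else:
        z = (g - np.nanmean(g)) / sd
    tbl["combined_audibility"] = z + tbl["trial"].map(td_by_trial).to_numpy(float)
    return GlimpseMap(tbl, glimpse.threshold_db)


def _word_sample_mask(iv: Interval, n_samples: int, rate: float) -> np.ndarray:
    a = int(np.floor(iv.onset * rate + 0.5))
    b = int(np.floor(iv.offset * rate + 0.5))
    m = np.zeros(n_samples, bool)
    m[max(a, 0) : min(b, n_samples)] = True
    return m


def split_fit_by_audibility(
    observed: dict[int, np.ndarray],
    predicted: dict[int, np.ndarray],
    scores: pd.DataFrame,
    condition_labels: dict[int, str],
    word_intervals: dict[int, list[Interval]],
    rate: float,
    cluster_idx: list[int] | None = None,
) -> pd.DataFrame:
    """Prediction correlations for high- vs low-audibility word segments.

    ``scores`` has columns (trial, word_index, combined_audibility).
    Within each condition (correct/incorrect), words are split at the
    median combined audibility (ties to the low half) so each half holds
    about half of the evaluated signal per condition; Pearson r between
    observed and cross-validated predicted EEG is computed per channel
    on each half's pooled samples. Returns one row per (condition,
    half) with the channel-wise r and its mean over ``cluster_idx``;
    feed per-participant results to :func:`compare_audibility_halves`
    for the paired tests.
    """
    halves: dict[tuple[str, str], list[tuple[int, np.ndarray]]] = {}
    for cond in set(condition_labels.values()):
        trials = [t for t, c in condition_labels.items() if c == cond]
        sub = scores[scores["trial"].isin(trials)].dropna(subset=["combined_audibility"])
        if sub.empty:
            raise ValueError(f"no scored words for condition {cond!r}")
        med = float(sub["combined_audibility"].median())
        low = sub[sub["combined_audibility"] <= med]
        high = sub[sub["combined_audibility"] > med]
        if low.empty or high.empty:
            raise ValueError(f"degenerate audibility split for condition {cond!r}")
        for name, part in (("low", low), ("high", high)):
            sel = []
            for t in trials:
                words = part[part["trial"] == t]["word_index"].to_numpy(int)
                if words.size == 0:
                    continue
                n = observed[t].shape[1]
                m = np.zeros(n, bool)
                for w in words:
                    m |= _word_sample_mask(word_intervals[t][w], n, rate)
                sel.append((t, m))
            halves[(cond, name)] = sel

    rows = []
    for (cond, half), sel in halves.items():
        obs = np.concatenate([observed[t][:, m] for t, m in sel], axis=1)
        pred = np.concatenate([predicted[t][:, m] for t, m in sel], axis=1)
        r = _score(pred, obs)
        val = float(r[cluster_idx].mean()) if cluster_idx is not None else float(r.mean())
        rows.append({"condition": cond, "half": half, "r_cluster": val, "r_channels": r})
    return pd.DataFrame(rows)


def compare_audibility_halves(per_participant: pd.DataFrame) -> pd.DataFrame:
    """Paired t-tests of high vs low audibility fits per condition.

    ``per_participant`` has columns (participant, condition, half,
    r_cluster) — one cluster-summarized fit per participant, condition
    and audibility half. Reports the uncorrected and BH-FDR corrected
    p-value per condition (the split analysis is exploratory, so both
    are given).
    """
    tests = []
    for cond, grp in per_participant.groupby("condition"):
        wide = grp.pivot(index="participant", columns="half", values="r_cluster")
        if not {"high", "low"} <= set(wide.columns):
            raise ValueError(f"missing half for condition {cond!r}")
        d = (wide["high"] - wide["low"]).dropna().to_numpy()
        if d.size < 3 or np.isclose(d.std(ddof=1), 0.0):
            raise ValueError(f"degenerate high/low differences for condition {cond!r}")
        t, p = stats.ttest_1samp(d, 0.0)
        tests.append({"condition": cond, "t": float(t), "df": d.size - 1, "p": float(p)})
    out = pd.DataFrame(tests)
    out["p_fdr"] = stats.false_discovery_control(out["p"], method="bh")
    return out
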