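"""Shuffling nulls, TFCE sensor statistics, ROI selection, paired tests.

Significance of encoding-model fits is assessed against feature
shuffles that keep model dimensionality constant: acoustic feature
groups are shuffled by permuting the trial pairing between features
and EEG; sparse linguistic features are shuffled more conservatively
by permuting event *values* globally across sentences while keeping
every onset in place. Subtracting mean shuffled fits from observed
fits yields per-participant deltas, tested channel-wise with
one-sample t-statistics enhanced by TFCE (threshold-free cluster
enhancement) and corrected via the max-TFCE sign-flip distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats

from .acoustic import EventStream, FeatureMatrix
from .layout import ChannelGraph
from .trf import FitScores

__all__ = [
    "FEATURE_GROUPS",
    "GROUP_MODES",
    "ShufflePlan",
    "shuffle_features",
    "shuffle_trial_labels",
    "shuffle_event_values",
    "null_distribution",
    "delta_fits",
    "tfce_scores",
    "tfce_test",
    "StatMap",
    "select_roi",
    "compare_conditions",
]

#: feature group -> features shuffled for that group's null
FEATURE_GROUPS: dict[str, list[str]] = {
    "acoustic": ["envelope", "acoustic_onsets"],
    "onsets": ["word_onsets", "phoneme_onsets"],
    "word_linguistic": ["word_surprisal", "word_frequency"],
    "phoneme_linguistic": ["phoneme_surprisal", "cohort_entropy"],
}

#: default shuffle mode per group (acoustic models: trial labels;
#: linguistic models: values with onsets preserved)
GROUP_MODES: dict[str, str] = {
    "acoustic": "trial_labels",
    "onsets": "trial_labels",
    "word_linguistic": "values_preserve_onsets",
    "phoneme_linguistic": "values_preserve_onsets",
}


@dataclass
class ShufflePlan:
    """How to build the null for one feature group.

    ``stream`` appends a stream suffix to the shuffled feature names
    (predictors are stream-specific columns, e.g. ``envelope_target``),
    so each group x stream combination gets its own null.
    """

    feature_group: str
    mode: str | None = None
    n_iterations: int = 50
    seed: int = 0
    stream: str | None = None
    shuffled_features: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.feature_group not in FEATURE_GROUPS and not self.shuffled_features:
            raise ValueError(f"unknown feature group {self.feature_group!r}")
        if not self.shuffled_features:
            self.shuffled_features = list(FEATURE_GROUPS[self.feature_group])
            if self.stream is not None:
                self.shuffled_features = [
                    f"{name}_{self.stream}" for name in self.shuffled_features
                ]
        if self.mode is None:
            self.mode = GROUP_MODES.get(self.feature_group, "trial_labels")
        if self.mode not in ("trial_labels", "values_preserve_onsets"):
            raise ValueError(f"unknown shuffle mode {self.mode!r}")

    def rng(self, iteration: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, iteration])


def shuffle_trial_labels(
    features: dict[int, FeatureMatrix],
    shuffled_names: list[str],
    rng: np.random.Generator,
) -> dict[int, FeatureMatrix]:
    """Permute which trial's group columns pair with which EEG trial.

    The shuffled columns of trial *t* are replaced by those of a
    permuted trial (truncated or zero-padded to t's length); all other
    predictors stay in place.
    """
    tids = list(features)
    perm = rng.permutation(len(tids))
    out = {}
    for i, tid in enumerate(tids):
        fm = features[tid]
        src = features[tids[perm[i]]]
        data = fm.data.copy()
        for name in shuffled_names:
            if name not in fm.names:
                continue
            col = src.column(name)
            n = min(col.size, data.shape[0])
            newcol = np.zeros(data.shape[0])
            newcol[:n] = col[:n]
            data[:, fm.names.index(name)] = newcol
        out[tid] = FeatureMatrix(data, list(fm.names), fm.sfreq, dict(fm.normalization))
    return out


def shuffle_event_values(
    trial_streams: dict[int, dict[str, EventStream]],
    shuffled_names: list[str],
    rng: np.random.Generator,
) -> dict[int, dict[str, EventStream]]:
    """Permute event values globally across sentences, onsets fixed.

    For each named feature independently, the values of all events
    pooled over trials are permuted and written back at the original
    onset times, retaining the value distribution exactly.
    """
    out = {tid: dict(items) for tid, items in trial_streams.items()}
    for name in shuffled_names:
        pool, index = [], []
        for tid, items in trial_streams.items():
            es = items.get(name)
            if es is None or not isinstance(es, EventStream):
                continue
            pool.append(es.values)
            index.append((tid, len(es)))
        if not pool:
            raise ValueError(f"feature {name!r} has no events to shuffle")
        values = np.concatenate(pool)
        perm = rng.permutation(values.size)
        shuffled = values[perm]
        pos = 0
        for tid, n in index:
            es = trial_streams[tid][name]
            out[tid][name] = EventStream(
                es.times.copy(), shuffled[pos : pos + n], es.label, es.stream
            )
            pos += n
    return out


def shuffle_features(features, plan: ShufflePlan, iteration: int):
    """Dispatch to the plan's shuffle mode, deterministic per
    (seed, iteration)."""
    rng = plan.rng(iteration)
    if plan.mode == "trial_labels":
        return shuffle_trial_labels(features, plan.shuffled_features, rng)
    return shuffle_event_values(features, plan.shuffled_features, rng)


def null_distribution(refit, features, plan: ShufflePlan) -> list[FitScores]:
    """Full refit + rescore per shuffle iteration.

    ``refit`` is a callable mapping a features object (same type as
    ``features``) to :class:`FitScores`, closing over the fixed lambda,
    folds and evaluation masks of the base analysis.
    """
    ensemble = []
    for it in range(plan.n_iterations):
        shuffled = shuffle_features(features, plan, it)
        try:
            ensemble.append(refit(shuffled))
        except Exception as err:
            raise RuntimeError(f"null refit failed at iteration {it}") from err
    return ensemble


def delta_fits(
    observed: FitScores,
    null: list[FitScores],
    variant: str,
) -> pd.DataFrame:
    """Observed minus mean-shuffled fits per participant x channel.

    Trial-wise scores are first averaged within participant (for the
    given variant), then the across-iteration mean of the null is
    subtracted.
    """
    obs = observed.mean_by_participant(variant)
    nulls = [fs.mean_by_participant(variant) for fs in null]
    for nm in nulls:
        if not nm.index.equals(obs.index):
            raise ValueError("null ensemble indexes participants differently")
    mean_null = sum(nm.to_numpy() for nm in nulls) / len(nulls)
    return pd.DataFrame(obs.to_numpy() - mean_null, index=obs.index, columns=obs.columns)


# ---------------------------------------------------------------------------
# TFCE


def tfce_scores(
    t_values: np.ndarray,
    graph: ChannelGraph,
    E: float = 0.5,
    H: float = 2.0,
    dh: float = 0.1,
) -> np.ndarray:
    """Threshold-free cluster enhancement of a channel |t| map.

    ``TFCE(c) = sum_h extent(c, h)^E * h^H * dh`` over the threshold
    grid ``h = dh, 2dh, ...`` up to max|t|, where extent is the size of
    the suprathreshold connected component containing *c* at height h.
    Implemented as a single descending sweep with union-find merging.
    """
    t_abs = np.abs(np.asarray(t_values, float))
    n = t_abs.size
    if n != graph.n_channels:
        raise ValueError("t map length does not match the graph")
    hmax = t_abs.max()
    if hmax <= 0:
        return np.zeros(n)
    n_steps = int(np.floor(hmax / dh + 1e-9))
    if n_steps == 0:
        return np.zeros(n)
    adj = graph.neighbors()
    parent = np.arange(n)
    size = np.ones(n, int)
    active = np.zeros(n, bool)

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra == rb:
            return
        if size[ra] < size[rb]:
            ra, rb = rb, ra
        parent[rb] = ra
        size[ra] += size[rb]

    scores = np.zeros(n)
    order = np.argsort(-t_abs)  # nodes activate in descending height
    ptr = 0
    for k in range(n_steps, 0, -1):
        h = k * dh
        while ptr < n and t_abs[order[ptr]] >= h - 1e-9:
            node = order[ptr]
            active[node] = True
            for nb in adj[node]:
                if active[nb]:
                    union(node, nb)
            ptr += 1
        if not active.any():
            continue
        roots = np.fromiter((find(i) for i in range(n)), int, n)
        extent = size[roots].astype(float)
        inc = np.where(active, extent**E * h**H * dh, 0.0)
        scores += inc
    return scores


@dataclass
class StatMap:
    """Channel-wise t values, TFCE scores, and corrected p-values."""

    frame: pd.DataFrame  # columns: channel, t, tfce, p
    alpha: float = 0.05
    tails: int = 2
    max_tfce_null: np.ndarray | None = None

    def significant(self) -> list[str]:
        return self.frame.loc[self.frame["p"] < self.alpha, "channel"].tolist()


def _t_one_sample(deltas: np.ndarray) -> np.ndarray:
    m = deltas.mean(axis=0)
    sd = deltas.std(axis=0, ddof=1)
    n = deltas.shape[0]
    zero = sd == 0
    if zero.any():
        warnings.warn("zero-variance channel; t set to 0", stacklevel=3)
    t = np.zeros_like(m)
    np.divide(m, sd / np.sqrt(n), out=t, where=~zero)
    return t


def tfce_test(
    deltas: np.ndarray | pd.DataFrame,
    graph: ChannelGraph,
    E: float = 0.5,
    H: float = 2.0,
    dh: float = 0.1,
    n_signflips: int | str = 1024,
    seed: int = 0,
    alpha: float = 0.05,
) -> StatMap:
    """Mass-univariate one-sample t-test with TFCE correction.

    ``deltas`` is participants x channels (observed minus mean-null
    fits). Two-tailed inference runs on |t|; corrected p-values come
    from the distribution of the maximum TFCE score under participant
    sign flips (``n_signflips`` random flips, or ``"all"`` for full
    enumeration on small samples, where the test is permutation-exact).
    """
    if isinstance(deltas, pd.DataFrame):
        ch_names = list(deltas.columns)
        deltas = deltas.to_numpy(float)
    else:
        deltas = np.asarray(deltas, float)
        ch_names = [f"CH{i:02d}" for i in range(deltas.shape[1])]
    P, C = deltas.shape
    if P < 2:
        raise ValueError("need at least 2 participants")
    t_obs = _t_one_sample(deltas)
    tfce_obs = tfce_scores(t_obs, graph, E, H, dh)

    sq_sum = (deltas**2).sum(axis=0)  # invariant under sign flips
    if n_signflips == "all":
        signs = np.array(list(product((1.0, -1.0), repeat=P)))
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice([1.0, -1.0], size=(int(n_signflips), P))
    means = signs @ deltas / P
    var = (sq_sum[None, :] - P * means**2) / (P - 1)
    var = np.maximum(var, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_null = np.where(var > 0, means / np.sqrt(var / P), 0.0)
    max_null = np.empty(signs.shape[0])
    for i in range(signs.shape[0]):
        max_null[i] = tfce_scores(t_null[i], graph, E, H, dh).max() if np.any(t_null[i]) else 0.0

    if n_signflips == "all":
        p = (max_null[None, :] >= tfce_obs[:, None]).mean(axis=1)
    else:
        p = (1.0 + (max_null[None, :] >= tfce_obs[:, None]).sum(axis=1)) / (
            1.0 + signs.shape[0]
        )
    frame = pd.DataFrame(
        {"channel": ch_names, "t": t_obs, "tfce": tfce_obs, "p": np.clip(p, 0.0, 1.0)}
    )
    return StatMap(frame, alpha=alpha, tails=2, max_tfce_null=max_null)


# ---------------------------------------------------------------------------
# ROI selection and condition comparison


def select_roi(
    control_fits: FitScores,
    candidate_clusters: dict[str, list[str]],
    variant: str | None = None,
) -> tuple[str, pd.DataFrame]:
    """Choose the candidate cluster with the highest mean control fit.

    Control-condition trials are held out from the main analysis; the
    cluster of sensors that predicts best there defines the ROI used
    for all condition comparisons, avoiding double dipping. Ties go to
    the first cluster in declared order, with a warning.
    """
    if not candidate_clusters:
        raise ValueError("no candidate clusters")
    sel = np.ones(len(control_fits.frame), bool)
    if variant is not None:
        sel = (control_fits.frame["variant"] == variant).to_numpy()
    rows = []
    for name, channels in candidate_clusters.items():
        if not channels:
            raise ValueError(f"cluster {name!r} is empty")
        idx = [control_fits.ch_names.index(c) for c in channels]
        rows.append((name, float(control_fits.scores[np.ix_(sel, idx)].mean())))
    table = pd.DataFrame(rows, columns=["cluster", "mean_fit"])
    best = table["mean_fit"].max()
    winners = table.loc[np.isclose(table["mean_fit"], best), "cluster"].tolist()
    if len(winners) > 1:
        warnings.warn(
            f"cluster tie between {winners}; keeping first declared", stacklevel=2
        )
    return winners[0], table


def compare_conditions(fits: pd.DataFrame) -> pd.DataFrame:
    """Paired t-tests of correct vs incorrect cluster-mean fits.

    ``fits`` has columns (feature, stream, participant, fit_correct,
    fit_incorrect). Per feature x stream: paired two-sided t (df =
    N - 1), BH-FDR corrected p across the table, and Cohen's d (mean
    difference / SD of differences). Degenerate inputs (N < 3, or a
    non-zero constant difference) are refused.
    """
    rows = []
    for (feature, stream_), grp in fits.groupby(["feature", "stream"]):
        d = (grp["fit_correct"] - grp["fit_incorrect"]).to_numpy(float)
        if d.size < 3:
            raise ValueError(f"{feature}/{stream_}: need at least 3 participants")
        sd = d.std(ddof=1)
        if sd <= 1e-12 * max(1.0, np.abs(d).max()):
            if np.allclose(d, 0):
                rows.append((feature, stream_, 0.0, d.size - 1, 1.0, 0.0))
                continue
            raise ValueError(
                f"{feature}/{stream_}: constant non-zero difference, t undefined"
            )
        t, p = stats.ttest_rel(grp["fit_correct"], grp["fit_incorrect"])
        rows.append((feature, stream_, float(t), d.size - 1, float(p), float(d.mean() / sd)))
    out = pd.DataFrame(rows, columns=["feature", "stream", "t", "df", "p", "cohens_d"])
    out["p_fdr"] = stats.false_discovery_control(out["p"], method="bh")
    return out
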