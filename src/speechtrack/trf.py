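"""Temporal response functions: ridge-regularized lagged regression.

A TRF is a linear kernel ``w(lag, predictor, channel)`` mapping
stimulus features to the EEG response: the prediction at time *t* sums
feature values at ``t - lag`` over all lags in the modelled window
(default -100..800 ms). Estimation is penalized least squares
(Tikhonov/ridge with an identity penalty scaled by the mean design
covariance), and model quality is the per-channel Pearson correlation
between predicted and observed EEG, optionally restricted to samples
near event onsets.

The model/results split follows the statsmodels convention:
:class:`TemporalResponseModel` holds data, :meth:`fit` returns
:class:`TRFResults` with the kernels and prediction methods.
:func:`crossval_fit` runs the cross-participant 80-20 scheme in which
models for correct and incorrect trials are trained across participants
and each trial is scored by models that never saw its participant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .acoustic import FeatureMatrix
from .dataset import EEGDataset

__all__ = [
    "DEFAULT_LAG_RANGE_MS",
    "ACOUSTIC_LAMBDA",
    "LINGUISTIC_LAMBDA",
    "lag_samples",
    "LagDesign",
    "build_lagged_design",
    "TemporalResponseModel",
    "TRFResults",
    "fit_trf",
    "predict",
    "score",
    "event_mask",
    "FoldPlan",
    "make_fold_plan",
    "FitScores",
    "crossval_fit",
    "tune_lambda",
]

DEFAULT_LAG_RANGE_MS = (-100.0, 800.0)
#: regularization presets fitted across participants and variants
ACOUSTIC_LAMBDA = 0.1
LINGUISTIC_LAMBDA = 1e-7


def lag_samples(lag_range_ms: tuple[float, float] = DEFAULT_LAG_RANGE_MS, rate: float = 128.0) -> np.ndarray:
    """Integer sample lags covering ``lag_range_ms`` at ``rate``.

    Edges are rounded to the nearest sample: (-100, 800) ms at 128 Hz
    gives lags -13..102, i.e. 116 lags per predictor.
    """
    lo = int(np.round(lag_range_ms[0] / 1000.0 * rate))
    hi = int(np.round(lag_range_ms[1] / 1000.0 * rate))
    if hi < lo:
        raise ValueError("empty lag range")
    return np.arange(lo, hi + 1)


@dataclass
class LagDesign:
    """Time x (predictor x lag) design matrix.

    Column ``(p, l)`` at row *t* holds feature *p* at ``t - l``
    (zero-padded outside the epoch). Columns are predictor-major.
    """

    matrix: np.ndarray
    lags: np.ndarray  # integer sample offsets
    predictor_names: list[str]
    sfreq: float

    @property
    def n_lags(self) -> int:
        return self.lags.size


def build_lagged_design(
    features: FeatureMatrix,
    lag_range_ms: tuple[float, float] = DEFAULT_LAG_RANGE_MS,
    rate: float | None = None,
) -> LagDesign:
    rate = features.sfreq if rate is None else rate
    if rate != features.sfreq:
        raise ValueError("rate must match the feature sampling rate")
    lags = lag_samples(lag_range_ms, rate)
    T, P = features.data.shape
    L = lags.size
    X = np.zeros((T, P * L))
    for p in range(P):
        col = features.data[:, p]
        for j, l in enumerate(lags):
            if abs(l) >= T:
                continue  # shift exceeds the epoch; column stays zero
            if l > 0:
                X[l:, p * L + j] = col[: T - l]
            elif l < 0:
                X[: T + l, p * L + j] = col[-l:]
            else:
                X[:, p * L + j] = col
    return LagDesign(X, lags, list(features.names), rate)


# ---------------------------------------------------------------------------
# model / results


class TemporalResponseModel:
    """Multivariate TRF encoding model for one response dataset.

    Parameters
    ----------
    response
        EEG as (n_channels, n_samples), or a list of per-trial arrays.
    features
        Matching :class:`FeatureMatrix` (or list of them, one per trial).
    lag_range_ms
        Kernel window relative to the feature sample.
    """

    def __init__(
        self,
        response: np.ndarray | list[np.ndarray],
        features: FeatureMatrix | list[FeatureMatrix],
        lag_range_ms: tuple[float, float] = DEFAULT_LAG_RANGE_MS,
    ):
        if isinstance(features, FeatureMatrix):
            features = [features]
            response = [np.atleast_2d(np.asarray(response, float))]
        else:
            response = [np.atleast_2d(np.asarray(r, float)) for r in response]
        names = features[0].names
        for fm in features:
            if fm.names != names:
                raise ValueError("all trials must share predictor names")
        self.features = features
        self.response = response
        self.lag_range_ms = tuple(lag_range_ms)
        self.sfreq = features[0].sfreq
        self.predictor_names = list(names)
        self.lags = lag_samples(lag_range_ms, self.sfreq)
        self.n_channels = response[0].shape[0]

    def _accumulate(self):
        K = len(self.predictor_names) * self.lags.size
        C = self.n_channels
        Sxx = np.zeros((K, K))
        Sxy = np.zeros((K, C))
        xsum = np.zeros(K)
        ysum = np.zeros(C)
        n = 0
        for fm, resp in zip(self.features, self.response):
            X = build_lagged_design(fm, self.lag_range_ms).matrix
            T = min(X.shape[0], resp.shape[1])
            X, Y = X[:T], resp[:, :T].T
            Sxx += X.T @ X
            Sxy += X.T @ Y
            xsum += X.sum(axis=0)
            ysum += Y.sum(axis=0)
            n += T
        return Sxx, Sxy, xsum, ysum, n

    def fit(self, alpha: float = ACOUSTIC_LAMBDA) -> "TRFResults":
        """Estimate kernels by scale-stabilized ridge regression.

        Solves ``(Xc'Xc + alpha * m * I) W = Xc'Yc`` on column-centered
        data, where ``m`` is the mean diagonal of ``Xc'Xc`` so that
        ``alpha`` is comparable across designs of different scale; the
        intercept is recovered from the means. ``alpha=0`` on a singular
        design falls back to the pseudo-inverse with a warning.
        """
        if alpha < 0:
            raise ValueError("alpha must be >= 0")
        Sxx, Sxy, xsum, ysum, n = self._accumulate()
        xm, ym = xsum / n, ysum / n
        XtXc = Sxx - n * np.outer(xm, xm)
        XtYc = Sxy - n * np.outer(xm, ym)
        m = float(np.mean(np.diag(XtXc)))
        A = XtXc + alpha * m * np.eye(XtXc.shape[0])
        try:
            W = np.linalg.solve(A, XtYc)
            if not np.all(np.isfinite(W)):
                raise np.linalg.LinAlgError
        except np.linalg.LinAlgError:
            warnings.warn("singular lagged design; using pseudo-inverse", stacklevel=2)
            W = np.linalg.pinv(A) @ XtYc
        intercept = ym - W.T @ xm
        return TRFResults(self, W, intercept, float(alpha))


@dataclass
class TRFResults:
    """Fitted TRF kernels plus prediction and scoring methods."""

    model: TemporalResponseModel
    weights: np.ndarray = field(repr=False)  # (P*L, C)
    intercept: np.ndarray = field(repr=False)  # (C,)
    alpha: float = 0.0
    variant: str = ""

    @property
    def kernels(self) -> np.ndarray:
        """Kernels as (n_lags, n_predictors, n_channels)."""
        L = self.model.lags.size
        P = len(self.model.predictor_names)
        return self.weights.reshape(P, L, -1).transpose(1, 0, 2)

    @property
    def lags_s(self) -> np.ndarray:
        return self.model.lags / self.model.sfreq

    def predict(self, features: FeatureMatrix) -> np.ndarray:
        """Predicted EEG (n_channels, n_samples) for one trial."""
        if features.names != self.model.predictor_names:
            raise ValueError("predictor names do not match the fitted model")
        X = build_lagged_design(features, self.model.lag_range_ms).matrix
        return (X @ self.weights + self.intercept).T

    def score(
        self,
        features: FeatureMatrix,
        observed: np.ndarray,
        mask: np.ndarray | None = None,
    ) -> np.ndarray:
        """Per-channel prediction correlation on one trial."""
        return score(self.predict(features), observed, mask)

    def plot_kernels(self, predictor: str, ax=None):
        """Plot the kernel of one predictor across channels."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        p = self.model.predictor_names.index(predictor)
        ax.plot(self.lags_s * 1000, self.kernels[:, p, :], lw=0.6)
        ax.set_xlabel("lag (ms)")
        ax.set_ylabel("kernel weight")
        ax.set_title(predictor)
        return ax


def fit_trf(
    features: FeatureMatrix | list[FeatureMatrix],
    response: np.ndarray | list[np.ndarray],
    alpha: float,
    lag_range_ms: tuple[float, float] = DEFAULT_LAG_RANGE_MS,
) -> TRFResults:
    """Functional wrapper: build the model and fit in one call."""
    return TemporalResponseModel(response, features, lag_range_ms).fit(alpha)


def predict(results: TRFResults, features: FeatureMatrix) -> np.ndarray:
    return results.predict(features)


def score(
    predicted: np.ndarray,
    observed: np.ndarray,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Per-channel Pearson r between predicted and observed EEG.

    ``mask`` selects the evaluated samples (event-constrained scoring).
    Zero-variance channels under the mask score 0 with a warning.
    """
    predicted = np.atleast_2d(np.asarray(predicted, float))
    observed = np.atleast_2d(np.asarray(observed, float))
    T = min(predicted.shape[1], observed.shape[1])
    predicted, observed = predicted[:, :T], observed[:, :T]
    if mask is not None:
        mask = np.asarray(mask, bool)[:T]
        if not mask.any():
            raise ValueError("empty evaluation mask")
        predicted, observed = predicted[:, mask], observed[:, mask]
    p = predicted - predicted.mean(axis=1, keepdims=True)
    o = observed - observed.mean(axis=1, keepdims=True)
    sp = np.sqrt((p**2).sum(axis=1))
    so = np.sqrt((o**2).sum(axis=1))
    bad = (sp == 0) | (so == 0)
    if bad.any():
        warnings.warn("zero-variance channel under mask; r set to 0", stacklevel=2)
    denom = np.where(bad, 1.0, sp * so)
    r = (p * o).sum(axis=1) / denom
    return np.where(bad, 0.0, np.clip(r, -1.0, 1.0))


def event_mask(
    event_times: np.ndarray | list[float],
    n_samples: int,
    rate: float = 128.0,
    window_s: tuple[float, float] = (0.0, 0.8),
) -> np.ndarray:
    """Boolean sample mask covering ``window_s`` after each event onset.

    Sparse (linguistic) models are evaluated only where events can
    plausibly drive the response: 0-800 ms after an event onset.
    """
    mask = np.zeros(n_samples, bool)
    for t in np.asarray(event_times, float):
        a = int(np.floor((t + window_s[0]) * rate + 0.5))
        b = int(np.floor((t + window_s[1]) * rate + 0.5))
        mask[max(a, 0) : min(b + 1, n_samples)] = True
    return mask


# ---------------------------------------------------------------------------
# cross-participant cross-validation


@dataclass
class FoldPlan:
    """Train/test participant splits for cross-participant validation."""

    folds: list[tuple[tuple, tuple]]
    seed: int | None = None

    def __post_init__(self):
        for train, test in self.folds:
            if set(train) & set(test):
                raise ValueError("train and test participants overlap")

    @property
    def n_folds(self) -> int:
        return len(self.folds)


def make_fold_plan(
    participants: list,
    n_folds: int = 50,
    test_size: int = 8,
    seed: int = 0,
) -> FoldPlan:
    """Random 80-20-style folds: ``test_size`` held-out participants per fold."""
    participants = list(participants)
    if len(participants) < test_size + 1:
        raise ValueError("need more participants than test_size")
    rng = np.random.default_rng(seed)
    if n_folds * test_size < len(participants):
        warnings.warn(
            "fewer test slots than participants; some participants will "
            "receive no scores",
            stacklevel=2,
        )
        folds = []
        for _ in range(n_folds):
            test = tuple(rng.choice(participants, size=test_size, replace=False))
            folds.append((tuple(p for p in participants if p not in set(test)), test))
        return FoldPlan(folds, seed)
    for attempt in range(1000):
        folds = []
        tested: set = set()
        for _ in range(n_folds):
            test = tuple(rng.choice(participants, size=test_size, replace=False))
            train = tuple(p for p in participants if p not in set(test))
            folds.append((train, test))
            tested.update(test)
        if tested == set(participants):
            if attempt:
                warnings.warn(
                    f"fold plan resampled {attempt} time(s) so every "
                    "participant is tested at least once",
                    stacklevel=2,
                )
            return FoldPlan(folds, seed)
    raise RuntimeError("could not cover all participants; increase n_folds or test_size")


@dataclass
class FitScores:
    """Per (participant, trial, variant) channel-wise prediction correlations.

    Scores are fold-averaged: each row is the mean r over the folds in
    which the trial's participant was held out.
    """

    frame: pd.DataFrame  # columns: participant, trial, variant, n_folds
    scores: np.ndarray  # (n_rows, n_channels)
    ch_names: list[str]

    def mean_by_participant(self, variant: str | None = None) -> pd.DataFrame:
        """Mean score per participant x channel (optionally one variant)."""
        sel = np.ones(len(self.frame), bool)
        if variant is not None:
            sel = (self.frame["variant"] == variant).to_numpy()
        df = pd.DataFrame(self.scores[sel], columns=self.ch_names)
        df["participant"] = self.frame.loc[sel, "participant"].to_numpy()
        return df.groupby("participant").mean()

    def cluster_mean(self, channels: list[str]) -> np.ndarray:
        idx = [self.ch_names.index(c) for c in channels]
        return self.scores[:, idx].mean(axis=1)

    def trialwise_z(self, channels: list[str] | None = None) -> pd.DataFrame:
        """Standardized trial-wise fits (z across trials within
        participant and variant), averaged over ``channels``."""
        vals = (
            self.cluster_mean(channels)
            if channels is not None
            else self.scores.mean(axis=1)
        )
        df = self.frame.copy()
        df["fit"] = vals

        def _z(x):
            s = x.std(ddof=0)
            return (x - x.mean()) / s if s > 0 else x * 0.0

        df["fit_z"] = df.groupby(["participant", "variant"])["fit"].transform(_z)
        return df


def crossval_fit(
    datasets: dict[str, EEGDataset],
    features: dict[int, FeatureMatrix],
    plan: FoldPlan,
    alpha: float,
    lag_range_ms: tuple[float, float] = DEFAULT_LAG_RANGE_MS,
    variants: tuple[str, ...] = ("correct", "incorrect"),
    masks: dict[int, np.ndarray] | None = None,
) -> FitScores:
    """Cross-participant TRF fitting and trial-wise scoring.

    Per fold, one model per variant is trained on the pooled trials of
    the train participants carrying that variant label, then every test
    participant's trials of that variant are scored channel-wise.
    Scores are averaged over the folds in which each trial was tested.
    """
    pids = list(datasets)
    any_ds = datasets[pids[0]]
    ch_names = any_ds.ch_names

    # per-trial design quantities, shared across participants
    design_cache: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}

    def _design(tid: int):
        if tid not in design_cache:
            X = build_lagged_design(features[tid], lag_range_ms).matrix
            design_cache[tid] = (X, X.T @ X, X.sum(axis=0))
        return design_cache[tid]

    # per (participant, variant) accumulated train-side statistics
    acc: dict[tuple[str, str], list] = {}
    trial_index: dict[tuple[str, str], list[int]] = {}
    for pid, ds in datasets.items():
        for k, (tid, lab) in enumerate(zip(ds.trial_ids, ds.condition_labels)):
            if lab not in variants:
                continue
            trial_index.setdefault((pid, lab), []).append(k)
            X, Sxx, xsum = _design(tid)
            Y = ds.epochs[k]
            T = min(X.shape[0], Y.shape[1])
            Yt = Y[:, :T].T
            Xt = X[:T]
            key = (pid, lab)
            if key not in acc:
                K, C = X.shape[1], len(ch_names)
                acc[key] = [np.zeros((K, K)), np.zeros((K, C)), np.zeros(K), np.zeros(C), 0]
            a = acc[key]
            if T == X.shape[0]:
                a[0] += Sxx
                a[2] += xsum
            else:
                a[0] += Xt.T @ Xt
                a[2] += Xt.sum(axis=0)
            a[1] += Xt.T @ Yt
            a[3] += Yt.sum(axis=0)
            a[4] += T

    for v in variants:
        for pid in pids:
            if (pid, v) not in acc:
                raise ValueError(f"participant {pid} has no {v!r} trials")

    # score accumulators
    rows: list[tuple[str, int, str]] = []
    row_of: dict[tuple[str, int, str], int] = {}
    sums: list[np.ndarray] = []
    counts: list[int] = []

    K = next(iter(design_cache.values()))[0].shape[1]
    C = len(ch_names)
    for train, test in plan.folds:
        for v in variants:
            Sxx = np.zeros((K, K))
            Sxy = np.zeros((K, C))
            xsum = np.zeros(K)
            ysum = np.zeros(C)
            n = 0
            for pid in train:
                a = acc[(pid, v)]
                Sxx += a[0]
                Sxy += a[1]
                xsum += a[2]
                ysum += a[3]
                n += a[4]
            xm, ym = xsum / n, ysum / n
            XtXc = Sxx - n * np.outer(xm, xm)
            XtYc = Sxy - n * np.outer(xm, ym)
            m = float(np.mean(np.diag(XtXc)))
            A = XtXc + alpha * m * np.eye(K)
            try:
                W = np.linalg.solve(A, XtYc)
            except np.linalg.LinAlgError:
                W = np.linalg.pinv(A) @ XtYc
            icpt = ym - W.T @ xm
            for pid in test:
                ds = datasets[pid]
                for k in trial_index.get((pid, v), []):
                    tid = ds.trial_ids[k]
                    X = _design(tid)[0]
                    Y = ds.epochs[k]
                    pred = (X @ W + icpt).T
                    msk = None if masks is None else masks.get(tid)
                    r = score(pred, Y, msk)
                    key = (pid, tid, v)
                    if key not in row_of:
                        row_of[key] = len(rows)
                        rows.append(key)
                        sums.append(np.zeros(C))
                        counts.append(0)
                    i = row_of[key]
                    sums[i] += r
                    counts[i] += 1

    frame = pd.DataFrame(rows, columns=["participant", "trial", "variant"])
    frame["n_folds"] = counts
    scores = np.array([s / c for s, c in zip(sums, counts)])
    return FitScores(frame, scores, list(ch_names))


def within_participant_scores(
    datasets: dict[str, EEGDataset],
    features: dict[int, FeatureMatrix],
    alpha: float,
    lag_range_ms: tuple[float, float] = DEFAULT_LAG_RANGE_MS,
    masks: dict[int, np.ndarray] | None = None,
    n_splits: int = 2,
) -> pd.DataFrame:
    """Trial-wise cross-validated scores with participant-specific models.

    Each participant's TRF is trained on their own trials only
    (``n_splits``-fold over trials) and scored on the held-out trials;
    the result is one mean score per participant x channel. Unlike the
    cross-participant scheme, the scores of different participants are
    statistically independent given the stimuli, which keeps
    participant-level sign-flip inference exact in small samples.
    """
    pids = list(datasets)
    ch_names = datasets[pids[0]].ch_names
    lags = lag_samples(lag_range_ms, datasets[pids[0]].sfreq)

    gram_cache: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}

    def _design(tid):
        if tid not in gram_cache:
            X = build_lagged_design(features[tid], lag_range_ms).matrix
            gram_cache[tid] = (X, X.T @ X, X.sum(axis=0))
        return gram_cache[tid]

    out = np.zeros((len(pids), len(ch_names)))
    for pi, pid in enumerate(pids):
        ds = datasets[pid]
        n_tr = ds.n_trials
        if n_tr < n_splits:
            raise ValueError(f"participant {pid} has fewer trials than splits")
        splits = [list(range(k, n_tr, n_splits)) for k in range(n_splits)]
        accum = np.zeros(len(ch_names))
        count = 0
        K = _design(ds.trial_ids[0])[0].shape[1]
        for held in range(n_splits):
            Sxx = np.zeros((K, K))
            Sxy = np.zeros((K, len(ch_names)))
            xsum = np.zeros(K)
            ysum = np.zeros(len(ch_names))
            n = 0
            for k in range(n_tr):
                if k in splits[held]:
                    continue
                X, G, xs = _design(ds.trial_ids[k])
                Y = ds.epochs[k]
                T = min(X.shape[0], Y.shape[1])
                Xt, Yt = X[:T], Y[:, :T].T
                if T == X.shape[0]:
                    Sxx += G
                    xsum += xs
                else:
                    Sxx += Xt.T @ Xt
                    xsum += Xt.sum(axis=0)
                Sxy += Xt.T @ Yt
                ysum += Yt.sum(axis=0)
                n += T
            xm, ym = xsum / n, ysum / n
            XtXc = Sxx - n * np.outer(xm, xm)
            XtYc = Sxy - n * np.outer(xm, ym)
            m = float(np.mean(np.diag(XtXc)))
            A = XtXc + alpha * m * np.eye(K)
            try:
                W = np.linalg.solve(A, XtYc)
            except np.linalg.LinAlgError:
                W = np.linalg.pinv(A) @ XtYc
            icpt = ym - W.T @ xm
            for k in splits[held]:
                tid = ds.trial_ids[k]
                X = _design(tid)[0]
                pred = (X @ W + icpt).T
                msk = None if masks is None else masks.get(tid)
                accum += score(pred, ds.epochs[k], msk)
                count += 1
        out[pi] = accum / count
    return pd.DataFrame(out, index=pids, columns=ch_names)


def tune_lambda(
    grid: list[float],
    datasets: dict[str, EEGDataset],
    features: dict[int, FeatureMatrix],
    plan: FoldPlan,
    **kwargs,
) -> float:
    """Select the single lambda maximizing the mean cross-validated
    score summed over model variants (shared across participants and
    variants, as the main analysis requires)."""
    if not grid:
        raise ValueError("empty lambda grid")
    best, best_val = None, -np.inf
    for lam in grid:
        fs = crossval_fit(datasets, features, plan, alpha=lam, **kwargs)
        val = float(fs.scores.mean())
        if val > best_val:
            best, best_val = lam, val
    return float(best)
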