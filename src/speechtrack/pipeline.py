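"""Orchestration: preprocessing, feature building, and the full run.

Ties the stages together on a reproducible footing: EEG preprocessing
(band-pass, mastoid re-reference, downsampling to the analysis rate,
epoching to the target sentence), assembly of stream-wise acoustic and
linguistic predictors from a stimulus set, the nuisance/residualize ->
fit -> shuffle-null -> audibility -> behavior chain, and a run manifest
recording seeds and output hashes. All randomness is drawn from named
per-stage seeds held in :class:`RunConfig`.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import inference, residualize as rez
from .acoustic import (
    ANALYSIS_RATE,
    ContinuousSeries,
    EventStream,
    FeatureMatrix,
    Interval,
    assemble_trials,
    compute_acoustic_onsets,
    make_onset_trains,
)
from .audibility import combined_audibility, glimpse_rate
from .behavior import fit_glmm
from .dataset import EEGDataset
from .lexicon import BigramProvider, linguistic_event_streams, make_lexicon
from .simulate import (
    CONTROL_TD_DB,
    StimulusSet,
    StimulusTrial,
    make_ground_truth_kernels,
    simulate_eeg,
    simulate_stimuli,
)
from .trf import (
    ACOUSTIC_LAMBDA,
    LINGUISTIC_LAMBDA,
    FitScores,
    crossval_fit,
    event_mask,
    make_fold_plan,
)

__all__ = [
    "ACOUSTIC_BASE",
    "LINGUISTIC_BASE",
    "SPEAKER_RATINGS",
    "preprocess_eeg",
    "trial_streams",
    "build_features",
    "reassemble_shuffled",
    "linguistic_masks",
    "RunConfig",
    "run_pipeline",
]

#: base predictor names; actual columns carry a stream suffix
ACOUSTIC_BASE = ["envelope", "acoustic_onsets", "word_onsets", "phoneme_onsets", "initial_onset"]
LINGUISTIC_BASE = ["word_surprisal", "word_frequency", "phoneme_surprisal", "cohort_entropy"]

#: speaker-characteristic ratings (consumed as constants; the three
#: characteristics on which the talkers differ perceptibly)
SPEAKER_RATINGS: dict[str, dict[str, float]] = {
    "age": {"target": 0.5, "distractor": -0.5},
    "dominance": {"target": 0.3, "distractor": -0.3},
    "attractiveness": {"target": -0.2, "distractor": 0.2},
}


# ---------------------------------------------------------------------------
# preprocessing


def preprocess_eeg(
    raw: np.ndarray,
    sfreq: float,
    ch_names: list[str],
    epochs: list[tuple[float, float]],
    band: tuple[float, float] = (0.5, 15.0),
    target_rate: float = ANALYSIS_RATE,
    reference_channels: tuple[str, ...] = ("A1", "A2"),
    condition_labels: list[str] | None = None,
    participant: str = "p01",
    positions: np.ndarray | None = None,
) -> EEGDataset:
    """Filter, re-reference, downsample, and epoch a continuous recording.

    Zero-phase band-pass (default 0.5-15 Hz), average-mastoid
    re-reference when the reference channels are present (they are then
    dropped), resampling to the analysis rate, and epoching to the
    target-sentence spans. Artifact correction (ICA, bad-channel
    interpolation) is assumed to have been done upstream on real data
    and is skipped for synthetic data.
    """
    import mne

    raw = np.atleast_2d(np.asarray(raw, float))
    if band[1] >= sfreq / 2:
        raise ValueError("band exceeds Nyquist")
    filt = mne.filter.filter_data(
        raw, sfreq, band[0], band[1], verbose="error", phase="zero"
    )
    refs = [c for c in reference_channels if c in ch_names]
    if refs:
        ridx = [ch_names.index(c) for c in refs]
        ref = filt[ridx].mean(axis=0)
        keep = [i for i, c in enumerate(ch_names) if c not in refs]
        filt = filt[keep] - ref
        ch_names = [ch_names[i] for i in keep]
        if positions is not None:
            positions = positions[keep]
    if target_rate != sfreq:
        filt = mne.filter.resample(filt, down=sfreq / target_rate, verbose="error")
    n = filt.shape[1]
    out_epochs = []
    for t0, t1 in epochs:
        a = int(round(t0 * target_rate))
        b = int(round(t1 * target_rate))
        if a < 0 or b > n or b <= a:
            raise ValueError(f"epoch ({t0}, {t1}) s outside the recording")
        out_epochs.append(filt[:, a:b].copy())
    labels = condition_labels if condition_labels is not None else ["correct"] * len(epochs)
    return EEGDataset(
        participant, out_epochs, list(range(len(out_epochs))), ch_names, target_rate, labels, positions
    )


# ---------------------------------------------------------------------------
# feature building


def _crop_events(es: EventStream, t0: float, span: float) -> EventStream:
    sel = (es.times >= t0 - 1e-9) & (es.times < t0 + span - 1e-9)
    return EventStream(es.times[sel] - t0, es.values[sel], es.label, es.stream)


def _crop_series(cs: ContinuousSeries, t0: float, span: float) -> ContinuousSeries:
    a = int(round(t0 * cs.sfreq))
    b = int(round((t0 + span) * cs.sfreq))
    return ContinuousSeries(cs.values[a:b], cs.sfreq, cs.label, cs.stream)


def trial_streams(
    trial: StimulusTrial,
    lexicon,
    provider: BigramProvider | None = None,
    include_linguistic: bool = True,
    include_nuisance: bool = False,
    speaker_ratings: dict[str, dict[str, float]] | None = None,
) -> dict[str, EventStream | ContinuousSeries]:
    """All predictor streams for one trial on the epoch time base.

    The epoch spans the target sentence; distractor events earlier than
    the target onset (the 0.5 s head start) are dropped, which for the
    distractor also stands in for the word-level exclusion that the
    head-start cut imposes.
    """
    t0 = trial.target_onset
    span = trial.target_offset - t0
    items: dict[str, EventStream | ContinuousSeries] = {}
    for stream in ("target", "distractor"):
        words = trial.target_words if stream == "target" else trial.distractor_words
        phons = trial.target_phonemes if stream == "target" else trial.distractor_phonemes
        tokens = trial.target_tokens if stream == "target" else trial.distractor_tokens
        env = trial.envelope(stream)
        items[f"envelope_{stream}"] = _crop_series(env, t0, span)
        items[f"acoustic_onsets_{stream}"] = _crop_series(
            compute_acoustic_onsets(env), t0, span
        )
        trains = make_onset_trains(words, [iv for w in phons for iv in w], stream)
        for name, es in trains.items():
            items[f"{name}_{stream}"] = _crop_events(es, t0, span)
        if include_linguistic:
            ling = linguistic_event_streams(
                tokens, words, phons, lexicon, provider=provider, stream=stream
            )
            for name, es in ling.items():
                items[f"{name}_{stream}"] = _crop_events(es, t0, span)
        if include_nuisance:
            f0 = trial.f0_target if stream == "target" else trial.f0_distractor
            items[f"f0_{stream}"] = _crop_series(f0, t0, span)
            ratings = speaker_ratings or SPEAKER_RATINGS
            onsets = np.array([iv.onset for iv in words])
            for name, es in rez.speaker_characteristic_streams(
                onsets, {k: v[stream] for k, v in ratings.items()}, stream
            ).items():
                items[name] = _crop_events(es, t0, span)
    return items


def build_features(
    stim: StimulusSet,
    provider: BigramProvider | None = None,
    rate: float = ANALYSIS_RATE,
) -> dict[str, dict[int, FeatureMatrix]]:
    """Assemble the per-trial feature matrices for every model family.

    Returns dicts of trial id -> :class:`FeatureMatrix` under keys
    ``"acoustic"`` (both streams' envelope/onset predictors),
    ``"linguistic"`` (the four lexical predictors per stream), and
    ``"nuisance"`` (acoustic plus F0 and speaker regressors), all
    min-max normalized with global scope, plus ``"streams"`` holding
    the raw per-trial event streams for value shuffling.
    """
    if provider is None:
        corpus = [t.target_tokens for t in stim.trials] + [
            t.distractor_tokens for t in stim.trials
        ]
        provider = BigramProvider(corpus)
    spans = [t.target_offset - t.target_onset for t in stim.trials]
    all_items = [
        trial_streams(t, stim.lexicon, provider, include_linguistic=True, include_nuisance=True)
        for t in stim.trials
    ]
    tids = [t.trial_id for t in stim.trials]

    def _subset(names_base: list[str], extra: list[str] = ()) -> list[dict]:
        keys = [f"{b}_{s}" for b in names_base for s in ("target", "distractor")]
        keys += list(extra)
        return [{k: items[k] for k in keys} for items in all_items]

    speaker_cols = [
        k for k in all_items[0] if k.startswith("speaker_")
    ]
    acoustic = assemble_trials(_subset(ACOUSTIC_BASE), rate, spans, "global")
    linguistic = assemble_trials(_subset(LINGUISTIC_BASE), rate, spans, "global")
    nuisance = assemble_trials(
        _subset(ACOUSTIC_BASE + ["f0"], speaker_cols), rate, spans, "global"
    )
    streams = {
        tid: {
            k: v
            for k, v in items.items()
            if isinstance(v, EventStream) and any(k.startswith(b) for b in LINGUISTIC_BASE)
        }
        for tid, items in zip(tids, all_items)
    }
    return {
        "acoustic": dict(zip(tids, acoustic)),
        "linguistic": dict(zip(tids, linguistic)),
        "nuisance": dict(zip(tids, nuisance)),
        "streams": streams,
    }


def reassemble_shuffled(
    streams: dict[int, dict[str, EventStream]],
    base: dict[int, FeatureMatrix],
    spans: dict[int, float],
    rate: float = ANALYSIS_RATE,
) -> dict[int, FeatureMatrix]:
    """Write value-shuffled event streams back into feature matrices.

    Shuffled columns are re-rasterized with the *original* global
    normalization bounds, so only the event values move; all other
    columns are carried over untouched.
    """
    from .acoustic import assemble_feature_matrix

    rebuilt = {}
    for tid, items in streams.items():
        fm = base[tid]
        data = fm.data.copy()
        fm2 = assemble_feature_matrix(
            items, rate, spans[tid], {k: fm.normalization[k] for k in items}
        )
        for k in items:
            col = fm2.column(k)
            n = min(col.size, data.shape[0])
            data[:, fm.names.index(k)] = 0.0
            data[: n, fm.names.index(k)] = col[:n]
        rebuilt[tid] = FeatureMatrix(data, list(fm.names), fm.sfreq, dict(fm.normalization))
    return rebuilt


def linguistic_masks(
    features: dict[int, FeatureMatrix],
    rate: float = ANALYSIS_RATE,
    window_s: tuple[float, float] = (0.0, 0.8),
) -> dict[int, np.ndarray]:
    """Event-constrained evaluation masks (0-800 ms after any event)."""
    masks = {}
    for tid, fm in features.items():
        times = np.nonzero(fm.data.any(axis=1))[0] / rate
        masks[tid] = event_mask(times, fm.n_samples, rate, window_s)
    return masks


# ---------------------------------------------------------------------------
# configuration and the full run


@dataclass
class RunConfig:
    """Parameters and per-stage seeds for one reproducible run.

    Defaults describe a scaled-down synthetic study that completes on a
    laptop; the published study's scale (43 participants, 240 trials,
    50 folds, 50 shuffle iterations) is reached by overriding the
    corresponding fields.
    """

    output_dir: str = "speechtrack_run"
    n_participants: int = 6
    n_trials: int = 24
    n_words_lexicon: int = 120
    n_channels: int = 16
    rate: float = ANALYSIS_RATE
    lag_range_ms: tuple[float, float] = (-100.0, 800.0)
    acoustic_lambda: float = ACOUSTIC_LAMBDA
    linguistic_lambda: float = LINGUISTIC_LAMBDA
    n_folds: int = 10
    test_size: int = 2
    shuffle_iterations: int = 10
    tfce_e: float = 0.5
    tfce_h: float = 2.0
    tfce_dh: float = 0.1
    n_signflips: int = 512
    glimpse_threshold_db: float = -5.0
    noise_sd: float = 1.0
    seeds: dict = field(
        default_factory=lambda: {
            "lexicon": 1,
            "stimuli": 2,
            "kernels": 3,
            "eeg": 4,
            "folds": 5,
            "shuffle": 6,
            "signflips": 7,
            "behavior": 8,
        }
    )
    stages: tuple[str, ...] = (
        "simulate",
        "features",
        "residualize",
        "fit",
        "infer",
        "audibility",
        "behavior",
    )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "lag_range_ms" in data:
            data["lag_range_ms"] = tuple(data["lag_range_ms"])
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig, stages: tuple[str, ...] | None = None) -> dict:
    """Execute the requested stages in dependency order.

    Returns the run manifest (also written to ``manifest.json`` in the
    output directory) recording the configuration, per-stage wall time,
    and SHA-256 hashes of the written outputs. Stage failures halt the
    run with the stage name; partial outputs stay on disk.
    """
    stages = tuple(stages or config.stages)
    order = ["simulate", "features", "residualize", "fit", "infer", "audibility", "behavior"]
    requested = [s for s in order if s in stages]
    # prerequisites: everything up to the last requested stage
    last = max(order.index(s) for s in requested)
    todo = order[: last + 1]

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    manifest: dict = {"stages": {}, "outputs": {}}
    state: dict = {}

    for stage in todo:
        t_start = time.time()
        try:
            _STAGES[stage](config, state, out)
        except Exception as err:
            manifest["stages"][stage] = {"status": "failed", "error": str(err)}
            (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
            raise RuntimeError(f"stage {stage!r} failed: {err}") from err
        manifest["stages"][stage] = {
            "status": "ok",
            "seconds": round(time.time() - t_start, 2),
        }
    for p in sorted(out.glob("*")):
        if p.is_file() and p.name != "manifest.json":
            manifest["outputs"][p.name] = _sha256(p)
    manifest["seeds"] = config.seeds
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def _stage_simulate(cfg: RunConfig, state: dict, out: Path) -> None:
    lex = make_lexicon(cfg.n_words_lexicon, seed=cfg.seeds["lexicon"])
    stim = simulate_stimuli(lex, cfg.n_trials, seed=cfg.seeds["stimuli"])
    state["lexicon"], state["stim"] = lex, stim
    lex.to_tsv(out / "lexicon.tsv")


def _stage_features(cfg: RunConfig, state: dict, out: Path) -> None:
    state["features"] = build_features(state["stim"], rate=cfg.rate)
    nuis_names = list(next(iter(state["features"]["nuisance"].values())).names)
    scale = {
        n: (0.2 if n.startswith(("speaker_", "f0")) else 1.0) for n in nuis_names
    }
    kern = make_ground_truth_kernels(
        nuis_names,
        cfg.n_channels,
        cfg.lag_range_ms,
        cfg.rate,
        scale=scale,
        seed=cfg.seeds["kernels"],
    )
    state["kernels"] = kern
    rng = np.random.default_rng(cfg.seeds["eeg"])
    datasets = {}
    for p in range(cfg.n_participants):
        labels = {}
        for t in state["stim"].trials:
            if t.is_control:
                labels[t.trial_id] = "control"
            else:
                p_corr = 1.0 / (1.0 + np.exp(-(t.td_db + 0.5)))
                labels[t.trial_id] = "correct" if rng.random() < p_corr else "incorrect"
            # guarantee both variants exist per participant
        labs = list(labels.values())
        if "correct" not in labs:
            labels[next(t.trial_id for t in state["stim"].trials if not t.is_control)] = "correct"
        if "incorrect" not in labs:
            labels[next(t.trial_id for t in reversed(state["stim"].trials) if not t.is_control)] = "incorrect"
        datasets[f"P{p:02d}"] = simulate_eeg(
            state["features"]["nuisance"],
            kern,
            noise_sd=cfg.noise_sd,
            condition_labels=labels,
            participant=f"P{p:02d}",
            seed=int(rng.integers(2**31)),
        )
    state["eeg"] = datasets


def _stage_residualize(cfg: RunConfig, state: dict, out: Path) -> None:
    nuis = rez.fit_nuisance_trf(
        state["features"]["nuisance"], state["eeg"], alpha=cfg.acoustic_lambda
    )
    state["nuisance_model"] = nuis
    state["eeg_resid"] = {
        pid: rez.residualize_eeg(ds, nuis, state["features"]["nuisance"])
        for pid, ds in state["eeg"].items()
    }


def _stage_fit(cfg: RunConfig, state: dict, out: Path) -> None:
    plan = make_fold_plan(
        list(state["eeg"]), cfg.n_folds, cfg.test_size, cfg.seeds["folds"]
    )
    state["plan"] = plan
    masks = linguistic_masks(state["features"]["linguistic"], cfg.rate)
    state["masks"] = masks
    state["fits_acoustic"] = crossval_fit(
        state["eeg"], state["features"]["acoustic"], plan, cfg.acoustic_lambda, cfg.lag_range_ms
    )
    state["fits_linguistic"] = crossval_fit(
        state["eeg_resid"],
        state["features"]["linguistic"],
        plan,
        cfg.linguistic_lambda,
        cfg.lag_range_ms,
        masks=masks,
    )
    for name in ("fits_acoustic", "fits_linguistic"):
        fs: FitScores = state[name]
        df = fs.frame.copy()
        for i, ch in enumerate(fs.ch_names):
            df[ch] = fs.scores[:, i]
        df.to_csv(out / f"{name}.tsv", sep="\t", index=False)


def _stage_infer(cfg: RunConfig, state: dict, out: Path) -> None:
    from .layout import ChannelGraph

    ch_names = next(iter(state["eeg"].values())).ch_names
    rng = np.random.default_rng(cfg.seeds["signflips"])
    # ring adjacency for synthetic generic channels (no montage positions)
    edges = [(i, (i + 1) % len(ch_names)) for i in range(len(ch_names))]
    graph = ChannelGraph(ch_names, edges)
    results = {}
    for group, stream in (("acoustic", "target"), ("word_linguistic", "target")):
        plan = inference.ShufflePlan(
            group, n_iterations=cfg.shuffle_iterations, seed=cfg.seeds["shuffle"], stream=stream
        )
        if plan.mode == "trial_labels":
            feats = state["features"]["acoustic"]

            def refit(f):
                return crossval_fit(
                    state["eeg"], f, state["plan"], cfg.acoustic_lambda, cfg.lag_range_ms
                )

            observed = state["fits_acoustic"]
        else:
            feats = state["features"]["streams"]
            spans = {
                t.trial_id: t.target_offset - t.target_onset for t in state["stim"].trials
            }
            base = state["features"]["linguistic"]

            def refit(streams):
                rebuilt = reassemble_shuffled(streams, base, spans, cfg.rate)
                return crossval_fit(
                    state["eeg_resid"],
                    rebuilt,
                    state["plan"],
                    cfg.linguistic_lambda,
                    cfg.lag_range_ms,
                    masks=state["masks"],
                )

            observed = state["fits_linguistic"]
        nulls = inference.null_distribution(refit, feats, plan)
        for variant in ("correct", "incorrect"):
            deltas = inference.delta_fits(observed, nulls, variant)
            stat = inference.tfce_test(
                deltas,
                graph,
                cfg.tfce_e,
                cfg.tfce_h,
                cfg.tfce_dh,
                cfg.n_signflips,
                seed=int(rng.integers(2**31)),
            )
            key = f"{group}_{stream}_{variant}"
            results[key] = stat
            stat.frame.to_csv(out / f"statmap_{key}.tsv", sep="\t", index=False)
    state["statmaps"] = results


def _stage_audibility(cfg: RunConfig, state: dict, out: Path) -> None:
    rows = []
    td = {}
    for t in state["stim"].trials:
        gm = glimpse_rate(
            t.target_spec,
            t.distractor_spec,
            t.target_words,
            cfg.glimpse_threshold_db,
            trial=t.trial_id,
        )
        rows.append(gm.table)
        td[t.trial_id] = t.td_db
    from .audibility import GlimpseMap

    gm_all = GlimpseMap(pd.concat(rows, ignore_index=True), cfg.glimpse_threshold_db)
    gm_all = combined_audibility(gm_all, td)
    gm_all.table.to_csv(out / "glimpse.tsv", sep="\t", index=False)
    state["glimpse"] = gm_all


def _stage_behavior(cfg: RunConfig, state: dict, out: Path) -> None:
    from .simulate import simulate_behavior

    stim = state["stim"]
    gm = state["glimpse"].table
    fits = state["fits_linguistic"].trialwise_z()
    word_rows = []
    for t in stim.trials:
        if t.is_control:
            continue
        n_words = len(t.target_tokens)
        for w in range(2, n_words):  # first two words unscored
            g = gm.query("trial == @t.trial_id and word_index == @w")["combined_audibility"]
            word_rows.append(
                {
                    "sentence_id": t.trial_id,
                    "word_index": w,
                    "audibility": float(g.iloc[0]) if len(g) else 0.0,
                    "surprisal": float(np.random.default_rng([cfg.seeds["behavior"], t.trial_id, w]).standard_normal()),
                    "word_frequency": 0.0,
                    "word_order": float(w),
                    "sentence_length": float(n_words),
                    "td_condition": t.td_db,
                }
            )
    word_table = pd.DataFrame(word_rows)
    for col in ("audibility", "surprisal", "td_condition", "word_order", "sentence_length"):
        sd = word_table[col].std()
        if sd > 0:
            word_table[col] = (word_table[col] - word_table[col].mean()) / sd
    table = simulate_behavior(
        word_table, "paper", n_subjects=cfg.n_participants, seed=cfg.seeds["behavior"]
    )
    table.to_csv(out / "behavior_table.tsv", sep="\t", index=False)
    res = fit_glmm(table)
    (out / "glmm_summary.txt").write_text(res.summary())
    res.coef_table().to_csv(out / "glmm_coefficients.tsv", sep="\t")
    state["glmm"] = res


_STAGES = {
    "simulate": _stage_simulate,
    "features": _stage_features,
    "residualize": _stage_residualize,
    "fit": _stage_fit,
    "infer": _stage_infer,
    "audibility": _stage_audibility,
    "behavior": _stage_behavior,
}
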