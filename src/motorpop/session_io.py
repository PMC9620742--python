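"""Session container I/O and the end-to-end pipeline.

A session lives in an HDF5 file (``/raw_f``, ``/dff``, ``/motion_index``,
``/roi/centroids_um``, ``/roi/cell_class``, ``/meta`` attributes) with the
trial table as a sibling CSV (``<name>.trials.csv``) so both are
inspectable with any toolchain.  Frames are 0-based, times in seconds,
distances in µm; the schema version is stamped at write time.

:func:`run_pipeline` chains the analysis stages — simulate → preprocess →
onsets → classify → decode → pca → spatial → report — deterministically
from a seeded JSON-style config, writing tidy CSV/JSON artifacts that all
carry the seed and config hash that produced them.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from . import decoding, onset_detect, popdynamics, response_class, spatiotemporal
from .datatypes import TRIAL_TABLE_COLUMNS, Responsiveness, SessionData
from .signal_prep import (
    MotionIndexSeries,
    align_trials,
    compute_dff,
    detect_motion_onset,
    loess_smooth,
)
from .synthgen import SynthConfig, generate_ramp_calibration_set, generate_session

SCHEMA_VERSION = 1


class SessionSchemaError(Exception):
    """Base class for malformed session containers."""


class MissingDatasetError(SessionSchemaError):
    pass


class ShapeMismatchError(SessionSchemaError):
    pass


class TrialTableError(SessionSchemaError):
    pass


class StageDependencyError(Exception):
    """A pipeline stage ran without the outputs it depends on."""


def _trials_path(h5_path: Path) -> Path:
    return h5_path.with_suffix(".trials.csv")


def write_session(session: SessionData, path: str | Path,
                  dff: np.ndarray | None = None) -> Path:
    """Write a session container (HDF5 + trial-table CSV)."""
    path = Path(path)
    session.validate()
    with h5py.File(path, "w") as f:
        f.create_dataset("raw_f", data=session.raw_f)
        if dff is not None:
            f.create_dataset("dff", data=dff)
        if session.motion_index is not None:
            f.create_dataset("motion_index", data=session.motion_index)
        roi = f.create_group("roi")
        roi.create_dataset("centroids_um", data=session.centroids_um)
        if session.cell_class is not None:
            roi.create_dataset(
                "cell_class", data=np.asarray(session.cell_class, dtype="S32")
            )
        meta = f.create_group("meta")
        meta.attrs["frame_rate"] = session.frame_rate
        meta.attrs["schema_version"] = SCHEMA_VERSION
        for k, v in session.meta.items():
            if isinstance(v, (str, int, float, np.integer, np.floating)):
                meta.attrs[k] = v
    session.trials.to_csv(_trials_path(path), index=False)
    return path


def read_session(path: str | Path) -> SessionData:
    """Read and validate a session container; raises named schema errors."""
    path = Path(path)
    with h5py.File(path, "r") as f:
        if "meta" not in f:
            raise MissingDatasetError("missing /meta")
        version = int(f["meta"].attrs.get("schema_version", -1))
        if version != SCHEMA_VERSION:
            raise SessionSchemaError(f"unsupported schema version {version}")
        for name in ("raw_f", "roi/centroids_um"):
            if name not in f:
                raise MissingDatasetError(f"missing /{name}")
        raw = f["raw_f"][()]
        centroids = f["roi/centroids_um"][()]
        cell_class = (
            f["roi/cell_class"][()].astype(str) if "roi/cell_class" in f else None
        )
        mi = f["motion_index"][()] if "motion_index" in f else None
        frame_rate = float(f["meta"].attrs["frame_rate"])
        meta = {k: v for k, v in f["meta"].attrs.items()}
    if centroids.shape != (raw.shape[0], 2):
        raise ShapeMismatchError("centroids_um does not match neuron count")
    if mi is not None and len(mi) != raw.shape[1]:
        raise ShapeMismatchError("motion_index does not match frame count")
    tpath = _trials_path(path)
    if not tpath.exists():
        raise TrialTableError(f"missing trial table {tpath.name}")
    trials = pd.read_csv(tpath)
    missing = set(TRIAL_TABLE_COLUMNS) - set(trials.columns)
    if missing:
        raise TrialTableError(f"trial table missing columns: {sorted(missing)}")
    times = trials[["cue_s", "motion_onset_s", "completion_s"]].to_numpy()
    if np.any(np.diff(times, axis=1) < 0):
        raise TrialTableError("unordered trial times")
    session = SessionData(
        raw_f=raw, frame_rate=frame_rate, trials=trials, centroids_um=centroids,
        cell_class=cell_class, motion_index=mi, meta=meta,
    )
    session.validate()
    return session


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

ALL_STAGES = ("simulate", "preprocess", "onsets", "classify",
              "decode", "pca", "spatial", "report")

#: stage -> state keys it requires
_REQUIRES = {
    "preprocess": ("session",),
    "onsets": ("aligned",),
    "classify": ("aligned", "onsets"),
    "decode": ("aligned",),
    "pca": ("aligned",),
    "spatial": ("aligned", "decode"),
    "report": ("classification",),
}


def config_hash(config: dict) -> str:
    """Hash of the scientific configuration (output location excluded, so
    identical analyses in different directories stamp the same hash)."""
    payload = {k: v for k, v in config.items() if k != "outdir"}
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def _stamp(df: pd.DataFrame, seed: int, chash: str) -> pd.DataFrame:
    df = df.copy()
    df["seed"] = seed
    df["config_hash"] = chash
    return df


def run_pipeline(config: dict) -> Path:
    """Run the configured stages in order; deterministic given seeds.

    ``config`` keys: ``seed`` (int), ``outdir`` (path), ``stages``
    (subset of :data:`ALL_STAGES`, default all), ``session`` (path of an
    existing container instead of simulating), ``synth`` (overrides for
    :class:`~motorpop.synthgen.SynthConfig`), ``align_window`` ((pre,
    post) s, default (2.5, 5.0)), ``decode`` (options: ``removal`` in
    {"none", "ordered", "both"}, ``eval_stride``).  A stage whose inputs
    are missing raises :class:`StageDependencyError`; completed outputs
    are preserved on failure.
    """
    seed = int(config.get("seed", 0))
    chash = config_hash(config)
    outdir = Path(config.get("outdir", "motorpop_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    stages = tuple(config.get("stages", ALL_STAGES))
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    state: dict = {}

    for stage in [s for s in ALL_STAGES if s in stages]:
        for need in _REQUIRES.get(stage, ()):
            if need not in state:
                raise StageDependencyError(
                    f"stage '{stage}' requires '{need}' (did an earlier stage run?)"
                )
        try:
            _STAGE_FNS[stage](state, config, outdir, seed, chash)
        except StageDependencyError:
            raise
        except Exception as exc:  # tag the failing stage, keep partial outputs
            raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc
    return outdir


def _stage_simulate(state, config, outdir, seed, chash):
    if "session" in config:
        state["session"] = read_session(config["session"])
        state["truth"] = None
        return
    synth = SynthConfig(seed=seed, **config.get("synth", {}))
    session, truth = generate_session(synth)
    state["session"], state["truth"] = session, truth
    write_session(session, outdir / "session.h5")
    _stamp(truth.to_frame(), seed, chash).to_csv(outdir / "ground_truth.csv", index=False)


def _stage_preprocess(state, config, outdir, seed, chash):
    session: SessionData = state["session"]
    rng = np.random.default_rng(seed + 1)
    traces = compute_dff(session.raw_f, session.frame_rate)
    mi_sm = loess_smooth(session.motion_index, 1.0, session.frame_rate)
    mi = MotionIndexSeries(np.clip(mi_sm, 0, None), session.frame_rate)
    onsets = np.array([
        detect_motion_onset(mi, row.cue_s, row.motion_onset_s, "imaging", rng=rng)
        for row in session.trials.itertuples()
    ])
    trials = session.trials.copy()
    trials["mi_onset_detected_s"] = onsets
    pre, post = config.get("align_window", (2.5, 5.0))
    aligned = align_trials(
        traces.dff, onsets, (pre, post), session.frame_rate,
        trials["type"].to_numpy(),
    )
    state.update(dff=traces, aligned=aligned, trials=trials, mi_onsets=onsets)
    _stamp(trials, seed, chash).to_csv(outdir / "trials_detected.csv", index=False)
    with h5py.File(outdir / "preprocessed.h5", "w") as f:
        f.create_dataset("dff", data=traces.dff)
        f.create_dataset("aligned", data=aligned.data)
        f.create_dataset("time_axis", data=aligned.time_axis)
        f.attrs["seed"] = seed
        f.attrs["config_hash"] = chash


def _stage_onsets(state, config, outdir, seed, chash):
    session: SessionData = state["session"]
    aligned = state["aligned"]
    rng = np.random.default_rng(seed + 2)
    noise_sd = config.get("synth", {}).get("noise_sd", SynthConfig().noise_sd)
    calib, calib_truth = generate_ramp_calibration_set(
        noise_sd=noise_sd, frame_rate=session.frame_rate, seed=seed + 100,
    )
    cfg0 = onset_detect.OnsetConfig()
    correction = onset_detect.calibrate_correction(calib, calib_truth, cfg0, rng=rng)
    cfg = onset_detect.OnsetConfig(correction=correction)
    onsets = np.full(aligned.n_neurons, np.nan)
    valid = np.asarray(aligned.valid_trials)
    base_f = aligned.time_axis < -0.15
    for i in range(aligned.n_neurons):
        trials = aligned.data[i, valid]
        # SSF tracks rising activity; for suppressed neurons the rise marks
        # the END of the response, so detect on the sign-matched trace
        mean_trace = trials.mean(axis=0) - trials[:, base_f].mean()
        sign = np.sign(mean_trace[np.argmax(np.abs(mean_trace))]) or 1.0
        try:
            onsets[i] = onset_detect.neuron_median_onset(
                sign * trials, aligned.time_axis, aligned.frame_rate, cfg, rng,
            )
        except ValueError:
            pass
    state["onsets"] = onsets
    state["onset_config"] = cfg
    _stamp(pd.DataFrame({"neuron": np.arange(len(onsets)),
                         "median_onset_s": onsets}),
           seed, chash).to_csv(outdir / "onsets.csv", index=False)
    (outdir / "onset_calibration.json").write_text(json.dumps({
        "correction_s": correction, "seed": seed, "config_hash": chash,
    }, indent=2))


def _stage_classify(state, config, outdir, seed, chash):
    aligned = state["aligned"]
    trials = state["trials"]
    rng = np.random.default_rng(seed + 3)
    rel_completion = (trials["completion_s"] - trials["mi_onset_detected_s"]).median()
    epochs = response_class.EpochSpec.from_trials(
        pd.DataFrame({"completion_s": [rel_completion], "motion_onset_s": [0.0]})
    )
    result = response_class.classify_neurons(
        aligned, epochs, state["onsets"], float(rel_completion), rng=rng,
    )
    state["classification"] = result
    state["epochs"] = epochs
    _stamp(result, seed, chash).to_csv(outdir / "classification.csv", index=False)


def _stage_decode(state, config, outdir, seed, chash):
    aligned = state["aligned"]
    rng = np.random.default_rng(seed + 4)
    opts = config.get("decode", {})
    valid = np.asarray(aligned.valid_trials)
    labels = aligned.trial_labels[valid]
    data = aligned.data[:, valid]
    # 5 s peri-movement decoding window centred on motion-index onset
    win = np.flatnonzero(np.abs(aligned.time_axis) <= 2.5 + 1e-9)
    t_win = aligned.time_axis[win]
    n_push = int((labels == "push").sum())
    n_pull = int((labels == "pull").sum())
    threshold = decoding.session_null_threshold((n_push, n_pull), rng=rng)
    rows, correct_all, epochs = [], [], []
    for i in range(aligned.n_neurons):
        correct = decoding.loo_nb_correct(data[i][:, win], labels)
        acc = correct.mean(axis=0)
        start, end, flagged = decoding.neuron_epoch(data[i][:, win], labels, t_win)
        hda = (not flagged) and decoding.flag_hda(
            correct, t_win, (start, end), threshold, rng=rng,
        )
        rows.append((i, float(acc.max()), start, end, flagged, hda))
        correct_all.append(correct)
        epochs.append((start, end))
    per_neuron = pd.DataFrame(rows, columns=[
        "neuron", "max_accuracy", "epoch_start_s", "epoch_end_s",
        "epoch_flagged", "hda",
    ])
    per_neuron["session_threshold"] = threshold
    # population decoding over the pooled epoch (earliest start, latest end)
    pop_epoch = (-0.150, float(max(e for _, e in epochs)))
    pop = decoding.population_accuracy(
        data[:, :, win], labels, t_win, pop_epoch,
        eval_stride=int(opts.get("eval_stride", 1)),
    )
    removal_mode = opts.get("removal", "ordered")
    curves = {}
    n_hda = int(per_neuron["hda"].sum())
    min_trials = min(n_push, n_pull)
    if removal_mode != "none" and (n_hda < 3 or min_trials < 10):
        removal_mode = "none"   # low counts: session excluded from removal
    if removal_mode in ("ordered", "both"):
        shuffle_ci = decoding.shuffle_accuracy_ci(
            data[:, :, win], labels, t_win, pop_epoch, rng=rng)
        curves["ordered"] = decoding.removal_curve(
            data[:, :, win], labels, t_win, pop_epoch,
            per_neuron["max_accuracy"].to_numpy(), order="by_accuracy",
            rng=rng, shuffle_ci=shuffle_ci,
        )
        if removal_mode == "both":
            curves["random"] = decoding.removal_curve(
                data[:, :, win], labels, t_win, pop_epoch,
                per_neuron["max_accuracy"].to_numpy(), order="random",
                rng=rng, shuffle_ci=shuffle_ci,
            )
    state["decode"] = {
        "per_neuron": per_neuron, "threshold": threshold,
        "correct": correct_all, "population": pop, "curves": curves,
        "window": win, "t_win": t_win,
    }
    _stamp(per_neuron, seed, chash).to_csv(outdir / "decoding.csv", index=False)
    with h5py.File(outdir / "decoding_arrays.h5", "w") as f:
        f.create_dataset("population_accuracy_ts", data=pop.accuracy_ts)
        f.create_dataset("population_frames", data=pop.frames)
        f.attrs["population_max_in_bin"] = pop.max_in_bin
        f.attrs["session_threshold"] = threshold
        f.attrs["seed"] = seed
        f.attrs["config_hash"] = chash
        for name, c in curves.items():
            g = f.create_group(f"removal_{name}")
            g.create_dataset("accuracy", data=c.accuracy)
            g.create_dataset("accuracy_ci", data=c.accuracy_ci)
            g.attrs["proportion_to_chance"] = c.proportion_to_chance


def _stage_pca(state, config, outdir, seed, chash):
    aligned = state["aligned"]
    trials = state["trials"]
    rng = np.random.default_rng(seed + 5)
    valid = np.asarray(aligned.valid_trials) & (trials["outcome"] == "success").to_numpy()
    # 7.5 s peri-movement window
    win = np.flatnonzero(
        (aligned.time_axis >= -2.5 - 1e-9) & (aligned.time_axis <= 5.0 + 1e-9)
    )
    n_pcs = min(16, aligned.n_neurons)
    traj = popdynamics.pca_trajectories(
        aligned.data[:, valid][:, :, win], aligned.trial_labels[valid],
        aligned.time_axis[win], n_pcs=n_pcs, rng=rng,
    )
    longest = float(
        (trials["completion_s"] - trials["mi_onset_detected_s"])[valid].max()
    )
    dp = popdynamics.dprime_timeseries(
        traj.projections, aligned.trial_labels[valid], aligned.time_axis[win],
        movement_window=(0.0, longest), rng=rng,
    )
    dp.explained_variance_fraction = traj.explained_variance_fraction
    state["pca"] = (traj, dp)
    _stamp(pd.DataFrame({
        "pc": np.arange(n_pcs),
        "explained_variance_fraction": traj.explained_variance_fraction,
        "separable": dp.separable,
        "max_dprime_in_window": np.where(
            dp.significant.any(axis=1),
            np.where(dp.significant, dp.dprime_ts, -np.inf).max(axis=1),
            np.nan),
    }), seed, chash).to_csv(outdir / "dprime.csv", index=False)


def _stage_spatial(state, config, outdir, seed, chash):
    aligned = state["aligned"]
    session: SessionData = state["session"]
    dec = state["decode"]
    rng = np.random.default_rng(seed + 6)
    hda = np.where(dec["per_neuron"]["hda"], "HDA", "LDA")
    epochs = state.get("epochs")
    epoch = epochs.peri if epochs is not None else (-0.150, 0.5)
    pairs = spatiotemporal.pairwise_activity_correlations(
        aligned.data[:, np.asarray(aligned.valid_trials)], aligned.time_axis,
        aligned.trial_labels[np.asarray(aligned.valid_trials)],
        session.centroids_um, epoch, aligned.frame_rate, groups=hda,
        animal_id=str(session.meta.get("animal_id", "animal0")),
    )
    med_r = spatiotemporal.group_median_difference(pairs, "pearson_r", rng=rng)
    med_d = spatiotemporal.group_median_difference(pairs, "distance_um", rng=rng)
    tc = spatiotemporal.hda_timecourse(dec["correct"], dec["threshold"], rng=rng)
    state["spatial"] = {"pairs": pairs, "median_r": med_r, "median_d": med_d,
                        "hda_timecourse": tc}
    _stamp(pairs, seed, chash).to_csv(outdir / "pairs.csv", index=False)
    (outdir / "spatial_summary.json").write_text(json.dumps({
        "hda_median_r_difference": med_r[0], "hda_median_r_ci": med_r[1],
        "hda_median_distance_difference": med_d[0], "hda_median_distance_ci": med_d[1],
        "seed": seed, "config_hash": chash,
    }, indent=2))


def _stage_report(state, config, outdir, seed, chash):
    cls = state["classification"]
    mr = cls[cls["responsiveness"] == Responsiveness.MOVEMENT_RELATED.value]
    n_mr = len(mr)
    bias_counts = mr["bias"].value_counts().to_dict()
    type_counts = (
        mr.loc[mr["bias"].isin(["push", "pull"]), "bias_type"]
        .value_counts().to_dict()
    )
    summary = {
        "n_neurons": int(len(cls)),
        "responsiveness_counts": cls["responsiveness"].value_counts().to_dict(),
        "proportion_movement_related": n_mr / len(cls),
        "bias_counts": {k: int(v) for k, v in bias_counts.items()},
        "proportion_invariant_of_movement_related":
            (bias_counts.get("invariant", 0) / n_mr) if n_mr else None,
        "bias_type_counts": {str(int(k)): int(v) for k, v in type_counts.items()
                             if k is not None and np.isfinite(float(k))},
        "seed": seed,
        "config_hash": chash,
    }
    if "decode" in state:
        dec = state["decode"]
        summary["median_single_neuron_max_accuracy"] = float(
            dec["per_neuron"]["max_accuracy"].median())
        summary["population_max_accuracy"] = float(dec["population"].max_in_bin)
        summary["n_hda"] = int(dec["per_neuron"]["hda"].sum())
        summary["session_threshold"] = float(dec["threshold"])
    if "pca" in state:
        _, dp = state["pca"]
        summary["max_significant_dprime"] = (
            None if not np.isfinite(dp.max_significant_dprime)
            else float(dp.max_significant_dprime))
        summary["cumulative_explained_variance_16pc"] = float(
            np.sum(dp.explained_variance_fraction))
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    state["summary"] = summary


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "onsets": _stage_onsets,
    "classify": _stage_classify,
    "decode": _stage_decode,
    "pca": _stage_pca,
    "spatial": _stage_spatial,
    "report": _stage_report,
}
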