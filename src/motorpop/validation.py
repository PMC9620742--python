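"""Ground-truth validation experiments on synthetic sessions.

Each function runs one calibration/recovery study end-to-end under the
package's standard study conditions (the synthetic generator defaults:
40 Hz imaging, ΔF/F₀ effect 5× the 0.1 noise SD, 40 trials per movement
unless a study names another size) and returns the measured quantities.
These are the numbers the acceptance checks and the numbered analysis
scripts report; they are computed fresh on every run.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import decoding, onset_detect, popdynamics, response_class, spatiotemporal
from .datatypes import SessionData
from .signal_prep import (
    MotionIndexSeries,
    align_trials,
    compute_dff,
    compute_motion_index,
    detect_motion_onset,
    loess_smooth,
)
from .synthgen import (
    SynthConfig,
    generate_ramp_calibration_set,
    generate_session,
)

#: expected (responsiveness, bias) per generated class
_EXPECTED = {
    "invariant_up": ("movement_related", "invariant"),
    "invariant_down": ("movement_related", "invariant"),
    "push_type1": ("movement_related", "push"),
    "push_type2": ("movement_related", "push"),
    "push_type3": ("movement_related", "push"),
    "push_type4": ("movement_related", "push"),
    "pull_type1": ("movement_related", "pull"),
    "pull_type2": ("movement_related", "pull"),
    "pull_type3": ("movement_related", "pull"),
    "pull_type4": ("movement_related", "pull"),
    "reward_phase": ("reward_phase", ""),
    "non_responsive": ("non_responsive", ""),
}


def _preprocess(session: SessionData, window=(1.5, 3.5), seed: int = 0):
    """ΔF/F₀, motion-index onset detection, alignment — the standard chain."""
    rng = np.random.default_rng(seed)
    traces = compute_dff(session.raw_f, session.frame_rate)
    mi_sm = loess_smooth(session.motion_index, 1.0, session.frame_rate)
    mi = MotionIndexSeries(np.clip(mi_sm, 0, None), session.frame_rate)
    onsets = np.array([
        detect_motion_onset(mi, row.cue_s, row.motion_onset_s, "imaging", rng=rng)
        for row in session.trials.itertuples()
    ])
    aligned = align_trials(traces.dff, onsets, window, session.frame_rate,
                           session.trials["type"].to_numpy())
    rel_completion = float((session.trials["completion_s"] - onsets).median())
    return aligned, rel_completion


def classification_recovery(seed: int = 0) -> dict:
    """Criterion: class recovery on the standard 100-neuron session and
    stability of the null false-positive rate across seeds.

    100 neurons (60% invariant, 15% push bias, 15% pull bias, 10%
    non-responsive), 40 trials per movement, effect amplitude 5× noise SD.
    """
    cfg = SynthConfig(seed=seed)
    session, truth = generate_session(cfg)
    aligned, rel_completion = _preprocess(session, seed=seed)
    epochs = response_class.EpochSpec(peri=(-0.150, rel_completion + 0.040))
    result = response_class.classify_neurons(
        aligned, epochs, median_completion_s=rel_completion,
        rng=np.random.default_rng(seed + 1),
    )
    correct = 0
    for i, cls in enumerate(truth.true_class):
        exp_resp, exp_bias = _EXPECTED[cls]
        row = result.iloc[i]
        ok = row["responsiveness"] == exp_resp
        if exp_resp == "movement_related":
            ok = ok and row["bias"] == exp_bias
        correct += ok
    recovery = correct / len(truth.true_class)

    fp_rates = []
    for s_off in (1000, 2000):
        null_cfg = SynthConfig(
            n_neurons=1000, seed=seed + s_off,
            class_proportions={"non_responsive": 1.0},
        )
        n_sess, _ = generate_session(null_cfg)
        n_al, n_rel = _preprocess(n_sess, seed=seed + s_off)
        n_ep = response_class.EpochSpec(peri=(-0.150, n_rel + 0.040))
        n_res = response_class.classify_neurons(
            n_al, n_ep, median_completion_s=n_rel,
            rng=np.random.default_rng(seed + s_off + 1),
        )
        fp_rates.append(
            float((n_res["responsiveness"] != "non_responsive").mean())
        )
    return {
        "recovery_fraction": recovery,
        "null_fp_rates": fp_rates,
        "null_fp_shift_points": abs(fp_rates[0] - fp_rates[1]) * 100,
        "n_neurons": cfg.n_neurons,
    }


def onset_calibration(seed: int = 0) -> dict:
    """Criterion: the ramp-simulation design (100 cells × 30 trials,
    0.5 s rise, matched noise); median |error| on a held-out seed after
    calibration, in frames at 30 Hz."""
    cfg0 = onset_detect.OnsetConfig(n_boot=2000)
    calib, truth = generate_ramp_calibration_set(
        100, 30, noise_sd=0.1, frame_rate=30.0, seed=seed + 100)
    corr = onset_detect.calibrate_correction(
        calib, truth, cfg0, rng=np.random.default_rng(seed))
    cfg = onset_detect.OnsetConfig(n_boot=2000, correction=corr)
    held, h_truth = generate_ramp_calibration_set(
        100, 30, noise_sd=0.1, frame_rate=30.0, seed=seed + 200)
    errs = []
    for i in range(held.n_neurons):
        det = onset_detect.neuron_median_onset(
            held.neuron(i), held.time_axis, held.frame_rate, cfg,
            np.random.default_rng(seed + i))
        errs.append(det - h_truth.true_onset[i])
    errs = np.asarray(errs)
    return {
        "correction_s": corr,
        "median_abs_error_frames": float(np.median(np.abs(errs)) * 30.0),
        "median_error_frames": float(np.median(errs) * 30.0),
        "n_cells": held.n_neurons,
    }


def decoding_null_calibration(seed: int = 0, n_threshold_seeds: int = 20) -> dict:
    """Criterion: 100 null neurons at 40 trials/class — accuracy centred
    near chance, HDA false positives ≤ 10%, and the simulated-null
    threshold in (0.5, 1), decreasing with trial count."""
    cfg = SynthConfig(n_neurons=100, n_push_trials=40, n_pull_trials=40,
                      seed=seed + 5, class_proportions={"non_responsive": 1.0})
    session, _ = generate_session(cfg)
    aligned, _ = _preprocess(session, window=(2.5, 2.5), seed=seed + 5)
    rng = np.random.default_rng(seed + 6)
    valid = np.asarray(aligned.valid_trials)
    labels = aligned.trial_labels[valid]
    counts = (int((labels == "push").sum()), int((labels == "pull").sum()))
    threshold = decoding.session_null_threshold(counts, rng=rng)
    mean_accs, hda_flags = [], []
    for i in range(aligned.n_neurons):
        correct = decoding.loo_nb_correct(aligned.data[i, valid], labels)
        mean_accs.append(correct.mean())
        start, end, flagged = decoding.neuron_epoch(
            aligned.data[i, valid], labels, aligned.time_axis)
        hda_flags.append((not flagged) and decoding.flag_hda(
            correct, aligned.time_axis, (start, end), threshold,
            n_boot=4000, rng=rng))
    thr_by_n = {}
    for n in (20, 80):
        thr_by_n[n] = float(np.median([
            decoding.session_null_threshold((n, n), rng=np.random.default_rng(seed + 10 + s))
            for s in range(n_threshold_seeds)
        ]))
    return {
        "mean_accuracy": float(np.mean(mean_accs)),
        "hda_fp_rate": float(np.mean(hda_flags)),
        "threshold": float(threshold),
        "threshold_median_n20": thr_by_n[20],
        "threshold_median_n80": thr_by_n[80],
        "n_neurons": aligned.n_neurons,
    }


def removal_contrast(seed: int = 0) -> dict:
    """Criterion: 50 neurons with exactly 10 informative (movement-bias)
    cells; ordered removal reaches chance within 12 removals, random
    removal (median of 25 repetitions) takes strictly longer.

    20 trials per movement keep the retrained leave-one-out decoders
    tractable while leaving the ordered/random contrast intact.
    """
    cfg = SynthConfig(
        n_neurons=50, n_push_trials=20, n_pull_trials=20, seed=seed + 7,
        class_proportions={"push_type2": 0.1, "pull_type2": 0.1,
                           "invariant_up": 0.7, "non_responsive": 0.1},
    )
    session, truth = generate_session(cfg)
    aligned, rel_completion = _preprocess(session, window=(1.0, 2.0), seed=seed + 7)
    rng = np.random.default_rng(seed + 8)
    valid = np.asarray(aligned.valid_trials)
    labels = aligned.trial_labels[valid]
    data = aligned.data[:, valid]
    epoch = (-0.150, rel_completion + 0.5)
    single = np.array([
        decoding.nb_accuracy_timeseries(data[i], labels).max()
        for i in range(data.shape[0])
    ])
    shuffle_ci = decoding.shuffle_accuracy_ci(
        data, labels, aligned.time_axis, epoch, n_samples=500, rng=rng)
    ordered = decoding.removal_curve(
        data, labels, aligned.time_axis, epoch, single, order="by_accuracy",
        rng=rng, shuffle_ci=shuffle_ci)
    random = decoding.removal_curve(
        data, labels, aligned.time_axis, epoch, single, order="random",
        n_random_reps=25, rng=rng, shuffle_ci=shuffle_ci)
    n_informative = int(np.isin(truth.true_class, ["push_type2", "pull_type2"]).sum())
    return {
        "ordered_proportion_to_chance": ordered.proportion_to_chance,
        "random_proportion_to_chance": random.proportion_to_chance,
        "ordered_removals_to_chance": int(round(ordered.proportion_to_chance * 50)),
        "n_informative": n_informative,
        "n_neurons": 50,
    }


def dprime_oracle(seed: int = 0, n_null_sessions: int = 50) -> dict:
    """Criterion: Gaussian projections with Δµ = 1, σ = 1, 200 trials per
    class give empirical d' ≈ 1; label-shuffled sessions rarely declare
    separable PCs."""
    r = np.random.default_rng(seed + 9)
    n_t = 25
    proj = r.standard_normal((400, n_t, 2))
    proj[:200, :, 0] += 1.0
    labels = np.array(["push"] * 200 + ["pull"] * 200)
    ta = np.arange(n_t) / 40.0
    dp = popdynamics.dprime_timeseries(proj, labels, ta,
                                       movement_window=(0, ta[-1]), rng=r)
    sep_hits = sep_total = 0
    for s in range(n_null_sessions):
        rs = np.random.default_rng(seed + 100 + s)
        null_proj = rs.standard_normal((40, 20, 4))
        null_labels = np.array(["push"] * 20 + ["pull"] * 20)
        null = popdynamics.dprime_timeseries(
            null_proj, null_labels, np.arange(20) / 40.0,
            movement_window=(0, 0.5), rng=rs)
        sep_hits += int(null.separable.sum())
        sep_total += len(null.separable)
    return {
        "dprime_mean": float(dp.dprime_ts[0].mean()),
        "null_separable_fraction": sep_hits / sep_total,
        "n_trials_per_class": 200,
    }


def clustering_recovery(seed: int = 0, n_pairs: int = 2000) -> dict:
    """Criterion: null pair table (4 animals) has a distance slope within
    2 SE of 0; an injected slope is recovered in sign and magnitude."""
    r = np.random.default_rng(seed + 11)
    n_neurons = 100
    acc = r.uniform(0.4, 0.9, n_neurons)

    def make_pairs(slope):
        i = r.integers(0, n_neurons // 2, n_pairs)
        j = r.integers(n_neurons // 2, n_neurons, n_pairs)
        dist = r.uniform(0, 300, n_pairs)
        rr = r.normal(0.2, 0.1, n_pairs) + slope * (dist - dist.mean())
        return pd.DataFrame({
            "neuron_i": i, "neuron_j": j, "pearson_r": rr,
            "distance_um": dist, "group_i": "HDA", "group_j": "LDA",
            "movement": r.choice(["push", "pull"], n_pairs),
            "animal_id": r.choice(["m1", "m2", "m3", "m4"], n_pairs),
        })

    null_fit = spatiotemporal.fit_clustering_model(make_pairs(0.0), acc)
    beta = 4e-4
    inj_fit = spatiotemporal.fit_clustering_model(make_pairs(beta), acc)
    return {
        "null_slope": float(null_fit.params["dist_c"]),
        "null_slope_se": float(null_fit.bse["dist_c"]),
        "null_slope_z": float(null_fit.params["dist_c"] / null_fit.bse["dist_c"]),
        "injected_beta": beta,
        "injected_slope": float(inj_fit.params["dist_c"]),
        "injected_slope_se": float(inj_fit.bse["dist_c"]),
        "injected_error_se": float(
            abs(inj_fit.params["dist_c"] - beta) / inj_fit.bse["dist_c"]),
        "n_pairs": n_pairs,
    }


def exact_oracles(seed: int = 0) -> dict:
    """Criterion: closed-form/brute-force identities."""
    r = np.random.default_rng(seed + 13)
    frames = r.integers(0, 255, size=(10, 16, 16)).astype(float)
    mask = r.random((16, 16)) > 0.4
    mask[0, 0] = True
    mi = compute_motion_index(frames, mask).values
    brute = np.array([
        sum((frames[f + 1, a, b] - frames[f, a, b]) ** 2
            for a in range(16) for b in range(16) if mask[a, b])
        for f in range(9)
    ])
    X = np.array([[0.0], [0.0], [1.0], [1.0]])
    nb_acc = decoding.nb_accuracy_timeseries(
        X, np.array(["push", "push", "pull", "pull"]))[0]
    return {
        "motion_index_max_abs_diff": float(np.max(np.abs(mi - brute))),
        "nb_worked_case_accuracy": float(nb_acc),
        "dprime_formula_value": float(popdynamics.dprime_formula(2.0, 0.0, 1.0, 1.0)),
    }
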