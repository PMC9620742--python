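"""Movement-type decoding: single-neuron Gaussian naive Bayes with a
simulated-null significance threshold, and population logistic regression
with neuron-removal analyses.

Single neurons
--------------
At each frame of a 5 s peri-movement window, a leave-one-out (LOO)
Gaussian naive Bayes classifier is trained on all other trials' ΔF/F₀ at
that frame (per-class mean and variance with a small variance floor) and
tested on the held-out trial assuming a 50:50 class prior — the task's
balanced design; empirical LOO priors would systematically penalise the
held-out trial's own class.  The accuracy time series is the mean LOO
correctness per frame.  Chance level is not
assumed to be 0.5: the session threshold is the mean + 2 SD of the same
LOO accuracy computed on label-free Gaussian data with the session's
trial counts (1000 simulated datasets).  A neuron is "high decoding
accuracy" (HDA) when at least one 250 ms bin inside its peri-movement
epoch has a bootstrap accuracy CI whose lower bound exceeds the
threshold.

Population
----------
LOO L2-regularised logistic regression on the population vector, per
frame, with per-feature standardisation; the population summary is the
maximum bin-averaged accuracy in any 250 ms bin inside the epoch.
Removal curves retrain the decoder from scratch after removing neurons
one at a time (in descending single-neuron accuracy, or randomly with the
median over 25 repetitions) and report the fraction of the population
removed when the accuracy CI first overlaps the shuffled-label 95% CI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

VAR_FLOOR = 1e-6  # ΔF/F₀² floor on Gaussian NB variances


# ---------------------------------------------------------------------------
# Gaussian naive Bayes, leave-one-out, vectorised over frames and trials
# ---------------------------------------------------------------------------

def loo_nb_correct(X: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """LOO naive-Bayes correctness matrix.

    Parameters
    ----------
    X : (n_trials, n_frames) array
        Single-feature observations (one neuron's ΔF/F₀ per frame).
    labels : (n_trials,) array of str
        Two-class trial labels.

    Returns
    -------
    (n_trials, n_frames) boolean array: whether the held-out trial is
    classified correctly at that frame.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError("need exactly two classes")
    y = (np.asarray(labels) == classes[1]).astype(int)
    n = len(y)
    if min((y == 0).sum(), (y == 1).sum()) < 2:
        raise ValueError("need at least 2 trials per class")

    out = np.empty(X.shape, dtype=bool)
    stats = {}
    for c in (0, 1):
        m = y == c
        stats[c] = (m.sum(), X[m].sum(axis=0), (X[m] ** 2).sum(axis=0))
    for c in (0, 1):
        n_c, s_c, q_c = stats[c]
        n_o, s_o, q_o = stats[1 - c]
        mask = y == c
        Xi = X[mask]                                      # (n_c, F)
        # own-class stats with trial i removed
        mean_c = (s_c - Xi) / (n_c - 1)
        var_c = (q_c - Xi**2) / (n_c - 1) - mean_c**2
        var_c = np.maximum(var_c, VAR_FLOOR)
        mean_o = np.broadcast_to(s_o / n_o, Xi.shape)
        var_o = np.maximum(q_o / n_o - mean_o**2, VAR_FLOOR)
        # 50:50 prior: the log-prior terms cancel
        ll_c = -0.5 * np.log(var_c) - (Xi - mean_c) ** 2 / (2 * var_c)
        ll_o = -0.5 * np.log(var_o) - (Xi - mean_o) ** 2 / (2 * var_o)
        out[mask] = ll_c > ll_o
    return out


def nb_accuracy_timeseries(trials_x_time: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Mean LOO naive-Bayes accuracy per frame for one neuron."""
    return loo_nb_correct(trials_x_time, labels).mean(axis=0)


def session_null_threshold(
    n_trials_per_class: tuple[int, int],
    n_reps: int = 1000,
    rng: np.random.Generator | None = None,
) -> float:
    """Chance threshold: mean + 2 SD of LOO NB accuracy on label-free data.

    Each of ``n_reps`` simulated datasets draws every trial's feature from
    the same standard Gaussian regardless of label (50:50 design with the
    session's trial counts), so any accuracy above the returned value
    exceeds what trial-count artefacts alone produce.
    """
    n0, n1 = n_trials_per_class
    if n0 + n1 < 4:
        raise ValueError("need at least 4 trials")
    rng = np.random.default_rng(0) if rng is None else rng
    X = rng.standard_normal((n0 + n1, n_reps))
    labels = np.array(["a"] * n0 + ["b"] * n1)
    acc = loo_nb_correct(X, labels).mean(axis=0)
    return float(acc.mean() + 2 * acc.std(ddof=0))


def neuron_epoch(
    trials_x_time: np.ndarray,
    labels: np.ndarray,
    time_axis: np.ndarray,
    start: float = -0.150,
) -> tuple[float, float, bool]:
    """Per-neuron peri-movement epoch for the HDA test.

    The end is the later of the two per-movement median ΔF/F₀ peak times
    (peak of the across-trial median trace); the start is −0.15 s.
    Returns ``(start, end, flagged)``; ``flagged`` marks a collapsed epoch
    (peak before the start).
    """
    labels = np.asarray(labels)
    peaks = []
    for mv in np.unique(labels):
        med = np.median(trials_x_time[labels == mv], axis=0)
        peaks.append(float(time_axis[np.argmax(med)]))
    end = max(peaks)
    return start, end, end <= start


def flag_hda(
    correct: np.ndarray,
    time_axis: np.ndarray,
    epoch: tuple[float, float],
    threshold: float,
    bin_width: float = 0.250,
    n_boot: int = 10_000,
    rng: np.random.Generator | None = None,
) -> bool:
    """High-decoding-accuracy flag: any 250 ms bin in the epoch whose
    bootstrap accuracy CI lower bound exceeds the session threshold.

    ``correct`` is the per-trial LOO correctness matrix from
    :func:`loo_nb_correct`.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    start, end = epoch
    if end <= start:
        return False
    n_bins = max(1, int(np.floor((end - start) / bin_width + 1e-9)))
    n = correct.shape[0]
    idx = rng.integers(0, n, size=(n_boot, n))
    for b in range(n_bins):
        f = np.flatnonzero((time_axis >= start + b * bin_width - 1e-9)
                           & (time_axis < start + (b + 1) * bin_width - 1e-9))
        if len(f) == 0:
            continue
        per_trial = correct[:, f].mean(axis=1)
        lo = np.percentile(per_trial[idx].mean(axis=1), 2.5)
        if lo > threshold:
            return True
    return False


# ---------------------------------------------------------------------------
# population decoding: batched LOO ridge logistic regression
# ---------------------------------------------------------------------------

def _loo_logistic_correct(
    X: np.ndarray,
    y: np.ndarray,
    l2: float = 1.0,
    n_iter: int = 25,
    tol: float = 1e-6,
) -> np.ndarray:
    """LOO correctness of L2-regularised logistic regression, batched with
    Newton's method over frames × folds.

    Parameters
    ----------
    X : (F, n, d) array — per-frame design matrices (already standardised,
        without intercept column).
    y : (n,) or (F, n) binary labels (per-frame labels allow shuffles).
    """
    F, n, d = X.shape
    Xb = np.concatenate([X, np.ones((F, n, 1))], axis=2)       # intercept
    dd = d + 1
    if y.ndim == 1:
        Y = np.broadcast_to(y, (F, n)).astype(float)
    else:
        Y = y.astype(float)
    mask = 1.0 - np.eye(n)                                      # (folds, n)
    beta = np.zeros((F, n, dd))                                 # per frame, per fold
    ridge = l2 * np.eye(dd)
    ridge[-1, -1] = 0.0                                         # intercept unpenalised
    for _ in range(n_iter):
        z = np.einsum("fnd,fbd->fbn", Xb, beta)                 # (F, folds, n)
        p = 1.0 / (1.0 + np.exp(-np.clip(z, -30, 30)))
        r = (p - Y[:, None, :]) * mask                          # residuals, held-out zeroed
        g = np.einsum("fbn,fnd->fbd", r, Xb) + beta @ ridge
        w = np.clip(p * (1 - p), 1e-6, None) * mask
        Xw = w[:, :, :, None] * Xb[:, None, :, :]               # (F, folds, n, dd)
        H = np.einsum("fbnd,fne->fbde", Xw, Xb) + ridge
        step = np.linalg.solve(H, g[..., None])[..., 0]
        beta -= step
        if float(np.abs(step).max()) < tol:
            break
    z_test = np.einsum("fnd,fnd->fn", Xb, beta)                 # fold b tested on trial b
    pred = z_test > 0
    return (pred == (Y > 0.5)).T                                # (n, F)


def _standardize(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    return (X - mu) / np.where(sd < 1e-12, 1.0, sd)


def population_correct(
    data: np.ndarray,
    labels: np.ndarray,
    frames: np.ndarray,
    l2: float = 1.0,
    chunk: int = 64,
) -> np.ndarray:
    """Per-trial LOO logistic-regression correctness at the given frames.

    ``data`` is (neurons, trials, time); features are standardised per
    neuron across trials at each frame.  Returns (trials, len(frames)).
    """
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError("need exactly two classes")
    y = (np.asarray(labels) == classes[1]).astype(int)
    if min((y == 0).sum(), (y == 1).sum()) < 3:
        raise ValueError("need at least 3 trials per class")
    n, d = data.shape[1], data.shape[0]
    # keep the (F, folds, n, d+1) Newton intermediate near ~1e7 elements
    chunk = min(chunk, max(4, int(1e7 / max(1, n * n * (d + 1)))))
    out = np.empty((data.shape[1], len(frames)), dtype=bool)
    for s in range(0, len(frames), chunk):
        fs = frames[s:s + chunk]
        Xf = data[:, :, fs]                       # (neurons, trials, F)
        Xf = _standardize(Xf)
        Xf = np.ascontiguousarray(np.moveaxis(Xf, 0, -1))  # (trials, F, d) -> need (F,n,d)
        Xf = np.swapaxes(Xf, 0, 1)                # (F, trials, d)
        out[:, s:s + chunk] = _loo_logistic_correct(Xf, y, l2=l2)
    return out


@dataclass
class PopulationAccuracy:
    accuracy_ts: np.ndarray        # per evaluated frame
    frames: np.ndarray             # frame indices into the time axis
    max_in_bin: float              # max bin-averaged accuracy in the epoch
    best_bin: tuple[float, float]  # (start, end) s of the best bin
    correct: np.ndarray            # trials x frames correctness


def _bin_slices(time_axis: np.ndarray, frames: np.ndarray,
                epoch: tuple[float, float], bin_width: float):
    start, end = epoch
    n_bins = max(1, int(np.floor((end - start) / bin_width + 1e-9)))
    t = time_axis[frames]
    for b in range(n_bins):
        lo = start + b * bin_width
        sel = np.flatnonzero((t >= lo - 1e-9) & (t < lo + bin_width - 1e-9))
        if len(sel):
            yield (lo, lo + bin_width), sel


def population_accuracy(
    data: np.ndarray,
    labels: np.ndarray,
    time_axis: np.ndarray,
    epoch: tuple[float, float],
    bin_width: float = 0.250,
    eval_stride: int = 1,
    l2: float = 1.0,
) -> PopulationAccuracy:
    """Population LOO logistic decoding over the peri-movement epoch.

    Accuracy is computed per frame (optionally on a strided frame grid)
    and then averaged within non-overlapping 250 ms bins left-aligned to
    the epoch start; the summary is the maximum bin accuracy.
    """
    in_epoch = np.flatnonzero(
        (time_axis >= epoch[0] - 1e-9) & (time_axis < epoch[1] - 1e-9)
    )[::eval_stride]
    correct = population_correct(data, labels, in_epoch, l2=l2)
    acc = correct.mean(axis=0)
    best, best_bin = -1.0, (epoch[0], epoch[0] + bin_width)
    for (lo, hi), sel in _bin_slices(time_axis, in_epoch, epoch, bin_width):
        a = float(acc[sel].mean())
        if a > best:
            best, best_bin = a, (lo, hi)
    return PopulationAccuracy(acc, in_epoch, best, best_bin, correct)


def shuffle_accuracy_ci(
    data: np.ndarray,
    labels: np.ndarray,
    time_axis: np.ndarray,
    epoch: tuple[float, float],
    n_samples: int = 1000,
    level: float = 95.0,
    l2: float = 1.0,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Chance reference: LOO accuracy at randomly sampled time points with
    the trial labels randomised for each sample; returns the 95% interval.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    in_epoch = np.flatnonzero(
        (time_axis >= epoch[0] - 1e-9) & (time_axis < epoch[1] - 1e-9)
    )
    frames = rng.choice(in_epoch, size=n_samples, replace=True)
    classes = np.unique(labels)
    y = (np.asarray(labels) == classes[1]).astype(int)
    n = len(y)
    accs = np.empty(n_samples)
    chunk = max(4, int(1e7 / max(1, n * n * (data.shape[0] + 1))))
    for s in range(0, n_samples, chunk):
        fs = frames[s:s + chunk]
        Y = np.stack([rng.permutation(y) for _ in fs])          # (F, n)
        Xf = _standardize(data[:, :, fs])
        Xf = np.swapaxes(np.moveaxis(Xf, 0, -1), 0, 1)          # (F, n, d)
        correct = _loo_logistic_correct(Xf, Y, l2=l2)           # (n, F)
        accs[s:s + len(fs)] = correct.mean(axis=0)
    alpha = (100 - level) / 2
    return float(np.percentile(accs, alpha)), float(np.percentile(accs, 100 - alpha))


@dataclass
class RemovalCurve:
    n_removed: np.ndarray
    accuracy: np.ndarray               # max-in-bin accuracy per step
    accuracy_ci: np.ndarray            # (steps, 2) bootstrap CI over trials
    proportion_to_chance: float        # fraction removed at first chance overlap
    shuffle_ci: tuple[float, float]


def _curve_to_chance(acc_ci: np.ndarray, shuffle_ci: tuple[float, float],
                     n_total: int) -> float:
    lo_s, hi_s = shuffle_ci
    for step in range(acc_ci.shape[0]):
        lo, hi = acc_ci[step]
        if not (lo > hi_s or hi < lo_s):      # CIs overlap -> at chance
            return step / n_total
    return 1.0


def removal_curve(
    data: np.ndarray,
    labels: np.ndarray,
    time_axis: np.ndarray,
    epoch: tuple[float, float],
    single_accuracies: np.ndarray,
    order: str = "by_accuracy",
    n_random_reps: int = 25,
    bin_width: float = 0.250,
    eval_stride: int = 3,
    n_boot: int = 2000,
    l2: float = 1.0,
    rng: np.random.Generator | None = None,
    shuffle_ci: tuple[float, float] | None = None,
) -> RemovalCurve:
    """Accuracy versus number of neurons removed.

    ``order="by_accuracy"`` removes neurons in descending single-neuron
    accuracy (ties broken by index); ``order="random"`` repeats the
    removal ``n_random_reps`` times and uses the per-step median.  The
    decoder is retrained from scratch at every step; per-frame evaluation
    uses a strided grid inside the epoch (every ``eval_stride``-th frame)
    before bin averaging.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    n_neurons = data.shape[0]
    if shuffle_ci is None:
        shuffle_ci = shuffle_accuracy_ci(data, labels, time_axis, epoch,
                                         l2=l2, rng=rng)

    def eval_subset(keep: np.ndarray) -> tuple[float, tuple[float, float]]:
        pa = population_accuracy(data[keep], labels, time_axis, epoch,
                                 bin_width, eval_stride, l2)
        # bootstrap CI of the best bin's accuracy over trials
        (lo_b, hi_b) = pa.best_bin
        t = time_axis[pa.frames]
        fsel = np.flatnonzero((t >= lo_b - 1e-9) & (t < hi_b - 1e-9))
        per_trial = pa.correct[:, fsel].mean(axis=1)
        idx = rng.integers(0, len(per_trial), size=(n_boot, len(per_trial)))
        boot = per_trial[idx].mean(axis=1)
        return pa.max_in_bin, (float(np.percentile(boot, 2.5)),
                               float(np.percentile(boot, 97.5)))

    steps = n_neurons - 1  # keep at least one neuron
    if order == "by_accuracy":
        rank = np.lexsort((np.arange(n_neurons), -np.asarray(single_accuracies)))
        curves = np.empty((1, steps + 1))
        cis = np.empty((1, steps + 1, 2))
        keep = np.ones(n_neurons, dtype=bool)
        for step in range(steps + 1):
            a, ci = eval_subset(np.flatnonzero(keep))
            curves[0, step], cis[0, step] = a, ci
            if step < steps:
                keep[rank[step]] = False
        acc, ci_arr = curves[0], cis[0]
    elif order == "random":
        curves = np.empty((n_random_reps, steps + 1))
        cis = np.empty((n_random_reps, steps + 1, 2))
        for rep in range(n_random_reps):
            perm = rng.permutation(n_neurons)
            keep = np.ones(n_neurons, dtype=bool)
            for step in range(steps + 1):
                a, ci = eval_subset(np.flatnonzero(keep))
                curves[rep, step], cis[rep, step] = a, ci
                if step < steps:
                    keep[perm[step]] = False
        acc = np.median(curves, axis=0)
        ci_arr = np.median(cis, axis=0)
    else:
        raise ValueError(f"unknown order {order!r}")
    prop = _curve_to_chance(ci_arr, shuffle_ci, n_neurons)
    return RemovalCurve(np.arange(steps + 1), acc, ci_arr, prop, shuffle_ci)
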