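"""Signal preprocessing: motion index, LOESS smoothing, ΔF/F₀, motion-index
onset detection, trial alignment and fixed-length resampling.

The motion index quantifies gross forelimb movement from behavioural video:
for each consecutive frame pair the sum over masked pixels of squared
grayscale differences, ``MI_f = Σ_i (c_{f+1,i} − c_{f,i})²``.

ΔF/F₀ uses a per-neuron baseline F₀ defined as the 5th percentile of the
1 Hz low-pass filtered raw fluorescence; ΔF = F − F₀.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .datatypes import AlignedTensor


@dataclass
class MotionIndexSeries:
    """Per-frame motion index (squared grey-level units, ≥ 0)."""

    values: np.ndarray
    frame_rate: float
    onset_times: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < -1e-12):
            raise ValueError("motion index must be nonnegative")


@dataclass
class DeltaFTraces:
    """ΔF/F₀ traces with the per-neuron baseline that produced them."""

    dff: np.ndarray     # neurons x frames, dimensionless
    f0: np.ndarray      # per-neuron baseline, a.u., > 0
    frame_rate: float

    def __post_init__(self) -> None:
        if np.any(self.f0 <= 0):
            raise ValueError("f0 must be positive for every neuron")
        if not np.all(np.isfinite(self.dff)):
            raise ValueError("dff contains non-finite values")


def load_frame_stack(path, dataset: str = "frames") -> np.ndarray:
    """Load a grayscale frame stack from multi-page TIFF or HDF5.

    Returns a (n_frames, h, w) float array for
    :func:`compute_motion_index`.
    """
    import pathlib

    path = pathlib.Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        return np.asarray(tifffile.imread(path), dtype=float)
    import h5py

    with h5py.File(path, "r") as f:
        if dataset not in f:
            raise KeyError(f"dataset {dataset!r} not in {path.name}")
        return np.asarray(f[dataset][()], dtype=float)


def compute_motion_index(
    frames: np.ndarray, roi_mask: np.ndarray, frame_rate: float = 1.0
) -> MotionIndexSeries:
    """Sum of squared pixel differences between consecutive frames.

    Parameters
    ----------
    frames : (n_frames, h, w) array
        Grayscale image stack.
    roi_mask : (h, w) bool array
        Pixels to include (the forelimb region of interest).
    frame_rate : float
        Video frame rate in Hz (carried through, not used in the sum).

    Returns
    -------
    MotionIndexSeries with one value per consecutive frame pair
    (length ``n_frames − 1``).  Smoothing is the caller's choice
    (:func:`loess_smooth`).
    """
    frames = np.asarray(frames, dtype=float)
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if frames.ndim != 3 or frames.shape[0] < 2:
        raise ValueError("need a stack of at least 2 frames")
    if roi_mask.shape != frames.shape[1:]:
        raise ValueError("mask shape does not match frame shape")
    if not roi_mask.any():
        raise ValueError("empty ROI mask")
    diffs = np.diff(frames, axis=0)
    mi = np.einsum("fhw,hw->f", diffs**2, roi_mask.astype(float))
    return MotionIndexSeries(values=mi, frame_rate=frame_rate)


def _tricube(u: np.ndarray) -> np.ndarray:
    w = (1 - np.clip(np.abs(u), 0, 1) ** 3) ** 3
    return w


def loess_smooth(series: np.ndarray, span_s: float, frame_rate: float) -> np.ndarray:
    """LOESS: locally weighted linear regression with tricube weights.

    The window is ``span_s`` seconds wide, truncated (not padded) at the
    series boundaries.  For a uniformly sampled series the interior fit
    reduces to a fixed convolution (the symmetric tricube-weighted linear
    fit evaluated at the window centre equals the weighted mean), so only
    boundary points need explicit regressions.
    """
    y = np.asarray(series, dtype=float)
    n = len(y)
    half = int(round(span_s * frame_rate / 2))
    if 2 * half + 1 < 3:
        raise ValueError("span must cover at least 3 samples")
    half = min(half, n - 1)
    offsets = np.arange(-half, half + 1)
    w = _tricube(offsets / (half + 1))
    kernel = w / w.sum()
    out = np.convolve(y, kernel[::-1], mode="same")
    # boundary windows: truncated asymmetric tricube-weighted degree-1 fits
    for i in list(range(min(half, n))) + list(range(max(n - half, 0), n)):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        x = np.arange(lo, hi) - i
        wi = _tricube(x / (half + 1))
        X = np.stack([np.ones_like(x, dtype=float), x.astype(float)], axis=1)
        Xw = X * wi[:, None]
        beta, *_ = np.linalg.lstsq(Xw.T @ X, Xw.T @ y[lo:hi], rcond=None)
        out[i] = beta[0]
    return out


def compute_dff(raw: np.ndarray, frame_rate: float) -> DeltaFTraces:
    """ΔF/F₀ with F₀ = 5th percentile of the 1 Hz low-pass filtered trace.

    The low-pass filter is a zero-phase second-order Butterworth with a
    1 Hz cutoff (filtfilt, so no phase distortion of the baseline).
    """
    raw = np.atleast_2d(np.asarray(raw, dtype=float))
    if np.any(raw <= 0):
        raise ValueError("raw fluorescence must be strictly positive")
    if raw.shape[1] / frame_rate < 10:
        raise ValueError("recording shorter than 10 s; filter would not settle")
    sos = sps.butter(2, 1.0, btype="low", fs=frame_rate, output="sos")
    filtered = sps.sosfiltfilt(sos, raw, axis=1)
    f0 = np.percentile(filtered, 5, axis=1)
    if np.any(f0 <= 0):
        raise ValueError("nonpositive baseline after filtering")
    dff = (raw - f0[:, None]) / f0[:, None]
    return DeltaFTraces(dff=dff, f0=f0, frame_rate=frame_rate)


def _bootstrap_mean_upper(
    x: np.ndarray, n_boot: int, level: float, rng: np.random.Generator
) -> float:
    idx = rng.integers(0, len(x), size=(n_boot, len(x)))
    means = x[idx].mean(axis=1)
    return float(np.percentile(means, 50 + level / 2))


def detect_motion_onset(
    mi: MotionIndexSeries,
    cue_s: float,
    movement_s: float,
    mode: str = "imaging",
    baseline_s: float = 1.5,
    n_boot: int = 10_000,
    rng: np.random.Generator | None = None,
) -> float:
    """Movement onset from the motion index for one trial.

    imaging mode
        Threshold = upper bound of the 95% bootstrap CI of the mean MI in
        the pre-cue baseline (the ITI segment ``baseline_s`` seconds before
        the cue).  The onset is the start of the supra-threshold run that
        leads into the lever movement, i.e. the first point prior to
        movement where the (smoothed) MI exceeds the threshold.
    ephys mode
        Threshold = baseline mean + 2 SD over the 1.5 s before the cue; the
        onset is the first point after the cue above threshold.  If the MI
        is already above threshold at the cue, the trial is flagged for
        exclusion (NaN returned).

    Returns the onset in seconds, or NaN when the threshold is never
    crossed (or the trial is excluded).
    """
    fr = mi.frame_rate
    v = mi.values
    cue_i = int(round(cue_s * fr))
    move_i = int(round(movement_s * fr))
    base_lo = cue_i - int(round(baseline_s * fr))
    if base_lo < 0 or move_i >= len(v) or cue_i > move_i:
        raise ValueError("baseline or trial window out of range")
    baseline = v[base_lo:cue_i]
    if mode == "imaging":
        rng = np.random.default_rng(0) if rng is None else rng
        thr = _bootstrap_mean_upper(baseline, n_boot, 95.0, rng)
    elif mode == "ephys":
        thr = float(baseline.mean() + 2 * baseline.std(ddof=0))
    else:
        raise ValueError(f"unknown mode {mode!r}")

    above = v[cue_i : move_i + 1] > thr
    if mode == "ephys":
        if not above.any():
            return float("nan")
        first = int(np.argmax(above))
        if first == 0 and v[cue_i] > thr and cue_i > 0 and v[cue_i - 1] > thr:
            return float("nan")  # onset precedes the cue: excluded
        return (cue_i + first) / fr
    # imaging: walk back from the lever movement through the run above thr
    if not above.any():
        return float("nan")
    last = len(above) - 1
    if not above[last]:
        last = int(np.flatnonzero(above)[-1])
    start = last
    while start > 0 and above[start - 1]:
        start -= 1
    return (cue_i + start) / fr


def align_trials(
    traces: np.ndarray,
    events_s: np.ndarray,
    window: tuple[float, float],
    frame_rate: float,
    trial_labels: np.ndarray,
    alignment: str = "motion_onset",
) -> AlignedTensor:
    """Slice a (neurons × frames) matrix around per-trial events.

    Copies samples without interpolation; the time axis is zero at the
    event.  The window ``(pre, post)`` keeps ``round(pre·fr)`` samples
    before and ``round(post·fr)`` samples after the event frame (both
    endpoints included).  Trials whose window falls outside the recording
    are flagged invalid (NaN-filled), never silently dropped.
    """
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    events_s = np.asarray(events_s, dtype=float)
    pre_f = int(round(window[0] * frame_rate))
    post_f = int(round(window[1] * frame_rate))
    n_t = pre_f + post_f + 1
    n_neurons, n_frames = traces.shape
    data = np.full((n_neurons, len(events_s), n_t), np.nan)
    valid = np.zeros(len(events_s), dtype=bool)
    for k, ev in enumerate(events_s):
        c = int(round(ev * frame_rate))
        lo, hi = c - pre_f, c + post_f + 1
        if np.isnan(ev) or lo < 0 or hi > n_frames:
            continue
        data[:, k, :] = traces[:, lo:hi]
        valid[k] = True
    time_axis = (np.arange(n_t) - pre_f) / frame_rate
    return AlignedTensor(
        data=data,
        time_axis=time_axis,
        trial_labels=np.asarray(trial_labels),
        frame_rate=frame_rate,
        alignment=alignment,
        valid_trials=valid,
    )


def resample_trials_fixed_length(trials: list[np.ndarray], n_out: int) -> np.ndarray:
    """Linear interpolation of variable-length trials onto a common grid.

    Each trial is mapped onto ``n_out`` equally spaced points spanning its
    own duration (endpoints preserved).
    """
    if n_out < 2:
        raise ValueError("n_out must be at least 2")
    out = np.empty((len(trials), n_out))
    for k, tr in enumerate(trials):
        tr = np.asarray(tr, dtype=float)
        if len(tr) < 2:
            raise ValueError("each trial needs at least 2 samples")
        x_old = np.linspace(0.0, 1.0, len(tr))
        x_new = np.linspace(0.0, 1.0, n_out)
        out[k] = np.interp(x_new, x_old, tr)
    return out
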