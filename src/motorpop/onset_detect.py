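"""Slope-sum-function (SSF) onset detection for ΔF/F₀ transients.

The trace is Savitzky–Golay smoothed (27 frames, order 2 by default), the
first differences are clipped at zero, and the SSF at each frame is the
sum of positive slopes over a trailing 375 ms window.  The onset is the
first frame of the supra-threshold run that culminates in the SSF peak
(threshold = 10% of the peak), walked back to the preceding local SSF
minimum, then shifted by a correction factor.  Anchoring the crossing at
the peak's own run — rather than the globally earliest crossing — makes
the rule insensitive to spurious threshold crossings in the smoothed
baseline noise, whose position would otherwise depend on how much
baseline precedes the transient.  The peak search is restricted to the
peri-movement window.

The correction is not a free parameter: it is measured on simulated
linear-ramp transients with known onsets (the smoothing and the decision
rule both bias the raw estimate early) and then applied unchanged to
data.  Per-neuron onsets are the median of bootstrapped medians over
trials, which suppresses the influence of noisy individual trials.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import savgol_filter

from .datatypes import AlignedTensor, GroundTruth


@dataclass
class OnsetConfig:
    ssf_window: float = 0.375          # s
    sg_frames: int = 27                # Savitzky–Golay window, odd
    sg_order: int = 2
    peak_threshold_fraction: float = 0.10
    n_boot: int = 10_000
    correction: float = 0.0            # s, from calibrate_correction
    noise_gate_sd: float = 3.0         # peak must exceed baseline SSF mean + k·SD
    search_window: tuple[float, float] = (-2.5, 2.5)  # s, peri-movement peak search

    def validate(self) -> None:
        if self.sg_frames % 2 == 0 or self.sg_frames <= self.sg_order:
            raise ValueError("sg_frames must be odd and exceed sg_order")
        if not 0 < self.peak_threshold_fraction < 1:
            raise ValueError("peak_threshold_fraction must be in (0, 1)")


def slope_sum_function(trace: np.ndarray, frame_rate: float, config: OnsetConfig) -> np.ndarray:
    """SSF: trailing-window sum of positive slopes of the smoothed trace.

    Index ``j`` of the output corresponds to the slope arriving at sample
    ``j + 1`` of the input; the first window is truncated.
    """
    config.validate()
    if len(trace) <= config.sg_frames:
        raise ValueError("trace shorter than the smoothing window")
    smoothed = savgol_filter(trace, config.sg_frames, config.sg_order)
    slopes = np.clip(np.diff(smoothed), 0.0, None)
    w = max(1, int(round(config.ssf_window * frame_rate)))
    cs = np.concatenate([[0.0], np.cumsum(slopes)])
    idx = np.arange(len(slopes))
    lo = np.clip(idx - w + 1, 0, None)
    return cs[idx + 1] - cs[lo]


def ssf_onset_single_trial(
    trace: np.ndarray,
    time_axis: np.ndarray,
    frame_rate: float,
    config: OnsetConfig,
) -> float:
    """Onset time (s, same axis as ``time_axis``) of one trial, or NaN.

    Missing when the SSF peak does not exceed the noise gate: the mean +
    ``noise_gate_sd``·SD of the SSF over the pre-movement baseline
    (``time_axis < −0.25 s``), or simply zero when no baseline exists.
    """
    trace = np.asarray(trace, dtype=float)
    ssf = slope_sum_function(trace, frame_rate, config)
    t_ssf = time_axis[1:]  # slope j sits between samples j and j+1
    lo, hi = config.search_window
    in_search = (t_ssf >= lo) & (t_ssf <= hi)
    if not in_search.any():
        in_search = np.ones_like(t_ssf, dtype=bool)
    peak_idx = int(np.flatnonzero(in_search)[np.argmax(ssf[in_search])])
    peak = float(ssf[peak_idx])
    base = ssf[t_ssf < -0.25]
    gate = float(base.mean() + config.noise_gate_sd * base.std(ddof=0)) if len(base) else 0.0
    if peak <= max(gate, 0.0) or peak <= 0.0:
        return float("nan")
    thr = config.peak_threshold_fraction * peak
    i = peak_idx
    while i > 0 and ssf[i - 1] >= thr:   # back through the peak's own run
        i -= 1
    while i > 0 and ssf[i - 1] < ssf[i]:  # then to the local SSF minimum
        i -= 1
    return float(t_ssf[i] - config.correction)


def neuron_median_onset(
    trials_x_time: np.ndarray,
    time_axis: np.ndarray,
    frame_rate: float,
    config: OnsetConfig,
    rng: np.random.Generator | None = None,
) -> float:
    """Median of bootstrapped medians of per-trial SSF onsets.

    Trials with no detectable onset are excluded (never imputed); raises
    when no trial yields an onset.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    onsets = np.array([
        ssf_onset_single_trial(tr, time_axis, frame_rate, config)
        for tr in np.atleast_2d(trials_x_time)
    ])
    onsets = onsets[np.isfinite(onsets)]
    if len(onsets) == 0:
        raise ValueError("no trial-level onsets detected")
    idx = rng.integers(0, len(onsets), size=(config.n_boot, len(onsets)))
    return float(np.median(np.median(onsets[idx], axis=1)))


def calibrate_correction(
    calibration: AlignedTensor,
    truth: GroundTruth,
    config: OnsetConfig,
    min_detected: int = 10,
    rng: np.random.Generator | None = None,
) -> float:
    """Correction factor from a ramp calibration set with known onsets.

    Detects each cell's median onset with the uncorrected detector and
    returns ``median(detected − true)`` over cells; store the result into
    :class:`OnsetConfig` via :func:`calibrated_config`.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    raw = replace(config, correction=0.0)
    errors = []
    for i in range(calibration.n_neurons):
        try:
            det = neuron_median_onset(
                calibration.neuron(i), calibration.time_axis,
                calibration.frame_rate, raw, rng,
            )
        except ValueError:
            continue
        errors.append(det - truth.true_onset[i])
    if len(errors) < min_detected:
        raise ValueError(f"only {len(errors)} onsets detected; need {min_detected}")
    return float(np.median(errors))


def calibrated_config(
    config: OnsetConfig,
    calibration: AlignedTensor,
    truth: GroundTruth,
    rng: np.random.Generator | None = None,
) -> OnsetConfig:
    """Convenience: return a copy of ``config`` with the measured correction."""
    corr = calibrate_correction(calibration, truth, config, rng=rng)
    return replace(config, correction=corr)
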