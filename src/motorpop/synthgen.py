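"""Synthetic push/pull imaging sessions with known ground truth.

The generator emulates a head-fixed lever task recorded with a
GCaMP6s-like indicator: cued push and pull trials separated by 4–6 s
inter-trial intervals, somatic transients built from a
difference-of-exponentials kernel (0.5 s rise mimicking GCaMP6s, 1.5 s
decay by default), i.i.d. Gaussian photon noise on a positive baseline,
per-trial onset jitter, ROI centroids in a field of view, and a forelimb
motion index locked to movement initiation.

Planted neuron classes
----------------------
``invariant_up`` / ``invariant_down``
    equal (increased / decreased) ΔF/F₀ responses for push and pull.
``{push,pull}_type1..4``
    movement-bias types: 1 = increase in both movements, larger in the
    preferred one; 2 = increase in the preferred movement only; 3 =
    decrease in the preferred movement only; 4 = decrease in both,
    larger in the preferred one.
``reward_phase``
    transients starting 1.1 s after movement completion (the task inserts
    a 1 s delay between completion and reward delivery).
``non_responsive``
    baseline and noise only.

All defaults are the study conditions the rest of the package is
validated under; they are configurable but not re-tuned per analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import NEURON_CLASSES, AlignedTensor, GroundTruth, SessionData

#: Default class mix: 60% movement-invariant (85% increased / 15% decreased
#: activity), 15% push bias and 15% pull bias (type mix 75.1 / 13.8 / 8.3 /
#: 2.8% within each side), 10% non-responsive.
DEFAULT_PROPORTIONS: dict[str, float] = {
    "invariant_up": 0.51,
    "invariant_down": 0.09,
    "push_type1": 0.15 * 0.751,
    "push_type2": 0.15 * 0.138,
    "push_type3": 0.15 * 0.083,
    "push_type4": 0.15 * 0.028,
    "pull_type1": 0.15 * 0.751,
    "pull_type2": 0.15 * 0.138,
    "pull_type3": 0.15 * 0.083,
    "pull_type4": 0.15 * 0.028,
    "reward_phase": 0.0,
    "non_responsive": 0.10,
}


@dataclass
class SynthConfig:
    n_neurons: int = 100
    class_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PROPORTIONS)
    )
    n_push_trials: int = 40
    n_pull_trials: int = 40
    frame_rate: float = 40.0
    trial_window: tuple[float, float] = (2.0, 3.0)  # s (pre, post) around initiation
    kernel_rise: float = 0.5      # s, GCaMP6s-like rise
    kernel_decay: float = 1.5     # s
    effect_amplitude: float = 0.5  # ΔF/F₀ units (5 × default noise_sd)
    noise_sd: float = 0.1         # ΔF/F₀ units
    onset_jitter_sd: float = 0.05  # s
    fov_size: tuple[float, float] = (320.0, 320.0)  # µm
    spatial_clustering: bool = False
    cluster_radius_um: float = 40.0
    baseline_f: float = 100.0     # raw a.u.
    seed: int = 0

    def validate(self) -> None:
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_proportions sum to {total}, expected 1")
        unknown = set(self.class_proportions) - set(NEURON_CLASSES)
        if unknown:
            raise ValueError(f"unknown classes: {sorted(unknown)}")
        for name in ("kernel_rise", "kernel_decay", "noise_sd", "frame_rate"):
            if getattr(self, name) <= 0 and name != "noise_sd":
                raise ValueError(f"{name} must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_push_trials < 2 or self.n_pull_trials < 2:
            raise ValueError("need at least 2 trials per movement type")


#: (push, pull) amplitude multipliers per class, in units of effect_amplitude.
_CLASS_AMPLITUDES: dict[str, tuple[float, float]] = {
    "invariant_up": (1.0, 1.0),
    "invariant_down": (-1.0, -1.0),
    "push_type1": (1.0, 0.5),
    "push_type2": (1.0, 0.0),
    "push_type3": (-1.0, 0.0),
    "push_type4": (-1.0, -0.5),
    "pull_type1": (0.5, 1.0),
    "pull_type2": (0.0, 1.0),
    "pull_type3": (0.0, -1.0),
    "pull_type4": (-0.5, -1.0),
    "reward_phase": (1.0, 1.0),
    "non_responsive": (0.0, 0.0),
}


def allocate_classes(proportions: dict[str, float], n: int) -> np.ndarray:
    """Deterministic largest-remainder allocation of n neurons to classes."""
    names = [c for c in NEURON_CLASSES if proportions.get(c, 0.0) > 0]
    exact = np.array([proportions[c] * n for c in names])
    counts = np.floor(exact).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(exact - counts), kind="stable")
    counts[order[:remainder]] += 1
    labels = np.concatenate([[c] * k for c, k in zip(names, counts)])
    return labels.astype(object)


def transient_kernel(rise: float, decay: float, frame_rate: float) -> np.ndarray:
    """Difference-of-exponentials calcium kernel, normalised to peak 1."""
    t = np.arange(0, rise + 5 * decay, 1 / frame_rate)
    h = np.exp(-t / decay) - np.exp(-t / rise)
    peak = h.max()
    if peak <= 0:
        raise ValueError("degenerate kernel (rise >= decay scale)")
    return h / peak


def _build_trial_table(cfg: SynthConfig, rng: np.random.Generator) -> pd.DataFrame:
    types: list[str] = []
    np_, nl = cfg.n_push_trials, cfg.n_pull_trials
    while np_ or nl:
        if np_ and (len(types) % 2 == 0 or not nl):
            types.append("push")
            np_ -= 1
        else:
            types.append("pull")
            nl -= 1
    pre_pad = cfg.trial_window[0] + 2.5  # room for window + MI baseline
    rows = []
    t = pre_pad
    for k, ty in enumerate(types):
        cue = t
        init = cue + rng.uniform(0.2, 0.5)
        dur = rng.uniform(0.3, 0.5)
        completion = init + dur
        rows.append((k, ty, cue, init, completion, "success"))
        t = completion + rng.uniform(4.0, 6.0)  # randomised ITI
    return pd.DataFrame(rows, columns=[
        "trial_id", "type", "cue_s", "motion_onset_s", "completion_s", "outcome",
    ])


def _place_centroids(
    cfg: SynthConfig, classes: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    w, h = cfg.fov_size
    xy = np.column_stack([rng.uniform(0, w, len(classes)),
                          rng.uniform(0, h, len(classes))])
    if cfg.spatial_clustering:
        centers = {"push": np.array([w * 0.3, h * 0.3]),
                   "pull": np.array([w * 0.7, h * 0.7])}
        for side, c in centers.items():
            mask = np.array([str(cl).startswith(side) for cl in classes])
            k = int(mask.sum())
            pts = c + rng.normal(0, cfg.cluster_radius_um, size=(k, 2))
            xy[mask] = np.clip(pts, [0, 0], [w, h])
    return xy


def generate_session(config: SynthConfig) -> tuple[SessionData, GroundTruth]:
    """Generate one synthetic session plus its ground truth.

    Identical configs (including seed) give bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    fr = config.frame_rate
    classes = allocate_classes(config.class_proportions, config.n_neurons)
    trials = _build_trial_table(config, rng)
    duration = trials["completion_s"].iloc[-1] + config.trial_window[1] + \
        5 * config.kernel_decay + 3.0
    n_frames = int(math.ceil(duration * fr))
    kernel = transient_kernel(config.kernel_rise, config.kernel_decay, fr)

    amp_push = np.array([_CLASS_AMPLITUDES[c][0] for c in classes]) * config.effect_amplitude
    amp_pull = np.array([_CLASS_AMPLITUDES[c][1] for c in classes]) * config.effect_amplitude

    dff_true = np.zeros((config.n_neurons, n_frames))
    median_dur = float((trials["completion_s"] - trials["motion_onset_s"]).median())
    is_push = (trials["type"] == "push").to_numpy()
    inits = trials["motion_onset_s"].to_numpy()
    comps = trials["completion_s"].to_numpy()
    for i, cls in enumerate(classes):
        if cls == "non_responsive":
            continue
        amps = np.where(is_push, amp_push[i], amp_pull[i])
        if cls == "reward_phase":
            event_times = comps + 1.1
        else:
            event_times = inits
        jitter = rng.normal(0, config.onset_jitter_sd, size=len(event_times))
        for t0, a in zip(event_times + jitter, amps):
            if a == 0.0:
                continue
            f0 = int(round(t0 * fr))
            if f0 < 0 or f0 >= n_frames:
                continue
            seg = min(len(kernel), n_frames - f0)
            dff_true[i, f0:f0 + seg] += a * kernel[:seg]

    raw = config.baseline_f * (1.0 + dff_true)
    if config.noise_sd > 0:
        raw = raw + config.baseline_f * config.noise_sd * rng.standard_normal(raw.shape)
    raw = np.maximum(raw, 1e-3)  # raw fluorescence stays positive

    # motion index: half-sine bump spanning initiation -> completion
    mi = np.zeros(n_frames)
    t_axis = np.arange(n_frames) / fr
    for t0, t1 in zip(inits, comps):
        f0, f1 = int(round(t0 * fr)), int(round(t1 * fr))
        f1 = max(f1, f0 + 1)
        phase = (np.arange(f0, min(f1 + 1, n_frames)) - f0 + 1) / (f1 - f0 + 2)
        mi[f0:min(f1 + 1, n_frames)] += np.sin(np.pi * phase)
    if config.noise_sd > 0:
        mi = mi + (0.05 * rng.standard_normal(n_frames)) ** 2

    centroids = _place_centroids(config, classes, rng)
    true_onset = np.where(
        np.char.startswith(classes.astype(str), "reward"), median_dur + 1.1,
        np.where(classes.astype(str) == "non_responsive", np.nan, 0.0),
    )
    gt = GroundTruth(
        true_class=classes.astype(str),
        true_onset=true_onset,
        true_amplitude_push=amp_push,
        true_amplitude_pull=amp_pull,
        centroids_um=centroids,
    )
    session = SessionData(
        raw_f=raw,
        frame_rate=fr,
        trials=trials,
        centroids_um=centroids,
        cell_class=classes.astype(str),
        motion_index=mi,
        meta={"seed": config.seed, "generator": "motorpop.synthgen",
              "schema_version": 1, "time_axis_s": float(t_axis[-1])},
    )
    session.validate()
    return session, gt


def generate_ramp_calibration_set(
    n_cells: int = 100,
    n_trials: int = 30,
    rise: float = 0.5,
    noise_sd: float = 0.1,
    frame_rate: float = 30.0,
    seed: int = 0,
    window: tuple[float, float] = (1.0, 3.0),
) -> tuple[AlignedTensor, GroundTruth]:
    """Linear-ramp dataset for calibrating the onset detector.

    Each trial is a flat zero baseline followed by a linear ramp of
    duration ``rise`` starting at the cell's true onset, a plateau
    thereafter, and i.i.d. Gaussian noise of ``noise_sd``.  The standard
    design is 100 cells × 30 trials.
    """
    if n_cells < 1 or n_trials < 1:
        raise ValueError("need at least one cell and one trial")
    if rise <= 0:
        raise ValueError("rise must be positive")
    rng = np.random.default_rng(seed)
    pre, post = window
    n_t = int(round((pre + post) * frame_rate)) + 1
    time_axis = (np.arange(n_t) - int(round(pre * frame_rate))) / frame_rate
    onsets = rng.uniform(0.0, 0.5, size=n_cells)
    clean = np.empty((n_cells, n_t))
    for i, t0 in enumerate(onsets):
        clean[i] = np.clip((time_axis - t0) / rise, 0.0, 1.0)
    data = np.repeat(clean[:, None, :], n_trials, axis=1)
    if noise_sd > 0:
        data = data + rng.standard_normal(data.shape) * noise_sd
    gt = GroundTruth(
        true_class=np.array(["invariant_up"] * n_cells),
        true_onset=onsets,
        true_amplitude_push=np.ones(n_cells),
        true_amplitude_pull=np.ones(n_cells),
        centroids_um=np.zeros((n_cells, 2)),
    )
    tensor = AlignedTensor(
        data=data,
        time_axis=time_axis,
        trial_labels=np.array(["push"] * n_trials),
        frame_rate=frame_rate,
        alignment="motion_onset",
    )
    return tensor, gt
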