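"""Core containers shared across the pipeline.

All times are in seconds, frames are 0-based, distances are in micrometres
(µm), and fluorescence is either raw (arbitrary units) or ΔF/F₀
(dimensionless).  Windows are half-open ``[start, end)`` unless a function
documents otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

#: Neuron classes the synthetic generator can plant.  ``push_type1..4`` /
#: ``pull_type1..4`` follow the movement-bias taxonomy: type 1 = increased
#: activity in both movements (larger in the preferred one), type 2 =
#: increase in the preferred movement only, type 3 = decrease in the
#: preferred movement only, type 4 = decreased activity in both movements.
NEURON_CLASSES = (
    "invariant_up",
    "invariant_down",
    "push_type1",
    "push_type2",
    "push_type3",
    "push_type4",
    "pull_type1",
    "pull_type2",
    "pull_type3",
    "pull_type4",
    "reward_phase",
    "non_responsive",
)

TRIAL_TABLE_COLUMNS = (
    "trial_id",
    "type",
    "cue_s",
    "motion_onset_s",
    "completion_s",
    "outcome",
)


class Responsiveness(str, Enum):
    MOVEMENT_RELATED = "movement_related"
    REWARD_PHASE = "reward_phase"
    NON_RESPONSIVE = "non_responsive"
    UNCLASSIFIABLE = "unclassifiable"


class Bias(str, Enum):
    INVARIANT = "invariant"
    PUSH = "push"
    PULL = "pull"


@dataclass
class SessionData:
    """One recording session.

    Attributes
    ----------
    raw_f : (n_neurons, n_frames) float array
        Raw fluorescence, arbitrary units, strictly positive.
    frame_rate : float
        Imaging frame rate in Hz.
    trials : pandas.DataFrame
        One row per trial with columns :data:`TRIAL_TABLE_COLUMNS`;
        ``type`` is ``"push"`` or ``"pull"``, times in seconds from the
        start of the recording, ``outcome`` is ``"success"`` or ``"fail"``.
    centroids_um : (n_neurons, 2) float array
        ROI centroid coordinates in µm within the field of view.
    cell_class : optional array of str
        Projection/class labels when known (synthetic ground truth or
        PT/IT identity).
    motion_index : optional (n_frames,) array
        Behavioural motion index resampled to the imaging frame clock.
    meta : dict
        Provenance (seed, animal/fov ids, schema version, ...).
    """

    raw_f: np.ndarray
    frame_rate: float
    trials: pd.DataFrame
    centroids_um: np.ndarray
    cell_class: np.ndarray | None = None
    motion_index: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_neurons(self) -> int:
        return self.raw_f.shape[0]

    @property
    def n_frames(self) -> int:
        return self.raw_f.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate

    def validate(self) -> None:
        """Raise ``ValueError`` on any violated invariant."""
        if self.raw_f.ndim != 2:
            raise ValueError("raw_f must be neurons x frames")
        if not np.all(np.isfinite(self.raw_f)):
            raise ValueError("raw_f contains non-finite values")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.centroids_um.shape != (self.n_neurons, 2):
            raise ValueError("centroids_um must be (n_neurons, 2)")
        missing = set(TRIAL_TABLE_COLUMNS) - set(self.trials.columns)
        if missing:
            raise ValueError(f"trial table missing columns: {sorted(missing)}")
        times = self.trials[["cue_s", "motion_onset_s", "completion_s"]].to_numpy()
        if np.any(times < 0) or np.any(times > self.duration_s):
            raise ValueError("trial times outside the recording span")
        if np.any(np.diff(times, axis=1) < 0):
            raise ValueError("trial times are unordered (cue <= onset <= completion)")
        if self.motion_index is not None and len(self.motion_index) != self.n_frames:
            raise ValueError("motion_index length does not match frame count")


@dataclass
class GroundTruth:
    """Per-neuron generative truth for synthetic sessions."""

    true_class: np.ndarray            # str per neuron, from NEURON_CLASSES
    true_onset: np.ndarray            # s relative to movement initiation
    true_amplitude_push: np.ndarray   # ΔF/F₀ units
    true_amplitude_pull: np.ndarray   # ΔF/F₀ units
    centroids_um: np.ndarray          # (n, 2) µm

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "neuron": np.arange(len(self.true_class)),
                "true_class": self.true_class,
                "true_onset_s": self.true_onset,
                "true_amplitude_push": self.true_amplitude_push,
                "true_amplitude_pull": self.true_amplitude_pull,
                "x_um": self.centroids_um[:, 0],
                "y_um": self.centroids_um[:, 1],
            }
        )


@dataclass
class AlignedTensor:
    """Trial-aligned signal: neurons × trials × time.

    ``time_axis`` is in seconds relative to the alignment event and has
    uniform spacing ``1/frame_rate``.
    """

    data: np.ndarray
    time_axis: np.ndarray
    trial_labels: np.ndarray          # "push" | "pull" per trial
    frame_rate: float
    alignment: str = "motion_onset"   # motion_onset | cue | movement_completion
    valid_trials: np.ndarray | None = None  # bool mask, False = out-of-range

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("data must be neurons x trials x time")
        if len(self.time_axis) != self.data.shape[2]:
            raise ValueError("time_axis length mismatch")
        if len(self.trial_labels) != self.data.shape[1]:
            raise ValueError("trial_labels length mismatch")
        dt = np.diff(self.time_axis)
        if len(dt) and (np.any(dt <= 0) or not np.allclose(dt, dt[0], atol=1e-9)):
            raise ValueError("time_axis must be strictly increasing and uniform")
        if self.valid_trials is None:
            self.valid_trials = np.ones(self.data.shape[1], dtype=bool)

    @property
    def n_neurons(self) -> int:
        return self.data.shape[0]

    @property
    def n_trials(self) -> int:
        return self.data.shape[1]

    def neuron(self, i: int) -> np.ndarray:
        """Trials × time slice for one neuron."""
        return self.data[i]

    def select_trials(self, mask: np.ndarray) -> "AlignedTensor":
        return AlignedTensor(
            data=self.data[:, mask],
            time_axis=self.time_axis,
            trial_labels=self.trial_labels[mask],
            frame_rate=self.frame_rate,
            alignment=self.alignment,
            valid_trials=np.asarray(self.valid_trials)[mask],
        )
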