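"""Core in-memory containers shared by all analysis stages."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["StimulusEvent", "SessionRecording", "GroundTruth", "TrialTensor"]


@dataclass(frozen=True)
class StimulusEvent:
    """A single stimulus delivery: onset (s from recording start), panel label,
    and within-stimulus trial counter."""

    onset_s: float
    label: str
    trial_index: int

    def __post_init__(self) -> None:
        if self.onset_s < 0:
            raise ValueError(f"event onset must be >= 0, got {self.onset_s}")
        if self.trial_index < 0:
            raise ValueError("trial_index must be >= 0")


@dataclass
class SessionRecording:
    """One animal-session of miniscope data.

    traces are raw fluorescence (neurons x frames, arbitrary units);
    behavior is a scope-mounted accelerometer stream (g) with one sample
    per imaging frame.
    """

    traces: np.ndarray
    centroids: np.ndarray
    events: list[StimulusEvent]
    behavior: np.ndarray
    animal_id: str
    session_id: str
    day: int
    frame_rate: float
    condition: str = "normal"
    footprints: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.traces = np.asarray(self.traces)
        if not np.issubdtype(self.traces.dtype, np.floating):
            self.traces = self.traces.astype(float)
        self.behavior = np.asarray(self.behavior)
        if not np.issubdtype(self.behavior.dtype, np.floating):
            self.behavior = self.behavior.astype(float)
        if self.traces.ndim != 2:
            raise ValueError("traces must be neurons x frames")
        if self.behavior.shape[0] != self.n_frames:
            raise ValueError(
                f"behavior length {self.behavior.shape[0]} != frame count {self.n_frames}")
        if self.condition not in ("normal", "neuropathic", "uninjured_control"):
            raise ValueError(f"unknown condition {self.condition!r}")
        onsets = [e.onset_s for e in self.events]
        if onsets != sorted(onsets):
            raise ValueError("events must be sorted by onset time")
        duration = self.n_frames / self.frame_rate
        if onsets and onsets[-1] >= duration:
            raise ValueError("event onset beyond recording duration")

    @property
    def n_neurons(self) -> int:
        return self.traces.shape[0]

    @property
    def n_frames(self) -> int:
        return self.traces.shape[1]


@dataclass
class GroundTruth:
    """Planted truth for a synthetic session (the oracle for recovery tests)."""

    stimulus_panel: tuple[str, ...]
    tuning_matrix: np.ndarray              # neurons x stimuli, bool
    is_ensemble: np.ndarray                # neurons, bool: latent nociceptive class
    is_pain_specific: np.ndarray           # neurons, bool
    global_cell_ids: np.ndarray            # neurons, int
    planted_transients: list[np.ndarray]   # per neuron, (n_events, 2): onset_s, amplitude dF/F
    planted_behavior_amplitudes: np.ndarray  # per trial affective amplitude (NaN if none)
    planted_activation: np.ndarray         # per trial planted ensemble-activation fraction (NaN off-panel)

    def __post_init__(self) -> None:
        if self.tuning_matrix.shape[1] != len(self.stimulus_panel):
            raise ValueError("tuning_matrix columns must match stimulus panel")


@dataclass
class TrialTensor:
    """Stimulus-aligned trial windows: trials x neurons x frames.

    Values are dF/F after :func:`nociscope.preprocessing.slice_trials` and
    per-trial baseline z-scores after :func:`zscore_trials`.
    """

    values: np.ndarray
    trial_labels: np.ndarray
    window: tuple[float, float]            # (pre_s, post_s)
    frame_rate: float
    baseline_window: tuple[float, float] = (-5.0, 0.0)
    zscored: bool = False
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.trial_labels = np.asarray(self.trial_labels)
        if self.values.ndim != 3:
            raise ValueError("values must be trials x neurons x frames")
        if self.values.shape[0] != self.trial_labels.shape[0]:
            raise ValueError("one label per trial required")
        pre, post = self.window
        expect = int(round((pre + post) * self.frame_rate))
        if self.values.shape[2] != expect:
            raise ValueError(
                f"frame count {self.values.shape[2]} != round((pre+post)*rate) = {expect}")
        if self.baseline_window[1] > 0:
            raise ValueError("baseline window must precede stimulus onset")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.values.shape[1]

    @property
    def onset_frame(self) -> int:
        return int(round(self.window[0] * self.frame_rate))

    def frames_for(self, start_s: float, end_s: float) -> slice:
        """Half-open frame slice for a window given in seconds relative to onset."""
        a = self.onset_frame + int(round(start_s * self.frame_rate))
        b = self.onset_frame + int(round(end_s * self.frame_rate))
        return slice(a, b)
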