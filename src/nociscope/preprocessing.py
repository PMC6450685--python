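"""dF/F computation, stimulus-aligned trial slicing, and per-trial z-scoring.

Conventions: stimulus onset maps to frame index ceil(onset_s * frame_rate);
all windows are half-open [start, end) on 0-based frames.  Defaults bracket
the GCaMP6m decay: 5 s of pre-stimulus baseline, 10 s post.
"""

from __future__ import annotations

import logging
import math
import warnings

import numpy as np

from .types import SessionRecording, TrialTensor

__all__ = ["compute_dff", "slice_trials", "zscore_trials"]

logger = logging.getLogger(__name__)

SIGMA_FLOOR = 1e-6


def compute_dff(raw_trace: np.ndarray, percentile: float = 20.0) -> np.ndarray:
    """dF/F with a percentile baseline: F0 = given percentile of the whole
    trace, dF/F = (F - F0) / max(F0, eps).

    Accepts a 1-D trace or a neurons x frames matrix (row-wise F0).
    """
    x = np.asarray(raw_trace, dtype=float)
    if not 0 < percentile < 100:
        raise ValueError(f"percentile must be in (0, 100), got {percentile}")
    if x.shape[-1] < 2:
        raise ValueError("trace must contain at least 2 frames")
    f0 = np.percentile(x, percentile, axis=-1, keepdims=True)
    eps = 1e-9 * np.max(np.abs(x), axis=-1, keepdims=True)
    denom = np.maximum(f0, eps)
    if np.any(denom <= 0):
        warnings.warn("non-positive baseline; dF/F floored to zero where degenerate")
        denom = np.where(denom <= 0, 1.0, denom)
        return np.where(np.ptp(x, axis=-1, keepdims=True) == 0,
                        0.0, (x - f0) / denom)
    return (x - f0) / denom


def slice_trials(session: SessionRecording, pre_s: float = 5.0,
                 post_s: float = 10.0, traces: np.ndarray | None = None,
                 percentile: float = 20.0) -> TrialTensor:
    """Cut one aligned window per stimulus event from the session's dF/F.

    ``traces`` may supply precomputed dF/F (neurons x frames); otherwise
    dF/F is derived from the raw session traces.  Events whose window falls
    outside the recording are dropped with a logged count.
    """
    if pre_s <= 0 or post_s <= 0:
        raise ValueError("pre_s and post_s must be > 0")
    dff = compute_dff(session.traces, percentile) if traces is None \
        else np.asarray(traces, dtype=float)
    fr = session.frame_rate
    pre_f = int(round(pre_s * fr))
    post_f = int(round(post_s * fr))
    n_frames = dff.shape[1]

    slices, labels = [], []
    dropped = 0
    for ev in session.events:
        onset = int(math.ceil(ev.onset_s * fr))
        a, b = onset - pre_f, onset + post_f
        if a < 0 or b > n_frames:
            dropped += 1
            continue
        slices.append(dff[:, a:b])
        labels.append(ev.label)
    if dropped:
        logger.warning("slice_trials: dropped %d/%d events with out-of-bounds windows",
                       dropped, len(session.events))
    if not slices:
        raise ValueError("no usable events: every trial window exceeded the recording")
    return TrialTensor(values=np.stack(slices, axis=0).transpose(0, 1, 2),
                       trial_labels=np.array(labels),
                       window=(pre_s, post_s), frame_rate=fr,
                       baseline_window=(-pre_s, 0.0), n_dropped=dropped)


def zscore_trials(tensor: TrialTensor,
                  baseline_window: tuple[float, float] | None = None) -> TrialTensor:
    """Per-trial, per-neuron z-score against the pre-onset baseline window.

    z = (x - mu_baseline) / max(sigma_baseline, 1e-6); baseline statistics
    use only frames inside ``baseline_window`` (seconds relative to onset,
    default the tensor's own pre-window).
    """
    bw = tensor.baseline_window if baseline_window is None else baseline_window
    if bw[1] > 0 or bw[0] >= bw[1]:
        raise ValueError("baseline window must be a non-empty pre-onset interval")
    sl = tensor.frames_for(bw[0], bw[1])
    n_base = sl.stop - sl.start
    if n_base < 5:
        raise ValueError(f"baseline window holds {n_base} frames; need >= 5")
    base = tensor.values[:, :, sl]
    mu = base.mean(axis=2, keepdims=True)
    sd = np.maximum(base.std(axis=2, keepdims=True), SIGMA_FLOOR)
    return TrialTensor(values=(tensor.values - mu) / sd,
                       trial_labels=tensor.trial_labels,
                       window=tensor.window, frame_rate=tensor.frame_rate,
                       baseline_window=bw, zscored=True,
                       n_dropped=tensor.n_dropped)
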