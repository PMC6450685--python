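"""Accelerometer scoring: reflexive vs affective-motivational components,
and behavior-ensemble correlation.

A trial's reflexive peak is the maximum |acceleration| in the first second
after onset (withdrawal); its affective peak is the maximum in the 1-10 s
window (attending / escape).  Both are measured after subtracting the
median of the pre-onset baseline.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .stats import spearman

__all__ = ["score_trial_behavior", "behavior_ensemble_correlation",
           "session_affective_score"]

logger = logging.getLogger(__name__)

REFLEX_WINDOW: tuple[float, float] = (0.0, 1.0)
AFFECTIVE_WINDOW: tuple[float, float] = (1.0, 10.0)


def score_trial_behavior(behavior: np.ndarray, events, frame_rate: float,
                         reflex_window: tuple[float, float] = REFLEX_WINDOW,
                         affective_window: tuple[float, float] = AFFECTIVE_WINDOW,
                         baseline_window: tuple[float, float] = (-5.0, 0.0)
                         ) -> pd.DataFrame:
    """Per-trial reflexive and affective peaks (g) from an accelerometer
    stream sampled at the imaging frame rate.

    Trials whose windows exceed the stream are dropped with a logged count.
    """
    if reflex_window[1] > affective_window[0]:
        raise ValueError("reflex window must precede the affective window")
    a = np.asarray(behavior, dtype=float)
    n = len(a)

    def frames(onset_s: float, window: tuple[float, float]) -> tuple[int, int]:
        onset = int(math.ceil(onset_s * frame_rate))
        lo = onset + int(round(window[0] * frame_rate))
        hi = onset + int(round(window[1] * frame_rate))
        return lo, hi

    rows, dropped = [], 0
    for ev in events:
        b_lo, b_hi = frames(ev.onset_s, baseline_window)
        r_lo, r_hi = frames(ev.onset_s, reflex_window)
        f_lo, f_hi = frames(ev.onset_s, affective_window)
        if b_lo < 0 or f_hi > n:
            dropped += 1
            continue
        baseline = np.median(a[b_lo:b_hi])
        centered = a - baseline
        rows.append({
            "trial_index": ev.trial_index, "stimulus": ev.label,
            "onset_s": ev.onset_s,
            "reflexive_peak": float(np.max(np.abs(centered[r_lo:r_hi]))),
            "affective_peak": float(np.max(np.abs(centered[f_lo:f_hi]))),
        })
    if dropped:
        logger.warning("score_trial_behavior: dropped %d/%d trials outside the stream",
                       dropped, len(events))
    return pd.DataFrame(rows)


def session_affective_score(metrics: pd.DataFrame,
                            stimuli: tuple[str, ...]) -> float:
    """Session-level behavior summary: mean affective peak over the given
    (typically noxious) stimuli."""
    sub = metrics[metrics["stimulus"].isin(stimuli)]
    if sub.empty:
        return float("nan")
    return float(sub["affective_peak"].mean())


def behavior_ensemble_correlation(activations, behaviors, groups=None) -> dict:
    """Session-level Spearman correlation between ensemble activation and
    affective behavior, per condition group.

    ``activations`` and ``behaviors`` are equal-length per-session values;
    ``groups`` gives each session's condition label (a single pooled group
    when omitted).  Requires >= 5 sessions per group.
    """
    act = np.asarray(activations, dtype=float)
    beh = np.asarray(behaviors, dtype=float)
    if act.shape != beh.shape:
        raise ValueError("activations and behaviors must align per session")
    if groups is None:
        groups = np.full(len(act), "all")
    groups = np.asarray(groups)
    out = {}
    for g in dict.fromkeys(groups.tolist()):
        mask = groups == g
        if mask.sum() < 5:
            raise ValueError(f"group {g!r} has {int(mask.sum())} sessions; need >= 5")
        out[g] = spearman(act[mask], beh[mask])
    return out
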