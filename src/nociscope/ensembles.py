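"""Responder classification against a circular-shift null, nociceptive-ensemble
definition, overlap (Venn) quantification, and per-trial ensemble activation.

The responder statistic for a (neuron, stimulus) pair is the mean over that
stimulus's trials of the mean z-scored dF/F inside the response window
(default the first 2 s after onset).  The null preserves each trial's
autocorrelation by circularly shifting the whole trial trace by an
independent uniform offset (never zero); one-sided p-values
(1 + #{null >= observed}) / (1 + n_shuffles) are corrected by
Benjamini-Hochberg across neurons within each (session, stimulus).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from ._rng import substream
from .config import NOXIOUS_STIMULI
from .stats import benjamini_hochberg
from .types import TrialTensor

__all__ = [
    "classify_responders", "define_ensembles", "overlap_counts",
    "ensemble_activation", "EnsembleSets", "RESPONSE_WINDOW",
]

#: Response window (s, relative to onset) used by responder classification,
#: decoding features, and ensemble activation.
RESPONSE_WINDOW: tuple[float, float] = (0.0, 2.0)


def _circular_window_means(z: np.ndarray, start: int, length: int) -> np.ndarray:
    """Mean of each length-``length`` circular window for every start frame.

    z is trials x neurons x frames; returns trials x neurons x frames where
    entry [..., s] is the mean of z over frames s..s+length-1 (mod frames).
    The observed (unshifted) statistic sits at index ``start``.
    """
    t, n, f = z.shape
    ext = np.concatenate([z, z[:, :, :length - 1]], axis=2)
    cs = np.cumsum(ext, axis=2)
    zero = np.zeros((t, n, 1))
    cs = np.concatenate([zero, cs], axis=2)
    return (cs[:, :, length:length + f] - cs[:, :, :f]) / length


def classify_responders(tensor: TrialTensor, n_shuffles: int = 1000,
                        q_threshold: float = 0.05, seed: int = 0,
                        response_window: tuple[float, float] = RESPONSE_WINDOW,
                        min_trials: int = 5) -> pd.DataFrame:
    """Per-(neuron, stimulus) responder table for one session.

    Returns a DataFrame with columns neuron, stimulus, effect (observed mean
    response-window z), null_percentile, p_value, q_value, responsive.
    """
    if not tensor.zscored:
        raise ValueError("classify_responders expects a z-scored TrialTensor")
    if n_shuffles < 1000:
        raise ValueError("n_shuffles must be >= 1000 for stable tail estimates")
    sl = tensor.frames_for(*response_window)
    length = sl.stop - sl.start
    if length < 1:
        raise ValueError("empty response window")
    n_frames = tensor.values.shape[2]
    wm = _circular_window_means(tensor.values, sl.start, length)
    obs_all = wm[:, :, sl.start]                       # trials x neurons

    rng = substream(seed, "responders")
    labels = np.asarray(tensor.trial_labels)
    stimuli = list(dict.fromkeys(labels.tolist()))     # stable order of appearance
    rows = []
    for stim in stimuli:
        trials = np.flatnonzero(labels == stim)
        if trials.size < min_trials:
            raise ValueError(
                f"stimulus {stim!r} has {trials.size} trials; need >= {min_trials}")
        obs = obs_all[trials].mean(axis=0)             # neurons
        # circular shift of trial t by offset o reads the window at
        # (start - o) mod frames; offsets are uniform on 1..frames-1
        offsets = rng.integers(1, n_frames, size=(n_shuffles, trials.size))
        starts = (sl.start - offsets) % n_frames
        null = wm[trials[None, :], :, starts].mean(axis=1)   # shuffles x neurons
        ge = (null >= obs[None, :]).sum(axis=0)
        p = (1.0 + ge) / (1.0 + n_shuffles)
        pct = 100.0 * (null < obs[None, :]).mean(axis=0)
        reject, q = benjamini_hochberg(p, q_threshold)
        for i in range(tensor.n_neurons):
            rows.append((i, stim, obs[i], pct[i], p[i], q[i], bool(reject[i])))
    return pd.DataFrame(rows, columns=["neuron", "stimulus", "effect",
                                       "null_percentile", "p_value", "q_value",
                                       "responsive"])


@dataclass
class EnsembleSets:
    """Responder sets of one session and the derived nociceptive ensemble."""

    n_neurons: int
    responders: dict[str, frozenset]
    nociceptive: frozenset
    pain_specific: frozenset
    fractions: dict[str, float] = field(default_factory=dict)

    def fraction_of_ensemble(self, stimulus: str) -> float:
        if not self.nociceptive:
            return float("nan")
        return len(self.responders[stimulus] & self.nociceptive) / len(self.nociceptive)


def define_ensembles(table: pd.DataFrame,
                     noxious: tuple[str, ...] = NOXIOUS_STIMULI,
                     n_neurons: int | None = None) -> EnsembleSets:
    """Nociceptive ensemble (union of noxious responder sets) and the
    pain-specific subset (no non-noxious response) from a responder table."""
    present = set(table["stimulus"].unique())
    missing = set(noxious) - present
    if missing:
        raise ValueError(f"responder table lacks noxious stimuli: {sorted(missing)}")
    if n_neurons is None:
        n_neurons = int(table["neuron"].max()) + 1 if len(table) else 0
    responders = {
        stim: frozenset(grp.loc[grp["responsive"], "neuron"].astype(int))
        for stim, grp in table.groupby("stimulus", sort=False)
    }
    nociceptive = frozenset().union(*(responders[s] for s in noxious))
    non_noxious = [s for s in responders if s not in noxious]
    specific = frozenset(
        n for n in nociceptive
        if not any(n in responders[s] for s in non_noxious))
    fractions = {}
    if n_neurons:
        fractions = {s: len(r) / n_neurons for s, r in responders.items()}
        fractions["nociceptive"] = len(nociceptive) / n_neurons
        fractions["pain_specific"] = len(specific) / n_neurons
    return EnsembleSets(n_neurons=n_neurons, responders=responders,
                        nociceptive=nociceptive, pain_specific=specific,
                        fractions=fractions)


def overlap_counts(sets: EnsembleSets, stimuli: list[str]) -> pd.DataFrame:
    """Counts and fractions for every exclusive region of the Venn partition
    over the requested sets.

    ``stimuli`` entries name responder sets, or the special label
    ``"nociceptive"`` for the derived ensemble.  Fractions are reported
    relative to all active neurons and to the nociceptive ensemble.
    """
    if len(stimuli) > 5:
        raise ValueError("Venn partition limited to 5 sets")
    members = []
    for s in stimuli:
        if s == "nociceptive":
            members.append(set(sets.nociceptive))
        elif s in sets.responders:
            members.append(set(sets.responders[s]))
        else:
            raise KeyError(f"unknown set label {s!r}")
    n_active = sets.n_neurons
    n_ens = len(sets.nociceptive)
    rows = []
    for pattern in product((True, False), repeat=len(stimuli)):
        if not any(pattern):
            continue
        region = None
        for inside, grp in zip(pattern, members):
            if inside:
                region = set(grp) if region is None else region & grp
        for inside, grp in zip(pattern, members):
            if not inside:
                region -= grp
        count = len(region)
        rows.append({
            "region": "&".join(s for s, b in zip(stimuli, pattern) if b),
            **{f"in_{s}": b for s, b in zip(stimuli, pattern)},
            "count": count,
            "frac_active": count / n_active if n_active else float("nan"),
            "frac_ensemble": count / n_ens if n_ens else float("nan"),
        })
    return pd.DataFrame(rows)


def ensemble_activation(tensor: TrialTensor, ensemble, z_active: float = 2.0,
                        response_window: tuple[float, float] = RESPONSE_WINDOW
                        ) -> np.ndarray:
    """Per-trial fraction of ensemble neurons whose mean response-window z
    reaches ``z_active``."""
    ensemble = sorted(ensemble)
    if not ensemble:
        raise ValueError("ensemble is empty")
    if not tensor.zscored:
        raise ValueError("ensemble_activation expects a z-scored TrialTensor")
    sl = tensor.frames_for(*response_window)
    resp = tensor.values[:, ensemble, sl].mean(axis=2)
    return (resp >= z_active).mean(axis=1)
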