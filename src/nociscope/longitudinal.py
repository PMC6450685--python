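"""Cross-day cell registration and chronic-pain ensemble metrics.

Registration uses a translation-only drift model: the rigid offset between
two sessions is estimated as the componentwise median of nearest-neighbor
displacements, then corrected centroids are matched one-to-one by Hungarian
assignment with a hard distance gate.  Chains of day pairs propagate global
cell identities; a cell missing on an intermediate day terminates its chain
(no gap-jumping).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial import cKDTree

from .config import NOXIOUS_STIMULI
from .ensembles import EnsembleSets

__all__ = [
    "RegistrationPair", "RegistrationMap", "register_pair", "chain_days",
    "stable_responder_fraction", "allodynia_expansion_index",
    "light_touch_ensemble_fraction",
]


@dataclass
class RegistrationPair:
    """One-to-one correspondence between two sessions' neurons."""

    matches: np.ndarray          # (k, 2) int: neuron index in a, in b
    distances: np.ndarray        # (k,) px, after translation correction
    translation: np.ndarray      # (2,) estimated b - a rigid offset
    unmatched_a: np.ndarray
    unmatched_b: np.ndarray
    max_distance: float
    day_a: int | None = None
    day_b: int | None = None


@dataclass
class RegistrationMap:
    """Global cell identities across an ordered day grid."""

    days: tuple[int, ...]
    global_ids: dict            # (day, neuron) -> global id
    pairs: list

    def neurons_on(self, day: int) -> dict:
        return {n: g for (d, n), g in self.global_ids.items() if d == day}

    def gids_spanning(self, first: int, last: int) -> set:
        a = set(self.neurons_on(first).values())
        b = set(self.neurons_on(last).values())
        return a & b

    def to_frame(self) -> pd.DataFrame:
        rows = [{"day": d, "neuron": n, "global_id": g}
                for (d, n), g in sorted(self.global_ids.items())]
        return pd.DataFrame(rows)


def register_pair(centroids_a: np.ndarray, centroids_b: np.ndarray,
                  max_distance: float = 5.0, day_a: int | None = None,
                  day_b: int | None = None) -> RegistrationPair:
    """Match two days' centroid clouds (translation correction + Hungarian)."""
    a = np.asarray(centroids_a, dtype=float)
    b = np.asarray(centroids_b, dtype=float)
    if a.ndim != 2 or b.ndim != 2 or a.shape[0] == 0 or b.shape[0] == 0:
        raise ValueError("both days need at least one centroid (n x 2 arrays)")

    tree = cKDTree(b)
    _, nearest = tree.query(a)
    translation = np.median(b[nearest] - a, axis=0)

    shifted = a + translation
    diff = shifted[:, None, :] - b[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=2))
    # forbid pairings beyond the gate but keep the problem feasible
    big = max_distance * 1e6 + 1.0
    cost = np.where(dist <= max_distance, dist, big)
    rows, cols = linear_sum_assignment(cost)
    keep = dist[rows, cols] <= max_distance
    matches = np.column_stack([rows[keep], cols[keep]]).astype(int)
    matched_a = set(matches[:, 0].tolist())
    matched_b = set(matches[:, 1].tolist())
    return RegistrationPair(
        matches=matches, distances=dist[rows[keep], cols[keep]],
        translation=translation,
        unmatched_a=np.array(sorted(set(range(len(a))) - matched_a)),
        unmatched_b=np.array(sorted(set(range(len(b))) - matched_b)),
        max_distance=max_distance, day_a=day_a, day_b=day_b)


def chain_days(fragments: list[RegistrationPair]) -> RegistrationMap:
    """Propagate global ids along an ordered path of day pairs.

    Fragments must share endpoints (day_a of fragment i+1 == day_b of
    fragment i).  A neuron unmatched on any day starts a fresh global id;
    identities never jump a missing day.
    """
    if not fragments:
        raise ValueError("no registration fragments")
    for f in fragments:
        if f.day_a is None or f.day_b is None:
            raise ValueError("fragments must carry day labels for chaining")
    for prev, nxt in zip(fragments, fragments[1:]):
        if prev.day_b != nxt.day_a:
            raise ValueError(
                f"fragment endpoints do not chain: {prev.day_b} != {nxt.day_a}")

    days = [fragments[0].day_a] + [f.day_b for f in fragments]
    global_ids: dict = {}
    counter = 0
    first = fragments[0]
    n_first = (int(max(first.matches[:, 0].max(initial=-1),
                       first.unmatched_a.max(initial=-1))) + 1)
    for n in range(n_first):
        global_ids[(first.day_a, n)] = counter
        counter += 1
    for frag in fragments:
        seen_b = set()
        for ia, ib in frag.matches:
            gid = global_ids.get((frag.day_a, int(ia)))
            if gid is None:
                gid = counter
                counter += 1
                global_ids[(frag.day_a, int(ia))] = gid
            key = (frag.day_b, int(ib))
            if key in global_ids:
                raise ValueError(f"neuron {key} assigned twice during chaining")
            global_ids[key] = gid
            seen_b.add(int(ib))
        for ib in frag.unmatched_b.tolist():
            global_ids[(frag.day_b, int(ib))] = counter
            counter += 1
    return RegistrationMap(days=tuple(days), global_ids=global_ids,
                           pairs=list(fragments))


def stable_responder_fraction(tables: dict, registration: RegistrationMap,
                              noxious: tuple[str, ...] = NOXIOUS_STIMULI,
                              min_span_days: int = 8,
                              return_counts: bool = False):
    """Fraction of cross-day-aligned neurons that respond to at least one
    noxious stimulus on every registered day of the span.

    ``tables`` maps day -> responder table.  The denominator is the set of
    global ids present on both the first and last day (chaining implies
    presence on every intermediate registered day).
    """
    days = sorted(tables)
    if len(days) < 2:
        raise ValueError("need responder tables for at least 2 registered days")
    span = days[-1] - days[0]
    if span < min_span_days:
        raise ValueError(f"day span {span} < min_span_days {min_span_days}")
    aligned = registration.gids_spanning(days[0], days[-1])
    if not aligned:
        raise ValueError("no cross-day-aligned neurons in the span")

    stable = set(aligned)
    for day in days:
        table = tables[day]
        local_to_gid = registration.neurons_on(day)
        resp = table[table["responsive"] & table["stimulus"].isin(noxious)]
        responsive_local = set(resp["neuron"].astype(int))
        day_stable = {g for n, g in local_to_gid.items() if n in responsive_local}
        stable &= day_stable
    frac = len(stable) / len(aligned)
    if return_counts:
        return frac, (len(stable), len(aligned))
    return frac


def light_touch_ensemble_fraction(sets: EnsembleSets,
                                  label: str = "light_touch") -> float:
    """|light-touch responders within the nociceptive ensemble| / |ensemble|."""
    if not sets.nociceptive:
        raise ValueError("empty nociceptive ensemble")
    return len(sets.responders.get(label, frozenset()) & sets.nociceptive) \
        / len(sets.nociceptive)


def allodynia_expansion_index(pre_sets, post_sets,
                              label: str = "light_touch") -> float:
    """Percent change of the light-touch fraction of the nociceptive
    ensemble, post- vs pre-injury.

    Each argument is an :class:`EnsembleSets` or a list of them (multiple
    sessions per epoch are averaged).  Positive values mean expansion.
    """
    def epoch_fraction(sets) -> float:
        if isinstance(sets, EnsembleSets):
            sets = [sets]
        if not sets:
            raise ValueError("epoch contains no sessions")
        return float(np.mean([light_touch_ensemble_fraction(s, label)
                              for s in sets]))

    f_pre = epoch_fraction(pre_sets)
    f_post = epoch_fraction(post_sets)
    if f_pre == 0:
        raise ValueError("pre-injury light-touch fraction is zero; index undefined")
    return 100.0 * (f_post - f_pre) / f_pre
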