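"""Latent-class tuning model for synthetic BLA neurons.

Each neuron is a nociceptive-ensemble member with probability
``ensemble_prob``.  Members draw their noxious modality profile from a
conditioned Bernoulli distribution (independent heat/cold/pin coins given at
least one success) whose coin probabilities are solved so that the
within-class marginals match the documented responder fractions.  A
``pain_specific_prob`` share of members carries no non-noxious tuning at
all; the remainder draws non-noxious tunings with class-conditional
probabilities, which is what produces the documented enrichment of light and
mild touch inside the ensemble.  Non-members never carry noxious tuning and
draw non-noxious tunings at lower baseline rates chosen to preserve the
marginal tuned fraction of every stimulus.
"""

from __future__ import annotations

from itertools import product

import numpy as np

from ..config import NOXIOUS_STIMULI, GeneratorConfig

__all__ = [
    "solve_noxious_coins", "draw_tuning", "expected_fractions",
    "tuning_pattern_distribution",
]


def solve_noxious_coins(config: GeneratorConfig, tol: float = 1e-12,
                        max_iter: int = 500) -> np.ndarray:
    """Coin probabilities q for the conditioned-Bernoulli noxious profile.

    Solves q_s = r_s * Z with Z = 1 - prod(1 - q) by fixed-point iteration,
    where r_s = membership_probs[s] / ensemble_prob is the required
    within-class marginal.  Z is the acceptance mass of the >=1 condition.
    """
    r = np.array([config.membership_probs[s] / config.ensemble_prob
                  for s in config.noxious_stimuli])
    if np.any(r > 1):
        raise ValueError("noxious marginals exceed ensemble_prob")
    z = 1.0 - np.prod(1.0 - r)  # starting guess
    for _ in range(max_iter):
        q = r * z
        z_new = 1.0 - np.prod(1.0 - q)
        if abs(z_new - z) < tol:
            break
        z = z_new
    q = r * z
    if np.any(q > 1):
        raise ValueError("no valid conditioned-Bernoulli solution for these marginals")
    return q


def _draw_conditioned_noxious(rng: np.random.Generator, q: np.ndarray,
                              n: int) -> np.ndarray:
    """n draws of >=3 coins conditioned on at least one success (rejection-free:
    resample only failed rows, expected constant passes)."""
    out = rng.random((n, len(q))) < q
    bad = ~out.any(axis=1)
    while bad.any():
        out[bad] = rng.random((bad.sum(), len(q))) < q
        bad = ~out.any(axis=1)
    return out


def draw_tuning(config: GeneratorConfig, n_neurons: int,
                rng: np.random.Generator):
    """Draw (tuning_matrix, is_ensemble, is_pain_specific) for fresh neurons."""
    panel = config.stimulus_panel
    nox_idx = [panel.index(s) for s in config.noxious_stimuli]
    q = solve_noxious_coins(config)
    base = config.baseline_probs()

    is_ens = rng.random(n_neurons) < config.ensemble_prob
    is_ps = is_ens & (rng.random(n_neurons) < config.pain_specific_prob)

    tuning = np.zeros((n_neurons, len(panel)), dtype=bool)
    n_ens = int(is_ens.sum())
    if n_ens:
        tuning[np.ix_(is_ens, nox_idx)] = _draw_conditioned_noxious(rng, q, n_ens)
    for j, s in enumerate(panel):
        if s in NOXIOUS_STIMULI:
            continue
        p_in = config.within_ensemble_probs[s]
        p_out = base[s]
        u = rng.random(n_neurons)
        tuning[:, j] = np.where(is_ens & ~is_ps, u < p_in,
                                np.where(is_ens, False, u < p_out))
    return tuning, is_ens, is_ps


# ---------------------------------------------------------------------------
# closed-form expectations (documented fractions; cross-checked in tests by
# an independent brute-force enumeration)
# ---------------------------------------------------------------------------

def tuning_pattern_distribution(config: GeneratorConfig) -> dict[tuple[int, ...], float]:
    """Exact probability of every 9-bit tuning pattern under the model."""
    panel = config.stimulus_panel
    nox = list(config.noxious_stimuli)
    non_nox = [s for s in panel if s not in nox]
    q = solve_noxious_coins(config)
    z = 1.0 - np.prod(1.0 - q)
    base = config.baseline_probs()
    ens, ps = config.ensemble_prob, config.pain_specific_prob

    dist: dict[tuple[int, ...], float] = {}

    def add(pattern: dict, prob: float) -> None:
        key = tuple(int(pattern.get(s, 0)) for s in panel)
        dist[key] = dist.get(key, 0.0) + prob

    # ensemble branch: noxious profile conditioned on >=1
    for nox_bits in product((0, 1), repeat=len(nox)):
        if not any(nox_bits):
            continue
        p_nox = np.prod([q[i] if b else 1 - q[i] for i, b in enumerate(nox_bits)]) / z
        # pain-specific: nothing else
        add(dict(zip(nox, nox_bits)), ens * ps * p_nox)
        # non-specific member: class-conditional non-noxious coins
        for nn_bits in product((0, 1), repeat=len(non_nox)):
            p_nn = np.prod([config.within_ensemble_probs[s] if b
                            else 1 - config.within_ensemble_probs[s]
                            for s, b in zip(non_nox, nn_bits)])
            pattern = dict(zip(nox, nox_bits)) | dict(zip(non_nox, nn_bits))
            add(pattern, ens * (1 - ps) * p_nox * p_nn)
    # non-member branch: baseline non-noxious coins, no noxious tuning
    for nn_bits in product((0, 1), repeat=len(non_nox)):
        p_nn = np.prod([base[s] if b else 1 - base[s]
                        for s, b in zip(non_nox, nn_bits)])
        add(dict(zip(non_nox, nn_bits)), (1 - ens) * p_nn)
    return dist


def expected_fractions(config: GeneratorConfig) -> dict[str, float]:
    """Closed-form planted fractions implied by the defaults.

    Keys: each stimulus marginal, 'nociceptive', 'pain_specific' (empirical
    noxious-only fraction of all neurons), and 'light_touch_in_ensemble'.
    """
    panel = config.stimulus_panel
    nox = set(config.noxious_stimuli)
    dist = tuning_pattern_distribution(config)
    out = {s: 0.0 for s in panel}
    union = specific = lt_and_union = 0.0
    lt_j = panel.index("light_touch") if "light_touch" in panel else None
    for pattern, p in dist.items():
        tuned = [s for s, b in zip(panel, pattern) if b]
        for s in tuned:
            out[s] += p
        has_nox = any(s in nox for s in tuned)
        if has_nox:
            union += p
            if all(s in nox for s in tuned):
                specific += p
            if lt_j is not None and pattern[lt_j]:
                lt_and_union += p
    out["nociceptive"] = union
    out["pain_specific"] = specific
    if lt_j is not None and union > 0:
        out["light_touch_in_ensemble"] = lt_and_union / union
    return out
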