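"""Ground-truthed synthetic miniscope sessions.

A session is built in four steps: (1) draw neuron identities and their
latent-class tunings (:mod:`.tuning`); (2) lay out a trial schedule that
interleaves the nine-stimulus panel; (3) superimpose double-exponential
GCaMP6m-like transients -- stimulus-locked for tuned neurons, Poisson
spontaneous events for everyone -- on a noisy baseline; (4) synthesize an
accelerometer stream whose affective-bout amplitudes are coupled to the
planted ensemble activation through a Gaussian copula.

Multi-day cohorts evolve each animal's neuron pool with carryover
(re-imaging), a stationary Markov chain on nociceptive-class membership,
and -- for neuropathic cohorts -- post-injury recruitment of light-touch
tuning into the ensemble (allodynia).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .._rng import substream
from ..config import GeneratorConfig
from ..stats import midranks
from ..types import GroundTruth, SessionRecording, StimulusEvent
from .tuning import draw_tuning

__all__ = [
    "coupling_from_spearman", "transient_kernel",
    "generate_session", "generate_cohort", "generate_longitudinal_cohort",
]

_REFLEX_STIMULI = frozenset({"noxious_heat", "noxious_cold", "pin",
                             "light_touch", "mild_touch", "footshock"})

#: Onset range (s, relative to stimulus onset) within which a spontaneous
#: transient contributes enough signal to the 2-s response window to count a
#: neuron as active at the default kernel and threshold.
_SPONT_ACTIVE_WINDOW_S: tuple[float, float] = (-0.25, 1.5)


def coupling_from_spearman(target_rho: float) -> float:
    """Pearson correlation of a bivariate Gaussian copula whose Spearman
    correlation equals ``target_rho`` (inverts rho_s = (6/pi) asin(r/2))."""
    if not -1.0 <= target_rho <= 1.0:
        raise ValueError(f"|target_rho| must be <= 1, got {target_rho}")
    return 2.0 * math.sin(math.pi * target_rho / 6.0)


def transient_kernel(frame_rate: float, rise_tau: float, decay_tau: float,
                     cutoff: float = 1e-3) -> np.ndarray:
    """Difference-of-exponentials calcium kernel sampled on the frame grid,
    normalized to unit peak; truncated once the decay falls below ``cutoff``."""
    if rise_tau <= 0 or decay_tau <= 0 or rise_tau >= decay_tau:
        raise ValueError("need 0 < rise_tau < decay_tau")
    t_peak = rise_tau * decay_tau / (decay_tau - rise_tau) * math.log(decay_tau / rise_tau)
    peak = math.exp(-t_peak / decay_tau) - math.exp(-t_peak / rise_tau)
    t_max = decay_tau * math.log(1.0 / cutoff)
    t = np.arange(0.0, t_max, 1.0 / frame_rate)
    k = (np.exp(-t / decay_tau) - np.exp(-t / rise_tau)) / peak
    return np.clip(k, 0.0, None)


# ---------------------------------------------------------------------------
# per-animal state for multi-day simulation
# ---------------------------------------------------------------------------

@dataclass
class _Pool:
    """Currently imaged neurons of one animal."""
    gids: np.ndarray
    base_centroids: np.ndarray
    tuning: np.ndarray
    is_ens: np.ndarray
    is_ps: np.ndarray
    injury_seen: np.ndarray    # post-injury light-touch adjustment already applied
    next_gid: int = 0
    occupied: np.ndarray | None = None   # all centroids ever placed (spacing)

    @property
    def n(self) -> int:
        return len(self.gids)


def _place_centroids(rng: np.random.Generator, n: int, fov: tuple[int, int],
                     spacing: float, occupied: np.ndarray | None,
                     max_tries: int = 20000) -> np.ndarray:
    placed = [] if occupied is None or len(occupied) == 0 else [occupied]
    pts = np.concatenate(placed) if placed else np.zeros((0, 2))
    out = np.zeros((n, 2))
    margin = spacing / 2.0
    for i in range(n):
        for _ in range(max_tries):
            cand = rng.uniform([margin, margin],
                               [fov[0] - margin, fov[1] - margin])
            if len(pts) == 0 or np.min(np.hypot(*(pts - cand).T)) >= spacing:
                out[i] = cand
                pts = np.vstack([pts, cand])
                break
        else:
            raise RuntimeError(
                f"could not place neuron {i + 1}/{n} with spacing {spacing} px "
                f"in a {fov[0]}x{fov[1]} px field of view; enlarge the frame")
    return out


def _fresh_pool(config: GeneratorConfig, n: int, rng: np.random.Generator,
                pool: _Pool | None) -> _Pool:
    tuning, is_ens, is_ps = draw_tuning(config, n, rng)
    start = 0 if pool is None else pool.next_gid
    cents = _place_centroids(rng, n, config.fov_size_px,
                             config.min_centroid_spacing_px,
                             None if pool is None else pool.occupied)
    fresh = _Pool(
        gids=np.arange(start, start + n),
        base_centroids=cents,
        tuning=tuning, is_ens=is_ens, is_ps=is_ps,
        injury_seen=np.zeros(n, dtype=bool),
        next_gid=start + n,
    )
    fresh.occupied = cents if pool is None or pool.occupied is None \
        else np.vstack([pool.occupied, cents])
    return fresh


def _concat_pools(a: _Pool, b: _Pool) -> _Pool:
    return _Pool(
        gids=np.concatenate([a.gids, b.gids]),
        base_centroids=np.vstack([a.base_centroids, b.base_centroids]),
        tuning=np.vstack([a.tuning, b.tuning]),
        is_ens=np.concatenate([a.is_ens, b.is_ens]),
        is_ps=np.concatenate([a.is_ps, b.is_ps]),
        injury_seen=np.concatenate([a.injury_seen, b.injury_seen]),
        next_gid=b.next_gid,
        occupied=b.occupied,
    )


def _subset_pool(pool: _Pool, mask: np.ndarray) -> _Pool:
    return _Pool(
        gids=pool.gids[mask], base_centroids=pool.base_centroids[mask],
        tuning=pool.tuning[mask], is_ens=pool.is_ens[mask],
        is_ps=pool.is_ps[mask], injury_seen=pool.injury_seen[mask],
        next_gid=pool.next_gid, occupied=pool.occupied,
    )


def _transition_tuning(config: GeneratorConfig, pool: _Pool,
                       rng: np.random.Generator) -> None:
    """One session-to-session step of the stationary class Markov chain.

    Members keep their whole tuning profile while they remain in the class;
    leavers fall back to baseline non-noxious rates; entrants draw a fresh
    class profile.  Gain rate is balanced so the class marginal stays at
    ensemble_prob.
    """
    pi = config.persistence_prob
    ens = config.ensemble_prob
    gain = (1.0 - pi) * ens / (1.0 - ens) if ens < 1.0 else 1.0
    u = rng.random(pool.n)
    leave = pool.is_ens & (u >= pi)
    enter = ~pool.is_ens & (u < gain)
    # redraw both groups from their new conditional distribution; the single
    # draw_tuning call keeps the stream layout independent of who moves where
    movers = leave | enter
    if movers.any():
        t_new, e_new, ps_new = draw_tuning(config, int(movers.sum()), rng)
        # leavers: force non-member profile; entrants: force member profile
        idx = np.flatnonzero(movers)
        for k, i in enumerate(idx):
            want_member = bool(enter[i])
            if e_new[k] != want_member:
                # resample until the class matches (cheap: flip via fresh draw)
                while True:
                    t_i, e_i, ps_i = draw_tuning(config, 1, rng)
                    if bool(e_i[0]) == want_member:
                        t_new[k], e_new[k], ps_new[k] = t_i[0], e_i[0], ps_i[0]
                        break
        pool.tuning[movers] = t_new
        pool.is_ens[movers] = e_new
        pool.is_ps[movers] = ps_new
        pool.injury_seen[movers] = False


def _apply_injury_dynamics(config: GeneratorConfig, pool: _Pool, day: int,
                           rng: np.random.Generator) -> None:
    if config.injury_day is None or day < config.injury_day:
        return
    lt_j = config.stimulus_panel.index("light_touch")
    fresh = pool.is_ens & ~pool.injury_seen
    if not fresh.any():
        return
    u = rng.random(pool.n)
    if config.condition == "neuropathic":
        recruit = fresh & ~pool.tuning[:, lt_j] & \
            (u < config.post_injury_light_touch_recruit_prob)
        pool.tuning[recruit, lt_j] = True
    elif config.condition == "uninjured_control":
        lose = fresh & pool.tuning[:, lt_j] & \
            (u >= config.uninjured_light_touch_drift)
        pool.tuning[lose, lt_j] = False
    pool.injury_seen[fresh] = True


# ---------------------------------------------------------------------------
# single-session synthesis
# ---------------------------------------------------------------------------

def _trial_schedule(config: GeneratorConfig, rng: np.random.Generator):
    panel = config.stimulus_panel
    labels = np.repeat(np.arange(len(panel)), config.trials_per_stimulus)
    rng.shuffle(labels)
    lo, hi = config.inter_trial_interval_s
    gaps = rng.uniform(lo, hi, size=len(labels))
    onsets = config.lead_in_s + np.concatenate([[0.0], np.cumsum(gaps[:-1])])
    counters = {s: 0 for s in panel}
    events = []
    for onset, j in zip(onsets, labels):
        label = panel[j]
        events.append(StimulusEvent(onset_s=float(onset), label=label,
                                    trial_index=counters[label]))
        counters[label] += 1
    duration = float(onsets[-1]) + max(hi, 12.0) + config.tail_s
    return events, duration


def _lognormal_amplitudes(rng: np.random.Generator, mean: float, cv: float,
                          n: int) -> np.ndarray:
    if cv <= 0:
        return np.full(n, mean)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return mean * rng.lognormal(-0.5 * sigma * sigma, sigma, size=n)


def _synthesize_session(config: GeneratorConfig, pool: _Pool, animal: int,
                        session_key: str, day: int,
                        rng_events: np.random.Generator,
                        rng_traces: np.random.Generator,
                        rng_behavior: np.random.Generator):
    panel = config.stimulus_panel
    fr = config.frame_rate
    n = pool.n
    events, duration = _trial_schedule(config, rng_events)
    n_frames = int(math.ceil(duration * fr))

    kernel = transient_kernel(fr, config.transient_rise_tau, config.transient_decay_tau)
    klen = len(kernel)

    # -- planted transient catalogue ------------------------------------
    neuron_ids: list[np.ndarray] = []
    onset_frames: list[np.ndarray] = []
    amplitudes: list[np.ndarray] = []
    responded = np.zeros((len(events), n), dtype=bool)

    for t_idx, ev in enumerate(events):
        j = panel.index(ev.label)
        tuned = np.flatnonzero(pool.tuning[:, j])
        if tuned.size == 0:
            continue
        fires = tuned[rng_traces.random(tuned.size) < config.response_reliability]
        if fires.size == 0:
            continue
        responded[t_idx, fires] = True
        f0 = int(math.ceil(ev.onset_s * fr))
        neuron_ids.append(fires)
        onset_frames.append(np.full(fires.size, f0))
        amplitudes.append(_lognormal_amplitudes(
            rng_traces, config.response_amplitude_dff,
            config.amplitude_jitter_cv, fires.size))

    len_stim_events = int(sum(a.size for a in neuron_ids))

    # spontaneous transients, Poisson per neuron
    counts = rng_traces.poisson(config.event_rate_hz * duration, size=n)
    spont_amp = config.spontaneous_amplitude_dff \
        if config.spontaneous_amplitude_dff is not None \
        else config.response_amplitude_dff
    for i in np.flatnonzero(counts):
        c = int(counts[i])
        f0 = np.ceil(rng_traces.uniform(0.0, duration, size=c) * fr).astype(int)
        f0 = np.minimum(f0, n_frames - 1)
        neuron_ids.append(np.full(c, i))
        onset_frames.append(f0)
        amplitudes.append(_lognormal_amplitudes(
            rng_traces, spont_amp, config.amplitude_jitter_cv, c))

    if neuron_ids:
        nid = np.concatenate(neuron_ids)
        ofr = np.concatenate(onset_frames)
        amp = np.concatenate(amplitudes)
    else:
        nid = np.zeros(0, dtype=int)
        ofr = np.zeros(0, dtype=int)
        amp = np.zeros(0)

    # -- dF/F via kernel superposition: scatter-add into a frame axis
    # padded by the kernel length, so no boundary masking is needed
    padded = n_frames + klen
    if nid.size:
        offs = np.arange(klen)
        flat = (nid * padded)[:, None] + ofr[:, None] + offs[None, :]
        weights = amp[:, None] * kernel[None, :]
        dff = np.bincount(flat.ravel(), weights=weights.ravel(),
                          minlength=n * padded).reshape(n, padded)[:, :n_frames]
    else:
        dff = np.zeros((n, n_frames))

    signal = 1.0 + dff
    if config.noise_sd_dff > 0:
        signal = signal + rng_traces.standard_normal((n, n_frames)) * config.noise_sd_dff
    # float32 keeps a ~30 min session around 17 MB without losing analysis precision
    traces = (config.baseline_fluorescence * signal).astype(np.float32)

    # -- ground-truth transient lists per neuron ------------------------
    planted: list[np.ndarray] = []
    order = np.argsort(nid, kind="mergesort")
    nid_s, ofr_s, amp_s = nid[order], ofr[order], amp[order]
    bounds = np.searchsorted(nid_s, np.arange(n + 1))
    for i in range(n):
        a, b = bounds[i], bounds[i + 1]
        rows = np.column_stack([ofr_s[a:b] / fr, amp_s[a:b]])
        planted.append(rows[np.argsort(rows[:, 0])])

    # -- planted ensemble activation per trial --------------------------
    # a neuron counts as active when any planted transient (stimulus-evoked
    # or spontaneous) lands close enough to the onset to lift the mean
    # response-window z above threshold; the spontaneous acceptance window
    # below reproduces that criterion for the default kernel
    n_ens = int(pool.is_ens.sum())
    activation = np.full(len(events), np.nan)
    noxious = set(config.noxious_stimuli)
    nox_trials = [t for t, ev in enumerate(events) if ev.label in noxious]
    if n_ens:
        spont_lo, spont_hi = _SPONT_ACTIVE_WINDOW_S
        order_sp = np.argsort(ofr[len_stim_events:], kind="mergesort") + len_stim_events \
            if nid.size > len_stim_events else np.zeros(0, dtype=int)
        sp_onsets = ofr[order_sp] / fr
        sp_nid = nid[order_sp]
        ens_mask = pool.is_ens
        for t in nox_trials:
            t0 = events[t].onset_s
            active = responded[t].copy()
            lo = np.searchsorted(sp_onsets, t0 + spont_lo)
            hi = np.searchsorted(sp_onsets, t0 + spont_hi)
            active[sp_nid[lo:hi]] = True
            activation[t] = active[ens_mask].sum() / n_ens

    # -- behavior stream -------------------------------------------------
    behavior, planted_beh = _synthesize_behavior(
        config, events, activation, nox_trials, n_frames, rng_behavior)

    session = SessionRecording(
        traces=traces,
        centroids=_session_centroids(config, pool, rng_events),
        events=events, behavior=behavior,
        animal_id=f"A{animal:03d}", session_id=session_key, day=day,
        frame_rate=fr, condition=config.condition,
    )
    truth = GroundTruth(
        stimulus_panel=panel,
        tuning_matrix=pool.tuning.copy(),
        is_ensemble=pool.is_ens.copy(),
        is_pain_specific=pool.is_ps.copy(),
        global_cell_ids=pool.gids.copy(),
        planted_transients=planted,
        planted_behavior_amplitudes=planted_beh,
        planted_activation=activation,
    )
    return session, truth


def _session_centroids(config: GeneratorConfig, pool: _Pool,
                       rng: np.random.Generator) -> np.ndarray:
    drift = rng.uniform(-config.max_drift_px, config.max_drift_px, size=2)
    jitter = rng.standard_normal((pool.n, 2)) * config.centroid_jitter_px
    return pool.base_centroids + drift + jitter


_MOMENT_CACHE: dict = {}


def _activation_summary_moments(config: GeneratorConfig) -> tuple[float, float]:
    """Mean and SD of the session-level planted activation summary (mean
    ensemble-activation fraction over noxious trials) under the tuning model.

    Estimated once per configuration by a deterministic internal simulation
    (fixed private stream, independent of user seeds), and used to convert a
    session's realized activation into a standard-normal score for the
    session-level behavior copula.
    """
    key = (config.neurons_per_session_mean, config.neurons_per_session_sd,
           config.ensemble_prob, config.pain_specific_prob,
           tuple(sorted(config.membership_probs.items())),
           config.trials_per_stimulus, config.response_reliability,
           config.event_rate_hz)
    if key in _MOMENT_CACHE:
        return _MOMENT_CACHE[key]
    rng = np.random.default_rng(987654321)
    reps = 2000
    nox_idx = [config.stimulus_panel.index(s) for s in config.noxious_stimuli]
    lo, hi = _SPONT_ACTIVE_WINDOW_S
    p_spont = min(1.0, config.event_rate_hz * (hi - lo))
    rel = config.response_reliability
    summaries = np.zeros(reps)
    n_all = np.maximum(np.round(rng.normal(config.neurons_per_session_mean,
                                           config.neurons_per_session_sd,
                                           size=reps)).astype(int), 5)
    for i in range(reps):
        tuning, is_ens, _ = draw_tuning(config, int(n_all[i]), rng)
        n_ens = int(is_ens.sum())
        if n_ens == 0:
            continue
        fracs = []
        for j in nox_idx:
            k = int((tuning[:, j] & is_ens).sum())
            # tuned members: evoked or spontaneous; untuned: spontaneous only
            active = rng.binomial(k, rel + (1 - rel) * p_spont,
                                  size=config.trials_per_stimulus) \
                + rng.binomial(n_ens - k, p_spont, size=config.trials_per_stimulus)
            fracs.append(active / n_ens)
        summaries[i] = float(np.mean(np.concatenate(fracs)))
    mu, sd = float(summaries.mean()), float(summaries.std())
    _MOMENT_CACHE[key] = (mu, max(sd, 1e-9))
    return _MOMENT_CACHE[key]


def _synthesize_behavior(config: GeneratorConfig, events, activation,
                         nox_trials, n_frames: int,
                         rng: np.random.Generator):
    fr = config.frame_rate
    stream = rng.standard_normal(n_frames) * config.behavior_noise_g
    planted = np.full(len(events), np.nan)

    # Coupling operates on two scales with the same Gaussian-copula target:
    # within a session, affective-bout amplitudes follow the ranks of the
    # per-trial planted activation; across sessions, a lognormal session
    # gain follows the normal score of the session's mean activation, so the
    # session-level Spearman matches the target as well.
    if nox_trials:
        a = np.array([activation[t] for t in nox_trials])
        if np.all(np.isnan(a)):
            z1 = np.zeros(len(nox_trials))
            a = np.zeros(len(nox_trials))
        else:
            r = midranks(a)
            z1 = norm.ppf(r / (len(r) + 1.0))
        rho_target = config.behavior_coupling_rho * config.coupling_attenuation_correction
        rho_p = coupling_from_spearman(max(-0.999, min(0.999, rho_target)))
        resid = math.sqrt(max(0.0, 1.0 - rho_p ** 2))
        eps = rng.standard_normal(len(nox_trials))
        z2 = rho_p * z1 + resid * eps
        sig = config.affective_amplitude_sigma
        amps = config.affective_amplitude_g * np.exp(sig * z2 - 0.5 * sig * sig)

        mu_a, sd_a = _activation_summary_moments(config)
        z1_sess = (float(np.mean(a)) - mu_a) / sd_a
        z2_sess = rho_p * z1_sess + resid * rng.standard_normal()
        gain = math.exp(sig * z2_sess - 0.5 * sig * sig)
        amps = gain * amps
        for t, amp in zip(nox_trials, amps):
            planted[t] = amp

    def add_bump(center_s: float, width_s: float, amplitude: float) -> None:
        f0 = int(round((center_s - width_s / 2) * fr))
        f1 = int(round((center_s + width_s / 2) * fr))
        f0c, f1c = max(f0, 0), min(f1, n_frames)
        if f1c <= f0c:
            return
        t = np.arange(f0c, f1c) - f0
        stream[f0c:f1c] += amplitude * np.sin(np.pi * (t + 0.5) / max(f1 - f0, 1))

    noxious = set(config.noxious_stimuli)
    for t_idx, ev in enumerate(events):
        if ev.label in _REFLEX_STIMULI:
            scale = 1.0 if ev.label in noxious else 0.4
            amp = scale * config.reflex_amplitude_g * \
                float(_lognormal_amplitudes(rng, 1.0, 0.3, 1)[0])
            add_bump(ev.onset_s + 0.15, 0.3, amp)
        if not np.isnan(planted[t_idx]):
            add_bump(ev.onset_s + 3.5, 4.0, float(planted[t_idx]))
    return stream.astype(np.float32), planted


# ---------------------------------------------------------------------------
# public generators
# ---------------------------------------------------------------------------

def _draw_neuron_count(config: GeneratorConfig, rng: np.random.Generator) -> int:
    n = int(round(rng.normal(config.neurons_per_session_mean,
                             config.neurons_per_session_sd)))
    return max(n, 5)


def generate_session(config: GeneratorConfig, seed: int):
    """One standalone session plus its ground truth (day = first grid day)."""
    config.validate()
    rng_pool = substream(seed, 0, 0, "pool")
    n = _draw_neuron_count(config, rng_pool)
    pool = _fresh_pool(config, n, rng_pool, None)
    day = int(config.days[0]) if config.days else 0
    _apply_injury_dynamics(config, pool, day,
                           substream(seed, 0, 0, "injury"))
    return _synthesize_session(
        config, pool, animal=0, session_key="A000_S00", day=day,
        rng_events=substream(seed, 0, 0, "events"),
        rng_traces=substream(seed, 0, 0, "traces"),
        rng_behavior=substream(seed, 0, 0, "behavior"),
    )


def _animal_sessions(config: GeneratorConfig, seed: int, animal: int,
                     days: list[int]):
    out = []
    pool: _Pool | None = None
    for s_idx, day in enumerate(days):
        rng_pool = substream(seed, animal, s_idx, "pool")
        target = _draw_neuron_count(config, rng_pool)
        if pool is None:
            pool = _fresh_pool(config, target, rng_pool, None)
        else:
            kept = rng_pool.random(pool.n) < config.carryover_prob
            pool = _subset_pool(pool, kept)
            _transition_tuning(config, pool, rng_pool)
            n_new = max(target - pool.n, 0)
            if n_new:
                fresh = _fresh_pool(config, n_new, rng_pool, pool)
                pool = _concat_pools(pool, fresh)
        _apply_injury_dynamics(config, pool, day,
                               substream(seed, animal, s_idx, "injury"))
        out.append(_synthesize_session(
            config, pool, animal=animal,
            session_key=f"A{animal:03d}_S{s_idx:02d}", day=day,
            rng_events=substream(seed, animal, s_idx, "events"),
            rng_traces=substream(seed, animal, s_idx, "traces"),
            rng_behavior=substream(seed, animal, s_idx, "behavior"),
        ))
    return out


def iter_cohort(config: GeneratorConfig, seed: int):
    """Lazy variant of :func:`generate_cohort`: yields (session, truth)
    animal by animal so large cohorts never need to sit in memory at once."""
    config.validate()
    days = list(range(config.sessions_per_animal))
    for animal in range(config.n_animals):
        yield from _animal_sessions(config, seed, animal, days)


def generate_cohort(config: GeneratorConfig, seed: int):
    """n_animals x sessions_per_animal sessions on consecutive days, with
    per-animal neuron identity carryover.  Returns a flat list of
    (SessionRecording, GroundTruth)."""
    return list(iter_cohort(config, seed))


def iter_longitudinal_cohort(config: GeneratorConfig, seed: int):
    """Lazy variant of :func:`generate_longitudinal_cohort` (animal-major
    order, one session per grid day)."""
    config.validate()
    if config.condition in ("neuropathic", "uninjured_control"):
        if config.injury_day is None:
            raise ValueError("longitudinal injury cohorts require injury_day")
        pre = [d for d in config.days if d < config.injury_day]
        post = [d for d in config.days if d >= config.injury_day]
        if not pre or not post:
            raise ValueError("day grid must include pre- and post-injury sessions")
        if max(post) - min(pre) < 8:
            raise ValueError("pre/post sessions must span at least 8 days")
    for animal in range(config.n_animals):
        yield from _animal_sessions(config, seed, animal, list(config.days))


def generate_longitudinal_cohort(config: GeneratorConfig, seed: int):
    """One session per day of ``config.days`` per animal, spanning injury.

    For neuropathic cohorts ``injury_day`` must sit inside the day grid and
    the grid must contain a pre/post pair at least 8 days apart.
    """
    return list(iter_longitudinal_cohort(config, seed))
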