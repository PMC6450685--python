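"""Generator configuration: the study conditions every synthetic cohort emulates.

The default numbers are the package's documented reconstruction of the
imaging regime they mirror: ~117 +/- 8 active BLA neurons per session, a
nine-stimulus panel delivered in ten trials each, GCaMP6m-like transient
kinetics, a nociceptive ensemble holding 24% of active neurons with 15/13/13%
heat/cold/pin responders, 18% of the ensemble co-responsive to light touch
(7% of all neurons), a ~6% pain-specific subset, week-scale tuning stability
of 11%, and a +291% (neuropathic) / -38% (uninjured) post-injury change in
the light-touch fraction of the ensemble.  See docs/methods.md for the
derivation of each value.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

__all__ = [
    "STIMULUS_PANEL", "NOXIOUS_STIMULI", "GeneratorConfig",
    "make_default_config", "neuropathic_config", "uninjured_config",
    "config_to_yaml", "config_from_yaml",
]

#: Canonical nine-stimulus panel covering noxious, innocuous, anticipatory,
#: aversive, and appetitive classes.
STIMULUS_PANEL: tuple[str, ...] = (
    "noxious_heat", "noxious_cold", "pin",
    "light_touch", "mild_touch", "approach_no_contact",
    "footshock", "aversive_nonsomatic", "sucrose",
)

#: The three noxious modalities whose responder union defines the
#: nociceptive ensemble.
NOXIOUS_STIMULI: tuple[str, ...] = ("noxious_heat", "noxious_cold", "pin")

_NON_NOXIOUS: tuple[str, ...] = tuple(s for s in STIMULUS_PANEL if s not in NOXIOUS_STIMULI)

# Marginal tuned fractions per stimulus (fraction of all active neurons).
_DEFAULT_MEMBERSHIP = {
    "noxious_heat": 0.15,
    "noxious_cold": 0.13,
    "pin": 0.13,
    "light_touch": 0.07,
    "mild_touch": 0.13,
    "approach_no_contact": 0.07,
    "footshock": 0.10,
    "aversive_nonsomatic": 0.10,
    "sucrose": 0.18,
}

# P(tuned to s | ensemble member that is not pain-specific).  Solved from the
# documented ensemble-overlap fractions: light touch 18% and mild touch 31% of
# the ensemble, sucrose overlap 7% of all neurons, aversive/shock union
# overlap 10% of all neurons, approach overlap 1.8% of all neurons, with
# ensemble mass 0.24 and pain-specific share 0.08 of the ensemble
# (see synthetic.calibrate.solve_within_ensemble_probs).
_DEFAULT_WITHIN_ENSEMBLE = {
    "light_touch": 0.195652,
    "mild_touch": 0.336957,
    "approach_no_contact": 0.081522,
    "footshock": 0.260337,
    "aversive_nonsomatic": 0.260337,
    "sucrose": 0.317029,
}


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic-session generator; defaults are the study
    conditions (module docstring)."""

    # cohort shape
    n_animals: int = 9
    sessions_per_animal: int = 3
    neurons_per_session_mean: float = 117.0
    neurons_per_session_sd: float = 8.0

    # acquisition
    frame_rate: float = 20.0
    trials_per_stimulus: int = 10
    stimulus_panel: tuple[str, ...] = STIMULUS_PANEL
    inter_trial_interval_s: tuple[float, float] = (15.0, 25.0)
    lead_in_s: float = 30.0
    tail_s: float = 30.0

    # tuning model
    ensemble_prob: float = 0.24
    pain_specific_prob: float = 0.08        # conditional on ensemble membership
    membership_probs: dict = field(default_factory=lambda: dict(_DEFAULT_MEMBERSHIP))
    within_ensemble_probs: dict = field(default_factory=lambda: dict(_DEFAULT_WITHIN_ENSEMBLE))

    # transient model (GCaMP6m-like)
    transient_rise_tau: float = 0.1         # s
    transient_decay_tau: float = 1.0        # s
    response_amplitude_dff: float = 1.0     # dF/F units
    amplitude_jitter_cv: float = 0.2        # lognormal trial-to-trial jitter
    response_reliability: float = 0.85      # P(tuned neuron fires on its trial)
    noise_sd_dff: float = 0.1               # dF/F units, per frame
    event_rate_hz: float = 0.1              # spontaneous transients per neuron
    spontaneous_amplitude_dff: float | None = None  # None: same as evoked
    baseline_fluorescence: float = 100.0    # arbitrary units

    # field of view / centroids
    fov_size_px: tuple[int, int] = (300, 300)
    min_centroid_spacing_px: float = 10.0
    centroid_jitter_px: float = 0.5         # per-session per-cell jitter SD
    max_drift_px: float = 3.0               # per-session rigid translation bound

    # multi-day dynamics
    persistence_prob: float = 0.42          # class membership kept per session step
    carryover_prob: float = 0.6             # cell re-imaged on the next session
    days: tuple[int, ...] = (0, 1, 2)
    injury_day: int | None = None
    post_injury_light_touch_recruit_prob: float = 0.497
    uninjured_light_touch_drift: float = 0.4735
    condition: str = "normal"

    # behavior
    behavior_coupling_rho: float = 0.54     # target session Spearman (normal group)
    # planted-copula boost compensating the rank attenuation between the
    # pipeline's measured ensemble activation and the planted summary
    # (1 / 0.859, measured at default SNR; see docs/methods.md)
    coupling_attenuation_correction: float = 1.164
    behavior_noise_g: float = 0.05
    reflex_amplitude_g: float = 1.5
    affective_amplitude_g: float = 1.0
    affective_amplitude_sigma: float = 0.5  # lognormal sigma of the bout amplitude

    seed: int = 0

    def __post_init__(self) -> None:
        self.stimulus_panel = tuple(self.stimulus_panel)
        self.validate()

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        panel = self.stimulus_panel
        if len(panel) != 9 or len(set(panel)) != 9:
            raise ValueError("stimulus_panel must contain exactly 9 unique labels")
        for name in ("frame_rate", "transient_rise_tau", "transient_decay_tau",
                     "neurons_per_session_mean", "baseline_fluorescence"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("noise_sd_dff", "event_rate_hz", "neurons_per_session_sd",
                     "centroid_jitter_px", "max_drift_px", "behavior_noise_g"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        probs = {
            "ensemble_prob": self.ensemble_prob,
            "pain_specific_prob": self.pain_specific_prob,
            "response_reliability": self.response_reliability,
            "persistence_prob": self.persistence_prob,
            "carryover_prob": self.carryover_prob,
            "post_injury_light_touch_recruit_prob": self.post_injury_light_touch_recruit_prob,
            "uninjured_light_touch_drift": self.uninjured_light_touch_drift,
        }
        probs.update({f"membership_probs[{k}]": v for k, v in self.membership_probs.items()})
        probs.update({f"within_ensemble_probs[{k}]": v
                      for k, v in self.within_ensemble_probs.items()})
        for name, value in probs.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1], got {value}")
        if not -1.0 <= self.behavior_coupling_rho <= 1.0:
            raise ValueError("behavior_coupling_rho must lie in [-1, 1]")
        if self.coupling_attenuation_correction <= 0:
            raise ValueError("coupling_attenuation_correction must be > 0")
        if self.spontaneous_amplitude_dff is not None \
                and self.spontaneous_amplitude_dff < 0:
            raise ValueError("spontaneous_amplitude_dff must be >= 0")
        if set(self.membership_probs) != set(panel):
            raise ValueError("membership_probs must cover exactly the stimulus panel")
        missing = set(panel) - set(NOXIOUS_STIMULI) - set(self.within_ensemble_probs)
        if missing:
            raise ValueError(f"within_ensemble_probs missing labels: {sorted(missing)}")
        if self.n_animals < 1 or self.sessions_per_animal < 1:
            raise ValueError("cohort must contain at least one animal and session")
        if self.trials_per_stimulus < 1:
            raise ValueError("trials_per_stimulus must be >= 1")
        lo, hi = self.inter_trial_interval_s
        if not 0 < lo <= hi:
            raise ValueError("inter_trial_interval_s must satisfy 0 < lo <= hi")
        if self.condition not in ("normal", "neuropathic", "uninjured_control"):
            raise ValueError(f"unknown condition {self.condition!r}")
        if len(self.days) != len(set(self.days)) or list(self.days) != sorted(self.days):
            raise ValueError("days must be strictly increasing")
        if self.injury_day is not None and self.condition == "neuropathic":
            if not (self.days[0] < self.injury_day <= self.days[-1]):
                raise ValueError("injury_day must fall inside the day grid")

    # -- derived quantities ---------------------------------------------
    @property
    def noxious_stimuli(self) -> tuple[str, ...]:
        return tuple(s for s in NOXIOUS_STIMULI if s in self.stimulus_panel)

    def baseline_probs(self) -> dict:
        """P(tuned to s | not an ensemble member) for non-noxious stimuli,
        derived so the marginal tuned fractions equal membership_probs."""
        out = {}
        mass = self.ensemble_prob * (1.0 - self.pain_specific_prob)
        for s in _NON_NOXIOUS:
            if s not in self.stimulus_panel:
                continue
            overlap = mass * self.within_ensemble_probs[s]
            b = (self.membership_probs[s] - overlap) / (1.0 - self.ensemble_prob)
            if not 0.0 <= b <= 1.0:
                raise ValueError(
                    f"membership_probs[{s}]={self.membership_probs[s]} inconsistent with "
                    f"within_ensemble_probs[{s}] (implied baseline prob {b:.4f})")
            out[s] = b
        return out

    def replace(self, **changes) -> "GeneratorConfig":
        return dataclasses.replace(self, **changes)


def make_default_config(**overrides) -> GeneratorConfig:
    """The default study conditions: 9 animals x 3 sessions, ~117 neurons per
    session, and tuning fractions documented in the module docstring."""
    return GeneratorConfig(**overrides)


def neuropathic_config(**overrides) -> GeneratorConfig:
    """Longitudinal neuropathic cohort: 13 animals imaged one week before and
    42 days after sciatic nerve injury at day 0."""
    base = dict(n_animals=13, sessions_per_animal=1, days=(-7, 42), injury_day=0,
                condition="neuropathic", behavior_coupling_rho=0.33)
    base.update(overrides)
    return GeneratorConfig(**base)


def uninjured_config(**overrides) -> GeneratorConfig:
    """Longitudinal uninjured control cohort: 4 animals on the same day grid,
    with a mild downward drift in light-touch tuning instead of recruitment."""
    base = dict(n_animals=4, sessions_per_animal=1, days=(-7, 42), injury_day=0,
                condition="uninjured_control", behavior_coupling_rho=0.58)
    base.update(overrides)
    return GeneratorConfig(**base)


# -- YAML round trip -----------------------------------------------------

def config_to_yaml(config: GeneratorConfig) -> str:
    d = dataclasses.asdict(config)
    for key in ("stimulus_panel", "inter_trial_interval_s", "fov_size_px", "days"):
        d[key] = list(d[key])
    return yaml.safe_dump(d, sort_keys=True)


def config_from_yaml(text: str) -> GeneratorConfig:
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError("config YAML must be a mapping")
    known = {f.name for f in dataclasses.fields(GeneratorConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("stimulus_panel", "inter_trial_interval_s", "fov_size_px", "days"):
        if key in data:
            data[key] = tuple(data[key])
    return GeneratorConfig(**data)
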