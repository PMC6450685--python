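"""End-to-end orchestration: generate (or load) sessions, preprocess,
classify responders, build ensembles, decode, track across days, and score
behavior -- emitting one machine-readable report.

The master seed fans out to named substreams per stage and cohort, so
toggling one stage never changes another stage's randomness.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._rng import substream
from .behavior import (AFFECTIVE_WINDOW, REFLEX_WINDOW, behavior_ensemble_correlation,
                       score_trial_behavior, session_affective_score)
from .config import (NOXIOUS_STIMULI, GeneratorConfig, make_default_config,
                     neuropathic_config, uninjured_config)
from .decoding import cross_validated_confusion, diagonal_significance
from .ensembles import (RESPONSE_WINDOW, EnsembleSets, classify_responders,
                        define_ensembles, ensemble_activation, overlap_counts)
from .longitudinal import (allodynia_expansion_index, chain_days,
                           light_touch_ensemble_fraction, register_pair,
                           stable_responder_fraction)
from .preprocessing import slice_trials, zscore_trials
from .stats import mean_sem
from .synthetic import iter_cohort, iter_longitudinal_cohort
from .types import SessionRecording, TrialTensor

__all__ = ["PipelineConfig", "validate_config", "run_pipeline",
           "analyze_session", "summarize_cohort", "longitudinal_summary",
           "REPORT_SCHEMA", "validate_report"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    generator: GeneratorConfig = field(default_factory=make_default_config)
    pre_s: float = 5.0
    post_s: float = 10.0
    response_window: tuple[float, float] = RESPONSE_WINDOW
    n_shuffles: int = 1000
    q_threshold: float = 0.05
    k_folds: int = 5
    n_repeats: int = 10
    z_active: float = 2.0
    registration_max_distance_px: float = 5.0
    min_span_days: int = 8
    reflex_window: tuple[float, float] = REFLEX_WINDOW
    affective_window: tuple[float, float] = AFFECTIVE_WINDOW
    run_decoder: bool = True
    run_longitudinal: bool = True
    run_behavior: bool = True
    outdir: str | None = None
    seed: int = 1

    def __post_init__(self) -> None:
        if self.pre_s <= 0 or self.post_s <= 0:
            raise ValueError("pre_s and post_s must be > 0")
        if not 0 < self.q_threshold < 1:
            raise ValueError("q_threshold must be in (0, 1)")
        if self.k_folds < 2 or self.n_repeats < 1:
            raise ValueError("need k_folds >= 2 and n_repeats >= 1")
        if self.seed != int(self.seed):
            raise ValueError("seed must be an integer")

    def smoke(self) -> "PipelineConfig":
        """Reduced-scale configuration for quick end-to-end checks."""
        gen = self.generator.replace(n_animals=2, sessions_per_animal=1,
                                     neurons_per_session_mean=60,
                                     neurons_per_session_sd=3,
                                     trials_per_stimulus=6)
        return dataclasses.replace(self, generator=gen, n_repeats=2,
                                   run_longitudinal=False)


_TUPLE_KEYS = {"response_window", "reflex_window", "affective_window"}


def validate_config(path) -> PipelineConfig:
    """Load and fully validate a pipeline YAML; unknown keys are rejected."""
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ValueError("pipeline config must be a YAML mapping")
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown pipeline config keys: {sorted(unknown)}")
    gen = data.pop("generator", None)
    if gen is not None:
        if not isinstance(gen, dict):
            raise ValueError("generator section must be a mapping")
        from .config import config_from_yaml
        gen = config_from_yaml(yaml.safe_dump(gen))
    for key in _TUPLE_KEYS & set(data):
        data[key] = tuple(data[key])
    kwargs = {"generator": gen} if gen is not None else {}
    return PipelineConfig(**kwargs, **data)


def config_to_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    gen = d["generator"]
    for key in ("stimulus_panel", "inter_trial_interval_s", "fov_size_px", "days"):
        gen[key] = list(gen[key])
    for key in _TUPLE_KEYS:
        d[key] = list(d[key])
    return d


# ---------------------------------------------------------------------------
# per-session and per-cohort analysis
# ---------------------------------------------------------------------------

def preprocess_session(session: SessionRecording, cfg: PipelineConfig) -> TrialTensor:
    return zscore_trials(slice_trials(session, cfg.pre_s, cfg.post_s))


def analyze_session(session: SessionRecording, cfg: PipelineConfig,
                    seed: int, decode: bool | None = None) -> dict:
    """Run classification (and optionally decoding and behavior scoring) on
    one session.

    Returns a lightweight result dict (session metadata, responder table,
    ensemble sets, confusion matrix, session activation, behavior metrics);
    the trial tensor and raw traces are released so whole cohorts can be
    analyzed in a stream.
    """
    tensor = preprocess_session(session, cfg)
    table = classify_responders(tensor, n_shuffles=cfg.n_shuffles,
                                q_threshold=cfg.q_threshold,
                                seed=seed, response_window=cfg.response_window)
    sets = define_ensembles(table, n_neurons=session.n_neurons)
    out = {"session_id": session.session_id, "animal_id": session.animal_id,
           "day": session.day, "condition": session.condition,
           "n_neurons": session.n_neurons, "n_dropped": tensor.n_dropped,
           "panel": session_panel(session),
           "table": table, "sets": sets,
           "confusion": None, "activation": None, "behavior": None}
    if decode if decode is not None else cfg.run_decoder:
        out["confusion"] = cross_validated_confusion(
            tensor, k_folds=cfg.k_folds, n_repeats=cfg.n_repeats, seed=seed,
            class_order=out["panel"],
            response_window=cfg.response_window,
            session_id=session.session_id)
    if cfg.run_behavior:
        metrics = score_trial_behavior(session.behavior, session.events,
                                       session.frame_rate, cfg.reflex_window,
                                       cfg.affective_window,
                                       baseline_window=(-cfg.pre_s, 0.0))
        out["behavior"] = metrics
        if sets.nociceptive:
            noxious_mask = np.isin(tensor.trial_labels, NOXIOUS_STIMULI)
            act = ensemble_activation(tensor, sets.nociceptive, cfg.z_active,
                                      cfg.response_window)
            out["activation"] = float(act[noxious_mask].mean()) \
                if noxious_mask.any() else float("nan")
    return out


def session_panel(session: SessionRecording) -> tuple[str, ...]:
    from .config import STIMULUS_PANEL
    present = {e.label for e in session.events}
    return tuple(s for s in STIMULUS_PANEL if s in present) or tuple(sorted(present))


def _pack(values) -> dict:
    mean, sem, n = mean_sem(values)
    return {"mean": mean, "sem": sem, "n": n}


def summarize_cohort(results: list[dict], cfg: PipelineConfig) -> dict:
    """Cross-session means +/- SEM of responder fractions, ensemble
    fractions, overlaps, decoding, and behavior coupling."""
    panel = results[0]["panel"]
    frac = {s: [] for s in panel}
    ens, spec, lt_in_ens = [], [], []
    for r in results:
        sets: EnsembleSets = r["sets"]
        for s in panel:
            frac[s].append(sets.fractions.get(s, 0.0))
        ens.append(sets.fractions.get("nociceptive", 0.0))
        spec.append(sets.fractions.get("pain_specific", 0.0))
        if sets.nociceptive:
            lt_in_ens.append(light_touch_ensemble_fraction(sets))
    summary = {
        "n_sessions": len(results),
        "neurons_per_session": _pack([r["n_neurons"] for r in results]),
        "responder_fractions_pct": {s: _pack(100 * np.asarray(v))
                                    for s, v in frac.items()},
        "nociceptive_fraction_pct": _pack(100 * np.asarray(ens)),
        "pain_specific_fraction_pct": _pack(100 * np.asarray(spec)),
        "light_touch_in_ensemble_pct": _pack(100 * np.asarray(lt_in_ens)),
    }

    venn = [overlap_counts(r["sets"], list(NOXIOUS_STIMULI)) for r in results]
    regions = venn[0]["region"]
    summary["noxious_venn_counts"] = {
        reg: _pack([v.loc[v["region"] == reg, "count"].iloc[0] for v in venn])
        for reg in regions}

    confusions = [r["confusion"] for r in results if r["confusion"] is not None]
    if confusions:
        mean_cm = np.mean([c.matrix for c in confusions], axis=0)
        summary["decoder"] = {
            "labels": list(confusions[0].labels),
            "mean_confusion_pct": mean_cm.tolist(),
            "mean_diagonal_pct": float(np.mean(np.diagonal(mean_cm))),
        }
        if len(confusions) >= 5:
            diag = diagonal_significance(confusions, q=cfg.q_threshold)
            summary["decoder"]["significant_columns"] = sorted(
                diag.loc[diag["column_significant"], "column"].unique().tolist())

    acts = [r["activation"] for r in results if r.get("activation") is not None]
    behs = [session_affective_score(r["behavior"], NOXIOUS_STIMULI)
            for r in results if r.get("behavior") is not None
            and r.get("activation") is not None]
    if len(acts) >= 5 and len(acts) == len(behs):
        rho = behavior_ensemble_correlation(acts, behs)["all"]
        summary["behavior_coupling"] = {"spearman_rho": rho, "n_sessions": len(acts)}
    return summary


# ---------------------------------------------------------------------------
# longitudinal analysis
# ---------------------------------------------------------------------------

def longitudinal_summary(cohort, cfg: PipelineConfig, seed: int,
                         injury_day: int = 0) -> dict:
    """Registration, stability, and expansion metrics for one longitudinal
    cohort (an iterable of (session, truth) pairs in animal-major order
    spanning a day grid; sessions are analyzed and released one at a time)."""
    total_aligned = total_stable = 0
    indices, dropped = [], 0
    registrations = {}
    n_animals = 0

    def animal_groups():
        current_id, group = None, []
        for session, _truth in cohort:
            if current_id is not None and session.animal_id != current_id:
                yield current_id, group
                group = []
            current_id = session.animal_id
            group.append(session)
        if group:
            yield current_id, group

    for animal, sessions in animal_groups():
        n_animals += 1
        sessions.sort(key=lambda s: s.day)
        days = [s.day for s in sessions]
        frags = [register_pair(sessions[i].centroids, sessions[i + 1].centroids,
                               cfg.registration_max_distance_px,
                               day_a=days[i], day_b=days[i + 1])
                 for i in range(len(sessions) - 1)]
        regmap = chain_days(frags)
        registrations[animal] = regmap

        tables = {}
        results = {}
        for s_i, session in enumerate(sessions):
            res = analyze_session(session, cfg, seed=substream_seed(seed, animal, s_i),
                                  decode=False)
            tables[session.day] = res["table"]
            results[session.day] = res
        sessions.clear()

        aligned = regmap.gids_spanning(days[0], days[-1])
        if aligned:
            frac, counts = stable_responder_fraction(
                tables, regmap, min_span_days=cfg.min_span_days,
                return_counts=True)
            total_aligned += counts[1]
            total_stable += counts[0]

        pre = [results[d]["sets"] for d in days if d < injury_day]
        post = [results[d]["sets"] for d in days if d >= injury_day]
        try:
            indices.append(allodynia_expansion_index(pre, post))
        except ValueError:
            dropped += 1

    stable_pct = 100.0 * total_stable / total_aligned if total_aligned else float("nan")
    return {
        "n_animals": n_animals,
        "aligned_neurons": int(total_aligned),
        "stable_noxious_responder_pct": stable_pct,
        "expansion_index_pct": _pack(indices),
        "expansion_undefined_animals": dropped,
        "registrations": registrations,
    }


def substream_seed(seed: int, *labels) -> int:
    """Derived integer seed (< 2^31) for a named child stage."""
    return int(substream(seed, *labels).integers(2 ** 31))


# ---------------------------------------------------------------------------
# top level
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every enabled stage and return (and optionally write) the report."""
    t0 = time.time()
    seed = int(config.seed)
    timings = {}

    stage = time.time()
    results = []
    for i, (session, _truth) in enumerate(
            iter_cohort(config.generator, substream_seed(seed, "cohort"))):
        results.append(analyze_session(session, config,
                                       seed=substream_seed(seed, "analyze", i)))
    timings["generate_and_analyze_s"] = round(time.time() - stage, 2)

    stage = time.time()
    report = {
        "provenance": {
            "package_version": __version__,
            "seed": seed,
            "config_sha256": hashlib.sha256(
                json.dumps(config_to_dict(config), sort_keys=True).encode()).hexdigest(),
            "n_dropped_trials": int(sum(r["n_dropped"] for r in results)),
        },
        "cohort": summarize_cohort(results, config),
    }
    timings["summarize_s"] = round(time.time() - stage, 2)

    if config.run_longitudinal:
        stage = time.time()
        gen = config.generator
        neuro = neuropathic_config(
            frame_rate=gen.frame_rate, trials_per_stimulus=gen.trials_per_stimulus,
            neurons_per_session_mean=gen.neurons_per_session_mean,
            neurons_per_session_sd=gen.neurons_per_session_sd)
        uninj = uninjured_config(
            frame_rate=gen.frame_rate, trials_per_stimulus=gen.trials_per_stimulus,
            neurons_per_session_mean=gen.neurons_per_session_mean,
            neurons_per_session_sd=gen.neurons_per_session_sd)
        neuro_sum = longitudinal_summary(
            iter_longitudinal_cohort(neuro, substream_seed(seed, "neuropathic")),
            config, substream_seed(seed, "neuro-analysis"))
        uninj_sum = longitudinal_summary(
            iter_longitudinal_cohort(uninj, substream_seed(seed, "uninjured")),
            config, substream_seed(seed, "uninj-analysis"))
        neuro_sum.pop("registrations")
        uninj_sum.pop("registrations")
        report["longitudinal"] = {"neuropathic": neuro_sum, "uninjured": uninj_sum}
        timings["longitudinal_s"] = round(time.time() - stage, 2)

    timings["total_s"] = round(time.time() - t0, 2)
    report["provenance"]["stage_timings"] = timings

    if config.outdir:
        _write_outputs(Path(config.outdir), config, report, results)
    validate_report(report, require_longitudinal=config.run_longitudinal)
    return report


def _round_floats(obj, digits: int = 10):
    if isinstance(obj, float):
        return float(f"{obj:.{digits}g}")
    if isinstance(obj, dict):
        return {k: _round_floats(v, digits) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_round_floats(v, digits) for v in obj]
    return obj


def _write_outputs(outdir: Path, config: PipelineConfig, report: dict,
                   results: list[dict]) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "report.json").write_text(
        json.dumps(_round_floats(report), indent=2, sort_keys=True))
    (outdir / "report_schema.json").write_text(json.dumps(_schema_names(REPORT_SCHEMA),
                                                          indent=2))
    tables = []
    for r in results:
        t = r["table"].copy()
        t.insert(0, "session_id", r["session_id"])
        tables.append(t)
    pd.concat(tables, ignore_index=True).to_csv(outdir / "responders.csv", index=False)
    for r in results:
        if r["confusion"] is not None:
            r["confusion"].to_frame().to_csv(
                outdir / f"confusion_{r['session_id']}.csv")
    behavior = [r["behavior"].assign(session_id=r["session_id"])
                for r in results if r["behavior"] is not None]
    if behavior:
        pd.concat(behavior, ignore_index=True).to_csv(
            outdir / "behavior_metrics.csv", index=False)


# ---------------------------------------------------------------------------
# report schema (structural validation, no external dependency)
# ---------------------------------------------------------------------------

REPORT_SCHEMA = {
    "provenance": {"package_version": str, "seed": int, "config_sha256": str,
                   "n_dropped_trials": int, "stage_timings": dict},
    "cohort": {"n_sessions": int, "neurons_per_session": dict,
               "responder_fractions_pct": dict, "nociceptive_fraction_pct": dict,
               "pain_specific_fraction_pct": dict,
               "light_touch_in_ensemble_pct": dict, "noxious_venn_counts": dict},
}


def _schema_names(schema: dict) -> dict:
    return {k: _schema_names(v) if isinstance(v, dict) else v.__name__
            for k, v in schema.items()}


def validate_report(report: dict, require_longitudinal: bool = False) -> None:
    """Check the report against the shipped structural schema; every packed
    mean must carry mean/sem/n and contain no NaNs in its mean."""
    def check(node, schema, path):
        for key, expected in schema.items():
            if key not in node:
                raise ValueError(f"report missing key {path}{key}")
            if isinstance(expected, dict):
                if not isinstance(node[key], dict):
                    raise ValueError(f"report key {path}{key} must be a mapping")
                check(node[key], expected, f"{path}{key}.")
            elif not isinstance(node[key], expected):
                raise ValueError(f"report key {path}{key} has wrong type")

    check(report, REPORT_SCHEMA, "")
    if require_longitudinal and "longitudinal" not in report:
        raise ValueError("longitudinal section missing from report")

    def walk(node, path):
        if isinstance(node, dict):
            if set(node) >= {"mean", "sem", "n"} and isinstance(node["n"], int):
                if node["n"] > 0 and not np.isfinite(node["mean"]):
                    raise ValueError(f"non-finite mean at {path}")
            for k, v in node.items():
                walk(v, f"{path}{k}.")

    walk(report, "")
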