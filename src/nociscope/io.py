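"""Readers and writers for the shared on-disk layouts.

Sessions live in HDF5 (groups /traces, /centroids, /events, /behavior,
/meta), stimulus events additionally as CSV, movies as multi-page TIFF,
ground truth as a JSON manifest, and configs as YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .config import GeneratorConfig, config_from_yaml, config_to_yaml
from .types import GroundTruth, SessionRecording, StimulusEvent

__all__ = [
    "save_session", "load_session", "events_to_csv", "events_from_csv",
    "save_movie", "load_movie", "save_ground_truth", "load_ground_truth",
    "save_config", "load_config",
]


def save_session(path, session: SessionRecording) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("traces", data=session.traces, compression="gzip")
        f.create_dataset("centroids", data=session.centroids)
        f.create_dataset("behavior", data=session.behavior)
        ev = f.create_group("events")
        ev.create_dataset("onset_s", data=[e.onset_s for e in session.events])
        ev.create_dataset("label", data=np.array([e.label for e in session.events],
                                                 dtype=h5py.string_dtype()))
        ev.create_dataset("trial_index", data=[e.trial_index for e in session.events])
        meta = f.create_group("meta")
        meta.attrs["animal_id"] = session.animal_id
        meta.attrs["session_id"] = session.session_id
        meta.attrs["day"] = session.day
        meta.attrs["frame_rate"] = session.frame_rate
        meta.attrs["condition"] = session.condition
        if session.footprints is not None:
            f.create_dataset("footprints", data=session.footprints, compression="gzip")


def load_session(path) -> SessionRecording:
    with h5py.File(path, "r") as f:
        events = [StimulusEvent(onset_s=float(o), label=l.decode() if isinstance(l, bytes) else str(l),
                                trial_index=int(t))
                  for o, l, t in zip(f["events/onset_s"][...],
                                     f["events/label"][...],
                                     f["events/trial_index"][...])]
        meta = f["meta"].attrs
        return SessionRecording(
            traces=f["traces"][...], centroids=f["centroids"][...],
            events=events, behavior=f["behavior"][...],
            animal_id=str(meta["animal_id"]), session_id=str(meta["session_id"]),
            day=int(meta["day"]), frame_rate=float(meta["frame_rate"]),
            condition=str(meta["condition"]),
            footprints=f["footprints"][...] if "footprints" in f else None)


def events_to_csv(path, events: list[StimulusEvent]) -> None:
    pd.DataFrame([{"onset_s": e.onset_s, "label": e.label,
                   "trial_index": e.trial_index} for e in events]).to_csv(
        path, index=False, float_format="%.17g")


def events_from_csv(path) -> list[StimulusEvent]:
    df = pd.read_csv(path, float_precision="round_trip")
    return [StimulusEvent(onset_s=float(r.onset_s), label=str(r.label),
                          trial_index=int(r.trial_index))
            for r in df.itertuples()]


def save_movie(path, movie: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(movie, dtype=np.float32))


def load_movie(path) -> np.ndarray:
    return tifffile.imread(path).astype(float)


def save_ground_truth(path, truth: GroundTruth) -> None:
    manifest = {
        "stimulus_panel": list(truth.stimulus_panel),
        "tuning_matrix": truth.tuning_matrix.astype(int).tolist(),
        "is_ensemble": truth.is_ensemble.astype(int).tolist(),
        "is_pain_specific": truth.is_pain_specific.astype(int).tolist(),
        "global_cell_ids": truth.global_cell_ids.tolist(),
        "planted_transients": [t.tolist() for t in truth.planted_transients],
        "planted_behavior_amplitudes": _nan_to_none(truth.planted_behavior_amplitudes),
        "planted_activation": _nan_to_none(truth.planted_activation),
    }
    Path(path).write_text(json.dumps(manifest))


def _nan_to_none(arr: np.ndarray) -> list:
    return [None if np.isnan(v) else float(v) for v in arr]


def _none_to_nan(values) -> np.ndarray:
    return np.array([np.nan if v is None else float(v) for v in values])


def load_ground_truth(path) -> GroundTruth:
    m = json.loads(Path(path).read_text())
    return GroundTruth(
        stimulus_panel=tuple(m["stimulus_panel"]),
        tuning_matrix=np.array(m["tuning_matrix"], dtype=bool),
        is_ensemble=np.array(m["is_ensemble"], dtype=bool),
        is_pain_specific=np.array(m["is_pain_specific"], dtype=bool),
        global_cell_ids=np.array(m["global_cell_ids"], dtype=int),
        planted_transients=[np.array(t).reshape(-1, 2) for t in m["planted_transients"]],
        planted_behavior_amplitudes=_none_to_nan(m["planted_behavior_amplitudes"]),
        planted_activation=_none_to_nan(m["planted_activation"]))


def save_config(path, config: GeneratorConfig) -> None:
    Path(path).write_text(config_to_yaml(config))


def load_config(path) -> GeneratorConfig:
    return config_from_yaml(Path(path).read_text())
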