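"""Readers, writers and configuration for the pipeline's text formats.

All artifacts are plain UTF-8 CSV (comma separated, header row, "."
decimal) or JSON. Dialects:

* trials CSV — one row per trial: ``trial_index, stimulus_class,
  concentration_vv, intensity_kmh, outcome, latency_s, reinforced,
  start_s, end_s`` (``concentration_vv`` empty on diluent trials);
* pokes CSV — ``trial_index, onset_s, duration_s``;
* heart-rate CSV — ``timestamp_s, bpm``;
* PID trace CSV — ``timestamp_s, voltage_v, valve_on`` plus optional
  ``distance_cm`` / ``dilution_vv`` metadata columns.

Dataset directories carry a ``manifest.json`` embedding the seed and a
hash of the generating configuration so outputs are provenance-checked and
byte-identical under identical inputs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .dog import DogModel, StudyResult
from .session import PokeEvent, SessionResult, TrialTiming

__all__ = [
    "ConfigError",
    "session_to_frames",
    "sessions_to_frame",
    "write_session",
    "write_study",
    "read_trials",
    "read_pokes",
    "read_hr",
    "read_study",
    "read_pid_trace",
    "write_pid_trace",
    "load_config",
    "default_config",
    "build_model",
    "build_timing",
    "config_hash",
]

#: float format guaranteeing exact round-trip of IEEE doubles through CSV
FLOAT_FORMAT = "%.17g"

TRIAL_COLUMNS = [
    "trial_index",
    "stimulus_class",
    "concentration_vv",
    "intensity_kmh",
    "outcome",
    "latency_s",
    "reinforced",
    "start_s",
    "end_s",
]


class ConfigError(ValueError):
    """A study configuration is missing or malformed."""


def session_to_frames(session: SessionResult) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tabulate one scored session as (trials, pokes) DataFrames."""
    plan = session.plan
    rows = []
    for spec, res in zip(plan.trials, session.results):
        rows.append(
            {
                "trial_index": res.trial_index,
                "stimulus_class": "target" if spec.is_target else "diluent",
                "concentration_vv": spec.concentration if spec.is_target else np.nan,
                "intensity_kmh": plan.intensity,
                "outcome": res.outcome,
                "latency_s": res.latency_s,
                "reinforced": res.reinforced,
                "start_s": res.start_s,
                "end_s": res.end_s,
            }
        )
    trials = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    poke_rows = []
    for spec, pokes in zip(plan.trials, session.pokes):
        for p in pokes:
            poke_rows.append(
                {"trial_index": spec.trial_index, "onset_s": p.onset_s, "duration_s": p.duration_s}
            )
    pokes = pd.DataFrame(poke_rows, columns=["trial_index", "onset_s", "duration_s"])
    return trials, pokes


def sessions_to_frame(sessions: Iterable[SessionResult]) -> pd.DataFrame:
    """Concatenate sessions into one trials table with a session_index column."""
    frames = []
    for i, s in enumerate(sessions):
        t, _ = session_to_frames(s)
        t.insert(0, "session_index", i + 1)
        t.insert(1, "block_index", s.plan.block_index)
        frames.append(t)
    return pd.concat(frames, ignore_index=True)


def write_session(
    out_dir, session: SessionResult, index: int, hr: pd.DataFrame | None = None
) -> list[Path]:
    """Write one session's trials/pokes (and optional HR) CSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stem = f"session_{index:02d}_block{session.plan.block_index}_{session.plan.intensity}kmh"
    trials, pokes = session_to_frames(session)
    paths = [out / f"{stem}_trials.csv", out / f"{stem}_pokes.csv"]
    trials.to_csv(paths[0], index=False, float_format=FLOAT_FORMAT)
    pokes.to_csv(paths[1], index=False, float_format=FLOAT_FORMAT)
    if hr is not None:
        p = out / f"{stem}_hr.csv"
        hr.to_csv(p, index=False, float_format=FLOAT_FORMAT)
        paths.append(p)
    return paths


def write_study(
    out_dir, study: StudyResult, config: dict | None = None, seed: int | None = None
) -> Path:
    """Write a full study dataset directory with a provenance manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: list[str] = []
    for i, sess in enumerate(study.sessions, start=1):
        hr = study.hr[i - 1] if i - 1 < len(study.hr) else None
        for p in write_session(out, sess, i, hr=hr):
            files.append(p.name)
    manifest = {
        "format": "olfex-study/1",
        "seed": seed,
        "config_hash": config_hash(config) if config is not None else None,
        "n_sessions": len(study.sessions),
        "stopped_block": study.stopped_block,
        "files": sorted(files),
    }
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def _read_csv(path, required: Sequence[str]) -> pd.DataFrame:
    # round_trip parser: exact inverse of the %.17g writer
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def read_trials(path) -> pd.DataFrame:
    df = _read_csv(path, TRIAL_COLUMNS)
    df["reinforced"] = df["reinforced"].astype(bool)
    for col in ("concentration_vv", "latency_s", "start_s", "end_s"):
        df[col] = df[col].astype(float)
    return df


def read_pokes(path) -> pd.DataFrame:
    df = _read_csv(path, ["trial_index", "onset_s", "duration_s"])
    return df.astype({"onset_s": float, "duration_s": float})


def read_hr(path) -> pd.DataFrame:
    df = _read_csv(path, ["timestamp_s", "bpm"])
    return df.astype({"timestamp_s": float, "bpm": float})


def read_study(data_dir) -> tuple[pd.DataFrame, dict[int, pd.DataFrame], dict]:
    """Load a dataset directory.

    Returns (trials, hr_by_session, manifest): the concatenated trials
    table with ``session_index``/``block_index``/``intensity_kmh`` columns,
    per-session heart-rate frames, and the manifest (empty dict if absent).
    """
    data = Path(data_dir)
    trial_files = sorted(data.glob("session_*_trials.csv"))
    if not trial_files:
        raise FileNotFoundError(f"no sessions found in {data}")
    frames = []
    hr: dict[int, pd.DataFrame] = {}
    for f in trial_files:
        stem = f.name[: -len("_trials.csv")]
        idx = int(stem.split("_")[1])
        block = int(stem.split("_")[2].removeprefix("block"))
        t = read_trials(f)
        t.insert(0, "session_index", idx)
        t.insert(1, "block_index", block)
        frames.append(t)
        hr_path = data / f"{stem}_hr.csv"
        if hr_path.exists():
            hr[idx] = read_hr(hr_path)
    manifest = {}
    mpath = data / "manifest.json"
    if mpath.exists():
        manifest = json.loads(mpath.read_text())
    return pd.concat(frames, ignore_index=True), hr, manifest


def read_pid_trace(path) -> "object":
    """Load a PID trace CSV into a :class:`~olfex.pid.PIDTrace`."""
    from .pid import PIDTrace

    df = _read_csv(path, ["timestamp_s", "voltage_v", "valve_on"])
    ts = df["timestamp_s"].to_numpy(dtype=float)
    if len(ts) > 1:
        rate = 1.0 / np.median(np.diff(ts))
    else:
        rate = 500.0
    distance = None
    if "distance_cm" in df.columns and df["distance_cm"].notna().any():
        distance = float(df["distance_cm"].iloc[0])
    return PIDTrace(
        df["voltage_v"].to_numpy(dtype=float),
        df["valve_on"].to_numpy(dtype=bool),
        float(rate),
        distance,
    )


def write_pid_trace(path, trace) -> Path:
    ts = np.arange(len(trace)) / trace.sample_rate_hz
    df = pd.DataFrame(
        {"timestamp_s": ts, "voltage_v": trace.voltage, "valve_on": trace.valve_on.astype(int)}
    )
    if trace.distance_cm is not None:
        df["distance_cm"] = trace.distance_cm
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    return Path(path)


# ---------------------------------------------------------------------------
# configuration


def default_config() -> dict:
    """Default study configuration (the conditions the paradigm defines)."""
    return {
        "seed": 0,
        "dog": {f: getattr(DogModel(), f) for f in DogModel.__dataclass_fields__},
        "study": {
            "first_top_concentration": 1e-2,
            "max_blocks": 3,
            "cr_reinforcement_rate": 0.40,
            "stop_rule_inclusive": True,
        },
        "timing": {f: getattr(TrialTiming(), f) for f in TrialTiming.__dataclass_fields__},
        "analysis": {
            "sdt_correction": True,
            "determining_intensity": "either",
            "hr_offset_s": 0.0,
        },
    }


_REQUIRED_SECTIONS = ("dog", "study", "timing", "analysis")


def load_config(path) -> dict:
    """Load and validate a YAML study configuration.

    Missing sections or fields fall back to defaults is *not* done for the
    ``dog`` and ``study`` sections: every field must be present so a run is
    fully specified; unknown fields raise, naming the offender.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    defaults = default_config()
    for section in _REQUIRED_SECTIONS:
        if section not in cfg:
            raise ConfigError(f"missing required section: {section}")
        if not isinstance(cfg[section], dict):
            raise ConfigError(f"section {section} must be a mapping")
        for key in defaults[section]:
            if key not in cfg[section]:
                raise ConfigError(f"missing required field: {section}.{key}")
        for key in cfg[section]:
            if key not in defaults[section]:
                raise ConfigError(f"unknown field: {section}.{key}")
    if "seed" not in cfg:
        raise ConfigError("missing required field: seed")
    return cfg


def build_model(cfg: dict) -> DogModel:
    try:
        return DogModel(**cfg["dog"])
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc


def build_timing(cfg: dict) -> TrialTiming:
    try:
        return TrialTiming(**cfg["timing"])
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc


def config_hash(cfg: dict) -> str:
    """Stable SHA-256 over the canonical JSON form of a configuration."""
    blob = json.dumps(cfg, sort_keys=True, default=float).encode()
    return hashlib.sha256(blob).hexdigest()
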