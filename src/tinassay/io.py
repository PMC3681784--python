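"""Readers, writers, and run configuration.

Behavioral sessions travel as paired CSV files (there is no community
standard for operant logs): a press file with columns
``animal_id, session, t_sec`` and a companion schedule file with columns
``period_index, start_sec, end_sec, kind, stimulus, freq_khz, level_db``.
Floats are written with ``repr`` so a write-read round trip reproduces the
log exactly.  A session can also travel as a single JSON document.
Run configuration is YAML.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import numpy as np
import yaml

from .behavior import (
    BACKGROUND,
    PROBE,
    Period,
    Protocol,
    SessionLog,
    Stimulus,
    default_catalog,
)

__all__ = [
    "SessionFormatError",
    "write_session_csv",
    "read_session_csv",
    "session_to_dict",
    "session_from_dict",
    "write_session_json",
    "read_session_json",
    "RunConfig",
    "load_config",
    "config_hash",
]

PRESS_COLUMNS = ["animal_id", "session", "t_sec"]
SCHEDULE_COLUMNS = ["period_index", "start_sec", "end_sec", "kind", "stimulus", "freq_khz", "level_db"]


class SessionFormatError(ValueError):
    """Raised on malformed session files, with the offending line number."""


def _schedule_path_for(press_path: Path) -> Path:
    return press_path.with_suffix(".schedule.csv")


def write_session_csv(
    log: SessionLog, press_path, schedule_path=None
) -> tuple[Path, Path]:
    """Write one session as press CSV plus companion schedule CSV."""
    press_path = Path(press_path)
    schedule_path = Path(schedule_path) if schedule_path else _schedule_path_for(press_path)
    with open(press_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(PRESS_COLUMNS)
        for t in log.press_times:
            w.writerow([log.animal_id, log.session_index, repr(float(t))])
    with open(schedule_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(SCHEDULE_COLUMNS)
        for i, p in enumerate(log.schedule):
            stim = p.stimulus
            w.writerow(
                [
                    i,
                    repr(p.start_sec),
                    repr(p.end_sec),
                    p.kind,
                    stim.kind if stim else "",
                    "" if stim is None or stim.freq_khz is None else repr(stim.freq_khz),
                    "" if stim is None or stim.level_db is None else repr(stim.level_db),
                ]
            )
    return press_path, schedule_path


def _parse_float(value: str, what: str, path, line_no: int) -> float:
    try:
        return float(value)
    except ValueError:
        raise SessionFormatError(f"{path}:{line_no}: invalid {what} {value!r}") from None


def read_session_csv(press_path, schedule_path=None) -> SessionLog:
    """Read a session from press + schedule CSVs (LF or CRLF, either way)."""
    press_path = Path(press_path)
    schedule_path = Path(schedule_path) if schedule_path else _schedule_path_for(press_path)
    if not schedule_path.exists():
        raise FileNotFoundError(
            f"schedule file {schedule_path} not found (required alongside {press_path})"
        )

    periods: list[Period] = []
    with open(schedule_path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != SCHEDULE_COLUMNS:
            raise SessionFormatError(f"{schedule_path}:1: expected header {SCHEDULE_COLUMNS}")
        for line_no, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(SCHEDULE_COLUMNS):
                raise SessionFormatError(
                    f"{schedule_path}:{line_no}: expected {len(SCHEDULE_COLUMNS)} fields"
                )
            _, start_s, end_s, kind, stim_kind, freq_s, level_s = row
            if kind not in (BACKGROUND, PROBE):
                raise SessionFormatError(f"{schedule_path}:{line_no}: unknown period kind {kind!r}")
            stim = None
            if stim_kind:
                stim = Stimulus(
                    stim_kind,
                    _parse_float(freq_s, "freq_khz", schedule_path, line_no) if freq_s else None,
                    _parse_float(level_s, "level_db", schedule_path, line_no) if level_s else None,
                )
            periods.append(
                Period(
                    _parse_float(start_s, "start_sec", schedule_path, line_no),
                    _parse_float(end_s, "end_sec", schedule_path, line_no),
                    kind,
                    stim,
                )
            )
    if not periods:
        raise SessionFormatError(f"{schedule_path}: no schedule periods")

    times: list[float] = []
    animal_id = ""
    session_index = 0
    with open(press_path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != PRESS_COLUMNS:
            raise SessionFormatError(f"{press_path}:1: expected header {PRESS_COLUMNS}")
        for line_no, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(PRESS_COLUMNS):
                raise SessionFormatError(f"{press_path}:{line_no}: expected 3 fields")
            animal_id = row[0]
            try:
                session_index = int(row[1])
            except ValueError:
                raise SessionFormatError(
                    f"{press_path}:{line_no}: invalid session index {row[1]!r}"
                ) from None
            times.append(_parse_float(row[2], "t_sec", press_path, line_no))
    return SessionLog(
        animal_id=animal_id,
        press_times=np.asarray(times, dtype=float),
        schedule=tuple(periods),
        session_index=session_index,
    )


def session_to_dict(log: SessionLog) -> dict:
    return {
        "animal_id": log.animal_id,
        "session": log.session_index,
        "press_times": [float(t) for t in log.press_times],
        "schedule": [
            {
                "start_sec": p.start_sec,
                "end_sec": p.end_sec,
                "kind": p.kind,
                "stimulus": None
                if p.stimulus is None
                else {
                    "kind": p.stimulus.kind,
                    "freq_khz": p.stimulus.freq_khz,
                    "level_db": p.stimulus.level_db,
                },
            }
            for p in log.schedule
        ],
    }


def session_from_dict(doc: dict) -> SessionLog:
    periods = tuple(
        Period(
            p["start_sec"],
            p["end_sec"],
            p["kind"],
            None
            if p.get("stimulus") is None
            else Stimulus(
                p["stimulus"]["kind"], p["stimulus"].get("freq_khz"), p["stimulus"].get("level_db")
            ),
        )
        for p in doc["schedule"]
    )
    return SessionLog(
        animal_id=doc["animal_id"],
        press_times=np.asarray(doc["press_times"], dtype=float),
        schedule=periods,
        session_index=int(doc.get("session", 0)),
    )


def write_session_json(log: SessionLog, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(session_to_dict(log), indent=1))
    return path


def read_session_json(path) -> SessionLog:
    return session_from_dict(json.loads(Path(path).read_text()))


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (YAML-serialisable)."""

    seed: int = 0
    # protocol
    session_minutes: int = 60
    n_probes: int = 10
    n_speaker_off: int = 2
    probe_kind: str = "tone"
    probe_freq_khz: float = 20.0
    probe_levels_db: tuple = (30.0, 40.0, 50.0, 60.0, 70.0, 80.0, 90.0)
    background_level_db: float = 60.0
    # cohort
    n_exposed: int = 5
    n_unexposed: int = 3
    n_sessions: int = 10
    tau_distribution: tuple = ("constant", 0.8)
    lambda_bg_median: float = 15.0
    lambda_bg_sigma: float = 0.8
    c_off: float = 0.9
    # QC
    qc_min_presses: int = 200
    qc_min_background_r: float = 0.4
    # subgrouping
    classify: bool = False
    # IHC
    ihc: bool = True
    ihc_base_blobs: int = 18
    ihc_effect: float = 2.0
    ihc_animal_sigma: float = 0.2
    threshold_method: str = "otsu"
    min_particle_size_px: int = 4

    def __post_init__(self) -> None:
        if self.qc_min_presses < 0:
            raise ValueError("qc_min_presses must be non-negative")
        if not (0.0 <= self.qc_min_background_r <= 1.0):
            raise ValueError("qc_min_background_r must lie in [0, 1]")
        if self.min_particle_size_px < 0:
            raise ValueError("min_particle_size_px must be non-negative")
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("seed must be an integer")

    def protocol(self) -> Protocol:
        return Protocol(
            session_minutes=self.session_minutes,
            n_probes=self.n_probes,
            n_speaker_off=self.n_speaker_off,
            probe_catalog=default_catalog(
                self.probe_kind, self.probe_freq_khz, self.probe_levels_db
            ),
            background_level_db=self.background_level_db,
        )


def load_config(path) -> RunConfig:
    """Load a RunConfig from YAML; unknown keys are an error."""
    doc = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in fields(RunConfig)}
    unknown = set(doc) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("probe_levels_db", "tau_distribution"):
        if key in doc and isinstance(doc[key], list):
            doc[key] = tuple(doc[key])
    return RunConfig(**doc)


def config_hash(config: RunConfig) -> str:
    """Stable hash of a config for the run manifest."""
    payload = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
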