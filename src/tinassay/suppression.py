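"""Suppression-ratio scoring: epoching, the running R statistic, and QC.

The central statistic is the suppression ratio R = B/(A+B), where A is the
lever-press count in the preceding 1-min segment and B the count in the
current one.  R runs from 0 (complete suppression) through 0.5 (no change)
to 1 (resumption after a silent minute) and is computed as a running
measure over successive 1-min epochs of a session.

Sessions enter group analysis only if they pass two conjoint quality
criteria: at least 200 total lever presses, and a mean suppression ratio of
at least 0.4 over background (ambient-noise) minutes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behavior import BACKGROUND, MINUTE_SEC, PROBE, SessionLog

__all__ = [
    "suppression_ratio",
    "running_R",
    "epoch_counts",
    "epoch_series",
    "session_qc",
    "probe_R",
    "QCReport",
    "UNDEFINED_R",
]

logger = logging.getLogger(__name__)

#: Sentinel for epochs where A + B = 0 and R is undefined (excluded from
#: every average downstream rather than imputed).
UNDEFINED_R = float("nan")


def suppression_ratio(a: int, b: int) -> float:
    """R = B/(A+B); NaN sentinel when A+B = 0.

    A and B are non-negative press counts of the preceding and current
    minute.  R(A=B) = 0.5, R(B=0) = 0, R(A=0, B>0) = 1.
    """
    if a < 0 or b < 0:
        raise ValueError("press counts must be non-negative")
    total = a + b
    if total == 0:
        return UNDEFINED_R
    return b / total


def running_R(counts) -> np.ndarray:
    """Running suppression ratio over successive 1-min epoch counts.

    Minute k uses A = counts[k-1], B = counts[k]; minute 0 has no
    preceding segment and is undefined.
    """
    counts = np.asarray(counts)
    if counts.ndim != 1 or counts.size < 2:
        raise ValueError("need a 1-D series of at least 2 per-minute counts")
    if np.any(counts < 0):
        raise ValueError("press counts must be non-negative")
    r = np.full(counts.size, UNDEFINED_R)
    a = counts[:-1].astype(float)
    b = counts[1:].astype(float)
    tot = a + b
    ok = tot > 0
    r[1:][ok] = b[ok] / tot[ok]
    return r


def epoch_counts(log: SessionLog) -> np.ndarray:
    """Per-minute press counts aligned to the schedule (half-open bins)."""
    n = log.n_minutes
    end = log.schedule[-1].end_sec
    t = log.press_times
    if t.size and (t.min() < 0 or t.max() >= end):
        raise ValueError("press times outside session bounds")
    edges = np.arange(n + 1) * MINUTE_SEC
    counts, _ = np.histogram(t, bins=edges)
    return counts.astype(int)


def epoch_series(log: SessionLog) -> pd.DataFrame:
    """Per-minute epoch table: counts, running R, and schedule annotations.

    Columns: minute, count, prev_count, R, kind (background/probe),
    stim_kind, freq_khz, level_db, stim_label.
    """
    counts = epoch_counts(log)
    r = running_R(counts)
    rows = []
    for minute, period in enumerate(log.schedule):
        stim = period.stimulus
        rows.append(
            {
                "minute": minute,
                "count": int(counts[minute]),
                "prev_count": int(counts[minute - 1]) if minute > 0 else -1,
                "R": r[minute],
                "kind": period.kind,
                "stim_kind": stim.kind if stim else "",
                "freq_khz": stim.freq_khz if stim and stim.freq_khz is not None else np.nan,
                "level_db": stim.level_db if stim and stim.level_db is not None else np.nan,
                "stim_label": stim.label if stim else "",
            }
        )
    return pd.DataFrame(rows)


def _background_eligible(series: pd.DataFrame) -> pd.Series:
    """Background minutes whose R is a clean background measure.

    Excludes minute 0 (no preceding segment), probe minutes, and the minute
    immediately following a probe (its A comes from the probe minute and is
    contaminated by the test stimulus).
    """
    prev_kind = series["kind"].shift(1)
    return (series["minute"] > 0) & (series["kind"] == BACKGROUND) & (prev_kind == BACKGROUND)


@dataclass(frozen=True)
class QCReport:
    """Outcome of the two conjoint session-inclusion criteria."""

    animal_id: str
    session_index: int
    total_presses: int
    mean_background_R: float
    n_background_epochs: int
    passed: bool
    failure_reasons: tuple[str, ...] = field(default_factory=tuple)


def session_qc(
    log: SessionLog,
    series: pd.DataFrame | None = None,
    min_presses: int = 200,
    min_background_r: float = 0.4,
) -> QCReport:
    """Apply the session-inclusion criteria (both must hold; boundaries pass).

    (a) total lever presses >= ``min_presses``; (b) mean of defined R over
    eligible background minutes >= ``min_background_r``.
    """
    if series is None:
        series = epoch_series(log)
    total = int(series["count"].sum())
    eligible = series.loc[_background_eligible(series), "R"].dropna()
    mean_bg = float(eligible.mean()) if len(eligible) else float("nan")

    reasons = []
    if total < min_presses:
        reasons.append(f"press-count: {total} < {min_presses}")
    if not len(eligible):
        reasons.append("background-R: no defined background epochs")
    elif mean_bg < min_background_r:
        reasons.append(f"background-R: {mean_bg:.4f} < {min_background_r}")
    return QCReport(
        animal_id=log.animal_id,
        session_index=log.session_index,
        total_presses=total,
        mean_background_R=mean_bg,
        n_background_epochs=int(len(eligible)),
        passed=not reasons,
        failure_reasons=tuple(reasons),
    )


def probe_R(series: pd.DataFrame) -> pd.DataFrame:
    """One row per probe minute with a defined suppression ratio.

    Columns: minute, stim_kind, freq_khz, level_db, stim_label, A (the
    preceding minute's count), B, R.  Probe minutes with A + B = 0 are
    dropped; the number dropped is logged.
    """
    probes = series[series["kind"] == PROBE]
    defined = probes["R"].notna()
    n_dropped = int((~defined).sum())
    if n_dropped:
        logger.info("probe_R: dropped %d probe minutes with undefined R", n_dropped)
    out = probes.loc[defined, ["minute", "stim_kind", "freq_khz", "level_db", "stim_label", "prev_count", "count", "R"]]
    return out.rename(columns={"prev_count": "A", "count": "B"}).reset_index(drop=True)
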