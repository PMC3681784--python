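"""Group-level inference on the conditioned-suppression assay.

Builds psychophysical discrimination functions (mean suppression ratio R
per stimulus and presentation level), applies the prominent/weak-tinnitus
subgroup classification rule (lowest 16 of 24 exposed animals by mean
20 kHz probe R), and runs the group comparisons: a two-way mixed-design
ANOVA (group between subjects, level within subjects, speaker-off data
excluded) computed from sums of squares, and uncorrected independent
t-tests for immunoreactivity percent-area data.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .behavior import SPEAKER_OFF, CohortAnimal
from .suppression import epoch_series, probe_R, session_qc

__all__ = [
    "score_cohort",
    "discrimination_function",
    "animal_level_means",
    "classify_subgroups",
    "mixed_anova",
    "group_compare",
    "ihc_group_ttest",
    "TTestResult",
]

PROMINENT_ANTAGONIST = "exposed_prominent_antagonist"
PROMINENT_NO_DRUG = "exposed_prominent_no_drug"
WEAK_AGONIST = "exposed_weak_agonist"
UNASSIGNED = "exposed_unassigned"


def score_cohort(
    cohort: Sequence[CohortAnimal],
    min_presses: int = 200,
    min_background_r: float = 0.4,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score every session of a cohort and pool probe rows from QC passers.

    Returns (probe_df, qc_df): probe_df has one row per probe minute of
    every QC-passing session (columns animal_id, exposed, session,
    stim_kind, freq_khz, level_db, stim_label, A, B, R); qc_df has one row
    per session with the QC outcome.
    """
    probe_rows = []
    qc_rows = []
    for animal in cohort:
        for log in animal.sessions:
            series = epoch_series(log)
            report = session_qc(
                log, series, min_presses=min_presses, min_background_r=min_background_r
            )
            qc_rows.append(
                {
                    "animal_id": log.animal_id,
                    "session": log.session_index,
                    "total_presses": report.total_presses,
                    "mean_background_R": report.mean_background_R,
                    "passed": report.passed,
                    "failure_reasons": "; ".join(report.failure_reasons),
                }
            )
            if report.passed:
                rows = probe_R(series)
                rows.insert(0, "session", log.session_index)
                rows.insert(0, "exposed", animal.state.exposed)
                rows.insert(0, "animal_id", log.animal_id)
                probe_rows.append(rows)
    probe_df = (
        pd.concat(probe_rows, ignore_index=True)
        if probe_rows
        else pd.DataFrame(
            columns=[
                "animal_id",
                "exposed",
                "session",
                "minute",
                "stim_kind",
                "freq_khz",
                "level_db",
                "stim_label",
                "A",
                "B",
                "R",
            ]
        )
    )
    return probe_df, pd.DataFrame(qc_rows)


def _level_key(probe_df: pd.DataFrame) -> pd.Series:
    # speaker-off has no level; order it below every sounded level
    return probe_df["level_db"].fillna(-np.inf)


def discrimination_function(
    probe_df: pd.DataFrame,
    stimulus: str,
    include_speaker_off: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-animal and pooled discrimination functions for one stimulus kind.

    Animals are weighted equally: each animal's per-level mean R is
    computed first (across all of its QC-passing probe minutes), then the
    pooled function takes the mean and SEM of those animal means.  SEM is
    NaN when only one animal contributes.

    Returns (per_animal, pooled); ``level_db`` is NaN on the speaker-off
    row, which sorts before the sounded levels.
    """
    if stimulus == SPEAKER_OFF:
        raise ValueError("speaker_off is a reference point, not a stimulus axis")
    keep = probe_df["stim_kind"] == stimulus
    if include_speaker_off:
        keep = keep | (probe_df["stim_kind"] == SPEAKER_OFF)
    sub = probe_df[keep].copy()
    if not (sub["stim_kind"] == stimulus).any():
        raise ValueError(f"no probe data for stimulus kind {stimulus!r}")
    sub["_lvl"] = _level_key(sub)

    per_animal = (
        sub.groupby(["animal_id", "_lvl"], as_index=False)
        .agg(mean_R=("R", "mean"), n_probes=("R", "size"))
        .sort_values(["animal_id", "_lvl"])
    )
    pooled = (
        per_animal.groupby("_lvl", as_index=False)
        .agg(
            mean_R=("mean_R", "mean"),
            sem_R=("mean_R", lambda x: x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else np.nan),
            n_animals=("mean_R", "size"),
        )
        .sort_values("_lvl")
    )
    for frame in (per_animal, pooled):
        frame["level_db"] = frame["_lvl"].replace(-np.inf, np.nan)
        frame.drop(columns="_lvl", inplace=True)
    return per_animal.reset_index(drop=True), pooled.reset_index(drop=True)


def animal_level_means(probe_df: pd.DataFrame, stimulus: str) -> pd.DataFrame:
    """Long table animal_id x level_db -> mean R for one sounded stimulus.

    Speaker-off rows are excluded (the group ANOVA is applied to all data
    excluding speaker-off results).
    """
    sub = probe_df[(probe_df["stim_kind"] == stimulus) & probe_df["level_db"].notna()]
    if sub.empty:
        raise ValueError(f"no probe data for stimulus kind {stimulus!r}")
    return (
        sub.groupby(["animal_id", "level_db"], as_index=False)
        .agg(mean_R=("R", "mean"))
        .sort_values(["animal_id", "level_db"])
        .reset_index(drop=True)
    )


def mean_probe_R(probe_df: pd.DataFrame, stimulus: str = "tone", freq_khz: float | None = 20.0) -> pd.Series:
    """Mean probe R per animal for the diagnostic stimulus (default 20 kHz).

    Session probe rows are already pooled, so each QC-passing probe minute
    weighs equally within an animal.
    """
    sub = probe_df[probe_df["stim_kind"] == stimulus]
    if freq_khz is not None:
        sub = sub[sub["freq_khz"] == freq_khz]
    if sub.empty:
        raise ValueError("no matching probe rows for the ranking stimulus")
    return sub.groupby("animal_id")["R"].mean()


def classify_subgroups(
    mean_r: Mapping[str, float] | pd.Series | Iterable[tuple[str, float]],
    seed=0,
    n_prominent: int = 16,
    n_weak: int = 8,
) -> pd.DataFrame:
    """Designate prominent/weak tinnitus subgroups among exposed animals.

    Animals are ranked ascending by their mean 20 kHz probe suppression
    ratio (ties broken by animal_id order).  The ``n_prominent`` lowest are
    designated prominent tinnitus and randomly halved (seeded) into
    antagonist and no-drug subgroups; the next ``n_weak`` (highest ratios)
    are the weak-tinnitus agonist subgroup.  Any animals beyond the
    16 + 8 design are labelled unassigned.
    """
    if isinstance(mean_r, pd.Series):
        items = list(mean_r.items())
    elif isinstance(mean_r, Mapping):
        items = list(mean_r.items())
    else:
        items = list(mean_r)
    required = n_prominent + n_weak
    if len(items) < required:
        raise ValueError(
            f"subgroup design needs at least {required} exposed animals "
            f"({n_prominent} prominent + {n_weak} weak); got {len(items)}"
        )
    ranked = sorted(items, key=lambda kv: (kv[1], kv[0]))
    rng = np.random.default_rng(seed)
    half = n_prominent // 2
    split = rng.permutation(n_prominent)
    labels = {}
    for rank, (animal_id, _) in enumerate(ranked):
        if rank < n_prominent:
            labels[animal_id] = PROMINENT_ANTAGONIST if split[rank] < half else PROMINENT_NO_DRUG
        elif rank < required:
            labels[animal_id] = WEAK_AGONIST
        else:
            labels[animal_id] = UNASSIGNED
    return pd.DataFrame(
        {
            "animal_id": [aid for aid, _ in ranked],
            "mean_20khz_R": [v for _, v in ranked],
            "rank": np.arange(len(ranked)),
            "group": [labels[aid] for aid, _ in ranked],
        }
    )


def mixed_anova(
    data: pd.DataFrame,
    dv: str = "mean_R",
    subject: str = "animal_id",
    between: str = "group",
    within: str = "level_db",
) -> pd.DataFrame:
    """Two-way mixed-design (split-plot) ANOVA from sums of squares.

    Between-subjects factor ``between`` (each subject in exactly one
    group), within-subjects factor ``within`` (each subject measured at
    every level).  Reports the group main effect (tested against subjects
    within groups), the level main effect and the group x level
    interaction (tested against the within-subjects residual).  No
    sphericity correction is applied.
    """
    df = data[[subject, between, within, dv]].copy()
    groups_per_subject = df.groupby(subject)[between].nunique()
    if (groups_per_subject > 1).any():
        bad = groups_per_subject[groups_per_subject > 1].index.tolist()
        raise ValueError(f"subjects assigned to multiple groups: {bad}")
    wide = df.pivot_table(index=subject, columns=within, values=dv, aggfunc="mean")
    missing = [
        (subj, lvl)
        for subj in wide.index
        for lvl in wide.columns
        if pd.isna(wide.loc[subj, lvl])
    ]
    if missing:
        raise ValueError(f"empty subject x level cells: {missing}")

    levels = list(wide.columns)
    n_levels = len(levels)
    group_of = df.groupby(subject)[between].first()
    groups = sorted(group_of.unique())
    if len(groups) < 2 or n_levels < 2:
        raise ValueError("need at least 2 groups and 2 within-subject levels")

    grand = wide.values.mean()
    subj_means = wide.mean(axis=1)
    n_subjects = len(wide)

    ss_total = float(((wide.values - grand) ** 2).sum())
    ss_between_subj = float(n_levels * ((subj_means - grand) ** 2).sum())
    ss_group = 0.0
    for g in groups:
        members = group_of[group_of == g].index
        g_mean = wide.loc[members].values.mean()
        ss_group += len(members) * n_levels * (g_mean - grand) ** 2
    ss_subj_within = ss_between_subj - ss_group

    level_means = wide.mean(axis=0)
    ss_level = float(n_subjects * ((level_means - grand) ** 2).sum())

    ss_inter = 0.0
    for g in groups:
        members = group_of[group_of == g].index
        g_mean = wide.loc[members].values.mean()
        for lvl in levels:
            cell = wide.loc[members, lvl].mean()
            ss_inter += len(members) * (cell - g_mean - level_means[lvl] + grand) ** 2
    ss_within_subj = ss_total - ss_between_subj
    ss_error = ss_within_subj - ss_level - ss_inter

    g = len(groups)
    df_group = g - 1
    df_subj = n_subjects - g
    df_level = n_levels - 1
    df_inter = df_group * df_level
    df_error = df_subj * df_level

    ms = lambda ss, d: ss / d if d > 0 else np.nan
    ms_group, ms_subj = ms(ss_group, df_group), ms(ss_subj_within, df_subj)
    ms_level, ms_inter, ms_error = (
        ms(ss_level, df_level),
        ms(ss_inter, df_inter),
        ms(ss_error, df_error),
    )

    def f_p(ms_effect, df_effect, ms_err, df_err):
        if not np.isfinite(ms_effect) or not np.isfinite(ms_err) or ms_err == 0:
            f = 0.0 if ms_effect == 0 else np.inf
        else:
            f = ms_effect / ms_err
        p = float(stats.f.sf(f, df_effect, df_err)) if np.isfinite(f) else 0.0
        return f, p

    f_group, p_group = f_p(ms_group, df_group, ms_subj, df_subj)
    f_level, p_level = f_p(ms_level, df_level, ms_error, df_error)
    f_inter, p_inter = f_p(ms_inter, df_inter, ms_error, df_error)

    return pd.DataFrame(
        [
            {"effect": "group", "SS": ss_group, "df": df_group, "df_error": df_subj,
             "MS": ms_group, "F": f_group, "p": p_group},
            {"effect": "subjects(group)", "SS": ss_subj_within, "df": df_subj,
             "df_error": np.nan, "MS": ms_subj, "F": np.nan, "p": np.nan},
            {"effect": "level", "SS": ss_level, "df": df_level, "df_error": df_error,
             "MS": ms_level, "F": f_level, "p": p_level},
            {"effect": "group:level", "SS": ss_inter, "df": df_inter, "df_error": df_error,
             "MS": ms_inter, "F": f_inter, "p": p_inter},
            {"effect": "residual", "SS": ss_error, "df": df_error, "df_error": np.nan,
             "MS": ms_error, "F": np.nan, "p": np.nan},
        ]
    )


def group_compare(
    level_means: pd.DataFrame,
    group_of: Mapping[str, str] | pd.Series,
    dv: str = "mean_R",
) -> pd.DataFrame:
    """Mixed ANOVA comparing groups of animals across presentation levels.

    ``level_means`` is the long table from :func:`animal_level_means`
    (speaker-off already excluded); ``group_of`` maps animal_id to group.
    """
    data = level_means.copy()
    data["group"] = data["animal_id"].map(dict(group_of))
    if data["group"].isna().any():
        missing = sorted(data.loc[data["group"].isna(), "animal_id"].unique())
        raise ValueError(f"animals without a group assignment: {missing}")
    return mixed_anova(data, dv=dv)


class TTestResult(NamedTuple):
    t: float
    df: int
    p: float


def ihc_group_ttest(
    exposed_values: Sequence[float], unexposed_values: Sequence[float]
) -> TTestResult:
    """Uncorrected equal-variance two-sample t-test (two-sided).

    Used for exposed-vs-unexposed immunoreactivity percent-area
    comparisons; no multiple-testing correction is applied, by design.
    When both groups have zero variance and equal means, t = 0 and p = 1.
    """
    x = np.asarray(exposed_values, dtype=float)
    y = np.asarray(unexposed_values, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    dof = int(x.size + y.size - 2)
    if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
        if x.mean() == y.mean():
            return TTestResult(0.0, dof, 1.0)
        t = math.inf if x.mean() > y.mean() else -math.inf
        return TTestResult(t, dof, 0.0)
    t, p = stats.ttest_ind(x, y, equal_var=True)
    return TTestResult(float(t), dof, float(p))
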