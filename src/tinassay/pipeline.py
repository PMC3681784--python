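"""End-to-end pipeline: simulate -> score -> QC -> inference -> report.

All randomness flows from the configured seed; a manifest records the
seed, a config hash, and the package version, so re-running a config
reproduces every output byte-for-byte.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import __version__
from .behavior import simulate_cohort
from .ihc import quantify_cohort, synth_ihc_cohort
from .inference import (
    animal_level_means,
    classify_subgroups,
    discrimination_function,
    group_compare,
    ihc_group_ttest,
    mean_probe_R,
    score_cohort,
)
from .io import RunConfig, config_hash

__all__ = ["run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _plot_discrimination(pooled_by_group: dict[str, pd.DataFrame], path: Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    for label, pooled in pooled_by_group.items():
        x = pooled["level_db"].to_numpy(dtype=float)
        off = np.isnan(x)
        x_plot = np.where(off, (np.nanmin(x) if (~off).any() else 30.0) - 10.0, x)
        ax.errorbar(x_plot, pooled["mean_R"], yerr=pooled["sem_R"], marker="o", label=label)
    ax.set_xlabel("presentation level (dB SPL; leftmost point = speaker off)")
    ax.set_ylabel("suppression ratio R")
    ax.set_ylim(0, 1)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Run the configured pipeline and write the report bundle to outdir.

    Writes qc.csv, probes.csv, discrimination.csv, anova.csv (when
    inference runs), optionally classification.csv and ihc.csv, plus
    summary.json, manifest.json and discrimination.png.  Returns the
    summary dict.  When no session passes QC the psychophysical inference
    is aborted with an explicit message in the summary (the bundle is
    still written).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"n_exposed": config.n_exposed, "n_unexposed": config.n_unexposed}

    try:
        cohort = simulate_cohort(
            n_exposed=config.n_exposed,
            n_unexposed=config.n_unexposed,
            tau_distribution=config.tau_distribution,
            n_sessions=config.n_sessions,
            seed=config.seed,
            protocol=config.protocol(),
            lambda_bg_median=config.lambda_bg_median,
            lambda_bg_sigma=config.lambda_bg_sigma,
            c_off=config.c_off,
        )
    except Exception as exc:
        raise PipelineError(f"simulate: {exc}") from exc

    try:
        probe_df, qc_df = score_cohort(
            cohort,
            min_presses=config.qc_min_presses,
            min_background_r=config.qc_min_background_r,
        )
    except Exception as exc:
        raise PipelineError(f"score: {exc}") from exc
    qc_df.to_csv(outdir / "qc.csv", index=False)
    probe_df.to_csv(outdir / "probes.csv", index=False)
    n_pass = int(qc_df["passed"].sum()) if len(qc_df) else 0
    summary["qc"] = {
        "n_sessions": int(len(qc_df)),
        "n_analyzable": n_pass,
        "n_excluded": int(len(qc_df)) - n_pass,
    }

    if n_pass == 0 or probe_df.empty:
        summary["psychophysics"] = {
            "aborted": "no sessions passed QC; psychophysical inference not run"
        }
    else:
        try:
            group_label = {
                a.state.animal_id: ("exposed" if a.state.exposed else "unexposed")
                for a in cohort
            }
            per_animal, _ = discrimination_function(probe_df, config.probe_kind)
            pooled_by_group: dict[str, pd.DataFrame] = {}
            disc_rows = []
            for label in sorted(set(group_label.values())):
                members = [aid for aid, g in group_label.items() if g == label]
                sub = probe_df[probe_df["animal_id"].isin(members)]
                if sub.empty or not (sub["stim_kind"] == config.probe_kind).any():
                    continue
                _, pooled = discrimination_function(sub, config.probe_kind)
                pooled.insert(0, "group", label)
                pooled_by_group[label] = pooled
                disc_rows.append(pooled)
            disc_df = pd.concat(disc_rows, ignore_index=True)
            disc_df.to_csv(outdir / "discrimination.csv", index=False)
            _plot_discrimination(pooled_by_group, outdir / "discrimination.png")

            psycho: dict = {
                "group_means": {
                    label: pooled.set_index(pooled["level_db"].astype(str))["mean_R"].to_dict()
                    for label, pooled in pooled_by_group.items()
                }
            }
            if len(pooled_by_group) >= 2:
                lm = animal_level_means(probe_df, config.probe_kind)
                anova = group_compare(lm, group_label)
                anova.to_csv(outdir / "anova.csv", index=False)
                eff = anova.set_index("effect")
                psycho["anova"] = {
                    "group": {
                        "F": float(eff.loc["group", "F"]),
                        "df": [int(eff.loc["group", "df"]), int(eff.loc["group", "df_error"])],
                        "p": float(eff.loc["group", "p"]),
                    },
                    "group_x_level": {
                        "F": float(eff.loc["group:level", "F"]),
                        "df": [
                            int(eff.loc["group:level", "df"]),
                            int(eff.loc["group:level", "df_error"]),
                        ],
                        "p": float(eff.loc["group:level", "p"]),
                    },
                    "sphericity_correction": "none",
                }
            else:
                psycho["anova"] = {"aborted": "fewer than 2 groups with probe data"}

            if config.classify:
                exposed_means = mean_probe_R(
                    probe_df[probe_df["exposed"]], config.probe_kind, config.probe_freq_khz
                )
                assignments = classify_subgroups(exposed_means, seed=config.seed)
                assignments.to_csv(outdir / "classification.csv", index=False)
                psycho["classification"] = assignments["group"].value_counts().to_dict()
            summary["psychophysics"] = psycho
        except (ValueError, KeyError) as exc:
            raise PipelineError(f"inference: {exc}") from exc

    if config.ihc:
        try:
            micros, truth = synth_ihc_cohort(
                n_exposed=config.n_exposed,
                n_unexposed=config.n_unexposed,
                base_blobs=config.ihc_base_blobs,
                effect=config.ihc_effect,
                animal_sigma=config.ihc_animal_sigma,
                seed=config.seed + 1,
            )
            per_micro, per_animal_ihc = quantify_cohort(
                micros,
                method=config.threshold_method,
                min_size_px=config.min_particle_size_px,
            )
            per_micro.to_csv(outdir / "ihc.csv", index=False)
            exposed_vals = per_animal_ihc[
                per_animal_ihc["animal_id"].str.startswith("E")
            ]["percent_area"]
            unexposed_vals = per_animal_ihc[
                per_animal_ihc["animal_id"].str.startswith("U")
            ]["percent_area"]
            tt = ihc_group_ttest(exposed_vals, unexposed_vals)
            summary["ihc"] = {
                "mean_percent_area": {
                    "exposed": float(exposed_vals.mean()),
                    "unexposed": float(unexposed_vals.mean()),
                },
                "t_test": {"t": tt.t, "df": tt.df, "p": tt.p, "correction": "none"},
            }
        except Exception as exc:
            raise PipelineError(f"quantify-ihc: {exc}") from exc

    manifest = {
        "seed": config.seed,
        "config_hash": config_hash(config),
        "config": asdict(config),
        "version": __version__,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1, default=str))
    return summary
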