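"""End-to-end study runner: simulate -> preprocess -> variability -> stats.

``run_study`` chains every stage for a whole synthetic cohort (or previously
simulated inputs) and produces

* a study table (one row per participant x task: group, mean SampEn,
  CV(SampEn), mean RT, accuracy, sleepiness pre/post);
* an ANOVA report shaped like a group-comparison results table (per metric
  and task: group means ± SD, F with df, p, partial η², post-hoc power,
  Tukey pairwise differences);
* a regression report (spatial variability vs reaction time and accuracy in
  the working-memory arm);
* a manifest with the resolved configuration hash for reproducibility.

Identical (config, seed) always yields byte-identical tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as nio
from .behavior import score_participant, sss_change
from .entropy import EntropyParams, channel_entropy_map, variability_summary
from .preprocess import PreprocessConfig, preprocess_recording, default_layout
from .protocols import make_protocol
from .stats import anova_oneway, tukey_hsd, linear_regression, wilcoxon_signed_rank
from .synthetic import GROUPS, SyntheticConfig, simulate_participant

__all__ = ["RunConfig", "StudyResult", "run_study", "validate_inputs", "study_stats"]

METRICS = ["mean_sampen", "cv_sampen", "mean_rt", "accuracy"]


@dataclass
class RunConfig:
    synthetic: SyntheticConfig
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    entropy: EntropyParams = field(default_factory=EntropyParams)
    tasks: tuple[str, ...] = ("flanker", "nback")
    optical_loop: bool = True  # forward-model to intensity and back
    groups: tuple[str, ...] = GROUPS

    @property
    def seed(self) -> int:
        return self.synthetic.seed


@dataclass
class StudyResult:
    study_table: pd.DataFrame
    anova_table: pd.DataFrame
    regression_table: pd.DataFrame
    sss_table: pd.DataFrame
    manifest: dict


def _process_one(config: RunConfig, group: str, pid: str, task: str) -> dict:
    sim = simulate_participant(config.synthetic, group, pid, task)
    try:
        if config.optical_loop:
            haemo = preprocess_recording(
                sim["intensity"],
                sim["layout"],
                sim["events"],
                sim["protocol"],
                config.synthetic.fs,
                pid,
                task,
                config.preprocess,
            )
        else:
            haemo = sim["haemo"]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            vs = variability_summary(channel_entropy_map(haemo, config.entropy))
        beh = score_participant(sim["trials"])
    except Exception as e:  # annotate failures with stage context
        raise RuntimeError(f"stage failure for participant {pid}, task {task}: {e}") from e
    return {
        "participant_id": pid,
        "group": group,
        "task": task,
        "mean_sampen": vs.mean_sampen,
        "cv_sampen": vs.cv_sampen,
        "n_channels_used": vs.n_channels_used,
        "mean_rt": beh.mean_rt,
        "accuracy": beh.accuracy,
        "n_fast_excluded": beh.n_fast_excluded,
        "n_slow_excluded": beh.n_slow_excluded,
        "sss_pre": sim["sss_pre"],
        "sss_post": sim["sss_post"],
    }


def run_study(config: RunConfig) -> StudyResult:
    """Execute every stage for the configured cohort."""
    rows = []
    for task in config.tasks:
        for group in config.groups:
            for i in range(config.synthetic.n_per_group):
                pid = f"{group.lower()}-{i + 1:02d}"
                rows.append(_process_one(config, group, pid, task))
    table = pd.DataFrame(rows)
    table["config_hash"] = nio.config_hash(config)
    anova_df, reg_df, sss_df = study_stats(table)
    manifest = {
        "config_hash": nio.config_hash(config),
        "seed": config.seed,
        "n_rows": len(table),
        "tasks": list(config.tasks),
        "groups": list(config.groups),
    }
    return StudyResult(
        study_table=table,
        anova_table=anova_df,
        regression_table=reg_df,
        sss_table=sss_df,
        manifest=manifest,
    )


def study_stats(
    table: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Group statistics from a study table (can be re-run on saved CSVs)."""
    anova_rows = []
    for task, sub in table.groupby("task", sort=False):
        for metric in METRICS:
            if metric not in sub:
                continue
            by_group = {g: s[metric].to_numpy() for g, s in sub.groupby("group", sort=False)}
            try:
                a = anova_oneway(by_group)
                t = tukey_hsd(by_group)
            except ValueError:
                continue
            row = {
                "parameter": metric,
                "task": task,
                "F": a.F,
                "df_between": a.df_between,
                "df_within": a.df_within,
                "p": a.p,
                "partial_eta2": a.partial_eta2,
                "power": a.power,
            }
            for g in by_group:
                row[f"mean_{g}"] = a.group_means[g]
                row[f"sd_{g}"] = a.group_sds[g]
            for (ga, gb), diff, padj in zip(t.pairs, t.mean_diffs, t.p_adjusted):
                row[f"diff_{ga}-{gb}"] = diff
                row[f"tukey_p_{ga}-{gb}"] = padj
            anova_rows.append(row)

    reg_rows = []
    nback = table[table["task"] == "nback"]
    if len(nback) >= 4:
        for response in ("mean_rt", "accuracy"):
            try:
                r = linear_regression(nback[response], nback["cv_sampen"])
            except ValueError:
                continue
            reg_rows.append(
                {
                    "response": response,
                    "predictor": "cv_sampen",
                    "task": "nback",
                    "intercept": r.intercept,
                    "intercept_se": r.intercept_se,
                    "slope": r.slopes[0],
                    "slope_se": r.slope_ses[0],
                    "adjusted_r2": r.adjusted_r2,
                    "F": r.F,
                    "df_model": r.df_model,
                    "df_resid": r.df_resid,
                    "p": r.p,
                }
            )

    sss_rows = []
    if {"sss_pre", "sss_post"} <= set(table.columns):
        summary = sss_change(table)
        for _, row in summary.iterrows():
            sub = table[(table["group"] == row["group"]) & (table["task"] == row["task"])]
            entry = dict(row)
            try:
                w = wilcoxon_signed_rank(sub["sss_pre"], sub["sss_post"])
                entry.update(
                    {"wilcoxon_w": w.statistic, "wilcoxon_p": w.p, "method": w.method}
                )
            except ValueError:
                entry.update({"wilcoxon_w": np.nan, "wilcoxon_p": np.nan, "method": "n/a"})
            sss_rows.append(entry)

    return pd.DataFrame(anova_rows), pd.DataFrame(reg_rows), pd.DataFrame(sss_rows)


def validate_inputs(
    haemo=None,
    table: pd.DataFrame | None = None,
    expect_long: int = 17,
    expect_short: int = 8,
) -> list[str]:
    """Validation report (list of failure messages; empty = pristine)."""
    failures: list[str] = []
    if haemo is not None:
        n_long = sum(1 for r in haemo.roles if r == "long")
        n_short = sum(1 for r in haemo.roles if r == "short")
        if n_long != expect_long:
            failures.append(f"layout: {n_long} long channels, expected {expect_long}")
        if n_short != expect_short:
            failures.append(f"layout: {n_short} short channels, expected {expect_short}")
        try:
            protocol = make_protocol(haemo.task)
            last_end = max(
                (e.onset_s for e in haemo.events if e.kind == "block_end"), default=None
            )
            if last_end is None:
                failures.append("events: no block_end markers")
            else:
                duration = haemo.n_samples / haemo.fs
                if last_end > duration:
                    failures.append(
                        f"events: final block ends at {last_end:.1f}s beyond "
                        f"recording of {duration:.1f}s (window coverage)"
                    )
                n_starts = sum(1 for e in haemo.events if e.kind == "block_start")
                if n_starts != protocol.n_blocks:
                    failures.append(
                        f"events: {n_starts} blocks marked, protocol has "
                        f"{protocol.n_blocks} (window coverage)"
                    )
        except ValueError:
            failures.append(f"unknown task {haemo.task!r}")
        if not np.isfinite(haemo.hbo).all():
            failures.append("data: non-finite ΔHbO samples")
    if table is not None:
        dup = table.duplicated(subset=["participant_id", "task"]).sum()
        if dup:
            failures.append(f"study table: {dup} duplicate participant x task rows")
        if {"sss_pre", "sss_post"} <= set(table.columns):
            missing = table[["sss_pre", "sss_post"]].isna().any(axis=1).sum()
            if missing:
                failures.append(f"study table: {missing} unpaired sleepiness records")
        bad_groups = set(table.get("group", pd.Series(dtype=str))) - set(GROUPS)
        if bad_groups:
            failures.append(f"study table: unknown groups {sorted(bad_groups)}")
    return failures
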