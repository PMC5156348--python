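"""High-level analysis pipeline assembling the published-table machinery.

Each function takes a corpus of recordings and returns tidy DataFrames
shaped like the study's report tables: within-day repeatability at 1h and
3h windows with their paired comparison, window-vs-daily prediction grids,
within-stage repeatability from the mid-day 3h samples, diurnal polynomial
fits, and division-of-labour models.
"""

from __future__ import annotations

import math
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import models, prediction, repeatability as rpt, windows as win
from .ethogram import DURATION_METRICS, NestRecording

#: metrics analysed per stage; post-hatching attendance is dropped because
#: it tracks brooding almost perfectly, and feeding share is added
INCUBATION_METRICS = DURATION_METRICS
PROVISIONING_METRICS = ("male_care", "female_care", "joint_care", "total_care",
                        "prop_male_feedings")


def metrics_for_stage(stage: str) -> Tuple[str, ...]:
    return INCUBATION_METRICS if stage == "incubation" else PROVISIONING_METRICS


def full_day_recs(recs: Sequence[NestRecording], stage: str, day: int,
                  min_hours: float = 12.0) -> List[NestRecording]:
    return [r for r in recs
            if r.stage == stage and r.stage_day == day
            and (r.record_end - r.record_start) >= min_hours * 3600.0 - 1e-9]


def day_repeatability(recs: Sequence[NestRecording], stage: str, day: int, *,
                      widths: Sequence[float] = (1.0, 3.0),
                      alpha: float = 0.05) -> pd.DataFrame:
    """Within-day repeatability table for one full-day recording day."""
    day_recs = full_day_recs(recs, stage, day)
    frames = []
    for width in widths:
        mats = [win.effort_matrix(day_recs, m, width)
                for m in metrics_for_stage(stage)]
        tab = rpt.repeatability_table(mats, alpha=alpha)
        frames.append(tab)
    out = pd.concat(frames, ignore_index=True)
    out.insert(0, "stage", stage)
    out.insert(1, "stage_day", day)
    return out


def paired_width_comparison(table: pd.DataFrame, *, round_dp: Optional[int] = 2,
                            alpha: float = 0.05) -> pd.DataFrame:
    """1h-vs-3h paired t test over a day's repeatability table.

    Only metrics significantly repeatable at *both* widths enter the
    comparison (mirroring the gating used in the published summaries).
    Estimates are rounded to ``round_dp`` decimals first, since published
    summary statistics derive from 2-dp table values.
    """
    rows = []
    for (stage, day), g in table.groupby(["stage", "stage_day"]):
        wide = g.pivot(index="metric", columns="window_width",
                       values=["r", "significant"])
        ok = wide["significant"].all(axis=1)
        r1 = wide.loc[ok, ("r", 1.0)].astype(float)
        r3 = wide.loc[ok, ("r", 3.0)].astype(float)
        if round_dp is not None:
            r1, r3 = r1.round(round_dp), r3.round(round_dp)
        if len(r1) < 2 or (r1 - r3).std(ddof=1) == 0:
            continue
        t, df, p = rpt.paired_t(r1.to_numpy(), r3.to_numpy())
        rows.append({"stage": stage, "stage_day": day, "n_metrics": len(r1),
                     "mean_r_1h": r1.mean(), "mean_r_3h": r3.mean(),
                     "t": t, "df": df, "p": p})
    return pd.DataFrame(rows)


def day_prediction(recs: Sequence[NestRecording], stage: str, day: int = 3, *,
                   B: int = 10_000, seed: Optional[int] = None,
                   alpha: float = 0.05) -> pd.DataFrame:
    """Window-vs-daily prediction grid for one full-day recording day."""
    day_recs = full_day_recs(recs, stage, day)
    tab = prediction.prediction_table(day_recs, metrics_for_stage(stage),
                                      (1.0, 3.0), B=B, seed=seed, alpha=alpha)
    tab.insert(0, "stage", stage)
    tab.insert(1, "stage_day", day)
    return tab


def stage_repeatability(recs: Sequence[NestRecording], stage: str, *,
                        alpha: float = 0.05) -> pd.DataFrame:
    """Across-days repeatability from the mid-day 3h samples of one stage."""
    stage_recs = [r for r in recs if r.stage == stage]
    mats = [win.stage_effort_matrix(stage_recs, m)
            for m in metrics_for_stage(stage)]
    tab = rpt.repeatability_table(mats, alpha=alpha)
    tab.insert(0, "stage", stage)
    return tab


def diurnal_report(recs: Sequence[NestRecording], stage: str, day: int, *,
                   max_degree: int = 6) -> pd.DataFrame:
    """AIC-selected diurnal polynomial fits on 1h windows of one day."""
    day_recs = full_day_recs(recs, stage, day)
    rows = []
    for metric in metrics_for_stage(stage):
        mat = win.effort_matrix(day_recs, metric, 1.0)
        fit = models.fit_diurnal(mat, max_degree=max_degree)
        rows.append({"stage": stage, "stage_day": day, "metric": metric,
                     "selected_degree": fit.selected_degree, "chi2": fit.chi2,
                     "df": fit.df, "p": fit.p,
                     "used_fallback": fit.used_fallback})
    return pd.DataFrame(rows)


def division_report(recs: Sequence[NestRecording], stage: str,
                    behaviours: Sequence[str] = ("care",)) -> pd.DataFrame:
    """Sex x stage LRT table per behaviour for one stage."""
    frames = []
    for behaviour in behaviours:
        data = models.division_long_data(recs, stage, behaviour)
        fit = models.fit_division(data, metric=f"{stage}:{behaviour}")
        tab = fit.terms.copy()
        tab.insert(0, "stage", stage)
        tab.insert(1, "behaviour", behaviour)
        tab["random_structure"] = fit.random_structure
        frames.append(tab)
    return pd.concat(frames, ignore_index=True)


def full_report(recs: Sequence[NestRecording], *, B: int = 10_000,
                seed: Optional[int] = None,
                alpha: float = 0.05) -> Dict[str, pd.DataFrame]:
    """Run the whole analysis chain on a corpus.

    Returns a dict of named tables; keys are stable and used as CSV file
    stems by the CLI ``report`` command.
    """
    days = sorted({(r.stage, r.stage_day) for r in recs
                   if (r.record_end - r.record_start) >= 12 * 3600.0 - 1e-9})
    rep_frames = [day_repeatability(recs, s, d, alpha=alpha) for s, d in days]
    rep = pd.concat(rep_frames, ignore_index=True) if rep_frames else pd.DataFrame()
    out: Dict[str, pd.DataFrame] = {"within_day_repeatability": rep}
    if not rep.empty:
        out["paired_width_comparison"] = paired_width_comparison(rep, alpha=alpha)
    pred_frames = [day_prediction(recs, s, d, B=B, seed=seed, alpha=alpha)
                   for s, d in days if d == 3]
    if pred_frames:
        out["window_prediction"] = pd.concat(pred_frames, ignore_index=True)
    stage_frames = []
    diurnal_frames = []
    division_frames = []
    for stage in sorted({r.stage for r in recs}):
        n_days = len({r.stage_day for r in recs if r.stage == stage})
        if n_days >= 2:
            stage_frames.append(stage_repeatability(recs, stage, alpha=alpha))
        for s, d in days:
            if s == stage:
                diurnal_frames.append(diurnal_report(recs, stage, d))
        try:
            behaviours = ("care", "attendance") if stage == "incubation" else ("care",)
            division_frames.append(division_report(recs, stage, behaviours))
        except models.ModelDataError:
            pass
    if stage_frames:
        out["within_stage_repeatability"] = pd.concat(stage_frames,
                                                      ignore_index=True)
    if diurnal_frames:
        out["diurnal_fits"] = pd.concat(diurnal_frames, ignore_index=True)
    if division_frames:
        out["division_of_labour"] = pd.concat(division_frames, ignore_index=True)
    return out
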