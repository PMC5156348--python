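"""Mixed-model analyses: diurnal trends and division of labour.

Diurnal trend: effort per 1h window modelled on an orthogonalized
polynomial of window index with a random intercept per nest; the degree is
chosen by AIC over 1..6 and tested against the intercept-only null by a
likelihood-ratio test.  Division of labour: effort per recording modelled
on sex, stage and their interaction with nest (and parent within nest)
random terms, each fixed term tested by LRT between nested ML fits.

All fits use maximum likelihood (not REML) because compared models differ
in their fixed effects.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .ethogram import MIDDAY_3H, PARENTS, NestRecording
from .windows import EffortMatrix, window_effort


class ModelDataError(ValueError):
    pass


@dataclass
class DiurnalFit:
    metric: str
    selected_degree: int
    chi2: float
    df: int
    p: float
    aic_by_degree: Dict[int, float]
    loglik_by_degree: Dict[int, float]
    used_fallback: bool = False


@dataclass
class DivisionFit:
    metric: str
    terms: pd.DataFrame  # columns: term, chi2, df, p
    loglik_full: float
    random_structure: str


def orthogonal_poly(x: Sequence[float], degree: int) -> np.ndarray:
    """Orthonormal polynomial basis (columns 1..degree), as R's poly().

    Built by QR-decomposing the centered Vandermonde matrix; column j spans
    the same space as x^j orthogonal to lower powers.
    """
    x = np.asarray(x, dtype=float)
    xc = x - x.mean()
    V = np.vander(xc, degree + 1, increasing=True)
    Q, R = np.linalg.qr(V)
    Q = Q * np.sign(np.diag(R))
    norms = np.sqrt((Q ** 2).sum(axis=0))
    return (Q / norms)[:, 1:]


def _mixed_loglik(y: np.ndarray, X: np.ndarray, groups: np.ndarray
                  ) -> Tuple[float, bool]:
    """ML log-likelihood of a random-intercept LMM; falls back to OLS.

    Returns (loglik, used_fallback).  Fallback triggers on convergence or
    linear-algebra failures, or a singular (zero) random-effect variance
    where the mixed likelihood equals the fixed-effects one anyway.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.MixedLM(y, X, groups=groups).fit(reml=False, method="lbfgs")
            if np.isfinite(res.llf):
                return float(res.llf), False
        except (np.linalg.LinAlgError, ValueError):
            pass
    ols = sm.OLS(y, X).fit()
    return float(ols.llf), True


def fit_diurnal(mat: EffortMatrix, *, max_degree: int = 6) -> DiurnalFit:
    """AIC-selected polynomial diurnal trend with nest random intercepts.

    Expects a per-window effort matrix of a full-day corpus (>= 3 windows).
    Degree 0 (intercept-only) is fitted as the LRT null; the selection runs
    over degrees 1..max_degree; AIC ties break toward the lower degree.
    """
    values = mat.values
    n_windows = values.shape[1]
    if n_windows < 3:
        raise ModelDataError("need at least 3 windows for a diurnal fit")
    long = values.stack(future_stack=True).rename("value").reset_index()
    long.columns = ["row", "window", "value"]
    long = long.dropna(subset=["value"])
    nest_of = {key: (key[0] if isinstance(key, tuple) else key)
               for key in values.index}
    groups = long["row"].map(nest_of).to_numpy()
    y = long["value"].to_numpy(dtype=float)
    period = long["window"].rank(method="dense").to_numpy(dtype=float)

    basis = orthogonal_poly(period, max_degree)
    aic: Dict[int, float] = {}
    llf: Dict[int, float] = {}
    fallback = False
    for d in range(0, max_degree + 1):
        cols = [np.ones_like(y)]
        if d:
            cols.append(basis[:, :d])
        X = np.column_stack(cols)
        ll, fb = _mixed_loglik(y, X, groups)
        fallback = fallback or fb
        llf[d] = ll
        # params: d+1 fixed, residual var, RE var
        aic[d] = -2.0 * ll + 2.0 * (d + 1 + 2)
    candidates = {d: a for d, a in aic.items() if d >= 1}
    best = min(sorted(candidates), key=lambda d: (round(candidates[d], 10), d))
    chi2 = max(0.0, 2.0 * (llf[best] - llf[0]))
    p = float(stats.chi2.sf(chi2, best))
    return DiurnalFit(metric=mat.metric, selected_degree=best, chi2=chi2,
                      df=best, p=p, aic_by_degree=aic, loglik_by_degree=llf,
                      used_fallback=fallback)


def division_long_data(recs: Sequence[NestRecording], stage: str,
                       behaviour: str = "care",
                       window=MIDDAY_3H) -> pd.DataFrame:
    """Long-format per-parent efforts for the division-of-labour model.

    Takes every recording of ``stage`` that covers the mid-day window and
    extracts each parent's effort in it; rows carry sex, stage_day, nest
    and parent identity for the nested random terms.
    """
    rows = []
    for rec in recs:
        if rec.stage != stage:
            continue
        if rec.record_start > window[0] or rec.record_end < window[1]:
            continue
        for sex in PARENTS:
            rows.append({
                "value": window_effort(rec, f"{sex}_{behaviour}", window),
                "sex": sex, "stage_day": rec.stage_day,
                "nest_id": rec.nest_id, "parent_id": f"{rec.nest_id}-{sex}",
            })
    if not rows:
        raise ModelDataError(f"no {stage} recordings cover the mid-day window")
    return pd.DataFrame(rows)


def _division_loglik(df: pd.DataFrame, formula: str, vc: Optional[dict],
                     re_formula: str = "1") -> Tuple[float, int]:
    import statsmodels.formula.api as smf

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, df, groups=df["nest_id"],
                            re_formula=re_formula, vc_formula=vc)
        res = model.fit(reml=False, method="lbfgs")
        return float(res.llf), int(model.k_fe)


def fit_division(data: pd.DataFrame, *, metric: str = "") -> DivisionFit:
    """Sex x stage division-of-labour LMM with LRTs per fixed term.

    ``data`` is long-format with columns value, sex, stage_day, nest_id,
    parent_id (one row per parent per recording).  Random structure: nest
    intercept plus parent nested in nest.  Terms tested: interaction (df 2),
    and sex (df 1) / stage (df 2) from the additive model.
    """
    required = {"value", "sex", "stage_day", "nest_id", "parent_id"}
    missing = required - set(data.columns)
    if missing:
        raise ModelDataError(f"missing columns: {sorted(missing)}")
    df = data.dropna(subset=["value"]).copy()
    bad = [nest for nest, g in df.groupby("nest_id")
           if set(g["sex"]) != {"male", "female"}]
    if bad:
        raise ModelDataError(f"nests missing one sex: {bad}")
    df["stage_day"] = df["stage_day"].astype("category")

    vc = {"parent": "0 + C(parent_id)"}
    random_structure = "nest intercept + parent nested in nest"

    def ll(formula: str) -> Tuple[float, int]:
        try:
            return _division_loglik(df, formula, vc)
        except (np.linalg.LinAlgError, ValueError):
            # singular nested term: drop to nest intercept only
            nonlocal random_structure
            random_structure = "nest intercept (nested term singular)"
            return _division_loglik(df, formula, None)

    ll_full, _ = ll("value ~ C(sex) * C(stage_day)")
    ll_add, _ = ll("value ~ C(sex) + C(stage_day)")
    ll_nosex, _ = ll("value ~ C(stage_day)")
    ll_nostage, _ = ll("value ~ C(sex)")

    n_stage = df["stage_day"].nunique()
    rows = []
    for term, ll_red, dof in [
        ("sex:stage", ll_add, (n_stage - 1) * 1),
        ("sex", ll_nosex, 1),
        ("stage", ll_nostage, n_stage - 1),
    ]:
        base = ll_full if term == "sex:stage" else ll_add
        chi2 = max(0.0, 2.0 * (base - ll_red))
        rows.append({"term": term, "chi2": chi2, "df": dof,
                     "p": float(stats.chi2.sf(chi2, dof))})
    return DivisionFit(metric=metric, terms=pd.DataFrame(rows),
                       loglik_full=ll_full, random_structure=random_structure)
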