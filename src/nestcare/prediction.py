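"""Window-vs-daily prediction accuracy: OLS R² with bootstrap CIs.

For each sampling window, per-nest effort in that window is regressed on
the nest's overall daily effort; the proportion of variance explained
quantifies how well a single short sample stands in for a full-day
recording.  Confidence intervals come from nonparametric case resampling
of nests.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from . import windows as win
from .ethogram import NestRecording


class ZeroVarianceError(ValueError):
    pass


@dataclass(frozen=True)
class OLSResult:
    r2: float
    slope: float
    p: float
    n: int
    flag: str = ""


@dataclass(frozen=True)
class PredictionResult:
    metric: str
    window_start: float
    width_hours: float
    r2: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    significant: bool


def ols_r2(x: Sequence[float], y: Sequence[float]) -> OLSResult:
    """Simple least-squares regression of y on x; R² = 1 - SS_res/SS_tot."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise ZeroVarianceError(f"need >= 3 complete pairs, got {n}")
    if np.ptp(x) == 0:
        raise ZeroVarianceError("predictor has zero variance")
    if np.ptp(y) == 0:
        return OLSResult(r2=0.0, slope=0.0, p=math.nan, n=n, flag="zero_y_variance")
    res = stats.linregress(x, y)
    return OLSResult(r2=float(res.rvalue ** 2), slope=float(res.slope),
                     p=float(res.pvalue), n=n)


def bootstrap_r2_ci(x: Sequence[float], y: Sequence[float], *,
                    B: int = 10_000, seed: Optional[int] = None,
                    level: float = 0.95,
                    method: str = "percentile") -> Tuple[float, float]:
    """Nonparametric bootstrap CI for R² by resampling cases (nests).

    Resamples with replacement ``B`` times; a resample with zero predictor
    variance is discarded and redrawn (a warning is emitted if redraws
    exceed 1% of ``B``).  Deterministic given ``seed``.  ``method`` is
    ``"percentile"`` (default) or ``"bca"``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise ZeroVarianceError(f"need >= 3 complete pairs, got {n}")
    rng = np.random.default_rng(seed)

    def r2_of(xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
        # vectorized over resamples (rows)
        xm = xs.mean(axis=1, keepdims=True)
        ym = ys.mean(axis=1, keepdims=True)
        sxx = ((xs - xm) ** 2).sum(axis=1)
        syy = ((ys - ym) ** 2).sum(axis=1)
        sxy = ((xs - xm) * (ys - ym)).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(syy == 0, 0.0, sxy ** 2 / np.where(sxx * syy == 0,
                                                               np.nan, sxx * syy))

    stats_out = np.empty(B)
    filled = 0
    redraws = 0
    while filled < B:
        m = B - filled
        idx = rng.integers(0, n, size=(m, n))
        xs, ys = x[idx], y[idx]
        valid = np.ptp(xs, axis=1) > 0
        redraws += int((~valid).sum())
        good = r2_of(xs[valid], ys[valid])
        stats_out[filled:filled + good.size] = good
        filled += good.size
    if redraws > 0.01 * B:
        warnings.warn(f"{redraws} of {B + redraws} bootstrap resamples had zero "
                      "predictor variance and were redrawn")
    alpha = 1.0 - level
    if method == "percentile":
        lo, hi = np.percentile(stats_out, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    elif method == "bca":
        lo, hi = _bca_bounds(x, y, stats_out, alpha)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(lo), float(hi)


def _bca_bounds(x, y, boot, alpha):
    theta = ols_r2(x, y).r2
    n = x.size
    prop = (boot < theta).mean()
    prop = min(max(prop, 1e-9), 1 - 1e-9)
    z0 = stats.norm.ppf(prop)
    jack = []
    for i in range(n):
        m = np.ones(n, dtype=bool)
        m[i] = False
        try:
            jack.append(ols_r2(x[m], y[m]).r2)
        except ZeroVarianceError:
            continue
    jack = np.asarray(jack)
    jm = jack.mean()
    num = ((jm - jack) ** 3).sum()
    den = 6.0 * (((jm - jack) ** 2).sum()) ** 1.5
    a = 0.0 if den == 0 else num / den
    z = stats.norm.ppf([alpha / 2, 1 - alpha / 2])
    adj = stats.norm.cdf(z0 + (z0 + z) / (1 - a * (z0 + z)))
    return tuple(np.percentile(boot, 100 * adj))


def prediction_table(recs: Sequence[NestRecording], metrics: Sequence[str],
                     widths: Sequence[float] = (1.0, 3.0), *,
                     B: int = 10_000, seed: Optional[int] = None,
                     alpha: float = 0.05) -> pd.DataFrame:
    """Full grid of window-vs-daily prediction results.

    One row per (metric, window); bootstrap seeds are derived from ``seed``
    per cell so the whole table is deterministic.
    """
    recs = list(recs)
    rows: List[dict] = []
    ss = np.random.SeedSequence(seed)
    for metric in metrics:
        daily = np.array([win.daily_effort(r, metric) for r in recs])
        for width in widths:
            mat = win.effort_matrix(recs, metric, width)
            # align rows to recs order via row keys
            keys = [win._row_key(r, metric) for r in recs]
            vals = mat.values.loc[keys].to_numpy(dtype=float)
            for j, start in enumerate(mat.values.columns):
                cell_seed = ss.spawn(1)[0]
                xcol = vals[:, j]
                try:
                    ols = ols_r2(xcol, daily)
                    lo, hi = bootstrap_r2_ci(xcol, daily, B=B,
                                             seed=cell_seed)
                except ZeroVarianceError as exc:
                    rows.append({"metric": metric, "window_start": float(start),
                                 "width_h": width, "R2": math.nan,
                                 "ci_low": math.nan, "ci_high": math.nan,
                                 "p": math.nan, "n": len(recs),
                                 "significant": False, "note": str(exc)})
                    continue
                rows.append({"metric": metric, "window_start": float(start),
                             "width_h": width, "R2": ols.r2, "ci_low": lo,
                             "ci_high": hi, "p": ols.p, "n": ols.n,
                             "significant": (not math.isnan(ols.p)) and ols.p < alpha})
    return pd.DataFrame(rows)
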