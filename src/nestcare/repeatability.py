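"""One-way ANOVA intraclass repeatability (Harper's method).

Rows of an effort matrix are treated as groups (individuals or nests);
within-group observations are the sampling windows or stage days.  The
repeatability ``r`` is the share of total variance attributable to
between-group differences, obtained from the ANOVA mean squares via the
effective group size ``n0``; for balanced designs this reduces to the
familiar ``r = (F - 1) / (F + n - 1)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .windows import EffortMatrix


class DegenerateDataError(ValueError):
    pass


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding, as used in printed report tables.

    Python's built-in ``round`` is banker's rounding on binary floats
    (``round(0.365, 2) == 0.36``), which disagrees with how summary tables
    are conventionally printed.
    """
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class AnovaDecomposition:
    k: int                  # number of groups
    N: int                  # total observations
    group_sizes: Tuple[int, ...]
    MS_A: float             # among-group mean square
    MS_W: float             # within-group mean square
    F: float
    df: Tuple[int, int]
    p: float


@dataclass(frozen=True)
class RepeatabilityEstimate:
    anova: AnovaDecomposition
    n0: float
    r: float
    significant: bool
    alpha: float = 0.05


def one_way_anova(mat) -> AnovaDecomposition:
    """Standard one-way decomposition over the rows of an effort matrix.

    Missing cells are excluded; rows with fewer than two non-missing cells
    are dropped.  Accepts an :class:`EffortMatrix` or any 2D array-like.
    """
    values = mat.values.to_numpy(dtype=float) if isinstance(mat, EffortMatrix) \
        else np.asarray(mat, dtype=float)
    groups = [row[~np.isnan(row)] for row in values]
    groups = [g for g in groups if g.size >= 2]
    if len(groups) < 2:
        raise DegenerateDataError("need at least 2 groups with >=2 observations each")
    k = len(groups)
    sizes = tuple(int(g.size) for g in groups)
    N = sum(sizes)
    grand = np.concatenate(groups).mean()
    ss_a = sum(n * (g.mean() - grand) ** 2 for g, n in zip(groups, sizes))
    ss_w = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_a, df_w = k - 1, N - k
    ms_a = ss_a / df_a
    ms_w = ss_w / df_w
    if ms_w == 0.0:
        f = math.inf if ms_a > 0 else math.nan
        p = 0.0 if ms_a > 0 else math.nan
    else:
        f = ms_a / ms_w
        p = float(stats.f.sf(f, df_a, df_w))
    return AnovaDecomposition(k=k, N=N, group_sizes=sizes, MS_A=ms_a, MS_W=ms_w,
                              F=f, df=(df_a, df_w), p=p)


def effective_group_size(anova: AnovaDecomposition) -> float:
    """Harper's n0 = (N - sum(n_i^2)/N) / (k - 1)."""
    n = np.array(anova.group_sizes, dtype=float)
    return float((anova.N - (n ** 2).sum() / anova.N) / (anova.k - 1))


def harper_r(anova: AnovaDecomposition, *, alpha: float = 0.05,
             balanced_shortcut: bool = True) -> RepeatabilityEstimate:
    """Variance-component repeatability from a one-way decomposition.

    ``s2_A = (MS_A - MS_W) / n0`` and ``r = s2_A / (s2_A + MS_W)``.  For a
    balanced design this is algebraically ``(F - 1)/(F + n - 1)``; when
    ``balanced_shortcut`` is set and the design is balanced, that form is
    used directly (they agree to machine precision).  Negative r (MS_A <
    MS_W) is returned as-is, never truncated.
    """
    n0 = effective_group_size(anova)
    balanced = len(set(anova.group_sizes)) == 1
    if balanced and balanced_shortcut and math.isfinite(anova.F):
        n = anova.group_sizes[0]
        r = (anova.F - 1.0) / (anova.F + n - 1.0)
    elif math.isinf(anova.F):
        r = 1.0
    elif math.isnan(anova.F):
        r = math.nan
    else:
        s2_a = (anova.MS_A - anova.MS_W) / n0
        r = s2_a / (s2_a + anova.MS_W)
    significant = (not math.isnan(anova.p)) and anova.p < alpha
    return RepeatabilityEstimate(anova=anova, n0=n0, r=float(r),
                                 significant=significant, alpha=alpha)


def harper_r_from_f(F: float, k: int, n: int) -> float:
    """Balanced-design conversion from a printed F ratio: (F-1)/(F+n-1).

    ``k`` groups of ``n`` observations each; used to reproduce published
    repeatability columns from their F statistics.
    """
    if k < 2 or n < 2:
        raise DegenerateDataError("need k >= 2 groups and n >= 2 observations")
    return (F - 1.0) / (F + n - 1.0)


def repeatability_table(mats: Iterable[EffortMatrix], alpha: float = 0.05):
    """Per-metric repeatability report (r, F, df, p, significance).

    r is always computed; the ``significant`` flag implements the gating
    used when emulating published tables (estimates shown only when the
    ANOVA is significant at ``alpha``).
    """
    import pandas as pd

    rows = []
    for mat in mats:
        try:
            an = one_way_anova(mat)
            est = harper_r(an, alpha=alpha)
            rows.append({
                "metric": mat.metric, "window_width": mat.window_width,
                "r": est.r, "F": an.F, "df1": an.df[0], "df2": an.df[1],
                "p": an.p, "significant": est.significant,
            })
        except DegenerateDataError as exc:
            rows.append({
                "metric": mat.metric, "window_width": mat.window_width,
                "r": math.nan, "F": math.nan, "df1": 0, "df2": 0,
                "p": math.nan, "significant": False, "note": str(exc),
            })
    return pd.DataFrame(rows)


def paired_t(x: Sequence[float], y: Sequence[float]) -> Tuple[float, int, float]:
    """Classical paired t test; returns (t, df, two-sided p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise DegenerateDataError("need >= 2 pairs of equal length")
    d = x - y
    if d.std(ddof=1) == 0:
        raise DegenerateDataError("zero variance of paired differences")
    res = stats.ttest_rel(x, y)
    return float(res.statistic), int(x.size - 1), float(res.pvalue)


def one_sample_t(x: Sequence[float], mu: float) -> Tuple[float, int, float]:
    """One-sample t test against a reference mean; returns (t, df, p)."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise DegenerateDataError("need >= 2 observations")
    if x.std(ddof=1) == 0:
        raise DegenerateDataError("zero sample variance")
    res = stats.ttest_1samp(x, mu)
    return float(res.statistic), int(x.size - 1), float(res.pvalue)
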