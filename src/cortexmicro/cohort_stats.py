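"""Group comparisons and correlations for demographic/psychosexual variables.

Classical one-way ANOVA with LSD post hocs is used by default; when Levene's
test flags heterogeneity of variance the robust alternatives are reported:
the Welch and Brown–Forsythe equal-means statistics and the Games–Howell
post hoc (Welch-type standard errors, Welch–Satterthwaite df, studentized-
range reference).  Two-tailed alpha = 0.05 throughout; LSD p-values are by
definition unadjusted.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AnovaReport",
    "one_way_anova",
    "levene_test",
    "welch_anova",
    "brown_forsythe",
    "lsd_posthoc",
    "games_howell_posthoc",
    "pearson_r",
    "describe_groups",
    "anova_report",
]


def _as_groups(groups) -> list[np.ndarray]:
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least 2 groups")
    for i, g in enumerate(gs):
        if g.size < 2:
            raise ValueError(f"group {i} has n={g.size} < 2")
    return gs


def one_way_anova(groups) -> tuple[float, tuple[int, int], float]:
    """Classical one-way ANOVA: F, (df1, df2), p."""
    gs = _as_groups(groups)
    k = len(gs)
    n_total = sum(g.size for g in gs)
    df = (k - 1, n_total - k)
    sw = sum(((g - g.mean()) ** 2).sum() for g in gs)
    if sw == 0 and len({g.mean() for g in gs}) > 1:
        warnings.warn("zero within-group variance with unequal means; p = 0")
        return float("inf"), df, 0.0
    f, p = stats.f_oneway(*gs)
    return float(f), df, float(p)


def levene_test(groups, center: str = "mean") -> tuple[float, float]:
    """Levene's test of equal variances (mean-centered variant)."""
    gs = _as_groups(groups)
    if all(np.ptp(g) == 0 for g in gs):
        raise ValueError("all groups constant: Levene statistic undefined")
    w, p = stats.levene(*gs, center=center)
    return float(w), float(p)


def welch_anova(groups) -> tuple[float, int, float, float]:
    """Welch's heteroscedasticity-robust test of equal means.

    Returns (F, df1, df2, p) with variance-weighted group means and the
    Satterthwaite-type denominator df.
    """
    gs = _as_groups(groups)
    k = len(gs)
    n = np.array([g.size for g in gs], dtype=float)
    m = np.array([g.mean() for g in gs])
    v = np.array([g.var(ddof=1) for g in gs])
    w = n / v
    w_sum = w.sum()
    m_w = (w * m).sum() / w_sum
    a = (w * (m - m_w) ** 2).sum() / (k - 1)
    lam = ((1 - w / w_sum) ** 2 / (n - 1)).sum()
    f = a / (1 + 2 * (k - 2) * lam / (k**2 - 1))
    df2 = (k**2 - 1) / (3 * lam)
    p = stats.f.sf(f, k - 1, df2)
    return float(f), k - 1, float(df2), float(p)


def brown_forsythe(groups) -> tuple[float, int, float, float]:
    """Brown–Forsythe robust test of equal means: (F*, df1, df2, p).

    F* = sum n_i (m_i - m)^2 / sum (1 - n_i/N) s_i^2, with Satterthwaite
    denominator df.
    """
    gs = _as_groups(groups)
    k = len(gs)
    n = np.array([g.size for g in gs], dtype=float)
    big_n = n.sum()
    m = np.array([g.mean() for g in gs])
    v = np.array([g.var(ddof=1) for g in gs])
    grand = np.concatenate(gs).mean()
    num = (n * (m - grand) ** 2).sum()
    denom_terms = (1 - n / big_n) * v
    denom = denom_terms.sum()
    f = num / denom
    c = denom_terms / denom
    df2 = 1.0 / ((c**2 / (n - 1)).sum())
    p = stats.f.sf(f, k - 1, df2)
    return float(f), k - 1, float(df2), float(p)


def lsd_posthoc(groups, labels=None) -> pd.DataFrame:
    """Fisher's LSD pairwise comparisons using the pooled ANOVA MSE.

    Unadjusted two-sided p from t with N-k df; symmetric in pair order.
    """
    gs = _as_groups(groups)
    labels = labels or [f"g{i}" for i in range(len(gs))]
    n_total = sum(g.size for g in gs)
    df_w = n_total - len(gs)
    mse = sum(((g - g.mean()) ** 2).sum() for g in gs) / df_w
    rows = []
    for (i, gi), (j, gj) in itertools.combinations(enumerate(gs), 2):
        diff = gi.mean() - gj.mean()
        se = np.sqrt(mse * (1 / gi.size + 1 / gj.size))
        t = diff / se if se > 0 else 0.0
        rows.append(
            {"group1": labels[i], "group2": labels[j], "method": "LSD",
             "mean_diff": diff, "se": se, "t": t, "df": df_w,
             "p": float(2 * stats.t.sf(abs(t), df_w))}
        )
    return pd.DataFrame(rows)


def games_howell_posthoc(groups, labels=None) -> pd.DataFrame:
    """Games–Howell pairwise comparisons, robust to unequal variances.

    Welch-type SE and Welch–Satterthwaite df per pair; p from the
    studentized-range distribution with k groups.
    """
    gs = _as_groups(groups)
    k = len(gs)
    labels = labels or [f"g{i}" for i in range(k)]
    rows = []
    for (i, gi), (j, gj) in itertools.combinations(enumerate(gs), 2):
        vi, vj = gi.var(ddof=1), gj.var(ddof=1)
        ni, nj = gi.size, gj.size
        se2 = vi / ni + vj / nj
        se = np.sqrt(se2)
        df = se2**2 / ((vi / ni) ** 2 / (ni - 1) + (vj / nj) ** 2 / (nj - 1))
        diff = gi.mean() - gj.mean()
        q = abs(diff) / np.sqrt(se2 / 2)
        p = float(stats.studentized_range.sf(q, k, df))
        rows.append(
            {"group1": labels[i], "group2": labels[j], "method": "Games-Howell",
             "mean_diff": diff, "se": se, "df": float(df), "p": p}
        )
    return pd.DataFrame(rows)


def pearson_r(x, y) -> tuple[float, float]:
    """Product-moment correlation with its two-sided t-reference p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a zero-variance variable")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class AnovaReport:
    """Omnibus + robust tests + post hocs for one variable across groups."""

    variable: str
    f: float
    df: tuple[int, int]
    p: float
    levene_w: float
    levene_p: float
    welch: tuple[float, int, float, float]
    brown_forsythe: tuple[float, int, float, float]
    posthoc: pd.DataFrame = field(repr=False)
    posthoc_method: str = "LSD"

    def to_dict(self) -> dict:
        w_f, w_df1, w_df2, w_p = self.welch
        b_f, b_df1, b_df2, b_p = self.brown_forsythe
        return {
            "variable": self.variable,
            "F": round(self.f, 2), "df1": self.df[0], "df2": self.df[1],
            "p": round(self.p, 3),
            "levene_p": round(self.levene_p, 3),
            "welch": {"F": round(w_f, 2), "df1": w_df1, "df2": round(w_df2, 2),
                      "p": round(w_p, 3)},
            "brown_forsythe": {"F": round(b_f, 2), "df1": b_df1,
                               "df2": round(b_df2, 2), "p": round(b_p, 3)},
            "posthoc_method": self.posthoc_method,
            "posthoc": self.posthoc.round(3).to_dict(orient="records"),
        }


def anova_report(groups, labels=None, variable: str = "", alpha: float = 0.05) -> AnovaReport:
    """Full comparison for one variable: omnibus, Levene, robust tests, post hoc.

    The Games–Howell post hoc replaces LSD when Levene's test is significant
    at ``alpha``, mirroring standard practice for heteroscedastic groups.
    """
    f, df, p = one_way_anova(groups)
    w, lp = levene_test(groups)
    hetero = lp < alpha
    posthoc = (games_howell_posthoc if hetero else lsd_posthoc)(groups, labels)
    return AnovaReport(
        variable=variable, f=f, df=df, p=p, levene_w=w, levene_p=lp,
        welch=welch_anova(groups), brown_forsythe=brown_forsythe(groups),
        posthoc=posthoc, posthoc_method="Games-Howell" if hetero else "LSD",
    )


def describe_groups(df: pd.DataFrame, variable: str, group_col: str = "group",
                    group_order=None) -> pd.DataFrame:
    """Per-group M / SD / range table for one variable."""
    order = group_order or list(dict.fromkeys(df[group_col]))
    rows = []
    for g in order:
        x = df.loc[df[group_col] == g, variable].dropna().to_numpy(dtype=float)
        rows.append({"group": g, "n": x.size, "mean": x.mean(),
                     "sd": x.std(ddof=1), "min": x.min(), "max": x.max()})
    return pd.DataFrame(rows)
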