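"""Group-level inference for the cohort analysis.

One-way ANOVA (from raw data or from published mean/SD/n summaries), Tukey
post hoc comparisons, homogeneity and normality checks, a chi-square test for
categorical demographics, a Kruskal-Wallis rank variant, and an ANCOVA-style
linear model of measure ~ group + region + group x region + age + sex with
type-III (partial) sums of squares, estimated marginal means and
Bonferroni-corrected pairwise contrasts.

The model is deliberately a Gaussian-identity linear model: reported mean
squares and R^2 are only defined there, and the covariate-adjusted marginal
means match conventional statistical-package output under sum-to-zero factor
coding.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "one_way_anova",
    "anova_from_summary",
    "tukey_posthoc",
    "variance_and_normality_checks",
    "kruskal_wallis",
    "chi_square_contingency",
    "fit_glm",
    "GlmResult",
    "add_cingulate_rows",
]


def add_cingulate_rows(records: pd.DataFrame, measure: str,
                       region_col: str = "region",
                       subject_col: str = "subject_id") -> pd.DataFrame:
    """Append per-subject CINGULATE rows combining the ACC and PCC measures.

    The combined cingulate measure is the sum of a subject's ACC and PCC
    values (only subjects with both present contribute), giving the
    three-level region factor used in the whole-cohort model.
    """
    df = records.copy()
    wide = df.pivot_table(index=subject_col, columns=region_col,
                          values=measure, aggfunc="first")
    if not {"ACC", "PCC"} <= set(wide.columns):
        raise ValueError("records must contain ACC and PCC rows")
    both = wide.dropna(subset=["ACC", "PCC"])
    meta_cols = [c for c in df.columns
                 if c not in (measure, region_col) and df.groupby(subject_col)[c].nunique().max() <= 1]
    meta = df[meta_cols].drop_duplicates(subset=subject_col).set_index(subject_col)
    rows = meta.loc[both.index].reset_index()
    rows[region_col] = "CINGULATE"
    rows[measure] = (both["ACC"] + both["PCC"]).to_numpy()
    return pd.concat([df, rows[df.columns.intersection(rows.columns)]],
                     ignore_index=True)


@dataclass(frozen=True)
class GroupSummary:
    """Published per-group moments: mean, SD and sample size."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.n < 2:
            raise ValueError("n must be >= 2")


def one_way_anova(groups) -> tuple[float, int, int, float]:
    """Between/within F test. Returns (F, df_between, df_within, p)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    ns = np.array([len(g) for g in groups])
    df_b = len(groups) - 1
    df_w = int(ns.sum()) - len(groups)
    means = np.array([g.mean() for g in groups])
    grand = np.concatenate(groups).mean()
    ss_b = float((ns * (means - grand) ** 2).sum())
    ss_w = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
    if ss_w == 0:
        if ss_b == 0:
            return 0.0, df_b, df_w, 1.0
        return math.inf, df_b, df_w, 0.0
    F = (ss_b / df_b) / (ss_w / df_w)
    return F, df_b, df_w, float(sps.f.sf(F, df_b, df_w))


def anova_from_summary(summaries: list[GroupSummary]
                       ) -> tuple[float, int, int, float]:
    """One-way ANOVA recomputed from printed mean +/- SD (n) summaries.

    Identical to :func:`one_way_anova` on any raw data with those exact
    moments: SSb = sum n_i (mean_i - grand)^2, SSw = sum (n_i - 1) sd_i^2.
    Returns (F, df_between, df_within, p).
    """
    if len(summaries) < 2:
        raise ValueError("need >= 2 group summaries")
    ns = np.array([s.n for s in summaries], dtype=float)
    means = np.array([s.mean for s in summaries])
    sds = np.array([s.sd for s in summaries])
    grand = float((ns * means).sum() / ns.sum())
    ss_b = float((ns * (means - grand) ** 2).sum())
    ss_w = float(((ns - 1) * sds ** 2).sum())
    df_b = len(summaries) - 1
    df_w = int(ns.sum()) - len(summaries)
    if ss_w == 0:
        if ss_b == 0:
            return 0.0, df_b, df_w, 1.0
        return math.inf, df_b, df_w, 0.0
    F = (ss_b / df_b) / (ss_w / df_w)
    return F, df_b, df_w, float(sps.f.sf(F, df_b, df_w))


def tukey_posthoc(groups, labels: list[str] | None = None) -> pd.DataFrame:
    """Tukey-Kramer pairwise comparisons (studentized range, unequal-n safe)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    if labels is None:
        labels = [f"group{i}" for i in range(len(groups))]
    res = sps.tukey_hsd(*groups)
    rows = []
    for i, j in itertools.combinations(range(len(groups)), 2):
        rows.append({
            "group_a": labels[i], "group_b": labels[j],
            "mean_difference": float(np.mean(groups[i]) - np.mean(groups[j])),
            "p_adjusted": float(res.pvalue[i, j]),
        })
    return pd.DataFrame(rows)


def variance_and_normality_checks(groups) -> dict:
    """Levene's homogeneity test (mean-centered) plus per-group Shapiro-Wilk.

    Levene's W is computed directly from absolute deviations about the group
    means; the Shapiro-Wilk p-values delegate to an established routine.
    Constant groups are flagged as degenerate rather than tested.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    ns = np.array([len(g) for g in groups])
    if k < 2 or any(n < 3 for n in ns):
        raise ValueError("need >= 2 groups with >= 3 observations each")
    z = [np.abs(g - g.mean()) for g in groups]
    n_tot = int(ns.sum())
    zbar = np.concatenate(z).mean()
    zmeans = np.array([zi.mean() for zi in z])
    num = float((ns * (zmeans - zbar) ** 2).sum()) / (k - 1)
    den = float(sum(((zi - zi.mean()) ** 2).sum() for zi in z)) / (n_tot - k)
    degenerate = [bool(np.ptp(g) == 0) for g in groups]
    if den == 0:
        W, p = (0.0, 1.0) if num == 0 else (math.inf, 0.0)
    else:
        W = num / den
        p = float(sps.f.sf(W, k - 1, n_tot - k))
    shapiro_p = [math.nan if d else float(sps.shapiro(g).pvalue)
                 for g, d in zip(groups, degenerate)]
    return {"levene_W": W, "levene_p": p, "levene_df": (k - 1, n_tot - k),
            "shapiro_p": shapiro_p, "degenerate": degenerate}


def kruskal_wallis(groups) -> tuple[float, int, float]:
    """Rank-based one-way test (H statistic, df, p); thin scipy delegation."""
    H, p = sps.kruskal(*[np.asarray(g, dtype=float) for g in groups])
    return float(H), len(list(groups)) - 1, float(p)


def chi_square_contingency(table) -> tuple[float, int, float]:
    """Pearson chi-square on an r x c count table, no continuity correction."""
    t = np.asarray(table, dtype=float)
    if (t < 0).any():
        raise ValueError("counts must be >= 0")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero marginal in contingency table")
    chi2, p, df, _ = sps.chi2_contingency(t, correction=False)
    return float(chi2), int(df), float(p)


# ---------------------------------------------------------------------------
# ANCOVA-style linear model with type-III tests and EMM contrasts
# ---------------------------------------------------------------------------

@dataclass
class GlmResult:
    """Effect table, pairwise contrasts and fit summary of the linear model."""

    effects: pd.DataFrame       # Source, df, mean_square, F, p
    contrasts: pd.DataFrame     # factor, level_a, level_b, estimate, se, p_adj, CI
    emmeans: dict               # factor -> {level: adjusted mean}
    r_squared: float
    residual_df: int
    mse: float


def _sum_code(values: pd.Series, levels: list[str]) -> np.ndarray:
    """Sum-to-zero (deviation) coding: k levels -> k-1 columns."""
    vals = np.asarray(values)
    cols = np.zeros((len(vals), len(levels) - 1))
    for j, lev in enumerate(levels[:-1]):
        cols[vals == lev, j] = 1.0
    cols[vals == levels[-1], :] = -1.0
    return cols


def _sum_code_row(level: str, levels: list[str]) -> np.ndarray:
    row = np.zeros(len(levels) - 1)
    if level == levels[-1]:
        row[:] = -1.0
    else:
        row[levels.index(level)] = 1.0
    return row


def fit_glm(records: pd.DataFrame, response: str = "measure",
            group_col: str = "group", region_col: str = "region",
            age_col: str = "age", sex_col: str = "sex",
            include_interaction: bool = True, alpha: float = 0.05) -> GlmResult:
    """Covariate-adjusted linear model of a concentration measure.

    Fits measure ~ group + region + group x region + age + sex by ordinary
    least squares with sum-to-zero factor coding, reports a per-term effect
    table using partial (type-III-style) sums of squares, and Bonferroni-
    adjusted pairwise contrasts of estimated marginal means (factor means at
    the covariate mean, averaged over the other factor's levels) for both
    group and region.
    """
    df = records.dropna(subset=[response, group_col, region_col, age_col, sex_col])
    y = df[response].to_numpy(dtype=float)
    n = len(y)
    groups = sorted(df[group_col].unique())
    regions = sorted(df[region_col].unique())
    sexes = sorted(df[sex_col].unique())
    if len(groups) < 2 or len(regions) < 1:
        raise ValueError("need >= 2 groups")

    age = df[age_col].to_numpy(dtype=float)
    age_c = age - age.mean()

    blocks: dict[str, np.ndarray] = {"Intercept": np.ones((n, 1))}
    G = _sum_code(df[group_col], groups)
    blocks["Group"] = G
    R = None
    if len(regions) > 1:
        R = _sum_code(df[region_col], regions)
        blocks["Region"] = R
        if include_interaction:
            inter = np.stack([G[:, i] * R[:, j]
                              for i in range(G.shape[1])
                              for j in range(R.shape[1])], axis=1)
            blocks["Group x region"] = inter
    blocks["Age"] = age_c[:, None]
    if len(sexes) > 1:
        blocks["Gender"] = _sum_code(df[sex_col], sexes)

    names = list(blocks)
    X = np.hstack([blocks[k] for k in names])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design (aliased term); check cell coverage")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    df_resid = n - X.shape[1]
    mse = rss / df_resid
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 1.0

    # type-III: drop each non-intercept block in turn
    rows = []
    col_index = {}
    start = 0
    for k in names:
        col_index[k] = slice(start, start + blocks[k].shape[1])
        start += blocks[k].shape[1]
    for k in names:
        if k == "Intercept":
            continue
        keep = np.ones(X.shape[1], dtype=bool)
        keep[col_index[k]] = False
        Xr = X[:, keep]
        br, _, _, _ = np.linalg.lstsq(Xr, y, rcond=None)
        rss_r = float(((y - Xr @ br) ** 2).sum())
        df_k = blocks[k].shape[1]
        ss = rss_r - rss
        F = (ss / df_k) / mse
        rows.append({"Source": k, "df": df_k, "mean_square": ss / df_k,
                     "F": F, "p": float(sps.f.sf(F, df_k, df_resid))})
    rows.append({"Source": "Error", "df": df_resid, "mean_square": mse,
                 "F": math.nan, "p": math.nan})
    effects = pd.DataFrame(rows)

    XtX_inv = np.linalg.inv(X.T @ X)

    def design_row(group: str | None, region: str | None) -> np.ndarray:
        """EMM row: covariates at their means, other factor averaged over levels."""
        parts = {"Intercept": np.ones(1), "Age": np.zeros(1)}
        if "Gender" in blocks:
            parts["Gender"] = np.zeros(len(sexes) - 1)  # balanced over sexes
        g_levels = [group] if group else groups
        r_levels = [region] if region else regions
        g_rows = np.mean([_sum_code_row(g, groups) for g in g_levels], axis=0)
        parts["Group"] = g_rows
        if R is not None:
            r_rows = np.mean([_sum_code_row(r, regions) for r in r_levels], axis=0)
            parts["Region"] = r_rows
            if "Group x region" in blocks:
                inter = np.mean([np.outer(_sum_code_row(g, groups),
                                          _sum_code_row(r, regions)).ravel()
                                 for g in g_levels for r in r_levels], axis=0)
                parts["Group x region"] = inter
        return np.concatenate([parts[k] for k in names])

    emmeans = {"group": {g: float(design_row(g, None) @ beta) for g in groups}}
    if R is not None:
        emmeans["region"] = {r: float(design_row(None, r) @ beta) for r in regions}

    crows = []
    for factor, levels, maker in (
            ("group", groups, lambda lv: design_row(lv, None)),
            ("region", regions if R is not None else [], lambda lv: design_row(None, lv))):
        pairs = list(itertools.combinations(levels, 2))
        m = len(pairs)
        for a, b in pairs:
            L = maker(a) - maker(b)
            est = float(L @ beta)
            se = math.sqrt(mse * float(L @ XtX_inv @ L))
            tval = est / se if se > 0 else math.inf
            p_raw = 2.0 * float(sps.t.sf(abs(tval), df_resid))
            p_adj = min(1.0, m * p_raw)
            tcrit = float(sps.t.ppf(1.0 - alpha / (2.0 * m), df_resid))
            crows.append({"factor": factor, "level_a": a, "level_b": b,
                          "estimate": est, "se": se, "p_adj": p_adj,
                          "ci_low": est - tcrit * se, "ci_high": est + tcrit * se})
    contrasts = pd.DataFrame(crows)
    return GlmResult(effects=effects, contrasts=contrasts, emmeans=emmeans,
                     r_squared=r2, residual_df=df_resid, mse=mse)
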