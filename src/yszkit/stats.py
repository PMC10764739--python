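"""Field-relative stratification statistics.

Soil metrics vary far more between fields (texture and climate gradients)
than within them, so within-field zone contrasts are computed on z-scores
taken per field: z = (x - field mean) / field SD.  On that scale the module
provides the analyses a zone-stratified soil survey needs: Pearson
correlation matrices, bidirectional stepwise OLS by AIC, one-way ANOVA with
Tukey HSD intervals and eta-squared, a Brown-Forsythe (median-centred
Levene) variance check, bootstrapped post-hoc power, and per-field HS-LS
management contrasts.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

log = logging.getLogger(__name__)


def field_zscore(
    table: pd.DataFrame, columns: list[str], field_col: str = "field_id"
) -> pd.DataFrame:
    """Append per-field z-scored twins (``z_<col>``) of the given columns.

    Uses the sample SD (n-1).  Fields with zero SD in a column get missing
    z-scores and a logged warning.
    """
    out = table.copy()
    for col in columns:
        if col not in out.columns:
            raise ValueError(f"column {col!r} not in table")
        grp = out.groupby(field_col)[col]
        mean = grp.transform("mean")
        sd = grp.transform("std")  # ddof=1
        z = (out[col] - mean) / sd
        n_zero = int((sd == 0).sum())
        if n_zero:
            log.warning("column %s: %d rows in zero-SD fields -> z set missing", col, n_zero)
            z[sd == 0] = np.nan
        out[f"z_{col}"] = z
    return out


def _stars(p: float) -> str:
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


def correlation_matrix(
    table: pd.DataFrame, variables: list[str]
) -> dict[str, pd.DataFrame]:
    """Pairwise-complete Pearson correlations with r^2, p and stars.

    Returns dict of square DataFrames keyed "r", "r2", "p", "stars".
    Constant variables produce missing entries and a warning.
    """
    k = len(variables)
    r = pd.DataFrame(np.eye(k), index=variables, columns=variables)
    p = pd.DataFrame(np.zeros((k, k)), index=variables, columns=variables)
    stars = pd.DataFrame("", index=variables, columns=variables)
    for a, b in itertools.combinations(variables, 2):
        sub = table[[a, b]].dropna()
        if len(sub) < 3:
            r.loc[a, b] = r.loc[b, a] = np.nan
            p.loc[a, b] = p.loc[b, a] = np.nan
            continue
        xa, xb = sub[a].to_numpy(float), sub[b].to_numpy(float)
        if np.ptp(xa) == 0 or np.ptp(xb) == 0:
            log.warning("constant variable in pair (%s, %s); correlation undefined", a, b)
            r.loc[a, b] = r.loc[b, a] = np.nan
            p.loc[a, b] = p.loc[b, a] = np.nan
            continue
        res = sps.pearsonr(xa, xb)
        r.loc[a, b] = r.loc[b, a] = res.statistic
        p.loc[a, b] = p.loc[b, a] = res.pvalue
        stars.loc[a, b] = stars.loc[b, a] = _stars(res.pvalue)
    return {"r": r, "r2": r**2, "p": p, "stars": stars}


@dataclass
class StepwiseResult:
    model: object                     # fitted statsmodels OLS results
    selected: list[str]
    aic_trace: list[tuple[str, float]]

    @property
    def params(self) -> pd.Series:
        return self.model.params

    @property
    def adj_r2(self) -> float:
        return float(self.model.rsquared_adj)

    @property
    def f_pvalue(self) -> float:
        return float(self.model.f_pvalue)


def _fit_ols(y: np.ndarray, X: pd.DataFrame, terms: list[str]):
    mat = sm.add_constant(X[terms], has_constant="add") if terms else \
        pd.DataFrame({"const": np.ones(len(y))}, index=X.index)
    return sm.OLS(y, mat).fit()


def stepwise_mlr(
    table: pd.DataFrame, response: str, candidates: list[str]
) -> StepwiseResult:
    """Bidirectional stepwise OLS starting from the full model, minimising AIC.

    Complete-case rows are used; candidates collinear to machine precision
    are dropped with a warning.  Deterministic given the data.
    """
    data = table[[response] + list(candidates)].dropna()
    if len(data) <= len(candidates) + 2:
        raise ValueError("too few complete-case rows for the candidate set")
    y = data[response].to_numpy(float)
    X = data[list(candidates)].astype(float)

    # drop exactly collinear candidates (rank-revealing QR on centred columns)
    keep: list[str] = []
    for c in candidates:
        trial = keep + [c]
        mat = np.column_stack([np.ones(len(X))] + [X[t].to_numpy() for t in trial])
        if np.linalg.matrix_rank(mat) == mat.shape[1]:
            keep.append(c)
        else:
            log.warning("dropping collinear candidate %s", c)

    current = list(keep)
    fit = _fit_ols(y, X, current)
    trace = [("full:" + "+".join(current) if current else "null", float(fit.aic))]
    improved = True
    while improved:
        improved = False
        moves = [("drop", t) for t in current] + \
                [("add", t) for t in keep if t not in current]
        best = (fit.aic, None, None)
        for action, term in moves:
            trial = [t for t in current if t != term] if action == "drop" \
                else current + [term]
            aic = _fit_ols(y, X, trial).aic
            if aic < best[0] - 1e-10:
                best = (aic, action, term)
        if best[1] is not None:
            action, term = best[1], best[2]
            current = [t for t in current if t != term] if action == "drop" \
                else current + [term]
            fit = _fit_ols(y, X, current)
            trace.append((f"{action}:{term}", float(fit.aic)))
            improved = True
    return StepwiseResult(model=fit, selected=current, aic_trace=trace)


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    eta_squared: float
    tukey: pd.DataFrame       # pair, diff, ci_low, ci_high, p_adj, reject
    levene_stat: float
    levene_p: float


def anova_tukey(
    table: pd.DataFrame, response: str, grouping: str
) -> AnovaResult:
    """One-way ANOVA with Tukey HSD 95% intervals, eta-squared, and a
    median-centred Levene (Brown-Forsythe) homogeneity check."""
    data = table[[response, grouping]].dropna()
    groups = {g: sub[response].to_numpy(float) for g, sub in data.groupby(grouping, observed=True)}
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g, v in groups.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
    values = list(groups.values())
    F, p = sps.f_oneway(*values)
    all_v = np.concatenate(values)
    grand = all_v.mean()
    ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in values)
    ss_total = float(((all_v - grand) ** 2).sum())
    eta2 = ss_between / ss_total if ss_total > 0 else 0.0
    if ss_total == 0:
        F, p = 0.0, 1.0

    hsd = pairwise_tukeyhsd(
        data[response].to_numpy(float), data[grouping].astype(str).to_numpy(), alpha=0.05
    )
    pairs = list(itertools.combinations(hsd.groupsunique, 2))
    tukey = pd.DataFrame({
        "a": [p[0] for p in pairs],
        "b": [p[1] for p in pairs],
        "diff": hsd.meandiffs,
        "ci_low": hsd.confint[:, 0],
        "ci_high": hsd.confint[:, 1],
        "p_adj": hsd.pvalues,
        "reject": hsd.reject,
    })
    lev_stat, lev_p = sps.levene(*values, center="median")
    return AnovaResult(
        F=float(F), df_between=len(groups) - 1, df_within=len(all_v) - len(groups),
        p=float(p), eta_squared=float(eta2), tukey=tukey,
        levene_stat=float(lev_stat), levene_p=float(lev_p),
    )


def bootstrap_power(
    table: pd.DataFrame,
    response: str,
    grouping: str,
    n_iter: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Post-hoc power by bootstrapped ANOVA.

    Each iteration resamples with replacement within each group (preserving
    group sizes, i.e. stratified by zone), reruns the one-way ANOVA, and
    power is the fraction of iterations with p < alpha.  Returns the
    estimate with a binomial 95% CI; deterministic per seed.
    """
    data = table[[response, grouping]].dropna()
    groups = [sub[response].to_numpy(float) for _, sub in data.groupby(grouping, observed=True)]
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs at least 2 observations")
    rng = np.random.default_rng(seed)
    n_sig = 0
    n_skipped = 0
    for _ in range(n_iter):
        resampled = [g[rng.integers(0, len(g), len(g))] for g in groups]
        if all(np.ptp(r) == 0 for r in resampled):
            n_skipped += 1
            continue
        _, p = sps.f_oneway(*resampled)
        if np.isnan(p):
            n_skipped += 1
            continue
        if p < alpha:
            n_sig += 1
    n_eff = n_iter - n_skipped
    if n_skipped > 0.01 * n_iter:
        log.warning("%d of %d bootstrap iterations degenerate and skipped", n_skipped, n_iter)
    power = n_sig / n_eff if n_eff else float("nan")
    se = np.sqrt(power * (1 - power) / n_eff) if n_eff else float("nan")
    return {
        "power": power,
        "ci_low": max(0.0, power - 1.96 * se),
        "ci_high": min(1.0, power + 1.96 * se),
        "n_iter": n_iter,
        "n_skipped": n_skipped,
        "alpha": alpha,
    }


def management_contrast(
    table: pd.DataFrame,
    response: str,
    management_flag: str,
    zone_col: str = "zone",
    field_col: str = "field_id",
    depth_col: str = "depth_top_cm",
) -> pd.DataFrame:
    """Mean per-field (HS - LS) difference of a response by management level
    and depth increment.

    Fields missing either zone at a depth are excluded with a warning.  No
    inferential test is attached: with a handful of fields per management
    level these are descriptive trends only.
    """
    rows = []
    for (fid, depth), sub in table.groupby([field_col, depth_col]):
        hs = sub.loc[sub[zone_col] == "HS", response].dropna()
        ls = sub.loc[sub[zone_col] == "LS", response].dropna()
        if hs.empty or ls.empty:
            log.warning("field %s depth %s lacks HS or LS samples; excluded", fid, depth)
            continue
        flag_vals = sub[management_flag].unique()
        rows.append({
            field_col: fid, depth_col: depth,
            management_flag: flag_vals[0],
            "hs_ls_diff": hs.mean() - ls.mean(),
        })
    per_field = pd.DataFrame(rows)
    if per_field.empty:
        return per_field
    return (
        per_field.groupby([management_flag, depth_col], observed=True)["hs_ls_diff"]
        .agg(mean_diff="mean", n_fields="count")
        .reset_index()
    )
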