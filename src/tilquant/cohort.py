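"""Cohort-level statistics linking image metrics to treatment response.

The statistical battery around the image metrics: univariate and
multivariate logistic regression of pathological complete response (pCR)
reported as odds ratios with Wald 95% confidence intervals, a backward
stepwise screen over the 15 metrics, clinical adjustment, a likelihood
ratio test for treatment-sequence interaction, a paired pre/post
density-change analysis, rank-based group comparisons, Pearson correlation
matrices, decile response tables and pathologist-score concordance.

Models are exposed statsmodels-style: a fitting function returns a
:class:`ModelFit` results object carrying per-term estimates, their
uncertainties and diagnostics, with a ``summary()`` table.  Analyses are
complete-case throughout: rows missing any model variable are dropped and
counted.

Modelling scale conventions: absolute cell counts enter models as
``log10(count + 1)``, densities as ``log10(density)`` and fractions
untransformed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

from .spatial import METRIC_FIELDS

Z_95 = stats.norm.ppf(0.975)

CLINICAL_COVARIATES = (
    "age", "tumour_size_gt50", "node_positive", "grade", "er_positive", "her2_positive",
)

_COUNT_METRICS = ("count_c", "count_s", "count_l")
_DENSITY_METRICS = tuple(m for m in METRIC_FIELDS if m.startswith("d"))


def transform_metric(name: str, values: pd.Series) -> pd.Series:
    """Apply the modelling-scale transform for one of the 15 metrics."""
    if name in _COUNT_METRICS or name == "total_cells":
        return np.log10(values + 1.0)
    if name in _DENSITY_METRICS:
        with np.errstate(divide="ignore"):
            return np.log10(values)
    return values.astype(float)


# ---------------------------------------------------------------------------
# logistic fits


@dataclass
class ModelFit:
    """Results of one logistic fit: per-term OR, Wald 95% CI and p-value."""

    terms: pd.DataFrame        # index = term; columns coef, or, ci_low, ci_high, se, p
    n_observations: int
    n_dropped: int
    converged: bool
    log_likelihood: float
    flags: list[str] = field(default_factory=list)

    def term(self, name: str) -> pd.Series:
        return self.terms.loc[name]

    def odds_ratio(self, name: str) -> float:
        return float(self.terms.loc[name, "or"])

    def summary(self) -> str:
        lines = [
            f"Logistic regression (n = {self.n_observations}, "
            f"{self.n_dropped} incomplete rows dropped)",
            f"log-likelihood = {self.log_likelihood:.3f}   converged = {self.converged}",
        ]
        if self.flags:
            lines.append("flags: " + ", ".join(self.flags))
        lines.append(f"{'term':<22}{'OR':>9}{'95% CI':>21}{'p':>12}")
        for name, row in self.terms.iterrows():
            ci = f"({row['ci_low']:.3g}, {row['ci_high']:.3g})"
            lines.append(f"{name:<22}{row['or']:>9.3g}{ci:>21}{row['p']:>12.3g}")
        return "\n".join(lines)


def _complete_cases(outcome: pd.Series, design: pd.DataFrame):
    df = pd.concat([outcome.rename("__y__"), design], axis=1)
    ok = df.notna().all(axis=1)
    return df.loc[ok, "__y__"].astype(float), df.loc[ok, design.columns].astype(float), int((~ok).sum())


def fit_logistic(outcome: pd.Series, design: pd.DataFrame, add_intercept: bool = True) -> ModelFit:
    """Maximum-likelihood logistic fit of a binary outcome.

    Complete-case: rows with any missing value are dropped and counted.
    Constant predictors and collinear columns are flagged and excluded from
    the fit (they are not estimable); perfect separation is flagged and no
    estimates are reported for the affected fit.
    """
    y, X, n_dropped = _complete_cases(pd.Series(outcome), pd.DataFrame(design))
    if len(y) == 0 or y.nunique() < 2:
        raise ValueError("need at least one event and one non-event among complete cases")

    flags: list[str] = []
    cols = list(X.columns)
    if add_intercept:
        X = sm.add_constant(X, has_constant="add")

    # identifiability screen: constant columns, then greedy rank check
    keep: list[str] = ["const"] if add_intercept else []
    mat = X[keep].to_numpy() if keep else np.empty((len(X), 0))
    for c in cols:
        v = X[c].to_numpy()
        if np.ptp(v) == 0:
            flags.append(f"non_identifiable:{c}")
            continue
        trial = np.column_stack([mat, v])
        if np.linalg.matrix_rank(trial) <= mat.shape[1]:
            flags.append(f"rank_deficient:{c}")
            continue
        keep.append(c)
        mat = trial
    X = X[keep]

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        converged = bool(res.mle_retvals.get("converged", False))
        llf = float(res.llf)
        params, bse, pvals = res.params, res.bse, res.pvalues
    except (PerfectSeparationError, PerfectSeparationWarning, np.linalg.LinAlgError):
        flags.append("perfect_separation")
        nan = pd.Series(np.nan, index=X.columns)
        params, bse, pvals = nan, nan, nan
        converged, llf = False, float("nan")

    terms = pd.DataFrame(
        {
            "coef": params,
            "or": np.exp(params),
            "ci_low": np.exp(params - Z_95 * bse),
            "ci_high": np.exp(params + Z_95 * bse),
            "se": bse,
            "p": pvals,
        }
    )
    return ModelFit(terms, len(y), n_dropped, converged, llf, flags)


def fit_logistic_2x2(events_exposed, n_exposed, events_unexposed, n_unexposed) -> ModelFit:
    """Convenience fit of a single binary predictor from 2x2 counts; the
    MLE odds ratio equals the cross-product ratio of the table."""
    y = np.concatenate([
        np.ones(events_exposed), np.zeros(n_exposed - events_exposed),
        np.ones(events_unexposed), np.zeros(n_unexposed - events_unexposed),
    ])
    x = np.concatenate([np.ones(n_exposed), np.zeros(n_unexposed)])
    return fit_logistic(pd.Series(y), pd.DataFrame({"exposed": x}))


# ---------------------------------------------------------------------------
# metric screen and model building


def univariate_metric_screen(
    records: pd.DataFrame,
    metrics: tuple[str, ...] = METRIC_FIELDS,
    outcome: str = "pcr",
) -> pd.DataFrame:
    """One single-predictor logistic fit per metric against pCR.

    Returns one row per metric (OR, 95% CI, p, n) on the modelling scale,
    plus a Bonferroni-adjusted p column for information; the screen itself
    is reported at nominal p values.  Metrics missing for every patient are
    skipped with a warning.
    """
    rows = []
    for m in metrics:
        x = transform_metric(m, records[m]).replace([np.inf, -np.inf], np.nan)
        if x.notna().sum() == 0:
            warnings.warn(f"metric {m!r} missing for all patients; skipped")
            continue
        fit = fit_logistic(records[outcome], pd.DataFrame({m: x}))
        row = fit.terms.loc[m]
        rows.append(
            {
                "metric": m, "or": row["or"], "ci_low": row["ci_low"],
                "ci_high": row["ci_high"], "p": row["p"], "n": fit.n_observations,
            }
        )
    out = pd.DataFrame(rows).set_index("metric")
    out["p_bonferroni"] = np.minimum(out["p"] * len(out), 1.0)
    return out


@dataclass
class StepwiseResult:
    removal_trace: list[tuple[str, float]]
    final_terms: list[str]
    final_fit: ModelFit | None


def backward_stepwise(
    records: pd.DataFrame,
    candidates: tuple[str, ...] = METRIC_FIELDS,
    outcome: str = "pcr",
    threshold: float = 0.05,
    transform: bool = True,
) -> StepwiseResult:
    """Backward elimination over candidate metrics.

    Starts from the full multivariate fit and repeatedly removes the term
    with the largest Wald p >= ``threshold``, refitting until every
    remaining term is retained at p < ``threshold`` or the model is empty.
    Exact p ties are broken by removing the lexicographically later name.
    """
    if len(candidates) < 2:
        raise ValueError("need at least two candidate terms")
    design = pd.DataFrame(
        {
            m: (transform_metric(m, records[m]) if transform else records[m]).replace(
                [np.inf, -np.inf], np.nan
            )
            for m in candidates
        }
    )
    current = [m for m in candidates if design[m].notna().any()]
    trace: list[tuple[str, float]] = []
    fit = None
    while current:
        fit = fit_logistic(records[outcome], design[current])
        if not fit.converged:
            raise RuntimeError(f"stepwise fit failed to converge (flags: {fit.flags})")
        pvals = fit.terms.drop(index="const")["p"]
        worst = pvals.max()
        if worst < threshold:
            break
        tied = sorted(pvals.index[pvals == worst])
        victim = tied[-1]  # lexicographically later name goes first
        trace.append((victim, float(worst)))
        current = [m for m in current if m != victim]
        fit = None
    if current and fit is None:
        fit = fit_logistic(records[outcome], design[current])
    return StepwiseResult(trace, current, fit if current else None)


def adjusted_model(
    records: pd.DataFrame,
    metric: str,
    clinical: tuple[str, ...] = CLINICAL_COVARIATES,
    outcome: str = "pcr",
    grade_coding: str = "ordinal",
) -> ModelFit:
    """A metric plus the six clinical covariates.

    Grade enters as one ordinal numeric term by default (a single OR per
    unit grade step); ``grade_coding='dummy'`` expands it to indicator
    columns instead.  Age is continuous, the rest are binary indicators.
    """
    design = {metric: transform_metric(metric, records[metric]).replace([np.inf, -np.inf], np.nan)}
    for c in clinical:
        if c == "grade" and grade_coding == "dummy":
            dummies = pd.get_dummies(records[c], prefix="grade", drop_first=True, dtype=float)
            dummies[records[c].isna()] = np.nan
            design.update({col: dummies[col] for col in dummies})
        else:
            design[c] = records[c].astype(float)
    return fit_logistic(records[outcome], pd.DataFrame(design))


@dataclass
class LRTResult:
    statistic: float
    df: int
    p: float
    fit_full: ModelFit
    fit_reduced: ModelFit
    group_fits: dict[int, ModelFit]

    def group_odds_ratio(self, level: int, term: str) -> float:
        return self.group_fits[level].odds_ratio(term)


def interaction_lrt(
    records: pd.DataFrame,
    metric: str,
    group: str,
    outcome: str = "pcr",
    transform: bool = True,
) -> LRTResult:
    """Likelihood ratio test for effect modification by a binary factor.

    Compares ``outcome ~ metric + group + metric:group`` against the model
    without the interaction term on the same complete cases; the statistic
    is ``2 (LL_full - LL_reduced)`` referred to chi-square(1).  Per-group
    single-predictor fits are reported alongside.
    """
    x = transform_metric(metric, records[metric]) if transform else records[metric].astype(float)
    x = x.replace([np.inf, -np.inf], np.nan)
    g = records[group].astype(float)
    if g.dropna().nunique() < 2:
        raise ValueError(f"group factor {group!r} is constant")
    y = records[outcome]

    df = pd.DataFrame({"__y__": y, "x": x, "g": g}).dropna()
    for lvl, sub in df.groupby("g"):
        if sub["__y__"].nunique() < 2:
            raise ValueError(f"group level {lvl:g} lacks both events and non-events")

    full = fit_logistic(df["__y__"], pd.DataFrame({"x": df["x"], "g": df["g"], "x:g": df["x"] * df["g"]}))
    reduced = fit_logistic(df["__y__"], pd.DataFrame({"x": df["x"], "g": df["g"]}))
    stat = max(0.0, 2.0 * (full.log_likelihood - reduced.log_likelihood))
    p = float(stats.chi2.sf(stat, 1))

    group_fits = {
        int(lvl): fit_logistic(sub["__y__"], pd.DataFrame({"x": sub["x"]}))
        for lvl, sub in df.groupby("g")
    }
    return LRTResult(stat, 1, p, full, reduced, group_fits)


# ---------------------------------------------------------------------------
# paired pre/post change


@dataclass
class PairedChangeResult:
    table: pd.DataFrame        # waterfall-ordered per-patient change table
    fit: ModelFit              # pCR on continuous delta
    fit_adjusted: ModelFit     # additionally adjusted for pre-treatment log density
    n_decrease: int
    n_increase: int
    n_no_change: int


def paired_change_analysis(
    records: pd.DataFrame,
    pre_col: str = "pre_dmed_l",
    post_col: str = "post_dmed_l",
    outcome: str = "pcr",
    sort_group: str = "taxane_second",
) -> PairedChangeResult:
    """Change in log10 median lymphocyte density between paired samples.

    ``delta = log10(post) - log10(pre)``; direction is 'decrease' iff
    delta < 0 (exact zeros count as no-change).  The returned table is
    waterfall-ordered with the treatment-sequence group as the primary sort
    key and delta as the secondary.  pCR is modelled on the continuous
    delta, and again adjusted for the pre-treatment log density.
    """
    paired = records.dropna(subset=[pre_col, post_col]).copy()
    if len(paired) == 0:
        raise ValueError("no patients with both phases defined")
    with np.errstate(divide="ignore"):
        paired["pre_log_density"] = np.log10(paired[pre_col])
        paired["delta_log_density"] = np.log10(paired[post_col]) - paired["pre_log_density"]
    paired["direction"] = np.select(
        [paired["delta_log_density"] < 0, paired["delta_log_density"] > 0],
        ["decrease", "increase"],
        default="no_change",
    )
    n_dec = int((paired["direction"] == "decrease").sum())
    n_inc = int((paired["direction"] == "increase").sum())
    n_zero = len(paired) - n_dec - n_inc

    keys = [sort_group, "delta_log_density"] if sort_group in paired else ["delta_log_density"]
    table = paired.sort_values(keys, kind="mergesort").reset_index(drop=True)

    if paired["delta_log_density"].nunique() < 2:
        nan_terms = pd.DataFrame(
            np.nan, index=["const", "delta_log_density"],
            columns=["coef", "or", "ci_low", "ci_high", "se", "p"],
        )
        fit = ModelFit(nan_terms, len(paired), 0, False, float("nan"), ["non_identifiable:delta_log_density"])
        fit_adj = fit
    else:
        fit = fit_logistic(paired[outcome], paired[["delta_log_density"]])
        fit_adj = fit_logistic(paired[outcome], paired[["delta_log_density", "pre_log_density"]])
    return PairedChangeResult(table, fit, fit_adj, n_dec, n_inc, n_zero)


# ---------------------------------------------------------------------------
# nonparametric comparisons, correlations, deciles, concordance


def group_distribution_tests(values_by_group: dict) -> tuple[float, float, str]:
    """Rank-sum (2 groups) or Kruskal-Wallis (>2 groups) comparison.

    Two-group comparisons use the exact null enumeration when both groups
    have at most 10 untied observations, otherwise the tie-corrected
    normal approximation.
    """
    groups = [np.asarray(v, dtype=float) for v in values_by_group.values()]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("every group needs at least one value")
    if len(groups) == 2:
        a, b = groups
        pooled = np.concatenate([a, b])
        exact = len(a) <= 10 and len(b) <= 10 and len(np.unique(pooled)) == len(pooled)
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="exact" if exact else "asymptotic"
        )
        return float(res.statistic), float(res.pvalue), "rank-sum"
    res = stats.kruskal(*groups)
    return float(res.statistic), float(res.pvalue), "kruskal-wallis"


@dataclass
class CorrelationResult:
    matrix: pd.DataFrame
    strongest_positive: tuple[str, str, float] | None
    strongest_negative: tuple[str, str, float] | None
    undefined: list[str]


def correlation_matrix(table: pd.DataFrame, min_pairs: int = 3) -> CorrelationResult:
    """Pairwise-complete Pearson correlations between metric columns."""
    counts = table.notna().astype(int)
    mat = table.corr(method="pearson", min_periods=min_pairs)
    undefined = [c for c in table.columns if table[c].dropna().nunique() <= 1]
    mat.loc[undefined, :] = np.nan
    mat.loc[:, undefined] = np.nan
    for c in set(table.columns) - set(undefined):
        mat.loc[c, c] = 1.0

    off = mat.where(~np.eye(len(mat), dtype=bool))
    stacked = off.stack()
    pos = neg = None
    if len(stacked):
        imax, imin = stacked.idxmax(), stacked.idxmin()
        if stacked[imax] > 0:
            pos = (imax[0], imax[1], float(stacked[imax]))
        if stacked[imin] < 0:
            neg = (imin[0], imin[1], float(stacked[imin]))
    return CorrelationResult(mat, pos, neg, undefined)


def decile_response_table(
    records: pd.DataFrame, metric: str, outcome: str = "pcr", n_bins: int = 10
) -> pd.DataFrame:
    """Response proportion by decile of a metric.

    Patients are ranked by the metric; bins are near-equal with the
    remainder spread over the lowest bins, and tied metric values are all
    assigned to the lowest decile any of them would occupy.
    """
    df = records.dropna(subset=[metric, outcome])
    if len(df) < n_bins:
        raise ValueError(f"need at least {n_bins} patients with metric and outcome")
    df = df.sort_values(metric, kind="mergesort")
    n = len(df)
    base, rem = divmod(n, n_bins)
    sizes = [base + 1] * rem + [base] * (n_bins - rem)
    provisional = pd.Series(np.repeat(np.arange(1, n_bins + 1), sizes), index=df.index)
    lowest_bin_per_value = provisional.groupby(df[metric]).min()
    assigned = df[metric].map(lowest_bin_per_value)

    rows = []
    for d in range(1, n_bins + 1):
        sub = df[assigned == d]
        k = int(sub[outcome].sum())
        rows.append({"decile": d, "n": len(sub), "pcr_count": k,
                     "proportion": k / len(sub) if len(sub) else math.nan})
    return pd.DataFrame(rows)


def pathologist_concordance(
    records: pd.DataFrame,
    category_col: str = "til_category",
    metrics: tuple[str, ...] = ("count_l", "frac_l", "dmed_l"),
) -> pd.DataFrame:
    """Kruskal-Wallis of each lymphocyte metric across ordinal pathologist
    categories of lymphocytic infiltration."""
    rows = []
    for m in metrics:
        df = records.dropna(subset=[m, category_col])
        groups = {lvl: sub[m].to_numpy() for lvl, sub in df.groupby(category_col) if len(sub)}
        if len(groups) < 2:
            raise ValueError(f"need >= 2 populated categories for {m!r}")
        stat, p = stats.kruskal(*groups.values())
        rows.append({"metric": m, "statistic": float(stat), "p": float(p), "n": len(df)})
    return pd.DataFrame(rows).set_index("metric")
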