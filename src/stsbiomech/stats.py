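"""Group-difference and outcome-association statistics.

One-way ANOVA with Tukey HSD on component scores and demographics,
Pearson chi-square on categorical distributions, covariate-adjusted linear
regression of patient-reported outcomes (pain VAS, disability ODI) on
component scores with variance-inflation-factor collinearity checks, and a
summary-statistics ANOVA that recovers the F test from published group
means/SDs/sizes alone.

Controls carry no VAS/ODI, so outcome regressions pool the two patient
groups; an optional group indicator can be added as a covariate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.outliers_influence import variance_inflation_factor

from .errors import InvalidArgumentError, InvalidDataError


@dataclass
class TukeyPair:
    group_a: str
    group_b: str
    mean_difference: float     # mean(b) - mean(a)
    p_adjusted: float
    ci_low: float
    ci_high: float


@dataclass
class AnovaResult:
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    group_means: dict[str, float] = field(default_factory=dict)
    tukey: list[TukeyPair] = field(default_factory=list)


@dataclass
class RegressionResult:
    outcome: str
    params: dict[str, float]
    standard_errors: dict[str, float]
    p_values: dict[str, float]
    vif: dict[str, float]
    n_obs: int
    r_squared: float


def anova_tukey(values, groups) -> AnovaResult:
    """One-way ANOVA with Tukey HSD pairwise comparisons.

    ``values`` is one scalar per subject, ``groups`` the matching labels.
    Requires at least two groups with at least two subjects each.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if not np.all(np.isfinite(values)):
        raise InvalidDataError("values contain missing entries")
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise InvalidDataError("ANOVA needs at least two groups")
    small = labels[counts < 2]
    if len(small):
        raise InvalidDataError(f"groups with fewer than two subjects: {list(small)}")

    samples = [values[groups == g] for g in labels]
    f_stat, p = sps.f_oneway(*samples)
    tukey_res = pairwise_tukeyhsd(values, groups)
    frame = pd.DataFrame(tukey_res.summary().data[1:], columns=tukey_res.summary().data[0])
    pairs = [TukeyPair(str(r.group1), str(r.group2), float(r.meandiff),
                       float(r["p-adj"]), float(r.lower), float(r.upper))
             for _, r in frame.iterrows()]
    return AnovaResult(
        f_statistic=float(f_stat),
        df_between=len(labels) - 1,
        df_within=len(values) - len(labels),
        p_value=float(p),
        group_means={str(g): float(s.mean()) for g, s in zip(labels, samples)},
        tukey=pairs,
    )


def summary_stats_anova(means, sds, ns) -> tuple[float, tuple[int, int], float]:
    """One-way ANOVA recovered from per-group summary statistics.

    Between-group sum of squares uses the size-weighted grand mean; the
    within-group sum of squares is sum (n_g - 1) sd_g^2.  Returns
    ``(F, (df_between, df_within), p)`` and agrees exactly with a raw-data
    ANOVA when fed exact group summaries.
    """
    means = np.asarray(means, float)
    sds = np.asarray(sds, float)
    ns = np.asarray(ns)
    if len(means) != len(sds) or len(means) != len(ns) or len(means) < 2:
        raise InvalidArgumentError("means, sds, ns must align, with >= 2 groups")
    if np.any(ns < 2):
        raise InvalidArgumentError("each group needs n >= 2")
    if np.any(sds <= 0):
        raise InvalidArgumentError("group SDs must be positive")
    n_total = int(ns.sum())
    grand = float(np.sum(ns * means) / n_total)
    ssb = float(np.sum(ns * (means - grand) ** 2))
    ssw = float(np.sum((ns - 1) * sds**2))
    dfb, dfw = len(means) - 1, n_total - len(means)
    f = (ssb / dfb) / (ssw / dfw)
    p = float(sps.f.sf(f, dfb, dfw))
    return f, (dfb, dfw), p


def weighted_grand_mean(means, ns) -> float:
    """Size-weighted pooled mean from group summaries."""
    means = np.asarray(means, float)
    ns = np.asarray(ns, float)
    return float(np.sum(ns * means) / np.sum(ns))


def chi_square_counts(table) -> tuple[float, int, float]:
    """Pearson chi-square (no continuity correction) on an r x c count table."""
    table = np.asarray(table)
    if np.any(table < 0) or not np.issubdtype(table.dtype, np.integer):
        raise InvalidDataError("counts must be non-negative integers")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise InvalidDataError("table has a zero marginal")
    res = sps.chi2_contingency(table, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def sex_counts_from_proportions(male_fractions, ns) -> np.ndarray:
    """Reconstruct integer male/female counts from printed group proportions."""
    male_fractions = np.asarray(male_fractions, float)
    ns = np.asarray(ns, int)
    males = np.round(male_fractions * ns).astype(int)
    return np.vstack([males, ns - males])


def regress_outcomes(
    scores: pd.DataFrame,
    outcome: pd.Series,
    covariates: pd.DataFrame | None = None,
    outcome_name: str = "outcome",
) -> RegressionResult:
    """OLS of a patient-reported outcome on component scores + covariates.

    Rows with a missing outcome (e.g. controls, for whom VAS/ODI are not
    assessed) are dropped.  VIFs are reported per predictor over the
    centered design.
    """
    X = scores.copy()
    if covariates is not None:
        X = pd.concat([X, covariates], axis=1)
    mask = outcome.notna() & X.notna().all(axis=1)
    X, y = X.loc[mask], outcome.loc[mask].astype(float)
    if len(X) < X.shape[1] + 2:
        raise InvalidDataError(
            f"too few complete rows ({len(X)}) for {X.shape[1]} predictors"
        )
    Xc = sm.add_constant(X)
    rank = np.linalg.matrix_rank(Xc.to_numpy())
    if rank < Xc.shape[1]:
        corr = X.corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        worst = corr.stack().idxmax()
        raise InvalidDataError(f"perfectly collinear predictors (check {worst})")
    fit = sm.OLS(y, Xc).fit()
    vif = {col: float(variance_inflation_factor(Xc.to_numpy(), i))
           for i, col in enumerate(Xc.columns) if col != "const"}
    return RegressionResult(
        outcome=outcome_name,
        params={k: float(v) for k, v in fit.params.items()},
        standard_errors={k: float(v) for k, v in fit.bse.items()},
        p_values={k: float(v) for k, v in fit.pvalues.items()},
        vif=vif,
        n_obs=int(fit.nobs),
        r_squared=float(fit.rsquared),
    )
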