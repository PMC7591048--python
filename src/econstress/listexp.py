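"""List-experiment (item-count technique) estimators and diagnostics.

Respondents in a treatment arm see the four uncontroversial statements plus
one sensitive statement and report only *how many* they agree with. The mean
item-count difference between a treatment arm and the control arm identifies
the share agreeing with the sensitive statement; its contrast with the
direct-questioning arm quantifies social-desirability bias (SDB). The module
also implements the joint respondent-type proportion test for a design effect
(a change in control-item answering induced by the sensitive item) and
covariate balance checks across the four randomized arms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

N_CONTROL_ITEMS = 4

#: Covariates the supporting regressions adjust for (country dummies are added
#: automatically for pooled-scope fits).
DEFAULT_COVARIATES: tuple[str, ...] = (
    "female",
    "age",
    "married",
    "unemployed",
    "household_size",
    "children_school",
    "income_category",
    "education",
    "homeowner",
    "living_area",
)

BALANCE_COVARIATES: tuple[str, ...] = (
    "gender",
    "age",
    "married",
    "unemployed",
    "household_size",
    "children_school",
    "income_category",
    "education",
    "homeowner",
    "living_area",
    "buffer_stock",
    "stress_events",
    "income_loss",
)


class EstimationError(ValueError):
    """Raised when an arm is empty or a design matrix is degenerate."""


@dataclass(frozen=True)
class ListEstimate:
    statement: int
    scope: str
    method: str  # "diff_means" or "regression"
    support_hat: float
    se: float
    t_stat: float
    n_control: int
    n_treat: int

    def confint(self, level: float = 0.95) -> tuple[float, float]:
        z = stats.norm.ppf(0.5 + level / 2)
        return self.support_hat - z * self.se, self.support_hat + z * self.se


@dataclass(frozen=True)
class DirectEstimate:
    statement: int
    scope: str
    share: float
    se: float
    n: int


@dataclass(frozen=True)
class SDBEstimate:
    statement: int
    scope: str
    list_support: float
    direct_support: float
    sdb: float
    se: float
    t_stat: float


@dataclass(frozen=True)
class DesignEffectResult:
    statement: int
    #: one row per respondent type (y = control-item subtotal, z = sensitive
    #: agreement) with its estimated proportion, SE and one-sided p-value.
    pi_table: pd.DataFrame
    min_pi_hat: float
    p_value: float  # Bonferroni-corrected over the testable proportions
    reject: bool
    low_power: bool


def _scoped(data: pd.DataFrame, scope: str) -> pd.DataFrame:
    if scope == "pooled":
        return data
    sub = data[data["country"] == scope]
    if sub.empty:
        raise EstimationError(f"no respondents in scope {scope!r}")
    return sub


def _treatment_arm(statement: int) -> str:
    if statement not in (1, 2):
        raise ValueError("statement must be 1 or 2")
    return "T1" if statement == 1 else "T2"


def estimate_support_diff_means(
    data: pd.DataFrame, statement: int, scope: str = "pooled"
) -> ListEstimate:
    """Difference in mean item counts, treatment arm minus control.

    The standard error uses Welch's unequal-variance formula.
    """
    sub = _scoped(data, scope)
    arm = _treatment_arm(statement)
    y_c = sub.loc[sub["arm"] == "control", "item_count"].dropna().astype(float)
    y_t = sub.loc[sub["arm"] == arm, "item_count"].dropna().astype(float)
    for name, y in (("control", y_c), (arm, y_t)):
        if len(y) == 0:
            raise EstimationError(f"empty {name!r} arm in scope {scope!r}")
    est = y_t.mean() - y_c.mean()
    se = float(np.sqrt(y_t.var(ddof=1) / len(y_t) + y_c.var(ddof=1) / len(y_c)))
    return ListEstimate(
        statement=statement,
        scope=scope,
        method="diff_means",
        support_hat=float(est),
        se=se,
        t_stat=float(est / se) if se > 0 else np.inf * np.sign(est),
        n_control=len(y_c),
        n_treat=len(y_t),
    )


def _build_design(sub: pd.DataFrame, covariates: tuple[str, ...], scope: str) -> pd.DataFrame:
    X = pd.DataFrame(index=sub.index)
    for cov in covariates:
        if cov == "female":
            X["female"] = (sub["gender"] == "F").astype(float)
        else:
            X[cov] = sub[cov].astype(float)
    if scope == "pooled" and covariates and sub["country"].nunique() > 1:
        dummies = pd.get_dummies(sub["country"], prefix="country", drop_first=True)
        X = pd.concat([X, dummies.astype(float)], axis=1)
    return X


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    """Name columns that a pivoted QR flags as linearly dependent."""
    from scipy.linalg import qr

    _, r, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    return [names[i] for i in piv[rank:]]


def estimate_support_regression(
    data: pd.DataFrame,
    statement: int,
    scope: str = "pooled",
    covariates: tuple[str, ...] | None = DEFAULT_COVARIATES,
) -> ListEstimate:
    """OLS of item count on a treatment indicator plus covariates.

    The treatment-indicator coefficient is the covariate-adjusted support
    estimate; standard errors are heteroskedasticity-robust (HC1). With an
    empty covariate set this reduces exactly to the difference in means.
    """
    sub = _scoped(data, scope)
    arm = _treatment_arm(statement)
    sub = sub[sub["arm"].isin(["control", arm])]
    for name in ("control", arm):
        if (sub["arm"] == name).sum() == 0:
            raise EstimationError(f"empty {name!r} arm in scope {scope!r}")
    covariates = tuple(covariates or ())
    X = _build_design(sub, covariates, scope)
    X.insert(0, "treated", (sub["arm"] == arm).astype(float))
    y = sub["item_count"].astype(float)
    keep = y.notna() & X.notna().all(axis=1)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("regression: listwise deletion dropped %d rows", dropped)
    X, y = X[keep], y[keep]
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        bad = _collinear_columns(design.to_numpy(), list(design.columns))
        raise EstimationError(f"rank-deficient design matrix; collinear columns: {bad}")
    fit = sm.OLS(y, design).fit(cov_type="HC1")
    return ListEstimate(
        statement=statement,
        scope=scope,
        method="regression",
        support_hat=float(fit.params["treated"]),
        se=float(fit.bse["treated"]),
        t_stat=float(fit.tvalues["treated"]),
        n_control=int((X["treated"] == 0).sum()),
        n_treat=int((X["treated"] == 1).sum()),
    )


def estimate_direct(data: pd.DataFrame, statement: int, scope: str = "pooled") -> DirectEstimate:
    """Share admitting agreement in the direct-questioning arm, binomial SE."""
    sub = _scoped(data, scope)
    col = f"direct_stmt{_treatment_arm(statement)[-1]}"
    answers = sub.loc[sub["arm"] == "direct", col].dropna().astype(float)
    if len(answers) == 0:
        raise EstimationError(f"empty 'direct' arm in scope {scope!r}")
    p = float(answers.mean())
    se = float(np.sqrt(p * (1 - p) / len(answers)))
    return DirectEstimate(statement=statement, scope=scope, share=p, se=se, n=len(answers))


def estimate_sdb(list_est: ListEstimate, direct_est: DirectEstimate) -> SDBEstimate:
    """Social-desirability bias: list-experiment support minus direct support.

    The two estimates come from disjoint random subsamples, so their variances
    add.
    """
    if (list_est.statement, list_est.scope) != (direct_est.statement, direct_est.scope):
        raise EstimationError(
            "mismatched statement/scope: "
            f"({list_est.statement}, {list_est.scope!r}) vs "
            f"({direct_est.statement}, {direct_est.scope!r})"
        )
    sdb = list_est.support_hat - direct_est.share
    se = float(np.sqrt(list_est.se**2 + direct_est.se**2))
    return SDBEstimate(
        statement=list_est.statement,
        scope=list_est.scope,
        list_support=list_est.support_hat,
        direct_support=direct_est.share,
        sdb=float(sdb),
        se=se,
        t_stat=float(sdb / se) if se > 0 else np.inf * np.sign(sdb),
    )


def design_effect_test(
    data: pd.DataFrame, statement: int, alpha: float = 0.05
) -> DesignEffectResult:
    """Joint respondent-type proportion test for a design effect.

    With J = 4 control items, let G and H be the empirical item-count CDFs in
    the control and treatment arm. The proportion of respondents with
    control-item subtotal y who agree with the sensitive item is identified as
    pi(y, 1) = G(y) - H(y), and of those who do not as
    pi(y, 0) = H(y) - G(y - 1). Under no design effect every proportion is
    non-negative; each estimate that *can* go negative (2(J+1) - 2 = 8 of the
    10 types) gets a one-sided normal test, combined by Bonferroni.
    """
    y_c = data.loc[data["arm"] == "control", "item_count"].dropna().astype(int).to_numpy()
    arm = _treatment_arm(statement)
    y_t = data.loc[data["arm"] == arm, "item_count"].dropna().astype(int).to_numpy()
    for name, y in (("control", y_c), (arm, y_t)):
        if len(y) == 0:
            raise EstimationError(f"empty {name!r} arm")
    low_power = min(len(y_c), len(y_t)) < 30
    if low_power:
        logger.warning(
            "design_effect_test: arm sizes (%d, %d) below 30; result is low-power",
            len(y_c), len(y_t),
        )

    J = N_CONTROL_ITEMS
    n_c, n_t = len(y_c), len(y_t)

    def cdf(sample: np.ndarray, n: int, y: int) -> float:
        if y < 0:
            return 0.0
        return float((sample <= y).sum() / n)

    rows = []
    for y in range(J + 1):
        G_y, H_y, G_ym1 = cdf(y_c, n_c, y), cdf(y_t, n_t, y), cdf(y_c, n_c, y - 1)
        for z in (1, 0):
            if z == 1:
                pi = G_y - H_y
                var = G_y * (1 - G_y) / n_c + H_y * (1 - H_y) / n_t
            else:
                pi = H_y - G_ym1
                var = H_y * (1 - H_y) / n_t + G_ym1 * (1 - G_ym1) / n_c
            # pi(J, 1) = 1 - H(J) and pi(0, 0) = H(0) are non-negative by
            # construction and are excluded from the test family.
            testable = not ((z == 1 and y == J) or (z == 0 and y == 0))
            se = float(np.sqrt(var))
            if testable:
                p = float(stats.norm.cdf(pi / se)) if se > 0 else (1.0 if pi >= 0 else 0.0)
            else:
                p = np.nan
            rows.append(
                {"y": y, "z": z, "pi_hat": pi, "se": se, "p_one_sided": p, "testable": testable}
            )
    table = pd.DataFrame(rows)
    m = int(table["testable"].sum())
    p_corr = float(min(1.0, m * table.loc[table["testable"], "p_one_sided"].min()))
    return DesignEffectResult(
        statement=statement,
        pi_table=table,
        min_pi_hat=float(table["pi_hat"].min()),
        p_value=p_corr,
        reject=bool(p_corr < alpha),
        low_power=low_power,
    )


def balance_tests(
    data: pd.DataFrame, covariates: tuple[str, ...] = BALANCE_COVARIATES
) -> pd.DataFrame:
    """Per-covariate equality test across the four randomized arms.

    Numeric covariates get a one-way ANOVA F test, categorical ones a
    chi-square test of independence with arm. Constant covariates are skipped
    with a note.
    """
    rows = []
    arms = [a for a in ("control", "T1", "T2", "direct") if (data["arm"] == a).any()]
    for cov in covariates:
        series = data[cov]
        if series.dropna().nunique() <= 1:
            rows.append(
                {"covariate": cov, "test": "skipped", "statistic": np.nan,
                 "p_value": np.nan, "note": "constant covariate"}
            )
            continue
        if pd.api.types.is_numeric_dtype(series):
            groups = [series[data["arm"] == a].dropna().to_numpy(dtype=float) for a in arms]
            stat, p = stats.f_oneway(*groups)
            rows.append(
                {"covariate": cov, "test": "anova_F", "statistic": float(stat),
                 "p_value": float(p), "note": ""}
            )
        else:
            ct = pd.crosstab(data["arm"], series)
            stat, p, _, _ = stats.chi2_contingency(ct)
            rows.append(
                {"covariate": cov, "test": "chi2", "statistic": float(stat),
                 "p_value": float(p), "note": ""}
            )
    return pd.DataFrame(rows)
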