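"""Association statistics linking DSA-response groups to covariates/outcomes.

Univariate: 2x2 odds ratios with Wald CIs, Fisher two-tailed exact tests for
binary covariates, Wilcoxon rank-sum for continuous ones.  Multivariable:
forward/backward stepwise logistic regression driven by an F statistic on
the deviance change between nested fits (enter p < 0.05, remove p > 0.1),
with ROC-AUC and PR-AUC reported against their baselines (0.5 and the
positive-class prevalence).  Survival: Kaplan-Meier curves per response type
with a two-group log-rank test.

2x2 table orientation
---------------------
``ContingencyTable2x2(a, b, c, d)`` lays out rows = exposure levels
(reference first), columns = outcome levels (negative first)::

                 outcome-      outcome+
    unexposed        a             b
    exposed          c             d

so OR = odds(outcome | exposed) / odds(outcome | unexposed) = (a*d)/(b*c).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score

__all__ = [
    "ContingencyTable2x2",
    "OddsRatio",
    "LrModel",
    "AucMeasures",
    "KaplanMeierResult",
    "odds_ratio",
    "fisher_exact_2tail",
    "wilcoxon_rank_sum",
    "auc_measures",
    "stepwise_lr",
    "kaplan_meier",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    a: int  # unexposed, outcome-negative
    b: int  # unexposed, outcome-positive
    c: int  # exposed, outcome-negative
    d: int  # exposed, outcome-positive

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(x < 0 for x in cells):
            raise ValueError("cell counts must be non-negative")
        if sum(cells) == 0:
            raise ValueError("table is empty")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


@dataclass(frozen=True)
class OddsRatio:
    value: float | None  # None marks "n/a" (zero cell)
    ci_low: float | None = None
    ci_high: float | None = None

    @property
    def available(self) -> bool:
        return self.value is not None


def odds_ratio(table: ContingencyTable2x2) -> OddsRatio:
    """Cross-product odds ratio with Wald 95% CI.

    Any zero cell yields the not-available marker (printed "n/a"), matching
    the convention for degenerate strata.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if 0 in (a, b, c, d):
        return OddsRatio(value=None)
    log_or = np.log(a * d / (b * c))
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return OddsRatio(
        value=float(np.exp(log_or)),
        ci_low=float(np.exp(log_or - 1.96 * se)),
        ci_high=float(np.exp(log_or + 1.96 * se)),
    )


def fisher_exact_2tail(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p (sum of hypergeometric probabilities <= observed)."""
    arr = table.as_array()
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("table has an empty margin")
    return float(stats.fisher_exact(arr, alternative="two-sided")[1])


def wilcoxon_rank_sum(x, y) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact null distribution for combined n <= 20 without ties; normal
    approximation with tie correction otherwise.  All-tied input returns
    p = 1 with a warning.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.unique(pooled).size == 1:
        warnings.warn("all values tied across both groups; p = 1", stacklevel=2)
        return 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= 20 and not has_ties) else "asymptotic"
    return float(
        stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
    )


@dataclass(frozen=True)
class AucMeasures:
    roc_auc: float
    pr_auc: float
    baseline_roc: float  # 0.5 (chance-level ranking)
    baseline_pr: float  # positive-class prevalence
    roc_ratio: float
    pr_ratio: float


def auc_measures(scores, labels) -> AucMeasures:
    """ROC-AUC (rank formulation) and PR-AUC (step interpolation) with baselines.

    ROC-AUC via the Mann-Whitney rank statistic; PR-AUC as average precision
    (step-wise interpolation, avoiding the optimistic trapezoidal bias).
    Baselines: 0.5 for ROC, positive prevalence for PR; ratios reported.
    """
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=np.float64)
    if np.unique(labels).size < 2:
        raise ValueError("both outcome classes must be present")
    roc = float(roc_auc_score(labels, scores))
    pr = float(average_precision_score(labels, scores))
    prev = float(labels.mean())
    return AucMeasures(
        roc_auc=roc,
        pr_auc=pr,
        baseline_roc=0.5,
        baseline_pr=prev,
        roc_ratio=roc / 0.5,
        pr_ratio=pr / prev,
    )


@dataclass
class LrModel:
    """Stepwise logistic-regression fit."""

    included_terms: list[str]
    coefficients: dict[str, float]  # log-odds, incl. intercept
    or_with_ci: dict[str, OddsRatio]
    deviance: float
    auc: AucMeasures | None
    excluded_separated: list[str] = field(default_factory=list)

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for term, coef in self.coefficients.items():
            orr = self.or_with_ci.get(term)
            rows.append(
                {
                    "term": term,
                    "coef": coef,
                    "odds_ratio": orr.value if orr else np.exp(coef),
                    "ci_low": orr.ci_low if orr else np.nan,
                    "ci_high": orr.ci_high if orr else np.nan,
                }
            )
        return pd.DataFrame(rows)


def _fit_logit(X: pd.DataFrame, y: np.ndarray):
    model = sm.GLM(y, X, family=sm.families.Binomial())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return model.fit(maxiter=100)


def _f_test_p(dev_small: float, dev_big: float, df_diff: int, dev_full: float, df_resid_full: int) -> float:
    """p-value of the deviance F test between nested binomial fits.

    F = (ΔDeviance / Δdf) / (Deviance_larger / df_resid_larger), referred to
    an F(Δdf, df_resid) distribution — the classic quasi-likelihood F test
    used by stepwise GLM tools.
    """
    if df_resid_full <= 0:
        return 1.0
    scale = dev_full / df_resid_full
    if scale <= 0:
        return 0.0
    f = max(dev_small - dev_big, 0.0) / df_diff / scale
    return float(stats.f.sf(f, df_diff, df_resid_full))


def _is_separated(res, threshold: float = 15.0) -> bool:
    return bool(np.any(np.abs(res.params.to_numpy()) > threshold))


def stepwise_lr(
    candidates: pd.DataFrame,
    outcome,
    p_enter: float = 0.05,
    p_remove: float = 0.1,
    max_steps: int = 100,
) -> LrModel:
    """Forward/backward stepwise logistic regression with F-test stepping.

    Starting from the intercept-only model, at each step the candidate whose
    addition gives the smallest F-test p < ``p_enter`` is added, then any
    included term whose removal F-test p > ``p_remove`` is dropped (largest
    first).  Stops when no move qualifies.  Terms whose fit shows complete
    separation are flagged and excluded with a warning.
    """
    if candidates.isna().any().any():
        raise ValueError("candidate covariates contain missing values")
    y = np.asarray(outcome).astype(float)
    X_all = candidates.astype(float)
    n = len(y)
    included: list[str] = []
    separated: list[str] = []

    def design(terms):
        X = sm.add_constant(X_all[terms], has_constant="add")
        return X

    current = _fit_logit(design([]), y)
    for _ in range(max_steps):
        changed = False
        # forward
        best_p, best_term, best_fit = None, None, None
        for term in X_all.columns:
            if term in included or term in separated:
                continue
            try:
                fit = _fit_logit(design(included + [term]), y)
            except Exception:
                continue
            if _is_separated(fit):
                separated.append(term)
                warnings.warn(
                    f"term {term!r} shows complete separation; excluded", stacklevel=2
                )
                continue
            p = _f_test_p(
                current.deviance,
                fit.deviance,
                1,
                fit.deviance,
                n - len(included) - 2,
            )
            if best_p is None or p < best_p:
                best_p, best_term, best_fit = p, term, fit
        if best_p is not None and best_p < p_enter:
            included.append(best_term)
            current = best_fit
            changed = True
        # backward
        while len(included) > 0:
            worst_p, worst_term = None, None
            for term in included:
                rest = [t for t in included if t != term]
                fit_rest = _fit_logit(design(rest), y)
                p = _f_test_p(
                    fit_rest.deviance,
                    current.deviance,
                    1,
                    current.deviance,
                    n - len(included) - 1,
                )
                if worst_p is None or p > worst_p:
                    worst_p, worst_term = p, term
            if worst_p is not None and worst_p > p_remove:
                included.remove(worst_term)
                current = _fit_logit(design(included), y)
                changed = True
            else:
                break
        if not changed:
            break

    params = current.params
    bse = current.bse
    coefficients = {name: float(params[name]) for name in params.index}
    or_ci = {
        name: OddsRatio(
            value=float(np.exp(params[name])),
            ci_low=float(np.exp(params[name] - 1.96 * bse[name])),
            ci_high=float(np.exp(params[name] + 1.96 * bse[name])),
        )
        for name in params.index
    }
    auc = None
    if included and np.unique(y).size == 2:
        scores = np.asarray(current.predict(design(included)))
        auc = auc_measures(scores, y)
    return LrModel(
        included_terms=included,
        coefficients=coefficients,
        or_with_ci=or_ci,
        deviance=float(current.deviance),
        auc=auc,
        excluded_separated=separated,
    )


@dataclass
class KaplanMeierResult:
    curves: dict[str, pd.DataFrame]  # group -> columns time, survival, at_risk
    logrank_p: float
    medians: dict[str, float]


def kaplan_meier(time, event, group) -> KaplanMeierResult:
    """Product-limit survival per group with a two-group log-rank test."""
    df = pd.DataFrame({"time": time, "event": event, "group": group})
    if (df["time"] <= 0).any():
        raise ValueError("survival times must be positive")
    names = sorted(df["group"].unique())
    if len(names) != 2:
        raise ValueError("kaplan_meier expects exactly two groups")
    curves, medians = {}, {}
    for name in names:
        sub = df[df["group"] == name]
        if len(sub) == 0:
            raise ValueError(f"group {name} has no cases")
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], sub["event"], label=str(name))
        at_risk = kmf.event_table["at_risk"]
        curves[str(name)] = pd.DataFrame(
            {
                "time": kmf.survival_function_.index.to_numpy(),
                "survival": kmf.survival_function_.iloc[:, 0].to_numpy(),
                "at_risk": at_risk.reindex(kmf.survival_function_.index).to_numpy(),
            }
        )
        medians[str(name)] = float(kmf.median_survival_time_)
    g0, g1 = names
    res = _ll_logrank(
        df.loc[df["group"] == g0, "time"],
        df.loc[df["group"] == g1, "time"],
        df.loc[df["group"] == g0, "event"],
        df.loc[df["group"] == g1, "event"],
    )
    return KaplanMeierResult(curves=curves, logrank_p=float(res.p_value), medians=medians)
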