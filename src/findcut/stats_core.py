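"""Statistical engines shared by the cutpoint search and the validation step.

Ordinary model fits go through the field-standard libraries — lifelines for
the Cox partial likelihood (Efron tie handling, the ``coxph`` default) and
Kaplan-Meier curves, statsmodels for logistic maximum likelihood, scipy for
chi-square, scikit-learn for AUC.  This module wraps them behind small typed
results so the search and CLI layers stay library-agnostic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from scipy.special import xlogy
from sklearn.metrics import roc_auc_score

from .data_model import GroupAssignment
from .exceptions import ConfigurationError, DegenerateDataError, FindcutError

__all__ = [
    "CoxFit",
    "LogisticFit",
    "TestResult",
    "KMCurve",
    "fit_cox",
    "logrank_test",
    "fit_logistic",
    "lr_test",
    "compute_auc",
    "km_estimate",
    "chi2_test",
    "classification_metrics",
]


@dataclass
class TestResult:
    """A chi-square referenced test: statistic, degrees of freedom, p-value."""

    statistic: float
    df: int
    p: float
    method: str

    def __post_init__(self) -> None:
        self.statistic = float(self.statistic)
        self.p = float(self.p)


def _chi2_result(statistic: float, df: int, method: str) -> TestResult:
    return TestResult(statistic, df, float(stats.chi2.sf(statistic, df)), method)


@dataclass
class CoxFit:
    """Cox proportional-hazards fit on the group dummies (plus covariates).

    ``beta``/``se`` are in log hazard-ratio units; ``loglik`` is the
    maximized log partial likelihood and ``loglik_null`` its value at beta=0.
    ``names`` labels the coefficients (dummies first, then covariates).
    """

    beta: np.ndarray
    se: np.ndarray
    loglik: float
    loglik_null: float
    converged: bool
    names: list[str] = field(default_factory=list)
    baseline: pd.DataFrame | None = None

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.beta)

    @property
    def df(self) -> int:
        return len(self.beta)

    def lrt(self) -> TestResult:
        return lr_test(self.loglik, self.loglik_null, self.df, method="cox_lrt")

    def summary(self) -> pd.DataFrame:
        z = self.beta / self.se
        p = 2 * stats.norm.sf(np.abs(z))
        ci = 1.959963984540054 * self.se
        return pd.DataFrame(
            {
                "coef": self.beta,
                "hr": self.hr,
                "se": self.se,
                "hr_low95": np.exp(self.beta - ci),
                "hr_high95": np.exp(self.beta + ci),
                "p": p,
            },
            index=self.names or None,
        )


@dataclass
class LogisticFit:
    """Logistic fit on the group dummies; intercept = reference-group log odds."""

    intercept: float
    beta: np.ndarray
    se: np.ndarray
    loglik: float
    loglik_null: float
    converged: bool
    names: list[str] = field(default_factory=list)
    group_probs: np.ndarray | None = None

    @property
    def or_(self) -> np.ndarray:
        return np.exp(self.beta)

    @property
    def df(self) -> int:
        return len(self.beta)

    def lrt(self) -> TestResult:
        return lr_test(self.loglik, self.loglik_null, self.df, method="logistic_lrt")

    def summary(self) -> pd.DataFrame:
        z = self.beta / self.se
        p = 2 * stats.norm.sf(np.abs(z))
        ci = 1.959963984540054 * self.se
        return pd.DataFrame(
            {
                "coef": self.beta,
                "or": self.or_,
                "se": self.se,
                "or_low95": np.exp(self.beta - ci),
                "or_high95": np.exp(self.beta + ci),
                "p": p,
            },
            index=self.names or None,
        )


@dataclass
class KMCurve:
    """Product-limit survival estimate for one risk group."""

    group: int
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n: int
    n_events: int


def _design_frame(
    assign: GroupAssignment | None,
    extra_covariates: pd.DataFrame | np.ndarray | None,
    coding: str,
) -> tuple[pd.DataFrame, list[str]]:
    parts: list[pd.DataFrame] = []
    names: list[str] = []
    if assign is not None and assign.k > 0:
        dm = assign.dummy_matrix(coding)
        dnames = [f"group_ge_{k}" if coding == "cumulative" else f"group_{k}"
                  for k in range(1, assign.k + 1)]
        parts.append(pd.DataFrame(dm, columns=dnames))
        names += dnames
    if extra_covariates is not None:
        xc = pd.DataFrame(extra_covariates).reset_index(drop=True)
        xc.columns = [str(c) for c in xc.columns]
        parts.append(xc)
        names += list(xc.columns)
    if not parts:
        return pd.DataFrame(index=range(len(assign.group) if assign is not None else 0)), []
    return pd.concat(parts, axis=1), names


def fit_cox(
    assign: GroupAssignment,
    time,
    event,
    extra_covariates: pd.DataFrame | None = None,
    coding: str = "cumulative",
) -> CoxFit:
    """Maximize the Cox partial likelihood (Efron ties) on the group dummies.

    With cumulative coding each coefficient is the log-HR increment between
    adjacent risk groups; with one-hot coding it is the log-HR of that group
    versus the reference (group 0).  Both codings give identical likelihoods.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if event.sum() == 0:
        raise DegenerateDataError("no events observed; Cox model is undefined")
    X, names = _design_frame(assign, extra_covariates, coding)
    if not names:
        raise ConfigurationError("fit_cox needs at least one dummy or covariate")
    df = X.copy()
    df["_time"] = time
    df["_event"] = event
    cph = CoxPHFitter()
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            cph.fit(df, duration_col="_time", event_col="_event")
        except Exception as err:  # monotone likelihood / separation
            raise DegenerateDataError(f"Cox fit failed: {err}") from err
        converged = bool(np.all(np.abs(cph.params_.values) < 15))
    return CoxFit(
        beta=cph.params_.to_numpy(),
        se=cph.standard_errors_.to_numpy(),
        loglik=float(cph.log_likelihood_),
        loglik_null=float(cph._ll_null_),
        converged=converged,
        names=names,
        baseline=cph.baseline_cumulative_hazard_,
    )


def logrank_test(group, time, event, trend: bool = False) -> TestResult:
    """K-sample log-rank test across ordinal risk groups.

    Default is the heterogeneity form on #groups-1 df; ``trend=True`` gives
    the 1-df trend version using the ordinal group codes as scores.
    """
    group = np.asarray(group)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    labels = np.unique(group)
    if len(labels) < 2:
        raise ConfigurationError("log-rank test needs at least two non-empty groups")
    if event.sum() == 0:
        raise DegenerateDataError("no events observed")
    if trend:
        stat = _logrank_trend_statistic(group, time, event)
        return _chi2_result(stat, 1, "logrank_trend")
    res = multivariate_logrank_test(time, group, event)
    return TestResult(float(res.test_statistic), len(labels) - 1, float(res.p_value), "logrank")


def _logrank_trend_statistic(group, time, event) -> float:
    scores = group.astype(float)
    stat_num = 0.0
    var = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        d = int(((time == t) & (event == 1)).sum())
        n_t = int(at_risk.sum())
        if n_t <= 1:
            continue
        s = scores[at_risk]
        sbar = s.mean()
        obs = scores[(time == t) & (event == 1)].sum()
        stat_num += obs - d * sbar
        var += d * (n_t - d) / (n_t - 1) * ((s**2).mean() - sbar**2)
    if var <= 0:
        return 0.0
    return stat_num**2 / var


def fit_logistic(
    assign: GroupAssignment,
    y,
    extra_covariates: pd.DataFrame | None = None,
    coding: str = "cumulative",
) -> LogisticFit:
    """Logistic MLE of the outcome on group dummies (plus covariates).

    The unadjusted model is saturated in the groups, so the fitted group
    probabilities equal the observed group event fractions.  A group with
    all-0 or all-1 outcomes gives quasi-separation; the fit is returned with
    ``converged=False`` so callers can reject that cutpoint candidate.
    """
    import statsmodels.api as sm

    y = np.asarray(y, dtype=int)
    if y.min() == y.max():
        raise DegenerateDataError("outcome has a single class; logistic fit undefined")
    X, names = _design_frame(assign, extra_covariates, coding)
    exog = sm.add_constant(X.to_numpy(dtype=float), has_constant="add")
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.Logit(y, exog)
        try:
            res = model.fit(disp=0, maxiter=100)
            converged = bool(res.mle_retvals.get("converged", True))
        except Exception:
            res = model.fit(disp=0, maxiter=200, method="bfgs")
            converged = False
    params = np.asarray(res.params, dtype=float)
    bse = np.asarray(res.bse, dtype=float)
    if np.any(np.abs(params) > 15) or not np.all(np.isfinite(bse)):
        converged = False
    group_probs = None
    if assign is not None and assign.k >= 0 and extra_covariates is None:
        probs = np.asarray(res.predict(exog), dtype=float)
        group_probs = np.array(
            [probs[assign.group == g].mean() if (assign.group == g).any() else np.nan
             for g in range(assign.n_groups)]
        )
    n = len(y)
    p0 = y.mean()
    loglik_null = float(xlogy(y.sum(), p0) + xlogy(n - y.sum(), 1 - p0))
    return LogisticFit(
        intercept=float(params[0]),
        beta=params[1:],
        se=bse[1:],
        loglik=float(res.llf),
        loglik_null=loglik_null,
        converged=converged,
        names=names,
        group_probs=group_probs,
    )


def lr_test(full_loglik: float, null_loglik: float, df: int, method: str = "lrt") -> TestResult:
    """Likelihood-ratio test: 2*(full - null) against chi-square(df)."""
    if df < 1:
        raise ConfigurationError("lr_test requires df >= 1")
    statistic = 2.0 * (full_loglik - null_loglik)
    if statistic < -1e-8:
        raise FindcutError(
            f"nested-model log-likelihoods out of order (LRT statistic {statistic:.3g}); "
            "a fit likely failed to converge"
        )
    if statistic < 0:
        warnings.warn("clipping a tiny negative LRT statistic to 0", stacklevel=2)
        statistic = 0.0
    return _chi2_result(statistic, df, method)


def compute_auc(score, y) -> float:
    """Area under the ROC curve: P(score+ > score-) + 0.5 * P(tie)."""
    y = np.asarray(y, dtype=int)
    if y.min() == y.max():
        raise DegenerateDataError("AUC undefined: only one outcome class present")
    return float(roc_auc_score(y, np.asarray(score, dtype=float)))


def km_estimate(group, time, event) -> list[KMCurve]:
    """Kaplan-Meier product-limit curve per risk group."""
    group = np.asarray(group)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if len(time) == 0:
        raise DegenerateDataError("empty input")
    curves = []
    for g in np.unique(group):
        mask = group == g
        kmf = KaplanMeierFitter()
        kmf.fit(time[mask], event[mask])
        tbl = kmf.event_table
        curves.append(
            KMCurve(
                group=int(g),
                times=kmf.survival_function_.index.to_numpy(dtype=float),
                survival=kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float),
                at_risk=tbl["at_risk"].to_numpy(dtype=float),
                n=int(mask.sum()),
                n_events=int(event[mask].sum()),
            )
        )
    return curves


def chi2_test(table) -> TestResult:
    """Pearson chi-square on a groups-by-outcome contingency table
    (no continuity correction)."""
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or min(table.shape) < 2:
        raise ConfigurationError("contingency table must be at least 2x2")
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    expected = np.outer(row, col) / table.sum()
    if np.any(expected == 0):
        raise DegenerateDataError("contingency table has a zero expected count")
    statistic = float(((table - expected) ** 2 / expected).sum())
    df = (table.shape[0] - 1) * (table.shape[1] - 1)
    return _chi2_result(statistic, df, "chi2")


def classification_metrics(
    group, y, fit: LogisticFit, rule: str = "prob", threshold: float = 0.5
) -> dict:
    """Sensitivity, specificity, their sum and accuracy of the grouped model.

    Multi-group fits are collapsed to a binary prediction: ``rule='prob'``
    predicts positive where the fitted group probability >= ``threshold``
    (default); ``rule='top_group'`` predicts positive only for the highest
    risk group.
    """
    group = np.asarray(group)
    y = np.asarray(y, dtype=int)
    if rule == "prob":
        if fit.group_probs is None:
            raise ConfigurationError("fit has no group probabilities")
        pred = (fit.group_probs[group] >= threshold).astype(int)
    elif rule == "top_group":
        pred = (group == group.max()).astype(int)
    else:
        raise ConfigurationError(f"unknown rule {rule!r}")
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    if pred.min() == pred.max():
        warnings.warn("all subjects predicted to one class", stacklevel=2)
    sens = tp / (tp + fn) if tp + fn else np.nan
    spec = tn / (tn + fp) if tn + fp else np.nan
    return {
        "sensitivity": sens,
        "specificity": spec,
        "sens_plus_spec": sens + spec,
        "accuracy": (tp + tn) / len(y),
    }
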