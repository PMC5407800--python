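"""Hold-out validation of discovered cutpoints.

Cutpoints located on the training cohort are applied to the held-out test
cohort as a categorical risk-group factor, and a multivariate model (Cox or
logistic, depending on the outcome) is fitted together with adjustment
covariates such as age, stage or histology.  Group coefficients are
reported versus the lowest risk group (one-hot coding); categorical
covariates are one-hot encoded with their most frequent level as reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import CohortTable, CutpointSet, encode_groups
from .exceptions import ConfigurationError
from .stats_core import CoxFit, LogisticFit, TestResult, fit_cox, fit_logistic, logrank_test

__all__ = ["HoldoutValidation", "build_covariate_matrix", "validate_holdout"]


@dataclass
class HoldoutValidation:
    """Adjusted model fit of discovered cuts on a held-out cohort."""

    cuts: CutpointSet
    fit: CoxFit | LogisticFit
    table: pd.DataFrame  # coefficient summary (HR/OR, 95% CI, p)
    group_counts: np.ndarray
    logrank: TestResult | None = None  # unadjusted group comparison (survival)


def build_covariate_matrix(df: pd.DataFrame, covariates) -> pd.DataFrame:
    """Numeric covariates pass through; categorical ones are one-hot encoded
    with the most frequent level as the reference."""
    parts = []
    for name in covariates:
        if name not in df.columns:
            raise ConfigurationError(f"covariate column {name!r} not found")
        col = df[name]
        if pd.api.types.is_numeric_dtype(col) and col.nunique() > 2:
            parts.append(col.astype(float).rename(name).to_frame())
        else:
            levels = col.astype(str)
            ref = levels.value_counts().idxmax()
            dummies = pd.get_dummies(levels, prefix=name, dtype=float)
            dummies = dummies.drop(columns=f"{name}_{ref}")
            parts.append(dummies)
    if not parts:
        return pd.DataFrame(index=df.index)
    return pd.concat(parts, axis=1)


def validate_holdout(
    test: CohortTable,
    cuts: CutpointSet | list[float],
    covariates: list[str] | None = None,
) -> HoldoutValidation:
    """Fit the adjusted categorized model on the test cohort.

    Returns group-versus-reference hazard/odds ratios with 95% CIs and
    Wald p-values, plus (survival mode) the unadjusted log-rank test of the
    induced risk groups.
    """
    if not isinstance(cuts, CutpointSet):
        cuts = CutpointSet(cuts)
    if cuts.k == 0:
        raise ConfigurationError("validation requires at least one cutpoint")
    assign = encode_groups(test.z, cuts)
    covariates = list(covariates or test.spec.covariates)
    extra = build_covariate_matrix(test.df.reset_index(drop=True), covariates)
    extra = extra if len(extra.columns) else None
    logrank = None
    if test.mode == "survival":
        fit = fit_cox(assign, test.time, test.event, extra_covariates=extra, coding="onehot")
        if len(np.unique(assign.group)) > 1:
            logrank = logrank_test(assign.group, test.time, test.event)
    else:
        fit = fit_logistic(assign, test.y, extra_covariates=extra, coding="onehot")
    return HoldoutValidation(
        cuts=cuts,
        fit=fit,
        table=fit.summary(),
        group_counts=assign.counts(),
        logrank=logrank,
    )
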