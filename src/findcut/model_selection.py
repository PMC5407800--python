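"""Choosing the optimal *number* of cutpoints by AIC minimization.

For each candidate K the best K cutpoints are located by the search
criterion, the corresponding categorized model is fitted (Cox partial
likelihood for survival outcomes, logistic likelihood for binary ones), and
AIC = 2 * n_params - 2 * loglik is recorded; the selected K minimizes AIC,
with ties resolved toward the smaller K (parsimony).  n_params counts the
regression coefficients (plus the logistic intercept), not the cutpoint
locations — the standard AIC of the fitted model.  K = 0 (no split) is
scanned by default as a sanity floor.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import xlogy

from . import _engine
from .data_model import CohortTable, CutpointSet, encode_groups
from .exceptions import ConfigurationError, NoFeasibleSplitError
from .search import (
    BINARY_CRITERIA,
    SURVIVAL_CRITERIA,
    CandidateGrid,
    SearchResult,
    search_cutpoints,
)
from .stats_core import fit_cox, fit_logistic

logger = logging.getLogger(__name__)

__all__ = ["AICProfile", "findcutnum", "compare_aic", "default_criterion"]


def default_criterion(mode: str) -> str:
    return "logrank" if mode == "survival" else "logistic_lrt"


@dataclass
class AICProfile:
    """AIC per scanned number of cutpoints, with the minimizing K."""

    entries: pd.DataFrame  # columns: k, loglik, n_params, aic
    cuts_used: dict[int, CutpointSet] = field(default_factory=dict)
    searches: dict[int, SearchResult] = field(default_factory=dict)
    ic: str = "aic"

    @property
    def best_k(self) -> int:
        e = self.entries.sort_values(["aic", "k"], kind="stable")
        return int(e["k"].iloc[0])

    def aic_of(self, k: int) -> float:
        return float(self.entries.set_index("k").loc[k, "aic"])


def _ic_penalty(ic: str, n_params: int, n: int) -> float:
    if ic == "aic":
        return 2.0 * n_params
    if ic == "bic":
        return math.log(n) * n_params
    if ic == "aicc":
        if n - n_params - 1 <= 0:
            return math.inf
        return 2.0 * n_params + 2.0 * n_params * (n_params + 1) / (n - n_params - 1)
    raise ConfigurationError(f"unknown information criterion {ic!r}")


def _null_entry(cohort: CohortTable) -> tuple[float, int]:
    if cohort.mode == "survival":
        return _engine.null_partial_loglik(cohort.time, cohort.event), 0
    y = cohort.y
    p0 = y.mean()
    ll = float(xlogy(y.sum(), p0) + xlogy(len(y) - y.sum(), 1 - p0))
    return ll, 1


def _fitted_loglik(cohort: CohortTable, cuts: CutpointSet) -> tuple[float, int]:
    assign = encode_groups(cohort.z, cuts)
    if cohort.mode == "survival":
        fit = fit_cox(assign, cohort.time, cohort.event)
        return fit.loglik, cuts.k
    fit = fit_logistic(assign, cohort.y)
    return fit.loglik, cuts.k + 1


def _quantile_cuts(cohort: CohortTable, k: int) -> CutpointSet:
    qs = np.arange(1, k + 1) / (k + 1)
    cuts = np.quantile(cohort.z, qs)
    if len(np.unique(cuts)) < k:
        raise NoFeasibleSplitError(f"quantile cuts for k={k} are not distinct")
    return CutpointSet(np.unique(cuts))


def findcutnum(
    cohort: CohortTable,
    k_range=(0, 1, 2),
    criterion: str | None = None,
    grid: CandidateGrid | None = None,
    fixed_quantile_cuts: bool = False,
    ic: str = "aic",
) -> AICProfile:
    """Scan candidate cut counts and score each by the AIC of its best model.

    For each K >= 1 the cuts are the criterion-optimal ones from
    :func:`findcut.search.search_cutpoints` (or equally spaced quantile cuts
    with ``fixed_quantile_cuts=True``); infeasible K are omitted with a
    warning.  ``ic`` switches the penalty (aic default; bic, aicc offered).
    """
    if len(k_range) == 0:
        raise ConfigurationError("k_range must be non-empty")
    criterion = criterion or default_criterion(cohort.mode)
    allowed = SURVIVAL_CRITERIA if cohort.mode == "survival" else BINARY_CRITERIA
    if criterion not in allowed:
        raise ConfigurationError(
            f"criterion {criterion!r} incompatible with {cohort.mode} outcome"
        )
    rows = []
    cuts_used: dict[int, CutpointSet] = {}
    searches: dict[int, SearchResult] = {}
    for k in sorted(set(int(k) for k in k_range)):
        try:
            if k == 0:
                loglik, n_params = _null_entry(cohort)
                cuts = CutpointSet(())
            else:
                if fixed_quantile_cuts:
                    cuts = _quantile_cuts(cohort, k)
                else:
                    res = search_cutpoints(cohort, k, criterion, grid)
                    searches[k] = res
                    cuts = res.best
                loglik, n_params = _fitted_loglik(cohort, cuts)
        except NoFeasibleSplitError as err:
            logger.warning("k=%d omitted from AIC profile: %s", k, err)
            continue
        aic = _ic_penalty(ic, n_params, cohort.n) - 2.0 * loglik
        rows.append({"k": k, "loglik": loglik, "n_params": n_params, "aic": aic})
        cuts_used[k] = cuts
    if not rows:
        raise NoFeasibleSplitError("no candidate number of cutpoints was feasible")
    entries = pd.DataFrame(rows)
    return AICProfile(entries=entries, cuts_used=cuts_used, searches=searches, ic=ic)


def compare_aic(profile: AICProfile) -> pd.DataFrame:
    """Ranked AIC report: K, loglik, n_params, AIC, delta from the minimum,
    and the cuts each K used."""
    e = profile.entries.copy()
    e["delta_aic"] = e["aic"] - e["aic"].min()
    e["cuts"] = [
        ",".join(f"{c:g}" for c in profile.cuts_used[k]) for k in e["k"]
    ]
    e = e.sort_values(["aic", "k"], kind="stable").reset_index(drop=True)
    e["best"] = [k == profile.best_k for k in e["k"]]
    return e
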