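"""Candidate-grid construction and exhaustive optimal-cutpoint search.

The optimal K cutpoints are the tuple maximizing the chosen criterion over
every strictly increasing K-tuple of admissible candidate values:

* survival outcomes — K-sample log-rank statistic or Cox likelihood-ratio
  statistic (minimal p-value at fixed df);
* binary outcomes — logistic likelihood-ratio statistic, AUC of the grouped
  model, or the Pearson chi-square of the (K+1) x 2 table (the traditional
  baseline).

The scan is exact (no pruning); ties break toward the smallest cutpoints in
lexicographic order.  Candidates default to the distinct observed values of
z, screened so either side of a single cut keeps at least
``min_group_frac`` of the cohort; during the search every induced group
must additionally satisfy the size floor and, in survival mode, a minimum
event count — an unconstrained minimal-p search is unstable at the edges of
the observed range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import _engine
from .data_model import CohortTable, CutpointSet
from .exceptions import ConfigurationError, NoFeasibleSplitError

__all__ = [
    "SURVIVAL_CRITERIA",
    "BINARY_CRITERIA",
    "CandidateGrid",
    "SearchResult",
    "candidate_cutpoints",
    "search_cutpoints",
    "chi2_baseline_search",
]

SURVIVAL_CRITERIA = ("logrank", "cox_lrt")
BINARY_CRITERIA = ("logistic_lrt", "max_auc", "chi2")


@dataclass(frozen=True)
class CandidateGrid:
    """Admissible cutpoint candidates plus the search constraints."""

    values: np.ndarray
    min_group_frac: float = 0.10
    min_events_per_group: int = 5
    n: int = 0

    @property
    def min_group_size(self) -> int:
        return max(1, math.ceil(self.min_group_frac * self.n))

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class SearchResult:
    """Criterion surface over the candidate grid and its argmax."""

    criterion: str
    k: int
    best: CutpointSet
    best_value: float
    best_p: float | None
    surface: pd.DataFrame = field(repr=False)
    n_evaluated: int = 0
    n_invalid: int = 0

    def surface_tsv(self, path) -> None:
        self.surface.to_csv(path, sep="\t", index=False)


def candidate_cutpoints(
    z,
    min_group_frac: float = 0.10,
    min_events_per_group: int = 5,
    midpoints: bool = False,
) -> CandidateGrid:
    """Admissible candidate cut values from the observed risk-factor values.

    Candidates are the sorted distinct observed values (or, with
    ``midpoints=True``, midpoints of consecutive distinct values); a value is
    excluded when a single cut there would leave either side with fewer than
    ``ceil(min_group_frac * n)`` subjects (at least one).
    """
    z = np.asarray(z, dtype=float)
    n = len(z)
    distinct = np.unique(z)
    if len(distinct) < 2:
        raise NoFeasibleSplitError("risk factor is constant; no candidate cutpoints")
    values = (distinct[:-1] + distinct[1:]) / 2.0 if midpoints else distinct
    s = max(1, math.ceil(min_group_frac * n))
    lower = np.searchsorted(np.sort(z), values, side="left")
    keep = (lower >= s) & (n - lower >= s)
    values = values[keep]
    if len(values) == 0:
        raise NoFeasibleSplitError(
            "no candidate cutpoint satisfies the minimum-group-size constraint"
        )
    return CandidateGrid(
        values=values,
        min_group_frac=min_group_frac,
        min_events_per_group=min_events_per_group,
        n=n,
    )


def _resolve_grid(cohort: CohortTable, grid: CandidateGrid | None) -> CandidateGrid:
    if grid is not None:
        return grid
    return candidate_cutpoints(cohort.z)


def _scan(cohort: CohortTable, k: int, criterion: str, grid: CandidateGrid):
    if criterion in SURVIVAL_CRITERIA:
        if cohort.mode != "survival":
            raise ConfigurationError(
                f"criterion {criterion!r} requires a survival outcome"
            )
        return _engine.scan_survival(
            cohort.z,
            cohort.time,
            cohort.event,
            grid.values,
            k,
            criterion,
            grid.min_group_size,
            grid.min_events_per_group,
        )
    if criterion in BINARY_CRITERIA:
        if cohort.mode != "binary":
            raise ConfigurationError(
                f"criterion {criterion!r} requires a binary outcome"
            )
        return _engine.scan_binary(
            cohort.z, cohort.y, grid.values, k, criterion, grid.min_group_size
        )
    raise ConfigurationError(f"unknown criterion {criterion!r}")


def search_cutpoints(
    cohort: CohortTable,
    k: int,
    criterion: str,
    grid: CandidateGrid | None = None,
) -> SearchResult:
    """Exhaustive search for the best K cutpoints under one criterion.

    Every strictly increasing K-tuple of grid values whose induced K+1
    groups satisfy the size (and, for survival, event-count) floors is
    evaluated; the returned :class:`SearchResult` holds the full surface and
    the maximizing tuple (= minimal p at fixed df for the test criteria).
    """
    if k < 1:
        raise ConfigurationError("k must be >= 1")
    grid = _resolve_grid(cohort, grid)
    if len(grid) < k:
        raise NoFeasibleSplitError(
            f"grid has {len(grid)} candidates; cannot place {k} cutpoints"
        )
    out = _scan(cohort, k, criterion, grid)
    cut_cols = {f"cut{j + 1}": grid.values[out.cut_indices[:, j]] for j in range(k)}
    surface = pd.DataFrame(cut_cols)
    surface["value"] = out.values
    if out.df >= 1:
        surface["p"] = stats.chi2.sf(out.values, out.df)
    surface["valid"] = out.valid
    r = out.best_index()
    if r < 0:
        raise NoFeasibleSplitError(
            f"no feasible {k}-cutpoint split under the grid constraints"
        )
    best = CutpointSet(grid.values[out.cut_indices[r]])
    best_value = float(out.values[r])
    best_p = float(stats.chi2.sf(best_value, out.df)) if out.df >= 1 else None
    return SearchResult(
        criterion=criterion,
        k=k,
        best=best,
        best_value=best_value,
        best_p=best_p,
        surface=surface,
        n_evaluated=out.n_evaluated,
        n_invalid=out.n_invalid,
    )


def chi2_baseline_search(
    cohort: CohortTable, k: int, grid: CandidateGrid | None = None
) -> SearchResult:
    """Traditional contingency-table baseline: maximize Pearson chi-square.

    Same exhaustive scheme as :func:`search_cutpoints`, with the (K+1) x 2
    Pearson statistic as the criterion; binary outcomes only.
    """
    if cohort.mode != "binary":
        raise ConfigurationError("chi-square baseline requires a binary outcome")
    return search_cutpoints(cohort, k, "chi2", grid)
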