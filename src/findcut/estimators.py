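"""scikit-learn style transformers around the cutpoint machinery.

:class:`CutpointBinner` applies a fixed set of cutpoints as an ordinal
discretizer; :class:`OptimalCutpointBinner` learns the cutpoints (and
optionally their number, by AIC) from an outcome during ``fit``.  Both
follow the sklearn estimator contract (``get_params``/``set_params``,
fitted attributes with trailing underscores, ``transform`` returning a
column of ordinal group codes) so they compose with pipelines; for survival
outcomes ``y`` is a structured array with ``event``/``time`` fields, the
scikit-survival convention.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .data_model import CohortTable, CutpointSet, OutcomeSpec, encode_groups
from .exceptions import ConfigurationError
from .model_selection import default_criterion, findcutnum
from .search import candidate_cutpoints, search_cutpoints

__all__ = ["CutpointBinner", "OptimalCutpointBinner"]


def _as_1d(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 2:
        if X.shape[1] != 1:
            raise ConfigurationError(
                "cutpoint binners operate on a single risk-factor column"
            )
        X = X[:, 0]
    elif X.ndim != 1:
        raise ConfigurationError("X must be 1-d or a single-column 2-d array")
    if not np.isfinite(X).all():
        raise ConfigurationError("risk factor contains non-finite values")
    return X


def survival_y(time, event) -> np.ndarray:
    """Pack (time, event) into the structured survival-outcome array."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    y = np.empty(len(time), dtype=[("event", "?"), ("time", "<f8")])
    y["event"] = event.astype(bool)
    y["time"] = time
    return y


def _unpack_survival_y(y) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(y, pd.DataFrame):
        return y["time"].to_numpy(float), y["event"].to_numpy(int)
    arr = np.asarray(y)
    if arr.dtype.names:
        names = set(arr.dtype.names)
        if not {"time", "event"} <= names:
            raise ConfigurationError(
                "structured survival y must have 'time' and 'event' fields"
            )
        return arr["time"].astype(float), arr["event"].astype(int)
    if isinstance(y, (tuple, list)) and len(y) == 2:
        return np.asarray(y[0], float), np.asarray(y[1], int)
    raise ConfigurationError(
        "survival outcome must be a structured array with event/time fields, "
        "a (time, event) pair, or a DataFrame with those columns"
    )


def _cohort_from_xy(X, y, outcome: str) -> CohortTable:
    z = _as_1d(X)
    if outcome == "survival":
        time, event = _unpack_survival_y(y)
        df = pd.DataFrame({"z": z, "time": time, "event": event})
        spec = OutcomeSpec(mode="survival", z="z", time="time", event="event")
    else:
        df = pd.DataFrame({"z": z, "y": np.asarray(y, dtype=int)})
        spec = OutcomeSpec(mode="binary", z="z", y="y")
    return CohortTable(df, spec)


class CutpointBinner(TransformerMixin, BaseEstimator):
    """Ordinal discretizer at fixed, user-supplied cutpoints.

    A value equal to a cutpoint joins the upper group.  ``transform``
    returns a single column of group codes 0..K.
    """

    def __init__(self, cuts=()):
        self.cuts = cuts

    def fit(self, X, y=None):
        _as_1d(X)
        self.cutpoints_ = CutpointSet(self.cuts)
        self.n_features_in_ = 1
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "cutpoints_")
        assign = encode_groups(_as_1d(X), self.cutpoints_)
        return assign.group[:, None]

    def dummies(self, X, coding: str = "cumulative") -> np.ndarray:
        """K indicator columns ('cumulative' threshold or 'onehot' coding)."""
        check_is_fitted(self, "cutpoints_")
        return encode_groups(_as_1d(X), self.cutpoints_).dummy_matrix(coding)

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "cutpoints_")
        return np.asarray(["risk_group"], dtype=object)


class OptimalCutpointBinner(CutpointBinner):
    """Learn optimal cutpoints (and optionally their number) from an outcome.

    Parameters
    ----------
    n_cuts : int or "auto"
        Number of cutpoints; "auto" scans ``k_range`` and picks the AIC
        minimizer.
    outcome : "binary" or "survival"
        With "survival", ``y`` is a structured event/time array.
    criterion : str or None
        Search criterion ("logrank"/"cox_lrt" for survival,
        "logistic_lrt"/"max_auc"/"chi2" for binary); None picks the mode
        default (log-rank / logistic LRT).
    min_group_frac, min_events_per_group, midpoints
        Candidate-grid constraints (see :func:`findcut.search.candidate_cutpoints`).
    k_range : tuple of int
        Cut counts scanned when ``n_cuts="auto"``.
    """

    def __init__(
        self,
        n_cuts=1,
        outcome="binary",
        criterion=None,
        min_group_frac=0.10,
        min_events_per_group=5,
        midpoints=False,
        k_range=(0, 1, 2),
    ):
        self.n_cuts = n_cuts
        self.outcome = outcome
        self.criterion = criterion
        self.min_group_frac = min_group_frac
        self.min_events_per_group = min_events_per_group
        self.midpoints = midpoints
        self.k_range = k_range

    def fit(self, X, y):
        if self.outcome not in ("binary", "survival"):
            raise ConfigurationError(f"unknown outcome mode {self.outcome!r}")
        cohort = _cohort_from_xy(X, y, self.outcome)
        grid = candidate_cutpoints(
            cohort.z,
            min_group_frac=self.min_group_frac,
            min_events_per_group=self.min_events_per_group,
            midpoints=self.midpoints,
        )
        crit = self.criterion or default_criterion(cohort.mode)
        if self.n_cuts == "auto":
            profile = findcutnum(cohort, k_range=self.k_range, criterion=crit, grid=grid)
            self.aic_profile_ = profile
            k = profile.best_k
            self.cutpoints_ = profile.cuts_used[k]
            self.search_result_ = profile.searches.get(k)
        else:
            k = int(self.n_cuts)
            self.search_result_ = search_cutpoints(cohort, k, crit, grid)
            self.cutpoints_ = self.search_result_.best
            self.aic_profile_ = None
        self.n_cuts_ = self.cutpoints_.k
        self.criterion_ = crit
        self.best_value_ = (
            self.search_result_.best_value if self.search_result_ else None
        )
        self.best_p_ = self.search_result_.best_p if self.search_result_ else None
        self.n_features_in_ = 1
        return self
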