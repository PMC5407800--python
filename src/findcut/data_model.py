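"""Cohort ingestion, outcome specification, group encoding and train/test splits.

The central objects are :class:`CohortTable` (one row per subject: the
continuous risk factor ``z`` plus either a right-censored survival outcome
``(time, event)`` or a binary outcome ``y``, and optional adjustment
covariates) and :class:`CutpointSet` (K strictly increasing thresholds that
turn ``z`` into an ordinal risk variable with K+1 levels).

Boundary convention: a subject whose value **equals** a cutpoint joins the
**upper** group, i.e. group(v) = #{c : v >= c}.  This matches the clinical
reading "5 or more nodes = high risk" / "at or larger than 3.25 cm".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .exceptions import CohortValidationError, ConfigurationError

logger = logging.getLogger(__name__)

__all__ = [
    "OutcomeSpec",
    "CohortTable",
    "CutpointSet",
    "GroupAssignment",
    "load_cohort",
    "encode_groups",
    "split_cohort",
]


@dataclass(frozen=True)
class OutcomeSpec:
    """Declares which columns hold the outcome and the risk factor.

    mode : ``"survival"`` uses ``(time, event)``; ``"binary"`` uses ``y``.
    """

    mode: Literal["survival", "binary"]
    z: str
    time: str | None = None
    event: str | None = None
    y: str | None = None
    covariates: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.mode == "survival":
            if self.time is None or self.event is None:
                raise ConfigurationError(
                    "survival mode requires 'time' and 'event' column names"
                )
        elif self.mode == "binary":
            if self.y is None:
                raise ConfigurationError("binary mode requires a 'y' column name")
        else:
            raise ConfigurationError(f"unknown outcome mode {self.mode!r}")
        object.__setattr__(self, "covariates", tuple(self.covariates))

    @property
    def outcome_columns(self) -> tuple[str, ...]:
        if self.mode == "survival":
            return (self.time, self.event)
        return (self.y,)


@dataclass
class CohortTable:
    """Typed per-subject cohort with a declared outcome mode.

    Attributes
    ----------
    df : DataFrame indexed by subject id with at least the declared columns.
    spec : the :class:`OutcomeSpec` naming those columns.
    n_dropped : rows removed at load time for missing z/outcome values.
    """

    df: pd.DataFrame
    spec: OutcomeSpec
    n_dropped: int = 0

    def __post_init__(self) -> None:
        _validate_cohort(self.df, self.spec)

    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def mode(self) -> str:
        return self.spec.mode

    @property
    def z(self) -> np.ndarray:
        return self.df[self.spec.z].to_numpy(dtype=float)

    @property
    def time(self) -> np.ndarray:
        return self.df[self.spec.time].to_numpy(dtype=float)

    @property
    def event(self) -> np.ndarray:
        return self.df[self.spec.event].to_numpy(dtype=int)

    @property
    def y(self) -> np.ndarray:
        return self.df[self.spec.y].to_numpy(dtype=int)

    def covariate_frame(self) -> pd.DataFrame:
        return self.df[list(self.spec.covariates)]

    def subset(self, index) -> "CohortTable":
        return CohortTable(self.df.loc[index], self.spec, n_dropped=0)


def _validate_cohort(df: pd.DataFrame, spec: OutcomeSpec) -> None:
    needed = (spec.z,) + spec.outcome_columns + spec.covariates
    for col in needed:
        if col not in df.columns:
            raise ConfigurationError(f"column {col!r} not found in cohort table")
    z = df[spec.z]
    if not np.isfinite(z.to_numpy(dtype=float)).all():
        raise CohortValidationError(f"non-finite values remain in column {spec.z!r}")
    if spec.mode == "survival":
        t = df[spec.time].to_numpy(dtype=float)
        if (t < 0).any():
            raise CohortValidationError("follow-up times must be non-negative")
        _check_binary(df[spec.event], spec.event)
    else:
        _check_binary(df[spec.y], spec.y)


def _check_binary(col: pd.Series, name: str) -> None:
    vals = set(pd.unique(col.dropna()))
    if not vals <= {0, 1, 0.0, 1.0, True, False}:
        raise CohortValidationError(
            f"column {name!r} must be binary 0/1; found values {sorted(map(float, vals))}"
        )


def load_cohort(path, spec: OutcomeSpec, sep: str | None = None) -> CohortTable:
    """Read a delimited text file into a :class:`CohortTable`.

    Rows with missing ``z`` or outcome values are dropped and counted
    (listwise deletion, logged); the delimiter is sniffed unless given.
    """
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    for col in (spec.z,) + spec.outcome_columns + spec.covariates:
        if col not in df.columns:
            raise ConfigurationError(f"column {col!r} not found in {path}")
    required = [spec.z, *spec.outcome_columns]
    n0 = len(df)
    df = df.dropna(subset=required)
    n_dropped = n0 - len(df)
    if n_dropped:
        logger.warning(
            "dropped %d of %d rows with missing values in %s", n_dropped, n0, required
        )
    return CohortTable(df, spec, n_dropped=n_dropped)


@dataclass(frozen=True)
class CutpointSet:
    """K strictly increasing cutpoint locations, in the units of z."""

    cuts: tuple[float, ...]

    def __init__(self, cuts: Sequence[float]) -> None:
        cuts = tuple(float(c) for c in cuts)
        if any(b <= a for a, b in zip(cuts, cuts[1:])):
            raise ConfigurationError(f"cutpoints must be strictly increasing: {cuts}")
        object.__setattr__(self, "cuts", cuts)

    @property
    def k(self) -> int:
        return len(self.cuts)

    def __iter__(self):
        return iter(self.cuts)

    def __len__(self) -> int:
        return self.k


@dataclass
class GroupAssignment:
    """Ordinal group per subject plus the K cumulative dummy columns.

    ``group[i] = g`` iff exactly the first g cumulative dummies are 1 for
    subject i (threshold coding: dummy k indicates group >= k).
    """

    group: np.ndarray
    cuts: CutpointSet
    coding: str = "cumulative"

    @property
    def k(self) -> int:
        return self.cuts.k

    @property
    def n_groups(self) -> int:
        return self.k + 1

    @property
    def dummies(self) -> np.ndarray:
        return self.dummy_matrix(self.coding)

    def dummy_matrix(self, coding: str = "cumulative") -> np.ndarray:
        """K indicator columns; 'cumulative' (group >= k) or 'onehot'
        (group == k, group 0 as reference).  The two are linear
        reparameterizations and give identical model fits."""
        k = self.k
        cols = np.arange(1, k + 1)
        if coding == "cumulative":
            return (self.group[:, None] >= cols).astype(float)
        if coding == "onehot":
            return (self.group[:, None] == cols).astype(float)
        raise ConfigurationError(f"unknown dummy coding {coding!r}")

    def counts(self) -> np.ndarray:
        return np.bincount(self.group, minlength=self.n_groups)


def encode_groups(z: Sequence[float], cuts: CutpointSet | Sequence[float]) -> GroupAssignment:
    """Assign each value to its ordinal risk group: group(v) = #{c : v >= c}.

    A value equal to a cutpoint joins the upper group.  Empty ``cuts`` is
    legal and yields a single group (no dummies).
    """
    if not isinstance(cuts, CutpointSet):
        cuts = CutpointSet(cuts)
    z = np.asarray(z, dtype=float)
    group = np.searchsorted(np.asarray(cuts.cuts, dtype=float), z, side="right")
    return GroupAssignment(group=group.astype(np.int64), cuts=cuts)


def split_cohort(
    table: CohortTable, n_train: int, seed: int
) -> tuple[CohortTable, CohortTable]:
    """Seeded simple random split into disjoint train/test cohorts."""
    n = table.n
    if not 0 < n_train < n:
        raise ConfigurationError(f"n_train must be in (0, {n}); got {n_train}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train_idx = table.df.index[np.sort(perm[:n_train])]
    test_idx = table.df.index[np.sort(perm[n_train:])]
    return table.subset(train_idx), table.subset(test_idx)
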