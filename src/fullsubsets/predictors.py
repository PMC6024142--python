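"""Predictor declarations and pairwise-association screening.

Candidate models containing strongly associated predictor pairs are removed
from the model set before fitting.  Association is measured on a common
[0, 1] scale for every pair kind:

* continuous-continuous: absolute Pearson correlation,
* continuous-factor: correlation ratio (square root of the between-level
  share of variance of the continuous variable),
* factor-factor: Cramer's V.

All three reduce to |r| behaviour in the all-continuous case the default
cutoff of 0.28 was calibrated for.  Cyclic variables are screened as
ordinary continuous variables (no circular correlation estimator is used).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PredictorSpec",
    "AssociationMatrix",
    "InclusionMatrix",
    "estimate_associations",
    "build_inclusion_matrix",
]


@dataclass(frozen=True)
class PredictorSpec:
    """A declared predictor.

    Parameters
    ----------
    name : str
        Column name in the data table.
    role : {"continuous", "factor"}
    cyclic : bool
        Continuous only; the variable lives on a circle of circumference
        ``period`` and its smooths use a cyclic basis.
    linear : bool
        Continuous only; the variable enters parametrically (a straight
        slope) instead of as a smooth.
    period : float or None
        Required iff ``cyclic``; in the variable's own units
        (e.g. 29.53 for lunar day, 12 for month).
    levels : tuple of str
        Factor only; the ordered observed levels.
    """

    name: str
    role: str = "continuous"
    cyclic: bool = False
    linear: bool = False
    period: float | None = None
    levels: tuple = field(default_factory=tuple)

    def __post_init__(self):
        if self.role not in ("continuous", "factor"):
            raise ValueError(f"predictor {self.name!r}: unknown role {self.role!r}")
        if self.role == "factor" and (self.cyclic or self.linear):
            raise ValueError(
                f"predictor {self.name!r}: cyclic/linear flags require role='continuous'"
            )
        if self.cyclic and self.linear:
            raise ValueError(
                f"predictor {self.name!r}: cyclic and linear are mutually exclusive"
            )
        if self.cyclic:
            if self.period is None or not self.period > 0:
                raise ValueError(
                    f"cyclic predictor {self.name!r} needs a positive period"
                )
        elif self.period is not None:
            raise ValueError(f"predictor {self.name!r}: period given but not cyclic")

    @property
    def is_factor(self) -> bool:
        return self.role == "factor"


def validate_predictors(predictors: list[PredictorSpec], response: str | None = None):
    """Check name uniqueness and response clash; return the list unchanged."""
    names = [p.name for p in predictors]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise ValueError(f"duplicate predictor names: {sorted(dupes)}")
    if response is not None and response in names:
        raise ValueError(f"response {response!r} also declared as a predictor")
    return predictors


def _as_square_frame(names, values) -> pd.DataFrame:
    return pd.DataFrame(np.asarray(values, dtype=float), index=list(names),
                        columns=list(names))


@dataclass
class AssociationMatrix:
    """Symmetric matrix of pairwise association magnitudes in [0, 1]."""

    names: list
    values: np.ndarray
    method: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        k = len(self.names)
        if self.values.shape != (k, k):
            raise ValueError("association matrix shape does not match names")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("association matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 1.0):
            raise ValueError("association matrix diagonal must be 1")
        if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12:
            raise ValueError("association magnitudes must lie in [0, 1]")
        self.values = np.clip(self.values, 0.0, 1.0)

    def loc(self, a: str, b: str) -> float:
        i, j = self.names.index(a), self.names.index(b)
        return float(self.values[i, j])

    def to_frame(self) -> pd.DataFrame:
        return _as_square_frame(self.names, self.values)


@dataclass
class InclusionMatrix:
    """Boolean co-occurrence matrix: ``allowed[i, j]`` iff predictors i and j
    may appear together in one candidate model."""

    names: list
    allowed: np.ndarray

    def __post_init__(self):
        self.allowed = np.asarray(self.allowed, dtype=bool)
        k = len(self.names)
        if self.allowed.shape != (k, k):
            raise ValueError("inclusion matrix shape does not match names")
        if not (self.allowed == self.allowed.T).all():
            raise ValueError("inclusion matrix must be symmetric")
        np.fill_diagonal(self.allowed, True)

    def pair_allowed(self, a: str, b: str) -> bool:
        if a == b:
            return True
        i, j = self.names.index(a), self.names.index(b)
        return bool(self.allowed[i, j])

    def to_frame(self) -> pd.DataFrame:
        return _as_square_frame(self.names, self.allowed.astype(int))

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "InclusionMatrix":
        if list(frame.index) != list(frame.columns):
            raise ValueError("inclusion matrix CSV must have matching row/column names")
        return cls(names=list(frame.columns), allowed=frame.to_numpy(dtype=bool))


def _pearson_abs(x: np.ndarray, y: np.ndarray) -> float:
    return abs(float(np.corrcoef(x, y)[0, 1]))


def _correlation_ratio(x: np.ndarray, groups: np.ndarray) -> float:
    """sqrt(SS_between / SS_total) of x across the factor levels."""
    grand = x.mean()
    ss_total = float(((x - grand) ** 2).sum())
    if ss_total == 0.0:
        raise ValueError("zero-variance continuous column in correlation ratio")
    ss_between = 0.0
    for g in np.unique(groups):
        xg = x[groups == g]
        ss_between += len(xg) * (xg.mean() - grand) ** 2
    return float(np.sqrt(ss_between / ss_total))


def _cramers_v(a: np.ndarray, b: np.ndarray) -> float:
    table = pd.crosstab(pd.Series(a), pd.Series(b)).to_numpy()
    chi2 = stats.chi2_contingency(table, correction=False)[0]
    n = table.sum()
    r, c = table.shape
    denom = n * (min(r, c) - 1)
    return float(np.sqrt(chi2 / denom))


def estimate_associations(data: pd.DataFrame,
                          predictors: list[PredictorSpec]) -> AssociationMatrix:
    """Estimate the full pairwise association matrix on the (already
    listwise-complete) data.

    Raises
    ------
    ValueError
        For a zero-variance continuous column or a factor with fewer than
        two observed levels.
    """
    validate_predictors(predictors)
    cols = {}
    for p in predictors:
        if p.name not in data.columns:
            raise KeyError(f"predictor column {p.name!r} not found in data")
        col = data[p.name]
        if p.is_factor:
            vals = col.astype(str).to_numpy()
            if len(np.unique(vals)) < 2:
                raise ValueError(
                    f"factor {p.name!r} has fewer than 2 observed levels"
                )
        else:
            vals = col.to_numpy(dtype=float)
            if np.ptp(vals) == 0.0:
                raise ValueError(f"continuous column {p.name!r} is constant")
        cols[p.name] = vals

    k = len(predictors)
    values = np.eye(k)
    method = {}
    for i in range(k):
        for j in range(i + 1, k):
            pi, pj = predictors[i], predictors[j]
            if not pi.is_factor and not pj.is_factor:
                v = _pearson_abs(cols[pi.name], cols[pj.name])
                m = "pearson"
            elif pi.is_factor and pj.is_factor:
                v = _cramers_v(cols[pi.name], cols[pj.name])
                m = "cramers_v"
            else:
                fac, cont = (pi, pj) if pi.is_factor else (pj, pi)
                v = _correlation_ratio(cols[cont.name], cols[fac.name])
                m = "correlation_ratio"
            values[i, j] = values[j, i] = min(v, 1.0)
            method[(pi.name, pj.name)] = m
    return AssociationMatrix(names=[p.name for p in predictors], values=values,
                             method=method)


def build_inclusion_matrix(assoc: AssociationMatrix,
                           cutoff: float = 0.28) -> InclusionMatrix:
    """Derive the binary co-occurrence matrix from association magnitudes.

    A pair is *excluded* when its association is strictly greater than
    ``cutoff``; a value exactly equal to the cutoff is kept.
    """
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError(f"cutoff must lie in [0, 1], got {cutoff}")
    allowed = assoc.values <= cutoff
    np.fill_diagonal(allowed, True)
    return InclusionMatrix(names=list(assoc.names), allowed=allowed)
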