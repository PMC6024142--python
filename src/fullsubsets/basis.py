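"""Penalized spline bases and design-matrix assembly.

Smooths are represented by B-spline bases with difference penalties
(P-splines):

* cubic regression margins ("cr"): degree-3 B-splines with interior knots
  at quantiles of the training data and a second-order difference penalty;
* cyclic margins ("cc"): periodic B-splines on [0, period] built by
  wrapping an extended knot sequence, with a circular second-order
  difference penalty — the basis is exactly periodic, so fitted curves
  satisfy f(0) = f(period) by construction;
* tensor smooths: row-wise Kronecker products of two marginal bases with
  one penalty per margin (kron(S1, I) and kron(I, S2));
* by-variable smooths: a centred marginal basis replicated per level of
  the by-factor (or factor-interaction), sharing one smoothing parameter
  across levels.

Identifiability: every smooth block is centred (sum-to-zero over the
training rows) by projecting onto the null space of its column-mean
vector, so intercept and factor main effects remain estimable alongside
smooths and by-smooths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.interpolate import BSpline

from .candidates import TermSpec
from .formula import FitSpec, SmoothConfig

__all__ = ["Design", "build_design", "DegenerateDataError"]


class DegenerateDataError(ValueError):
    """Raised when the data cannot support the requested design
    (single-level factor, constant smooth margin, ...)."""


def _difference_penalty(k: int, order: int = 2) -> np.ndarray:
    d = np.diff(np.eye(k), n=order, axis=0)
    return d.T @ d


def _circular_difference_penalty(k: int) -> np.ndarray:
    rows = []
    for i in range(k):
        r = np.zeros(k)
        r[(i - 1) % k] += 1.0
        r[i] += -2.0
        r[(i + 1) % k] += 1.0
        rows.append(r)
    d = np.array(rows)
    return d.T @ d


@dataclass
class _Marginal:
    """One smooth margin: knots, degree, wrapping and evaluation range."""

    knots: np.ndarray
    degree: int
    wrap: int = 0          # >0 for cyclic: number of columns folded back
    period: float | None = None
    lo: float = 0.0
    hi: float = 1.0

    @property
    def ncol(self) -> int:
        n_raw = len(self.knots) - self.degree - 1
        return n_raw - self.wrap

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.period is not None:
            x = np.mod(x, self.period)
        x = np.clip(x, self.lo, self.hi)
        b = BSpline.design_matrix(x, self.knots, self.degree).toarray()
        if self.wrap:
            k = self.ncol
            b[:, :self.wrap] += b[:, k:k + self.wrap]
            b = b[:, :k]
        return b

    def penalty(self) -> np.ndarray:
        if self.wrap:
            return _circular_difference_penalty(self.ncol)
        return _difference_penalty(self.ncol)


def _cr_marginal(x: np.ndarray, k: int) -> _Marginal:
    ux = np.unique(x)
    if ux.size < 2:
        raise DegenerateDataError("constant column in smooth margin")
    degree = 3 if k >= 4 else 2
    n_interior = k - (degree + 1)
    lo, hi = float(ux[0]), float(ux[-1])
    if n_interior > 0:
        probs = np.arange(1, n_interior + 1) / (n_interior + 1)
        interior = np.quantile(ux, probs)
    else:
        interior = np.array([])
    interior = np.unique(interior[(interior > lo) & (interior < hi)])
    knots = np.concatenate([np.full(degree + 1, lo), interior,
                            np.full(degree + 1, hi)])
    return _Marginal(knots=knots, degree=degree, lo=lo, hi=hi)


def _cc_marginal(period: float, k: int) -> _Marginal:
    degree = 3 if k >= 4 else 2
    base = np.linspace(0.0, period, k + 1)
    left = base[-(degree + 1):-1] - period
    right = base[1:degree + 1] + period
    knots = np.concatenate([left, base, right])
    return _Marginal(knots=knots, degree=degree, wrap=degree, period=period,
                     lo=knots[degree], hi=knots[-degree - 1])


def _marginal_for(x: np.ndarray, cfg: SmoothConfig) -> _Marginal:
    if cfg.basis == "cyclic_cubic":
        return _cc_marginal(cfg.period, cfg.k)
    return _cr_marginal(x, cfg.k)


def _centering_projection(cols: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the null space of the column-mean vector."""
    c = cols.mean(axis=0, keepdims=True)
    z = linalg.null_space(c)
    if z.shape[1] != cols.shape[1] - 1:  # pragma: no cover - defensive
        raise DegenerateDataError("centering constraint is degenerate")
    return z


def _dummies(values: np.ndarray, levels: tuple, name: str) -> np.ndarray:
    """Treatment (drop-first) coding against declared levels."""
    return np.column_stack([(values == l).astype(float) for l in levels[1:]])


# --------------------------------------------------------------------------
# column blocks

@dataclass
class _Block:
    term_label: str
    penalties: list = field(default_factory=list)  # block-local penalty mats

    def transform(self, data: pd.DataFrame) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


@dataclass
class _InterceptBlock(_Block):
    def transform(self, data):
        return np.ones((len(data), 1))


@dataclass
class _LinearBlock(_Block):
    var: str = ""

    def transform(self, data):
        return data[self.var].to_numpy(dtype=float)[:, None]


@dataclass
class _FactorBlock(_Block):
    factors: tuple = ()
    levels: dict = field(default_factory=dict)

    def transform(self, data):
        mats = [_dummies(data[f].astype(str).to_numpy(), self.levels[f], f)
                for f in self.factors]
        out = mats[0]
        for m in mats[1:]:  # interaction: all products of drop-first dummies
            out = np.einsum("ij,ik->ijk", out, m).reshape(len(out), -1)
        return out


@dataclass
class _SmoothBlock(_Block):
    var: str = ""
    marginal: _Marginal | None = None
    z: np.ndarray | None = None

    def transform(self, data):
        return self.marginal.evaluate(data[self.var].to_numpy(dtype=float)) @ self.z


@dataclass
class _BySmoothBlock(_Block):
    var: str = ""
    marginal: _Marginal | None = None
    z: np.ndarray | None = None
    by_factors: tuple = ()
    by_levels: tuple = ()  # tuple of level-combination tuples

    def _indicators(self, data):
        cols = [data[f].astype(str).to_numpy() for f in self.by_factors]
        return [np.all([c == l for c, l in zip(cols, combo)], axis=0)
                for combo in self.by_levels]

    def transform(self, data):
        base = self.marginal.evaluate(data[self.var].to_numpy(dtype=float)) @ self.z
        return np.column_stack([base * ind[:, None].astype(float)
                                for ind in self._indicators(data)])


@dataclass
class _TensorBlock(_Block):
    vars: tuple = ()
    marginals: tuple = ()
    z: np.ndarray | None = None

    def transform(self, data):
        b1 = self.marginals[0].evaluate(data[self.vars[0]].to_numpy(dtype=float))
        b2 = self.marginals[1].evaluate(data[self.vars[1]].to_numpy(dtype=float))
        raw = np.einsum("ij,ik->ijk", b1, b2).reshape(len(b1), -1)
        return raw @ self.z


# --------------------------------------------------------------------------

@dataclass
class Design:
    """Assembled design: blocks, full design matrix on the training data,
    and full-size embedded penalty matrices (one smoothing parameter each).
    """

    blocks: list
    X: np.ndarray
    penalties: list          # list of (p, p) matrices
    col_slices: list         # per-block slice into X

    @property
    def ncol(self) -> int:
        return self.X.shape[1]

    def matrix(self, data: pd.DataFrame) -> np.ndarray:
        """Design matrix for new data (same blocks/knots/constraints)."""
        return np.column_stack([b.transform(data) for b in self.blocks])


def _build_block(term: TermSpec, spec: FitSpec, data: pd.DataFrame) -> _Block:
    label = term.canonical()
    if term.kind == "linear":
        return _LinearBlock(term_label=label, var=term.vars[0])
    if term.kind in ("factor_main", "factor_interaction"):
        levels = {f: spec.factor_levels[f] for f in term.factors}
        return _FactorBlock(term_label=label, factors=term.factors, levels=levels)
    if term.kind == "smooth":
        x = data[term.vars[0]].to_numpy(dtype=float)
        marg = _marginal_for(x, spec.config_for(term.vars[0]))
        raw = marg.evaluate(x)
        z = _centering_projection(raw)
        s = z.T @ marg.penalty() @ z
        return _SmoothBlock(term_label=label, var=term.vars[0], marginal=marg,
                            z=z, penalties=[s])
    if term.kind == "by_smooth":
        x = data[term.vars[0]].to_numpy(dtype=float)
        marg = _marginal_for(x, spec.config_for(term.vars[0]))
        raw = marg.evaluate(x)
        z = _centering_projection(raw)
        s = z.T @ marg.penalty() @ z
        bf = term.by_factor
        level_lists = [spec.factor_levels[f] for f in bf.factors]
        combos = [(l,) for l in level_lists[0]]
        if len(level_lists) == 2:
            combos = [(a, b) for a in level_lists[0] for b in level_lists[1]]
        block = _BySmoothBlock(term_label=label, var=term.vars[0], marginal=marg,
                               z=z, by_factors=bf.factors, by_levels=tuple(combos))
        # shared smoothing parameter: one block-diagonal penalty over levels
        block.penalties = [linalg.block_diag(*([s] * len(combos)))]
        return block
    if term.kind == "tensor_smooth":
        margs, raws = [], []
        for v in term.vars:
            x = data[v].to_numpy(dtype=float)
            m = _marginal_for(x, spec.config_for(v))
            margs.append(m)
            raws.append(m.evaluate(x))
        raw = np.einsum("ij,ik->ijk", raws[0], raws[1]).reshape(len(data), -1)
        z = _centering_projection(raw)
        k1, k2 = margs[0].ncol, margs[1].ncol
        s1 = z.T @ np.kron(margs[0].penalty(), np.eye(k2)) @ z
        s2 = z.T @ np.kron(np.eye(k1), margs[1].penalty()) @ z
        return _TensorBlock(term_label=label, vars=term.vars,
                            marginals=tuple(margs), z=z, penalties=[s1, s2])
    raise ValueError(f"unknown term kind {term.kind!r}")  # pragma: no cover


def build_design(spec: FitSpec, data: pd.DataFrame) -> Design:
    """Assemble the full design for one FitSpec on the (listwise-complete)
    training data.  Raises :class:`DegenerateDataError` for data that
    cannot support the design."""
    for f in spec.factor_levels:
        if f in data.columns:
            if data[f].astype(str).nunique() < 2:
                raise DegenerateDataError(
                    f"factor {f!r} has fewer than 2 observed levels in the "
                    f"used data")
    blocks: list[_Block] = [_InterceptBlock(term_label="(Intercept)")]
    for term in spec.all_terms:
        blocks.append(_build_block(term, spec, data))

    mats, slices, penalties = [], [], []
    start = 0
    for b in blocks:
        m = b.transform(data)
        mats.append(m)
        stop = start + m.shape[1]
        slices.append(slice(start, stop))
        start = stop
    p = start
    X = np.column_stack(mats)
    for b, sl in zip(blocks, slices):
        for s in b.penalties:
            full = np.zeros((p, p))
            full[sl, sl] = s
            penalties.append(full)
    return Design(blocks=blocks, X=X, penalties=penalties, col_slices=slices)
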