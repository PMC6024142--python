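"""Fit specifications and the canonical formula dialect.

Each surviving candidate model is turned into a :class:`FitSpec`, a
backend-neutral description of the fit: which continuous margins are
smoothed with which basis (cubic regression spline by default, cyclic
cubic on a declared period for cyclic variables), which enter
parametrically, and the fixed null terms shared by every model.

``render_formula_string`` emits a deterministic mgcv-dialect string per
model (an interoperability aid, e.g. ``y ~ s(x1, k=5, bs="cr") + fA``);
``parse_formula_string`` reads that same canonical dialect back.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .candidates import ModelSpec, TermSpec
from .predictors import PredictorSpec

__all__ = ["SmoothConfig", "FitSpec", "build_fit_spec",
           "render_formula_string", "parse_formula_string"]

FAMILIES = ("gaussian", "binomial", "poisson")


@dataclass(frozen=True)
class SmoothConfig:
    """Basis choice for one smooth margin.

    k is the basis dimension before the sum-to-zero identifiability
    constraint; cyclic margins carry their declared period and pin their
    knots to [0, period].
    """

    basis: str = "cubic_regression"
    k: int = 5
    period: float | None = None

    def __post_init__(self):
        if self.basis not in ("cubic_regression", "cyclic_cubic"):
            raise ValueError(f"unknown basis {self.basis!r}")
        if self.k < 3:
            raise ValueError(f"basis dimension k must be >= 3, got {self.k}")
        if self.basis == "cyclic_cubic" and (self.period is None or self.period <= 0):
            raise ValueError("cyclic_cubic basis needs a positive period")

    @property
    def bs(self) -> str:
        return "cc" if self.basis == "cyclic_cubic" else "cr"


@dataclass(frozen=True)
class FitSpec:
    """Everything a backend needs to fit one candidate model."""

    model: ModelSpec
    response: str
    family: str = "gaussian"
    smooth_configs: dict = field(default_factory=dict)  # cont var -> SmoothConfig
    factor_levels: dict = field(default_factory=dict)   # factor -> tuple of levels
    random_terms: tuple = ()

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unsupported family {self.family!r}")

    @property
    def all_terms(self) -> tuple:
        """Candidate terms plus the fixed null terms, in render order."""
        return tuple(self.model.terms) + tuple(self.model.null_terms)

    def config_for(self, var: str) -> SmoothConfig:
        return self.smooth_configs[var]


def build_fit_spec(model: ModelSpec, predictors: list[PredictorSpec],
                   response: str, family: str = "gaussian", k: int = 5,
                   random_terms: tuple = ()) -> FitSpec:
    """Resolve basis choices for one candidate model.

    Smooth margins get a cubic regression basis of dimension ``k``
    (default 5); predictors declared cyclic get a cyclic cubic basis with
    their period, including inside by-smooths and tensor margins;
    predictors declared linear stay parametric and never receive a basis.
    """
    if k < 3:
        raise ValueError(f"basis dimension k must be >= 3, got {k}")
    by_name = {p.name: p for p in predictors}
    smooth_configs = {}
    factor_levels = {}
    for term in tuple(model.terms) + tuple(model.null_terms):
        for v in term.vars:
            p = by_name[v]
            if term.kind == "linear":
                continue
            if p.cyclic:
                smooth_configs[v] = SmoothConfig("cyclic_cubic", k=k,
                                                 period=p.period)
            else:
                smooth_configs[v] = SmoothConfig("cubic_regression", k=k)
        for f in term.footprint():
            p = by_name.get(f)
            if p is not None and p.is_factor:
                factor_levels[f] = tuple(p.levels)
    return FitSpec(model=model, response=response, family=family,
                   smooth_configs=smooth_configs, factor_levels=factor_levels,
                   random_terms=tuple(random_terms))


def _render_term(term: TermSpec, spec: FitSpec) -> str:
    if term.kind == "smooth":
        cfg = spec.config_for(term.vars[0])
        return f's({term.vars[0]}, k={cfg.k}, bs="{cfg.bs}")'
    if term.kind == "by_smooth":
        cfg = spec.config_for(term.vars[0])
        return (f's({term.vars[0]}, k={cfg.k}, bs="{cfg.bs}", '
                f'by={term.by_factor.canonical()})')
    if term.kind == "tensor_smooth":
        c1, c2 = (spec.config_for(v) for v in term.vars)
        return (f'te({term.vars[0]}, {term.vars[1]}, k=c({c1.k},{c2.k}), '
                f'bs=c("{c1.bs}","{c2.bs}"))')
    if term.kind == "linear":
        return term.vars[0]
    return term.canonical()  # factor_main / factor_interaction


def render_formula_string(spec: FitSpec) -> str:
    """Canonical, deterministic formula string for one FitSpec."""
    parts = [_render_term(t, spec) for t in spec.all_terms]
    rhs = " + ".join(parts) if parts else "1"
    return f"{spec.response} ~ {rhs}"


_S_RE = re.compile(
    r's\((?P<var>\w+), k=(?P<k>\d+), bs="(?P<bs>cr|cc)"'
    r'(?:, by=(?P<by>\w+(?::\w+)?))?\)$')
_TE_RE = re.compile(
    r'te\((?P<v1>\w+), (?P<v2>\w+), k=c\((?P<k1>\d+),(?P<k2>\d+)\), '
    r'bs=c\("(?P<b1>cr|cc)","(?P<b2>cr|cc)"\)\)$')


def _parse_by(by: str) -> TermSpec:
    if ":" in by:
        return TermSpec(kind="factor_interaction", factors=tuple(by.split(":")))
    return TermSpec(kind="factor_main", factors=(by,))


def parse_formula_string(formula: str,
                         predictors: list[PredictorSpec] | None = None,
                         ) -> tuple[str, list[TermSpec]]:
    """Parse a string in our own canonical dialect back to (response, terms).

    Only the exact output of :func:`render_formula_string` is accepted;
    this exists for round-trip validation, not for general formula input.
    Basis/k annotations are parsed and discarded (they are carried by the
    FitSpec, not the TermSpec).  Bare tokens are ambiguous between a
    linear continuous term and a factor main effect; pass ``predictors``
    to resolve them, else a factor main is assumed.
    """
    linear_names = set()
    if predictors is not None:
        linear_names = {p.name for p in predictors if not p.is_factor}
    lhs, _, rhs = formula.partition("~")
    response = lhs.strip()
    rhs = rhs.strip()
    terms: list[TermSpec] = []
    if rhs == "1":
        return response, terms
    for tok in rhs.split(" + "):
        m = _S_RE.match(tok)
        if m:
            if m.group("by"):
                terms.append(TermSpec(kind="by_smooth", vars=(m.group("var"),),
                                      by_factor=_parse_by(m.group("by"))))
            else:
                terms.append(TermSpec(kind="smooth", vars=(m.group("var"),)))
            continue
        m = _TE_RE.match(tok)
        if m:
            terms.append(TermSpec(kind="tensor_smooth",
                                  vars=(m.group("v1"), m.group("v2"))))
            continue
        if ":" in tok:
            terms.append(TermSpec(kind="factor_interaction",
                                  factors=tuple(tok.split(":"))))
        elif re.fullmatch(r"\w+", tok):
            if tok in linear_names:
                terms.append(TermSpec(kind="linear", vars=(tok,)))
            else:
                terms.append(TermSpec(kind="factor_main", factors=(tok,)))
        else:
            raise ValueError(f"cannot parse term {tok!r}")
    return response, terms
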