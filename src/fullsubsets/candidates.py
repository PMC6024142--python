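"""Candidate model-set construction.

The model set is built bottom-up: a term vocabulary is derived from the
declared predictors and the three interaction switches, every combination
of 1 .. max_predictors terms is enumerated, and the result is pruned by
five validity checks:

1. the model's predictor footprint exceeds the maximum number of
   predictors (possible once interaction terms are in the vocabulary);
2. a by-variable smooth appears without its factor as a main effect (for a
   factor-interaction by-variable, the interaction term and both marginal
   factor mains are required);
3. a continuous predictor appears both inside a by-variable smooth and as
   a single smooth/linear term;
4. a continuous predictor appears both inside a bivariate tensor smooth
   and as a single smooth/linear term;
5. two predictors of the footprint form a pair disallowed by the
   inclusion (collinearity) matrix.

Every removed model is logged with the lowest-numbered check that caught
it.  The null model (null terms only, or intercept only) always survives.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .predictors import InclusionMatrix, PredictorSpec

__all__ = [
    "TermSpec",
    "ModelSpec",
    "CandidateSet",
    "TermOptions",
    "enumerate_terms",
    "enumerate_models",
    "apply_checks",
]

_KINDS = ("smooth", "linear", "factor_main", "factor_interaction",
          "by_smooth", "tensor_smooth")


@dataclass(frozen=True)
class TermSpec:
    """One model term.

    ``vars`` holds the continuous predictor names (1 for smooth/linear/
    by_smooth, 2 for tensor_smooth); ``factors`` the factor names
    (factor_main: 1, factor_interaction: 2); ``by_factor`` is the factor
    term modulating a by_smooth (a factor_main or factor_interaction
    TermSpec).
    """

    kind: str
    vars: tuple = ()
    factors: tuple = ()
    by_factor: "TermSpec | None" = None

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown term kind {self.kind!r}")
        object.__setattr__(self, "vars", tuple(self.vars))
        object.__setattr__(self, "factors", tuple(sorted(self.factors)))
        if self.kind in ("smooth", "linear") and len(self.vars) != 1:
            raise ValueError(f"{self.kind} term needs exactly 1 continuous var")
        if self.kind == "tensor_smooth":
            if len(self.vars) != 2 or self.vars[0] == self.vars[1]:
                raise ValueError("tensor_smooth needs 2 distinct continuous vars")
            object.__setattr__(self, "vars", tuple(sorted(self.vars)))
        if self.kind == "by_smooth":
            if len(self.vars) != 1 or self.by_factor is None:
                raise ValueError("by_smooth needs 1 continuous var and a by_factor")
            if self.by_factor.kind not in ("factor_main", "factor_interaction"):
                raise ValueError("by_factor must be a factor main or interaction term")
        if self.kind == "factor_main" and len(self.factors) != 1:
            raise ValueError("factor_main needs exactly 1 factor")
        if self.kind == "factor_interaction" and len(self.factors) != 2:
            raise ValueError("factor_interaction needs exactly 2 distinct factors")

    def canonical(self) -> str:
        if self.kind == "smooth":
            return f"s({self.vars[0]})"
        if self.kind == "linear":
            return f"lin({self.vars[0]})"
        if self.kind == "factor_main":
            return self.factors[0]
        if self.kind == "factor_interaction":
            return ":".join(self.factors)
        if self.kind == "by_smooth":
            return f"s({self.vars[0]},by={self.by_factor.canonical()})"
        return f"te({self.vars[0]},{self.vars[1]})"

    def footprint(self) -> frozenset:
        """All predictor names the term touches."""
        names = set(self.vars) | set(self.factors)
        if self.by_factor is not None:
            names |= self.by_factor.footprint()
        return frozenset(names)

    def __str__(self):  # pragma: no cover - convenience
        return self.canonical()


@dataclass(frozen=True)
class ModelSpec:
    """An ordered set of candidate terms plus the shared null terms."""

    terms: tuple
    null_terms: tuple = ()

    def __post_init__(self):
        ordered = tuple(sorted(self.terms, key=lambda t: t.canonical()))
        canons = [t.canonical() for t in ordered]
        if len(set(canons)) != len(canons):
            raise ValueError("duplicate terms in one model")
        object.__setattr__(self, "terms", ordered)
        object.__setattr__(self, "null_terms", tuple(self.null_terms))

    @property
    def id(self) -> str:
        if not self.terms:
            return "null"
        return "+".join(t.canonical() for t in self.terms)

    @property
    def is_null(self) -> bool:
        return not self.terms

    def footprint(self) -> frozenset:
        """Union of term footprints, excluding null terms."""
        out = set()
        for t in self.terms:
            out |= t.footprint()
        return frozenset(out)


@dataclass
class CandidateSet:
    """Surviving models (null model first) and the removal log."""

    models: list
    removed: list = field(default_factory=list)

    @property
    def ids(self) -> list:
        return [m.id for m in self.models]

    def __len__(self):
        return len(self.models)


@dataclass
class TermOptions:
    """Interaction switches and restriction lists for the term vocabulary.

    Restriction lists default to None (everything eligible allowed); an
    empty list allows nothing of that kind even when the switch is on.
    """

    factor_factor_interactions: bool = False
    factor_smooth_interactions: bool = False
    smooth_smooth_interactions: bool = False
    factor_interaction_restrict: list | None = None
    by_factor_restrict: list | None = None
    tensor_restrict: list | None = None


def _check_restrict(names, known, what):
    if names is None:
        return None
    unknown = [n for n in names if n not in known]
    if unknown:
        raise ValueError(f"{what} restriction names unknown predictors: {unknown}")
    return list(names)


def enumerate_terms(predictors: list[PredictorSpec],
                    options: TermOptions | None = None) -> list[TermSpec]:
    """Build the term vocabulary the model set is enumerated from.

    One smooth (or linear) term per continuous predictor and one main
    effect per factor are always present; the three switches add factor
    interactions, by-variable smooths (of factor mains and, when factor
    interactions are also enabled, of factor-interaction terms) and
    bivariate tensor smooths.
    """
    options = options or TermOptions()
    cont = [p for p in predictors if not p.is_factor]
    facts = [p for p in predictors if p.is_factor]
    fact_names = [p.name for p in facts]
    smooth_names = [p.name for p in cont if not p.linear]

    fi_allowed = _check_restrict(options.factor_interaction_restrict, fact_names,
                                 "factor-interaction")
    by_allowed = _check_restrict(options.by_factor_restrict, fact_names, "by-factor")
    te_allowed = _check_restrict(options.tensor_restrict, smooth_names,
                                 "smooth-interaction")

    terms: list[TermSpec] = []
    for p in cont:
        kind = "linear" if p.linear else "smooth"
        terms.append(TermSpec(kind=kind, vars=(p.name,)))
    for p in facts:
        terms.append(TermSpec(kind="factor_main", factors=(p.name,)))

    fact_inter: list[TermSpec] = []
    if options.factor_factor_interactions:
        eligible = fact_names if fi_allowed is None else fi_allowed
        for a, b in itertools.combinations(sorted(eligible), 2):
            fact_inter.append(TermSpec(kind="factor_interaction", factors=(a, b)))
        terms.extend(fact_inter)

    if options.factor_smooth_interactions:
        by_terms = [TermSpec(kind="factor_main", factors=(f,))
                    for f in (fact_names if by_allowed is None else by_allowed)]
        by_terms += fact_inter
        for v in smooth_names:
            for bt in by_terms:
                terms.append(TermSpec(kind="by_smooth", vars=(v,), by_factor=bt))

    if options.smooth_smooth_interactions:
        eligible = smooth_names if te_allowed is None else te_allowed
        for a, b in itertools.combinations(sorted(eligible), 2):
            terms.append(TermSpec(kind="tensor_smooth", vars=(a, b)))

    return terms


def enumerate_models(terms: list[TermSpec], max_predictors: int = 3,
                     null_terms: tuple = ()) -> list[ModelSpec]:
    """All 1 .. max_predictors combinations of terms, plus the null model.

    Combination size counts *terms*; the predictor footprint is bounded
    later by check 1.
    """
    if max_predictors < 1:
        raise ValueError("max_predictors must be >= 1")
    if not terms:
        raise ValueError("empty term vocabulary")
    ordered = sorted(terms, key=lambda t: t.canonical())
    models = [ModelSpec(terms=(), null_terms=null_terms)]
    for m in range(1, max_predictors + 1):
        for combo in itertools.combinations(ordered, m):
            models.append(ModelSpec(terms=combo, null_terms=null_terms))
    return models


def _violates(model: ModelSpec, inclusion: InclusionMatrix | None,
              max_predictors: int) -> tuple[int, str] | None:
    """Return (check number, reason) for the lowest-numbered failing check."""
    if model.is_null:
        return None
    foot = model.footprint()

    if len(foot) > max_predictors:
        return 1, (f"footprint {sorted(foot)} has {len(foot)} predictors "
                   f"(max {max_predictors})")

    canons = {t.canonical() for t in model.terms}
    for t in model.terms:
        if t.kind != "by_smooth":
            continue
        bf = t.by_factor
        required = [bf.canonical()]
        if bf.kind == "factor_interaction":
            required += list(bf.factors)
        missing = [r for r in required if r not in canons]
        if missing:
            return 2, (f"by-smooth {t.canonical()} lacks main effect(s) "
                       f"{missing}")

    by_vars = {t.vars[0] for t in model.terms if t.kind == "by_smooth"}
    single_vars = {t.vars[0] for t in model.terms if t.kind in ("smooth", "linear")}
    clash = by_vars & single_vars
    if clash:
        return 3, (f"continuous predictor(s) {sorted(clash)} occur in a "
                   f"by-smooth and as a single term")

    te_vars = set()
    for t in model.terms:
        if t.kind == "tensor_smooth":
            te_vars |= set(t.vars)
    clash = te_vars & single_vars
    if clash:
        return 4, (f"continuous predictor(s) {sorted(clash)} occur in a "
                   f"tensor smooth and as a single term")

    if inclusion is not None:
        for a, b in itertools.combinations(sorted(foot), 2):
            if a in inclusion.names and b in inclusion.names:
                if not inclusion.pair_allowed(a, b):
                    return 5, f"predictors {a!r} and {b!r} are too correlated"
    return None


def apply_checks(models: list[ModelSpec], inclusion: InclusionMatrix | None,
                 max_predictors: int = 3) -> CandidateSet:
    """Prune the enumerated models with checks 1-5 (see module docstring).

    Order-independent: the surviving set and log depend only on the set of
    model ids, and each removed model carries exactly the lowest-numbered
    check that caught it.
    """
    seen = set()
    kept, removed = [], []
    for model in sorted(models, key=lambda m: (len(m.terms), m.id)):
        if model.id in seen:
            continue
        seen.add(model.id)
        verdict = _violates(model, inclusion, max_predictors)
        if verdict is None:
            kept.append(model)
        else:
            removed.append((model.id, verdict[0], verdict[1]))
    # null model first, then by size/id (already the sort order)
    return CandidateSet(models=kept, removed=removed)
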