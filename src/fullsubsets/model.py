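"""The user-facing modelling objects.

:class:`FullSubsetsGAM` is built from a data table plus predictor
declarations; construction performs listwise deletion, association
screening, and candidate-set enumeration/pruning, so the candidate set
can be inspected before any model is fitted.  :meth:`FullSubsetsGAM.fit`
fits every candidate through the backend and returns a
:class:`FullSubsetsResults` carrying the comparison table, Akaike-weight
variable importance, failure diagnostics and a text ``summary()``.

Example
-------
>>> from fullsubsets import FullSubsetsGAM
>>> from fullsubsets.synthetic import scenario_library, generate
>>> cfg = scenario_library()["one_active"]
>>> gam = FullSubsetsGAM.from_scenario(cfg, generate(cfg))
>>> res = gam.fit()
>>> print(res.summary())                         # doctest: +SKIP
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import inference
from .backend import FitRecord, PenalizedSplineBackend, fit_all
from .candidates import (CandidateSet, ModelSpec, TermOptions, TermSpec,
                         apply_checks, enumerate_models, enumerate_terms)
from .formula import FitSpec, build_fit_spec, render_formula_string
from .predictors import (AssociationMatrix, InclusionMatrix, PredictorSpec,
                         build_inclusion_matrix, estimate_associations,
                         validate_predictors)

__all__ = ["FullSubsetsGAM", "FullSubsetsResults"]

log = logging.getLogger("fullsubsets")


def _default_term(p: PredictorSpec) -> TermSpec:
    if p.is_factor:
        return TermSpec(kind="factor_main", factors=(p.name,))
    kind = "linear" if p.linear else "smooth"
    return TermSpec(kind=kind, vars=(p.name,))


class FullSubsetsGAM:
    """Full-subsets multiple regression over generalized additive models.

    Parameters
    ----------
    data : DataFrame
        The raw data table; rows with missing values in the response or
        any declared predictor are dropped (and counted) up front so all
        candidate models share one row set.
    response : str
    continuous, factors : sequence of str
        Predictor roles.  ``cyclic`` maps a continuous name to its period;
        names in ``linear`` enter parametrically instead of as smooths.
    null_terms : sequence of str
        Predictor names forced into every model (their default term);
        they are excluded from the candidate vocabulary and from
        footprints.
    inclusion_matrix : DataFrame, optional
        User-supplied square 0/1 co-occurrence matrix overriding the
        cutoff-derived one.
    """

    def __init__(self, data: pd.DataFrame, response: str,
                 continuous=(), factors=(), cyclic: dict | None = None,
                 linear=(), family: str = "gaussian", null_terms=(),
                 max_predictors: int = 3, cor_cutoff: float = 0.28,
                 k: int = 5,
                 factor_factor_interactions: bool = False,
                 factor_smooth_interactions: bool = False,
                 smooth_smooth_interactions: bool = False,
                 factor_interaction_restrict=None,
                 by_factor_restrict=None, tensor_restrict=None,
                 inclusion_matrix: pd.DataFrame | None = None,
                 r2_type: str = "deviance",
                 importance_criterion: str = "AICc",
                 backend=None):
        cyclic = dict(cyclic or {})
        continuous, factors = list(continuous), list(factors)
        linear, null_terms = list(linear), list(null_terms)
        if response not in data.columns:
            raise KeyError(f"response column {response!r} not in data")
        unknown = [c for c in continuous + factors if c not in data.columns]
        if unknown:
            raise KeyError(f"predictor column(s) not in data: {unknown}")
        bad_cyc = sorted(set(cyclic) - set(continuous))
        if bad_cyc:
            raise ValueError(f"cyclic variable(s) not declared continuous: "
                             f"{bad_cyc}")
        bad_lin = sorted(set(linear) - set(continuous))
        if bad_lin:
            raise ValueError(f"linear variable(s) not declared continuous: "
                             f"{bad_lin}")
        bad_null = sorted(set(null_terms) - set(continuous) - set(factors))
        if bad_null:
            raise ValueError(f"null term(s) not declared predictors: {bad_null}")
        if r2_type not in ("deviance", "cor"):
            raise ValueError(f"unknown r2_type {r2_type!r}")

        used_cols = [response] + continuous + factors
        n_before = len(data)
        used = data[used_cols].dropna().reset_index(drop=True)
        self.n_dropped = n_before - len(used)
        if self.n_dropped:
            log.info("listwise deletion removed %d of %d rows",
                     self.n_dropped, n_before)
        if used.empty:
            raise ValueError("no complete rows after listwise deletion")
        self.data = used
        self.response = response
        self.family = family
        self.k = k
        self.r2_type = r2_type
        self.importance_criterion = importance_criterion
        self.max_predictors = max_predictors
        self.cor_cutoff = cor_cutoff
        self._backend = backend or PenalizedSplineBackend()

        specs = []
        for name in continuous:
            specs.append(PredictorSpec(
                name=name, role="continuous", cyclic=name in cyclic,
                linear=name in linear, period=cyclic.get(name)))
        for name in factors:
            levels = tuple(sorted(used[name].astype(str).unique()))
            if len(levels) < 2:
                raise ValueError(f"factor {name!r} has fewer than 2 observed "
                                 f"levels in the used data")
            specs.append(PredictorSpec(name=name, role="factor", levels=levels))
        self.predictors = validate_predictors(specs, response=response)
        self._by_name = {p.name: p for p in self.predictors}

        self.associations: AssociationMatrix = estimate_associations(
            used, self.predictors)
        if inclusion_matrix is not None:
            self.inclusion = InclusionMatrix.from_frame(inclusion_matrix)
        else:
            self.inclusion = build_inclusion_matrix(self.associations,
                                                    cor_cutoff)

        null_term_specs = tuple(_default_term(self._by_name[n])
                                for n in null_terms)
        vocab_predictors = [p for p in self.predictors
                            if p.name not in null_terms]
        options = TermOptions(
            factor_factor_interactions=factor_factor_interactions,
            factor_smooth_interactions=factor_smooth_interactions,
            smooth_smooth_interactions=smooth_smooth_interactions,
            factor_interaction_restrict=factor_interaction_restrict,
            by_factor_restrict=by_factor_restrict,
            tensor_restrict=tensor_restrict)
        self.terms = enumerate_terms(vocab_predictors, options)
        enumerated = enumerate_models(self.terms, max_predictors,
                                      null_terms=null_term_specs)
        self.candidate_set: CandidateSet = apply_checks(
            enumerated, self.inclusion, max_predictors)
        log.info("terms: %d; models enumerated: %d; surviving: %d; removed: %d",
                 len(self.terms), len(enumerated), len(self.candidate_set),
                 len(self.candidate_set.removed))

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_config(cls, config, data: pd.DataFrame | None = None,
                    **overrides) -> "FullSubsetsGAM":
        """Build from a :class:`fullsubsets.config.RunConfig`."""
        from .config import read_table
        if data is None:
            data = read_table(config.data, continuous=config.continuous)
        kw = config.model_kwargs()
        kw.update(overrides)
        return cls(data, **kw)

    @classmethod
    def from_scenario(cls, scenario, data: pd.DataFrame,
                      **overrides) -> "FullSubsetsGAM":
        """Build from a synthetic :class:`ScenarioConfig` and a table drawn
        from it."""
        kw = dict(
            response=scenario.response, family=scenario.family,
            continuous=scenario.continuous_names(),
            factors=scenario.factor_names(),
            cyclic=scenario.cyclic_periods(),
            max_predictors=scenario.max_predictors,
            cor_cutoff=scenario.cor_cutoff, k=scenario.k,
            factor_factor_interactions=scenario.factor_factor_interactions,
            factor_smooth_interactions=scenario.factor_smooth_interactions,
            smooth_smooth_interactions=scenario.smooth_smooth_interactions)
        kw.update(overrides)
        return cls(data, **kw)

    # -- fitting -----------------------------------------------------------

    def fit_specs(self) -> list[FitSpec]:
        return [build_fit_spec(m, self.predictors, self.response,
                               family=self.family, k=self.k)
                for m in self.candidate_set.models]

    def fit(self, parallel: bool = False, n_jobs: int = -1,
            backend=None) -> "FullSubsetsResults":
        records = fit_all(self.fit_specs(), self.data,
                          backend=backend or self._backend,
                          parallel=parallel, n_jobs=n_jobs)
        n_failed = sum(r.status == "failed" for r in records)
        if n_failed:
            log.info("%d of %d models failed to fit", n_failed, len(records))
        return FullSubsetsResults(model=self, records=records)


@dataclass
class FullSubsetsResults:
    """Fitted candidate set with comparison table and importance scores."""

    model: FullSubsetsGAM
    records: list

    table: pd.DataFrame = field(init=False)
    importance: pd.DataFrame = field(init=False)

    def __post_init__(self):
        m = self.model
        foot_names = sorted({n for ms in m.candidate_set.models
                             for n in ms.footprint()})
        self.table = inference.build_comparison_table(
            self.records, m.candidate_set, r2_type=m.r2_type,
            y=m.data[m.response].to_numpy(dtype=float),
            predictor_names=foot_names)
        if self.table.empty:
            raise RuntimeError("no candidate model fitted successfully")
        self.importance = inference.variable_importance(
            self.table, criterion=m.importance_criterion)

    # -- accessors ---------------------------------------------------------

    @property
    def failed(self) -> list:
        return [r for r in self.records if r.status == "failed"]

    @property
    def success(self) -> list:
        return [r for r in self.records if r.status == "ok"]

    @property
    def best_model_id(self) -> str:
        return str(self.table.iloc[0]["model_id"])

    def record(self, model_id: str) -> FitRecord:
        for r in self.records:
            if r.model_id == model_id:
                return r
        raise KeyError(model_id)

    def importance_for(self, predictor: str) -> float:
        row = self.importance.loc[self.importance["predictor"] == predictor]
        if row.empty:
            raise KeyError(predictor)
        return float(row["raw"].iloc[0])

    # -- presentation ------------------------------------------------------

    def summary(self, top: int = 10) -> str:
        m = self.model
        t = self.table.head(top)
        lines = [
            "Full-subsets GAM comparison",
            "=" * 66,
            f"Response: {m.response}   Family: {m.family}   "
            f"n = {len(m.data)} (dropped {m.n_dropped})",
            f"Candidate models: {len(m.candidate_set)} "
            f"({len(m.candidate_set.removed)} removed by checks; "
            f"{len(self.failed)} failed to fit)",
            "",
            f"Top {len(t)} models by AICc:",
        ]
        show = t[["model_id", "k", "AICc", "delta_AICc", "wi_AICc", "r2"]]
        lines.append(show.to_string(index=False,
                                    float_format=lambda v: f"{v:.3f}"))
        lines += ["", f"Variable importance (summed wi, {m.importance_criterion}):"]
        imp = self.importance[["predictor", "raw", "rescaled"]]
        lines.append(imp.to_string(index=False,
                                   float_format=lambda v: f"{v:.3f}"))
        return "\n".join(lines)

    # -- persistence -------------------------------------------------------

    def save(self, outdir) -> dict:
        """Write the output bundle; returns {name: path}."""
        from pathlib import Path
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        m = self.model
        paths = {}

        def _write_csv(name, frame, **kw):
            p = out / name
            frame.to_csv(p, **kw)
            paths[name] = p

        _write_csv("comparison_table.csv", self.table, index=False)
        _write_csv("used_data.csv", m.data, index=False)
        _write_csv("predictor_correlations.csv", m.associations.to_frame())
        _write_csv("inclusion_matrix.csv", m.inclusion.to_frame())
        _write_csv("variable_importance.csv", self.importance, index=False)
        removed = pd.DataFrame(m.candidate_set.removed,
                               columns=["model_id", "check", "detail"])
        _write_csv("removed_models.csv", removed, index=False)

        blocks = []
        for r in self.failed:
            blocks.append(f"model: {r.model_id}\nformula: {r.formula}\n"
                          f"error: {r.error_message}\n")
        (out / "failed_models.txt").write_text(
            "\n".join(blocks) if blocks else "no failed models\n")
        paths["failed_models.txt"] = out / "failed_models.txt"

        registry = {}
        for r in self.success:
            registry[r.model_id] = {
                "formula": r.formula, "loglik": r.loglik,
                "edf": r.edf, "n_params": r.n_params, "n_obs": r.n_obs,
                "deviance": r.deviance,
                "deviance_explained": r.deviance_explained,
                "lambdas": list(r.lambdas)}
        (out / "fitted_models.json").write_text(
            json.dumps(registry, indent=2, sort_keys=True))
        paths["fitted_models.json"] = out / "fitted_models.json"

        formulas = [r.formula for r in self.records]
        (out / "formulas.txt").write_text("\n".join(formulas) + "\n")
        paths["formulas.txt"] = out / "formulas.txt"
        return paths
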