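"""Run configuration, tabular I/O and the end-to-end driver.

A run is declared in a JSON (or YAML) file; every default is made
explicit again in the emitted ``manifest.json`` so a run can be
reproduced from its manifest alone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

__all__ = ["RunConfig", "load_config", "read_table", "run"]

log = logging.getLogger("fullsubsets")

_DEFAULTS = dict(max_predictors=3, cor_cutoff=0.28, k=5)


@dataclass
class RunConfig:
    """The declared analysis: data location, predictor roles, model-set
    switches and output options.  Defaults: max_predictors 3, cor_cutoff
    0.28, k 5."""

    data: str = ""
    response: str = ""
    family: str = "gaussian"
    continuous: list = field(default_factory=list)
    factors: list = field(default_factory=list)
    cyclic: dict = field(default_factory=dict)       # name -> period
    linear: list = field(default_factory=list)
    null_terms: list = field(default_factory=list)
    factor_factor_interactions: bool = False
    factor_smooth_interactions: bool = False
    smooth_smooth_interactions: bool = False
    factor_interaction_restrict: list | None = None
    by_factor_restrict: list | None = None
    tensor_restrict: list | None = None
    max_predictors: int = _DEFAULTS["max_predictors"]
    cor_cutoff: float = _DEFAULTS["cor_cutoff"]
    k: int = _DEFAULTS["k"]
    importance_criterion: str = "AICc"
    r2_type: str = "deviance"
    parallel: bool = False
    cor_matrix: str | None = None                    # CSV inclusion override
    out: str = "fullsubsets_out"
    seed: int | None = None

    def validate(self) -> None:
        errors = []
        if not self.response:
            errors.append("response: required")
        if not self.continuous and not self.factors:
            errors.append("continuous/factors: at least one predictor required")
        if self.family not in ("gaussian", "binomial", "poisson"):
            errors.append(f"family: unsupported value {self.family!r}")
        for name in self.cyclic:
            if name not in self.continuous:
                errors.append(f"cyclic.{name}: not in continuous list")
        for name in self.linear:
            if name not in self.continuous:
                errors.append(f"linear.{name}: not in continuous list")
        both = set(self.cyclic) & set(self.linear)
        for name in sorted(both):
            errors.append(f"cyclic.{name}/linear.{name}: mutually exclusive")
        overlap = set(self.continuous) & set(self.factors)
        for name in sorted(overlap):
            errors.append(f"continuous/factors overlap: {name}")
        for name in self.null_terms:
            if name not in self.continuous and name not in self.factors:
                errors.append(f"null_terms.{name}: not a declared predictor")
        if self.max_predictors < 1:
            errors.append("max_predictors: must be >= 1")
        if not 0.0 <= self.cor_cutoff <= 1.0:
            errors.append("cor_cutoff: must lie in [0, 1]")
        if self.k < 3:
            errors.append("k: must be >= 3")
        if self.importance_criterion not in ("AICc", "BIC"):
            errors.append("importance_criterion: must be 'AICc' or 'BIC'")
        if self.r2_type not in ("deviance", "cor"):
            errors.append("r2_type: must be 'deviance' or 'cor'")
        if errors:
            raise ValueError("invalid run configuration:\n  " +
                             "\n  ".join(errors))

    def model_kwargs(self) -> dict:
        """Keyword arguments for :class:`FullSubsetsGAM`."""
        kw = dict(
            response=self.response, family=self.family,
            continuous=list(self.continuous), factors=list(self.factors),
            cyclic=dict(self.cyclic), linear=list(self.linear),
            null_terms=list(self.null_terms),
            max_predictors=self.max_predictors, cor_cutoff=self.cor_cutoff,
            k=self.k,
            factor_factor_interactions=self.factor_factor_interactions,
            factor_smooth_interactions=self.factor_smooth_interactions,
            smooth_smooth_interactions=self.smooth_smooth_interactions,
            factor_interaction_restrict=self.factor_interaction_restrict,
            by_factor_restrict=self.by_factor_restrict,
            tensor_restrict=self.tensor_restrict,
            r2_type=self.r2_type,
            importance_criterion=self.importance_criterion)
        if self.cor_matrix:
            kw["inclusion_matrix"] = pd.read_csv(self.cor_matrix, index_col=0)
        return kw

    def manifest(self) -> dict:
        return asdict(self)


def load_config(path) -> RunConfig:
    """Read a JSON or YAML run configuration and validate it."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yml", ".yaml"):
        import yaml
        raw = yaml.safe_load(text)
    else:
        raw = json.loads(text)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    known = set(RunConfig.__dataclass_fields__)
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ValueError(f"{path}: unknown configuration field(s): {unknown}")
    cfg = RunConfig(**raw)
    cfg.validate()
    return cfg


def read_table(path, continuous=()) -> pd.DataFrame:
    """Read a CSV data table with a header row.

    Columns named in ``continuous`` are coerced to numeric; a stray text
    cell in one of them is an error naming the row and column.  Duplicate
    column names and empty files are rejected.  Categorical labels are
    preserved verbatim.
    """
    import csv
    with open(path, newline="") as fh:
        header = next(csv.reader(fh), None)
    if not header:
        raise ValueError(f"{path}: empty file")
    dupes = sorted({c for c in header if header.count(c) > 1})
    if dupes:
        raise ValueError(f"{path}: duplicate column name(s): {dupes}")
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty file")
    if frame.empty:
        raise ValueError(f"{path}: no data rows")
    for col in continuous:
        if col not in frame.columns:
            continue  # reported later against the full declaration
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = coerced.isna() & frame[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise ValueError(
                f"{path}: non-numeric value {frame[col][row]!r} in numeric "
                f"column {col!r} at row {row}")
        frame[col] = coerced
    return frame


def run(config: RunConfig, data: pd.DataFrame | None = None) -> dict:
    """Execute a full run and write the artifact bundle.

    Returns {artifact name: path}.  Raises RuntimeError if no candidate
    model fits (the CLI maps that to a nonzero exit status).
    """
    from .model import FullSubsetsGAM

    config.validate()
    model = FullSubsetsGAM.from_config(config, data=data)
    results = model.fit(parallel=config.parallel)
    paths = results.save(config.out)
    manifest_path = Path(config.out) / "manifest.json"
    manifest = config.manifest()
    manifest["n_rows_used"] = int(len(model.data))
    manifest["n_rows_dropped"] = int(model.n_dropped)
    manifest["n_candidate_models"] = len(model.candidate_set)
    manifest["n_failed"] = len(results.failed)
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    paths["manifest.json"] = manifest_path
    log.info("wrote %d artifacts to %s", len(paths), config.out)
    return paths
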