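"""Multimodel inference over the fitted candidate set.

AICc = -2 loglik + 2k + 2k(k+1)/(n-k-1)     (Hurvich & Tsai correction)
BIC  = -2 loglik + k ln(n)

with k the model's effective number of parameters (penalty-adjusted
degrees of freedom plus any scale parameter).  Akaike weights are
computed from criterion deltas, w_i = exp(-d_i/2) / sum_j exp(-d_j/2),
separately under AICc and BIC; failed fits carry no likelihood and are
excluded from normalization, as are models whose AICc correction is
undefined (n - k - 1 <= 0).  Variable importance is the summed weight of
all models whose predictor footprint contains the variable; a rescaled
score (raw / max raw) is reported alongside.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

from .candidates import CandidateSet

__all__ = ["aicc", "bic", "akaike_weights", "build_comparison_table",
           "variable_importance"]


def aicc(loglik: float, k: float, n: int) -> float:
    """Small-sample corrected AIC; NaN (with a warning) when the
    correction denominator n - k - 1 is not positive."""
    if n - k - 1 <= 0:
        warnings.warn(
            f"AICc undefined: n - k - 1 = {n - k - 1:.3g} <= 0 "
            f"(n={n}, k={k:.3g}); model excluded from weights")
        return math.nan
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0)


def bic(loglik: float, k: float, n: int) -> float:
    if n < 1:
        raise ValueError("n must be >= 1")
    return -2.0 * loglik + k * math.log(n)


def akaike_weights(criteria) -> np.ndarray:
    """Weights from a list of criterion values.

    Computed from deltas (minimum subtracted) for overflow safety.
    Non-finite criteria get weight NaN with a warning; the remaining
    weights renormalize to 1.
    """
    crit = np.asarray(list(criteria), dtype=float)
    if crit.size == 0:
        raise ValueError("empty criterion list")
    finite = np.isfinite(crit)
    if not finite.any():
        raise ValueError("no finite criterion values")
    if not finite.all():
        warnings.warn(f"{(~finite).sum()} non-finite criterion value(s) "
                      f"excluded from Akaike weights")
    out = np.full(crit.shape, np.nan)
    delta = crit[finite] - crit[finite].min()
    w = np.exp(-delta / 2.0)
    out[finite] = w / w.sum()
    return out


def build_comparison_table(records, candidates: CandidateSet,
                           r2_type: str = "deviance",
                           y: np.ndarray | None = None,
                           predictor_names: list | None = None) -> pd.DataFrame:
    """One row per successfully fitted model, sorted by AICc (ties broken
    by footprint size, then model id).

    Columns: model_id, formula, loglik, k (effective parameters), n_obs,
    AICc, BIC, delta_AICc, delta_BIC, wi_AICc, wi_BIC, r2, and one 0/1
    presence column per predictor (``p_<name>``).
    """
    by_id = {m.id: m for m in candidates.models}
    ok = [r for r in records if r.status == "ok"]
    if not ok:
        return pd.DataFrame()

    if r2_type not in ("deviance", "cor"):
        raise ValueError(f"unknown r2_type {r2_type!r}")

    if predictor_names is None:
        names = set()
        for m in candidates.models:
            names |= m.footprint()
        predictor_names = sorted(names)

    rows = []
    for r in ok:
        model = by_id[r.model_id]
        if r2_type == "deviance":
            r2 = r.deviance_explained
        else:
            if y is None:
                raise ValueError("r2_type='cor' requires the observed response")
            if np.std(r.fitted) == 0.0 or np.std(y) == 0.0:
                r2 = 0.0
            else:
                r2 = float(np.corrcoef(y, r.fitted)[0, 1] ** 2)
        foot = model.footprint()
        row = {
            "model_id": r.model_id,
            "formula": r.formula,
            "loglik": r.loglik,
            "k": r.n_params,
            "n_obs": r.n_obs,
            "AICc": aicc(r.loglik, r.n_params, r.n_obs),
            "BIC": bic(r.loglik, r.n_params, r.n_obs),
            "r2": r2,
            "_size": len(foot),
        }
        for p in predictor_names:
            row[f"p_{p}"] = int(p in foot)
        rows.append(row)

    table = pd.DataFrame(rows)
    for crit in ("AICc", "BIC"):
        table[f"delta_{crit}"] = table[crit] - table[crit].min()
        table[f"wi_{crit}"] = akaike_weights(table[crit].to_numpy())
    table = table.sort_values(["AICc", "_size", "model_id"],
                              na_position="last").drop(columns="_size")
    front = ["model_id", "formula", "loglik", "k", "n_obs", "AICc",
             "delta_AICc", "wi_AICc", "BIC", "delta_BIC", "wi_BIC", "r2"]
    table = table[front + [c for c in table.columns if c not in front]]
    return table.reset_index(drop=True)


def variable_importance(table: pd.DataFrame,
                        criterion: str = "AICc") -> pd.DataFrame:
    """Summed Akaike weights per predictor.

    raw = sum of model weights over models containing the predictor;
    rescaled = raw / max(raw).  Invariant to table row order.
    """
    if criterion not in ("AICc", "BIC"):
        raise ValueError(f"criterion must be 'AICc' or 'BIC', got {criterion!r}")
    if table.empty:
        raise ValueError("no fitted models: importance undefined")
    wcol = f"wi_{criterion}"
    pcols = [c for c in table.columns if c.startswith("p_")]
    w = table[wcol].fillna(0.0).to_numpy()
    rows = []
    for c in sorted(pcols):
        raw = float((w * table[c].to_numpy()).sum())
        rows.append({"predictor": c[2:], "raw": raw})
    out = pd.DataFrame(rows)
    mx = out["raw"].max()
    out["rescaled"] = out["raw"] / mx if mx > 0 else 0.0
    out["criterion"] = criterion
    return out
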