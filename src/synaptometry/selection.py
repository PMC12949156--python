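"""AICc model ranking on a common complete-case observation set.

Unlike cross-validation, which estimates out-of-sample error, the corrected
Akaike information criterion ranks models fit to the full dataset while
penalizing parameter count, with a small-sample correction:

    AIC  = 2k - 2*loglik
    AICc = AIC + 2k(k+1) / (n - k - 1)

``k`` counts the intercept, every slope, and the residual-variance parameter
of the Gaussian likelihood. Because AICc values are only comparable on
identical observations, every row that is incomplete in *any* column used by
*any* model in the grid is dropped first. Differences from the best model
(dAICc) are tiered following the conventional guidelines: <= 2 comparable,
2-10 ambiguous, > 10 a clear preference for the better model.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .models import FitResult, ModelSpec, fit_model

__all__ = [
    "AICcComparison",
    "complete_case_filter",
    "compute_aicc",
    "compare_models_aicc",
    "delta_aicc_tier",
    "pivot_delta_table",
]

TIER_COMPARABLE = "COMPARABLE"
TIER_AMBIGUOUS = "AMBIGUOUS"
TIER_INFERIOR = "INFERIOR"


@dataclass
class AICcComparison:
    """Per-model AICc results on a shared observation set."""

    table: pd.DataFrame  # model, evoked, adjustment, aicc, delta_aicc, tier, k
    n_obs: int
    n_ears: int
    scope: str  # "all" or "excluding_<group>"

    @property
    def best_model(self) -> str:
        return str(self.table.loc[self.table["delta_aicc"].idxmin(), "model"])


def complete_case_filter(
    table: pd.DataFrame, required_columns: list[str]
) -> pd.DataFrame:
    """Keep only rows complete in every required column."""
    missing = [c for c in required_columns if c not in table.columns]
    if missing:
        raise KeyError(f"columns absent from table: {missing}")
    out = table.dropna(subset=list(required_columns))
    if len(out) == 0:
        raise ValueError("complete-case filter left no rows")
    return out


def compute_aicc(fit: FitResult) -> float:
    """AICc of a Gaussian OLS fit; requires ``n - k - 1 > 0``."""
    n, k = fit.n, fit.k
    if n - k - 1 <= 0:
        raise ValueError(f"AICc undefined: n={n} too small for k={k}")
    aic = 2.0 * k - 2.0 * fit.loglik
    return float(aic + 2.0 * k * (k + 1.0) / (n - k - 1.0))


def delta_aicc_tier(delta: float) -> str:
    if delta <= 2.0:
        return TIER_COMPARABLE
    if delta <= 10.0:
        return TIER_AMBIGUOUS
    return TIER_INFERIOR


def compare_models_aicc(
    grid: list[ModelSpec],
    table: pd.DataFrame,
    scope: str = "all",
    exclude_group: str = "acute_noise",
) -> AICcComparison:
    """Fit every model in ``grid`` on the common complete-case rows and rank
    by dAICc.

    ``scope="excluding_acute"`` drops the focal-synaptopathy group's rows
    before filtering (the separate ranking the broad-loss comparison uses).
    """
    if not grid:
        raise ValueError("empty model grid")
    data = table
    if scope != "all":
        data = data[data["group"] != exclude_group]
    required = sorted({c for spec in grid for c in spec.required_columns if c != "sex"})
    data = complete_case_filter(data, required)

    rows = []
    for spec in grid:
        try:
            fit = fit_model(spec, data)
        except Exception as err:
            raise RuntimeError(f"model {spec.name} failed to fit: {err}") from err
        rows.append(
            {
                "model": spec.name,
                "evoked": "+".join(spec.evoked) if spec.evoked else "none",
                "adjustment": spec.dpoae or "none",
                "aicc": compute_aicc(fit),
                "k": fit.k,
                "n_obs": fit.n,
            }
        )
    out = pd.DataFrame(rows)
    out["delta_aicc"] = out["aicc"] - out["aicc"].min()
    out["tier"] = out["delta_aicc"].map(delta_aicc_tier)
    return AICcComparison(
        table=out,
        n_obs=int(out["n_obs"].iloc[0]),
        n_ears=int(data["ear_id"].nunique()) if "ear_id" in data.columns else len(data),
        scope=scope,
    )


def pivot_delta_table(comparison: AICcComparison) -> pd.DataFrame:
    """dAICc grid shaped rows = evoked-measure sets, columns = adjustment
    arms (the published-table layout; the best cell is 0)."""
    return comparison.table.pivot(
        index="evoked", columns="adjustment", values="delta_aicc"
    )
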