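"""Correlation screening with Bonferroni-corrected Fisher-z intervals.

Associations between measures are screened with the Pearson product-moment
coefficient. Confidence intervals use the Fisher transformation,
``tanh(atanh(r) +/- z * (n - 3)**-0.5)``, at a Bonferroni-corrected
confidence level ``(1 - (1 - c/100)/n_comparisons) * 100``; an association is
flagged significant when its corrected interval excludes zero. No p-values
are reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CorrelationResult",
    "bonferroni_conf_level",
    "pearson_with_ci",
    "correlation_screen",
    "screen_to_frame",
]


@dataclass
class CorrelationResult:
    measure: str
    target: str
    r: float
    ci_low: float
    ci_high: float
    conf_level_pct: float
    n: int
    significant: bool
    degenerate: bool = False
    excluded_group: str | None = None


def bonferroni_conf_level(c_pct: float, n_comparisons: int) -> float:
    """Corrected confidence level ``(1 - (1 - c/100)/n) * 100`` in percent."""
    if not 0.0 < c_pct < 100.0:
        raise ValueError("confidence level must be in (0, 100)")
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    return (1.0 - (1.0 - c_pct / 100.0) / n_comparisons) * 100.0


def pearson_with_ci(
    x, y, conf_level_pct: float = 95.0, measure: str = "", target: str = ""
) -> CorrelationResult:
    """Pearson r with a two-sided Fisher-transform confidence interval."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("at least 4 observations required")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("finite values required")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise ValueError("zero variance in x or y")
    r = float(sps.pearsonr(x, y).statistic)
    degenerate = bool(abs(r) >= 1.0 - 1e-15)
    if degenerate:
        lo = hi = r
    else:
        z = np.arctanh(r)
        zcrit = sps.norm.ppf(0.5 + conf_level_pct / 200.0)
        half = zcrit / np.sqrt(n - 3)
        lo, hi = float(np.tanh(z - half)), float(np.tanh(z + half))
    return CorrelationResult(
        measure=measure,
        target=target,
        r=r,
        ci_low=lo,
        ci_high=hi,
        conf_level_pct=conf_level_pct,
        n=n,
        significant=bool(lo > 0.0 or hi < 0.0),
        degenerate=degenerate,
    )


def correlation_screen(
    table: pd.DataFrame,
    pairs: list[tuple[str, str]],
    exclude_group: str | None = None,
    base_conf_pct: float = 95.0,
) -> list[CorrelationResult]:
    """Screen a list of (measure, target) column pairs at the Bonferroni-
    corrected level for ``len(pairs)`` comparisons.

    ``exclude_group`` drops that group's rows before computing (e.g. the
    acute-noise ears, whose focal loss decouples measures from 32 kHz synapse
    counts). Pairs with fewer than 4 complete observations are reported with
    ``r = nan`` rather than failing the screen.
    """
    for m, t in pairs:
        if m not in table.columns or t not in table.columns:
            raise KeyError(f"column missing from table: {m if m not in table.columns else t}")
    level = bonferroni_conf_level(base_conf_pct, len(pairs))
    if exclude_group is not None:
        table = table[table["group"] != exclude_group]
    results = []
    for m, t in pairs:
        sub = table[[m, t]].dropna()
        if len(sub) < 4:
            results.append(
                CorrelationResult(m, t, np.nan, np.nan, np.nan, level, len(sub),
                                  False, excluded_group=exclude_group)
            )
            continue
        res = pearson_with_ci(sub[m], sub[t], level, measure=m, target=t)
        res.excluded_group = exclude_group
        results.append(res)
    return results


def screen_to_frame(results: list[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "measure": [r.measure for r in results],
            "target": [r.target for r in results],
            "r": [r.r for r in results],
            "ci_low": [r.ci_low for r in results],
            "ci_high": [r.ci_high for r in results],
            "conf_level_pct": [r.conf_level_pct for r in results],
            "n": [r.n for r in results],
            "significant": [r.significant for r in results],
            "excluded_group": [r.excluded_group for r in results],
        }
    )
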