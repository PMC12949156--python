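"""Linear synapse-prediction models and repeated ear-grouped cross-validation.

The model family is ordinary least squares on the long (ear x frequency)
analysis table, pooling 16 and 32 kHz with no frequency term:

    y = b0 + sum_j b1j * M_j + b2 * xi + b3 * S + e

where ``y`` is synapses/IHC, ``M_j`` are evoked-potential measures, ``xi`` is
an optional DPOAE covariate (threshold, DPOAE_40, or DPOAE_55), and ``S`` is
an optional female-sex indicator. The empty model is the intercept-only
baseline (predicting the sample mean); DPOAE-only models are the
OHC-collinearity baseline.

Out-of-sample error is estimated by ten repeats of ten-fold cross-validation
in which the acute-noise ears are first set aside as an independent test set
(their focal synaptopathy is the hardest condition) and the remaining ears
are shuffled and partitioned at the *ear* level, so both rows of an ear stay
in the same fold. Each trained fold model is scored on its held-out
validation fold and on the full acute-noise test set; means and standard
errors of the RMSE pool all repeats x folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.model_selection import KFold

__all__ = [
    "DPOAE_COLUMNS",
    "ModelSpec",
    "FitResult",
    "CVConfig",
    "CVResult",
    "build_analysis_table",
    "fit_model",
    "predict",
    "rmse",
    "repeated_grouped_cv",
    "delta_rmse_vs_reference",
]

DPOAE_COLUMNS = ("dpoae_threshold", "dpoae_40", "dpoae_55")


@dataclass(frozen=True)
class ModelSpec:
    """One cell of the model grid.

    ``evoked`` names zero or more evoked-measure columns of the analysis
    table (e.g. ``("abr_80",)`` or ``("ram_1000_f0",)``); ``dpoae`` is the
    OHC-adjustment column or ``None``; ``include_sex`` adds the female
    indicator. Empty ``evoked`` with ``dpoae=None`` is the intercept-only
    model; empty ``evoked`` with an adjustment is a DPOAE-only model.
    """

    evoked: tuple = ()
    dpoae: str | None = None
    include_sex: bool = False
    outcome: str = "synapses"

    def __post_init__(self) -> None:
        if self.dpoae is not None and self.dpoae not in DPOAE_COLUMNS:
            raise ValueError(f"unknown DPOAE adjustment {self.dpoae!r}")

    @property
    def predictor_columns(self) -> tuple:
        cols = tuple(self.evoked)
        if self.dpoae is not None:
            cols += (self.dpoae,)
        return cols

    @property
    def required_columns(self) -> tuple:
        cols = (self.outcome,) + self.predictor_columns
        if self.include_sex:
            cols += ("sex",)
        return cols

    @property
    def name(self) -> str:
        ev = "+".join(self.evoked) if self.evoked else "intercept"
        adj = self.dpoae if self.dpoae else "none"
        return f"{ev}|{adj}" + ("|sex" if self.include_sex else "")


@dataclass
class FitResult:
    """OLS fit summary: coefficients, ML residual scale, and log-likelihood.

    ``k`` counts the intercept, every slope, and the residual-variance
    parameter (the Gaussian AICc convention)."""

    spec: ModelSpec
    params: pd.Series
    resid_scale: float
    n: int
    k: int
    loglik: float

    def predict_frame(self, table: pd.DataFrame) -> np.ndarray:
        X = _design_matrix(self.spec, table)
        return X @ self.params.values


def build_analysis_table(
    ground_truth: pd.DataFrame,
    *measure_tables: pd.DataFrame,
    frequencies: tuple = (16000.0, 32000.0),
) -> pd.DataFrame:
    """Join ground truth and measure tables on (ear_id, frequency_hz),
    restricted to the analysis frequencies. Missing cells stay missing;
    duplicate (ear, frequency) keys are an error."""
    table = ground_truth.copy()
    if "synapses" not in table.columns and "synapses_per_ihc" in table.columns:
        table = table.rename(columns={"synapses_per_ihc": "synapses"})
    for m in measure_tables:
        overlap = [c for c in m.columns if c in table.columns and c not in ("ear_id", "frequency_hz")]
        table = table.merge(m.drop(columns=overlap), on=["ear_id", "frequency_hz"], how="left")
    table = table[table["frequency_hz"].isin(frequencies)].reset_index(drop=True)
    if table.duplicated(["ear_id", "frequency_hz"]).any():
        dup = table[table.duplicated(["ear_id", "frequency_hz"])]["ear_id"].unique()
        raise ValueError(f"duplicate (ear, frequency) rows for ears {list(dup)[:5]}")
    return table


def _design_matrix(spec: ModelSpec, table: pd.DataFrame) -> np.ndarray:
    cols = [np.ones(len(table))]
    for c in spec.predictor_columns:
        cols.append(table[c].to_numpy(dtype=float))
    if spec.include_sex:
        cols.append((table["sex"] == "F").to_numpy(dtype=float))
    return np.column_stack(cols)


def complete_rows(spec: ModelSpec, table: pd.DataFrame) -> pd.DataFrame:
    """Rows complete in every column the model uses (complete-case)."""
    cols = [c for c in spec.required_columns if c != "sex"]
    return table.dropna(subset=cols)


def fit_model(spec: ModelSpec, table: pd.DataFrame) -> FitResult:
    """Fit the model by OLS on the complete-case rows of ``table``.

    Raises on rank deficiency, naming the collinear columns. ``loglik`` is
    the Gaussian maximum likelihood (sigma^2 = SSR/n), as statsmodels
    reports for OLS.
    """
    data = complete_rows(spec, table)
    p = len(spec.predictor_columns) + int(spec.include_sex)
    if len(data) < p + 3:
        raise ValueError(
            f"{spec.name}: {len(data)} complete rows, need at least {p + 3}"
        )
    X = _design_matrix(spec, data)
    y = data[spec.outcome].to_numpy(dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        names = ["intercept", *spec.predictor_columns]
        if spec.include_sex:
            names.append("sex")
        raise ValueError(f"rank-deficient design; collinear columns among {names}")
    res = sm.OLS(y, X).fit()
    names = ["intercept", *spec.predictor_columns] + (["sex_f"] if spec.include_sex else [])
    n = len(y)
    return FitResult(
        spec=spec,
        params=pd.Series(res.params, index=names),
        resid_scale=float(np.sqrt(res.ssr / n)),
        n=n,
        k=X.shape[1] + 1,  # + residual variance
        loglik=float(res.llf),
    )


def predict(fit: FitResult, table: pd.DataFrame) -> np.ndarray:
    return fit.predict_frame(table)


def rmse(y, yhat) -> float:
    """Root-mean-squared prediction error, sqrt(mean((y - yhat)^2))."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if len(y) == 0 or len(y) != len(yhat):
        raise ValueError("y and yhat must be equal-length and non-empty")
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


@dataclass
class CVConfig:
    k_folds: int = 10
    repeats: int = 10
    group_key: str = "ear_id"
    test_group: str = "acute_noise"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")


@dataclass
class CVResult:
    """Per-(repeat, fold) validation and test RMSEs plus pooled summaries."""

    spec: ModelSpec
    rmse_validation: np.ndarray  # (repeats, folds)
    rmse_test: np.ndarray  # (repeats, folds); NaN when no test rows
    n_complete: int
    fold_hash: int = 0
    seed: int = 0
    #: per (repeat, fold): frozenset of validation-fold ear ids
    fold_ears: list = field(default_factory=list)

    @property
    def mean_val(self) -> float:
        return float(np.mean(self.rmse_validation))

    @property
    def sem_val(self) -> float:
        v = self.rmse_validation.ravel()
        return float(np.std(v, ddof=1) / np.sqrt(v.size))

    @property
    def mean_test(self) -> float:
        return float(np.mean(self.rmse_test))

    @property
    def sem_test(self) -> float:
        v = self.rmse_test.ravel()
        return float(np.std(v, ddof=1) / np.sqrt(v.size))


def _ols_fit_predict(Xtr, ytr, Xva):
    beta, *_ = np.linalg.lstsq(Xtr, ytr, rcond=None)
    return Xva @ beta


def repeated_grouped_cv(
    spec: ModelSpec, table: pd.DataFrame, cfg: CVConfig | None = None
) -> CVResult:
    """Repeated k-fold cross-validation grouped at the ear level.

    Rows of the test group (default acute-noise) are excluded from fold
    assignment and scored as an independent test set by every fold's trained
    model. For each repeat the unique non-test ears are shuffled and split
    into ``k_folds`` folds (sizes differing by at most one ear); identical
    seeds give identical fold assignments and bit-identical results.
    """
    if cfg is None:
        cfg = CVConfig()
    data = complete_rows(spec, table)
    test_mask = data["group"] == cfg.test_group if "group" in data.columns else (
        pd.Series(False, index=data.index)
    )
    pool = data[~test_mask]
    test = data[test_mask]

    ears = np.sort(pool[cfg.group_key].unique())
    if len(ears) < cfg.k_folds:
        raise ValueError(
            f"{len(ears)} ears available but {cfg.k_folds} folds requested"
        )

    y_pool = pool[spec.outcome].to_numpy(dtype=float)
    X_pool = _design_matrix(spec, pool)
    ear_of_row = pool[cfg.group_key].to_numpy()
    if len(test):
        X_test = _design_matrix(spec, test)
        y_test = test[spec.outcome].to_numpy(dtype=float)

    val = np.full((cfg.repeats, cfg.k_folds), np.nan)
    tst = np.full((cfg.repeats, cfg.k_folds), np.nan)
    fold_hash = 0
    fold_ears = []
    for rep in range(cfg.repeats):
        kf = KFold(n_splits=cfg.k_folds, shuffle=True, random_state=cfg.seed + rep)
        for fold, (tr_idx, va_idx) in enumerate(kf.split(ears)):
            va_ears = frozenset(ears[va_idx])
            va_mask = np.isin(ear_of_row, list(va_ears))
            Xtr, ytr = X_pool[~va_mask], y_pool[~va_mask]
            beta, *_ = np.linalg.lstsq(Xtr, ytr, rcond=None)
            val[rep, fold] = rmse(y_pool[va_mask], X_pool[va_mask] @ beta)
            if len(test):
                tst[rep, fold] = rmse(y_test, X_test @ beta)
            fold_hash = hash((fold_hash, tuple(sorted(va_ears))))
            fold_ears.append(va_ears)
    return CVResult(
        spec=spec,
        rmse_validation=val,
        rmse_test=tst,
        n_complete=len(data),
        fold_hash=fold_hash,
        seed=cfg.seed,
        fold_ears=fold_ears,
    )


def delta_rmse_vs_reference(
    results: dict[str, CVResult],
    reference_evoked: tuple = ("abr_80",),
    metric: str = "validation",
) -> pd.DataFrame:
    """Change in prediction error of each model relative to the reference
    evoked-measure family, matched on DPOAE adjustment.

    The reference for a model with adjustment ``a`` is the
    ``reference_evoked`` model with the same adjustment. When two results
    share identical fold assignments (same seed and partition) the SEM of the
    difference is computed pairwise per (repeat, fold); otherwise SEMs are
    combined in quadrature.
    """
    refs = {
        r.spec.dpoae: r
        for r in results.values()
        if tuple(r.spec.evoked) == tuple(reference_evoked)
    }
    rows = []
    for name, r in results.items():
        if tuple(r.spec.evoked) == tuple(reference_evoked):
            continue
        if r.spec.dpoae not in refs:
            raise KeyError(
                f"no matched reference ({reference_evoked}, adjustment={r.spec.dpoae})"
            )
        ref = refs[r.spec.dpoae]
        a = r.rmse_validation if metric == "validation" else r.rmse_test
        b = ref.rmse_validation if metric == "validation" else ref.rmse_test
        paired = (r.fold_hash == ref.fold_hash) and (r.seed == ref.seed)
        delta = float(np.mean(a) - np.mean(b))
        if paired:
            d = (a - b).ravel()
            sem = float(np.std(d, ddof=1) / np.sqrt(d.size))
        else:
            sem = float(np.hypot(
                np.std(a.ravel(), ddof=1) / np.sqrt(a.size),
                np.std(b.ravel(), ddof=1) / np.sqrt(b.size),
            ))
        rows.append(
            {
                "model": name,
                "adjustment": r.spec.dpoae or "none",
                "delta_rmse": delta,
                "sem": sem,
                "paired": paired,
            }
        )
    return pd.DataFrame(rows)
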