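"""Multiple imputation of cost components and effects; Rubin's-rules pooling.

Costs are imputed at the level of individual cost components (each
reporting category separately), never as a pre-summed total: totals are
recomputed from imputed components afterwards, which keeps information
from patients with partially observed costs.

Imputation uses chained equations with predictive-mean matching (PMM) for
continuous variables — robust for right-skewed cost data because imputed
values are always drawn from observed donors. The chained-equation engine
is statsmodels' MICE; this module owns the predictor specification,
reproducibility, validation and diagnostics around it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, ValidationError

DEFAULT_PREDICTORS = (
    "arm_mic",
    "age",
    "sex_female",
    "utility_baseline",
    "coopwonca_baseline",
    "gars_baseline",
)


@dataclass(frozen=True)
class ImputationSpec:
    """Settings for multiple imputation.

    m : number of completed datasets (5 in the study analysis).
    predictors : complete covariate columns used in every chained equation.
    k_pmm : donors considered per predictive-mean match.
    n_burn : chained-equation sweeps before the first dataset is taken,
        and between consecutive datasets.
    log_columns : targets imputed on the log1p scale — standard for
        right-skewed cost components; PMM still draws observed donor
        values, so the back-transform is exact.
    """

    m: int = 5
    predictors: tuple[str, ...] = DEFAULT_PREDICTORS
    k_pmm: int = 3
    n_burn: int = 5
    log_columns: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self):
        if self.m < 2:
            raise ValidationError(f"m must be >= 2, got {self.m}")
        if not self.predictors:
            raise ValidationError("predictor set must be non-empty")


def impute(
    data: pd.DataFrame,
    columns: list[str],
    spec: ImputationSpec,
) -> list[pd.DataFrame]:
    """Return ``spec.m`` completed copies of ``data``.

    ``columns`` are the imputation targets (cost components and effect
    measures). Predictors must exist and be fully observed; a target that
    is 100% missing is unrecoverable and raises; a frame with no missing
    targets returns m identical copies with a warning.
    """
    missing_preds = [p for p in spec.predictors if p not in data.columns]
    if missing_preds:
        raise ValidationError(f"predictors not in dataset: {missing_preds}")
    missing_cols = [c for c in columns if c not in data.columns]
    if missing_cols:
        raise ValidationError(f"imputation targets not in dataset: {missing_cols}")
    for c in columns:
        if data[c].isna().all():
            raise DataError(f"column {c!r} is 100% missing; nothing to match on")
    pred_na = data[list(spec.predictors)].isna().any()
    if pred_na.any():
        bad = list(pred_na.index[pred_na])
        raise DataError(f"predictors contain missing values: {bad}")

    if not data[columns].isna().any().any():
        warnings.warn("no missing values among imputation targets; returning m copies")
        return [data.copy() for _ in range(spec.m)]

    from statsmodels.imputation.mice import MICEData

    work = data[list(spec.predictors) + list(columns)].copy()
    logged = [c for c in spec.log_columns if c in columns]
    for c in logged:
        if (data[c].dropna() < 0).any():
            raise ValidationError(f"log_columns target {c!r} has negative values")
        work[c] = np.log1p(work[c])
    # MICEData formulas need clean names; ours already are (snake_case)
    completed = []
    # statsmodels MICE draws from the global numpy RandomState
    np.random.seed(spec.seed % (2**31))
    md = MICEData(work, perturbation_method="boot", k_pmm=spec.k_pmm)
    for col in columns:
        if work[col].isna().any():
            md.set_imputer(col, formula=" + ".join(spec.predictors), k_pmm=spec.k_pmm)
    md.update_all(spec.n_burn)
    for _ in range(spec.m):
        md.update_all(spec.n_burn)
        filled = data.copy()
        for col in columns:
            v = md.data[col].to_numpy(float)
            filled[col] = np.expm1(v) if col in logged else v
        completed.append(filled)
    return completed


def imputation_diagnostics(data: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    """Per-variable missing fraction and PMM donor-pool size."""
    rows = []
    for c in columns:
        n_missing = int(data[c].isna().sum())
        rows.append(
            {
                "variable": c,
                "n": len(data),
                "n_missing": n_missing,
                "missing_fraction": n_missing / len(data) if len(data) else 0.0,
                "donor_pool": int(data[c].notna().sum()),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PooledEstimate:
    """Rubin's-rules combination of m per-imputation analyses.

    estimate : mean of the per-imputation point estimates.
    within_var : W, mean of the per-imputation variances.
    between_var : B, sample variance of the point estimates.
    total_var : T = W + (1 + 1/m) B.
    df : Rubin's small-sample degrees of freedom, (m-1)(1 + W/((1+1/m)B))^2
         (infinite when B = 0).
    """

    estimate: float
    within_var: float
    between_var: float
    total_var: float
    m: int
    df: float

    @property
    def se(self) -> float:
        return float(np.sqrt(self.total_var))

    def confidence_interval(self, alpha: float = 0.05) -> tuple[float, float]:
        if np.isinf(self.df):
            crit = stats.norm.ppf(1 - alpha / 2)
        else:
            crit = stats.t.ppf(1 - alpha / 2, self.df)
        return (self.estimate - crit * self.se, self.estimate + crit * self.se)


def rubin_pool(estimates, variances) -> PooledEstimate:
    """Pool per-imputation estimates and variances by Rubin's rules."""
    est = np.asarray(estimates, float)
    var = np.asarray(variances, float)
    if est.shape != var.shape or est.ndim != 1:
        raise ValidationError("estimates and variances must be equal-length 1-d")
    m = len(est)
    if m < 2:
        raise ValidationError(f"Rubin pooling needs m >= 2 imputations, got {m}")
    if np.any(var < 0):
        raise ValidationError("variances must be non-negative")
    W = float(var.mean())
    B = float(est.var(ddof=1))
    T = W + (1 + 1 / m) * B
    if B == 0:
        df = float("inf")
    else:
        # numpy arithmetic saturates to inf instead of raising when the
        # between-imputation variance is vanishingly small
        with np.errstate(over="ignore"):
            df = float((m - 1) * (1 + np.float64(W) / ((1 + 1 / m) * np.float64(B))) ** 2)
    return PooledEstimate(
        estimate=float(est.mean()),
        within_var=W,
        between_var=B,
        total_var=T,
        m=m,
        df=df,
    )


@dataclass(frozen=True)
class DropoutProfile:
    """Completer vs non-completer comparison on baseline covariates — the
    selective-missingness check. ``suppressed`` is set when either group is
    empty (e.g. no dropout at all)."""

    suppressed: bool
    n_completers: int
    n_noncompleters: int
    comparisons: pd.DataFrame | None  # variable, mean_diff, ci_low, ci_high


def dropout_profile(
    data: pd.DataFrame,
    completer_col: str = "completer",
    variables: tuple[str, ...] = ("age", "gars_baseline"),
    alpha: float = 0.05,
) -> DropoutProfile:
    """Mean differences (non-completer minus completer) with Welch normal
    CIs for baseline age and ADL restriction (GARS). In the trial, those
    who dropped out were older but less ADL-restricted than completers."""
    comp = data[data[completer_col].astype(bool)]
    nonc = data[~data[completer_col].astype(bool)]
    if len(comp) == 0 or len(nonc) == 0:
        return DropoutProfile(True, len(comp), len(nonc), None)
    z = stats.norm.ppf(1 - alpha / 2)
    rows = []
    for v in variables:
        a = nonc[v].dropna().to_numpy(float)
        b = comp[v].dropna().to_numpy(float)
        diff = a.mean() - b.mean()
        se = np.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b))
        rows.append(
            {
                "variable": v,
                "mean_noncompleter": a.mean(),
                "mean_completer": b.mean(),
                "mean_diff": diff,
                "ci_low": diff - z * se,
                "ci_high": diff + z * se,
            }
        )
    return DropoutProfile(False, len(comp), len(nonc), pd.DataFrame(rows))
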