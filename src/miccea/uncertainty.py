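"""Nonparametric bootstrap for cost differences and cost-effect pairs.

Patient-level costs are heavily right-skewed, so arm differences are
bootstrapped (within-arm resampling with replacement) rather than treated
as normal. Intervals:

* ``percentile`` — order statistics of the replicate distribution, linear
  interpolation at the quantiles;
* ``bca`` — bias-corrected and accelerated: percentile endpoints adjusted
  by a median-bias correction z0 (share of replicates below the point
  estimate) and a jackknife-estimated acceleration a (skewness of the
  leave-one-out statistic);
* ``abc`` — analytic approximate-bootstrap-confidence endpoints for the
  mean-difference statistic, computed from empirical influence values
  without resampling (for a linear statistic the quadratic ABC terms
  vanish and z0 = a).

For cost-effectiveness, (Δcost, Δeffect) is computed on the *same*
within-arm resample so the cost-effect correlation is preserved; across
multiply-imputed datasets, B replicates are drawn per dataset and stacked.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .errors import ValidationError


@dataclass(frozen=True)
class BootstrapSpec:
    """Bootstrap settings.

    B : replicates per dataset (study analysis used 5000).
    stratify_by_arm : resample within arm (standard for two-arm trials).
    cluster_resample : resample homes (clusters) within arm instead of
        patients — methodological comparison only; the primary analysis
        resamples patients, ignoring clustering.
    ci_method : 'percentile' | 'bca' | 'abc'.
    """

    B: int = 5000
    stratify_by_arm: bool = True
    cluster_resample: bool = False
    seed: int = 0
    ci_method: str = "bca"
    alpha: float = 0.05

    def __post_init__(self):
        if self.B < 100:
            raise ValidationError(f"B must be >= 100 for interval construction, got {self.B}")
        if self.ci_method not in ("percentile", "bca", "abc"):
            raise ValidationError(f"unknown ci_method {self.ci_method!r}")
        if not 0 < self.alpha < 1:
            raise ValidationError(f"alpha must be in (0,1), got {self.alpha}")

    def replace(self, **kw) -> "BootstrapSpec":
        return dataclasses.replace(self, **kw)


@dataclass
class BootstrapResult:
    point: float
    replicates: np.ndarray
    interval: tuple[float, float]
    method: str
    degenerate: bool = False  # all observations identical in some arm
    z0: float | None = None
    acceleration: float | None = None


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def percentile_interval(replicates, alpha=0.05) -> tuple[float, float]:
    """Equal-tailed percentile interval; quantile ties broken by linear
    interpolation between order statistics."""
    lo, hi = np.quantile(replicates, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def jackknife_acceleration(a_vals, b_vals) -> float:
    """Acceleration for the two-sample mean difference: skewness of the
    pooled leave-one-out statistics.

    Dropping one observation from either arm gives n_a + n_b jackknife
    values of the statistic; a = sum((mean - t_i)^3) / (6 sum((mean - t_i)^2)^1.5).
    """
    a_vals = np.asarray(a_vals, float)
    b_vals = np.asarray(b_vals, float)
    na, nb = len(a_vals), len(b_vals)
    ma, mb = a_vals.mean(), b_vals.mean()
    # closed-form leave-one-out means
    loo_a = (na * ma - a_vals) / (na - 1) - mb
    loo_b = ma - (nb * mb - b_vals) / (nb - 1)
    theta = np.concatenate([loo_a, loo_b])
    d = theta.mean() - theta
    denom = (d**2).sum() ** 1.5
    if denom == 0:
        return 0.0
    return float((d**3).sum() / (6 * denom))


def bca_interval(
    replicates, point, acceleration, alpha=0.05
) -> tuple[tuple[float, float], float]:
    """BCa endpoints from replicates, a point estimate and an acceleration.

    Returns ((low, high), z0). With z0 = 0 and a = 0 the adjusted quantile
    levels reduce exactly to alpha/2 and 1 - alpha/2, i.e. the percentile
    interval.
    """
    reps = np.asarray(replicates, float)
    B = len(reps)
    prop = (np.sum(reps < point) + 0.5 * np.sum(reps == point)) / B
    prop = min(max(prop, 1 / (2 * B)), 1 - 1 / (2 * B))  # keep ndtri finite
    z0 = ndtri(prop)
    a = acceleration
    out = []
    for z in (ndtri(alpha / 2), ndtri(1 - alpha / 2)):
        num = z0 + z
        level = ndtr(z0 + num / (1 - a * num))
        out.append(float(np.quantile(reps, level)))
    return (out[0], out[1]), float(z0)


def abc_interval(a_vals, b_vals, alpha=0.05) -> tuple[tuple[float, float], float, float]:
    """Analytic ABC interval for the mean difference, from empirical
    influence values (no resampling). Returns ((low, high), z0, a)."""
    x = np.asarray(a_vals, float)
    y = np.asarray(b_vals, float)
    point = x.mean() - y.mean()
    L = np.concatenate([(x - x.mean()) / len(x), -(y - y.mean()) / len(y)])
    sigma = np.sqrt((L**2).sum())
    if sigma == 0:
        return (point, point), 0.0, 0.0
    a = (L**3).sum() / (6 * (L**2).sum() ** 1.5)
    z0 = a  # quadratic terms vanish for a linear statistic
    out = []
    for z in (ndtri(alpha / 2), ndtri(1 - alpha / 2)):
        w = z0 + z
        lam = w / (1 - a * w) ** 2
        out.append(float(point + sigma * lam))
    return (out[0], out[1]), float(z0), float(a)


def _resample_means(values, clusters, spec, rng) -> np.ndarray:
    """B bootstrap means of one arm, resampling patients or whole homes."""
    values = np.asarray(values, float)
    n = len(values)
    if not spec.cluster_resample:
        idx = rng.integers(0, n, size=(spec.B, n))
        return values[idx].mean(axis=1)
    homes = pd.unique(np.asarray(clusters))
    sums = np.array([values[clusters == h].sum() for h in homes])
    counts = np.array([(clusters == h).sum() for h in homes])
    hidx = rng.integers(0, len(homes), size=(spec.B, len(homes)))
    return sums[hidx].sum(axis=1) / counts[hidx].sum(axis=1)


def bootstrap_difference(
    values_mic,
    values_uc,
    spec: BootstrapSpec,
    clusters_mic=None,
    clusters_uc=None,
) -> BootstrapResult:
    """Bootstrap the MIC-minus-UC mean difference with within-arm
    resampling and build the configured confidence interval."""
    mic = np.asarray(values_mic, float)
    uc = np.asarray(values_uc, float)
    if len(mic) < 2 or len(uc) < 2:
        raise ValidationError("need >= 2 observations per arm")
    if np.isnan(mic).any() or np.isnan(uc).any():
        raise ValidationError("missing values must be imputed before bootstrapping")
    point = float(mic.mean() - uc.mean())
    rng = _rng(spec.seed)
    reps = _resample_means(mic, clusters_mic, spec, rng) - _resample_means(
        uc, clusters_uc, spec, rng
    )
    # a constant arm leaves no resampling variation to correct for; flag it
    # and fall back to the percentile interval (BCa's z0 is undefined there)
    degenerate = (np.ptp(mic) == 0) or (np.ptp(uc) == 0)

    z0 = acc = None
    if spec.ci_method == "percentile" or degenerate:
        interval = percentile_interval(reps, spec.alpha)
    elif spec.ci_method == "bca":
        acc = jackknife_acceleration(mic, uc)
        interval, z0 = bca_interval(reps, point, acc, spec.alpha)
    else:  # abc
        interval, z0, acc = abc_interval(mic, uc, spec.alpha)
    return BootstrapResult(
        point=point,
        replicates=reps,
        interval=interval,
        method=spec.ci_method,
        degenerate=degenerate,
        z0=z0,
        acceleration=acc,
    )


@dataclass
class CEPairs:
    """Bootstrap replicates of (Δcost, Δeffect), MIC minus UC.

    ``effect_direction`` records whether larger raw effect values are
    better ('higher') or worse ('lower', e.g. the quality-of-care score);
    downstream CEA converts to benefit-signed effects using it.
    """

    replicates: pd.DataFrame  # columns: delta_cost, delta_effect, imputation, replicate
    outcome_kind: str
    effect_direction: str = "higher"
    point_delta_cost: float = float("nan")
    point_delta_effect: float = float("nan")

    def __post_init__(self):
        if self.effect_direction not in ("higher", "lower"):
            raise ValidationError(f"effect_direction must be higher|lower, got {self.effect_direction!r}")

    @property
    def delta_cost(self) -> np.ndarray:
        return self.replicates["delta_cost"].to_numpy(float)

    @property
    def delta_effect(self) -> np.ndarray:
        return self.replicates["delta_effect"].to_numpy(float)

    @property
    def benefit_effect(self) -> np.ndarray:
        s = 1.0 if self.effect_direction == "higher" else -1.0
        return s * self.delta_effect


def bootstrap_ce_pairs(
    datasets: list[pd.DataFrame],
    spec: BootstrapSpec,
    outcome_kind: str,
    cost_col: str = "total_cost",
    effect_col: str | None = None,
    effect_direction: str = "higher",
) -> CEPairs:
    """Bootstrap incremental cost-effect pairs across (possibly multiply
    imputed) completed datasets.

    Each dataset needs columns ``arm`` ('MIC'/'UC'), the cost column and
    the effect column, with no missing values (imputation must precede).
    Per replicate, patients are resampled within arm and (Δcost, Δeffect)
    computed on the same resample; B replicates per dataset are stacked
    across the m datasets, giving m*B pairs.
    """
    effect_col = effect_col or outcome_kind
    frames = []
    pd_cost = pd_eff = 0.0
    for i, df in enumerate(datasets):
        sub = df[["arm", cost_col, effect_col]]
        if sub[[cost_col, effect_col]].isna().any().any():
            raise ValidationError(
                f"dataset {i}: missing {cost_col}/{effect_col} values reached the bootstrap"
            )
        rng = _rng([spec.seed, i])
        mic = sub[sub["arm"] == "MIC"]
        uc = sub[sub["arm"] == "UC"]
        if len(mic) < 2 or len(uc) < 2:
            raise ValidationError("need >= 2 patients per arm")
        dcost = np.empty(spec.B)
        deff = np.empty(spec.B)
        for arm_df, sign in ((mic, 1.0), (uc, -1.0)):
            c = arm_df[cost_col].to_numpy(float)
            e = arm_df[effect_col].to_numpy(float)
            idx = rng.integers(0, len(arm_df), size=(spec.B, len(arm_df)))
            contrib_c = c[idx].mean(axis=1)
            contrib_e = e[idx].mean(axis=1)
            if sign > 0:
                dcost[:] = contrib_c
                deff[:] = contrib_e
            else:
                dcost -= contrib_c
                deff -= contrib_e
        frames.append(
            pd.DataFrame(
                {
                    "delta_cost": dcost,
                    "delta_effect": deff,
                    "imputation": i,
                    "replicate": np.arange(spec.B),
                }
            )
        )
        pd_cost += mic[cost_col].mean() - uc[cost_col].mean()
        pd_eff += mic[effect_col].mean() - uc[effect_col].mean()
    m = len(datasets)
    return CEPairs(
        replicates=pd.concat(frames, ignore_index=True),
        outcome_kind=outcome_kind,
        effect_direction=effect_direction,
        point_delta_cost=pd_cost / m,
        point_delta_effect=pd_eff / m,
    )
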