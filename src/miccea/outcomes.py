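"""Clinical effect measures per resident.

Three outcomes drive the economic evaluation:

* quality-of-care indicator sum score — percent of *applicable* care-quality
  indicators that are *present* for a resident (0-100, lower = better care);
* COOP WONCA functional health — sum of six ordinal charts (1-5 each),
  higher = better, analysed as baseline-to-follow-up change;
* QALYs — area under the piecewise-linear utility curve over the follow-up
  window, utilities on the SF-6D scale in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError

N_COOPWONCA_DIMENSIONS = 6
FOLLOWUP_YEARS = 0.5


def qoc_sum_score(applicable, present, weights=None) -> float:
    """Quality-of-care sum score in percent: 100 x present / applicable.

    Lower scores indicate higher quality of care (an indicator being
    "present" flags a care problem, e.g. a feeding tube). Indicators that
    are not applicable to the resident are excluded from both numerator
    and denominator. Returns NaN when no indicator is applicable — the
    resident contributes nothing to this outcome and is flagged upstream.

    ``weights`` optionally weights indicators; the default is unweighted.
    """
    applicable = np.asarray(applicable, dtype=bool)
    present = np.asarray(present, dtype=bool)
    if applicable.shape != present.shape:
        raise ValidationError("applicable and present must have equal length")
    if np.any(present & ~applicable):
        raise ValidationError("indicator marked present but not applicable")
    w = np.ones(applicable.shape) if weights is None else np.asarray(weights, float)
    if w.shape != applicable.shape or np.any(w < 0):
        raise ValidationError("weights must be non-negative, one per indicator")
    denom = w[applicable].sum()
    if denom == 0:
        return float("nan")
    return 100.0 * w[present].sum() / denom


def qaly(times, utilities) -> float:
    """Quality-adjusted life-years: trapezoid-rule area under the utility
    trajectory, with health-state transitions linearly interpolated.

    ``times`` in years since baseline, strictly increasing; utilities in
    [0, 1]. A constant utility u over T years yields exactly u*T.
    """
    t = np.asarray(times, float)
    u = np.asarray(utilities, float)
    if t.ndim != 1 or t.shape != u.shape or len(t) < 2:
        raise ValidationError("need >= 2 (time, utility) points of equal length")
    if np.any(np.diff(t) <= 0):
        raise ValidationError("times must be strictly increasing")
    if np.any((u < 0) | (u > 1)) or np.any(np.isnan(u)):
        raise ValidationError("utilities must lie in [0, 1]")
    return float(np.trapezoid(u, t))


def coopwonca_total(dimensions) -> int:
    """Total COOP WONCA score: sum of the six chart dimensions
    (physical fitness, feelings, daily activities, social activities,
    change in health, overall health), each scored 1-5.
    Higher totals indicate better functional health."""
    d = np.asarray(dimensions)
    if d.shape != (N_COOPWONCA_DIMENSIONS,):
        raise ValidationError(
            f"expected exactly {N_COOPWONCA_DIMENSIONS} dimension scores, got shape {d.shape}"
        )
    if np.any((d < 1) | (d > 5)) or not np.allclose(d, np.round(d)):
        raise ValidationError("each dimension must be an integer in 1..5")
    return int(d.sum())


@dataclass(frozen=True)
class EffectDifference:
    """Mean difference MIC minus UC on an outcome's native scale."""

    difference: float
    mic_mean: float
    uc_mean: float
    ci_low: float
    ci_high: float
    n_mic: int
    n_uc: int


def effect_difference(values_mic, values_uc, bootstrap_spec=None) -> EffectDifference:
    """Arithmetic mean difference (MIC - UC) with a bootstrap confidence
    interval. The sign convention of the outcome is preserved: a negative
    quality-of-care difference means better care in MIC."""
    from .uncertainty import BootstrapSpec, bootstrap_difference

    mic = np.asarray(values_mic, float)
    uc = np.asarray(values_uc, float)
    mic = mic[~np.isnan(mic)]
    uc = uc[~np.isnan(uc)]
    if len(mic) < 2 or len(uc) < 2:
        raise ValidationError("need >= 2 non-missing observations per arm")
    spec = bootstrap_spec or BootstrapSpec(B=2000, seed=0)
    res = bootstrap_difference(mic, uc, spec=spec)
    return EffectDifference(
        difference=float(mic.mean() - uc.mean()),
        mic_mean=float(mic.mean()),
        uc_mean=float(uc.mean()),
        ci_low=res.interval[0],
        ci_high=res.interval[1],
        n_mic=len(mic),
        n_uc=len(uc),
    )


# ---------------------------------------------------------------------------
# patient-table outcome construction


def build_outcomes(
    patients: pd.DataFrame,
    include_decedents: bool = False,
    indicator_count: int = 32,
    death_time_years: float = FOLLOWUP_YEARS / 2,
) -> pd.DataFrame:
    """Per-patient outcome table from the patients file.

    Produces ``qoc_score`` (percent), ``coopwonca_change`` (follow-up total
    minus baseline total) and ``qaly``, with NaN where source data are
    missing, plus ``excluded``/``exclusion_reason`` flags implementing the
    main-analysis rule: residents who died during the study or provided no
    baseline data are excluded.

    With ``include_decedents=True`` (third sensitivity analysis) decedents
    are retained and valued at utility zero from death onward; lacking an
    observed death date, death is placed at the midpoint of follow-up.
    """
    out = pd.DataFrame(index=patients.index)
    out["patient_id"] = patients["patient_id"]
    out["arm"] = patients["arm"]

    app = patients[[f"ind_app_{k}" for k in range(1, indicator_count + 1)]].to_numpy(float)
    pres = patients[[f"ind_pres_{k}" for k in range(1, indicator_count + 1)]].to_numpy(float)
    qoc = np.full(len(patients), np.nan)
    observed_panel = ~np.isnan(pres).any(axis=1)
    for i in np.flatnonzero(observed_panel):
        qoc[i] = qoc_sum_score(app[i].astype(bool), pres[i].astype(bool))
    out["qoc_score"] = qoc

    base_dims = patients[[f"cw_base_{k}" for k in range(1, 7)]].to_numpy(float)
    fu_dims = patients[[f"cw_fu_{k}" for k in range(1, 7)]].to_numpy(float)
    out["coopwonca_baseline"] = base_dims.sum(axis=1)
    out["coopwonca_change"] = fu_dims.sum(axis=1) - base_dims.sum(axis=1)

    u0 = patients["utility_baseline"].to_numpy(float)
    u6 = patients["utility_6m"].to_numpy(float)
    q = np.full(len(patients), np.nan)
    ok = ~np.isnan(u0) & ~np.isnan(u6)
    # trapezoid over (0, 0.5) years
    q[ok] = (u0[ok] + u6[ok]) / 2 * FOLLOWUP_YEARS
    out["qaly"] = q

    died = patients["died"].astype(bool).to_numpy()
    no_baseline = patients["no_baseline"].astype(bool).to_numpy()
    if include_decedents:
        # decedents: utility falls linearly to 0 at death, 0 afterwards
        dec = died & ~np.isnan(u0)
        out.loc[dec, "qaly"] = u0[dec] * death_time_years / 2
        excluded = np.zeros(len(patients), bool)
        reason = np.where(excluded, "", "")
    else:
        excluded = died | no_baseline
        reason = np.select(
            [died, no_baseline], ["died", "no_baseline"], default=""
        )
    out["excluded"] = excluded
    out["exclusion_reason"] = reason
    out["qoc_undefined"] = observed_panel & np.isnan(qoc)
    return out
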