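"""Cost-effectiveness analysis: ICERs, CE-plane quadrants, CEAC curves.

Effects enter benefit-signed: for lower-is-better outcomes (the
quality-of-care sum score) the incremental effect is sign-flipped to an
"improvement" before any ratio or quadrant logic, so an ICER of 62 reads
"each one-point improvement on the quality-of-care scale costs €62 extra".
The CE plane follows the usual orientation: NE = costlier & more
effective, NW = costlier & less effective, SE = cheaper & more effective
(dominant), SW = cheaper & less effective.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .uncertainty import CEPairs

QUADRANTS = ("NE", "NW", "SE", "SW")


@dataclass(frozen=True)
class ICERResult:
    delta_cost: float
    delta_effect: float  # benefit-signed (improvement > 0)
    icer: float  # NaN when not interpretable
    quadrant: str
    interpretable: bool


def _benefit(delta_effect: float, direction: str) -> float:
    if direction not in ("higher", "lower"):
        raise ValidationError(f"direction must be higher|lower, got {direction!r}")
    return delta_effect if direction == "higher" else -delta_effect


def _quadrant(delta_cost: float, benefit: float) -> str:
    ns = "N" if delta_cost > 0 else "S"
    ew = "E" if benefit > 0 else "W"
    return ns + ew


def icer(delta_cost: float, delta_effect: float, direction: str = "higher") -> ICERResult:
    """Incremental cost-effectiveness ratio: Δcost / Δeffect with the
    effect benefit-signed. A zero effect leaves the ratio undefined
    (``interpretable=False``) rather than raising; a ratio whose sign mixes
    dominance quadrants is reported but flagged the same way, since a
    negative ICER can mean either "dominant" (SE) or "dominated" (NW)."""
    b = _benefit(delta_effect, direction)
    quadrant = _quadrant(delta_cost, b)
    if b == 0:
        return ICERResult(delta_cost, b, float("nan"), quadrant, False)
    value = delta_cost / b
    # a positive ratio (NE or SW) trades money against effect; a negative
    # one signals dominance and its magnitude is not a price per unit
    interpretable = value >= 0
    return ICERResult(delta_cost, b, float(value), quadrant, interpretable)


@dataclass(frozen=True)
class QuadrantSummary:
    proportions: dict[str, float]

    def __getitem__(self, q: str) -> float:
        return self.proportions[q]


def quadrant_proportions(pairs: CEPairs) -> QuadrantSummary:
    """Share of bootstrap replicates falling in each CE-plane quadrant.

    Boundary ties (a replicate with exactly zero incremental cost or
    benefit) count toward the south/west side, so the four shares always
    sum to one.
    """
    dc = pairs.delta_cost
    b = pairs.benefit_effect
    if len(dc) == 0:
        raise ValidationError("need at least one replicate")
    north = dc > 0
    east = b > 0
    n = len(dc)
    props = {
        "NE": float((north & east).sum()) / n,
        "NW": float((north & ~east).sum()) / n,
        "SE": float((~north & east).sum()) / n,
        "SW": float((~north & ~east).sum()) / n,
    }
    return QuadrantSummary(props)


@dataclass(frozen=True)
class CEACCurve:
    """Probability that the intervention is cost-effective as a function of
    the ceiling ratio λ (societal willingness to pay per unit of effect)."""

    lambdas: np.ndarray
    probabilities: np.ndarray

    def __post_init__(self):
        lam = np.asarray(self.lambdas, float)
        if len(lam) == 0 or np.any(lam < 0):
            raise ValidationError("lambda grid must be non-empty and non-negative")
        if np.any(np.diff(lam) <= 0):
            raise ValidationError("lambda grid must be strictly increasing")
        p = np.asarray(self.probabilities, float)
        if np.any((p < 0) | (p > 1)):
            raise ValidationError("probabilities must lie in [0, 1]")


def ceac(pairs: CEPairs, lambdas) -> CEACCurve:
    """Cost-effectiveness acceptability curve.

    P(λ) is the fraction of replicates with positive net monetary benefit
    λ·Δeffect − Δcost (effect benefit-signed, strict inequality: ties count
    as not cost-effective). At λ = 0 this is exactly the probability that
    the intervention saves money.
    """
    lam = np.asarray(lambdas, float)
    dc = pairs.delta_cost
    b = pairs.benefit_effect
    probs = np.empty(len(lam))
    # block over the grid: a full lambda x replicate NMB matrix can be GBs
    step = max(1, int(2**22 / max(len(dc), 1)))
    for i in range(0, len(lam), step):
        chunk = lam[i : i + step, None] * b[None, :] - dc[None, :]
        probs[i : i + step] = (chunk > 0).mean(axis=1)
    return CEACCurve(lambdas=lam, probabilities=probs)


def wtp_threshold(curve: CEACCurve, p: float):
    """Smallest grid λ whose acceptability probability reaches ``p``;
    ``None`` when the curve never reaches it (as for an intervention whose
    maximum probability of being cost-effective stays below the target)."""
    hits = np.flatnonzero(np.asarray(curve.probabilities) >= p)
    if len(hits) == 0:
        return None
    return float(np.asarray(curve.lambdas)[hits[0]])


def default_lambda_grid(outcome_kind: str) -> np.ndarray:
    """λ grids matching the scales on which the outcomes are discussed:
    fine euro steps for point-scale outcomes, thousand-euro steps up to
    €500k for QALYs (conventional WTP ranges)."""
    if outcome_kind == "qaly":
        return np.arange(0, 500_001, 1000, dtype=float)
    return np.arange(0, 10_001, 1, dtype=float)
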