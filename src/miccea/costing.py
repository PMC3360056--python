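"""Societal costing: unit prices, resource-use valuation, intervention costs.

All per-record valuation is done in integer cents (quantity x unit price
rounded half-up to the cent) so that per-patient category totals and the
grand total are exactly additive, matching printed integer-euro tables
without float drift. Downstream statistics work on float euros.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .errors import UnpricedCategoryError, ValidationError

#: Reporting cost groups, in table order. ``implementation`` is attached
#: per patient by the pipeline (top-down intervention cost), not priced from
#: resource-use records.
COST_GROUPS = ("primary_care", "secondary_care", "medication", "informal_care")
ALL_GROUPS = COST_GROUPS + ("implementation",)


@dataclass(frozen=True)
class UnitPriceTable:
    """Maps resource-use categories to unit prices (euros, study year).

    ``groups`` maps each category to the cost group it is reported under
    (primary care, secondary care, medication, informal care).
    """

    prices: dict[str, float]
    groups: dict[str, str]
    currency_year: int = 2007

    def __post_init__(self):
        for cat, p in self.prices.items():
            if p < 0:
                raise ValidationError(f"unit price for {cat!r} is negative: {p}")
            if cat not in self.groups:
                raise ValidationError(f"category {cat!r} has a price but no group")

    def price(self, category: str) -> float:
        try:
            return self.prices[category]
        except KeyError:
            raise UnpricedCategoryError(category) from None

    def group(self, category: str) -> str:
        return self.groups[category]

    @classmethod
    def from_frame(cls, df: pd.DataFrame, **kw) -> "UnitPriceTable":
        return cls(
            prices=dict(zip(df["category"], df["price_eur_2007"].astype(float))),
            groups=dict(zip(df["category"], df["group"])),
            **kw,
        )

    @classmethod
    def from_csv(cls, path, **kw) -> "UnitPriceTable":
        return cls.from_frame(pd.read_csv(path), **kw)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "category": list(self.prices),
                "price_eur_2007": [self.prices[c] for c in self.prices],
                "group": [self.groups[c] for c in self.prices],
            }
        )


def load_default_prices() -> UnitPriceTable:
    """The packaged 2007 Dutch unit-price table used by the study pipeline."""
    ref = importlib.resources.files("miccea.data").joinpath("unit_prices_2007.csv")
    with importlib.resources.as_file(ref) as path:
        return UnitPriceTable.from_csv(path)


def cpi_adjust(amount: float, factor: float) -> float:
    """Re-express ``amount`` in target-year euros via a consumer-price-index factor."""
    if factor <= 0:
        raise ValidationError(f"CPI factor must be positive, got {factor}")
    return amount * factor


def _cents(quantity: float, price: float) -> int:
    """quantity x price in integer cents, rounded half-up."""
    d = Decimal(str(quantity)) * Decimal(str(price)) * 100
    return int(d.quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def price_resource_use(
    records: pd.DataFrame,
    prices: UnitPriceTable,
    patient_ids=None,
) -> pd.DataFrame:
    """Value resource-use records and aggregate per patient by cost group.

    Parameters
    ----------
    records
        Long-format table with columns ``patient_id``, ``category``,
        ``quantity``. A NaN quantity marks the record as unobserved and
        makes the patient's whole cost group NaN (to be imputed later).
    prices
        Unit-price table covering every category present.
    patient_ids
        Optional full roster; patients with no records get an all-zero
        breakdown instead of being absent.

    Returns
    -------
    DataFrame indexed by patient_id with one float-euro column per cost
    group plus ``total`` (NaN-propagating sum of the groups).
    """
    if patient_ids is not None:
        index = pd.Index(patient_ids, name="patient_id")
    elif len(records):
        index = pd.Index(sorted(records["patient_id"].unique()), name="patient_id")
    else:
        index = pd.Index([], name="patient_id")
    out = pd.DataFrame(0.0, index=index, columns=list(COST_GROUPS))

    if len(records):
        for cat in records["category"].unique():
            prices.price(cat)  # raises UnpricedCategoryError
        qty = records["quantity"].to_numpy(float)
        if np.nanmin(qty, initial=0.0) < 0:
            raise ValidationError("negative resource-use quantity encountered")
        rec = pd.DataFrame(
            {
                "patient_id": records["patient_id"].to_numpy(),
                "group": records["category"].map(prices.groups).to_numpy(),
                "cost_cents": [
                    np.nan if pd.isna(q) else _cents(q, prices.prices[c])
                    for q, c in zip(records["quantity"], records["category"])
                ],
            }
        )
        g = rec.groupby(["patient_id", "group"])
        sums = g["cost_cents"].sum().unstack()  # NaN records excluded here
        masked = rec["cost_cents"].isna().groupby(
            [rec["patient_id"], rec["group"]]
        ).any().unstack()
        for grp in COST_GROUPS:
            if grp in sums.columns:
                col = sums[grp].reindex(index).fillna(0.0) / 100.0
                # a single unobserved record makes the whole group missing
                col[masked[grp].reindex(index).eq(True)] = np.nan
                out[grp] = col

    out["total"] = out[list(COST_GROUPS)].sum(axis=1, skipna=False)
    return out


@dataclass(frozen=True)
class InterventionCostModel:
    """Top-down intervention cost: annual components proportioned to the
    trial period and divided over the residents of the intervention homes.

    components : euros per year, e.g. organizational, training of staff,
        assessment performance, multidisciplinary meeting costs.
    period_fraction : fraction of a year covered by the trial (0.5 for a
        6-month follow-up).
    n_residents : residents across whom the total is divided.
    """

    components: dict[str, float] = field(
        default_factory=lambda: {
            "organizational": 2510.0,
            "training": 6824.0,
            "interrai_assessment": 1999.0,
            "meetings": 1780.0,
        }
    )
    period_fraction: float = 0.5
    n_residents: int = 230

    def __post_init__(self):
        for name, v in self.components.items():
            if v < 0:
                raise ValidationError(f"intervention component {name!r} negative: {v}")
        if not (0 < self.period_fraction <= 1):
            raise ValidationError(
                f"period_fraction must be in (0, 1], got {self.period_fraction}"
            )
        if self.n_residents < 1:
            raise ValidationError(f"n_residents must be >= 1, got {self.n_residents}")

    def total_components(self) -> float:
        """Annual cost summed over components (euros)."""
        return float(sum(self.components.values()))

    def per_patient(self) -> float:
        """Trial-period intervention cost allocated per resident."""
        return self.total_components() * self.period_fraction / self.n_residents

    def masked(self, keep: set[str]) -> "InterventionCostModel":
        """Sensitivity variant retaining only the named components
        (e.g. assessment licensing/subscription only)."""
        unknown = keep - set(self.components)
        if unknown:
            raise ValidationError(f"unknown intervention components: {sorted(unknown)}")
        return InterventionCostModel(
            components={k: v for k, v in self.components.items() if k in keep},
            period_fraction=self.period_fraction,
            n_residents=self.n_residents,
        )


def arm_cost_summary(
    breakdowns: pd.DataFrame,
    bootstrap_spec=None,
    categories=ALL_GROUPS + ("total",),
) -> pd.DataFrame:
    """Arm-level cost table: mean and SE per arm plus MIC-minus-UC difference
    with a bootstrap confidence interval per cost category.

    ``breakdowns`` holds one row per patient with an ``arm`` column
    ("MIC"/"UC") and one column per category; rows with NaN in a category
    are dropped for that category only.
    """
    from .uncertainty import BootstrapSpec, bootstrap_difference

    arms = set(breakdowns["arm"].unique())
    if not {"MIC", "UC"} <= arms:
        raise ValidationError(f"need both arms MIC and UC, got {sorted(arms)}")
    spec = bootstrap_spec or BootstrapSpec(B=2000, seed=0)
    rows = []
    for i, cat in enumerate(categories):
        if cat not in breakdowns.columns:
            continue
        mic = breakdowns.loc[breakdowns["arm"] == "MIC", cat].dropna().to_numpy(float)
        uc = breakdowns.loc[breakdowns["arm"] == "UC", cat].dropna().to_numpy(float)
        if len(mic) < 2 or len(uc) < 2:
            raise ValidationError(f"category {cat!r}: need >=2 patients per arm")
        res = bootstrap_difference(
            mic, uc, spec=spec.replace(seed=spec.seed + i)
        )
        rows.append(
            {
                "category": cat,
                "mic_mean": mic.mean(),
                "mic_se": mic.std(ddof=1) / np.sqrt(len(mic)),
                "uc_mean": uc.mean(),
                "uc_se": uc.std(ddof=1) / np.sqrt(len(uc)),
                "difference": mic.mean() - uc.mean(),
                "ci_low": res.interval[0],
                "ci_high": res.interval[1],
            }
        )
    return pd.DataFrame(rows)
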