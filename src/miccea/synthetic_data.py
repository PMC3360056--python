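"""Synthetic cluster-randomized two-arm trial generator.

Emulates the structure of a 6-month residential-home trial: two arms of
``homes_per_arm`` homes (randomization at home level), ~46 residents per
home, right-skewed per-category patient costs (gamma by default),
SF-6D utilities around 0.64 (SD 0.1), COOP WONCA totals around 18, a
32-indicator quality-of-care panel with applicability masks, ~10%
mortality over follow-up, and MAR dropout in which non-completers are
about two years older and less ADL-restricted (GARS difference ≈ −3.4)
than completers.

Complete (pre-missingness) values are retained in ``*_true`` columns so
imputation bias is measurable against generator truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit, logit

from .costing import COST_GROUPS, UnitPriceTable, load_default_prices
from .errors import ValidationError

#: How each cost group's per-patient cost is split across resource-use
#: categories (fixed shares; quantities follow as cost / unit price).
RESOURCE_SPLIT = {
    "primary_care": {
        "gp_office_visit": 0.30,
        "gp_home_visit": 0.25,
        "gp_phone": 0.05,
        "physiotherapy": 0.22,
        "ergotherapy": 0.05,
        "psychologist": 0.05,
        "psychiatrist": 0.04,
        "social_psychiatric_nurse": 0.04,
    },
    "secondary_care": {
        "geriatrician": 0.10,
        "other_specialist": 0.15,
        "hospital_day_care": 0.15,
        "hospital_overnight": 0.60,
    },
    "medication": {"medication": 1.0},
    "informal_care": {"informal_care": 1.0},
}

#: Groups whose data come from records rather than resident interview;
#: these can be missing component-wise independent of dropout.
RECORD_BASED_GROUPS = ("primary_care", "secondary_care", "medication")


@dataclass(frozen=True)
class DropoutModel:
    """Logistic missing-at-random dropout on age and baseline GARS
    (ADL restriction, higher = more restricted): logit P(drop) =
    intercept + beta_age (age - 86) + beta_gars (gars - 47).

    Defaults are calibrated so that, at the default covariate
    distribution, ~31% of surviving residents drop out, non-completers
    average ~2 years older and their GARS averages ~3.4 points lower
    (better ADL) than completers'. All-zero coefficients with
    intercept -inf give no dropout.
    """

    intercept: float = -0.8452
    beta_age: float = 0.0433
    beta_gars: float = -0.0443
    age_center: float = 86.0
    gars_center: float = 47.0

    def probability(self, age, gars) -> np.ndarray:
        # the all-zero model is the documented "off" switch (an intercept of
        # -inf in the limit): no dropout at all
        if self.intercept == self.beta_age == self.beta_gars == 0:
            return np.zeros(np.broadcast(np.asarray(age), np.asarray(gars)).shape)
        eta = (
            self.intercept
            + self.beta_age * (np.asarray(age, float) - self.age_center)
            + self.beta_gars * (np.asarray(gars, float) - self.gars_center)
        )
        return expit(eta)


@dataclass(frozen=True)
class ClusterSD:
    """Between-home random-intercept SDs (additive on each scale's linear
    predictor); set all to 0 for a no-clustering generator."""

    cost: float = 60.0  # euros, on group cost means
    utility: float = 0.015
    coopwonca: float = 0.5  # points on the total-score change
    qoc_logit: float = 0.12  # log-odds of indicator presence


def _default_prevalences() -> tuple[float, ...]:
    # heterogeneous indicator prevalences averaging 0.1763, the control-arm
    # quality-of-care score (17.63%) on the proportion scale
    return tuple(float(p) for p in np.round(np.linspace(0.0563, 0.2963, 32), 6))


@dataclass(frozen=True)
class TrialConfig:
    """All knobs of the synthetic trial. Defaults reproduce the study
    conditions (arm margins, skew, missingness profile); the three effect
    parameters are the true MIC-minus-UC differences the generator plants.
    """

    homes_per_arm: int = 5
    residents_per_home_mean: float = 46.0
    participation_prob: float = 0.736  # 340 of 462 invited

    # true effects (MIC minus UC)
    effect_qoc: float = -6.51  # percentage points on the sum score (negative = better care)
    effect_cost: float = 197.0  # euros per patient across resource-use groups
    effect_utility: float = -0.0065  # SF-6D units at follow-up
    effect_coopwonca: float = 0.2  # points on the change score

    # costs: control-arm gamma means/shapes per group and the shares of
    # effect_cost attributed to each group (shares sum to 1)
    uc_cost_means: dict = field(
        default_factory=lambda: {
            "primary_care": 389.0,
            "secondary_care": 533.0,
            "medication": 429.0,
            "informal_care": 282.0,
        }
    )
    cost_shapes: dict = field(
        default_factory=lambda: {
            "primary_care": 0.36,
            "secondary_care": 0.14,
            "medication": 0.60,
            "informal_care": 0.34,
        }
    )
    cost_effect_shares: dict = field(
        default_factory=lambda: {
            "primary_care": -90 / 197,
            "secondary_care": 212 / 197,
            "medication": -10 / 197,
            "informal_care": 85 / 197,
        }
    )
    cost_family: str = "gamma"  # or "lognormal"
    # lognormal loading of each group's cost mean on standardized baseline
    # GARS (ADL restriction): mean_i = mean * exp(g z_i - g^2/2), which
    # leaves the group mean unchanged but makes costs covariate-dependent,
    # so MAR dropout on GARS genuinely biases complete-case cost means
    cost_gars_loadings: dict = field(
        default_factory=lambda: {
            "primary_care": 0.10,
            "secondary_care": 0.0,
            "medication": 0.15,
            "informal_care": 0.35,
        }
    )

    # utilities and functional health
    utility_mean: float = 0.64
    utility_sd: float = 0.10
    utility_change_sd: float = 0.05
    coopwonca_mean: float = 18.0
    coopwonca_sd: float = 3.9
    coopwonca_change_mean: float = 0.65  # control-arm mean change
    coopwonca_change_sd: float = 5.0

    # quality-of-care indicator panel
    indicator_count: int = 32
    indicator_prevalences: tuple = field(default_factory=_default_prevalences)
    applicability_prob: float = 0.8

    # demographics
    age_mean: float = 86.0
    age_sd: float = 7.0
    female_prob: float = 0.75
    gars_mean: float = 47.0
    gars_sd: float = 9.0

    # missingness and death
    mortality_prob: float = 0.10
    no_baseline_prob: float = 0.015
    dropout_model: DropoutModel = field(default_factory=DropoutModel)
    cost_missing_prob: float = 0.10

    cluster_sd: ClusterSD = field(default_factory=ClusterSD)

    # per-patient implementation cost margins (top-down in MIC; costed
    # usual-care multidisciplinary meetings in UC — not zero)
    implementation_cost_mic: float = 225.0
    implementation_cost_uc: float = 23.0

    seed: int = 0

    def validate(self) -> None:
        def prob(name, v):
            if not 0 <= v <= 1:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")

        if self.homes_per_arm < 1:
            raise ValidationError(f"homes_per_arm must be >= 1, got {self.homes_per_arm}")
        if self.residents_per_home_mean <= 0:
            raise ValidationError(
                f"residents_per_home_mean must be positive, got {self.residents_per_home_mean}"
            )
        prob("participation_prob", self.participation_prob)
        prob("mortality_prob", self.mortality_prob)
        prob("no_baseline_prob", self.no_baseline_prob)
        prob("cost_missing_prob", self.cost_missing_prob)
        prob("applicability_prob", self.applicability_prob)
        prob("female_prob", self.female_prob)
        if self.cost_family not in ("gamma", "lognormal"):
            raise ValidationError(f"cost_family must be gamma|lognormal, got {self.cost_family!r}")
        for g in COST_GROUPS:
            if g not in self.uc_cost_means:
                raise ValidationError(f"uc_cost_means missing group {g!r}")
            if self.uc_cost_means[g] <= 0:
                raise ValidationError(f"uc_cost_means[{g!r}] must be positive")
            if self.cost_shapes.get(g, 0) <= 0:
                raise ValidationError(f"cost_shapes[{g!r}] must be strictly positive")
        if abs(sum(self.cost_effect_shares.values()) - 1) > 1e-9:
            raise ValidationError("cost_effect_shares must sum to 1")
        if not 0 < self.utility_mean < 1:
            raise ValidationError(f"utility_mean must be in (0, 1), got {self.utility_mean}")
        if self.utility_sd <= 0:
            raise ValidationError(f"utility_sd must be positive, got {self.utility_sd}")
        if len(self.indicator_prevalences) != self.indicator_count:
            raise ValidationError(
                "indicator_prevalences length "
                f"{len(self.indicator_prevalences)} != indicator_count {self.indicator_count}"
            )
        for p in self.indicator_prevalences:
            prob("indicator_prevalences[*]", p)

    def replace(self, **kw) -> "TrialConfig":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["indicator_prevalences"] = list(self.indicator_prevalences)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrialConfig":
        d = dict(d)
        if "dropout_model" in d and isinstance(d["dropout_model"], dict):
            d["dropout_model"] = DropoutModel(**d["dropout_model"])
        if "cluster_sd" in d and isinstance(d["cluster_sd"], dict):
            d["cluster_sd"] = ClusterSD(**d["cluster_sd"])
        if "indicator_prevalences" in d:
            d["indicator_prevalences"] = tuple(d["indicator_prevalences"])
        return cls(**d)


@dataclass
class TrialDataset:
    """A generated trial: resident-level table, long resource-use table,
    unit prices, and the provenance (config incl. seed) that made it."""

    patients: pd.DataFrame
    resource_use: pd.DataFrame
    prices: UnitPriceTable
    config: TrialConfig

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.patients.to_csv(outdir / "patients.csv", index=False, float_format="%.10g")
        self.resource_use.to_csv(outdir / "resource_use.csv", index=False, float_format="%.10g")
        self.prices.to_frame().to_csv(outdir / "prices.csv", index=False)
        with open(outdir / "provenance.yaml", "w") as fh:
            yaml.safe_dump({"trial_config": self.config.to_dict()}, fh, sort_keys=True)

    @classmethod
    def read(cls, outdir) -> "TrialDataset":
        outdir = Path(outdir)
        with open(outdir / "provenance.yaml") as fh:
            cfg = TrialConfig.from_dict(yaml.safe_load(fh)["trial_config"])
        return cls(
            patients=pd.read_csv(outdir / "patients.csv"),
            resource_use=pd.read_csv(outdir / "resource_use.csv"),
            prices=UnitPriceTable.from_csv(outdir / "prices.csv"),
            config=cfg,
        )


def _presence_logit_shift(prevalences: np.ndarray, effect_pp: float) -> float:
    """Common log-odds shift delta such that mean(expit(logit(p) + delta))
    equals mean(p) + effect_pp/100 — realizes the configured mean
    quality-score difference exactly in expectation."""
    if effect_pp == 0:
        return 0.0
    target = prevalences.mean() + effect_pp / 100.0
    if not 0 < target < 1:
        raise ValidationError(
            f"effect_qoc={effect_pp} pushes mean indicator prevalence outside (0,1)"
        )
    lo = logit(prevalences)

    def f(delta):
        return expit(lo + delta).mean() - target

    return brentq(f, -20.0, 20.0)


def _truncnorm01(rng, mean, sd, size):
    """Normal draws truncated to [0, 1] by redraw (negligible mass outside
    for the study calibration 0.64 +/- 0.10)."""
    x = rng.normal(mean, sd, size)
    bad = (x < 0) | (x > 1)
    while bad.any():
        x[bad] = rng.normal(mean, sd, bad.sum())
        bad = (x < 0) | (x > 1)
    return x


def _group_cost_draw(rng, mean, shape, family, size):
    if family == "gamma":
        return rng.gamma(shape, mean / shape, size)
    # lognormal with the same mean and the gamma's coefficient of variation
    sigma2 = np.log1p(1.0 / shape)
    mu = np.log(mean) - sigma2 / 2
    return rng.lognormal(mu, np.sqrt(sigma2), size)


def generate_trial(config: TrialConfig, prices: UnitPriceTable | None = None) -> TrialDataset:
    """Generate one complete trial (no missingness applied yet).

    Same (config, seed) is bit-identical. Home-level randomization: each
    home belongs to one arm; additive normal home intercepts perturb
    costs, utilities, COOP WONCA change and indicator-presence log-odds.
    """
    config.validate()
    prices = prices or load_default_prices()
    rng = np.random.default_rng(config.seed)

    n_homes = 2 * config.homes_per_arm
    home_ids = [f"MIC-{i + 1}" for i in range(config.homes_per_arm)] + [
        f"UC-{i + 1}" for i in range(config.homes_per_arm)
    ]
    home_arm = ["MIC"] * config.homes_per_arm + ["UC"] * config.homes_per_arm
    u_cost = rng.normal(0, config.cluster_sd.cost, n_homes)
    u_util = rng.normal(0, config.cluster_sd.utility, n_homes)
    u_cw = rng.normal(0, config.cluster_sd.coopwonca, n_homes)
    u_qoc = rng.normal(0, config.cluster_sd.qoc_logit, n_homes)
    sizes = np.maximum(rng.poisson(config.residents_per_home_mean, n_homes), 2)

    prev = np.asarray(config.indicator_prevalences, float)
    delta_qoc = _presence_logit_shift(prev, config.effect_qoc)

    rows = []
    resource_rows = []
    pid = 0
    for h in range(n_homes):
        arm = home_arm[h]
        mic = 1.0 if arm == "MIC" else 0.0
        n = sizes[h]
        age = np.clip(rng.normal(config.age_mean, config.age_sd, n), 65, 105)
        female = rng.random(n) < config.female_prob
        gars = np.clip(rng.normal(config.gars_mean, config.gars_sd, n), 18, 72)
        participated = rng.random(n) < config.participation_prob
        no_baseline = rng.random(n) < config.no_baseline_prob
        died = rng.random(n) < config.mortality_prob

        u0 = _truncnorm01(rng, config.utility_mean, config.utility_sd, n)
        u6 = np.clip(
            u0
            + config.effect_utility * mic
            + u_util[h]
            + rng.normal(0, config.utility_change_sd, n),
            0.0,
            1.0,
        )

        dim_mean = config.coopwonca_mean / 6
        dim_sd = config.coopwonca_sd / np.sqrt(6)
        cw_base = np.clip(
            np.round(rng.normal(dim_mean, dim_sd, (n, 6))), 1, 5
        ).astype(int)
        change = config.coopwonca_change_mean + config.effect_coopwonca * mic + u_cw[h]
        cw_fu = np.clip(
            np.round(
                cw_base
                + rng.normal(change / 6, config.coopwonca_change_sd / np.sqrt(6), (n, 6))
            ),
            1,
            5,
        ).astype(int)

        k = config.indicator_count
        applicable = rng.random((n, k)) < config.applicability_prob
        p = expit(logit(prev) + delta_qoc * mic + u_qoc[h])
        present = (rng.random((n, k)) < p[None, :]) & applicable

        z_gars = (gars - config.gars_mean) / config.gars_sd
        group_costs = {}
        for g in COST_GROUPS:
            mean_g = config.uc_cost_means[g] + config.effect_cost * config.cost_effect_shares[g] * mic
            mean_h = max(mean_g + u_cost[h], 1.0)
            gam = config.cost_gars_loadings.get(g, 0.0)
            scale_i = np.exp(gam * z_gars - gam**2 / 2)  # mean-one multiplier
            group_costs[g] = scale_i * _group_cost_draw(
                rng, mean_h, config.cost_shapes[g], config.cost_family, n
            )

        for i in range(n):
            pid += 1
            row = {
                "patient_id": pid,
                "home_id": home_ids[h],
                "arm": arm,
                "participated": bool(participated[i]),
                "age": age[i],
                "sex": "F" if female[i] else "M",
                "gars_baseline": gars[i],
                "no_baseline": bool(no_baseline[i]),
                "died": bool(died[i]),
                "utility_baseline": u0[i],
                "utility_6m": u6[i],
                "implementation_cost": (
                    config.implementation_cost_mic if mic else config.implementation_cost_uc
                ),
            }
            for d in range(6):
                row[f"cw_base_{d + 1}"] = cw_base[i, d]
                row[f"cw_fu_{d + 1}"] = cw_fu[i, d]
            for j in range(k):
                row[f"ind_app_{j + 1}"] = int(applicable[i, j])
                row[f"ind_pres_{j + 1}"] = int(present[i, j])
            rows.append(row)
            for g in COST_GROUPS:
                for cat, share in RESOURCE_SPLIT[g].items():
                    cost = group_costs[g][i] * share
                    resource_rows.append(
                        {
                            "patient_id": pid,
                            "category": cat,
                            "quantity": cost / prices.price(cat),
                        }
                    )

    patients = pd.DataFrame(rows)
    resource_use = pd.DataFrame(resource_rows)
    resource_use["quantity_true"] = resource_use["quantity"]
    return TrialDataset(patients=patients, resource_use=resource_use, prices=prices, config=config)


#: follow-up fields masked when a resident drops out (interview-based)
_FOLLOWUP_INTERVIEW_COLS = ["utility_6m"] + [f"cw_fu_{d}" for d in range(1, 7)]


def impose_missingness(data: TrialDataset, config: TrialConfig | None = None) -> TrialDataset:
    """Apply deaths and MAR dropout to a complete dataset.

    Dropout is Bernoulli per surviving participant with probability from
    the logistic model on age and baseline GARS — both retained observed
    covariates, so the mechanism is MAR by construction. Dropouts lose all
    interview-based follow-up data (follow-up utility, COOP WONCA charts,
    the indicator panel, informal-care hours); deaths mask all follow-up
    outcomes and resource use; record-based cost groups are additionally
    missing completely at random with ``cost_missing_prob`` per component.
    Pre-missingness truth is kept in ``*_true`` columns.
    """
    config = config or data.config
    rng = np.random.default_rng([config.seed, 1])
    patients = data.patients.copy()
    resource = data.resource_use.copy()
    k = config.indicator_count

    p_drop = config.dropout_model.probability(
        patients["age"], patients["gars_baseline"]
    )
    at_risk = patients["participated"] & ~patients["died"] & ~patients["no_baseline"]
    dropout = (rng.random(len(patients)) < p_drop) & at_risk
    patients["dropout_prob"] = p_drop
    patients["dropout"] = dropout
    patients["completer"] = at_risk & ~dropout

    panel_cols = [f"ind_app_{j}" for j in range(1, k + 1)] + [
        f"ind_pres_{j}" for j in range(1, k + 1)
    ]
    baseline_cols = (
        ["utility_baseline", "gars_baseline"] + [f"cw_base_{d}" for d in range(1, 7)]
    )
    mask_cols = _FOLLOWUP_INTERVIEW_COLS + panel_cols
    for col in mask_cols + baseline_cols:
        patients[f"{col}_true"] = patients[col]
    lost = (dropout | patients["died"]).to_numpy()
    patients.loc[lost, mask_cols] = np.nan
    patients.loc[patients["no_baseline"].to_numpy(), baseline_cols] = np.nan

    # resource use: informal care is interview-sourced -> lost with dropout;
    # record-based groups go missing component-wise, MCAR
    died_ids = set(patients.loc[patients["died"], "patient_id"])
    drop_ids = set(patients.loc[dropout, "patient_id"])
    groups = resource["category"].map(data.prices.groups)
    q = resource["quantity"].to_numpy(float)
    is_died = resource["patient_id"].isin(died_ids).to_numpy()
    is_drop = resource["patient_id"].isin(drop_ids).to_numpy()
    q[is_died] = np.nan
    q[is_drop & (groups == "informal_care").to_numpy()] = np.nan
    if config.cost_missing_prob > 0:
        alive_ids = patients.loc[~patients["died"] & patients["participated"], "patient_id"]
        miss = {
            (pid_, g)
            for pid_ in alive_ids
            for g in RECORD_BASED_GROUPS
            if rng.random() < config.cost_missing_prob
        }
        keys = list(zip(resource["patient_id"], groups))
        q[[key in miss for key in keys]] = np.nan
    resource["quantity"] = q
    return TrialDataset(patients=patients, resource_use=resource, prices=data.prices, config=config)


def simulate(config: TrialConfig, prices: UnitPriceTable | None = None) -> TrialDataset:
    """generate_trial followed by impose_missingness (the usual entry point)."""
    return impose_missingness(generate_trial(config, prices), config)
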