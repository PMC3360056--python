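"""End-to-end orchestration: simulate -> outcomes & costs -> impute ->
bootstrap -> CEA -> report.

Each stage reads its inputs from and writes its outputs to the run's
output directory, so stages can be re-run individually from the command
line. All tables are delimited text with a fixed float format, making a
re-run with the same configuration and seed byte-identical.

Analysis modes (exactly one per run):

* ``main`` — exclude residents who died or gave no baseline data, impute
  the rest (the primary analysis);
* ``complete_case`` — same exclusions, then restrict to residents with
  fully observed costs and effects, no imputation;
* ``license_only_costs`` — as main, but the intervention cost keeps only
  the assessment licensing/subscription component (usual-care meeting
  costs drop out as well);
* ``include_decedents`` — retain decedents (utility zero from death) and
  residents without baseline data; their missing values are imputed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, cea, costing, missing_data, outcomes, synthetic_data, uncertainty
from .errors import PipelineError, ValidationError

log = logging.getLogger("miccea")

MODES = ("main", "complete_case", "license_only_costs", "include_decedents")
OUTCOMES = {
    # column -> effect direction (is a larger raw value better or worse?)
    "qoc_score": "lower",
    "coopwonca_change": "higher",
    "qaly": "higher",
}
_FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    outdir: Path
    mode: str = "main"
    seed: int = 0
    trial: synthetic_data.TrialConfig | None = None  # None -> read input_dir
    input_dir: Path | None = None
    imputation: missing_data.ImputationSpec = field(default_factory=missing_data.ImputationSpec)
    bootstrap: uncertainty.BootstrapSpec = field(default_factory=uncertainty.BootstrapSpec)
    intervention_model: costing.InterventionCostModel = field(
        default_factory=costing.InterventionCostModel
    )
    license_components: tuple[str, ...] = ("interrai_assessment",)
    lambda_grids: dict = field(default_factory=dict)  # outcome -> array; default per outcome

    def __post_init__(self):
        self.outdir = Path(self.outdir)
        if self.mode not in MODES:
            raise ValidationError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.trial is None and self.input_dir is None:
            raise ValidationError("either a trial config (simulate) or input_dir is required")
        if self.input_dir is not None and not Path(self.input_dir).exists():
            raise ValidationError(f"input_dir does not exist: {self.input_dir}")
        # one root seed, split per stage
        ss = np.random.SeedSequence(self.seed)
        s = [int(x) & 0x7FFFFFFF for x in ss.generate_state(4)]
        self.stage_seeds = {"simulate": s[0], "impute": s[1], "bootstrap": s[2], "summary": s[3]}

    def grid(self, outcome: str) -> np.ndarray:
        if outcome in self.lambda_grids:
            return np.asarray(self.lambda_grids[outcome], float)
        return cea.default_lambda_grid(outcome)

    def to_manifest_dict(self) -> dict:
        d = {
            "version": __version__,
            "mode": self.mode,
            "seed": self.seed,
            "stage_seeds": self.stage_seeds,
            "imputation": dataclasses.asdict(self.imputation),
            "bootstrap": dataclasses.asdict(self.bootstrap),
            "intervention_model": dataclasses.asdict(self.intervention_model),
            "license_components": list(self.license_components),
        }
        if self.trial is not None:
            d["trial_config"] = self.trial.to_dict()
        if self.input_dir is not None:
            d["input_dir"] = str(self.input_dir)
        return d


def _write(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------- stages


def stage_simulate(cfg: RunConfig) -> synthetic_data.TrialDataset:
    """Generate (or ingest) the trial dataset and write the three input
    tables plus provenance."""
    if cfg.trial is not None:
        trial = cfg.trial.replace(seed=cfg.stage_seeds["simulate"])
        ds = synthetic_data.simulate(trial)
    else:
        ds = synthetic_data.TrialDataset.read(cfg.input_dir)
    ds.write(cfg.outdir / "data")
    n = len(ds.patients)
    log.info("simulate: %d residents invited, %d randomized", n, int(ds.patients["participated"].sum()))
    return ds


def stage_build(cfg: RunConfig, ds: synthetic_data.TrialDataset | None = None) -> pd.DataFrame:
    """Construct the per-patient analysis table: clinical outcomes, priced
    cost components, implementation costs, exclusion flags."""
    if ds is None:
        ds = synthetic_data.TrialDataset.read(cfg.outdir / "data")
    include_dec = cfg.mode == "include_decedents"
    patients = ds.patients[ds.patients["participated"]].reset_index(drop=True)

    out = outcomes.build_outcomes(
        patients, include_decedents=include_dec, indicator_count=ds.config.indicator_count
    )
    costs = costing.price_resource_use(
        ds.resource_use[ds.resource_use["patient_id"].isin(patients["patient_id"])],
        ds.prices,
        patient_ids=patients["patient_id"],
    )

    df = pd.DataFrame(
        {
            "patient_id": patients["patient_id"],
            "home_id": patients["home_id"],
            "arm": patients["arm"],
            "arm_mic": (patients["arm"] == "MIC").astype(int),
            "age": patients["age"],
            "sex_female": (patients["sex"] == "F").astype(int),
            "gars_baseline": patients["gars_baseline"],
            "utility_baseline": patients["utility_baseline"],
            "coopwonca_baseline": out["coopwonca_baseline"],
            "qoc_score": out["qoc_score"],
            "coopwonca_change": out["coopwonca_change"],
            "qaly": out["qaly"],
            "completer": patients["completer"],
            "excluded": out["excluded"],
            "exclusion_reason": out["exclusion_reason"],
        }
    )
    df = df.merge(costs.reset_index(), on="patient_id", how="left")

    if cfg.mode == "license_only_costs":
        model = cfg.intervention_model.masked(set(cfg.license_components))
        df["implementation"] = np.where(df["arm"] == "MIC", model.per_patient(), 0.0)
    else:
        df["implementation"] = patients["implementation_cost"].to_numpy()
    df["total_cost"] = df[list(costing.COST_GROUPS)].sum(axis=1, skipna=False) + df["implementation"]

    flow = {
        "invited": int(len(ds.patients)),
        "randomized": int(len(patients)),
        "no_baseline": int(patients["no_baseline"].sum()),
        "died": int(patients["died"].sum()),
    }
    analyzed = df[~df["excluded"]].drop(columns=["excluded", "exclusion_reason", "total"])
    flow["analyzed"] = int(len(analyzed))
    flow["completers"] = int(analyzed["completer"].sum())
    log.info("build: flow %s", flow)

    prof = missing_data.dropout_profile(analyzed)
    if not prof.suppressed:
        _write(prof.comparisons, cfg.outdir / "dropout_profile.csv")
    _write(analyzed, cfg.outdir / "analysis.csv")
    with open(cfg.outdir / "flow.json", "w") as fh:
        json.dump(flow, fh, indent=2, sort_keys=True)
    return analyzed


_IMPUTE_TARGETS = [
    "qoc_score",
    "coopwonca_change",
    "qaly",
    "primary_care",
    "secondary_care",
    "medication",
    "informal_care",
]


def stage_impute(cfg: RunConfig, analysis: pd.DataFrame | None = None) -> list[pd.DataFrame]:
    """Produce the completed dataset(s) for the chosen mode. Cost totals
    are recomputed from imputed components, never imputed directly."""
    if analysis is None:
        analysis = pd.read_csv(cfg.outdir / "analysis.csv")

    if cfg.mode == "complete_case":
        complete = analysis.dropna(subset=_IMPUTE_TARGETS).reset_index(drop=True)
        log.info("complete case: %d of %d residents fully observed", len(complete), len(analysis))
        completed = [complete]
    else:
        targets = list(_IMPUTE_TARGETS)
        spec = cfg.imputation
        if cfg.mode == "include_decedents":
            # baseline covariates can be missing here; impute them as well
            targets += ["utility_baseline", "coopwonca_baseline", "gars_baseline"]
            spec = dataclasses.replace(spec, predictors=("arm_mic", "age", "sex_female"))
        spec = dataclasses.replace(spec, seed=cfg.stage_seeds["impute"])
        completed = missing_data.impute(analysis, targets, spec)
        diag = missing_data.imputation_diagnostics(analysis, targets)
        _write(diag, cfg.outdir / "imputation_diagnostics.csv")
    for i, df in enumerate(completed):
        df["total_cost"] = df[list(costing.COST_GROUPS)].sum(axis=1) + df["implementation"]
        _write(df, cfg.outdir / f"completed_{i + 1}.csv")
    return completed


def _mi_bootstrap_ci(completed, col, spec) -> dict:
    """Pooled MIC-minus-UC difference for one column with a stacked-
    replicate percentile CI (B replicates per completed dataset)."""
    diffs, reps = [], []
    for i, df in enumerate(completed):
        mic = df.loc[df["arm"] == "MIC", col].to_numpy(float)
        uc = df.loc[df["arm"] == "UC", col].to_numpy(float)
        res = uncertainty.bootstrap_difference(
            mic, uc, spec=spec.replace(seed=spec.seed + i, ci_method="percentile")
        )
        diffs.append(res.point)
        reps.append(res.replicates)
    stacked = np.concatenate(reps)
    lo, hi = uncertainty.percentile_interval(stacked, spec.alpha)
    return {"difference": float(np.mean(diffs)), "ci_low": lo, "ci_high": hi}


def _pooled_arm_stats(completed, col, arm) -> tuple[float, float]:
    """Rubin-pooled arm mean and its standard error across imputations."""
    ests, variances = [], []
    for df in completed:
        v = df.loc[df["arm"] == arm, col].to_numpy(float)
        ests.append(v.mean())
        variances.append(v.var(ddof=1) / len(v))
    if len(completed) == 1:
        return ests[0], float(np.sqrt(variances[0]))
    pooled = missing_data.rubin_pool(ests, variances)
    return pooled.estimate, pooled.se


def stage_bootstrap(cfg: RunConfig, completed=None) -> dict[str, uncertainty.CEPairs]:
    """Bootstrap cost-category differences (study-shaped cost table),
    effect differences (study-shaped effects table) and the joint
    incremental cost-effect pairs per outcome."""
    if completed is None:
        m = cfg.imputation.m if cfg.mode != "complete_case" else 1
        completed = [
            pd.read_csv(cfg.outdir / f"completed_{i + 1}.csv")
            for i in range(m)
            if (cfg.outdir / f"completed_{i + 1}.csv").exists()
        ]
    spec = cfg.bootstrap.replace(seed=cfg.stage_seeds["bootstrap"])

    rows = []
    for j, col in enumerate(list(costing.ALL_GROUPS) + ["total_cost"]):
        stats = _mi_bootstrap_ci(completed, col, spec.replace(seed=spec.seed + 101 * j))
        mic_mean, mic_se = _pooled_arm_stats(completed, col, "MIC")
        uc_mean, uc_se = _pooled_arm_stats(completed, col, "UC")
        rows.append(
            {
                "category": col,
                "mic_mean": mic_mean,
                "mic_se": mic_se,
                "uc_mean": uc_mean,
                "uc_se": uc_se,
                **stats,
            }
        )
    _write(pd.DataFrame(rows), cfg.outdir / "costs_table.csv")

    rows = []
    pairs_by_outcome = {}
    for j, (col, direction) in enumerate(OUTCOMES.items()):
        stats = _mi_bootstrap_ci(completed, col, spec.replace(seed=spec.seed + 211 * j + 7))
        mic_mean, mic_se = _pooled_arm_stats(completed, col, "MIC")
        uc_mean, uc_se = _pooled_arm_stats(completed, col, "UC")
        rows.append(
            {
                "outcome": col,
                "mic_mean": mic_mean,
                "mic_se": mic_se,
                "uc_mean": uc_mean,
                "uc_se": uc_se,
                **stats,
            }
        )
        pairs = uncertainty.bootstrap_ce_pairs(
            completed,
            spec=spec.replace(seed=spec.seed + 499 * j + 13),
            outcome_kind=col,
            effect_direction=direction,
        )
        pairs_by_outcome[col] = pairs
        _write(pairs.replicates, cfg.outdir / f"ce_pairs_{col}.csv")
    _write(pd.DataFrame(rows), cfg.outdir / "effects_table.csv")
    return pairs_by_outcome


def stage_cea(cfg: RunConfig, pairs_by_outcome=None) -> pd.DataFrame:
    """ICERs, quadrant shares, acceptability curves and WTP thresholds."""
    if pairs_by_outcome is None:
        pairs_by_outcome = {}
        for col, direction in OUTCOMES.items():
            reps = pd.read_csv(cfg.outdir / f"ce_pairs_{col}.csv")
            pairs_by_outcome[col] = uncertainty.CEPairs(
                replicates=reps, outcome_kind=col, effect_direction=direction
            )
    effects = pd.read_csv(cfg.outdir / "effects_table.csv").set_index("outcome")
    costs = pd.read_csv(cfg.outdir / "costs_table.csv").set_index("category")
    delta_cost = float(costs.loc["total_cost", "difference"])

    rows = []
    for col, pairs in pairs_by_outcome.items():
        delta_effect = float(effects.loc[col, "difference"])
        res = cea.icer(delta_cost, delta_effect, direction=pairs.effect_direction)
        quad = cea.quadrant_proportions(pairs)
        curve = cea.ceac(pairs, cfg.grid(col))
        _write(
            pd.DataFrame({"lambda": curve.lambdas, "probability": curve.probabilities}),
            cfg.outdir / f"ceac_{col}.csv",
        )
        thresh = cea.wtp_threshold(curve, 0.95)
        rows.append(
            {
                "outcome": col,
                "delta_cost": res.delta_cost,
                "delta_effect_benefit_signed": res.delta_effect,
                "icer": res.icer,
                "quadrant": res.quadrant,
                "interpretable": res.interpretable,
                "prop_NE": quad["NE"],
                "prop_NW": quad["NW"],
                "prop_SE": quad["SE"],
                "prop_SW": quad["SW"],
                "ceac_max_probability": float(np.max(curve.probabilities)),
                "wtp_for_95pct": thresh if thresh is not None else np.nan,
            }
        )
    table = pd.DataFrame(rows)
    _write(table, cfg.outdir / "cea_table.csv")
    return table


def stage_report(cfg: RunConfig) -> dict:
    """Write the run manifest (config + seed + version + record flow)."""
    manifest = cfg.to_manifest_dict()
    flow_path = cfg.outdir / "flow.json"
    if flow_path.exists():
        manifest["record_flow"] = json.loads(flow_path.read_text())
    with open(cfg.outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest


_STAGES = ("simulate", "build", "impute", "bootstrap", "cea", "report")


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage in order; any stage failure aborts with the stage
    name and the underlying error code."""
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(cfg.outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    results = {}
    try:
        t0 = time.time()
        ds = _run_stage("simulate", stage_simulate, cfg)
        analysis = _run_stage("build", stage_build, cfg, ds)
        completed = _run_stage("impute", stage_impute, cfg, analysis)
        pairs = _run_stage("bootstrap", stage_bootstrap, cfg, completed)
        results["cea_table"] = _run_stage("cea", stage_cea, cfg, pairs)
        results["manifest"] = _run_stage("report", stage_report, cfg)
        log.info("pipeline complete in %.1f s", time.time() - t0)
    finally:
        log.removeHandler(handler)
        handler.close()
    return results


def _run_stage(name, fn, cfg, *args):
    t0 = time.time()
    try:
        out = fn(cfg, *args)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(name, exc) from exc
    log.info("stage %s done in %.2f s", name, time.time() - t0)
    return out


# ------------------------------------------------------------- config file


def load_run_config(path, outdir=None, seed=None, mode=None) -> RunConfig:
    """Build a RunConfig from a YAML file, with optional overrides."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kw = {}
    if "trial" in raw:
        kw["trial"] = synthetic_data.TrialConfig.from_dict(raw["trial"])
    if "input_dir" in raw:
        kw["input_dir"] = Path(raw["input_dir"])
    if "imputation" in raw:
        kw["imputation"] = missing_data.ImputationSpec(
            **{**raw["imputation"], "predictors": tuple(raw["imputation"].get("predictors", missing_data.DEFAULT_PREDICTORS))}
        )
    if "bootstrap" in raw:
        kw["bootstrap"] = uncertainty.BootstrapSpec(**raw["bootstrap"])
    if "intervention_model" in raw:
        kw["intervention_model"] = costing.InterventionCostModel(**raw["intervention_model"])
    if "license_components" in raw:
        kw["license_components"] = tuple(raw["license_components"])
    if "lambda_grids" in raw:
        kw["lambda_grids"] = {
            k: np.arange(v["start"], v["stop"], v["step"], dtype=float)
            for k, v in raw["lambda_grids"].items()
        }
    return RunConfig(
        outdir=Path(outdir if outdir is not None else raw.get("outdir", "results/run")),
        mode=mode if mode is not None else raw.get("mode", "main"),
        seed=seed if seed is not None else int(raw.get("seed", 0)),
        **kw,
    )
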