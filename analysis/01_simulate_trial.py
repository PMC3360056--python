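"""Generate the study-calibrated synthetic trial and summarize its baseline.

Creates the three delimited-text inputs (patients, resource use, unit
prices) for a cluster-randomized two-arm trial of 2 x 5 residential homes
(~46 residents each), and writes an arm-by-arm baseline characteristics
table to results/baseline_characteristics.csv.

Run from the repository root:  python analysis/01_simulate_trial.py [--seed 1]
"""

import argparse
from pathlib import Path

import pandas as pd

from miccea.synthetic_data import TrialConfig, simulate

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--outdir", type=Path, default=Path("scratch/analysis/data"))
args = parser.parse_args()

ds = simulate(TrialConfig(seed=args.seed))
ds.write(args.outdir)
p = ds.patients[ds.patients["participated"]]

rows = []
for arm, grp in p.groupby("arm"):
    rows.append(
        {
            "arm": arm,
            "n_randomized": len(grp),
            "mean_age": grp["age"].mean(),
            "female_pct": 100 * (grp["sex"] == "F").mean(),
            "mean_utility_baseline": grp["utility_baseline_true"].mean(),
            "mean_coopwonca_baseline": grp[[f"cw_base_{k}_true" for k in range(1, 7)]]
            .sum(axis=1)
            .mean(),
            "mean_gars_baseline": grp["gars_baseline_true"].mean(),
            "died_pct": 100 * grp["died"].mean(),
            "dropout_pct": 100 * grp["dropout"].mean(),
        }
    )
table = pd.DataFrame(rows)
Path("results").mkdir(exist_ok=True)
table.to_csv("results/baseline_characteristics.csv", index=False, float_format="%.3f")

print(f"wrote trial inputs to {args.outdir}")
print(
    f"invited {len(ds.patients)}, randomized {len(p)} "
    f"({(p['arm'] == 'MIC').sum()} MIC / {(p['arm'] == 'UC').sum()} UC)"
)
print(table.to_string(index=False))
print(
    "\nBaseline utilities sit near 0.64 and COOP WONCA totals near 18 in both "
    "arms, mirroring the balance of the study population; roughly one in ten "
    "residents dies over follow-up and about a third of survivors drop out."
)
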