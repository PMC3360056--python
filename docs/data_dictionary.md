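# Data dictionary

The generator (and any external dataset wishing to use the pipeline)
speaks three delimited-text tables plus a provenance sidecar.

## patients.csv — one row per invited resident

| column | type | meaning |
|---|---|---|
| patient_id | int | unique resident id |
| home_id | str | cluster id, e.g. `MIC-3`, `UC-1`; every home belongs to exactly one arm |
| arm | str | `MIC` (multidisciplinary integrated care) or `UC` (usual care), assigned at home level |
| participated | bool | consented and randomized (≈74% of invited) |
| age | float | years at baseline |
| sex | str | `F`/`M` |
| gars_baseline | float | Groningen Activity Restriction Scale, 18–72, higher = more ADL restriction |
| no_baseline | bool | provided no baseline data (baseline fields masked) |
| died | bool | died before the 6-month follow-up (all follow-up fields masked) |
| dropout | bool | surviving non-completer per the logistic MAR model |
| dropout_prob | float | model probability used for the dropout draw |
| completer | bool | participated, alive, baseline present, not dropped out |
| utility_baseline, utility_6m | float in [0,1] | SF-6D utilities at 0 and 6 months |
| cw_base_1..6, cw_fu_1..6 | int 1–5 | COOP WONCA chart dimensions at baseline / follow-up |
| ind_app_1..32 | 0/1 | quality indicator k applicable to this resident |
| ind_pres_1..32 | 0/1 | quality indicator k present (a care problem); present ⇒ applicable |
| implementation_cost | float € | per-patient implementation cost margin for the resident's arm |
| `*_true` | — | pre-missingness value of every maskable column (generator truth) |

## resource_use.csv — long format, one row per (resident, category)

| column | type | meaning |
|---|---|---|
| patient_id | int | resident |
| category | str | one of the 14 priced categories (see prices.csv) |
| quantity | float | visits / days / hours / euros over follow-up; NaN = unobserved |
| quantity_true | float | pre-missingness quantity |

## prices.csv — the 2007 unit-price table

| column | type | meaning |
|---|---|---|
| category | str | machine key, e.g. `gp_office_visit`, `hospital_overnight` |
| label | str | human-readable description |
| unit | str | per visit / per day / per hour / per euro |
| price_eur_2007 | float | unit price in 2007 euros (CPI-adjusted) |
| group | str | reporting group: primary_care, secondary_care, medication, informal_care |

`medication` has unit price 1.00: medication costs may be supplied
pre-costed, with the "quantity" being euros.

## provenance.yaml

The full `TrialConfig` (including the seed) that generated the dataset;
re-running the generator with it reproduces every file bit for bit.
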