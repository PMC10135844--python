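# lagfuse

Personalised multi-step blood glucose forecasting with **nested ensemble lag
fusion**.

## The problem

Data-driven glucose forecasters for type 1 diabetes predict the next 30 or
60 minutes of continuous glucose monitoring (CGM) readings from a look-back
window of recent glucose, physical activity, carbohydrate intake and bolus
insulin data. Choosing the look-back length is awkward: short histories miss
information, long histories add redundancy, and the best length differs
across patients — so per-patient lag tuning fragments the analysis while a
single global lag is suboptimal for most people.

`lagfuse` sidesteps lag selection by studying *all* candidate lags and
fusing them:

* **Non-stacking (base) models** — a one-hidden-layer MLP and a vanilla
  LSTM (100 hidden units each) are trained separately on look-back windows
  of 30, 60, 90 and 120 min (8 models per prediction horizon PH ∈ {30, 60}
  min). Each maps an L×4 lag block to the H-step future glucose sequence
  (H = PH/5 on the 5-min CGM grid).
* **Stacking models** — per learner family, a meta-learner of the same
  family takes the four base models' predicted sequences as a 4-channel
  input and fuses them (2 models per horizon).
* **Nested stacking models** — a second-level meta-learner (one MLP, one
  LSTM) fuses the outputs of the two stacking models (2 models per
  horizon).

All networks share one blueprint: He-uniform initialisation, ReLU, MSE
loss, Adam, 100 epochs, batch 32, learning rate 0.01 reduced ×0.1 on a
10-epoch validation plateau. Models are evaluated on held-out test days
with MAE, RMSE, MAPE and r² (regression view), plus the Matthews
correlation coefficient over adverse-event labels (hypoglycaemia <70,
hyperglycaemia >180 mg/dL) and surveillance-error summaries (mean risk ASE,
risk-free proportion SE<0.5) for the clinical view. Model types are then
compared across patients with the Friedman test, post-hoc Nemenyi pairwise
tests, Holm–Bonferroni adjustment and critical-difference diagrams.

Because the reference clinical datasets (OhioT1DM) are access-restricted, a
synthetic cohort generator reproduces their structure — weeks of 5-min CGM
with missing runs, 1-min activity, sparse self-reported events, a final
test split — so the whole pipeline runs offline. An OhioT1DM XML loader is
included for licence holders.

## Worked example

```python
from lagfuse import CohortConfig, generate_patient, run_patient
from lagfuse.learners import TrainConfig
from lagfuse.metrics import evaluate

cfg = CohortConfig(n_patients=3, days_total=7, days_test=2, seed=3)
raw = generate_patient(cfg, 2)          # one synthetic patient

runs = {}
for seed in (0, 1):                     # two training runs
    for ps in run_patient(raw, horizons=(30,), cfg=TrainConfig(epochs=20),
                          run_seed=seed, base_kinds=("mlp",)):
        runs.setdefault(ps.model_id, []).append(ps)

for model_id, pred_sets in runs.items():
    rep = evaluate(pred_sets, policy="endpoint")
    print(f"{model_id}: RMSE {rep.mean('rmse'):.2f} ± {rep.sd('rmse'):.2f} mg/dL, "
          f"MCC {rep.mean('mcc'):.2f}, SE<0.5 {rep.mean('se50'):.2f}")
```

prints

```
('non-stacking', 'mlp', 30): RMSE 36.59 ± 0.05 mg/dL, MCC 0.54, SE<0.5 0.96
('non-stacking', 'mlp', 60): RMSE 35.97 ± 0.31 mg/dL, MCC 0.54, SE<0.5 0.95
('non-stacking', 'mlp', 90): RMSE 36.83 ± 0.09 mg/dL, MCC 0.51, SE<0.5 0.94
('non-stacking', 'mlp', 120): RMSE 35.52 ± 0.01 mg/dL, MCC 0.54, SE<0.5 0.95
('stacking', 'mlp', 'fused'): RMSE 36.10 ± 0.27 mg/dL, MCC 0.52, SE<0.5 0.95
('nested', 'mlp', 'fused'): RMSE 36.06 ± 0.13 mg/dL, MCC 0.51, SE<0.5 0.95
```

Each line is one model's test-span performance, mean ± SD over the two
training runs, evaluated at the value exactly 30 min ahead of each window:
RMSE in mg/dL, the adverse-event MCC, and the fraction of clinically
risk-free predictions. The fused models track the best single-lag model
without knowing which lag that is — the point of lag fusion.

## Command line

```sh
lagfuse simulate cohort/ --n-patients 6          # synthetic cohort as CSVs
lagfuse curate cohort/ curated/                  # six curation steps -> tidy CSV
lagfuse run --manifest experiment.yaml           # full pipeline, cached + resumable
lagfuse run --manifest experiment.yaml --dry-run # print the unit plan
lagfuse report --manifest experiment.yaml        # tables + CD diagrams
```

The YAML manifest names the data source (synthetic config, interchange CSV
directory, or OhioT1DM XML directory), horizons, lags, seeds, evaluation
policy and output directory; every output is stamped with the manifest
hash, and completed (patient, horizon, seed) units are skipped on re-runs.

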