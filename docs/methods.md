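# Methods

## Data model and curation

A patient record holds four channels: CGM glucose (mg/dL, nominally every
5 min), physical activity (heart rate or acceleration magnitude, 1- or
5-min), and self-reported carbohydrate (g) and bolus insulin (U) events.
Curation applies six steps in a fixed order:

1. **Trimming.** Sensor channels start/end when the devices were worn, at
   unequal times; all channels are cut to the common span
   [max(starts), min(ends)].
2. **Missingness.** Training-span gaps in sensor channels are filled by
   linear interpolation between observed neighbours. Test-span gaps are
   filled *causally*: each missing point is the linear continuation of the
   two most recent observed points, applied stepwise through a gap, so
   evaluation never observes future values and the models remain usable for
   real-time monitoring. A test gap with fewer than two prior observations
   falls back to carrying the last observation forward (logged). Filled
   glucose is clipped to the CGM reporting range [40, 400] mg/dL, because
   slope continuation through a long gap can otherwise leave the
   physiological band entirely (logged when it happens).
3. **Sparsity.** Non-reported timestamps in the event channels mean
   "nothing to report": carbs and bolus are densified to the CGM grid with
   zeros elsewhere; events map to their nearest grid point (ties toward the
   earlier point) and collisions are summed (logged).
4. **Alignment.** 1-min activity is downsampled by keeping, for each CGM
   timestamp, the temporally nearest activity sample (ties toward the
   earlier sample). A record with no activity channel degrades to 3-channel
   mode with a warning.
5. **Standardisation.** Every channel is centred and scaled by its
   *training-set* mean and SD (test data reuse the training statistics). A
   constant training channel is an error naming the channel.
6. **Differencing and reframing.** First-order differences stabilise the
   mean; the leading point is dropped rather than padded. KPSS and ADF
   tests are available as an advisory stationarity report (verdict
   "stationary" iff ADF rejects its unit-root null and KPSS fails to reject
   level-stationarity at 5%); the pipeline does not gate on it. A rolling
   window then produces supervised pairs: an L-step, 4-channel lag block
   against the next H glucose differences. On a contiguous segment of
   length n there are n−L−H+1 windows. Test windows may take lag context
   from before the split (past data at prediction time), so the first test
   target is the first test timestamp; windows whose target sequence
   straddles the split belong to neither role, and no training target
   touches the test span.

Models predict on the standardised-differenced scale. For evaluation,
predicted differences are cumulatively summed from the window's **anchor**
— the scaled glucose at the last lag timestamp, always available at
prediction time — and the standardisation is inverted, returning mg/dL.
The transform round-trip is exact to numerical precision; inverting the
true targets reproduces the curated glucose identically. Whether the
exogenous channels should also be differenced is not observable from the
modelling contract; all channels are treated uniformly, and the choice is
isolated behind the inversion helper.

## Learners

Both families have exactly one hidden layer of 100 units and a linear dense
output of H units (6 or 12 steps):

* MLP: flattened L×4 block → dense(100, ReLU) → dense(H);
* LSTM: sequence input → single vanilla LSTM(100) → dense(H).

He-uniform initialisation (forget-gate bias 1 for the LSTM), MSE loss, Adam
(β₁ = 0.9, β₂ = 0.999), 100 epochs, batch 32. The learning rate starts at
0.01 and is multiplied by 0.1 whenever the validation loss fails to improve
by more than 1e-4 for 10 consecutive epochs. The validation split is the
chronologically last 20% of the training windows — the only leakage-safe
choice for time series; batches are shuffled within the training split
only, governed by the run seed. The networks are implemented directly on
numpy: at this size a framework adds nothing, and a pure-numpy
implementation is bit-reproducible for a fixed seed, which the pipeline's
determinism contracts (and caching) rely on. Per-model seeds are derived
from (run seed, level, family, lag, horizon) through `SeedSequence`, so
cohorts, models and whole experiments are reproducible and extensible.

## Ensemble levels

Per patient and horizon: 8 base models (2 families × 4 lags of 30/60/90/120
min), 2 stacking models, 2 nested stacking models. Stacking meta-features
are the base models' predicted H-step sequences arranged as H steps × 4
channels (lag order fixed ascending); the nested meta-input is H steps × 2
channels (MLP stack first, then LSTM stack — fixed for weight
reproducibility). Meta-learners are trained on the already-trained base
models' *in-sample* predictions over the training span; an out-of-fold mode
would be a drop-in change behind `build_meta_features`, but in-sample is
the literal reading of the blueprint and is the default. Training windows
are aligned across lags on common end-times (the longest lag has the fewest
early windows); test windows share end-times across lags by construction.

## Evaluation

Seven metrics: MAE, RMSE (mg/dL), MAPE (%), r² (%, reference mean in the
denominator), MCC over adverse-event labels (glucose below 70 or above
180 mg/dL is adverse; the boundaries count as euglycaemic; a zero factor in
the MCC denominator yields 0, logged), and two surveillance-error
summaries: ASE (mean per-point risk) and SE<0.5 (proportion of risk-free
points). Metrics are computed per training run and reported as mean ±
population SD over runs.

The **evaluation-point policy** defaults to `endpoint`: only the value
exactly PH minutes ahead of each window is scored, the convention of the
glucose-prediction challenges this task comes from. Pooling all H steps
(`all`) is available, and the experiment manifest records which policy
produced any report.

The **surveillance risk surface** shipped in `data/seg_grid_synthetic.csv`
is a synthetic surrogate, not the clinically surveyed grid (which is not
redistributable): risk = 0.65·|s(pred) − s(ref)| on a monotone log-based
clinical-severity scale, tabulated over 20–580 mg/dL in 10 mg/dL steps and
looked up by bilinear interpolation, with out-of-band values clipped
(logged). It preserves every property the pipeline relies on — zero
diagonal, monotone growth away from the reference, small euglycaemic
deviations under the 0.5 risk-free cut-off, categories spanning ~0–4 —
but its absolute magnitudes are not comparable with values computed on the
clinical surface.

## Statistical comparison

For each (metric, horizon, family) panel — 7 × 2 × 2 = 28 panels — patients
are independent blocks. The representative single-lag model per patient is
the lag winning the most of the seven metrics (ties mark all; remaining
ties broken by lower RMSE, then lag order). The Friedman statistic
χ²_F = 12N/(k(k+1))·[Σ R̄_j² − k(k+1)²/4] uses within-row average ranks
(rank 1 = best under the metric's orientation); its p-value comes from the
χ²(k−1) approximation, with a seeded within-row permutation null available
for small cohorts (used automatically at N ≤ 12, where the χ² approximation
is optimistic). When Friedman rejects at 5%, pairwise Nemenyi p-values are
computed from the studentised-range distribution and the Holm–Bonferroni
step-down rule is applied to them as the significance gate (both raw and
Holm-gated decisions are kept); the critical distance is
CD = q_α·√(k(k+1)/(6N)) with q_α the studentised-range quantile over √2
(2.343 at k = 3, α = 0.05). Critical-difference diagrams default to the
classical convention (links join groups *not* separated by more than CD);
the inverse convention (linking significantly different pairs) is also
supported.

## Synthetic cohort

The generator emulates the structure of multi-week T1D sensor studies: 56
days per patient with the last 10 as the test split, glucose as a circadian
baseline (140 ± 25 mg/dL) plus a slow AR(1) wander (SD ≈ 12 mg/dL),
gamma-shaped meal excursions (~0.8 mg/dL per gram, peaking 40 min
post-meal), bolus responses (~7 mg/dL drop per unit, nadir at 75 min),
exercise bouts that raise heart rate and mildly lower glucose, sensor noise
(SD 3 mg/dL), clipping to [40, 400] mg/dL, ~10% missingness in
geometric-length runs (mean 30 min) from a two-state Markov dropout, ~3
meals and boluses per day (boluses mostly meal-paired), and channel
head/tail offsets. Patient streams derive from per-patient `SeedSequence`
keys, so cohorts are deterministic and extensible. An optional
patient-specific glucose oscillation (`lag_signal_amp`, default off) gives
each patient a different dominant period, constructing cohorts where the
most informative look-back length provably differs across patients — used
to exercise the lag-fusion claim.

The generator is a structural fixture, not a metabolic simulator: it
reproduces autocorrelation, event-driven excursions, gaps and sparsity, but
no insulin–glucose physiology, sensor drift, compression artefacts or
behavioural patterns. Tests passing on it show the pipeline's mechanics and
contracts are right; they do not certify clinical accuracy on real CGM
data.

## Problem sizes and numerical choices

Library defaults keep the full protocol (56-day records, 100 epochs, five
run seeds 0–4). The test suite and `scripts/acceptance.py` run the same
code at desk scale — records of 6–8 days, 2–30 epochs, 2–5 runs, 3–6
patients — chosen so the whole suite completes in minutes on one CPU while
every structural property (model counts, alignment, leakage, determinism,
schedule behaviour) is exercised at full fidelity. Degenerate inputs fail
loudly: empty sensor overlap, all-missing channels, constant training
channels, series shorter than L+H, single-class MCC references (warned, 0),
non-finite losses. Ties everywhere break deterministically (earlier grid
point, earlier sample, lower RMSE, first lag).

## Known limitations

* In-sample stacking lets meta-learners see base-model fit to their own
  training data; with flexible bases this can bias the fusion toward
  overfit lags. The module boundary admits an out-of-fold mode.
* The surrogate risk surface supports relative, not absolute, clinical
  risk statements.
* The causal test-fill is a two-point extrapolant; long gaps produce
  low-fidelity (clipped) reference values that are then scored as if
  observed — inherent to evaluating on gap-filled test spans.
* The χ² Friedman approximation is coarse for few patients; the permutation
  fallback mitigates but small-N comparisons remain low-powered.
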