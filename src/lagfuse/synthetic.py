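"""Synthetic diabetes cohort generator.

Emulates the structure of multi-week type 1 diabetes datasets collected with
a continuous glucose monitor (5-min grid), a fitness band (1- or 5-min
physical activity), and self-reported carbohydrate and bolus insulin events:
several weeks per patient with the final days held out as a test split,
missing spans in the sensor channels, strictly sparse event channels, and
channels that start and end at unequal times.

The glucose trace is an AR(1)-smoothed circadian baseline plus parametric
meal and bolus response kernels and Gaussian sensor noise. This is a
structural fixture, not a metabolic simulator: its only contract is the
statistical shape the downstream pipeline assumes (autocorrelation,
event-driven excursions, gaps, sparsity).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError

#: physiological clipping band for the CGM channel, mg/dL
BG_MIN, BG_MAX = 40.0, 400.0

#: fixed cohort epoch; absolute dates carry no meaning in the fixture
EPOCH = pd.Timestamp("2021-01-04 00:00:00")

#: mean missing-run length in grid steps (geometric runs, ~30 min on a 5-min grid)
MEAN_GAP_STEPS = 6.0

#: minutes after a carb event at which the meal excursion peaks
MEAL_PEAK_MIN = 40.0
#: minutes after a bolus at which the glucose-lowering effect peaks
BOLUS_PEAK_MIN = 75.0


@dataclass(frozen=True)
class CohortConfig:
    """Configuration of a synthetic cohort.

    Defaults mirror the acquisition protocol the pipeline targets: eight
    weeks per patient on a 5-min CGM grid with the last ten days held out
    for testing, 1-min activity sampling, ~10% sensor missingness in
    geometric runs, a few self-reported meals and boluses per day, and a
    few mg/dL of sensor noise.
    """

    n_patients: int
    days_total: int = 56
    days_test: int = 10
    bg_sampling: int = 5
    activity_sampling: int = 1
    missing_rate_bg: float = 0.10
    missing_rate_activity: float = 0.10
    meal_rate: float = 3.0
    bolus_rate: float = 3.0
    noise_sd: float = 3.0
    seed: int = 0
    # Optional patient-specific oscillation (amplitude mg/dL). When > 0 each
    # patient receives a glucose oscillation with a period cycling over
    # `lag_periods_min`, so the most informative look-back length differs
    # across patients by construction.
    lag_signal_amp: float = 0.0
    lag_periods_min: tuple[int, ...] = (60, 90, 120, 180)

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be >= 1")
        if not self.days_test < self.days_total:
            raise ConfigurationError("days_test must be < days_total")
        if self.bg_sampling not in (1, 5) or self.activity_sampling not in (1, 5):
            raise ConfigurationError("sampling intervals must be 1 or 5 minutes")
        for name in ("missing_rate_bg", "missing_rate_activity", "meal_rate",
                     "bolus_rate", "noise_sd", "lag_signal_amp"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not (self.missing_rate_bg < 1 and self.missing_rate_activity < 1):
            raise ConfigurationError("missing rates must be < 1")


@dataclass
class RawPatientData:
    """One patient's raw, uncurated record.

    ``bg`` and ``activity`` are timestamped sensor series with gaps
    (missing grid points are absent rows, not NaNs); ``carbs`` and
    ``bolus`` are sparse self-reported event series whose timestamps need
    not lie on the CGM grid. ``split_time`` is the first test timestamp.
    """

    patient_id: str
    bg: pd.Series
    activity: pd.Series
    carbs: pd.Series
    bolus: pd.Series
    split_time: pd.Timestamp


def meal_response(t_min: np.ndarray, grams: float) -> np.ndarray:
    """Glucose excursion (mg/dL) ``t_min`` minutes after eating ``grams`` g.

    Gamma-shaped rise peaking ``MEAL_PEAK_MIN`` minutes post-meal at
    ~0.8 mg/dL per gram, decayed by ~3 h.
    """
    tau = MEAL_PEAK_MIN / 2.0
    x = np.clip(t_min, 0.0, None) / tau
    kernel = (x ** 2) * np.exp(2.0 - x) / 4.0  # peak value 1 at x=2
    return 0.8 * grams * kernel


def bolus_response(t_min: np.ndarray, units: float) -> np.ndarray:
    """Glucose drop (mg/dL, negative) ``t_min`` minutes after ``units`` U bolus.

    Single-peak kernel with nadir ``BOLUS_PEAK_MIN`` minutes post-injection
    at ~7 mg/dL per unit, tailing off over ~5 h.
    """
    x = np.clip(t_min, 0.0, None) / BOLUS_PEAK_MIN
    kernel = x * np.exp(1.0 - x)  # peak value 1 at x=1
    return -7.0 * units * kernel


def _patient_rng(seed: int, patient_index: int) -> np.random.Generator:
    # Splittable discipline: one SeedSequence keyed by (seed, index) so
    # cohorts are reproducible and extensible patient by patient.
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(patient_index)]))


def _geometric_missing_mask(n: int, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Two-state Markov dropout: stationary missing fraction ``rate``,
    geometric missing-run lengths with mean ``MEAN_GAP_STEPS``."""
    if rate <= 0:
        return np.zeros(n, dtype=bool)
    p_exit = 1.0 / MEAN_GAP_STEPS
    p_enter = rate * p_exit / (1.0 - rate)
    u = rng.random(n)
    missing = np.empty(n, dtype=bool)
    state = rng.random() < rate
    for i in range(n):
        missing[i] = state
        if state:
            state = not (u[i] < p_exit)
        else:
            state = u[i] < p_enter
    return missing


def generate_patient(cfg: CohortConfig, patient_index: int) -> RawPatientData:
    """Generate one synthetic patient, deterministic in (seed, patient_index)."""
    cfg.validate()
    if not 0 <= patient_index < cfg.n_patients:
        raise ConfigurationError("patient_index out of range")
    rng = _patient_rng(cfg.seed, patient_index)

    n_min = cfg.days_total * 24 * 60
    t_min = np.arange(n_min, dtype=float)  # minute grid for latent trace
    hours = t_min / 60.0

    # latent glucose: circadian baseline + slow AR(1) wander
    baseline = 140.0 + 25.0 * np.sin(2 * np.pi * (hours - 6.0) / 24.0)
    phi = 0.995  # on the minute grid: smooth, hours-scale decorrelation
    innov = rng.normal(0.0, 1.0, n_min)
    ar = np.empty(n_min)
    ar[0] = innov[0] / np.sqrt(1 - phi**2)
    for i in range(1, n_min):
        ar[i] = phi * ar[i - 1] + innov[i]
    ar *= 12.0 * np.sqrt(1 - phi**2)  # stationary SD ~12 mg/dL
    latent = baseline + ar

    if cfg.lag_signal_amp > 0:
        period = cfg.lag_periods_min[patient_index % len(cfg.lag_periods_min)]
        phase = rng.uniform(0, 2 * np.pi)
        latent = latent + cfg.lag_signal_amp * np.sin(2 * np.pi * t_min / period + phase)

    # self-reported events: meals with paired boluses plus corrections
    n_meals = rng.poisson(cfg.meal_rate * cfg.days_total)
    meal_t = np.sort(rng.uniform(0, n_min - 240, n_meals))
    meal_g = rng.uniform(20.0, 80.0, n_meals)
    for tm, g in zip(meal_t, meal_g):
        latent += meal_response(t_min - tm, g)

    bolus_t, bolus_u = [], []
    n_bolus_target = rng.poisson(cfg.bolus_rate * cfg.days_total)
    paired = min(n_meals, n_bolus_target)
    pick = rng.choice(n_meals, size=paired, replace=False) if n_meals else np.array([], int)
    for j in sorted(pick):
        bolus_t.append(meal_t[j] + rng.uniform(0, 15))
        bolus_u.append(meal_g[j] / 10.0 + rng.normal(0, 0.5))
    for _ in range(n_bolus_target - paired):
        bolus_t.append(rng.uniform(0, n_min - 300))
        bolus_u.append(rng.uniform(1.0, 4.0))
    order = np.argsort(bolus_t)
    bolus_t = np.asarray(bolus_t, float)[order]
    bolus_u = np.clip(np.asarray(bolus_u, float)[order], 0.5, None)
    for tb, u in zip(bolus_t, bolus_u):
        latent += bolus_response(t_min - tb, u)

    # activity: heart-rate-like with circadian swing and exercise bouts
    act = 70.0 + 8.0 * np.sin(2 * np.pi * (hours - 14.0) / 24.0)
    n_bouts = rng.poisson(1.0 * cfg.days_total)
    for _ in range(n_bouts):
        t0 = rng.uniform(6 * 60, n_min - 90)
        dur = rng.uniform(20, 60)
        in_bout = (t_min >= t0) & (t_min < t0 + dur)
        act = act + 40.0 * in_bout
        # activity mildly lowers glucose during/after a bout
        latent += -15.0 * np.exp(-np.clip(t_min - t0, 0, None) / 90.0) * (t_min >= t0)
    act = act + rng.normal(0.0, 3.0, n_min)

    # sample onto sensor grids, add noise, clip, inject missing runs
    bg_step = cfg.bg_sampling
    bg_idx = np.arange(0, n_min, bg_step)
    bg_vals = latent[bg_idx] + rng.normal(0.0, cfg.noise_sd, bg_idx.size)
    bg_vals = np.clip(bg_vals, BG_MIN, BG_MAX)

    act_step = cfg.activity_sampling
    act_idx = np.arange(0, n_min, act_step)
    act_vals = act[act_idx]

    start = EPOCH
    bg_times = start + pd.to_timedelta(bg_idx, unit="m")
    act_times = start + pd.to_timedelta(act_idx, unit="m")

    # unequal heads/tails so that trimming is always exercised: the activity
    # band is worn later/removed earlier than the CGM sensor
    act_head = int(rng.integers(1, 40))
    act_tail = int(rng.integers(1, 40))
    act_sl = slice(act_head, act_idx.size - act_tail)

    bg = pd.Series(bg_vals, index=bg_times, name="bg")
    activity = pd.Series(act_vals[act_sl], index=act_times[act_sl], name="activity")

    bg_miss = _geometric_missing_mask(len(bg), cfg.missing_rate_bg, rng)
    act_miss = _geometric_missing_mask(len(activity), cfg.missing_rate_activity, rng)
    bg = bg[~bg_miss]
    activity = activity[~act_miss]

    carbs = pd.Series(
        meal_g, index=start + pd.to_timedelta(np.round(meal_t), unit="m"), name="carbs"
    )
    bolus = pd.Series(
        bolus_u, index=start + pd.to_timedelta(np.round(bolus_t), unit="m"), name="bolus"
    )

    split_time = start + pd.Timedelta(days=cfg.days_total - cfg.days_test)
    return RawPatientData(
        patient_id=f"S{patient_index:03d}",
        bg=bg,
        activity=activity,
        carbs=carbs,
        bolus=bolus,
        split_time=split_time,
    )


def generate_cohort(cfg: CohortConfig) -> list[RawPatientData]:
    """Generate the full cohort in stable patient order."""
    cfg.validate()
    return [generate_patient(cfg, i) for i in range(cfg.n_patients)]


# ---------------------------------------------------------------------------
# interchange format: one CSV per channel per patient + a small meta file
# ---------------------------------------------------------------------------

_CHANNELS = ("bg", "activity", "carbs", "bolus")


def write_interchange(raw: RawPatientData, outdir: str | Path) -> Path:
    """Write a patient as per-channel CSVs (ISO-8601 timestamps) + meta.json."""
    pdir = Path(outdir) / raw.patient_id
    pdir.mkdir(parents=True, exist_ok=True)
    for ch in _CHANNELS:
        s: pd.Series = getattr(raw, ch)
        df = pd.DataFrame({"ts": s.index.strftime("%Y-%m-%dT%H:%M:%S"), "value": s.values})
        df.to_csv(pdir / f"{ch}.csv", index=False)
    meta = {"patient_id": raw.patient_id, "split_time": raw.split_time.isoformat()}
    (pdir / "meta.json").write_text(json.dumps(meta, indent=1))
    return pdir


def read_interchange(pdir: str | Path) -> RawPatientData:
    """Read one patient directory written by :func:`write_interchange`."""
    pdir = Path(pdir)
    meta = json.loads((pdir / "meta.json").read_text())
    series = {}
    for ch in _CHANNELS:
        df = pd.read_csv(pdir / f"{ch}.csv")
        idx = pd.to_datetime(df["ts"])
        series[ch] = pd.Series(df["value"].to_numpy(float), index=idx, name=ch)
    return RawPatientData(
        patient_id=meta["patient_id"],
        split_time=pd.Timestamp(meta["split_time"]),
        **series,
    )


def read_interchange_dir(root: str | Path) -> list[RawPatientData]:
    """Read every patient directory under ``root`` (sorted by id)."""
    root = Path(root)
    return [read_interchange(p) for p in sorted(root.iterdir()) if (p / "meta.json").exists()]
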