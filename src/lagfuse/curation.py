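"""Pre-modelling curation of raw diabetes time series.

Six steps, applied in a fixed order:

1. trim the head/tail of all sensor channels to their common span;
2. fill missing sensor values — linear interpolation inside the training
   span, causal linear extrapolation inside the test span (so evaluation
   never observes future values);
3. densify the sparse self-reported event channels (zero at non-reported
   grid points);
4. align the activity channel onto the 5-min CGM grid (nearest-neighbour
   downsampling, ties toward the earlier sample);
5. standardise every channel with training-set statistics only;
6. first-order difference to stabilise the mean, then reframe the series
   into supervised (lag block -> future glucose sequence) window pairs.

Stationarity of the transformed series can be checked with KPSS and ADF
tests; the check is advisory and does not gate the pipeline.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ContractViolation, CurationError
from .synthetic import BG_MAX, BG_MIN, RawPatientData

logger = logging.getLogger(__name__)

#: fixed channel order of every lag block
CHANNEL_ORDER = ("bg", "activity", "carbs", "bolus")


@dataclass
class PatientSeries:
    """Aligned, gap-free multivariate series on a constant 5-min grid."""

    patient_id: str
    grid: pd.DatetimeIndex
    channels: dict[str, np.ndarray]
    split_index: int  # first test grid point
    transformed: bool = False

    @property
    def n(self) -> int:
        return len(self.grid)

    def validate(self) -> None:
        if len(self.grid) < 2:
            raise CurationError("series too short")
        steps = np.diff(self.grid.asi8)
        if not (steps > 0).all() or len(set(steps)) != 1:
            raise CurationError("grid must be strictly increasing with a constant step")
        for name, vals in self.channels.items():
            if len(vals) != self.n:
                raise CurationError(f"channel {name} length mismatch")
            if not np.isfinite(vals).all():
                raise CurationError(f"channel {name} contains missing values")


@dataclass
class ScalerState:
    """Training-set standardisation statistics plus differencing anchors.

    Stores everything needed to invert the standardise-then-difference
    transform exactly: per-channel train mean/SD, each channel's initial
    scaled value (consumed by differencing), the last scaled training
    value, and the full scaled (undifferenced) glucose trace from which
    per-window inversion anchors are read.
    """

    mean: dict[str, float]
    sd: dict[str, float]
    initial_scaled: dict[str, float]
    last_train_scaled: dict[str, float]
    split_index: int
    z_bg: np.ndarray  # scaled undifferenced glucose on the original grid

    def anchor(self, target_start_index: int | np.ndarray) -> np.ndarray:
        """Scaled glucose at the last lag timestamp of a window whose first
        predicted point has original grid index ``target_start_index``."""
        idx = np.asarray(target_start_index) - 1
        if np.any(idx < 0) or np.any(idx >= len(self.z_bg)):
            raise ContractViolation("anchor index outside the series")
        return self.z_bg[idx]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "mean": self.mean,
            "sd": self.sd,
            "initial_scaled": self.initial_scaled,
            "last_train_scaled": self.last_train_scaled,
            "split_index": self.split_index,
            "z_bg": self.z_bg.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "ScalerState":
        d = json.loads(Path(path).read_text())
        d["z_bg"] = np.asarray(d["z_bg"], float)
        return cls(**d)


@dataclass(frozen=True)
class StationarityReport:
    kpss_stat: float
    kpss_p: float
    adf_stat: float
    adf_p: float
    verdict: str  # stationary | non-stationary | inconclusive


@dataclass
class WindowedSet:
    """Supervised windows for one (lag, horizon) setting.

    ``X`` has shape (n_windows, lag_len, 4) in :data:`CHANNEL_ORDER`;
    ``y`` has shape (n_windows, horizon_len) and holds the future glucose
    sequence on the transformed scale. ``t0_index``/``end_index`` are the
    original-grid indices of each window's first/last predicted point.
    """

    lag_len: int
    horizon_len: int
    X: np.ndarray
    y: np.ndarray
    t0_index: np.ndarray
    end_index: np.ndarray
    window_end_times: pd.DatetimeIndex
    role: str  # train | test

    @property
    def n_windows(self) -> int:
        return len(self.y)


# ---------------------------------------------------------------------------
# step 1: trimming
# ---------------------------------------------------------------------------

def trim_common_span(raw: RawPatientData) -> RawPatientData:
    """Trim all channels to the common [max(starts), min(ends)] sensor span."""
    sensors = [s for s in (raw.bg, raw.activity) if len(s)]
    if not sensors:
        raise CurationError("no sensor data")
    start = max(s.index[0] for s in sensors)
    end = min(s.index[-1] for s in sensors)
    if start > end:
        raise CurationError("sensor channels have no overlapping span")

    def cut(s: pd.Series) -> pd.Series:
        if len(s) == 0:
            return s
        return s[(s.index >= start) & (s.index <= end)]

    return RawPatientData(
        patient_id=raw.patient_id,
        bg=cut(raw.bg),
        activity=cut(raw.activity),
        carbs=cut(raw.carbs),
        bolus=cut(raw.bolus),
        split_time=raw.split_time,
    )


# ---------------------------------------------------------------------------
# step 2: missingness treatment
# ---------------------------------------------------------------------------

def fill_missing_train(series: pd.Series, grid: pd.DatetimeIndex) -> np.ndarray:
    """Linear interpolation of missing grid points from observed neighbours.

    Observed points pass through unchanged; leading/trailing gaps hold the
    nearest observed value (interpolation has no bracketing pair there).
    """
    obs = series.dropna()
    if len(obs) < 2:
        raise CurationError("need at least two observed points to interpolate")
    t = grid.asi8.astype(float)
    to = obs.index.asi8.astype(float)
    filled = np.interp(t, to, obs.to_numpy(float))
    # exact pass-through of observed on-grid points
    pos = grid.get_indexer(obs.index)
    ok = pos >= 0
    filled[pos[ok]] = obs.to_numpy(float)[ok]
    return filled


def fill_missing_test(series: pd.Series, grid: pd.DatetimeIndex) -> np.ndarray:
    """Causal fill: each missing point is the linear continuation of the two
    most recent *observed* points, applied stepwise through a gap.

    A gap at the very start with fewer than two prior observations falls
    back to last-observation-carried-forward (logged).
    """
    obs = series.dropna()
    if len(obs) == 0:
        raise CurationError("channel has no observed values")
    t = grid.asi8.astype(float)
    out = np.full(len(grid), np.nan)
    pos = grid.get_indexer(obs.index)
    ok = pos >= 0
    out[pos[ok]] = obs.to_numpy(float)[ok]

    obs_t = obs.index.asi8.astype(float)
    obs_v = obs.to_numpy(float)
    for i in np.flatnonzero(~np.isfinite(out)):
        k = np.searchsorted(obs_t, t[i])  # observations strictly before t[i]
        if k >= 2:
            t1, t2 = obs_t[k - 1], obs_t[k - 2]
            v1, v2 = obs_v[k - 1], obs_v[k - 2]
            out[i] = v1 + (v1 - v2) / (t1 - t2) * (t[i] - t1)
        elif k == 1:
            logger.warning("causal fill fallback: <2 prior points, carrying last observation")
            out[i] = obs_v[0]
        else:
            logger.warning("causal fill fallback: no prior points, carrying first observation")
            out[i] = obs_v[0]
    return out


# ---------------------------------------------------------------------------
# step 3: sparsity handling
# ---------------------------------------------------------------------------

def densify_events(events: pd.Series, grid: pd.DatetimeIndex) -> np.ndarray:
    """Place sparse events at their nearest grid point (ties toward the
    earlier point), summing collisions (logged); zero elsewhere."""
    out = np.zeros(len(grid))
    if len(events) == 0:
        return out
    t = grid.asi8
    step = t[1] - t[0] if len(t) > 1 else 1
    ev_t = events.index.asi8
    ev_v = events.to_numpy(float)
    inside = (ev_t >= t[0] - step // 2) & (ev_t <= t[-1] + step // 2)
    ev_t, ev_v = ev_t[inside], ev_v[inside]
    right = np.searchsorted(t, ev_t)
    idx = np.empty(len(ev_t), dtype=int)
    for j, (et, r) in enumerate(zip(ev_t, right)):
        if r == 0:
            idx[j] = 0
        elif r == len(t):
            idx[j] = len(t) - 1
        else:
            d_left = et - t[r - 1]
            d_right = t[r] - et
            idx[j] = r - 1 if d_left <= d_right else r  # tie -> earlier
    counts = np.bincount(idx, minlength=len(grid))
    if (counts > 1).any():
        logger.info("densify: %d grid points received multiple events (summed)",
                    int((counts > 1).sum()))
    np.add.at(out, idx, ev_v)
    return out


# ---------------------------------------------------------------------------
# step 4: alignment
# ---------------------------------------------------------------------------

def downsample_align(activity: pd.Series, bg_grid: pd.DatetimeIndex) -> np.ndarray:
    """Keep, for each CGM timestamp, the temporally nearest activity sample
    (ties toward the earlier sample); discard the rest."""
    if len(activity) == 0:
        raise CurationError("activity channel is empty")
    at = activity.index.asi8
    av = activity.to_numpy(float)
    t = bg_grid.asi8
    right = np.searchsorted(at, t)
    out = np.empty(len(t))
    for i, (ti, r) in enumerate(zip(t, right)):
        if r == 0:
            out[i] = av[0]
        elif r == len(at):
            out[i] = av[-1]
        else:
            d_left = ti - at[r - 1]
            d_right = at[r] - ti
            out[i] = av[r - 1] if d_left <= d_right else av[r]
    return out


# ---------------------------------------------------------------------------
# steps 1-4 combined
# ---------------------------------------------------------------------------

def curate(raw: RawPatientData, bg_step_minutes: int = 5) -> PatientSeries:
    """Run trimming, filling, densification and alignment; return a complete
    aligned series on the CGM grid with the train/test split marked."""
    raw = trim_common_span(raw)
    if len(raw.bg) < 2:
        raise CurationError("glucose channel too short after trimming")
    step = pd.Timedelta(minutes=bg_step_minutes)
    grid = pd.date_range(raw.bg.index[0], raw.bg.index[-1], freq=step)

    split_index = int(np.searchsorted(grid.asi8, raw.split_time.value))
    if not 0 < split_index < len(grid):
        raise CurationError("train/test split time outside the trimmed span")

    def fill_sensor(series: pd.Series, target_grid: pd.DatetimeIndex, split_ts: int) -> np.ndarray:
        is_train = target_grid.asi8 < split_ts
        train_vals = fill_missing_train(series[series.index.asi8 < split_ts],
                                        target_grid[is_train])
        test_vals = fill_missing_test(series, target_grid)[~is_train]
        return np.concatenate([train_vals, test_vals])

    bg_vals = fill_sensor(raw.bg, grid, raw.split_time.value)
    # causal extrapolation through long gaps can leave the physiological
    # band; filled glucose is clipped to the CGM reporting range
    n_clip = int(np.sum((bg_vals < BG_MIN) | (bg_vals > BG_MAX)))
    if n_clip:
        logger.info("clipped %d extrapolated glucose values to [%g, %g] mg/dL",
                    n_clip, BG_MIN, BG_MAX)
        bg_vals = np.clip(bg_vals, BG_MIN, BG_MAX)

    channels = {"bg": bg_vals}
    if len(raw.activity) > 1:
        # activity: fill on its native grid first, then nearest-neighbour align
        act_step = pd.Timedelta(minutes=1) if (
            np.median(np.diff(raw.activity.index.asi8)) < step.value * 0.9
        ) else step
        act_grid = pd.date_range(raw.activity.index[0], raw.activity.index[-1], freq=act_step)
        act_full = fill_sensor(raw.activity, act_grid, raw.split_time.value)
        channels["activity"] = downsample_align(pd.Series(act_full, index=act_grid), grid)
    else:
        logger.warning("patient %s: no activity channel, falling back to 3-channel mode",
                       raw.patient_id)
    channels["carbs"] = densify_events(raw.carbs, grid)
    channels["bolus"] = densify_events(raw.bolus, grid)
    ps = PatientSeries(raw.patient_id, grid, channels, split_index)
    ps.validate()
    return ps


# ---------------------------------------------------------------------------
# steps 5-6: standardise, difference, invert
# ---------------------------------------------------------------------------

def fit_transform(ps: PatientSeries) -> tuple[PatientSeries, ScalerState]:
    """Standardise each channel with training statistics, then first-difference.

    The transformed series is one point shorter (differencing consumes the
    leading point); exact inversion data are returned in the scaler.
    """
    if ps.transformed:
        raise ContractViolation("series already transformed")
    s = ps.split_index
    mean, sd, z = {}, {}, {}
    for name, vals in ps.channels.items():
        m = float(np.mean(vals[:s]))
        v = float(np.std(vals[:s]))
        if v == 0.0:
            raise CurationError(f"zero training-set SD in channel '{name}'")
        mean[name], sd[name] = m, v
        z[name] = (vals - m) / v
    diffed = {name: np.diff(zz) for name, zz in z.items()}
    out = PatientSeries(
        patient_id=ps.patient_id,
        grid=ps.grid[1:],
        channels=diffed,
        split_index=s - 1,
        transformed=True,
    )
    scaler = ScalerState(
        mean=mean,
        sd=sd,
        initial_scaled={name: float(zz[0]) for name, zz in z.items()},
        last_train_scaled={name: float(zz[s - 1]) for name, zz in z.items()},
        split_index=s,
        z_bg=z["bg"].copy(),
    )
    return out, scaler


def invert_transform(ts: PatientSeries, scaler: ScalerState) -> dict[str, np.ndarray]:
    """Exact inverse of :func:`fit_transform` for every channel (round-trip
    check support): cumulative sum from the stored initial scaled value,
    then the affine z-inversion."""
    out = {}
    for name, d in ts.channels.items():
        z = scaler.initial_scaled[name] + np.concatenate([[0.0], np.cumsum(d)])
        out[name] = z * scaler.sd[name] + scaler.mean[name]
    return out


def invert_to_mgdl(
    pred_diffs: np.ndarray, scaler: ScalerState, anchor: np.ndarray | float
) -> np.ndarray:
    """Map predicted glucose differences back to mg/dL.

    ``anchor`` is the scaled (undifferenced) glucose at the last lag
    timestamp of each window — always available at prediction time. The
    predicted differences are cumulatively summed from the anchor and the
    standardisation is inverted.
    """
    pred_diffs = np.asarray(pred_diffs, float)
    anchor = np.asarray(anchor, float)
    if pred_diffs.ndim == 1:
        pred_diffs = pred_diffs[None, :]
        anchor = np.atleast_1d(anchor)
        squeeze = True
    else:
        squeeze = False
    if anchor.shape[0] != pred_diffs.shape[0]:
        raise ContractViolation("one anchor per window is required")
    z = anchor[:, None] + np.cumsum(pred_diffs, axis=1)
    x = z * scaler.sd["bg"] + scaler.mean["bg"]
    return x[0] if squeeze else x


# ---------------------------------------------------------------------------
# stationarity inspection
# ---------------------------------------------------------------------------

def check_stationarity(series: np.ndarray, alpha: float = 0.05) -> StationarityReport:
    """KPSS (level-stationarity null) and ADF (unit-root null) tests.

    Verdict is ``stationary`` iff ADF rejects and KPSS fails to reject at
    ``alpha``; ``non-stationary`` iff the opposite pattern holds;
    ``inconclusive`` otherwise. Advisory only.
    """
    from statsmodels.tsa.stattools import adfuller, kpss

    series = np.asarray(series, float)
    if len(series) < 30:
        raise CurationError("need at least 30 points for stationarity tests")
    if np.std(series) == 0:
        raise CurationError("constant series: stationarity tests are degenerate")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        kpss_stat, kpss_p, *_ = kpss(series, regression="c", nlags="auto")
        adf_stat, adf_p, *_ = adfuller(series, autolag="AIC")
    adf_rejects = adf_p < alpha
    kpss_rejects = kpss_p < alpha
    if adf_rejects and not kpss_rejects:
        verdict = "stationary"
    elif not adf_rejects and kpss_rejects:
        verdict = "non-stationary"
    else:
        verdict = "inconclusive"
    return StationarityReport(float(kpss_stat), float(kpss_p),
                              float(adf_stat), float(adf_p), verdict)


# ---------------------------------------------------------------------------
# problem reframing
# ---------------------------------------------------------------------------

def window_count(n: int, lag_len: int, horizon_len: int) -> int:
    """Rolling-window pair count on a contiguous segment of length ``n``."""
    return max(0, n - lag_len - horizon_len + 1)


def reframe(ts: PatientSeries, lag_len: int, horizon_len: int) -> tuple[WindowedSet, WindowedSet]:
    """Build supervised (lag block -> future glucose) pairs.

    Test windows may reach lag context back into the training span (past
    data at prediction time), so the first test target is the first test
    timestamp; windows whose target sequence straddles the split belong to
    neither set. On the transformed series, array index ``j`` corresponds
    to original grid index ``j + 1``.
    """
    if lag_len < 1 or horizon_len < 1:
        raise CurationError("lag and horizon must be positive")
    if not ts.transformed:
        raise ContractViolation("reframe expects the transformed series")
    n = ts.n
    L, H = lag_len, horizon_len
    total = window_count(n, L, H)
    if total < 1:
        raise CurationError(f"series of length {n} too short for lag {L} + horizon {H}")

    present = [c for c in CHANNEL_ORDER if c in ts.channels]
    stack = np.stack([ts.channels[c] for c in present], axis=-1)  # (n, n_channels)
    sw = np.lib.stride_tricks.sliding_window_view  # views; copied below
    X_all = sw(stack, (L,), axis=0)[: total].transpose(0, 2, 1)  # (total, L, 4)
    y_all = sw(ts.channels["bg"], (H,), axis=0)[L : L + total]  # (total, H)

    k = np.arange(total)
    t0_orig = k + L + 1  # original-grid index of each window's first target
    end_orig = k + L + H
    s_orig = ts.split_index + 1  # split index on the original grid

    is_train = end_orig <= s_orig - 1
    is_test = t0_orig >= s_orig

    def make(mask: np.ndarray, role: str) -> WindowedSet:
        return WindowedSet(
            lag_len=L,
            horizon_len=H,
            X=np.ascontiguousarray(X_all[mask], dtype=float),
            y=np.ascontiguousarray(y_all[mask], dtype=float),
            t0_index=t0_orig[mask],
            end_index=end_orig[mask],
            window_end_times=ts.grid[end_orig[mask] - 1],
            role=role,
        )

    return make(is_train, "train"), make(is_test, "test")
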