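"""Three-level lag-fusion ensemble per patient and prediction horizon.

Level 0 (non-stacking): an MLP and an LSTM are each trained on four
look-back lengths (30/60/90/120 min), giving eight base models. Level 1
(stacking): per learner family, a meta-learner of the same family fuses the
four base models' predicted horizon sequences (multivariate input of four
channels). Level 2 (nested stacking): a further meta-learner — one MLP, one
LSTM — fuses the two stacking models' outputs (two channels). All learners
share the blueprint and training schedule in :mod:`lagfuse.learners`.

Meta-learners are trained on the base models' in-sample predictions over
the training span; test-window lag context may reach back across the
train/test boundary (past data at prediction time), so every model predicts
the full test span and all levels stay aligned on window end-times.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .curation import (
    PatientSeries,
    ScalerState,
    WindowedSet,
    curate,
    fit_transform,
    invert_to_mgdl,
    reframe,
)
from .exceptions import ConfigurationError, OrchestrationError
from .learners import Network, NetworkSpec, TrainConfig, TrainedModel, build_network, predict, train
from .synthetic import RawPatientData

MINUTES_PER_STEP = 5


@dataclass(frozen=True)
class LevelPlan:
    """Model inventory for one prediction horizon."""

    horizon: int  # minutes, 30 or 60
    lags: tuple[int, ...] = (30, 60, 90, 120)  # minutes
    base_kinds: tuple[str, ...] = ("mlp", "lstm")
    nested_kinds: tuple[str, ...] = ("mlp", "lstm")
    stacking_mode: str = "in-sample"

    def validate(self) -> None:
        if self.horizon % MINUTES_PER_STEP or any(l % MINUTES_PER_STEP for l in self.lags):
            raise ConfigurationError("horizon and lags must be multiples of 5 minutes")
        if self.stacking_mode not in ("in-sample",):
            raise ConfigurationError(f"unsupported stacking mode: {self.stacking_mode!r}")

    @property
    def horizon_steps(self) -> int:
        return self.horizon // MINUTES_PER_STEP

    def lag_steps(self, lag_minutes: int) -> int:
        return lag_minutes // MINUTES_PER_STEP


@dataclass
class PredictionSet:
    """Test-span predictions of one model, inverted to mg/dL."""

    model_id: tuple  # (level, kind, lag minutes or "fused")
    horizon: int  # minutes
    y_pred_mgdl: np.ndarray  # (n_windows, H steps)
    y_ref_mgdl: np.ndarray
    t0_index: np.ndarray  # original-grid index of each window's first target
    window_end_times: pd.DatetimeIndex
    run_seed: int

    def validate(self) -> None:
        if self.y_pred_mgdl.shape != self.y_ref_mgdl.shape:
            raise OrchestrationError("prediction/reference shapes incongruent")
        if not np.isfinite(self.y_pred_mgdl).all() or not np.isfinite(self.y_ref_mgdl).all():
            raise OrchestrationError("non-finite prediction set")


def derive_seed(run_seed: int, *fields) -> int:
    """Deterministic per-model seed from the run seed and model identity.

    Stable across processes (no reliance on Python's randomised str hash).
    """
    import zlib

    codes = [int(run_seed)]
    for f in fields:
        codes.append(zlib.crc32(str(f).encode()) if isinstance(f, str) else int(f))
    return int(np.random.SeedSequence(codes).generate_state(1)[0] % (2**31))


def fit_base_models(
    windows_by_lag: Mapping[int, tuple[WindowedSet, WindowedSet]],
    plan: LevelPlan,
    cfg: TrainConfig,
    run_seed: int = 0,
) -> dict[tuple[str, int], TrainedModel]:
    """Train one model per (kind, lag); each sees only its own lag's windows."""
    plan.validate()
    models: dict[tuple[str, int], TrainedModel] = {}
    for kind in plan.base_kinds:
        for lag in plan.lags:
            if lag not in windows_by_lag:
                raise OrchestrationError(f"missing windowed set for lag {lag} min")
            train_ws, _ = windows_by_lag[lag]
            spec = NetworkSpec(
                kind=kind,
                input_shape=(plan.lag_steps(lag), train_ws.X.shape[2]),
                output_len=plan.horizon_steps,
            )
            seed = derive_seed(run_seed, "base", kind, lag, plan.horizon)
            net = build_network(spec, seed=seed)
            models[(kind, lag)] = train(
                net, train_ws.X, train_ws.y,
                cfg=_with_seed(cfg, seed),
            )
    return models


def _with_seed(cfg: TrainConfig, seed: int) -> TrainConfig:
    from dataclasses import replace

    return replace(cfg, run_seed=seed)


def build_meta_features(
    preds_by_lag: Mapping[int, np.ndarray],
    end_index_by_lag: Mapping[int, np.ndarray],
    targets: np.ndarray,
    target_end_index: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fuse four base models' H-step predictions into meta windows.

    Windows are aligned on common end-times (intersection across lags —
    longer lags have fewer early windows); the meta input per window is the
    H-step prediction of each lag arranged as H steps × n_lags channels,
    the meta target the true H-step sequence. Returns (X, y, end_index).
    """
    lags = sorted(preds_by_lag)
    common = end_index_by_lag[lags[0]]
    for lag in lags[1:]:
        common = np.intersect1d(common, end_index_by_lag[lag])
    common = np.intersect1d(common, target_end_index)
    if len(common) == 0:
        raise OrchestrationError("no common window end-times across lags")
    channels = []
    for lag in lags:
        pos = np.searchsorted(end_index_by_lag[lag], common)
        channels.append(np.asarray(preds_by_lag[lag])[pos])
    X = np.stack(channels, axis=-1)  # (n, H, n_lags)
    tpos = np.searchsorted(target_end_index, common)
    y = np.asarray(targets)[tpos]
    return X, y, common


def fit_stacking(
    meta_X: np.ndarray,
    meta_y: np.ndarray,
    kind: str,
    plan: LevelPlan,
    cfg: TrainConfig,
    run_seed: int = 0,
    level: str = "stacking",
) -> TrainedModel:
    """Train a same-family meta-learner on fused base predictions."""
    spec = NetworkSpec(
        kind=kind,
        input_shape=(meta_X.shape[1], meta_X.shape[2]),
        output_len=plan.horizon_steps,
    )
    seed = derive_seed(run_seed, level, kind, plan.horizon)
    net = build_network(spec, seed=seed)
    return train(net, meta_X, meta_y, cfg=_with_seed(cfg, seed))


def fit_nested_stacking(
    stack_preds: Mapping[str, np.ndarray],
    stack_end_index: np.ndarray,
    targets: np.ndarray,
    target_end_index: np.ndarray,
    nested_kind: str,
    plan: LevelPlan,
    cfg: TrainConfig,
    run_seed: int = 0,
) -> tuple[TrainedModel, np.ndarray, np.ndarray]:
    """Train a nested meta-learner on the two stacking models' outputs.

    Meta input channel order is fixed as (mlp stack, lstm stack) for weight
    reproducibility. Returns (model, X, end_index).
    """
    order = [k for k in ("mlp", "lstm") if k in stack_preds]
    X = np.stack([np.asarray(stack_preds[k]) for k in order], axis=-1)
    tpos = np.searchsorted(target_end_index, stack_end_index)
    y = np.asarray(targets)[tpos]
    model = fit_stacking(X, y, nested_kind, plan, cfg, run_seed, level="nested")
    return model, X, stack_end_index


# ---------------------------------------------------------------------------
# per-patient orchestration
# ---------------------------------------------------------------------------

def run_patient_horizon(
    ts: PatientSeries,
    scaler: ScalerState,
    plan: LevelPlan,
    cfg: TrainConfig,
    run_seed: int = 0,
) -> list[PredictionSet]:
    """All 12 prediction sets (8 base + 2 stacking + 2 nested) for one
    horizon on an already-transformed series."""
    plan.validate()
    H = plan.horizon_steps
    windows = {
        lag: reframe(ts, plan.lag_steps(lag), H) for lag in plan.lags
    }
    base = fit_base_models(windows, plan, cfg, run_seed)

    # test windows share target times across lags; align defensively anyway
    test_end = {lag: windows[lag][1].end_index for lag in plan.lags}
    common_test = test_end[plan.lags[0]]
    for lag in plan.lags[1:]:
        common_test = np.intersect1d(common_test, test_end[lag])
    ref_ws = windows[plan.lags[0]][1]
    tpos = np.searchsorted(ref_ws.end_index, common_test)
    y_test = ref_ws.y[tpos]
    t0_test = ref_ws.t0_index[tpos]
    end_times_test = ref_ws.window_end_times[tpos]
    anchors = scaler.anchor(t0_test)
    y_ref_mgdl = invert_to_mgdl(y_test, scaler, anchors)

    out: list[PredictionSet] = []

    def emit(level: str, kind: str, lag, pred_diffs: np.ndarray) -> None:
        ps = PredictionSet(
            model_id=(level, kind, lag),
            horizon=plan.horizon,
            y_pred_mgdl=invert_to_mgdl(pred_diffs, scaler, anchors),
            y_ref_mgdl=y_ref_mgdl,
            t0_index=t0_test,
            window_end_times=end_times_test,
            run_seed=run_seed,
        )
        ps.validate()
        out.append(ps)

    # level 0: base predictions, train span (for metas) and test span
    base_train_preds: dict[str, dict[int, np.ndarray]] = {k: {} for k in plan.base_kinds}
    base_test_preds: dict[str, dict[int, np.ndarray]] = {k: {} for k in plan.base_kinds}
    for (kind, lag), model in base.items():
        train_ws, test_ws = windows[lag]
        base_train_preds[kind][lag] = predict(model, train_ws.X)
        pos = np.searchsorted(test_ws.end_index, common_test)
        base_test_preds[kind][lag] = predict(model, test_ws.X)[pos]
        emit("non-stacking", kind, lag, base_test_preds[kind][lag])

    # level 1: per-family stacking
    longest = max(plan.lags)
    train_end = {lag: windows[lag][0].end_index for lag in plan.lags}
    target_train = windows[longest][0]
    stack_test_preds: dict[str, np.ndarray] = {}
    stack_train_preds: dict[str, np.ndarray] = {}
    stack_train_end: np.ndarray | None = None
    for kind in plan.base_kinds:
        Xm, ym, end_m = build_meta_features(
            base_train_preds[kind], train_end, target_train.y, target_train.end_index
        )
        stack = fit_stacking(Xm, ym, kind, plan, cfg, run_seed)
        stack_train_preds[kind] = predict(stack, Xm)
        stack_train_end = end_m
        X_test = np.stack(
            [base_test_preds[kind][lag] for lag in sorted(plan.lags)], axis=-1
        )
        stack_test_preds[kind] = predict(stack, X_test)
        emit("stacking", kind, "fused", stack_test_preds[kind])

    # level 2: nested stacking over the two family stacks
    for nested_kind in plan.nested_kinds:
        model, _, _ = fit_nested_stacking(
            stack_train_preds, stack_train_end, target_train.y,
            target_train.end_index, nested_kind, plan, cfg, run_seed,
        )
        X_test = np.stack(
            [stack_test_preds[k] for k in ("mlp", "lstm") if k in stack_test_preds],
            axis=-1,
        )
        emit("nested", nested_kind, "fused", predict(model, X_test))

    return out


def run_patient(
    raw: RawPatientData,
    horizons: Sequence[int] = (30, 60),
    cfg: TrainConfig | None = None,
    run_seed: int = 0,
    lags: Sequence[int] = (30, 60, 90, 120),
    base_kinds: Sequence[str] = ("mlp", "lstm"),
) -> list[PredictionSet]:
    """Curate one patient and produce, per horizon, the 12 test-span
    prediction sets of the full three-level blueprint, in mg/dL."""
    cfg = cfg or TrainConfig()
    ps = curate(raw)
    ts, scaler = fit_transform(ps)
    out: list[PredictionSet] = []
    for h in horizons:
        plan = LevelPlan(horizon=h, lags=tuple(lags), base_kinds=tuple(base_kinds),
                         nested_kinds=tuple(base_kinds))
        out.extend(run_patient_horizon(ts, scaler, plan, cfg, run_seed))
    return out
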