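"""Regression and clinical evaluation of glucose forecasts.

Regression view: MAE, RMSE and MAPE rate accuracy; the coefficient of
determination r² (reported in percent) measures agreement with the
reference, using the reference mean in its denominator.

Clinical view: Matthews correlation coefficient over adverse-event labels
(hypoglycaemia < 70 mg/dL or hyperglycaemia > 180 mg/dL versus euglycaemia,
boundaries counted as euglycaemic), and surveillance-error summaries — the
mean per-point risk (ASE) and the proportion of risk-free points with
error < 0.5 (SE50) — read off an error-grid risk surface by bilinear
interpolation.

Reports aggregate each metric as mean ± population SD over repeated
training runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .exceptions import ContractViolation

logger = logging.getLogger(__name__)

METRIC_NAMES = ("rmse", "mae", "mape", "r2", "mcc", "se50", "ase")

#: metrics where smaller is better; the rest are higher-better
LOWER_BETTER = frozenset({"rmse", "mae", "mape", "ase"})


@dataclass(frozen=True)
class GlycaemicLabeling:
    """Adverse-event thresholds: hypo below 70 mg/dL, hyper above 180 mg/dL.

    The positive class is an adverse event; glucose exactly at a boundary is
    euglycaemic.
    """

    hypo_threshold: float = 70.0
    hyper_threshold: float = 180.0

    def adverse(self, bg: np.ndarray) -> np.ndarray:
        if not self.hypo_threshold < self.hyper_threshold:
            raise ContractViolation("hypo threshold must lie below hyper threshold")
        return (bg < self.hypo_threshold) | (bg > self.hyper_threshold)


@dataclass
class MetricReport:
    """Per-model evaluation: each metric as mean ± SD over training runs."""

    model_id: tuple
    means: dict[str, float]
    sds: dict[str, float]
    n_points: int
    n_runs: int

    def mean(self, name: str) -> float:
        return self.means[name]

    def sd(self, name: str) -> float:
        return self.sds[name]


def _check_pair(ref, pred) -> tuple[np.ndarray, np.ndarray]:
    ref = np.asarray(ref, float).ravel()
    pred = np.asarray(pred, float).ravel()
    if len(ref) != len(pred):
        raise ContractViolation("reference and prediction lengths differ")
    if len(ref) == 0:
        raise ContractViolation("empty input")
    return ref, pred


def regression_metrics(ref, pred) -> tuple[float, float, float, float]:
    """Return (mae, rmse, mape %, r² %).

    MAE = Σ|y−ŷ|/N; RMSE = √(Σ(y−ŷ)²/N); MAPE = (Σ|y−ŷ|/y)/N × 100;
    r² = 1 − Σ(y−ŷ)²/Σ(y−ȳ)², reported ×100.
    """
    ref, pred = _check_pair(ref, pred)
    err = ref - pred
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err**2)))
    mape = float(np.mean(np.abs(err) / ref) * 100.0)
    ss_res = float(np.sum(err**2))
    ss_tot = float(np.sum((ref - ref.mean()) ** 2))
    r2 = (1.0 - ss_res / ss_tot) * 100.0 if ss_tot > 0 else (100.0 if ss_res == 0 else -np.inf)
    return mae, rmse, mape, r2


def mcc_glycaemic(ref, pred, labeling: GlycaemicLabeling | None = None) -> float:
    """Matthews correlation coefficient for adverse-event discrimination.

    MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN)); any zero
    factor in the denominator yields 0 by convention (logged).
    """
    ref, pred = _check_pair(ref, pred)
    lab = labeling or GlycaemicLabeling()
    a_ref = lab.adverse(ref)
    a_pred = lab.adverse(pred)
    if a_ref.all() or not a_ref.any():
        logger.warning("MCC degenerate: reference contains a single class; returning 0")
        return 0.0
    tp = int(np.sum(a_pred & a_ref))
    tn = int(np.sum(~a_pred & ~a_ref))
    fp = int(np.sum(a_pred & ~a_ref))
    fn = int(np.sum(~a_pred & a_ref))
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        logger.warning("MCC degenerate: zero denominator factor; returning 0")
        return 0.0
    return float((tp * tn - fp * fn) / np.sqrt(denom))


def mcc_from_counts(tp: int, tn: int, fp: int, fn: int) -> float:
    """MCC directly from confusion counts (zero denominator -> 0)."""
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return float((tp * tn - fp * fn) / np.sqrt(denom))


# ---------------------------------------------------------------------------
# surveillance error surface
# ---------------------------------------------------------------------------

SEG_RANGE = (20.0, 580.0)
SEG_STEP = 10.0


def _clinical_scale(g: np.ndarray) -> np.ndarray:
    """Monotone clinical-severity scale of a glucose value (log-based,
    compressing high readings and expanding the hypoglycaemic range)."""
    g = np.asarray(g, float)
    return 1.509 * (np.log(g) ** 1.084 - 5.381)


def surrogate_risk_surface(ref: np.ndarray, pred: np.ndarray) -> np.ndarray:
    """Synthetic surveillance-style risk surface (see ``data/`` provenance).

    Constructed, not measured: risk = 0.65·|s(pred) − s(ref)| on a monotone
    clinical scale s, which is zero on the diagonal, non-decreasing as the
    prediction moves away from the reference, small (<0.5) for small
    deviations inside the euglycaemic band, and reaches ~4 in the corners of
    the supported range [20, 580] mg/dL.
    """
    return 0.65 * np.abs(_clinical_scale(pred) - _clinical_scale(ref))


def generate_surrogate_grid() -> tuple[np.ndarray, np.ndarray]:
    """Tabulate the surrogate risk surface on the vendored lookup grid."""
    axis = np.arange(SEG_RANGE[0], SEG_RANGE[1] + SEG_STEP, SEG_STEP)
    rr, pp = np.meshgrid(axis, axis, indexing="ij")
    return axis, np.round(surrogate_risk_surface(rr, pp), 6)


_SEG_CACHE: tuple[np.ndarray, np.ndarray] | None = None


def _seg_grid() -> tuple[np.ndarray, np.ndarray]:
    global _SEG_CACHE
    if _SEG_CACHE is None:
        path = Path(__file__).parent / "data" / "seg_grid_synthetic.csv"
        table = np.loadtxt(path, delimiter=",")
        axis = table[0, 1:]
        values = table[1:, 1:]
        _SEG_CACHE = (axis, values)
    return _SEG_CACHE


def surveillance_errors(ref, pred) -> np.ndarray:
    """Per-point unitless risk of each (reference, predicted) glucose pair.

    Values are clipped to the supported range [20, 580] mg/dL before lookup
    (logged), the risk is bilinearly interpolated on the vendored grid, and
    exact agreement is risk-free by definition.
    """
    ref, pred = _check_pair(ref, pred)
    axis, values = _seg_grid()
    lo, hi = axis[0], axis[-1]
    if (ref < lo).any() or (ref > hi).any() or (pred < lo).any() or (pred > hi).any():
        logger.info("surveillance grid: values outside [%g, %g] clipped", lo, hi)
    r = np.clip(ref, lo, hi)
    p = np.clip(pred, lo, hi)
    step = axis[1] - axis[0]
    ir = np.clip(((r - lo) // step).astype(int), 0, len(axis) - 2)
    ip = np.clip(((p - lo) // step).astype(int), 0, len(axis) - 2)
    fr = (r - axis[ir]) / step
    fp = (p - axis[ip]) / step
    v00 = values[ir, ip]
    v01 = values[ir, ip + 1]
    v10 = values[ir + 1, ip]
    v11 = values[ir + 1, ip + 1]
    out = (
        v00 * (1 - fr) * (1 - fp)
        + v01 * (1 - fr) * fp
        + v10 * fr * (1 - fp)
        + v11 * fr * fp
    )
    out[r == p] = 0.0  # the diagonal is risk-free
    return out


def se_summaries(errors) -> tuple[float, float]:
    """Return (SE50 = proportion of errors < 0.5, ASE = mean error)."""
    errors = np.asarray(errors, float).ravel()
    if len(errors) == 0:
        raise ContractViolation("empty input")
    return float(np.mean(errors < 0.5)), float(np.mean(errors))


# ---------------------------------------------------------------------------
# aggregation over runs
# ---------------------------------------------------------------------------

def _eval_points(pred_set, policy: str) -> tuple[np.ndarray, np.ndarray]:
    ref = np.asarray(pred_set.y_ref_mgdl, float)
    pred = np.asarray(pred_set.y_pred_mgdl, float)
    if ref.shape != pred.shape:
        raise ContractViolation("prediction/reference shape mismatch")
    if policy == "endpoint":
        return ref[:, -1], pred[:, -1]
    if policy == "all":
        return ref.ravel(), pred.ravel()
    raise ContractViolation(f"unknown eval point policy: {policy!r}")


def metrics_for_run(pred_set, policy: str = "endpoint",
                    labeling: GlycaemicLabeling | None = None) -> dict[str, float]:
    """All seven metrics for one prediction set of one training run."""
    ref, pred = _eval_points(pred_set, policy)
    mae, rmse, mape, r2 = regression_metrics(ref, pred)
    mcc = mcc_glycaemic(ref, pred, labeling)
    se50, ase = se_summaries(surveillance_errors(ref, pred))
    return {"rmse": rmse, "mae": mae, "mape": mape, "r2": r2,
            "mcc": mcc, "se50": se50, "ase": ase}


def evaluate(runs: Sequence, policy: str = "endpoint",
             labeling: GlycaemicLabeling | None = None) -> MetricReport:
    """Aggregate one model's prediction sets over repeated runs.

    Metrics are computed per run on the evaluated points chosen by
    ``policy`` ("endpoint": the value exactly one horizon ahead per window;
    "all": every predicted step pooled), then reported as mean ± population
    SD across runs.
    """
    runs = list(runs)
    if not runs:
        raise ContractViolation("need at least one run")
    model_id = getattr(runs[0], "model_id", ())
    shapes = {np.asarray(r.y_pred_mgdl).shape for r in runs}
    if len(shapes) != 1:
        raise ContractViolation("prediction sets differ in shape across runs")
    per_run = [metrics_for_run(r, policy, labeling) for r in runs]
    means = {k: float(np.mean([m[k] for m in per_run])) for k in METRIC_NAMES}
    sds = {k: float(np.std([m[k] for m in per_run])) for k in METRIC_NAMES}
    ref, _ = _eval_points(runs[0], policy)
    return MetricReport(model_id=model_id, means=means, sds=sds,
                        n_points=len(ref), n_runs=len(runs))
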