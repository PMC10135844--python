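"""Rank-based statistical comparison of model types across patients.

Patients are treated as independent data sources. For each (metric,
horizon, learner family) scenario the representative single-lag model, the
stacking model and the nested stacking model are compared with the Friedman
test; when it detects a difference at the 5% level, the post-hoc Nemenyi
test compares the models pairwise, the Holm step-down rule adjusts the
significance decisions, and a critical-difference diagram layout summarises
the average ranks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .exceptions import ContractViolation
from .metrics import LOWER_BETTER, METRIC_NAMES, MetricReport

MODEL_TYPES = ("non-stacking", "stacking", "nested")


@dataclass
class ComparisonMatrix:
    """Patients × model-types matrix of one metric's values."""

    values: np.ndarray  # (N patients, k models)
    rows: tuple  # patient ids
    columns: tuple  # model labels
    metric_name: str
    higher_better: bool

    def validate(self) -> None:
        v = np.asarray(self.values, float)
        if v.ndim != 2 or v.shape[0] < 2 or v.shape[1] < 2:
            raise ContractViolation("need >=2 patients and >=2 models")
        if not np.isfinite(v).all():
            raise ContractViolation("comparison matrix has missing cells")

    def ranks(self) -> np.ndarray:
        """Within-row ranks, rank 1 = best under the metric's orientation
        (average ranks on ties)."""
        v = np.asarray(self.values, float)
        oriented = -v if self.higher_better else v
        return np.apply_along_axis(sps.rankdata, 1, oriented)


@dataclass
class RankComparison:
    metric: str
    horizon: int
    learner_kind: str
    matrix: ComparisonMatrix
    friedman_stat: float
    friedman_p: float
    avg_ranks: np.ndarray
    significant: bool
    critical_distance: float | None = None
    pairwise_p: np.ndarray | None = None
    holm_decisions: np.ndarray | None = None
    representative_lags: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "metric": self.metric,
            "horizon": self.horizon,
            "learner_kind": self.learner_kind,
            "columns": list(self.matrix.columns),
            "patients": list(self.matrix.rows),
            "values": np.asarray(self.matrix.values).tolist(),
            "friedman_stat": self.friedman_stat,
            "friedman_p": self.friedman_p,
            "avg_ranks": np.asarray(self.avg_ranks).tolist(),
            "significant": self.significant,
            "representative_lags": {str(k): v for k, v in self.representative_lags.items()},
        }
        if self.significant:
            d["critical_distance"] = self.critical_distance
            d["pairwise_p"] = np.asarray(self.pairwise_p).tolist()
            d["holm_decisions"] = np.asarray(self.holm_decisions).tolist()
        return d


# ---------------------------------------------------------------------------
# representative-model selection
# ---------------------------------------------------------------------------

def select_representative(reports_by_lag: Mapping[int, MetricReport]) -> int:
    """Pick the look-back length whose model wins the most metrics.

    Per metric the best lag(s) are marked (ties mark all); the
    representative is the lag with the most marks, ties broken by lower
    RMSE, then by lag order.
    """
    lags = sorted(reports_by_lag)
    marks = {lag: 0 for lag in lags}
    for name in METRIC_NAMES:
        vals = np.array([reports_by_lag[lag].mean(name) for lag in lags])
        best = vals.min() if name in LOWER_BETTER else vals.max()
        for lag, v in zip(lags, vals):
            if v == best:
                marks[lag] += 1
    top = max(marks.values())
    candidates = [lag for lag in lags if marks[lag] == top]
    if len(candidates) > 1:
        rmses = [reports_by_lag[lag].mean("rmse") for lag in candidates]
        best_rmse = min(rmses)
        candidates = [lag for lag, r in zip(candidates, rmses) if r == best_rmse]
    return candidates[0]


# ---------------------------------------------------------------------------
# Friedman test
# ---------------------------------------------------------------------------

def _as_ranks(matrix) -> np.ndarray:
    if isinstance(matrix, ComparisonMatrix):
        matrix.validate()
        return matrix.ranks()
    v = np.asarray(matrix, float)
    if v.ndim != 2 or v.shape[0] < 2 or v.shape[1] < 2:
        raise ContractViolation("need >=2 rows and >=2 columns")
    return np.apply_along_axis(sps.rankdata, 1, v)


def _friedman_stat(ranks: np.ndarray) -> float:
    n, k = ranks.shape
    rbar = ranks.mean(axis=0)
    return float(12.0 * n / (k * (k + 1)) * (np.sum(rbar**2) - k * (k + 1) ** 2 / 4.0))


def friedman(
    matrix,
    method: str = "chi2",
    n_perm: int = 100_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Friedman test on an N×k block design (rows = patients).

    The statistic is χ²_F = 12N/(k(k+1)) · [Σ R̄_j² − k(k+1)²/4] with
    average ranks on ties. ``method``: "chi2" takes p from the χ²(k−1)
    approximation; "permutation" from within-row random permutations of the
    observed values (suited to small N); "auto" uses the permutation null
    for N ≤ 12 and χ² otherwise.
    """
    ranks = _as_ranks(matrix)
    n, k = ranks.shape
    stat = _friedman_stat(ranks)
    if method == "auto":
        method = "permutation" if n <= 12 else "chi2"
    if method == "chi2":
        p = float(sps.chi2.sf(stat, k - 1))
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        # permuting ranks within rows is equivalent to permuting the values
        perms = np.argsort(rng.random((n_perm, n, k)), axis=2)
        permuted = np.take_along_axis(
            np.broadcast_to(ranks, (n_perm, n, k)), perms, axis=2
        )
        rbar = permuted.mean(axis=1)
        stats_null = 12.0 * n / (k * (k + 1)) * (
            np.sum(rbar**2, axis=1) - k * (k + 1) ** 2 / 4.0
        )
        p = float((np.sum(stats_null >= stat - 1e-12) + 1) / (n_perm + 1))
    else:
        raise ContractViolation(f"unknown method: {method!r}")
    return stat, min(p, 1.0)


# ---------------------------------------------------------------------------
# Nemenyi post hoc + critical distance
# ---------------------------------------------------------------------------

def nemenyi(avg_ranks: np.ndarray, n: int, alpha: float = 0.05) -> tuple[np.ndarray, float]:
    """Pairwise Nemenyi p-values and the critical distance.

    p-values come from the studentised-range distribution of average-rank
    differences; CD = q_α·√(k(k+1)/(6N)) with q_α the α-level studentised
    range quantile divided by √2 (q_0.05 ≈ 2.343 at k = 3).
    """
    avg_ranks = np.asarray(avg_ranks, float)
    k = len(avg_ranks)
    se = np.sqrt(k * (k + 1) / (6.0 * n))
    diff = np.abs(avg_ranks[:, None] - avg_ranks[None, :])
    q = diff / se * np.sqrt(2.0)
    p = sps.studentized_range.sf(q, k, np.inf)
    p = np.where(np.eye(k, dtype=bool), 1.0, np.clip(p, 0.0, 1.0))
    p = (p + p.T) / 2.0  # enforce exact symmetry
    cd = sps.studentized_range.ppf(1 - alpha, k, np.inf) / np.sqrt(2.0) * se
    return p, float(cd)


def holm_adjust(pvalues, alpha: float = 0.05) -> np.ndarray:
    """Holm–Bonferroni step-down decisions.

    Sort ascending and reject while p_(i) ≤ α/(m−i+1); the first failure
    stops the procedure. Accepts a flat vector or a symmetric pairwise
    matrix (upper triangle tested; diagonal never rejected).
    """
    p = np.asarray(pvalues, float)
    if p.ndim == 2:
        iu = np.triu_indices(p.shape[0], k=1)
        flat_dec = holm_adjust(p[iu], alpha)
        out = np.zeros_like(p, dtype=bool)
        out[iu] = flat_dec
        return out | out.T
    m = len(p)
    order = np.argsort(p, kind="stable")
    decisions = np.zeros(m, dtype=bool)
    for i, idx in enumerate(order):
        if p[idx] <= alpha / (m - i):
            decisions[idx] = True
        else:
            break
    return decisions


def cd_diagram_data(
    avg_ranks: np.ndarray,
    critical_distance: float,
    labels: Sequence[str] | None = None,
    holm_decisions: np.ndarray | None = None,
    convention: str = "classical",
) -> dict:
    """Critical-difference diagram layout.

    Models are placed on a rank axis sorted by average rank. Under the
    ``classical`` convention, links join maximal groups of models whose
    average ranks are *not* separated by more than the critical distance;
    under ``different`` the links join pairs declared significantly
    different (by rank distance, intersected with the Holm decisions when
    given).
    """
    avg_ranks = np.asarray(avg_ranks, float)
    k = len(avg_ranks)
    labels = list(labels) if labels is not None else [f"model {i}" for i in range(k)]
    order = np.argsort(avg_ranks, kind="stable")
    positions = [
        {"label": labels[i], "rank": float(avg_ranks[i])} for i in order
    ]
    sorted_ranks = avg_ranks[order]
    links: list[list[str]] = []
    if convention == "classical":
        for i in range(k):
            j = i
            while j + 1 < k and sorted_ranks[j + 1] - sorted_ranks[i] <= critical_distance:
                j += 1
            if j > i:
                group = [labels[order[t]] for t in range(i, j + 1)]
                if not any(set(group) <= set(g) for g in links):
                    links.append(group)
    elif convention == "different":
        for a in range(k):
            for b in range(a + 1, k):
                apart = abs(avg_ranks[a] - avg_ranks[b]) > critical_distance
                if holm_decisions is not None:
                    apart = apart and bool(holm_decisions[a, b])
                if apart:
                    links.append([labels[a], labels[b]])
    else:
        raise ContractViolation(f"unknown linking convention: {convention!r}")
    return {
        "positions": positions,
        "critical_distance": float(critical_distance),
        "links": links,
        "convention": convention,
    }


# ---------------------------------------------------------------------------
# scenario-level comparison
# ---------------------------------------------------------------------------

def build_comparison_matrix(
    all_reports: Mapping[tuple, MetricReport],
    metric: str,
    horizon: int,
    learner_kind: str,
    lags: Sequence[int] = (30, 60, 90, 120),
) -> tuple[ComparisonMatrix, dict]:
    """Assemble the patients × {representative non-stacking, stacking,
    nested} matrix for one scenario.

    ``all_reports`` is keyed by (patient_id, horizon, level, kind, lag)
    with lag None for fused models.
    """
    patients = sorted({k[0] for k in all_reports})
    rows, reps = [], {}
    for pid in patients:
        by_lag = {}
        for lag in lags:
            key = (pid, horizon, "non-stacking", learner_kind, lag)
            if key not in all_reports:
                raise ContractViolation(f"missing report for {key}")
            by_lag[lag] = all_reports[key]
        rep_lag = select_representative(by_lag)
        reps[pid] = rep_lag
        row = [
            by_lag[rep_lag].mean(metric),
            all_reports[(pid, horizon, "stacking", learner_kind, None)].mean(metric),
            all_reports[(pid, horizon, "nested", learner_kind, None)].mean(metric),
        ]
        rows.append(row)
    cm = ComparisonMatrix(
        values=np.asarray(rows, float),
        rows=tuple(patients),
        columns=MODEL_TYPES,
        metric_name=metric,
        higher_better=metric not in LOWER_BETTER,
    )
    return cm, reps


def compare_model_types(
    all_reports: Mapping[tuple, MetricReport],
    metric: str,
    horizon: int,
    learner_kind: str,
    alpha: float = 0.05,
    friedman_method: str = "auto",
) -> RankComparison:
    """Friedman-gated comparison of the three model types for one scenario.

    Post-hoc Nemenyi p-values, Holm decisions and the critical distance are
    attached only when the Friedman p-value falls below ``alpha``.
    """
    cm, reps = build_comparison_matrix(all_reports, metric, horizon, learner_kind)
    stat, p = friedman(cm, method=friedman_method)
    avg_ranks = cm.ranks().mean(axis=0)
    rc = RankComparison(
        metric=metric,
        horizon=horizon,
        learner_kind=learner_kind,
        matrix=cm,
        friedman_stat=stat,
        friedman_p=p,
        avg_ranks=avg_ranks,
        significant=bool(p < alpha),
        representative_lags=reps,
    )
    if rc.significant:
        pairwise_p, cd = nemenyi(avg_ranks, n=len(cm.rows), alpha=alpha)
        rc.pairwise_p = pairwise_p
        rc.critical_distance = cd
        rc.holm_decisions = holm_adjust(pairwise_p, alpha)
    return rc


def compare_all(
    all_reports: Mapping[tuple, MetricReport],
    horizons: Sequence[int] = (30, 60),
    kinds: Sequence[str] = ("mlp", "lstm"),
    alpha: float = 0.05,
    friedman_method: str = "auto",
) -> list[RankComparison]:
    """One comparison per (metric, horizon, learner family) panel."""
    return [
        compare_model_types(all_reports, metric, h, kind, alpha, friedman_method)
        for kind in kinds
        for h in horizons
        for metric in METRIC_NAMES
    ]
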