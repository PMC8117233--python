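"""Scoring, lambda optimization and participant-aware cross-validation.

Accuracy between two field maps is the Spearman rank correlation over the
cells sampled in both; when either map is constant over the common cells the
rank correlation is undefined and accuracy falls back to
1 - mean(|a - b|) (1 for a perfect empty map).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .errors import ConfigError, InsufficientOverlapError
from .mapping import GridSpec, VisualFieldMap, backproject_coords, retinotopic_coords
from .observer import TrackingRecord
from .scotoma import ScotomaKind
from .tfce import (
    NormativeDistribution,
    TfceParams,
    TfceSeries,
    build_normative_distribution,
    deviation_series,
    tfce_transform,
)

LAMBDA_GRID: Tuple[int, ...] = tuple(range(1, 101))


@dataclass(frozen=True)
class FoldPlan:
    """Disjoint train/test participant splits covering every participant once."""

    folds: Tuple[Tuple[Tuple[str, ...], Tuple[str, ...]], ...]

    def __post_init__(self) -> None:
        seen: List[str] = []
        for train, test in self.folds:
            if set(train) & set(test):
                raise ConfigError("train and test sets overlap within a fold")
            seen.extend(test)
        if len(seen) != len(set(seen)):
            raise ConfigError("a participant appears in more than one test set")

    def __len__(self) -> int:
        return len(self.folds)


def make_fold_plan(participant_ids: Sequence[str], k: int = 5) -> FoldPlan:
    """Contiguous-block k-fold plan; fold 1 tests the *last* block, fold k the
    first (matching the canonical 50-participant enumeration)."""
    ids = list(participant_ids)
    if k < 2:
        raise ConfigError("k must be >= 2")
    if len(ids) < k:
        raise ConfigError(f"need at least {k} participants, got {len(ids)}")
    blocks = np.array_split(np.asarray(ids, dtype=object), k)
    folds = []
    for block in reversed(blocks):
        test = tuple(str(x) for x in block)
        train = tuple(i for i in ids if i not in set(test))
        folds.append((train, test))
    return FoldPlan(folds=tuple(folds))


def _common_values(map_a: VisualFieldMap, map_b: VisualFieldMap) -> Tuple[np.ndarray, np.ndarray]:
    if map_a.grid_spec != map_b.grid_spec:
        raise ConfigError("maps have different grid specs")
    common = map_a.sampled_mask & map_b.sampled_mask
    if common.sum() < 3:
        raise InsufficientOverlapError(
            f"only {int(common.sum())} commonly sampled cells (need >= 3)"
        )
    return map_a.grid[common], map_b.grid[common]


def spearman2d(map_a: VisualFieldMap, map_b: VisualFieldMap) -> float:
    """Rank correlation over commonly sampled cells, with the constant-map
    fallback 1 - mean|a - b| when either side has zero variance."""
    a, b = _common_values(map_a, map_b)
    if np.ptp(a) == 0.0 or np.ptp(b) == 0.0:
        return float(1.0 - np.mean(np.abs(a - b)))
    rho = stats.spearmanr(a, b).statistic
    return float(rho)


@dataclass
class ParticipantConditionData:
    """Pooled per-(participant, condition) inputs for map reconstruction."""

    participant_id: str
    condition: ScotomaKind
    tfce_values: np.ndarray   # pooled over the condition's trials
    rx: np.ndarray
    ry: np.ndarray
    gt_flags: np.ndarray
    gt_map: VisualFieldMap = None  # filled lazily
    _cells_grid: GridSpec = None   # cache key for the binning below
    _inside: np.ndarray = None
    _lin: np.ndarray = None
    _counts: np.ndarray = None
    _dropped: int = 0

    def _bin_cells(self, grid: GridSpec) -> None:
        ix = np.floor((self.rx + grid.x_halfwidth) / grid.cell_size).astype(int)
        iy = np.floor((self.ry + grid.y_halfwidth) / grid.cell_size).astype(int)
        inside = (ix >= 0) & (ix < grid.nx) & (iy >= 0) & (iy < grid.ny)
        self._lin = iy[inside] * grid.nx + ix[inside]
        self._inside = inside
        self._counts = np.bincount(self._lin, minlength=grid.n_cells) \
            .reshape(grid.ny, grid.nx)
        self._dropped = int(len(self.rx) - inside.sum())
        self._cells_grid = grid

    def reconstruct(self, threshold: float, grid: GridSpec) -> VisualFieldMap:
        """Threshold the pooled TFCE values and back-project (cached binning)."""
        if self._cells_grid != grid:
            self._bin_cells(grid)
        flags = self.tfce_values > threshold
        flagged = np.bincount(self._lin, weights=flags[self._inside].astype(float),
                              minlength=grid.n_cells).reshape(grid.ny, grid.nx)
        return VisualFieldMap(grid_spec=grid, flagged=flagged.astype(int),
                              counts=self._counts, dropped=self._dropped)


def prepare_participant_condition(
    records: Sequence[TrackingRecord],
    grid: GridSpec = GridSpec(),
    params: TfceParams = TfceParams(),
    tfce_series: Optional[Sequence[TfceSeries]] = None,
) -> ParticipantConditionData:
    """Compute (or accept precomputed) per-trial TFCE, pool it with the
    retinotopic coordinates and ground-truth flags, and build the GT map."""
    if not records:
        raise ConfigError("no records supplied")
    if tfce_series is None:
        tfce_series = [tfce_transform(deviation_series(r), params) for r in records]
    vals, rxs, rys, gts = [], [], [], []
    for r, s in zip(records, tfce_series):
        rx, ry = retinotopic_coords(r, grid)
        vals.append(np.asarray(s.values))
        rxs.append(rx)
        rys.append(ry)
        gts.append(np.asarray(r.occluded))
    data = ParticipantConditionData(
        participant_id=records[0].participant_id,
        condition=records[0].scotoma.kind,
        tfce_values=np.concatenate(vals),
        rx=np.concatenate(rxs),
        ry=np.concatenate(rys),
        gt_flags=np.concatenate(gts),
    )
    data.gt_map = backproject_coords(data.gt_flags, data.rx, data.ry, grid)
    return data


#: cohort data layout: {participant_id: {condition: ParticipantConditionData}}
CohortData = Dict[str, Dict[ScotomaKind, ParticipantConditionData]]


def prepare_cohort(
    cohort: Mapping[str, Mapping[ScotomaKind, Sequence[TrackingRecord]]],
    grid: GridSpec = GridSpec(),
    params: TfceParams = TfceParams(),
) -> CohortData:
    return {
        pid: {
            cond: prepare_participant_condition(records, grid, params)
            for cond, records in by_cond.items()
        }
        for pid, by_cond in cohort.items()
    }


def optimize_lambda(
    train_data: CohortData,
    F: NormativeDistribution,
    grid: GridSpec = GridSpec(),
    lambdas: Sequence[int] = LAMBDA_GRID,
) -> Tuple[int, np.ndarray]:
    """Grand-average accuracy over participants then conditions for each
    lambda; returns (optimal lambda, grand-average curve).  Ties take the
    lowest lambda."""
    conditions = {c for by_cond in train_data.values() for c in by_cond}
    if conditions != set(ScotomaKind):
        missing = set(ScotomaKind) - conditions
        raise ConfigError(f"training set lacks conditions: {sorted(m.value for m in missing)}")
    thresholds = np.percentile(F.values, lambdas)
    curve = np.empty(len(lambdas))
    for i, thr in enumerate(thresholds):
        per_condition = []
        for cond in ScotomaKind:
            accs = [
                spearman2d(d[cond].reconstruct(thr, grid), d[cond].gt_map)
                for d in train_data.values() if cond in d
            ]
            per_condition.append(np.mean(accs))
        curve[i] = np.mean(per_condition)
    best = int(np.argmax(curve))  # argmax returns the first (lowest) maximum
    return int(lambdas[best]), curve


def error_maps(
    reconstructed: VisualFieldMap,
    truth: VisualFieldMap,
    threshold: float = 0.5,
) -> Tuple[np.ndarray, np.ndarray, Dict[str, Optional[float]]]:
    """Per-cell false-positive / false-negative indicator maps (NaN outside
    the common support) and total FPR/FNR.  A rate with no eligible cells is
    reported as None, not 0."""
    if reconstructed.grid_spec != truth.grid_spec:
        raise ConfigError("maps have different grid specs")
    common = reconstructed.sampled_mask & truth.sampled_mask
    rec_loss = reconstructed.grid > threshold
    tru_loss = truth.grid > threshold
    fp = common & rec_loss & ~tru_loss
    fn = common & ~rec_loss & tru_loss
    neg = int((common & ~tru_loss).sum())
    pos = int((common & tru_loss).sum())
    totals = {
        "fpr": (float(fp.sum() / neg) if neg else None),
        "fnr": (float(fn.sum() / pos) if pos else None),
    }
    fp_map = np.where(common, fp.astype(float), np.nan)
    fn_map = np.where(common, fn.astype(float), np.nan)
    return fp_map, fn_map, totals


def summarize(
    accuracies: Mapping[str, Mapping[str, Sequence[float]]],
) -> Dict[str, object]:
    """Per-method, per-condition median/mean/IQR plus a Kruskal-Wallis
    comparison across methods for each condition.

    ``accuracies[method][condition]`` is a list of per-participant scores.
    """
    methods = list(accuracies)
    if not methods:
        raise ConfigError("no accuracies supplied")
    conditions = sorted({c for m in methods for c in accuracies[m]})
    report: Dict[str, object] = {"methods": methods, "per_condition": {}}
    for cond in conditions:
        entry: Dict[str, object] = {}
        samples = []
        for m in methods:
            vals = np.asarray(accuracies[m].get(cond, []), dtype=float)
            if vals.size == 0:
                continue
            q25, q75 = np.percentile(vals, [25, 75])
            entry[m] = {
                "n": int(vals.size),
                "median": float(np.median(vals)),
                "mean": float(np.mean(vals)),
                "iqr": float(q75 - q25),
            }
            samples.append(vals)
        if len(samples) >= 2 and all(s.size > 0 for s in samples):
            try:
                stat, p = stats.kruskal(*samples)
                entry["kruskal"] = {"statistic": float(stat), "p_value": float(p)}
            except ValueError:  # all values identical across groups
                entry["kruskal"] = {"statistic": 0.0, "p_value": 1.0}
        report["per_condition"][cond] = entry
    return report


@dataclass
class CrossValidationResult:
    fold_plan: FoldPlan
    optimal_lambdas: List[int]
    curves: List[np.ndarray]
    accuracies: Dict[str, Dict[str, List[float]]]  # {"tfce": {condition: [...]}}

    @property
    def deployment_lambda(self) -> float:
        """Average of per-fold optima (threshold usable without ground truth)."""
        return float(np.mean(self.optimal_lambdas))


def cross_validate_tfce(
    cohort_data: CohortData,
    grid: GridSpec = GridSpec(),
    k: int = 5,
    lambdas: Sequence[int] = LAMBDA_GRID,
) -> CrossValidationResult:
    """Participant-aware k-fold CV of the TFCE reconstruction pipeline.

    Per fold: pool the train participants' no-loss TFCE values into the
    normative distribution, optimize lambda on the train set, then score the
    test participants' reconstructions against their ground-truth maps.
    """
    plan = make_fold_plan(sorted(cohort_data), k=k)
    optimal: List[int] = []
    curves: List[np.ndarray] = []
    acc: Dict[str, List[float]] = {c.value: [] for c in ScotomaKind}
    for train_ids, test_ids in plan.folds:
        train = {pid: cohort_data[pid] for pid in train_ids}
        norm_values = np.concatenate([
            train[pid][ScotomaKind.NONE].tfce_values for pid in train_ids
        ])
        F = NormativeDistribution(values=norm_values, source_ids=list(train_ids))
        lam, curve = optimize_lambda(train, F, grid, lambdas)
        optimal.append(lam)
        curves.append(curve)
        thr = F.percentile(lam)
        for pid in test_ids:
            for cond, data in cohort_data[pid].items():
                rec = data.reconstruct(thr, grid)
                acc[cond.value].append(spearman2d(rec, data.gt_map))
    return CrossValidationResult(
        fold_plan=plan, optimal_lambdas=optimal, curves=curves,
        accuracies={"tfce": acc},
    )
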