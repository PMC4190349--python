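"""Beat-detection scoring and brute-force parameter search.

Detections are matched one-to-one to annotated beats within a +/-50 ms
window (the tolerance shared by all detectors for a fair comparison).
Sensitivity SE = TP/(TP+FN) and positive predictivity +P = TP/(TP+FP) are
reported as percentages; the ranking metric is their mean ("overall
accuracy").  Published per-record percentages correspond to *truncation*
at two decimals (43/44 -> 97.72), so both the full-precision value and the
truncated rendering are exposed.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, InputError
from .preprocess import PPGRecord
from .terma import TermaParams, detect_a

__all__ = [
    "EvalResult",
    "GridPoint",
    "match_detections",
    "summarize",
    "overall_accuracy",
    "truncate2",
    "evaluate_record",
    "grid_search",
    "DEFAULT_GRID",
]


def truncate2(x: float) -> str:
    """Render a percentage truncated (not rounded) to two decimals."""
    if math.isnan(x):
        return "NaN"
    return f"{math.floor(x * 100.0) / 100.0:.2f}"


@dataclass(frozen=True)
class EvalResult:
    """TP/FP/FN counts with the derived percentages.

    SE is NaN when there are no annotated beats (TP+FN = 0), mirroring the
    degenerate rows of detectors that mark nothing real; +P is NaN when
    nothing was detected at all.
    """

    tp: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn) < 0:
            raise InputError("counts must be nonnegative")

    @property
    def se_percent(self) -> float:
        denom = self.tp + self.fn
        return 100.0 * self.tp / denom if denom else float("nan")

    @property
    def ppv_percent(self) -> float:
        denom = self.tp + self.fp
        return 100.0 * self.tp / denom if denom else float("nan")

    @property
    def overall_percent(self) -> float:
        return overall_accuracy(self.se_percent, self.ppv_percent)

    @property
    def se_rendered(self) -> str:
        return truncate2(self.se_percent)

    @property
    def ppv_rendered(self) -> str:
        return truncate2(self.ppv_percent)

    def __add__(self, other: "EvalResult") -> "EvalResult":
        return EvalResult(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn)


def overall_accuracy(se_percent: float, ppv_percent: float) -> float:
    """Ranking metric: the mean of SE and +P (both in percent)."""
    return (se_percent + ppv_percent) / 2.0


def match_detections(
    detected: np.ndarray, truth: np.ndarray, fs: float, tol_ms: float = 50.0
) -> EvalResult:
    """One-to-one chronological matching within +/-tol_ms.

    Both index lists must be sorted.  A two-pointer sweep pairs each
    annotated beat with at most one detection; for sorted sequences and a
    symmetric window this greedy pairing attains the maximum number of
    matches (asserted against an exhaustive oracle in the test suite).
    """
    detected = np.asarray(detected, dtype=float)
    truth = np.asarray(truth, dtype=float)
    for name, arr in (("detected", detected), ("truth", truth)):
        if arr.size > 1 and np.any(np.diff(arr) < 0):
            raise InputError(f"{name} indices must be sorted")
    tol = tol_ms / 1000.0 * fs
    i = j = tp = 0
    while i < detected.size and j < truth.size:
        d = detected[i] - truth[j]
        if abs(d) <= tol:
            tp += 1
            i += 1
            j += 1
        elif d < 0:
            i += 1
        else:
            j += 1
    return EvalResult(tp=tp, fp=detected.size - tp, fn=truth.size - tp)


def summarize(tp: int, fp: int, fn: int) -> EvalResult:
    """Build an EvalResult from raw counts (thin constructor alias)."""
    return EvalResult(tp=tp, fp=fp, fn=fn)


def evaluate_record(
    rec: PPGRecord,
    truth_a: np.ndarray,
    params: TermaParams | None = None,
    tol_ms: float = 50.0,
) -> EvalResult:
    """Run the TERMA detector on one record and score it against truth."""
    ann, _ = detect_a(rec, params)
    return match_detections(ann.a_indices, truth_a, rec.fs, tol_ms)


@dataclass(frozen=True)
class GridPoint:
    params: TermaParams
    result: EvalResult


#: Default search ranges; the published search space is a superset whose
#: exact step sizes are not recorded, so the ranges (not the steps) are kept.
DEFAULT_GRID = {
    "f1_hz": [0.5, 1.0],
    "f2_hz": list(range(7, 16)),
    "w1_ms": list(range(100, 205, 5)),
    "w2_ms": list(range(1000, 1300, 50)),
    "beta_percent": list(range(0, 11)),
}


def grid_search(
    records: list[tuple[PPGRecord, np.ndarray]],
    grid: dict | None = None,
    tol_ms: float = 50.0,
) -> list[GridPoint]:
    """Exhaustive evaluation of every parameter combination, pooled over records.

    Rows are sorted by overall accuracy (descending), ties broken by SE and
    then by the lexical order of the parameter tuple, mirroring the
    brute-force optimization table.
    """
    grid = dict(DEFAULT_GRID, **(grid or {}))
    if not records:
        raise ConfigurationError("grid_search needs at least one annotated record")
    keys = ("f1_hz", "f2_hz", "w1_ms", "w2_ms", "beta_percent")
    for k in keys:
        if not grid.get(k):
            raise ConfigurationError(f"empty grid range for {k}")
    points: list[GridPoint] = []
    for combo in itertools.product(*(grid[k] for k in keys)):
        params = TermaParams(**dict(zip(keys, combo)))
        pooled = EvalResult(0, 0, 0)
        for rec, truth in records:
            pooled = pooled + evaluate_record(rec, truth, params, tol_ms)
        points.append(GridPoint(params=params, result=pooled))

    def sort_key(p: GridPoint):
        ov = p.result.overall_percent
        se = p.result.se_percent
        ov = -1.0 if math.isnan(ov) else ov
        se = -1.0 if math.isnan(se) else se
        return (
            -ov,
            -se,
            p.params.f1_hz,
            p.params.f2_hz,
            p.params.w1_ms,
            p.params.w2_ms,
            p.params.beta_percent,
        )

    return sorted(points, key=sort_key)
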