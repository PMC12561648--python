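"""Retrieval metrics: slice-index MAE, Top-k-in-range accuracy, deltas.

Validation-style records carry a single ground-truth slice index and are
scored by mean absolute error in slice units.  Test-style records carry
an inclusive 0-based range ``[lo, hi]`` of acceptable slices; Acc@1 is
the percentage of sentences whose top prediction falls inside the range
and Acc@k the percentage whose top-k list intersects it.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .errors import InputError

__all__ = ["EvalRecord", "MetricReport", "mae", "topk_accuracy", "improvement_report"]


@dataclasses.dataclass
class EvalRecord:
    """One evaluated sentence: prediction, ranking and ground truth."""

    sentence_id: str
    predicted_index: int
    top_k: list[int] = dataclasses.field(default_factory=list)
    truth_index: int | None = None
    truth_range: tuple[int, int] | None = None  # inclusive [lo, hi], 0-based

    def __post_init__(self) -> None:
        if self.truth_range is not None:
            lo, hi = self.truth_range
            if lo > hi:
                raise InputError(f"malformed range [{lo}, {hi}]")
        if not self.top_k:
            self.top_k = [self.predicted_index]


@dataclasses.dataclass
class MetricReport:
    """Summary mirroring the retrieval-accuracy table layout."""

    n: int
    mode: str = "soft"
    mae_mean: float | None = None
    mae_std: float | None = None
    acc_at_1: float | None = None
    acc_at_5: float | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def mae(records: Sequence[EvalRecord], mode: str = "soft") -> tuple[float, float]:
    """Mean and population std of |predicted - truth| over single-index records."""
    if not records:
        raise InputError("no records")
    errors = []
    for r in records:
        if r.truth_index is None:
            raise InputError(f"record {r.sentence_id!r} has no single-index truth")
        errors.append(abs(r.predicted_index - r.truth_index))
    errors = np.asarray(errors, dtype=np.float64)
    return float(errors.mean()), float(errors.std())


def topk_accuracy(records: Sequence[EvalRecord], k: int = 1) -> float:
    """Percent of records whose top-k slices intersect the truth range.

    For ``k == 1`` this is the percent of top predictions inside the range.
    """
    if not records:
        raise InputError("no records")
    if k < 1:
        raise InputError(f"k must be >= 1, got {k}")
    hits = 0
    for r in records:
        if r.truth_range is None:
            raise InputError(f"record {r.sentence_id!r} has no range truth")
        lo, hi = r.truth_range
        if any(lo <= idx <= hi for idx in r.top_k[:k]):
            hits += 1
    return 100.0 * hits / len(records)


def improvement_report(baseline: float, finetuned: float) -> float:
    """Fine-tuned minus baseline, in percentage points, rounded to 2 decimals."""
    for v in (baseline, finetuned):
        if not (0.0 <= v <= 100.0):
            raise InputError(f"percentages must lie in [0, 100], got {v}")
    return round(finetuned - baseline, 2)
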