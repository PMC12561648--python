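"""Organ-presence calibration and classification via the Youden index.

For each organ, cosine similarities between an organ prompt and every
validation slice are split into positive (organ present) and negative
scores.  The decision threshold maximizing the Youden index
J = TPR - FPR over midpoint candidates is frozen and then applied to test
slices: a slice is called positive when its score is >= the threshold.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .curation import DEFAULT_TEMPLATE, OrganLabels
from .errors import CalibrationError, ConfigError, InputError, ShapeError
from .slice_selection import SimilarityProfile

__all__ = [
    "OrganThreshold",
    "OrganThresholds",
    "calibrate_threshold",
    "classify_organ_presence",
    "build_organ_prompts",
    "evaluate_organ_awareness",
    "OrganMetrics",
]


@dataclasses.dataclass(frozen=True)
class OrganThreshold:
    threshold: float
    youden: float


@dataclasses.dataclass
class OrganThresholds:
    """Per-organ decision cutoffs with the Youden index achieved at each."""

    per_organ: dict[str, OrganThreshold]
    prompt_mode: str = "sentence"

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            organ: {
                "threshold": t.threshold,
                "youden": t.youden,
                "prompt_mode": self.prompt_mode,
            }
            for organ, t in self.per_organ.items()
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "OrganThresholds":
        payload = json.loads(Path(path).read_text())
        modes = {v.get("prompt_mode", "sentence") for v in payload.values()}
        return cls(
            per_organ={
                organ: OrganThreshold(v["threshold"], v["youden"])
                for organ, v in payload.items()
            },
            prompt_mode=modes.pop() if len(modes) == 1 else "sentence",
        )


def calibrate_threshold(
    pos_scores: Sequence[float], neg_scores: Sequence[float]
) -> tuple[float, float]:
    """Threshold maximizing J = TPR - FPR over midpoint candidates.

    Candidates are midpoints between consecutive distinct values of the
    pooled sorted scores; classification is positive at ``score >= t``;
    ties in J break to the smallest threshold (preferring sensitivity).
    Identical pooled scores are non-informative and raise
    :class:`CalibrationError`.
    """
    pos = np.asarray(pos_scores, dtype=np.float64)
    neg = np.asarray(neg_scores, dtype=np.float64)
    if pos.size == 0 or neg.size == 0:
        raise InputError("both positive and negative score lists must be non-empty")
    pooled = np.unique(np.concatenate([pos, neg]))
    if pooled.size < 2:
        raise CalibrationError(
            "all scores identical: non-informative, no threshold separates classes"
        )
    candidates = (pooled[:-1] + pooled[1:]) / 2
    best_t, best_j = None, -np.inf
    for t in candidates:
        j = np.mean(pos >= t) - np.mean(neg >= t)
        if j > best_j + 1e-12:
            best_t, best_j = float(t), float(j)
    return best_t, best_j


def classify_organ_presence(
    profile: SimilarityProfile | np.ndarray, threshold: float
) -> np.ndarray:
    """Per-slice presence call: ``scores >= threshold``."""
    if not np.isfinite(threshold):
        raise InputError(f"threshold must be finite, got {threshold}")
    scores = profile.scores if isinstance(profile, SimilarityProfile) else np.asarray(profile)
    return scores >= threshold


def build_organ_prompts(
    organs: Sequence[str], mode: str = "sentence", template: str = DEFAULT_TEMPLATE
) -> list[str]:
    """Word prompts ("Heart") or template sentences ("This CT image includes the heart")."""
    if not organs:
        raise ConfigError("organ list is empty")
    if mode == "word":
        return [o[:1].upper() + o[1:] for o in organs]
    if mode == "sentence":
        if "{organ}" not in template:
            raise ConfigError("sentence template must contain the {organ} placeholder")
        return [template.format(organ=o) for o in organs]
    raise ConfigError(f"mode must be 'word' or 'sentence', got {mode!r}")


@dataclasses.dataclass
class OrganMetrics:
    """Per-organ and macro accuracy/F1 for organ-presence classification."""

    per_organ: dict[str, dict[str, float]]
    macro_accuracy: float
    macro_accuracy_std: float
    macro_f1: float
    macro_f1_std: float

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _binary_metrics(truth: np.ndarray, pred: np.ndarray) -> dict[str, float]:
    tp = int(np.sum(pred & truth))
    fp = int(np.sum(pred & ~truth))
    fn = int(np.sum(~pred & truth))
    tn = int(np.sum(~pred & ~truth))
    acc = (tp + tn) / truth.size
    if tp == 0 and fp == 0 and fn == 0:
        # no true and no predicted positives: a vacuously perfect organ
        precision = recall = f1 = 1.0
    else:
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return {"accuracy": acc, "precision": precision, "recall": recall, "f1": f1}


def evaluate_organ_awareness(
    predictions: Mapping[str, np.ndarray], truth: OrganLabels
) -> OrganMetrics:
    """Accuracy and F1 per organ, plus unweighted macro mean ± population std.

    ``predictions`` maps organ name to a length-N boolean vector of
    presence calls for the same slices as ``truth``.
    """
    per_organ = {}
    for organ, pred in predictions.items():
        if organ not in truth.organs:
            raise ShapeError(f"organ {organ!r} not in truth labels")
        col = truth.presence[:, truth.organs.index(organ)]
        pred = np.asarray(pred, dtype=bool)
        if pred.shape != col.shape:
            raise ShapeError(
                f"prediction for {organ!r} has shape {pred.shape}, truth {col.shape}"
            )
        per_organ[organ] = _binary_metrics(col, pred)
    accs = np.array([m["accuracy"] for m in per_organ.values()])
    f1s = np.array([m["f1"] for m in per_organ.values()])
    return OrganMetrics(
        per_organ=per_organ,
        macro_accuracy=float(accs.mean()),
        macro_accuracy_std=float(accs.std()),
        macro_f1=float(f1s.mean()),
        macro_f1_std=float(f1s.std()),
    )
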