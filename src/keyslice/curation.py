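"""Training-pair curation: lesion range expansion and organ pseudo-findings.

The fine-tuning set is *dual-supervised*: (i) lesion-positive pairs link a
report sentence to its annotated key slice, expanded to neighbouring
slices in proportion to the lesion's bounding-box area, and (ii) normal
anatomy pairs link template pseudo-findings ("This CT image includes the
heart") to every slice in which the named organ is present, using
per-slice organ labels produced by an external segmenter.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, InputError, MissingStudyError

__all__ = [
    "LesionAnnotation",
    "OrganLabels",
    "SentenceSlicePair",
    "expansion_padding",
    "expand_lesion_range",
    "generate_pseudo_findings",
    "build_training_set",
    "read_annotations_csv",
    "read_organ_labels_csv",
    "write_pairs_jsonl",
    "read_pairs_jsonl",
    "DEFAULT_ORGANS",
    "DEFAULT_TEMPLATE",
    "TextRewriter",
    "identity_rewriter",
]

# 15 major thoracoabdominal organs (editable default; any list is accepted)
DEFAULT_ORGANS: tuple[str, ...] = (
    "lung",
    "heart",
    "esophagus",
    "aorta",
    "liver",
    "gallbladder",
    "spleen",
    "stomach",
    "pancreas",
    "kidney",
    "adrenal gland",
    "duodenum",
    "small bowel",
    "colon",
    "bladder",
)

DEFAULT_TEMPLATE = "This CT image includes the {organ}"

# area thresholds (pixels) -> slices of padding above and below the key slice
_AREA_THRESHOLDS = (2000, 4000, 6000)


@dataclasses.dataclass(frozen=True)
class LesionAnnotation:
    """One radiologist-annotated finding: sentence, key slice and lesion box.

    ``bbox`` is a half-open pixel box ``(row0, col0, row1, col1)``; its
    area in pixels drives the slice-range expansion.
    """

    study_id: str
    sentence: str
    key_slice: int
    bbox: tuple[int, int, int, int]

    @property
    def bbox_area(self) -> int:
        r0, c0, r1, c1 = self.bbox
        return (r1 - r0) * (c1 - c0)

    def __post_init__(self) -> None:
        if self.bbox_area <= 0:
            raise InputError(f"bbox {self.bbox} has non-positive area")


@dataclasses.dataclass
class OrganLabels:
    """Per-slice boolean organ presence for one study (slices x organs)."""

    study_id: str
    organs: list[str]
    presence: np.ndarray

    def __post_init__(self) -> None:
        self.presence = np.asarray(self.presence, dtype=bool)
        if self.presence.ndim != 2 or self.presence.shape[1] != len(self.organs):
            raise InputError(
                f"presence matrix {self.presence.shape} does not match "
                f"{len(self.organs)} organs"
            )

    @property
    def n_slices(self) -> int:
        return self.presence.shape[0]


@dataclasses.dataclass(frozen=True)
class SentenceSlicePair:
    """One curated training/eval record linking a sentence to slice indices."""

    sentence: str
    study_id: str
    slice_indices: tuple[int, ...]
    source: str  # "lesion" | "organ_template"
    organ: str | None = None

    def __post_init__(self) -> None:
        if not self.slice_indices:
            raise InputError("pair has no slice indices")
        if self.source not in ("lesion", "organ_template"):
            raise InputError(f"unknown pair source {self.source!r}")


# A pluggable rewriter lets LLM paraphrasing be slotted in; the default is
# a no-op so the core never makes network calls.
TextRewriter = Callable[[str], str]


def identity_rewriter(sentence: str) -> str:
    return sentence


def expansion_padding(bbox_area: int) -> int:
    """Slices of padding each side of the key slice, by lesion box area.

    Strictly-greater thresholds: area > 2000 px -> 1, > 4000 -> 2,
    > 6000 -> 3, else 0.  An area exactly at a threshold takes the smaller
    padding.
    """
    if bbox_area <= 0:
        raise InputError(f"bbox_area must be positive, got {bbox_area}")
    return sum(bbox_area > t for t in _AREA_THRESHOLDS)


def expand_lesion_range(ann: LesionAnnotation, n_slices: int) -> list[int]:
    """Contiguous slice indices ``[k - p, k + p]`` clamped to the volume."""
    if not (0 <= ann.key_slice < n_slices):
        raise InputError(
            f"key_slice {ann.key_slice} outside volume of {n_slices} slices"
        )
    p = expansion_padding(ann.bbox_area)
    lo = max(0, ann.key_slice - p)
    hi = min(n_slices - 1, ann.key_slice + p)
    return list(range(lo, hi + 1))


def generate_pseudo_findings(
    labels: OrganLabels,
    template: str = DEFAULT_TEMPLATE,
    mode: str = "sentence",
    rewriter=identity_rewriter,
) -> list[SentenceSlicePair]:
    """One normal-anatomy pair per (slice, present organ).

    ``sentence`` mode formats ``template`` with each organ name; ``word``
    mode emits the bare organ name.  ``rewriter`` may paraphrase the text
    (default: identity).
    """
    if mode not in ("word", "sentence"):
        raise ConfigError(f"mode must be 'word' or 'sentence', got {mode!r}")
    if mode == "sentence" and "{organ}" not in template:
        raise ConfigError("sentence template must contain the {organ} placeholder")
    pairs = []
    for i in range(labels.n_slices):
        for j, organ in enumerate(labels.organs):
            if labels.presence[i, j]:
                text = organ if mode == "word" else template.format(organ=organ)
                pairs.append(
                    SentenceSlicePair(
                        sentence=rewriter(text),
                        study_id=labels.study_id,
                        slice_indices=(i,),
                        source="organ_template",
                        organ=organ,
                    )
                )
    return pairs


def build_training_set(
    annotations: Sequence[LesionAnnotation],
    labels: Sequence[OrganLabels],
    n_slices_by_study: dict[str, int] | None = None,
    template: str = DEFAULT_TEMPLATE,
    template_mode: str = "sentence",
    rewriter=identity_rewriter,
) -> tuple[list[SentenceSlicePair], dict]:
    """Assemble the dual-supervised pair table and its manifest.

    Lesion pairs get area-expanded slice indices; organ pairs come from
    :func:`generate_pseudo_findings`.  Ordering is deterministic
    (study_id, slice, organ) so identical inputs give byte-identical
    output.  The manifest records counts by source.
    """
    labels_by_study = {lab.study_id: lab for lab in labels}
    if n_slices_by_study is None:
        n_slices_by_study = {sid: lab.n_slices for sid, lab in labels_by_study.items()}

    lesion_pairs: list[SentenceSlicePair] = []
    for ann in sorted(annotations, key=lambda a: (a.study_id, a.key_slice, a.sentence)):
        if ann.study_id not in n_slices_by_study:
            raise MissingStudyError(f"annotation refers to unknown study {ann.study_id!r}")
        indices = expand_lesion_range(ann, n_slices_by_study[ann.study_id])
        lesion_pairs.append(
            SentenceSlicePair(
                sentence=ann.sentence,
                study_id=ann.study_id,
                slice_indices=tuple(indices),
                source="lesion",
            )
        )

    organ_pairs: list[SentenceSlicePair] = []
    for sid in sorted(labels_by_study):
        organ_pairs.extend(
            generate_pseudo_findings(
                labels_by_study[sid], template=template, mode=template_mode,
                rewriter=rewriter,
            )
        )

    pairs = lesion_pairs + organ_pairs
    manifest = {
        "n_lesion_pairs": len(lesion_pairs),
        "n_lesion_slice_links": int(sum(len(p.slice_indices) for p in lesion_pairs)),
        "n_organ_pairs": len(organ_pairs),
        "n_pairs": len(pairs),
        "template_mode": template_mode,
        "template": template if template_mode == "sentence" else None,
    }
    return pairs, manifest


# ---------------------------------------------------------------------------
# on-disk schemas


def read_annotations_csv(path: str | Path) -> list[LesionAnnotation]:
    """Columns: study_id, sentence, key_slice, row0, col0, row1, col1."""
    df = pd.read_csv(path)
    required = {"study_id", "sentence", "key_slice", "row0", "col0", "row1", "col1"}
    if not required.issubset(df.columns):
        raise ConfigError(f"annotation CSV missing columns {required - set(df.columns)}")
    return [
        LesionAnnotation(
            study_id=str(r.study_id),
            sentence=str(r.sentence),
            key_slice=int(r.key_slice),
            bbox=(int(r.row0), int(r.col0), int(r.row1), int(r.col1)),
        )
        for r in df.itertuples()
    ]


def read_organ_labels_csv(path: str | Path, organs: Sequence[str] | None = None) -> list[OrganLabels]:
    """Long-format columns: study_id, slice, organ, present (0/1)."""
    df = pd.read_csv(path)
    required = {"study_id", "slice", "organ", "present"}
    if not required.issubset(df.columns):
        raise ConfigError(f"organ-label CSV missing columns {required - set(df.columns)}")
    out = []
    for sid, grp in df.groupby("study_id", sort=True):
        organ_list = list(organs) if organs else sorted(grp["organ"].unique())
        n = int(grp["slice"].max()) + 1
        presence = np.zeros((n, len(organ_list)), dtype=bool)
        idx = {o: j for j, o in enumerate(organ_list)}
        for r in grp.itertuples():
            if r.organ in idx:
                presence[int(r.slice), idx[r.organ]] = bool(r.present)
        out.append(OrganLabels(study_id=str(sid), organs=organ_list, presence=presence))
    return out


def write_pairs_jsonl(pairs: Iterable[SentenceSlicePair], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for p in pairs:
            fh.write(
                json.dumps(
                    {
                        "sentence": p.sentence,
                        "study_id": p.study_id,
                        "slice_indices": list(p.slice_indices),
                        "source": p.source,
                        "organ": p.organ,
                    }
                )
                + "\n"
            )
    return path


def read_pairs_jsonl(path: str | Path) -> list[SentenceSlicePair]:
    pairs = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                d = json.loads(line)
                pairs.append(
                    SentenceSlicePair(
                        sentence=d["sentence"],
                        study_id=d["study_id"],
                        slice_indices=tuple(d["slice_indices"]),
                        source=d["source"],
                        organ=d.get("organ"),
                    )
                )
    return pairs
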