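"""Phantom CT volumes, annotations and profiles with exact ground truth.

Phantoms validate computation, not radiology: each organ is a
constant-intensity rectangle occupying a known contiguous slice interval,
and each lesion is a distinct-intensity box planted around a known key
slice.  Every concept (organ or lesion type) carries a unique Hounsfield
intensity code inside the soft-tissue window, so the
:class:`~keyslice.encoders.OracleEncoder` can detect exactly which
concepts appear in a slice and every downstream quantity (key slice,
curation counts, organ F1) has a closed-form expected value.

:func:`make_fixture_cohort` materializes a small multi-study cohort with
train/validation/test splits, on disk in the same CSV/NIfTI schemas the
CLI consumes.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np

from .ct_volume import CTVolume, PreprocessSpec, WindowSpec, write_volume
from .curation import DEFAULT_ORGANS, LesionAnnotation, OrganLabels
from .errors import SpecError

__all__ = [
    "OrganSpec",
    "LesionSpec",
    "PhantomSpec",
    "ProfileSpec",
    "generate_phantom",
    "generate_profiles",
    "random_phantom_spec",
    "make_fixture_cohort",
    "Cohort",
    "concept_intensities",
    "LESION_TYPES",
    "BACKGROUND_HU",
]

BACKGROUND_HU = -1000.0  # air

LESION_TYPES: tuple[str, ...] = (
    "mass", "cyst", "nodule", "tumor", "metastasis", "polyp", "abscess", "hematoma",
)

_LESION_SENTENCE = "A {lesion} is seen on this slice"


def concept_intensities(
    organs: Sequence[str] = DEFAULT_ORGANS, lesion_types: Sequence[str] = LESION_TYPES
) -> dict[str, float]:
    """Unique HU code per concept, all strictly inside the default window.

    Organs get 20, 32, 44, ... HU; lesion types 196, 201, ... HU; the
    always-present "body" background sits at 8 HU.  Codes are spaced
    further apart than the oracle's detection tolerance.
    """
    codes = {"body": 8.0}
    codes.update({name: 20.0 + 12.0 * i for i, name in enumerate(organs)})
    codes.update({name: 196.0 + 5.0 * j for j, name in enumerate(lesion_types)})
    return codes


@dataclasses.dataclass(frozen=True)
class OrganSpec:
    """Constant-intensity rectangle over an inclusive slice interval."""

    name: str
    slice_lo: int
    slice_hi: int  # inclusive
    region: tuple[int, int, int, int]  # half-open (row0, col0, row1, col1)
    intensity: float


@dataclasses.dataclass(frozen=True)
class LesionSpec:
    """Distinct-intensity box planted around a key slice.

    The blob spans the inclusive slice interval ``extent`` (by default the
    key slice ±1, clamped), emulating the through-plane extent of a real
    lesion; the annotation records ``key_slice`` and the pixel bounding
    box.
    """

    sentence: str
    key_slice: int
    bbox: tuple[int, int, int, int]
    intensity: float
    extent: tuple[int, int] | None = None
    lesion_type: str = ""
    organ: str = ""


@dataclasses.dataclass
class PhantomSpec:
    n_slices: int
    image_size: tuple[int, int] = (64, 64)
    organs: list[OrganSpec] = dataclasses.field(default_factory=list)
    lesions: list[LesionSpec] = dataclasses.field(default_factory=list)
    # drawn like organs but excluded from the presence labels (e.g. the
    # "body" background that keeps every slice non-empty, as in real scans)
    backgrounds: list[OrganSpec] = dataclasses.field(default_factory=list)
    noise_sd: float = 0.0
    seed: int = 0
    study_id: str = "phantom"


def generate_phantom(
    spec: PhantomSpec,
) -> tuple[CTVolume, list[LesionAnnotation], OrganLabels]:
    """Render a phantom volume with its annotations and exact organ labels."""
    n, (h, w) = spec.n_slices, spec.image_size
    for org in spec.organs:
        if not (0 <= org.slice_lo <= org.slice_hi < n):
            raise SpecError(f"organ {org.name!r} interval outside [0, {n})")
        r0, c0, r1, c1 = org.region
        if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
            raise SpecError(f"organ {org.name!r} region {org.region} outside image")
    vol = np.full((n, h, w), BACKGROUND_HU, dtype=np.float32)
    for org in list(spec.backgrounds) + list(spec.organs):
        r0, c0, r1, c1 = org.region
        vol[org.slice_lo : org.slice_hi + 1, r0:r1, c0:c1] = org.intensity

    annotations = []
    for les in spec.lesions:
        if not (0 <= les.key_slice < n):
            raise SpecError(f"lesion key slice {les.key_slice} outside [0, {n})")
        r0, c0, r1, c1 = les.bbox
        if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
            raise SpecError(f"lesion bbox {les.bbox} outside image")
        lo, hi = les.extent if les.extent else (les.key_slice - 1, les.key_slice + 1)
        lo, hi = max(0, lo), min(n - 1, hi)
        vol[lo : hi + 1, r0:r1, c0:c1] = les.intensity
        annotations.append(
            LesionAnnotation(
                study_id=spec.study_id,
                sentence=les.sentence,
                key_slice=les.key_slice,
                bbox=les.bbox,
            )
        )

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        vol = vol + rng.normal(0.0, spec.noise_sd, vol.shape).astype(np.float32)

    organ_names = [o.name for o in spec.organs]
    presence = np.zeros((n, len(organ_names)), dtype=bool)
    for j, org in enumerate(spec.organs):
        presence[org.slice_lo : org.slice_hi + 1, j] = True
    labels = OrganLabels(study_id=spec.study_id, organs=organ_names, presence=presence)
    return (
        CTVolume(slices=vol, study_id=spec.study_id, spacing=(5.0, 1.0, 1.0)),
        annotations,
        labels,
    )


def random_phantom_spec(
    study_id: str,
    rng: np.random.Generator,
    organs: Sequence[str] = DEFAULT_ORGANS,
    n_lesions: int = 2,
    n_slices: int | None = None,
    image_size: tuple[int, int] = (64, 64),
    noise_sd: float = 0.0,
    interval_len: tuple[int, int] = (4, 9),
) -> PhantomSpec:
    """Draw a study: every organ gets its own grid cell and a random interval.

    Organ intervals cover roughly 15-35% of the scan each, so a random
    slice guess lands inside a given organ's interval only ~25% of the
    time.  A "body" background spans every slice (as in real scans), so
    no slice is ever concept-free.  Lesions get distinct types, a key
    slice inside the host organ's interval and a small box inside the
    host organ's region.
    """
    if n_lesions > len(LESION_TYPES):
        raise SpecError(f"at most {len(LESION_TYPES)} lesions per study")
    n = int(n_slices if n_slices is not None else rng.integers(24, 33))
    h, w = image_size
    codes = concept_intensities(organs)
    grid = int(np.ceil(np.sqrt(len(organs))))
    cell_h, cell_w = h // grid, w // grid
    organ_specs = []
    for i, name in enumerate(organs):
        gr, gc = divmod(i, grid)
        r0, c0 = gr * cell_h + 1, gc * cell_w + 1
        r1, c1 = r0 + cell_h - 2, c0 + cell_w - 2
        length = int(rng.integers(interval_len[0], interval_len[1] + 1))
        lo = int(rng.integers(0, max(1, n - length)))
        organ_specs.append(
            OrganSpec(name, lo, min(n - 1, lo + length - 1), (r0, c0, r1, c1), codes[name])
        )

    lesion_specs = []
    types = rng.choice(len(LESION_TYPES), size=n_lesions, replace=False)
    hosts = rng.choice(len(organ_specs), size=n_lesions, replace=False)
    for t_idx, o_idx in zip(types, hosts):
        ltype = LESION_TYPES[int(t_idx)]
        host = organ_specs[int(o_idx)]
        # keep lesions off the first/last few slices: boundary-truncated
        # smoothing windows are a documented degenerate case, not the
        # regime the recovery suite validates
        key = int(np.clip(rng.integers(host.slice_lo, host.slice_hi + 1), 3, n - 4))
        hr0, hc0, hr1, hc1 = host.region
        bh = int(rng.integers(3, max(4, (hr1 - hr0) // 2)))
        bw = int(rng.integers(3, max(4, (hc1 - hc0) // 2)))
        r0 = int(rng.integers(hr0, hr1 - bh))
        c0 = int(rng.integers(hc0, hc1 - bw))
        lesion_specs.append(
            LesionSpec(
                sentence=_LESION_SENTENCE.format(lesion=ltype),
                key_slice=key,
                bbox=(r0, c0, r0 + bh, c0 + bw),
                intensity=codes[ltype],
                lesion_type=ltype,
                organ=host.name,
            )
        )
    body = OrganSpec("body", 0, n - 1, (0, 0, h, w), codes["body"])
    return PhantomSpec(
        n_slices=n,
        image_size=image_size,
        organs=organ_specs,
        lesions=lesion_specs,
        backgrounds=[body],
        noise_sd=noise_sd,
        seed=int(rng.integers(0, 2**31 - 1)),
        study_id=study_id,
    )


# ---------------------------------------------------------------------------
# similarity-profile simulator (drives hard-vs-soft experiments)


@dataclasses.dataclass(frozen=True)
class ProfileSpec:
    """Unimodal Gaussian bump plus iid Gaussian noise, clipped to [-1, 1]."""

    n_slices: int
    peak_index: int
    peak_width: float = 2.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.peak_index < self.n_slices):
            raise SpecError(f"peak {self.peak_index} outside [0, {self.n_slices})")
        if self.peak_width <= 0:
            raise SpecError(f"peak_width must be > 0, got {self.peak_width}")


def generate_profiles(spec: ProfileSpec, n_reps: int = 1) -> list[tuple[np.ndarray, int]]:
    """``scores_i = exp(-(i - k*)² / (2 width²)) + ε_i``, clipped to [-1, 1]."""
    if n_reps < 1:
        raise SpecError(f"n_reps must be >= 1, got {n_reps}")
    rng = np.random.default_rng(spec.seed)
    i = np.arange(spec.n_slices)
    base = np.exp(-((i - spec.peak_index) ** 2) / (2 * spec.peak_width**2))
    out = []
    for _ in range(n_reps):
        noise = rng.normal(0.0, spec.noise_sd, spec.n_slices) if spec.noise_sd > 0 else 0.0
        out.append((np.clip(base + noise, -1.0, 1.0), spec.peak_index))
    return out


# ---------------------------------------------------------------------------
# on-disk fixture cohort


@dataclasses.dataclass
class Cohort:
    """In-memory view of a generated multi-study fixture cohort."""

    volumes: dict[str, CTVolume]
    annotations: list[LesionAnnotation]
    labels: dict[str, OrganLabels]
    ranges: dict[str, dict]  # sentence_id -> {study_id, lo, hi, key_slice, sentence}
    split: dict[str, list[str]]
    vocabulary: list[str]
    intensities: dict[str, float]
    window: WindowSpec
    preprocess: PreprocessSpec

    def studies(self, split: str | None = None) -> list[str]:
        if split is None:
            return sorted(self.volumes)
        return list(self.split[split])


def make_fixture_cohort(
    n_studies: int,
    seed: int,
    out_dir: str | Path | None = None,
    organs: Sequence[str] = DEFAULT_ORGANS,
    n_lesions: int = 2,
    noise_sd: float = 0.0,
    image_size: tuple[int, int] = (64, 64),
    split_ratio: tuple[int, int, int] = (4, 1, 1),
) -> Cohort:
    """Generate a reproducible cohort; optionally write it to ``out_dir``.

    On disk: one NIfTI per study, ``annotations.csv`` and
    ``organ_labels.csv`` in the curation schemas, ``ranges.csv`` with the
    inclusive ground-truth slice range per lesion sentence (0-based,
    flagged by an ``index_base`` column), ``split.json`` and
    ``encoder.json`` (oracle vocabulary, intensity codes, window and
    preprocessing settings).
    """
    if n_studies < 3:
        raise SpecError(f"need at least 3 studies for a 3-way split, got {n_studies}")
    rng = np.random.default_rng(seed)
    codes = concept_intensities(organs)

    volumes: dict[str, CTVolume] = {}
    labels: dict[str, OrganLabels] = {}
    annotations: list[LesionAnnotation] = []
    ranges: dict[str, dict] = {}
    for s in range(n_studies):
        sid = f"study_{s:03d}"
        spec = random_phantom_spec(
            sid, rng, organs=organs, n_lesions=n_lesions,
            image_size=image_size, noise_sd=noise_sd,
        )
        vol, anns, labs = generate_phantom(spec)
        volumes[sid] = vol
        labels[sid] = labs
        annotations.extend(anns)
        for j, les in enumerate(spec.lesions):
            lo, hi = les.extent if les.extent else (les.key_slice - 1, les.key_slice + 1)
            lo, hi = max(0, lo), min(spec.n_slices - 1, hi)
            ranges[f"{sid}:L{j}"] = {
                "study_id": sid,
                "sentence": les.sentence,
                "lo": lo,
                "hi": hi,
                "key_slice": les.key_slice,
            }

    # deterministic proportional split, train first
    total = sum(split_ratio)
    counts = [n_studies * r // total for r in split_ratio]
    counts[0] += n_studies - sum(counts)
    for i in (1, 2):
        if counts[i] == 0 and counts[0] > 1:
            counts[0] -= 1
            counts[i] += 1
    sids = sorted(volumes)
    split = {
        "train": sids[: counts[0]],
        "val": sids[counts[0] : counts[0] + counts[1]],
        "test": sids[counts[0] + counts[1] :],
    }

    window = WindowSpec()
    preprocess = PreprocessSpec(crop_frac=0.0, out_size=image_size, window=window)
    # vocabulary: organs, the body background, and every planted lesion type
    planted = sorted({r["sentence"].split()[1] for r in ranges.values()})
    vocabulary = list(organs) + ["body"] + [t for t in LESION_TYPES if t in planted]

    cohort = Cohort(
        volumes=volumes,
        annotations=annotations,
        labels=labels,
        ranges=ranges,
        split=split,
        vocabulary=vocabulary,
        intensities={c: codes[c] for c in vocabulary},
        window=window,
        preprocess=preprocess,
    )
    if out_dir is not None:
        _write_cohort(cohort, Path(out_dir))
    return cohort


def _write_cohort(cohort: Cohort, out_dir: Path) -> None:
    import pandas as pd

    out_dir.mkdir(parents=True, exist_ok=True)
    vol_dir = out_dir / "volumes"
    vol_dir.mkdir(exist_ok=True)
    for sid, vol in cohort.volumes.items():
        write_volume(vol, vol_dir / f"{sid}.nii.gz")

    pd.DataFrame(
        [
            {
                "study_id": a.study_id,
                "sentence": a.sentence,
                "key_slice": a.key_slice,
                "row0": a.bbox[0], "col0": a.bbox[1],
                "row1": a.bbox[2], "col1": a.bbox[3],
            }
            for a in cohort.annotations
        ]
    ).to_csv(out_dir / "annotations.csv", index=False)

    rows = []
    for sid in sorted(cohort.labels):
        lab = cohort.labels[sid]
        for i in range(lab.n_slices):
            for j, organ in enumerate(lab.organs):
                rows.append(
                    {"study_id": sid, "slice": i, "organ": organ,
                     "present": int(lab.presence[i, j])}
                )
    pd.DataFrame(rows).to_csv(out_dir / "organ_labels.csv", index=False)

    pd.DataFrame(
        [
            {"sentence_id": sid_l, "study_id": r["study_id"], "sentence": r["sentence"],
             "lo": r["lo"], "hi": r["hi"], "key_slice": r["key_slice"], "index_base": 0}
            for sid_l, r in sorted(cohort.ranges.items())
        ]
    ).to_csv(out_dir / "ranges.csv", index=False)

    (out_dir / "split.json").write_text(json.dumps(cohort.split, indent=2))
    (out_dir / "encoder.json").write_text(
        json.dumps(
            {
                "vocabulary": cohort.vocabulary,
                "intensities": cohort.intensities,
                "window": {"level": cohort.window.level, "width": cohort.window.width},
                "preprocess": {
                    "crop_frac": cohort.preprocess.crop_frac,
                    "out_size": list(cohort.preprocess.out_size),
                },
            },
            indent=2,
        )
    )


def load_cohort(path: str | Path) -> Cohort:
    """Re-read a cohort written by :func:`make_fixture_cohort`."""
    import pandas as pd

    from .ct_volume import load_volume
    from .curation import read_annotations_csv, read_organ_labels_csv

    path = Path(path)
    enc = json.loads((path / "encoder.json").read_text())
    window = WindowSpec(**enc["window"])
    preprocess = PreprocessSpec(
        crop_frac=enc["preprocess"]["crop_frac"],
        out_size=tuple(enc["preprocess"]["out_size"]),
        window=window,
    )
    volumes = {
        p.name.split(".")[0]: load_volume(p)
        for p in sorted((path / "volumes").glob("*.nii.gz"))
    }
    organs = [c for c in enc["vocabulary"] if c not in LESION_TYPES and c != "body"]
    labels = {
        lab.study_id: lab
        for lab in read_organ_labels_csv(path / "organ_labels.csv", organs=organs)
    }
    ranges_df = pd.read_csv(path / "ranges.csv")
    ranges = {
        r.sentence_id: {
            "study_id": r.study_id, "sentence": r.sentence,
            "lo": int(r.lo), "hi": int(r.hi), "key_slice": int(r.key_slice),
        }
        for r in ranges_df.itertuples()
    }
    return Cohort(
        volumes=volumes,
        annotations=read_annotations_csv(path / "annotations.csv"),
        labels=labels,
        ranges=ranges,
        split=json.loads((path / "split.json").read_text()),
        vocabulary=enc["vocabulary"],
        intensities=enc["intensities"],
        window=window,
        preprocess=preprocess,
    )
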