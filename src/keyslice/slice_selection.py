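"""Key-slice selection: similarity profiling, hard/soft argmax, Top-k.

Given one finding sentence and one CT volume, the sentence embedding is
compared against every slice embedding by cosine similarity.  *Hard*
prediction takes the argmax of the raw profile; *soft* prediction first
applies a moving average over the ±``radius`` neighbouring slices (default
±2) to exploit the through-plane continuity of CT anatomy, then takes the
argmax of the smoothed profile.  Ties always break toward the lowest
slice index so results are deterministic.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .ct_volume import CTVolume, PreprocessSpec
from .encoders import EmbeddingModel, encode_text, encode_volume
from .errors import InputError, ParameterError, ShapeError

__all__ = [
    "SimilarityProfile",
    "SliceSelection",
    "similarity_profile",
    "smooth_profile",
    "select_key_slice",
    "top_k_slices",
    "select_for_sentence",
    "DEFAULT_RADIUS",
]

DEFAULT_RADIUS = 2


@dataclasses.dataclass
class SimilarityProfile:
    """Per-slice cosine similarities for one sentence against one volume."""

    scores: np.ndarray
    smoothed: np.ndarray | None = None
    radius: int = DEFAULT_RADIUS
    volume_id: str = ""
    sentence_id: str = ""

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if self.scores.ndim != 1 or self.scores.size < 1:
            raise InputError(f"profile must be a non-empty vector, got shape {self.scores.shape}")
        if np.any(np.abs(self.scores) > 1 + 1e-9):
            raise InputError("cosine scores must lie in [-1, 1]")

    @property
    def n_slices(self) -> int:
        return self.scores.size


@dataclasses.dataclass
class SliceSelection:
    """Result of selecting slices for one sentence: key index plus ranking."""

    key_index: int
    mode: str
    top_k: list[int]
    profile: SimilarityProfile


def similarity_profile(
    text_emb: np.ndarray,
    volume_embs: np.ndarray,
    volume_id: str = "",
    sentence_id: str = "",
) -> SimilarityProfile:
    """Cosine of one unit text vector against N unit slice rows (dot products)."""
    text_emb = np.asarray(text_emb, dtype=np.float64)
    volume_embs = np.asarray(volume_embs, dtype=np.float64)
    if volume_embs.ndim != 2 or text_emb.ndim != 1 or volume_embs.shape[1] != text_emb.size:
        raise ShapeError(
            f"dim mismatch: text {text_emb.shape} vs volume {volume_embs.shape}"
        )
    scores = np.clip(volume_embs @ text_emb, -1.0, 1.0)
    return SimilarityProfile(scores=scores, volume_id=volume_id, sentence_id=sentence_id)


def smooth_profile(profile: SimilarityProfile, radius: int = DEFAULT_RADIUS) -> SimilarityProfile:
    """Moving average over ±``radius`` slices with truncated boundary windows.

    ``smoothed[i]`` is the mean of ``scores`` over indices
    ``[max(0, i - radius), min(N - 1, i + radius)]``; near the volume ends
    the window simply contains fewer terms.
    """
    if radius < 0:
        raise ParameterError(f"radius must be >= 0, got {radius}")
    kernel = np.ones(2 * radius + 1)
    sums = np.convolve(profile.scores, kernel, mode="same")
    counts = np.convolve(np.ones_like(profile.scores), kernel, mode="same")
    return dataclasses.replace(profile, smoothed=sums / counts, radius=radius)


def _ranking_scores(profile: SimilarityProfile, mode: str) -> np.ndarray:
    if mode == "hard":
        return profile.scores
    if mode == "soft":
        if profile.smoothed is None:
            raise InputError("soft mode requires smooth_profile to have been applied")
        return profile.smoothed
    raise ParameterError(f"mode must be 'hard' or 'soft', got {mode!r}")


def select_key_slice(profile: SimilarityProfile, mode: str = "soft") -> SliceSelection:
    """Argmax selection; ties break to the lowest index."""
    scores = _ranking_scores(profile, mode)
    key = int(np.argmax(scores))  # np.argmax returns the first (lowest) maximum
    order = top_k_slices(profile, k=profile.n_slices, mode=mode)
    return SliceSelection(key_index=key, mode=mode, top_k=order, profile=profile)


def top_k_slices(profile: SimilarityProfile, k: int, mode: str = "soft") -> list[int]:
    """Indices of the ``min(k, N)`` best slices, score-descending, ties index-ascending."""
    if k < 1:
        raise ParameterError(f"k must be >= 1, got {k}")
    scores = _ranking_scores(profile, mode)
    order = np.lexsort((np.arange(scores.size), -scores))
    return [int(i) for i in order[: min(k, scores.size)]]


def select_for_sentence(
    model: EmbeddingModel,
    volume: CTVolume,
    sentence: str,
    spec: PreprocessSpec | None = None,
    mode: str = "soft",
    radius: int = DEFAULT_RADIUS,
    top_k: int = 5,
    sentence_id: str = "",
) -> SliceSelection:
    """End-to-end selection for one (sentence, volume) pair.

    Encodes the sentence and every preprocessed slice, builds the cosine
    profile, smooths it when ``mode == 'soft'`` and returns the selection
    with the ``top_k`` ranking attached.
    """
    spec = spec or PreprocessSpec()
    text_emb = encode_text(model, sentence)
    volume_embs = encode_volume(model, volume, spec)
    profile = similarity_profile(
        text_emb, volume_embs, volume_id=volume.study_id, sentence_id=sentence_id
    )
    if mode == "soft":
        profile = smooth_profile(profile, radius)
    selection = select_key_slice(profile, mode)
    selection.top_k = selection.top_k[: min(top_k, profile.n_slices)]
    return selection
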