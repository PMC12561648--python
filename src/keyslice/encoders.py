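"""Dual-encoder contract and reference encoders.

The selection, calibration and training modules only assume the
:class:`EmbeddingModel` contract: a text map and an image map into one
shared space of unit-norm vectors.  Two reference implementations ship
with the package:

* :class:`OracleEncoder` — a deterministic concept detector over phantom
  volumes whose embeddings are one-hot (text) and normalized multi-hot
  (image) over a concept vocabulary.  It makes every retrieval quantity
  exactly computable and is the test oracle for the whole pipeline.
* :class:`TinyTrainableEncoder` — a small linear dual encoder (hashed
  bag-of-tokens text map, pooled-pixel image map, learnable temperature)
  that the training module can fine-tune on a CPU in seconds.  It is a
  desk-scale stand-in for transformer backbones, not a clinical model.

Pretrained backbones can be plugged in through :func:`register_model`;
anything satisfying the contract is accepted downstream.
"""

from __future__ import annotations

import re
import zlib
from typing import Callable, Mapping, Protocol, runtime_checkable

import numpy as np

from .ct_volume import CTVolume, PreprocessSpec, WindowSpec, apply_window, preprocess_slice
from .errors import ConfigError, InputError, ShapeError

__all__ = [
    "EmbeddingModel",
    "OracleEncoder",
    "TinyTrainableEncoder",
    "encode_text",
    "encode_image",
    "encode_volume",
    "tokenize",
    "truncate_tokens",
    "get_model",
    "register_model",
    "MAX_TOKENS",
]

MAX_TOKENS = 77  # CLIP-style context length; longer sentences are truncated

_TOKEN_RE = re.compile(r"[a-z0-9]+")


def tokenize(sentence: str) -> list[str]:
    """Lowercase word-boundary tokens (reference-encoder tokenizer)."""
    return _TOKEN_RE.findall(sentence.lower())


def truncate_tokens(tokens: list[str], max_tokens: int = MAX_TOKENS) -> list[str]:
    return tokens[:max_tokens]


@runtime_checkable
class EmbeddingModel(Protocol):
    """Duck-typed dual-encoder contract used by all downstream modules."""

    dim: int
    max_tokens: int

    def encode_text(self, sentence: str) -> np.ndarray: ...

    def encode_image(self, image: np.ndarray) -> np.ndarray: ...


def _unit(v: np.ndarray) -> np.ndarray:
    n = float(np.linalg.norm(v))
    if n == 0.0:
        # degenerate (e.g. empty slice): uniform direction avoids NaN
        return np.full(v.shape, 1.0 / np.sqrt(v.size), dtype=np.float64)
    return (v / n).astype(np.float64)


def encode_text(model: EmbeddingModel, sentence: str) -> np.ndarray:
    """Encode one sentence to a unit vector, truncating to ``max_tokens``."""
    if not sentence or not sentence.strip():
        raise InputError("sentence is empty")
    return model.encode_text(sentence)


def encode_image(model: EmbeddingModel, image: np.ndarray) -> np.ndarray:
    return model.encode_image(image)


def encode_volume(
    model: EmbeddingModel, volume: CTVolume, spec: PreprocessSpec
) -> np.ndarray:
    """Encode every axial slice; row ``i`` embeds slice ``i`` (N x d, unit rows)."""
    rows = [
        model.encode_image(preprocess_slice(volume.slices[i], spec))
        for i in range(volume.n_slices)
    ]
    return np.stack(rows)


class OracleEncoder:
    """Concept-detecting reference encoder over phantom volumes.

    Each concept (organ or lesion name) is tied to a known HU intensity
    code.  ``encode_text`` returns the normalized sum of one-hots of the
    concepts named in the sentence; ``encode_image`` detects which
    intensity codes appear in a windowed slice and returns the normalized
    sum of their one-hots.  With the phantom generator this makes
    cosine(text concept c, slice with concept set S) exactly
    ``1/sqrt(|S|)`` if ``c in S`` and ``0`` otherwise.
    """

    def __init__(
        self,
        vocabulary: list[str],
        intensities: Mapping[str, float],
        window: WindowSpec | None = None,
        tol_hu: float = 1.5,
        min_pixels: int = 4,
    ) -> None:
        if not vocabulary:
            raise ConfigError("oracle vocabulary is empty")
        missing = [c for c in vocabulary if c not in intensities]
        if missing:
            raise ConfigError(f"no intensity code for concepts: {missing}")
        self.vocabulary = list(vocabulary)
        self.intensities = {c: float(intensities[c]) for c in vocabulary}
        self.window = window or WindowSpec()
        self.tol_hu = float(tol_hu)
        self.min_pixels = int(min_pixels)
        self.dim = len(vocabulary)
        self.max_tokens = MAX_TOKENS
        self._index = {c: i for i, c in enumerate(vocabulary)}
        self._concept_tokens = {c: tuple(tokenize(c)) for c in vocabulary}

    def concepts_in_sentence(self, sentence: str) -> list[str]:
        tokens = truncate_tokens(tokenize(sentence), self.max_tokens)
        found = []
        for concept, ctoks in self._concept_tokens.items():
            k = len(ctoks)
            if any(tuple(tokens[i : i + k]) == ctoks for i in range(len(tokens) - k + 1)):
                found.append(concept)
        return found

    def encode_text(self, sentence: str) -> np.ndarray:
        if not sentence or not sentence.strip():
            raise InputError("sentence is empty")
        v = np.zeros(self.dim)
        for concept in self.concepts_in_sentence(sentence):
            v[self._index[concept]] = 1.0
        return _unit(v)

    def concepts_in_image(self, image01: np.ndarray) -> list[str]:
        img = np.asarray(image01, dtype=np.float64)
        tol = self.tol_hu / self.window.width
        found = []
        for concept in self.vocabulary:
            expected = float(apply_window(self.intensities[concept], self.window))
            if np.count_nonzero(np.abs(img - expected) <= tol) >= self.min_pixels:
                found.append(concept)
        return found

    def encode_image(self, image01: np.ndarray) -> np.ndarray:
        img = np.asarray(image01)
        if img.ndim != 2:
            raise ShapeError(f"expected a 2D image, got shape {img.shape}")
        v = np.zeros(self.dim)
        for concept in self.concepts_in_image(img):
            v[self._index[concept]] = 1.0
        return _unit(v)


class TinyTrainableEncoder:
    """Linear dual encoder trainable in seconds on one CPU.

    Text: tokens are hashed into ``n_bins`` count features (CRC32, stable
    across processes), then mapped by ``W_text`` and L2-normalized.
    Image: the slice is mean-pooled to a ``pool x pool`` grid, flattened,
    mapped by ``W_img`` and L2-normalized.  Both feature vectors carry a
    constant bias component.  ``logit_scale`` is the learnable
    log-inverse-temperature used by the contrastive objective.
    """

    def __init__(
        self,
        dim: int = 32,
        n_bins: int = 256,
        pool: int = 16,
        seed: int = 0,
        init_scale: float = 1.0,
        temperature_init: float = 0.07,
    ) -> None:
        rng = np.random.default_rng(seed)
        self.dim = dim
        self.n_bins = n_bins
        self.pool = pool
        self.max_tokens = MAX_TOKENS
        self.params: dict[str, np.ndarray] = {
            "W_text": rng.standard_normal((n_bins + 1, dim)) * init_scale / np.sqrt(n_bins),
            "W_img": rng.standard_normal((pool * pool + 1, dim)) * init_scale / pool,
            "logit_scale": np.array([np.log(1.0 / temperature_init)]),
        }

    # -- feature extraction (fixed, not trained) --------------------------
    def text_features(self, sentence: str) -> np.ndarray:
        tokens = truncate_tokens(tokenize(sentence), self.max_tokens)
        x = np.zeros(self.n_bins + 1)
        for tok in tokens:
            x[zlib.crc32(tok.encode()) % self.n_bins] += 1.0
        x[-1] = 1.0  # bias
        return x

    def image_features(self, image01: np.ndarray) -> np.ndarray:
        img = np.asarray(image01, dtype=np.float64)
        if img.ndim != 2:
            raise ShapeError(f"expected a 2D image, got shape {img.shape}")
        from skimage.transform import resize

        pooled = resize(
            img, (self.pool, self.pool), order=1, mode="edge",
            anti_aliasing=False, preserve_range=True,
        )
        return np.concatenate([pooled.ravel(), [1.0]])

    # -- contract ----------------------------------------------------------
    def encode_text(self, sentence: str) -> np.ndarray:
        if not sentence or not sentence.strip():
            raise InputError("sentence is empty")
        return _unit(self.text_features(sentence) @ self.params["W_text"])

    def encode_image(self, image01: np.ndarray) -> np.ndarray:
        return _unit(self.image_features(image01) @ self.params["W_img"])

    @property
    def temperature(self) -> float:
        return float(np.exp(-self.params["logit_scale"][0]))

    # -- (de)serialization -------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: Mapping[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = np.asarray(state[k], dtype=np.float64).copy()

    def save(self, path) -> None:
        np.savez(
            path,
            dim=self.dim, n_bins=self.n_bins, pool=self.pool,
            **{f"param_{k}": v for k, v in self.params.items()},
        )

    @classmethod
    def load(cls, path) -> "TinyTrainableEncoder":
        data = np.load(path)
        model = cls(dim=int(data["dim"]), n_bins=int(data["n_bins"]), pool=int(data["pool"]))
        model.load_state_dict({k[len("param_"):]: data[k] for k in data.files if k.startswith("param_")})
        return model


_REGISTRY: dict[str, Callable[..., EmbeddingModel]] = {
    "oracle": OracleEncoder,
    "tiny": TinyTrainableEncoder,
}


def register_model(name: str, factory: Callable[..., EmbeddingModel]) -> None:
    """Register an adapter factory (e.g. a pretrained CLIP wrapper) by name."""
    _REGISTRY[name] = factory


def get_model(name: str, **kwargs) -> EmbeddingModel:
    try:
        factory = _REGISTRY[name]
    except KeyError:
        raise ConfigError(f"unknown model {name!r}; registered: {sorted(_REGISTRY)}") from None
    return factory(**kwargs)
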