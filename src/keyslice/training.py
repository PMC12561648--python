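"""Contrastive fine-tuning of the dual encoder on curated pairs.

The objective is the standard symmetric InfoNCE: with unit text rows T
and unit image rows I of a batch of n matched pairs, logits
L = (T Iᵀ)/τ, and the loss is the mean of the row-wise and column-wise
cross-entropies against the diagonal.  The temperature τ is learnable
(parameterized as a log-inverse scale, initialized at 0.07).  Training
uses AdamW with a per-step cosine-annealed learning rate (defaults
5e-5 -> 1e-6 over 20 epochs, batch 64) and returns the checkpoint with
the lowest validation loss.

Gradients for :class:`~keyslice.encoders.TinyTrainableEncoder` are
computed in closed form (backprop through the L2 normalization and the
linear maps), so no autodiff framework is needed.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .ct_volume import CTVolume, PreprocessSpec, augment as augment_slice, preprocess_slice
from .curation import SentenceSlicePair
from .encoders import TinyTrainableEncoder
from .errors import InputError, MissingStudyError, ParameterError, TrainingError

__all__ = [
    "TrainConfig",
    "TrainingExample",
    "TrainResult",
    "contrastive_loss",
    "lr_schedule",
    "train",
    "examples_from_pairs",
]


@dataclasses.dataclass
class TrainConfig:
    """Hyperparameters; defaults follow the fine-tuning recipe."""

    batch_size: int = 64
    epochs: int = 20
    lr_max: float = 5e-5
    lr_min: float = 1e-6
    temperature_init: float = 0.07
    seed: int = 0
    lesion_weight: float = 0.5  # target fraction of lesion examples per batch
    stratify: bool = True
    dedupe_concepts: bool = True  # at most one pair per (study, concept) per batch
    weight_decay: float = 0.01
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8

    def __post_init__(self) -> None:
        if not (self.lr_max >= self.lr_min >= 0):
            raise ParameterError("need lr_max >= lr_min >= 0")
        if self.batch_size < 2:
            raise ParameterError("batch_size must be >= 2")
        if self.temperature_init <= 0:
            raise ParameterError("temperature must be > 0")


@dataclasses.dataclass
class TrainingExample:
    """One resolved (sentence, preprocessed slice) pair."""

    sentence: str
    image: np.ndarray
    source: str = "organ_template"
    study_id: str = ""
    concept: str = ""


@dataclasses.dataclass
class TrainResult:
    model: TinyTrainableEncoder
    best_epoch: int
    best_val_loss: float
    history: pd.DataFrame


def contrastive_loss(
    text_embs: np.ndarray, img_embs: np.ndarray, temperature: float
) -> float:
    """Symmetric InfoNCE over matched rows.

    loss = ½ [CE(rows of L, diag) + CE(cols of L, diag)] averaged over n,
    with L = (text_embs img_embsᵀ)/τ.  Equals ln n when all logits are
    equal.
    """
    if temperature <= 0:
        raise ParameterError(f"temperature must be > 0, got {temperature}")
    T = np.asarray(text_embs, dtype=np.float64)
    I = np.asarray(img_embs, dtype=np.float64)
    if T.shape != I.shape or T.ndim != 2:
        raise InputError(f"embedding shapes must match, got {T.shape} vs {I.shape}")
    n = T.shape[0]
    if n < 2:
        raise InputError("contrastive loss needs at least 2 pairs")
    logits = (T @ I.T) / temperature
    return float(_loss_from_logits(logits))


def _loss_from_logits(logits: np.ndarray) -> float:
    n = logits.shape[0]
    row = logits - logits.max(axis=1, keepdims=True)
    col = logits - logits.max(axis=0, keepdims=True)
    log_pr = row - np.log(np.exp(row).sum(axis=1, keepdims=True))
    log_pc = col - np.log(np.exp(col).sum(axis=0, keepdims=True))
    diag = np.arange(n)
    return -0.5 * (log_pr[diag, diag].mean() + log_pc[diag, diag].mean())


def lr_schedule(t: int, total: int, lr_max: float, lr_min: float) -> float:
    """Cosine annealing: lr(t) = lr_min + ½(lr_max - lr_min)(1 + cos(πt/T))."""
    if total < 1:
        raise ParameterError(f"total steps must be >= 1, got {total}")
    if not (0 <= t <= total):
        raise ParameterError(f"step {t} outside [0, {total}]")
    return lr_min + 0.5 * (lr_max - lr_min) * (1 + np.cos(np.pi * t / total))


def examples_from_pairs(
    pairs: Sequence[SentenceSlicePair],
    volumes: dict[str, CTVolume],
    spec: PreprocessSpec | None = None,
    augment_config: dict | None = None,
    seed: int = 0,
) -> list[TrainingExample]:
    """Resolve curated pairs to (sentence, preprocessed slice) examples.

    Each slice index of a pair becomes its own example.  If
    ``augment_config`` is given, seeded train-time augmentation is applied
    to each preprocessed slice (never use this for evaluation examples).
    """
    spec = spec or PreprocessSpec()
    out = []
    for j, pair in enumerate(pairs):
        if pair.study_id not in volumes:
            raise MissingStudyError(f"pair refers to unknown study {pair.study_id!r}")
        vol = volumes[pair.study_id]
        concept = pair.organ if pair.organ else pair.sentence
        for idx in pair.slice_indices:
            img = preprocess_slice(vol.slices[idx], spec)
            if augment_config is not None:
                img = augment_slice(img, augment_config, seed=seed * 1_000_003 + j * 131 + idx)
            out.append(
                TrainingExample(
                    sentence=pair.sentence,
                    image=img,
                    source=pair.source,
                    study_id=pair.study_id,
                    concept=concept,
                )
            )
    return out


def _batch_loss_and_grads(
    model: TinyTrainableEncoder, Xt: np.ndarray, Xi: np.ndarray
) -> tuple[float, dict[str, np.ndarray]]:
    """Closed-form gradients of the symmetric InfoNCE for the tiny encoder."""
    Wt, Wi = model.params["W_text"], model.params["W_img"]
    rho = model.params["logit_scale"][0]
    n = Xt.shape[0]

    Ut = Xt @ Wt
    Ui = Xi @ Wi
    rt = np.linalg.norm(Ut, axis=1, keepdims=True)
    ri = np.linalg.norm(Ui, axis=1, keepdims=True)
    rt = np.where(rt == 0, 1.0, rt)
    ri = np.where(ri == 0, 1.0, ri)
    T = Ut / rt
    I = Ui / ri

    scale = np.exp(rho)
    S = T @ I.T
    logits = scale * S
    loss = _loss_from_logits(logits)

    row = logits - logits.max(axis=1, keepdims=True)
    col = logits - logits.max(axis=0, keepdims=True)
    Pr = np.exp(row) / np.exp(row).sum(axis=1, keepdims=True)
    Pc = np.exp(col) / np.exp(col).sum(axis=0, keepdims=True)
    eye = np.eye(n)
    G = 0.5 / n * ((Pr - eye) + (Pc - eye))

    d_rho = float(np.sum(G * logits))
    dS = scale * G
    dT = dS @ I
    dI = dS.T @ T
    # backprop through row-wise L2 normalization
    dUt = (dT - (np.sum(dT * T, axis=1, keepdims=True)) * T) / rt
    dUi = (dI - (np.sum(dI * I, axis=1, keepdims=True)) * I) / ri
    grads = {
        "W_text": Xt.T @ dUt,
        "W_img": Xi.T @ dUi,
        "logit_scale": np.array([d_rho]),
    }
    return loss, grads


def _val_loss(model: TinyTrainableEncoder, Xt: np.ndarray, Xi: np.ndarray, batch: int) -> float:
    n = Xt.shape[0]
    if n <= max(batch, 1024):
        loss, _ = _batch_loss_and_grads(model, Xt, Xi)
        return loss
    losses, sizes = [], []
    for s in range(0, n - 1, batch):
        chunk = slice(s, min(s + batch, n))
        if chunk.stop - chunk.start < 2:
            break
        loss, _ = _batch_loss_and_grads(model, Xt[chunk], Xi[chunk])
        losses.append(loss)
        sizes.append(chunk.stop - chunk.start)
    return float(np.average(losses, weights=sizes))


def _compose_batches(
    examples: Sequence[TrainingExample], config: TrainConfig, rng: np.random.Generator
) -> list[list[int]]:
    idx_lesion = [i for i, e in enumerate(examples) if e.source == "lesion"]
    idx_organ = [i for i, e in enumerate(examples) if e.source != "lesion"]
    n = len(examples)
    b = min(config.batch_size, n)
    n_batches = max(1, n // b)
    batches = []
    if config.stratify and idx_lesion and idx_organ:
        n_les = max(1, int(round(b * config.lesion_weight)))
        n_org = b - n_les
        for _ in range(n_batches):
            les = rng.choice(idx_lesion, size=min(n_les, b - 1), replace=True)
            org = rng.choice(idx_organ, size=n_org, replace=len(idx_organ) < n_org)
            batches.append(list(les) + list(org))
    else:
        perm = rng.permutation(n)
        for s in range(0, n_batches * b, b):
            batches.append(list(perm[s : s + b]))
    if config.dedupe_concepts:
        deduped = []
        for batch in batches:
            seen, kept = set(), []
            for i in batch:
                key = (examples[i].study_id, examples[i].concept)
                if key not in seen:
                    seen.add(key)
                    kept.append(i)
            if len(kept) >= 2:
                deduped.append(kept)
        batches = deduped
    return [bt for bt in batches if len(bt) >= 2]


def train(
    model: TinyTrainableEncoder,
    examples: Sequence[TrainingExample],
    val_examples: Sequence[TrainingExample],
    config: TrainConfig | None = None,
) -> TrainResult:
    """Fine-tune the tiny dual encoder; returns the min-validation-loss checkpoint.

    Loss history (per-epoch train mean and validation loss, with the
    pre-training validation loss at epoch -1) is returned as a DataFrame.
    A fixed seed gives a reproducible history.
    """
    config = config or TrainConfig()
    if not examples:
        raise InputError("training set is empty")
    if not val_examples:
        raise InputError("validation set is empty")
    model.params["logit_scale"] = np.array([np.log(1.0 / config.temperature_init)])
    rng = np.random.default_rng(config.seed)

    Xt = np.stack([model.text_features(e.sentence) for e in examples])
    Xi = np.stack([model.image_features(e.image) for e in examples])
    Xt_val = np.stack([model.text_features(e.sentence) for e in val_examples])
    Xi_val = np.stack([model.image_features(e.image) for e in val_examples])

    # AdamW state
    m = {k: np.zeros_like(v) for k, v in model.params.items()}
    v = {k: np.zeros_like(p) for k, p in model.params.items()}
    adam_t = 0

    steps_per_epoch = max(1, len(examples) // min(config.batch_size, len(examples)))
    total_steps = config.epochs * steps_per_epoch

    history = []
    val0 = _val_loss(model, Xt_val, Xi_val, config.batch_size)
    history.append({"epoch": -1, "train_loss": np.nan, "val_loss": val0, "lr": np.nan})
    best_val, best_epoch = val0, -1
    best_state = model.state_dict()

    step = 0
    for epoch in range(config.epochs):
        batch_losses = []
        for batch in _compose_batches(examples, config, rng):
            lr = lr_schedule(step, total_steps, config.lr_max, config.lr_min)
            loss, grads = _batch_loss_and_grads(model, Xt[batch], Xi[batch])
            if not np.isfinite(loss):
                raise TrainingError(f"non-finite loss at epoch {epoch}")
            adam_t += 1
            for k, p in model.params.items():
                g = grads[k]
                m[k] = config.beta1 * m[k] + (1 - config.beta1) * g
                v[k] = config.beta2 * v[k] + (1 - config.beta2) * g * g
                m_hat = m[k] / (1 - config.beta1**adam_t)
                v_hat = v[k] / (1 - config.beta2**adam_t)
                update = m_hat / (np.sqrt(v_hat) + config.eps)
                if k != "logit_scale":  # decoupled decay; temperature undecayed
                    update = update + config.weight_decay * p
                model.params[k] = p - lr * update
            batch_losses.append(loss)
            step = min(step + 1, total_steps)
        val = _val_loss(model, Xt_val, Xi_val, config.batch_size)
        if not np.isfinite(val):
            raise TrainingError(f"non-finite validation loss at epoch {epoch}")
        history.append(
            {
                "epoch": epoch,
                "train_loss": float(np.mean(batch_losses)) if batch_losses else np.nan,
                "val_loss": val,
                "lr": lr_schedule(step, total_steps, config.lr_max, config.lr_min),
            }
        )
        if val < best_val:
            best_val, best_epoch = val, epoch
            best_state = model.state_dict()

    model.load_state_dict(best_state)
    return TrainResult(
        model=model,
        best_epoch=best_epoch,
        best_val_loss=float(best_val),
        history=pd.DataFrame(history),
    )
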