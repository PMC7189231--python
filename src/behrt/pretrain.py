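"""Masked-language-model pretraining on diagnosis-code sequences.

Corruption draws one category per disease token, independently:
keep with probability 0.865, replace by [MASK] with 0.12, replace by a
uniformly random disease code with 0.015.  Special tokens and padding
are never touched, and the age/segment/position channels stay intact.
Loss is softmax cross-entropy at the corrupted positions only; the
monitoring metric is a per-patient precision at an elementwise-sigmoid
threshold of 0.5, averaged over patients.

RNG stream contract of :func:`corrupt_batch` (relied on by replay
tests): one ``rng.random`` call of the full token-array shape draws the
category uniforms, then one ``rng.integers`` call draws all random
replacement codes.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit

from .corpus import (IGNORE_LABEL, MASK_ID, DiseaseVocabulary, PatientRecord,
                     TokenizedSequence, build_vocab, collate, encode_patient)
from .model import BehrtModel, ModelConfig
from .optim import AdamW, clip_global_norm, linear_warmup_decay


@dataclass
class MaskingPolicy:
    """Per-token corruption proportions over eligible (disease) tokens."""

    p_keep: float = 0.865
    p_mask: float = 0.12
    p_random: float = 0.015

    def __post_init__(self):
        total = self.p_keep + self.p_mask + self.p_random
        if abs(total - 1.0) > 1e-9:
            raise ValueError("masking proportions must sum to 1")
        if min(self.p_keep, self.p_mask, self.p_random) < 0:
            raise ValueError("masking proportions must be non-negative")


@dataclass
class MaskedBatch:
    """Corrupted token ids plus the MLM label array.

    ``labels`` holds the original disease id wherever the category draw
    was mask-or-random (a random draw may coincidentally redraw the
    original code) and ``IGNORE_LABEL`` everywhere else.  The other
    channels are shared, untouched, with the source batch.
    """

    token_ids: np.ndarray
    labels: np.ndarray
    age_ids: np.ndarray
    segment_ids: np.ndarray
    position_ids: np.ndarray
    padding_mask: np.ndarray

    def as_batch(self) -> dict[str, np.ndarray]:
        return {
            "token_ids": self.token_ids,
            "age_ids": self.age_ids,
            "segment_ids": self.segment_ids,
            "position_ids": self.position_ids,
            "padding_mask": self.padding_mask,
        }


def corrupt_batch(batch: dict[str, np.ndarray], vocab: DiseaseVocabulary,
                  policy: MaskingPolicy, rng: np.random.Generator) -> MaskedBatch:
    """Corrupt every eligible disease token independently per the policy."""
    tokens = batch["token_ids"]
    eligible = tokens >= vocab.first_disease_id
    u = rng.random(tokens.shape)
    to_mask = eligible & (u >= policy.p_keep) & (u < policy.p_keep + policy.p_mask)
    to_random = eligible & (u >= policy.p_keep + policy.p_mask)
    n_random = int(to_random.sum())
    replacements = vocab.first_disease_id + rng.integers(
        0, vocab.n_diseases, size=n_random)
    corrupted = tokens.copy()
    corrupted[to_mask] = MASK_ID
    corrupted[to_random] = replacements
    labels = np.full(tokens.shape, IGNORE_LABEL, dtype=np.int64)
    changed = to_mask | to_random
    labels[changed] = tokens[changed]
    return MaskedBatch(
        token_ids=corrupted, labels=labels,
        age_ids=batch["age_ids"], segment_ids=batch["segment_ids"],
        position_ids=batch["position_ids"], padding_mask=batch["padding_mask"],
    )


def corrupt(seq: TokenizedSequence, vocab: DiseaseVocabulary,
            policy: MaskingPolicy, rng: np.random.Generator) -> MaskedBatch:
    """Single-sequence convenience wrapper around :func:`corrupt_batch`."""
    return corrupt_batch(collate([seq], trim=False), vocab, policy, rng)


def mlm_loss(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mean softmax cross-entropy at labelled positions (0 if none)."""
    loss, _ = mlm_loss_and_grad(scores, labels)
    return loss


def mlm_loss_and_grad(scores: np.ndarray,
                      labels: np.ndarray) -> tuple[float, np.ndarray]:
    sel = labels != IGNORE_LABEL
    d = np.zeros_like(scores)
    n = int(sel.sum())
    if n == 0:
        return 0.0, d
    logits = scores[sel]                       # [N, V]
    targets = labels[sel]
    z = logits - logits.max(axis=1, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=1))
    loss = float(np.mean(logsumexp - z[np.arange(n), targets]))
    probs = np.exp(z) / np.exp(z).sum(axis=1, keepdims=True)
    probs[np.arange(n), targets] -= 1.0
    d[sel] = probs / n
    return loss, d


def mlm_precision(scores: np.ndarray, labels: np.ndarray,
                  threshold: float = 0.5) -> float:
    """Precision of thresholded per-class sigmoid predictions.

    For each patient (batch row), predicted positives are the
    (position, class) pairs whose sigmoid score exceeds ``threshold`` at
    labelled positions; a true positive is a predicted positive whose
    class equals the label.  Precision is computed per patient and
    averaged over patients; patients with no predicted positives are
    skipped.  Raises if no position anywhere carries a label.
    """
    sel = labels != IGNORE_LABEL
    if not sel.any():
        raise ValueError("mlm_precision is undefined: no labelled positions")
    precisions = []
    for b in range(scores.shape[0]):
        rows = np.where(sel[b])[0]
        if rows.size == 0:
            continue
        probs = expit(scores[b, rows])            # [n_pos, V]
        pred = probs > threshold
        n_pred = int(pred.sum())
        if n_pred == 0:
            continue
        tp = int(pred[np.arange(rows.size), labels[b, rows]].sum())
        precisions.append(tp / n_pred)
    if not precisions:
        return float("nan")
    return float(np.mean(precisions))


def constant_baseline_precision(label_batches: list[np.ndarray],
                                code_id: int) -> float:
    """Precision of the constant predictor that always flags ``code_id``.

    The baseline predicts exactly one positive class per labelled
    position, so its per-patient precision is the fraction of that
    patient's labels equal to ``code_id``.
    """
    precisions = []
    for labels in label_batches:
        for b in range(labels.shape[0]):
            lab = labels[b][labels[b] != IGNORE_LABEL]
            if lab.size:
                precisions.append(float((lab == code_id).mean()))
    return float(np.mean(precisions))


def most_frequent_disease_id(corpus: list[PatientRecord],
                             vocab: DiseaseVocabulary) -> int:
    """Token id of the most frequent disease code (by token count)."""
    counts: dict[str, int] = {}
    for rec in corpus:
        for v in rec.visits:
            for c in v.codes:
                counts[c] = counts.get(c, 0) + 1
    code = max(sorted(counts), key=counts.get)
    return vocab.code_to_id[code]


@dataclass
class TrainConfig:
    """Optimisation settings shared by pretraining and fine-tuning.

    ``dropout`` of ``None`` leaves the model's configured dropout in
    place; a float overrides it for the run (fine-tuning defaults to 0:
    the short supervised schedules are noise-limited, not
    capacity-limited, at desk scale).
    """

    epochs: int = 20
    batch_size: int = 32
    lr: float = 2e-3
    warmup_frac: float = 0.1
    weight_decay: float = 0.01
    clip_norm: float = 1.0
    max_len: int = 256
    dropout: Optional[float] = None
    seed: int = 0

    @classmethod
    def pretraining_default(cls, seed: int = 0) -> "TrainConfig":
        return cls(epochs=20, lr=2e-3, batch_size=32, seed=seed)

    @classmethod
    def finetuning_default(cls, seed: int = 0) -> "TrainConfig":
        return cls(epochs=40, lr=5e-3, batch_size=32, dropout=0.0, seed=seed)


def pretrain(
    corpus: list[PatientRecord],
    model_config: ModelConfig,
    train_config: TrainConfig,
    vocab: Optional[DiseaseVocabulary] = None,
    policy: Optional[MaskingPolicy] = None,
) -> tuple[BehrtModel, pd.DataFrame]:
    """MLM-pretrain on a filtered corpus; returns (model, epoch history).

    Corruption is resampled freshly every epoch.  History columns:
    ``epoch``, ``loss`` (mean over batches), ``precision`` (per-patient
    thresholded precision over the epoch's corrupted data).
    """
    if vocab is None:
        vocab = build_vocab(corpus)
    if policy is None:
        policy = MaskingPolicy()
    model_config.vocab_size = vocab.size
    model = BehrtModel(model_config, vocab=vocab, seed=train_config.seed)
    if train_config.dropout is not None:
        model.set_dropout(train_config.dropout)
    seqs = [encode_patient(rec, vocab, train_config.max_len) for rec in corpus]

    rng = np.random.default_rng(train_config.seed)
    params = dict(model.named_parameters())
    opt = AdamW(params, lr=train_config.lr,
                weight_decay=train_config.weight_decay)
    n = len(seqs)
    bs = train_config.batch_size
    # Batches are bucketed by sequence length (cuts padding waste); the
    # batch order is reshuffled every epoch.
    length_order = np.argsort([s.n_real for s in seqs], kind="stable")
    batches_idx = [length_order[s:s + bs] for s in range(0, n, bs)]
    total_steps = len(batches_idx) * train_config.epochs

    history = []
    step = 0
    for epoch in range(train_config.epochs):
        losses, precisions, weights = [], [], []
        for b in rng.permutation(len(batches_idx)):
            idx = batches_idx[b]
            batch = collate([seqs[i] for i in idx])
            masked = corrupt_batch(batch, vocab, policy, rng)
            model.zero_grad()
            out = model.encode(masked.as_batch(), rng=rng, train=True)
            scores = model.mlm_head(out.hidden_states)
            loss, d_scores = mlm_loss_and_grad(scores, masked.labels)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"MLM loss diverged (epoch {epoch}, step {step}): {loss}")
            model._encode_backward(model._mlm_head_backward(d_scores))
            grads = dict(model.named_gradients())
            clip_global_norm(grads, train_config.clip_norm)
            opt.step(grads, linear_warmup_decay(
                step, total_steps, train_config.warmup_frac))
            step += 1
            losses.append(loss)
            if (masked.labels != IGNORE_LABEL).any():
                precisions.append(mlm_precision(scores, masked.labels))
                weights.append(len(idx))
        prec = (float(np.average(precisions, weights=weights))
                if precisions else float("nan"))
        history.append({"epoch": epoch + 1,
                        "loss": float(np.mean(losses)),
                        "precision": prec})
    return model, pd.DataFrame(history)
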