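"""The BEHRT network: four-channel embedding sum, bidirectional
self-attention encoder, MLM head, and CLS-pooled multi-label classifier.

The embedding layer sums up to four channels per token — learned disease,
age and visit-segment tables plus a fixed sinusoidal positional table
indexed by visit ordinal.  Channels can be deactivated (for ablations);
a deactivated channel is never even looked up, so the output is exactly
invariant to its ids.  The encoder is a stack of post-norm transformer
blocks (GELU feed-forward, layer-norm epsilon 1e-12, BERT lineage
defaults).  Pooling is BERT-style first-token (CLS) pooling with tanh.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Optional

import numpy as np

from . import nn
from .corpus import (AGE_VOCAB_SIZE, DiseaseVocabulary, TokenizedSequence,
                     collate)

ALL_CHANNELS = ("disease", "age", "segment", "position")


def positional_table(max_position: int, hidden_size: int) -> np.ndarray:
    """Fixed sinusoidal positional-encoding table.

    Entry ``(p, 2i)`` is ``sin(p / 10000**(2i/hidden_size))`` and entry
    ``(p, 2i+1)`` is the cosine of the same argument.  The table is
    non-trainable.
    """
    if hidden_size % 2:
        raise ValueError("hidden_size must be even for the sinusoidal table")
    pos = np.arange(max_position)[:, None]
    i2 = np.arange(0, hidden_size, 2)[None, :]
    arg = pos / np.power(10000.0, i2 / hidden_size)
    table = np.empty((max_position, hidden_size))
    table[:, 0::2] = np.sin(arg)
    table[:, 1::2] = np.cos(arg)
    return table


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    The defaults are the desk-scale configuration used throughout the
    test suite; ``paper_scale()`` returns the full-size architecture
    (6 layers, 12 heads, hidden 288, intermediate 512).
    """

    vocab_size: int = 65          # diseases + 5 special tokens
    n_layers: int = 2
    n_heads: int = 2
    hidden_size: int = 32
    intermediate_size: int = 64
    max_position: int = 64
    dropout: float = 0.1
    age_vocab_size: int = AGE_VOCAB_SIZE
    segment_vocab_size: int = 2
    active_channels: tuple[str, ...] = ALL_CHANNELS
    pooling: str = "mean"  # "mean" over real tokens, or first-token "cls"

    def __post_init__(self):
        if self.hidden_size % self.n_heads:
            raise ValueError("hidden_size must be divisible by n_heads")
        unknown = set(self.active_channels) - set(ALL_CHANNELS)
        if unknown:
            raise ValueError(f"unknown channels: {sorted(unknown)}")
        if "disease" not in self.active_channels:
            raise ValueError("the disease channel is mandatory")
        self.active_channels = tuple(self.active_channels)
        if self.pooling not in ("mean", "cls"):
            raise ValueError("pooling must be 'mean' or 'cls'")

    @classmethod
    def paper_scale(cls, vocab_size: int) -> "ModelConfig":
        return cls(vocab_size=vocab_size, n_layers=6, n_heads=12,
                   hidden_size=288, intermediate_size=512, max_position=256)


@dataclass
class EncoderOutput:
    """Final hidden states plus every layer's attention maps."""

    hidden_states: np.ndarray            # [B, L, H]
    attentions: list[np.ndarray]         # per layer, [B, n_heads, L, L]


class BehrtModel(nn.Module):
    """Encoder plus MLM and classification heads, with explicit backprop."""

    def __init__(self, config: ModelConfig, vocab: Optional[DiseaseVocabulary] = None,
                 seed: int = 0, n_labels: Optional[int] = None):
        super().__init__()
        self.config = config
        self.vocab = vocab
        rng = np.random.default_rng(seed)
        h = config.hidden_size

        self.tok_emb = self.add_child(
            "tok_emb", nn.EmbeddingTable(config.vocab_size, h, rng))
        self.age_emb = self.add_child(
            "age_emb", nn.EmbeddingTable(config.age_vocab_size, h, rng))
        self.seg_emb = self.add_child(
            "seg_emb", nn.EmbeddingTable(config.segment_vocab_size, h, rng))
        self.pos_table = positional_table(config.max_position, h)  # frozen

        self.emb_ln = self.add_child("emb_ln", nn.LayerNorm(h))
        self.emb_drop = self.add_child("emb_drop", nn.Dropout(config.dropout))
        self.layers = [
            self.add_child(f"layer{i}", nn.EncoderLayer(
                h, config.intermediate_size, config.n_heads, config.dropout, rng))
            for i in range(config.n_layers)
        ]

        # MLM head: dense + GELU + layer-norm + output projection.
        self.mlm_dense = self.add_child("mlm_dense", nn.GeluDense(h, h, rng))
        self.mlm_ln = self.add_child("mlm_ln", nn.LayerNorm(h))
        self.mlm_out = self.add_child("mlm_out", nn.Dense(h, config.vocab_size, rng))

        # Pooling + multi-label classifier (re-initialised at fine-tuning).
        if n_labels is None:
            n_labels = vocab.n_diseases if vocab is not None else 1
        self.n_labels = n_labels
        self._head_rng_seed = seed
        self.pooler = self.add_child("pooler", nn.Dense(h, h, rng))
        self.classifier = self.add_child("classifier", nn.Dense(h, n_labels, rng))

    # -- embedding ----------------------------------------------------------

    def embed(self, batch: dict[str, np.ndarray]) -> np.ndarray:
        """Elementwise sum of the active channels' embedding lookups."""
        cfg = self.config
        self._active_cache = cfg.active_channels
        for name, ids, size in (
            ("disease", batch["token_ids"], cfg.vocab_size),
            ("age", batch["age_ids"], cfg.age_vocab_size),
            ("segment", batch["segment_ids"], cfg.segment_vocab_size),
            ("position", batch["position_ids"], cfg.max_position),
        ):
            if name in cfg.active_channels and (ids.min() < 0 or ids.max() >= size):
                raise ValueError(f"{name} ids out of table range [0, {size})")
        e = np.zeros(batch["token_ids"].shape + (cfg.hidden_size,))
        if "disease" in cfg.active_channels:
            e += self.tok_emb.forward(batch["token_ids"])
        if "age" in cfg.active_channels:
            e += self.age_emb.forward(batch["age_ids"])
        if "segment" in cfg.active_channels:
            e += self.seg_emb.forward(batch["segment_ids"])
        if "position" in cfg.active_channels:
            e += self.pos_table[batch["position_ids"]]
        return e

    def _embed_backward(self, d: np.ndarray) -> None:
        if "disease" in self._active_cache:
            self.tok_emb.backward(d)
        if "age" in self._active_cache:
            self.age_emb.backward(d)
        if "segment" in self._active_cache:
            self.seg_emb.backward(d)
        # positional table is frozen: no gradient

    # -- encoder ------------------------------------------------------------

    def encode(self, batch: dict[str, np.ndarray], rng=None,
               train: bool = False) -> EncoderOutput:
        mask = batch["padding_mask"]
        x = self.emb_drop.forward(
            self.emb_ln.forward(self.embed(batch)), rng, train)
        attns = []
        for layer in self.layers:
            x = layer.forward(x, mask, rng, train)
            attns.append(layer.attn.attn)
        return EncoderOutput(hidden_states=x, attentions=attns)

    def encode_sequence(self, seq: TokenizedSequence) -> EncoderOutput:
        """Convenience single-sequence (eval-mode) encoding."""
        out = self.encode(collate([seq]))
        return EncoderOutput(hidden_states=out.hidden_states[0],
                             attentions=[a[0] for a in out.attentions])

    def _encode_backward(self, d: np.ndarray) -> None:
        for layer in reversed(self.layers):
            d = layer.backward(d)
        d = self.emb_ln.backward(self.emb_drop.backward(d))
        self._embed_backward(d)

    # -- heads --------------------------------------------------------------

    def mlm_head(self, hidden_states: np.ndarray) -> np.ndarray:
        """Per-position score vector over the full token vocabulary."""
        return self.mlm_out.forward(
            self.mlm_ln.forward(self.mlm_dense.forward(hidden_states)))

    def _mlm_head_backward(self, d_scores: np.ndarray) -> np.ndarray:
        return self.mlm_dense.backward(
            self.mlm_ln.backward(self.mlm_out.backward(d_scores)))

    def classify_logits(self, hidden_states: np.ndarray,
                        padding_mask: Optional[np.ndarray] = None) -> np.ndarray:
        """Pooled patient representation -> dense+tanh -> per-disease logits.

        Pooling is either the masked mean over real tokens (default) or
        the first-token (CLS) hidden state, per the model config.
        """
        if self.config.pooling == "cls":
            self._pool_mask = None
            rep = hidden_states[:, 0, :]
        else:
            if padding_mask is None:
                padding_mask = np.ones(hidden_states.shape[:2], dtype=bool)
            self._pool_mask = padding_mask
            counts = padding_mask.sum(axis=1, keepdims=True)
            rep = (hidden_states * padding_mask[..., None]).sum(axis=1) / counts
        self._pool_pre = self.pooler.forward(rep)
        self._pooled = np.tanh(self._pool_pre)
        return self.classifier.forward(self._pooled)

    def _classify_backward(self, d_logits: np.ndarray,
                           seq_len: int) -> np.ndarray:
        d_pooled = self.classifier.backward(d_logits)
        d_pre = d_pooled * (1.0 - self._pooled ** 2)
        d_rep = self.pooler.backward(d_pre)
        d_hidden = np.zeros((d_rep.shape[0], seq_len, d_rep.shape[1]))
        if self._pool_mask is None:
            d_hidden[:, 0, :] = d_rep
        else:
            counts = self._pool_mask.sum(axis=1)
            d_hidden[...] = (d_rep[:, None, :] / counts[:, None, None]) \
                * self._pool_mask[..., None]
        return d_hidden

    def pool_and_classify(self, hidden_states: np.ndarray,
                          padding_mask: Optional[np.ndarray] = None) -> np.ndarray:
        """Per-disease probabilities in (0, 1) for each patient."""
        from scipy.special import expit
        return expit(self.classify_logits(hidden_states, padding_mask))

    def set_dropout(self, p: float) -> None:
        """Override the dropout rate of every dropout layer in place."""
        self.config.dropout = p
        self.emb_drop.p = p
        for layer in self.layers:
            layer.drop1.p = layer.drop2.p = layer.attn.drop.p = p

    def reset_heads(self, n_labels: int, seed: int) -> None:
        """Fresh pooling/classifier head (used when fine-tuning starts).

        Glorot-scale initialisation: the freshly added layers must carry
        signal from the first optimisation steps of a short fine-tuning
        schedule, unlike the pretrained trunk.
        """
        rng = np.random.default_rng(seed)
        h = self.config.hidden_size
        self.n_labels = n_labels
        self.pooler = self.add_child(
            "pooler", nn.Dense(h, h, rng, init_std=np.sqrt(2.0 / (h + h))))
        self.classifier = self.add_child(
            "classifier",
            nn.Dense(h, n_labels, rng, init_std=np.sqrt(2.0 / (h + n_labels))))

    # -- bookkeeping --------------------------------------------------------

    def parameter_count(self) -> int:
        return sum(p.size for _, p in self.named_parameters())

    def disease_embeddings(self) -> np.ndarray:
        """Learned embeddings of the G disease codes, vocab order [G, H]."""
        if self.vocab is None:
            raise ValueError("model carries no vocabulary")
        return self.tok_emb.P["weight"][self.vocab.first_disease_id:]


# ---------------------------------------------------------------------------
# Checkpoints: a single .npz holding config, vocabulary and parameters.
# ---------------------------------------------------------------------------

def _json_to_u8(obj) -> np.ndarray:
    return np.frombuffer(json.dumps(obj).encode(), dtype=np.uint8)


def _u8_to_json(arr: np.ndarray):
    return json.loads(arr.tobytes().decode())


def save_checkpoint(model: BehrtModel, path) -> None:
    arrays = {"param:" + k: v for k, v in model.named_parameters()}
    cfg = asdict(model.config)
    cfg["active_channels"] = list(cfg["active_channels"])
    arrays["config_json"] = _json_to_u8(cfg)
    arrays["n_labels"] = np.array(model.n_labels)
    if model.vocab is not None:
        arrays["vocab_json"] = _json_to_u8(list(model.vocab.codes))
    np.savez(path, **arrays)


def load_checkpoint(path) -> BehrtModel:
    with np.load(path) as data:
        cfg_dict = _u8_to_json(data["config_json"])
        cfg_dict["active_channels"] = tuple(cfg_dict["active_channels"])
        config = ModelConfig(**cfg_dict)
        vocab = None
        if "vocab_json" in data:
            vocab = DiseaseVocabulary.from_codes(_u8_to_json(data["vocab_json"]))
        model = BehrtModel(config, vocab=vocab,
                           n_labels=int(data["n_labels"]))
        params = dict(model.named_parameters())
        for key in data.files:
            if key.startswith("param:"):
                name = key[len("param:"):]
                params[name][...] = data[key]
    return model


def export_embeddings_tsv(model: BehrtModel, path) -> None:
    """Disease code + hidden_size floats per row (for external projection)."""
    emb = model.disease_embeddings()
    with open(path, "w") as fh:
        for code, row in zip(model.vocab.codes, emb):
            fh.write(code + "\t" + "\t".join(f"{x:.8g}" for x in row) + "\n")
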