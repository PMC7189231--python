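"""Interpretability surfaces: attention association maps and
disease-embedding nearest neighbours.

Attention maps expose the row-stochastic weights of a chosen encoder
layer (the last by default), averaged over heads and stripped of
padding, with human-readable token labels.  The maps are read as
non-directional disease associations.  Neighbour tables rank the other
disease codes by cosine similarity of their learned embeddings.
"""
from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .corpus import DiseaseVocabulary, TokenizedSequence
from .model import BehrtModel


@dataclass
class AttentionMap:
    patient_id: str
    token_labels: list[str]
    matrix: np.ndarray  # [n_real, n_real], rows sum to 1

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"patient_id": self.patient_id,
                       "token_labels": self.token_labels,
                       "matrix": self.matrix.tolist()}, fh)


@dataclass
class NeighborTable:
    query_code: str
    neighbors: list[tuple[str, float]]  # (code, cosine), descending

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for code, sim in self.neighbors:
                fh.write(f"{code}\t{sim:.6f}\n")


def _token_label(vocab: DiseaseVocabulary, token_id: int, position: int,
                 age_id: int) -> str:
    code = vocab.id_to_code(int(token_id))
    if position == 0:
        return code  # [CLS]
    return f"{code}@v{position}(age {age_id})"


def attention_map(model: BehrtModel, seq: TokenizedSequence,
                  layer: int = -1, head_aggregation: str = "mean") -> AttentionMap:
    """Aggregated attention of one encoder layer for one patient.

    ``head_aggregation`` is ``"mean"`` (average over heads) or an
    integer-like head index.  Padding rows/columns are stripped.
    """
    n_layers = model.config.n_layers
    if not (-n_layers <= layer < n_layers):
        raise IndexError(f"layer {layer} out of range for {n_layers} layers")
    out = model.encode_sequence(seq)
    attn = out.attentions[layer]          # [n_heads, L, L]
    if head_aggregation == "mean":
        mat = attn.mean(axis=0)
    else:
        mat = attn[int(head_aggregation)]
    n = seq.n_real
    labels = [
        _token_label(model.vocab, seq.token_ids[i], int(seq.position_ids[i]),
                     int(seq.age_ids[i]))
        for i in range(n)
    ]
    return AttentionMap(patient_id=seq.patient_id, token_labels=labels,
                        matrix=mat[:n, :n])


def nearest_diseases(embedding_table: np.ndarray, vocab: DiseaseVocabulary,
                     query_code: str, k: int = 10) -> NeighborTable:
    """Top-k cosine neighbours of a disease code among the G diseases.

    ``embedding_table`` holds one row per disease in vocabulary order
    (special tokens excluded).  Ties break by vocabulary order; the
    query is excluded from its own list.
    """
    if query_code not in vocab.code_to_id or query_code not in vocab.codes:
        raise KeyError(f"unknown disease code {query_code!r}")
    if embedding_table.shape[0] != vocab.n_diseases:
        raise ValueError("embedding table must have one row per disease")
    qi = vocab.disease_index(query_code)
    q = embedding_table[qi]
    norms = np.linalg.norm(embedding_table, axis=1)
    qn = np.linalg.norm(q)
    with np.errstate(invalid="ignore", divide="ignore"):
        sims = embedding_table @ q / np.where(norms * qn > 0, norms * qn, 1.0)
    idx = np.array([i for i in range(vocab.n_diseases) if i != qi])
    # primary key: similarity descending; secondary: vocabulary order
    order = idx[np.lexsort((idx, -sims[idx]))]
    top = order[: min(k, len(order))]
    return NeighborTable(
        query_code=query_code,
        neighbors=[(vocab.codes[i], float(sims[i])) for i in top],
    )


def group_cosine_separation(embedding_table: np.ndarray,
                            vocab: DiseaseVocabulary,
                            group_of_code: dict[str, int]) -> tuple[float, float]:
    """Mean within-group and between-group cosine similarity of the
    disease embeddings (the planted-structure recovery statistic)."""
    emb = embedding_table / np.linalg.norm(embedding_table, axis=1, keepdims=True)
    sims = emb @ emb.T
    groups = np.array([group_of_code[c] for c in vocab.codes])
    same = groups[:, None] == groups[None, :]
    off_diag = ~np.eye(len(groups), dtype=bool)
    within = float(sims[same & off_diag].mean())
    between = float(sims[~same].mean())
    return within, between
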