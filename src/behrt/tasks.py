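"""Supervised task construction, fine-tuning, and evaluation.

Three tasks are built from a patient's visit sequence: predict the
distinct diseases of the next visit (T1), or of the next 6 / 12 months
(T2 / T3).  Each patient contributes exactly one input-output pair: a
random split index j (with at least 4 visits of history) yields the
input prefix and a multi-hot label over the G diseases.  Visit timing
for horizon arithmetic is carried as age-in-months (a visit's stored
month-level age when present, else 12 * its integer year age).

Evaluation computes average precision (APS) and AUROC per patient first
and then averages across patients; disease-wise and first-incidence
variants mirror the cohort-level analyses.  APS/AUROC go through
scikit-learn; ties in AUROC earn 0.5 credit per tied pair.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from .corpus import (DiseaseVocabulary, PatientRecord, Visit, collate,
                     encode_visits)
from .model import BehrtModel, ModelConfig, load_checkpoint
from .optim import AdamW, clip_global_norm, linear_warmup_decay
from .pretrain import TrainConfig
from .synthetic import GroundTruth

MIN_HISTORY_VISITS = 4  # j > 3: at least four visits of input history


@dataclass(frozen=True)
class TaskExample:
    """Input history prefix plus a multi-hot future-disease label."""

    input_visits: tuple[Visit, ...]
    label: np.ndarray              # length-G multi-hot
    split_index: int               # j, 1-based count of input visits
    patient_id: str
    task_tag: str                  # "T1" | "T2" | "T3"
    attributes: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self):
        if len(self.input_visits) < MIN_HISTORY_VISITS:
            raise ValueError("a task example needs at least 4 input visits")
        if self.label.sum() < 1:
            raise ValueError("a task example label needs at least one positive")


@dataclass
class PredictionResult:
    """Per-patient probability vectors next to their labels."""

    probabilities: np.ndarray      # [N, G], entries in (0, 1)
    labels: np.ndarray             # [N, G] multi-hot
    patient_ids: list[str]


@dataclass
class EvaluationReport:
    mean_aps: float
    mean_auroc: float
    n_patients: int
    n_auroc_undefined: int         # patients without a negative class
    per_disease: Optional[pd.DataFrame] = None


def split_patients(
    corpus: list[PatientRecord], test_fraction: float = 0.2, seed: int = 0
) -> tuple[list[PatientRecord], list[PatientRecord]]:
    """Seeded, exhaustive patient-level train/test partition."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(corpus))
    n_test = int(round(test_fraction * len(corpus)))
    test_idx = set(order[:n_test].tolist())
    train = [rec for i, rec in enumerate(corpus) if i not in test_idx]
    test = [rec for i, rec in enumerate(corpus) if i in test_idx]
    return train, test


def _multi_hot(codes: Iterable[str], vocab: DiseaseVocabulary) -> np.ndarray:
    label = np.zeros(vocab.n_diseases, dtype=np.int64)
    for c in codes:
        label[vocab.disease_index(c)] = 1
    return label


def make_t1_example(
    record: PatientRecord, vocab: DiseaseVocabulary, rng: np.random.Generator
) -> Optional[TaskExample]:
    """Next-visit task: j uniform over 3 < j < n_p, label = visit j+1."""
    n = record.n_visits
    if n < 5:
        return None
    j = int(rng.integers(MIN_HISTORY_VISITS, n))      # 4 .. n-1 inclusive
    label = _multi_hot(record.visits[j].codes, vocab)  # visit j+1, 0-based j
    return TaskExample(
        input_visits=record.visits[:j], label=label, split_index=j,
        patient_id=record.patient_id, task_tag="T1",
        attributes=record.attributes,
    )


def last_eligible_index(visit_months: Sequence[int], observation_end: int,
                        horizon_months: int) -> int:
    """n*: the largest (1-based) visit index with a full horizon of
    follow-up after it, or 0 if none."""
    n_star = 0
    for i, m in enumerate(visit_months, start=1):
        if observation_end >= m + horizon_months:
            n_star = i
    return n_star


def horizon_window_label(
    visit_months: Sequence[int], visit_codes: Sequence[Sequence[str]],
    j: int, horizon_months: int,
) -> set[str]:
    """Distinct codes of visits with month-age in (m_j, m_j + horizon]."""
    m_j = visit_months[j - 1]
    out: set[str] = set()
    for m, codes in zip(visit_months, visit_codes):
        if m_j < m <= m_j + horizon_months:
            out.update(codes)
    return out


def make_horizon_example(
    record: PatientRecord, vocab: DiseaseVocabulary, horizon_months: int,
    rng: np.random.Generator,
) -> Optional[TaskExample]:
    """Fixed-horizon task (6 or 12 months of future EHR after visit j).

    A patient is eligible only if the observation horizon extends at
    least ``horizon_months`` past visit 4; j is then uniform over
    3 < j <= n*, and a patient whose drawn window holds no diagnosis is
    excluded.
    """
    if horizon_months not in (6, 12):
        raise ValueError("horizon must be 6 or 12 months")
    n = record.n_visits
    if n < 5:
        return None
    months = [v.month_age for v in record.visits]
    if record.observation_end_age_months < months[MIN_HISTORY_VISITS - 1] + horizon_months:
        return None
    n_star = last_eligible_index(months, record.observation_end_age_months,
                                 horizon_months)
    if n_star < MIN_HISTORY_VISITS:
        return None
    j = int(rng.integers(MIN_HISTORY_VISITS, n_star + 1))  # 4 .. n* inclusive
    window = horizon_window_label(
        months, [v.codes for v in record.visits], j, horizon_months)
    if not window:
        return None
    return TaskExample(
        input_visits=record.visits[:j], label=_multi_hot(window, vocab),
        split_index=j, patient_id=record.patient_id,
        task_tag="T2" if horizon_months == 6 else "T3",
        attributes=record.attributes,
    )


def make_examples(
    corpus: list[PatientRecord], vocab: DiseaseVocabulary, task: str,
    seed: int = 0,
) -> list[TaskExample]:
    """One example per eligible patient for task ``t1`` / ``t2`` / ``t3``."""
    rng = np.random.default_rng(seed)
    out = []
    for rec in corpus:
        if task == "t1":
            ex = make_t1_example(rec, vocab, rng)
        elif task == "t2":
            ex = make_horizon_example(rec, vocab, 6, rng)
        elif task == "t3":
            ex = make_horizon_example(rec, vocab, 12, rng)
        else:
            raise ValueError(f"unknown task {task!r}")
        if ex is not None:
            out.append(ex)
    return out


# ---------------------------------------------------------------------------
# Fine-tuning
# ---------------------------------------------------------------------------

def _bce_loss_and_grad(logits: np.ndarray,
                       labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean per-disease binary cross-entropy and gradient w.r.t. logits."""
    from scipy.special import expit
    p = expit(logits)
    eps = 1e-12
    loss = -float(np.mean(labels * np.log(p + eps)
                          + (1 - labels) * np.log(1 - p + eps)))
    return loss, (p - labels) / labels.size


def finetune(
    checkpoint, examples: list[TaskExample], train_config: TrainConfig,
    head_seed: Optional[int] = None,
) -> tuple[BehrtModel, pd.DataFrame]:
    """Fine-tune a pretrained encoder on task examples.

    ``checkpoint`` is a checkpoint path or a :class:`BehrtModel`.  The
    pooling/classifier head is freshly initialised; every encoder weight
    is trained end-to-end with mean per-disease binary cross-entropy.
    """
    model = checkpoint if isinstance(checkpoint, BehrtModel) else load_checkpoint(checkpoint)
    if model.vocab is None:
        raise ValueError("fine-tuning requires a model with a vocabulary")
    n_labels = model.vocab.n_diseases
    if examples and len(examples[0].label) != n_labels:
        raise ValueError(
            f"label length {len(examples[0].label)} does not match the "
            f"checkpoint vocabulary ({n_labels} diseases)")
    model.reset_heads(n_labels, train_config.seed if head_seed is None else head_seed)
    if train_config.dropout is not None:
        model.set_dropout(train_config.dropout)

    seqs = [encode_visits(ex.input_visits, model.vocab, train_config.max_len,
                          patient_id=ex.patient_id) for ex in examples]
    labels = np.stack([ex.label for ex in examples]).astype(float)

    rng = np.random.default_rng(train_config.seed)
    params = dict(model.named_parameters())
    opt = AdamW(params, lr=train_config.lr,
                weight_decay=train_config.weight_decay)
    n, bs = len(seqs), train_config.batch_size
    length_order = np.argsort([s.n_real for s in seqs], kind="stable")
    batches_idx = [length_order[s:s + bs] for s in range(0, n, bs)]
    total_steps = len(batches_idx) * train_config.epochs

    history = []
    step = 0
    for epoch in range(train_config.epochs):
        losses = []
        for b in rng.permutation(len(batches_idx)):
            idx = batches_idx[b]
            batch = collate([seqs[i] for i in idx])
            model.zero_grad()
            out = model.encode(batch, rng=rng, train=True)
            logits = model.classify_logits(out.hidden_states,
                                           batch["padding_mask"])
            loss, d_logits = _bce_loss_and_grad(logits, labels[idx])
            if not np.isfinite(loss):
                raise RuntimeError(f"fine-tuning loss diverged at epoch {epoch}")
            d_hidden = model._classify_backward(d_logits, batch["token_ids"].shape[1])
            model._encode_backward(d_hidden)
            grads = dict(model.named_gradients())
            clip_global_norm(grads, train_config.clip_norm)
            opt.step(grads, linear_warmup_decay(
                step, total_steps, train_config.warmup_frac))
            step += 1
            losses.append(loss)
        history.append({"epoch": epoch + 1, "loss": float(np.mean(losses))})
    return model, pd.DataFrame(history)


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def predict(model: BehrtModel, examples: list[TaskExample],
            batch_size: int = 128, max_len: int = 256) -> PredictionResult:
    """Eval-mode per-disease probabilities for every example."""
    probs = []
    for s in range(0, len(examples), batch_size):
        chunk = examples[s:s + batch_size]
        seqs = [encode_visits(ex.input_visits, model.vocab, max_len,
                              patient_id=ex.patient_id) for ex in chunk]
        batch = collate(seqs)
        out = model.encode(batch)
        probs.append(model.pool_and_classify(out.hidden_states,
                                             batch["padding_mask"]))
    return PredictionResult(
        probabilities=np.concatenate(probs),
        labels=np.stack([ex.label for ex in examples]),
        patient_ids=[ex.patient_id for ex in examples],
    )


def _per_patient_metrics(probs: np.ndarray,
                         labels: np.ndarray) -> tuple[float, float, int, int]:
    aps, aurocs = [], []
    n_undef = 0
    for p, y in zip(probs, labels):
        aps.append(average_precision_score(y, p))
        if 0 < y.sum() < len(y):
            aurocs.append(roc_auc_score(y, p))
        else:
            n_undef += 1
    mean_auroc = float(np.mean(aurocs)) if aurocs else float("nan")
    return float(np.mean(aps)), mean_auroc, len(labels), n_undef


def evaluate(model: BehrtModel, examples: list[TaskExample],
             result: Optional[PredictionResult] = None) -> EvaluationReport:
    """Per-patient APS/AUROC, averaged across patients.

    Patients whose AUROC is undefined (label has no negative class) are
    excluded from the AUROC mean and counted in the report.
    """
    if not examples:
        raise ValueError("cannot evaluate an empty example set")
    if result is None:
        result = predict(model, examples)
    mean_aps, mean_auroc, n, n_undef = _per_patient_metrics(
        result.probabilities, result.labels)
    return EvaluationReport(mean_aps=mean_aps, mean_auroc=mean_auroc,
                            n_patients=n, n_auroc_undefined=n_undef)


def disease_wise_eval(
    model: BehrtModel, examples: list[TaskExample],
    prevalence_floor: float = 0.01,
    result: Optional[PredictionResult] = None,
) -> pd.DataFrame:
    """Per-disease APS/AUROC across patients, with a prevalence floor.

    Prevalence (occurrence ratio) is the fraction of evaluated patients
    whose label carries the disease; diseases below the floor or with
    zero positives are excluded, and AUROC is NaN when a disease has no
    negatives.
    """
    if result is None:
        result = predict(model, examples)
    probs, labels = result.probabilities, result.labels
    prevalence = labels.mean(axis=0)
    rows = []
    for i, code in enumerate(model.vocab.codes):
        prev = float(prevalence[i])
        if prev < prevalence_floor or labels[:, i].sum() == 0:
            continue
        aps = float(average_precision_score(labels[:, i], probs[:, i]))
        auroc = (float(roc_auc_score(labels[:, i], probs[:, i]))
                 if labels[:, i].sum() < len(labels) else float("nan"))
        rows.append({"code": code, "prevalence": prev, "aps": aps, "auroc": auroc})
    return pd.DataFrame(rows, columns=["code", "prevalence", "aps", "auroc"])


def first_incidence_eval(
    model: BehrtModel, examples: list[TaskExample],
    result: Optional[PredictionResult] = None,
) -> EvaluationReport:
    """Evaluate on labels restricted to first-ever diagnoses.

    Each patient's label is restricted to diseases absent from their
    input history; patients left with an all-zero label are dropped.
    """
    if result is None:
        result = predict(model, examples)
    keep_probs, keep_labels = [], []
    for ex, p in zip(examples, result.probabilities):
        history = {c for v in ex.input_visits for c in v.codes}
        hist_idx = [model.vocab.disease_index(c) for c in history]
        restricted = ex.label.copy()
        restricted[hist_idx] = 0
        if restricted.sum() == 0:
            continue
        keep_probs.append(p)
        keep_labels.append(restricted)
    if not keep_probs:
        raise ValueError("no patient retains a first-incidence label")
    mean_aps, mean_auroc, n, n_undef = _per_patient_metrics(
        np.stack(keep_probs), np.stack(keep_labels))
    return EvaluationReport(mean_aps=mean_aps, mean_auroc=mean_auroc,
                            n_patients=n, n_auroc_undefined=n_undef)


def prevalence_baseline_report(train_examples: list[TaskExample],
                               test_examples: list[TaskExample]) -> EvaluationReport:
    """Rank diseases by training-label prevalence; score every patient
    with that same vector (the floor a learned model must beat)."""
    prev = np.stack([ex.label for ex in train_examples]).mean(axis=0)
    probs = np.tile(prev, (len(test_examples), 1))
    labels = np.stack([ex.label for ex in test_examples])
    mean_aps, mean_auroc, n, n_undef = _per_patient_metrics(probs, labels)
    return EvaluationReport(mean_aps=mean_aps, mean_auroc=mean_auroc,
                            n_patients=n, n_auroc_undefined=n_undef)


# ---------------------------------------------------------------------------
# Ablation and audit
# ---------------------------------------------------------------------------

def ablation_suite(
    corpus: list[PatientRecord],
    channel_subsets: list[tuple[str, ...]],
    model_config: ModelConfig,
    pretrain_config: TrainConfig,
    finetune_config: TrainConfig,
    task: str = "t1",
    seed: int = 0,
    test_fraction: float = 0.2,
) -> pd.DataFrame:
    """Train and evaluate one model per channel subset (disease always on).

    Every arm sees identical data, splits, example draws and seeds; only
    the set of active embedding channels differs.  Returns one row per
    requested subset with mean per-patient APS and AUROC.
    """
    from dataclasses import replace
    from .pretrain import pretrain
    from .corpus import build_vocab

    vocab = build_vocab(corpus)
    train, test = split_patients(corpus, test_fraction, seed)
    train_ex = make_examples(train, vocab, task, seed)
    test_ex = make_examples(test, vocab, task, seed)
    rows = []
    for subset in channel_subsets:
        channels = tuple(dict.fromkeys(("disease",) + tuple(subset)))
        cfg = replace(model_config, active_channels=channels,
                      vocab_size=vocab.size)
        model, _ = pretrain(train, cfg, pretrain_config, vocab=vocab)
        model, _ = finetune(model, train_ex, finetune_config)
        report = evaluate(model, test_ex)
        rows.append({"channels": "+".join(channels),
                     "aps": report.mean_aps, "auroc": report.mean_auroc})
    return pd.DataFrame(rows, columns=["channels", "aps", "auroc"])


@dataclass
class AuditSummary:
    """Attribute-consistency audit of fine-tuned predictions."""

    mean_disallowed_prob: float
    mean_allowed_prob: float
    mean_ratio: float               # per-patient disallowed/allowed mean ratio
    ratios: np.ndarray
    disallowed_in_topk: int         # disallowed codes among any patient's top-k
    n_patients: int
    top_k: int


def attribute_consistency_audit(
    model: BehrtModel, examples: list[TaskExample], ground_truth: GroundTruth,
    top_k: int = 10, result: Optional[PredictionResult] = None,
) -> AuditSummary:
    """Compare predicted probabilities of attribute-disallowed vs allowed
    codes for each patient (the synthetic analogue of checking that
    sex-specific diseases are not predicted for the wrong sex)."""
    exclusive = ground_truth.exclusive_codes()
    if not exclusive:
        raise ValueError("ground truth contains no attribute-exclusive codes")
    if result is None:
        result = predict(model, examples)
    vocab = model.vocab
    allowed_of = ground_truth.allowed_attribute
    ratios, dis_means, all_means = [], [], []
    topk_hits = 0
    for ex, p in zip(examples, result.probabilities):
        attr = ex.attributes.get("attribute")
        if attr is None:
            raise ValueError(f"patient {ex.patient_id} has no attribute")
        dis_idx = [vocab.disease_index(c) for c in exclusive
                   if allowed_of[c] != attr]
        all_idx = [i for i in range(vocab.n_diseases) if i not in set(dis_idx)]
        if not dis_idx:
            continue
        d, a = float(p[dis_idx].mean()), float(p[all_idx].mean())
        dis_means.append(d)
        all_means.append(a)
        ratios.append(d / a)
        top = np.argsort(-p)[:top_k]
        topk_hits += int(np.isin(top, dis_idx).sum())
    return AuditSummary(
        mean_disallowed_prob=float(np.mean(dis_means)),
        mean_allowed_prob=float(np.mean(all_means)),
        mean_ratio=float(np.mean(ratios)),
        ratios=np.asarray(ratios),
        disallowed_in_topk=topk_hits,
        n_patients=len(ratios),
        top_k=top_k,
    )
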