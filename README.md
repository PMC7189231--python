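# behrt

A transformer encoder for coded longitudinal electronic health records
(EHR), in the BEHRT ("BERT for EHR") family: it treats a diagnosis code
as a word, a clinical visit as a sentence, and a patient's history as a
document, pretrains with a masked-language-model (MLM) objective, and
fine-tunes for simultaneous multi-label prediction of future diagnoses.
The package is aimed at methods researchers in clinical risk modelling
who want a fully tested, CPU-scale, dependency-light implementation of
this model class — including a seeded synthetic patient-trajectory
simulator, so the entire pipeline runs and is verifiable without access
to restricted EHR databases.

## The model

A patient's record is the visit sequence V_p = {v_p^1, …, v_p^(n_p)},
where visit v_p^j is a set of m_p^j diagnosis codes drawn from a
vocabulary D = {d_1, …, d_G} at an integer patient age.  The input
layout is

```
[CLS] v^1 [SEP] v^2 [SEP] … v^(n_p) [SEP]
```

and each token is embedded as the sum of four channels:

* **disease** — learned embedding of the code (or [CLS]/[SEP]/[MASK]);
* **age** — learned embedding, one id per year of age, shared by all
  tokens of a visit (a universal, cross-patient notion of time);
* **segment** — learned A/B embedding alternating between consecutive
  visits;
* **position** — fixed sinusoidal encoding of the *visit ordinal*
  (not the token index), shared by all tokens of a visit.

Because age, segment, and position are identical within a visit, the
encoder is exactly order-invariant to the arrangement of diagnoses
inside a visit.  The summed embeddings pass through a stack of
bidirectional multi-head self-attention blocks (post-norm, GELU
feed-forward).

**Pretraining (MLM):** each disease token is independently left
unchanged with probability 0.865, replaced by [MASK] with 0.12, or
replaced by a random disease code with 0.015; the model is trained with
cross-entropy to recover the original codes at corrupted positions, and
monitored with a per-patient precision score at a 0.5 sigmoid
threshold.

**Fine-tuning:** a pooled patient representation feeds a single
feed-forward classifier emitting a probability y*_p[i] for every
disease d_i.  Three tasks are built per corpus — diseases of the next
visit (T1), of the next 6 months (T2), and of the next 12 months (T3) —
with one input/label pair per patient (split index j uniform over
3 < j < n_p, label w_{j+1}, w_6m or w_12m), trained with per-disease
binary cross-entropy on an 80/20 patient split.  Evaluation computes
average precision (APS) and AUROC per patient first and then averages,
plus disease-wise, first-incidence (labels never seen in the history),
channel-ablation, and attribute-consistency analyses.

The encoder, its backward pass, and the AdamW optimizer with linear
warmup/decay are implemented directly in numpy (no deep-learning
framework required); analytic gradients are verified against finite
differences in the test suite.

## The synthetic cohort

`behrt.synthetic` draws seeded corpora with planted, recoverable
structure: diseases partitioned into groups with a latent per-visit
"active group" evolving as a self-biased Markov chain whose switches
drift toward age-appropriate groups; codes drawn mostly from the active
group; a binary patient attribute (a gender-analog) that forbids a
fraction of codes for one level; irregular month-level visit gaps; and
a follow-up horizon gating the 6/12-month tasks.  Every planted feature
corresponds to a downstream check: group recovery by embedding cosine,
age/position ablation margins, and the attribute-consistency audit.

## Worked example

```python
from behrt import (ModelConfig, SimConfig, TrainConfig, build_vocab,
                   generate_corpus, pretrain, evaluate, finetune,
                   split_patients, nearest_diseases)
from behrt.tasks import make_examples, prevalence_baseline_report

corpus, truth = generate_corpus(SimConfig(seed=0))   # 2,000 patients, 60 codes
vocab = build_vocab(corpus)

model, history = pretrain(corpus, ModelConfig(),
                          TrainConfig.pretraining_default(seed=0))
print(f"MLM loss {history['loss'].iloc[0]:.3f} -> {history['loss'].iloc[-1]:.3f}, "
      f"precision {history['precision'].iloc[-1]:.3f}")

print(f"D007 belongs to planted group {truth.group_of_code['D007']}")
for code, sim in nearest_diseases(model.disease_embeddings(), vocab,
                                  "D007", k=3).neighbors:
    print(f"  D007 ~ {code}  cosine {sim:+.3f}  (group {truth.group_of_code[code]})")

train, test = split_patients(corpus, test_fraction=0.2, seed=0)
train_ex = make_examples(train, vocab, "t1", seed=0)
test_ex = make_examples(test, vocab, "t1", seed=0)
model, _ = finetune(model, train_ex, TrainConfig.finetuning_default(seed=0))
report = evaluate(model, test_ex)
baseline = prevalence_baseline_report(train_ex, test_ex)
print(f"next-visit prediction: APS {report.mean_aps:.3f} "
      f"(prevalence baseline {baseline.mean_aps:.3f}), "
      f"AUROC {report.mean_auroc:.3f}")
```

Output (a few minutes on one CPU core):

```
MLM loss 4.132 -> 3.408, precision 0.038
D007 belongs to planted group 0
  D007 ~ D001  cosine +0.983  (group 0)
  D007 ~ D004  cosine +0.971  (group 0)
  D007 ~ D003  cosine +0.968  (group 0)
next-visit prediction: APS 0.228 (prevalence baseline 0.139), AUROC 0.719
```

Reading the numbers: MLM pretraining pushes the corruption-recovery
loss well below the ln 60 ≈ 4.09 marginal floor, and the three nearest
embedding neighbours of code D007 all come from its own planted disease
group — the model has recovered the co-occurrence structure without
ever being told the groups.  After fine-tuning, ranking the 60 diseases
by predicted probability for each held-out patient gives a mean
per-patient average precision of 0.228 against 0.139 for ranking by
training-set prevalence, i.e. the model uses individual history, not
just population frequencies.

The same pipeline is scriptable from the shell via the `behrt` console
command (`simulate`, `pretrain`, `finetune`, `evaluate`, `ablate`,
`interpret`), each subcommand reading a YAML config and writing its
outputs, resolved config, seeds and logs to a run directory.

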