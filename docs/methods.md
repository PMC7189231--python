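# Methods

This note records the modelling assumptions, parameter choices, and
numerical conventions behind the package, and what the synthetic
experiments do and do not establish.

## Data model and tokenisation

A corpus is a list of patients; a patient is a time-ordered list of
visits, each a non-empty set of diagnosis codes at an integer age in
years (optionally with month-level age for horizon arithmetic), plus an
end-of-observation age in months and an optional map of latent
attributes used only for audits.  Patients with fewer than five
diagnosis-carrying visits are excluded; visits without diagnoses are
dropped when a corpus is read.

Tokenisation emits `[CLS] v^1 [SEP] v^2 [SEP] …` with four parallel id
channels.  Conventions that the data format leaves open were fixed as
follows:

* **Age granularity** — one embedding id per year of age, 0–110, plus a
  single bucket for ages above 110.  The model embeds age per event;
  year-level granularity matches the corpus format and keeps the table
  small.  Month-level ages, when present, serve only the 6/12-month
  task windows, not the embedding.
* **Special-token channels** — `[CLS]` takes the first retained visit's
  age, segment 0, position 0; each `[SEP]` inherits its preceding
  visit's age/segment/position.  This preserves the property that all
  tokens of a visit share identical non-disease channels, which is what
  makes the encoder order-invariant within a visit.
* **Position** — the visit ordinal (CLS = 0, first visit = 1, …),
  shared by all tokens of a visit, encoded by the fixed sinusoidal
  table sin/cos(p / 10000^(2i/H)).  The table is non-trainable: skewed
  sequence-length distributions give rare long positions too little
  gradient to learn a positional embedding well.
* **Truncation** — sequences longer than `max_len` (default 256) drop
  whole oldest visits first, keep `[CLS]`, and renumber the retained
  visits from 1; a visit that cannot fit alone is an error.  Recent
  history is the prediction-relevant context; truncation never splits a
  visit.

## Architecture and training

Desk-scale defaults: 2 encoder layers, 2 heads, hidden size 32,
intermediate size 64, dropout 0.1, layer-norm epsilon 1e-12, GELU
feed-forward, post-norm residuals.  A paper-scale constructor
(6/12/288/512) exists but is not exercised by the tests.  The forward
and backward passes are written directly in numpy in float64; the
analytic gradients of both heads are checked against central finite
differences at tolerance 1e-4 in the suite.  The optimizer is AdamW
(decoupled weight decay 0.01, biases and layer-norm parameters exempt)
with linear warmup over the first 10% of steps and linear decay to
zero, plus global-norm gradient clipping at 1.0.

**Masking.**  Each disease token draws its corruption category
independently: keep 0.865, `[MASK]` 0.12, random disease 0.015.  This
is a flat per-token scheme, not the two-stage select-15%-then-subdivide
scheme of the original BERT lineage: the three stated fractions sum to
one over all disease words, leaving no room for a "selected but kept,
still predicted" category.  Consequently the MLM loss is computed only
at changed positions; a random replacement may coincidentally redraw
the original code (uniform over the G diseases) and still counts as a
labelled position.  Special tokens, padding, and the age/segment/
position channels are never touched.

**MLM precision.**  The monitoring metric applies an elementwise
sigmoid to the scores at labelled positions, thresholds at 0.5, counts
a true positive when a predicted-positive class equals the label,
computes precision per patient, and averages over patients, skipping
patients with no predicted positives.  A per-class sigmoid is the only
reading under which a fixed 0.5 threshold is meaningful; this
definition is declared, not claimed to be uniquely implied by the
metric's name.

**Pooling.**  The classification head pools the final hidden states by
a masked mean over real tokens, then dense + tanh, then a linear
per-disease classifier with sigmoid outputs.  First-token (CLS) pooling
is available (`ModelConfig(pooling="cls")`) but is not the default: the
MLM objective places no gradient on the `[CLS]` position, so at desk
scale its post-pretraining hidden state is nearly patient-independent
(across-patient standard deviation on the order of 0.1% of its norm),
and the short fine-tuning schedules cannot recover from that
bottleneck — fine-tuned CLS-pooled models stay at the prevalence
predictor.  Mean pooling gives every token a direct gradient path and
trains reliably.  At cohort scale with ~10^5 fine-tuning steps the
distinction is expected to vanish, which is why CLS pooling remains an
option.

**Head initialisation.**  The freshly added pooler/classifier layers
are initialised at Glorot scale (√(2/(fan_in+fan_out))) rather than the
trunk's 0.02: two stacked 0.02-std layers attenuate the pooled signal
by ~4 orders of magnitude and stall short schedules.

**Schedules.**  Pretraining default: 20 epochs, batch 32, lr 2e-3.
Fine-tuning default: 40 epochs, batch 32, lr 5e-3, dropout 0.  These
are step-count choices (~1,250 and ~2,000 optimizer steps on the
default 2,000-patient corpus): what matters for convergence of a small
transformer is the number of Adam steps, so small corpora need many
more epochs than large ones, and epoch counts quoted for cohort-scale
training do not transfer.  Dropout is disabled during fine-tuning
because the short supervised schedules at this scale are noise-limited
rather than capacity-limited.  Batches are bucketed by sequence length
(shuffled at the batch level each epoch) to avoid padding waste; MLM
corruption is resampled freshly every epoch.

## Tasks and evaluation

* T1 draws the split index j uniformly from 3 < j < n_p; the label is
  the set of distinct codes of visit j+1.  T2/T3 require at least one
  horizon (6/12 months) of observation after visit 4, draw j uniformly
  from 3 < j ≤ n* (n* = the last visit with a full horizon of follow-up
  after it, inclusive reading), and label with distinct codes of visits
  whose month-age falls in (m_j, m_j + horizon].  Patients whose drawn
  window contains no diagnosis are excluded, so every example has at
  least one positive.  Each patient contributes exactly one example.
* APS and AUROC go through scikit-learn; AUROC tie handling is the
  standard half credit per tied pair.  Per-patient metrics are averaged
  over patients; patients whose label has no negative class have
  undefined AUROC and are excluded from that mean and counted.
  Disease-wise evaluation keeps diseases whose label prevalence in the
  evaluation example set (the "in our data" reading adopted here) is at
  least the 1% floor.
* First-incidence evaluation zeroes label entries for codes present
  anywhere in the input history and drops patients left without
  positives.
* The ablation suite retrains pretraining + fine-tuning per channel
  subset (disease always active) with identical data, splits, example
  draws and seeds; a deactivated channel is never looked up, so model
  output is bitwise invariant to its ids.
* The attribute-consistency audit compares each patient's mean
  predicted probability over codes disallowed for their attribute with
  the mean over allowed codes, and counts disallowed codes inside
  top-k predictions — the synthetic analogue of checking that
  sex-specific diseases are not assigned to the wrong sex.

## The synthetic cohort

The generator plants exactly the structure the pipeline claims to
exploit.  Defaults (the reference study conditions): 2,000 patients, 60
codes in 6 groups of 10, 20% of codes exclusive to one level of a
binary attribute, start age ~ N(40, 15²) years, 5–16 visits of 1–4
distinct codes, inter-visit gaps max(1, round(N(6, 4²))) months, 12
months of follow-up after the last visit, seed 0.

Each visit has a latent active group.  Within-visit code draws weight
active-group codes by `within_group_affinity` (default 25, i.e. ~83% of
a visit's codes come from its active group); the group evolves with
self-transition probability aff/(aff + n_groups − 1) (~0.83), and
switches drift toward age-appropriate groups (each group prefers ages
around an evenly spaced centre in 20–80 years, width 15).  The affinity
default was chosen so that the planted groups are recoverable at all —
at weak affinity the conditional code distribution given full context
is close to the marginal and no learner (including a co-occurrence
count) can separate the groups, which would make every downstream check
vacuous.  The age-directed switching gives the age channel predictive
signal that code history alone cannot fully supply, which is what a
channel ablation is supposed to detect.

What the simulator does **not** model: real nosology and ontology
structure, calendar dates, care-seeking and coding biases, mortality
and informative censoring, code cardinality in the hundreds, and
corpus sizes in the millions.  Passing tests on this cohort establish
that the implementation learns the structures it is pointed at and that
every metric matches an independent oracle; they say nothing about
clinical performance on real EHR, and the absolute APS/AUROC values
here are not comparable to cohort-scale results.

## Numerical conventions and degenerate inputs

Attention masking adds −1e9 to padded key positions (their weights
underflow to exactly zero); rows of padded queries are computed but
carry no gradient.  The MLM loss with zero labelled positions is
defined as 0; MLM precision with no labelled positions anywhere raises.
Cosine neighbour ties break by vocabulary order; the query is excluded
from its own neighbour list.  Checkpoints are single `.npz` containers
holding the config, the vocabulary and every named parameter tensor.
Corpus generation, corruption, batching, splits and initialisation are
all driven by explicit integer seeds; identical seeds reproduce corpora
byte-for-byte and training histories bit-for-bit on a given platform.

## Known limitations

* No GPU path and no mixed precision; the numpy implementation is
  practical to a few thousand patients and small hidden sizes.
* Hyperparameter search is a plain config sweep (one run per config);
  no Bayesian optimisation.
* The MLM precision metric is one declared reading of an
  under-specified monitoring score; comparisons to precision values
  computed under other readings are not meaningful.
* 2-D projections of the exported embeddings (t-SNE and similar) are
  out of scope; embeddings are exported as TSV for external tools.
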