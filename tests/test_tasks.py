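"""Task construction, fine-tuning, and the evaluation suite."""
import numpy as np
import pytest

from behrt.corpus import DiseaseVocabulary, build_vocab
from behrt.model import BehrtModel, ModelConfig
from behrt.pretrain import TrainConfig
from behrt.tasks import (PredictionResult, ablation_suite,
                         attribute_consistency_audit, disease_wise_eval,
                         evaluate, finetune, first_incidence_eval,
                         horizon_window_label, last_eligible_index,
                         make_examples, make_horizon_example, make_t1_example,
                         prevalence_baseline_report, split_patients)
from behrt.synthetic import GroundTruth
from conftest import record

VOC3 = DiseaseVocabulary.from_codes(["A", "B", "C"])


# -- independent scalar metric oracles --------------------------------------

def aps_brute(y, s):
    """Precision at each positive rank, averaged (assumes unique scores)."""
    order = np.argsort(-s)
    hits, precs = 0, []
    for rank, i in enumerate(order, start=1):
        if y[i]:
            hits += 1
            precs.append(hits / rank)
    return float(np.mean(precs))


def auroc_brute(y, s):
    """Exhaustive pair counting with half credit for ties."""
    pos, neg = s[y == 1], s[y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestSplit:
    def test_eighty_twenty_partition(self, small_corpus):
        train, test = split_patients(small_corpus[:10], 0.2, seed=0)
        assert len(train) == 8 and len(test) == 2
        ids = {r.patient_id for r in train} | {r.patient_id for r in test}
        assert ids == {r.patient_id for r in small_corpus[:10]}

    def test_same_seed_same_split(self, small_corpus):
        a = split_patients(small_corpus, 0.2, seed=5)
        b = split_patients(small_corpus, 0.2, seed=5)
        assert [r.patient_id for r in a[0]] == [r.patient_id for r in b[0]]

    def test_disjoint(self, small_corpus):
        train, test = split_patients(small_corpus, 0.3, seed=1)
        assert not ({r.patient_id for r in train}
                    & {r.patient_id for r in test})


class TestT1Builder:
    def test_five_visits_force_index_four(self):
        rec = record("p", [30, 31, 32, 33, 34],
                     [["A"], ["B"], ["A"], ["C"], ["B", "C"]])
        ex = make_t1_example(rec, VOC3, np.random.default_rng(0))
        assert ex.split_index == 4
        assert len(ex.input_visits) == 4
        np.testing.assert_array_equal(ex.label, [0, 1, 1])  # B and C

    def test_duplicate_codes_collapse_in_label(self):
        rec = record("p", [30] * 5, [["A"]] * 4 + [["A", "A", "B"]])
        ex = make_t1_example(rec, VOC3, np.random.default_rng(0))
        assert ex.label.sum() == 2

    def test_too_short_history_excluded(self):
        rec = record("p", [30] * 4, [["A"]] * 4)
        assert make_t1_example(rec, VOC3, np.random.default_rng(0)) is None

    def test_split_index_uniform_over_interior(self):
        rec = record("p", [30] * 8, [["A"]] * 8)
        rng = np.random.default_rng(0)
        draws = np.array([make_t1_example(rec, VOC3, rng).split_index
                          for _ in range(10_000)])
        p = 1 / 4
        sigma = np.sqrt(p * (1 - p) * 10_000)
        for j in (4, 5, 6, 7):
            assert abs((draws == j).sum() - 2500) < 3 * sigma
        assert set(draws) == {4, 5, 6, 7}


class TestHorizonBuilder:
    def test_hand_evaluated_window(self):
        # visit month-ages ..., 400, 403, 407; follow-up ends at 406
        months = [380, 385, 390, 395, 400, 403, 407]
        codes = [["A"], ["A"], ["B"], ["B"], ["A"], ["C"], ["B"]]
        n_star = last_eligible_index(months, observation_end=406,
                                     horizon_months=6)
        assert n_star == 5  # the month-400 visit is the last with 6 months left
        label = horizon_window_label(months, codes, j=5, horizon_months=6)
        assert label == {"C"}  # only the month-403 visit falls in (400, 406]

    def test_patient_without_horizon_after_visit_four_excluded(self):
        rec = record("p", [30] * 5, [["A"]] * 5,
                     months=[360, 361, 362, 363, 364], obs_end=366)
        assert make_horizon_example(rec, VOC3, 6,
                                    np.random.default_rng(0)) is None

    def test_example_built_when_eligible(self):
        months = [360, 362, 364, 366, 368, 370]
        rec = record("p", [30] * 6, [["A"], ["A"], ["B"], ["B"], ["C"], ["A"]],
                     months=months, obs_end=380)
        ex = make_horizon_example(rec, VOC3, 6, np.random.default_rng(1))
        assert ex is not None
        assert ex.task_tag == "T2"
        assert 4 <= ex.split_index
        # label matches an independent window evaluation
        want = horizon_window_label(months,
                                    [v.codes for v in rec.visits],
                                    ex.split_index, 6)
        got = {VOC3.codes[i] for i in np.where(ex.label)[0]}
        assert got == want

    def test_widening_horizon_never_shrinks_label(self):
        months = [360, 362, 364, 366, 368, 370, 374, 380]
        codes = [["A"], ["A"], ["B"], ["B"], ["C"], ["A"], ["B"], ["C"]]
        for j in (4, 5, 6):
            lab6 = horizon_window_label(months, codes, j, 6)
            lab12 = horizon_window_label(months, codes, j, 12)
            assert lab6 <= lab12

    def test_empty_window_excludes_patient(self):
        # no visit in (m_j, m_j + 6] for any eligible j
        months = [360, 361, 362, 363, 364]
        rec = record("p", [30] * 5, [["A"]] * 5, months=months, obs_end=500)
        rng = np.random.default_rng(0)
        for _ in range(20):
            ex = make_horizon_example(rec, VOC3, 6, rng)
            assert ex is None or ex.label.sum() >= 1

    def test_one_example_per_patient(self, small_corpus, vocab):
        for task in ("t1", "t2", "t3"):
            examples = make_examples(small_corpus, vocab, task, seed=0)
            assert len(examples) <= len(small_corpus)
            assert len({e.patient_id for e in examples}) == len(examples)
            for e in examples:
                assert e.label.sum() >= 1 and len(e.input_visits) >= 4


def constant_result(examples, probs_row):
    n = len(examples)
    return PredictionResult(
        probabilities=np.tile(probs_row, (n, 1)),
        labels=np.stack([e.label for e in examples]),
        patient_ids=[e.patient_id for e in examples])


class TestEvaluate:
    def _dummy_model(self, vocab):
        return BehrtModel(ModelConfig(vocab_size=vocab.size, n_layers=1,
                                      hidden_size=4, intermediate_size=8,
                                      dropout=0.0),
                          vocab=vocab, seed=0)

    def test_perfect_ranking_gives_ones(self, small_corpus, vocab):
        examples = make_examples(small_corpus[:20], vocab, "t1", 0)
        model = self._dummy_model(vocab)
        res = PredictionResult(
            probabilities=np.stack([
                0.9 * e.label + 0.05 for e in examples]).astype(float),
            labels=np.stack([e.label for e in examples]),
            patient_ids=[e.patient_id for e in examples])
        rep = evaluate(model, examples, result=res)
        assert rep.mean_aps == pytest.approx(1.0)
        assert rep.mean_auroc == pytest.approx(1.0)

    def test_three_disease_hand_case(self):
        y = np.array([0, 1, 0])
        s = np.array([0.9, 0.8, 0.1])
        assert aps_brute(y, s) == pytest.approx(0.5)
        assert auroc_brute(y, s) == pytest.approx(0.5)
        from sklearn.metrics import average_precision_score, roc_auc_score
        assert average_precision_score(y, s) == pytest.approx(0.5)
        assert roc_auc_score(y, s) == pytest.approx(0.5)

    def test_report_matches_bruteforce_on_random_patients(
            self, small_corpus, vocab):
        examples = make_examples(small_corpus[:20], vocab, "t1", 0)
        model = self._dummy_model(vocab)
        rng = np.random.default_rng(3)
        res = PredictionResult(
            probabilities=rng.uniform(0.01, 0.99,
                                      (len(examples), vocab.n_diseases)),
            labels=np.stack([e.label for e in examples]),
            patient_ids=[e.patient_id for e in examples])
        rep = evaluate(model, examples, result=res)
        want_aps = np.mean([aps_brute(y, s)
                            for y, s in zip(res.labels, res.probabilities)])
        want_auc = np.mean([auroc_brute(y, s)
                            for y, s in zip(res.labels, res.probabilities)])
        assert rep.mean_aps == pytest.approx(want_aps, abs=1e-10)
        assert rep.mean_auroc == pytest.approx(want_auc, abs=1e-10)

    def test_disease_wise_matches_bruteforce_columns(self, small_corpus, vocab):
        examples = make_examples(small_corpus[:30], vocab, "t1", 0)
        model = self._dummy_model(vocab)
        rng = np.random.default_rng(4)
        res = PredictionResult(
            probabilities=rng.uniform(size=(len(examples), vocab.n_diseases)),
            labels=np.stack([e.label for e in examples]),
            patient_ids=[e.patient_id for e in examples])
        table = disease_wise_eval(model, examples, prevalence_floor=0.0,
                                  result=res)
        assert (table["prevalence"] > 0).all()
        for _, row in table.head(8).iterrows():
            i = vocab.disease_index(row["code"])
            y, s = res.labels[:, i], res.probabilities[:, i]
            assert row["aps"] == pytest.approx(aps_brute(y, s), abs=1e-10)
            if 0 < y.sum() < len(y):
                assert row["auroc"] == pytest.approx(auroc_brute(y, s),
                                                     abs=1e-10)

    def test_prevalence_floor_excludes_rare_diseases(self, small_corpus, vocab):
        examples = make_examples(small_corpus, vocab, "t1", 0)
        model = self._dummy_model(vocab)
        rng = np.random.default_rng(5)
        res = PredictionResult(
            probabilities=rng.uniform(size=(len(examples), vocab.n_diseases)),
            labels=np.stack([e.label for e in examples]),
            patient_ids=[e.patient_id for e in examples])
        prev = res.labels.mean(axis=0)
        table = disease_wise_eval(model, examples, prevalence_floor=0.05,
                                  result=res)
        assert set(table["code"]) == {
            vocab.codes[i] for i in range(vocab.n_diseases)
            if prev[i] >= 0.05}

    def test_first_incidence_restriction(self):
        rec = record("p", [30] * 5, [["A"], ["B"], ["A"], ["B"], ["A", "C"]])
        ex = make_t1_example(rec, VOC3, np.random.default_rng(0))
        model = BehrtModel(ModelConfig(vocab_size=VOC3.size, n_layers=1,
                                       hidden_size=4, intermediate_size=8),
                           vocab=VOC3, seed=0)
        res = constant_result([ex], np.array([0.2, 0.3, 0.4]))
        rep = first_incidence_eval(model, [ex], result=res)
        # history {A, B}; label {A, C} -> restricted label {C}
        assert rep.n_patients == 1
        assert rep.mean_aps == pytest.approx(
            aps_brute(np.array([0, 0, 1]), res.probabilities[0]))

    def test_first_incidence_drops_fully_seen_labels(self):
        rec = record("p", [30] * 5, [["A"], ["B"], ["A"], ["B"], ["A", "B"]])
        ex = make_t1_example(rec, VOC3, np.random.default_rng(0))
        model = BehrtModel(ModelConfig(vocab_size=VOC3.size, n_layers=1,
                                       hidden_size=4, intermediate_size=8),
                           vocab=VOC3, seed=0)
        res = constant_result([ex], np.array([0.2, 0.3, 0.4]))
        with pytest.raises(ValueError, match="first-incidence"):
            first_incidence_eval(model, [ex], result=res)


class TestFinetune:
    def test_smoke_run_updates_classifier(self, small_corpus, vocab):
        examples = make_examples(small_corpus[:20], vocab, "t1", 0)
        model = BehrtModel(ModelConfig(vocab_size=vocab.size, n_layers=1,
                                       hidden_size=8, intermediate_size=16),
                           vocab=vocab, seed=0)
        before = model.classifier.P["W"].copy()
        trained, history = finetune(model, examples,
                                    TrainConfig(epochs=1, seed=0))
        assert len(history) == 1
        assert trained.classifier.P["W"].shape == (8, vocab.n_diseases)
        assert not np.array_equal(before[:, :vocab.n_diseases],
                                  trained.classifier.P["W"])

    def test_training_loss_decreases(self, small_corpus, vocab):
        examples = make_examples(small_corpus, vocab, "t1", 0)
        model = BehrtModel(ModelConfig(vocab_size=vocab.size), vocab=vocab,
                           seed=0)
        _, history = finetune(model, examples,
                              TrainConfig(epochs=10, lr=5e-3, dropout=0.0,
                                          seed=0))
        assert history["loss"].iloc[-1] < history["loss"].iloc[0]

    def test_vocab_mismatch_rejected(self, small_corpus, vocab):
        examples = make_examples(small_corpus[:10], vocab, "t1", 0)
        other = DiseaseVocabulary.from_codes(["A", "B"])
        model = BehrtModel(ModelConfig(vocab_size=other.size), vocab=other,
                           seed=0)
        with pytest.raises(ValueError, match="vocabulary"):
            finetune(model, examples, TrainConfig(epochs=1, seed=0))


class TestBaselinesAndAudit:
    def test_prevalence_baseline_scores_are_train_prevalence(
            self, small_corpus, vocab):
        tr = make_examples(small_corpus[:40], vocab, "t1", 0)
        te = make_examples(small_corpus[40:60], vocab, "t1", 0)
        rep = prevalence_baseline_report(tr, te)
        assert rep.n_patients == len(te)
        assert 0 <= rep.mean_aps <= 1

    def test_uniform_predictor_gives_unit_ratio(self, small_corpus, vocab,
                                                ground_truth):
        examples = make_examples(small_corpus[:30], vocab, "t1", 0)
        model = BehrtModel(ModelConfig(vocab_size=vocab.size, n_layers=1,
                                       hidden_size=4, intermediate_size=8),
                           vocab=vocab, seed=0)
        res = constant_result(examples, np.full(vocab.n_diseases, 0.5))
        audit = attribute_consistency_audit(model, examples, ground_truth,
                                            result=res)
        assert audit.mean_ratio == pytest.approx(1.0)
        assert audit.n_patients == len(examples)

    def test_counts_match_bruteforce_scan(self, small_corpus, vocab,
                                          ground_truth):
        examples = make_examples(small_corpus[:30], vocab, "t1", 0)
        model = BehrtModel(ModelConfig(vocab_size=vocab.size, n_layers=1,
                                       hidden_size=4, intermediate_size=8),
                           vocab=vocab, seed=0)
        rng = np.random.default_rng(8)
        res = PredictionResult(
            probabilities=rng.uniform(size=(len(examples), vocab.n_diseases)),
            labels=np.stack([e.label for e in examples]),
            patient_ids=[e.patient_id for e in examples])
        audit = attribute_consistency_audit(model, examples, ground_truth,
                                            top_k=5, result=res)
        hits = 0
        for ex, p in zip(examples, res.probabilities):  # brute-force scan
            attr = ex.attributes["attribute"]
            dis = {vocab.disease_index(c)
                   for c in ground_truth.exclusive_codes()
                   if ground_truth.allowed_attribute[c] != attr}
            top = set(np.argsort(-p)[:5].tolist())
            hits += len(top & dis)
        assert audit.disallowed_in_topk == hits

    def test_audit_requires_exclusive_codes(self, small_corpus, vocab):
        examples = make_examples(small_corpus[:5], vocab, "t1", 0)
        gt = GroundTruth(group_of_code={c: 0 for c in vocab.codes},
                         allowed_attribute={c: None for c in vocab.codes})
        model = BehrtModel(ModelConfig(vocab_size=vocab.size, n_layers=1,
                                       hidden_size=4, intermediate_size=8),
                           vocab=vocab, seed=0)
        with pytest.raises(ValueError, match="exclusive"):
            attribute_consistency_audit(model, examples, gt)


class TestAblationSuite:
    def test_one_row_per_subset(self, small_corpus):
        cfg = ModelConfig(n_layers=1, n_heads=1, hidden_size=8,
                          intermediate_size=16)
        quick = TrainConfig(epochs=1, seed=0)
        table = ablation_suite(small_corpus[:40],
                               [("age", "segment", "position"), ()],
                               cfg, quick, quick, task="t1", seed=0)
        assert len(table) == 2
        assert table["channels"].tolist() == [
            "disease+age+segment+position", "disease"]
        assert table["aps"].between(0, 1).all()
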