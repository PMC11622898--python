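"""Concatenation, stratified splitting, the metric suite, and the
run-level significance test."""

import numpy as np
import pytest

from tcrembed import (
    EmbeddingMatrix,
    EvalConfig,
    SequenceRecord,
    SequenceSet,
    SyntheticConfig,
    concat_embeddings,
    evaluate,
    generate,
    significance_from_runs,
    stratified_split,
    tcellr2vec_embed,
)
from tcrembed.baselines import spike2vec_embed
from tcrembed.evaluate import compute_metrics


def labeled_set(n_per_class: int, classes=("a", "b", "c", "d", "e"), seed=0):
    rng = np.random.default_rng(seed)
    letters = list("ACDEFGHIKLMNPQRSTVWY")
    records = []
    i = 0
    for c in classes:
        for _ in range(n_per_class):
            seq = "".join(rng.choice(letters, size=12))
            records.append(SequenceRecord(f"r{i}", seq, label=c))
            i += 1
    return SequenceSet(records)


class TestConcat:
    def test_feature_plus_kmer_width(self, random_sequences):
        seqs = random_sequences(5, seed=1, min_len=4)
        both = concat_embeddings([tcellr2vec_embed(seqs), spike2vec_embed(seqs)])
        assert both.shape == (5, 8026)

    def test_single_part_identity(self, random_sequences):
        emb = tcellr2vec_embed(random_sequences(4, seed=2, min_len=4))
        out = concat_embeddings([emb])
        assert np.array_equal(out.values, emb.values)
        assert out.feature_names == emb.feature_names

    def test_order_preserved_but_values_equal_as_multisets(self, random_sequences):
        seqs = random_sequences(4, seed=3, min_len=4)
        a, b = tcellr2vec_embed(seqs), spike2vec_embed(seqs)
        ab, ba = concat_embeddings([a, b]), concat_embeddings([b, a])
        assert ab.feature_names != ba.feature_names
        for i in range(4):
            assert sorted(ab.values[i]) == sorted(ba.values[i])

    def test_misaligned_rows_rejected(self):
        a = EmbeddingMatrix(np.ones((2, 1)), ["x"], ["r0", "r1"])
        b = EmbeddingMatrix(np.ones((2, 1)), ["y"], ["r0", "OTHER"])
        with pytest.raises(ValueError, match="aligned"):
            concat_embeddings([a, b])


class TestStratifiedSplit:
    def test_exact_proportions_on_balanced_set(self):
        seqs = labeled_set(20)  # 100 records, 5 classes of 20
        cfg = EvalConfig(seed=0)
        train, tune, test = stratified_split(seqs, cfg, 0)
        assert len(test) == 30
        labels = np.array(seqs.labels)
        for c in "abcde":
            assert np.count_nonzero(labels[test] == c) == 6

    def test_partition_disjoint_and_exhaustive(self):
        seqs = labeled_set(20)
        for repeat in range(3):
            train, tune, test = stratified_split(seqs, EvalConfig(seed=5), repeat)
            parts = np.concatenate([train, tune, test])
            assert len(parts) == seqs.n
            assert len(np.unique(parts)) == seqs.n

    def test_reproducible_and_repeat_streams_differ(self):
        seqs = labeled_set(20)
        cfg = EvalConfig(seed=1)
        a = stratified_split(seqs, cfg, 0)
        b = stratified_split(seqs, cfg, 0)
        c = stratified_split(seqs, cfg, 1)
        for x, y in zip(a, b):
            assert np.array_equal(x, y)
        assert any(not np.array_equal(x, z) for x, z in zip(a, c))

    def test_tune_is_tenth_of_train(self):
        seqs = labeled_set(20)
        train, tune, test = stratified_split(seqs, EvalConfig(), 0)
        assert len(tune) == 7  # 10% of the 70-record training split

    def test_singleton_class_rejected(self):
        records = labeled_set(2).records + [SequenceRecord("solo", "CASSF", label="z")]
        with pytest.raises(ValueError, match="z"):
            stratified_split(SequenceSet(records), EvalConfig(), 0)


class TestMetricSuite:
    # 3 classes x 4 samples; confusion-matrix quantities worked by hand:
    # per-class TP/pred/true counts give precision (.5,.75,.75),
    # recall (.5,.75,.75), accuracy 8/12, macro F1 = weighted F1 = 2/3,
    # indicator one-vs-rest AUC = ((.5+.75)/2, (.75+.875)/2 x2) -> mean .75
    Y_TRUE = [0, 0, 0, 0, 1, 1, 1, 1, 2, 2, 2, 2]
    Y_PRED = [0, 0, 1, 2, 1, 1, 0, 1, 2, 2, 2, 0]

    def test_hand_computed_confusion_matrix_values(self):
        m = compute_metrics(self.Y_TRUE, self.Y_PRED)
        assert m["accuracy"] == pytest.approx(2 / 3)
        assert m["precision"] == pytest.approx(2 / 3)
        assert m["recall"] == pytest.approx(2 / 3)
        assert m["f1_weighted"] == pytest.approx(2 / 3)
        assert m["f1_macro"] == pytest.approx(2 / 3)
        assert m["roc_auc"] == pytest.approx(0.75)

    def test_perfect_prediction_identity(self):
        m = compute_metrics(self.Y_TRUE, self.Y_TRUE)
        for name in ("accuracy", "precision", "recall", "f1_weighted", "f1_macro", "roc_auc"):
            assert m[name] == 1.0


class TestEvaluate:
    def test_shuffled_labels_score_at_chance(self):
        """On a balanced 5-class set with labels shuffled uniformly, mean
        accuracy sits at the 1/5 chance level within 3 binomial sd."""
        cfg = SyntheticConfig(
            n=500, seed=21, concentration=0.1, class_priors=(0.2,) * 5
        )
        seqs = generate(cfg)
        rng = np.random.default_rng(99)
        labels = np.array(seqs.labels)
        rng.shuffle(labels)
        shuffled = SequenceSet(
            [
                SequenceRecord(r.id, r.sequence, label=labels[i])
                for i, r in enumerate(seqs)
            ]
        )
        emb = tcellr2vec_embed(shuffled)
        res = evaluate(
            emb, shuffled, EvalConfig(repeats=5, classifiers=("LR",), seed=3)
        )
        mean_acc = res.runs("LR", "accuracy").mean()
        n_test = 150
        assert abs(mean_acc - 0.2) <= 3 * np.sqrt(0.2 * 0.8 / n_test)

    def test_separable_synthetic_set_rf_macro_f1(self):
        seqs = generate(SyntheticConfig(n=1000, seed=11, concentration=0.1))
        emb = tcellr2vec_embed(seqs)
        res = evaluate(emb, seqs, EvalConfig(repeats=5, classifiers=("RF",), seed=0))
        assert res.runs("RF", "f1_macro").mean() >= 0.8

    def test_reproducible_except_train_time(self):
        seqs = labeled_set(10, classes=("a", "b", "c"), seed=4)
        emb = tcellr2vec_embed(seqs)
        cfg = EvalConfig(repeats=2, classifiers=("DT", "NB"), seed=7)
        a = evaluate(emb, seqs, cfg).per_run.drop(columns="train_time")
        b = evaluate(emb, seqs, cfg).per_run.drop(columns="train_time")
        assert a.equals(b)

    def test_metrics_bounded_and_train_time_nonnegative(self):
        seqs = labeled_set(10, classes=("a", "b", "c"), seed=4)
        res = evaluate(
            tcellr2vec_embed(seqs), seqs, EvalConfig(repeats=2, classifiers=("KNN",))
        )
        metrics = res.per_run[
            ["accuracy", "precision", "recall", "f1_weighted", "f1_macro", "roc_auc"]
        ].to_numpy()
        assert np.all((metrics >= 0) & (metrics <= 1))
        assert np.all(res.per_run["train_time"] >= 0)

    def test_unlabeled_and_single_class_rejected(self, random_sequences):
        seqs = random_sequences(10, seed=0, min_len=4)
        with pytest.raises(ValueError, match="label"):
            evaluate(tcellr2vec_embed(seqs), seqs)
        mono = SequenceSet(
            [SequenceRecord(r.id, r.sequence, label="only") for r in seqs]
        )
        with pytest.raises(ValueError, match="two classes"):
            evaluate(tcellr2vec_embed(mono), mono)


class TestSignificance:
    def test_identical_constant_samples(self):
        assert significance_from_runs([0.5] * 5, [0.5] * 5) == 1.0

    def test_distinct_constant_samples(self):
        assert significance_from_runs([1.0] * 5, [0.0] * 5) == 0.0

    def test_clearly_separated_samples(self):
        a = [1.0, 0.999, 1.0, 0.998, 1.0]
        b = [0.0, 0.001, 0.002, 0.0, 0.001]
        assert significance_from_runs(a, b) < 0.001

    def test_symmetry(self):
        a, b = [0.4, 0.5, 0.6, 0.45, 0.55], [0.6, 0.7, 0.65, 0.72, 0.68]
        assert significance_from_runs(a, b) == pytest.approx(
            significance_from_runs(b, a)
        )

    def test_matches_welch_formula(self):
        """Brute-force Welch statistic + Satterthwaite df against scipy."""
        from scipy import stats as sps

        a = np.array([0.41, 0.44, 0.39, 0.46, 0.42])
        b = np.array([0.48, 0.52, 0.47, 0.50, 0.49])
        va, vb = a.var(ddof=1) / 5, b.var(ddof=1) / 5
        t = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / 4 + vb**2 / 4)
        expected = 2 * sps.t.sf(abs(t), df)
        assert significance_from_runs(a, b) == pytest.approx(expected, abs=1e-12)

    def test_too_short_samples_rejected(self):
        with pytest.raises(ValueError):
            significance_from_runs([0.5], [0.5, 0.6])
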