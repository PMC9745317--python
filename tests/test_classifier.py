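"""Classifier surface: loss/metric formulas, determinism, prediction contracts."""

import numpy as np
import pytest

from drnaprom.classifier import (
    PromoterTransformer,
    bce_loss,
    scan_region,
    sigmoid_probability,
    train_classifier,
)
from drnaprom.io_formats import GenomeSequence, reverse_complement
from drnaprom.metrics import confusion_counts, evaluate
from drnaprom.sim import SimulationConfig, simulate_labelled_sequences


class TestSigmoid:
    def test_symmetry_point(self):
        assert sigmoid_probability(0.0) == pytest.approx(0.5)

    def test_identity(self):
        x = np.random.default_rng(0).normal(size=50) * 5
        assert np.allclose(sigmoid_probability(x) + sigmoid_probability(-x), 1.0)

    def test_saturation(self):
        assert sigmoid_probability(20.0) > 0.999999
        assert sigmoid_probability(-20.0) < 1e-6


class TestBceLoss:
    def test_uninformative_is_ln2(self):
        assert bce_loss([0.5, 0.5], [1, 0]) == pytest.approx(np.log(2))

    def test_perfect_predictions_near_zero(self):
        assert bce_loss([1.0, 0.0], [1, 0]) == pytest.approx(0.0, abs=1e-5)

    def test_direct_evaluation(self):
        assert bce_loss([0.9], [1]) == pytest.approx(-np.log(0.9))

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            bce_loss([0.5], [1, 0])


# ---- metric oracles (tests/oracles.py) -----------------------------------

from oracles import auroc_pairwise, average_precision_stepwise


class TestEvaluate:
    def test_hand_confusion_counts(self):
        # 9 true positives at score .9, 1 FP, 1 FN, 9 TN
        probs = np.array([0.9] * 10 + [0.1] * 10)
        labels = np.array([1] * 9 + [0] + [1] + [0] * 9)
        rep = evaluate(probs, labels)
        assert rep.positive.precision == pytest.approx(0.9)
        assert rep.positive.recall == pytest.approx(0.9)
        assert rep.positive.f1 == pytest.approx(0.9)
        assert rep.counts.tp == 9 and rep.counts.fp == 1

    def test_perfect_separation(self):
        rep = evaluate(np.array([0.9, 0.8, 0.2, 0.1]), np.array([1, 1, 0, 0]))
        assert rep.auroc == 1.0
        assert rep.auprc == 1.0

    def test_constant_scores_give_half_auroc(self):
        rep = evaluate(np.full(10, 0.5), np.array([1, 0] * 5))
        assert rep.auroc == pytest.approx(0.5)

    def test_single_class_errors(self):
        with pytest.raises(ValueError, match="single class"):
            evaluate(np.array([0.1, 0.9]), np.array([1, 1]))

    def test_matches_brute_force_oracles(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            n = int(rng.integers(10, 60))
            scores = rng.choice(np.round(rng.random(8), 2), size=n)  # force ties
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            rep = evaluate(scores, labels)
            assert rep.auroc == pytest.approx(auroc_pairwise(scores, labels), abs=1e-12)
            assert rep.auprc == pytest.approx(
                average_precision_stepwise(scores, labels), abs=1e-12)

    def test_f1_is_harmonic_mean(self):
        rng = np.random.default_rng(1)
        scores = rng.random(100)
        labels = rng.integers(0, 2, size=100)
        rep = evaluate(scores, labels)
        for cls in (rep.positive, rep.negative):
            if cls.precision + cls.recall > 0:
                hm = 2 * cls.precision * cls.recall / (cls.precision + cls.recall)
                assert cls.f1 == pytest.approx(hm)


# ---- training and prediction ---------------------------------------------

class TestTraining:
    def test_same_seed_identical_first_epoch(self):
        cfg = SimulationConfig(seed=21)
        table = simulate_labelled_sequences(100, 30, cfg)
        X = table["sequence"].tolist()
        y = (table["label"] == "promoter").astype(int).to_numpy()
        losses = []
        for _ in range(2):
            est = PromoterTransformer(preset="tiny", seed=5, max_epochs=1)
            est.fit(X, y)
            losses.append(est.history_[0]["train_loss"])
        assert losses[0] == losses[1]

    def test_loss_decreases_over_first_epochs(self):
        # the planted motif is strong signal: BCE falls monotonically early on
        for seed in (0, 1, 2):
            cfg = SimulationConfig(seed=30 + seed)
            table = simulate_labelled_sequences(300, 50, cfg)
            est = PromoterTransformer(preset="tiny", seed=seed, max_epochs=3,
                                      patience=5)
            est.fit(table["sequence"].tolist(),
                    (table["label"] == "promoter").astype(int).to_numpy())
            losses = [h["train_loss"] for h in est.history_]
            assert losses[0] > losses[1] > losses[2]

    def test_string_labels_accepted(self):
        cfg = SimulationConfig(seed=22)
        table = simulate_labelled_sequences(50, 30, cfg)
        est = PromoterTransformer(preset="tiny", seed=0, max_epochs=1)
        est.fit(table["sequence"].tolist(), table["label"].to_numpy())
        assert list(est.classes_) == [0, 1]

    def test_mixed_lengths_rejected(self):
        est = PromoterTransformer()
        with pytest.raises(ValueError, match="one length"):
            est.fit(["ACGT", "ACGTA"], [0, 1])


class TestPrediction:
    def test_pure_function(self, trained_model):
        est, X_test, _, _ = trained_model
        a = est.predict_proba(X_test[:20])
        b = est.predict_proba(X_test[:20])
        assert np.array_equal(a, b)

    def test_batching_invariance(self, trained_model):
        est, X_test, _, _ = trained_model
        batch = est.predict_proba(X_test[:64])[:, 1]
        singles = np.array([est.predict_proba([x])[0, 1] for x in X_test[:8]])
        assert np.allclose(batch[:8], singles, atol=1e-9)

    def test_reverse_complement_no_crash(self, trained_model):
        # single-strand model: the revcomp score is defined but unconstrained
        est, X_test, _, _ = trained_model
        probs = est.predict_proba([reverse_complement(X_test[0])])
        assert probs.shape == (1, 2)

    def test_probabilities_sum_to_one(self, trained_model):
        est, X_test, _, _ = trained_model
        probs = est.predict_proba(X_test[:10])
        assert np.allclose(probs.sum(axis=1), 1.0)

    def test_save_load_round_trip(self, tmp_path, trained_model):
        est, X_test, _, _ = trained_model
        est.save(tmp_path / "model")
        back = PromoterTransformer.load(tmp_path / "model")
        assert np.array_equal(
            back.predict_proba(X_test[:32]), est.predict_proba(X_test[:32]))

    def test_sklearn_param_round_trip(self):
        est = PromoterTransformer(max_epochs=7, seed=3)
        clone = PromoterTransformer(**est.get_params())
        assert clone.get_params() == est.get_params()


class TestScanRegion:
    def test_single_window_genome(self, trained_model):
        est, X_test, _, _ = trained_model
        genome = GenomeSequence("g", X_test[0])
        table = scan_region(est, genome, window=50)
        assert len(table) == 2  # one window per strand
        assert set(table["strand"]) == {"+", "-"}

    def test_stride_consistency(self, trained_model):
        est, X_test, _, _ = trained_model
        genome = GenomeSequence("g", "".join(X_test[:3]))
        dense = scan_region(est, genome, window=50, stride=1)
        sparse = scan_region(est, genome, window=50, stride=5)
        merged = sparse.merge(dense, on=["replicon", "start", "end", "strand"],
                              suffixes=("_s", "_d"))
        assert len(merged) == len(sparse)
        assert np.allclose(merged["score_s"], merged["score_d"], atol=1e-9)

    def test_window_mismatch_errors(self, trained_model):
        est, X_test, _, _ = trained_model
        with pytest.raises(ValueError, match="training sequence length"):
            scan_region(est, GenomeSequence("g", X_test[0]), window=40)

    def test_short_genome_errors(self, trained_model):
        est, *_ = trained_model
        with pytest.raises(ValueError, match="shorter"):
            scan_region(est, GenomeSequence("g", "ACGT"), window=50)


def test_scan_ranks_planted_tss_windows_highly(trained_model):
    """Windows ending at a planted TSS outscore the background distribution."""
    est, _, _, sim_cfg = trained_model
    from drnaprom.sim import simulate_genome
    cfg = SimulationConfig(genome_length=10_000, n_tss=25, seed=17,
                           motif_mutation_rate=0.1)
    genome, truth = simulate_genome(cfg)
    table = scan_region(est, genome, window=50, stride=1)
    hits, background_scores = [], []
    tss_lookup = {(p, s) for _, p, s in truth.tss_positions}
    for row in table.itertuples(index=False):
        # promoter window: ends at p-1 on +, starts at p+1 on -
        key = (row.end, "+") if row.strand == "+" else (row.start - 1, "-")
        if key in tss_lookup:
            hits.append(row.score)
        else:
            background_scores.append(row.score)
    assert len(hits) >= 20  # edge windows may be missing
    cutoff = np.percentile(background_scores, 95)
    assert np.mean(np.asarray(hits) > cutoff) >= 0.9


def test_train_classifier_wrapper(planted_sequences):
    _, table = planted_sequences
    shuffled = table.sample(frac=1.0, random_state=0).reset_index(drop=True)
    est = train_classifier(shuffled.iloc[:300], shuffled.iloc[300:400],
                           preset="tiny", max_epochs=1, seed=0)
    assert hasattr(est, "encoder_")
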