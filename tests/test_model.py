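import numpy as np
import pytest

import hope
from hope.containers import LabelMatrix
from hope.model import (
    HopeClassifier,
    TrainConfig,
    load_model,
    make_splits,
    save_model,
    split_tasks,
    task_loss,
)


def labels_from_prevalence(prevs, n=10):
    """Label matrix whose column prevalences are exactly ``prevs``."""
    Y = np.zeros((n, len(prevs)), dtype=int)
    for c, p in enumerate(prevs):
        Y[: int(round(p * n)), c] = 1
    Y[:, 0] = np.maximum(Y[:, 0], 1)  # keep every OTU labeled
    return LabelMatrix([f"o{i}" for i in range(n)],
                       [f"K{c}" for c in range(len(prevs))], Y)


class TestSplitTasks:
    def test_direct_rule(self):
        labels = labels_from_prevalence([0.8, 0.6, 0.1])
        s = split_tasks(labels, 0.5)
        assert s.ko_ma == ["K0", "K1"]
        assert s.ko_mi == ["K2"]

    def test_boundary_all_minority(self):
        # no all-ones column: every class is minority at tau just below 1
        Y = np.array([[1, 0, 1], [1, 1, 0], [0, 1, 1], [1, 1, 0]])
        labels = LabelMatrix([f"o{i}" for i in range(4)],
                             ["K0", "K1", "K2"], Y)
        s = split_tasks(labels, 0.999)
        assert s.ko_ma == []
        assert set(s.ko_mi) == {"K0", "K1", "K2"}

    def test_matches_column_sum_oracle_on_fixture(self):
        cfg = hope.SyntheticConfig(n_classes=20,
                                   class_prevalence_exponent=2.0, seed=1)
        labels = hope.generate_labels(cfg)
        s = split_tasks(labels, 0.5)
        labeled = labels.Y.any(axis=1)
        prev = labels.Y[labeled].sum(axis=0) / labeled.sum()
        for k, p in zip(labels.ko_ids, prev):
            assert (k in s.ko_ma) == (p > 0.5)

    def test_partition_property(self):
        labels = labels_from_prevalence([0.9, 0.5, 0.3, 0.7])
        s = split_tasks(labels, 0.5)
        assert sorted(s.ko_ma + s.ko_mi) == sorted(labels.ko_ids)
        assert not (set(s.ko_ma) & set(s.ko_mi))


class TestTaskLoss:
    def test_single_cell_half(self):
        assert task_loss([[0.5]], [[1]]) == pytest.approx(np.log(2))

    def test_perfect_prediction_near_zero(self):
        truth = np.array([[1, 0], [0, 1]])
        assert task_loss(truth.astype(float), truth) < 1e-5

    def test_matches_elementwise_oracle(self):
        rng = np.random.default_rng(8)
        pred = rng.uniform(0.01, 0.99, size=(5, 3))
        truth = rng.integers(0, 2, size=(5, 3))
        expected = 0.0
        for i in range(5):
            for j in range(3):
                p, y = pred[i, j], truth[i, j]
                expected += -(y * np.log(p) + (1 - y) * np.log(1 - p))
        assert task_loss(pred, truth) == pytest.approx(expected, abs=1e-10)

    def test_additivity_over_column_split(self):
        rng = np.random.default_rng(9)
        pred = rng.uniform(0.01, 0.99, size=(6, 5))
        truth = rng.integers(0, 2, size=(6, 5))
        total = task_loss(pred, truth)
        parts = task_loss(pred[:, :2], truth[:, :2]) + task_loss(
            pred[:, 2:], truth[:, 2:]
        )
        assert total == pytest.approx(parts, rel=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            task_loss(np.ones((2, 2)) / 2, np.ones((2, 3)))


class TestMakeSplits:
    def test_sizes(self):
        ids = [f"o{i}" for i in range(100)]
        test, folds = make_splits(ids, 0.2, 8, seed=0)
        assert len(test) == 20
        assert len(folds) == 8
        assert all(len(va) == 10 for _, va in folds)

    def test_partition(self):
        ids = [f"o{i}" for i in range(53)]
        test, folds = make_splits(ids, 0.2, 4, seed=1)
        vals = [v for _, va in folds for v in va]
        assert sorted(test + vals) == sorted(ids)
        for tr, va in folds:
            assert not (set(tr) & set(va))
            assert not (set(tr) & set(test))
            assert sorted(tr + va + test) == sorted(ids)

    def test_deterministic(self):
        ids = [f"o{i}" for i in range(40)]
        assert make_splits(ids, 0.25, 3, seed=5) == make_splits(ids, 0.25, 3, seed=5)

    def test_too_few_nodes_rejected(self):
        with pytest.raises(ValueError):
            make_splits(["a", "b"], 0.2, 4, seed=0)


class TestTraining:
    def test_loss_decreases(self, small_trained):
        _, _, _, _, res = small_trained
        h = res.history
        assert h["train_loss"].iloc[-1] < h["train_loss"].iloc[0]

    def test_total_loss_is_sum_of_task_losses(self, small_trained):
        _, _, _, _, res = small_trained
        h = res.history
        np.testing.assert_allclose(
            h["train_loss"], h["train_loss_ma"] + h["train_loss_mi"]
        )

    def test_deterministic_history_and_predictions(self, small_trained):
        com, net, fm, clf, res = small_trained
        clf2 = HopeClassifier(net, fm, com.labels,
                              sampler=hope.SamplerConfig([5, 3], 0))
        cfg = TrainConfig(epochs=20, seed=0, embed_dim=16, hidden_dim=16)
        res2 = clf2.fit(net.otu_ids[:30], net.otu_ids[30:], cfg)
        np.testing.assert_allclose(
            res.history["train_loss"], res2.history["train_loss"]
        )
        P1, _ = res.predict(net.otu_ids)
        P2, _ = res2.predict(net.otu_ids)
        np.testing.assert_array_equal(P1, P2)

    def test_zero_learning_rate_is_identity(self, small_trained):
        com, net, fm, _, _ = small_trained
        preds = []
        for epochs in (1, 5):
            clf = HopeClassifier(net, fm, com.labels, variant="hope-seq")
            cfg = TrainConfig(learning_rate=0.0, dropout=0.0, epochs=epochs,
                              seed=0, embed_dim=16, hidden_dim=16)
            res = clf.fit(net.otu_ids, None, cfg)
            # no sampling, no dropout, no update: loss constant across epochs
            np.testing.assert_allclose(
                res.history["train_loss"],
                res.history["train_loss"].iloc[0],
                rtol=1e-12,
            )
            preds.append(res.predict(net.otu_ids)[0])
        np.testing.assert_allclose(preds[0], preds[1], atol=1e-12)

    def test_fit_capacity_on_noiseless_fixture(self):
        """Assortative noiseless labels are memorized almost perfectly."""
        syn = hope.SyntheticConfig(n_guilds=4, otus_per_guild=10,
                                   n_classes=10, label_noise=0.0, seed=5)
        com = hope.generate_community(syn)
        net = hope.build_network(hope.sparcc_correlation(com.abundance))
        fm = hope.kmer_frequencies(com.sequences, k=3)
        clf = HopeClassifier(net, fm, com.labels,
                             sampler=hope.SamplerConfig([5, 3], 0))
        cfg = TrainConfig(epochs=200, seed=0, embed_dim=32, hidden_dim=32)
        res = clf.fit(net.otu_ids, None, cfg)
        _, B = res.predict(net.otu_ids)
        Y = clf._label_rows(net.otu_ids)
        assert (B == Y).mean() > 0.95

    def test_divergence_aborts_with_epoch(self, small_trained):
        com, net, fm, _, _ = small_trained
        clf = HopeClassifier(net, fm, com.labels,
                             sampler=hope.SamplerConfig([5, 3], 0))
        cfg = TrainConfig(learning_rate=1e300, epochs=10, seed=0,
                          embed_dim=16, hidden_dim=16)
        with np.errstate(over="ignore", invalid="ignore"):
            with pytest.raises(RuntimeError, match="epoch"):
                clf.fit(net.otu_ids, None, cfg)


class TestPredict:
    def test_probabilities_in_unit_interval(self, small_trained):
        _, net, _, _, res = small_trained
        P, B = res.predict(net.otu_ids)
        assert ((P > 0) & (P < 1)).all()
        assert np.isin(B, (0, 1)).all()

    def test_columns_follow_label_vocabulary_order(self, small_trained):
        com, net, fm, clf, res = small_trained
        # the split interleaves majority/minority; output must be in the
        # original KO order, so majority-class columns sit at their
        # vocabulary positions
        P, _ = res.predict(net.otu_ids)
        assert P.shape == (net.n_nodes, com.labels.n_classes)
        model = res.model
        assert set(model.split.ko_ma + model.split.ko_mi) == set(com.labels.ko_ids)

    def test_unknown_node_rejected(self, small_trained):
        _, _, _, _, res = small_trained
        with pytest.raises(KeyError):
            res.predict(["nonexistent-otu"])

    def test_save_load_round_trip(self, small_trained, tmp_path):
        com, net, fm, _, res = small_trained
        path = tmp_path / "model.npz"
        save_model(res.model, path)
        loaded = load_model(path)
        P1, B1 = res.predict(net.otu_ids)
        P2, B2 = hope.predict(loaded, net, fm, net.otu_ids)
        np.testing.assert_allclose(P1, P2, atol=1e-12)
        np.testing.assert_array_equal(B1, B2)


class TestVariants:
    @pytest.mark.parametrize("variant", ["hope-one", "hope-seq", "gs-mean",
                                         "gs-pooling"])
    def test_variants_train_and_predict(self, small_trained, variant):
        com, net, fm, _, _ = small_trained
        clf = HopeClassifier(net, fm, com.labels, variant=variant,
                             sampler=hope.SamplerConfig([5, 3], 0))
        cfg = TrainConfig(epochs=5, seed=0, embed_dim=16, hidden_dim=16)
        res = clf.fit(net.otu_ids[:30], None, cfg)
        P, _ = res.predict(net.otu_ids[30:])
        assert P.shape == (10, com.labels.n_classes)
        if variant in ("hope-one", "gs-mean", "gs-pooling"):
            assert res.model.stack_mi is None  # single task
        if variant == "hope-seq":
            assert res.model.stack_ma.embed_layers == []  # no graph
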