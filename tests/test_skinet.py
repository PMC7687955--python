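"""Supervised SOM layer: hit accumulation, discriminant index,
classification, cross-validation and repeated-initialization evaluation."""

import numpy as np
import pytest

from somspec import (
    LabeledDataset,
    SOMConfig,
    SupervisedSOM,
    accumulate_hits,
    classify,
    cross_validate,
    evaluate,
    find_bmu,
    somdi,
)
from somspec.skinet import (
    ConfusionMatrix,
    load_model,
    neuron_labels,
    predict,
    save_model,
)
from somspec.som import SOMGrid, hex_coordinates
from tests.test_som import grid_from_weights, make_dataset


def grid_with_hits(W, rows, cols, hits, classes):
    g = grid_from_weights(W, rows, cols)
    g.class_hits = np.asarray(hits, float)
    g.classes = tuple(classes)
    return g


class TestAccumulateHits:
    def test_single_spectrum_single_hit(self, rng):
        W = rng.random(size=(4, 10)) + 0.1
        grid = grid_from_weights(W, 2, 2)
        x = W[2] + 0.001
        ds = make_dataset(x, ["A"], ("A", "B"))
        out = accumulate_hits(grid, ds)
        assert out.class_hits[2, 0] == 1
        assert out.class_hits.sum() == 1

    def test_hit_conservation(self, separable_dataset, small_som_config):
        grid = grid_from_weights(
            np.abs(np.random.default_rng(0).random((16, separable_dataset.wavenumbers.size))) + 0.1,
            4, 4)
        out = accumulate_hits(grid, separable_dataset)
        assert out.class_hits.sum() == separable_dataset.n_spectra

    def test_matches_brute_force_bmu_scan(self, separable_dataset):
        rng = np.random.default_rng(1)
        grid = grid_from_weights(
            rng.random((9, separable_dataset.wavenumbers.size)) + 0.1, 3, 3)
        out = accumulate_hits(grid, separable_dataset)
        brute = np.zeros_like(out.class_hits)
        kidx = {c: k for k, c in enumerate(separable_dataset.classes)}
        for i in range(separable_dataset.n_spectra):
            b = find_bmu(grid, separable_dataset.intensities[i])
            brute[b, kidx[separable_dataset.labels[i]]] += 1
        np.testing.assert_array_equal(out.class_hits, brute)

    def test_unknown_label_rejected(self, rng):
        grid = grid_from_weights(rng.random((4, 5)) + 0.1, 2, 2)
        axis = np.arange(605.0, 610.0)
        ds = LabeledDataset(axis, rng.random((2, 5)) + 0.1, ["A", "C"],
                            ["m", "m"], ["i", "i"], ("A", "C"))
        good = accumulate_hits(grid, ds)       # sanity: declared classes fine
        assert good.class_hits.sum() == 2
        ds.classes = ("A", "B")                # force inconsistency
        with pytest.raises(ValueError, match="outside class set"):
            accumulate_hits(grid, ds)


class TestSOMDI:
    def test_identical_hit_distributions_give_zero_discriminant(self, rng):
        W = rng.random((6, 12))
        hits = np.tile(rng.integers(1, 5, size=(6, 1)), (1, 2)).astype(float)
        grid = grid_with_hits(W, 2, 3, hits, ("A", "B"))
        res = somdi(grid)
        assert np.max(np.abs(res.vectors)) < 1e-9

    def test_pseudo_class_split_of_one_class_is_null(self, rng):
        """A dataset duplicated into two identical pseudo-classes must
        produce zero discriminants (permutation-null construction)."""
        W = rng.random((8, 20)) + 0.1
        X = rng.random((30, 20)) + 0.1
        ds = make_dataset(np.vstack([X, X]), ["p1"] * 30 + ["p2"] * 30)
        grid = accumulate_hits(grid_from_weights(W, 2, 4), ds)
        res = somdi(grid)
        assert np.max(np.abs(res.vectors)) < 1e-9

    def test_discriminant_points_at_planted_features(self):
        """Class A hits only the neuron whose weights load channel 0, so
        its discriminant must be positive there and negative on the
        channel loading the class-B neuron."""
        W = np.array([[1.0, 0.1], [0.1, 1.0], [0.5, 0.5], [0.5, 0.5]])
        hits = np.array([[10, 0], [0, 10], [2, 2], [2, 2]], float)
        res = somdi(grid_with_hits(W, 2, 2, hits, ("A", "B")))
        assert res.vector("A")[0] > 0 > res.vector("A")[1]
        assert res.vector("B")[1] > 0 > res.vector("B")[0]

    def test_zero_hit_class_rejected(self, rng):
        grid = grid_with_hits(rng.random((4, 6)), 2, 2,
                              [[1, 0], [2, 0], [1, 0], [3, 0]], ("A", "B"))
        with pytest.raises(ValueError, match="'B'"):
            somdi(grid)


class TestClassify:
    def test_majority_class_at_bmu(self):
        W = np.eye(4)
        grid = grid_with_hits(W, 2, 2, [[10, 0], [0, 5], [1, 1], [0, 0]],
                              ("A", "B"))
        assert classify(grid, W[0]) == "A"
        assert classify(grid, W[1]) == "B"

    def test_tie_takes_first_declared_class(self):
        W = np.eye(4)
        grid = grid_with_hits(W, 2, 2, [[5, 5], [0, 1], [1, 0], [1, 1]],
                              ("A", "B"))
        assert classify(grid, W[0]) == "A"

    def test_empty_bmu_falls_back_to_nearest_hit_neuron(self):
        # neuron 3 (coords row 1) has no hits; nearest with hits decides
        W = np.eye(4)
        hits = [[0, 3], [0, 0], [0, 0], [0, 0]]
        grid = grid_with_hits(W, 2, 2, hits, ("A", "B"))
        assert classify(grid, W[3]) == "B"

    def test_no_hits_anywhere_rejected(self):
        grid = grid_with_hits(np.eye(4), 2, 2, np.zeros((4, 2)), ("A", "B"))
        with pytest.raises(ValueError, match="no neuron"):
            classify(grid, np.eye(4)[0])

    def test_matches_brute_force_on_random_spectra(self, rng):
        W = rng.random((12, 25)) + 0.05
        hits = rng.integers(0, 4, size=(12, 3)).astype(float)
        hits[rng.random(12) < 0.4] = 0          # some empty neurons
        hits[0] = [1, 0, 0]                     # guarantee occupancy
        grid = grid_with_hits(W, 3, 4, hits, ("A", "B", "C"))
        coords = grid.coords
        for _ in range(200):
            x = rng.random(25) + 0.01
            b = find_bmu(grid, x)
            if hits[b].sum() > 0:
                expected = ("A", "B", "C")[int(np.argmax(hits[b]))]
            else:
                occ = np.flatnonzero(hits.sum(axis=1) > 0)
                d = np.linalg.norm(coords[occ] - coords[b], axis=1)
                j = occ[int(np.argmin(d))]
                expected = ("A", "B", "C")[int(np.argmax(hits[j]))]
            assert classify(grid, x) == expected

    def test_invariant_to_positive_scaling(self, rng):
        W = rng.random((9, 15)) + 0.1
        hits = rng.integers(1, 5, size=(9, 2)).astype(float)
        grid = grid_with_hits(W, 3, 3, hits, ("A", "B"))
        x = rng.random(15) + 0.01
        assert classify(grid, x) == classify(grid, 42.0 * x)


class TestCrossValidate:
    def test_each_spectrum_predicted_once(self, rng):
        X = rng.random((8, 10)) + 0.1
        ds = make_dataset(X, ["A"] * 4 + ["B"] * 4)
        cfg = SOMConfig(rows=2, cols=2, epochs=2, seed=0)
        res = cross_validate(ds, cfg, k=2, seed=0)
        assert np.all(res.fold_ids >= 0)
        assert not np.any([p is None for p in res.predictions])
        assert res.accuracies.shape == (2,)

    def test_fold_sizes_balanced_within_groups(self, rng):
        X = rng.random((30, 10)) + 0.1
        ds = make_dataset(X, ["A"] * 13 + ["B"] * 17)
        res = cross_validate(ds, SOMConfig(rows=2, cols=2, epochs=1, seed=0),
                             k=3, seed=1)
        for cls, lab in (("A", "A"), ("B", "B")):
            sizes = [np.sum((res.fold_ids == f) & (np.array(ds.labels) == lab))
                     for f in range(3)]
            assert max(sizes) - min(sizes) <= 1

    def test_separable_data_nearly_perfect(self, separable_dataset):
        cfg = SOMConfig(rows=3, cols=3, epochs=2, seed=3)
        res = cross_validate(separable_dataset, cfg, k=2, seed=0)
        assert res.mean >= 0.99

    def test_too_few_per_group_rejected(self, rng):
        ds = make_dataset(rng.random((4, 6)) + 0.1, ["A", "A", "A", "B"])
        with pytest.raises(ValueError, match="fewer"):
            cross_validate(ds, SOMConfig(rows=2, cols=2), k=3)


class TestEvaluate:
    def test_rows_sum_to_one_hundred(self, separable_dataset, small_som_config):
        from somspec import split_dataset

        tr, te = split_dataset(separable_dataset)
        cm = evaluate(tr, te, small_som_config, repeats=2)
        np.testing.assert_allclose(cm.matrix.sum(axis=1), 100.0, atol=0.1)

    def test_deterministic_rerun(self, separable_dataset, small_som_config):
        from somspec import split_dataset

        tr, te = split_dataset(separable_dataset)
        a = evaluate(tr, te, small_som_config, repeats=1)
        b = evaluate(tr, te, small_som_config, repeats=1)
        np.testing.assert_array_equal(a.matrix, b.matrix)

    def test_class_absent_from_test_rejected(self, separable_dataset,
                                             small_som_config):
        te = separable_dataset.subset(
            np.flatnonzero(separable_dataset.labels == "sham"))
        with pytest.raises(ValueError, match="absent"):
            evaluate(separable_dataset, te, small_som_config)

    def test_confusion_row_sum_validation(self):
        with pytest.raises(ValueError, match="sum to 100"):
            ConfusionMatrix(("A", "B"), np.array([[50.0, 40.0], [0.0, 100.0]]),
                            np.zeros(2), 1)


class TestInvariantsAndModelObject:
    def test_train_accuracy_not_below_test_accuracy(self, small_dataset):
        """No anti-generalization pathology: training-set accuracy beats
        held-out accuracy on average over 5 seeds."""
        from somspec import preprocess_dataset, split_dataset

        ds = preprocess_dataset(small_dataset, baseline=False)
        tr, te = split_dataset(ds)
        diffs = []
        for seed in range(5):
            res = SupervisedSOM(tr, SOMConfig(rows=4, cols=4, epochs=2,
                                              seed=seed)).fit()
            diffs.append(res.score(tr) - res.score(te))
        assert np.mean(diffs) >= 0

    def test_permuted_labels_null_somdi(self, separable_dataset):
        """With labels shuffled, class assignment carries no information:
        the mean discriminant at every default band center stays within
        3 SE of zero over 20 permutations."""
        cfg = SOMConfig(rows=3, cols=3, epochs=2, seed=0)
        res = SupervisedSOM(separable_dataset, cfg).fit()
        rng = np.random.default_rng(77)
        centers = [850.0, 1003.0, 1098.0, 1266.0, 1337.0, 1660.0]
        vals = {c: [] for c in centers}
        for _ in range(20):
            perm = rng.permutation(separable_dataset.n_spectra)
            shuffled = LabeledDataset(
                separable_dataset.wavenumbers, separable_dataset.intensities,
                separable_dataset.labels[perm], separable_dataset.mouse_ids[perm],
                separable_dataset.eye_sides[perm], separable_dataset.classes)
            sd = somdi(accumulate_hits(res.grid, shuffled))
            for c in centers:
                vals[c].append(sd.value_at("sTBI", c))
        for c in centers:
            arr = np.asarray(vals[c])
            se = arr.std(ddof=1) / np.sqrt(arr.size)
            assert abs(arr.mean()) <= 3 * se + 1e-12

    def test_model_results_roundtrip_and_summary(self, separable_dataset,
                                                 small_som_config, tmp_path):
        model = SupervisedSOM(separable_dataset, small_som_config)
        res = model.fit()
        assert res.score(separable_dataset) >= 0.99
        text = res.summary()
        assert "quantization error" in text and "training hits" in text
        path = str(tmp_path / "model.npz")
        save_model(res.grid, path)
        back = load_model(path)
        np.testing.assert_array_equal(back.weights, res.grid.weights)
        np.testing.assert_array_equal(back.class_hits, res.grid.class_hits)
        assert back.classes == res.grid.classes
        preds = predict(back, separable_dataset)
        np.testing.assert_array_equal(preds, res.predict(separable_dataset))
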