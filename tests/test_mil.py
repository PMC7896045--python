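"""MIL suite: selection, aggregation, EM thresholds, bag estimators."""

import numpy as np
import pytest

from _oracles import brute_force_bag_max, brute_force_topk
from wsiweak.mil import (
    Bag,
    MILRNN,
    PredictionMap,
    build_bag,
    class_histogram,
    em_select,
    histogram_bag_classifier,
    infer_bag_max,
    maxfeat_aggregate,
    mil_train_epoch,
    prediction_map,
    rnn_aggregate,
    score_instances,
    select_topk,
)
from wsiweak.nn import Adam, SmallConvNet
from wsiweak.synthdata import SyntheticSlideSpec, generate_slide
from wsiweak.tiling import Tile


def make_bag(n, label="ADC", seed=0, side=32):
    rng = np.random.default_rng(seed)
    tiles = [
        Tile(rng.integers(0, 220, (side, side, 3), dtype=np.uint8), r, c)
        for r, c in [(i // 4, i % 4) for i in range(n)]
    ]
    return Bag(slide_id=f"bag{seed}", instances=tiles, label=label,
               grid_shape=(max(1, (n + 3) // 4), 4))


class TestSelectTopk:
    def test_simple_argmax(self):
        scores = np.array([[0.8, 0.1, 0.1], [0.05, 0.9, 0.05],
                           [0.3, 0.5, 0.2]])
        assert select_topk(scores, "ADC", 1).indices == [1]

    def test_k_clipped_to_bag_size(self):
        assert sorted(select_topk(np.array([0.3, 0.7]), 0, 3).indices) == \
            [0, 1]

    def test_tie_broken_by_lowest_index(self):
        s = np.array([0.1, 0.2, 0.7, 0.5, 0.3, 0.7])
        assert select_topk(s, 0, 1).indices == [2]

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_sort_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 21))
        s = np.round(rng.random(n), 2)      # induce ties
        k = int(rng.integers(1, 8))
        assert select_topk(s, 0, k).indices == brute_force_topk(s, k)


class TestInferBagMax:
    def test_single_instance_passthrough_shape(self):
        probs = infer_bag_max(np.array([[0.2, 0.5, 0.3]]))
        assert probs.argmax() == 1
        assert probs.sum() == pytest.approx(1.0)

    def test_adc_score_is_instance_max(self):
        scores = np.array([[0.8, 0.2, 0.0], [0.1, 0.9, 0.0],
                           [0.6, 0.4, 0.0]])
        probs = infer_bag_max(scores)
        # ADC = max over instances (0.9), NC = min over instances (0.1)
        np.testing.assert_allclose(probs[1], 0.9 / (0.9 + 0.1))

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_and_permutation_invariant(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.dirichlet([1, 1, 1], size=int(rng.integers(1, 15)))
        np.testing.assert_allclose(
            infer_bag_max(scores), brute_force_bag_max(scores)
        )
        perm = rng.permutation(len(scores))
        np.testing.assert_allclose(
            infer_bag_max(scores[perm]), infer_bag_max(scores)
        )


class TestScoreInstances:
    def test_alignment_and_determinism(self):
        model = SmallConvNet(channels=(4,), seed=0)
        bag = make_bag(5)
        a = score_instances(model, bag)
        b = score_instances(model, bag)
        assert a.shape == (5, 3)
        np.testing.assert_array_equal(a, b)

    def test_duplicated_instance_scores_identically(self):
        model = SmallConvNet(channels=(4,), seed=0)
        bag = make_bag(3)
        bag.instances.append(bag.instances[0])
        bag._x = None
        scores = score_instances(model, bag)
        np.testing.assert_allclose(scores[0], scores[3], atol=1e-6)

    def test_batching_invariance(self):
        model = SmallConvNet(channels=(4,), seed=1)
        bag = make_bag(7)
        batched = model.predict_proba(bag.x, batch=3)
        single = np.concatenate(
            [model.predict_proba(bag.x[i:i + 1]) for i in range(7)]
        )
        np.testing.assert_allclose(batched, single, atol=1e-5)


class TestEMSelect:
    def _pmap(self, grid, mask=None):
        grid = np.asarray(grid, dtype=float)
        probs = np.zeros(grid.shape + (3,))
        probs[:, :, 1] = grid
        mask = np.ones(grid.shape, bool) if mask is None else mask
        return PredictionMap(probs=probs, mask=mask)

    def test_uniform_map_selects_nothing(self):
        sel = em_select(self._pmap(np.full((4, 4), 0.5)), "ADC")
        assert sel.indices == []

    def test_hot_cell_selected(self):
        grid = np.full((5, 5), 0.1)
        grid[2, 3] = 0.9
        sel = em_select(self._pmap(grid), "ADC")
        assert 2 * 5 + 3 in sel.indices

    def test_blur_of_impulse_is_gaussian_stencil(self):
        from wsiweak.mil import _masked_blur
        grid = np.zeros((5, 5))
        grid[2, 2] = 1.0
        blurred = _masked_blur(grid, np.ones((5, 5), bool))
        w = np.exp(-0.5 * np.array([1, 0, 1]))
        k1 = w / w.sum()
        expected = np.outer(k1, k1)
        np.testing.assert_allclose(blurred[1:4, 1:4], expected, atol=1e-12)
        assert blurred[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_class_threshold_enables_extra_cells(self):
        grid = np.full((4, 4), 0.2)
        grid[0, 0] = 0.6
        pm = self._pmap(grid)
        base = em_select(pm, "ADC", image_pct=0.001)
        wide = em_select(pm, "ADC", image_pct=0.001, class_threshold=0.1)
        assert set(base.indices) <= set(wide.indices)
        assert len(wide.indices) == 16

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="foreground"):
            em_select(self._pmap(np.zeros((3, 3)), np.zeros((3, 3), bool)),
                      "ADC")

    def test_tiny_image_pct_keeps_only_argmax_region(self):
        rng = np.random.default_rng(0)
        grid = rng.random((6, 6))
        pm = self._pmap(grid)
        sel = em_select(pm, "ADC", image_pct=1e-9)
        from wsiweak.mil import _masked_blur
        blurred = _masked_blur(grid, np.ones((6, 6), bool))
        assert sel.indices == [int(np.argmax(blurred))]


class TestHistogram:
    def test_histogram_sum_example(self):
        h = class_histogram(np.array([[0.2, 0.5, 0.3], [0.4, 0.4, 0.2]]))
        np.testing.assert_allclose(h, [0.6, 0.9, 0.5])
        assert h.sum() == pytest.approx(2.0)

    def test_separable_histograms_fit_perfectly(self):
        rng = np.random.default_rng(1)
        h_pos = rng.random((20, 3)) + [0, 5, 0]
        h_neg = rng.random((20, 3)) + [5, 0, 0]
        X = np.vstack([h_pos, h_neg])
        y = np.array(["ADC"] * 20 + ["NC"] * 20)
        for kind in ("LR", "SVM-RBF"):
            clf = histogram_bag_classifier(X, y, kind)
            assert clf.score(X, y) == 1.0

    def test_lr_and_svm_agree_on_separable_data(self):
        rng = np.random.default_rng(2)
        X = np.vstack([rng.random((15, 3)) + [0, 4, 0],
                       rng.random((15, 3)) + [4, 0, 0]])
        y = np.array(["ADC"] * 15 + ["NC"] * 15)
        lr = histogram_bag_classifier(X, y, "LR")
        svm = histogram_bag_classifier(X, y, "SVM-RBF")
        np.testing.assert_array_equal(lr.predict(X), svm.predict(X))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="two classes"):
            histogram_bag_classifier(np.ones((4, 3)), ["NC"] * 4)


class TestMaxFeat:
    def test_k1_returns_top_instance_embedding(self):
        model = SmallConvNet(channels=(4,), seed=3)
        bag = make_bag(6, seed=3)
        probs = score_instances(model, bag)
        suspicion = 1.0 - probs[:, 0]
        top = int(np.argmax(suspicion))
        agg = maxfeat_aggregate(bag, model, k=1)
        np.testing.assert_allclose(agg, model.embed(bag.x[[top]])[0],
                                   atol=1e-6)

    def test_identical_instances_mean_is_that_embedding(self):
        model = SmallConvNet(channels=(4,), seed=4)
        rng = np.random.default_rng(0)
        px = rng.integers(0, 220, (32, 32, 3), dtype=np.uint8)
        tiles = [Tile(px.copy(), 0, i) for i in range(4)]
        bag = Bag("b", tiles, "ADC", (1, 4))
        agg = maxfeat_aggregate(bag, model, k=3)
        np.testing.assert_allclose(agg, model.embed(bag.x[:1])[0], atol=1e-5)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_sort_then_average_oracle(self, seed):
        model = SmallConvNet(channels=(4,), seed=seed)
        bag = make_bag(9, seed=seed)
        probs = score_instances(model, bag)
        suspicion = 1.0 - probs[:, 0]
        idx = brute_force_topk(suspicion, 3)
        expected = model.embed(bag.x[idx]).mean(axis=0)
        np.testing.assert_allclose(maxfeat_aggregate(bag, model, 3),
                                   expected, atol=1e-6)


class TestMILRNN:
    def _toy_sequences(self, n=60, d=8, seed=0):
        """Label is determined by the first (top-scoring) embedding."""
        rng = np.random.default_rng(seed)
        seqs, labels = [], []
        protos = {"NC": np.zeros(d), "ADC": np.eye(d)[0] * 3,
                  "SqCC": np.eye(d)[1] * 3}
        for i in range(n):
            label = ("NC", "ADC", "SqCC")[i % 3]
            first = protos[label] + 0.3 * rng.standard_normal(d)
            rest = [0.3 * rng.standard_normal(d) for _ in range(2)]
            seqs.append(np.stack([first] + rest).astype(np.float32))
            labels.append(label)
        return seqs, labels

    def test_deterministic_output(self):
        seqs, labels = self._toy_sequences()
        a = MILRNN(hidden=16, epochs=5, seed=1)._fit_sequences(seqs, labels)
        b = MILRNN(hidden=16, epochs=5, seed=1)._fit_sequences(seqs, labels)
        np.testing.assert_array_equal(a.params_["Wx"], b.params_["Wx"])

    def test_single_step_sequence(self):
        seqs, labels = self._toy_sequences()
        rnn = MILRNN(hidden=16, epochs=2, seed=0)._fit_sequences(seqs, labels)
        out = rnn.aggregate(seqs[0][:1])
        assert out.shape == (3,)
        assert out.sum() == pytest.approx(1.0, abs=1e-5)

    def test_empty_sequence_rejected(self):
        seqs, labels = self._toy_sequences()
        rnn = MILRNN(hidden=16, epochs=1, seed=0)._fit_sequences(seqs, labels)
        with pytest.raises(ValueError):
            rnn_aggregate(np.zeros((0, 8)), rnn)

    def test_learns_top1_determined_labels(self):
        seqs, labels = self._toy_sequences(n=90, seed=2)
        rnn = MILRNN(hidden=32, epochs=60, lr=5e-3, seed=0)
        rnn._fit_sequences(seqs[:60], labels[:60])
        test_probs = np.stack([rnn.aggregate(s) for s in seqs[60:]])
        pred = test_probs.argmax(axis=1)
        truth = np.array(
            [("NC", "ADC", "SqCC").index(l) for l in labels[60:]]
        )
        assert (pred == truth).mean() > 0.9


class TestMILTraining:
    @pytest.fixture(scope="class")
    def tiny_corpus_bags(self):
        slides = []
        for i, (label, frac) in enumerate(
            [("NC", 0.0)] * 4 + [("ADC", 0.3)] * 4 + [("SqCC", 0.3)] * 4
        ):
            slides.append(
                generate_slide(
                    SyntheticSlideSpec(
                        label=label, lesion_fraction=frac,
                        tissue_fraction=0.5, width_px=448, height_px=448,
                        seed=100 + i,
                    )
                )
            )
        return [build_bag(s) for s in slides], slides

    def test_epoch_determinism(self, tiny_corpus_bags):
        bags, _ = tiny_corpus_bags

        def run():
            model = SmallConvNet(channels=(4, 8), seed=0)
            opt = Adam(lr=1e-3)
            rng = np.random.default_rng(0)
            sels = []
            for _ in range(3):
                _, s = mil_train_epoch(model, bags, 3, opt, rng)
                sels.append(s)
            return sels

        assert run() == run()

    def test_loss_decreases_on_all_nc_corpus(self):
        slides = [
            generate_slide(
                SyntheticSlideSpec(label="NC", tissue_fraction=0.5,
                                   width_px=448, height_px=448,
                                   seed=200 + i)
            )
            for i in range(4)
        ]
        bags = [build_bag(s) for s in slides]
        model = SmallConvNet(channels=(4, 8), seed=1)
        opt = Adam(lr=1e-3)
        rng = np.random.default_rng(1)
        losses = [mil_train_epoch(model, bags, 3, opt, rng)[0]
                  for _ in range(5)]
        assert losses[-1] < losses[0]

    def test_selection_concentrates_on_lesion_tiles(self, tiny_corpus_bags):
        bags, slides = tiny_corpus_bags
        model = SmallConvNet(channels=(4, 8), seed=2)
        opt = Adam(lr=2e-3)
        rng = np.random.default_rng(2)
        for _ in range(10):
            _, selections = mil_train_epoch(model, bags, 1, opt, rng)
        hits = total = 0
        for bag in bags:
            if bag.label == "NC":
                continue
            for i in selections[bag.slide_id]:
                total += 1
                hits += bag.lesion_overlap[i] > 0
        assert hits / total >= 0.8


def test_prediction_map_alignment(adc_slide):
    bag = build_bag(adc_slide)
    model = SmallConvNet(channels=(4,), seed=0)
    pm = prediction_map(model, bag)
    assert pm.probs.shape[:2] == pm.mask.shape == bag.grid_shape
    scores = score_instances(model, bag)
    for t, s in zip(bag.instances, scores):
        np.testing.assert_allclose(pm.probs[t.grid_row, t.grid_col], s)
        assert pm.mask[t.grid_row, t.grid_col]
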