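"""Detector assembly: shapes, matching, decoding, training and fusion."""

import copy
import itertools
import time

import numpy as np
import pytest

from cropdet import nn
from cropdet.boxes import cxcywh_to_xyxy
from cropdet.model import (AIFI, Backbone, Detector, FeaturePyramid, ModelConfig,
                           build_detector, count_parameters, hungarian_match,
                           params_in_millions, predict, training_step)
from cropdet.nn import Tensor
from tests.conftest import randomize_bn_stats


@pytest.fixture(scope="module")
def tiny_model():
    return build_detector("tiny", num_classes=2, seed=0)


class TestBackbone:
    def test_stride_arithmetic(self):
        nn.seed_all(0)
        bb = Backbone(ModelConfig.preset("tiny"))
        x = Tensor(np.zeros((1, 3, 160, 160)))
        pyr = bb.eval()(x)
        assert pyr.p3.shape[2:] == (20, 20)
        assert pyr.p4.shape[2:] == (10, 10)
        assert pyr.p5.shape[2:] == (5, 5)

    def test_indivisible_input_rejected(self):
        nn.seed_all(0)
        bb = Backbone(ModelConfig.preset("tiny"))
        with pytest.raises(ValueError, match="32"):
            bb(Tensor(np.zeros((1, 3, 100, 100))))

    def test_tiny_forward_under_a_second(self):
        nn.seed_all(0)
        bb = Backbone(ModelConfig.preset("tiny")).eval()
        x = Tensor(np.random.default_rng(0).normal(size=(1, 3, 160, 160)))
        t0 = time.time()
        bb(x)
        assert time.time() - t0 < 1.0

    def test_deterministic_under_seed(self):
        x = np.random.default_rng(1).normal(size=(1, 3, 64, 64))
        nn.seed_all(7)
        y1 = Backbone(ModelConfig.preset("tiny")).eval()(Tensor(x)).p5.data
        nn.seed_all(7)
        y2 = Backbone(ModelConfig.preset("tiny")).eval()(Tensor(x)).p5.data
        assert np.array_equal(y1, y2)


class TestAIFI:
    def test_shape_preserved_and_dim_checked(self, rng):
        nn.seed_all(0)
        aifi = AIFI(32, 4, 64)
        x = Tensor(rng.normal(size=(2, 32, 5, 5)))
        assert aifi(x).shape == (2, 32, 5, 5)
        with pytest.raises(ValueError, match="dim"):
            aifi(Tensor(rng.normal(size=(1, 16, 5, 5))))

    def test_batch_equivariance(self, rng):
        nn.seed_all(1)
        aifi = AIFI(16, 4, 32)
        x = rng.normal(size=(3, 16, 4, 4))
        y = aifi(Tensor(x)).data
        y_perm = aifi(Tensor(x[[2, 0, 1]])).data
        assert np.allclose(y[[2, 0, 1]], y_perm, atol=1e-12)


class TestDecoder:
    def test_boxes_stay_in_unit_interval(self, tiny_model, rng):
        x = Tensor(rng.uniform(0, 1, (1, 3, 160, 160)))
        outs = tiny_model.eval()(x)
        assert len(outs) == 6       # deep supervision hooks
        for logits, boxes in outs:
            assert boxes.data.min() >= 0 and boxes.data.max() <= 1

    def test_zero_refinement_returns_initial_references(self, rng):
        model = build_detector("tiny", num_classes=2, seed=3)
        for head in model.decoder.box_heads:
            for layer in head.layers:
                layer.weight.data[:] = 0
                layer.bias.data[:] = 0
        x = Tensor(rng.uniform(0, 1, (1, 3, 160, 160)))
        outs = model.eval()(x)
        init_ref = 1 / (1 + np.exp(-model.decoder.ref_logit.data))
        assert np.allclose(outs[-1][1].data[0], init_ref, atol=1e-9)


class TestHungarian:
    def test_single_pair(self):
        qi, gi = hungarian_match(np.zeros((1, 2)), np.array([[0.5, 0.5, 0.2, 0.2]]),
                                 np.array([[0.5, 0.5, 0.2, 0.2]]), np.array([0]))
        assert list(qi) == [0] and list(gi) == [0]

    def test_empty_gt(self):
        qi, gi = hungarian_match(np.zeros((3, 2)), np.zeros((3, 4)),
                                 np.zeros((0, 4)), np.zeros(0, int))
        assert len(qi) == 0 and len(gi) == 0

    def test_too_many_gt_rejected(self):
        with pytest.raises(ValueError):
            hungarian_match(np.zeros((1, 2)), np.zeros((1, 4)),
                            np.zeros((2, 4)), np.zeros(2, int))

    def test_assignment_equals_bruteforce_up_to_n6(self, rng):
        from scipy.optimize import linear_sum_assignment
        for _ in range(200):
            n = int(rng.integers(1, 7))
            m = int(rng.integers(n, 9))
            cost = rng.normal(size=(m, n))
            qi, gi = linear_sum_assignment(cost)
            best = min(sum(cost[list(perm), range(n)])
                       for perm in itertools.permutations(range(m), n))
            assert cost[qi, gi].sum() == pytest.approx(best, abs=1e-9)

    def test_cost_matrix_2x2_example(self):
        from scipy.optimize import linear_sum_assignment
        qi, gi = linear_sum_assignment(np.array([[1.0, 2.0], [2.0, 1.0]]))
        assert list(qi) == [0, 1] and list(gi) == [0, 1]


class TestTrainingStep:
    def _batch(self, rng, n=2):
        x = Tensor(rng.uniform(0, 1, (n, 3, 160, 160)))
        tg = [{"boxes": np.array([[0.3, 0.3, 0.2, 0.2]]), "labels": np.array([0])}
              for _ in range(n)]
        return x, tg

    def test_loss_finite_and_gradients_flow(self, rng):
        model = build_detector("tiny", num_classes=2, seed=1).train()
        x, tg = self._batch(rng)
        loss, comps = training_step(model, x, tg)
        assert np.isfinite(loss.data)
        loss.backward()
        missing = [n for n, p in model.named_parameters() if p.grad is None]
        assert missing == []
        assert all(np.isfinite(p.grad).all() for p in model.parameters())

    def test_identical_images_same_loss_components(self, rng):
        model = build_detector("tiny", num_classes=2, seed=2).eval()
        img = rng.uniform(0, 1, (1, 3, 160, 160))
        x = Tensor(np.concatenate([img, img]))
        tg = [{"boxes": np.array([[0.4, 0.4, 0.3, 0.3]]), "labels": np.array([1])}] * 2
        _, c2 = training_step(model, x, tg)
        _, c1 = training_step(model, Tensor(img), tg[:1])
        assert c2["cls"] == pytest.approx(2 * c1["cls"], rel=1e-9)
        assert c2["box"] == pytest.approx(2 * c1["box"], rel=1e-9)

    def test_empty_annotations_contribute_classification_only(self, rng):
        model = build_detector("tiny", num_classes=2, seed=2).eval()
        x = Tensor(rng.uniform(0, 1, (1, 3, 160, 160)))
        tg = [{"boxes": np.zeros((0, 4)), "labels": np.zeros(0, int)}]
        loss, comps = training_step(model, x, tg)
        assert comps["box"] == 0.0 and comps["l1"] == 0.0 and comps["cls"] > 0

    def test_loss_decreases_on_fixed_batch(self, rng):
        from cropdet.nn.optim import AdamW
        model = build_detector("tiny", num_classes=2, seed=4).train()
        x = Tensor(rng.uniform(0, 1, (2, 3, 160, 160)).astype(np.float64))
        tg = [{"boxes": np.array([[0.3, 0.3, 0.2, 0.2], [0.7, 0.6, 0.15, 0.2]]),
               "labels": np.array([0, 1])} for _ in range(2)]
        opt = AdamW(model.parameters(), lr=1e-3, warmup_steps=10)
        first = None
        for _ in range(60):
            loss, _ = training_step(model, x, tg)
            if first is None:
                first = loss.item()
            opt.zero_grad()
            loss.backward()
            opt.step()
        assert loss.item() < 0.5 * first


class TestPredictAndFusion:
    def test_detection_record_contract(self, tiny_model, rng):
        img = rng.integers(0, 255, size=(130, 210, 3)).astype(np.uint8)
        rec = predict(tiny_model, img, top_k=25)
        assert len(rec) == 25
        assert np.all(np.diff(rec.scores) <= 1e-12)
        assert rec.boxes[:, [0, 2]].min() >= 0 and rec.boxes[:, [0, 2]].max() <= 210
        assert rec.boxes[:, [1, 3]].min() >= 0 and rec.boxes[:, [1, 3]].max() <= 130
        with pytest.raises(ValueError):
            predict(tiny_model, img, top_k=10_000)

    def test_end_to_end_fusion_equivalence(self, rng):
        model = build_detector("tiny", num_classes=2, seed=5)
        randomize_bn_stats(model, rng)
        model.eval()
        img = rng.integers(0, 255, size=(160, 160, 3)).astype(np.uint8)
        before = predict(model, img, top_k=15)
        fused = copy.deepcopy(model).fuse()
        after = predict(fused, img, top_k=15)
        assert np.abs(before.boxes - after.boxes).max() <= 1e-3
        assert np.abs(before.scores - after.scores).max() <= 1e-4
        assert count_parameters(model, "deploy") < count_parameters(model, "train")


class TestParameterCounting:
    def test_plain_conv_count(self):
        nn.seed_all(0)
        conv = nn.Conv2d(2, 4, 3, bias=True)
        assert conv.num_parameters() == 2 * 4 * 9 + 4 == 76

    def test_count_invariant_to_image_size(self, tiny_model, rng):
        n = count_parameters(tiny_model, "train")
        tiny_model.eval()
        for size in (96, 160):
            tiny_model(Tensor(rng.uniform(0, 1, (1, 3, size, size))))
            assert count_parameters(tiny_model, "train") == n

    def test_cfb_deploy_count_equals_plain_baseline(self):
        a = build_detector("tiny", num_classes=2, use_cfb=True, seed=0)
        b = build_detector("tiny", num_classes=2, use_cfb=False, seed=0)
        assert count_parameters(a, "train") > count_parameters(b, "train")
        assert count_parameters(a, "deploy") == count_parameters(b, "deploy")

    def test_millions_formatting(self):
        assert params_in_millions(37_670_123) == 37.67
        assert params_in_millions(38_144_999) == 38.14
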