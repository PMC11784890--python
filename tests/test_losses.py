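"""Loss-family unit and property tests.

Expected values below were either computed by hand-arithmetic (areas,
substitutions) or frozen from an independent oracle; the Monte-Carlo
point-membership oracle re-estimates overlap quantities from scratch.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cropdet import losses as L
from cropdet.boxes import Box
from cropdet.nn import Tensor


# ---------------------------------------------------------------------------
# Monte-Carlo point-membership oracle (quasi-random for tight error)
# ---------------------------------------------------------------------------

def mc_overlap_oracle(a, b, n=1 << 18):
    """Estimate IoU and GIoU by point membership inside the enclosing box."""
    from scipy.stats import qmc
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    ex1, ey1 = min(a[0], b[0]), min(a[1], b[1])
    ex2, ey2 = max(a[2], b[2]), max(a[3], b[3])
    pts = qmc.Sobol(2, seed=7).random(n)
    xs = ex1 + pts[:, 0] * (ex2 - ex1)
    ys = ey1 + pts[:, 1] * (ey2 - ey1)
    in_a = (xs >= a[0]) & (xs <= a[2]) & (ys >= a[1]) & (ys <= a[3])
    in_b = (xs >= b[0]) & (xs <= b[2]) & (ys >= b[1]) & (ys <= b[3])
    union = np.mean(in_a | in_b)
    inter = np.mean(in_a & in_b)
    iou = inter / union if union > 0 else 0.0
    giou = iou - (1.0 - union)
    return iou, giou


def random_boxes(rng, n):
    c = rng.uniform(0.1, 0.9, size=(n, 2))
    wh = rng.uniform(0.05, 0.5, size=(n, 2))
    return np.concatenate([c - wh / 2, c + wh / 2], axis=1)


# ---------------------------------------------------------------------------
# worked examples
# ---------------------------------------------------------------------------

class TestWorkedExamples:
    def test_iou_identity_disjoint_and_overlap(self):
        assert L.iou((0, 0, 2, 2), (0, 0, 2, 2)) == 1.0
        assert L.iou((0, 0, 1, 1), (2, 2, 3, 3)) == 0.0
        assert L.iou((0, 0, 2, 2), (1, 1, 3, 3)) == pytest.approx(1 / 7, abs=1e-12)

    def test_giou_values(self):
        assert L.giou((0, 0, 2, 2), (0, 0, 2, 2)) == 1.0
        assert L.giou((0, 0, 1, 1), (2, 2, 3, 3)) == pytest.approx(-7 / 9, abs=1e-9)
        # nested: enclosing box equals the outer box, so giou == iou
        outer, inner = (0, 0, 4, 4), (1, 1, 2, 2)
        assert L.giou(outer, inner) == pytest.approx(L.iou(outer, inner), abs=1e-12)

    def test_eiou_loss_value(self):
        assert L.eiou_loss((0, 0, 2, 2), (0, 0, 2, 2)) == 0.0
        # IoU .25, centre 2/32, width and height terms 4/16 each
        assert L.eiou_loss((0, 0, 2, 2), (0, 0, 4, 4)) == pytest.approx(1.3125, abs=1e-9)

    def test_eiou_decreases_along_translation_path(self):
        a = np.array([0.0, 0.0, 2.0, 2.0])
        b = (5.0, 0.0, 7.0, 2.0)
        vals = [L.eiou_loss(tuple(a + [t, 0, t, 0]), b) for t in np.linspace(0, 5, 21)]
        assert all(x > y for x, y in zip(vals, vals[1:]))

    def test_siou_angle_term(self):
        # centres sharing y: angle contribution vanishes
        t = L.siou_terms((0, 0, 2, 2), (4, 0, 6, 2))
        assert t.lambda_angle == pytest.approx(0.0, abs=1e-12)
        # 45-degree offset: maximal angle term
        t45 = L.siou_terms((0, 0, 2, 2), (3, 3, 5, 5))
        assert t45.lambda_angle == pytest.approx(1.0, abs=1e-12)

    def test_siou_identity_and_worked_value(self):
        t = L.siou_terms((1, 1, 3, 5), (1, 1, 3, 5))
        assert t.delta_dist == 0.0 and t.omega_shape == 0.0
        assert L.siou_loss((1, 1, 3, 5), (1, 1, 3, 5)) == 0.0
        # same shape, x-offset 2: delta = 1 - exp(-0.5), omega = 0, iou = 0
        expected = 1.0 + 0.5 * (1.0 - math.exp(-0.5))
        assert L.siou_loss((0, 0, 2, 2), (2, 0, 4, 2)) == pytest.approx(expected, abs=1e-6)

    def test_siou_lower_bound(self):
        rng = np.random.default_rng(5)
        a, b = random_boxes(rng, 50), random_boxes(rng, 50)
        assert np.all(L.siou_loss(a, b) >= (1.0 - L.iou(a, b)) - 1e-12)

    def test_inner_iou(self):
        a, b = (0, 0, 2, 2), (1, 1, 3, 3)
        assert L.inner_iou(a, b, 1.0) == pytest.approx(L.iou(a, b), abs=1e-12)
        # shrunken boxes touch only at a corner
        assert L.inner_iou(a, b, 0.5) == 0.0
        assert L.inner_iou(a, a, 0.77) == 1.0
        with pytest.raises(ValueError):
            L.inner_iou(a, b, 0.0)

    def test_simiou_worked_value(self):
        # inner 1/7, d1 = d2 = 2 * 0.25^2, equal aspect ratios
        v = L.simiou_loss((0, 0, 0.5, 0.5), (0.25, 0.25, 0.75, 0.75))
        assert v == pytest.approx(1 - 1 / 7 + 0.125, abs=1e-5)

    def test_simiou_identity_is_exactly_zero(self):
        assert L.simiou_loss((0, 0, 2, 2), (0, 0, 2, 2), img_w=4, img_h=4) == 0.0

    def test_simiou_corner_norm_variant(self):
        a, b = (0, 0, 0.5, 0.5), (0.25, 0.25, 0.75, 0.75)
        half = L.simiou_loss(a, b, corner_norm="half")
        shape = L.simiou_loss(a, b, corner_norm="shape")
        # with h = w = 1 the variant weighs d2 twice as heavily
        assert shape == pytest.approx(half + 0.0625, abs=1e-9)

    def test_simiou_rejects_bad_input(self):
        with pytest.raises(ValueError):
            L.simiou_loss((0, 0, np.nan, 1), (0, 0, 1, 1))
        with pytest.raises(ValueError):
            L.simiou_loss((0, 0, 1, 1), (0, 0, 1, 1), img_w=0)

    def test_focal_loss(self):
        assert L.focal_loss(1.0) == 0.0
        assert L.focal_loss(0.5) == pytest.approx(0.25 * 0.25 * math.log(2), rel=1e-9)
        p = L.LossParams(focal_alpha=1.0, focal_gamma=0.0)
        assert L.focal_loss(0.3, p) == pytest.approx(-math.log(0.3), rel=1e-9)

    def test_elementwise_losses(self):
        z = L.elementwise_losses([0.2, 0.8], [0.2, 0.8])
        assert z["mse"] == 0.0 and z["l1"] == 0.0
        assert L.elementwise_losses([0, 2], [1, 1])["mse"] == 1.0
        assert L.elementwise_losses([1.0], [0.5])["bce"] == pytest.approx(math.log(2), rel=1e-6)
        with pytest.raises(ValueError):
            L.elementwise_losses([1, 2], [1])


# ---------------------------------------------------------------------------
# oracles and properties
# ---------------------------------------------------------------------------

def test_overlap_losses_match_monte_carlo_oracle():
    rng = np.random.default_rng(11)
    a, b = random_boxes(rng, 40), random_boxes(rng, 40)
    for ai, bi in zip(a, b):
        iou_mc, giou_mc = mc_overlap_oracle(ai, bi)
        assert L.iou(ai, bi) == pytest.approx(iou_mc, abs=1e-3)
        assert L.giou(ai, bi) == pytest.approx(giou_mc, abs=2e-3)
        # inner IoU at ratio r is the IoU of the rescaled boxes
        r = 0.8
        ar = Box(*ai).scaled_about_center(r).as_xyxy()
        br = Box(*bi).scaled_about_center(r).as_xyxy()
        assert L.inner_iou(ai, bi, r) == pytest.approx(mc_overlap_oracle(ar, br)[0], abs=1e-3)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(x1=st.floats(-50, 50), y1=st.floats(-50, 50),
       w=st.floats(0.01, 40), h=st.floats(0.01, 40))
def test_identity_losses_are_zero_for_any_valid_box(x1, y1, w, h):
    a = (x1, y1, x1 + w, y1 + h)
    assert L.eiou_loss(a, a) == 0.0
    assert L.siou_loss(a, a) == 0.0
    assert L.simiou_loss(a, a, img_w=100, img_h=100) == 0.0


@settings(max_examples=40, deadline=None, derandomize=True)
@given(dx=st.floats(-30, 30), dy=st.floats(-30, 30), s=st.floats(0.1, 10))
def test_losses_invariant_to_joint_translation_and_scale(dx, dy, s):
    a = np.array([1.0, 2.0, 4.0, 5.0])
    b = np.array([2.0, 1.0, 5.0, 3.5])
    shift = np.array([dx, dy, dx, dy])
    for fn in (lambda u, v: L.iou(u, v), lambda u, v: L.giou(u, v),
               L.eiou_loss, L.siou_loss):
        base = fn(tuple(a), tuple(b))
        assert fn(tuple(a + shift), tuple(b + shift)) == pytest.approx(base, rel=1e-6, abs=1e-9)
        assert fn(tuple(a * s), tuple(b * s)) == pytest.approx(base, rel=1e-6, abs=1e-9)
    # simiou is invariant once coordinates are normalized by the image
    base = L.simiou_loss(tuple(a), tuple(b), img_w=10, img_h=10)
    scaled = L.simiou_loss(tuple(a * s), tuple(b * s), img_w=10 * s, img_h=10 * s)
    assert scaled == pytest.approx(base, rel=1e-6, abs=1e-9)


def test_theta_intensifies_inner_penalty():
    a, b = (0, 0, 0.4, 0.4), (0.1, 0.1, 0.5, 0.5)
    inner = L.inner_iou(a, b)
    assert 0 < inner < 1
    for t1, t2 in [(1.0, 2.0), (1.5, 3.0), (2.0, 4.0)]:
        assert 1 - inner ** t2 > 1 - inner ** t1


def test_simiou_decreases_as_corners_close_at_fixed_overlap():
    # slide a congruent box toward coincidence: corner distances shrink
    vals = []
    for off in np.linspace(0.2, 0.0, 11):
        vals.append(L.simiou_loss((0.1, 0.1, 0.5, 0.5),
                                  (0.1 + off, 0.1 + off, 0.5 + off, 0.5 + off)))
    assert all(x > y for x, y in zip(vals, vals[1:]))


def test_box_loss_registry_and_gradients():
    with pytest.raises(ValueError, match="giou"):
        L.box_loss("nope", (0, 0, 1, 1), (0, 0, 1, 1))
    a = Tensor(np.array([[0.1, 0.1, 0.5, 0.6], [0.2, 0.3, 0.7, 0.9]]), requires_grad=True)
    b = Tensor(np.array([[0.2, 0.2, 0.6, 0.7], [0.1, 0.2, 0.6, 0.8]]))
    for name in L.LOSS_NAMES:
        a.grad = None
        out = L.box_loss(name, a, b)
        out.sum().backward()
        assert np.isfinite(a.grad).all() and np.abs(a.grad).max() > 0


def test_zero_area_boxes_convention():
    assert L.iou((1, 1, 1, 1), (2, 2, 2, 2)) == 0.0
    assert L.iou((1, 1, 1, 1), (1, 1, 1, 1)) == 0.0
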