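"""Loss mathematics against brute-force oracles and closed forms.

The independent oracle throughout is plain-Python summation over the
probability simplex (math.exp/math.log, no numpy vectorization), so it
shares no code path with the implementation it checks.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from meddistill.data import TaskSpec
from meddistill.losses import (DistillConfig, hard_label_loss, kl_divergence,
                               multilabel_soft_loss, soft_target_kl_loss,
                               temperature_softmax, total_loss)

MC = TaskSpec("multiclass", 2)
ML2 = TaskSpec("multilabel", 2, "indicator")


# ---------------------------------------------------------------------------
# brute-force oracles (plain python floats)

def oracle_softmax(z, t):
    e = [math.exp((v - max(z)) / t) for v in z]
    s = sum(e)
    return [x / s for x in e]


def oracle_kl(p, q):
    return sum(pi * math.log(pi / qi) for pi, qi in zip(p, q) if pi > 0)


def oracle_soft_kl(tz, sz, t):
    return t * t * oracle_kl(oracle_softmax(tz, t), oracle_softmax(sz, t))


def oracle_hard_ce(z, y):
    return -math.log(oracle_softmax(z, 1.0)[y])


def oracle_bce(z, targets):
    terms = []
    for zi, yi in zip(z, targets):
        p = 1.0 / (1.0 + math.exp(-zi))
        terms.append(-(yi * math.log(p) + (1 - yi) * math.log(1 - p)))
    return sum(terms) / len(terms)


def oracle_ml_soft(tz, sz, t):
    total = 0.0
    for a, b in zip(tz, sz):
        p = 1.0 / (1.0 + math.exp(-a / t))
        q = 1.0 / (1.0 + math.exp(-b / t))
        total += oracle_kl([p, 1 - p], [q, 1 - q])
    return t * t * total / len(tz)


# ---------------------------------------------------------------------------
# worked examples (values frozen from the oracles above)

def test_temperature_softmax_worked_examples():
    assert np.allclose(temperature_softmax([0.0, 0.0, 0.0], 3.7).probs, 1 / 3)
    p = temperature_softmax([2.0, 0.0], 2.0).probs
    assert np.allclose(p, [0.7311, 0.2689], atol=5e-5)
    # large-t limit: soft labels approach uniform
    p = temperature_softmax([1.0, 2.0, 3.0], 1e6).probs
    assert np.all(np.abs(p - 1 / 3) < 1e-5)


def test_temperature_softmax_rejects_nonpositive_temperature():
    with pytest.raises(ValueError):
        temperature_softmax([1.0, 2.0], 0.0)


def test_kl_divergence_worked_examples():
    u = temperature_softmax([0.0, 0.0], 1.0)
    assert kl_divergence(u, u) == pytest.approx(0.0, abs=1e-12)
    assert kl_divergence([0.9, 0.1], [0.5, 0.5]) == pytest.approx(0.36806, abs=5e-5)
    assert kl_divergence([1.0, 0.0], [0.5, 0.5]) == pytest.approx(math.log(2), abs=1e-9)


def test_kl_divergence_support_violation():
    with pytest.raises(ValueError, match="support"):
        kl_divergence([0.5, 0.5], [1.0, 0.0])


def test_soft_target_kl_worked_examples():
    assert soft_target_kl_loss([1.0, -2.0], [1.0, -2.0], 3.0) == pytest.approx(0.0, abs=1e-12)
    assert soft_target_kl_loss([2.0, 0.0], [0.0, 0.0], 2.0) == pytest.approx(0.44378, abs=5e-5)
    assert soft_target_kl_loss([0.0, 0.0], [2.0, 0.0], 1.0) == pytest.approx(0.43378, abs=5e-5)


def test_hard_label_loss_worked_examples():
    # near-certain correct prediction
    z = np.array([50.0, 0.0, 0.0])
    assert hard_label_loss(z, [0], TaskSpec("multiclass", 3)) < 1e-6
    assert hard_label_loss([0.0, 0.0], [0], MC) == pytest.approx(math.log(2), abs=1e-9)
    assert hard_label_loss([0.0, 0.0], [[1, 0]], ML2) == pytest.approx(math.log(2), abs=1e-9)


def test_hard_label_loss_rejects_bad_labels():
    with pytest.raises(ValueError):
        hard_label_loss([0.0, 0.0], [5], MC)
    with pytest.raises(ValueError):
        hard_label_loss([0.0, 0.0], [[2, 0]], ML2)


def test_multilabel_soft_loss_reduces_to_two_class_case():
    assert multilabel_soft_loss([1.0, -1.0], [1.0, -1.0], 2.0) == pytest.approx(0.0, abs=1e-12)
    # a single label is exactly the binary softmax case with logit gap z
    assert multilabel_soft_loss([2.0], [0.0], 2.0) == pytest.approx(0.44378, abs=5e-5)
    fwd = multilabel_soft_loss([2.0, -1.0], [0.0, 0.5], 2.0)
    rev = multilabel_soft_loss([0.0, 0.5], [2.0, -1.0], 2.0)
    assert fwd != pytest.approx(rev, abs=1e-6)  # KL asymmetry


def test_total_loss_mixture():
    cfg = DistillConfig(temperature=2.0, alpha=0.2)
    lb = total_loss(math.log(2), 0.44378, cfg)
    assert lb.total == pytest.approx(0.49365, abs=5e-5)
    assert total_loss(0.6, 0.3, DistillConfig(2.0, 1.0)).total == pytest.approx(0.6)
    assert total_loss(0.6, 0.3, DistillConfig(2.0, 0.0)).total == pytest.approx(0.3)


def test_distill_config_invariants():
    assert DistillConfig(2.0, 0.3).beta == pytest.approx(0.7)
    with pytest.raises(ValueError):
        DistillConfig(temperature=-1.0)
    with pytest.raises(ValueError):
        DistillConfig(alpha=1.5)


# ---------------------------------------------------------------------------
# randomized oracle-equivalence (the acceptance script repeats this check)

def test_losses_match_brute_force_oracles_on_random_instances():
    rng = np.random.default_rng(123)
    for _ in range(200):
        m = int(rng.integers(2, 8))
        t = float(rng.uniform(0.3, 10.0))
        tz = rng.normal(0, 3, m)
        sz = rng.normal(0, 3, m)
        p = temperature_softmax(tz, t).probs
        assert np.abs(p - oracle_softmax(tz, t)).max() < 1e-8
        assert abs(kl_divergence(temperature_softmax(tz, t), temperature_softmax(sz, t))
                   - oracle_kl(oracle_softmax(tz, t), oracle_softmax(sz, t))) < 1e-8
        assert abs(soft_target_kl_loss(tz, sz, t) - oracle_soft_kl(tuple(tz), tuple(sz), t)) < 1e-8
        y = int(rng.integers(0, m))
        task = TaskSpec("multiclass", m)
        assert abs(hard_label_loss(tz, [y], task) - oracle_hard_ce(tuple(tz), y)) < 1e-8
        targets = rng.integers(0, 2, m)
        task_ml = TaskSpec("multilabel", m, "indicator")
        assert abs(hard_label_loss(sz, targets[None], task_ml)
                   - oracle_bce(tuple(sz), tuple(targets))) < 1e-8
        assert abs(multilabel_soft_loss(tz, sz, t) - oracle_ml_soft(tuple(tz), tuple(sz), t)) < 1e-8
        a = float(rng.uniform(0, 1))
        h, d = float(rng.uniform(0, 3)), float(rng.uniform(0, 3))
        assert abs(total_loss(h, d, DistillConfig(t, a)).total - (a * h + (1 - a) * d)) < 1e-8


# ---------------------------------------------------------------------------
# property tests

@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.lists(st.floats(-1e4, 1e4), min_size=2, max_size=10),
       st.floats(0.1, 100.0))
def test_softmax_normalizes_across_magnitudes(z, t):
    p = temperature_softmax(np.array(z), t).probs
    assert abs(p.sum() - 1.0) < 1e-6
    assert np.all(p >= 0)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_soft_kl_nonnegative_and_zero_iff_equal(seed):
    rng = np.random.default_rng(seed)
    m = int(rng.integers(2, 6))
    tz, sz = rng.normal(0, 2, m), rng.normal(0, 2, m)
    t = float(rng.uniform(0.5, 8))
    assert soft_target_kl_loss(tz, sz, t) >= 0.0
    assert soft_target_kl_loss(tz, tz, t) == pytest.approx(0.0, abs=1e-12)
    # equal softened distributions (shift-invariance) also give zero
    assert soft_target_kl_loss(tz, tz + 1.7, t) == pytest.approx(0.0, abs=1e-9)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.floats(0, 1), st.floats(0, 5), st.floats(0, 5))
def test_total_loss_is_convex_combination(alpha, hard, dist):
    lb = total_loss(hard, dist, DistillConfig(2.0, alpha))
    assert min(hard, dist) - 1e-12 <= lb.total <= max(hard, dist) + 1e-12


def test_soft_kl_gradient_direction_two_class():
    """With the teacher gap fixed, the loss decreases as the student gap
    approaches it from below and increases above it (finite differences)."""
    t, teacher_gap = 2.0, 1.5
    tz = np.array([teacher_gap, 0.0])

    def loss(gap):
        return soft_target_kl_loss(tz, np.array([gap, 0.0]), t)

    eps = 1e-5
    for gap in (0.0, 0.7, 1.2):   # below the teacher gap
        assert (loss(gap + eps) - loss(gap - eps)) / (2 * eps) < 0
    for gap in (1.8, 2.5, 4.0):   # above
        assert (loss(gap + eps) - loss(gap - eps)) / (2 * eps) > 0
    assert abs((loss(teacher_gap + eps) - loss(teacher_gap - eps)) / (2 * eps)) < 1e-3
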