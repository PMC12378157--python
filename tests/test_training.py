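"""Training loops: schedule, early stopping, reductions, frozen teacher,
determinism, and loss accounting."""

from dataclasses import replace

import numpy as np
import pytest

from meddistill.data import Preprocessor
from meddistill.models import build_student, build_teacher
from meddistill.synthetic import SyntheticSpec, generate_dataset
from meddistill.training import (TrainConfig, distill, early_stop_check,
                                 fit_linear_probe, lr_at_epoch, train_student)

from conftest import small_train_config


def test_lr_schedule_reference_values():
    cfg = TrainConfig(epochs=100, milestones=(50, 75), base_lr=1e-3, gamma=0.1,
                      patience=1000)
    assert lr_at_epoch(cfg, 10) == pytest.approx(1e-3)
    assert lr_at_epoch(cfg, 49) == pytest.approx(1e-3)
    assert lr_at_epoch(cfg, 50) == pytest.approx(1e-4)
    assert lr_at_epoch(cfg, 60) == pytest.approx(1e-4)
    assert lr_at_epoch(cfg, 75) == pytest.approx(1e-5)
    assert lr_at_epoch(cfg, 80) == pytest.approx(1e-5)
    with pytest.raises(ValueError):
        lr_at_epoch(cfg, 100)


def test_train_config_validation():
    with pytest.raises(ValueError):
        TrainConfig(milestones=(75, 50))
    with pytest.raises(ValueError):
        TrainConfig(milestones=(50, 120), epochs=100)
    with pytest.raises(ValueError):
        TrainConfig(patience=0)
    with pytest.raises(ValueError):
        TrainConfig(monitor="val_f1")


def test_early_stop_semantics():
    assert not early_stop_check([0.1, 0.2, 0.3, 0.4], patience=2)
    assert early_stop_check([0.5, 0.5, 0.5], patience=2)       # ties = no improvement
    assert early_stop_check([0.5, 0.4, 0.4, 0.3], patience=3)
    # improvement on the last allowed epoch resets the counter
    assert not early_stop_check([0.5, 0.4, 0.4, 0.6], patience=3)
    with pytest.raises(ValueError):
        early_stop_check([], patience=1)


@pytest.fixture(scope="module")
def moderate_bundle():
    spec = SyntheticSpec("multiclass", 3, n_train=160, n_val=60, n_test=60,
                         noise_sigma=90.0, seed=17)
    return generate_dataset(spec)


@pytest.fixture(scope="module")
def moderate_pre(moderate_bundle):
    return Preprocessor(moderate_bundle, 28, "dataset")


@pytest.fixture(scope="module")
def probed_teacher(moderate_bundle, moderate_pre):
    cfg = small_train_config(alpha=1.0, epochs=6, seed=17)
    proto = build_student("tiny", moderate_bundle.task, seed=99)
    proto, _ = train_student(proto, moderate_bundle, cfg, preprocess=moderate_pre)
    teacher = build_teacher("tiny", moderate_bundle.task, seed=17,
                            backbone=proto.backbone)
    teacher, history = fit_linear_probe(teacher, moderate_bundle,
                                        small_train_config(epochs=10, seed=17),
                                        moderate_pre)
    return teacher, history


def test_probe_trains_head_only_and_backbone_untouched(probed_teacher,
                                                       moderate_bundle,
                                                       moderate_pre):
    teacher, _ = probed_teacher
    before = teacher.parameter_bytes("backbone")
    t2, _ = fit_linear_probe(teacher, moderate_bundle,
                             small_train_config(epochs=4, seed=3), moderate_pre)
    assert t2.parameter_bytes("backbone") == before


def test_probe_on_separable_data_reaches_high_accuracy(trained_tiny,
                                                       easy_mc4_bundle,
                                                       easy_preprocessor):
    """A tiny teacher whose backbone has seen the easy, well-separated
    problem probes to >= 0.9 validation accuracy."""
    import copy
    pretrained, _ = trained_tiny
    teacher = build_teacher("tiny", easy_mc4_bundle.task, seed=2,
                            backbone=copy.deepcopy(pretrained.backbone))
    teacher, history = fit_linear_probe(teacher, easy_mc4_bundle,
                                        small_train_config(epochs=20, seed=2),
                                        easy_preprocessor)
    assert history.records[history.best_epoch].val_acc >= 0.9


def test_probe_deterministic(moderate_bundle, moderate_pre):
    cfg = small_train_config(epochs=4, seed=5)
    heads = []
    for _ in range(2):
        teacher = build_teacher("tiny", moderate_bundle.task, seed=5)
        teacher, _ = fit_linear_probe(teacher, moderate_bundle, cfg, moderate_pre)
        heads.append((teacher.head.W.value.copy(), teacher.head.b.value.copy()))
    assert np.array_equal(heads[0][0], heads[1][0])
    assert np.array_equal(heads[0][1], heads[1][1])


def test_teacher_frozen_through_distillation(probed_teacher, moderate_bundle,
                                             moderate_pre):
    teacher, _ = probed_teacher
    before = teacher.parameter_bytes("all")
    student = build_student("tiny", moderate_bundle.task, seed=1)
    distill(teacher, student, moderate_bundle,
            small_train_config(epochs=3, seed=1), moderate_pre)
    assert teacher.parameter_bytes("all") == before


def test_alpha_one_reproduces_supervised_run(probed_teacher, moderate_bundle,
                                             moderate_pre):
    """With alpha=1 the distillation term has zero weight: the trajectory
    must match a plain supervised run step for step."""
    teacher, _ = probed_teacher
    cfg = small_train_config(alpha=1.0, epochs=4, seed=7)
    s1 = build_student("tiny", moderate_bundle.task, seed=7)
    s1, h1 = distill(teacher, s1, moderate_bundle, cfg, moderate_pre)
    s2 = build_student("tiny", moderate_bundle.task, seed=7)
    s2, h2 = train_student(s2, moderate_bundle, cfg, preprocess=moderate_pre)
    p1, p2 = s1.named_params(), s2.named_params()
    assert all(np.array_equal(p1[k].value, p2[k].value) for k in p1)
    assert [r.val_auc for r in h1.records] == [r.val_auc for r in h2.records]


def test_alpha_zero_ignores_labels(probed_teacher, moderate_bundle, moderate_pre):
    """At alpha=0 the hard term has zero weight, so shuffling the training
    labels cannot change the learned parameters."""
    teacher, _ = probed_teacher
    cfg = small_train_config(alpha=0.0, epochs=3, seed=9)
    s1 = build_student("tiny", moderate_bundle.task, seed=9)
    s1, _ = distill(teacher, s1, moderate_bundle, cfg, moderate_pre)

    shuffled = moderate_bundle
    rng = np.random.default_rng(0)
    shuffled = replace(shuffled,
                       train_labels=rng.permutation(shuffled.train_labels))
    s2 = build_student("tiny", moderate_bundle.task, seed=9)
    s2, _ = distill(teacher, s2, shuffled, cfg, moderate_pre)
    p1, p2 = s1.named_params(), s2.named_params()
    assert all(np.array_equal(p1[k].value, p2[k].value) for k in p1)


def test_seed_determinism_and_loss_accounting(probed_teacher, moderate_bundle,
                                              moderate_pre):
    teacher, _ = probed_teacher
    cfg = small_train_config(alpha=0.3, epochs=3, seed=21)
    runs = []
    for _ in range(2):
        s = build_student("tiny", moderate_bundle.task, seed=21)
        s, h = distill(teacher, s, moderate_bundle, cfg, moderate_pre)
        runs.append((s, h))
    (s1, h1), (s2, h2) = runs
    p1, p2 = s1.named_params(), s2.named_params()
    assert all(np.array_equal(p1[k].value, p2[k].value) for k in p1)
    for r1, r2 in zip(h1.records, h2.records):
        assert vars(r1) == vars(r2)
    for r in h1.records:
        assert r.lr == lr_at_epoch(cfg, r.epoch)
        assert r.total == pytest.approx(cfg.alpha * r.hard + cfg.beta * r.distill,
                                        abs=1e-6)


def test_task_mismatch_rejected(probed_teacher, moderate_pre):
    teacher, _ = probed_teacher
    other = generate_dataset(SyntheticSpec("multiclass", 5, n_train=20, n_val=10,
                                           n_test=10, seed=2))
    student = build_student("tiny", other.task, seed=0)
    with pytest.raises(ValueError, match="task"):
        distill(teacher, student, other, small_train_config(epochs=2), moderate_pre)


def test_early_stopping_terminates_run(moderate_bundle, moderate_pre):
    cfg = small_train_config(alpha=1.0, epochs=8, patience=2, seed=31)
    s = build_student("tiny", moderate_bundle.task, seed=31)
    s, h = train_student(s, moderate_bundle, cfg, preprocess=moderate_pre)
    assert len(h.records) <= cfg.epochs
    if "early stop" in h.stop_reason:
        best = h.best_epoch
        assert len(h.records) - 1 - best >= cfg.patience
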