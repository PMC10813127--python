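"""Trainer: schedule anchors, determinism, reductions, teacher immutability."""

import numpy as np
import pytest
from sklearn.base import clone

from dspkd.backbones import build_backbone, shufflenet_v2_parameter_count
from dspkd.engine import Linear
from dspkd.trainer import (DistilledStudentClassifier, TinyCNNClassifier,
                           TrainSchedule, build_lr_schedule, count_parameters,
                           run_stage1, run_stage2, train_single)


# ---------------------------------------------------------------------------
# learning-rate schedule
# ---------------------------------------------------------------------------

def test_lr_schedule_anchor_points():
    s = TrainSchedule()  # 120 epochs, 20 warm-up, 0.001 -> 1e-5
    assert build_lr_schedule(s.warmup_epochs, s) == pytest.approx(0.001)
    assert build_lr_schedule(s.total_epochs - 1, s) == pytest.approx(1e-5)
    assert build_lr_schedule(0, s) == pytest.approx(s.lr_min)
    # cosine midpoint: with an even post-warmup span the middle epoch sits
    # exactly at (lr_init + lr_min) / 2
    s = TrainSchedule(total_epochs=11, warmup_epochs=2, lr_init=0.01, lr_min=0.001,
                      stage1_epochs=5)
    assert build_lr_schedule(6, s) == pytest.approx((0.01 + 0.001) / 2)
    with pytest.raises(ValueError):
        build_lr_schedule(11, s)
    with pytest.raises(ValueError):
        build_lr_schedule(-1, s)


def test_lr_schedule_monotone_after_warmup():
    s = TrainSchedule(total_epochs=30, warmup_epochs=5, stage1_epochs=10)
    lrs = [build_lr_schedule(e, s) for e in range(30)]
    assert all(a <= b + 1e-15 for a, b in zip(lrs[:5], lrs[1:6]))   # warm-up rises
    assert all(a >= b - 1e-15 for a, b in zip(lrs[5:-1], lrs[6:]))  # cosine falls


def test_schedule_validation():
    with pytest.raises(ValueError):
        TrainSchedule(total_epochs=10, warmup_epochs=10)
    with pytest.raises(ValueError):
        TrainSchedule(total_epochs=10, warmup_epochs=2, stage1_epochs=10)
    with pytest.raises(ValueError):
        TrainSchedule(lr_init=-1.0)


# ---------------------------------------------------------------------------
# parameter counting
# ---------------------------------------------------------------------------

def test_count_parameters_examples():
    assert count_parameters(Linear(10, 5)) == 55
    assert count_parameters(build_backbone("tiny-student", n_classes=6)) == 15774
    with pytest.raises(TypeError):
        count_parameters("not a model")


def test_shufflenet_v2_published_counts():
    # the widely published 1000-class total for the 1.0x multiplier
    assert shufflenet_v2_parameter_count("1.0x", 1000) == 2_278_604
    assert round(shufflenet_v2_parameter_count("1.0x", 8) / 1e6, 3) == 1.262


# ---------------------------------------------------------------------------
# training loops
# ---------------------------------------------------------------------------

def _fast_kwargs(**kw):
    base = dict(warmup_epochs=1, lr=0.05, lr_min=1e-4, batch_size=32, random_state=0)
    base.update(kw)
    return base


@pytest.fixture(scope="module")
def toy_teacher(easy_two_class):
    x, y = easy_two_class
    return TinyCNNClassifier(arch="tiny-teacher", epochs=6,
                             **_fast_kwargs(random_state=1)).fit(x, y)


def test_zero_epochs_returns_initial_weights(easy_two_class):
    x, y = easy_two_class
    model = build_backbone("tiny-student", n_classes=2, seed=0)
    before = model.state_bytes()
    history = train_single(model, (x, y), TrainSchedule(total_epochs=0, warmup_epochs=0,
                                                        stage1_epochs=0))
    assert model.state_bytes() == before
    assert history.empty


def test_separable_toy_reaches_high_training_accuracy(easy_two_class):
    x, y = easy_two_class
    clf = TinyCNNClassifier(arch="tiny-student", epochs=20, **_fast_kwargs()).fit(x, y)
    assert (clf.predict(x) == y).mean() >= 0.95


def test_same_seed_gives_identical_runs(easy_two_class):
    x, y = easy_two_class
    a = TinyCNNClassifier(arch="tiny-student", epochs=3, **_fast_kwargs()).fit(x, y)
    b = TinyCNNClassifier(arch="tiny-student", epochs=3, **_fast_kwargs()).fit(x, y)
    assert a.history_.equals(b.history_)
    assert a.model_.state_bytes() == b.model_.state_bytes()


def test_stage1_mode_none_equals_single_model_prefix(easy_two_class, toy_teacher):
    """With no feature objective, stage 1 is plain task training: its history
    must coincide with the first epochs of a same-seed single-model run."""
    from dspkd.trainer import DistillPlan
    x, y = easy_two_class
    s = TrainSchedule(total_epochs=4, warmup_epochs=1, stage1_epochs=2,
                      lr_init=0.05, lr_min=1e-4, seed=5)
    student_a = build_backbone("tiny-student", n_classes=2, seed=5)
    h1 = run_stage1(toy_teacher.model_, student_a, (x, y), DistillPlan(mode="none"), s)
    student_b = build_backbone("tiny-student", n_classes=2, seed=5)
    s_single = TrainSchedule(total_epochs=4, warmup_epochs=1, stage1_epochs=2,
                             lr_init=0.05, lr_min=1e-4, seed=5)
    h2 = train_single(student_b, (x, y), s_single)
    assert np.allclose(h1[["lr", "task"]], h2[["lr", "task"]].iloc[:2])


def test_dsp_with_zero_stage1_equals_nkd_only(easy_two_class, toy_teacher):
    x, y = easy_two_class
    kwargs = dict(total_epochs=3, stage1_epochs=0, **_fast_kwargs(random_state=3))
    a = DistilledStudentClassifier(teacher=toy_teacher, mode="dsp", **kwargs).fit(x, y)
    b = DistilledStudentClassifier(teacher=toy_teacher, mode="nkd", **kwargs).fit(x, y)
    assert a.history_.equals(b.history_)
    assert a.model_.state_bytes() == b.model_.state_bytes()


def test_vkd_and_nkd_share_stage1_but_differ_in_stage2(easy_two_class, toy_teacher):
    x, y = easy_two_class
    kwargs = dict(total_epochs=3, stage1_epochs=1, **_fast_kwargs(random_state=2))
    a = DistilledStudentClassifier(teacher=toy_teacher, mode="vkd", **kwargs).fit(x, y)
    b = DistilledStudentClassifier(teacher=toy_teacher, mode="nkd", **kwargs).fit(x, y)
    assert a.history_.iloc[0][["task", "lr"]].equals(b.history_.iloc[0][["task", "lr"]])
    assert not np.allclose(a.history_["kd"].iloc[1:], b.history_["kd"].iloc[1:])


def test_stage1_loss_history_decreases(easy_two_class, toy_teacher):
    from dspkd.trainer import DistillPlan
    x, y = easy_two_class
    s = TrainSchedule(total_epochs=5, warmup_epochs=1, stage1_epochs=4,
                      lr_init=0.05, lr_min=1e-4, seed=0)
    student = build_backbone("tiny-student", n_classes=2, seed=0)
    h = run_stage1(toy_teacher.model_, student, (x, y), DistillPlan(mode="dsp"), s)
    drops = sum(h["total"].iloc[i + 1] < h["total"].iloc[i] for i in range(3))
    assert drops >= 2


def test_stage2_distillation_term_zero_for_identical_logits(easy_two_class, toy_teacher):
    """A student that equals the teacher at the start has zero distillation
    loss on the first recorded step."""
    from dspkd.logitdistill import normkd_loss
    x, y = easy_two_class
    from dspkd.trainer import to_tensor
    logits = toy_teacher.model_.predict_logits(to_tensor(x))
    assert normkd_loss(logits, logits) == 0.0


def test_teacher_frozen_through_distillation(easy_two_class, toy_teacher):
    x, y = easy_two_class
    before = toy_teacher.model_.state_bytes()
    DistilledStudentClassifier(teacher=toy_teacher, mode="dsp", total_epochs=2,
                               stage1_epochs=1, **_fast_kwargs()).fit(x, y)
    assert toy_teacher.model_.state_bytes() == before


def test_estimators_are_sklearn_clonable():
    est = DistilledStudentClassifier(mode="mgd_hf", alpha=0.5, t_norm=3.0)
    params = est.get_params()
    assert params["alpha"] == 0.5 and params["t_norm"] == 3.0
    cloned = clone(est)
    assert cloned.get_params() == params
    est2 = clone(TinyCNNClassifier(arch="tiny-teacher", epochs=7))
    assert est2.epochs == 7


@pytest.mark.parametrize("mode", ["mgd", "mgd_hf", "mgd_hf_vkd"])
def test_ablation_modes_run_and_report_components(easy_two_class, toy_teacher, mode):
    x, y = easy_two_class
    clf = DistilledStudentClassifier(teacher=toy_teacher, mode=mode, total_epochs=2,
                                     stage1_epochs=1, **_fast_kwargs()).fit(x, y)
    assert len(clf.history_) == 2
    stage1 = clf.history_.iloc[0]
    assert stage1["reconstruction"] > 0 and stage1["orig"] > 0
    assert set(clf.predict(x)) <= set(clf.classes_)


def test_learnable_alpha_shrinks_under_pure_descent(easy_two_class, toy_teacher):
    """With d(loss)/d(alpha) = reconstruction >= 0, an unregularized learnable
    alpha can only decrease — the documented degenerate behavior."""
    x, y = easy_two_class
    clf = DistilledStudentClassifier(teacher=toy_teacher, mode="dsp", total_epochs=2,
                                     stage1_epochs=1, alpha=1.0, alpha_learnable=True,
                                     **_fast_kwargs()).fit(x, y)
    r_learn = clf.history_.iloc[0]["reconstruction"]
    fixed = DistilledStudentClassifier(teacher=toy_teacher, mode="dsp", total_epochs=2,
                                       stage1_epochs=1, alpha=1.0,
                                       **_fast_kwargs()).fit(x, y)
    assert r_learn <= fixed.history_.iloc[0]["reconstruction"] + 1e-9
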