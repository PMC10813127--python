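"""Dual-stage progressive distillation training.

Stage 1: the student reconstructs the (frozen) teacher's deepest feature
map from an attention-masked view of its own adapted features, alongside
the task cross-entropy.  Stage 2: the same student, carrying its Stage-1
weights, distills the teacher's per-sample normalized logits.  Ablation
modes swap either stage for its baseline (random-mask reconstruction,
vanilla soft labels) or for plain task training, mirroring the standard
ablation lattice of the method.

The public surface is a pair of scikit-learn-style estimators
(:class:`TinyCNNClassifier`, :class:`DistilledStudentClassifier`) plus
procedure-level functions (:func:`train_single`, :func:`run_stage1`,
:func:`run_stage2`, :func:`run_dsp`) over the same internals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import softmax
from sklearn.base import BaseEstimator, ClassifierMixin

from . import featdistill as fd
from . import logitdistill as ld
from .backbones import TinyCNN, build_backbone
from .engine import Module, SGD
from .evalmetrics import evaluate_predictions

__all__ = ["TrainSchedule", "DistillPlan", "build_lr_schedule", "train_single",
           "run_stage1", "run_stage2", "run_dsp", "count_parameters",
           "TinyCNNClassifier", "DistilledStudentClassifier", "to_tensor"]

#: ablation modes -> (stage-1 objective, stage-2 objective)
MODES = {
    "none": ("ce", "ce"),
    "mgd": ("mgd", "ce"),
    "mgd_hf": ("hf", "ce"),
    "vkd": ("ce", "vkd"),
    "nkd": ("ce", "nkd"),
    "mgd_hf_vkd": ("hf", "vkd"),
    "dsp": ("hf", "nkd"),
}


@dataclass
class TrainSchedule:
    """Optimizer schedule: linear warm-up then cosine annealing.

    Defaults follow the convention for full-scale dermatoscopy training
    (120 distillation epochs, 20 warm-up epochs, SGD 0.001 with momentum
    0.9 and weight decay 5e-4, cosine floor 1e-5); CPU-scale benchmark runs
    use the shorter, hotter schedule defined in :mod:`dspkd.benchmark`.
    """

    total_epochs: int = 120
    warmup_epochs: int = 20
    lr_init: float = 0.001
    lr_min: float = 1e-5
    momentum: float = 0.9
    weight_decay: float = 0.0005
    stage1_epochs: int | None = None  # default: half the total
    batch_size: int = 32
    seed: int = 0
    warmup_direction: str = "up"  # "up": ramp to lr_init; "down": anneal from lr_init

    def __post_init__(self):
        if self.total_epochs < 0 or self.warmup_epochs < 0:
            raise ValueError("epoch counts must be non-negative")
        if self.total_epochs > 0 and not self.warmup_epochs < self.total_epochs:
            raise ValueError("warmup_epochs must be < total_epochs")
        if self.stage1_epochs is None:
            self.stage1_epochs = self.total_epochs // 2
        if self.total_epochs > 0 and self.stage1_epochs >= self.total_epochs:
            raise ValueError("stage1_epochs must be < total_epochs")
        if min(self.lr_init, self.lr_min) <= 0:
            raise ValueError("learning rates must be positive")


def build_lr_schedule(epoch: int, s: TrainSchedule) -> float:
    """Learning rate at ``epoch``: linear warm-up to ``lr_init`` over the
    first ``warmup_epochs``, then half-cosine decay down to ``lr_min`` at
    the final epoch."""
    if not 0 <= epoch < s.total_epochs:
        raise ValueError(f"epoch {epoch} outside [0, {s.total_epochs})")
    if epoch < s.warmup_epochs:
        frac = epoch / s.warmup_epochs
        if s.warmup_direction == "up":
            return s.lr_min + (s.lr_init - s.lr_min) * frac
        return s.lr_init - (s.lr_init - s.lr_min) * frac
    span = max(s.total_epochs - 1 - s.warmup_epochs, 1)
    t = (epoch - s.warmup_epochs) / span
    return s.lr_min + 0.5 * (s.lr_init - s.lr_min) * (1.0 + math.cos(math.pi * t))


@dataclass
class DistillPlan:
    """What to distill and how, for both stages."""

    mode: str = "dsp"
    stage1: fd.Stage1Config = field(default_factory=fd.Stage1Config)
    stage2: ld.NormKDConfig = field(default_factory=ld.NormKDConfig)
    teacher_id: str = "tiny-teacher"
    student_id: str = "tiny-student"
    vkd_temperature: float = 4.0
    lambda_kd: float = 1.0
    mgd_mask_prob: float = 0.5

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {sorted(MODES)}")


def count_parameters(model) -> int:
    """Total learnable parameter elements of an engine module."""
    if isinstance(model, Module):
        return model.num_parameters()
    if isinstance(model, TinyCNN):
        return model.num_parameters()
    raise TypeError("count_parameters expects an engine Module")


# ---------------------------------------------------------------------------
# Data plumbing
# ---------------------------------------------------------------------------

def to_tensor(images: np.ndarray) -> np.ndarray:
    """uint8 (N, H, W, 3) images -> standardized float32 (N, 3, H, W)."""
    x = np.asarray(images)
    if x.ndim != 4:
        raise ValueError("expected a batch of images")
    if x.shape[-1] == 3 and x.shape[1] != 3:
        x = x.transpose(0, 3, 1, 2)
    x = x.astype(np.float32)
    if x.max() > 1.5:  # uint8 scale
        x = x / 255.0
    return (x - 0.5) / 0.25


def _softmax_ce(logits: np.ndarray, y: np.ndarray):
    """Mean cross-entropy and its gradient w.r.t. the logits."""
    p = softmax(logits.astype(np.float64), axis=1)
    n = logits.shape[0]
    loss = float(-np.log(np.clip(p[np.arange(n), y], 1e-12, None)).mean())
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    return loss, (grad / n).astype(np.float32)


def _epoch_batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start:start + batch_size]


def _accuracy(model: TinyCNN, x: np.ndarray, y: np.ndarray) -> float:
    pred = model.predict_logits(x).argmax(axis=1)
    return float((pred == y).mean())


def _avgpool_to(a: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Block-average a 2-D map down to ``shape`` (sizes divide evenly)."""
    h, w = a.shape
    th, tw = shape
    fh, fw = h // th, w // tw
    return a[: th * fh, : tw * fw].reshape(th, fh, tw, fw).mean(axis=(1, 3))


# ---------------------------------------------------------------------------
# Teacher-side caches (the teacher is frozen, so its features, attention
# masks and logits over a fixed training set are computed once per run)
# ---------------------------------------------------------------------------

def _teacher_cache(teacher: TinyCNN, x: np.ndarray, levels: tuple[int, ...],
                   cfg: fd.Stage1Config, need_masks: bool, batch_size: int = 128):
    feats = {lvl: [] for lvl in levels}
    masks = {lvl: [] for lvl in levels}
    logits_all = []
    for start in range(0, len(x), batch_size):
        logits, taps = teacher.forward_with_taps(x[start:start + batch_size], train=False)
        logits_all.append(logits)
        for lvl in levels:
            feats[lvl].append(taps[lvl - 1])
        if need_masks:
            for i in range(taps[0].shape[0]):
                att = fd.hf_fuse([fd.level_attention(t[i]) for t in taps],
                                 list(cfg.fusion_weights) if cfg.fusion_weights else None)
                for lvl in levels:
                    target = taps[lvl - 1].shape[2:]
                    att_lvl = _avgpool_to(att, target) if att.shape != target else att
                    masks[lvl].append(fd.guided_mask(att_lvl, cfg))
    out_feats = {lvl: np.concatenate(v) for lvl, v in feats.items()}
    out_masks = {lvl: np.stack(v).astype(np.float32) for lvl, v in masks.items()} \
        if need_masks else None
    return out_feats, out_masks, np.concatenate(logits_all)


def _teacher_fingerprint(teacher: TinyCNN) -> bytes:
    return teacher.state_bytes()


# ---------------------------------------------------------------------------
# Training loops
# ---------------------------------------------------------------------------

def _make_schedule_slice(s: TrainSchedule, start: int, n_epochs: int) -> list[float]:
    return [build_lr_schedule(e, s) for e in range(start, start + n_epochs)]


def _train_ce(model: TinyCNN, data, lrs: list[float], s: TrainSchedule,
              rng: np.random.Generator, history: list[dict], epoch_offset: int = 0,
              kd=None) -> None:
    """Shared epoch loop: cross-entropy plus an optional logit-KD term.

    ``kd`` is ``None`` or ``(kind, teacher_logits, plan)`` with kind in
    {"vkd", "nkd"}.
    """
    x, y, xv, yv = data
    opt = SGD(model.parameters(), momentum=s.momentum, weight_decay=s.weight_decay)
    for e, lr in enumerate(lrs):
        opt.lr = lr
        ce_sum = kd_sum = 0.0
        n_batches = 0
        for idx in _epoch_batches(len(x), s.batch_size, rng):
            logits, _ = model.forward_with_taps(x[idx], train=True)
            ce, dlogits = _softmax_ce(logits, y[idx])
            if kd is not None:
                kind, t_logits, plan = kd
                if kind == "vkd":
                    kd_loss = ld.vanilla_kd_loss(logits, t_logits[idx], plan.vkd_temperature)
                    dkd = ld.vanilla_kd_grad(logits, t_logits[idx], plan.vkd_temperature)
                else:
                    kd_loss = ld.normkd_loss(logits, t_logits[idx], plan.stage2)
                    dkd = ld.normkd_grad(logits, t_logits[idx], plan.stage2)
                dlogits = dlogits + plan.lambda_kd * dkd.astype(np.float32)
                kd_sum += kd_loss
            model.zero_grad()
            model.backward(dlogits)
            opt.step()
            ce_sum += ce
            n_batches += 1
        rec = {"epoch": epoch_offset + e, "lr": lr, "task": ce_sum / n_batches,
               "kd": kd_sum / n_batches, "orig": 0.0, "reconstruction": 0.0}
        rec["total"] = rec["task"] + rec["kd"]
        rec["val_acc"] = _accuracy(model, xv, yv) if xv is not None else float("nan")
        history.append(rec)


def _train_stage1_feature(student: TinyCNN, teacher: TinyCNN, data, lrs, s: TrainSchedule,
                          plan: DistillPlan, objective: str,
                          rng: np.random.Generator, history: list[dict]) -> None:
    """Stage-1 loop: cross-entropy + masked generative feature reconstruction."""
    x, y, xv, yv = data
    cfg = plan.stage1
    levels = tuple(cfg.distill_levels)
    t_feats, t_masks, _ = _teacher_cache(teacher, x, levels, cfg,
                                         need_masks=(objective == "hf"))
    activation = "gelu" if objective == "hf" else "relu"
    adapters: dict[int, fd.FeatureAdapter] = {}
    blocks: dict[int, fd.GenerationBlock] = {}
    params = list(student.parameters())
    for lvl in levels:
        c_s = student.channels[lvl - 1]
        c_t = teacher.channels[lvl - 1]
        adapters[lvl] = fd.FeatureAdapter(fd.AdapterConfig(c_s, c_t),
                                          seed=int(rng.integers(2 ** 31)))
        blocks[lvl] = fd.GenerationBlock(c_t, activation=activation,
                                         seed=int(rng.integers(2 ** 31)))
        params += adapters[lvl].parameters() + blocks[lvl].parameters()
    from .engine import Parameter
    alpha_param = Parameter(np.array([cfg.alpha], dtype=np.float32))
    if cfg.alpha_learnable:
        params.append(alpha_param)
    opt = SGD(params, momentum=s.momentum, weight_decay=s.weight_decay)

    for e, lr in enumerate(lrs):
        opt.lr = lr
        sums = {"task": 0.0, "orig": 0.0, "reconstruction": 0.0}
        n_batches = 0
        for idx in _epoch_batches(len(x), s.batch_size, rng):
            opt.zero_grad()
            logits, taps = student.forward_with_taps(x[idx], train=True)
            ce, dlogits = _softmax_ce(logits, y[idx])
            dtaps: list[np.ndarray | None] = [None] * 4
            for lvl in levels:
                f_t = t_feats[lvl][idx]
                f_s = taps[lvl - 1]
                n_b = f_s.shape[0]
                # feature losses are averaged per element and per sample to
                # keep their gradient scale commensurate with cross-entropy
                scale = np.float32(1.0 / (f_t.shape[1] * f_t.shape[2] * f_t.shape[3] * n_b))
                f_sa = adapters[lvl].forward(f_s, train=True)
                if objective == "hf":
                    m = t_masks[lvl][idx][:, None, :, :]
                else:
                    m = np.stack([fd.random_mask(f_s.shape[2], f_s.shape[3],
                                                 plan.mgd_mask_prob,
                                                 int(rng.integers(2 ** 31)))
                                  for _ in range(n_b)])[:, None, :, :]
                masked = f_sa * m
                g = blocks[lvl].forward(masked, train=True)
                diff_recon = g - f_t
                diff_orig = f_sa - f_t
                alpha = max(float(alpha_param.value[0]), 0.0)  # clamp if learnable
                recon_raw = float(np.sum(diff_recon ** 2) * scale)
                sums["reconstruction"] += alpha * recon_raw
                sums["orig"] += float(np.sum(diff_orig ** 2) * scale)
                if cfg.alpha_learnable:
                    alpha_param.grad += np.float32(recon_raw)
                dg = (2.0 * alpha * scale) * diff_recon
                d_masked = blocks[lvl].backward(dg.astype(np.float32))
                d_fsa = d_masked * m + (2.0 * scale) * diff_orig
                dtaps[lvl - 1] = adapters[lvl].backward(d_fsa.astype(np.float32))
            student.backward(dlogits, dtaps)
            opt.step()
            sums["task"] += ce
            n_batches += 1
        rec = {"epoch": e, "lr": lr, **{k: v / n_batches for k, v in sums.items()},
               "kd": 0.0}
        rec["total"] = rec["task"] + rec["orig"] + rec["reconstruction"]
        rec["val_acc"] = _accuracy(student, xv, yv) if xv is not None else float("nan")
        history.append(rec)


def _prepare_data(x, y, x_val=None, y_val=None):
    x = to_tensor(x)
    y = np.asarray(y, dtype=np.int64)
    xv = to_tensor(x_val) if x_val is not None else None
    yv = np.asarray(y_val, dtype=np.int64) if y_val is not None else None
    return x, y, xv, yv


def train_single(model: TinyCNN, data, s: TrainSchedule) -> pd.DataFrame:
    """Plain task training (teachers and no-distillation baselines).

    ``data`` is ``(X, y)`` or ``(X, y, X_val, y_val)``; returns the history
    DataFrame (epoch, lr, loss components, val_acc).  Zero epochs returns
    the model untouched.
    """
    data = _prepare_data(*data)
    history: list[dict] = []
    rng = np.random.default_rng(s.seed)
    lrs = _make_schedule_slice(s, 0, s.total_epochs)
    _train_ce(model, data, lrs, s, rng, history)
    return pd.DataFrame(history)


def run_stage1(teacher: TinyCNN, student: TinyCNN, data, plan: DistillPlan,
               s: TrainSchedule) -> pd.DataFrame:
    """Stage-1 training for ``s.stage1_epochs`` epochs.

    The stage objective follows ``plan.mode``: attention-guided masked
    reconstruction (hf modes), random-mask reconstruction (mgd), or plain
    cross-entropy (logit-only and baseline modes).  The teacher is never
    updated; this is asserted on its serialized state.
    """
    obj1, _ = MODES[plan.mode]
    data = _prepare_data(*data)
    fingerprint = _teacher_fingerprint(teacher)
    history: list[dict] = []
    rng = np.random.default_rng(s.seed)
    lrs = _make_schedule_slice(s, 0, s.stage1_epochs)
    if obj1 == "ce":
        _train_ce(student, data, lrs, s, rng, history)
    else:
        _train_stage1_feature(student, teacher, data, lrs, s, plan, obj1, rng, history)
    if _teacher_fingerprint(teacher) != fingerprint:
        raise RuntimeError("teacher parameters changed during stage 1")
    return pd.DataFrame(history)


def run_stage2(teacher: TinyCNN, student: TinyCNN, data, plan: DistillPlan,
               s: TrainSchedule) -> pd.DataFrame:
    """Stage-2 training for the remaining epochs.

    Cross-entropy plus the mode's logit-distillation term (normalized or
    vanilla soft labels) against the frozen teacher's cached logits.
    """
    _, obj2 = MODES[plan.mode]
    data = _prepare_data(*data)
    fingerprint = _teacher_fingerprint(teacher)
    history: list[dict] = []
    rng = np.random.default_rng(s.seed + 1)
    n_epochs = s.total_epochs - s.stage1_epochs
    lrs = _make_schedule_slice(s, s.stage1_epochs, n_epochs)
    kd = None
    if obj2 != "ce":
        t_logits = teacher.predict_logits(data[0])
        kd = ("vkd" if obj2 == "vkd" else "nkd", t_logits, plan)
    _train_ce(student, data, lrs, s, rng, history, epoch_offset=s.stage1_epochs, kd=kd)
    if _teacher_fingerprint(teacher) != fingerprint:
        raise RuntimeError("teacher parameters changed during stage 2")
    return pd.DataFrame(history)


def run_dsp(teacher: TinyCNN, student: TinyCNN, data, plan: DistillPlan,
            s: TrainSchedule):
    """Full dual-stage run: stage 1 then stage 2 with the same teacher.

    Returns ``(history, report)`` where ``report`` is the final metrics
    evaluation on the held-out split (or the training split when no
    held-out data is given).
    """
    h1 = run_stage1(teacher, student, data, plan, s)
    h2 = run_stage2(teacher, student, data, plan, s)
    history = pd.concat([h1, h2], ignore_index=True)
    x, y, xv, yv = _prepare_data(*data)
    x_eval, y_eval = (xv, yv) if xv is not None else (x, y)
    pred = student.predict_logits(x_eval).argmax(axis=1)
    report = evaluate_predictions(y_eval, pred, n_classes=student.n_classes)
    return history, report


# ---------------------------------------------------------------------------
# scikit-learn estimators
# ---------------------------------------------------------------------------

class _ImageClassifierBase(ClassifierMixin, BaseEstimator):
    """Shared prediction plumbing for image classifiers over engine models."""

    def predict_logits(self, X) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise AttributeError("estimator is not fitted yet")
        return self.model_.predict_logits(to_tensor(X))

    def predict_proba(self, X) -> np.ndarray:
        return softmax(self.predict_logits(X), axis=1)

    def predict(self, X) -> np.ndarray:
        return self.classes_[self.predict_logits(X).argmax(axis=1)]

    def _encode(self, y):
        self.classes_, encoded = np.unique(y, return_inverse=True)
        return encoded.astype(np.int64)


class TinyCNNClassifier(_ImageClassifierBase):
    """Single-model image classifier (teachers and no-distillation baselines).

    Parameters mirror the SGD schedule: linear warm-up to ``lr`` then
    cosine annealing to ``lr_min``.  ``X`` is a batch of RGB images,
    ``(N, H, W, 3)`` uint8 or ``(N, 3, H, W)`` float.
    """

    def __init__(self, arch: str = "tiny-student", epochs: int = 20,
                 warmup_epochs: int = 2, lr: float = 0.05, lr_min: float = 1e-4,
                 momentum: float = 0.9, weight_decay: float = 5e-4,
                 batch_size: int = 32, random_state: int = 0):
        self.arch = arch
        self.epochs = epochs
        self.warmup_epochs = warmup_epochs
        self.lr = lr
        self.lr_min = lr_min
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.batch_size = batch_size
        self.random_state = random_state

    def _schedule(self, total: int, stage1: int | None = None) -> TrainSchedule:
        return TrainSchedule(total_epochs=total, warmup_epochs=self.warmup_epochs,
                             lr_init=self.lr, lr_min=self.lr_min,
                             momentum=self.momentum, weight_decay=self.weight_decay,
                             stage1_epochs=stage1, batch_size=self.batch_size,
                             seed=self.random_state)

    def fit(self, X, y, X_val=None, y_val=None):
        encoded = self._encode(y)
        self.model_ = build_backbone(self.arch, n_classes=len(self.classes_),
                                     seed=self.random_state)
        self.history_ = train_single(self.model_, (X, encoded, X_val, y_val),
                                     self._schedule(self.epochs))
        self.n_parameters_ = self.model_.num_parameters()
        return self


class DistilledStudentClassifier(_ImageClassifierBase):
    """Student classifier trained by dual-stage progressive distillation.

    ``teacher`` is a fitted :class:`TinyCNNClassifier` (or a raw backbone);
    it is frozen throughout.  ``mode`` selects the ablation variant:
    ``dsp`` (attention-masked feature reconstruction then normalized logit
    distillation), ``mgd``/``mgd_hf`` (feature-stage only variants),
    ``vkd``/``nkd`` (logit-stage only), ``mgd_hf_vkd``, or ``none`` (plain
    task training of the student).
    """

    def __init__(self, teacher=None, mode: str = "dsp",
                 student_arch: str = "tiny-student", total_epochs: int = 40,
                 stage1_epochs: int = 20, warmup_epochs: int = 2,
                 lr: float = 0.05, lr_min: float = 1e-4, momentum: float = 0.9,
                 weight_decay: float = 5e-4, batch_size: int = 32,
                 alpha: float = 1.0, alpha_learnable: bool = False,
                 mask_mode: str = "ratio",
                 mask_ratio: float = 0.5, t_norm: float = 2.0,
                 lambda_kd: float = 1.0, vkd_temperature: float = 4.0,
                 random_state: int = 0):
        self.teacher = teacher
        self.mode = mode
        self.student_arch = student_arch
        self.total_epochs = total_epochs
        self.stage1_epochs = stage1_epochs
        self.warmup_epochs = warmup_epochs
        self.lr = lr
        self.lr_min = lr_min
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.batch_size = batch_size
        self.alpha = alpha
        self.alpha_learnable = alpha_learnable
        self.mask_mode = mask_mode
        self.mask_ratio = mask_ratio
        self.t_norm = t_norm
        self.lambda_kd = lambda_kd
        self.vkd_temperature = vkd_temperature
        self.random_state = random_state

    def _teacher_model(self) -> TinyCNN:
        if isinstance(self.teacher, TinyCNN):
            return self.teacher
        if hasattr(self.teacher, "model_"):
            return self.teacher.model_
        raise ValueError("teacher must be a fitted classifier or a TinyCNN")

    def fit(self, X, y, X_val=None, y_val=None):
        encoded = self._encode(y)
        schedule = TrainSchedule(
            total_epochs=self.total_epochs, warmup_epochs=self.warmup_epochs,
            lr_init=self.lr, lr_min=self.lr_min, momentum=self.momentum,
            weight_decay=self.weight_decay, stage1_epochs=self.stage1_epochs,
            batch_size=self.batch_size, seed=self.random_state)
        plan = DistillPlan(
            mode=self.mode,
            stage1=fd.Stage1Config(alpha=self.alpha, mask_mode=self.mask_mode,
                                   phi_or_ratio=self.mask_ratio,
                                   alpha_learnable=self.alpha_learnable),
            stage2=ld.NormKDConfig(t_norm=self.t_norm),
            student_id=self.student_arch,
            lambda_kd=self.lambda_kd, vkd_temperature=self.vkd_temperature)
        self.model_ = build_backbone(self.student_arch, n_classes=len(self.classes_),
                                     seed=self.random_state)
        data = (X, encoded, X_val, y_val)
        if self.mode == "none":
            self.history_ = train_single(self.model_, data, schedule)
            self.report_ = None
        else:
            teacher = self._teacher_model()
            self.history_, self.report_ = run_dsp(teacher, self.model_, data,
                                                  plan, schedule)
        self.n_parameters_ = self.model_.num_parameters()
        return self
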