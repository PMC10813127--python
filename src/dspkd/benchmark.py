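"""The packaged CPU-scale synthetic distillation benchmark.

Study conditions: six lesion classes, 200 images per class at 64 x 64, an
8:2 stratified split, a tiny-teacher trained for 20 epochs, and students
trained for a 20 + 20 epoch dual-stage budget (the no-distillation baseline
gets the same 40-epoch budget).  Distilled-vs-baseline comparisons average
over three student training seeds.

Optimizer conditions for this short CPU schedule are SGD with momentum 0.9,
weight decay 5e-4, batch 32, linear warm-up over 2 epochs to lr 0.05 and
cosine annealing to 1e-4.
"""

from __future__ import annotations

import numpy as np
from sklearn.model_selection import train_test_split

from .synthdata import SynthSpec, generate_dataset
from .trainer import DistilledStudentClassifier, TinyCNNClassifier

__all__ = ["BENCHMARK", "make_benchmark_data", "train_benchmark_teacher",
           "run_benchmark"]

BENCHMARK = {
    "n_classes": 6,
    "images_per_class": 200,
    "side": 64,
    "teacher_epochs": 20,
    "stage1_epochs": 20,
    "stage2_epochs": 20,
    "student_seeds": (1, 2, 3),
    "lr": 0.05,
    "lr_min": 1e-4,
    "warmup_epochs": 2,
    "batch_size": 32,
}


def make_benchmark_data(seed: int = 0, images_per_class: int | None = None):
    """Generate the benchmark dataset and its stratified 8:2 split.

    Returns ``(X_train, y_train, X_test, y_test)`` as uint8 image batches
    and integer labels.
    """
    spec = SynthSpec(n_classes=BENCHMARK["n_classes"],
                     images_per_class=images_per_class or BENCHMARK["images_per_class"],
                     side=BENCHMARK["side"], seed=seed)
    ds = generate_dataset(spec)
    x_tr, x_te, y_tr, y_te = train_test_split(
        ds.images, ds.labels, test_size=0.2, stratify=ds.labels, random_state=seed)
    return x_tr, y_tr, x_te, y_te


def train_benchmark_teacher(data, seed: int = 1, epochs: int | None = None) -> TinyCNNClassifier:
    x_tr, y_tr, x_te, y_te = data
    teacher = TinyCNNClassifier(
        arch="tiny-teacher", epochs=epochs or BENCHMARK["teacher_epochs"],
        warmup_epochs=BENCHMARK["warmup_epochs"], lr=BENCHMARK["lr"],
        lr_min=BENCHMARK["lr_min"], batch_size=BENCHMARK["batch_size"],
        random_state=seed)
    return teacher.fit(x_tr, y_tr, x_te, y_te)


def _student(teacher, mode: str, seed: int) -> DistilledStudentClassifier:
    total = BENCHMARK["stage1_epochs"] + BENCHMARK["stage2_epochs"]
    return DistilledStudentClassifier(
        teacher=teacher, mode=mode, total_epochs=total,
        stage1_epochs=BENCHMARK["stage1_epochs"],
        warmup_epochs=BENCHMARK["warmup_epochs"], lr=BENCHMARK["lr"],
        lr_min=BENCHMARK["lr_min"], batch_size=BENCHMARK["batch_size"],
        random_state=seed)


def run_benchmark(data_seed: int = 0, modes: tuple[str, ...] = ("none", "dsp"),
                  student_seeds: tuple[int, ...] | None = None,
                  images_per_class: int | None = None) -> dict:
    """Full benchmark: teacher + per-seed student runs for each mode.

    Returns a dict with the teacher's training accuracy, per-mode per-seed
    student test accuracies and their means, and a flag confirming the
    teacher's weights were untouched by distillation.
    """
    student_seeds = student_seeds or BENCHMARK["student_seeds"]
    data = make_benchmark_data(data_seed, images_per_class)
    x_tr, y_tr, x_te, y_te = data
    teacher = train_benchmark_teacher(data, seed=student_seeds[0])
    teacher_train_acc = float(
        (teacher.predict(x_tr) == teacher.classes_[y_tr]).mean())
    before = teacher.model_.state_bytes()
    results: dict = {
        "teacher_train_accuracy": teacher_train_acc,
        "teacher_test_accuracy": float(teacher.score(x_te, y_te)),
        "n_train": int(len(x_tr)),
        "n_test": int(len(x_te)),
        "modes": {},
    }
    for mode in modes:
        accs = []
        for seed in student_seeds:
            student = _student(teacher, mode, seed).fit(x_tr, y_tr, x_te, y_te)
            accs.append(float(student.score(x_te, y_te)))
        results["modes"][mode] = {"test_accuracies": accs,
                                  "mean_test_accuracy": float(np.mean(accs))}
    results["teacher_unchanged"] = teacher.model_.state_bytes() == before
    return results
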