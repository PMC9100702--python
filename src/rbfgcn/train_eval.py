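"""Training, 10-fold cross-validation and the ACC/SEN/SPE metrics.

Four staging tasks are supported: three binary contrasts (NC vs AD, NC vs MCI,
MCI vs AD) and the three-way NC vs MCI vs AD. In each binary task the more
severe diagnosis is the "patient" (positive) class; the multiclass task is
scored by accuracy only.

    ACC = (TP + TN) / (TP + FN + TN + FP)
    SEN = TP / (TP + FN)
    SPE = TN / (TN + FP)

Training uses mean negative log-likelihood with Adam, Xavier-normal
initialization and minibatches of 20 subjects; evaluation takes final-epoch
parameters (no validation split or early stopping).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .model import RBFConfig, RBFGCNModel
from .network_data import BrainNetwork, LABEL_TO_INT

__all__ = [
    "TASKS",
    "TaskSpec",
    "TrainConfig",
    "ConfusionCounts",
    "Metrics",
    "TrainingDiverged",
    "filter_task",
    "make_folds",
    "train_model",
    "compute_metrics",
    "cross_validate",
    "CVResult",
]


@dataclass(frozen=True)
class TaskSpec:
    """One classification task over the severity-ordered labels {0,1,2}."""

    name: str
    classes: tuple[int, ...]
    patient_class: int | None  # the positive class for binary tasks

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    @property
    def is_binary(self) -> bool:
        return self.n_classes == 2


TASKS: dict[str, TaskSpec] = {
    "NC_vs_AD": TaskSpec("NC_vs_AD", (0, 2), patient_class=2),
    "NC_vs_MCI": TaskSpec("NC_vs_MCI", (0, 1), patient_class=1),
    "MCI_vs_AD": TaskSpec("MCI_vs_AD", (1, 2), patient_class=2),
    "NC_vs_MCI_vs_AD": TaskSpec("NC_vs_MCI_vs_AD", (0, 1, 2), patient_class=None),
}


@dataclass
class TrainConfig:
    """Optimization hyperparameters (reference defaults)."""

    epochs: int = 500
    learning_rate: float = 1e-3
    batch_size: int = 20
    folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs <= 0 or self.batch_size <= 0 or self.learning_rate < 0:
            raise ValueError("epochs/batch_size must be positive, lr nonnegative")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")


class TrainingDiverged(RuntimeError):
    """Raised when the training loss becomes non-finite."""


def filter_task(
    networks: list[BrainNetwork], task: TaskSpec
) -> tuple[list[BrainNetwork], np.ndarray]:
    """Select the task's classes and map labels to contiguous task indices.

    Binary tasks map healthy -> 0, patient -> 1; the multiclass task keeps the
    severity order NC=0, MCI=1, AD=2.
    """
    keep: list[BrainNetwork] = []
    ys: list[int] = []
    class_to_idx = {c: i for i, c in enumerate(sorted(task.classes))}
    for net in networks:
        if net.label is None:
            continue
        y = LABEL_TO_INT[net.label]
        if y in class_to_idx:
            keep.append(net)
            ys.append(class_to_idx[y])
    return keep, np.asarray(ys, dtype=int)


def make_folds(
    labels: np.ndarray, k: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified k-fold partitions (train_idx, test_idx), deterministic in seed."""
    labels = np.asarray(labels)
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        warnings.warn(
            f"smallest class has {counts.min()} members for k={k} folds; "
            "stratification is best-effort", stacklevel=2,
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in skf.split(np.zeros(len(labels)), labels)]


def train_model(
    networks: list[BrainNetwork],
    labels: np.ndarray,
    model_config: RBFConfig,
    train_config: TrainConfig,
) -> tuple[RBFGCNModel, list[float]]:
    """Fit an RBF-GCN on a labeled cohort; returns the model and per-epoch loss.

    The per-epoch loss is the subject-weighted mean minibatch NLL. A
    non-finite loss aborts with :class:`TrainingDiverged` naming the epoch.
    """
    from .nn import Adam

    labels = np.asarray(labels, dtype=int)
    m, d = networks[0].m, networks[0].d
    model = RBFGCNModel(model_config, m=m, d=d, seed=train_config.seed)
    inputs = model.prepare_inputs(networks)
    optimizer = Adam(lr=train_config.learning_rate)
    rng = np.random.default_rng(train_config.seed)
    n = len(networks)
    trace: list[float] = []
    for epoch in range(train_config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, train_config.batch_size):
            idx = order[start:start + train_config.batch_size]
            loss, grads = model.loss_and_grads(
                RBFGCNModel.take(inputs, idx), labels[idx]
            )
            if not np.isfinite(loss):
                raise TrainingDiverged(
                    f"non-finite loss at epoch {epoch} (batch starting {start})"
                )
            model.set_params(optimizer.step(model.get_params(), grads))
            epoch_loss += loss * len(idx)
        trace.append(epoch_loss / n)
    return model, trace


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion-table counts with the patient class as positive."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_predictions(
        cls, predictions: np.ndarray, labels: np.ndarray
    ) -> "ConfusionCounts":
        predictions = np.asarray(predictions)
        labels = np.asarray(labels)
        return cls(
            tp=int(np.sum((predictions == 1) & (labels == 1))),
            fp=int(np.sum((predictions == 1) & (labels == 0))),
            tn=int(np.sum((predictions == 0) & (labels == 0))),
            fn=int(np.sum((predictions == 0) & (labels == 1))),
        )


@dataclass(frozen=True)
class Metrics:
    """ACC/SEN/SPE; an undefined metric (zero denominator) is None."""

    acc: float | None
    sen: float | None
    spe: float | None


def compute_metrics(counts: ConfusionCounts) -> Metrics:
    """Accuracy, sensitivity and specificity from confusion counts."""
    def ratio(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    return Metrics(
        acc=ratio(counts.tp + counts.tn, counts.total),
        sen=ratio(counts.tp, counts.tp + counts.fn),
        spe=ratio(counts.tn, counts.tn + counts.fp),
    )


@dataclass
class CVResult:
    """Per-fold metrics and their mean +/- sample standard deviation."""

    task: str
    per_fold: list[Metrics] = field(default_factory=list)

    def _column(self, name: str) -> list[float]:
        return [getattr(mx, name) for mx in self.per_fold
                if getattr(mx, name) is not None]

    def mean(self, name: str = "acc") -> float:
        return float(np.mean(self._column(name)))

    def sd(self, name: str = "acc") -> float:
        vals = self._column(name)
        return float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0

    def summary(self) -> dict[str, str]:
        """Formatted ``mean ± sd`` strings in percent, per available metric."""
        out = {}
        for name in ("acc", "sen", "spe"):
            if self._column(name):
                out[name.upper()] = (
                    f"{100 * self.mean(name):.2f} ± {100 * self.sd(name):.2f}"
                )
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"task": self.task, "fold": i, "ACC": mx.acc, "SEN": mx.sen,
             "SPE": mx.spe}
            for i, mx in enumerate(self.per_fold)
        ]
        return pd.DataFrame(rows)


def _gcn_trainer(train_nets, train_labels, model_config, train_config):
    model, _ = train_model(train_nets, train_labels, model_config, train_config)

    def predict(test_nets: list[BrainNetwork]) -> np.ndarray:
        return model.predict(model.prepare_inputs(test_nets))

    return predict


def cross_validate(
    networks: list[BrainNetwork],
    task: TaskSpec | str,
    model_config: RBFConfig | None = None,
    train_config: TrainConfig | None = None,
    trainer=None,
) -> CVResult:
    """Stratified k-fold cross-validation of a classifier on one task.

    ``trainer(train_nets, train_labels, model_config, train_config)`` must
    return a ``predict(test_nets) -> labels`` callable; by default it trains
    an :class:`~rbfgcn.model.RBFGCNModel`. Binary tasks report ACC/SEN/SPE,
    the multiclass task accuracy only.
    """
    if isinstance(task, str):
        task = TASKS[task]
    train_config = train_config or TrainConfig()
    if model_config is None:
        model_config = RBFConfig.from_arm("rbf_gcn_c", n_classes=task.n_classes)
    if model_config.n_classes != task.n_classes:
        raise ValueError(
            f"model predicts {model_config.n_classes} classes, "
            f"task {task.name} has {task.n_classes}"
        )
    trainer = trainer or _gcn_trainer
    nets, ys = filter_task(networks, task)
    folds = make_folds(ys, train_config.folds, train_config.seed)
    result = CVResult(task=task.name)
    for fold_i, (tr, te) in enumerate(folds):
        fold_cfg = TrainConfig(
            epochs=train_config.epochs,
            learning_rate=train_config.learning_rate,
            batch_size=train_config.batch_size,
            folds=train_config.folds,
            seed=int((train_config.seed + 1000003 * (fold_i + 1)) % (2**31)),
        )
        predict = trainer(
            [nets[i] for i in tr], ys[tr], model_config, fold_cfg
        )
        preds = np.asarray(predict([nets[i] for i in te]))
        if task.is_binary:
            counts = ConfusionCounts.from_predictions(preds, ys[te])
            result.per_fold.append(compute_metrics(counts))
        else:
            acc = float(np.mean(preds == ys[te]))
            result.per_fold.append(Metrics(acc=acc, sen=None, spe=None))
    return result
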