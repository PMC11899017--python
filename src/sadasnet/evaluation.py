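"""Fitness evaluation and the final model report.

A candidate genome becomes a fitness value by decoding it, repairing and
budget-checking the architecture, training it under the fixed protocol
(SGD with momentum 0.9, initial learning rate 1e-4 with a piecewise schedule
multiplying by 0.8 every 5 epochs, batch size 32, L2 1e-4, validation
measured every 50 iterations) and scoring

    L = 1 - accuracy

on the fitness split.  Infeasible or diverging candidates receive the
worst-case fitness 1.0 rather than crashing the search.

The final report covers the multiclass confusion matrix, one-vs-rest
precision / recall / specificity / F1 / accuracy per class with macro
averages, one-vs-rest ROC-AUC, and Cohen's kappa.  The fitness split defaults
to the test split, matching the protocol this tool reimplements; note this
leaks test data into the search, so ``fitness_split="validation"`` is the
recommended mode for new studies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import train_test_split

from .architecture import ArchitectureSpec, decode, feasibility_check, repair
from .backend import SGDM, Model, build_model, cross_entropy_loss
from .data import ImageDataset, balance_dataset, balance_plan
from .pso import SwarmConfig, run as pso_run
from .search_space import GenomeLayout

__all__ = [
    "SplitSpec",
    "TrainConfig",
    "Budget",
    "EvalReport",
    "split_dataset",
    "subsample_per_class",
    "train_model",
    "evaluate_model",
    "fitness",
    "confusion_matrix",
    "metrics_from_confusion",
    "roc_auc_ovr",
    "cohen_kappa",
    "two_stage_search",
]

logger = logging.getLogger(__name__)


class TrainingDiverged(RuntimeError):
    pass


@dataclass(frozen=True)
class SplitSpec:
    """80/20 train/test split; 10% of the training pool held out for validation."""

    test_fraction: float = 0.20
    validation_fraction_of_train: float = 0.10
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for f in (self.test_fraction, self.validation_fraction_of_train):
            if not (0 < f < 1):
                raise ValueError("split fractions must lie in (0, 1)")


@dataclass(frozen=True)
class TrainConfig:
    momentum: float = 0.9
    initial_lr: float = 1e-4
    lr_decay: float = 0.8
    lr_step_epochs: int = 5
    epochs: int = 50
    batch_size: int = 32
    l2: float = 1e-4
    validation_frequency: int = 50  # iterations
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if min(self.batch_size, self.validation_frequency, self.lr_step_epochs) < 1:
            raise ValueError("batch_size, validation_frequency, lr_step_epochs must be >= 1")

    def lr_at(self, epoch: int) -> float:
        """Piecewise schedule: lr * decay^floor(epoch / step)."""
        return self.initial_lr * self.lr_decay ** (epoch // self.lr_step_epochs)


@dataclass(frozen=True)
class Budget:
    """Hardware-independent stand-in for a GPU memory budget."""

    max_parameters: int = 10_000_000
    max_activation_cells: int = 50_000_000


@dataclass
class EvalReport:
    confusion: np.ndarray
    class_names: tuple[str, ...]
    per_class: dict[str, list[float]]
    macro: dict[str, float]
    overall_accuracy: float
    per_class_auc: list[float | None]
    macro_auc: float | None
    kappa: float
    loss: float
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict[str, Any]:
        return {
            "confusion_matrix": self.confusion.tolist(),
            "class_names": list(self.class_names),
            "per_class": self.per_class,
            "macro": self.macro,
            "overall_accuracy": self.overall_accuracy,
            "per_class_auc": self.per_class_auc,
            "macro_auc": self.macro_auc,
            "kappa": self.kappa,
            "loss": self.loss,
            "flags": self.flags,
        }


def split_dataset(ds: ImageDataset, spec: SplitSpec) -> dict[str, ImageDataset]:
    """Disjoint, exhaustive train/validation/test split.

    Test gets ``round(0.2 N)`` samples, validation ``round(0.1 |train pool|)``;
    stratification preserves per-class proportions within one sample.
    """
    n = len(ds)
    if n == 0:
        raise ValueError("empty dataset")
    if spec.stratified:
        counts = ds.class_counts()
        thin = [ds.class_names[c] for c in np.flatnonzero((counts > 0) & (counts < 2))]
        if thin:
            raise ValueError(f"stratified split impossible: classes with one sample: {thin}")
    n_test = int(round(spec.test_fraction * n))
    idx = np.arange(n)
    strat = ds.labels if spec.stratified else None
    pool_idx, test_idx = train_test_split(
        idx, test_size=n_test, random_state=spec.seed, stratify=strat
    )
    n_val = int(round(spec.validation_fraction_of_train * len(pool_idx)))
    strat_pool = ds.labels[pool_idx] if spec.stratified else None
    train_idx, val_idx = train_test_split(
        pool_idx, test_size=n_val, random_state=spec.seed, stratify=strat_pool
    )
    return {
        "train": ds.subset(np.sort(train_idx)),
        "validation": ds.subset(np.sort(val_idx)),
        "test": ds.subset(np.sort(test_idx)),
    }


def subsample_per_class(ds: ImageDataset, n_per_class: int = 200, seed: int = 0) -> ImageDataset:
    """Fixed-size class-balanced screening subset (all of a class if smaller)."""
    rng = np.random.default_rng(seed)
    keep: list[np.ndarray] = []
    for c in range(ds.num_classes):
        pool = np.flatnonzero(ds.labels == c)
        if pool.size < n_per_class:
            if pool.size:
                logger.warning(
                    "class %s has %d < %d samples; taking all",
                    ds.class_names[c], pool.size, n_per_class,
                )
            keep.append(pool)
        else:
            keep.append(np.sort(rng.choice(pool, size=n_per_class, replace=False)))
    return ds.subset(np.concatenate(keep))


def _to_tensor(images: np.ndarray) -> np.ndarray:
    """uint8 HWC [0,255] -> float32 NCHW in [-1, 1]."""
    x = images.astype(np.float32) / 255.0
    return np.ascontiguousarray((x - 0.5) * 2.0).transpose(0, 3, 1, 2)


def _accuracy(model: Model, x: np.ndarray, y: np.ndarray) -> float:
    return float((model.predict_proba(x).argmax(axis=1) == y).mean())


def train_model(
    arch: ArchitectureSpec,
    train: ImageDataset,
    validation: ImageDataset,
    config: TrainConfig,
) -> tuple[Model, dict[str, list]]:
    """Train under the fixed protocol; returns the model and learning curves.

    Curves record (iteration, train loss, train accuracy, validation loss,
    validation accuracy) every ``validation_frequency`` iterations.
    Deterministic for fixed seeds.  Raises :class:`TrainingDiverged` on a
    non-finite loss.
    """
    rng = np.random.default_rng(config.seed)
    model = build_model(arch, rng)
    opt = SGDM(model, momentum=config.momentum, l2=config.l2)
    xtr, ytr = _to_tensor(train.images), train.labels
    xva, yva = _to_tensor(validation.images), validation.labels
    curves: dict[str, list] = {
        "iteration": [], "lr": [], "train_loss": [], "train_accuracy": [],
        "validation_loss": [], "validation_accuracy": [],
    }
    it = 0
    for epoch in range(config.epochs):
        lr = config.lr_at(epoch)
        order = rng.permutation(len(ytr))
        for start in range(0, len(ytr), config.batch_size):
            b = order[start:start + config.batch_size]
            logits = model.forward(xtr[b], train=True)
            loss, dlogits = cross_entropy_loss(logits, ytr[b])
            if not np.isfinite(loss):
                raise TrainingDiverged(f"non-finite loss at iteration {it}")
            model.backward(dlogits)
            opt.step(lr)
            it += 1
            if it % config.validation_frequency == 0 and len(yva):
                vp = model.predict_proba(xva)
                vl = float(-np.log(vp[np.arange(len(yva)), yva] + 1e-12).mean())
                curves["iteration"].append(it)
                curves["lr"].append(lr)
                curves["train_loss"].append(loss)
                curves["train_accuracy"].append(
                    float((logits.argmax(axis=1) == ytr[b]).mean())
                )
                curves["validation_loss"].append(vl)
                curves["validation_accuracy"].append(
                    float((vp.argmax(axis=1) == yva).mean())
                )
    return model, curves


def confusion_matrix(y_true: np.ndarray, y_pred: np.ndarray, num_classes: int) -> np.ndarray:
    """K x K count table; rows are true classes, columns predictions."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    for name, y in (("y_true", y_true), ("y_pred", y_pred)):
        if y.size and (y.min() < 0 or y.max() >= num_classes):
            raise ValueError(f"{name} contains labels outside [0, {num_classes})")
    cm = np.zeros((num_classes, num_classes), dtype=np.int64)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


def metrics_from_confusion(cm: np.ndarray) -> dict[str, Any]:
    """One-vs-rest precision, recall, specificity, F1 and accuracy per class.

    Per class: TP is the diagonal entry, FP the rest of its column, FN the
    rest of its row, TN everything else.  Degenerate denominators yield 0 and
    are flagged.  Macro values are unweighted class means; overall accuracy
    is trace / N.
    """
    cm = np.asarray(cm, dtype=np.int64)
    n = cm.sum()
    tp = np.diag(cm).astype(float)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    tn = n - tp - fp - fn
    flags: list[str] = []

    def safe(num: np.ndarray, den: np.ndarray, what: str) -> np.ndarray:
        out = np.zeros_like(num, dtype=float)
        ok = den > 0
        out[ok] = num[ok] / den[ok]
        for c in np.flatnonzero(~ok):
            flags.append(f"{what} undefined for class {c}; reported 0")
        return out

    precision = safe(tp, tp + fp, "precision")
    recall = safe(tp, tp + fn, "recall")
    specificity = safe(tn, tn + fp, "specificity")
    f1 = safe(2 * tp, 2 * tp + fp + fn, "f1")
    accuracy = safe(tp + tn, np.full_like(tp, n), "accuracy")
    return {
        "per_class": {
            "precision": precision.tolist(),
            "recall": recall.tolist(),
            "specificity": specificity.tolist(),
            "f1": f1.tolist(),
            "accuracy": accuracy.tolist(),
        },
        "macro": {
            "precision": float(precision.mean()),
            "recall": float(recall.mean()),
            "specificity": float(specificity.mean()),
            "f1": float(f1.mean()),
            "accuracy": float(accuracy.mean()),
        },
        "overall_accuracy": float(tp.sum() / n) if n else 0.0,
        "flags": flags,
    }


def roc_auc_ovr(scores: np.ndarray, labels: np.ndarray) -> dict[str, Any]:
    """One-vs-rest ROC-AUC per class via the midrank (Mann-Whitney) statistic,
    equivalent to the trapezoidal ROC integral with tie handling."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    k = scores.shape[1]
    per_class: list[float | None] = []
    for c in range(k):
        pos = labels == c
        n_pos, n_neg = int(pos.sum()), int((~pos).sum())
        if n_pos == 0 or n_neg == 0:
            per_class.append(None)
            continue
        ranks = rankdata(scores[:, c])
        auc = (ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
        per_class.append(float(auc))
    defined = [a for a in per_class if a is not None]
    return {
        "per_class": per_class,
        "macro": float(np.mean(defined)) if defined else None,
    }


def cohen_kappa(cm: np.ndarray) -> float:
    """Chance-corrected agreement (po - pe) / (1 - pe); 0 if pe = 1."""
    cm = np.asarray(cm, dtype=float)
    n = cm.sum()
    if n == 0:
        raise ValueError("empty confusion matrix")
    po = np.trace(cm) / n
    pe = float((cm.sum(axis=1) * cm.sum(axis=0)).sum()) / n**2
    if pe >= 1.0:
        logger.warning("expected agreement pe = 1; kappa reported as 0")
        return 0.0
    return float((po - pe) / (1 - pe))


def evaluate_model(model: Model, test: ImageDataset) -> EvalReport:
    """Full final report on a held-out split; loss is 1 - overall accuracy."""
    proba = model.predict_proba(_to_tensor(test.images))
    preds = proba.argmax(axis=1)
    cm = confusion_matrix(test.labels, preds, test.num_classes)
    m = metrics_from_confusion(cm)
    auc = roc_auc_ovr(proba, test.labels)
    return EvalReport(
        confusion=cm,
        class_names=test.class_names,
        per_class=m["per_class"],
        macro=m["macro"],
        overall_accuracy=m["overall_accuracy"],
        per_class_auc=auc["per_class"],
        macro_auc=auc["macro"],
        kappa=cohen_kappa(cm),
        loss=1.0 - m["overall_accuracy"],
        flags=m["flags"],
    )


def fitness(
    genome: np.ndarray,
    layout: GenomeLayout,
    splits: dict[str, ImageDataset],
    input_shape: tuple[int, int, int],
    num_classes: int,
    train_config: TrainConfig,
    budget: Budget = Budget(),
    fitness_split: str = "test",
    screening_train: ImageDataset | None = None,
) -> float:
    """Total fitness function: decode -> repair -> budget check -> train ->
    1 - accuracy on the fitness split.  Never raises; failures map to 1.0."""
    try:
        arch = decode(genome, layout, input_shape, num_classes)
        arch, removed = repair(arch)
        if removed:
            logger.debug("repair removed %d layer(s)", len(removed))
        check = feasibility_check(arch, budget.max_parameters, budget.max_activation_cells)
        if not check["feasible"]:
            logger.info("infeasible candidate (%s); worst-case fitness", check["violated"])
            return 1.0
        train = screening_train if screening_train is not None else splits["train"]
        model, _ = train_model(arch, train, splits["validation"], train_config)
        acc = _accuracy(model, _to_tensor(splits[fitness_split].images), splits[fitness_split].labels)
        return 1.0 - acc
    except Exception:
        logger.exception("candidate evaluation failed; worst-case fitness")
        return 1.0


def two_stage_search(
    ds: ImageDataset,
    swarm_config: SwarmConfig,
    layout: GenomeLayout,
    input_shape: tuple[int, int, int] | None = None,
    split_spec: SplitSpec | None = None,
    screening_config: TrainConfig | None = None,
    final_config: TrainConfig | None = None,
    budget: Budget = Budget(),
    screening_per_class: int = 200,
    fitness_split: str = "test",
    balance: bool = True,
    balance_before_split: bool = False,
    balance_strategy: str = "transform-oversample",
) -> dict[str, Any]:
    """Screen-then-finalize architecture search.

    Stage 1 runs the swarm where each fitness call trains the candidate for a
    few epochs on a class-balanced screening subsample; stage 2 retrains the
    best architecture at full length on the full training split and produces
    the final report on the test split.  Class balancing defaults to
    after-the-split (train split only), avoiding synthetic kin leaking across
    splits; ``balance_before_split=True`` reproduces the balance-first
    ordering instead.
    """
    h, w, c = input_shape or ds.images.shape[1:]
    split_spec = split_spec or SplitSpec(seed=swarm_config.seed)
    screening_config = screening_config or TrainConfig(epochs=5, seed=swarm_config.seed)
    final_config = final_config or TrainConfig(epochs=50, seed=swarm_config.seed)

    if balance and balance_before_split:
        ds = balance_dataset(ds, balance_plan(ds.class_counts()), balance_strategy,
                             seed=swarm_config.seed)
    splits = split_dataset(ds, split_spec)
    if balance and not balance_before_split:
        train = splits["train"]
        splits["train"] = balance_dataset(
            train, balance_plan(train.class_counts()), balance_strategy,
            seed=swarm_config.seed,
        )
    screening = subsample_per_class(splits["train"], screening_per_class,
                                    seed=swarm_config.seed)

    def stage1_fitness(genome: np.ndarray) -> float:
        return fitness(
            genome, layout, splits, (h, w, c), ds.num_classes,
            screening_config, budget, fitness_split, screening_train=screening,
        )

    result = pso_run(swarm_config, layout, stage1_fitness)

    best_arch, _ = repair(decode(result["best_genome"], layout, (h, w, c), ds.num_classes))
    model, curves = train_model(best_arch, splits["train"], splits["validation"], final_config)
    report = evaluate_model(model, splits["test"])
    return {
        "best_genome": result["best_genome"],
        "best_fitness": result["best_fitness"],
        "history": result["history"],
        "evaluations": result["evaluations"],
        "best_architecture": best_arch,
        "model": model,
        "curves": curves,
        "report": report,
        "splits": splits,
    }
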