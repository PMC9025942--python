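"""Training: loss, optimizers, hold-out and k-fold protocols, grid search.

The loss is a binary cross-entropy summed over the three one-vs-rest class
terms of the softmax output,

    U = -(1/m) * sum_batch sum_classes [ r log s + (1 - r) log(1 - s) ],

minimised with mini-batch Adam (or Adagrad/Adadelta) under a stepwise
learning-rate decay ``lr * rate ** floor(step / decay_steps)``. A strict
categorical cross-entropy (-sum r log s) is available via ``loss_mode``.
"""

from __future__ import annotations

import itertools
import time
from dataclasses import dataclass, replace

import numpy as np

from .evaluation import MetricsReport, confusion_counts, compute_metrics
from .network import Model, ModelSpec, build_model, softmax
from .records import CLASSES

__all__ = [
    "Hyperparams",
    "TrainingResult",
    "FoldPlan",
    "TrainingDivergenceError",
    "cross_entropy_loss",
    "loss_and_grad",
    "learning_rate_at",
    "train",
    "evaluate_model",
    "make_fold_plan",
    "run_cv",
    "holdout_split",
    "grid_search",
]

_CLIP = 1e-12


class TrainingDivergenceError(RuntimeError):
    """Loss became non-finite; carries the last good weights and history."""

    def __init__(self, msg: str, history: list, last_good_state: dict):
        super().__init__(msg)
        self.history = history
        self.last_good_state = last_good_state


@dataclass(frozen=True)
class Hyperparams:
    """Training configuration.

    Defaults follow the final Adam operating point: learning rate 1e-4 with
    decay rate 0.95 every 1000 steps, mini-batches of 10, 20 epochs, 32 LSTM
    hidden units, 50% dropout.
    """

    learning_rate: float = 1e-4
    batch_size: int = 10
    epochs: int = 20
    hidden_units: int = 32
    dropout_rate: float = 0.5
    kernel_size: int = 3
    optimizer: str = "adam"
    lr_decay_rate: float = 0.95
    lr_decay_steps: int = 1000
    loss_mode: str = "binary_ovr"  # or "categorical"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size < 1 or self.epochs < 0:
            raise ValueError("invalid learning_rate/batch_size/epochs")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if not 0.0 < self.lr_decay_rate <= 1.0:
            raise ValueError("lr_decay_rate must be in (0, 1]")
        if self.optimizer not in ("adam", "adagrad", "adadelta"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        if self.loss_mode not in ("binary_ovr", "categorical"):
            raise ValueError(f"unknown loss_mode {self.loss_mode!r}")

    @classmethod
    def scaled_down(cls, seed: int = 0) -> "Hyperparams":
        """Desk-scale preset: 10 epochs, Adam at 1e-3 (no decay kicks in
        within the short run)."""
        return cls(learning_rate=1e-3, epochs=10, seed=seed)


@dataclass
class TrainingResult:
    history: list[dict]
    final_state: dict
    elapsed_s: float
    config_fingerprint: str


@dataclass(frozen=True)
class FoldPlan:
    """A partition of items into K folds (``assignments[i]`` = fold of item i)."""

    K: int
    assignments: np.ndarray
    stratified: bool
    split_unit: str

    def fold_indices(self, fold_id: int) -> tuple[np.ndarray, np.ndarray]:
        test = np.flatnonzero(self.assignments == fold_id)
        train_idx = np.flatnonzero(self.assignments != fold_id)
        return train_idx, test


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------


def _one_hot(labels, classes=CLASSES) -> np.ndarray:
    idx = np.array([classes.index(l) for l in labels])
    return np.eye(len(classes))[idx]


def cross_entropy_loss(
    predicted_probs: np.ndarray,
    targets: np.ndarray,
    batch_size: int | None = None,
    mode: str = "binary_ovr",
) -> float:
    """Cost U of predictions ``s`` against one-hot targets ``r``.

    ``binary_ovr``: U = -(1/m) sum [r log s + (1-r) log(1-s)] over all class
    terms; ``categorical``: U = -(1/m) sum r log s. Probabilities are clipped
    at 1e-12 before the logs; U >= 0.
    """
    s = np.atleast_2d(np.asarray(predicted_probs, dtype=np.float64))
    r = np.atleast_2d(np.asarray(targets, dtype=np.float64))
    if s.shape != r.shape:
        raise ValueError(f"shape mismatch: probs {s.shape} vs targets {r.shape}")
    m = batch_size if batch_size is not None else s.shape[0]
    s = np.clip(s, _CLIP, 1.0 - _CLIP)
    if mode == "binary_ovr":
        per = r * np.log(s) + (1.0 - r) * np.log(1.0 - s)
    elif mode == "categorical":
        per = r * np.log(s)
    else:
        raise ValueError(f"unknown loss mode {mode!r}")
    return float(-per.sum() / m)


def loss_and_grad(
    logits: np.ndarray, targets: np.ndarray, mode: str = "binary_ovr"
) -> tuple[float, np.ndarray]:
    """Loss value and its gradient with respect to the logits."""
    s = softmax(logits)
    m = logits.shape[0]
    loss = cross_entropy_loss(s, targets, m, mode=mode)
    sc = np.clip(s, _CLIP, 1.0 - _CLIP)
    if mode == "categorical":
        dlogits = (sc - targets) / m
    else:
        ds = -(targets / sc - (1.0 - targets) / (1.0 - sc)) / m
        t = ds * s
        dlogits = t - s * t.sum(axis=1, keepdims=True)
    return loss, dlogits


def learning_rate_at(hp: Hyperparams, step: int) -> float:
    """Stepwise schedule: lr * rate ** floor(step / decay_steps)."""
    return hp.learning_rate * hp.lr_decay_rate ** (step // hp.lr_decay_steps)


# ---------------------------------------------------------------------------
# optimizers
# ---------------------------------------------------------------------------


class _Optimizer:
    def __init__(self, model: Model):
        self.slots: dict[str, dict[str, np.ndarray]] = {}
        self.model = model

    def _slot(self, key, shape, names):
        if key not in self.slots:
            self.slots[key] = {n: np.zeros(shape) for n in names}
        return self.slots[key]

    def step(self, lr: float, t: int) -> None:
        raise NotImplementedError


class Adam(_Optimizer):
    def __init__(self, model, beta1=0.9, beta2=0.999, eps=1e-8):
        super().__init__(model)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps

    def step(self, lr, t):
        for key, layer, name in self.model.parameters():
            g = layer.grads.get(name)
            if g is None:
                continue
            s = self._slot(key, g.shape, ("m", "v"))
            s["m"] = self.beta1 * s["m"] + (1 - self.beta1) * g
            s["v"] = self.beta2 * s["v"] + (1 - self.beta2) * g * g
            mhat = s["m"] / (1 - self.beta1**t)
            vhat = s["v"] / (1 - self.beta2**t)
            layer.params[name] = layer.params[name] - lr * mhat / (np.sqrt(vhat) + self.eps)


class Adagrad(_Optimizer):
    def __init__(self, model, eps=1e-8):
        super().__init__(model)
        self.eps = eps

    def step(self, lr, t):
        for key, layer, name in self.model.parameters():
            g = layer.grads.get(name)
            if g is None:
                continue
            s = self._slot(key, g.shape, ("a",))
            s["a"] += g * g
            layer.params[name] = layer.params[name] - lr * g / (np.sqrt(s["a"]) + self.eps)


class Adadelta(_Optimizer):
    def __init__(self, model, rho=0.95, eps=1e-6):
        super().__init__(model)
        self.rho, self.eps = rho, eps

    def step(self, lr, t):
        for key, layer, name in self.model.parameters():
            g = layer.grads.get(name)
            if g is None:
                continue
            s = self._slot(key, g.shape, ("a", "d"))
            s["a"] = self.rho * s["a"] + (1 - self.rho) * g * g
            upd = np.sqrt(s["d"] + self.eps) / np.sqrt(s["a"] + self.eps) * g
            s["d"] = self.rho * s["d"] + (1 - self.rho) * upd * upd
            layer.params[name] = layer.params[name] - lr * upd


_OPTIMIZERS = {"adam": Adam, "adagrad": Adagrad, "adadelta": Adadelta}


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------


def _as_float_images(x: np.ndarray) -> np.ndarray:
    if x.dtype == np.uint8:
        return x.astype(np.float32) / 255.0
    return x.astype(np.float32)


def train(
    model: Model,
    images: np.ndarray,
    labels,
    hyperparams: Hyperparams,
    val_images: np.ndarray | None = None,
    val_labels=None,
) -> TrainingResult:
    """Seeded, shuffled mini-batch optimisation of the cross-entropy cost.

    ``images`` is (N, H, W, 3), uint8 (scaled by 1/255) or float in [0, 1].
    The per-epoch history records train loss/accuracy (running over the
    epoch's mini-batches) and validation loss/accuracy when a validation set
    is given. Deterministic for fixed (data, hyperparams, seed).
    """
    labels = list(labels)
    if len(set(labels)) < 2:
        raise ValueError("training requires at least two classes present")
    hp = hyperparams
    rng = np.random.default_rng(hp.seed)
    n = images.shape[0]
    targets = _one_hot(labels)
    opt = _OPTIMIZERS[hp.optimizer](model)

    history: list[dict] = []
    last_good = model.get_state()
    t0 = time.perf_counter()
    step = 0
    for epoch in range(hp.epochs):
        order = rng.permutation(n)
        losses, correct = [], 0
        for lo in range(0, n, hp.batch_size):
            idx = order[lo : lo + hp.batch_size]
            xb = _as_float_images(images[idx])
            rb = targets[idx]
            logits = model.forward(xb, train=True)
            loss, dlogits = loss_and_grad(logits, rb, mode=hp.loss_mode)
            if not np.isfinite(loss):
                raise TrainingDivergenceError(
                    f"non-finite loss at epoch {epoch + 1}", history, last_good
                )
            model.backward(dlogits)
            step += 1
            opt.step(learning_rate_at(hp, step - 1), step)
            losses.append(loss)
            correct += int((logits.argmax(axis=1) == rb.argmax(axis=1)).sum())
        row = {
            "epoch": epoch + 1,
            "train_loss": float(np.mean(losses)),
            "train_accuracy": correct / n,
        }
        if val_images is not None:
            val_loss, val_acc = _eval_loss_acc(model, val_images, val_labels, hp)
            row["val_loss"], row["val_accuracy"] = val_loss, val_acc
        history.append(row)
        last_good = model.get_state()

    fingerprint = f"{hash((tuple(sorted(hp.__dict__.items())), n)) & 0xFFFFFFFF:08x}"
    return TrainingResult(
        history=history,
        final_state=model.get_state(),
        elapsed_s=time.perf_counter() - t0,
        config_fingerprint=fingerprint,
    )


def _eval_loss_acc(model, images, labels, hp) -> tuple[float, float]:
    probs = model.predict_proba(_as_float_images(images))
    targets = _one_hot(labels)
    loss = cross_entropy_loss(probs, targets, mode=hp.loss_mode)
    acc = float((probs.argmax(axis=1) == targets.argmax(axis=1)).mean())
    return loss, acc


def evaluate_model(model: Model, images: np.ndarray, labels) -> MetricsReport:
    """Predict and compute the full one-vs-rest metric report."""
    predicted = model.predict(_as_float_images(images), CLASSES)
    counts = confusion_counts(list(labels), predicted)
    return compute_metrics(counts)


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------


def make_fold_plan(
    labels,
    K: int = 10,
    stratified: bool = True,
    split_unit: str = "chunk",
    groups=None,
    seed: int = 0,
) -> FoldPlan:
    """Seeded K-fold partition of items.

    ``split_unit="chunk"`` assigns items independently (the per-image pool);
    ``"record"`` keeps all chunks of one recording in the same fold
    (leakage-safe), requiring ``groups`` (one group id per item). Stratified
    plans balance class counts within one item per fold.
    """
    labels = list(labels)
    n = len(labels)
    if K < 2:
        raise ValueError("K must be >= 2")
    if K > n:
        raise ValueError(f"K={K} exceeds {n} items")
    rng = np.random.default_rng(seed)
    assignments = np.full(n, -1, dtype=int)

    if split_unit == "chunk":
        units = np.arange(n)
        unit_labels = labels
        unit_of_item = units
    elif split_unit == "record":
        if groups is None:
            raise ValueError("record-level folds require groups")
        groups = list(groups)
        uniq = list(dict.fromkeys(groups))
        if K > len(uniq):
            raise ValueError(f"K={K} exceeds {len(uniq)} record groups")
        units = np.arange(len(uniq))
        unit_labels = [labels[groups.index(g)] for g in uniq]
        gidx = {g: i for i, g in enumerate(uniq)}
        unit_of_item = np.array([gidx[g] for g in groups])
    else:
        raise ValueError(f"unknown split_unit {split_unit!r}")

    unit_fold = np.full(len(units), -1, dtype=int)
    if stratified:
        # deal each class's (shuffled) units round-robin, rotating the fold
        # offset between classes to keep fold sizes even overall
        offset = 0
        for cls in CLASSES:
            cls_units = [u for u in units if unit_labels[u] == cls]
            rng.shuffle(cls_units)
            for j, u in enumerate(cls_units):
                unit_fold[u] = (j + offset) % K
            offset += len(cls_units) % K
    else:
        perm = rng.permutation(len(units))
        for j, u in enumerate(perm):
            unit_fold[u] = j % K
    assignments = unit_fold[unit_of_item]
    return FoldPlan(K=K, assignments=assignments, stratified=stratified,
                    split_unit=split_unit)


def holdout_split(
    labels,
    test_fraction: float = 0.30,
    stratified: bool = True,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded train/test split; per-class test size is round(n_c * fraction).

    Returns (train_idx, test_idx), disjoint and exhaustive.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    labels = list(labels)
    n = len(labels)
    rng = np.random.default_rng(seed)
    test: list[int] = []
    if stratified:
        for cls in CLASSES:
            idx = np.array([i for i, l in enumerate(labels) if l == cls])
            if idx.size == 0:
                continue
            rng.shuffle(idx)
            k = int(round(idx.size * test_fraction))
            test.extend(idx[:k].tolist())
    else:
        idx = rng.permutation(n)
        test = idx[: int(round(n * test_fraction))].tolist()
    test_idx = np.array(sorted(test), dtype=int)
    mask = np.ones(n, dtype=bool)
    mask[test_idx] = False
    return np.flatnonzero(mask), test_idx


# ---------------------------------------------------------------------------
# cross-validation and grid search
# ---------------------------------------------------------------------------


def run_cv(
    images: np.ndarray,
    labels,
    spec: ModelSpec,
    hyperparams: Hyperparams,
    fold_plan: FoldPlan,
) -> tuple[list[tuple[int, MetricsReport]], MetricsReport]:
    """Train/evaluate around every fold; returns per-fold reports and the
    pooled report (confusion counts summed over held-out folds)."""
    labels = list(labels)
    reports: list[tuple[int, MetricsReport]] = []
    all_true: list[str] = []
    all_pred: list[str] = []
    for fold_id in range(fold_plan.K):
        train_idx, test_idx = fold_plan.fold_indices(fold_id)
        model = build_model(spec, seed=hyperparams.seed + fold_id)
        hp = replace(hyperparams, seed=hyperparams.seed + fold_id)
        try:
            train(model, images[train_idx], [labels[i] for i in train_idx], hp)
        except TrainingDivergenceError as exc:
            exc.args = (f"fold {fold_id}: {exc.args[0]}",)
            model.set_state(exc.last_good_state)
        predicted = model.predict(_as_float_images(images[test_idx]), CLASSES)
        true = [labels[i] for i in test_idx]
        reports.append((fold_id, compute_metrics(confusion_counts(true, predicted))))
        all_true.extend(true)
        all_pred.extend(predicted)
    pooled = compute_metrics(confusion_counts(all_true, all_pred))
    return reports, pooled


def grid_search(
    param_grid: dict[str, list],
    images: np.ndarray,
    labels,
    spec: ModelSpec,
    eval_protocol: FoldPlan,
    base_hyperparams: Hyperparams | None = None,
) -> list[tuple[Hyperparams, float]]:
    """Exhaustive search over the cartesian product of the grid axes.

    Each combination is scored by its mean cross-validated accuracy (percent,
    unweighted mean of per-fold overall accuracies); a combination whose
    training diverges on some fold is scored with the accuracy its last good
    weights achieve. Returns all evaluated points, best first.
    """
    if not param_grid or any(len(v) == 0 for v in param_grid.values()):
        raise ValueError("param_grid must be non-empty with non-empty axes")
    base = base_hyperparams or Hyperparams()
    keys = sorted(param_grid)
    results: list[tuple[Hyperparams, float]] = []
    for combo in itertools.product(*(param_grid[k] for k in keys)):
        hp = replace(base, **dict(zip(keys, combo)))
        fold_accs = []
        for fold_id in range(eval_protocol.K):
            train_idx, test_idx = eval_protocol.fold_indices(fold_id)
            model = build_model(spec, seed=hp.seed + fold_id)
            try:
                train(model, images[train_idx],
                      [labels[i] for i in train_idx],
                      replace(hp, seed=hp.seed + fold_id))
            except TrainingDivergenceError as exc:
                model.set_state(exc.last_good_state)
            probs = model.predict_proba(_as_float_images(images[test_idx]))
            true = _one_hot([labels[i] for i in test_idx])
            fold_accs.append(float((probs.argmax(1) == true.argmax(1)).mean()))
        results.append((hp, 100.0 * float(np.mean(fold_accs))))
    results.sort(key=lambda pair: -pair[1])
    return results
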