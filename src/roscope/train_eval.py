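"""Training recipe and evaluation outputs for the slice classifiers.

Training minimizes softmax cross-entropy with Adam at learning rate 0.0001
over 10 epochs (batch size 32, reshuffled each epoch from the run seed).
Per-epoch train/validation loss and accuracy are recorded, the
best-validation-accuracy weights are retained, and evaluation produces the
test accuracy, a confusion matrix oriented with true negatives in the upper
left and true positives in the lower right (positive = CBD), and one-vs-rest
ROC curves with AUC.

Because the network is pure NumPy, a fixed seed reproduces the entire
history bit for bit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn import metrics as skmetrics

from .model import ArchitectureSpec, CNNClassifier, image_to_input, softmax_probs

logger = logging.getLogger("roscope.train_eval")

TREATMENT_CLASSES = ("control", "CBD")  # class 1 (CBD) is the positive class
CONDITION_CLASSES = ("LPS", "GP120", "Abeta42")


@dataclass
class TrainConfig:
    """The training recipe: Adam on cross-entropy, lr 1e-4, 10 epochs."""

    learning_rate: float = 1e-4
    epochs: int = 10
    batch_size: int = 32
    seed: int = 0
    init_calibration: bool = True  # LSUV rescaling on the first batch
    stop_at_train_acc: float | None = None  # early exit for capacity checks

    def validate(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch size must be >= 1")


@dataclass
class TrainingHistory:
    """Per-epoch curves; accuracies are percentages in [0, 100]."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)
    test_acc: list[float] = field(default_factory=list)
    best_epoch: int = 0

    @property
    def epochs(self) -> int:
        return len(self.train_loss)

    def to_frame(self):
        import pandas as pd

        data = {"epoch": list(range(1, self.epochs + 1)),
                "train_loss": self.train_loss, "val_loss": self.val_loss,
                "train_acc": self.train_acc, "val_acc": self.val_acc}
        if self.test_acc:
            data["test_acc"] = self.test_acc
        return pd.DataFrame(data)


@dataclass
class EvalReport:
    """Test-set performance: accuracy (%), confusion counts, ROC/AUC."""

    accuracy: float
    confusion: np.ndarray  # rows = true class, columns = predicted class
    roc: dict[int, tuple[np.ndarray, np.ndarray]]  # class -> (fpr, tpr)
    auc: dict[int, float | None]
    macro_auc: float | None
    undefined_classes: list[int]

    def to_json_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "confusion": self.confusion.tolist(),
            "auc": {str(k): v for k, v in self.auc.items()},
            "macro_auc": self.macro_auc,
            "undefined_classes": self.undefined_classes,
        }


# ---------------------------------------------------------------------------
# data assembly
# ---------------------------------------------------------------------------


def slices_to_arrays(slices, task: str = "treatment") -> tuple[np.ndarray, np.ndarray]:
    """Stack processed slices into (N, 1, H, W) zero-centered float32 plus labels."""
    classes = TREATMENT_CLASSES if task == "treatment" else CONDITION_CLASSES
    if task not in ("treatment", "condition"):
        raise ValueError(f"unknown task {task!r}")
    x = image_to_input(np.stack([s.pixels for s in slices]))[:, None]
    labels = [s.treatment if task == "treatment" else s.condition for s in slices]
    try:
        y = np.array([classes.index(l) for l in labels], dtype=np.int64)
    except ValueError:
        bad = sorted(set(labels) - set(classes))
        raise ValueError(f"labels {bad} do not match task {task!r} classes {classes}") from None
    return x, y


def _cross_entropy(logits: np.ndarray, y: np.ndarray) -> float:
    z = logits - logits.max(axis=1, keepdims=True)
    log_probs = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    return float(-log_probs[np.arange(y.size), y].mean())


class _Adam:
    def __init__(self, model: CNNClassifier, lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.state = [(w, g, np.zeros_like(w), np.zeros_like(w))
                      for _, _, w, g in model.parameters()]

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for w, g, m, v in self.state:
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            w -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def _epoch_eval(model: CNNClassifier, x: np.ndarray, y: np.ndarray,
                batch_size: int) -> tuple[float, float]:
    losses, correct = [], 0
    for lo in range(0, x.shape[0], batch_size):
        logits = model.forward(x[lo:lo + batch_size], train=False)
        losses.append(_cross_entropy(logits, y[lo:lo + batch_size]) * logits.shape[0])
        correct += int((logits.argmax(axis=1) == y[lo:lo + batch_size]).sum())
    return sum(losses) / x.shape[0], 100.0 * correct / x.shape[0]


def train(spec: ArchitectureSpec, x_train: np.ndarray, y_train: np.ndarray,
          x_val: np.ndarray, y_val: np.ndarray, config: TrainConfig,
          x_test: np.ndarray | None = None, y_test: np.ndarray | None = None,
          ) -> tuple[CNNClassifier, TrainingHistory]:
    """Train a classifier from the spec; returns the model with its
    best-validation-accuracy weights restored, plus the full history.

    When a test partition is supplied, per-epoch test accuracy is recorded
    too (the accuracy-curve convention: percentage of test cases correctly
    predicted after each epoch).
    """
    config.validate()
    if x_train.shape[0] == 0 or x_val.shape[0] == 0:
        raise ValueError("train and validation partitions must be nonempty")
    for y in (y_train, y_val) + ((y_test,) if y_test is not None else ()):
        if y.min() < 0 or y.max() >= spec.n_classes:
            raise ValueError(f"labels must lie in [0, {spec.n_classes}) for this model")

    input_shape = x_train.shape[1:]
    model = CNNClassifier(spec, input_shape=input_shape, seed=config.seed)
    if config.init_calibration:
        model.calibrate_activations(x_train[:config.batch_size])
    model.set_dropout_rng(np.random.default_rng(config.seed + 1))
    shuffle_rng = np.random.default_rng(config.seed + 2)
    opt = _Adam(model, config.learning_rate)

    history = TrainingHistory()
    best_acc, best_weights = -1.0, model.get_weights()
    n = x_train.shape[0]
    for epoch in range(config.epochs):
        perm = shuffle_rng.permutation(n)
        loss_sum, correct = 0.0, 0
        for lo in range(0, n, config.batch_size):
            sel = perm[lo:lo + config.batch_size]
            xb, yb = x_train[sel], y_train[sel]
            logits = model.forward(xb, train=True)
            loss_sum += _cross_entropy(logits, yb) * xb.shape[0]
            correct += int((logits.argmax(axis=1) == yb).sum())
            probs = softmax_probs(logits)
            probs[np.arange(yb.size), yb] -= 1.0
            model.backward((probs / xb.shape[0]).astype(np.float32))
            opt.step()
        history.train_loss.append(loss_sum / n)
        history.train_acc.append(100.0 * correct / n)
        val_loss, val_acc = _epoch_eval(model, x_val, y_val, config.batch_size)
        history.val_loss.append(val_loss)
        history.val_acc.append(val_acc)
        if x_test is not None:
            _, test_acc = _epoch_eval(model, x_test, y_test, config.batch_size)
            history.test_acc.append(test_acc)
        if val_acc > best_acc:
            best_acc = val_acc
            best_weights = model.get_weights()
            history.best_epoch = epoch + 1
        logger.info("epoch %d: train loss %.4f acc %.1f%% | val loss %.4f acc %.1f%%",
                    epoch + 1, history.train_loss[-1], history.train_acc[-1],
                    val_loss, val_acc)
        if (config.stop_at_train_acc is not None
                and history.train_acc[-1] >= config.stop_at_train_acc):
            break
    model.set_weights(best_weights)
    return model, history


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


def evaluate(model: CNNClassifier, x_test: np.ndarray, y_test: np.ndarray) -> EvalReport:
    """Deterministic test-set report given the trained weights.

    Confusion matrix rows are true classes and columns predictions, so for
    the binary task (positive = CBD = class 1) true negatives sit in the
    upper left, false positives upper right, false negatives lower left and
    true positives lower right.  A class absent from the test set gets an
    undefined (None) AUC and is flagged.
    """
    if x_test.shape[0] == 0:
        raise ValueError("test partition must be nonempty")
    n_classes = model.spec.n_classes
    probs = model.predict_proba(x_test)
    pred = probs.argmax(axis=1)
    confusion = skmetrics.confusion_matrix(y_test, pred, labels=list(range(n_classes)))
    accuracy = 100.0 * float((pred == y_test).mean())

    roc: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    auc: dict[int, float | None] = {}
    undefined = []
    for c in range(n_classes):
        y_bin = (y_test == c).astype(int)
        if y_bin.min() == y_bin.max():
            auc[c] = None
            undefined.append(c)
            continue
        fpr, tpr, _ = skmetrics.roc_curve(y_bin, probs[:, c])
        roc[c] = (fpr, tpr)
        auc[c] = float(skmetrics.auc(fpr, tpr))
    defined = [v for v in auc.values() if v is not None]
    macro = float(np.mean(defined)) if defined else None
    if undefined:
        logger.warning("classes %s absent from the test set: AUC undefined", undefined)
    return EvalReport(accuracy=accuracy, confusion=confusion, roc=roc, auc=auc,
                      macro_auc=macro, undefined_classes=undefined)


@dataclass
class GapReport:
    """Train/validation loss divergence summary."""

    final_gap: float
    max_gap: float
    diverging: bool


def overfit_divergence(history: TrainingHistory) -> GapReport:
    """Quantifies loss-curve divergence (the overfitting signature).

    Flags "diverging" when validation loss rises over at least 3 consecutive
    epoch-to-epoch steps while training loss falls over the same steps.
    """
    tr = np.asarray(history.train_loss, dtype=float)
    va = np.asarray(history.val_loss, dtype=float)
    if tr.size == 0 or tr.size != va.size:
        raise ValueError("history is incomplete")
    gaps = va - tr
    diverging = False
    up = (np.diff(va) > 0) & (np.diff(tr) < 0)
    run = 0
    for flag in up:
        run = run + 1 if flag else 0
        if run >= 3:
            diverging = True
            break
    return GapReport(final_gap=float(gaps[-1]), max_gap=float(gaps.max()),
                     diverging=diverging)


# ---------------------------------------------------------------------------
# plots (thin matplotlib wrappers used by the CLI)
# ---------------------------------------------------------------------------


def plot_history(history: TrainingHistory, path: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
    epochs = np.arange(1, history.epochs + 1)
    axes[0].plot(epochs, history.train_acc, label="train")
    axes[0].plot(epochs, history.val_acc, label="validation")
    if history.test_acc:
        axes[0].plot(epochs, history.test_acc, label="test")
    axes[0].set(xlabel="epoch", ylabel="accuracy (%)")
    axes[0].legend()
    axes[1].plot(epochs, history.train_loss, label="train")
    axes[1].plot(epochs, history.val_loss, label="validation")
    axes[1].set(xlabel="epoch", ylabel="cross-entropy loss")
    axes[1].legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_confusion(confusion: np.ndarray, path: str, class_names=None) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = confusion.shape[0]
    names = class_names or [str(i) for i in range(n)]
    fig, ax = plt.subplots(figsize=(4, 3.5))
    im = ax.imshow(confusion, cmap="Blues")
    for i in range(n):
        for j in range(n):
            ax.text(j, i, str(confusion[i, j]), ha="center", va="center")
    ax.set(xticks=range(n), yticks=range(n), xticklabels=names, yticklabels=names,
           xlabel="predicted", ylabel="true")
    fig.colorbar(im)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
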