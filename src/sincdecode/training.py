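"""Dataset splitting, the visual-guided loss, and the three training regimes.

The classifier is trained in one of three regimes: on perception trials
alone ("visual"), on imagination trials alone ("imagine"), or on the
pooled set ("mix").  The loss is the sum of softmax cross-entropy and a
feature-matching mean squared error that pulls the 2048-dim EEG feature
layer toward the class's image-embedding target — the MSE term is computed
only over trials that came from the visual task, where a ground-truth
image was actually on screen.

Optimization uses Adam (lr 5e-4) with early stopping on validation loss
(patience 30 epochs, best-epoch parameters restored).  Default batch sizes
are 128 for the visual and mixed regimes and 64 for imagination-only,
which roughly equalizes steps per epoch across regimes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nn
from .autodiff import Tensor
from .data import IMAGINATION, VISUAL, TrialSet
from .model import ModelOutputs, SincEEGNet, predict_proba
from .synthetic import FeatureProvider

__all__ = ["SplitSpec", "TrainConfig", "visual_guided_loss", "split_dataset",
           "train", "evaluate", "EvalResult", "expected_accuracy"]

REGIMES = ("visual", "imagine", "mix")
_DEFAULT_BATCH = {"visual": 128, "mix": 128, "imagine": 64}


@dataclass
class SplitSpec:
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


def split_dataset(trials: TrialSet, spec: SplitSpec = SplitSpec()
                  ) -> tuple[TrialSet, TrialSet, TrialSet]:
    """Stratified train/val/test split, per class label.

    Imagination segments from one block may land in different splits: the
    division is per label, not per block.  Deterministic under the seed.
    """
    rng = np.random.default_rng([spec.seed % (2**31), 11])
    train_idx, val_idx, test_idx = [], [], []
    for cls in np.unique(trials.labels):
        idx = np.flatnonzero(trials.labels == cls)
        if len(idx) < 3:
            raise ValueError(f"class {cls} has only {len(idx)} trials; "
                             "cannot split three ways")
        idx = rng.permutation(idx)
        n = len(idx)
        n_val = max(1, round(spec.fractions[1] * n))
        n_test = max(1, round(spec.fractions[2] * n))
        test_idx.extend(idx[:n_test])
        val_idx.extend(idx[n_test:n_test + n_val])
        train_idx.extend(idx[n_test + n_val:])
    return (trials.select(np.sort(train_idx)),
            trials.select(np.sort(val_idx)),
            trials.select(np.sort(test_idx)))


@dataclass
class TrainConfig:
    regime: str = "mix"
    lr: float = 5e-4
    patience: int = 30
    max_epochs: int = 500
    batch_size: int | None = None      # regime default unless overridden
    seed: int = 0

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"regime must be one of {REGIMES}")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.batch_size is None:
            self.batch_size = _DEFAULT_BATCH[self.regime]


def visual_guided_loss(logits: Tensor, labels: np.ndarray,
                       features: Tensor,
                       target_features: np.ndarray | None,
                       visual_mask: np.ndarray) -> Tensor:
    """Cross-entropy plus feature-matching MSE over visual-task trials.

    L = mean CE(softmax(logits), labels)
      + mean((features − targets)²) over trials with ``visual_mask`` true.
    The MSE term vanishes when the mask is empty.
    """
    visual_mask = np.asarray(visual_mask, dtype=bool)
    loss = nn.cross_entropy(logits, labels)
    idx = np.flatnonzero(visual_mask)
    if len(idx):
        if target_features is None:
            raise ValueError("visual trials present but no target features "
                             "provided")
        targets = np.asarray(target_features)
        if targets.shape[0] != len(idx):
            raise ValueError(f"{len(idx)} visual trials but "
                             f"{targets.shape[0]} target feature rows")
        diff = features[idx] - targets
        loss = loss + (diff * diff).mean()
    return loss


def _batch_loss(model: SincEEGNet, trials: TrialSet,
                provider: FeatureProvider | None) -> tuple[Tensor, ModelOutputs]:
    out = model(trials.epochs)
    mask = trials.task == VISUAL
    targets = None
    if provider is not None and mask.any():
        targets = provider(trials.labels[mask])
    elif provider is None:
        mask = np.zeros(len(trials), dtype=bool)
    loss = visual_guided_loss(out.logits, trials.labels, out.features,
                              targets, mask)
    return loss, out


def _validation_metrics(model: SincEEGNet, val: TrialSet,
                        provider: FeatureProvider | None,
                        batch_size: int) -> dict:
    from .autodiff import no_grad
    model.eval()
    losses, n_seen = [], 0
    correct = {VISUAL: [0, 0], IMAGINATION: [0, 0]}
    with no_grad():
        for i in range(0, len(val), batch_size):
            chunk = val.select(np.arange(i, min(i + batch_size, len(val))))
            loss, out = _batch_loss(model, chunk, provider)
            losses.append(loss.item() * len(chunk))
            n_seen += len(chunk)
            pred = out.probs.argmax(axis=1)
            for task in (VISUAL, IMAGINATION):
                m = chunk.task == task
                correct[task][0] += int((pred[m] == chunk.labels[m]).sum())
                correct[task][1] += int(m.sum())
    accs = {t: (c / n if n else np.nan) for t, (c, n) in correct.items()}
    total_correct = sum(c for c, _ in correct.values())
    return {
        "val_loss": sum(losses) / n_seen,
        "val_acc": total_correct / n_seen,
        "val_acc_visual": accs[VISUAL],
        "val_acc_imagine": accs[IMAGINATION],
    }


def train(model: SincEEGNet, train_set: TrialSet, val_set: TrialSet,
          config: TrainConfig = TrainConfig(),
          feature_provider: FeatureProvider | None = None
          ) -> tuple[SincEEGNet, pd.DataFrame]:
    """Fit the classifier under one regime with early stopping.

    ``train_set``/``val_set`` should contain only the regime's tasks
    (both for "mix"); mixed batches are drawn from the pooled training
    set without enforcing task ratios.  Returns the model with the
    best-validation-epoch parameters restored, plus the epoch history.
    """
    if len(train_set) == 0:
        raise ValueError("empty training set")
    tasks = set(np.unique(train_set.task))
    if config.regime == "mix" and tasks != {VISUAL, IMAGINATION}:
        raise ValueError(f"mix regime needs both tasks, found {tasks}")
    if config.regime == "visual" and tasks != {VISUAL}:
        raise ValueError(f"visual regime expects visual trials only, "
                         f"found {tasks}")
    if config.regime == "imagine" and tasks != {IMAGINATION}:
        raise ValueError(f"imagine regime expects imagination trials only, "
                         f"found {tasks}")

    rng = np.random.default_rng([config.seed % (2**31), 73])
    opt = nn.Adam(model.parameters(), lr=config.lr)
    history: list[dict] = []
    best_loss = np.inf
    best_state = model.clone_state()
    since_best = 0
    bs = config.batch_size

    for epoch in range(config.max_epochs):
        model.train()
        order = rng.permutation(len(train_set))
        epoch_loss, n_seen = 0.0, 0
        for i in range(0, len(order), bs):
            batch = train_set.select(order[i:i + bs])
            opt.zero_grad()
            loss, _ = _batch_loss(model, batch, feature_provider)
            loss.backward()
            opt.step()
            epoch_loss += loss.item() * len(batch)
            n_seen += len(batch)
        metrics = _validation_metrics(model, val_set, feature_provider, bs)
        metrics.update(epoch=epoch, train_loss=epoch_loss / n_seen)
        history.append(metrics)
        if metrics["val_loss"] < best_loss:
            best_loss = metrics["val_loss"]
            best_state = model.clone_state()
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.patience:
                break
    model.load_clone(best_state)
    model.eval()
    return model, pd.DataFrame(history)


@dataclass
class EvalResult:
    accuracy: float
    per_class_accuracy: np.ndarray
    confusion: np.ndarray
    n_trials: int = 0

    def __post_init__(self):
        self.n_trials = int(self.confusion.sum())


def evaluate(model: SincEEGNet, trials: TrialSet,
             batch_size: int = 256) -> EvalResult:
    """Top-1 accuracy and the per-class confusion matrix (eval mode)."""
    if len(trials) == 0:
        raise ValueError("empty evaluation set")
    probs = predict_proba(model, trials.epochs, batch_size)
    pred = probs.argmax(axis=1)
    n_classes = model.config.n_classes
    confusion = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(confusion, (trials.labels, pred), 1)
    row = confusion.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_class = np.where(row > 0, np.diag(confusion) / row, np.nan)
    return EvalResult(accuracy=float((pred == trials.labels).mean()),
                      per_class_accuracy=per_class, confusion=confusion)


def expected_accuracy(probs: np.ndarray, labels: np.ndarray) -> float:
    """Expected top-1 accuracy of a probabilistic predictor that samples
    its prediction from ``probs`` — for a uniform predictor over N classes
    this is exactly 1/N regardless of the label distribution."""
    probs = np.asarray(probs, dtype=np.float64)
    return float(probs[np.arange(len(labels)), np.asarray(labels)].mean())
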