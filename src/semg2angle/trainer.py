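"""Training recipe and cross-validation protocol.

Mini-batch Adam on mean-squared error with L2 weight decay and a step
learning-rate schedule (halved every 10 epochs from 1e-3), batch size 50,
50 epochs. Cross-validation defaults to contiguous trial-level blocks so
overlapping windows from one trial never straddle the train/test split;
window-level random splitting is available to demonstrate the leakage it
causes.

Targets are z-scored with statistics fit on the training folds only (the
networks are initialized near zero, so regressing degree-scale targets
directly would spend most of the budget growing the output head);
predictions are mapped back to degrees before any metric is computed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .nets.layers import Parameter
from .nets.models import ModelSpec, NeuralModel, build_model
from .nets.wiener import WienerModel
from .windows import Normalizer, WindowSet

__all__ = ["TrainSpec", "FoldResult", "DivergenceError", "Adam", "lr_at", "train", "cross_validate"]


class DivergenceError(RuntimeError):
    """Raised when the training loss becomes non-finite."""

    def __init__(self, epoch: int, loss: float):
        super().__init__(f"non-finite loss {loss} at epoch {epoch}")
        self.epoch = epoch


@dataclass(frozen=True)
class TrainSpec:
    """Optimizer, schedule and cross-validation settings."""

    lr0: float = 1e-3
    lr_step: int = 10
    lr_gamma: float = 0.5
    epochs: int = 50
    batch: int = 50
    weight_decay: float = 1e-4
    folds: int = 5
    split_policy: str = "by_block"
    grad_clip: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.split_policy not in ("by_block", "by_window"):
            raise ValueError(f"unknown split_policy {self.split_policy!r}")
        if self.batch < 1 or self.lr_step < 1:
            raise ValueError("batch and lr_step must be >= 1")


def lr_at(epoch: int, spec: TrainSpec) -> float:
    """Step decay: lr0 * gamma ** floor(epoch / step)."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    return spec.lr0 * spec.lr_gamma ** (epoch // spec.lr_step)


class Adam:
    """Adaptive-moment optimizer with decoupled-from-loss L2 term added to grads."""

    def __init__(self, params: list[Parameter], beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = params
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            if self.weight_decay > 0:
                g = g + self.weight_decay * p.data
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.data -= lr * mhat / (np.sqrt(vhat) + self.eps)


def train(
    model_spec: ModelSpec, ws: WindowSet, tspec: TrainSpec
) -> tuple[NeuralModel | WienerModel, list[float]]:
    """Fit one estimator on a (already normalized, if desired) window set.

    Returns the model in evaluation mode together with the per-epoch mean
    training loss. The linear baseline is solved in closed form; its
    "trajectory" is the single final MSE.
    """
    if len(ws) == 0:
        raise ValueError("empty training set")
    model = build_model(model_spec)
    x, y = ws.inputs, ws.targets

    if isinstance(model, WienerModel):
        model.fit(x, y)
        mse = float(np.mean((model.predict(x) - y) ** 2))
        return model, [mse]

    rng = np.random.default_rng((tspec.seed, 0x5EED))
    opt = Adam(model.parameters(), weight_decay=tspec.weight_decay)
    n = len(ws)
    losses: list[float] = []
    for epoch in range(tspec.epochs):
        lr = lr_at(epoch, tspec)
        perm = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, tspec.batch):
            idx = perm[start: start + tspec.batch]
            xb, yb = x[idx], y[idx]
            pred = model.forward(xb, training=True)
            err = pred - yb
            loss = float(np.mean(err**2))
            if not np.isfinite(loss):
                raise DivergenceError(epoch, loss)
            model.zero_grad()
            model.backward(2.0 * err / err.size)
            if tspec.grad_clip is not None:
                total = np.sqrt(sum(float(np.sum(p.grad**2)) for p in model.parameters()))
                if total > tspec.grad_clip:
                    scale = tspec.grad_clip / total
                    for p in model.parameters():
                        p.grad *= scale
            opt.step(lr)
            epoch_loss += loss
            n_batches += 1
        losses.append(epoch_loss / n_batches)
    return model, losses


@dataclass
class FoldResult:
    """Held-out predictions and bookkeeping for one cross-validation fold."""

    fold: int
    model: NeuralModel | WienerModel
    predictions: np.ndarray  # (n_test, n_joints), degrees
    targets: np.ndarray  # (n_test, n_joints), degrees
    test_trial_ids: np.ndarray
    train_losses: list[float] = field(default_factory=list)
    normalizer: Normalizer | None = None


def _fold_masks(ws: WindowSet, tspec: TrainSpec) -> list[np.ndarray]:
    n = len(ws)
    if tspec.split_policy == "by_block":
        trials = np.unique(ws.trial_ids)
        if len(trials) < tspec.folds:
            raise ValueError(
                f"{len(trials)} trial blocks cannot fill {tspec.folds} folds; "
                "use split_policy='by_window' or record more trials"
            )
        groups = np.array_split(trials, tspec.folds)
        return [np.isin(ws.trial_ids, g) for g in groups]
    rng = np.random.default_rng((tspec.seed, 0xF01D))
    perm = rng.permutation(n)
    masks = []
    for part in np.array_split(perm, tspec.folds):
        m = np.zeros(n, dtype=bool)
        m[part] = True
        masks.append(m)
    return masks


def cross_validate(
    model_spec: ModelSpec, ws: WindowSet, tspec: TrainSpec
) -> list[FoldResult]:
    """K-fold protocol with per-fold normalization fit on training data only."""
    results = []
    for fold, test_mask in enumerate(_fold_masks(ws, tspec)):
        train_ws = ws.subset(~test_mask)
        test_ws = ws.subset(test_mask)
        norm = Normalizer().fit(train_ws)
        train_z = dataclasses.replace(
            train_ws,
            inputs=norm.transform_x(train_ws.inputs),
            targets=norm.transform_y(train_ws.targets),
        )
        fold_spec = dataclasses.replace(model_spec, seed=model_spec.seed + fold)
        model, losses = train(fold_spec, train_z, tspec)
        pred_z = model.predict(norm.transform_x(test_ws.inputs))
        results.append(
            FoldResult(
                fold=fold,
                model=model,
                predictions=norm.inverse_y(pred_z),
                targets=test_ws.targets,
                test_trial_ids=test_ws.trial_ids,
                train_losses=losses,
                normalizer=norm,
            )
        )
    return results
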