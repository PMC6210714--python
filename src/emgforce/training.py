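"""Training loop with the RMSE% objective and six-epoch early stopping.

The loss is the percentage root-mean-square error

    RMSE% = 100 * sqrt( sum (F - F_hat)^2 / sum F^2 ),

computed by default over the whole concatenated mini-batch (a single
ratio, matching the metric's definition; a per-sample mean is available).
The development loss is evaluated in evaluation mode every epoch; training
stops when it has risen for ``patience`` (default 6) consecutive epochs,
and the parameters from the epoch of minimum development loss are restored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import SampleSet
from .models import Model
from .nn import Adam


def rmse_pct(F: np.ndarray, F_hat: np.ndarray) -> float:
    """Percentage RMSE of a prediction against the measured force."""
    F = np.asarray(F, dtype=float).ravel()
    F_hat = np.asarray(F_hat, dtype=float).ravel()
    if F.size == 0:
        raise ValueError("empty input")
    if F.shape != F_hat.shape:
        raise ValueError("shape mismatch")
    denom = float(np.sum(F * F))
    if denom == 0.0:
        raise ValueError("RMSE% undefined: measured force is identically zero")
    return 100.0 * float(np.sqrt(np.sum((F - F_hat) ** 2) / denom))


def _rmse_pct_grad(F: np.ndarray, F_hat: np.ndarray) -> tuple[float, np.ndarray]:
    """Loss and its gradient with respect to the predictions."""
    diff = F_hat - F
    num = float(np.sum(diff ** 2))
    denom = float(np.sum(F ** 2))
    if denom == 0.0:
        raise ValueError("RMSE% undefined: measured force is identically zero")
    loss = 100.0 * np.sqrt(num / denom)
    if num == 0.0:
        return 0.0, np.zeros_like(F_hat)
    grad = 100.0 * diff / np.sqrt(num * denom)
    return loss, grad


def early_stop_check(dev_losses, patience: int = 6, mode: str = "consecutive") -> bool:
    """True when training should stop.

    ``mode="consecutive"``: the last ``patience`` epoch-to-epoch changes were
    all strictly increasing.  ``mode="above_min"``: the last ``patience``
    losses all exceed the running minimum (the laxer reading of "stayed
    increasing").
    """
    d = list(dev_losses)
    if len(d) < patience + 1:
        return False
    if mode == "consecutive":
        return all(d[-i] > d[-i - 1] for i in range(1, patience + 1))
    if mode == "above_min":
        running_min = min(d[:-patience])
        return all(v > running_min for v in d[-patience:])
    raise ValueError(f"unknown early-stop mode {mode!r}")


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 32
    max_epochs: int = 200
    patience: int = 6
    lr: float = 1e-3
    seed: int = 0
    loss_mode: str = "batch_ratio"       # or "per_sample_mean"
    stop_mode: str = "consecutive"
    dev_eval_every: int = 1

    def __post_init__(self):
        if self.patience < 1 or self.batch_size < 1:
            raise ValueError("patience and batch_size must be >= 1")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    dev_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1                 # 0-based index into dev_loss
    stopped_early: bool = False


def evaluate_loss(model: Model, dataset: SampleSet, batch_size: int = 256) -> float:
    """Mean per-sample RMSE% in evaluation mode."""
    vals = []
    for i in range(0, len(dataset), batch_size):
        pred = model.forward(dataset.x[i:i + batch_size], training=False)
        for j in range(pred.shape[0]):
            vals.append(rmse_pct(dataset.y[i + j], pred[j]))
    return float(np.mean(vals))


def train_model(model: Model, train: SampleSet, dev: SampleSet,
                cfg: TrainConfig = TrainConfig(),
                dev_loss_override=None) -> tuple[Model, TrainHistory]:
    """Mini-batch Adam optimization of the RMSE% objective.

    Restores the parameters of the epoch with minimum development loss.
    ``dev_loss_override`` (callable epoch -> float) replaces the dev
    evaluation; it exists so the stopping rule can be exercised against an
    injected loss trajectory.
    """
    if len(train) == 0 or len(dev) == 0:
        raise ValueError("train and dev sets must be non-empty")
    if train.Q != model.Q or dev.Q != model.Q:
        raise ValueError("sample length Q differs between model and data")
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.net.params(), lr=cfg.lr)
    hist = TrainHistory()
    best_state = model.net.get_state()
    best_loss = np.inf
    n = len(train)

    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        batch_losses = []
        for i in range(0, n, cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            xb, yb = train.x[idx], train.y[idx]
            model.net.zero_grad()
            pred = model.net.forward(xb, training=True)
            if cfg.loss_mode == "batch_ratio":
                loss, grad = _rmse_pct_grad(yb, pred)
            elif cfg.loss_mode == "per_sample_mean":
                losses, grads = [], np.empty_like(pred)
                for j in range(pred.shape[0]):
                    lj, gj = _rmse_pct_grad(yb[j], pred[j])
                    losses.append(lj)
                    grads[j] = gj / pred.shape[0]
                loss, grad = float(np.mean(losses)), grads
            else:
                raise ValueError(f"unknown loss mode {cfg.loss_mode!r}")
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged (non-finite loss) at epoch {epoch}")
            model.net.backward(grad)
            opt.step()
            batch_losses.append(loss)
        hist.train_loss.append(float(np.mean(batch_losses)))

        if dev_loss_override is not None:
            dev_loss = float(dev_loss_override(epoch))
        else:
            dev_loss = evaluate_loss(model, dev)
        hist.dev_loss.append(dev_loss)
        if dev_loss < best_loss:
            best_loss = dev_loss
            hist.best_epoch = epoch
            best_state = model.net.get_state()
        if early_stop_check(hist.dev_loss, cfg.patience, cfg.stop_mode):
            hist.stopped_early = True
            break

    model.net.set_state(best_state)
    return model, hist
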