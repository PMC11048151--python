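"""Training loop: mean-squared-error objective and the Adam recipe.

The loss is the plain per-sample mean squared error between the reference
and reconstructed ECG segment.  Samples removed by an injected gap are
zero-filled in the target and *included* in the mean by default, which is
the literal reading of the objective; setting ``masked_loss`` restricts the
mean to present samples (the mask's False entries are excluded and ``l``
becomes the count of included samples).

The optimisation recipe: Adam, 500 epochs, batch size 128, learning rate
1e-3 decayed by a factor of 0.1 every 100 epochs.  Batch shuffling and
dropout are driven by seeds derived from the run seed, so two runs with the
same configuration produce identical loss histories.  The returned model
carries the parameters of the epoch with minimum validation loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .nn import Adam, DTYPE
from .preprocess import SegmentPair
from .recordio import RunConfig, child_seed
from .wnet import WNet

__all__ = ["TrainState", "mse_loss", "lr_schedule", "train", "predict_segments"]


def mse_loss(
    reference: np.ndarray,
    reconstructed: np.ndarray,
    mask: Optional[np.ndarray] = None,
) -> float:
    """Mean squared difference; with a mask, the mean over included samples."""
    reference = np.asarray(reference, dtype=np.float64)
    reconstructed = np.asarray(reconstructed, dtype=np.float64)
    if reference.shape != reconstructed.shape:
        raise ValueError(
            f"shape mismatch: {reference.shape} vs {reconstructed.shape}"
        )
    if reference.size == 0:
        raise ValueError("loss of empty signals is undefined")
    d2 = (reference - reconstructed) ** 2
    if mask is None:
        return float(d2.mean())
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != reference.shape:
        raise ValueError("mask shape must match the signals")
    n = int(mask.sum())
    if n == 0:
        raise ValueError("masked loss with an all-false mask is undefined")
    return float(d2[mask].sum() / n)


def lr_schedule(
    epoch: int, base: float = 1e-3, factor: float = 0.1, step: int = 100
) -> float:
    """Step decay: ``base * factor ** floor(epoch / step)``."""
    if epoch < 0:
        raise ValueError("epoch must be non-negative")
    return base * factor ** (epoch // step)


@dataclass
class TrainState:
    """History and bookkeeping of one training run."""

    seed: int
    epochs_run: int = 0
    train_loss: List[float] = field(default_factory=list)
    val_loss: List[float] = field(default_factory=list)
    learning_rates: List[float] = field(default_factory=list)
    best_epoch: int = -1
    best_val_loss: float = float("inf")
    adam_betas: Tuple[float, float] = (0.9, 0.999)
    adam_eps: float = 1e-8


def _stack(segments: Sequence[SegmentPair]) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    x = np.stack([s.ppg_in for s in segments])[:, None, :].astype(DTYPE)
    y = np.stack([s.ecg_target for s in segments])[:, None, :].astype(DTYPE)
    m = np.stack([s.mask for s in segments])[:, None, :]
    return x, y, m


def _epoch_eval(model: WNet, x: np.ndarray, y: np.ndarray, batch: int) -> float:
    model.set_training(False)
    total, n = 0.0, 0
    for lo in range(0, len(x), batch):
        out = model.forward(x[lo : lo + batch])
        sl = y[lo : lo + batch]
        total += float(((out - sl) ** 2).sum())
        n += sl.size
    return total / n


def train(
    model: WNet,
    train_segments: Sequence[SegmentPair],
    val_segments: Sequence[SegmentPair],
    cfg: RunConfig,
) -> Tuple[WNet, TrainState]:
    """Optimise ``model`` on the training segments with the Adam recipe.

    Returns the model re-loaded with its minimum-validation-loss checkpoint
    together with the full per-epoch history.
    """
    if len(train_segments) == 0:
        raise ValueError("empty training set")
    if len(val_segments) == 0:
        raise ValueError("empty validation set")
    x_tr, y_tr, m_tr = _stack(train_segments)
    x_va, y_va, _ = _stack(val_segments)
    use_mask = cfg.masked_loss and not m_tr.all()

    opt = Adam(model.parameters(), lr=cfg.lr)
    state = TrainState(seed=cfg.seed, adam_betas=opt.betas, adam_eps=opt.eps)
    shuffle_rng = np.random.default_rng(child_seed(cfg.seed, "batch_shuffle"))
    n = len(x_tr)
    batch = min(cfg.batch_size, n)
    best_state = model.state_dict()

    for epoch in range(cfg.epochs):
        opt.lr = lr_schedule(epoch, cfg.lr, cfg.lr_decay_factor, cfg.lr_decay_step)
        order = shuffle_rng.permutation(n)
        model.set_training(True)
        ep_loss, ep_count = 0.0, 0
        for lo in range(0, n, batch):
            idx = order[lo : lo + batch]
            xb, yb = x_tr[idx], y_tr[idx]
            out = model.forward(xb)
            diff = out - yb
            if use_mask:
                mb = m_tr[idx]
                cnt = int(mb.sum())
                if cnt == 0:
                    raise ValueError("masked loss with an all-false batch mask")
                diff = np.where(mb, diff, 0.0).astype(DTYPE)
                loss = float((diff**2).sum()) / cnt
                grad = (2.0 / cnt) * diff
            else:
                loss = float((diff**2).mean())
                grad = (2.0 / diff.size) * diff
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}; aborting"
                )
            opt.zero_grad()
            model.backward(grad.astype(DTYPE))
            opt.step()
            ep_loss += loss * len(idx)
            ep_count += len(idx)
        state.train_loss.append(ep_loss / ep_count)
        vl = _epoch_eval(model, x_va, y_va, batch)
        state.val_loss.append(vl)
        state.learning_rates.append(opt.lr)
        state.epochs_run = epoch + 1
        if vl < state.best_val_loss:
            state.best_val_loss = vl
            state.best_epoch = epoch
            best_state = model.state_dict()

    model.load_state_dict(best_state)
    model.set_training(False)
    return model, state


def predict_segments(
    model: WNet, segments: Sequence[SegmentPair], batch_size: int = 64
) -> List[np.ndarray]:
    """Run the model over segments in evaluation mode; one 1-D array each."""
    model.set_training(False)
    x = np.stack([s.ppg_in for s in segments])[:, None, :].astype(DTYPE)
    outs: List[np.ndarray] = []
    for lo in range(0, len(x), batch_size):
        y = model.forward(x[lo : lo + batch_size])
        outs.extend(np.asarray(y[i, 0], dtype=np.float64) for i in range(len(y)))
    return outs
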