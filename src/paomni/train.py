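"""Training loop, context-assembly protocols and inference.

Context protocols
-----------------
*Training* uses a sliding window: the context for the item at position
``i`` is the next ``window`` (default 4) input/output pairs of the
training split, wrapping modulo the split size, so the target pair is
never its own context.  The small training context forces the network to
extract task information from few examples instead of memorizing a
fixed conditioning set.

*Inference* uses a static context: the first ``k`` (default 16) pairs of
the training split, in stored order, shared by every test input.

Model selection follows validation loss (computed with the training
context protocol on the validation split): the checkpoint kept is the
epoch with the lowest validation loss, and training stops early once the
validation loss has not improved for ``early_stop_patience`` epochs.

Both PA OmniNet and the baseline U-net train through the same
:class:`Trainer`; a thin adapter supplies the only difference (whether a
context set enters the forward pass).
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .autodiff import Tensor
from .dataset import DatasetBundle, ImagePair
from .losses import make_loss
from .nnet import Adam
from .omninet import OmniNet
from .report import MetricReport, evaluate_pairs
from .unet import BaselineUNet

__all__ = [
    "TrainConfig", "InferConfig", "ContextSet", "sliding_context", "static_context",
    "group_context", "OmniNetAdapter", "UNetAdapter", "Trainer", "TrainResult",
    "TrainingDivergedError", "EarlyStopper", "infer", "context_size_sweep",
    "context_swap",
]


@dataclass(frozen=True)
class TrainConfig:
    loss: str = "alpha"                 # mse | ssim | alpha | srmse
    alpha: float = 0.84
    learning_rate: float = 1e-4
    max_epochs: int = 500
    early_stop_patience: int = 20
    batch_size: int = 8
    context_size_train: int = 4
    srmse_scale: float = 255.0
    shuffle: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.early_stop_patience < 1:
            raise ValueError("early_stop_patience must be >= 1")
        if self.context_size_train < 1:
            raise ValueError("context_size_train must be >= 1")
        if self.max_epochs < 1 or self.batch_size < 1:
            raise ValueError("max_epochs and batch_size must be >= 1")


@dataclass(frozen=True)
class InferConfig:
    context_size_test: int = 16

    def __post_init__(self) -> None:
        if self.context_size_test < 1:
            raise ValueError("context_size_test must be >= 1")


@dataclass(frozen=True)
class ContextSet:
    """Ordered collection of K labeled input/output pairs."""

    pairs: tuple[ImagePair, ...]

    def __post_init__(self) -> None:
        if len(self.pairs) < 1:
            raise ValueError("context set must contain at least one pair")
        shape = self.pairs[0].sparse_input.shape
        for p in self.pairs:
            if p.sparse_input.shape != shape:
                raise ValueError("context pairs must be co-shaped")

    @property
    def k(self) -> int:
        return len(self.pairs)

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """(K, H, W) stacks of context inputs and outputs."""
        ci = np.stack([p.sparse_input for p in self.pairs])
        co = np.stack([p.ground_truth for p in self.pairs])
        return ci, co

    def take(self, k: int) -> "ContextSet":
        if k > self.k:
            raise ValueError(f"cannot take {k} of {self.k} context pairs")
        return ContextSet(pairs=self.pairs[:k])


def sliding_context(pairs: list[ImagePair], index: int, window: int = 4) -> ContextSet:
    """The next ``window`` pairs after ``index``, wrapping modulo the size."""
    n = len(pairs)
    if window < 1:
        raise ValueError("window must be >= 1")
    if n <= window:
        raise ValueError(f"dataset of {n} pairs too small for window {window}")
    idx = [(index + 1 + j) % n for j in range(window)]
    return ContextSet(pairs=tuple(pairs[i] for i in idx))


def static_context(train_pairs: list[ImagePair], k: int = 16) -> ContextSet:
    """The first ``k`` training pairs in stored order (inference protocol)."""
    if len(train_pairs) < k:
        raise ValueError(f"need {k} pairs for a static context, have {len(train_pairs)}")
    return ContextSet(pairs=tuple(train_pairs[:k]))


def group_context(bundle: DatasetBundle, group_id: int, k: int,
                  split: str = "train") -> ContextSet:
    """First ``k`` pairs of one group within a split (same task, one subject)."""
    pairs = [p for p in bundle.split(split) if p.group_id == group_id]
    if len(pairs) < k:
        raise ValueError(f"group {group_id} has only {len(pairs)} pairs in {split!r}")
    return ContextSet(pairs=tuple(pairs[:k]))


class OmniNetAdapter:
    """Context-conditioned forward for the shared training harness."""

    needs_context = True

    def __init__(self, model: OmniNet):
        self.model = model

    @property
    def params(self):
        return self.model.params

    def forward(self, x: np.ndarray, context: ContextSet | None) -> Tensor:
        if context is None:
            raise ValueError("PA OmniNet requires a context set")
        ci, co = context.arrays()
        return self.model.forward(x, ci, co)


class UNetAdapter:
    """Context-free baseline forward; the context argument is ignored."""

    needs_context = False

    def __init__(self, model: BaselineUNet):
        self.model = model

    @property
    def params(self):
        return self.model.params

    def forward(self, x: np.ndarray, context: ContextSet | None = None) -> Tensor:
        return self.model.forward(x)


class TrainingDivergedError(RuntimeError):
    pass


class EarlyStopper:
    """Validation-loss early stopping with strict-improvement patience.

    ``update`` returns True when training should stop: the validation
    loss has not strictly improved on the best epoch for ``patience``
    consecutive epochs.  ``best_epoch`` is the checkpoint to keep.
    """

    def __init__(self, patience: int):
        if patience < 1:
            raise ValueError("patience must be >= 1")
        self.patience = patience
        self.best_epoch = 0
        self.best_loss = np.inf

    def update(self, epoch: int, val_loss: float) -> bool:
        if val_loss < self.best_loss:
            self.best_loss = val_loss
            self.best_epoch = epoch
        return epoch - self.best_epoch >= self.patience


@dataclass
class TrainResult:
    """Fitted model plus the training trajectory and selection diagnostics."""

    adapter: object
    history: pd.DataFrame = field(repr=False)
    best_epoch: int
    best_val_loss: float
    stopped_early: bool
    config: TrainConfig
    wall_time_s: float = 0.0

    @property
    def model(self):
        return self.adapter.model

    @property
    def n_epochs(self) -> int:
        return len(self.history)

    def summary(self) -> str:
        cfg = self.config
        rows = [
            ("model", type(self.model).__name__),
            ("parameters", f"{self.model.n_parameters:,}"),
            ("loss", cfg.loss + (f" (alpha={cfg.alpha})" if cfg.loss == "alpha" else "")),
            ("optimizer", f"Adam(lr={cfg.learning_rate:g})"),
            ("epochs run", f"{self.n_epochs} (max {cfg.max_epochs})"),
            ("best epoch", f"{self.best_epoch} (val loss {self.best_val_loss:.6f})"),
            ("early stopped", str(self.stopped_early)),
            ("final train loss", f"{self.history['train_loss'].iloc[-1]:.6f}"),
            ("wall time", f"{self.wall_time_s:.1f} s"),
        ]
        width = max(len(k) for k, _ in rows)
        lines = ["Training results", "=" * 40]
        lines += [f"{k.ljust(width)}  {v}" for k, v in rows]
        return "\n".join(lines)


class Trainer:
    """Shared optimization harness for both architectures."""

    def __init__(self, adapter, bundle: DatasetBundle, config: TrainConfig = TrainConfig(),
                 context_fn=None):
        """``context_fn(pairs, index) -> ContextSet`` overrides the default
        sliding-window assembly (used e.g. to keep contexts within one task
        during joint multi-task training)."""
        self.adapter = adapter
        self.bundle = bundle
        self.config = config
        self.context_fn = context_fn
        self.loss_fn = make_loss(config.loss, alpha=config.alpha,
                                 srmse_scale=config.srmse_scale)

    def _context_for(self, pairs: list[ImagePair], index: int) -> ContextSet | None:
        if not self.adapter.needs_context:
            return None
        if self.context_fn is not None:
            return self.context_fn(pairs, index)
        return sliding_context(pairs, index, self.config.context_size_train)

    def _epoch_loss(self, pairs: list[ImagePair], train: bool,
                    opt: Adam | None, rng: np.random.Generator) -> float:
        cfg = self.config
        order = rng.permutation(len(pairs)) if (train and cfg.shuffle) else np.arange(len(pairs))
        total = 0.0
        pending = 0
        for pos, i in enumerate(order):
            ctx = self._context_for(pairs, int(i))
            pred = self.adapter.forward(pairs[int(i)].sparse_input, ctx)
            loss = self.loss_fn(pred, pairs[int(i)].ground_truth)
            val = float(loss.data)
            if not np.isfinite(val):
                raise TrainingDivergedError(
                    f"non-finite loss {val} at item {int(i)} "
                    f"({'train' if train else 'val'})")
            total += val
            if train:
                loss.backward()
                pending += 1
                if pending == cfg.batch_size or pos == len(order) - 1:
                    for p in self.adapter.params.values():
                        if p.grad is not None:
                            p.grad /= pending
                    opt.step()
                    opt.zero_grad()
                    pending = 0
        return total / len(pairs)

    def fit(self, verbose: bool = False) -> TrainResult:
        cfg = self.config
        train_pairs, val_pairs = self.bundle.train, self.bundle.val
        if not train_pairs or not val_pairs:
            raise ValueError("training requires nonempty train and val splits")
        if self.adapter.needs_context and len(train_pairs) <= cfg.context_size_train:
            raise ValueError("train split smaller than the sliding context window")
        rng = np.random.default_rng(cfg.seed)
        opt = Adam(self.adapter.params, lr=cfg.learning_rate)
        stopper = EarlyStopper(cfg.early_stop_patience)
        history = []
        best_state: dict[str, np.ndarray] = {}
        stopped = False
        t0 = time.time()
        for epoch in range(1, cfg.max_epochs + 1):
            tr = self._epoch_loss(train_pairs, True, opt, rng)
            vl = self._epoch_loss(val_pairs, False, None, rng)
            history.append({"epoch": epoch, "train_loss": tr, "val_loss": vl})
            if verbose:
                print(f"epoch {epoch:4d}  train {tr:.6f}  val {vl:.6f}")
            stop = stopper.update(epoch, vl)
            if stopper.best_epoch == epoch:  # new best: snapshot weights
                best_state = {k: p.data.copy() for k, p in self.adapter.params.items()}
            if stop:
                stopped = True
                break
        for k, p in self.adapter.params.items():
            p.data = best_state[k]
        return TrainResult(
            adapter=self.adapter, history=pd.DataFrame(history),
            best_epoch=stopper.best_epoch, best_val_loss=float(stopper.best_loss),
            stopped_early=stopped, config=cfg, wall_time_s=time.time() - t0,
        )


def infer(adapter, inputs: list[np.ndarray], context: ContextSet | None = None,
          clip: bool = True) -> list[np.ndarray]:
    """Reconstruct a list of images under one fixed context set."""
    outs = []
    for x in inputs:
        y = adapter.forward(np.asarray(x), context).data
        outs.append(np.clip(y, 0.0, 1.0) if clip else y)
    return outs


def _score(adapter, pairs: list[ImagePair], context: ContextSet | None,
           dataset: str, model: str) -> MetricReport:
    preds = infer(adapter, [p.sparse_input for p in pairs], context)
    return evaluate_pairs(preds, [p.ground_truth for p in pairs],
                          dataset=dataset, model=model)


def context_size_sweep(adapter, test_pairs: list[ImagePair], context_pool: ContextSet,
                       sizes: list[int]) -> pd.DataFrame:
    """Evaluate the same test set under growing context prefixes."""
    rows = []
    for s in sizes:
        rep = _score(adapter, test_pairs, context_pool.take(s),
                     dataset="sweep", model=f"k={s}")
        rows.append({"context_size": s, "ssim": rep.mean_ssim,
                     "rmse": rep.mean_rmse, "psnr": rep.mean_psnr})
    return pd.DataFrame(rows)


def context_swap(adapter, test_pairs: list[ImagePair],
                 contexts: dict[str, ContextSet]) -> dict[str, MetricReport]:
    """Evaluate the same test set under each named candidate context."""
    if not contexts:
        raise ValueError("context_swap requires at least one candidate context")
    return {name: _score(adapter, test_pairs, ctx, dataset="swap", model=name)
            for name, ctx in contexts.items()}
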