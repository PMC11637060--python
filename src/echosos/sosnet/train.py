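"""Training loop for the SoS regression network and its transfer-learning
(frozen-base, residual-head) refinement.

Loss is mean-square error on the normalized SoS scale; history is logged as
RMSE in m/s.  The train/validation split is per phantom (no frame leakage),
and the best-validation parameters are retained.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .layers import F32, SGD
from .model import (SoSNet, AugmentedSoSNet, SOS_OFFSET, SOS_SCALE)


@dataclass
class TrainConfig:
    lr: float = 1e-4
    batch: int = 10
    epochs: int = 100
    split: float = 0.9
    momentum: float = 0.0
    seed: int = 0
    patience: Optional[int] = None  # early stop on validation plateau
    # optional step schedule: ((epoch, lr), ...) switches the rate from the
    # given epoch onward (annealing settles the late-epoch SGD noise)
    lr_steps: Optional[Tuple[Tuple[int, float], ...]] = None
    # Polyak averaging of the weights (0 disables): validation and the
    # retained checkpoint use the averaged parameters, which smooths the
    # mini-batch noise of momentum SGD
    ema_decay: float = 0.0

    def __post_init__(self) -> None:
        if self.lr < 0:
            raise ValueError("learning rate must be >= 0")
        if not (0.0 < self.split < 1.0):
            raise ValueError("split must lie in (0, 1)")


Dataset = Sequence[Tuple[np.ndarray, np.ndarray]]  # (rf 128x1024, label 384x384 m/s)


def _normalize_labels(labels: np.ndarray) -> np.ndarray:
    return ((labels - SOS_OFFSET) / SOS_SCALE).astype(F32)


def _split_dataset(dataset: Dataset, split: float, seed: int):
    n = len(dataset)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = max(1, int(round(split * n)))
    if n_train == n and n > 1:
        n_train = n - 1
    return [dataset[i] for i in order[:n_train]], [dataset[i] for i in order[n_train:]]


def _epoch_rmse(model, pairs: Dataset, batch: int, forward=None) -> float:
    """RMSE (m/s) over a dataset in eval mode."""
    if not pairs:
        return float("nan")
    forward = forward or model.forward
    se, count = 0.0, 0
    for i in range(0, len(pairs), batch):
        chunk = pairs[i:i + batch]
        x = np.stack([p[0] for p in chunk]).astype(F32)
        y = _normalize_labels(np.stack([p[1] for p in chunk]))
        pred = forward(x, train=False)
        se += float(((pred - y) ** 2).sum())
        count += y.size
    return float(np.sqrt(se / count) * SOS_SCALE)


def _cache_base_outputs(model: AugmentedSoSNet, pairs: Dataset,
                        batch: int) -> List[Tuple[np.ndarray, np.ndarray]]:
    out = []
    for i in range(0, len(pairs), batch):
        chunk = pairs[i:i + batch]
        x = np.stack([p[0] for p in chunk]).astype(F32)
        base = model.base.forward(x, train=False)
        out.extend((base[j], chunk[j][1]) for j in range(len(chunk)))
    return out


def train(model: SoSNet | AugmentedSoSNet, dataset: Dataset,
          cfg: Optional[TrainConfig] = None,
          valid_set: Optional[Dataset] = None) -> Tuple[object, Dict[str, List[float]]]:
    """Mini-batch SGD on MSE; returns (model with best-validation weights,
    history dict with per-epoch train/validation RMSE in m/s)."""
    cfg = cfg or TrainConfig()
    if len(dataset) < 2 and valid_set is None:
        raise ValueError("need at least 2 samples to split train/validation")
    if valid_set is None:
        train_set, valid_set = _split_dataset(dataset, cfg.split, cfg.seed)
    else:
        train_set = list(dataset)
    # frozen base: run it once per sample and train the head on cached maps
    forward = model.forward
    if isinstance(model, AugmentedSoSNet):
        train_set = _cache_base_outputs(model, train_set, cfg.batch)
        valid_set = _cache_base_outputs(model, valid_set, cfg.batch)
        forward = model.forward_from_base
    opt = SGD(model.param_groups(), lr=cfg.lr, momentum=cfg.momentum)
    rng = np.random.default_rng(cfg.seed + 1)
    history: Dict[str, List[float]] = {"train_rmse": [], "valid_rmse": []}

    def snapshot():
        if isinstance(model, SoSNet):
            return model.state_dict()
        return [copy.deepcopy(l.params) for l in model.head_layers]

    def restore(state):
        if isinstance(model, SoSNet):
            model.load_state_dict(state)
        else:
            for l, saved in zip(model.head_layers, state):
                for k in l.params:
                    l.params[k][...] = saved[k]

    ema: Optional[Dict[str, np.ndarray]] = None
    if cfg.ema_decay and isinstance(model, SoSNet):
        ema = model.state_dict()

    def with_ema(fn):
        """Evaluate fn() under the averaged weights, then restore."""
        if ema is None:
            return fn()
        raw = snapshot()
        restore(ema)
        try:
            return fn()
        finally:
            restore(raw)

    # seed the best-checkpoint with the initial state so training can never
    # return something worse than where it started (on the validation set)
    best_valid = _epoch_rmse(model, valid_set, cfg.batch, forward)
    if not np.isfinite(best_valid):
        best_valid = np.inf
    best_state = snapshot()
    stall = 0
    for epoch in range(cfg.epochs):
        if cfg.lr_steps:
            for at_epoch, lr in cfg.lr_steps:
                if epoch == at_epoch:
                    opt.lr = lr
        order = rng.permutation(len(train_set))
        se, count = 0.0, 0
        for i in range(0, len(order), cfg.batch):
            chunk = [train_set[j] for j in order[i:i + cfg.batch]]
            x = np.stack([p[0] for p in chunk]).astype(F32)
            y = _normalize_labels(np.stack([p[1] for p in chunk]))
            pred = forward(x, train=True)
            err = pred - y
            loss = float((err ** 2).mean())
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"NaN/Inf loss at epoch {epoch}, batch {i // cfg.batch}: "
                    f"lr={cfg.lr}, |pred|max={np.abs(pred).max():.3g}")
            model.backward((2.0 / err.size) * err)
            opt.step()
            if ema is not None:
                d = cfg.ema_decay
                cur = model.state_dict()
                for k in ema:
                    ema[k] = d * ema[k] + (1 - d) * cur[k]
            se += float((err ** 2).sum())
            count += err.size
        train_rmse = float(np.sqrt(se / count) * SOS_SCALE)
        valid_rmse = with_ema(lambda: _epoch_rmse(model, valid_set, cfg.batch, forward))
        history["train_rmse"].append(train_rmse)
        history["valid_rmse"].append(valid_rmse)
        score = valid_rmse if np.isfinite(valid_rmse) else train_rmse
        if score < best_valid - 1e-9:
            best_valid = score
            stall = 0
            best_state = with_ema(snapshot)
        else:
            stall += 1
            if cfg.patience is not None and stall >= cfg.patience:
                break
    if best_state is not None:
        restore(best_state)
    return model, history


def fine_tune(augmented: AugmentedSoSNet, dataset: Dataset,
              cfg: Optional[TrainConfig] = None,
              valid_set: Optional[Dataset] = None
              ) -> Tuple[AugmentedSoSNet, Dict[str, List[float]]]:
    """Transfer learning: update only the residual head, epoch cap 20 with a
    validation-plateau stop; the frozen base is bit-identical afterwards."""
    if len(dataset) == 0:
        raise ValueError("empty fine-tuning dataset")
    cfg = cfg or TrainConfig(epochs=20, patience=5)
    if cfg.epochs > 20:
        cfg = TrainConfig(lr=cfg.lr, batch=cfg.batch, epochs=20, split=cfg.split,
                          momentum=cfg.momentum, seed=cfg.seed, patience=cfg.patience)
    return train(augmented, dataset, cfg, valid_set=valid_set)


def save_checkpoint(path: str, model: SoSNet, history: Dict[str, List[float]],
                    seed: int) -> None:
    """Framework-native .npz + JSON sidecar (config, seed, RMSE history)."""
    state = model.state_dict()
    np.savez_compressed(path, **state)
    sidecar = {"seed": seed, "history": history,
               "config": {k: v for k, v in model.cfg.__dict__.items()}}
    with open(str(path) + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2, default=str)


def load_checkpoint(path: str, model: SoSNet) -> SoSNet:
    data = np.load(path)
    model.load_state_dict({k: data[k] for k in data.files})
    return model
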