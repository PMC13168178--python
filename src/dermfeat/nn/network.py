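"""Dual-stream residual squeeze-excite network (DSRSENet).

A two-branch convolutional feature extractor for dermoscopy images: a
shallow stream (stride-1, three RSE blocks of 64/64/128 filters) preserving
spatial detail and a deep stream (stride-2 downsampling, four RSE blocks of
128/256/512/1024 filters) capturing fine-grained semantics. Each stream ends
in a CBAM attention block and global average pooling; the pooled descriptors
are concatenated and projected by a GeLU dense layer of width 2048, which is
the per-image deep feature vector. A dropout + sigmoid dense head on top
trains the network for benign/malignant classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .layers import CBAM, Conv2d, Dense, Dropout, GlobalAvgPool, Module, RSEBlock
from .optim import Adam


@dataclass
class NetConfig:
    """Architecture configuration.

    The filter schedules, SE ratio and head width are the model definition;
    ``input_size`` only sets the expected spatial resolution (the parameter
    count does not depend on it because each stream is globally pooled).
    """

    input_size: int = 299
    shallow_filters: tuple[int, ...] = (64, 64, 128)
    deep_filters: tuple[int, ...] = (128, 256, 512, 1024)
    stem_filters: int = 64
    se_ratio: int = 16
    block_dropout: float = 0.2
    head_width: int = 2048
    head_dropout: float = 0.3
    merge: str = "add"
    seed: int = 0

    def validate(self) -> None:
        for f in self.shallow_filters + self.deep_filters:
            if f % self.se_ratio != 0:
                raise ValueError(
                    f"SE ratio {self.se_ratio} must divide filter count {f}")
        if self.merge not in ("add", "concat"):
            raise ValueError(f"unknown merge mode {self.merge!r}")
        if self.input_size < 16:
            raise ValueError("input_size too small for the stride schedule")


@dataclass
class TrainConfig:
    learning_rate: float = 0.001
    batch_size: int = 32
    max_epochs: int = 100
    patience: int = 15
    seed: int = 0


class DSRSENet(Module):
    def __init__(self, config: NetConfig | None = None):
        super().__init__()
        self.config = config or NetConfig()
        self.config.validate()
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)

        # shallow stream: stride-1 throughout
        self.shallow_stem = Conv2d(3, cfg.stem_filters, 3, rng)
        c = cfg.stem_filters
        self.shallow_blocks: list[RSEBlock] = []
        for i, f in enumerate(cfg.shallow_filters):
            blk = RSEBlock(c, f, rng, cfg.se_ratio, cfg.block_dropout,
                           cfg.merge, stride=1)
            setattr(self, f"shallow_rse{i}", blk)
            self.shallow_blocks.append(blk)
            c = blk.out_channels
        self.shallow_cbam = CBAM(c, rng, ratio=cfg.se_ratio)
        shallow_out = c

        # deep stream: stride-2 stem and stride-2 RSE blocks
        self.deep_stem = Conv2d(3, cfg.stem_filters, 3, rng, stride=2)
        c = cfg.stem_filters
        self.deep_blocks: list[RSEBlock] = []
        for i, f in enumerate(cfg.deep_filters):
            blk = RSEBlock(c, f, rng, cfg.se_ratio, cfg.block_dropout,
                           cfg.merge, stride=2)
            setattr(self, f"deep_rse{i}", blk)
            self.deep_blocks.append(blk)
            c = blk.out_channels
        self.deep_cbam = CBAM(c, rng, ratio=cfg.se_ratio)
        deep_out = c

        self.gap = GlobalAvgPool()
        self.feature_dense = Dense(shallow_out + deep_out, cfg.head_width, rng)
        self.head_drop = Dropout(cfg.head_dropout, rng)
        self.head_dense = Dense(cfg.head_width, 1, rng)

    # -- forward passes ----------------------------------------------------
    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim != 4 or x.shape[-1] != 3:
            raise ValueError("expected images of shape (n, H, W, 3)")
        s = self.config.input_size
        if x.shape[1] != s or x.shape[2] != s:
            raise ValueError(
                f"expected {s}x{s} input, got {x.shape[1]}x{x.shape[2]}; "
                "resize explicitly before feature extraction")
        return np.ascontiguousarray(x.transpose(0, 3, 1, 2))

    def features(self, x: Tensor) -> Tensor:
        """Per-image feature vector from the post-concatenation dense layer."""
        s = self.shallow_stem(x)
        for blk in self.shallow_blocks:
            s = blk(s)
        s = self.gap(self.shallow_cbam(s))
        d = self.deep_stem(x)
        for blk in self.deep_blocks:
            d = blk(d)
        d = self.gap(self.deep_cbam(d))
        return ag.gelu(self.feature_dense(ag.concat([s, d], axis=1)))

    def logits(self, x: Tensor) -> Tensor:
        return self.head_dense(self.head_drop(self.features(x)))

    def forward(self, x: Tensor) -> Tensor:
        return ag.sigmoid(self.logits(x))


def build_network(config: NetConfig | None = None) -> DSRSENet:
    return DSRSENet(config)


def count_parameters(model: Module) -> int:
    return model.num_parameters()


def extract_features(model: DSRSENet, images: np.ndarray,
                     batch_size: int = 8) -> np.ndarray:
    """Inference-mode deep features, one row per image (order preserved)."""
    x = model._check_input(images)
    model.eval()
    out = []
    with ag.no_grad():
        for i in range(0, x.shape[0], batch_size):
            out.append(model.features(Tensor(x[i:i + batch_size])).data)
    return np.concatenate(out, axis=0)


def predict_proba(model: DSRSENet, images: np.ndarray,
                  batch_size: int = 8) -> np.ndarray:
    x = model._check_input(images)
    model.eval()
    out = []
    with ag.no_grad():
        for i in range(0, x.shape[0], batch_size):
            out.append(model(Tensor(x[i:i + batch_size])).data.ravel())
    return np.concatenate(out)


def train(model: DSRSENet, x_train: np.ndarray, y_train: np.ndarray,
          x_val: np.ndarray | None = None, y_val: np.ndarray | None = None,
          config: TrainConfig | None = None) -> dict:
    """Train with binary cross-entropy / Adam and accuracy early stopping.

    Returns a history dict with per-epoch train loss/accuracy and, when a
    validation split is given, validation loss/accuracy; early stopping
    restores the best-validation-accuracy weights.
    """
    cfg = config or TrainConfig()
    if len(x_train) == 0:
        raise ValueError("empty training split")
    y_train = np.asarray(y_train, dtype=np.float32)
    if x_val is not None and len(x_val) == 0:
        raise ValueError("empty validation split")
    xt = model._check_input(x_train)
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    history: dict[str, list[float]] = {
        "train_loss": [], "train_acc": [], "val_loss": [], "val_acc": []}
    best_acc, best_state, wait = -np.inf, None, 0
    n = xt.shape[0]
    for epoch in range(cfg.max_epochs):
        model.train()
        order = rng.permutation(n)
        losses, correct = [], 0
        for i in range(0, n, cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            xb = Tensor(xt[idx])
            logits = model.logits(xb)
            loss = ag.bce_with_logits(logits, y_train[idx])
            model.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            preds = (logits.data.ravel() > 0).astype(int)
            correct += int((preds == y_train[idx]).sum())
        history["train_loss"].append(float(np.mean(losses)))
        history["train_acc"].append(correct / n)
        if x_val is not None:
            pv = predict_proba(model, x_val)
            val_loss = float(np.mean(
                -(y_val * np.log(pv + 1e-12)
                  + (1 - np.asarray(y_val)) * np.log(1 - pv + 1e-12))))
            val_acc = float(np.mean((pv > 0.5).astype(int) == y_val))
            history["val_loss"].append(val_loss)
            history["val_acc"].append(val_acc)
            if val_acc > best_acc:
                best_acc, wait = val_acc, 0
                best_state = {k: v.copy()
                              for k, v in model.state_arrays().items()}
            else:
                wait += 1
                if wait >= cfg.patience:
                    break
    if best_state is not None:
        model.load_state_arrays(best_state)
    model.eval()
    return history


def save_checkpoint(model: DSRSENet, path: str) -> None:
    cfg = model.config
    np.savez(path,
             __config__=np.array([cfg.input_size, cfg.se_ratio,
                                  cfg.head_width, cfg.seed,
                                  1 if cfg.merge == "add" else 0]),
             **model.state_arrays())


def load_checkpoint(path: str) -> DSRSENet:
    data = np.load(path)
    c = data["__config__"]
    cfg = NetConfig(input_size=int(c[0]), se_ratio=int(c[1]),
                    head_width=int(c[2]), seed=int(c[3]),
                    merge="add" if int(c[4]) else "concat")
    model = DSRSENet(cfg)
    state = {k: data[k] for k in data.files if k != "__config__"}
    model.load_state_arrays(state)
    return model
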