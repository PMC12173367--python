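"""The SE-multi-input CNN: two convolutional branches over the dual-scale
spectrograms, squeeze-and-excitation channel attention, bicubic feature
fusion, and a softmax head.

Branch A consumes the single-cycle spectrogram with 3x3 kernels, branch B
the three-cycle spectrogram with 5x5 kernels; both stack four stride-1
same-padded conv+ReLU layers with 4, 8, 16 and 32 filters, with SE gates
after the third (16 channels, reduced to 8) and fourth (32 channels,
reduced to 16) convolutions.  Branch B's feature map is bicubically
resized to branch A's spatial grid and the two maps are summed
element-wise, passed through a trainable per-channel normalization,
flattened, and classified by a 64-unit hidden layer and a softmax output.

Spectrogram inputs are standardized per image (zero mean, unit variance)
before entering the network.  Training minimises cross-entropy against
(possibly soft, Mixup-produced) target distributions with Adam.

Ablation variants are selected by config: ``branch_mode`` keeps only one
branch, ``use_se`` drops the SE gates.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .nn import (
    Adam,
    BatchNorm2D,
    BicubicResize2D,
    Conv2D,
    Dense,
    ReLU,
    SEBlock,
    softmax,
    softmax_cross_entropy,
)

__all__ = ["ModelConfig", "TrainReport", "SEMultiInputCNN", "standardize"]


@dataclass(frozen=True)
class ModelConfig:
    n_classes: int = 5
    branch_mode: str = "both"  # "both" | "single" | "three"
    use_se: bool = True
    filters: tuple[int, ...] = (4, 8, 16, 32)
    kernel_single: int = 3
    kernel_three: int = 5
    fc_hidden: int = 64
    epochs: int = 30
    batch_size: int = 256
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("need at least two classes")
        if self.branch_mode not in ("both", "single", "three"):
            raise ValueError("branch_mode must be 'both', 'single' or 'three'")
        if any(b <= a for a, b in zip(self.filters, self.filters[1:])):
            raise ValueError("filter counts must be strictly increasing")


@dataclass
class TrainReport:
    epochs: int
    train_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)


def standardize(images: np.ndarray) -> np.ndarray:
    """Per-image zero-mean unit-variance normalization of (..., H, W) stacks."""
    images = np.asarray(images, dtype=np.float32)
    mean = images.mean(axis=(-2, -1), keepdims=True)
    std = images.std(axis=(-2, -1), keepdims=True)
    return (images - mean) / np.maximum(std, 1e-8)


def _build_branch(kernel: int, filters, use_se: bool, rng):
    layers = []
    c_in = 1
    for i, c_out in enumerate(filters):
        layers.append(Conv2D(kernel, c_in, c_out, rng))
        layers.append(ReLU())
        if use_se and i >= len(filters) - 2:  # after conv 3 and conv 4
            layers.append(SEBlock(c_out, c_out // 2, rng))
        c_in = c_out
    return layers


def _seq_forward(layers, x, train):
    for l in layers:
        x = l.forward(x, train=train)
    return x


def _seq_backward(layers, d):
    for l in reversed(layers):
        d = l.backward(d)
    return d


class SEMultiInputCNN:
    """Dual-branch SE-attention classifier over spectrogram pairs.

    ``shape_single`` / ``shape_three`` are the (rows, cols) of the two
    spectrogram inputs; they are fixed at construction.
    """

    def __init__(
        self,
        cfg: ModelConfig,
        shape_single: tuple[int, int],
        shape_three: tuple[int, int],
    ):
        self.cfg = cfg
        self.shape_single = tuple(shape_single)
        self.shape_three = tuple(shape_three)
        rng = np.random.default_rng(cfg.seed)
        c_top = cfg.filters[-1]

        self.branch_a = (
            _build_branch(cfg.kernel_single, cfg.filters, cfg.use_se, rng)
            if cfg.branch_mode in ("both", "single")
            else []
        )
        self.branch_b = (
            _build_branch(cfg.kernel_three, cfg.filters, cfg.use_se, rng)
            if cfg.branch_mode in ("both", "three")
            else []
        )
        self.fuse_resize = (
            BicubicResize2D(self.shape_three, self.shape_single)
            if cfg.branch_mode == "both"
            else None
        )
        fused_shape = self.shape_three if cfg.branch_mode == "three" else self.shape_single
        self.post_norm = BatchNorm2D(c_top)
        self.n_flat = fused_shape[0] * fused_shape[1] * c_top
        self.fc1 = Dense(self.n_flat, cfg.fc_hidden, rng)
        self.fc1_act = ReLU()
        self.fc2 = Dense(cfg.fc_hidden, cfg.n_classes, rng)
        self.head = [self.post_norm, self.fc1, self.fc1_act, self.fc2]

    # ---- forward / backward -------------------------------------------------

    @property
    def layers(self):
        return self.branch_a + self.branch_b + self.head

    def _check(self, x, name, shape):
        if x.shape[1:] != shape:
            raise ValueError(f"{name} input has shape {x.shape[1:]}, expected {shape}")
        if not np.all(np.isfinite(x)):
            raise ValueError(f"non-finite values in {name} input")

    def forward(self, xa: np.ndarray | None, xb: np.ndarray | None, train: bool = False):
        """Class probabilities for a batch of (single, three) spectrogram pairs."""
        mode = self.cfg.branch_mode
        fa = fb = None
        if mode in ("both", "single"):
            self._check(xa, "single-cycle", self.shape_single)
            fa = _seq_forward(self.branch_a, xa[..., None].astype(np.float32), train)
        if mode in ("both", "three"):
            self._check(xb, "three-cycle", self.shape_three)
            fb = _seq_forward(self.branch_b, xb[..., None].astype(np.float32), train)
        if mode == "both":
            fused = fa + self.fuse_resize.forward(fb, train=train)
        else:
            fused = fa if mode == "single" else fb
        h = self.post_norm.forward(fused, train=train)
        flat = h.reshape(h.shape[0], -1)
        z = self.fc2.forward(
            self.fc1_act.forward(self.fc1.forward(flat, train=train), train=train), train=train
        )
        if train:
            self._fused_shape = fused.shape
        return z  # logits; apply softmax() for probabilities

    def predict_proba(self, xa, xb, batch_size: int = 32) -> np.ndarray:
        n = (xa if xa is not None else xb).shape[0]
        out = []
        for i in range(0, n, batch_size):
            sl = slice(i, i + batch_size)
            out.append(
                softmax(
                    self.forward(
                        None if xa is None else xa[sl],
                        None if xb is None else xb[sl],
                        train=False,
                    )
                )
            )
        return np.concatenate(out, axis=0)

    def predict(self, xa, xb, batch_size: int = 32) -> np.ndarray:
        return self.predict_proba(xa, xb, batch_size).argmax(axis=1)

    def _backward(self, dlogits):
        d = self.fc2.backward(dlogits)
        d = self.fc1.backward(self.fc1_act.backward(d))
        d = self.post_norm.backward(d.reshape(self._fused_shape))
        mode = self.cfg.branch_mode
        if mode == "both":
            _seq_backward(self.branch_a, d)
            _seq_backward(self.branch_b, self.fuse_resize.backward(d))
        elif mode == "single":
            _seq_backward(self.branch_a, d)
        else:
            _seq_backward(self.branch_b, d)

    # ---- training -----------------------------------------------------------

    def train(
        self,
        xa: np.ndarray | None,
        xb: np.ndarray | None,
        targets: np.ndarray,
        val: tuple | None = None,
    ) -> TrainReport:
        """Mini-batch Adam training on soft target distributions.

        ``targets`` is (N, n_classes) on the probability simplex.  ``val``
        optionally holds (xa, xb, targets) evaluated after each epoch.
        """
        cfg = self.cfg
        n = targets.shape[0]
        if n == 0:
            raise ValueError("empty training set")
        if targets.ndim != 2 or targets.shape[1] != cfg.n_classes:
            raise ValueError("targets must be (N, n_classes) distributions")
        opt = Adam(self.layers, lr=cfg.learning_rate)
        rng = np.random.default_rng(cfg.seed + 1)
        report = TrainReport(epochs=cfg.epochs)
        for _ in range(cfg.epochs):
            order = rng.permutation(n)
            losses, correct = [], 0
            for i in range(0, n, cfg.batch_size):
                idx = order[i : i + cfg.batch_size]
                logits = self.forward(
                    None if xa is None else xa[idx],
                    None if xb is None else xb[idx],
                    train=True,
                )
                loss, dlogits = softmax_cross_entropy(logits, targets[idx])
                losses.append(loss * idx.size)
                correct += int((logits.argmax(1) == targets[idx].argmax(1)).sum())
                self._backward(dlogits)
                opt.step()
            report.train_loss.append(float(np.sum(losses) / n))
            report.train_acc.append(correct / n)
            if val is not None:
                va, vb, vt = val
                probs = self.predict_proba(va, vb)
                eps = 1e-12
                report.val_loss.append(float(-(vt * np.log(probs + eps)).sum(1).mean()))
                report.val_acc.append(float((probs.argmax(1) == vt.argmax(1)).mean()))
        return report

    # ---- persistence --------------------------------------------------------

    def save(self, path: str) -> None:
        """Write weights + config to an .npz checkpoint."""
        arrays = {}
        for i, layer in enumerate(self.layers):
            for k, v in layer.params.items():
                arrays[f"layer{i}:{k}"] = v
        arrays["post_norm:running_mean"] = self.post_norm.running_mean
        arrays["post_norm:running_var"] = self.post_norm.running_var
        meta = {
            "config": asdict(self.cfg),
            "shape_single": list(self.shape_single),
            "shape_three": list(self.shape_three),
        }
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str) -> "SEMultiInputCNN":
        data = np.load(path)
        meta = json.loads(bytes(data["__meta__"]).decode())
        cfg_d = meta["config"]
        cfg_d["filters"] = tuple(cfg_d["filters"])
        model = cls(ModelConfig(**cfg_d), tuple(meta["shape_single"]), tuple(meta["shape_three"]))
        for i, layer in enumerate(model.layers):
            for k in layer.params:
                layer.params[k][...] = data[f"layer{i}:{k}"]
        model.post_norm.running_mean[...] = data["post_norm:running_mean"]
        model.post_norm.running_var[...] = data["post_norm:running_var"]
        return model
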