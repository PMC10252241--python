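"""Symbolic layer plan for the dense-block classifier and its instantiation.

The plan is an ordered, human-readable description of the ten-stage stack
(stem convolution, max-pool, four dense blocks interleaved with three
transition layers, classification head) with the spatial tensor size
computed per stage.  ``instantiate_network`` turns a plan into a runnable
NumPy model whose probed shapes match the plan.

The stand-alone size calculators (``conv_output_size`` with its stride-1
``l - m + 1`` special case, and the literal max-pool element-count formula)
are kept separate from the builder: the builder uses "same"-style padding
(p=3 for the 7x7 stem, p=1 for the 3x3 pool), which is the only convention
that yields the 224 -> 112 -> 56 -> ... -> 7 -> 1 progression.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import nn

__all__ = [
    "LayerSpec",
    "LayerPlan",
    "build_layer_plan",
    "conv_output_size",
    "maxpool_size_eq2",
    "sgd_update",
    "instantiate_network",
    "PlanNet",
]

DEFAULT_BLOCK_LAYERS = (6, 12, 32, 32)  # DenseNet-169 layers per dense block
DEFAULT_GROWTH_RATE = 32


@dataclass(frozen=True)
class LayerSpec:
    name: str
    kind: str  # convolution | maxpool | dense_block | transition | classification
    kernel: str
    stride: int
    dropout: float
    activation: str  # relu | softmax | none
    out_spatial: int


@dataclass(frozen=True)
class LayerPlan:
    layers: tuple[LayerSpec, ...]
    input_size: tuple[int, int, int]  # (H, W, C)
    num_classes: int
    growth_rate: int = DEFAULT_GROWTH_RATE
    block_layers: tuple[int, ...] = DEFAULT_BLOCK_LAYERS
    stem_channels: int = field(default=0)

    def spatial_sizes(self) -> list[int]:
        return [spec.out_spatial for spec in self.layers]

    def to_table(self) -> str:
        rows = [f"{'Layer':<16}{'Kernel':<24}{'Parameters':<28}{'Tensor size'}"]
        for s in self.layers:
            params = []
            if s.kind in ("convolution", "maxpool", "transition"):
                params.append(f"Stride = {s.stride}")
            if s.dropout:
                params.append(f"Dropout = {s.dropout}")
            if s.activation != "none":
                params.append(s.activation.capitalize())
            rows.append(
                f"{s.name:<16}{s.kernel:<24}{', '.join(params):<28}"
                f"{s.out_spatial}x{s.out_spatial}"
            )
        return "\n".join(rows)

    def to_json(self) -> str:
        return json.dumps(
            {
                "input_size": list(self.input_size),
                "num_classes": self.num_classes,
                "growth_rate": self.growth_rate,
                "block_layers": list(self.block_layers),
                "layers": [vars(s) for s in self.layers],
            },
            indent=2,
        )

    def fingerprint(self) -> str:
        return json.dumps(
            {
                "input_size": list(self.input_size),
                "num_classes": self.num_classes,
                "growth_rate": self.growth_rate,
                "block_layers": list(self.block_layers),
                "spatial": self.spatial_sizes(),
            },
            sort_keys=True,
        )


def conv_output_size(in_size: int, kernel: int, stride: int = 1, padding: int = 0) -> int:
    """``floor((l - m + 2p) / s) + 1``; reduces to ``l - m + 1`` at s=1, p=0."""
    if kernel > in_size + 2 * padding:
        raise ValueError(
            f"kernel {kernel} exceeds padded input {in_size + 2 * padding}"
        )
    if stride < 1 or padding < 0 or in_size < 1:
        raise ValueError("require in_size >= 1, stride >= 1, padding >= 0")
    return (in_size - kernel + 2 * padding) // stride + 1


def maxpool_size_eq2(n_h: int, n_w: int, n_c: int, f: int, s: int) -> float:
    """Literal pooled element count ``n_c * (n_h - f + 1) * (n_w - f + 1) / s**2``.

    A real number, not guaranteed integral — kept as a calculator, not used
    by the model builder (which pools with padding to preserve the halving
    progression).
    """
    if f > n_h or f > n_w:
        raise ValueError(f"filter {f} larger than feature map {n_h}x{n_w}")
    if s < 1:
        raise ValueError("stride must be >= 1")
    return n_c * (n_h - f + 1) * (n_w - f + 1) / s**2


def sgd_update(param, grad, lr: float):
    """Plain gradient step ``phi - lr * dphi``; applies to weights and biases."""
    param = np.asarray(param, dtype=np.float64) if np.isscalar(param) else np.asarray(param)
    grad = np.asarray(grad, dtype=param.dtype if param.dtype.kind == "f" else np.float64)
    if not (np.all(np.isfinite(param)) and np.all(np.isfinite(grad)) and np.isfinite(lr)):
        raise ValueError("sgd_update requires finite param, grad and learning rate")
    out = param - lr * grad
    return out.item() if out.ndim == 0 else out


def build_layer_plan(
    input_size: tuple[int, int, int],
    num_classes: int,
    growth_rate: int = DEFAULT_GROWTH_RATE,
    block_layers: Sequence[int] = DEFAULT_BLOCK_LAYERS,
) -> LayerPlan:
    """Construct the ten-row plan; for 224x224 input the spatial column is
    [112, 56, 56, 28, 28, 14, 14, 7, 7, 1].

    Requires a square input with side divisible by 16; odd intermediate
    sizes are floor-halved (the realized pooling crops the odd edge row).
    """
    h, w, c = input_size
    if h != w:
        raise ValueError(f"input must be square, got {h}x{w}")
    if h % 16:
        raise ValueError(f"input side must be divisible by 16, got {h}")
    if num_classes < 2:
        raise ValueError("num_classes must be >= 2")
    if len(block_layers) != 4:
        raise ValueError("exactly four dense blocks are required")

    layers: list[LayerSpec] = []
    s = conv_output_size(h, 7, stride=2, padding=3)
    layers.append(LayerSpec("Convolution", "convolution", "Conv=7x7", 2, 0.0, "relu", s))
    s = conv_output_size(s, 3, stride=2, padding=1)
    layers.append(LayerSpec("Pooling", "maxpool", "MaxPool=3x3", 2, 0.0, "none", s))
    for i, n_layers in enumerate(block_layers, start=1):
        layers.append(
            LayerSpec(
                f"Dense {i}",
                "dense_block",
                f"Conv=1x1x{n_layers} Conv=3x3x{n_layers}",
                1,
                0.2,
                "relu",
                s,
            )
        )
        if i < 4:
            s //= 2
            layers.append(
                LayerSpec(
                    f"Transition {i}",
                    "transition",
                    "Conv=1x1 AvgPool=2x2",
                    2,
                    0.0,
                    "relu",
                    s,
                )
            )
    layers.append(
        LayerSpec(
            "Classification",
            "classification",
            f"AvgPool={s}x{s} {num_classes}D fully connected",
            1,
            0.0,
            "softmax",
            1,
        )
    )
    plan = LayerPlan(
        layers=tuple(layers),
        input_size=(h, w, c),
        num_classes=num_classes,
        growth_rate=growth_rate,
        block_layers=tuple(block_layers),
        stem_channels=2 * growth_rate,
    )
    sizes = plan.spatial_sizes()
    assert all(a >= b for a, b in zip(sizes, sizes[1:])), "spatial sizes must not increase"
    return plan


class _DenseBlock:
    """n composite layers: 1x1 bottleneck -> relu -> 3x3 -> relu -> dropout,
    each appending `growth` channels to the running feature stack."""

    def __init__(self, in_ch: int, n_layers: int, growth: int, dropout: float,
                 rng: np.random.Generator, drop_rng: np.random.Generator):
        self.layers = []
        ch = in_ch
        for _ in range(n_layers):
            bottleneck = min(4 * growth, max(ch, growth))
            self.layers.append(
                {
                    "conv1": nn.Conv2d(ch, bottleneck, 1, rng=rng),
                    "relu1": nn.ReLU(),
                    "conv2": nn.Conv2d(bottleneck, growth, 3, pad=1, rng=rng),
                    "relu2": nn.ReLU(),
                    "drop": nn.Dropout(dropout, drop_rng),
                }
            )
            ch += growth
        self.out_ch = ch

    def forward(self, x, train=False):
        self._in_ch = []
        feats = x
        for lyr in self.layers:
            self._in_ch.append(feats.shape[1])
            h = lyr["conv1"].forward(feats, train)
            h = lyr["relu1"].forward(h, train)
            h = lyr["conv2"].forward(h, train)
            h = lyr["relu2"].forward(h, train)
            h = lyr["drop"].forward(h, train)
            feats = np.concatenate([feats, h], axis=1)
        return feats

    def backward(self, dout):
        for lyr, in_ch in zip(reversed(self.layers), reversed(self._in_ch)):
            dfeats, dh = dout[:, :in_ch], dout[:, in_ch:]
            dh = lyr["drop"].backward(dh)
            dh = lyr["relu2"].backward(dh)
            dh = lyr["conv2"].backward(dh)
            dh = lyr["relu1"].backward(dh)
            dh = lyr["conv1"].backward(dh)
            dout = dfeats + dh
        return dout

    def params(self):
        return [p for lyr in self.layers for m in ("conv1", "conv2") for p in lyr[m].params()]

    def grads(self):
        return [g for lyr in self.layers for m in ("conv1", "conv2") for g in lyr[m].grads()]


class _Transition:
    """1x1 channel-halving convolution -> relu -> 2x2 average pool."""

    def __init__(self, in_ch: int, rng: np.random.Generator):
        self.out_ch = max(in_ch // 2, 1)
        self.conv = nn.Conv2d(in_ch, self.out_ch, 1, rng=rng)
        self.relu = nn.ReLU()
        self.pool = nn.AvgPool2d(2)

    def forward(self, x, train=False):
        return self.pool.forward(self.relu.forward(self.conv.forward(x, train), train), train)

    def backward(self, dout):
        return self.conv.backward(self.relu.backward(self.pool.backward(dout)))

    def params(self):
        return self.conv.params()

    def grads(self):
        return self.conv.grads()


class PlanNet:
    """Runnable model conforming to a :class:`LayerPlan`.

    Construction is deterministic per seed.  ``probe_shapes`` reports the
    per-stage output spatial size (pixels per side) so the realized network
    can be checked against the symbolic plan.
    """

    def __init__(self, plan: LayerPlan, seed: int):
        self.plan = plan
        self.seed = seed
        rng = np.random.default_rng(seed)
        self._drop_rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
        h, w, c = plan.input_size
        g = plan.growth_rate
        self.stem = nn.Conv2d(c, plan.stem_channels, 7, stride=2, pad=3, rng=rng)
        self.stem_relu = nn.ReLU()
        self.pool = nn.MaxPool2d(3, 2, pad=1)
        ch = plan.stem_channels
        self.blocks: list = []
        for i, n_layers in enumerate(plan.block_layers):
            blk = _DenseBlock(ch, n_layers, g, 0.2, rng, self._drop_rng)
            ch = blk.out_ch
            self.blocks.append(blk)
            if i < 3:
                tr = _Transition(ch, rng)
                ch = tr.out_ch
                self.blocks.append(tr)
        self.gap = nn.GlobalAvgPool()
        self.head = nn.Linear(ch, plan.num_classes, rng=rng)
        self._modules = [self.stem, *self.blocks, self.head]

    # ------------------------------------------------------------------ core
    def forward_logits(self, x: np.ndarray, train: bool = False,
                       record_shapes: list | None = None) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[:, None]
        if x.shape[1] != self.plan.input_size[2] or x.shape[2] != self.plan.input_size[0]:
            raise ValueError(
                f"input {x.shape[1:]} does not match plan input {self.plan.input_size}"
            )
        # per-image standardization: centers the raw [0,1] grayscale input so
        # plain SGD conditions well; constants per image, so gradients pass
        # through unchanged
        mu = x.mean(axis=(2, 3), keepdims=True)
        sd = x.std(axis=(2, 3), keepdims=True) + 1e-6
        x = (x - mu) / sd
        rec = record_shapes if record_shapes is not None else None
        h = self.stem_relu.forward(self.stem.forward(x, train), train)
        if rec is not None:
            rec.append(h.shape[-1])
        h = self.pool.forward(h, train)
        if rec is not None:
            rec.append(h.shape[-1])
        for mod in self.blocks:
            h = mod.forward(h, train)
            if rec is not None:
                rec.append(h.shape[-1])
        h = self.gap.forward(h, train)
        if rec is not None:
            rec.append(1)
        return self.head.forward(h, train)

    def _backward(self, dlogits: np.ndarray) -> None:
        d = self.head.backward(dlogits)
        d = self.gap.backward(d)
        for mod in reversed(self.blocks):
            d = mod.backward(d)
        d = self.pool.backward(d)
        self.stem.backward(self.stem_relu.backward(d))

    # ------------------------------------------------------------- interface
    def probe_shapes(self) -> list[int]:
        """Spatial size after each plan row, via a forward pass on zeros."""
        h, w, c = self.plan.input_size
        rec: list[int] = []
        self.forward_logits(np.zeros((1, c, h, w), dtype=np.float32), record_shapes=rec)
        return rec

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        outs = []
        x = np.asarray(x, dtype=np.float32)
        for i in range(0, len(x), batch_size):
            outs.append(nn.softmax(self.forward_logits(x[i : i + batch_size])))
        return np.concatenate(outs, axis=0)

    def train_step(self, x: np.ndarray, y: np.ndarray, lr: float,
                   grad_scale: float | None = None) -> float:
        logits = self.forward_logits(x, train=True)
        loss, dlogits = nn.softmax_ce_loss_grad(logits, np.asarray(y), grad_scale)
        self._backward(dlogits)
        for p, g in zip(self.parameters(), self.gradients()):
            p[...] = sgd_update(p, g, lr)
        return loss

    def eval_loss(self, x: np.ndarray, y: np.ndarray) -> float:
        logits = self.forward_logits(x)
        loss, _ = nn.softmax_ce_loss_grad(logits, np.asarray(y))
        return loss

    def parameters(self) -> list[np.ndarray]:
        return [p for m in self._modules for p in m.params()]

    def gradients(self) -> list[np.ndarray]:
        return [g for m in self._modules for g in m.grads()]

    def get_state(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters()]

    def set_state(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError("state does not match model parameter count")
        for p, s in zip(params, state):
            if p.shape != s.shape:
                raise ValueError("checkpoint/plan mismatch: parameter shapes differ")
            p[...] = s

    # ------------------------------------------------------------ checkpoint
    def save_checkpoint(self, path) -> None:
        arrays = {f"p{i}": p for i, p in enumerate(self.parameters())}
        np.savez(path, fingerprint=np.array(self.plan.fingerprint()), **arrays)

    def load_checkpoint(self, path) -> None:
        data = np.load(path, allow_pickle=False)
        fp = str(data["fingerprint"])
        if fp != self.plan.fingerprint():
            raise ValueError("checkpoint fingerprint does not match this plan")
        self.set_state([data[f"p{i}"] for i in range(len(self.parameters()))])


def instantiate_network(plan: LayerPlan, seed: int) -> PlanNet:
    """Build a runnable model from the plan; deterministic per seed."""
    return PlanNet(plan, seed)
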