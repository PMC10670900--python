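"""Residual U-Net for slice-to-slice CT synthesis.

Layout: one conventional convolution block (two 3x3 convs), ``depth``
encoder residual blocks each preceded by 2x2 max-pooling with filter counts
doubling per level, ``depth`` up-sampling residual blocks (2x2/stride-2
transposed convolution, skip concatenation, residual block with filters
halving), and a linear 1x1 output head.  Batch normalisation follows every
convolution except the head; the residual shortcut is the identity when the
channel counts match and a 1x1 projection otherwise.

Spatial sides must be divisible by ``2**depth`` so skip tensors line up
without cropping.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass

import numpy as np

from .layers import (
    BatchNorm2d,
    Conv1x1,
    Conv3x3,
    ConvTranspose2x2,
    MaxPool2x2,
    ReLU,
)

__all__ = [
    "NetworkConfig",
    "ResidualUNet",
    "build_model",
    "parameter_checksum",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyper-parameters.

    ``base_filters`` is the stem width; each encoder level doubles it
    (64 -> 1024 at depth 4 for the full model; tests use 8-16).
    """

    in_channels: int = 1
    out_channels: int = 1
    depth: int = 4
    base_filters: int = 64
    batch_norm: bool = True

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.base_filters < 4:
            raise ValueError("base_filters must be >= 4")

    @property
    def divisor(self) -> int:
        return 2**self.depth


class _ConvBlock:
    """conv3x3 -> [BN] -> ReLU, twice."""

    def __init__(self, cin, cout, rng, use_bn):
        self.layers = [Conv3x3(cin, cout, rng, bias=not use_bn)]
        if use_bn:
            self.layers.append(BatchNorm2d(cout))
        self.layers.append(ReLU())
        self.layers.append(Conv3x3(cout, cout, rng, bias=not use_bn))
        if use_bn:
            self.layers.append(BatchNorm2d(cout))
        self.layers.append(ReLU())

    def forward(self, x, training):
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def sublayers(self):
        return self.layers


class _ResBlock:
    """Residual block: main path conv-BN-ReLU-conv-BN, shortcut added
    before the final ReLU; 1x1+BN projection when channels change."""

    def __init__(self, cin, cout, rng, use_bn):
        self.conv1 = Conv3x3(cin, cout, rng, bias=not use_bn)
        self.bn1 = BatchNorm2d(cout) if use_bn else None
        self.relu1 = ReLU()
        self.conv2 = Conv3x3(cout, cout, rng, bias=not use_bn)
        self.bn2 = BatchNorm2d(cout) if use_bn else None
        if self.bn2 is not None:
            # zero-gamma residual init: the block starts as (a rectified
            # projection of) its shortcut, which stabilises early training
            self.bn2.gamma.value[...] = 0.0
        if cin != cout:
            self.proj = Conv1x1(cin, cout, rng, bias=not use_bn)
            self.proj_bn = BatchNorm2d(cout) if use_bn else None
        else:
            self.proj = None
            self.proj_bn = None
        self.relu_out = ReLU()

    def forward(self, x, training):
        h = self.conv1.forward(x, training)
        if self.bn1:
            h = self.bn1.forward(h, training)
        h = self.relu1.forward(h, training)
        h = self.conv2.forward(h, training)
        if self.bn2:
            h = self.bn2.forward(h, training)
        if self.proj is not None:
            s = self.proj.forward(x, training)
            if self.proj_bn:
                s = self.proj_bn.forward(s, training)
        else:
            s = x
        return self.relu_out.forward(h + s, training)

    def backward(self, dy):
        dy = self.relu_out.backward(dy)
        ds = dy
        if self.proj is not None:
            if self.proj_bn:
                ds = self.proj_bn.backward(ds)
            dx_short = self.proj.backward(ds)
        else:
            dx_short = ds
        dh = dy
        if self.bn2:
            dh = self.bn2.backward(dh)
        dh = self.conv2.backward(dh)
        dh = self.relu1.backward(dh)
        if self.bn1:
            dh = self.bn1.backward(dh)
        dx_main = self.conv1.backward(dh)
        return dx_main + dx_short

    def sublayers(self):
        out = [self.conv1]
        if self.bn1:
            out.append(self.bn1)
        out.append(self.conv2)
        if self.bn2:
            out.append(self.bn2)
        if self.proj is not None:
            out.append(self.proj)
            if self.proj_bn:
                out.append(self.proj_bn)
        return out


class ResidualUNet:
    """The full encoder-decoder with explicit forward/backward wiring."""

    def __init__(self, cfg: NetworkConfig, seed: int):
        self.cfg = cfg
        self.seed = seed
        rng = np.random.default_rng(seed)
        f = cfg.base_filters
        bn = cfg.batch_norm

        self.stem = _ConvBlock(cfg.in_channels, f, rng, bn)
        self.pools = []
        self.enc = []
        ch = f
        for _ in range(cfg.depth):
            self.pools.append(MaxPool2x2())
            self.enc.append(_ResBlock(ch, ch * 2, rng, bn))
            ch *= 2
        self.ups = []
        self.dec = []
        for _ in range(cfg.depth):
            self.ups.append(ConvTranspose2x2(ch, ch // 2, rng))
            # concatenated skip doubles the input channels again
            self.dec.append(_ResBlock(ch, ch // 2, rng, bn))
            ch //= 2
        # output head starts small so initial predictions sit near the
        # data scale instead of amplifying feature noise
        self.head = Conv1x1(ch, cfg.out_channels, rng, bias=True, w_scale=0.1)
        self._skip_channels = None

    # -- graph execution ---------------------------------------------------

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Map a (N, C, H, W) batch to a batch of the same shape."""
        x = np.ascontiguousarray(x, dtype=np.float32)
        if x.ndim != 4:
            raise ValueError(f"expected NCHW batch, got shape {x.shape}")
        h, w = x.shape[2], x.shape[3]
        d = self.cfg.divisor
        if h % d or w % d:
            raise ValueError(
                f"spatial sides ({h}x{w}) must be divisible by 2**depth = {d}"
            )
        skips = []
        out = self.stem.forward(x, training)
        for pool, block in zip(self.pools, self.enc):
            skips.append(out)
            out = pool.forward(out, training)
            out = block.forward(out, training)
        self._skip_channels = []
        for up, block in zip(self.ups, self.dec):
            out = up.forward(out, training)
            skip = skips.pop()
            self._skip_channels.append(skip.shape[1])
            out = np.concatenate([skip, out], axis=1)
            out = block.forward(out, training)
        return self.head.forward(out, training)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        """Backpropagate d(loss)/d(output); accumulates parameter grads."""
        dy = np.ascontiguousarray(dy, dtype=np.float32)
        d = self.head.backward(dy)
        dskips = []
        for up, block, c_skip in zip(
            reversed(self.ups), reversed(self.dec), reversed(self._skip_channels)
        ):
            d = block.backward(d)
            dskips.append(d[:, :c_skip])
            d = up.backward(d[:, c_skip:])
        for pool, block, dskip in zip(
            reversed(self.pools), reversed(self.enc), reversed(dskips)
        ):
            d = block.backward(d)
            d = pool.backward(d)
            d = d + dskip
        return self.stem.backward(d)

    # -- parameter access --------------------------------------------------

    def _blocks(self):
        yield "stem", self.stem.sublayers()
        for i, b in enumerate(self.enc):
            yield f"enc{i}", b.sublayers()
        for i, (u, b) in enumerate(zip(self.ups, self.dec)):
            yield f"up{i}", [u]
            yield f"dec{i}", b.sublayers()
        yield "head", [self.head]

    def named_params(self):
        for bname, layers in self._blocks():
            for li, layer in enumerate(layers):
                for pname, p in layer.params():
                    yield f"{bname}.{li}.{pname}", p

    def named_state(self):
        for bname, layers in self._blocks():
            for li, layer in enumerate(layers):
                for sname, arr in layer.state():
                    yield f"{bname}.{li}.{sname}", arr

    def zero_grad(self) -> None:
        for _, p in self.named_params():
            p.zero_grad()

    def n_parameters(self) -> int:
        return sum(p.value.size for _, p in self.named_params())

    def state_dict(self) -> dict[str, np.ndarray]:
        d = {f"param/{k}": p.value.copy() for k, p in self.named_params()}
        d.update({f"state/{k}": v.copy() for k, v in self.named_state()})
        return d

    def load_state_dict(self, d: dict[str, np.ndarray]) -> None:
        for k, p in self.named_params():
            p.value[...] = d[f"param/{k}"]
        for k, arr in self.named_state():
            arr[...] = d[f"state/{k}"]


def build_model(cfg: NetworkConfig, seed: int = 0) -> ResidualUNet:
    """Construct a seeded residual U-Net (He-initialised convolutions)."""
    return ResidualUNet(cfg, seed)


def parameter_checksum(model: ResidualUNet) -> str:
    """SHA-256 over all parameters and running statistics, in a fixed order."""
    h = hashlib.sha256()
    d = model.state_dict()
    for k in sorted(d):
        h.update(k.encode())
        h.update(np.ascontiguousarray(d[k]).tobytes())
    return h.hexdigest()


def save_checkpoint(model: ResidualUNet, path, provenance: dict | None = None) -> None:
    """Single-file archive: parameters, running stats, config, provenance."""
    meta = {
        "format_version": 1,
        "config": asdict(model.cfg),
        "seed": model.seed,
        "provenance": provenance or {},
    }
    arrays = model.state_dict()
    arrays["__meta__"] = np.frombuffer(
        json.dumps(meta).encode("utf-8"), dtype=np.uint8
    ).copy()
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_checkpoint(path) -> tuple[ResidualUNet, dict]:
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["__meta__"]).decode("utf-8"))
        if meta.get("format_version") != 1:
            raise ValueError(f"unsupported checkpoint version: {meta}")
        cfg = NetworkConfig(**meta["config"])
        model = build_model(cfg, seed=meta["seed"])
        d = {k: npz[k] for k in npz.files if k != "__meta__"}
    model.load_state_dict(d)
    return model, meta["provenance"]
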