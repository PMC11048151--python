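"""W-shaped 1-D encoder-decoder architectures for PPG -> ECG translation.

The model is two cascaded U-shaped encoder-decoder blocks ("WNet").  Each U
has four down blocks (strided conv k4/s2 + batch norm + ReLU, halving the
length 384 -> 192 -> 96 -> 48 -> 24 while doubling channels from a base of
32), a dropout (0.5) bottleneck, and four up blocks (transposed conv k4/s2 +
batch norm + ReLU) with skip concatenation from the same-level encoder
output.  Input segments of 375 samples are constant-padded to 384 on entry
(375 is odd, so repeated halving needs the pad) and cropped back on exit;
the second U's output passes a final 1x1 convolution activated by Tanh, so
every output sample lies in [-1, 1].

The ``wnet_bilstm`` variant additionally runs one bidirectional LSTM over
the 24 bottleneck steps of the second U (hidden size = half the bottleneck
channels per direction, concatenated back), capturing the beat-to-beat
rhythm context between the contraction and expansion paths.

Every architectural degree of freedom lives in :class:`ModelSpec`; the
kernel size (4), stride (2) and dropout rate (0.5) are fixed properties of
the architecture and are validated rather than silently changed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import List, Optional, Tuple

import numpy as np

from . import nn
from .recordio import child_seed

__all__ = ["ModelSpec", "WNet", "build_model", "count_parameters", "model_summary"]

SEGMENT_LEN = 375


@dataclass
class ModelSpec:
    """Hyperparameters fully determining a WNet or WNet-BiLSTM instance."""

    variant: str = "wnet"
    in_len: int = SEGMENT_LEN
    levels: int = 4
    base_channels: int = 32
    kernel_size: int = 4
    stride: int = 2
    dropout: float = 0.5
    upsample_conv: bool = False  # replace transposed convs by upsample+conv
    seed: int = 0
    allow_custom_len: bool = False

    def __post_init__(self) -> None:
        if self.variant not in ("wnet", "wnet_bilstm"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.kernel_size != 4 or self.stride != 2:
            raise ValueError("kernel size 4 and stride 2 are fixed by the architecture")
        if self.dropout != 0.5:
            raise ValueError("dropout rate 0.5 is fixed by the architecture")
        if self.in_len != SEGMENT_LEN and not self.allow_custom_len:
            raise ValueError(
                f"in_len {self.in_len} != {SEGMENT_LEN}; set allow_custom_len to override"
            )
        if self.levels < 1:
            raise ValueError("levels must be >= 1")

    @property
    def padded_len(self) -> int:
        mult = self.stride**self.levels
        return ((self.in_len + mult - 1) // mult) * mult

    @property
    def bottleneck_channels(self) -> int:
        return self.base_channels * 2 ** (self.levels - 1)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ModelSpec":
        return cls(**json.loads(text))


class _DownBlock(nn.Module):
    """Strided conv + batch norm + ReLU (one encoder level)."""

    def __init__(self, c_in: int, c_out: int, spec: ModelSpec, rng, name: str):
        self.name = name
        self.block = nn.Sequential(
            nn.Conv1d(c_in, c_out, spec.kernel_size, spec.stride, 1, rng, f"{name}.conv"),
            nn.BatchNorm1d(c_out, name=f"{name}.bn"),
            nn.ReLU(),
        )

    def forward(self, x):
        return self.block.forward(x)

    def backward(self, g):
        return self.block.backward(g)


class _UpBlock(nn.Module):
    """Transposed conv (or upsample+conv) + batch norm + ReLU (one decoder level)."""

    def __init__(self, c_in: int, c_out: int, spec: ModelSpec, rng, name: str):
        self.name = name
        if spec.upsample_conv:
            up: List[nn.Module] = [
                nn.Upsample1d(spec.stride),
                nn.Conv1d(c_in, c_out, 3, 1, 1, rng, f"{name}.conv"),
            ]
        else:
            up = [
                nn.ConvTranspose1d(
                    c_in, c_out, spec.kernel_size, spec.stride, 1, rng, f"{name}.tconv"
                )
            ]
        self.block = nn.Sequential(*up, nn.BatchNorm1d(c_out, name=f"{name}.bn"), nn.ReLU())

    def forward(self, x):
        return self.block.forward(x)

    def backward(self, g):
        return self.block.backward(g)


class _UBlock(nn.Module):
    """One U-shaped encoder-decoder with intra-U skip concatenations."""

    def __init__(
        self,
        c_in: int,
        spec: ModelSpec,
        rng: np.random.Generator,
        dropout_rng: np.random.Generator,
        name: str,
        with_bilstm: bool = False,
    ):
        base, levels = spec.base_channels, spec.levels
        ch = [base * 2**i for i in range(levels)]
        self.down: List[_DownBlock] = []
        prev = c_in
        for i in range(levels):
            self.down.append(_DownBlock(prev, ch[i], spec, rng, f"{name}.down{i + 1}"))
            prev = ch[i]
        self.bilstm: Optional[nn.BiLSTM] = (
            nn.BiLSTM(ch[-1], rng=rng, name=f"{name}.bilstm") if with_bilstm else None
        )
        self.dropout = nn.Dropout(spec.dropout, rng=dropout_rng)
        self.up: List[_UpBlock] = []
        cur = ch[-1]
        for j in range(levels - 1, 0, -1):
            self.up.append(_UpBlock(cur, ch[j - 1], spec, rng, f"{name}.up{levels - j}"))
            cur = 2 * ch[j - 1]  # skip concatenation doubles the channels
        self.up.append(_UpBlock(cur, base, spec, rng, f"{name}.up{levels}"))
        self.out_channels = base
        self.name = name

    def forward(self, x: np.ndarray) -> np.ndarray:
        skips: List[np.ndarray] = []
        for blk in self.down:
            x = blk.forward(x)
            skips.append(x)
        x = self.dropout.forward(x)
        if self.bilstm is not None:
            x = self.bilstm.forward(x)
        self._skip_channels = []
        for i, blk in enumerate(self.up[:-1]):
            x = blk.forward(x)
            skip = skips[-(i + 2)]
            self._skip_channels.append(x.shape[1])
            x = np.concatenate([x, skip], axis=1)
        x = self.up[-1].forward(x)
        return x

    def backward(self, gout: np.ndarray) -> np.ndarray:
        g = self.up[-1].backward(gout)
        skip_grads: List[np.ndarray] = []
        for i in range(len(self.up) - 2, -1, -1):
            c = self._skip_channels[i]
            g_up, g_skip = g[:, :c], g[:, c:]
            skip_grads.append(g_skip)
            g = self.up[i].backward(np.ascontiguousarray(g_up))
        if self.bilstm is not None:
            g = self.bilstm.backward(g)
        g = self.dropout.backward(g)
        # skip_grads[i-1] is the gradient w.r.t. the output of down[i-1]
        for i in range(len(self.down) - 1, -1, -1):
            g = self.down[i].backward(g)
            if i >= 1:
                g = g + skip_grads[i - 1]
        return g


class WNet(nn.Module):
    """Two cascaded U-blocks mapping a 375-sample PPG segment to ECG."""

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        rng = np.random.default_rng(child_seed(spec.seed, "weights"))
        pad_total = spec.padded_len - spec.in_len
        left = pad_total // 2
        self.pad = nn.ConstantPad1d(left, pad_total - left)
        self.u1 = _UBlock(
            1, spec, rng, np.random.default_rng(child_seed(spec.seed, "dropout1")), "u1"
        )
        self.u2 = _UBlock(
            spec.base_channels,
            spec,
            rng,
            np.random.default_rng(child_seed(spec.seed, "dropout2")),
            "u2",
            with_bilstm=(spec.variant == "wnet_bilstm"),
        )
        self.final = nn.Conv1d(spec.base_channels, 1, 1, 1, 0, rng, "final.conv")
        self.tanh = nn.Tanh()
        self.crop = nn.Crop1d(left, pad_total - left)

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=nn.DTYPE)
        if x.ndim != 3 or x.shape[1] != 1 or x.shape[2] != self.spec.in_len:
            raise ValueError(
                f"expected input shape (batch, 1, {self.spec.in_len}), got {x.shape}"
            )
        h = self.pad.forward(x)
        h = self.u1.forward(h)
        h = self.u2.forward(h)
        h = self.final.forward(h)
        h = self.tanh.forward(h)
        return self.crop.forward(h)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        g = self.crop.backward(gout)
        g = self.tanh.backward(g)
        g = self.final.backward(g)
        g = self.u2.backward(g)
        g = self.u1.backward(g)
        return self.pad.backward(g)


def build_model(spec: ModelSpec) -> WNet:
    """Instantiate a WNet/WNet-BiLSTM with seeded weight initialisation."""
    return WNet(spec)


def count_parameters(model: nn.Module) -> int:
    """Total number of trainable scalar parameters."""
    return sum(p.size for p in model.parameters())


def model_summary(spec: ModelSpec) -> str:
    """Human-readable layer table: name, length in/out, channels, parameters."""
    model = build_model(spec)
    rows: List[Tuple[str, str, str, int]] = []
    L = spec.padded_len
    rows.append(("pad", f"1x{spec.in_len}", f"1x{L}", 0))

    def block_params(m: nn.Module) -> int:
        return sum(p.size for p in m.parameters())

    for u in (model.u1, model.u2):
        lengths = [L // spec.stride**i for i in range(spec.levels + 1)]
        c_prev = 1 if u is model.u1 else spec.base_channels
        for i, blk in enumerate(u.down):
            c_out = blk.block.layers[0].out_channels
            rows.append(
                (blk.name, f"{c_prev}x{lengths[i]}", f"{c_out}x{lengths[i + 1]}", block_params(blk))
            )
            c_prev = c_out
        rows.append((f"{u.name}.dropout", f"{c_prev}x{lengths[-1]}", f"{c_prev}x{lengths[-1]}", 0))
        if u.bilstm is not None:
            rows.append(
                (
                    f"{u.name}.bilstm",
                    f"{c_prev}x{lengths[-1]}",
                    f"{c_prev}x{lengths[-1]}",
                    block_params(u.bilstm),
                )
            )
        cur = c_prev
        for i, blk in enumerate(u.up):
            lin = lengths[spec.levels - i]
            lout = lengths[spec.levels - i - 1]
            c_out = blk.block.layers[-2].num_features
            rows.append((blk.name, f"{cur}x{lin}", f"{c_out}x{lout}", block_params(blk)))
            cur = 2 * c_out if i < len(u.up) - 1 else c_out
        c_prev = cur
    rows.append(("final.conv", f"{spec.base_channels}x{L}", f"1x{L}", block_params(model.final)))
    rows.append(("tanh", f"1x{L}", f"1x{L}", 0))
    rows.append(("crop", f"1x{L}", f"1x{spec.in_len}", 0))

    total = sum(r[3] for r in rows)
    assert total == count_parameters(model), "summary does not conserve parameters"
    widths = (max(len(r[0]) for r in rows), 12, 12, 10)
    lines = [
        f"{'layer':<{widths[0]}}  {'in':>12}  {'out':>12}  {'params':>10}",
        "-" * (sum(widths) + 6),
    ]
    for name, cin, cout, n in rows:
        lines.append(f"{name:<{widths[0]}}  {cin:>12}  {cout:>12}  {n:>10}")
    lines.append("-" * (sum(widths) + 6))
    lines.append(f"{'total':<{widths[0]}}  {'':>12}  {'':>12}  {total:>10}")
    return "\n".join(lines)
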