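"""The S-shaped dual-branch segmentation network.

The encoder runs two parallel four-layer branches over the input patch:

* a **downsampling branch** whose resolution halves per layer (cumulative
  stride ``2^i``), the conventional U-Net path that accumulates semantic
  context at the cost of an exponentially growing receptive field;
* a **resampling branch** that keeps (a configurable fraction of) the
  input resolution at every layer, so each 3x3x3 convolution contributes
  only its own small receptive field — this is what lets the network keep
  track of structures a voxel or two across.

At every layer a multiple cross-aggregation module (MCAM) exchanges
information between the branches::

    F[i+1]^R = F[i]^R + Interp(F[i]^D + PReLU(Conv(F[i]^D)))
    F[i+1]^D = F[i]^D + Interp(F[i]^R + PReLU(Conv(F[i]^R)))

where ``Conv`` is a stack of three 3x3x3 convolutions each followed by a
PReLU, and ``Interp`` is trilinear resampling (corner-aligned) to the other
branch's grid. The decoder upsamples with 2x2x2 stride-2 transposed
convolutions, concatenates the matching-resolution downsampling-branch
features (long skips), applies convolutions with an additive short skip,
and attaches a 1x1x1 + sigmoid prediction head to every stage; all four
heads are brought to input resolution by trilinear upsampling so they can
be supervised jointly. The first two encoder layers use unit dilation,
layers three and four use the dilated schedule {2,3,4,5} to diversify the
receptive fields.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import nn
from .nn.autograd import Tensor

__all__ = [
    "ConfigError", "NetworkConfig", "EncoderFeatures", "ReceptiveFieldSpec",
    "MCAM", "SNet", "build_network", "make_variant", "receptive_field",
    "conv_rf_edge", "probe_receptive_field", "save_checkpoint",
    "load_checkpoint", "VARIANTS",
]

VARIANTS = ("BN+SL", "BN+ML", "SNet+SL", "SNet+ML")


class ConfigError(ValueError):
    """Inconsistent network configuration."""


@dataclass(frozen=True)
class NetworkConfig:
    in_channels: int = 1
    depth: int = 4
    base_width: int = 16
    width_growth: int = 2
    convs_per_block: int = 2
    mcam_convs: int = 3
    dilation_schedule: tuple[tuple[int, int], ...] = ((2, 2), (3, 3), (4, 4), (5, 5))
    dropout_prob: float = 0.3
    resample_scale: float = 1.0
    supervision: str = "multi"
    dual_branch: bool = True
    binarize_threshold: float = 0.5

    def __post_init__(self):
        if self.depth != 4:
            raise ConfigError("the published configuration has 4 encoding layers")
        if len(self.dilation_schedule) != 4:
            raise ConfigError("dilation_schedule must list 4 (padding, dilation) pairs")
        if self.supervision not in ("single", "multi"):
            raise ConfigError("supervision must be 'single' or 'multi'")
        if not (0.0 < self.resample_scale <= 1.0):
            raise ConfigError("resample_scale must lie in (0, 1]")
        if not (0.0 <= self.dropout_prob < 1.0):
            raise ConfigError("dropout_prob must lie in [0, 1)")

    # channel width of encoder layer i (1-based); layer 0 = decoder output width
    def width(self, i: int) -> int:
        if i == 0:
            return max(self.base_width // self.width_growth, 2)
        return self.base_width * self.width_growth ** (i - 1)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["dilation_schedule"] = [list(p) for p in self.dilation_schedule]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        d = dict(d)
        if "dilation_schedule" in d:
            d["dilation_schedule"] = tuple(tuple(p) for p in d["dilation_schedule"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def from_yaml(cls, path) -> "NetworkConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def make_variant(config: NetworkConfig, variant: str) -> NetworkConfig:
    """Ablation variants: BN* drops the resampling branch (residual U-Net
    backbone), *SL supervises only the full-resolution head."""
    if variant not in VARIANTS:
        raise ConfigError(f"unknown variant {variant!r}; choose from {VARIANTS}")
    backbone, sup = variant.split("+")
    return dataclasses.replace(
        config,
        dual_branch=(backbone == "SNet"),
        supervision="single" if sup == "SL" else "multi",
    )


# -- receptive fields --------------------------------------------------------

@dataclass(frozen=True)
class ReceptiveFieldSpec:
    layer: int
    branch: str
    edge: int               # edge length of the receptive cube, input voxels
    cumulative_stride: int


def conv_rf_edge(kernel: int, dilation: int) -> int:
    """Receptive-field edge of a single convolution: d*(k-1)+1."""
    return dilation * (kernel - 1) + 1


def _block_dilations(config: NetworkConfig, layer: int) -> list[int]:
    if layer <= 2:
        return [1] * config.convs_per_block
    idx = 0 if layer == 3 else 2
    return [d for _, d in config.dilation_schedule[idx:idx + 2]]


def receptive_field(config: NetworkConfig, layer: int, branch: str
                    ) -> ReceptiveFieldSpec:
    """Analytic receptive field of the layer's own branch path.

    Composition rule: each stage adds ``(edge_stage - 1) * jump`` where
    ``jump`` is the cumulative stride before the stage. The downsampling
    branch multiplies ``jump`` by 2 at every transition, so a 3x3x3
    convolution seen from layer i spreads over ``2^i`` times its kernel
    extent in input space; the resampling branch keeps ``jump = 1``, which
    is the architecture's central property. Cross-branch MCAM mixing is
    intentionally excluded: this is the receptive field of the branch's
    convolution chain (what :func:`probe_receptive_field` measures with
    ``cross_aggregate=False``).
    """
    if not 1 <= layer <= config.depth:
        raise ValueError(f"layer must lie in [1, {config.depth}]")
    if branch not in ("D", "R"):
        raise ValueError("branch must be 'D' or 'R'")
    rf, jump = 1, 1
    for i in range(1, layer + 1):
        if branch == "D":
            rf += (conv_rf_edge(2, 1) - 1) * jump  # 2^3 stride-2 transition
            jump *= 2
        else:
            rf += (conv_rf_edge(3, 1) - 1) * jump  # 3^3 stride-1 transition
        for d in _block_dilations(config, i):
            rf += (conv_rf_edge(3, d) - 1) * jump
    return ReceptiveFieldSpec(layer, branch, rf, jump)


# -- building blocks ---------------------------------------------------------

class _ConvPReLU(nn.Module):
    def __init__(self, cin, cout, kernel, stride=1, padding=0, dilation=1, *, rng):
        self.conv = nn.Conv3d(cin, cout, kernel, stride=stride, padding=padding,
                              dilation=dilation, rng=rng)
        self.act = nn.PReLU(cout)

    def __call__(self, x):
        return self.act(self.conv(x))


class _ConvBlock(nn.Module):
    """Stack of 3x3x3 conv+PReLU with an additive short skip (channels fixed)."""

    def __init__(self, channels: int, dilations: list[int], *, rng):
        self.stages = [
            _ConvPReLU(channels, channels, 3, padding=d, dilation=d, rng=rng)
            for d in dilations
        ]

    def __call__(self, x):
        y = x
        for stage in self.stages:
            y = stage(y)
        return y + x


class MCAM(nn.Module):
    """Multiple cross-aggregation: each branch receives a convolved,
    residual-augmented, trilinearly-resampled copy of the other."""

    def __init__(self, channels: int, n_convs: int = 3, *, rng):
        self.stack_d = [_ConvPReLU(channels, channels, 3, padding=1, rng=rng)
                        for _ in range(n_convs)]
        self.stack_r = [_ConvPReLU(channels, channels, 3, padding=1, rng=rng)
                        for _ in range(n_convs)]

    @staticmethod
    def _branch(f, stack, out_shape):
        y = f
        for stage in stack:
            y = stage(y)
        return nn.interp_trilinear(f + y, out_shape)

    def __call__(self, f_d: Tensor, f_r: Tensor) -> tuple[Tensor, Tensor]:
        """Returns ``(F[i+1]^R, F[i+1]^D)`` given layer-i branch features."""
        if f_d.shape[-1] != f_r.shape[-1]:
            raise ValueError(
                f"MCAM needs equal channel counts, got {f_d.shape[-1]} (D) "
                f"and {f_r.shape[-1]} (R)")
        next_r = f_r + self._branch(f_d, self.stack_d, f_r.shape[1:4])
        next_d = f_d + self._branch(f_r, self.stack_r, f_d.shape[1:4])
        return next_r, next_d


@dataclass
class EncoderFeatures:
    """Per-layer branch features: ``f_d[i]`` at 1/2^(i+1) resolution,
    ``f_r[i]`` at the resampling-branch resolution (0-based lists).
    ``carried`` holds the post-aggregation features entering the decoder."""
    f_d: list
    f_r: list | None
    carried: Tensor


class SNet(nn.Module):
    """See module docstring. Built via :func:`build_network`."""

    def __init__(self, config: NetworkConfig, *, rng: np.random.Generator):
        self.config = config
        cw = [config.width(i) for i in range(config.depth + 1)]  # cw[0] decoder out
        cin = config.in_channels
        self.trans_d, self.block_d = [], []
        self.trans_r, self.block_r, self.mcam = [], [], []
        for i in range(1, config.depth + 1):
            prev = cin if i == 1 else cw[i - 1]
            dil = _block_dilations(config, i)
            self.trans_d.append(_ConvPReLU(prev, cw[i], 2, stride=2, rng=rng))
            self.block_d.append(_ConvBlock(cw[i], dil, rng=rng))
            if config.dual_branch:
                self.trans_r.append(_ConvPReLU(prev, cw[i], 3, padding=1, rng=rng))
                self.block_r.append(_ConvBlock(cw[i], dil, rng=rng))
                self.mcam.append(MCAM(cw[i], config.mcam_convs, rng=rng))
        self.up, self.dec_block, self.dec_skipmix, self.heads = [], [], [], []
        for k in range(1, config.depth + 1):
            c_in = cw[config.depth] if k == 1 else cw[config.depth - k + 1]
            c_out = cw[config.depth - k]
            self.up.append(nn.ConvTranspose3d(c_in, c_out, 2, stride=2, rng=rng))
            has_skip = k < config.depth
            c_cat = c_out * 2 if has_skip else c_out
            stages = [_ConvPReLU(c_cat, c_out, 3, padding=1, rng=rng)]
            stages += [_ConvPReLU(c_out, c_out, 3, padding=1, rng=rng)
                       for _ in range(config.convs_per_block - 1)]
            self.dec_block.append(stages)
            self.heads.append(nn.Conv3d(c_out, 1, 1, rng=rng))
        self.up_act = [nn.PReLU(cw[config.depth - k]) for k in range(1, config.depth + 1)]

    # -- encoder -----------------------------------------------------------
    def _r_shape(self, in_shape) -> tuple[int, int, int]:
        s = self.config.resample_scale
        return tuple(max(1, round(s * n)) for n in in_shape)

    def encode(self, x: Tensor, *, training: bool = False,
               rng: np.random.Generator | None = None,
               cross_aggregate: bool = True) -> EncoderFeatures:
        cfg = self.config
        in_shape = x.shape[1:4]
        for ax, n in enumerate(in_shape):
            if n % (2 ** cfg.depth) != 0:
                raise ValueError(
                    f"input axis {ax} has size {n}, not divisible by 2^{cfg.depth}")
        drop = (lambda t: nn.dropout(t, cfg.dropout_prob, rng, training)
                ) if training and rng is not None else (lambda t: t)
        f_d_list, f_r_list = [], []
        prev_d = x
        prev_r = nn.interp_trilinear(x, self._r_shape(in_shape)) if cfg.dual_branch else None
        for i in range(cfg.depth):
            f_d = self.block_d[i](self.trans_d[i](prev_d))
            f_d_list.append(f_d)
            if cfg.dual_branch:
                f_r = self.block_r[i](self.trans_r[i](prev_r))
                f_r_list.append(f_r)
                if cross_aggregate:
                    next_r, next_d = self.mcam[i](f_d, f_r)
                else:
                    next_r, next_d = f_r, f_d
                prev_d, prev_r = drop(next_d), drop(next_r)
            else:
                prev_d = drop(f_d)
        return EncoderFeatures(f_d_list, f_r_list if cfg.dual_branch else None,
                               prev_d)

    # -- decoder -----------------------------------------------------------
    def decode(self, feats: EncoderFeatures, *, training: bool = False,
               rng: np.random.Generator | None = None) -> list[Tensor]:
        cfg = self.config
        drop = (lambda t: nn.dropout(t, cfg.dropout_prob, rng, training)
                ) if training and rng is not None else (lambda t: t)
        y = feats.carried
        outputs = []
        for k in range(cfg.depth):
            up = self.up_act[k](self.up[k](y))
            if k < cfg.depth - 1:
                skip = feats.f_d[cfg.depth - 2 - k]
                if skip.shape[1:4] != up.shape[1:4]:
                    raise ValueError(
                        f"decoder stage {k + 1}: skip resolution {skip.shape[1:4]} "
                        f"does not match upsampled {up.shape[1:4]}")
                z = nn.concat([up, skip], axis=-1)
            else:
                z = up
            for stage in self.dec_block[k]:
                z = stage(z)
            y = drop(z + up)  # additive short skip
            outputs.append(y)
        return outputs

    def predict_heads(self, decoder_feats: list[Tensor],
                      out_shape: tuple[int, int, int]) -> list[Tensor]:
        """Per-stage 1x1x1 conv -> trilinear upsample -> sigmoid."""
        preds = []
        for k, feat in enumerate(decoder_feats):
            logit = self.heads[k](feat)
            preds.append(nn.sigmoid(nn.interp_trilinear(logit, out_shape)))
        return preds

    def forward(self, x: Tensor, *, training: bool = False,
                rng: np.random.Generator | None = None) -> list[Tensor]:
        """Probability maps at input resolution; the last entry is the
        full-resolution head used for inference. Single-supervision mode
        returns that head only."""
        feats = self.encode(x, training=training, rng=rng)
        dec = self.decode(feats, training=training, rng=rng)
        preds = self.predict_heads(dec, x.shape[1:4])
        if self.config.supervision == "single":
            return [preds[-1]]
        return preds

    __call__ = forward

    def predict(self, volume: np.ndarray) -> np.ndarray:
        """Inference on one patch: full-resolution foreground probability."""
        x = Tensor(volume[None, ..., None].astype(np.float32))
        return self.forward(x, training=False)[-1].data[0, ..., 0]


def build_network(config: NetworkConfig, seed: int = 0) -> SNet:
    """Instantiate the network with fan-in-scaled seeded initialization."""
    return SNet(config, rng=np.random.default_rng(seed))


def probe_receptive_field(net: SNet, layer: int, branch: str,
                          input_size: int, *, cross_aggregate: bool = False
                          ) -> tuple[int, ...]:
    """Gradient-footprint probe: backpropagate from the center voxel of one
    encoder feature map and return the edge lengths of the bounding box of
    nonzero input gradient. With ``cross_aggregate=False`` the probe
    isolates the branch's own convolution chain, which is what the analytic
    calculator describes."""
    if not 1 <= layer <= net.config.depth:
        raise ValueError("layer out of range")
    x = Tensor(np.zeros((1,) + (input_size,) * 3 + (net.config.in_channels,),
                        dtype=np.float32), requires_grad=True)
    feats = net.encode(x, cross_aggregate=cross_aggregate)
    fmap = feats.f_d[layer - 1] if branch == "D" else feats.f_r[layer - 1]
    center = tuple(s // 2 for s in fmap.shape[1:4])
    seed_grad = np.zeros(fmap.shape, dtype=np.float32)
    seed_grad[(0,) + center + (0,)] = 1.0
    fmap.backward(seed_grad)
    nz = np.nonzero(x.grad[0, ..., 0])
    return tuple(int(idx.max() - idx.min() + 1) for idx in nz)


# -- checkpoints -------------------------------------------------------------

def save_checkpoint(path, net: SNet, *, optimizer: nn.Adam | None = None,
                    extra: dict | None = None) -> None:
    """Parameter archive (.npz) plus a JSON sidecar holding the full
    network configuration, so a checkpoint is self-describing."""
    path = Path(path)
    arrays = dict(net.state_dict())
    if optimizer is not None:
        for key, val in optimizer.state_dict().items():
            arrays[f"opt/{key}"] = val
    np.savez(path.with_suffix(".npz"), **arrays)
    sidecar = {"config": net.config.to_dict(), "extra": extra or {}}
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh, indent=2)


def load_checkpoint(path) -> tuple[SNet, dict, dict]:
    """Returns ``(network, optimizer_state, extra)``."""
    path = Path(path)
    with open(path.with_suffix(".json")) as fh:
        sidecar = json.load(fh)
    config = NetworkConfig.from_dict(sidecar["config"])
    net = build_network(config, seed=0)
    with np.load(path.with_suffix(".npz")) as data:
        params = {k: data[k] for k in data.files if not k.startswith("opt/")}
        opt_state = {k[4:]: data[k] for k in data.files if k.startswith("opt/")}
    net.load_state_dict(params)
    return net, opt_state, sidecar.get("extra", {})
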