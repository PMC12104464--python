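"""Three-branch encoder–decoder segmentation network.

The model consists of two independent U-Net encoders (positive and
reverse perspective) and three decoders:

* the positive decoder up-samples by bilinear interpolation followed by a
  1x1 channel-reducing convolution,
* the reverse and fusion decoders up-sample by 2x2/stride-2 transposed
  convolution.

The reverse branch's raw scores are negated by the Reverse Module before
softmax, so that branch learns background-region features while being
supervised against the unmodified ground truth.  The fusion decoder
consumes features produced by the Perspective Fusion Module at every
encoder level: f_fus = f_pos - softmax(-f_pos) * softmax(f_rev), which
damps channel activations the two perspectives agree on and amplifies
the disputed (typically boundary) responses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


@dataclass
class NetworkConfig:
    """Architecture hyper-parameters.

    depth counts resolution levels (>= 2); base_width is the channel count
    at full resolution and doubles per level; share_encoders ties the two
    perspective encoders to a single parameter set (ablation switch);
    fuse_levels selects where the Perspective Fusion Module is applied for
    the fusion decoder ("all" levels or "bottleneck_only").
    """

    in_channels: int = 1
    n_classes: int = 2
    base_width: int = 16
    depth: int = 4
    share_encoders: bool = False
    fuse_levels: str = "all"  # "all" | "bottleneck_only"
    enabled_branches: tuple[str, ...] = ("pos", "rev", "fus")
    reverse_module: bool = True  # False => second branch is a plain positive branch

    def __post_init__(self):
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.base_width < 4:
            raise ValueError("base_width must be >= 4")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.fuse_levels not in ("all", "bottleneck_only"):
            raise ValueError("fuse_levels must be 'all' or 'bottleneck_only'")


@dataclass
class PerspectiveOutputs:
    """Everything a training step needs from one forward pass."""

    O_pos: Tensor
    O_rev: Tensor | None
    O_fus: Tensor | None
    P_pos: Tensor
    P_rev: Tensor | None
    P_fus: Tensor | None
    enc_pyramids: dict = field(default_factory=dict)  # branch -> [level0..bottleneck]
    dec_pyramids: dict = field(default_factory=dict)  # branch -> [level0..level depth-2]

    @property
    def O_rev_neg(self) -> Tensor | None:
        """Positive-orientation reverse scores O'_rev = -O_rev."""
        return None if self.O_rev is None else reverse_module(self.O_rev)


def reverse_module(scores: Tensor) -> Tensor:
    """Elementwise negation of a score/feature map (an involution)."""
    return -scores


def perspective_fusion(f_pos: Tensor, f_rev: Tensor) -> Tensor:
    """Fuse positive and reverse feature maps.

    f_r_pos = softmax(-f_pos) over channels; f_mul = f_r_pos * softmax(f_rev);
    returns f_pos - f_mul (same shape as the inputs).
    """
    if f_pos.shape != f_rev.shape:
        raise ValueError(f"shape mismatch: {f_pos.shape} vs {f_rev.shape}")
    f_r_pos = ad.softmax_channels(reverse_module(f_pos))
    f_mul = f_r_pos * ad.softmax_channels(f_rev)
    return f_pos - f_mul


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

class _Params:
    """Flat registry of named parameters and batchnorm buffers."""

    def __init__(self):
        self.params: dict[str, Tensor] = {}
        self.buffers: dict[str, np.ndarray] = {}

    def parameter(self, name: str, array: np.ndarray) -> Tensor:
        t = Tensor(array.astype(np.float32), requires_grad=True)
        self.params[name] = t
        return t

    def buffer(self, name: str, array: np.ndarray) -> np.ndarray:
        self.buffers[name] = array
        return array


class _ConvBNReLU:
    def __init__(self, reg: _Params, name: str, cin: int, cout: int, rng: np.random.Generator):
        # Kaiming-normal fan-in init for the ReLU nonlinearity
        std = np.sqrt(2.0 / (cin * 9))
        self.w = reg.parameter(f"{name}.w", rng.normal(0, std, (cout, cin, 3, 3)))
        self.b = reg.parameter(f"{name}.b", np.zeros(cout))
        self.gamma = reg.parameter(f"{name}.gamma", np.ones(cout))
        self.beta = reg.parameter(f"{name}.beta", np.zeros(cout))
        self.rm = reg.buffer(f"{name}.running_mean", np.zeros(cout, dtype=np.float32))
        self.rv = reg.buffer(f"{name}.running_var", np.ones(cout, dtype=np.float32))

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        y = ad.conv2d(x, self.w, self.b, padding=1)
        y = ad.batchnorm2d(y, self.gamma, self.beta, self.rm, self.rv, training)
        return ad.relu(y)


class _DoubleConv:
    def __init__(self, reg, name, cin, cout, rng):
        self.c1 = _ConvBNReLU(reg, f"{name}.0", cin, cout, rng)
        self.c2 = _ConvBNReLU(reg, f"{name}.1", cout, cout, rng)

    def __call__(self, x, training):
        return self.c2(self.c1(x, training), training)


class _Encoder:
    """U-Net encoder; returns feature pyramid [level0, ..., bottleneck]."""

    def __init__(self, reg, name, cfg: NetworkConfig, rng):
        self.blocks = []
        cin = cfg.in_channels
        for lvl in range(cfg.depth):
            cout = cfg.base_width * 2**lvl
            self.blocks.append(_DoubleConv(reg, f"{name}.lvl{lvl}", cin, cout, rng))
            cin = cout

    def __call__(self, x, training):
        feats = []
        for i, blk in enumerate(self.blocks):
            if i > 0:
                x = ad.maxpool2x2(x)
            x = blk(x, training)
            feats.append(x)
        return feats


class _Decoder:
    """U-Net decoder over a feature pyramid.

    upsample is "bilinear" (interpolation + 1x1 conv) or "transposed"
    (2x2/stride-2 transposed convolution).  Returns the class score map and
    the decoder feature pyramid ordered from full resolution upward.
    """

    def __init__(self, reg, name, cfg: NetworkConfig, rng, upsample: str):
        self.upsample = upsample
        self.up, self.blocks = [], []
        for lvl in range(cfg.depth - 2, -1, -1):
            cin = cfg.base_width * 2 ** (lvl + 1)
            cout = cfg.base_width * 2**lvl
            if upsample == "bilinear":
                std = np.sqrt(2.0 / cin)
                w = reg.parameter(f"{name}.up{lvl}.w", rng.normal(0, std, (cout, cin, 1, 1)))
                b = reg.parameter(f"{name}.up{lvl}.b", np.zeros(cout))
            else:
                std = np.sqrt(2.0 / (cin * 4))
                w = reg.parameter(f"{name}.up{lvl}.w", rng.normal(0, std, (cin, cout, 2, 2)))
                b = reg.parameter(f"{name}.up{lvl}.b", np.zeros(cout))
            self.up.append((w, b))
            self.blocks.append(_DoubleConv(reg, f"{name}.dec{lvl}", cout * 2, cout, rng))
        std = np.sqrt(2.0 / cfg.base_width)
        self.head_w = reg.parameter(f"{name}.head.w", rng.normal(0, std, (cfg.n_classes, cfg.base_width, 1, 1)))
        self.head_b = reg.parameter(f"{name}.head.b", np.zeros(cfg.n_classes))

    def __call__(self, pyramid: list[Tensor], training: bool):
        x = pyramid[-1]
        dec_feats = []
        for (w, b), blk, skip in zip(self.up, self.blocks, pyramid[-2::-1]):
            if self.upsample == "bilinear":
                x = ad.bilinear_resize(x, skip.shape[2], skip.shape[3])
                x = ad.conv2d(x, w, b, padding=0)
            else:
                x = ad.conv_transpose2x2(x, w, b)
            x = blk(ad.concat([x, skip], axis=1), training)
            dec_feats.append(x)
        scores = ad.conv2d(x, self.head_w, self.head_b, padding=0)
        return scores, dec_feats[::-1]  # level0 first


# ---------------------------------------------------------------------------
# the full model
# ---------------------------------------------------------------------------

class MPDCNet:
    """Two independent encoders + positive/reverse/fusion decoders."""

    def __init__(self, config: NetworkConfig, rng_seed: int = 0):
        self.config = config
        self.reg = _Params()
        rng = np.random.default_rng(rng_seed)
        self.enc_pos = _Encoder(self.reg, "enc_pos", config, rng)
        if config.share_encoders:
            self.enc_rev = self.enc_pos
        else:
            self.enc_rev = _Encoder(self.reg, "enc_rev", config, rng)
        self.dec_pos = _Decoder(self.reg, "dec_pos", config, rng, upsample="bilinear")
        self.dec_rev = _Decoder(self.reg, "dec_rev", config, rng, upsample="transposed")
        if "fus" in config.enabled_branches:
            self.dec_fus = _Decoder(self.reg, "dec_fus", config, rng, upsample="transposed")
        else:
            self.dec_fus = None
        self.training = True

    # -- bookkeeping ----------------------------------------------------
    def train(self) -> None:
        self.training = True

    def eval(self) -> None:
        self.training = False

    def parameters(self) -> list[Tensor]:
        return list(self.reg.params.values())

    def named_parameters(self) -> dict[str, Tensor]:
        return dict(self.reg.params)

    def parameter_groups(self) -> dict[str, list[str]]:
        """Names grouped by parameter set (theta_eP, theta_eR, theta_dP, ...)."""
        groups: dict[str, list[str]] = {"enc_pos": [], "enc_rev": [], "dec_pos": [], "dec_rev": [], "dec_fus": []}
        for name in self.reg.params:
            groups[name.split(".")[0]].append(name)
        return groups

    def state_dict(self) -> dict[str, np.ndarray]:
        st = {f"param:{k}": v.data for k, v in self.reg.params.items()}
        st.update({f"buffer:{k}": v for k, v in self.reg.buffers.items()})
        return st

    def load_state_dict(self, st: dict[str, np.ndarray]) -> None:
        for k, t in self.reg.params.items():
            t.data = np.array(st[f"param:{k}"], dtype=np.float32, copy=True)
        for k in self.reg.buffers:
            self.reg.buffers[k][...] = st[f"buffer:{k}"]

    # -- forward ---------------------------------------------------------
    def validate_input(self, images: np.ndarray) -> None:
        if images.ndim != 4 or images.shape[1] != self.config.in_channels:
            raise ValueError(f"expected B x {self.config.in_channels} x H x W input, got {images.shape}")
        div = 2 ** (self.config.depth - 1)
        if images.shape[2] % div or images.shape[3] % div:
            raise ValueError(f"spatial size must be divisible by {div}")

    def forward(self, images: np.ndarray | Tensor) -> PerspectiveOutputs:
        x = images if isinstance(images, Tensor) else Tensor(np.asarray(images, dtype=np.float32))
        self.validate_input(x.data)
        cfg = self.config
        f_pos = self.enc_pos(x, self.training)
        f_rev = self.enc_rev(x, self.training)
        O_pos, dpos = self.dec_pos(f_pos, self.training)
        O_rev, drev = self.dec_rev(f_rev, self.training)
        P_pos = ad.softmax_channels(O_pos)
        if cfg.reverse_module:
            P_rev = ad.softmax_channels(reverse_module(O_rev))
        else:
            P_rev = ad.softmax_channels(O_rev)
        out = PerspectiveOutputs(
            O_pos=O_pos, O_rev=O_rev, O_fus=None,
            P_pos=P_pos, P_rev=P_rev, P_fus=None,
            enc_pyramids={"pos": f_pos, "rev": f_rev},
            dec_pyramids={"pos": dpos, "rev": drev},
        )
        if self.dec_fus is not None:
            if cfg.fuse_levels == "all":
                fused = [perspective_fusion(p, r) for p, r in zip(f_pos, f_rev)]
            else:
                fused = list(f_pos[:-1]) + [perspective_fusion(f_pos[-1], f_rev[-1])]
            O_fus, _ = self.dec_fus(fused, self.training)
            out.O_fus = O_fus
            out.P_fus = ad.softmax_channels(O_fus)
        return out

    __call__ = forward

    def predict(self, images: np.ndarray, head: str = "pos") -> np.ndarray:
        """Inference mask (argmax of the chosen head's confidence map)."""
        was_training = self.training
        self.eval()
        try:
            outs = self.forward(images)
        finally:
            self.training = was_training
        pmap = {"pos": outs.P_pos, "rev": outs.P_rev, "fus": outs.P_fus}[head]
        if pmap is None:
            raise ValueError(f"branch {head!r} is not enabled")
        return pmap.data.argmax(axis=1).astype(np.int64)
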