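"""Stage-2 segmentation network: ResNet34-block encoder + AMFF head + decoder.

The architecture follows the DeepLabv3 pattern with its multi-scale head
swapped for an Attentional Multi-scale Feature Fusion (AMFF) module:

* **Encoder** — a 7x7/stride-2 convolution with batch normalization,
  followed by four cascaded groups of 512-channel residual basic blocks
  ("blocks 1-4", four 3x3 convolutions each); the first convolution of
  blocks 1 and 2 has stride 2, blocks 3 and 4 keep stride 1.  A 256x256
  input therefore maps to a 512x32x32 feature (overall stride 8).
* **AMFF head** — four parallel 3x3 convolution branches with increasing
  dilation rates (1, 6, 12, 18; padding = dilation so the 32x32 grid is
  preserved).  Branch *i* receives the encoder feature plus the
  pre-attention output of branch *i-1* (hierarchical connections that let
  small-scale features flow into large-receptive-field branches), applies
  a spatial-attention gate, and all post-attention branch outputs are
  concatenated into the 2048x32x32 fused feature.
* **Decoder** — two convolutions reduce 2048 channels to three (one
  channel per vessel: PA, Ao, SVC), followed by 8x bilinear upsampling
  back to the input resolution and a per-channel sigmoid.

An ASPP head (parallel dilated branches, no hierarchy, no attention) with
an identical shape contract is provided as the ablation baseline; the two
heads are drop-in replacements for each other.

Grayscale inputs are replicated to 3 channels before the first
convolution.  Default widths reproduce the printed tensor sizes
(512x32x32 fused to 2048x32x32); a narrower ``width`` yields a desk-scale
model with the same topology.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import (BasicBlock, BatchNorm2d, BilinearUpsample, Conv2d,
                 Module, ReLU, SpatialAttention, sigmoid)


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyperparameters (defaults = full-size model)."""

    width: int = 512                     # encoder/branch channel count
    branch_count: int = 4
    dilations: tuple = (1, 6, 12, 18)
    decode_channels: int = 256
    out_channels: int = 3
    head: str = "amff"                   # "amff" | "aspp"
    seed: int = 0

    def __post_init__(self):
        if len(self.dilations) != self.branch_count:
            raise ValueError("need one dilation rate per branch")
        if any(b <= a for a, b in zip(self.dilations, self.dilations[1:])):
            raise ValueError("dilation rates must be strictly increasing")
        if self.head not in ("amff", "aspp"):
            raise ValueError(f"unknown head {self.head!r}")

    @property
    def fused_channels(self) -> int:
        # branch_count x branch_channels; branch channels equal the encoder width
        return self.branch_count * self.width

    def small(self, width=16, decode_channels=32, **kw) -> "NetworkConfig":
        import dataclasses
        return dataclasses.replace(self, width=width,
                                   decode_channels=decode_channels, **kw)


@dataclass
class NetworkOutput:
    """Per-class probability maps (and their logits) at input resolution."""

    logits: np.ndarray          # (N, 3, H, W)
    probabilities: np.ndarray   # sigmoid(logits), in [0, 1]

    def masks(self, threshold: float = 0.5) -> np.ndarray:
        """Labeled masks: argmax over channels where max prob >= threshold.

        Ties go to the lower class index (argmax picks the first maximum).
        """
        p = self.probabilities
        labels = p.argmax(axis=1).astype(np.uint8) + 1
        labels[p.max(axis=1) < threshold] = 0
        return labels


class Encoder(Module):
    """7x7 stem + four cascaded residual groups; output stride 8."""

    def __init__(self, width=512, in_ch=3, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.width = width
        self.stem_conv = Conv2d(in_ch, width, 7, stride=2, padding=3,
                                bias=False, rng=rng)
        self.stem_bn = BatchNorm2d(width)
        self.stem_relu = ReLU()
        # blocks 1-4: four 3x3 convs each (= two basic blocks); stride 2 in 1-2
        self.blocks = []
        for stride in (2, 2, 1, 1):
            self.blocks.append(BasicBlock(width, stride=stride, rng=rng))
            self.blocks.append(BasicBlock(width, stride=1, rng=rng))

    def forward(self, x):
        if x.ndim != 4:
            raise ValueError(f"expected NCHW input, got shape {x.shape}")
        if x.shape[2] % 8 or x.shape[3] % 8:
            raise ValueError(f"input spatial size {x.shape[2:]} must be divisible by 8")
        self._replicated = x.shape[1] == 1
        if self._replicated:
            x = np.repeat(x, 3, axis=1)   # grayscale replicated to 3 channels
        y = self.stem_relu(self.stem_bn(self.stem_conv(x)))
        for b in self.blocks:
            y = b(y)
        return y

    def backward(self, grad):
        for b in reversed(self.blocks):
            grad = b.backward(grad)
        grad = self.stem_conv.backward(self.stem_bn.backward(
            self.stem_relu.backward(grad)))
        if self._replicated:
            grad = grad.sum(axis=1, keepdims=True)   # undo channel replication
        return grad


class _Branch(Module):
    def __init__(self, ch, dilation, attention, rng):
        super().__init__()
        self.conv = Conv2d(ch, ch, 3, padding=dilation, dilation=dilation,
                           bias=False, rng=rng)
        self.bn = BatchNorm2d(ch)
        self.relu = ReLU()
        self.attn = SpatialAttention(rng=rng) if attention else None

    def pre_attention(self, x):
        return self.relu(self.bn(self.conv(x)))


class AMFF(Module):
    """Attentional multi-scale feature fusion head.

    Branch i consumes (encoder feature + branch i-1 pre-attention output),
    so small-scale detail captured by low-dilation branches feeds the
    larger receptive fields; each branch output passes a spatial-attention
    gate before channel concatenation.
    """

    def __init__(self, in_ch=512, branch_count=4, dilations=(1, 6, 12, 18),
                 rng=None):
        super().__init__()
        if len(dilations) != branch_count:
            raise ValueError("need one dilation per branch")
        rng = rng or np.random.default_rng(0)
        self.in_ch = in_ch
        self.out_ch = branch_count * in_ch
        self.branches = [_Branch(in_ch, d, attention=True, rng=rng)
                         for d in dilations]

    def forward(self, x):
        if x.shape[1] != self.in_ch:
            raise ValueError(f"expected {self.in_ch} channels, got {x.shape[1]}")
        outs = []
        prev = None
        for br in self.branches:
            inp = x if prev is None else x + prev
            f = br.pre_attention(inp)
            prev = f
            outs.append(br.attn(f))
        return np.concatenate(outs, axis=1)

    def backward(self, grad):
        n_br = len(self.branches)
        gs = np.split(grad, n_br, axis=1)
        dx = np.zeros((grad.shape[0], self.in_ch, grad.shape[2], grad.shape[3]),
                      dtype=grad.dtype)
        df_next = 0.0          # gradient flowing into this branch's pre-attn output
        for i in range(n_br - 1, -1, -1):
            br = self.branches[i]
            df = br.attn.backward(gs[i]) + df_next
            g_in = br.conv.backward(br.bn.backward(br.relu.backward(df)))
            dx += g_in
            df_next = g_in if i > 0 else 0.0   # hierarchical feed from branch i-1
        return dx


class ASPPHead(Module):
    """Parallel dilated branches, concatenated: the ablation baseline.

    Same shape contract as :class:`AMFF`, but no hierarchical connections
    and no attention gates.
    """

    def __init__(self, in_ch=512, branch_count=4, dilations=(1, 6, 12, 18),
                 rng=None):
        super().__init__()
        if len(dilations) != branch_count:
            raise ValueError("need one dilation per branch")
        rng = rng or np.random.default_rng(0)
        self.in_ch = in_ch
        self.out_ch = branch_count * in_ch
        self.branches = [_Branch(in_ch, d, attention=False, rng=rng)
                         for d in dilations]

    def forward(self, x):
        if x.shape[1] != self.in_ch:
            raise ValueError(f"expected {self.in_ch} channels, got {x.shape[1]}")
        return np.concatenate([br.pre_attention(x) for br in self.branches],
                              axis=1)

    def backward(self, grad):
        gs = np.split(grad, len(self.branches), axis=1)
        dx = 0.0
        for br, g in zip(self.branches, gs):
            dx = dx + br.conv.backward(br.bn.backward(br.relu.backward(g)))
        return dx


def build_aspp_head(in_ch=512, branch_count=4, dilations=(1, 6, 12, 18),
                    rng=None) -> ASPPHead:
    """ASPP baseline with the same interface/shape contract as AMFF."""
    return ASPPHead(in_ch=in_ch, branch_count=branch_count,
                    dilations=dilations, rng=rng)


class Decoder(Module):
    """Two convolutions down to 3 channels, then 8x bilinear upsampling."""

    def __init__(self, in_ch=2048, mid_ch=256, out_ch=3, up=8, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.in_ch = in_ch
        self.conv1 = Conv2d(in_ch, mid_ch, 3, padding=1, bias=False, rng=rng)
        self.bn = BatchNorm2d(mid_ch)
        self.relu = ReLU()
        self.conv2 = Conv2d(mid_ch, out_ch, 1, bias=True, rng=rng)
        # foreground is sparse: bias the logits towards background at init
        self.conv2.bias.data[...] = -2.0
        self.up = BilinearUpsample(up)

    def forward(self, x):
        if x.shape[1] != self.in_ch:
            raise ValueError(f"expected {self.in_ch} channels, got {x.shape[1]}")
        return self.up(self.conv2(self.relu(self.bn(self.conv1(x)))))

    def backward(self, grad):
        g = self.up.backward(grad)
        g = self.conv2.backward(g)
        g = self.conv1.backward(self.bn.backward(self.relu.backward(g)))
        return g


class VesselSegNet(Module):
    """Encoder -> (AMFF | ASPP) -> decoder; outputs one channel per vessel."""

    def __init__(self, config: NetworkConfig = NetworkConfig()):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.encoder = Encoder(width=config.width, rng=rng)
        head_cls = AMFF if config.head == "amff" else ASPPHead
        self.head = head_cls(in_ch=config.width,
                             branch_count=config.branch_count,
                             dilations=config.dilations, rng=rng)
        self.decoder = Decoder(in_ch=config.fused_channels,
                               mid_ch=config.decode_channels,
                               out_ch=config.out_channels, up=8, rng=rng)

    def forward(self, x) -> np.ndarray:
        """Logits (N, 3, H, W) at input resolution."""
        return self.decoder(self.head(self.encoder(x)))

    def backward(self, grad):
        return self.encoder.backward(self.head.backward(self.decoder.backward(grad)))

    def predict(self, x) -> NetworkOutput:
        """Inference-mode forward with probabilities."""
        was_training = self.training
        self.eval()
        logits = self.forward(np.asarray(x))
        if was_training:
            self.train(True)
        return NetworkOutput(logits=logits, probabilities=sigmoid(logits))


def forward_image(model: VesselSegNet, image: np.ndarray) -> NetworkOutput:
    """Run one (H, W) grayscale image through the network."""
    x = np.asarray(image, dtype=float)[None, None]
    return model.predict(x)


def save_weights(model: Module, path) -> None:
    np.savez(path, **model.state_dict())


def load_weights(model: Module, path) -> Module:
    with np.load(path) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model
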