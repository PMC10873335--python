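"""Restoration network architectures and the adversarial objective.

Three image-to-image models map a unit-range artifact image to a
unit-range restored image:

* **AE** — plain four-level encoder-decoder (conv-ReLU-maxpool down,
  transposed-conv up), 3x3 kernels, 8 initial filters, no skips.
* **U-Net** — same encoder but with skip connections concatenating each
  encoder stage into the decoder; 64 initial filters at full scale.
* **CGAN generator** — U-Net-shaped encoder-decoder built from
  convolution -> batch-norm -> ReLU modules with stride-2 downsampling and
  dropout in the decoder.  The dropout is the model's noise source (the
  pix2pix convention: no explicit noise channel).
* **PatchGAN discriminator** — four stride-2 convolutions over the
  channel-concatenated (condition, candidate) pair followed by a 1-channel
  sigmoid head, yielding a 2D map of per-patch real/fake scores.

The adversarial value is E[log D(x, y)] + E[log(1 - D(x, G(x, z)))] with
patch-map means realizing the expectations; the generator objective adds
lambda * L1 (lambda = 100 by default).
"""

from __future__ import annotations

import math

import numpy as np

from . import nn

__all__ = [
    "adversarial_loss", "generator_objective",
    "AENet", "UNet", "Generator", "PatchDiscriminator", "build_model",
    "LAMBDA_L1", "SCORE_EPS",
]

LAMBDA_L1 = 100.0
SCORE_EPS = 1e-7


def adversarial_loss(d_real_map, d_fake_map, eps: float = SCORE_EPS) -> float:
    """Minimax value: mean log D(x,y) + mean log(1 - D(x,G(x,z))).

    Patch-score maps in (0, 1); scores are clamped ``eps`` away from the
    boundaries before the logs.  The value is <= 0, with supremum 0 for a
    perfect discriminator.
    """
    d_real = np.asarray(d_real_map, dtype=np.float64)
    d_fake = np.asarray(d_fake_map, dtype=np.float64)
    for name, arr in (("d_real_map", d_real), ("d_fake_map", d_fake)):
        if arr.size == 0:
            raise ValueError(f"{name} is empty")
        if np.any(arr < 0.0) or np.any(arr > 1.0):
            raise ValueError(f"{name} scores must lie in [0, 1]")
    d_real = np.clip(d_real, eps, 1.0 - eps)
    d_fake = np.clip(d_fake, eps, 1.0 - eps)
    return float(np.mean(np.log(d_real)) + np.mean(np.log(1.0 - d_fake)))


def generator_objective(adversarial: float, l1: float,
                        lambda_l1: float = LAMBDA_L1) -> float:
    """Total generator objective: adversarial value + lambda * L1."""
    if l1 < 0:
        raise ValueError("l1 must be non-negative")
    return float(adversarial + lambda_l1 * l1)


def _check_divisible(size: int, depth: int) -> None:
    if size % (2 ** depth) != 0:
        raise ValueError(f"input size {size} not divisible by 2^{depth}")


class AENet(nn.Sequential):
    """Encoder-decoder without skips (conv-ReLU-maxpool / transposed conv)."""

    def __init__(self, base_filters: int = 8, depth: int = 4,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        self.base_filters, self.depth = base_filters, depth
        layers: list[nn.Layer] = []
        c = 1
        chans = [base_filters * 2 ** d for d in range(depth)]
        for co in chans:
            layers += [nn.Conv2d(c, co, 3, rng=rng, dtype=dtype), nn.ReLU(),
                       nn.MaxPool2d()]
            c = co
        for co in reversed(chans):
            layers += [nn.ConvTranspose2d(c, co, rng=rng, dtype=dtype), nn.ReLU()]
            c = co
        layers += [nn.Conv2d(c, 1, 3, rng=rng, dtype=dtype), nn.Sigmoid()]
        super().__init__(*layers)

    def forward(self, x, train: bool = True):
        _check_divisible(x.shape[2], self.depth)
        _check_divisible(x.shape[3], self.depth)
        return super().forward(x, train)


class _ConvBlock(nn.Layer):
    """conv -> (batch norm) -> activation, optionally stride 2."""

    def __init__(self, c_in, c_out, rng, stride=1, norm=True, act="relu",
                 init="he", dtype=np.float32):
        self.conv = nn.Conv2d(c_in, c_out, 3, stride=stride, rng=rng,
                              init=init, dtype=dtype)
        self.norm = nn.BatchNorm2d(c_out, dtype=dtype) if norm else None
        self.act = nn.LeakyReLU(0.2) if act == "leaky" else nn.ReLU()

    def params(self):
        ps = self.conv.params()
        if self.norm is not None:
            ps += self.norm.params()
        return ps

    def forward(self, x, train: bool = True):
        x = self.conv.forward(x, train)
        if self.norm is not None:
            x = self.norm.forward(x, train)
        return self.act.forward(x, train)

    def backward(self, dy):
        dy = self.act.backward(dy)
        if self.norm is not None:
            dy = self.norm.backward(dy)
        return self.conv.backward(dy)


class UNet(nn.Layer):
    """Four-depth U-Net: conv-ReLU-maxpool encoder, skip-concat decoder.

    Decoder stage at depth d consumes ``2 * base_filters * 2**(d-1)``
    channels: half from upsampling, half from the matching encoder stage.
    """

    def __init__(self, base_filters: int = 64, depth: int = 4,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        self.base_filters, self.depth = base_filters, depth
        chans = [base_filters * 2 ** d for d in range(depth)]  # encoder stages
        self.enc = []
        c = 1
        for co in chans:
            self.enc.append((nn.Conv2d(c, co, 3, rng=rng, dtype=dtype),
                             nn.ReLU(), nn.MaxPool2d()))
            c = co
        self.bottleneck = (nn.Conv2d(c, 2 * c, 3, rng=rng, dtype=dtype),
                           nn.ReLU())
        c = 2 * c
        self.dec = []
        for co in reversed(chans):
            self.dec.append((nn.ConvTranspose2d(c, co, rng=rng, dtype=dtype),
                             nn.Conv2d(2 * co, co, 3, rng=rng, dtype=dtype),
                             nn.ReLU()))
            c = co
        self.head = nn.Conv2d(c, 1, 3, rng=rng, dtype=dtype)
        self.out_act = nn.Sigmoid()

    def params(self):
        ps = []
        for conv, _, _ in self.enc:
            ps += conv.params()
        ps += self.bottleneck[0].params()
        for up, merge, _ in self.dec:
            ps += up.params() + merge.params()
        return ps + self.head.params()

    def forward(self, x, train: bool = True):
        _check_divisible(x.shape[2], self.depth)
        _check_divisible(x.shape[3], self.depth)
        skips = []
        for conv, act, pool in self.enc:
            x = act.forward(conv.forward(x, train), train)
            skips.append(x)
            x = pool.forward(x, train)
        x = self.bottleneck[1].forward(
            self.bottleneck[0].forward(x, train), train)
        self._nskip = []
        for (up, merge, act), skip in zip(self.dec, reversed(skips)):
            x = up.forward(x, train)
            self._nskip.append(skip.shape[1])
            x = np.concatenate([x, skip], axis=1)
            x = act.forward(merge.forward(x, train), train)
        return self.out_act.forward(self.head.forward(x, train), train)

    def backward(self, dy):
        dy = self.head.backward(self.out_act.backward(dy))
        dskips = []
        for (up, merge, act), ns in zip(reversed(self.dec),
                                        reversed(self._nskip)):
            d = merge.backward(act.backward(dy))
            dup, dskip = d[:, :-ns], d[:, -ns:]
            dskips.append(dskip)
            dy = up.backward(dup)
        dy = self.bottleneck[0].backward(self.bottleneck[1].backward(dy))
        for (conv, act, pool), dskip in zip(reversed(self.enc),
                                            reversed(dskips)):
            dy = pool.backward(dy)
            dy = conv.backward(act.backward(dy + dskip))
        return dy


class Generator(nn.Layer):
    """pix2pix-style U-Net generator from conv-BN-ReLU modules.

    Stride-2 convolutions downsample; transposed convolutions upsample;
    dropout (the noise source) acts on the deepest decoder stages during
    training.
    """

    def __init__(self, base_filters: int = 64, depth: int = 4,
                 dropout: float = 0.5, n_dropout_stages: int = 2,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        self.base_filters, self.depth = base_filters, depth
        chans = [base_filters * 2 ** d for d in range(depth)]
        self.enc = []
        c = 1
        for i, co in enumerate(chans):
            self.enc.append(_ConvBlock(c, co, rng, stride=2, norm=(i > 0),
                                       dtype=dtype))
            c = co
        self.dec = []
        for i, co in enumerate(reversed(chans[:-1])):
            drop = nn.Dropout(dropout, rng) if i < n_dropout_stages else None
            self.dec.append((nn.ConvTranspose2d(c, co, rng=rng, dtype=dtype),
                             nn.BatchNorm2d(co, dtype=dtype), nn.ReLU(), drop,
                             _ConvBlock(2 * co, co, rng, dtype=dtype)))
            c = co
        self.final_up = nn.ConvTranspose2d(c, base_filters, rng=rng,
                                           dtype=dtype)
        self.final_act = nn.ReLU()
        self.head = nn.Conv2d(base_filters, 1, 3, rng=rng, dtype=dtype)
        self.out_act = nn.Sigmoid()

    def params(self):
        ps = []
        for blk in self.enc:
            ps += blk.params()
        for up, bn, _, _, merge in self.dec:
            ps += up.params() + bn.params() + merge.params()
        return ps + self.final_up.params() + self.head.params()

    def forward(self, x, train: bool = True):
        _check_divisible(x.shape[2], self.depth)
        _check_divisible(x.shape[3], self.depth)
        skips = []
        for blk in self.enc:
            x = blk.forward(x, train)
            skips.append(x)
        self._nskip = []
        for (up, bn, act, drop, merge), skip in zip(
                self.dec, list(reversed(skips))[1:]):
            x = act.forward(bn.forward(up.forward(x, train), train), train)
            if drop is not None:
                x = drop.forward(x, train)
            self._nskip.append(skip.shape[1])
            x = np.concatenate([x, skip], axis=1)
            x = merge.forward(x, train)
        x = self.final_act.forward(self.final_up.forward(x, train), train)
        return self.out_act.forward(self.head.forward(x, train), train)

    def backward(self, dy):
        dy = self.head.backward(self.out_act.backward(dy))
        dy = self.final_up.backward(self.final_act.backward(dy))
        dskips = []
        for (up, bn, act, drop, merge), ns in zip(reversed(self.dec),
                                                  reversed(self._nskip)):
            d = merge.backward(dy)
            dup, dskip = d[:, :-ns], d[:, -ns:]
            dskips.append(dskip)
            if drop is not None:
                dup = drop.backward(dup)
            dy = up.backward(bn.backward(act.backward(dup)))
        # Deepest encoder output feeds the decoder stem directly (no concat).
        for blk, dskip in zip(reversed(self.enc), [None] + dskips[::-1]):
            if dskip is not None:
                dy = dy + dskip
            dy = blk.backward(dy)
        return dy


class PatchDiscriminator(nn.Sequential):
    """Four stride-2 conv layers + sigmoid head over (condition, candidate)."""

    def __init__(self, base_filters: int = 64, in_channels: int = 2,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        rng = rng or np.random.default_rng(0)
        self.base_filters = base_filters
        f = base_filters
        super().__init__(
            nn.Conv2d(in_channels, f, 3, stride=2, rng=rng, init=0.05, dtype=dtype),
            nn.LeakyReLU(0.2),
            nn.Conv2d(f, 2 * f, 3, stride=2, rng=rng, init=0.05, dtype=dtype),
            nn.BatchNorm2d(2 * f, dtype=dtype),
            nn.LeakyReLU(0.2),
            nn.Conv2d(2 * f, 4 * f, 3, stride=2, rng=rng, init=0.05, dtype=dtype),
            nn.BatchNorm2d(4 * f, dtype=dtype),
            nn.LeakyReLU(0.2),
            nn.Conv2d(4 * f, 8 * f, 3, stride=2, rng=rng, init=0.05, dtype=dtype),
            nn.BatchNorm2d(8 * f, dtype=dtype),
            nn.LeakyReLU(0.2),
            nn.Conv2d(8 * f, 1, 3, rng=rng, init=0.05, dtype=dtype),
            nn.Sigmoid(),
        )


_KINDS = {"ae", "unet", "cgan-generator", "cgan-discriminator"}


def build_model(kind: str, base_filters: int | None = None, depth: int = 4,
                seed: int = 0, dtype=np.float32, **kwargs):
    """Factory for the restoration networks.

    ``kind`` is one of ``ae`` (8 initial filters), ``unet`` (64),
    ``cgan-generator`` (64) or ``cgan-discriminator`` (64); pass
    ``base_filters`` explicitly for desk-scale variants.
    """
    kind = kind.lower().replace("_", "-")
    if kind not in _KINDS:
        raise ValueError(f"unknown model kind {kind!r}; choose from {_KINDS}")
    rng = np.random.default_rng(seed)
    if kind == "ae":
        return AENet(base_filters or 8, depth, rng=rng, dtype=dtype, **kwargs)
    if kind == "unet":
        return UNet(base_filters or 64, depth, rng=rng, dtype=dtype, **kwargs)
    if kind == "cgan-generator":
        return Generator(base_filters or 64, depth, rng=rng, dtype=dtype,
                         **kwargs)
    return PatchDiscriminator(base_filters or 64, rng=rng, dtype=dtype,
                              **kwargs)
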