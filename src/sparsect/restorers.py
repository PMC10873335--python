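"""Scikit-learn style estimators for artifact restoration.

Each restorer follows the ``fit(X, y) / predict(X)`` contract on stacks of
HU images with shape ``(n_images, height, width)``: ``X`` holds the
streaked sparse-view reconstructions, ``y`` the matching artifact-free
originals.  Images are min-max normalized to (0, 1) per pair using the
artifact image's range (the only range available at inference time), the
network operates on unit-range data, and predictions are mapped back to HU
with the same record — so predicted HU values always lie inside the input
image's range.

Training is fully deterministic in ``seed``: weight initialization, data
order and dropout all derive from one generator, and two fits with the
same seed produce bit-identical weights.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from . import nn
from .models import (AENet, Generator, PatchDiscriminator, UNet,
                     SCORE_EPS, adversarial_loss)

__all__ = ["AERestorer", "UNetRestorer", "CGANRestorer"]


def _validate_images(X, name="X"):
    X = np.asarray(X, dtype=np.float32)
    if X.ndim == 2:
        X = X[None]
    if X.ndim != 3:
        raise ValueError(f"{name} must have shape (n_images, height, width)")
    if not np.all(np.isfinite(X)):
        raise ValueError(f"{name} contains non-finite values")
    return X


def _normalize_pairs(X, y):
    """Scale each pair into (0, 1) with the artifact image's (min, max)."""
    lo = X.min(axis=(1, 2), keepdims=True)
    hi = X.max(axis=(1, 2), keepdims=True)
    if np.any(hi <= lo):
        raise ValueError("constant artifact image: normalization undefined")
    Xn = (X - lo) / (hi - lo)
    yn = np.clip((y - lo) / (hi - lo), 0.0, 1.0)
    return Xn[:, None], yn[:, None]  # add channel axis


class _ImageRestorer(BaseEstimator):
    """Shared plumbing: validation, normalization, batched inference."""

    _kind = "base"

    def _build(self, rng):  # pragma: no cover - overridden
        raise NotImplementedError

    def _fit_loop(self, Xn, yn, rng):  # pragma: no cover - overridden
        raise NotImplementedError

    def fit(self, X, y):
        X = _validate_images(X, "X")
        y = _validate_images(y, "y")
        if X.shape != y.shape:
            raise ValueError("X and y must have identical shapes")
        if X.shape[0] == 0:
            raise ValueError("empty training set")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        size = X.shape[1]
        if size % (2 ** self.depth) != 0:
            raise ValueError(
                f"image size {size} not divisible by 2^{self.depth}")
        Xn, yn = _normalize_pairs(X, y)
        rng = np.random.default_rng(self.seed)
        self._build(rng)
        self.loss_history_ = self._fit_loop(Xn, yn, rng)
        self.n_epochs_ = len(self.loss_history_)
        self.input_shape_ = X.shape[1:]
        return self

    def _forward_eval(self, Xn):
        out = np.empty_like(Xn)
        for start in range(0, Xn.shape[0], 8):
            out[start:start + 8] = self.net_.forward(
                Xn[start:start + 8], train=False)
        return out

    def predict(self, X):
        if not hasattr(self, "net_"):
            raise RuntimeError("estimator is not fitted")
        X = _validate_images(X, "X")
        if X.shape[1:] != self.input_shape_:
            raise ValueError(
                f"expected images of shape {self.input_shape_}, "
                f"got {X.shape[1:]}")
        lo = X.min(axis=(1, 2), keepdims=True)
        hi = X.max(axis=(1, 2), keepdims=True)
        if np.any(hi <= lo):
            raise ValueError("constant input image: normalization undefined")
        Xn = ((X - lo) / (hi - lo))[:, None]
        out = self._forward_eval(Xn)[:, 0]
        return out * (hi - lo) + lo

    def score(self, X, y):
        """Mean global SSIM of predictions against targets (HU domain)."""
        from .metrics import ssim_global
        pred = self.predict(X)
        y = _validate_images(y, "y")
        return float(np.mean([ssim_global(p, t) for p, t in zip(pred, y)]))


class _SupervisedRestorer(_ImageRestorer):
    """MSE-trained encoder-decoder (AE and U-Net share the loop)."""

    def _fit_loop(self, Xn, yn, rng):
        opt = nn.Adam(self.net_.params(), self.learning_rate)
        n = Xn.shape[0]
        bs = max(1, int(self.batch_size))
        history = []
        for _ in range(self.epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, bs):
                sel = order[start:start + bs]
                xb, yb = Xn[sel], yn[sel]
                out = self.net_.forward(xb, train=True)
                diff = out - yb
                losses.append(float(np.mean(diff ** 2)))
                self.net_.backward((2.0 / diff.size) * diff)
                opt.step()
                opt.zero_grad()
            history.append({"mse": float(np.mean(losses))})
        return history


class AERestorer(_SupervisedRestorer):
    """Autoencoder restorer: four conv-ReLU-maxpool encoder layers, 3x3
    kernels, 8 initial filters, transposed-convolution decoder; Adam with
    learning rate 0.001, batch size 4, MSE loss."""

    _kind = "ae"

    def __init__(self, base_filters: int = 8, depth: int = 4,
                 epochs: int = 200, learning_rate: float = 1e-3,
                 batch_size: int = 4, seed: int = 0):
        self.base_filters = base_filters
        self.depth = depth
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.seed = seed

    def _build(self, rng):
        self.net_ = AENet(self.base_filters, self.depth, rng=rng)


class UNetRestorer(_SupervisedRestorer):
    """U-Net restorer: four encoder/decoder depths with skip connections,
    3x3 kernels, 64 initial filters at full scale; Adam with learning rate
    0.001, batch size 4, MSE loss."""

    _kind = "unet"

    def __init__(self, base_filters: int = 64, depth: int = 4,
                 epochs: int = 200, learning_rate: float = 1e-3,
                 batch_size: int = 4, seed: int = 0):
        self.base_filters = base_filters
        self.depth = depth
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.seed = seed

    def _build(self, rng):
        self.net_ = UNet(self.base_filters, self.depth, rng=rng)


class CGANRestorer(_ImageRestorer):
    """Conditional GAN restorer (pix2pix-style).

    The generator minimizes the non-saturating adversarial term plus
    ``lambda_l1`` times the L1 distance to the original image; the PatchGAN
    discriminator maximizes the minimax value on (condition, candidate)
    pairs.  Adam with learning rate 0.0002 for both networks, batch size 1.

    ``disc_filters`` defaults to a quarter of the generator's base filters
    (at least 2): an over-strong discriminator unbalances the game and its
    gradient noise stalls the generator's L1 convergence, which bites hard
    at small filter counts.  Pass ``disc_filters=base_filters`` for the
    symmetric pix2pix sizing.

    ``warmup_epochs`` (default: a third of ``epochs``) trains the
    generator on the weighted L1 term alone before the adversarial game
    starts, so the discriminator never faces — and never overwhelms — an
    untrained generator.
    """

    _kind = "cgan"

    def __init__(self, base_filters: int = 64, depth: int = 4,
                 epochs: int = 200, learning_rate: float = 2e-4,
                 batch_size: int = 1, lambda_l1: float = 100.0,
                 dropout: float = 0.5, beta1: float = 0.5,
                 disc_filters: int | None = None,
                 warmup_epochs: int | None = None, seed: int = 0):
        self.base_filters = base_filters
        self.depth = depth
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.lambda_l1 = lambda_l1
        self.dropout = dropout
        self.beta1 = beta1
        self.disc_filters = disc_filters
        self.warmup_epochs = warmup_epochs
        self.seed = seed

    def _build(self, rng):
        self.net_ = Generator(self.base_filters, self.depth,
                              dropout=self.dropout, rng=rng)
        d_filters = self.disc_filters or max(2, self.base_filters // 4)
        self.disc_ = PatchDiscriminator(d_filters, rng=rng)

    @staticmethod
    def _dlog(scores, sign):
        """Gradient of -mean(log s) (sign=+1) or -mean(log(1-s)) (sign=-1),
        zero where the score was clamped."""
        clipped = np.clip(scores, SCORE_EPS, 1.0 - SCORE_EPS)
        inside = (scores > SCORE_EPS) & (scores < 1.0 - SCORE_EPS)
        if sign > 0:
            g = -1.0 / (clipped * scores.size)
        else:
            g = 1.0 / ((1.0 - clipped) * scores.size)
        return np.where(inside, g, 0.0).astype(scores.dtype)

    def _fit_loop(self, Xn, yn, rng):
        g_opt = nn.Adam(self.net_.params(), self.learning_rate,
                        betas=(self.beta1, 0.999))
        d_opt = nn.Adam(self.disc_.params(), self.learning_rate,
                        betas=(self.beta1, 0.999))
        n = Xn.shape[0]
        warmup = self.warmup_epochs
        if warmup is None:
            warmup = self.epochs // 3
        history = []
        for epoch in range(self.epochs):
            adversarial = epoch >= warmup
            order = rng.permutation(n)
            l1_losses, adv_losses = [], []
            for i in order:
                x = Xn[i:i + 1]
                y = yn[i:i + 1]
                fake = self.net_.forward(x, train=True)

                if adversarial:
                    # Discriminator ascent on log D(x,y) + log(1-D(x,G(x,z))),
                    # halved (the usual convention slowing D relative to G).
                    d_real = self.disc_.forward(
                        np.concatenate([x, y], axis=1), train=True)
                    self.disc_.backward(0.5 * self._dlog(d_real, +1))
                    d_fake = self.disc_.forward(
                        np.concatenate([x, fake], axis=1), train=True)
                    self.disc_.backward(0.5 * self._dlog(d_fake, -1))
                    d_opt.step()
                    d_opt.zero_grad()
                    adv_losses.append(adversarial_loss(d_real, d_fake))

                    # Generator: non-saturating adversarial term + L1.
                    fake = self.net_.forward(x, train=True)
                    d_gen = self.disc_.forward(
                        np.concatenate([x, fake], axis=1), train=True)
                    dpair = self.disc_.backward(self._dlog(d_gen, +1))
                    d_opt.zero_grad()  # discriminator unchanged by this pass
                    dadv = dpair[:, 1:2]
                else:
                    adv_losses.append(0.0)
                    dadv = 0.0
                diff = fake - y
                l1 = float(np.mean(np.abs(diff)))
                l1_losses.append(l1)
                dfake = dadv + (self.lambda_l1 / diff.size) \
                    * np.sign(diff).astype(fake.dtype)
                self.net_.backward(dfake)
                g_opt.step()
                g_opt.zero_grad()
            history.append({"l1": float(np.mean(l1_losses)),
                            "adversarial": float(np.mean(adv_losses))})
        return history
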