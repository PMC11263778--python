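"""Candidate-region segmentation: a U-Net implemented in numpy.

The network maps a normalized vascular phase image to a same-size
candidate-region score map.  Architecture: an encoder of five levels (one
3x3 convolution per level, 2x2 max-pooling between levels) and a decoder
of four levels (2x nearest-neighbour upsampling, skip concatenation and
two convolutions per level), 13 convolutional layers in total.  Every
convolution is followed by batch normalization and ReLU except the last,
a 1x1 convolution producing the single-channel output trained with
squared error.  Optimization is Adam (alpha 0.001, beta1 0.9, beta2
0.999, eps 1e-8) for 50 epochs by default.

Channel widths double per level from ``base_width`` (default 16); a
reduced ``base_width`` gives a desk-scale model that trains in minutes on
one CPU.  Everything — initialization, shuffling, training — is driven by
explicit seeds; exact bit reproducibility additionally requires a fixed
BLAS configuration, otherwise reproducibility is statistical.

Forward/backward passes are written directly in numpy (im2col
convolutions); no deep-learning framework is used anywhere in the
package.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import AnalysisError, ConfigError, UnsuitableCurveError
from .phase_builder import PhaseImage, normalize_phase

_DTYPE = np.float32


# --------------------------------------------------------------------------
# Layers
# --------------------------------------------------------------------------


class Conv2d:
    """Same-padding 2D convolution with He-normal initialization."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        self.c_in, self.c_out, self.k = c_in, c_out, k
        std = math.sqrt(2.0 / (c_in * k * k))
        self.W = rng.normal(0.0, std, size=(c_out, c_in * k * k)).astype(_DTYPE)
        self.b = np.zeros(c_out, dtype=_DTYPE)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cols = None
        self._shape = None

    @staticmethod
    def _im2col(x: np.ndarray, k: int) -> np.ndarray:
        n, c, h, w = x.shape
        p = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(xp, (k, k), axis=(2, 3))  # (n,c,h,w,k,k)
        return win.transpose(0, 2, 3, 1, 4, 5).reshape(n, h * w, c * k * k)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        n, c, h, w = x.shape
        cols = self._im2col(x, self.k)
        out = cols @ self.W.T + self.b
        if training:
            self._cols = cols
            self._shape = (n, c, h, w)
        return out.transpose(0, 2, 1).reshape(n, self.c_out, h, w)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        g = dy.reshape(n, self.c_out, h * w).transpose(0, 2, 1)  # (n, hw, c_out)
        self.dW += np.einsum("npo,npk->ok", g, self._cols, optimize=True)
        self.db += g.sum(axis=(0, 1))
        self._cols = None
        # dX = full correlation of dy with flipped kernels
        w4 = self.W.reshape(self.c_out, self.c_in, self.k, self.k)
        wb = w4[:, :, ::-1, ::-1].transpose(1, 0, 2, 3).reshape(
            self.c_in, self.c_out * self.k * self.k
        )
        dyn = dy.reshape(n, self.c_out, h, w)
        cols_dy = self._im2col(dyn, self.k)
        dx = cols_dy @ wb.T
        return dx.transpose(0, 2, 1).reshape(n, self.c_in, h, w)

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def zero_grad(self):
        self.dW[:] = 0
        self.db[:] = 0


class BatchNorm2d:
    """Per-channel batch normalization with running statistics."""

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(c, dtype=_DTYPE)
        self.beta = np.zeros(c, dtype=_DTYPE)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(c, dtype=_DTYPE)
        self.running_var = np.ones(c, dtype=_DTYPE)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mu
            ).astype(_DTYPE)
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            ).astype(_DTYPE)
        else:
            mu, var = self.running_mean, self.running_var
        ivar = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None, None]) * ivar[None, :, None, None]
        if training:
            self._cache = (xhat, ivar)
        return self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, ivar = self._cache
        self._cache = None
        m = dy.shape[0] * dy.shape[2] * dy.shape[3]
        self.dgamma += (dy * xhat).sum(axis=(0, 2, 3))
        self.dbeta += dy.sum(axis=(0, 2, 3))
        dxhat = dy * self.gamma[None, :, None, None]
        s1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        dx = ivar[None, :, None, None] / m * (m * dxhat - s1 - xhat * s2)
        return dx.astype(_DTYPE)

    def params(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]

    def zero_grad(self):
        self.dgamma[:] = 0
        self.dbeta[:] = 0


class _ReLU:
    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = dy * self._mask
        self._mask = None
        return dx


class _MaxPool2:
    def __init__(self):
        self._idx = None
        self._shape = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(n, c, h // 2, w // 2, 4)
        if training:
            self._idx = xr.argmax(axis=-1)
            self._shape = (n, c, h, w)
        return xr.max(axis=-1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        flat = np.zeros((n, c, h // 2, w // 2, 4), dtype=dy.dtype)
        np.put_along_axis(flat, self._idx[..., None], dy[..., None], axis=-1)
        self._idx = None
        out = flat.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return out.reshape(n, c, h, w)


class _Upsample2:
    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = dy.shape
        return (
            dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5)).astype(dy.dtype)
        )


class _ConvBlock:
    """Conv followed (optionally) by batch norm and ReLU."""

    def __init__(self, c_in, c_out, k, rng, bn: bool = True, relu: bool = True):
        self.conv = Conv2d(c_in, c_out, k, rng)
        self.bn = BatchNorm2d(c_out) if bn else None
        self.relu = _ReLU() if relu else None

    def forward(self, x, training):
        x = self.conv.forward(x, training)
        if self.bn is not None:
            x = self.bn.forward(x, training)
        if self.relu is not None:
            x = self.relu.forward(x, training)
        return x

    def backward(self, dy):
        if self.relu is not None:
            dy = self.relu.backward(dy)
        if self.bn is not None:
            dy = self.bn.backward(dy)
        return self.conv.backward(dy)

    def params(self):
        p = self.conv.params()
        if self.bn is not None:
            p += self.bn.params()
        return p

    def zero_grad(self):
        self.conv.zero_grad()
        if self.bn is not None:
            self.bn.zero_grad()


# --------------------------------------------------------------------------
# The U-Net
# --------------------------------------------------------------------------


@dataclass
class UNetSpec:
    """Architecture hyperparameters.

    ``depth`` encoder levels with one convolution each, ``depth - 1``
    decoder levels with two each: ``3 * depth - 2`` convolutions (13 at
    depth 5).  ``base_width`` channels at the top level, doubling per
    level.
    """

    depth: int = 5
    base_width: int = 16
    in_channels: int = 1

    def __post_init__(self) -> None:
        if self.depth < 2:
            raise ConfigError("depth must be >= 2")
        if self.base_width < 1 or self.in_channels < 1:
            raise ConfigError("base_width and in_channels must be >= 1")

    @property
    def n_conv_layers(self) -> int:
        return 3 * self.depth - 2

    @property
    def tile(self) -> int:
        """Input dims must be divisible by this (padded otherwise)."""
        return 2 ** (self.depth - 1)


class UNet:
    """Numpy U-Net with explicit forward/backward passes."""

    def __init__(self, spec: UNetSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        d = spec.depth
        widths = [spec.base_width * 2**i for i in range(d)]
        self.widths = widths
        self.enc = []
        c_prev = spec.in_channels
        for lvl in range(d):
            self.enc.append(_ConvBlock(c_prev, widths[lvl], 3, rng))
            c_prev = widths[lvl]
        self.pools = [_MaxPool2() for _ in range(d - 1)]
        self.ups = [_Upsample2() for _ in range(d - 1)]
        self.dec_a = []
        self.dec_b = []
        for lvl in range(d - 2, -1, -1):  # d-2 .. 0
            self.dec_a.append(
                _ConvBlock(widths[lvl + 1] + widths[lvl], widths[lvl], 3, rng)
            )
            if lvl > 0:
                self.dec_b.append(_ConvBlock(widths[lvl], widths[lvl], 3, rng))
            else:
                # final 1x1 output convolution: no batch norm, no ReLU
                self.dec_b.append(
                    _ConvBlock(widths[0], 1, 1, rng, bn=False, relu=False)
                )
        self._cache = None

    # -- introspection ----------------------------------------------------

    @property
    def conv_blocks(self) -> list[_ConvBlock]:
        """All convolution blocks in forward order (13 at depth 5)."""
        blocks = list(self.enc)
        for a, b in zip(self.dec_a, self.dec_b):
            blocks += [a, b]
        return blocks

    def audit(self) -> list[dict]:
        """Per-layer architecture summary for contract checks."""
        return [
            {
                "c_in": blk.conv.c_in,
                "c_out": blk.conv.c_out,
                "kernel": blk.conv.k,
                "batch_norm": blk.bn is not None,
                "relu": blk.relu is not None,
            }
            for blk in self.conv_blocks
        ]

    def _modules(self):
        return self.conv_blocks

    def parameters(self):
        out = []
        for m in self._modules():
            out += m.params()
        return out

    def zero_grad(self):
        for m in self._modules():
            m.zero_grad()

    # -- passes -----------------------------------------------------------

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """(N, C, H, W) -> (N, 1, H, W); H and W must be multiples of
        ``spec.tile`` (use :func:`predict_candidate` for automatic
        padding)."""
        x = np.ascontiguousarray(x, dtype=_DTYPE)
        if x.ndim != 4 or x.shape[1] != self.spec.in_channels:
            raise AnalysisError("input must be (N, C_in, H, W)")
        if x.shape[2] % self.spec.tile or x.shape[3] % self.spec.tile:
            raise AnalysisError(
                f"input dims must be multiples of {self.spec.tile}"
            )
        d = self.spec.depth
        skips = []
        h = x
        for lvl in range(d):
            h = self.enc[lvl].forward(h, training)
            if lvl < d - 1:
                skips.append(h)
                h = self.pools[lvl].forward(h, training)
        for i, lvl in enumerate(range(d - 2, -1, -1)):
            up = self.ups[i].forward(h, training)
            h = np.concatenate([up, skips[lvl]], axis=1)
            h = self.dec_a[i].forward(h, training)
            h = self.dec_b[i].forward(h, training)
        if training:
            self._up_channels = [self.widths[lvl + 1] for lvl in range(d - 2, -1, -1)]
        return h

    def backward(self, dy: np.ndarray) -> None:
        """Accumulate parameter gradients for the last training forward."""
        d = self.spec.depth
        g = np.ascontiguousarray(dy, dtype=_DTYPE)
        g_skip = {}
        for i in range(d - 2, -1, -1):  # reverse decoder order
            lvl = d - 2 - i
            g = self.dec_b[i].backward(g)
            g = self.dec_a[i].backward(g)
            cu = self._up_channels[i]
            g_up, g_s = g[:, :cu], g[:, cu:]
            g_skip[lvl] = g_s
            g = self.ups[i].backward(g_up)
        # g now flows into the bottleneck encoder output
        for lvl in range(d - 1, -1, -1):
            if lvl < d - 1:
                g = self.pools[lvl].backward(g)
                g = g + g_skip[lvl]
            g = self.enc[lvl].backward(g)


def build_model(spec: UNetSpec | None = None, seed: int = 0) -> UNet:
    """Seed-deterministic model construction."""
    return UNet(spec or UNetSpec(), seed=seed)


# --------------------------------------------------------------------------
# Training
# --------------------------------------------------------------------------


@dataclass
class TrainConfig:
    """Adam hyperparameters and schedule (defaults: alpha 0.001, beta1 0.9,
    beta2 0.999, eps 1e-8, 50 iterations over the training set, 6 folds)."""

    lr: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    iterations: int = 50  # epochs over the (augmented) training set
    batch_size: int = 8
    k_folds: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.iterations < 1 or self.batch_size < 1:
            raise ConfigError("iterations and batch_size must be >= 1")
        if not (0 <= self.beta1 < 1 and 0 <= self.beta2 < 1):
            raise ConfigError("beta1/beta2 must be in [0, 1)")


class Adam:
    def __init__(self, config: TrainConfig):
        self.cfg = config
        self.t = 0
        self._m: dict[int, np.ndarray] = {}
        self._v: dict[int, np.ndarray] = {}

    def step(self, params: list[tuple[np.ndarray, np.ndarray]]) -> None:
        c = self.cfg
        self.t += 1
        for i, (p, g) in enumerate(params):
            m = self._m.setdefault(i, np.zeros_like(p))
            v = self._v.setdefault(i, np.zeros_like(p))
            m += (1 - c.beta1) * (g - m)
            v += (1 - c.beta2) * (g * g - v)
            mhat = m / (1 - c.beta1**self.t)
            vhat = v / (1 - c.beta2**self.t)
            p -= c.lr * mhat / (np.sqrt(vhat) + c.eps)


def train(
    model: UNet,
    pairs: list[tuple[np.ndarray, np.ndarray]],
    config: TrainConfig | None = None,
) -> tuple[UNet, list[float]]:
    """Train on (image, label) pairs with squared-error loss.

    Labels are binary masks in {0, 1}.  Returns the model and the
    per-iteration (epoch) mean squared error trace.  Aborts with
    diagnostics if the loss turns non-finite.
    """
    if not pairs:
        raise ConfigError("training needs at least one pair")
    config = config or TrainConfig()
    for img, lab in pairs:
        if np.shape(img) != np.shape(lab):
            raise ConfigError("image and label shapes differ")
    x_all = np.stack([np.asarray(p[0], dtype=_DTYPE) for p in pairs])[:, None]
    y_all = np.stack([np.asarray(p[1], dtype=_DTYPE) for p in pairs])[:, None]
    rng = np.random.default_rng(config.seed)
    opt = Adam(config)
    losses: list[float] = []
    n = len(pairs)
    for epoch in range(config.iterations):
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            x, y = x_all[idx], y_all[idx]
            out = model.forward(x, training=True)
            diff = out - y
            loss = float(np.mean(diff**2))
            if not np.isfinite(loss):
                raise AnalysisError(
                    f"non-finite loss at iteration {epoch}, batch {n_batches}"
                )
            model.zero_grad()
            model.backward((2.0 / diff.size) * diff)
            opt.step(model.parameters())
            epoch_loss += loss
            n_batches += 1
        losses.append(epoch_loss / n_batches)
    return model, losses


def make_phase_label_pairs(
    cases, target: str = "PA", skip_unsuitable: bool = True
) -> tuple[list[tuple[np.ndarray, np.ndarray]], list[int]]:
    """Build (normalized phase image, binary label) training pairs from
    simulated ``(series, truth)`` cases.

    Cases whose count curve lacks the target peak (e.g. slow injections)
    are skipped when ``skip_unsuitable``.  Returns the pairs and the
    indices of the kept cases.
    """
    from .phase_builder import (
        build_phase_image, detect_peak_frame, global_count_curve,
        normalize_phase as _norm,
    )

    pairs, kept = [], []
    for i, (series, truth) in enumerate(cases):
        try:
            peak = detect_peak_frame(global_count_curve(series), target)
        except UnsuitableCurveError:
            if skip_unsuitable:
                continue
            raise
        phase = _norm(build_phase_image(series, peak, target=target))
        pairs.append((phase.image, truth.masks[target].astype(float)))
        kept.append(i)
    return pairs, kept


def crossval_split(
    case_ids: list, k: int = 6, seed: int = 0
) -> list[list]:
    """Randomly partition case ids into k folds of near-equal size.

    Folds are disjoint, cover all cases, and differ in size by at most one;
    the split is deterministic for a given seed.
    """
    if k < 1:
        raise ConfigError("k must be >= 1")
    if k > len(case_ids):
        raise ConfigError(f"k={k} exceeds number of cases ({len(case_ids)})")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(case_ids))
    folds: list[list] = [[] for _ in range(k)]
    for i, idx in enumerate(order):
        folds[i % k].append(case_ids[int(idx)])
    return folds


# --------------------------------------------------------------------------
# Inference
# --------------------------------------------------------------------------


@dataclass
class CandidateMask:
    """Continuous candidate score map (clipped to [0, 1]) and, once the
    P-tile step has run, its binarized form."""

    score_map: np.ndarray
    target: str
    binary: np.ndarray | None = None


def predict_candidate(model: UNet, phase: PhaseImage) -> CandidateMask:
    """Run the network on a (normalized) phase image.

    Inputs whose dimensions are not multiples of the network tile are
    zero-padded for the pass and cropped back.  The score map is clipped
    to [0, 1].
    """
    if not phase.normalized:
        phase = normalize_phase(phase)
    img = np.asarray(phase.image, dtype=_DTYPE)
    h, w = img.shape
    tile = model.spec.tile
    ph = (-h) % tile
    pw = (-w) % tile
    x = np.pad(img, ((0, ph), (0, pw)))[None, None]
    out = model.forward(x, training=False)[0, 0, :h, :w]
    score = np.clip(out, 0.0, 1.0)
    return CandidateMask(score_map=np.asarray(score, dtype=float),
                         target=phase.target)


# --------------------------------------------------------------------------
# Checkpoints
# --------------------------------------------------------------------------


def save_model(model: UNet, path: str | Path) -> None:
    """Write ``<path>.npz`` (weights) and ``<path>.manifest.json``."""
    base = Path(path)
    if base.suffix == ".npz":
        base = base.with_suffix("")
    arrays: dict[str, np.ndarray] = {}
    for bi, blk in enumerate(model.conv_blocks):
        arrays[f"conv{bi}_W"] = blk.conv.W
        arrays[f"conv{bi}_b"] = blk.conv.b
        if blk.bn is not None:
            arrays[f"bn{bi}_gamma"] = blk.bn.gamma
            arrays[f"bn{bi}_beta"] = blk.bn.beta
            arrays[f"bn{bi}_mean"] = blk.bn.running_mean
            arrays[f"bn{bi}_var"] = blk.bn.running_var
    np.savez_compressed(base.with_suffix(".npz"), **arrays)
    manifest = {
        "depth": model.spec.depth,
        "base_width": model.spec.base_width,
        "in_channels": model.spec.in_channels,
        "n_conv_layers": model.spec.n_conv_layers,
        "layers": model.audit(),
    }
    base.with_name(base.name + ".manifest.json").write_text(
        json.dumps(manifest, indent=2)
    )


def load_model(path: str | Path) -> UNet:
    base = Path(path)
    if base.suffix == ".npz":
        base = base.with_suffix("")
    manifest_path = base.with_name(base.name + ".manifest.json")
    if not manifest_path.exists():
        raise ConfigError(f"missing model manifest {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    spec = UNetSpec(
        depth=manifest["depth"],
        base_width=manifest["base_width"],
        in_channels=manifest["in_channels"],
    )
    model = UNet(spec, seed=0)
    with np.load(base.with_suffix(".npz")) as data:
        for bi, blk in enumerate(model.conv_blocks):
            blk.conv.W = data[f"conv{bi}_W"].astype(_DTYPE)
            blk.conv.b = data[f"conv{bi}_b"].astype(_DTYPE)
            blk.conv.dW = np.zeros_like(blk.conv.W)
            blk.conv.db = np.zeros_like(blk.conv.b)
            if blk.bn is not None:
                blk.bn.gamma = data[f"bn{bi}_gamma"].astype(_DTYPE)
                blk.bn.beta = data[f"bn{bi}_beta"].astype(_DTYPE)
                blk.bn.running_mean = data[f"bn{bi}_mean"].astype(_DTYPE)
                blk.bn.running_var = data[f"bn{bi}_var"].astype(_DTYPE)
                blk.bn.dgamma = np.zeros_like(blk.bn.gamma)
                blk.bn.dbeta = np.zeros_like(blk.bn.beta)
    return model
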