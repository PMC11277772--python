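"""Sparse-coding super-resolution network (SCNN).

The network maps a bicubically upscaled low-resolution slice to a
high-resolution prediction through an unrolled sparse-coding layer:

1. ``H1``: a first convolution + ReLU extracts an ``n1``-dimensional
   feature vector per pixel of the upscaled input.
2. Per patch (size ``p``, stride ``s``), the feature vector at the patch
   center is sparse-coded against a low-resolution dictionary ``Dlow`` by
   ``k`` unrolled ISTA steps

       z_{k+1} = h_theta( (1/L) Dlow^T x + (I - (1/L) Dlow^T Dlow) z_k )

   with the clamped soft-threshold shrinkage ``h_theta(v) = sign(v) *
   max(|v| - theta, 0)``, ``theta = alpha / L`` and ``L`` an upper bound
   on the largest eigenvalue of ``Dlow^T Dlow``.
3. ``H3``: a 1x1 convolution + ReLU maps the sparse code to the
   high-resolution code space; multiplying by the high-resolution
   dictionary ``DHigh`` yields a flattened ``p x p`` patch.
4. Overlapping patches are averaged (unweighted) into the output canvas;
   ``H4``, a final convolution (+ ReLU, as the output layer is printed),
   then produces the high-resolution image from the assembled canvas.

Training is plain backpropagation through the unrolled graph (LISTA
style): every block in ``W = {F1, b1, Dlow, alpha, F3, b3, DHigh, F4,
b4}`` receives an analytic gradient of the mean-squared reconstruction
loss; ``L`` is a stored parameter refreshed from ``Dlow`` after each
optimizer step and treated as constant inside the graph. The analytic
gradients are verified against central finite differences in the test
suite.

All images handled here live on the [0, 1] intensity scale;
:func:`enhance_image` wraps the raw 8/16-bit scale conversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage

from pulmotex.types import GrayImage

__all__ = [
    "SCNNConfig",
    "SCNNParams",
    "bicubic_upscale",
    "conv_relu",
    "soft_threshold",
    "ista_sparse_code",
    "scnn_forward",
    "mse_loss",
    "init_params",
    "train_scnn",
    "enhance_image",
]


def bicubic_upscale(image: GrayImage, factor: int) -> GrayImage:
    """Cubic-spline upscaling by an integer factor in {2, 3, 4}."""
    if factor not in (2, 3, 4):
        raise ValueError("factor must be 2, 3 or 4")
    up = ndimage.zoom(image.pixels, factor, order=3, mode="reflect", grid_mode=True)
    return GrayImage(up, image.bit_depth)


def _upscale_array(a: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return a.copy()
    return ndimage.zoom(a, factor, order=3, mode="reflect", grid_mode=True)


def conv_relu(
    inputs: np.ndarray, filters: np.ndarray, biases: np.ndarray, relu: bool = True
) -> np.ndarray:
    """Valid cross-correlation plus bias, optionally rectified.

    ``inputs``: (C_in, H, W); ``filters``: (C_out, C_in, fh, fw) with odd
    spatial size; ``biases``: (C_out,). Returns (C_out, H-fh+1, W-fw+1).
    """
    inputs = np.asarray(inputs, dtype=float)
    filters = np.asarray(filters, dtype=float)
    if inputs.ndim == 2:
        inputs = inputs[None]
    if filters.ndim == 3:
        filters = filters[:, None]
    c_out, c_in, fh, fw = filters.shape
    if fh % 2 == 0 or fw % 2 == 0:
        raise ValueError("filter spatial size must be odd")
    if inputs.shape[0] != c_in:
        raise ValueError("channel count mismatch")
    if fh > inputs.shape[1] or fw > inputs.shape[2]:
        raise ValueError("filter larger than input")
    windows = sliding_window_view(inputs, (fh, fw), axis=(1, 2))  # (C_in, H', W', fh, fw)
    out = np.tensordot(filters, windows, axes=([1, 2, 3], [0, 3, 4]))
    out += np.asarray(biases, dtype=float)[:, None, None]
    if relu:
        out = np.maximum(out, 0.0)
    return out


def soft_threshold(v: np.ndarray, theta: np.ndarray | float) -> np.ndarray:
    """Clamped shrinkage ``sign(v) * max(|v| - theta, 0)``."""
    theta = np.asarray(theta, dtype=float)
    if np.any(theta < 0):
        raise ValueError("theta must be nonnegative")
    v = np.asarray(v, dtype=float)
    return np.sign(v) * np.maximum(np.abs(v) - theta, 0.0)


def lipschitz_bound(Dlow: np.ndarray) -> float:
    """Upper bound on the largest eigenvalue of ``Dlow^T Dlow``."""
    if not np.any(Dlow):
        raise ValueError("dictionary is identically zero")
    gram = Dlow.T @ Dlow
    return float(np.linalg.eigvalsh(gram)[-1] * (1.0 + 1e-6))


def ista_sparse_code(
    x: np.ndarray, Dlow: np.ndarray, alpha: float, k_iters: int, L: float | None = None
) -> np.ndarray:
    """k unrolled ISTA steps for the l1 sparse-coding problem
    ``argmin_z 0.5 ||x - Dlow z||^2 + alpha ||z||_1`` starting from 0.

    ``x`` may be a single vector (n,) or a batch (n, N).
    """
    Dlow = np.asarray(Dlow, dtype=float)
    if L is None:
        L = lipschitz_bound(Dlow)
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = x[:, None] if single else x
    if X.shape[0] != Dlow.shape[0]:
        raise ValueError("x length must match dictionary rows")
    theta = alpha / L
    B = Dlow.T @ X / L
    S = np.eye(Dlow.shape[1]) - Dlow.T @ Dlow / L
    Z = np.zeros((Dlow.shape[1], X.shape[1]))
    for _ in range(k_iters):
        Z = soft_threshold(B + S @ Z, theta)
    return Z[:, 0] if single else Z


def lasso_objective(x: np.ndarray, Dlow: np.ndarray, z: np.ndarray, alpha: float) -> float:
    """The sparse-coding energy ``0.5 ||x - D z||^2 + alpha ||z||_1``."""
    return float(0.5 * np.sum((x - Dlow @ z) ** 2) + alpha * np.sum(np.abs(z)))


def mse_loss(pred: np.ndarray | GrayImage, target: np.ndarray | GrayImage) -> float:
    """Mean squared error over pixels (and samples, when given stacks)."""
    p = pred.pixels if isinstance(pred, GrayImage) else np.asarray(pred, float)
    t = target.pixels if isinstance(target, GrayImage) else np.asarray(target, float)
    if p.shape != t.shape:
        raise ValueError("prediction/target shape mismatch")
    return float(np.mean((p - t) ** 2))


@dataclass
class SCNNConfig:
    """Architecture and training hyper-parameters.

    Sizes follow common super-resolution practice: 9x9 first-layer
    filters, 5x5 output filters, 16-pixel patches with stride 8. ``m_atoms``
    is the dictionary width; ``alpha0`` the initial sparsity weight;
    ``k_iters`` the number of unrolled ISTA steps.
    """

    factor: int = 2
    f1: int = 9
    n1: int = 64
    m_atoms: int = 64
    n2: int = 32
    f4: int = 5
    patch: int = 16
    stride: int = 8
    k_iters: int = 3
    alpha0: float = 1e-4
    init_sd: float = 0.001
    learning_rate: float = 1e-4
    epochs: int = 100


@dataclass
class SCNNParams:
    """The trainable parameter set W plus the stored Lipschitz bound."""

    F1: np.ndarray
    b1: np.ndarray
    Dlow: np.ndarray
    alpha: float
    F3: np.ndarray
    b3: np.ndarray
    DHigh: np.ndarray
    F4: np.ndarray
    b4: float
    L: float
    config: SCNNConfig = field(default_factory=SCNNConfig)

    def refresh_lipschitz(self) -> None:
        self.L = lipschitz_bound(self.Dlow)

    _BLOCKS = ("F1", "b1", "Dlow", "alpha", "F3", "b3", "DHigh", "F4", "b4")

    def blocks(self) -> dict[str, np.ndarray | float]:
        return {name: getattr(self, name) for name in self._BLOCKS}


def init_params(config: SCNNConfig | None = None, seed: int = 0) -> SCNNParams:
    """Gaussian(0, init_sd) filters, zero biases, unit-column dictionaries."""
    config = config or SCNNConfig()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5C44]))
    F1 = rng.normal(0.0, config.init_sd, (config.n1, config.f1, config.f1))
    b1 = np.zeros(config.n1)
    Dlow = rng.normal(size=(config.n1, config.m_atoms))
    Dlow /= np.linalg.norm(Dlow, axis=0, keepdims=True)
    F3 = rng.normal(0.0, config.init_sd, (config.n2, config.m_atoms))
    b3 = np.zeros(config.n2)
    DHigh = rng.normal(size=(config.patch**2, config.n2))
    DHigh /= np.linalg.norm(DHigh, axis=0, keepdims=True)
    F4 = rng.normal(0.0, config.init_sd, (config.f4, config.f4))
    b4 = 0.0
    params = SCNNParams(F1, b1, Dlow, config.alpha0, F3, b3, DHigh, F4, b4, 0.0, config)
    params.refresh_lipschitz()
    return params


def _patch_grid(H: int, W: int, p: int, s: int) -> tuple[np.ndarray, np.ndarray]:
    rows = list(range(0, H - p + 1, s))
    if rows[-1] != H - p:
        rows.append(H - p)
    cols = list(range(0, W - p + 1, s))
    if cols[-1] != W - p:
        cols.append(W - p)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    return rr.ravel(), cc.ravel()


def _forward(low: np.ndarray, params: SCNNParams, keep: bool = False):
    """Forward pass on a [0,1]-scale low-res array; returns (output, tape)."""
    cfg = params.config
    U = _upscale_array(low, cfg.factor)
    H, W = U.shape
    p, s = cfg.patch, cfg.stride
    if H < p or W < p:
        raise ValueError("upscaled image smaller than one patch")
    q1 = cfg.f1 // 2
    Upad = np.pad(U, q1)
    win1 = sliding_window_view(Upad, (cfg.f1, cfg.f1))  # (H, W, f1, f1)
    H1pre = np.tensordot(params.F1, win1, axes=([1, 2], [2, 3])) + params.b1[:, None, None]
    H1 = np.maximum(H1pre, 0.0)

    rows, cols = _patch_grid(H, W, p, s)
    ctr_r, ctr_c = rows + p // 2, cols + p // 2
    X = H1[:, ctr_r, ctr_c]  # (n1, Np)

    L = params.L
    theta = params.alpha / L
    We = params.Dlow.T / L
    S = np.eye(cfg.m_atoms) - params.Dlow.T @ params.Dlow / L
    B = We @ X
    Z = np.zeros((cfg.m_atoms, X.shape[1]))
    pres = []
    zs = [Z]
    for _ in range(cfg.k_iters):
        pre = B + S @ Z
        Z = soft_threshold(pre, theta)
        if keep:
            pres.append(pre)
            zs.append(Z)

    H3pre = params.F3 @ Z + params.b3[:, None]
    H3 = np.maximum(H3pre, 0.0)
    P = (params.DHigh @ H3).T.reshape(-1, p, p)  # (Np, p, p)

    # overlapping patches averaged into the high-resolution canvas; each
    # patch carries its detail prediction on top of the input patch mean
    # (standard sparse-coding SR patch normalization: the dictionary pair
    # codes the mean-free structure, the DC level comes from the input)
    canvas = np.zeros((H, W))
    counts = np.zeros((H, W))
    for i, (r, c) in enumerate(zip(rows, cols)):
        canvas[r : r + p, c : c + p] += P[i] + U[r : r + p, c : c + p].mean()
        counts[r : r + p, c : c + p] += 1.0
    canvas /= counts

    # final reconstruction convolution over the assembled image; the
    # upscaled input joins the pre-activation so the network learns the
    # refinement on top of bicubic rather than re-synthesizing the image
    q4 = cfg.f4 // 2
    Cpad = np.pad(canvas, q4)
    win4 = sliding_window_view(Cpad, (cfg.f4, cfg.f4))
    Rpre = np.tensordot(win4, params.F4, axes=([2, 3], [0, 1])) + params.b4 + U
    out = np.maximum(Rpre, 0.0)

    tape = None
    if keep:
        tape = dict(
            U=U, Upad=Upad, H1pre=H1pre, H1=H1, X=X, B=B, We=We, S=S,
            pres=pres, zs=zs, theta=theta, Z=Z, H3pre=H3pre, H3=H3, P=P,
            Cpad=Cpad, Rpre=Rpre, counts=counts,
            rows=rows, cols=cols, ctr_r=ctr_r, ctr_c=ctr_c,
        )
    return out, tape


def scnn_forward(low_image: GrayImage, params: SCNNParams) -> GrayImage:
    """Run the network on a low-resolution image ([0,1] scale pixels)."""
    out, _ = _forward(low_image.pixels, params)
    return GrayImage(out, low_image.bit_depth)


def _zero_grads(params: SCNNParams) -> dict:
    g = {}
    for name, val in params.blocks().items():
        g[name] = 0.0 if np.isscalar(val) else np.zeros_like(val)
    return g


def _backward(dout: np.ndarray, params: SCNNParams, tape: dict, grads: dict) -> None:
    """Accumulate dLoss/dW into ``grads`` given dLoss/dOutput."""
    cfg = params.config
    p = cfg.patch
    rows, cols = tape["rows"], tape["cols"]

    dRpre = dout * (tape["Rpre"] >= 0)
    grads["b4"] += float(dRpre.sum())
    q4 = cfg.f4 // 2
    win4 = sliding_window_view(tape["Cpad"], (cfg.f4, cfg.f4))
    grads["F4"] += np.tensordot(dRpre, win4, axes=([0, 1], [0, 1]))
    # full correlation of dRpre with the flipped kernel -> canvas gradient
    dRpre_pad = np.pad(dRpre, q4)
    winb = sliding_window_view(dRpre_pad, (cfg.f4, cfg.f4))
    dcanvas = np.tensordot(winb, params.F4[::-1, ::-1], axes=([2, 3], [0, 1]))
    dcanvas = dcanvas / tape["counts"]

    dP = np.empty_like(tape["P"])
    for i, (r, c) in enumerate(zip(rows, cols)):
        dP[i] = dcanvas[r : r + p, c : c + p]

    dH3 = params.DHigh.T @ dP.reshape(dP.shape[0], -1).T
    grads["DHigh"] += dP.reshape(dP.shape[0], -1).T @ tape["H3"].T

    dH3pre = dH3 * (tape["H3pre"] >= 0)
    grads["F3"] += dH3pre @ tape["Z"].T
    grads["b3"] += dH3pre.sum(axis=1)
    G = params.F3.T @ dH3pre

    S, theta = tape["S"], tape["theta"]
    dB = np.zeros_like(tape["B"])
    dS = np.zeros_like(S)
    dtheta = 0.0
    for k in range(cfg.k_iters - 1, -1, -1):
        pre = tape["pres"][k]
        active = np.abs(pre) >= theta
        dpre = G * active
        dtheta += float(np.sum(-np.sign(pre) * dpre))
        dB += dpre
        dS += dpre @ tape["zs"][k].T
        G = S.T @ dpre

    L = params.L
    dX = tape["We"].T @ dB
    dWe = dB @ tape["X"].T
    dDlow = dWe.T / L
    dDlow += -(params.Dlow @ (dS + dS.T)) / L
    grads["Dlow"] += dDlow
    grads["alpha"] += dtheta / L

    dH1 = np.zeros_like(tape["H1"])
    np.add.at(dH1, (slice(None), tape["ctr_r"], tape["ctr_c"]), dX)
    dH1pre = dH1 * (tape["H1pre"] >= 0)
    win1 = sliding_window_view(tape["Upad"], (cfg.f1, cfg.f1))
    grads["F1"] += np.tensordot(dH1pre, win1, axes=([1, 2], [0, 1]))
    grads["b1"] += dH1pre.sum(axis=(1, 2))


def loss_and_gradients(
    params: SCNNParams,
    lows: list[np.ndarray],
    highs: list[np.ndarray],
) -> tuple[float, dict]:
    """Mean-squared reconstruction loss over the pairs and its analytic
    gradient for every trainable block (``L`` held constant)."""
    grads = _zero_grads(params)
    total = 0.0
    n = len(lows)
    for low, high in zip(lows, highs):
        out, tape = _forward(np.asarray(low, float), params, keep=True)
        diff = out - np.asarray(high, float)
        total += float(np.mean(diff**2))
        dout = (2.0 / (diff.size * n)) * diff
        _backward(dout, params, tape, grads)
    return total / n, grads


class _Adam:
    def __init__(self, blocks: dict, lr: float):
        self.lr = lr
        self.t = 0
        self.m = {k: np.zeros_like(v) if not np.isscalar(v) else 0.0 for k, v in blocks.items()}
        self.v = {k: np.zeros_like(v) if not np.isscalar(v) else 0.0 for k, v in blocks.items()}

    def step(self, params: SCNNParams, grads: dict) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for name in params._BLOCKS:
            g = grads[name]
            self.m[name] = b1 * self.m[name] + (1 - b1) * g
            self.v[name] = b2 * self.v[name] + (1 - b2) * (
                g**2 if not np.isscalar(g) else g * g
            )
            mhat = self.m[name] / (1 - b1**self.t)
            vhat = self.v[name] / (1 - b2**self.t)
            update = self.lr * mhat / (np.sqrt(vhat) + eps)
            if np.isscalar(getattr(params, name)):
                setattr(params, name, float(getattr(params, name) - update))
            else:
                getattr(params, name)[...] -= update
        # the sparsity weight must stay positive
        params.alpha = max(params.alpha, 1e-6)


def train_scnn(
    pairs: list[tuple[GrayImage, GrayImage]],
    config: SCNNConfig | None = None,
    seed: int = 0,
) -> tuple[SCNNParams, np.ndarray]:
    """Full-batch Adam minimisation of the reconstruction MSE.

    ``pairs`` holds (low, high) images; pixels are normalized to [0, 1]
    internally. Returns the trained parameters and the per-epoch loss
    trace. Aborts with a diagnostic if the loss exceeds 10x its initial
    value for 3 consecutive epochs.
    """
    config = config or SCNNConfig()
    if len(pairs) < 16:
        raise ValueError("need at least 16 training pairs")
    params = init_params(config, seed)
    lows = [im.pixels / im.peak for im, _ in pairs]
    highs = [im.pixels / im.peak for _, im in pairs]

    optimizer = _Adam(params.blocks(), config.learning_rate)
    trace = np.empty(config.epochs)
    initial = None
    bad_epochs = 0
    for epoch in range(config.epochs):
        loss, grads = loss_and_gradients(params, lows, highs)
        trace[epoch] = loss
        if initial is None:
            initial = loss
        if loss > 10.0 * initial:
            bad_epochs += 1
            if bad_epochs >= 3:
                raise RuntimeError(
                    f"training diverged: loss {loss:.3g} > 10x initial {initial:.3g} "
                    f"for 3 epochs (epoch {epoch})"
                )
        else:
            bad_epochs = 0
        if config.learning_rate > 0:
            optimizer.step(params, grads)
            params.refresh_lipschitz()
    return params, trace


def enhance_image(image: GrayImage, params: SCNNParams) -> GrayImage:
    """Upscale + reconstruct a raw-scale image, clamping to valid range."""
    low = image.pixels / image.peak
    out, _ = _forward(low, params)
    return GrayImage(np.clip(out * image.peak, 0.0, image.peak), image.bit_depth)
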