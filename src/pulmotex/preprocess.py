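"""Frequency-domain Butterworth smoothing and PSNR reporting.

The Butterworth transfer function is maximally flat in the pass-band and
rolls off monotonically; its value at the cut-off distance ``di`` is
exactly 0.5 in both modes:

* low-pass:  ``M(u,v) = 1 / (1 + (d/di)**(2n))``
* high-pass: ``M(u,v) = 1 / (1 + (di/d)**(2n))`` with ``M = 0`` at the
  zero-frequency bin (the continuous limit).

``d`` is the Euclidean distance from the centered zero-frequency bin.
Filtering runs in the frequency domain: centered FFT, point-wise kernel
multiplication, inverse FFT, and the modulus of the result (which
rectifies any negative ringing).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from pulmotex.types import GrayImage

__all__ = [
    "FilterConfig",
    "butterworth_kernel",
    "apply_frequency_filter",
    "smooth_image",
    "psnr",
]


@dataclass
class FilterConfig:
    """Butterworth filter parameters.

    order_n : filter order (>= 1); higher orders sharpen the pass/stop
        transition at the cost of ringing.
    cutoff_di : half-power distance from the spectrum center, in pixels.
    mode : "lowpass" (denoising default) or "highpass".
    """

    order_n: int = 2
    cutoff_di: float | None = None
    mode: str = "lowpass"

    def __post_init__(self) -> None:
        if self.order_n < 1:
            raise ValueError("order_n must be >= 1")
        if self.cutoff_di is not None and self.cutoff_di <= 0:
            raise ValueError("cutoff_di must be positive")
        if self.mode not in ("lowpass", "highpass"):
            raise ValueError("mode must be 'lowpass' or 'highpass'")

    def resolved_cutoff(self, shape: tuple[int, int]) -> float:
        """Default cut-off: 0.35 of the smaller half-dimension."""
        if self.cutoff_di is not None:
            return self.cutoff_di
        return 0.35 * min(shape) / 2.0


def _distance_grid(shape: tuple[int, int]) -> np.ndarray:
    H, W = shape
    r = np.arange(H) - H // 2
    c = np.arange(W) - W // 2
    return np.hypot(r[:, None], c[None, :])


def butterworth_kernel(shape: tuple[int, int], config: FilterConfig) -> np.ndarray:
    """Frequency-domain Butterworth kernel for a centered spectrum."""
    H, W = shape
    if H < 2 or W < 2:
        raise ValueError("shape must be at least 2x2")
    di = config.resolved_cutoff(shape)
    if di <= 0:
        raise ValueError("cutoff must be positive")
    d = _distance_grid(shape)
    n2 = 2 * config.order_n
    if config.mode == "lowpass":
        return 1.0 / (1.0 + (d / di) ** n2)
    with np.errstate(divide="ignore"):
        kernel = 1.0 / (1.0 + (di / np.where(d == 0, np.inf, d)) ** n2)
    kernel[d == 0] = 0.0  # zero-frequency bin: continuous limit of the HP form
    return kernel


def apply_frequency_filter(image: GrayImage, kernel: np.ndarray) -> GrayImage:
    """Multiply the centered spectrum by ``kernel`` and return the modulus
    of the inverse transform."""
    if kernel.shape != image.pixels.shape:
        raise ValueError("kernel shape must match image shape")
    spectrum = np.fft.fftshift(np.fft.fft2(image.pixels))
    filtered = np.fft.ifft2(np.fft.ifftshift(spectrum * kernel))
    return GrayImage(np.abs(filtered), image.bit_depth)


def filtered_complex(image: GrayImage, kernel: np.ndarray) -> np.ndarray:
    """Pre-modulus complex result of the frequency filter (the linear part;
    useful for linearity checks and diagnostics)."""
    if kernel.shape != image.pixels.shape:
        raise ValueError("kernel shape must match image shape")
    spectrum = np.fft.fftshift(np.fft.fft2(image.pixels))
    return np.fft.ifft2(np.fft.ifftshift(spectrum * kernel))


def smooth_image(image: GrayImage, config: FilterConfig | None = None) -> GrayImage:
    """One-call Butterworth smoothing with default low-pass settings."""
    config = config or FilterConfig()
    kernel = butterworth_kernel(image.pixels.shape, config)
    return apply_frequency_filter(image, kernel)


def psnr(reference: GrayImage, processed: GrayImage, peak: float | None = None) -> float:
    """Peak signal-to-noise ratio, ``10 log10(peak^2 / MSE)`` in dB.

    Returns ``inf`` when the images are identical. ``peak`` defaults to the
    reference image's representable maximum.
    """
    if reference.pixels.shape != processed.pixels.shape:
        raise ValueError("images must share a shape")
    peak = reference.peak if peak is None else peak
    if peak <= 0:
        raise ValueError("peak must be positive")
    mse = float(np.mean((reference.pixels - processed.pixels) ** 2))
    if mse == 0.0:
        return float("inf")
    return 10.0 * np.log10(peak**2 / mse)
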