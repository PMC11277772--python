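"""Grey-level co-occurrence (GLCM) texture features and the sparsity-
regularised multi-space reconstruction (MIR) diagnostic.

Four Haralick-style statistics are computed from normalized co-occurrence
probabilities ``p(j, i)`` at the four standard offsets (0deg, 45deg, 90deg,
135deg):

* contrast      ``sum (j - i)^2 p(j, i)``
* correlation   ``(sum j i p(j, i) - mu_a mu_b) / (sigma_a sigma_b)``
* energy        ``sum p(j, i)^2``
* homogeneity   ``sum p(j, i) / (1 + |j - i|)``

The MIR objective scores a reconstruction: a squared-residual fit term
plus an entropy-like sparsity penalty on normalized activation magnitudes,
weighted by ``tau_s``. It is exposed as a diagnostic (there is no update
rule attached to it).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from pulmotex.types import GrayImage

__all__ = [
    "GLCM",
    "MIRConfig",
    "quantize_gray",
    "compute_glcm",
    "glcm_features",
    "extract_texture_vector",
    "texture_feature_names",
    "mir_objective",
]

ANGLES = (0, 45, 90, 135)
#: co-occurrence offsets in (row, col) with rows increasing downward
ANGLE_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


@dataclass
class GLCM:
    """A co-occurrence matrix with its construction metadata."""

    matrix: np.ndarray
    levels_L: int
    distance: int
    angle: int
    symmetric: bool
    normalized: bool


@dataclass
class MIRConfig:
    """Weights for the reconstruction diagnostic.

    tau_s : sparsity-penalty weight (>= 0).
    phi : constant offset subtracted from the fit term.
    eps_floor : floor inside the log, guards log(0).
    """

    tau_s: float = 1.0
    phi: float = 0.0
    eps_floor: float = 1e-12

    def __post_init__(self) -> None:
        if self.tau_s < 0:
            raise ValueError("tau_s must be >= 0")
        if not 0 < self.eps_floor <= 1e-3:
            raise ValueError("eps_floor must be in (0, 1e-3]")


def quantize_gray(image: GrayImage | np.ndarray, levels_L: int) -> np.ndarray:
    """Uniform min-max binning to integer levels ``{0..L-1}``.

    A constant image maps to all-zero levels.
    """
    if levels_L < 2:
        raise ValueError("levels_L must be >= 2")
    pixels = image.pixels if isinstance(image, GrayImage) else np.asarray(image, float)
    lo, hi = pixels.min(), pixels.max()
    if hi == lo:
        return np.zeros(pixels.shape, dtype=np.uint8)
    levels = np.floor((pixels - lo) / (hi - lo) * levels_L).astype(int)
    return np.clip(levels, 0, levels_L - 1).astype(np.uint8)


def compute_glcm(
    levels: np.ndarray,
    distance: int = 1,
    angle: int = 0,
    levels_L: int | None = None,
    symmetric: bool = True,
    normalize: bool = True,
) -> GLCM:
    """Co-occurrence counts at one (distance, angle) offset.

    The reference pixel's level indexes the row, the neighbour's level the
    column, at the (row, col) displacement in :data:`ANGLE_OFFSETS` (rows
    increase downward). Out-of-bounds pairs are dropped; the symmetric
    variant adds the transposed counts; normalization divides by the total
    count.
    """
    if angle not in ANGLE_OFFSETS:
        raise ValueError(f"angle must be one of {ANGLES}")
    levels = np.asarray(levels)
    if levels_L is None:
        levels_L = int(levels.max()) + 1
    if levels.max() >= levels_L:
        raise ValueError("grid values must be < levels_L")
    dr, dc = (distance * o for o in ANGLE_OFFSETS[angle])
    H, W = levels.shape
    if abs(dr) >= H or abs(dc) >= W:
        raise ValueError("image smaller than the co-occurrence offset")
    # slice out the aligned reference/neighbour views
    r0, r1 = max(0, -dr), min(H, H - dr)
    c0, c1 = max(0, -dc), min(W, W - dc)
    ref = levels[r0:r1, c0:c1].ravel()
    nbr = levels[r0 + dr : r1 + dr, c0 + dc : c1 + dc].ravel()
    mat = np.zeros((levels_L, levels_L))
    np.add.at(mat, (ref, nbr), 1.0)
    if symmetric:
        mat = mat + mat.T
    if normalize:
        total = mat.sum()
        if total == 0:
            raise ValueError("no valid co-occurrence pairs")
        mat = mat / total
    return GLCM(mat, levels_L, distance, angle, symmetric, normalize)


def glcm_features(glcm: GLCM) -> dict[str, float]:
    """Contrast, correlation, energy and homogeneity of one normalized GLCM.

    For a constant region both marginal standard deviations vanish;
    correlation is then defined as 1 (constant texture is perfectly
    self-correlated) and flagged via the ``degenerate`` key.
    """
    if not glcm.normalized:
        raise ValueError("glcm_features requires a normalized GLCM")
    p = glcm.matrix
    L = glcm.levels_L
    j = np.arange(L)[:, None]
    i = np.arange(L)[None, :]

    contrast = float(np.sum((j - i) ** 2 * p))
    energy = float(np.sum(p**2))
    homogeneity = float(np.sum(p / (1.0 + np.abs(j - i))))

    p_row = p.sum(axis=1)  # marginal over j (rows)
    p_col = p.sum(axis=0)
    mu_a = float(np.sum(np.arange(L) * p_row))
    mu_b = float(np.sum(np.arange(L) * p_col))
    var_a = float(np.sum((np.arange(L) - mu_a) ** 2 * p_row))
    var_b = float(np.sum((np.arange(L) - mu_b) ** 2 * p_col))
    sd = np.sqrt(var_a * var_b)
    degenerate = sd == 0.0
    if degenerate:
        correlation = 1.0
    else:
        correlation = float((np.sum(j * i * p) - mu_a * mu_b) / sd)

    return {
        "contrast": contrast,
        "correlation": correlation,
        "energy": energy,
        "homogeneity": homogeneity,
        "degenerate": degenerate,
    }


def texture_feature_names() -> list[str]:
    """Names of the 16 texture features in extraction order (angle-major)."""
    return [
        f"glcm_{angle}deg_{feat}"
        for angle in ANGLES
        for feat in ("contrast", "correlation", "energy", "homogeneity")
    ]


def extract_texture_vector(
    image: GrayImage | np.ndarray, distance: int = 1, levels_L: int = 8
) -> np.ndarray:
    """16-element texture vector: four features x four angles, angle-major
    order 0deg, 45deg, 90deg, 135deg x (contrast, correlation, energy,
    homogeneity)."""
    levels = quantize_gray(image, levels_L)
    out = []
    for angle in ANGLES:
        feats = glcm_features(
            compute_glcm(levels, distance=distance, angle=angle, levels_L=levels_L)
        )
        out.extend(
            [feats["contrast"], feats["correlation"], feats["energy"], feats["homogeneity"]]
        )
    return np.array(out)


def mir_objective(
    alpha_in: np.ndarray,
    alpha_out: np.ndarray,
    r: np.ndarray,
    config: MIRConfig | None = None,
) -> tuple[float, float, float]:
    """Reconstruction diagnostic: ``objective = fit + tau_s * sparsity``.

    fit = sum_j (alpha_out_j - alpha_in_j)^2 - phi
    sparsity = (1/n) sum_i of -r_i log(max(r_i, eps_floor))  (natural log,
    with n the activation-vector length)

    ``r`` holds normalized per-element activation magnitudes in [0, 1]
    (e.g. of a sparse code); negative entries are rejected.
    """
    config = config or MIRConfig()
    alpha_in = np.asarray(alpha_in, float)
    alpha_out = np.asarray(alpha_out, float)
    r = np.asarray(r, float)
    if alpha_in.shape != alpha_out.shape:
        raise ValueError("alpha_in and alpha_out must share a shape")
    if np.any(r < 0):
        raise ValueError("r entries must be nonnegative")
    fit = float(np.sum((alpha_out - alpha_in) ** 2) - config.phi)
    r_safe = np.maximum(r, config.eps_floor)
    sparsity = float(np.sum(-r * np.log(r_safe)) / alpha_in.size)
    objective = fit + config.tau_s * sparsity
    return objective, fit, sparsity
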