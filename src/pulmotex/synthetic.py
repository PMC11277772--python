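"""Seeded synthetic phantoms and planted feature tables.

Real CT archives (LUNA16 and kin) are out of scope; every stage of the
pipeline is instead exercised on phantoms with known ground truth:

* :func:`generate_phantom` draws a 2-D chest-slice phantom — two dark
  elliptical lung fields on brighter mediastinum/body tissue, additive
  Gaussian acquisition noise — and, for nodule classes, a bright blob whose
  geometry encodes the class: benign nodules are small and smooth-edged,
  malignant nodules are larger with a radially perturbed (spiculated,
  lobulated) boundary.
* :func:`generate_feature_table` plants class-shifted Gaussian features
  among pure-noise columns, the substrate for the selection algorithms.
* :func:`degrade_pair` produces low/high-resolution training pairs for the
  super-resolution network.

All generators are pure functions of their arguments including the seed:
two calls with identical arguments produce bitwise-identical output.
Master seeds are split into per-item seeds with a counter-based
``SeedSequence`` spawn so a dataset can be extended without reshuffling
existing items.
"""

from __future__ import annotations

import numpy as np

from pulmotex.types import (
    FeatureTable,
    GrayImage,
    LABELS,
    PhantomAnnotation,
    PlantedTable,
)

__all__ = [
    "generate_phantom",
    "generate_phantom_dataset",
    "generate_feature_table",
    "degrade_pair",
]

# intensity layout of the phantom on the 8-bit scale
_BODY = 170.0
_LUNG = 60.0
_NODULE = 225.0
_NOISE_SD = 5.0

# nodule diameters in mm-equivalent pixels
_BENIGN_DIAM = (4.0, 10.0)
_MALIGNANT_DIAM = (12.0, 25.0)


def _ordinal_score(value: float, lo: float, hi: float) -> int:
    """Map a geometry parameter monotonically onto the LIDC 1-5 scale."""
    t = np.clip((value - lo) / (hi - lo), 0.0, 1.0)
    return int(np.clip(1 + np.floor(t * 5), 1, 5))


def generate_phantom(
    label: str, size: int = 128, seed: int = 0
) -> tuple[GrayImage, PhantomAnnotation]:
    """Generate one chest-slice phantom and its ground-truth annotation.

    Parameters
    ----------
    label : {"normal", "benign", "malignant"}
    size : int
        Side length in pixels, at least 64.
    seed : int
        Drives every random draw; identical arguments reproduce the image
        bitwise.
    """
    if label not in LABELS:
        raise ValueError(f"unknown label {label!r}")
    if size < 64:
        raise ValueError("size must be >= 64")

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x9E3779B9]))
    rows, cols = np.mgrid[0:size, 0:size].astype(float)

    img = np.full((size, size), _BODY)

    # two dark elliptical lung fields, slightly jittered
    for cx_frac in (0.30, 0.70):
        cy = size * (0.5 + rng.uniform(-0.02, 0.02))
        cx = size * (cx_frac + rng.uniform(-0.02, 0.02))
        a = size * rng.uniform(0.17, 0.20)   # semi-axis across
        b = size * rng.uniform(0.30, 0.34)   # semi-axis down
        inside = ((cols - cx) / a) ** 2 + ((rows - cy) / b) ** 2 <= 1.0
        img[inside] = _LUNG

    annotation_kwargs: dict = {}
    if label != "normal":
        lo, hi = _BENIGN_DIAM if label == "benign" else _MALIGNANT_DIAM
        diameter = rng.uniform(lo, hi)
        radius = diameter / 2.0

        # nodule center well inside a lung field
        side = rng.choice([0.30, 0.70])
        c_row = size * 0.5 + rng.uniform(-0.12, 0.12) * size
        c_col = size * side + rng.uniform(-0.05, 0.05) * size

        theta = np.arctan2(rows - c_row, cols - c_col)
        dist = np.hypot(rows - c_row, cols - c_col)

        if label == "benign":
            spic_amp = rng.uniform(0.0, 0.04)
            n_lobes = int(rng.integers(0, 2))      # 0 or 1: smooth outline
            margin_sharp = rng.uniform(0.7, 1.0)   # crisp margin
        else:
            spic_amp = rng.uniform(0.25, 0.45)     # strong boundary spikes
            n_lobes = int(rng.integers(2, 5))      # >= 2 lobes
            margin_sharp = rng.uniform(0.35, 0.65)  # less defined margin

        phase = rng.uniform(0, 2 * np.pi)
        n_spikes = int(rng.integers(8, 14))
        boundary = radius * (
            1.0
            + spic_amp * np.sin(n_spikes * theta + phase)
            + (0.15 if n_lobes else 0.0) * np.sin(n_lobes * theta + phase / 2)
        )
        # soft edge: width controlled by margin sharpness
        edge_w = 0.6 + 1.2 * (1.0 - margin_sharp)
        blob = 1.0 / (1.0 + np.exp((dist - boundary) / edge_w))
        img = img + (_NODULE - img) * blob

        annotation_kwargs = dict(
            diameter_mm=float(diameter),
            margin=_ordinal_score(margin_sharp, 0.0, 1.0),
            spiculation=(
                _ordinal_score(spic_amp, 0.20, 0.45)
                if label == "malignant"
                else _ordinal_score(spic_amp, 0.0, 0.12)
            ),
            lobulation=_ordinal_score(n_lobes, 0, 5),
            subtlety=_ordinal_score(diameter, 3.0, 26.0),
            malignancy=(5 if label == "malignant" else rng.integers(1, 3)),
            center_row=float(c_row),
            center_col=float(c_col),
        )
        # generator guarantees: benign spiculation <= 2, malignant >= 4
        if label == "benign":
            annotation_kwargs["spiculation"] = min(annotation_kwargs["spiculation"], 2)
        else:
            annotation_kwargs["spiculation"] = max(annotation_kwargs["spiculation"], 4)
        annotation_kwargs["malignancy"] = int(annotation_kwargs["malignancy"])

    img += rng.normal(0.0, _NOISE_SD, img.shape)
    img = np.clip(img, 0.0, 255.0)

    annotation = PhantomAnnotation(label=label, seed=seed, **annotation_kwargs)
    return GrayImage(img, bit_depth=8), annotation


def generate_phantom_dataset(
    n_per_class: int, size: int = 128, seed: int = 0
) -> tuple[list[GrayImage], list[PhantomAnnotation]]:
    """Balanced phantom dataset: ``3 * n_per_class`` items.

    Per-item seeds derive deterministically from the master seed via a
    counter so item i is stable regardless of how many items follow it.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    images: list[GrayImage] = []
    annotations: list[PhantomAnnotation] = []
    counter = 0
    for label in LABELS:
        for _ in range(n_per_class):
            item_seed = int(
                np.random.SeedSequence([seed, counter]).generate_state(1)[0] % (2**31)
            )
            img, ann = generate_phantom(label, size=size, seed=item_seed)
            images.append(img)
            annotations.append(ann)
            counter += 1
    return images, annotations


def generate_feature_table(
    N: int,
    M: int,
    n_informative: int,
    effect: float,
    seed: int = 0,
) -> PlantedTable:
    """Three-class table with ``n_informative`` class-shifted Gaussian
    features planted among ``M - n_informative`` pure-noise columns.

    Informative column means are ``(class - 2) * effect`` for classes
    {1,2,3} (unit variance), so adjacent classes are separated by
    ``effect`` standard deviations. Noise columns are standard Gaussians
    independent of the label.
    """
    if N < 20:
        raise ValueError("N must be >= 20")
    if not 1 <= n_informative <= M:
        raise ValueError("need 1 <= n_informative <= M")

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5F3759DF]))
    labels = np.tile([1, 2, 3], N // 3 + 1)[:N]
    rng.shuffle(labels)

    informative = rng.choice(M, size=n_informative, replace=False)
    informative_set = frozenset(int(i) for i in informative)

    X = rng.normal(size=(N, M))
    shift = (labels - 2).astype(float) * effect
    for j in informative_set:
        X[:, j] += shift

    names = [
        f"inf{j}" if j in informative_set else f"noise{j}" for j in range(M)
    ]
    table = FeatureTable(X, labels, names)
    noise_set = frozenset(range(M)) - informative_set
    return PlantedTable(table, informative_set, noise_set)


def degrade_pair(
    image: GrayImage, factor: int, noise_sd: float = 5.0, seed: int = 0
) -> tuple[GrayImage, GrayImage]:
    """Produce a (low, high) resolution training pair.

    ``high`` is the input; ``low`` is the block-mean downsample by
    ``factor`` with additive Gaussian acquisition noise. Upscaling back is
    the super-resolution network's job, so ``low`` stays at the reduced
    ``(H/factor, W/factor)`` size.
    """
    if factor not in (2, 3, 4):
        raise ValueError("factor must be 2, 3 or 4")
    H, W = image.pixels.shape
    if H % factor or W % factor:
        raise ValueError("image dimensions must be divisible by factor")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x1B873593]))
    blocks = image.pixels.reshape(H // factor, factor, W // factor, factor)
    low = blocks.mean(axis=(1, 3))
    if noise_sd > 0:
        low = low + rng.normal(0.0, noise_sd, low.shape)
    low = np.clip(low, 0.0, image.peak)
    return GrayImage(low, image.bit_depth), GrayImage(image.pixels.copy(), image.bit_depth)
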