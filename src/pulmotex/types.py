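"""Shared domain containers used across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class GrayImage:
    """A 2-D grayscale image with intensity-range metadata.

    ``pixels`` is a float array; values are expected to lie inside
    ``[0, 2**bit_depth - 1]`` once written out (quantization happens at
    write time, not here).
    """

    pixels: np.ndarray
    bit_depth: int = 8

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("GrayImage requires a 2-D pixel grid")
        if self.pixels.shape[0] < 8 or self.pixels.shape[1] < 8:
            raise ValueError("GrayImage must be at least 8x8")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("GrayImage pixels must be finite")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def peak(self) -> float:
        """Maximum representable intensity, ``2**bit_depth - 1``."""
        return float(2 ** self.bit_depth - 1)


#: severity labels in canonical order; integer class codes are 1-based
LABELS = ("normal", "benign", "malignant")
LABEL_CODES = {"normal": 1, "benign": 2, "malignant": 3}


@dataclass
class PhantomAnnotation:
    """Ground-truth record for one synthetic nodule phantom.

    ``margin``, ``spiculation``, ``lobulation``, ``subtlety`` and
    ``malignancy`` follow the LIDC 1-5 ordinal convention; they are ``None``
    (together with ``diameter_mm``) for nodule-free *normal* slices.
    """

    label: str
    seed: int
    diameter_mm: float | None = None
    margin: int | None = None
    spiculation: int | None = None
    lobulation: int | None = None
    subtlety: int | None = None
    malignancy: int | None = None
    center_row: float | None = None
    center_col: float | None = None

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        nodule_fields = (
            self.diameter_mm,
            self.margin,
            self.spiculation,
            self.lobulation,
            self.subtlety,
            self.malignancy,
        )
        if self.label == "normal":
            if any(v is not None for v in nodule_fields):
                raise ValueError("normal phantoms carry no nodule attributes")
        else:
            if any(v is None for v in nodule_fields):
                raise ValueError("nodule phantoms require all six attributes")

    @property
    def class_code(self) -> int:
        return LABEL_CODES[self.label]

    def semantic_features(self) -> np.ndarray:
        """Six-element vector (diameter, margin, spiculation, lobulation,
        subtlety, malignancy); zeros for normal slices (no nodule)."""
        if self.label == "normal":
            return np.zeros(6)
        return np.array(
            [
                self.diameter_mm,
                self.margin,
                self.spiculation,
                self.lobulation,
                self.subtlety,
                self.malignancy,
            ],
            dtype=float,
        )


@dataclass
class AnnotationRecord:
    """One row of the LUNA16-style candidate CSV."""

    seriesuid: str
    coordX: float
    coordY: float
    coordZ: float
    diameter_mm: float

    def __post_init__(self) -> None:
        if not self.seriesuid:
            raise ValueError("seriesuid must be non-empty")
        if not self.diameter_mm > 0:
            raise ValueError("diameter_mm must be positive")


@dataclass
class FeatureTable:
    """N samples x M features with 1-based integer class labels."""

    features: np.ndarray
    labels: np.ndarray
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.features.ndim != 2:
            raise ValueError("features must be 2-D")
        if self.labels.shape[0] != self.features.shape[0]:
            raise ValueError("labels/features row mismatch")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("features must be finite")
        if not self.feature_names:
            self.feature_names = [f"f{i}" for i in range(self.features.shape[1])]
        if len(self.feature_names) != self.features.shape[1]:
            raise ValueError("feature_names length mismatch")

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    def restrict(self, mask: np.ndarray) -> "FeatureTable":
        """Sub-table keeping only the features where ``mask`` is set."""
        mask = np.asarray(mask, dtype=bool)
        names = [n for n, keep in zip(self.feature_names, mask) if keep]
        return FeatureTable(self.features[:, mask], self.labels.copy(), names)


@dataclass
class PlantedTable:
    """A feature table with known informative / noise feature indices."""

    table: FeatureTable
    informative_indices: frozenset[int]
    noise_indices: frozenset[int]

    def __post_init__(self) -> None:
        if self.informative_indices & self.noise_indices:
            raise ValueError("informative and noise sets overlap")
        if self.informative_indices | self.noise_indices != set(
            range(self.table.n_features)
        ):
            raise ValueError("index sets must cover all features")
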