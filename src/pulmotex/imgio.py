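"""Image and annotation I/O: 8/16-bit grayscale PNG and the LUNA16-style
candidate CSV dialect (``seriesuid,coordX,coordY,coordZ,diameter_mm``)."""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
from PIL import Image

from pulmotex.types import AnnotationRecord, GrayImage

__all__ = [
    "write_png",
    "read_png",
    "write_annotations",
    "read_annotations",
    "annotations_roundtrip",
]

CSV_HEADER = ["seriesuid", "coordX", "coordY", "coordZ", "diameter_mm"]


def write_png(image: GrayImage, path: str | Path) -> None:
    """Write as grayscale PNG, quantizing to the image's bit depth."""
    peak = image.peak
    quantized = np.clip(np.rint(image.pixels), 0, peak)
    if image.bit_depth == 8:
        Image.fromarray(quantized.astype(np.uint8), mode="L").save(path)
    else:
        Image.fromarray(quantized.astype(np.uint16)).save(path)


def read_png(path: str | Path) -> GrayImage:
    """Read an 8- or 16-bit grayscale PNG back into a :class:`GrayImage`."""
    with Image.open(path) as im:
        arr = np.asarray(im)
    if arr.ndim != 2:
        raise ValueError(f"{path}: not a single-channel grayscale image")
    bit_depth = 16 if arr.dtype.itemsize > 1 else 8
    return GrayImage(arr.astype(float), bit_depth=bit_depth)


def write_annotations(records: list[AnnotationRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_HEADER)
        for rec in records:
            writer.writerow(
                [
                    rec.seriesuid,
                    f"{rec.coordX:.6f}",
                    f"{rec.coordY:.6f}",
                    f"{rec.coordZ:.6f}",
                    f"{rec.diameter_mm:.6f}",
                ]
            )


def read_annotations(path: str | Path) -> list[AnnotationRecord]:
    """Parse the candidate CSV; malformed rows raise with their line number."""
    records: list[AnnotationRecord] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file, expected header") from None
        if header != CSV_HEADER:
            raise ValueError(
                f"{path}: bad header {header!r}, expected {','.join(CSV_HEADER)}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 5:
                raise ValueError(f"{path}: line {lineno}: expected 5 fields, got {len(row)}")
            try:
                records.append(
                    AnnotationRecord(
                        seriesuid=row[0],
                        coordX=float(row[1]),
                        coordY=float(row[2]),
                        coordZ=float(row[3]),
                        diameter_mm=float(row[4]),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
    return records


def annotations_roundtrip(
    records: list[AnnotationRecord], path: str | Path
) -> list[AnnotationRecord]:
    """Write then re-read the records (6-decimal fidelity)."""
    write_annotations(records, path)
    return read_annotations(path)
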