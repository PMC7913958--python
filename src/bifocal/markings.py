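"""Expert marking dots and case-level dataset splits.

A marking dot is one expert annotation: a pixel coordinate on a named slide
plus a class label.  H&E labels are the Roman-numeral feature classes
I..VI; IHC labels are positive/negative.  Coordinates are 0-based with
x = column and y = row (raster indexing); the CSV files written here carry a
header comment stating that convention.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "MarkingDot",
    "CaseSplit",
    "CLASS_LABELS",
    "CLASS_NAMES",
    "IHC_LABELS",
    "read_markings",
    "write_markings",
    "split_by_case",
]

CLASS_LABELS: tuple[str, ...] = ("I", "II", "III", "IV", "V", "VI")
CLASS_NAMES: dict[str, str] = {
    "I": "palisading_necrosis",
    "II": "microvascular_proliferation",
    "III": "normal_vessels",
    "IV": "geographic_necrosis",
    "V": "brain_tissue",
    "VI": "tumor_background",
}
IHC_LABELS: tuple[str, ...] = ("positive", "negative")

_HEADER = ["slide_id", "x", "y", "label", "modality"]
_COMMENT = "# 0-based pixel coordinates; x = column, y = row"


@dataclass(frozen=True)
class MarkingDot:
    slide_id: str
    x: int
    y: int
    label: str
    modality: str  # "HE" | "IHC"

    def __post_init__(self):
        if self.modality not in ("HE", "IHC"):
            raise ValueError(f"unknown modality {self.modality!r}")
        valid = CLASS_LABELS if self.modality == "HE" else IHC_LABELS
        if self.label not in valid:
            raise ValueError(
                f"label {self.label!r} is not valid for modality {self.modality}; "
                f"expected one of {valid}"
            )
        if self.x < 0 or self.y < 0:
            raise ValueError("marking coordinates must be non-negative")


@dataclass(frozen=True)
class CaseSplit:
    train_slide_ids: frozenset[str]
    test_slide_ids: frozenset[str]

    def __post_init__(self):
        if self.train_slide_ids & self.test_slide_ids:
            raise ValueError("train and test slide sets overlap")


def read_markings(path, slide_dims: dict[str, tuple[int, int]] | None = None) -> list[MarkingDot]:
    """Parse a marking CSV.  ``slide_dims`` maps slide_id -> (width, height)
    and, when given, enables coordinate bounds checking."""
    dots: list[MarkingDot] = []
    with open(path, newline="") as fh:
        lines = [(i + 1, line) for i, line in enumerate(fh) if not line.startswith("#")]
    if not lines:
        raise ValueError(f"{path}: empty marking file")
    header = next(csv.reader([lines[0][1]]))
    if header != _HEADER:
        raise ValueError(f"{path}: expected header {_HEADER}, got {header}")
    for lineno, raw in lines[1:]:
        row = next(csv.reader([raw]))
        if len(row) != 5:
            raise ValueError(f"{path}:{lineno}: expected 5 fields, got {len(row)}")
        slide_id, xs, ys, label, modality = row
        try:
            x, y = int(xs), int(ys)
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-integer coordinate: {exc}") from None
        try:
            dot = MarkingDot(slide_id, x, y, label, modality)
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from None
        if slide_dims is not None and slide_id in slide_dims:
            w, h = slide_dims[slide_id]
            if not (0 <= x < w and 0 <= y < h):
                raise ValueError(
                    f"{path}:{lineno}: coordinate ({x}, {y}) outside slide "
                    f"{slide_id} of size {w}x{h}"
                )
        dots.append(dot)
    return dots


def write_markings(dots: list[MarkingDot], path) -> None:
    """Write the marking CSV, rows sorted by (slide_id, y, x) so repeated
    writes of the same set diff clean."""
    ordered = sorted(dots, key=lambda d: (d.slide_id, d.y, d.x, d.label, d.modality))
    with open(path, "w", newline="") as fh:
        fh.write(_COMMENT + "\n")
        writer = csv.writer(fh)
        writer.writerow(_HEADER)
        for d in ordered:
            writer.writerow([d.slide_id, d.x, d.y, d.label, d.modality])


def split_by_case(slide_ids, test_fraction: float, rng_seed: int = 0) -> CaseSplit:
    """Case-level split: whole slides go to either train or test, never both.
    The test set receives ceil(test_fraction * n) slides (non-empty at any n)."""
    ids = sorted(set(slide_ids))
    if len(ids) < 2:
        raise ValueError("need at least 2 slides to split by case")
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie strictly between 0 and 1")
    n_test = math.ceil(test_fraction * len(ids))
    if n_test >= len(ids):
        raise ValueError(
            f"test_fraction {test_fraction} would send all {len(ids)} slides to test"
        )
    rng = np.random.default_rng(rng_seed)
    perm = rng.permutation(len(ids))
    test = frozenset(ids[i] for i in perm[:n_test])
    train = frozenset(ids[i] for i in perm[n_test:])
    return CaseSplit(train_slide_ids=train, test_slide_ids=test)
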