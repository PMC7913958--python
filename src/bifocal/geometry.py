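"""2-D affine transforms shared by the slide generator and the registration
stage.  Points are (x, y) with x = column, y = row, matching raster indexing
used throughout the package."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["Affine"]


@dataclass(frozen=True)
class Affine:
    """2x3 matrix mapping (x, y) -> (x', y'): ``p' = A p + t``."""

    matrix: np.ndarray  # shape (2, 3), float64

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=np.float64)
        if m.shape != (2, 3):
            raise ValueError(f"affine matrix must be 2x3, got {m.shape}")
        object.__setattr__(self, "matrix", m)
        if abs(np.linalg.det(m[:, :2])) < 1e-12:
            raise ValueError("affine transform is singular")

    @classmethod
    def identity(cls) -> "Affine":
        return cls(np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]))

    @classmethod
    def from_params(
        cls,
        rotation_deg: float = 0.0,
        scale: float = 1.0,
        translation: tuple[float, float] = (0.0, 0.0),
        center: tuple[float, float] = (0.0, 0.0),
    ) -> "Affine":
        """Rotation (counter-clockwise) and isotropic scale about ``center``,
        followed by a translation."""
        th = math.radians(rotation_deg)
        c, s = scale * math.cos(th), scale * math.sin(th)
        cx, cy = center
        tx, ty = translation
        # p' = R (p - c) + c + t
        a = np.array(
            [
                [c, -s, cx - c * cx + s * cy + tx],
                [s, c, cy - s * cx - c * cy + ty],
            ]
        )
        return cls(a)

    @property
    def linear(self) -> np.ndarray:
        return self.matrix[:, :2]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:, 2]

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        return pts @ self.linear.T + self.translation

    def compose(self, other: "Affine") -> "Affine":
        """self ∘ other (apply ``other`` first)."""
        a = self.linear @ other.linear
        t = self.linear @ other.translation + self.translation
        return Affine(np.hstack([a, t[:, None]]))

    def inverse(self) -> "Affine":
        inv = np.linalg.inv(self.linear)
        return Affine(np.hstack([inv, (-inv @ self.translation)[:, None]]))

    def to_cell_frame(self, origin: tuple[float, float], stride: float) -> "Affine":
        """Re-express a pixel-frame transform in heatmap-cell coordinates
        where cell (cx, cy) sits at pixel ``origin + stride * (cx, cy)``."""
        s = Affine(np.array([[stride, 0.0, origin[0]], [0.0, stride, origin[1]]]))
        return s.inverse().compose(self).compose(s)

    def max_abs_difference(self, other: "Affine") -> float:
        return float(np.abs(self.matrix - other.matrix).max())
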