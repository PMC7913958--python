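"""Training-time augmentation applied independently to each member of a
bifocal pair.

Because the wide and narrow tiles draw their augmentations independently,
``n`` augmentation types yield ``n**2`` distinct pair-level variants — the
combinatorial expansion that makes a modest marking set trainable.  The
inference path never imports this module; :func:`call_count` exposes a
counter so pipeline tests can assert that no augmentation runs at
recognition time.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .tiling import BifocalPair

__all__ = [
    "AugmentSpec",
    "apply_augmentation",
    "enumerate_pair_augmentations",
    "random_pair_augment",
    "default_augment_specs",
    "call_count",
]

KINDS = ("identity", "rotation", "contrast", "sharpness")
RIGHT_ANGLES = (0, 90, 180, 270)
FACTOR_RANGE = (0.7, 1.3)  # mild perturbations preserve class identity

_SMOOTH_KERNEL = np.array([[1, 1, 1], [1, 5, 1], [1, 1, 1]], dtype=np.float32) / 13.0

_calls = 0


def call_count() -> int:
    """Number of augmentations applied so far (test hook)."""
    return _calls


@dataclass(frozen=True)
class AugmentSpec:
    kind: str
    parameter: float = 0.0  # angle for rotation, factor for contrast/sharpness

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unsupported augmentation kind {self.kind!r}")
        if self.kind == "rotation" and int(self.parameter) not in RIGHT_ANGLES:
            raise ValueError("rotation is restricted to right angles (0/90/180/270)")
        if self.kind in ("contrast", "sharpness") and self.parameter <= 0:
            raise ValueError(f"{self.kind} factor must be positive")


def _smooth(tile_f: np.ndarray) -> np.ndarray:
    out = np.empty_like(tile_f)
    for ch in range(3):
        ndimage.convolve(tile_f[:, :, ch], _SMOOTH_KERNEL, output=out[:, :, ch], mode="reflect")
    return out


def apply_augmentation(tile: np.ndarray, spec: AugmentSpec) -> np.ndarray:
    """Apply one deterministic augmentation to a square RGB tile; the output
    has the tile's dimensions."""
    global _calls
    _calls += 1
    if tile.shape[0] != tile.shape[1]:
        raise ValueError("tile must be square")
    if spec.kind == "identity":
        return tile.copy()
    if spec.kind == "rotation":
        return np.ascontiguousarray(np.rot90(tile, int(spec.parameter) // 90))
    f = float(spec.parameter)
    if f == 1.0:
        return tile.copy()
    t = tile.astype(np.float32)
    if spec.kind == "contrast":
        # pivot on the mean luminance, as classic photometric enhancers do
        lum = 0.299 * t[:, :, 0] + 0.587 * t[:, :, 1] + 0.114 * t[:, :, 2]
        out = lum.mean() + f * (t - lum.mean())
    else:  # sharpness: blend away from a smoothed copy
        out = t + (f - 1.0) * (t - _smooth(t))
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def default_augment_specs(n_types: int) -> list[AugmentSpec]:
    base = [
        AugmentSpec("identity"),
        AugmentSpec("rotation", 90),
        AugmentSpec("rotation", 180),
        AugmentSpec("rotation", 270),
        AugmentSpec("contrast", 1.2),
        AugmentSpec("sharpness", 1.2),
    ]
    if not 1 <= n_types <= len(base):
        raise ValueError(f"n_types must lie in 1..{len(base)}")
    return base[:n_types]


def enumerate_pair_augmentations(specs) -> list[tuple[AugmentSpec, AugmentSpec]]:
    """Cartesian product of per-member augmentations: exactly n**2 entries.
    ``specs`` is a list of AugmentSpec, or an int selecting the first n
    default types."""
    if isinstance(specs, int):
        specs = default_augment_specs(specs)
    if len(specs) < 1:
        raise ValueError("need at least one augmentation type")
    return list(itertools.product(specs, specs))


def _draw_spec(rng: np.random.Generator) -> AugmentSpec:
    kind = KINDS[rng.integers(len(KINDS))]
    if kind == "identity":
        return AugmentSpec("identity")
    if kind == "rotation":
        return AugmentSpec("rotation", RIGHT_ANGLES[rng.integers(4)])
    return AugmentSpec(kind, float(rng.uniform(*FACTOR_RANGE)))


def random_pair_augment(pair: BifocalPair, rng: int | np.random.Generator) -> BifocalPair:
    """Independently drawn augmentations for the wide and narrow members;
    deterministic given the seed; the label is preserved."""
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    spec_wide = _draw_spec(rng)
    spec_narrow = _draw_spec(rng)
    return BifocalPair(
        wide=apply_augmentation(pair.wide, spec_wide),
        narrow=apply_augmentation(pair.narrow, spec_narrow),
        epicenter=pair.epicenter,
        label=pair.label,
        slide_id=pair.slide_id,
    )
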