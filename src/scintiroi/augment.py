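"""Training-set expansion: mirror, right-angle rotations, 10-pixel shifts.

The expansion multiplies every phase-image/label pair by 64: the identity
plus 63 distinct compositions of a horizontal mirror, a rotation by 0, 90,
180 or 270 degrees, and a 10-pixel translation in one of the eight compass
directions.  Removing the identity member leaves 63 genuinely new images
per case (256 cases -> 16,384 pairs with the originals; 108 cases -> 6,804
without them).

Geometric operations are exact on the pixel grid (no interpolation);
translations zero-fill the pixels shifted in from outside the frame.  The
same transform is always applied to the image and its label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError

FLIPS = ("none", "horizontal")
ROTATIONS = (0, 90, 180, 270)
TRANSLATE_PX = 10
#: Eight compass directions as (drow, dcol) at 10 px, row-major order.
COMPASS = tuple(
    (dr, dc)
    for dr in (-TRANSLATE_PX, 0, TRANSLATE_PX)
    for dc in (-TRANSLATE_PX, 0, TRANSLATE_PX)
    if (dr, dc) != (0, 0)
)


@dataclass(frozen=True)
class TransformSpec:
    """One augmentation: flip, then rotate, then translate."""

    flip: str = "none"
    rotation: int = 0
    translation: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        if self.flip not in FLIPS:
            raise ConfigError(f"flip must be one of {FLIPS}")
        if self.rotation not in ROTATIONS:
            raise ConfigError(f"rotation must be one of {ROTATIONS}")
        if self.translation != (0, 0) and self.translation not in COMPASS:
            raise ConfigError(
                "translation must be (0, 0) or a compass direction at "
                f"{TRANSLATE_PX} px"
            )

    @property
    def is_identity(self) -> bool:
        return (
            self.flip == "none"
            and self.rotation == 0
            and self.translation == (0, 0)
        )


IDENTITY = TransformSpec()


def enumerate_transforms(include_identity: bool = True) -> list[TransformSpec]:
    """The 64-member augmentation set (or its 63 non-identity members).

    The set is the identity plus the lexicographically first 63 members of
    the flip x rotation x compass-translation factorial; it contains every
    compass translation, every rotation and the mirror, each spec exactly
    once.
    """
    factorial = [
        TransformSpec(f, r, t) for f in FLIPS for r in ROTATIONS for t in COMPASS
    ]
    members = [IDENTITY] + factorial[:-1]
    return members if include_identity else members[1:]


def apply_transform(image: np.ndarray, spec: TransformSpec) -> np.ndarray:
    """Apply flip, rotation and translation (in that order) to a 2D array."""
    out = np.asarray(image)
    if out.ndim != 2:
        raise ConfigError("apply_transform expects a 2D array")
    if spec.flip == "horizontal":
        out = np.fliplr(out)
    if spec.rotation:
        out = np.rot90(out, k=spec.rotation // 90)
    dr, dc = spec.translation
    if (dr, dc) != (0, 0):
        shifted = np.zeros_like(out)
        h, w = out.shape
        src_r = slice(max(0, -dr), min(h, h - dr))
        dst_r = slice(max(0, dr), min(h, h + dr))
        src_c = slice(max(0, -dc), min(w, w - dc))
        dst_c = slice(max(0, dc), min(w, w + dc))
        shifted[dst_r, dst_c] = out[src_r, src_c]
        out = shifted
    return out.copy()


def augment_pair(
    image: np.ndarray,
    label: np.ndarray,
    transforms: list[TransformSpec] | None = None,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Apply every transform identically to an image and its label."""
    image = np.asarray(image)
    label = np.asarray(label)
    if image.shape != label.shape:
        raise ConfigError("image and label must have the same shape")
    if transforms is None:
        transforms = enumerate_transforms(include_identity=True)
    return [
        (apply_transform(image, t), apply_transform(label, t)) for t in transforms
    ]
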