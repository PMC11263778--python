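"""From candidate map to circular ROI: P-tile threshold, centroid, circle.

The network's candidate map is binarized with the P-tile rule (keep the
top-P fraction of pixels by score), the centroid of the foreground is
taken as the candidate ROI center, and a fixed-radius circular ROI
(3 px = 6.6 mm on the 2.21 mm grid) is placed there.  If the circle would
extend beyond the candidate region, the center is relocated to the
foreground pixel whose circle is best contained, so the ROI never reaches
outside the vessel.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import AnalysisError, ConfigError
from .frame_io import REFERENCE_PIXEL_MM

#: Default expected candidate-region area (pixels on the 2.21 mm grid) used
#: to derive the P-tile fraction when only an area prior is given.
DEFAULT_PTILE_AREA = 60


@dataclass
class ROISpec:
    """Circular ROI: continuous (row, col) center plus radius in pixels."""

    center: tuple[float, float]
    radius_px: float = 3.0
    pixel_mm: float = REFERENCE_PIXEL_MM
    target: str = "PA"
    containment: float = 1.0

    def __post_init__(self) -> None:
        if self.radius_px <= 0:
            raise ConfigError("radius_px must be positive")
        if self.pixel_mm <= 0:
            raise ConfigError("pixel_mm must be positive")

    @property
    def radius_mm(self) -> float:
        """Radius in mm, rounded to 1 decimal (3 px at 2.21 mm -> 6.6 mm)."""
        return round(self.radius_px * self.pixel_mm, 1)

    def to_dict(self) -> dict:
        return {
            "target": self.target,
            "center_row": self.center[0],
            "center_col": self.center[1],
            "radius_px": self.radius_px,
            "radius_mm": self.radius_mm,
            "containment": self.containment,
        }


def ptile_fraction_for_area(area_px: int, n_pixels: int) -> float:
    """P-tile fraction retaining ``area_px`` pixels of an ``n_pixels`` map."""
    if area_px < 1 or area_px >= n_pixels:
        raise ConfigError("area_px must be in [1, n_pixels)")
    return area_px / n_pixels


def ptile_threshold(score_map: np.ndarray, p_fraction: float) -> np.ndarray:
    """Binarize by keeping the ``ceil(p * n)`` highest-scoring pixels.

    Ties are broken by score and then by row-major position, so the result
    is fully deterministic.

    Raises
    ------
    AnalysisError
        If the map has no contrast (all pixels equal).
    """
    if not 0 < p_fraction < 1:
        raise ConfigError("p_fraction must be in (0, 1)")
    score = np.asarray(score_map, dtype=float)
    if score.ndim != 2:
        raise ConfigError("score_map must be 2D")
    flat = score.ravel()
    if flat.max() == flat.min():
        raise AnalysisError("no contrast: all pixels equal")
    k = math.ceil(p_fraction * flat.size)
    # primary key: score descending; secondary: row-major index ascending
    order = np.lexsort((np.arange(flat.size), -flat))
    mask = np.zeros(flat.size, dtype=bool)
    mask[order[:k]] = True
    return mask.reshape(score.shape)


def centroid(mask: np.ndarray) -> tuple[float, float]:
    """Arithmetic mean (row, col) of the foreground pixel coordinates."""
    mask = np.asarray(mask).astype(bool)
    rr, cc = np.nonzero(mask)
    if rr.size == 0:
        raise AnalysisError("centroid of an empty mask")
    return float(rr.mean()), float(cc.mean())


def _circle_pixels(center: tuple[float, float], radius_px: float) -> np.ndarray:
    """(row, col) integer pixels whose centers lie within ``radius_px`` of a
    (possibly fractional) circle center.  May include out-of-bounds pixels."""
    r0, c0 = center
    rr, cc = np.mgrid[
        math.floor(r0 - radius_px) : math.ceil(r0 + radius_px) + 1,
        math.floor(c0 - radius_px) : math.ceil(c0 + radius_px) + 1,
    ]
    keep = (rr - r0) ** 2 + (cc - c0) ** 2 <= radius_px**2
    return np.stack([rr[keep], cc[keep]], axis=1)


def roi_pixel_mask(roi: ROISpec, shape: tuple[int, int]) -> np.ndarray:
    """Pixels whose centers lie within ``radius_px`` of the ROI center.

    A 3 px radius on an integer center covers 29 pixels.  ROIs partially
    outside the image are clipped with a warning.
    """
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    r0, c0 = roi.center
    mask = (rr - r0) ** 2 + (cc - c0) ** 2 <= roi.radius_px**2
    if (
        r0 - roi.radius_px < -0.5
        or r0 + roi.radius_px > shape[0] - 0.5
        or c0 - roi.radius_px < -0.5
        or c0 + roi.radius_px > shape[1] - 0.5
    ):
        warnings.warn("ROI extends beyond image bounds; mask clipped")
    return mask


def _containment(
    mask: np.ndarray, center: tuple[float, float], radius_px: float
) -> float:
    """Fraction of the circle's pixels that fall inside the mask
    (out-of-bounds pixels count as not contained)."""
    px = _circle_pixels(center, radius_px)
    rr, cc = px[:, 0], px[:, 1]
    inside = (
        (rr >= 0) & (rr < mask.shape[0]) & (cc >= 0) & (cc < mask.shape[1])
    )
    hits = mask[rr[inside], cc[inside]].sum()
    return float(hits) / float(px.shape[0])


def place_circular_roi(
    binary_mask: np.ndarray,
    radius_px: float = 3.0,
    pixel_mm: float = REFERENCE_PIXEL_MM,
    target: str = "PA",
) -> ROISpec:
    """Place a fixed circular ROI that stays inside the candidate region.

    The centroid of the binary mask is the preferred center.  If the full
    circle around it lies inside the mask the ROI is placed there;
    otherwise the center moves to the foreground pixel maximizing the
    contained fraction of the circle (ties: closest to the centroid, then
    row-major order).  If even the best circle is not fully contained the
    ROI is returned with ``containment < 1`` and a warning.
    """
    mask = np.asarray(binary_mask).astype(bool)
    c = centroid(mask)
    frac = _containment(mask, c, radius_px)
    if frac == 1.0:
        return ROISpec(center=c, radius_px=radius_px, pixel_mm=pixel_mm,
                       target=target, containment=1.0)
    rr, cc = np.nonzero(mask)
    best = None
    for r0, c0 in zip(rr.tolist(), cc.tolist()):
        f = _containment(mask, (float(r0), float(c0)), radius_px)
        d = (r0 - c[0]) ** 2 + (c0 - c[1]) ** 2
        key = (-f, d, r0, c0)
        if best is None or key < best[0]:
            best = (key, (r0, c0), f)
    _, center, f = best
    if f < 1.0:
        warnings.warn(
            f"candidate region smaller than the ROI circle; best containment {f:.2f}"
        )
    return ROISpec(center=(float(center[0]), float(center[1])),
                   radius_px=radius_px, pixel_mm=pixel_mm,
                   target=target, containment=f)
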