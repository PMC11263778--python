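"""Dynamic-series container, on-disk interchange format and pixel-pitch
standardization.

A dynamic chest RI-angiography acquisition is an ordered stack of 2D count
frames recorded at a fixed frame rate (typically 1 frame/s) with a known
pixel pitch in mm.  On disk a series is an ``.npz`` array container holding
the frame stack plus a JSON sidecar with the acquisition metadata
(``pixel_mm``, ``frame_s``, ``mode``).

All images in the package use the 0-based ``(row, col)`` convention with
pixel centers at integer coordinates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from skimage.transform import resize

from .errors import ConfigError, FormatError

#: Reference pixel pitch in mm/pixel that all series are standardized to.
#: This is the smallest pitch encountered across the supported gamma-camera
#: systems, so standardization never splits voxels.
REFERENCE_PIXEL_MM = 2.21

MODES = ("IMP", "ECD")


def px_to_mm(px: float, pixel_mm: float = REFERENCE_PIXEL_MM) -> float:
    """Convert a pixel distance to mm on the given grid."""
    if pixel_mm <= 0:
        raise ConfigError("pixel_mm must be positive")
    return px * pixel_mm


@dataclass
class DynamicSeries:
    """Ordered stack of 2D count frames with acquisition metadata.

    Parameters
    ----------
    frames
        ``(n_frames, H, W)`` array of nonnegative counts.
    frame_s
        Frame duration in seconds (1 s for the supported protocols).
    pixel_mm
        Pixel pitch in mm/pixel.
    mode
        Acquisition protocol: ``"IMP"`` (123I-IMP, 60 s) or ``"ECD"``
        (99mTc-ECD, 100 s).
    """

    frames: np.ndarray
    frame_s: float = 1.0
    pixel_mm: float = REFERENCE_PIXEL_MM
    mode: str = "IMP"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise FormatError("frames must be a (n_frames, H, W) stack")
        if np.any(self.frames < 0):
            raise FormatError("frame counts must be nonnegative")
        if not np.all(np.isfinite(self.frames)):
            raise FormatError("frame counts must be finite")
        if self.pixel_mm <= 0:
            raise FormatError("pixel_mm must be positive")
        if self.frame_s <= 0:
            raise FormatError("frame_s must be positive")
        if self.mode not in MODES:
            raise FormatError(f"mode must be one of {MODES}, got {self.mode!r}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def image_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Frame start times in seconds."""
        return np.arange(self.n_frames) * self.frame_s


def _paths(path: str | Path) -> tuple[Path, Path]:
    base = Path(path)
    if base.suffix in {".npz", ".json"}:
        base = base.with_suffix("")
    return base.with_suffix(".npz"), base.with_suffix(".json")


def save_series(series: DynamicSeries, path: str | Path) -> None:
    """Write ``<path>.npz`` (frame stack) and ``<path>.json`` (sidecar)."""
    arr_path, sidecar_path = _paths(path)
    arr_path.parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(arr_path, frames=series.frames)
    sidecar = {
        "pixel_mm": series.pixel_mm,
        "frame_s": series.frame_s,
        "mode": series.mode,
    }
    sidecar.update(series.meta)
    sidecar_path.write_text(json.dumps(sidecar, indent=2, sort_keys=True))


def load_series(path: str | Path) -> DynamicSeries:
    """Load a series written by :func:`save_series`.

    Raises
    ------
    FormatError
        If the container or sidecar is missing, or required metadata keys
        (``pixel_mm``, ``frame_s``, ``mode``) are absent, or counts are
        negative.
    """
    arr_path, sidecar_path = _paths(path)
    if not arr_path.exists():
        raise FormatError(f"missing array container {arr_path}")
    if not sidecar_path.exists():
        raise FormatError(f"missing JSON sidecar {sidecar_path}")
    with np.load(arr_path) as data:
        if "frames" not in data:
            raise FormatError("array container lacks 'frames'")
        frames = data["frames"]
    sidecar = json.loads(sidecar_path.read_text())
    for key in ("pixel_mm", "frame_s", "mode"):
        if key not in sidecar:
            raise FormatError(f"sidecar lacks required key {key!r}")
    meta = {k: v for k, v in sidecar.items()
            if k not in ("pixel_mm", "frame_s", "mode")}
    return DynamicSeries(
        frames=frames,
        frame_s=float(sidecar["frame_s"]),
        pixel_mm=float(sidecar["pixel_mm"]),
        mode=str(sidecar["mode"]),
        meta=meta,
    )


def load_dicom_series(path: str | Path, mode: str | None = None) -> DynamicSeries:
    """Best-effort import of a multi-frame DICOM dynamic acquisition.

    Maps ``PixelSpacing`` (mm) and ``FrameTime`` (ms) onto the sidecar
    fields; ``mode`` is taken from the argument or guessed from the frame
    count (<= 60 s -> IMP, else ECD).  This is a convenience path for
    vendor exports, not a conformance layer.
    """
    try:
        import pydicom
    except ImportError as exc:  # pragma: no cover
        raise FormatError("DICOM import requires pydicom") from exc
    ds = pydicom.dcmread(str(path))
    frames = np.asarray(ds.pixel_array, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3:
        raise FormatError("expected a multi-frame 2D DICOM acquisition")
    spacing = getattr(ds, "PixelSpacing", None)
    if spacing is None:
        raise FormatError("DICOM lacks PixelSpacing")
    pixel_mm = float(spacing[0])
    frame_s = float(getattr(ds, "FrameTime", 1000.0)) / 1000.0
    if mode is None:
        mode = "IMP" if frames.shape[0] * frame_s <= 60 else "ECD"
    return DynamicSeries(frames=frames, frame_s=frame_s, pixel_mm=pixel_mm,
                         mode=mode)


def standardize_pixel_size(
    series: DynamicSeries, target_mm: float = REFERENCE_PIXEL_MM
) -> DynamicSeries:
    """Resample every frame onto the ``target_mm`` pixel grid.

    Each frame is bilinearly interpolated independently (no temporal
    interpolation) onto a grid of ``round(H * pixel_mm / target_mm)`` by
    ``round(W * pixel_mm / target_mm)`` pixels.  Interpolated values are
    rescaled by the pixel-area ratio so that total *counts* — the quantity
    the downstream TAC/AUC analysis sums — are preserved, not count
    densities.  A spatially uniform frame therefore stays exactly uniform,
    with its value scaled by the area ratio.
    """
    if target_mm <= 0:
        raise ConfigError("target_mm must be positive")
    if np.isclose(series.pixel_mm, target_mm):
        return replace(series, frames=series.frames.copy())
    h, w = series.image_shape
    zoom = series.pixel_mm / target_mm
    new_h = max(1, int(round(h * zoom)))
    new_w = max(1, int(round(w * zoom)))
    # Jacobian: counts per new pixel = density * new pixel area.
    area_ratio = (target_mm / series.pixel_mm) ** 2
    out = np.empty((series.n_frames, new_h, new_w), dtype=float)
    for t in range(series.n_frames):
        out[t] = resize(
            series.frames[t].astype(float),
            (new_h, new_w),
            order=1,
            mode="edge",
            anti_aliasing=False,
            preserve_range=True,
        )
    out *= area_ratio
    return DynamicSeries(
        frames=out,
        frame_s=series.frame_s,
        pixel_mm=target_mm,
        mode=series.mode,
        meta=dict(series.meta),
    )
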