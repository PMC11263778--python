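"""Vascular-phase image construction.

The segmentation network is not fed raw frames but a *phase image*: the
pixel-wise sum of a few frames centered on the vascular peak of interest.
The peak frame is found on the whole-image count curve — the first
prominent local maximum for the pulmonary artery (PA), the second for the
ascending aorta (AAo), whose transit follows the right-heart/PA peak.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks

from .errors import AnalysisError, UnsuitableCurveError
from .frame_io import DynamicSeries
from .tac_quant import TimeActivityCurve

TARGETS = ("PA", "AAo")

#: Default prominence threshold: a local maximum of the (3-point smoothed)
#: curve counts as a peak if it reaches this fraction of the curve maximum.
DEFAULT_PROMINENCE_FRAC = 0.3
SMOOTH_WINDOW = 3


@dataclass
class PhaseImage:
    """Sum of frames around a vascular peak.

    ``window`` records the effective ``(n_before, n_after)`` after any edge
    clamping.
    """

    image: np.ndarray
    peak_frame: int
    window: tuple[int, int]
    target: str
    normalized: bool = False


def global_count_curve(series: DynamicSeries) -> TimeActivityCurve:
    """Whole-image counts per frame (the curve peaks are searched on this)."""
    values = series.frames.sum(axis=(1, 2)).astype(float)
    return TimeActivityCurve(values=values, frame_s=series.frame_s)


def smooth_curve(values: np.ndarray, window: int = SMOOTH_WINDOW) -> np.ndarray:
    return uniform_filter1d(np.asarray(values, dtype=float), window, mode="nearest")


def find_prominent_peaks(
    values: np.ndarray, prominence_frac: float = DEFAULT_PROMINENCE_FRAC
) -> list[int]:
    """Indices of prominent local maxima, in time order.

    The curve is smoothed with a 3-point moving average; local maxima
    whose topographic prominence reaches ``prominence_frac`` of the
    smoothed curve's dynamic range (max minus min, so a constant
    background baseline does not mask or fake peaks) count as peaks.
    Each peak index is then refined to the raw-curve argmax within one
    frame of the smoothed maximum, earliest frame on ties.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 5:
        raise AnalysisError("curve too short for peak detection (need >= 5 frames)")
    sm = smooth_curve(values)
    rng_ = sm.max() - sm.min()
    if rng_ <= 0:
        return []
    idx, _ = find_peaks(sm, prominence=prominence_frac * rng_)
    refined: list[int] = []
    for p in idx:
        lo, hi = max(0, p - 1), min(values.size, p + 2)
        r = lo + int(np.argmax(values[lo:hi]))
        if r not in refined:
            refined.append(r)
    return refined


def detect_peak_frame(
    curve: TimeActivityCurve,
    target: str,
    prominence_frac: float = DEFAULT_PROMINENCE_FRAC,
) -> int:
    """Frame index of the target vascular peak on a count curve.

    PA uses the first prominent peak (bolus arrival in the central
    pulmonary circulation); AAo uses the second (systemic arrival after
    the right-heart/PA transit).

    Raises
    ------
    UnsuitableCurveError
        If the curve does not show the required peak — e.g. AAo requested
        on a unimodal curve, as happens with slow injections.
    """
    if target not in TARGETS:
        raise AnalysisError(f"target must be one of {TARGETS}, got {target!r}")
    peaks = find_prominent_peaks(curve.values, prominence_frac)
    need = 1 if target == "PA" else 2
    if len(peaks) < need:
        raise UnsuitableCurveError(
            f"{target} peak not found: {len(peaks)} prominent peak(s) detected"
        )
    return peaks[need - 1]


def build_phase_image(
    series: DynamicSeries,
    peak_frame: int,
    n_before: int = 2,
    n_after: int = 2,
    target: str = "PA",
) -> PhaseImage:
    """Pixel-wise sum of frames ``[peak-n_before, peak+n_after]``.

    The window is clamped at the series edges; the effective window is
    recorded in the result.
    """
    if not 0 <= peak_frame < series.n_frames:
        raise AnalysisError("peak_frame outside series")
    if n_before < 0 or n_after < 0:
        raise AnalysisError("window extents must be nonnegative")
    lo = max(0, peak_frame - n_before)
    hi = min(series.n_frames - 1, peak_frame + n_after)
    image = series.frames[lo : hi + 1].sum(axis=0)
    return PhaseImage(
        image=image,
        peak_frame=peak_frame,
        window=(peak_frame - lo, hi - peak_frame),
        target=target,
    )


def normalize_phase(phase: PhaseImage) -> PhaseImage:
    """Divide by the maximum pixel so the image peaks at 1 (idempotent)."""
    m = float(phase.image.max())
    if m <= 0:
        raise AnalysisError("cannot normalize an all-zero phase image")
    return replace(phase, image=phase.image / m, normalized=True)
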