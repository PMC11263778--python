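"""Synthetic dynamic chest RI-angiography phantoms with known ground truth.

The phantom emulates the first-pass transit of a radiotracer bolus through
the central circulation as seen by a planar gamma camera at 1 frame/s:

* **IMP protocol** (123I-IMP, 60 s): a sharp pulmonary-artery (PA) bolus
  peak followed by broad lung uptake/washout.  The PA time-activity curve
  (TAC) is single-peaked.
* **ECD protocol** (99mTc-ECD, 100 s): an early right-heart/PA transit
  peak followed by the ascending-aorta (AAo) peak.  Because the central
  blood pool overlaps the AAo in planar projection, a TAC probed over the
  AAo region is double-peaked — the second peak is the aortic transit.

Each structure is an axis-aligned ellipse whose pixels share a
gamma-variate TAC; frames are the sum of structure TACs plus a constant
background, optionally with independent Poisson counting noise.  The
generator records full ground truth (masks, kinetic parameters, centroid
centers, analytic AUC) so every downstream stage can be verified without
clinical data.

Slow injections are modeled by scaling the bolus time constant ``beta`` by
an ``injection_speed`` factor while conserving the injected activity
(the analytic AUC), so a slow bolus is proportionally wider and lower.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import gamma as gamma_fn

import json
from pathlib import Path

from .errors import ConfigError, FormatError
from .frame_io import REFERENCE_PIXEL_MM, DynamicSeries

# --------------------------------------------------------------------------
# Gamma-variate bolus model
# --------------------------------------------------------------------------


def gamma_variate_tac(
    t0: float, alpha: float, beta: float, K: float, times: np.ndarray
) -> np.ndarray:
    """Evaluate the gamma-variate bolus curve ``K (t-t0)^a exp(-(t-t0)/b)``.

    The curve is zero for ``t <= t0``, rises to its maximum at
    ``t0 + alpha*beta`` and decays exponentially; it is the canonical model
    of first-pass indicator transit.

    Parameters
    ----------
    t0 : float
        Bolus arrival time (s); the curve is 0 at and before ``t0``.
    alpha, beta : float
        Shape (unitless) and time constant (s); both must be positive.
    K : float
        Count-scale factor.
    times : array_like
        Nondecreasing sample times (s).
    """
    if alpha <= 0 or beta <= 0:
        raise ConfigError("gamma-variate parameters alpha and beta must be > 0")
    times = np.asarray(times, dtype=float)
    if times.size > 1 and np.any(np.diff(times) < 0):
        raise ConfigError("times must be nondecreasing")
    dt = times - t0
    out = np.zeros_like(dt)
    pos = dt > 0
    out[pos] = K * dt[pos] ** alpha * np.exp(-dt[pos] / beta)
    return out


def gamma_variate_auc(alpha: float, beta: float, K: float) -> float:
    """Closed-form integral of the gamma-variate over (t0, inf):
    ``K * beta**(alpha+1) * Gamma(alpha+1)``."""
    if alpha <= 0 or beta <= 0:
        raise ConfigError("gamma-variate parameters alpha and beta must be > 0")
    return float(K * beta ** (alpha + 1) * gamma_fn(alpha + 1))


def scale_for_peak(peak: float, alpha: float, beta: float) -> float:
    """Count-scale ``K`` giving the requested peak value at ``t0+alpha*beta``."""
    if alpha <= 0 or beta <= 0:
        raise ConfigError("gamma-variate parameters alpha and beta must be > 0")
    return peak * math.exp(alpha) / (alpha * beta) ** alpha


# --------------------------------------------------------------------------
# Phantom configuration
# --------------------------------------------------------------------------

#: Names with vascular kinetics, in required order of bolus arrival.
_DELAY_ORDER = ("right_heart", "PA", "lungs", "AAo")


def _delay_rank(name: str) -> int | None:
    if name.startswith("lung"):
        return _DELAY_ORDER.index("lungs")
    if name in _DELAY_ORDER:
        return _DELAY_ORDER.index(name)
    return None


@dataclass
class StructureSpec:
    """Axis-aligned elliptical structure with gamma-variate kinetics.

    ``peak`` is the nominal per-pixel peak count rate (counts/pixel/frame)
    at injection_speed 1.
    """

    name: str
    center: tuple[float, float]  # (row, col), pixels
    axes: tuple[float, float]  # semi-axes (rows, cols), pixels
    t0: float
    alpha: float
    beta: float
    peak: float

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
        a, b = self.axes
        return ((rr - self.center[0]) / a) ** 2 + (
            (cc - self.center[1]) / b
        ) ** 2 <= 1.0


@dataclass
class PhantomConfig:
    """Full description of one synthetic acquisition."""

    image_size: tuple[int, int] = (128, 128)
    pixel_mm: float = REFERENCE_PIXEL_MM
    n_frames: int = 60
    frame_s: float = 1.0
    mode: str = "IMP"
    structures: list[StructureSpec] = field(default_factory=list)
    background: float = 0.5  # counts/pixel/frame
    injection_speed: float = 1.0  # scales beta; >slow_cutoff flags "slow"
    slow_cutoff: float = 2.0
    noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_mm <= 0:
            raise ConfigError("pixel_mm must be positive")
        if self.injection_speed <= 0:
            raise ConfigError("injection_speed must be positive")
        if self.background < 0:
            raise ConfigError("background must be nonnegative")

    @property
    def is_slow(self) -> bool:
        return self.injection_speed > self.slow_cutoff


@dataclass
class PhantomTruth:
    """Ground truth accompanying a simulated series."""

    masks: dict[str, np.ndarray]
    params: dict[str, dict]
    centers: dict[str, tuple[float, float]]
    pixel_auc: dict[str, float]  # analytic per-pixel AUC (counts*s)
    pa_center: tuple[float, float] | None
    aao_center: tuple[float, float] | None
    slow: bool
    mode: str
    background: float


def _effective_kinetics(s: StructureSpec, speed: float) -> tuple[float, float, float]:
    """(t0, beta_eff, K_eff): beta scaled by injection speed, activity
    (analytic AUC) conserved."""
    beta_eff = s.beta * speed
    k_nom = scale_for_peak(s.peak, s.alpha, s.beta)
    auc_nom = gamma_variate_auc(s.alpha, s.beta, k_nom)
    k_eff = auc_nom / (beta_eff ** (s.alpha + 1) * gamma_fn(s.alpha + 1))
    return s.t0, beta_eff, float(k_eff)


def _check_structures(config: PhantomConfig) -> dict[str, np.ndarray]:
    shape = config.image_size
    masks: dict[str, np.ndarray] = {}
    for s in config.structures:
        if s.name in masks:
            raise ConfigError(f"duplicate structure name {s.name!r}")
        r0, c0 = s.center
        a, b = s.axes
        if r0 - a < 0 or r0 + a > shape[0] - 1 or c0 - b < 0 or c0 + b > shape[1] - 1:
            raise ConfigError(f"structure {s.name!r} extends outside image bounds")
        masks[s.name] = s.mask(shape)
        if not masks[s.name].any():
            raise ConfigError(f"structure {s.name!r} covers no pixels")
    if "PA" in masks and "AAo" in masks:
        if np.any(masks["PA"] & masks["AAo"]):
            raise ConfigError("PA and AAo masks must be disjoint")
    # bolus arrival ordering: right_heart <= PA <= lungs <= AAo
    ranked = [(rk, s.t0) for s in config.structures
              if (rk := _delay_rank(s.name)) is not None]
    ranked.sort()
    for (r1, t1), (r2, t2) in zip(ranked, ranked[1:]):
        if r1 != r2 and t1 > t2:
            raise ConfigError(
                "bolus delays must be ordered right_heart <= PA <= lungs <= AAo"
            )
    return masks


def make_phantom(config: PhantomConfig) -> tuple[DynamicSeries, PhantomTruth]:
    """Simulate one dynamic series plus its ground truth.

    Noiseless pixel values are the sum over structures containing the pixel
    of the structure's gamma-variate TAC, plus the constant background.
    With ``noise=True`` every frame is an independent Poisson draw around
    the noiseless frame.
    """
    masks = _check_structures(config)
    shape = config.image_size
    times = np.arange(config.n_frames) * config.frame_s
    clean = np.full((config.n_frames,) + tuple(shape), float(config.background))

    params: dict[str, dict] = {}
    centers: dict[str, tuple[float, float]] = {}
    pixel_auc: dict[str, float] = {}
    for s in config.structures:
        t0, beta_eff, k_eff = _effective_kinetics(s, config.injection_speed)
        tac = gamma_variate_tac(t0, s.alpha, beta_eff, k_eff, times)
        clean[:, masks[s.name]] += tac[:, None]
        params[s.name] = {
            "t0": t0,
            "alpha": s.alpha,
            "beta": beta_eff,
            "K": k_eff,
            "peak_time": t0 + s.alpha * beta_eff,
            "area_px": int(masks[s.name].sum()),
        }
        rr, cc = np.nonzero(masks[s.name])
        centers[s.name] = (float(rr.mean()), float(cc.mean()))
        pixel_auc[s.name] = gamma_variate_auc(s.alpha, beta_eff, k_eff)

    if config.noise:
        rng = np.random.default_rng(config.seed)
        frames = rng.poisson(clean).astype(float)
    else:
        frames = clean

    series = DynamicSeries(
        frames=frames,
        frame_s=config.frame_s,
        pixel_mm=config.pixel_mm,
        mode=config.mode,
        meta={"slow": config.is_slow},
    )
    truth = PhantomTruth(
        masks=masks,
        params=params,
        centers=centers,
        pixel_auc=pixel_auc,
        pa_center=centers.get("PA"),
        aao_center=centers.get("AAo"),
        slow=config.is_slow,
        mode=config.mode,
        background=config.background,
    )
    return series, truth


# --------------------------------------------------------------------------
# Default protocol configurations
# --------------------------------------------------------------------------

def imp_config(image_size: int = 128, seed: int = 0, noise: bool = True,
               injection_speed: float = 1.0) -> PhantomConfig:
    """Default 123I-IMP phantom: sharp PA bolus, broad lung washout.

    Geometry is specified on the 128-pixel reference grid and scaled
    proportionally for other sizes (pixel pitch scales inversely, so the
    simulated chest keeps its physical size).
    """
    s = image_size / 128.0
    structures = [
        StructureSpec("PA", (52 * s, 58 * s), (6 * s, 5 * s),
                      t0=6.0, alpha=3.0, beta=0.8, peak=100.0),
        StructureSpec("lung_left", (62 * s, 36 * s), (26 * s, 15 * s),
                      t0=10.0, alpha=3.0, beta=3.0, peak=2.0),
        StructureSpec("lung_right", (62 * s, 92 * s), (26 * s, 15 * s),
                      t0=10.0, alpha=3.0, beta=3.0, peak=2.0),
    ]
    return PhantomConfig(
        image_size=(image_size, image_size),
        pixel_mm=REFERENCE_PIXEL_MM / s,
        n_frames=60,
        mode="IMP",
        structures=structures,
        noise=noise,
        injection_speed=injection_speed,
        seed=seed,
    )


def ecd_config(image_size: int = 128, seed: int = 0, noise: bool = True,
               injection_speed: float = 1.0) -> PhantomConfig:
    """Default 99mTc-ECD phantom: right-heart/PA early peak then AAo peak.

    The central blood pool ("right_heart") overlaps the AAo in projection,
    so an AAo-region TAC is double-peaked, as required by the IBUR
    analysis.  Lung retention of 99mTc-ECD is small and is omitted.
    """
    s = image_size / 128.0
    structures = [
        StructureSpec("right_heart", (58 * s, 67 * s), (18 * s, 10 * s),
                      t0=5.0, alpha=3.0, beta=1.0, peak=40.0),
        StructureSpec("PA", (52 * s, 56 * s), (6 * s, 5 * s),
                      t0=6.0, alpha=3.0, beta=1.0, peak=80.0),
        StructureSpec("AAo", (50 * s, 70 * s), (5 * s, 5 * s),
                      t0=15.0, alpha=3.0, beta=1.3, peak=100.0),
        StructureSpec("left_heart", (82 * s, 65 * s), (11 * s, 11 * s),
                      t0=14.5, alpha=3.0, beta=1.4, peak=45.0),
    ]
    return PhantomConfig(
        image_size=(image_size, image_size),
        pixel_mm=REFERENCE_PIXEL_MM / s,
        n_frames=100,
        mode="ECD",
        structures=structures,
        noise=noise,
        injection_speed=injection_speed,
        seed=seed,
    )


def default_config(mode: str, **kwargs) -> PhantomConfig:
    if mode == "IMP":
        return imp_config(**kwargs)
    if mode == "ECD":
        return ecd_config(**kwargs)
    raise ConfigError(f"unknown mode {mode!r}")


# --------------------------------------------------------------------------
# Truth serialization
# --------------------------------------------------------------------------


def save_truth(truth: PhantomTruth, path: str | Path) -> None:
    """Write ``<path>.npz`` (structure masks) and ``<path>.json``."""
    base = Path(path)
    if base.suffix in {".npz", ".json"}:
        base = base.with_suffix("")
    base.parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(base.with_suffix(".npz"),
                        **{k: v.astype(np.uint8) for k, v in truth.masks.items()})
    meta = {
        "params": truth.params,
        "centers": {k: list(v) for k, v in truth.centers.items()},
        "pixel_auc": truth.pixel_auc,
        "pa_center": list(truth.pa_center) if truth.pa_center else None,
        "aao_center": list(truth.aao_center) if truth.aao_center else None,
        "slow": truth.slow,
        "mode": truth.mode,
        "background": truth.background,
    }
    base.with_suffix(".json").write_text(json.dumps(meta, indent=2, sort_keys=True))


def load_truth(path: str | Path) -> PhantomTruth:
    base = Path(path)
    if base.suffix in {".npz", ".json"}:
        base = base.with_suffix("")
    if not base.with_suffix(".npz").exists() or not base.with_suffix(".json").exists():
        raise FormatError(f"missing truth container/sidecar at {base}")
    with np.load(base.with_suffix(".npz")) as data:
        masks = {k: data[k].astype(bool) for k in data.files}
    meta = json.loads(base.with_suffix(".json").read_text())
    return PhantomTruth(
        masks=masks,
        params=meta["params"],
        centers={k: tuple(v) for k, v in meta["centers"].items()},
        pixel_auc=meta["pixel_auc"],
        pa_center=tuple(meta["pa_center"]) if meta["pa_center"] else None,
        aao_center=tuple(meta["aao_center"]) if meta["aao_center"] else None,
        slow=bool(meta["slow"]),
        mode=meta["mode"],
        background=float(meta["background"]),
    )


# --------------------------------------------------------------------------
# Dataset generation
# --------------------------------------------------------------------------


@dataclass
class DatasetRanges:
    """Seeded per-case variation applied to the default geometry/kinetics.

    Jitters are expressed on the 128-pixel reference grid and scaled with
    the image size.
    """

    center_jitter_px: float = 2.0
    axes_jitter_frac: float = 0.08
    peak_jitter_frac: float = 0.2
    t0_jitter_s: float = 1.0
    beta_jitter_frac: float = 0.1
    slow_fraction: float = 0.0
    slow_speed: float = 3.0

    def validate(self) -> None:
        if not 0 <= self.slow_fraction <= 1:
            raise ConfigError("slow_fraction must be in [0, 1]")
        for name in ("center_jitter_px", "axes_jitter_frac", "peak_jitter_frac",
                     "t0_jitter_s", "beta_jitter_frac"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be nonnegative")
        if self.slow_speed <= 0:
            raise ConfigError("slow_speed must be positive")


def _jitter_config(base: PhantomConfig, ranges: DatasetRanges,
                   rng: np.random.Generator) -> PhantomConfig:
    s = base.image_size[0] / 128.0
    for _ in range(100):
        structures = []
        for st in base.structures:
            dr, dc = rng.uniform(-1, 1, 2) * ranges.center_jitter_px * s
            fa, fb = 1 + rng.uniform(-1, 1, 2) * ranges.axes_jitter_frac
            fp = 1 + rng.uniform(-1, 1) * ranges.peak_jitter_frac
            dt = rng.uniform(0, ranges.t0_jitter_s)  # one-sided: keeps ordering
            fbeta = 1 + rng.uniform(-1, 1) * ranges.beta_jitter_frac
            structures.append(replace(
                st,
                center=(st.center[0] + dr, st.center[1] + dc),
                axes=(st.axes[0] * fa, st.axes[1] * fb),
                peak=st.peak * fp,
                t0=st.t0 + dt,
                beta=st.beta * fbeta,
            ))
        cand = replace(base, structures=structures)
        try:
            _check_structures(cand)
        except ConfigError:
            continue
        return cand
    raise ConfigError("could not draw a valid jittered phantom configuration")


def make_dataset(
    n_cases: int,
    ranges: DatasetRanges | None = None,
    seed: int = 0,
    mode: str = "IMP",
    image_size: int = 128,
    noise: bool = True,
) -> list[tuple[DynamicSeries, PhantomTruth]]:
    """Generate ``n_cases`` independent phantoms with seeded variation.

    A ``ranges.slow_fraction`` of the cases (rounded to the nearest count)
    receive a slow injection (``injection_speed = ranges.slow_speed``) and
    carry ``slow=True`` in their truth metadata, mirroring acquisitions
    unsuitable for quantitative analysis.
    """
    if n_cases < 1:
        raise ConfigError("n_cases must be >= 1")
    if ranges is None:
        ranges = DatasetRanges()
    ranges.validate()
    rng = np.random.default_rng(seed)
    n_slow = int(round(ranges.slow_fraction * n_cases))
    slow_idx = set(rng.choice(n_cases, size=n_slow, replace=False).tolist())
    cases = []
    for i in range(n_cases):
        base = default_config(mode, image_size=image_size, noise=noise)
        cfg = _jitter_config(base, ranges, rng)
        cfg = replace(
            cfg,
            injection_speed=ranges.slow_speed if i in slow_idx else 1.0,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        cases.append(make_phantom(cfg))
    return cases
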