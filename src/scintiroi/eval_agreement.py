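"""Agreement between automatic and reference ROIs and AUCs.

Three complementary views, matching how automated ROI placement is
validated against a manual reference:

* **coincidence ratio** — fraction of cases whose automatic ROI center
  lies within a pixel tolerance box of the reference center (inclusive;
  PA default +/-2 px in x, +/-3.5 px in y; AAo default +/-4 px in both);
* **correlation/regression** — Pearson r and ordinary least squares of the
  reference AUC on the automatic AUC;
* **Bland-Altman** — per-case percent difference (denominator: pairwise
  mean), its mean and the mean +/- 1.96 SD limits of agreement.

Throughout, x is the column direction and y the row direction of the
(row, col) image convention.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnalysisError
from .roi_setter import ROISpec

#: Inclusive coincidence tolerances (tol_x, tol_y) in pixels per target.
DEFAULT_TOLERANCES = {"PA": (2.0, 3.5), "AAo": (4.0, 4.0)}


def coincidence(
    roi_auto: ROISpec | tuple[float, float],
    roi_ref: ROISpec | tuple[float, float],
    tol_x: float,
    tol_y: float,
) -> bool:
    """True iff |dx| <= tol_x and |dy| <= tol_y (inclusive)."""
    a = roi_auto.center if isinstance(roi_auto, ROISpec) else roi_auto
    r = roi_ref.center if isinstance(roi_ref, ROISpec) else roi_ref
    dx = a[1] - r[1]
    dy = a[0] - r[0]
    return abs(dx) <= tol_x and abs(dy) <= tol_y


def coincidence_ratio(
    cases: list[tuple],
    target: str = "PA",
    tol: tuple[float, float] | None = None,
) -> float:
    """Fraction of (auto, reference) center pairs within tolerance."""
    if not cases:
        raise AnalysisError("coincidence_ratio needs at least one case")
    if tol is None:
        tol = DEFAULT_TOLERANCES[target]
    flags = [coincidence(a, r, *tol) for a, r in cases]
    return float(np.mean(flags))


def correlate_aucs(pairs: list[tuple[float, float]]) -> tuple[float, float, float]:
    """Pearson r and OLS of reference (y) on automatic (x).

    Returns ``(r, slope, intercept)``.
    """
    if len(pairs) < 3:
        raise AnalysisError("correlation needs at least 3 pairs")
    x = np.asarray([p[0] for p in pairs], dtype=float)
    y = np.asarray([p[1] for p in pairs], dtype=float)
    if np.var(x) == 0 or np.var(y) == 0:
        raise AnalysisError("correlation undefined for zero-variance data")
    res = stats.linregress(x, y)
    return float(res.rvalue), float(res.slope), float(res.intercept)


@dataclass
class BlandAltman:
    mean_pct: float
    sd_pct: float
    loa_low: float
    loa_high: float
    diffs_pct: list[float] = field(default_factory=list)


def bland_altman(pairs: list[tuple[float, float]]) -> BlandAltman:
    """Bland-Altman agreement on percent differences.

    Percent difference per case = ``100 * (auto - ref) / mean(auto, ref)``.
    Cases with nonpositive pair mean are excluded with a warning.  Limits
    of agreement are mean +/- 1.96 SD (population SD).
    """
    diffs = []
    for a, r in pairs:
        m = (a + r) / 2.0
        if m <= 0:
            warnings.warn("excluding pair with nonpositive mean from Bland-Altman")
            continue
        diffs.append(100.0 * (a - r) / m)
    if not diffs:
        raise AnalysisError("no valid pairs for Bland-Altman")
    d = np.asarray(diffs)
    mean = float(d.mean())
    sd = float(d.std())
    return BlandAltman(mean, sd, mean - 1.96 * sd, mean + 1.96 * sd, diffs)


@dataclass
class AgreementReport:
    """Per-case and summary agreement between automatic and reference."""

    target: str
    dx: list[float]
    dy: list[float]
    flags: list[bool]
    coincidence_ratio: float
    pearson_r: float | None = None
    slope: float | None = None
    intercept: float | None = None
    bland: BlandAltman | None = None

    def to_dict(self) -> dict:
        out = {
            "target": self.target,
            "n_cases": len(self.dx),
            "dx_px": self.dx,
            "dy_px": self.dy,
            "coincidence_flags": self.flags,
            "coincidence_ratio": self.coincidence_ratio,
        }
        if self.pearson_r is not None:
            out.update(pearson_r=self.pearson_r, slope=self.slope,
                       intercept=self.intercept)
        if self.bland is not None:
            out["bland_altman"] = {
                "mean_pct": self.bland.mean_pct,
                "sd_pct": self.bland.sd_pct,
                "loa_low": self.bland.loa_low,
                "loa_high": self.bland.loa_high,
            }
        return out

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def per_case_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"dx_px": self.dx, "dy_px": self.dy, "coincident": self.flags}
        )

    def to_csv(self, path: str | Path) -> None:
        self.per_case_frame().to_csv(path, index_label="case")


def evaluate_cases(
    auto_centers: list[tuple[float, float]] | list[ROISpec],
    ref_centers: list[tuple[float, float]] | list[ROISpec],
    target: str = "PA",
    auto_aucs: list[float] | None = None,
    ref_aucs: list[float] | None = None,
    tol: tuple[float, float] | None = None,
) -> AgreementReport:
    """Full agreement report over a matched case list."""
    if len(auto_centers) != len(ref_centers):
        raise AnalysisError("auto and reference case lists differ in length")
    if tol is None:
        tol = DEFAULT_TOLERANCES[target]
    a = [c.center if isinstance(c, ROISpec) else c for c in auto_centers]
    r = [c.center if isinstance(c, ROISpec) else c for c in ref_centers]
    dx = [ai[1] - ri[1] for ai, ri in zip(a, r)]
    dy = [ai[0] - ri[0] for ai, ri in zip(a, r)]
    flags = [coincidence(ai, ri, *tol) for ai, ri in zip(a, r)]
    report = AgreementReport(
        target=target, dx=dx, dy=dy, flags=flags,
        coincidence_ratio=float(np.mean(flags)),
    )
    if auto_aucs is not None and ref_aucs is not None:
        pairs = list(zip(auto_aucs, ref_aucs))
        if len(pairs) >= 3:
            report.pearson_r, report.slope, report.intercept = correlate_aucs(pairs)
        report.bland = bland_altman(pairs)
    return report


def scatter_plot(pairs, path: str | Path, xlabel="automatic AUC",
                 ylabel="reference AUC") -> None:
    """Scatter of reference vs automatic AUC with the OLS line."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.asarray([p[0] for p in pairs], float)
    y = np.asarray([p[1] for p in pairs], float)
    r, slope, intercept = correlate_aucs(list(pairs))
    fig, ax = plt.subplots()
    ax.scatter(x, y, s=18)
    xs = np.linspace(x.min(), x.max(), 50)
    ax.plot(xs, slope * xs + intercept, "k-",
            label=f"y={slope:.2f}x{intercept:+.1f}, r={r:.2f}")
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    ax.legend()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def bland_altman_plot(pairs, path: str | Path) -> None:
    """Percent-difference Bland-Altman plot with limits of agreement."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ba = bland_altman(list(pairs))
    means = [(a + r) / 2 for a, r in pairs if (a + r) / 2 > 0]
    fig, ax = plt.subplots()
    ax.scatter(means, ba.diffs_pct, s=18)
    for y, style in ((ba.mean_pct, "k-"), (ba.loa_low, "k--"), (ba.loa_high, "k--")):
        ax.axhline(y, ls=style[1:], c="k")
    ax.set_xlabel("pair mean")
    ax.set_ylabel("percent difference (auto - ref)")
    fig.savefig(path, dpi=120)
    plt.close(fig)
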