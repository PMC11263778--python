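# scintiroi

Automated region-of-interest (ROI) setting for the input functions of
noninvasive brain-perfusion SPECT quantification, from dynamic planar chest
RI-angiography.

## The problem

Quantitative regional cerebral blood flow by the SIMS method (¹²³I-IMP) and
the IBUR method (⁹⁹ᵐTc-ECD) needs an *input function*: the administered-dose
count term obtained from the time–activity curve (TAC) of a vascular ROI on
a dynamic chest acquisition (1 frame/s) — the **pulmonary artery (PA)** for
SIMS and the **ascending aorta (AAo)** for IBUR. Placing these small ROIs by
hand is the accuracy bottleneck; this package automates it:

1. **Standardize** the series to the reference 2.21 mm/pixel grid
   (bilinear, count-preserving).
2. **Phase image** — detect the vascular peak frame on the whole-image
   count curve (first prominent peak for PA, second for AAo) and sum
   frames `[peak−2, peak+2]`.
3. **Segment** — a U-Net (depth 5, 13 convolutional layers, batch norm +
   ReLU on all but the last, squared-error loss, Adam α=0.001) maps the
   normalized phase image to a candidate-region score map.
4. **ROI** — P-tile binarization (top-P pixels by score, area prior 60 px),
   centroid of the foreground, and a fixed circular ROI of radius 3 px
   (6.6 mm) placed so it never extends beyond the candidate region.
5. **Quantify** — extract the ROI TAC, classify its morphology
   (single-peak required for PA/SIMS, double-peak with the second peak
   integrated for AAo/IBUR; slow-injection boluses are rejected as
   unsuitable), and integrate the area under the curve (AUC):

   AUC = Σₜ∈window TAC(t)·Δt,  window = frames where the target peak
   exceeds f·peak (f = 0.05), bounded by the surrounding minima.

Training pairs are expanded 64-fold (mirror × four rotations × 10-pixel
translations; 256 cases → 16 384 images, or 63-fold without the originals:
108 cases → 6 804), and models are validated by six-fold cross-validation
splits.

No clinical data ship with the package. A synthetic phantom generator
(`scintiroi.phantom_sim`) emulates the first-pass bolus (gamma-variate
kinetics per structure, Poisson counting noise, variable pixel pitch and
injection speed) with full ground truth, so every stage is testable and
the agreement suite (coincidence ratio at pixel tolerances, Pearson/OLS
regression, Bland–Altman limits of agreement) runs end to end.

## Worked example

Simulate one IMP acquisition and analyze it with the ground-truth mask as
the candidate region (`oracle_segmentation=True` exercises every
deterministic stage without a trained network):

```python
import scintiroi as sr
from scintiroi.cli import run_case

series, truth = sr.make_phantom(sr.imp_config(seed=0, noise=True))
result = run_case(series, truth=truth, oracle_segmentation=True)
```

Output of the accompanying print statements:

```
mode: IMP frames: 60 pixel: 2.21 mm
peak frame: 8
ROI: {"target": "PA", "center_row": 52.0, "center_col": 58.0,
      "radius_px": 3.0, "radius_mm": 6.6, "containment": 1.0}
peak class: single window: [7, 13]
SIMS input-function counts (PA AUC): 10343
true PA center: (52.0, 58.0) analytic ROI AUC: 10355
```

The detected peak frame (8) brackets the true PA bolus peak (8.4 s); the
ROI lands exactly on the true PA centroid with the full circle contained
in the vessel; the TAC is single-peaked as SIMS requires; and the
integrated counts agree with the analytic gamma-variate integral to 0.1 %
despite Poisson noise.

The same flow is available from the shell:

```bash
scintiroi simulate --mode IMP --n-cases 20 --out data/
scintiroi train    --data data/ --target PA --width 8 --epochs 40 --out model
scintiroi run      --series data/case_000 --model model --out runs/
scintiroi evaluate --runs runs/ --truths data/ --target PA --out agree.json
```

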