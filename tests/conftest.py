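"""Shared fixtures: noiseless reference phantoms and one desk-scale
training run reused across the network tests and the acceptance suite."""

from __future__ import annotations

import numpy as np
import pytest

import scintiroi as sr
from scintiroi.unet_seg import (
    TrainConfig,
    UNetSpec,
    build_model,
    make_phase_label_pairs,
    predict_candidate,
    train,
)
from scintiroi.roi_setter import centroid, ptile_fraction_for_area, ptile_threshold

# Desk-scale study conditions: 70 phantoms on the native 128-px grid
# (50 train / 20 held out), reduced-width network, 40 epochs, 60-px
# candidate-region area prior.
DESK_IMAGE_SIZE = 128
DESK_N_TRAIN = 50
DESK_N_HELDOUT = 20
DESK_WIDTH = 8
DESK_EPOCHS = 40
DESK_PTILE_AREA = 60
DESK_DATA_SEED = 42
DESK_MODEL_SEED = 7
DESK_TRAIN_SEED = 1


@pytest.fixture(scope="session")
def imp_noiseless():
    return sr.make_phantom(sr.imp_config(noise=False))


@pytest.fixture(scope="session")
def ecd_noiseless():
    return sr.make_phantom(sr.ecd_config(noise=False))


@pytest.fixture(scope="session")
def desk_training():
    """Train the reduced-width U-Net once on desk-scale IMP phantoms and
    evaluate it on held-out cases; shared by network and acceptance tests."""
    cases = sr.make_dataset(
        DESK_N_TRAIN + DESK_N_HELDOUT,
        seed=DESK_DATA_SEED,
        mode="IMP",
        image_size=DESK_IMAGE_SIZE,
        noise=True,
    )
    pairs, _ = make_phase_label_pairs(cases, target="PA")
    assert len(pairs) == DESK_N_TRAIN + DESK_N_HELDOUT
    model = build_model(UNetSpec(base_width=DESK_WIDTH), seed=DESK_MODEL_SEED)
    model, losses = train(
        model,
        pairs[:DESK_N_TRAIN],
        TrainConfig(iterations=DESK_EPOCHS, batch_size=8, seed=DESK_TRAIN_SEED),
    )
    heldout = []
    for (img, label), (series, truth) in zip(
        pairs[DESK_N_TRAIN:], cases[DESK_N_TRAIN:]
    ):
        phase = sr.PhaseImage(image=img, peak_frame=0, window=(2, 2),
                              target="PA", normalized=True)
        cand = predict_candidate(model, phase)
        mask = ptile_threshold(
            cand.score_map,
            ptile_fraction_for_area(DESK_PTILE_AREA, cand.score_map.size),
        )
        c = centroid(mask)
        tc = truth.centers["PA"]
        err = float(np.hypot(c[0] - tc[0], c[1] - tc[1]))
        pa = truth.masks["PA"]
        dice = 2 * (mask & pa).sum() / (mask.sum() + pa.sum())
        heldout.append(
            {"series": series, "truth": truth, "cand": cand, "mask": mask,
             "centroid_err_px": err, "dice": float(dice)}
        )
    return {"model": model, "losses": losses, "heldout": heldout,
            "cases": cases}
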