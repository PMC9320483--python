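"""Reference desk-scale experiments, each fully seeded.

These bundle the package's stages into the two canonical study designs:

* :func:`bd_vs_sk_experiment` — generate separate synthetic training and
  test cohorts, train the small-preset network on 256 px tiles, calibrate
  the operating point on the training cohort, and report the section-level
  BD-vs-SK ROC AUC on the held-out cohort.
* :func:`calibration_recovery_trial` — a model-free probe of the
  minimum-area line search: heat maps are built from ground truth, with
  small high-probability noise speckles planted on negative sections and
  true-size lesions on positives; the selected minimum area should land
  strictly between the two planted scales.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .calibration import select_min_area
from .decision import SectionHeatMap
from .model import NetworkConfig, TrainingConfig, build_network, train
from .pipeline import (
    build_tile_dataset,
    calibrate_cohort,
    evaluate_cohort,
    predict_cohort,
)
from .synthetic import StyleParams, generate_cohort
from .tissue import TilingConfig

__all__ = ["BdVsSkResult", "bd_vs_sk_experiment", "calibration_recovery_trial"]

DESK_TILING = TilingConfig(tile_size_um=256.0, min_overlap_um=75.0, mpp=1.0)
DESK_MIN_SECTION_MM2 = 0.005


@dataclass
class BdVsSkResult:
    auc: float
    sensitivity: float
    specificity: float
    n_test_sections: int
    best_val_iou: float


def bd_vs_sk_experiment(seed: int, workdir: str | Path,
                        n_train: int = 30, n_test: int = 20,
                        separability: float = 0.9,
                        epochs: int = 8) -> BdVsSkResult:
    """Train, calibrate and evaluate the BD-vs-SK call end to end.

    Cohorts use an equal BD/SK mix; the test cohort is generated from an
    independent seed stream and never touches training or calibration.
    """
    workdir = Path(workdir)
    mix = {"BD": 0.5, "SK": 0.5}
    m_train = generate_cohort(n_train, mix, StyleParams(), seed=seed * 2 + 1,
                              outdir=workdir / "train",
                              separability=separability, split_label="train")
    m_test = generate_cohort(n_test, mix, StyleParams(), seed=seed * 2 + 2,
                             outdir=workdir / "test",
                             separability=separability, split_label="test")
    dataset = build_tile_dataset(m_train, DESK_TILING, DESK_MIN_SECTION_MM2)
    net = build_network(NetworkConfig(input_side=DESK_TILING.tile_px,
                                      preset="small", seed=seed))
    state, history = train(dataset, net,
                           TrainingConfig(learning_rate=1e-3, epochs=epochs,
                                          batch_size=8, seed=seed))
    net = state.make_network()
    pred_train = predict_cohort(net, m_train, DESK_TILING, DESK_MIN_SECTION_MM2)
    params, _ = calibrate_cohort(pred_train)
    pred_test = predict_cohort(net, m_test, DESK_TILING, DESK_MIN_SECTION_MM2)
    row = evaluate_cohort(pred_test, params, ["BD vs SK"]).iloc[0]
    return BdVsSkResult(auc=float(row["auc"]),
                        sensitivity=float(row["sensitivity"]),
                        specificity=float(row["specificity"]),
                        n_test_sections=len(pred_test),
                        best_val_iou=float(max(history.val_iou)))


def calibration_recovery_trial(seed: int, n_pos: int = 8, n_neg: int = 8,
                               speckle_mm2: tuple[float, float] = (0.0015, 0.0045),
                               lesion_mm2: tuple[float, float] = (0.055, 0.09),
                               ) -> tuple[float, float, float]:
    """One seeded minimum-area recovery probe.

    Returns ``(selected_area, max_planted_speckle, min_planted_lesion)``
    in mm^2; recovery succeeds when the selection lies strictly between
    the planted scales.
    """
    rng = np.random.default_rng(seed)
    side = 48  # output pixels at 8 um/px
    maps: list[SectionHeatMap] = []
    truths = []
    max_speckle, min_lesion = 0.0, np.inf
    for i in range(n_pos + n_neg):
        probs = rng.uniform(0.0, 0.25, size=(2, side, side)).astype(np.float32)
        positive = i < n_pos
        area = rng.uniform(*(lesion_mm2 if positive else speckle_mm2))
        n_px = int(round(area * 1e6 / 64.0))
        r = int(np.ceil(np.sqrt(n_px / np.pi)))
        cy, cx = rng.integers(r + 1, side - r - 1, size=2)
        yy, xx = np.mgrid[0:side, 0:side]
        disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
        idx = np.flatnonzero(disc.ravel())[:n_px]
        # constant plateau: only the positive-area scale separates the
        # classes, not the order statistics of the probability values
        probs[0].ravel()[idx] = 0.9
        actual = idx.size * 64.0 / 1e6
        if positive:
            min_lesion = min(min_lesion, actual)
        else:
            max_speckle = max(max_speckle, actual)
        maps.append(SectionHeatMap(probs=probs, section_id=i,
                                   bbox=(0, 0, side * 8, side * 8), mpp_out=8.0))
        truths.append(positive)
    selected, _ = select_min_area(maps, np.array(truths), channel=0)
    return selected, max_speckle, float(min_lesion)
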