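"""Operating-point calibration and evaluation statistics.

The two hyper-parameters of each section-level call — the minimum
positive area and the probability threshold — are selected by line
search: the minimum area maximises the ROC AUC of the per-section score
(smallest area on ties), then the threshold maximises the F-beta score

    F_beta = (1 + beta^2) * recall * precision / (recall + beta^2 * precision)

with beta = 2 for the BD call (sensitivity weighted) and beta = 1 for SK.

The continuous per-section score feeding the ROC sweep is the largest
probability threshold at which the positive area still reaches the
minimum area; sweeping a threshold over these scores reproduces exactly
the per-threshold binary calls, which makes "ROC over all thresholds"
well-defined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn import metrics as skmetrics

from .core import mm2_to_pixels
from .decision import SectionHeatMap, postprocess

__all__ = [
    "ConfusionCounts",
    "RocCurve",
    "CalibrationResult",
    "tpr_fpr",
    "fbeta",
    "section_score",
    "roc_auc",
    "select_min_area",
    "select_threshold",
    "calibrate_call",
    "evaluate_calls",
    "CALL_SPECS",
    "default_area_grid",
    "default_threshold_grid",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class RocCurve:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


@dataclass
class CalibrationResult:
    call: str
    min_area_mm2: float
    threshold: float
    auc: float
    fbeta: float
    beta: float


def tpr_fpr(c: ConfusionCounts) -> tuple[float, float]:
    """TPR = TP/(TP+FN) (= sensitivity), FPR = FP/(FP+TN) (= 1-specificity)."""
    if c.tp + c.fn == 0 or c.fp + c.tn == 0:
        raise ValueError("both classes must be present")
    return c.tp / (c.tp + c.fn), c.fp / (c.fp + c.tn)


def fbeta(precision: float, recall: float, beta: float) -> float:
    """Weighted harmonic mean of precision and recall; 0 at (0, 0)."""
    if not (0 <= precision <= 1 and 0 <= recall <= 1):
        raise ValueError("precision and recall must lie in [0, 1]")
    denom = recall + beta * beta * precision
    if denom == 0:
        return 0.0
    return (1 + beta * beta) * recall * precision / denom


def section_score(hmap: SectionHeatMap, min_area_mm2: float, channel: int,
                  postprocessed: bool = True, disc_radius: int = 2) -> float:
    """Largest threshold t at which the channel's area >= the minimum area.

    Equals the k-th largest probability with k = ceil(min area in output
    pixels); 0 when the map cannot reach the area at any threshold > 0.
    """
    pp = hmap if postprocessed else postprocess(hmap, disc_radius=disc_radius)
    vals = pp.probs[channel].ravel()
    k = int(np.ceil(mm2_to_pixels(min_area_mm2, pp.mpp_out)))
    k = max(k, 1)
    if k > vals.size:
        return 0.0
    return float(np.partition(vals, vals.size - k)[vals.size - k])


def roc_auc(scores: np.ndarray, truths: np.ndarray) -> RocCurve:
    """ROC curve + trapezoidal AUC (equals tie-corrected concordance)."""
    truths = np.asarray(truths, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    if truths.all() or not truths.any():
        raise ValueError("both classes must be present")
    fpr, tpr, thr = skmetrics.roc_curve(truths, scores)
    return RocCurve(thresholds=thr, tpr=tpr, fpr=fpr,
                    auc=float(skmetrics.roc_auc_score(truths, scores)))


def default_area_grid() -> np.ndarray:
    """20 log-spaced candidate minimum areas in [0.001, 0.1] mm^2."""
    return np.logspace(np.log10(0.001), np.log10(0.1), 20)


def default_threshold_grid() -> np.ndarray:
    """Probability grid 0.05 .. 0.95 in 0.05 steps."""
    return np.round(np.arange(0.05, 1.0, 0.05), 10)


def select_min_area(heatmaps: list[SectionHeatMap], truths: np.ndarray,
                    channel: int,
                    candidate_areas_mm2: np.ndarray | None = None,
                    ) -> tuple[float, float]:
    """Line search: the smallest candidate area maximising the AUC of the
    per-section scores. Returns (area, auc)."""
    areas = np.sort(np.asarray(
        default_area_grid() if candidate_areas_mm2 is None else candidate_areas_mm2,
        dtype=float))
    if areas.size == 0:
        raise ValueError("need at least one candidate area")
    best_area, best_auc = float(areas[0]), -1.0
    for a in areas:
        scores = np.array([section_score(h, a, channel) for h in heatmaps])
        auc = roc_auc(scores, truths).auc
        if auc > best_auc:  # strict: ties keep the smaller area
            best_area, best_auc = float(a), auc
    return best_area, best_auc


def select_threshold(heatmaps: list[SectionHeatMap], truths: np.ndarray,
                     channel: int, min_area_mm2: float, beta: float,
                     grid: np.ndarray | None = None) -> tuple[float, float]:
    """Line search: the threshold maximising F-beta of the section calls
    at the fixed minimum area (largest threshold on ties)."""
    grid = default_threshold_grid() if grid is None else np.asarray(grid, dtype=float)
    scores = np.array([section_score(h, min_area_mm2, channel) for h in heatmaps])
    truths = np.asarray(truths, dtype=bool)
    best_t, best_f = float(grid[0]), -1.0
    for t in np.sort(grid):
        calls = scores >= t
        tp = int(np.count_nonzero(calls & truths))
        fp = int(np.count_nonzero(calls & ~truths))
        fn = int(np.count_nonzero(~calls & truths))
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        f = fbeta(precision, recall, beta)
        if f >= best_f:  # >=: ties keep the larger threshold
            best_t, best_f = float(t), f
    return best_t, best_f


def calibrate_call(heatmaps: list[SectionHeatMap], truths: np.ndarray,
                   channel: int, beta: float, call_name: str,
                   candidate_areas_mm2: np.ndarray | None = None,
                   threshold_grid: np.ndarray | None = None) -> CalibrationResult:
    """Full per-call calibration: minimum area by AUC, then threshold by
    F-beta, mirroring the two-stage line search."""
    area, auc = select_min_area(heatmaps, truths, channel, candidate_areas_mm2)
    thr, f = select_threshold(heatmaps, truths, channel, area, beta, threshold_grid)
    return CalibrationResult(call=call_name, min_area_mm2=area, threshold=thr,
                             auc=auc, fbeta=f, beta=beta)


# call spec -> (positive truth test, subset truth test) over section truth
# labels in {"BD", "SK", "SK_with_BD_focus", "Normal"}. SK_with_BD_focus
# counts as SK ground truth (irritated SK is truth-benign).
CALL_SPECS: dict[str, tuple] = {
    "BD vs all": (lambda t: t == "BD", lambda t: True),
    "BD vs SK": (lambda t: t == "BD",
                 lambda t: t in ("BD", "SK", "SK_with_BD_focus")),
    "BD vs SK (non-irrit.)": (lambda t: t == "BD", lambda t: t in ("BD", "SK")),
    "BD vs SK (irrit.)": (lambda t: t == "BD",
                          lambda t: t in ("BD", "SK_with_BD_focus")),
    "BD vs Normal": (lambda t: t == "BD", lambda t: t in ("BD", "Normal")),
    "SK vs Normal": (lambda t: t in ("SK", "SK_with_BD_focus"),
                     lambda t: t != "BD"),
}


def evaluate_calls(pred_positive: np.ndarray, truth_labels: list[str],
                   call_spec: str,
                   scores: np.ndarray | None = None) -> dict[str, float]:
    """Sensitivity/specificity (and AUC when scores are given) for one
    call on its truth subset (e.g. "BD vs SK" drops Normal sections)."""
    if call_spec not in CALL_SPECS:
        raise ValueError(f"unknown call spec {call_spec!r}")
    pos_fn, subset_fn = CALL_SPECS[call_spec]
    keep = np.array([subset_fn(t) for t in truth_labels], dtype=bool)
    if not keep.any():
        raise ValueError("empty evaluation subset")
    truth = np.array([pos_fn(t) for t in truth_labels], dtype=bool)[keep]
    pred = np.asarray(pred_positive, dtype=bool)[keep]
    c = ConfusionCounts(
        tp=int(np.count_nonzero(pred & truth)),
        fp=int(np.count_nonzero(pred & ~truth)),
        tn=int(np.count_nonzero(~pred & ~truth)),
        fn=int(np.count_nonzero(~pred & truth)))
    tpr, fpr = tpr_fpr(c)
    out = {"call": call_spec, "sensitivity": tpr, "specificity": 1.0 - fpr,
           "tp": c.tp, "fp": c.fp, "tn": c.tn, "fn": c.fn}
    if scores is not None:
        out["auc"] = roc_auc(np.asarray(scores, dtype=float)[keep], truth).auc
    return out
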