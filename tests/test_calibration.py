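import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from skinseg.calibration import (
    ConfusionCounts,
    evaluate_calls,
    fbeta,
    roc_auc,
    section_score,
    select_min_area,
    select_threshold,
    tpr_fpr,
)
from skinseg.decision import SectionHeatMap


def _map(probs, mpp_out=8.0):
    probs = np.atleast_3d(probs)
    if probs.shape[0] != 2:
        probs = np.stack([probs[..., 0], np.zeros_like(probs[..., 0])])
    return SectionHeatMap(probs=probs.astype(np.float32), section_id=0,
                          bbox=(0, 0, probs.shape[1] * 8, probs.shape[2] * 8),
                          mpp_out=mpp_out)


def concordance_auc(scores, truths):
    """O(n^2) pairwise concordance oracle with half credit for ties."""
    pos = [s for s, t in zip(scores, truths) if t]
    neg = [s for s, t in zip(scores, truths) if not t]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else 0.5 if p == n else 0.0
    return total / (len(pos) * len(neg))


class TestTprFpr:
    def test_hand_confusion_table(self):
        assert tpr_fpr(ConfusionCounts(tp=3, fp=0, tn=5, fn=1)) == (0.75, 0.0)

    def test_perfect_classifier(self):
        assert tpr_fpr(ConfusionCounts(tp=4, fp=0, tn=6, fn=0)) == (1.0, 0.0)

    def test_sensitivity_specificity_duality(self):
        c = ConfusionCounts(tp=8, fp=3, tn=7, fn=2)
        tpr, fpr = tpr_fpr(c)
        sens = c.tp / (c.tp + c.fn)
        spec = c.tn / (c.tn + c.fp)
        assert tpr == pytest.approx(sens)
        assert 1 - fpr == pytest.approx(spec)

    def test_missing_class_rejected(self):
        with pytest.raises(ValueError):
            tpr_fpr(ConfusionCounts(tp=0, fp=1, tn=3, fn=0))


class TestFbeta:
    @given(x=st.floats(0.01, 1.0), beta=st.floats(0.1, 10.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_fixed_point_when_precision_equals_recall(self, x, beta):
        assert fbeta(x, x, beta) == pytest.approx(x, rel=1e-9)

    def test_hand_value_beta2(self):
        # (1+4)*1*0.5 / (1 + 4*0.5) = 0.8333...
        assert fbeta(0.5, 1.0, 2.0) == pytest.approx(5 * 0.5 / 3, rel=1e-9)

    def test_f1_symmetric(self):
        assert fbeta(0.3, 0.9, 1.0) == pytest.approx(fbeta(0.9, 0.3, 1.0))

    def test_zero_zero_defined_as_zero(self):
        assert fbeta(0.0, 0.0, 2.0) == 0.0

    @given(p=st.floats(0.05, 1.0), r=st.floats(0.05, 1.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_approaches_recall_as_beta_grows(self, p, r):
        assert fbeta(p, r, 100.0) == pytest.approx(r, abs=1e-3)

    @given(p1=st.floats(0.1, 0.9), p2=st.floats(0.1, 0.9),
           r=st.floats(0.1, 0.9), beta=st.floats(0.2, 5.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_in_precision(self, p1, p2, r, beta):
        lo, hi = sorted((p1, p2))
        assert fbeta(lo, r, beta) <= fbeta(hi, r, beta) + 1e-12


class TestSectionScore:
    def test_empty_map_scores_zero(self):
        assert section_score(_map(np.zeros((2, 8, 8))), 0.001, 0) == 0.0

    def test_constant_map_scores_its_value(self):
        # 8x8 output px at 8 um = 0.004096 mm^2 total; ask for half of it
        hm = _map(np.full((2, 8, 8), 0.7))
        assert section_score(hm, 0.002, 0) == pytest.approx(0.7)

    def test_score_monotone_in_added_mass(self):
        p = np.zeros((2, 8, 8))
        p[0, :2] = 0.5
        lo = section_score(_map(p.copy()), 0.001, 0)
        p[0, 2:4] = 0.8
        hi = section_score(_map(p), 0.001, 0)
        assert hi >= lo

    def test_min_area_beyond_map_scores_zero(self):
        hm = _map(np.full((2, 4, 4), 0.9))
        assert section_score(hm, 1.0, 0) == 0.0


class TestRocAuc:
    def test_perfect_separation(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        truths = np.array([True, True, False, False])
        assert roc_auc(scores, truths).auc == 1.0

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(0)
        scores = rng.random(4000)
        truths = rng.random(4000) > 0.5
        assert roc_auc(scores, truths).auc == pytest.approx(0.5, abs=0.05)

    @given(seed=st.integers(0, 500))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_trapezoid_equals_concordance_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 100))
        # quantised scores force ties to exercise the tie-handling
        scores = np.round(rng.random(n), 1)
        truths = rng.random(n) > 0.4
        if truths.all() or not truths.any():
            return
        assert roc_auc(scores, truths).auc == pytest.approx(
            concordance_auc(scores, truths), abs=1e-12)

    def test_curve_monotone(self):
        rng = np.random.default_rng(1)
        curve = roc_auc(rng.random(200), rng.random(200) > 0.5)
        # sklearn orders thresholds descending: TPR/FPR non-decreasing there,
        # i.e. non-increasing in increasing threshold
        assert np.all(np.diff(curve.tpr) >= 0)
        assert np.all(np.diff(curve.fpr) >= 0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.array([0.1, 0.2]), np.array([True, True]))


def _speckle_and_lesion_maps(rng, n_pos=8, n_neg=8,
                             speckle_mm2=(0.0015, 0.0045),
                             lesion_mm2=(0.055, 0.09)):
    """Ground-truth-corrupted heat maps: negatives carry sub-delta noise
    speckles, positives carry real-size lesions. Returns maps, truths and
    the planted scales (max speckle, min lesion) in mm^2."""
    maps, truths = [], []
    planted_speckle, planted_lesion = 0.0, np.inf
    side = 48  # output px; 48*8 um = 384 um
    for i in range(n_pos + n_neg):
        probs = np.zeros((2, side, side), dtype=np.float32)
        probs += rng.uniform(0.0, 0.25, size=probs.shape).astype(np.float32)
        positive = i < n_pos
        area = rng.uniform(*(lesion_mm2 if positive else speckle_mm2))
        n_px = int(round(area * 1e6 / 64.0))
        r = int(np.ceil(np.sqrt(n_px / np.pi)))
        cy, cx = rng.integers(r + 1, side - r - 1, size=2)
        yy, xx = np.mgrid[0:side, 0:side]
        disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
        idx = np.flatnonzero(disc.ravel())[:n_px]
        probs[0].ravel()[idx] = 0.9  # constant plateau; see experiments module
        actual = idx.size * 64.0 / 1e6
        if positive:
            planted_lesion = min(planted_lesion, actual)
        else:
            planted_speckle = max(planted_speckle, actual)
        maps.append(_map(probs))
        truths.append(positive)
    return maps, np.array(truths), planted_speckle, planted_lesion


class TestSelection:
    def test_single_candidate_returned(self):
        rng = np.random.default_rng(0)
        maps, truths, _, _ = _speckle_and_lesion_maps(rng)
        area, auc = select_min_area(maps, truths, 0, np.array([0.02]))
        assert area == 0.02

    def test_tie_prefers_smaller_area(self):
        rng = np.random.default_rng(1)
        maps, truths, _, _ = _speckle_and_lesion_maps(rng)
        # both candidates separate perfectly -> tie -> smaller one
        area, auc = select_min_area(maps, truths, 0, np.array([0.01, 0.02]))
        assert auc == 1.0 and area == 0.01

    def test_selected_area_separates_planted_scales(self):
        rng = np.random.default_rng(2)
        maps, truths, speckle, lesion = _speckle_and_lesion_maps(rng)
        area, _ = select_min_area(maps, truths, 0)
        assert speckle < area < lesion

    def test_threshold_argmax_contract(self):
        rng = np.random.default_rng(3)
        maps, truths, _, _ = _speckle_and_lesion_maps(rng)
        grid = np.round(np.arange(0.05, 1.0, 0.05), 10)
        t, f = select_threshold(maps, truths, 0, 0.02, beta=2.0, grid=grid)
        from skinseg.calibration import fbeta as fb

        scores = np.array([section_score(h, 0.02, 0) for h in maps])
        for g in grid:
            calls = scores >= g
            tp = int(np.count_nonzero(calls & truths))
            fp = int(np.count_nonzero(calls & ~truths))
            fn = int(np.count_nonzero(~calls & truths))
            p = tp / (tp + fp) if tp + fp else 0.0
            r = tp / (tp + fn) if tp + fn else 0.0
            assert f >= fb(p, r, 2.0) - 1e-12

    def test_degenerate_grid_tie_takes_largest(self):
        # maps where every threshold yields identical (all-positive) calls
        maps = [_map(np.full((2, 16, 16), 1.0)) for _ in range(4)]
        truths = np.array([True, True, False, False])
        t, _ = select_threshold(maps, truths, 0, 0.001, beta=1.0,
                                grid=np.array([0.2, 0.5, 0.8]))
        assert t == 0.8

    def test_beta2_threshold_not_above_beta1(self):
        rng = np.random.default_rng(4)
        maps, truths, _, _ = _speckle_and_lesion_maps(rng, n_pos=10, n_neg=10)
        # corrupt some positives so precision/recall actually trade off
        for h in maps[:3]:
            h.probs[0] *= 0.3
        t2, _ = select_threshold(maps, truths, 0, 0.02, beta=2.0)
        t1, _ = select_threshold(maps, truths, 0, 0.02, beta=1.0)
        assert t2 <= t1 + 1e-9


class TestEvaluateCalls:
    TRUTH = ["BD", "BD", "SK", "SK_with_BD_focus", "Normal", "Normal"]

    def test_perfect_calls(self):
        pred = np.array([True, True, False, False, False, False])
        row = evaluate_calls(pred, self.TRUTH, "BD vs all")
        assert row["sensitivity"] == 1.0 and row["specificity"] == 1.0

    def test_bd_vs_all_and_bd_vs_sk_share_sensitivity(self):
        pred = np.array([True, False, False, True, False, False])
        a = evaluate_calls(pred, self.TRUTH, "BD vs all")
        b = evaluate_calls(pred, self.TRUTH, "BD vs SK")
        assert a["sensitivity"] == b["sensitivity"] == 0.5

    def test_hand_computed_confusion(self):
        truth = ["BD"] * 4 + ["SK"] * 6
        pred = np.array([True, True, True, False,
                         True, False, False, False, False, False])
        row = evaluate_calls(pred, truth, "BD vs SK")
        assert row["tp"] == 3 and row["fn"] == 1
        assert row["fp"] == 1 and row["tn"] == 5
        assert row["sensitivity"] == pytest.approx(0.75)
        assert row["specificity"] == pytest.approx(5 / 6)

    def test_subset_filtering_excludes_normals(self):
        pred = np.array([True, True, False, False, True, True])
        row = evaluate_calls(pred, self.TRUTH, "BD vs SK")
        # the two Normal sections (predicted positive) are excluded
        assert row["tp"] + row["fp"] + row["tn"] + row["fn"] == 4
        assert row["specificity"] == 1.0

    def test_unknown_call_spec_rejected(self):
        with pytest.raises(ValueError):
            evaluate_calls(np.array([True]), ["BD"], "BD vs Mars")
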