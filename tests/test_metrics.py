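"""Counting/segmentation metrics against independent straight-loop oracles
and hand-computed worked examples."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import leafcount as lc
from leafcount.errors import ValidationError


# --- independent brute-force implementations (plain loops, no numpy math) ---

def bf_dic(pred, gt):
    return sum(p - g for p, g in zip(pred, gt)) / len(pred)


def bf_abs_dic(pred, gt):
    return sum(abs(p - g) for p, g in zip(pred, gt)) / len(pred)


def bf_mse(pred, gt):
    return sum((p - g) ** 2 for p, g in zip(pred, gt)) / len(pred)


def bf_r2(pred, gt):
    mean = sum(gt) / len(gt)
    ss_tot = sum((g - mean) ** 2 for g in gt)
    ss_res = sum((g - p) ** 2 for p, g in zip(pred, gt))
    return 1 - ss_res / ss_tot


def bf_agreement(pred, gt):
    return 100.0 * sum(1 for p, g in zip(pred, gt) if p == g) / len(pred)


def bf_mask_metrics(pm, gm):
    tp = fp = fn = tn = 0
    for p, g in zip(pm.ravel().tolist(), gm.ravel().tolist()):
        if p and g:
            tp += 1
        elif p:
            fp += 1
        elif g:
            fn += 1
        else:
            tn += 1
    acc = (tp + tn) / (tp + fp + fn + tn)
    iou = 1.0 if tp + fp + fn == 0 else tp / (tp + fp + fn)
    dce = 1.0 if 2 * tp + fp + fn == 0 else 2 * tp / (2 * tp + fp + fn)
    return acc, iou, dce


PRED, GT = [3, 5, 4], [3, 4, 6]


class TestWorkedExamples:
    """Hand-arithmetic examples, asserted as exact fractions."""

    def test_dic(self):
        assert lc.dic(PRED, GT) == pytest.approx(float(Fraction(-1, 3)), abs=1e-12)
        assert lc.dic(PRED, PRED) == 0.0
        assert lc.dic(PRED, GT) == -lc.dic(GT, PRED)

    def test_abs_dic(self):
        assert lc.abs_dic(PRED, GT) == pytest.approx(1.0, abs=1e-12)
        assert lc.abs_dic(PRED, PRED) == 0.0

    def test_mse(self):
        assert lc.mse_count(PRED, GT) == pytest.approx(float(Fraction(5, 3)), abs=1e-12)
        assert lc.mse_count(PRED, PRED) == 0.0

    def test_r2(self):
        assert lc.r2(PRED, GT) == pytest.approx(float(Fraction(-1, 14)), abs=1e-12)
        assert lc.r2(GT, GT) == 1.0
        mean_model = [sum(GT) / 3] * 3
        assert lc.r2(mean_model, GT) == pytest.approx(0.0, abs=1e-12)

    def test_r2_undefined_for_constant_gt(self):
        with pytest.raises(ValueError, match="constant"):
            lc.r2([1, 2, 3], [4, 4, 4])

    def test_percentage_agreement(self):
        assert lc.percentage_agreement(PRED, GT) == pytest.approx(float(Fraction(100, 3)),
                                                                  abs=1e-12)
        assert lc.percentage_agreement(GT, GT) == 100.0

    def test_agreement_invariant_under_joint_reordering(self):
        perm = [2, 0, 1]
        assert lc.percentage_agreement([PRED[i] for i in perm], [GT[i] for i in perm]) \
            == lc.percentage_agreement(PRED, GT)

    def test_pixel_accuracy(self):
        pred = np.array([[0, 1], [0, 0]], dtype=np.uint8)
        gt = np.array([[0, 1], [0, 1]], dtype=np.uint8)
        assert lc.pixel_accuracy(pred, gt) == 0.75
        assert lc.pixel_accuracy(gt, gt) == 1.0
        assert lc.pixel_accuracy(gt, 1 - gt) == 0.0

    def test_iou(self):
        pred = np.array([[1, 1], [0, 0]], dtype=np.uint8)
        gt = np.array([[0, 1], [0, 1]], dtype=np.uint8)
        assert lc.iou(pred, gt) == pytest.approx(1 / 3, abs=1e-12)
        assert lc.iou(gt, gt) == 1.0
        disjoint = np.array([[1, 0], [0, 0]], np.uint8), np.array([[0, 0], [0, 1]], np.uint8)
        assert lc.iou(*disjoint) == 0.0

    def test_dice(self):
        pred = np.array([[1, 1], [0, 0]], dtype=np.uint8)
        gt = np.array([[0, 1], [0, 1]], dtype=np.uint8)
        assert lc.dice(pred, gt) == pytest.approx(0.5, abs=1e-12)
        assert lc.dice(gt, gt) == 1.0

    def test_empty_mask_conventions(self):
        z = np.zeros((3, 3), dtype=np.uint8)
        o = np.eye(3, dtype=np.uint8)
        assert lc.iou(z, z) == 1.0 and lc.dice(z, z) == 1.0
        assert lc.iou(o, z) == 0.0 and lc.dice(z, o) == 0.0

    def test_errors(self):
        with pytest.raises(ValueError):
            lc.dic([1, 2], [1])
        with pytest.raises(ValueError):
            lc.dic([], [])
        with pytest.raises(ValueError, match="binary"):
            lc.iou(np.array([[0.4]]), np.array([[1.0]]))


class TestBruteForceEquivalence:
    def test_count_metrics_match_loop_oracle_on_1000_random_vectors(self):
        rng = np.random.default_rng(123)
        pred = rng.integers(0, 15, size=1000).astype(float)
        gt = rng.integers(0, 15, size=1000).astype(float)
        assert lc.dic(pred, gt) == pytest.approx(bf_dic(pred, gt), abs=1e-12)
        assert lc.abs_dic(pred, gt) == pytest.approx(bf_abs_dic(pred, gt), abs=1e-12)
        assert lc.mse_count(pred, gt) == pytest.approx(bf_mse(pred, gt), abs=1e-12)
        assert lc.r2(pred, gt) == pytest.approx(bf_r2(pred, gt), abs=1e-12)
        assert lc.percentage_agreement(pred, gt) == pytest.approx(bf_agreement(pred, gt),
                                                                  abs=1e-12)

    def test_mask_metrics_match_loop_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            pm = (rng.random((13, 17)) > 0.6).astype(np.uint8)
            gm = (rng.random((13, 17)) > 0.6).astype(np.uint8)
            acc, jac, dce = bf_mask_metrics(pm, gm)
            assert lc.pixel_accuracy(pm, gm) == pytest.approx(acc, abs=1e-12)
            assert lc.iou(pm, gm) == pytest.approx(jac, abs=1e-12)
            assert lc.dice(pm, gm) == pytest.approx(dce, abs=1e-12)


class TestInvariants:
    @given(st.integers(0, 2 ** 31 - 1))
    @settings(deadline=None, max_examples=25)
    def test_count_metric_inequalities(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 40))
        pred = rng.integers(0, 12, size=n).astype(float)
        gt = rng.integers(0, 12, size=n).astype(float)
        d, a, m = lc.dic(pred, gt), lc.abs_dic(pred, gt), lc.mse_count(pred, gt)
        assert a >= abs(d) - 1e-12
        assert m >= d ** 2 - 1e-9

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(deadline=None, max_examples=25)
    def test_dice_is_monotone_transform_of_iou(self, seed):
        rng = np.random.default_rng(seed)
        pm = (rng.random((9, 9)) > rng.random()).astype(np.uint8)
        gm = (rng.random((9, 9)) > rng.random()).astype(np.uint8)
        j, d = lc.iou(pm, gm), lc.dice(pm, gm)
        assert j <= d <= 1.0
        assert d == pytest.approx(2 * j / (1 + j), abs=1e-12)

    def test_full_agreement_implies_zero_errors(self):
        rep = lc.count_report([2, 5, 9], [2, 5, 9])
        assert (rep.dic, rep.abs_dic, rep.mse, rep.r2, rep.percentage_agreement) \
            == (0.0, 0.0, 0.0, 1.0, 100.0)

    def test_report_rejects_inconsistent_fields(self):
        with pytest.raises(ValidationError):
            lc.CountMetricsReport(dic=2.0, abs_dic=1.0, mse=5.0, r2=0.5,
                                  percentage_agreement=10.0, n=3)
        with pytest.raises(ValidationError):
            lc.CountMetricsReport(dic=2.0, abs_dic=2.0, mse=1.0, r2=0.5,
                                  percentage_agreement=10.0, n=3)


class TestReportAssembly:
    def test_report_fields_equal_individual_metrics(self):
        rng = np.random.default_rng(5)
        pred = rng.integers(0, 9, 50).astype(float)
        gt = rng.integers(0, 9, 50).astype(float)
        rep = lc.count_report(pred, gt)
        assert rep.dic == lc.dic(pred, gt)
        assert rep.abs_dic == lc.abs_dic(pred, gt)
        assert rep.mse == lc.mse_count(pred, gt)
        assert rep.r2 == lc.r2(pred, gt)
        assert rep.percentage_agreement == lc.percentage_agreement(pred, gt)
        assert rep.n == 50

    def test_evaluate_counts_round_trip(self, tmp_path):
        import pandas as pd

        from leafcount.data import ManifestRecord

        records = [ManifestRecord(f"i{k}.png", count=c, split="test")
                   for k, c in enumerate([3, 4, 6])]
        manifest = lc.DatasetManifest(tmp_path, records)
        pd.DataFrame({"image_path": [r.image_path for r in records],
                      "raw_prediction": [3.2, 4.9, 4.1],
                      "rounded_count": [3, 5, 4]}).to_csv(tmp_path / "p.csv", index=False)
        rep = lc.evaluate_counts(tmp_path / "p.csv", manifest, split="test")
        assert rep.percentage_agreement == pytest.approx(100 / 3)
        assert rep.abs_dic == pytest.approx(1.0)

    def test_evaluate_counts_reports_unmatched_records(self, tmp_path):
        import pandas as pd

        from leafcount.data import ManifestRecord

        manifest = lc.DatasetManifest(tmp_path, [ManifestRecord("a.png", count=3,
                                                                split="test")])
        pd.DataFrame({"image_path": ["b.png"], "raw_prediction": [3.0],
                      "rounded_count": [3]}).to_csv(tmp_path / "p.csv", index=False)
        with pytest.raises(ValidationError, match="a.png"):
            lc.evaluate_counts(tmp_path / "p.csv", manifest, split="test")

    def test_evaluate_masks_round_trip(self, tmp_path):
        from leafcount.data import ManifestRecord, write_mask

        rng = np.random.default_rng(9)
        (tmp_path / "pred").mkdir()
        records = []
        gts, preds = [], []
        for k in range(3):
            gt = (rng.random((16, 16)) > 0.5).astype(np.uint8)
            pred = gt.copy()
            pred[0, :4] ^= 1
            write_mask(tmp_path / f"m{k}.png", gt)
            write_mask(tmp_path / "pred" / f"i{k}.png", pred)
            records.append(ManifestRecord(f"i{k}.png", f"m{k}.png", split="test"))
            gts.append(gt)
            preds.append(pred)
        manifest = lc.DatasetManifest(tmp_path, records)
        rep = lc.evaluate_masks(tmp_path / "pred", manifest, split="test")
        expected = lc.mask_report(preds, gts)
        assert rep == expected
        assert rep.accuracy == pytest.approx(1 - 12 / (3 * 256))

    def test_agreement_on_1000_pairs_equals_brute_force_recount(self):
        rng = np.random.default_rng(2024)
        pred = rng.integers(0, 10, 1000)
        gt = rng.integers(0, 10, 1000)
        exact = sum(1 for p, g in zip(pred.tolist(), gt.tolist()) if p == g)
        assert lc.percentage_agreement(pred, gt) == pytest.approx(100 * exact / 1000,
                                                                  abs=1e-12)
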