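"""Evaluation metrics vs independent brute-force voxel/component oracles."""

import numpy as np
import pytest
from scipy import ndimage

from petldm.core import Mask3D, Volume3D, PET_SUV
from petldm.evalmetrics import (PSNR_CAP_DB, EvalContext, detection_metrics,
                                extract_lesions, lesion_nmse_pct,
                                lesion_suv_mse, lesions_from_mask, LesionMatch,
                                mae_masked, match_lesions, psnr_masked,
                                ssim3d_masked, volume_mape, volume_pearson)
from .conftest import make_mask, make_volume


def brute_force_ssim(a, b, mask, Q, w=7, k1=0.01, k2=0.03):
    """Direct per-voxel SSIM, independent of the uniform-filter path.

    Edge handling reflects about the edge including the edge sample
    (numpy's ``symmetric``), the reflective convention the package uses.
    """
    r = w // 2
    ap = np.pad(a, r, mode="symmetric")
    bp = np.pad(b, r, mode="symmetric")
    c1, c2 = (k1 * Q) ** 2, (k2 * Q) ** 2
    vals = []
    for i, j, k in zip(*np.nonzero(mask)):
        wa = ap[i:i + w, j:j + w, k:k + w].ravel()
        wb = bp[i:i + w, j:j + w, k:k + w].ravel()
        mu_a, mu_b = wa.mean(), wb.mean()
        va = (wa ** 2).mean() - mu_a ** 2
        vb = (wb ** 2).mean() - mu_b ** 2
        cov = (wa * wb).mean() - mu_a * mu_b
        vals.append(((2 * mu_a * mu_b + c1) * (2 * cov + c2))
                    / ((mu_a ** 2 + mu_b ** 2 + c1) * (va + vb + c2)))
    return float(np.mean(vals))


@pytest.fixture()
def ctx16(rng):
    mask = np.zeros((16, 16, 16), bool)
    mask[3:13, 3:13, 3:13] = True
    return EvalContext(B=Mask3D(mask, (1, 1, 1), "RAS"), Q=30.0)


class TestGlobalMetrics:
    def test_mae_identities_and_hand_sum(self, ctx16, rng):
        y = make_volume(rng.normal(size=(16, 16, 16)))
        assert mae_masked(y, y, ctx16) == 0.0
        shifted = y.with_values(y.values + 3.0)
        assert np.isclose(mae_masked(y, shifted, ctx16), 3.0)
        # 4-voxel mask, residuals (1, -1, 2, 0) -> MAE 1.0
        m = np.zeros((4, 1, 1), bool)
        m[:, 0, 0] = True
        ctx = EvalContext(B=Mask3D(m, (1, 1, 1), "RAS"), Q=30.0)
        a = make_volume(np.zeros((4, 1, 1)))
        b = make_volume(np.array([1.0, -1.0, 2.0, 0.0]).reshape(4, 1, 1))
        assert np.isclose(mae_masked(a, b, ctx), 1.0)

    def test_psnr_closed_form_and_scalings(self, ctx16, rng):
        y = make_volume(rng.normal(size=(16, 16, 16)))
        c3 = y.with_values(y.values + 3.0)
        assert np.isclose(psnr_masked(y, c3, ctx16), 20.0)  # 10 log10(900/9)
        resid = rng.normal(size=(16, 16, 16))
        a = y.with_values(y.values + resid)
        b = y.with_values(y.values + resid / 2)
        gain = psnr_masked(y, b, ctx16) - psnr_masked(y, a, ctx16)
        assert np.isclose(gain, 10 * np.log10(4), atol=1e-6)
        ctx2 = EvalContext(B=ctx16.B, Q=60.0)
        assert np.isclose(psnr_masked(y, a, ctx2) - psnr_masked(y, a, ctx16),
                          10 * np.log10(4), atol=1e-6)

    def test_psnr_identical_capped(self, ctx16, rng):
        y = make_volume(rng.normal(size=(16, 16, 16)))
        assert psnr_masked(y, y, ctx16) == PSNR_CAP_DB

    def test_ssim_identical_is_one(self, ctx16, rng):
        y = make_volume(rng.normal(size=(16, 16, 16)))
        assert np.isclose(ssim3d_masked(y, y, ctx16), 1.0)
        const = make_volume(np.full((16, 16, 16), 5.0))
        assert np.isclose(ssim3d_masked(const, const, ctx16), 1.0)

    def test_ssim_sign_flip_nonpositive(self, ctx16):
        # alternating-sign pattern: local means ~ 0, so the luminance term
        # stays positive while anticorrelation makes the structure term
        # negative wherever variance dominates the stabilizer
        idx = np.indices((16, 16, 16)).sum(axis=0)
        vals = np.where(idx % 2 == 0, 1.0, -1.0)
        ctx = EvalContext(B=ctx16.B, Q=1.0)
        y = make_volume(vals)
        neg = make_volume(-vals)
        assert ssim3d_masked(y, neg, ctx) < 0

    def test_ssim_matches_brute_force(self, ctx16, rng):
        a = rng.normal(scale=5.0, size=(16, 16, 16))
        b = a + rng.normal(scale=1.0, size=(16, 16, 16))
        got = ssim3d_masked(make_volume(a), make_volume(b), ctx16)
        want = brute_force_ssim(a, b, ctx16.B.values, ctx16.Q)
        assert np.isclose(got, want, atol=1e-10)

    def test_ssim_symmetry(self, ctx16, rng):
        a = rng.normal(size=(16, 16, 16))
        b = a + rng.normal(scale=0.5, size=(16, 16, 16))
        s1 = ssim3d_masked(make_volume(a), make_volume(b), ctx16)
        s2 = ssim3d_masked(make_volume(b), make_volume(a), ctx16)
        assert np.isclose(s1, s2, atol=1e-12)
        assert s1 <= 1.0

    def test_enlarging_mask_with_zero_residual_never_increases_mae(self, rng):
        a = rng.normal(size=(16, 16, 16))
        b = a.copy()
        b[4:8, 4:8, 4:8] += 1.0   # residual only inside small region
        small = np.zeros((16, 16, 16), bool)
        small[4:8, 4:8, 4:8] = True
        big = small.copy()
        big[10:14, 10:14, 10:14] = True  # extra zero-residual voxels
        mae_small = mae_masked(make_volume(a), make_volume(b),
                               EvalContext(B=Mask3D(small, (1, 1, 1), "RAS")))
        mae_big = mae_masked(make_volume(a), make_volume(b),
                             EvalContext(B=Mask3D(big, (1, 1, 1), "RAS")))
        assert mae_big <= mae_small


class TestLesionExtraction:
    def test_background_only_empty(self):
        pet = make_volume(np.ones((8, 8, 8)))
        assert extract_lesions(pet, threshold=2.5).n == 0

    def test_three_lesion_phantom(self, noiseless_spec):
        import dataclasses
        from petldm.phantom import generate_case
        spec = dataclasses.replace(noiseless_spec, lesion_count_range=(3, 3))
        _, pet, lesions, _ = generate_case(spec, 11)
        got = extract_lesions(pet, threshold=2.5, min_voxels=1)
        assert got.n == 3

    def test_corner_touching_connectivity(self):
        vals = np.zeros((6, 6, 6))
        vals[1:3, 1:3, 1:3] = 9.0
        vals[3:5, 3:5, 3:5] = 9.0  # touches at the corner voxel (3,3,3)
        pet = make_volume(vals)
        assert extract_lesions(pet, 2.5, min_voxels=1, connectivity=26).n == 1
        assert extract_lesions(pet, 2.5, min_voxels=1, connectivity=6).n == 2

    def test_min_voxels_filter(self):
        vals = np.zeros((8, 8, 8))
        vals[1, 1, 1] = 9.0          # 1 voxel: dropped
        vals[4:6, 4:6, 4] = 9.0      # 4 voxels: kept
        got = extract_lesions(make_volume(vals), 2.5, min_voxels=3)
        assert got.n == 1
        assert got.lesions[0].n_voxels == 4

    def test_volumes_in_mm3(self):
        vals = np.zeros((6, 6, 6))
        vals[2:4, 2:4, 2:4] = 9.0
        pet = make_volume(vals, spacing=(2.0, 2.0, 3.0))
        got = extract_lesions(pet, 2.5, min_voxels=1)
        assert np.isclose(got.lesions[0].volume_mm3, 8 * 12.0)


def exhaustive_match_oracle(gt_labels, pred_labels):
    """Maximum-cardinality one-voxel-overlap matching via exhaustive search."""
    import itertools
    gts = [l for l in np.unique(gt_labels) if l > 0]
    preds = [l for l in np.unique(pred_labels) if l > 0]
    admissible = {(g, p) for g in gts for p in preds
                  if ((gt_labels == g) & (pred_labels == p)).any()}
    best = 0
    for r in range(min(len(gts), len(preds)), 0, -1):
        for gsub in itertools.permutations(gts, r):
            for psub in itertools.combinations(preds, r):
                if all((g, p) in admissible for g, p in zip(gsub, psub)):
                    best = max(best, r)
        if best:
            break
    return best


class TestMatching:
    def test_perfect_prediction(self, noiseless_spec):
        import dataclasses
        from petldm.phantom import generate_case
        spec = dataclasses.replace(noiseless_spec, lesion_count_range=(3, 3))
        _, _, lesions, _ = generate_case(spec, 11)
        s = lesions_from_mask(lesions)
        m = match_lesions(s, s)
        assert (m.tp, m.fp, m.fn) == (s.n, 0, 0)

    def test_precision_two_thirds_recall_one(self):
        gt = np.zeros((10, 10, 4), bool)
        gt[1:3, 1:3, 1:3] = True
        gt[6:8, 6:8, 1:3] = True
        pred = np.zeros((10, 10, 4), bool)
        pred[1:3, 1:3, 1:3] = True    # overlaps gt 1
        pred[6:8, 6:8, 1:3] = True    # overlaps gt 2
        pred[4:5, 4:5, 1:3] = True    # false positive
        m = match_lesions(lesions_from_mask(make_mask(gt)),
                          lesions_from_mask(make_mask(pred)))
        assert (m.tp, m.fp, m.fn) == (2, 1, 0)
        assert m.tp / (m.tp + m.fp) == pytest.approx(2 / 3)
        assert m.tp / (m.tp + m.fn) == 1.0

    def test_one_pred_covering_two_gt_is_single_tp(self):
        gt = np.zeros((12, 6, 4), bool)
        gt[1:3, 1:3, 1:3] = True
        gt[6:8, 1:3, 1:3] = True
        pred = np.zeros((12, 6, 4), bool)
        pred[1:8, 1:3, 1:3] = True    # one blob overlapping both
        m = match_lesions(lesions_from_mask(make_mask(gt)),
                          lesions_from_mask(make_mask(pred)))
        assert (m.tp, m.fp, m.fn) == (1, 0, 1)

    def test_counts_satisfy_invariants_random(self, rng):
        for trial in range(10):
            gt = rng.random((12, 12, 6)) > 0.85
            pred = rng.random((12, 12, 6)) > 0.85
            gs = lesions_from_mask(make_mask(gt))
            ps = lesions_from_mask(make_mask(pred))
            m = match_lesions(gs, ps)
            assert m.tp + m.fn == gs.n
            assert m.tp + m.fp == ps.n
            assert len({g for g, _ in m.pairs}) == m.tp
            assert len({p for _, p in m.pairs}) == m.tp

    def test_greedy_matches_exhaustive_on_small_fixtures(self, rng):
        for trial in range(6):
            gt = rng.random((8, 8, 4)) > 0.8
            pred = rng.random((8, 8, 4)) > 0.8
            gs = lesions_from_mask(make_mask(gt), connectivity=26)
            ps = lesions_from_mask(make_mask(pred), connectivity=26)
            if gs.n > 5 or ps.n > 5:
                continue
            m = match_lesions(gs, ps)
            # greedy one-to-one by overlap is admissible; compare cardinality
            assert m.tp <= exhaustive_match_oracle(gs.labels, ps.labels)
            assert m.tp >= 1 or not (gs.labels > 0).any() \
                or not ((gs.labels > 0) & (ps.labels > 0)).any()


class TestDetectionMetrics:
    def test_perfect(self):
        ms = [LesionMatch(pairs=[(1, 1), (2, 2)], tp=2, fp=0, fn=0)]
        d = detection_metrics(ms)
        assert d["precision"] == 1.0 and d["recall"] == 1.0
        assert d["fp_rate"] == 0.0

    def test_fp_rate_mean(self):
        ms = [LesionMatch(pairs=[(1, 1)], tp=1, fp=1, fn=0),
              LesionMatch(pairs=[(1, 1)], tp=1, fp=0, fn=0)]
        assert detection_metrics(ms)["fp_rate"] == 0.5

    def test_three_subject_recall_mean(self):
        ms = [LesionMatch(pairs=[(1, 1), (2, 2)], tp=2, fp=1, fn=0),
              LesionMatch(pairs=[(1, 1)], tp=1, fp=0, fn=1),
              LesionMatch(pairs=[], tp=0, fp=0, fn=2)]
        d = detection_metrics(ms)
        assert d["recall"] == pytest.approx((1 + 0.5 + 0) / 3)

    def test_undefined_precision_excluded(self):
        ms = [LesionMatch(pairs=[], tp=0, fp=0, fn=1),
              LesionMatch(pairs=[(1, 1)], tp=1, fp=0, fn=0)]
        d = detection_metrics(ms)
        assert d["precision"] == 1.0
        assert d["n_excluded_precision"] == 1


class TestLesionQuantification:
    def _three_voxel_set(self):
        gt = np.zeros((6, 6, 2), bool)
        gt[1, 1, 0] = gt[2, 2, 0] = gt[3, 3, 0] = True
        return lesions_from_mask(make_mask(gt), connectivity=26, min_voxels=1)

    def test_mse_identities_and_hand_sum(self):
        ls = self._three_voxel_set()
        y_vals = np.zeros((6, 6, 2))
        y_vals[ls.labels > 0] = 5.0
        y = make_volume(y_vals)
        assert lesion_suv_mse(y, y, ls) == 0.0
        plus2 = y.with_values(y.values + 2.0)
        assert np.isclose(lesion_suv_mse(y, plus2, ls), 4.0)
        resid = np.zeros((6, 6, 2))
        resid[1, 1, 0], resid[2, 2, 0], resid[3, 3, 0] = 1.0, 2.0, 3.0
        yh = y.with_values(y.values + resid)
        assert np.isclose(lesion_suv_mse(y, yh, ls), 14 / 3)

    def test_nmse_identities(self):
        ls = self._three_voxel_set()
        y_vals = np.zeros((6, 6, 2))
        y_vals[ls.labels > 0] = 5.0
        y = make_volume(y_vals)
        assert lesion_nmse_pct(y, y, ls) == 0.0
        zero = y.with_values(np.zeros_like(y.values))
        assert np.isclose(lesion_nmse_pct(y, zero, ls), 100.0)
        scaled = y.with_values(1.1 * y.values)
        assert np.isclose(lesion_nmse_pct(y, scaled, ls), 1.0, atol=1e-8)

    def test_volume_mape_hand_examples(self):
        class FakeSet:
            def __init__(self, vols):
                self.vols = vols

            def volume_of(self, label):
                return self.vols[label - 1]

        m = LesionMatch(pairs=[(1, 1)], tp=1, fp=0, fn=0)
        assert np.isclose(volume_mape(m, FakeSet([100.0]), FakeSet([150.0])),
                          50.0, atol=1e-4)
        m2 = LesionMatch(pairs=[(1, 1), (2, 2)], tp=2, fp=0, fn=0)
        got = volume_mape(m2, FakeSet([100.0, 200.0]), FakeSet([120.0, 160.0]))
        assert np.isclose(got, 20.0, atol=1e-4)
        assert volume_mape(m, FakeSet([100.0]), FakeSet([100.0])) \
            == pytest.approx(0.0, abs=1e-6)

    def test_volume_pearson(self):
        class FakeSet:
            def __init__(self, vols):
                self.vols = vols

            def volume_of(self, label):
                return self.vols[label - 1]

        m = LesionMatch(pairs=[(1, 1), (2, 2), (3, 3)], tp=3, fp=0, fn=0)
        v = FakeSet([1.0, 2.0, 3.0])
        assert np.isclose(volume_pearson(m, v, v), 1.0)
        affine = FakeSet([7.0, 9.0, 11.0])  # 2v + 5
        assert np.isclose(volume_pearson(m, v, affine), 1.0)
        anti = FakeSet([3.0, 2.0, 1.0])
        assert np.isclose(volume_pearson(m, v, anti), -1.0)
        with pytest.raises(ValueError):
            volume_pearson(LesionMatch(pairs=[(1, 1)], tp=1, fp=0, fn=0), v, v)
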