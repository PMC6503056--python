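"""Feature extraction: oracle equivalence, closed forms, invariances."""

import math
import time

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter
from skimage.draw import disk

from nethcs import features as F
from nethcs import segmentation as seg
from nethcs import synthetic_imaging as si


def brute_force_haralick(img, mask, levels, offsets, symmetric=True):
    """Independent oracle: enumerate co-occurring pixel pairs one by one."""
    q = F.quantize(img, mask, levels)
    h, w = q.shape
    feats = {n: [] for n in F.HARALICK_NAMES}
    for dr, dc in offsets:
        C = np.zeros((levels, levels))
        for r in range(h):
            for c in range(w):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < h and 0 <= c2 < w and q[r, c] >= 0 and q[r2, c2] >= 0:
                    C[q[r, c], q[r2, c2]] += 1
        if symmetric:
            C = C + C.T
        if C.sum() == 0:
            continue
        p = C / C.sum()
        i = np.arange(levels)[:, None]
        j = np.arange(levels)[None, :]
        pi, pj = p.sum(1), p.sum(0)
        mu_i = (np.arange(levels) * pi).sum()
        mu_j = (np.arange(levels) * pj).sum()
        var_i = ((np.arange(levels) - mu_i) ** 2 * pi).sum()
        var_j = ((np.arange(levels) - mu_j) ** 2 * pj).sum()
        corr = (((i - mu_i) * (j - mu_j) * p).sum() / math.sqrt(var_i * var_j)
                if var_i > 0 and var_j > 0 else 1.0)
        nz = p[p > 0]
        vals = {
            "contrast": (p * (i - j) ** 2).sum(),
            "correlation": corr,
            "energy": (p**2).sum(),
            "homogeneity": (p / (1 + (i - j) ** 2)).sum(),
            "entropy": -(nz * np.log(nz)).sum(),
        }
        for n in F.HARALICK_NAMES:
            feats[n].append(vals[n])
    return {f"haralick_{n}": np.mean(v) for n, v in feats.items()}


class TestHaralick:
    def test_matches_brute_force_oracle_on_random_patches(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            img = rng.integers(0, 4096, (16, 16)).astype(float)
            mask = rng.random((16, 16)) > 0.2
            if mask.sum() < 4:
                continue
            ours = F.haralick_features(F.glcm(img, mask, levels=8))
            oracle = brute_force_haralick(img, mask, 8, F.DEFAULT_FEATURES.glcm_offsets)
            for k in ours:
                assert ours[k] == pytest.approx(oracle[k], abs=1e-10)

    def test_constant_patch_conventions(self):
        feats = F.haralick_features(F.glcm(np.full((6, 6), 3.0), np.ones((6, 6), bool)))
        assert feats["haralick_contrast"] == 0.0
        assert feats["haralick_energy"] == 1.0
        assert feats["haralick_homogeneity"] == 1.0
        assert feats["haralick_entropy"] == 0.0

    def test_checkerboard_closed_form(self):
        cb = np.array([[0.0, 1.0], [1.0, 0.0]])
        feats = F.haralick_features(
            F.glcm(cb, np.ones((2, 2), bool), levels=2, offsets=((0, 1),)))
        assert feats["haralick_contrast"] == pytest.approx(1.0)
        assert feats["haralick_energy"] == pytest.approx(0.5)

    def test_affine_intensity_invariance(self):
        rng = np.random.default_rng(1)
        img = rng.normal(500, 80, (20, 20))
        mask = np.ones((20, 20), bool)
        a = F.haralick_features(F.glcm(img, mask))
        b = F.haralick_features(F.glcm(3.7 * img + 250.0, mask))
        for k in a:
            assert a[k] == pytest.approx(b[k], rel=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="levels"):
            F.quantize(np.ones((4, 4)), np.ones((4, 4), bool), 1)
        with pytest.raises(ValueError, match="2 pixels"):
            mask = np.zeros((4, 4), bool)
            mask[0, 0] = True
            F.glcm(np.ones((4, 4)), mask)
        with pytest.raises(ValueError, match="offsets"):
            F.glcm(np.ones((4, 4)), np.ones((4, 4), bool), offsets=())


class TestMorphology:
    def test_disk_form_factor_near_one(self):
        m = np.zeros((60, 60), bool)
        rr, cc = disk((30, 30), 20.5)
        m[rr, cc] = True
        feats = F.morphology_features(m, 1.0)
        assert 0.95 <= feats["form_factor"] <= 1.05

    def test_square_closed_forms(self):
        m = np.zeros((20, 20), bool)
        m[5:15, 5:15] = True
        feats = F.morphology_features(m, 1.0)
        assert feats["area_um2"] == 100.0
        # raster estimators bracket the true outline length of 40
        assert 36.0 <= feats["perimeter_um"] <= 40.0
        assert math.pi / 4 <= feats["form_factor"] <= 1.0

    def test_pixel_size_scales_area(self):
        m = np.ones((10, 10), bool)
        assert F.morphology_features(m, 0.5)["area_um2"] == pytest.approx(25.0)

    def test_three_lobed_mask_counted(self):
        # three disks at triangle vertices: known lobe placement
        m = np.zeros((64, 64), bool)
        for ang in (0, 2 * math.pi / 3, 4 * math.pi / 3):
            center = (32 + 9 * math.sin(ang), 32 + 9 * math.cos(ang))
            rr, cc = disk(center, 7)
            m[rr, cc] = True
        feats = F.morphology_features(m, 0.5)
        assert feats["lobe_count"] == 3.0

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            F.morphology_features(np.zeros((5, 5), bool), 1.0)


class TestIntensity:
    def test_all_ones_object(self):
        img = np.ones((5, 5))
        mask = np.zeros((5, 5), bool)
        mask.flat[:10] = True
        feats = F.intensity_features(img, mask, 1.0)
        assert feats["intensity_mean"] == 1.0
        assert feats["intensity_sd"] == 0.0
        assert feats["intensity_total"] == 10.0

    def test_population_sd_convention(self):
        img = np.array([[0.0, 2.0]] * 2)
        feats = F.intensity_features(img, np.ones((2, 2), bool), 1.0)
        assert feats["intensity_mean"] == 1.0
        assert feats["intensity_sd"] == 1.0  # population, not sample

    def test_apoptotic_density_stochastically_larger(self):
        from scipy.stats import mannwhitneyu

        def densities(preset, n=60):
            out = []
            for s in range(n):
                p, m = si.render_nucleus(preset, s)
                out.append(F.intensity_features(p, m, 0.5)["density"])
            return out

        apo = densities(si.APOPTOTIC_PRESET)
        rest = densities(si.RESTING_PRESET)
        assert mannwhitneyu(apo, rest, alternative="greater").pvalue < 0.01


class TestGabor:
    def test_constant_image_near_zero_response(self):
        mask = np.zeros((64, 64), bool)
        mask[20:44, 20:44] = True
        feats = F.gabor_features(np.full((64, 64), 1000.0), mask)
        for k, v in feats.items():
            if k.startswith("gabor_mean"):
                assert v < 1e-2 * 1000.0  # zero-DC kernels annihilate constants

    def test_grating_maximal_at_aligned_orientation(self):
        x = np.arange(64)
        img = 100.0 * np.sin(2 * math.pi * 0.25 * x)[None, :].repeat(64, 0) + 200.0
        mask = np.zeros((64, 64), bool)
        mask[16:48, 16:48] = True
        feats = F.gabor_features(img, mask)
        means = {k: v for k, v in feats.items() if k.startswith("gabor_mean_f0.25")}
        assert max(means, key=means.get).endswith("_t0")

    def test_rotation_permutes_orientations(self):
        rng = np.random.default_rng(5)
        img = gaussian_filter(rng.normal(500, 100, (64, 64)), 1.0)
        mask = np.zeros((64, 64), bool)
        mask[24:40, 20:44] = True
        a = F.gabor_features(img, mask)
        b = F.gabor_features(np.rot90(img), np.rot90(mask))
        for f in F.DEFAULT_FEATURES.gabor_frequencies:
            v0 = a[f"gabor_mean_f{f:g}_t0"]
            v90 = b[f"gabor_mean_f{f:g}_t90"]
            assert v90 == pytest.approx(v0, rel=0.05)

    def test_empty_bank_rejected(self):
        with pytest.raises(ValueError, match="bank"):
            F.gabor_features(np.ones((64, 64)), np.ones((64, 64), bool),
                             F.FeatureParams(gabor_frequencies=()))


class TestSpotsEdgesRidges:
    mask = np.zeros((64, 64), bool)
    mask[16:48, 16:48] = True

    def test_constant_image_all_zero(self):
        feats = F.ser_features(np.full((64, 64), 300.0), self.mask)
        assert all(abs(v) < 1e-6 for v in feats.values())

    def test_blob_spot_dominates(self):
        yy, xx = np.mgrid[0:64, 0:64]
        blob = 100 * np.exp(-((yy - 32) ** 2 + (xx - 32) ** 2) / (2 * 2.0**2))
        feats = F.ser_features(blob + 1, self.mask, scales=(2.0,))
        assert feats["ser_spot_s2"] > feats["ser_ridge_s2"]

    def test_line_ridge_dominates(self):
        line = np.zeros((64, 64))
        line[32, :] = 100.0
        line = gaussian_filter(line, 1.0)
        feats = F.ser_features(line + 1, self.mask, scales=(2.0,))
        assert feats["ser_ridge_s2"] > feats["ser_spot_s2"]

    def test_illumination_invariance(self):
        rng = np.random.default_rng(2)
        img = gaussian_filter(rng.normal(400, 60, (64, 64)), 1.5) + 50
        a = F.ser_features(img, self.mask)
        b = F.ser_features(5.0 * img, self.mask)
        for k in a:
            assert a[k] == pytest.approx(b[k], rel=1e-9)

    def test_nonpositive_scale_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            F.ser_features(np.ones((64, 64)), self.mask, scales=(0.0,))


class TestSecondaryChannel:
    def test_zero_image_gives_zeros(self, mixed_field):
        img, truth = mixed_field
        from nethcs.plate_io import FieldImage

        zero = FieldImage(np.zeros(img.pixels.shape), "secondary", img.pixel_size)
        vals = F.secondary_channel_intensity(truth, zero)
        assert all(v == 0.0 for v in vals.values())

    def test_netotic_signal_higher(self, mixed_field):
        img, truth = mixed_field
        sec = si.simulate_secondary_field(truth, 123)
        vals = F.secondary_channel_intensity(truth, sec)
        by_label = {"netotic": [], "resting": []}
        for rec in truth:
            if rec.phenotype in by_label:
                by_label[rec.phenotype].append(vals[rec.object_id])
        assert np.mean(by_label["netotic"]) > np.mean(by_label["resting"])

    def test_dilation_on_uniform_field_is_noop(self):
        from nethcs.plate_io import CellRecord, FieldImage

        img = FieldImage(np.full((64, 64), 777.0), "secondary", 0.5)
        rec = CellRecord("A01", 0, 1, (20, 20), np.ones((8, 8), bool))
        v0 = F.secondary_channel_intensity([rec], img, dilation_px=0)
        v2 = F.secondary_channel_intensity([rec], img, dilation_px=2)
        assert v0[1] == v2[1] == 777.0


class TestBatchExtraction:
    def test_full_vector_finite_and_bounded(self, mixed_field):
        img, _ = mixed_field
        lo = seg.segment_nuclei(img)
        rows = F.extract_features(img, lo)
        assert len(rows) == len(lo.objects)
        names = F.feature_names()
        for row in rows:
            for n in names:
                assert np.isfinite(row[n]), n
            assert row["form_factor"] <= F.FORM_FACTOR_CAP
            assert 0 < row["haralick_energy"] <= 1.0
            assert 0 < row["haralick_homogeneity"] <= 1.0
            assert row["haralick_entropy"] >= 0.0
            assert 0 < row["solidity"] <= 1.0

    def test_throughput_thousand_cells(self, mixed_field):
        img, _ = mixed_field
        lo = seg.segment_nuclei(img)
        reps = -(-1000 // max(len(lo.objects), 1))  # ceil division
        start = time.time()
        for _ in range(reps):
            F.extract_features(img, lo)
        elapsed = time.time() - start
        assert reps * len(lo.objects) >= 1000
        assert elapsed < 60.0
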