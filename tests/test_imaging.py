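"""Otsu thresholding, particle detection, ROI classification, group tests."""

import numpy as np
import pytest
from skimage.filters import threshold_otsu as skimage_otsu

from ibioid.imaging import (
    DegenerateImageError,
    MultiChannelImage,
    ThClass,
    classify_th_rois,
    compare_target_intensity,
    detect_particles,
    generate_synaptosome_image,
    otsu_threshold,
    quantify_image,
)


def otsu_oracle(x, n_bins=256):
    """Exhaustive search over all candidate bin edges, maximizing
    between-class variance directly from the class definitions."""
    x = np.asarray(x, dtype=float).ravel()
    hist, edges = np.histogram(x, bins=n_bins, range=(x.min(), x.max()))
    centers = (edges[:-1] + edges[1:]) / 2.0
    variances = np.full(n_bins, -1.0)
    total = hist.sum()
    for k in range(n_bins):
        n0 = hist[: k + 1].sum()
        n1 = total - n0
        if n0 == 0 or n1 == 0:
            continue
        mu0 = (hist[: k + 1] * centers[: k + 1]).sum() / n0
        mu1 = (hist[k + 1 :] * centers[k + 1 :]).sum() / n1
        variances[k] = (n0 / total) * (n1 / total) * (mu0 - mu1) ** 2
    # lowest bin attaining the maximum, tolerant to round-off on exact ties
    vmax = variances.max()
    best_k = int(np.argmax(variances >= vmax * (1.0 - 1e-12)))
    return float(edges[best_k + 1])


class TestOtsu:
    def test_bimodal_separation(self):
        img = np.concatenate([np.zeros(50), np.full(50, 100.0)]).reshape(10, 10)
        t = otsu_threshold(img)
        assert 0 < t < 100
        assert (img > t).sum() == 50

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.gamma(2.0, 10.0, (32, 32))
        assert otsu_threshold(img) == pytest.approx(otsu_oracle(img), abs=1e-12)

    def test_agrees_with_skimage_within_a_bin(self):
        rng = np.random.default_rng(7)
        img = np.concatenate([rng.normal(20, 3, 600), rng.normal(90, 8, 400)])
        bin_w = (img.max() - img.min()) / 256
        assert abs(otsu_threshold(img) - skimage_otsu(img, nbins=256)) <= bin_w

    def test_constant_image_rejected(self):
        with pytest.raises(DegenerateImageError):
            otsu_threshold(np.full((8, 8), 3.0))

    def test_invariant_under_affine_rescale(self):
        rng = np.random.default_rng(1)
        img = rng.gamma(2.0, 10.0, (64, 64))
        t = otsu_threshold(img)
        t2 = otsu_threshold(3.0 * img + 7.0)
        assert t2 == pytest.approx(3.0 * t + 7.0, rel=1e-9)


class TestDetectParticles:
    def test_area_arithmetic_and_gating(self):
        img = np.zeros((16, 16))
        img[4:7, 4:7] = 100.0  # 9 px square
        rois = detect_particles(img, 50.0, pixel_size_um=0.2, area_range_um2=(0.2, 1.0))
        assert len(rois) == 1
        assert rois[0].area_um2 == pytest.approx(9 * 0.04)
        # same square at 0.5 um pixels: 2.25 um^2, outside every gate
        assert detect_particles(img, 50.0, 0.5, (0.2, 1.0)) == []
        assert detect_particles(img, 50.0, 0.5, (0.15, 2.0)) == []

    def test_oversized_blobs_rejected(self):
        rng_img = np.zeros((200, 200))
        centers = [(20 + 30 * i, 20 + 30 * j) for i in range(5) for j in range(2)]
        for r, c in centers:
            rng_img[r : r + 3, c : c + 3] = 80.0  # in-gate at 0.2 um: 0.36 um^2
        rng_img[150:190, 120:190] = 80.0  # oversized blob
        rois = detect_particles(rng_img, 40.0, 0.2, (0.2, 1.0))
        assert len(rois) == len(centers)

    def test_translation_invariance_of_count(self):
        img = np.zeros((64, 64))
        img[10:13, 10:13] = 90.0
        img[30:33, 40:43] = 90.0
        shifted = np.roll(img, (7, -5), axis=(0, 1))
        a = detect_particles(img, 45.0, 0.2, (0.2, 1.0))
        b = detect_particles(shifted, 45.0, 0.2, (0.2, 1.0))
        assert len(a) == len(b) == 2


class TestGenerator:
    def test_deterministic_per_seed(self):
        a, truth_a = generate_synaptosome_image(n_particles=20, seed=5, shape=(128, 128))
        b, truth_b = generate_synaptosome_image(n_particles=20, seed=5, shape=(128, 128))
        for ch in a.channels:
            assert np.array_equal(a.channels[ch], b.channels[ch])
        assert truth_a == truth_b

    def test_noiseless_recovery_of_planted_particles(self):
        image, truth = generate_synaptosome_image(
            n_particles=10, noise_sd=0.0, seed=2, shape=(128, 128)
        )
        th = image.channels["TH"]
        rois = detect_particles(
            th, otsu_threshold(th), image.pixel_size_um, (0.2, 1.0)
        )
        assert len(rois) == 10
        planted = np.array([t["center"] for t in truth])
        detected = np.array([r.centroid for r in rois])
        for p in planted:
            d = np.min(np.linalg.norm(detected - p, axis=1))
            assert d <= 1.0  # centroid within 1 px of the planted center

    def test_infeasible_packing_raises(self):
        with pytest.raises(ValueError, match="larger frame"):
            generate_synaptosome_image(n_particles=500, shape=(64, 64), seed=0)


class TestClassification:
    def test_classes_partition_th_rois(self):
        image, truth = generate_synaptosome_image(
            n_particles=100, frac_bassoon_pos=0.4, noise_sd=0.0, seed=3
        )
        rois, _ = quantify_image(image)
        counts = {cls: 0 for cls in ThClass}
        for r in rois:
            counts[r.th_class] += 1
        assert counts[ThClass.BASSOON_POS] == 40
        assert counts[ThClass.BASSOON_NEG] == 60
        assert counts[ThClass.EXCLUDED] == 0
        assert counts[ThClass.NA] == 0

    def test_overlap_rule_toy(self):
        bassoon = np.zeros((32, 32))
        bassoon[10:13, 10:13] = 100.0
        th = np.zeros((32, 32))
        th[10:13, 10:13] = 50.0  # overlaps the Bassoon ROI
        th[20:23, 20:23] = 50.0  # over zero Bassoon signal
        th_rois = detect_particles(th, 25.0, 0.2, (0.2, 1.0))
        bsn_rois = detect_particles(bassoon, 50.0, 0.2, (0.15, 2.0))
        classified = classify_th_rois(th_rois, bsn_rois, bassoon)
        by_pos = {tuple(np.round(r.centroid)): r.th_class for r in classified}
        assert by_pos[(11.0, 11.0)] is ThClass.BASSOON_POS
        assert by_pos[(21.0, 21.0)] is ThClass.BASSOON_NEG

    def test_intensity_rule_has_no_excluded(self):
        image, _ = generate_synaptosome_image(
            n_particles=60, frac_bassoon_pos=0.5, noise_sd=1.0, seed=9
        )
        rois, _ = quantify_image(image, rule="intensity")
        assert all(
            r.th_class in (ThClass.BASSOON_POS, ThClass.BASSOON_NEG) for r in rois
        )


class TestIntensityComparison:
    def test_identical_groups_are_null(self):
        image, _ = generate_synaptosome_image(n_particles=40, noise_sd=0.0, seed=4)
        rois, _ = quantify_image(image)
        pos = [r for r in rois if r.th_class is ThClass.BASSOON_POS]
        comp = compare_target_intensity(pos, pos, "TARGET")
        assert comp.t_statistic == pytest.approx(0.0, abs=1e-12)
        assert comp.ks_statistic == 0.0

    def test_t_statistic_matches_pooled_variance_formula(self):
        class R:
            def __init__(self, v):
                self.mean_intensity = {"TARGET": v}

        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [2.0, 4.0, 6.0, 8.0, 3.0]
        comp = compare_target_intensity([R(v) for v in x], [R(v) for v in y], "TARGET")
        nx, ny = len(x), len(y)
        sp2 = ((nx - 1) * np.var(x, ddof=1) + (ny - 1) * np.var(y, ddof=1)) / (nx + ny - 2)
        t_manual = (np.mean(x) - np.mean(y)) / np.sqrt(sp2 * (1 / nx + 1 / ny))
        assert comp.t_statistic == pytest.approx(t_manual, abs=1e-10)

    def test_positive_effect_detected_across_seeds(self):
        """Planted Bassoon+ intensity shift is recovered with p<0.05."""
        for seed in range(3):
            image, _ = generate_synaptosome_image(
                n_particles=120,
                frac_bassoon_pos=0.5,
                effect_size=15.0,
                noise_sd=2.0,
                seed=seed,
            )
            _, comp = quantify_image(image)
            pos_mean = np.nan_to_num(comp.t_statistic)
            assert comp.t_statistic > 0  # Bassoon+ mean higher
            assert comp.t_p < 0.05

    def test_null_calibration_small(self):
        """Reduced-size null check (the full 500-seed calibration runs in the
        acceptance suite): empirical FPR at alpha=0.05 stays near nominal."""
        ps = []
        for seed in range(60):
            image, _ = generate_synaptosome_image(
                n_particles=100, frac_bassoon_pos=0.5, effect_size=0.0, noise_sd=2.0, seed=seed
            )
            _, comp = quantify_image(image)
            ps.append(comp.t_p)
        fpr = float(np.mean(np.array(ps) < 0.05))
        assert 0.0 <= fpr <= 0.13  # 60 seeds: binomial 95% band around 0.05
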