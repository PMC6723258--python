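"""Label generation: normalisation, Otsu, splitting, erosion, the sweep."""

import numpy as np
import pytest
from scipy import ndimage as ndi
from skimage.morphology import disk

from phasetime import (
    BlobParams,
    InstanceMaskSet,
    binarize_otsu,
    erode_instances,
    erosion_sweep,
    generate_labels,
    normalize_minmax,
    patch_scale_config,
    simulate_scene,
    simulate_scenes,
    split_component,
)
from phasetime.evaluation import match_instances


PATCH_PARAMS = BlobParams.for_diameter_range(12.0, 26.0)


class TestNormalize:
    def test_linear_map(self):
        img = np.array([[10.0, 15.0], [20.0, 10.0]])
        out = normalize_minmax(img)
        assert out[0, 1] == pytest.approx(0.5)
        assert out.min() == 0.0 and out.max() == 1.0

    def test_constant_maps_to_zeros(self):
        assert (normalize_minmax(np.full((4, 4), 7.0)) == 0).all()

    def test_identity_on_unit_range(self):
        rng = np.random.default_rng(0)
        img = rng.random((8, 8))
        img[0, 0], img[-1, -1] = 0.0, 1.0
        assert np.allclose(normalize_minmax(img), img)

    def test_non_finite_rejected_with_count(self):
        img = np.ones((4, 4))
        img[0, 0] = np.nan
        img[1, 1] = np.inf
        with pytest.raises(ValueError, match="2 non-finite"):
            normalize_minmax(img)


class TestOtsu:
    def test_perfectly_separable(self):
        rng = np.random.default_rng(1)
        img = np.where(rng.random((16, 16)) > 0.7, 0.9, 0.1)
        fg = binarize_otsu(img)
        assert np.array_equal(fg, img == 0.9)

    def test_constant_image_all_background(self):
        assert not binarize_otsu(np.full((8, 8), 0.4)).any()

    def test_matches_exhaustive_between_class_variance(self):
        # brute-force oracle: the threshold implied by the foreground mask
        # must achieve the exhaustive maximum of between-class variance over
        # all 256-bin splits (ties across empty bins are equivalent splits)
        from skimage.filters import threshold_otsu

        rng = np.random.default_rng(2)
        for _ in range(100):
            n = int(rng.integers(50, 200))
            img = np.concatenate([
                rng.normal(0.25, 0.05, n), rng.normal(0.75, 0.05, n)
            ]).clip(0, 1).reshape(2, -1)
            hist, edges = np.histogram(img, bins=256, range=(img.min(), img.max()))
            centers = (edges[:-1] + edges[1:]) / 2
            total = hist.sum()
            variances = {}
            for k in range(1, 256):
                w0 = hist[:k].sum()
                w1 = total - w0
                if w0 == 0 or w1 == 0:
                    continue
                m0 = (hist[:k] * centers[:k]).sum() / w0
                m1 = (hist[k:] * centers[k:]).sum() / w1
                variances[k] = w0 * w1 * (m0 - m1) ** 2
            best = max(variances.values())
            t = threshold_otsu(img, nbins=256)
            k_chosen = int(np.searchsorted(centers, t, side="right"))
            assert variances[k_chosen] == pytest.approx(best, rel=1e-9)
            fg = binarize_otsu(img)
            assert np.array_equal(fg, img > t)


def gaussian_blob(shape, center, sigma, amp=1.0):
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    return amp * np.exp(-(((rr - center[0]) ** 2 + (cc - center[1]) ** 2)
                          / (2 * sigma**2)))


class TestSplitComponent:
    def test_isolated_blob_is_one_instance(self):
        img = gaussian_blob((48, 48), (24, 24), 6)
        comp = img > 0.3
        parts = split_component(comp, img, PATCH_PARAMS)
        assert len(parts) == 1
        assert np.array_equal(parts[0], comp)

    def test_bridged_blobs_split_at_true_centers(self):
        img = gaussian_blob((64, 64), (32, 20), 7) + gaussian_blob(
            (64, 64), (32, 44), 7)
        comp = img > 0.25
        assert ndi.label(comp)[1] == 1  # genuinely one bridged component
        parts = split_component(comp, img, PATCH_PARAMS)
        assert len(parts) == 2
        centers = sorted(ndi.center_of_mass(p) for p in parts)
        for got, true in zip(centers, [(32, 20), (32, 44)]):
            assert abs(got[0] - true[0]) <= 2 and abs(got[1] - true[1]) <= 2

    def test_partition_property(self):
        img = gaussian_blob((64, 64), (30, 22), 6) + gaussian_blob(
            (64, 64), (34, 42), 6)
        comp = img > 0.25
        parts = split_component(comp, img, PATCH_PARAMS)
        union = np.zeros_like(comp)
        overlap = np.zeros((64, 64), dtype=int)
        for p in parts:
            union |= p
            overlap += p.astype(int)
        assert np.array_equal(union, comp)  # exact tiling
        assert overlap.max() <= 1  # pairwise disjoint


class TestErodeInstances:
    def test_zero_erosion_identity(self):
        rng = np.random.default_rng(3)
        masks = [ndi.binary_dilation(np.eye(16, dtype=bool))]
        s = InstanceMaskSet((16, 16), masks)
        out = erode_instances(s, BlobParams(erosion_degree=0))
        assert out == s

    def test_disk_erosion_matches_morphology_oracle(self):
        # radius-10 disk eroded 4 times with a radius-1 disk element equals
        # 4 sequential applications of the scipy erosion oracle
        m = np.zeros((32, 32), dtype=bool)
        rr, cc = np.mgrid[:32, :32]
        m[(rr - 16) ** 2 + (cc - 16) ** 2 <= 100] = True
        s = InstanceMaskSet((32, 32), [m])
        out = erode_instances(s, BlobParams(erosion_degree=4, min_instance_area=1))
        oracle = m
        for _ in range(4):
            oracle = ndi.binary_erosion(oracle, structure=disk(1), border_value=0)
        assert np.array_equal(out.masks[0], oracle)

    def test_annihilation(self):
        m = np.zeros((16, 16), dtype=bool)
        m[6:9, 6:9] = True
        s = InstanceMaskSet((16, 16), [m])
        out = erode_instances(s, BlobParams(erosion_degree=5, min_instance_area=1))
        assert len(out) == 0

    def test_area_and_count_monotone_in_erosion(self):
        scene = simulate_scene(patch_scale_config(seed=13))
        prev_area, prev_count = np.inf, np.inf
        for e in (0, 2, 4, 6):
            p = BlobParams(erosion_degree=e,
                           log_sigma_range=PATCH_PARAMS.log_sigma_range)
            out = generate_labels(scene.fluor, p)
            area = sum(m.sum() for m in out.masks)
            assert area <= prev_area
            assert len(out) <= prev_count
            prev_area, prev_count = area, len(out)


class TestGenerateLabels:
    def test_blank_frame_empty_set(self, blank_scene):
        out = generate_labels(blank_scene.fluor, PATCH_PARAMS)
        assert len(out) == 0

    def test_recovers_synthetic_nuclei(self, small_scene):
        params = BlobParams.for_diameter_range(12, 26, erosion_degree=3)
        labels = generate_labels(small_scene.fluor, params)
        assert len(labels) == len(small_scene.truth)
        m = match_instances(small_scene.truth, labels, 0.5)
        assert m.fn == 0 and m.fp == 0
        assert all(iou >= 0.8 for _, _, iou in m.pairs)

    def test_output_disjoint(self, small_scene):
        labels = generate_labels(small_scene.fluor, PATCH_PARAMS)
        total = np.zeros(labels.shape, dtype=int)
        for m in labels.masks:
            total += m.astype(int)
        assert total.max() <= 1


class TestErosionSweep:
    def test_identity_case_gives_unit_iou(self, small_scene):
        # feed the generator's own E=0 output as golden: E=0 must score 1.0
        p0 = BlobParams(erosion_degree=0,
                        log_sigma_range=PATCH_PARAMS.log_sigma_range)
        golden = [generate_labels(small_scene.fluor, p0)]
        report = erosion_sweep([small_scene.fluor], golden, [0], p0)
        assert report["table"][0] == pytest.approx(1.0)
        assert report["best_e"] == 0

    def test_interior_optimum_with_positive_halo(self):
        scenes = simulate_scenes(patch_scale_config(seed=21), 6)
        report = erosion_sweep(
            [s.fluor for s in scenes], [s.truth for s in scenes],
            [0, 2, 4, 6, 8], PATCH_PARAMS)
        table = report["table"]
        best = report["best_e"]
        assert best not in (0, 8)  # interior optimum: rises then falls
        values = [table[e] for e in (0, 2, 4, 6, 8)]
        peak = values.index(max(values))
        assert all(values[i] <= values[i + 1] + 1e-9 for i in range(peak))
        assert all(values[i] >= values[i + 1] - 1e-9 for i in range(peak, 4))

    def test_empty_golden_raises(self, small_scene):
        with pytest.raises(ValueError):
            erosion_sweep([small_scene.fluor], [], [0, 2], PATCH_PARAMS)
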