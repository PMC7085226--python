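import numpy as np
import pytest
from scipy import ndimage
from scipy.spatial import cKDTree

from mpmquant import (
    ChannelRole,
    MpmImage,
    PreprocessConfig,
    SwsConfig,
    TpafPhantomParams,
    classify_nuclear_superpixels,
    generate_tpaf,
    mean_nuclear_area,
    measure_nuclei,
    preprocess_tpaf,
    segment_nuclei,
    sws_superpixels,
)
from mpmquant.nuclei import NucleusRecord, SuperpixelLabeling
from mpmquant.errors import ConfigError, DimensionError, NoNucleiError


def tpaf(arr, bit_depth=8):
    return MpmImage(np.asarray(arr), ChannelRole.TPAF, bit_depth=bit_depth)


class TestPreprocess:
    def test_constant_image_stays_constant(self):
        out = preprocess_tpaf(tpaf(np.full((32, 32), 123, np.uint8)), PreprocessConfig())
        assert np.ptp(out) == 0
        assert 0 <= out.min() and out.max() <= 255

    def test_dark_speck_grows_to_erosion_disk(self):
        # 9x9 bright field with one dark pixel; with negligible smoothing and
        # plain erosion (radius 2), exactly the 13 pixels of the radius-2
        # disk around the speck become dark
        arr = np.full((9, 9), 200, np.uint8)
        arr[4, 4] = 40
        cfg = PreprocessConfig(
            gaussian_sigma_px=0.01, erosion_radius_px=2, use_reconstruction=False
        )
        out = preprocess_tpaf(tpaf(arr), cfg)
        dark = out < 128
        rr, cc = np.mgrid[0:9, 0:9]
        disk = (np.abs(rr - 4) + np.abs(cc - 4) <= 2) | (
            ((rr - 4) ** 2 + (cc - 4) ** 2) <= 4
        )
        np.testing.assert_array_equal(dark, disk)
        assert dark.sum() == 13

    def test_output_stays_in_bit_range(self, rng):
        arr = rng.integers(0, 65536, (48, 48)).astype(np.uint16)
        out = preprocess_tpaf(tpaf(arr, bit_depth=16), PreprocessConfig())
        assert out.min() >= 0 and out.max() <= 65535

    def test_reconstruction_bounded_by_plain_erosion(self, rng):
        # opening-by-reconstruction lies between the eroded and smoothed image
        arr = rng.integers(0, 256, (32, 32)).astype(np.uint8)
        plain = preprocess_tpaf(
            tpaf(arr), PreprocessConfig(use_reconstruction=False)
        )
        rec = preprocess_tpaf(tpaf(arr), PreprocessConfig(use_reconstruction=True))
        assert np.all(rec >= plain - 1e-9)

    def test_too_small_image_raises(self):
        with pytest.raises(DimensionError):
            preprocess_tpaf(tpaf(np.zeros((3, 3), np.uint8)), PreprocessConfig())

    def test_wrong_channel_role_rejected(self):
        shg = MpmImage(np.zeros((16, 16), np.uint8), ChannelRole.SHG)
        with pytest.raises(ValueError):
            preprocess_tpaf(shg, PreprocessConfig())


class TestSws:
    @pytest.mark.parametrize("seed", range(5))
    def test_partition_with_one_connected_region_per_seed(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.normal(100, 20, (64, 80))
        lab = sws_superpixels(img, SwsConfig(seed_spacing_px=16))
        labels = lab.labels
        assert labels.min() == 1 and labels.max() == lab.n_regions
        assert len(np.unique(labels)) == lab.n_regions
        for k, (r, c) in enumerate(lab.seeds, start=1):
            assert labels[r, c] == k
        # every region 4-connected
        for k in range(1, lab.n_regions + 1):
            n_comp = ndimage.label(labels == k)[1]
            assert n_comp == 1

    def test_uniform_image_gives_voronoi_tessellation(self):
        img = np.full((100, 120), 50.0)
        lab = sws_superpixels(img, SwsConfig(seed_spacing_px=24))
        tree = cKDTree(lab.seeds)
        rr, cc = np.mgrid[0:100, 0:120]
        d, idx = tree.query(np.column_stack([rr.ravel(), cc.ravel()]), k=2)
        clear = d[:, 1] - d[:, 0] > 1.0  # outside the one-pixel tie band
        assert np.array_equal(
            lab.labels.ravel()[clear], idx[clear, 0] + 1
        )

    def test_no_region_spans_a_strong_edge(self):
        img = np.zeros((16, 16))
        img[:, 8:] = 200.0
        lab = sws_superpixels(img, SwsConfig(seed_spacing_px=5))
        left = set(np.unique(lab.labels[:, :8]))
        right = set(np.unique(lab.labels[:, 8:]))
        assert not left & right

    def test_oversized_spacing_rejected(self):
        with pytest.raises(ConfigError):
            sws_superpixels(np.zeros((16, 16)), SwsConfig(seed_spacing_px=16))


class TestClassification:
    def test_phantom_nuclei_found_exactly(self):
        p = TpafPhantomParams(
            n_nuclei=6, noise_sd=0, n_bright_blobs=0,
            nucleus_level=10, cytoplasm_level=200, seed=2,
        )
        img, gt = generate_tpaf(p)
        prep = preprocess_tpaf(img, PreprocessConfig())
        lab = sws_superpixels(prep, SwsConfig(seed_spacing_px=10))
        nuclear = classify_nuclear_superpixels(lab, prep)
        assert nuclear
        union = np.isin(lab.labels, sorted(nuclear))
        gt_mask = gt > 0
        # returned superpixels cover the nuclei and essentially nothing else
        assert (union & gt_mask).sum() / gt_mask.sum() > 0.9
        assert (union & ~gt_mask).sum() / union.sum() < 0.15

    def test_constant_image_yields_empty_set(self):
        prep = np.full((64, 64), 80.0)
        lab = sws_superpixels(prep, SwsConfig(seed_spacing_px=16))
        assert classify_nuclear_superpixels(lab, prep) == set()

    def test_inverted_phantom_returns_dark_side(self):
        # bright nuclei on dark field: out-of-contract input; the dark-side
        # convention then selects the background superpixels
        img = np.full((64, 64), 20.0)
        img[20:30, 20:30] = 220.0
        lab = sws_superpixels(img, SwsConfig(seed_spacing_px=16))
        picked = classify_nuclear_superpixels(lab, img)
        rest = set(range(1, lab.n_regions + 1)) - picked
        mean_picked = img[np.isin(lab.labels, sorted(picked))].mean()
        mean_rest = img[np.isin(lab.labels, sorted(rest))].mean()
        assert mean_picked < mean_rest


class TestMeasure:
    def test_single_superpixel_pixel_count(self):
        labels = np.ones((20, 35), dtype=np.int32)  # 700 px
        labels[0, 0] = 2
        lab = SuperpixelLabeling(labels=labels, seeds=np.array([[5, 5], [0, 0]]))
        recs = measure_nuclei(lab, {1}, SwsConfig())
        assert len(recs) == 1 and recs[0].area_px2 == 699

    def test_adjacent_nuclear_superpixels_merge(self):
        labels = np.full((30, 30), 3, dtype=np.int32)
        labels[0:10, 0:30] = 1   # 300 px
        labels[10:24, 0:25] = 2  # 350 px, touching region 1
        lab = SuperpixelLabeling(
            labels=labels, seeds=np.array([[5, 5], [15, 5], [28, 28]])
        )
        merged = measure_nuclei(lab, {1, 2}, SwsConfig(merge_adjacent_nuclear=True))
        assert [r.area_px2 for r in merged] == [650]

        split = measure_nuclei(lab, {1, 2}, SwsConfig(merge_adjacent_nuclear=False))
        assert sorted(r.area_px2 for r in split) == [300, 350]

    def test_small_component_filtered(self):
        labels = np.full((20, 20), 2, dtype=np.int32)
        labels[0:2, 0:5] = 1  # 10 px < min 50
        lab = SuperpixelLabeling(labels=labels, seeds=np.array([[0, 0], [10, 10]]))
        assert measure_nuclei(lab, {1}, SwsConfig()) == []

    def test_unknown_label_rejected(self):
        labels = np.ones((10, 10), dtype=np.int32)
        lab = SuperpixelLabeling(labels=labels, seeds=np.array([[5, 5]]))
        with pytest.raises(ValueError):
            measure_nuclei(lab, {9}, SwsConfig())


class TestMeanArea:
    def test_closed_forms(self):
        mk = lambda a: NucleusRecord(1, a, (0.0, 0.0), 0.0)
        assert mean_nuclear_area([mk(600)]) == 600
        assert mean_nuclear_area([mk(500), mk(700)]) == 600

    def test_empty_flagged_not_zero(self):
        with pytest.raises(NoNucleiError):
            mean_nuclear_area([])


class TestEndToEnd:
    def test_noise_free_recovery_within_15pct(self):
        p = TpafPhantomParams(
            image_shape=(256, 256), n_nuclei=8, nucleus_area_mean_px2=900,
            nucleus_area_sd_px2=280, noise_sd=0, n_bright_blobs=0, seed=1,
        )
        img, gt = generate_tpaf(p)
        recs, _, _ = segment_nuclei(img, sws_cfg=SwsConfig(seed_spacing_px=10))
        assert len(recs) == 8
        gt_areas = np.bincount(gt.ravel())[1:]
        cents = ndimage.center_of_mass(gt > 0, gt, np.arange(1, gt.max() + 1))
        for k, (cy, cx) in enumerate(cents):
            nearest = min(
                recs, key=lambda r: (r.centroid[0] - cy) ** 2 + (r.centroid[1] - cx) ** 2
            )
            assert abs(nearest.area_px2 - gt_areas[k]) / gt_areas[k] < 0.15

    def test_scaling_phantom_increases_measured_areas(self):
        areas = []
        for scale in (1.0, 1.4):
            p = TpafPhantomParams(
                image_shape=(256, 256), n_nuclei=5,
                nucleus_area_mean_px2=600 * scale**2, nucleus_area_sd_px2=0,
                noise_sd=0, n_bright_blobs=0, seed=7,
            )
            img, _ = generate_tpaf(p)
            recs, _, _ = segment_nuclei(img, sws_cfg=SwsConfig(seed_spacing_px=10))
            areas.append(sorted(r.area_px2 for r in recs))
        assert len(areas[0]) == len(areas[1]) == 5
        assert all(b > a for a, b in zip(*areas))

    def test_same_input_same_records(self):
        p = TpafPhantomParams(n_nuclei=5, seed=13)
        img, _ = generate_tpaf(p)
        r1, _, _ = segment_nuclei(img, sws_cfg=SwsConfig(seed_spacing_px=10))
        r2, _, _ = segment_nuclei(img, sws_cfg=SwsConfig(seed_spacing_px=10))
        assert [(r.nucleus_id, r.area_px2, r.centroid) for r in r1] == [
            (r.nucleus_id, r.area_px2, r.centroid) for r in r2
        ]
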