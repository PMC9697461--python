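"""Phantom generator: sampling fidelity, geometry invariants, ground truth."""

import numpy as np
import pytest

import mandifrac as mf
from mandifrac import phantom
from mandifrac.phantom import (CLASS_NAMES, DEFAULT_CLASS_PROBS, PhantomConfig,
                               PhantomError)


class TestClassSampling:
    def test_degenerate_distribution_is_constant(self, rng):
        labels = mf.sample_fracture_classes(5, (1, 0, 0, 0, 0, 0), rng)
        assert labels == ["symphysis"] * 5

    def test_uniform_frequencies_within_three_se(self, rng):
        n = 10_000
        labels = mf.sample_fracture_classes(n, [1 / 6] * 6, rng)
        se = np.sqrt((1 / 6) * (5 / 6) / n)
        for name in CLASS_NAMES:
            freq = labels.count(name) / n
            assert abs(freq - 1 / 6) <= 3 * se

    def test_clinical_probs_symphysis_frequency(self, rng):
        n = 624
        labels = mf.sample_fracture_classes(n, DEFAULT_CLASS_PROBS, rng)
        p = DEFAULT_CLASS_PROBS[0]
        se = np.sqrt(p * (1 - p) / n)
        assert abs(labels.count("symphysis") / n - p) <= 3 * se

    @pytest.mark.parametrize("bad", [(0.5, 0.5, 0.5, 0, 0, 0),
                                     (0.2,) * 6,
                                     (-0.1, 0.3, 0.2, 0.2, 0.2, 0.2)])
    def test_non_normalized_probs_rejected(self, bad, rng):
        with pytest.raises(PhantomError):
            mf.sample_fracture_classes(10, bad, rng)


class TestScene:
    def test_same_seed_gives_identical_scene(self, smoke_cfg):
        s1 = mf.build_scene(smoke_cfg, np.random.default_rng(7))
        s2 = mf.build_scene(smoke_cfg, np.random.default_rng(7))
        np.testing.assert_array_equal(s1.arch_polyline, s2.arch_polyline)
        np.testing.assert_array_equal(s1.tooth_polygon, s2.tooth_polygon)

    def test_arch_and_teeth_inside_bounds(self):
        cfg = PhantomConfig(width=512, height=512)
        scene = mf.build_scene(cfg, np.random.default_rng(0))
        for pts in (scene.arch_polyline, scene.tooth_polygon):
            assert pts[:, 0].min() >= 0 and pts[:, 0].max() < 512
            assert pts[:, 1].min() >= 0 and pts[:, 1].max() < 512

    def test_sectors_cover_arch_and_are_disjoint(self, smoke_cfg):
        scene = mf.build_scene(smoke_cfg, np.random.default_rng(1))
        intervals = sorted(
            iv for ivs in scene.sector_map.values() for iv in ivs)
        assert intervals[0][0] == 0.0 and intervals[-1][1] == 1.0
        for (a0, a1), (b0, b1) in zip(intervals, intervals[1:]):
            assert a1 == pytest.approx(b0)   # contiguous, non-overlapping
        assert set(scene.sector_map) == set(CLASS_NAMES)

    def test_too_small_image_rejected(self):
        with pytest.raises(PhantomError):
            PhantomConfig(width=64, height=64)


class TestRendering:
    def test_noise_free_render_is_deterministic(self, smoke_cfg):
        out = []
        for _ in range(2):
            rng = np.random.default_rng(3)
            scene = mf.build_scene(smoke_cfg, rng)
            out.append(mf.render_phantom(scene, [], 0.0, rng))
        np.testing.assert_array_equal(out[0], out[1])

    def test_oblique_gap_darker_than_flanking_bone(self, smoke_cfg):
        rng = np.random.default_rng(4)
        scene = mf.build_scene(smoke_cfg, rng)
        spec = phantom._place_fracture(scene, "body", "oblique_gap",
                                       smoke_cfg, rng)
        img = mf.render_phantom(scene, [spec], 0.0, rng)
        line = phantom.rasterize_polyline(spec.polyline, img.shape)
        bone = phantom._band_mask(scene.arch_polyline, scene.arch_halfwidth,
                                  scene.height, scene.width)
        gap = phantom.binary_dilation(
            line, structure=phantom._disk(1)) & bone
        flank = bone & ~phantom.binary_dilation(
            line, structure=phantom._disk(int(spec.gap_px) + 4))
        x0, y0, x1, y1 = spec.box
        flank_local = np.zeros_like(flank)
        flank_local[y0:y1, x0:x1] = flank[y0:y1, x0:x1]
        assert img[gap].mean() < img[flank_local].mean() - 20

    def test_displaced_fracture_has_no_line_label(self, smoke_cfg):
        rng = np.random.default_rng(5)
        scene = mf.build_scene(smoke_cfg, rng)
        spec = phantom._place_fracture(scene, "condyle", "displaced",
                                       smoke_cfg, rng)
        gt = mf.make_ground_truth(scene, [spec])
        x0, y0, x1, y1 = spec.box
        assert gt.line_mask[y0:y1, x0:x1].sum() == 0
        assert len(gt.boxes) == 1

    def test_displaced_morphology_restricted_to_condyle(self, smoke_cfg):
        rng = np.random.default_rng(6)
        scene = mf.build_scene(smoke_cfg, rng)
        with pytest.raises(PhantomError):
            phantom._place_fracture(scene, "body", "displaced", smoke_cfg, rng)


class TestGroundTruth:
    def test_empty_specs_give_empty_labels(self, smoke_cfg):
        scene = mf.build_scene(smoke_cfg, np.random.default_rng(0))
        gt = mf.make_ground_truth(scene, [])
        assert gt.line_mask.sum() == 0 and gt.boxes == []

    def test_oblique_plus_displaced_exclusion(self, smoke_cfg):
        rng = np.random.default_rng(8)
        scene = mf.build_scene(smoke_cfg, rng)
        specs = [phantom._place_fracture(scene, "body", "oblique_gap",
                                         smoke_cfg, rng),
                 phantom._place_fracture(scene, "condyle", "displaced",
                                         smoke_cfg, rng)]
        gt = mf.make_ground_truth(scene, specs)
        assert len(gt.boxes) == 2
        from skimage.measure import label
        assert label(gt.line_mask, connectivity=2).max() == 1

    def test_box_contains_polyline_raster(self, smoke_cfg):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            scene = mf.build_scene(smoke_cfg, rng)
            specs = phantom.sample_fracture_specs(scene, smoke_cfg, rng, n=3)
            for s in specs:
                x0, y0, x1, y1 = s.box
                assert s.polyline[:, 0].min() >= x0
                assert s.polyline[:, 1].min() >= y0
                assert s.polyline[:, 0].max() < x1
                assert s.polyline[:, 1].max() < y1

    def test_box_count_conservation(self, smoke_cfg):
        for seed in range(10):
            img, gt = mf.generate_phantom(smoke_cfg, 300 + seed)
            assert len(gt.boxes) == len(gt.specs)
            from skimage.measure import label
            n_lines = label(gt.line_mask, connectivity=2).max()
            n_crack = sum(1 for s in gt.specs if s.shape != "displaced")
            assert n_lines <= n_crack


class TestDataset:
    def test_file_counts_and_manifest(self, tmp_path):
        cfg = PhantomConfig(width=128, height=128, seed=11)
        manifest = mf.generate_dataset(cfg, 4, tmp_path)
        assert len(manifest["images"]) == 4
        for suffix, count in ((".png", 12), (".txt", 4)):
            files = [p for p in tmp_path.iterdir() if p.suffix == suffix]
            assert len(files) == count

    def test_regeneration_same_seed_identical_hashes(self, tmp_path):
        cfg = PhantomConfig(width=128, height=128, seed=21)
        digests = []
        for sub in ("a", "b"):
            mf.generate_dataset(cfg, 3, tmp_path / sub)
            digests.append(phantom.dataset_digest(tmp_path / sub))
        assert digests[0] == digests[1]

    def test_sampled_class_counts_match_clinical_distribution(self):
        from scipy.stats import chisquare
        rng = np.random.default_rng(0)
        labels = mf.sample_fracture_classes(624, DEFAULT_CLASS_PROBS, rng)
        obs = np.array([labels.count(c) for c in CLASS_NAMES])
        exp = np.asarray(DEFAULT_CLASS_PROBS) * 624
        stat, p = chisquare(obs, exp)
        assert p > 0.01
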