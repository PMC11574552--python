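"""Labelling, watershed decomposition and distance-transform covariates."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

from rhizokde import (
    ClassProbabilityStack,
    CovariateCalculator,
    PixelGrid,
    RootGeometry,
    SceneConfig,
    argmax_classify,
    compute_covariates,
    generate_scene,
    overlay_root,
    rasterize_root,
    watershed_decompose,
)
from rhizokde.segmentation import CLASS_INDEX, CLASS_NAMES, extract_patches


def one_hot_stack(labels: np.ndarray, px: float = 6.21) -> ClassProbabilityStack:
    probs = np.zeros((len(CLASS_NAMES),) + labels.shape, dtype=float)
    for k in range(len(CLASS_NAMES)):
        probs[k][labels == k] = 1.0
    return ClassProbabilityStack(probs, px)


class TestArgmaxClassify:
    def test_one_hot_stack_recovers_labels(self, rng):
        labels = rng.integers(0, 5, size=(32, 32)).astype(np.uint8)
        out = argmax_classify(one_hot_stack(labels))
        np.testing.assert_array_equal(out, labels)

    def test_uniform_stack_breaks_ties_to_particle(self):
        probs = np.full((5, 8, 8), 0.2)
        out = argmax_classify(ClassProbabilityStack(probs, 6.21))
        assert np.all(out == CLASS_INDEX["PARTICLE"])

    def test_nan_probabilities_rejected(self):
        probs = np.full((5, 4, 4), 0.2)
        probs[0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            ClassProbabilityStack(probs, 6.21)

    def test_flip_noise_keeps_high_pixel_agreement(self):
        """5% label-flip noise leaves ≥94% of pixels agreeing with the
        scene's ground truth labels."""
        cfg = SceneConfig(tile_width_mm=1.6, tile_height_mm=1.6,
                          label_flip_rate=0.05)
        s = generate_scene(cfg, 0, 24.0, seed=8)
        out = argmax_classify(ClassProbabilityStack(s.probstack.astype(float),
                                                    cfg.pixel_size_um))
        truth = s.labelmap.copy()
        truth[s.root_mask] = CLASS_INDEX["PORE"]
        agreement = np.mean(out == truth)
        assert agreement >= 0.94


class TestRasterizeRoot:
    def _rect_geom(self, x0, y0, x1, y1):
        boundary = np.array([[x0, y0], [x1, y0], [x1, y1], [x0, y1], [x0, y0]])
        centreline = np.array([[(x0 + x1) / 2, y1], [(x0 + x1) / 2, y0]])
        return RootGeometry(centreline=centreline, boundary=boundary)

    def test_rectangle_area(self):
        px = 10.0
        geom = self._rect_geom(100, 200, 400, 800)  # 300 × 600 µm
        mask = rasterize_root(geom, (100, 100), px)
        area = mask.sum() * px * px
        ring = 2 * (300 + 600) * px
        assert abs(area - 300 * 600) <= ring

    def test_empty_polygon_raises(self):
        geom = self._rect_geom(0, 0, 10, 10)
        geom.boundary = np.empty((0, 2))
        with pytest.raises(ValueError, match="empty"):
            rasterize_root(geom, (8, 8), 6.21)

    def test_open_polygon_raises(self):
        geom = self._rect_geom(0, 0, 50, 50)
        geom.boundary = geom.boundary[:-1]  # drop the closing vertex
        with pytest.raises(ValueError, match="closed"):
            rasterize_root(geom, (16, 16), 6.21)

    def test_matches_generator_mask_exactly(self, scene, default_config):
        mask = rasterize_root(scene.geometry, scene.root_mask.shape,
                              default_config.pixel_size_um)
        np.testing.assert_array_equal(mask, scene.root_mask)

    def test_root_overrides_all_other_labels(self, scene):
        stack = ClassProbabilityStack(scene.probstack.astype(float), 6.21)
        labels = overlay_root(argmax_classify(stack), scene.root_mask)
        assert np.all(labels[scene.root_mask] == 5)
        inside = labels[scene.root_mask]
        assert not np.isin(inside, [CLASS_INDEX[c] for c in
                                    ("PARTICLE", "MB", "RB", "PB")]).any()


def disc_mask(shape, center, radius):
    yy, xx = np.mgrid[:shape[0], :shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius ** 2


class TestWatershed:
    def test_two_bridged_discs_split_into_two(self):
        mask = disc_mask((60, 120), (30, 30), 12) | disc_mask((60, 120), (30, 80), 12)
        mask[30, 30:81] = True  # 1-px bridge
        labels = watershed_decompose(mask)
        ids = np.unique(labels[labels > 0])
        assert len(ids) == 2
        disc_area = disc_mask((60, 120), (30, 30), 12).sum()
        bridge = mask.sum() - 2 * disc_area
        for i in ids:
            assert abs((labels == i).sum() - disc_area) <= bridge + 2

    def test_single_disc_passes_through(self):
        mask = disc_mask((40, 40), (20, 20), 10)
        labels = watershed_decompose(mask)
        assert np.array_equal(labels > 0, mask)
        assert labels.max() == 1

    def test_empty_mask_gives_empty_labels(self):
        labels = watershed_decompose(np.zeros((16, 16), dtype=bool))
        assert labels.max() == 0

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="shape"):
            watershed_decompose(np.ones((8, 8), bool),
                                PixelGrid(np.zeros((9, 9)), 6.21))

    def test_partition_conserves_area_on_random_masks(self, rng):
        """Watershed regions partition the mask exactly: labelled pixels
        equal mask pixels and labels are disjoint by construction."""
        for _ in range(10):
            mask = ndimage.binary_dilation(
                rng.random((64, 64)) > 0.93, iterations=2)
            labels = watershed_decompose(mask)
            assert (labels > 0).sum() == mask.sum()
            assert np.array_equal(labels > 0, mask)


class TestCovariates:
    def _flat_scene(self):
        """Particle block on the left, straight vertical root at x≈40 px."""
        px = 6.21
        particle = np.zeros((64, 64), bool)
        particle[:, :8] = True
        root = np.zeros((64, 64), bool)
        root[:, 38:43] = True
        centre = np.array([[40.5 * px, 63.5 * px], [40.5 * px, 0.5 * px]])
        boundary = np.array([[38 * px, 0], [43 * px, 0], [43 * px, 64 * px],
                             [38 * px, 64 * px], [38 * px, 0]])
        geom = RootGeometry(centreline=centre, boundary=boundary)
        return particle, root, geom, px

    def test_point_on_particle_has_zero_dp(self):
        particle, root, geom, px = self._flat_scene()
        dp, _, _ = compute_covariates((4.5 * px, 10.5 * px), particle, root,
                                      geom, px)
        assert dp == 0.0

    def test_distance_from_flat_root_edge(self):
        particle, root, geom, px = self._flat_scene()
        # 10 pixels to the right of the root's last column (42)
        dp, dr, _ = compute_covariates(((42 + 10 + 0.5) * px, 30.5 * px),
                                       particle, root, geom, px)
        assert dr == pytest.approx(10 * px, abs=px / 2)

    def test_tip_point_has_zero_da(self):
        particle, root, geom, px = self._flat_scene()
        _, _, da = compute_covariates((40.5 * px, 63.0 * px), particle, root,
                                      geom, px)
        assert da <= px

    def test_point_outside_grid_raises(self):
        particle, root, geom, px = self._flat_scene()
        with pytest.raises(ValueError, match="outside"):
            compute_covariates((1000 * px, 30 * px), particle, root, geom, px)

    def test_distance_transforms_match_bruteforce(self, rng):
        """dp and dr agree with the brute-force minimum distance to any
        foreground pixel within half a pixel diagonal, on random masks."""
        px = 6.21
        for _ in range(5):
            particle = rng.random((64, 64)) > 0.97
            root = rng.random((64, 64)) > 0.98
            if not particle.any() or not root.any():
                continue
            geom = RootGeometry(centreline=np.array([[10.0, 10.0], [50.0, 50.0]]),
                                boundary=np.array([[0, 0], [1, 0], [1, 1],
                                                   [0, 0]], dtype=float))
            calc = CovariateCalculator(particle, root, geom, px)
            pts_idx = rng.integers(0, 64, size=(40, 2))
            pts = (pts_idx[:, ::-1] + 0.5) * px
            cov = calc(pts)
            pr, pc = np.nonzero(particle)
            rr, rc = np.nonzero(root)
            for k, (row, col) in enumerate(pts_idx):
                bf_dp = np.min(np.hypot(pr - row, pc - col)) * px
                bf_dr = np.min(np.hypot(rr - row, rc - col)) * px
                assert abs(cov[k, 0] - bf_dp) <= px * np.sqrt(2) / 2
                assert abs(cov[k, 1] - bf_dr) <= px * np.sqrt(2) / 2

    def test_dilating_particles_never_increases_dp(self, scene, default_config):
        px = default_config.pixel_size_um
        calc1 = CovariateCalculator(scene.particle_mask, scene.root_mask,
                                    scene.geometry, px)
        dilated = ndimage.binary_dilation(scene.particle_mask, iterations=2)
        calc2 = CovariateCalculator(dilated, scene.root_mask, scene.geometry, px)
        assert np.all(calc2.dp_map <= calc1.dp_map + 1e-9)


class TestExtractPatches:
    def _calc(self, shape, px):
        particle = np.zeros(shape, bool)
        particle[0, 0] = True
        root = np.zeros(shape, bool)
        root[-1, -1] = True
        geom = RootGeometry(centreline=np.array([[1.0, 1.0], [5.0, 5.0]]),
                            boundary=np.array([[0, 0], [1, 0], [1, 1],
                                               [0, 0]], dtype=float))
        return CovariateCalculator(particle, root, geom, px)

    def test_constant_square_area_and_intensity(self):
        px = 6.21
        labels = np.zeros((32, 32), np.int32)
        labels[10:20, 10:20] = 1
        img = PixelGrid(np.where(labels == 1, 50.0, 0.0), px)
        out = extract_patches(labels, "MB", img, self._calc((32, 32), px),
                              24.0, 0, 0)
        assert len(out) == 1
        assert out["area_um2"].iloc[0] == pytest.approx(100 * px * px)
        assert out["area_um2"].iloc[0] == pytest.approx(3856.41, abs=0.01)
        assert out["mean_intensity"].iloc[0] == 50.0

    def test_mean_of_three_intensities(self):
        px = 6.21
        labels = np.zeros((8, 8), np.int32)
        labels[2, 2:5] = 1
        img = np.zeros((8, 8))
        img[2, 2:5] = [10.0, 20.0, 30.0]
        out = extract_patches(labels, "MB", PixelGrid(img, px),
                              self._calc((8, 8), px), 12.0, 0, 0,
                              min_area_px=1)
        assert out["mean_intensity"].iloc[0] == pytest.approx(20.0)

    def test_small_regions_are_discarded(self):
        px = 6.21
        labels = np.zeros((8, 8), np.int32)
        labels[1, 1:4] = 1  # 3 px < default min_area_px=4
        img = PixelGrid(np.ones((8, 8)), px)
        out = extract_patches(labels, "MB", img, self._calc((8, 8), px),
                              12.0, 0, 0)
        assert len(out) == 0

    def test_noiseless_scene_total_intensity_conserved(self, scene,
                                                       default_config):
        """Per-class summed intensity A·I/px² of recovered patches equals the
        planted calibrated totals exactly on a noiseless scene (splitting or
        merging by the watershed cannot create or destroy fluorescence)."""
        import tempfile

        import rhizokde
        with tempfile.TemporaryDirectory() as d:
            rhizokde.write_scene_dir(scene, d)
            rec = rhizokde.segment_scene(d, min_area_px=1)
        px = default_config.pixel_size_um
        rec_tot = (rec["mean_intensity"] * rec["area_um2"] / px ** 2
                   ).groupby(rec["class"]).sum()
        gt_tot = scene.patches.groupby("class")["total_intensity"].sum()
        for cls in gt_tot.index:
            assert rec_tot[cls] == pytest.approx(gt_tot[cls], rel=1e-9)

    def test_noiseless_isolated_patches_roundtrip(self, scene, default_config):
        """Well-separated planted patches are recovered one-to-one with the
        planted area (within 2 boundary-pixel areas) and exact intensity."""
        import tempfile

        import rhizokde
        from rhizokde import render_scene
        from rhizokde.synthetic import SceneGroundTruth, write_scene_dir
        cfg = default_config
        px = cfg.pixel_size_um
        # plant patches at deep pore points separated by ≥ 600 µm
        depth = ndimage.distance_transform_edt(scene.pore_mask) * px
        order = np.argsort(depth.ravel())[::-1]
        pts, min_sep = [], 600.0
        for flat in order:
            r, c = np.unravel_index(flat, depth.shape)
            p = np.array([(c + 0.5) * px, (r + 0.5) * px])
            if depth[r, c] < 60:
                break
            if all(np.linalg.norm(p - q) > min_sep for q in pts):
                pts.append(p)
            if len(pts) == 6:
                break
        assert len(pts) == 6
        planted = pd.DataFrame({
            "class": ["MB", "MB", "RB", "RB", "PB", "PB"],
            "cx_um": [p[0] for p in pts], "cy_um": [p[1] for p in pts],
            "area_um2": [1500.0, 3000.0, 2000.0, 900.0, 1200.0, 2500.0],
            "cells": [50, 200, 400, 120, 300, 80],
        })
        cal = cfg.calibration()
        intensity, probstack, labelmap, realized = render_scene(
            planted, scene.particle_mask, scene.root_mask, cal, px, 0)
        s = SceneGroundTruth(
            config=cfg, root_id=0, tile_id=0, timepoint_h=24.0,
            intensity=intensity, probstack=probstack, labelmap=labelmap,
            particle_mask=scene.particle_mask, root_mask=scene.root_mask,
            pore_mask=scene.pore_mask, geometry=scene.geometry,
            patches=realized, achieved_packing=scene.achieved_packing, seed=0)
        with tempfile.TemporaryDirectory() as tmp:
            write_scene_dir(s, tmp)
            rec = rhizokde.segment_scene(tmp, timepoint_h=24.0, root_id=0,
                                         tile_id=0)
        gt = realized.sort_values(["cx_um", "cy_um"]).reset_index(drop=True)
        rec = rec.sort_values(["cx_um", "cy_um"]).reset_index(drop=True)
        assert len(rec) == len(gt)
        np.testing.assert_array_equal(rec["class"], gt["class"])
        total_rec = rec["mean_intensity"] * rec["area_um2"] / px ** 2
        np.testing.assert_allclose(total_rec, gt["total_intensity"], rtol=1e-9)
        np.testing.assert_allclose(rec["area_um2"], gt["area_um2"],
                                   atol=2 * px * px)
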