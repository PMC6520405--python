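"""ROI construction geometry and the 114-feature extractor."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Polygon

from tphen import (
    RoiConfig,
    build_rois,
    density_ratios,
    extract_features,
    feature_names,
    knn_cross_distance,
    roi_density,
)
from tphen.patch_factory import HeatmapClass, PatchSpec, melanin_heatmap_from_cells
from tphen.roi_features import ROI_NAMES, density_names
from tphen.types import CellMap

CFG = RoiConfig(pixel_size_um=4.0, heatmap_patch_px=20)  # 338 µm -> 85 px, 676 µm -> 169 px


def _square(cx, cy, half):
    return Polygon([(cx - half, cy - half), (cx + half, cy - half),
                    (cx + half, cy + half), (cx - half, cy + half)])


def _full_tissue(shape):
    return {"CD3": np.ones(shape, dtype=bool)}


class TestBuildRois:
    def test_band_area_matches_closed_form_for_square_tumor(self):
        # disk-dilation of an s x s square adds 4*s*w + pi*w^2 of area
        shape = (1200, 1200)
        s, w = 400, CFG.tme_small_px
        rois = build_rois(_square(600, 600, s // 2), [], _full_tissue(shape), None, CFG)
        expected = 4 * s * w + np.pi * w**2
        assert rois["tme_small"].sum() == pytest.approx(expected, rel=0.02)

    def test_exclusion_halves_the_band(self):
        shape = (1200, 1200)
        rois_free = build_rois(_square(600, 600, 200), [], _full_tissue(shape), None, CFG)
        # exclusion covering the left half of the frame
        excl = Polygon([(-1, -1), (599.5, -1), (599.5, 1201), (-1, 1201)])
        rois_half = build_rois(_square(600, 600, 200), [excl], _full_tissue(shape), None, CFG)
        ratio = rois_half["tme_small"].sum() / rois_free["tme_small"].sum()
        assert ratio == pytest.approx(0.5, abs=0.01)

    def test_stroma_is_frame_minus_tumor_without_exclusions(self):
        shape = (600, 600)
        rois = build_rois(_square(300, 300, 100), [], _full_tissue(shape), None, CFG)
        assert rois["stroma"].sum() == shape[0] * shape[1] - rois["tumor"].sum()

    def test_fully_eroded_tumor_warns_and_iti_equals_tumor(self):
        shape = (600, 600)
        with pytest.warns(UserWarning, match="fully eroded"):
            rois = build_rois(_square(300, 300, 80), [], _full_tissue(shape), None, CFG)
        assert (rois["iti"] == rois["tumor"]).all()
        assert not rois.tumor_core.any()

    @pytest.mark.parametrize("seed", range(10))
    def test_containment_and_disjointness_invariants(self, seed):
        rng = np.random.default_rng(seed)
        shape = (700, 700)
        cx, cy = rng.uniform(250, 450, size=2)
        n_vert = rng.integers(6, 14)
        phis = np.sort(rng.uniform(0, 2 * np.pi, n_vert))
        r = rng.uniform(120, 220, size=n_vert)
        poly = Polygon(np.column_stack([cx + r * np.cos(phis), cy + r * np.sin(phis)]))
        if not poly.is_valid or poly.area < 1000:
            pytest.skip("degenerate random polygon")
        excl = _square(rng.uniform(100, 600), rng.uniform(100, 600), 40)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rois = build_rois(poly, [excl], _full_tissue(shape), None, CFG)
        assert not (rois["iti"] & ~rois["tumor"]).any()
        assert not (rois["tme_small"] & ~rois["tme_large"]).any()
        assert not (rois["tme_large"] & rois["tumor"]).any()
        assert not (rois["stroma"] & rois["tumor"]).any()
        assert (rois["tumor_stroma"] == (rois["tumor"] | rois["stroma"])).all()
        for name in ROI_NAMES:
            assert not (rois[name] & rois.exclusions).any()
            assert not (rois[name] & ~rois.tissue).any()

    def test_empty_tumor_annotation_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            build_rois(_square(-500, -500, 10), [], _full_tissue((100, 100)), None, CFG)


class TestRoiDensity:
    def test_plain_count_over_area(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[:20, :20] = True  # 400 px = 1 heatmap unit at 20-px patches
        pts = np.column_stack([np.linspace(1, 18, 10), np.linspace(1, 18, 10)])
        assert roi_density(pts, mask, CFG) == pytest.approx(10.0)

    def test_all_positives_in_melanin_patches_gives_zero(self):
        mask = np.ones((40, 40), dtype=bool)
        pts = np.array([[5.0, 5.0], [15.0, 15.0]])
        spec = PatchSpec(patch_px=CFG.heatmap_patch_px, pixel_size_um=CFG.pixel_size_um)
        heat = melanin_heatmap_from_cells(pts, (40, 40), spec)
        assert roi_density(pts, mask, CFG, melanin_heatmap=heat) == 0.0

    def test_zero_area_roi_is_missing_not_zero(self):
        val = roi_density(np.zeros((0, 2)), np.zeros((10, 10), dtype=bool), CFG)
        assert np.isnan(val)

    def test_poisson_pattern_recovered_within_three_se(self, rng):
        lam = 4.0  # per heatmap unit of 400 px
        mask = np.ones((400, 400), dtype=bool)
        n_units = mask.size / CFG.heatmap_patch_px**2
        n = rng.poisson(lam * n_units)
        pts = rng.uniform(0, 399, size=(n, 2))
        est = roi_density(pts, mask, CFG)
        se = np.sqrt(lam / n_units)
        assert abs(est - lam) < 3 * se


class TestDensityRatios:
    def test_all_equal_densities_give_unit_ratios(self):
        dens = {name: 2.5 for name in density_names()}
        ratios = density_ratios(dens)
        assert len(ratios) == 66
        assert all(v == pytest.approx(1.0) for v in ratios.values())

    def test_ratio_above_published_cut_classifies_responder(self):
        dens = {name: 1.0 for name in density_names()}
        dens["density:CD8:iti"] = 5.5
        dens["density:CD8:stroma"] = 1.0
        ratios = density_ratios(dens)
        # canonical order emits stroma/iti; the reciprocal recovers iti/stroma
        assert 1.0 / ratios["ratio:CD8:stroma/CD8:iti"] == pytest.approx(5.5)

    def test_count_is_12_choose_2(self):
        assert len(density_ratios({n: 1.0 for n in density_names()})) == 66

    def test_zero_denominator_propagates_missing(self):
        dens = {name: 1.0 for name in density_names()}
        dens["density:CD8:iti"] = 0.0
        ratios = density_ratios(dens)
        assert np.isnan(ratios["ratio:CD8:stroma/CD8:iti"])


class TestKnnCrossDistance:
    def test_single_pair_distance_with_truncation_flag(self):
        val, truncated = knn_cross_distance(
            np.array([[0.0, 0.0]]), np.array([[3.0, 4.0]]), k=2, roi_mask=None,
            pixel_size_um=0.22,
        )
        assert val == pytest.approx(5 * 0.22)
        assert truncated

    def test_coincident_duplicated_points_give_zero(self):
        a = np.array([[5.0, 5.0]])
        b = np.array([[5.0, 5.0], [5.0, 5.0]])
        val, truncated = knn_cross_distance(a, b, k=2, roi_mask=None, pixel_size_um=1.0)
        assert val == 0.0 and not truncated

    def test_matches_brute_force_all_pairs(self, rng):
        a = rng.uniform(0, 100, size=(50, 2))
        b = rng.uniform(0, 100, size=(60, 2))
        val, _ = knn_cross_distance(a, b, k=4, roi_mask=None, pixel_size_um=1.0)
        d = np.sqrt(((a[:, None, :] - b[None, :, :]) ** 2).sum(-1))
        brute = np.sort(d, axis=1)[:, :4].mean()
        assert val == pytest.approx(brute, rel=1e-12)

    def test_empty_sets_missing(self):
        val, _ = knn_cross_distance(np.zeros((0, 2)), np.ones((3, 2)), 2, None, 1.0)
        assert np.isnan(val)

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            knn_cross_distance(np.ones((2, 2)), np.ones((2, 2)), 0, None, 1.0)


class TestExtractFeatures:
    def test_every_case_has_114_uniquely_named_features(self, cohort_features):
        table, _ = cohort_features
        names = feature_names()
        assert table.shape[1] == 114
        assert len(set(names)) == 114
        assert list(table.columns) == names

    def test_zero_cd8_case_keeps_column_count(self, cohort):
        cases, cellmaps, annotations = cohort
        cid = cases[0].case_id
        maps = dict(cellmaps[cid])
        cd8 = maps["CD8"]
        maps["CD8"] = CellMap(stain="CD8", cells=cd8.cells.iloc[:0], image_shape=cd8.image_shape,
                              pixel_size_um=cd8.pixel_size_um, tissue_mask=cd8.tissue_mask)
        ann = annotations[cid]
        from tphen.roi_features import build_rois

        cfg = RoiConfig(pixel_size_um=cd8.pixel_size_um)
        rois = build_rois(ann.tumor_polygon, [], {"CD3": maps["CD3"].tissue_mask}, None, cfg)
        row = extract_features(maps, rois, cfg, grid=ann.transform_cd8_to_cd3)
        assert len(row) == 114
        assert np.isnan(row["density:CD8:iti"])
        assert np.isnan(row["knn:CD3->CD8:tumor:k2"])
        assert np.isfinite(row["density:CD3:tumor"])

    def test_ratio_features_invariant_to_doubling_counts(self, cohort):
        cases, cellmaps, annotations = cohort
        cid = cases[0].case_id
        maps = cellmaps[cid]
        ann = annotations[cid]
        cfg = RoiConfig(pixel_size_um=maps["CD3"].pixel_size_um)
        from tphen.roi_features import build_rois, ratio_names

        rois = build_rois(ann.tumor_polygon, [], {"CD3": maps["CD3"].tissue_mask}, None, cfg)
        row = extract_features(maps, rois, cfg, grid=ann.transform_cd8_to_cd3)
        doubled = {}
        for stain, cm in maps.items():
            cells2 = pd.concat([cm.cells, cm.cells], ignore_index=True)
            doubled[stain] = CellMap(stain=stain, cells=cells2, image_shape=cm.image_shape,
                                     pixel_size_um=cm.pixel_size_um, tissue_mask=cm.tissue_mask)
        row2 = extract_features(doubled, rois, cfg, grid=ann.transform_cd8_to_cd3)
        for name in ratio_names():
            if np.isfinite(row[name]):
                assert row2[name] == pytest.approx(row[name], rel=1e-9)

    def test_distance_features_invariant_to_joint_translation(self, rng):
        shape = (600, 600)
        a = rng.uniform(150, 450, size=(40, 2))
        b = rng.uniform(150, 450, size=(40, 2))
        val, _ = knn_cross_distance(a, b, 4, None, 1.0)
        val_shift, _ = knn_cross_distance(a + 37.0, b + 37.0, 4, None, 1.0)
        assert val_shift == pytest.approx(val, rel=1e-12)
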