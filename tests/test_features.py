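"""Segmentation and the 17-parameter phase signature."""

import numpy as np
import pandas as pd
import pytest

from emscore import features, holography, simulate
from emscore.features import FEATURE_NAMES, CellMask

PITCH = 0.18


def _disk_height(radius=20, h=3000.0, shape=(128, 128), center=None):
    cy, cx = center or (shape[0] // 2, shape[1] // 2)
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    arr = np.where((yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2, h, 0.0)
    return holography.HeightMap(arr, PITCH)


class TestSegmentation:
    def test_single_disk(self):
        masks = features.segment_cells(_disk_height())
        assert len(masks) == 1
        expected = np.pi * 20**2
        assert masks[0].area_px == pytest.approx(expected, rel=0.05)

    def test_empty_map(self):
        assert features.segment_cells(holography.HeightMap(np.zeros((64, 64)))) == []

    def test_two_separated_disks(self):
        arr = _disk_height(center=(40, 40)).height + _disk_height(center=(40, 100)).height
        masks = features.segment_cells(holography.HeightMap(arr, PITCH))
        assert len(masks) == 2
        lbl = features.masks_to_label_image(masks, arr.shape)
        # brute-force pairwise disjointness
        assert np.sum((lbl == 1) & (lbl == 2)) == 0
        assert {m.area_px for m in masks} == {int((lbl == 1).sum()), int((lbl == 2).sum())}

    def test_touching_domes_split(self):
        yy, xx = np.mgrid[0:128, 0:200]
        d1 = np.clip(1 - ((yy - 64) ** 2 + (xx - 60) ** 2) / 40**2, 0, None)
        d2 = np.clip(1 - ((yy - 64) ** 2 + (xx - 140) ** 2) / 40**2, 0, None)
        arr = 3000 * np.maximum(d1, d2)
        masks = features.segment_cells(holography.HeightMap(arr, PITCH))
        assert len(masks) == 2

    def test_min_area_filter(self):
        arr = _disk_height(radius=3).height  # ~28 px < default 50
        assert features.segment_cells(holography.HeightMap(arr, PITCH)) == []

    def test_border_flagged(self):
        masks = features.segment_cells(_disk_height(center=(5, 64)))
        assert len(masks) == 1 and masks[0].touches_border


class TestExtractFeatures:
    def test_constant_disk(self):
        hmap = _disk_height(radius=25, h=2500.0)
        mask = features.segment_cells(hmap)[0]
        rec = features.extract_features(mask, hmap)
        assert rec["eccentricity"] < 0.05
        assert rec["circularity"] > 0.95
        assert rec["mean_height_nm"] == pytest.approx(2500.0)
        assert rec["max_height_nm"] == pytest.approx(2500.0)
        assert rec["height_sd_nm"] == 0.0
        # constant interior: one quantization level
        assert rec["glcm_energy"] == pytest.approx(1.0)
        assert rec["glcm_contrast"] == pytest.approx(0.0)
        assert rec["intensity_entropy_bits"] == pytest.approx(0.0)

    def test_ellipse_eccentricity(self):
        yy, xx = np.mgrid[0:128, 0:128]
        arr = np.where(((yy - 64) / 20) ** 2 + ((xx - 64) / 40) ** 2 <= 1, 1000.0, 0.0)
        hmap = holography.HeightMap(arr, PITCH)
        rec = features.extract_features(features.segment_cells(hmap)[0], hmap)
        assert rec["eccentricity"] == pytest.approx(np.sqrt(1 - 1 / 4), rel=0.02)
        assert rec["aspect_ratio"] == pytest.approx(2.0, rel=0.02)

    def test_phase_volume_closed_form(self):
        hmap = _disk_height(radius=20, h=1000.0)
        mask = features.segment_cells(hmap)[0]
        rec = features.extract_features(mask, hmap)
        expected = mask.area_px * PITCH**2 * 1.0  # 1000 nm = 1 μm
        assert rec["phase_volume_um3"] == pytest.approx(expected, rel=1e-6)

    def test_translation_and_rotation_invariance(self):
        """Shape features depend only on the mask geometry, not its pose."""
        yy, xx = np.mgrid[0:160, 0:160]
        base = np.where(((yy - 60) / 18) ** 2 + ((xx - 70) / 35) ** 2 <= 1, 900.0, 0.0)
        shifted = np.roll(base, (25, 12), axis=(0, 1))
        rotated = np.rot90(base)
        shape_feats = ["area_um2", "perimeter_um", "circularity", "eccentricity",
                       "solidity", "aspect_ratio"]
        recs = []
        for arr in (base, shifted, rotated):
            hmap = holography.HeightMap(arr, PITCH)
            recs.append(features.extract_features(features.segment_cells(hmap)[0], hmap))
        for f in shape_feats:
            vals = [r[f] for r in recs]
            assert max(vals) - min(vals) <= 0.02 * abs(np.mean(vals)) + 1e-9

    def test_empty_mask_rejected(self):
        m = CellMask(label=1, patch=np.zeros((4, 4), bool), bbox=(0, 0, 4, 4))
        with pytest.raises(ValueError):
            features.extract_features(m, np.zeros((8, 8)))


class TestFeatureTable:
    def test_empty_input_full_header(self):
        tbl = features.build_feature_table([])
        assert list(tbl.columns) == FEATURE_NAMES + features.METADATA_COLUMNS
        assert len(tbl) == 0

    def test_duplicate_field_ids_rejected(self):
        hmap = _disk_height()
        with pytest.raises(ValueError):
            features.build_feature_table([("f0", "A", hmap), ("f0", "B", hmap)])

    def test_order_invariance(self):
        h1, h2 = _disk_height(), _disk_height(radius=15, h=1500)
        t1 = features.build_feature_table([("a", "A", h1), ("b", "B", h2)])
        t2 = features.build_feature_table([("b", "B", h2), ("a", "A", h1)])
        key = ["field_id", "cell_id"]
        s1 = t1.sort_values(key).reset_index(drop=True)
        s2 = t2.sort_values(key).reset_index(drop=True)
        pd.testing.assert_frame_equal(s1, s2)

    def test_ground_truth_blend_attached(self):
        prof = simulate.LineProfile("E", 4, 0.3)
        cfg = simulate.SimulationConfig(
            line_profiles=(prof, simulate.MESENCHYMAL_ARCHETYPE), seed=6)
        pm, gt = simulate.generate_field(cfg, "E")
        hm = holography.phase_to_height(pm)
        tbl = features.build_feature_table([("f0", "E", hm, gt)])
        assert len(tbl) == 4
        assert np.allclose(tbl["blend_m"], 0.3)

    def test_archetype_contrast(self, feature_table):
        """Mesenchymal archetype cells measure more eccentric and flatter."""
        gie = feature_table[feature_table["line"] == "GIE"]
        hgf = feature_table[feature_table["line"] == "HGF"]
        assert hgf["eccentricity"].mean() > gie["eccentricity"].mean()
        assert gie["max_height_nm"].mean() > hgf["max_height_nm"].mean()
        assert hgf["area_um2"].mean() > gie["area_um2"].mean()
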