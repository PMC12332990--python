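import numpy as np
import pandas as pd
import pytest

from adrenalct.io import CTVolume, LabelMask
from adrenalct.phantom import PhantomSpec, generate_phantom
from adrenalct.preprocess import window_normalize
from adrenalct.radiomics import (
    GlandRegion,
    SelectionConfig,
    extract_features,
    extract_gland_regions,
    select_features,
)

FAMILIES = ("firstorder", "shape", "glcm", "glrlm", "glszm", "ngtdm")


def phantom_regions(nodule_left=None, seed=0):
    spec = PhantomSpec(
        dims=(48, 48, 24), spacing=(1.0, 1.0, 3.0), noise_sigma=5.0,
        nodule_left=nodule_left, seed=seed,
    )
    vol, mask, *_ = generate_phantom(spec)
    return extract_gland_regions(window_normalize(vol), mask)


class TestExtractRegions:
    def test_both_sides_tagged(self):
        regions = phantom_regions()
        assert [r.side for r in regions] == ["left", "right"]

    def test_volume_arithmetic(self):
        region = phantom_regions()[0]
        assert region.volume_mm3 == region.voxel_count * 3.0

    def test_single_label_single_region(self):
        m = np.zeros((10, 10, 4), dtype=np.int16)
        m[2:5, 2:5, 1:3] = 1
        regions = extract_gland_regions(
            CTVolume(np.random.default_rng(0).random((10, 10, 4))), LabelMask(m)
        )
        assert len(regions) == 1 and regions[0].side == "left"

    def test_empty_mask(self):
        regions = extract_gland_regions(
            CTVolume(np.zeros((5, 5, 5))), LabelMask(np.zeros((5, 5, 5), np.int16))
        )
        assert regions == []

    def test_misaligned_mask_rejected(self):
        with pytest.raises(ValueError, match="aligned"):
            extract_gland_regions(
                CTVolume(np.zeros((5, 5, 5))),
                LabelMask(np.ones((4, 4, 4), np.int16)),
            )


class TestExtractFeatures:
    def test_all_families_present(self):
        feats = extract_features(phantom_regions()[0])
        for fam in FAMILIES:
            assert any(k.startswith(fam + "_") for k in feats), fam
        assert all(np.isfinite(v) for v in feats.values())

    def test_constant_region_degenerate_texture(self):
        box = np.full((4, 4, 4), 0.5, dtype=np.float32)
        mask = np.ones((4, 4, 4), dtype=bool)
        region = GlandRegion("left", box, mask, (1, 1, 1), (0, 0, 0))
        feats = extract_features(region)
        assert feats["firstorder_Variance"] == 0.0
        assert feats["firstorder_Uniformity"] == 1.0  # single gray level
        assert feats["glcm_Contrast"] == 0.0

    def test_translation_invariance(self):
        rng = np.random.default_rng(3)
        box = rng.random((5, 6, 4)).astype(np.float32)
        mask = rng.random((5, 6, 4)) < 0.6
        mask[2, 2, 2] = True
        r1 = GlandRegion("left", box, mask, (1, 1, 3), (0, 0, 0))
        r2 = GlandRegion("left", box.copy(), mask.copy(), (1, 1, 3), (10, 20, 5))
        assert extract_features(r1) == extract_features(r2)

    def test_deterministic(self):
        r = phantom_regions()[1]
        assert extract_features(r) == extract_features(r)

    def test_volume_scaling_with_nodule(self):
        # doubling the nodule diameter multiplies its support volume ~x8
        # (identified as the bright voxels of a noiseless phantom)
        def nodule_volume(diameter):
            spec = PhantomSpec(
                dims=(48, 48, 24), spacing=(1.0, 1.0, 3.0), noise_sigma=0.0,
                nodule_left=(diameter, 40.0),
            )
            vol, mask, *_ = generate_phantom(spec)
            bright = (mask.voxels == 1) & (vol.voxels > spec.gland_hu + 20.0)
            return bright.sum() * 3.0

        ratio = nodule_volume(16.0) / nodule_volume(8.0)
        assert 5.0 < ratio < 11.0  # x8 within discretization tolerance

    def test_single_voxel_region(self):
        box = np.full((1, 1, 1), 0.4, dtype=np.float32)
        region = GlandRegion("right", box, np.ones((1, 1, 1), bool), (1, 1, 1), (0, 0, 0))
        feats = extract_features(region)
        assert np.isfinite(feats["firstorder_Mean"])
        assert np.isfinite(feats["shape_VolumeMm3"])
        assert np.isnan(feats["glcm_Contrast"])

    def test_mirror_symmetry(self):
        # mirroring the phantom left-right swaps the two sides' features
        spec = PhantomSpec(dims=(48, 48, 24), spacing=(1, 1, 3), noise_sigma=0.0)
        vol, mask, *_ = generate_phantom(spec)
        vol = window_normalize(vol)
        flipped_vol = vol.with_voxels(np.flip(vol.voxels, axis=1).copy())
        swap = np.flip(mask.voxels, axis=1).copy()
        swap = np.where(swap == 1, 3, swap)
        swap = np.where(swap == 2, 1, swap)
        swap = np.where(swap == 3, 2, swap).astype(np.int16)
        flipped_mask = mask.with_voxels(swap)
        orig = {r.side: extract_features(r) for r in extract_gland_regions(vol, mask)}
        mirr = {
            r.side: extract_features(r)
            for r in extract_gland_regions(flipped_vol, flipped_mask)
        }
        for key in orig["left"]:
            a, b = orig["left"][key], mirr["right"][key]
            assert a == pytest.approx(b, rel=1e-6), key


class TestSelectFeatures:
    def _table(self, X, y, side="left"):
        df = pd.DataFrame(X, columns=[f"f{i:02d}" for i in range(X.shape[1])])
        df["side"] = side
        df["label"] = y
        return df

    def test_planted_signal_recovered(self):
        # 3 signal columns among noise; majority over 20 seeds
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 200
            X = rng.normal(size=(n, 15))
            y = (X[:, 0] + X[:, 1] - X[:, 2] + 0.3 * rng.normal(size=n) > 0).astype(int)
            sel = select_features(
                self._table(X, y), "left", SelectionConfig(cap=3, seed=seed)
            )
            if set(sel.selected) == {"f00", "f01", "f02"}:
                hits += 1
        assert hits >= 11

    def test_duplicate_column_filtered(self, rng):
        X = rng.normal(size=(60, 5))
        X[:, 4] = X[:, 0]  # exact duplicate
        y = (X[:, 0] > 0).astype(int)
        sel = select_features(self._table(X, y), "left", SelectionConfig(cap=5))
        assert sel.trace["correlation_filter"] == 4
        assert not {"f00", "f04"} <= set(sel.selected)

    def test_cap_respected(self, rng):
        X = rng.normal(size=(80, 30))
        y = (X[:, :6].sum(axis=1) > 0).astype(int)
        sel = select_features(self._table(X, y), "left", SelectionConfig(cap=6))
        assert len(sel.selected) <= 6

    def test_one_class_error(self, rng):
        X = rng.normal(size=(20, 4))
        sel_err = self._table(X, np.ones(20, dtype=int))
        with pytest.raises(ValueError, match="one-class"):
            select_features(sel_err, "left")

    def test_zero_variance_dropped(self, rng):
        X = rng.normal(size=(50, 4))
        X[:, 3] = 7.0
        y = (X[:, 0] > 0).astype(int)
        sel = select_features(self._table(X, y), "left", SelectionConfig(cap=4))
        assert sel.trace["variance_filter"] == 3
        assert "f03" not in sel.selected

    def test_selection_separates_classes(self, tmp_path):
        # phantom cohort: at least one selected feature has AUC > 0.8
        from adrenalct.classify import roc_auc
        from adrenalct.phantom import generate_cohort
        from adrenalct.radiomics import build_feature_table
        from adrenalct.io import load_volume

        man = generate_cohort(
            30, 0.5, laterality_weights=(1.0, 0.0, 0.0), seed=5,
            out_dir=tmp_path, dims=(48, 48, 24), contrast_range=(40, 60),
            noise_sigma=5.0,
        )
        cases = [
            (
                r["patient_id"],
                window_normalize(load_volume(r["image"])),
                load_volume(r["mask"], as_mask=True),
                r["left_label"],
                r["right_label"],
            )
            for r in man.to_dict("records")
        ]
        table = build_feature_table(cases)
        sub = table[table["side"] == "left"]
        sel = select_features(sub, "left", SelectionConfig(cap=6, seed=0))
        aucs = [
            max(
                roc_auc(sub[f].to_numpy(), sub["label"]).auc,
                1 - roc_auc(sub[f].to_numpy(), sub["label"]).auc,
            )
            for f in sel.selected
        ]
        assert max(aucs) > 0.8
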