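"""Cropping, splits, balanced sampling, augmentation, MIL bags."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from morphoprof import (
    augment_crop,
    balanced_epoch_sample,
    build_mil_bags,
    crop_cells,
    filter_max_concentration,
    filter_min_cells,
    split_leave_cells_out,
    split_leave_plates_out,
)


def _index(rows):
    df = pd.DataFrame(rows)
    df.insert(0, "Cell_Id", np.arange(len(df)))
    return df


def make_cell_index(n_plates=2, wells=("A01", "A02"), cells_per_well=10,
                    treatments=None):
    rows = []
    for p in range(n_plates):
        for w in wells:
            t = treatments.get(w, "DMSO") if treatments else "DMSO"
            for c in range(cells_per_well):
                rows.append(
                    dict(Metadata_Plate=f"P{p+1:02d}", Metadata_Well=w,
                         Metadata_Site=1, Nuclei_Location_Center_X=10.0,
                         Nuclei_Location_Center_Y=10.0, Treatment=t,
                         Control=t == "DMSO", Concentration=0.0 if t == "DMSO" else 10.0)
                )
    return _index(rows)


class TestCropCells:
    def test_center_crop_of_constant_image(self):
        field = np.ones((64, 64, 2))
        crops = crop_cells(field, np.array([[32.0, 32.0]]), crop_size=16)
        assert crops.shape == (1, 16, 16, 2)
        assert (crops == 1).all()

    def test_corner_crop_zero_padded_layout(self):
        """Center (0,0): only the bottom-right quadrant of the crop overlaps
        the image; verified against explicit index arithmetic."""
        field = np.arange(128 * 128, dtype=float).reshape(128, 128)[:, :, None]
        crops = crop_cells(field, np.array([[0.0, 0.0]]), crop_size=128)
        crop = crops[0, :, :, 0]
        # window is [-64, 64) in both axes; image support covers [0, 64)
        assert (crop[:64, :] == 0).all()
        assert (crop[:, :64] == 0).all()
        np.testing.assert_array_equal(crop[64:, 64:], field[:64, :64, 0])
        assert (crop != 0).sum() == 64 * 64 - 1  # pixel (0,0) has value 0

    def test_order_preserved(self):
        field = np.zeros((64, 64, 1))
        field[10, 20, 0] = 1.0
        field[30, 40, 0] = 2.0
        centers = np.array([[20.0, 10.0], [40.0, 30.0], [20.0, 10.0]])
        crops = crop_cells(field, centers, crop_size=8)
        assert crops[0, 4, 4, 0] == 1.0
        assert crops[1, 4, 4, 0] == 2.0
        assert crops[2, 4, 4, 0] == 1.0

    def test_out_of_bounds_center_identifies_row(self):
        with pytest.raises(ValueError, match="row 1"):
            crop_cells(np.zeros((32, 32, 1)), np.array([[5.0, 5.0], [40.0, 5.0]]))

    def test_translation_consistency(self):
        rng = np.random.default_rng(0)
        field = rng.uniform(size=(64, 64, 1))
        shifted = np.roll(field, (3, 5), axis=(0, 1))
        a = crop_cells(field, np.array([[30.0, 30.0]]), crop_size=16)
        b = crop_cells(shifted, np.array([[35.0, 33.0]]), crop_size=16)
        np.testing.assert_array_equal(a, b)


class TestSplits:
    def test_leave_cells_out_well_fractions(self):
        idx = make_cell_index(cells_per_well=10)
        split = split_leave_cells_out(idx, train_frac=0.6, seed=0)
        merged = idx.assign(tag=split.tags.loc[idx["Cell_Id"]].to_numpy())
        for _, grp in merged.groupby(["Metadata_Plate", "Metadata_Well"]):
            assert (grp["tag"] == "train").sum() == 6

    def test_leave_cells_out_all_train_and_determinism(self):
        idx = make_cell_index()
        split = split_leave_cells_out(idx, train_frac=1.0, seed=3)
        assert (split.tags == "train").all()
        a = split_leave_cells_out(idx, seed=5).tags
        b = split_leave_cells_out(idx, seed=5).tags
        pd.testing.assert_series_equal(a, b)

    def test_leave_cells_out_empty_errors(self):
        with pytest.raises(ValueError):
            split_leave_cells_out(_index([]))

    def test_leave_plates_out_holds_two_wells_per_treatment(self):
        # 5 plates, every treatment on every plate -> 2 plates out
        rows = []
        for p in range(5):
            for w, t in [("A01", "T1"), ("A02", "T2"), ("A03", "DMSO")]:
                rows.append(dict(Metadata_Plate=f"P{p+1}", Metadata_Well=w,
                                 Metadata_Site=1, Treatment=t, Control=t == "DMSO"))
        idx = _index(rows)
        split = split_leave_plates_out(idx, n_replicate_wells_out=2)
        report = split.report.set_index("Treatment")
        assert (report["held_out_wells"] == 2).all()
        # plate atomicity
        merged = idx.assign(tag=split.tags.loc[idx["Cell_Id"]].to_numpy())
        assert (merged.groupby("Metadata_Plate")["tag"].nunique() == 1).all()

    def test_leave_plates_out_infeasible_design(self):
        rows = [
            dict(Metadata_Plate="P1", Metadata_Well="A01", Metadata_Site=1,
                 Treatment="T1", Control=False),
            dict(Metadata_Plate="P2", Metadata_Well="A01", Metadata_Site=1,
                 Treatment="DMSO", Control=True),
        ]
        with pytest.raises(ValueError, match="T1"):
            split_leave_plates_out(_index(rows), n_replicate_wells_out=2)


class TestBalancedEpochSample:
    def test_median_class_size_contract(self):
        rows = []
        for t, n in [("A", 10), ("B", 20), ("C", 60)]:
            rows += [dict(Metadata_Plate="P1", Metadata_Well="A01",
                          Metadata_Site=1, Treatment=t, Control=False)] * n
        idx = _index(rows)
        epoch = balanced_epoch_sample(idx, seed=0)
        assert len(epoch) == 60
        counts = idx.set_index("Cell_Id").loc[epoch, "Treatment"].value_counts()
        assert (counts == 20).all()
        # class A (10 cells) is oversampled with replacement
        a_ids = set(idx[idx["Treatment"] == "A"]["Cell_Id"])
        drawn_a = [i for i in epoch if i in a_ids]
        assert len(drawn_a) == 20 and len(set(drawn_a)) <= 10

    def test_equal_classes_give_permutation(self):
        rows = []
        for t in ("A", "B"):
            rows += [dict(Metadata_Plate="P1", Metadata_Well="A01",
                          Metadata_Site=1, Treatment=t, Control=False)] * 8
        idx = _index(rows)
        epoch = balanced_epoch_sample(idx, seed=1)
        assert sorted(epoch) == sorted(idx["Cell_Id"])

    def test_singleton_class_oversampled(self):
        rows = [dict(Metadata_Plate="P1", Metadata_Well="A01", Metadata_Site=1,
                     Treatment="A", Control=False)]
        rows += [dict(Metadata_Plate="P1", Metadata_Well="A01", Metadata_Site=1,
                      Treatment="B", Control=False)] * 20
        idx = _index(rows)
        epoch = balanced_epoch_sample(idx, seed=2)
        # m = round(median({1, 20})) = 10 or 11; singleton repeated m times
        counts = idx.set_index("Cell_Id").loc[epoch, "Treatment"].value_counts()
        assert counts["A"] == counts["B"]
        assert counts["A"] >= 10


class _ForcedRng:
    """Deterministic stub driving augment_crop through chosen branches."""

    def __init__(self, randoms, integers_vals, uniforms):
        self._r = list(randoms)
        self._i = list(integers_vals)
        self._u = list(uniforms)

    def random(self):
        return self._r.pop(0)

    def integers(self, lo, hi):
        return self._i.pop(0)

    def uniform(self, lo, hi=None):
        return self._u.pop(0)


class TestAugmentCrop:
    def test_identity_branches_return_input(self, rng):
        crop = rng.uniform(size=(16, 16, 2)).astype(np.float32)
        forced = _ForcedRng(randoms=[0.9, 0.9], integers_vals=[0],
                            uniforms=[0.0, 1.0, 0.0, 1.0])
        out = augment_crop(crop, forced)
        np.testing.assert_allclose(out, crop, atol=1e-6)

    def test_brightness_preserves_ranks(self, rng):
        crop = rng.uniform(0.2, 0.8, size=(16, 16, 3)).astype(np.float32)
        forced = _ForcedRng(randoms=[0.9, 0.9], integers_vals=[0],
                            uniforms=[0.1, 1.0, -0.1, 1.0, 0.05, 1.0])
        out = augment_crop(crop, forced)
        for c in range(3):
            rho = spearmanr(crop[:, :, c].ravel(), out[:, :, c].ravel()).statistic
            assert rho > 0.999

    def test_crop_branch_scales_disc_radius(self):
        h = 128
        yy, xx = np.mgrid[0:h, 0:h]
        disc = (np.hypot(yy - h / 2 + 0.5, xx - h / 2 + 0.5) < 30).astype(np.float32)
        crop = disc[:, :, None]
        # force: crop branch on with scale 0.8 centered, no flip/rot, no jitter
        forced = _ForcedRng(randoms=[0.1, 0.9],
                            integers_vals=[int((h - round(0.8 * h)) / 2),
                                           int((h - round(0.8 * h)) / 2), 0],
                            uniforms=[0.8, 0.0, 1.0])
        out = augment_crop(crop, forced)
        radius = np.sqrt((out[:, :, 0] > 0.5).sum() / np.pi)
        assert radius == pytest.approx(30 / 0.8, abs=1.0)

    def test_shape_unchanged_under_random_draws(self, rng):
        crop = rng.uniform(size=(32, 32, 5)).astype(np.float32)
        for _ in range(10):
            out = augment_crop(crop, rng)
            assert out.shape == crop.shape
            assert out.min() >= 0.0 and out.max() <= 1.0


class TestMILBags:
    def _idx(self):
        rows = []
        for t, n in [("DMSO", 40), ("T1", 20), ("T2", 6)]:
            rows += [dict(Metadata_Plate="P1", Metadata_Well="A01",
                          Metadata_Site=1, Treatment=t, Control=t == "DMSO")] * n
        return _index(rows)

    def test_bag_composition_rules(self):
        idx = self._idx()
        bags = build_mil_bags(idx, bag_size=16, bags_per_class=5, seed=0)
        by_id = idx.set_index("Cell_Id")
        counts = {}
        for bag in bags:
            assert len(bag.member_ids) == 16
            members = by_id.loc[bag.member_ids]
            if bag.label == "DMSO":
                assert members["Control"].all()
                assert bag.n_treated == 0
            else:
                n_t = (members["Treatment"] == bag.label).sum()
                assert 4 <= bag.n_treated <= 12
                assert n_t >= bag.n_treated  # drawn members carry the label
                assert (members["Control"] | (members["Treatment"] == bag.label)).all()
            counts[bag.label] = counts.get(bag.label, 0) + 1
        assert set(counts.values()) == {5}

    def test_no_controls_errors(self):
        idx = self._idx()
        with pytest.raises(ValueError, match="control"):
            build_mil_bags(idx[~idx["Control"]].reset_index(drop=True))

    def test_resampling_differs_by_seed(self):
        idx = self._idx()
        a = build_mil_bags(idx, seed=0)
        b = build_mil_bags(idx, seed=1)
        assert any(
            not np.array_equal(x.member_ids, y.member_ids) for x, y in zip(a, b)
        )


def test_filters():
    rows = []
    for t, n, conc in [("T1", 5, 10.0), ("T2", 120, 10.0), ("DMSO", 150, 0.0)]:
        rows += [dict(Metadata_Plate="P1", Metadata_Well="A01", Metadata_Site=1,
                      Treatment=t, Control=t == "DMSO", Concentration=conc)] * n
    rows += [dict(Metadata_Plate="P1", Metadata_Well="A02", Metadata_Site=1,
                  Treatment="T2", Control=False, Concentration=3.0)] * 50
    idx = _index(rows)
    kept = filter_max_concentration(idx)
    assert (kept.loc[kept["Treatment"] == "T2", "Concentration"] == 10.0).all()
    kept2 = filter_min_cells(kept, min_cells=100)
    assert set(kept2["Treatment"]) == {"T2", "DMSO"}
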