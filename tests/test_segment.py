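"""Segmentation operators against brute-force oracles and simulator truth."""
from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from hcscreen.segment import (
    SegmentationParams,
    SegmentationResult,
    adaptive_mean_threshold,
    check_mask_algebra,
    filter_small_objects,
    make_cell_masks,
    remove_edge_cells,
    rolling_ball_subtract,
    segment_field,
    split_touching_nuclei,
)
from hcscreen.simulate import render_field, sample_field_cells

from .oracles import grayscale_opening, local_mean, nearest_seed_dilation


def _disc_mask(shape, center, radius):
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


class TestRollingBall:
    def test_constant_image_maps_to_zero(self):
        img = np.full((40, 40), 37.0)
        assert np.all(rolling_ball_subtract(img, 5) == 0.0)

    def test_zeros_stay_zeros(self):
        assert np.all(rolling_ball_subtract(np.zeros((30, 30)), 10) == 0.0)

    def test_spot_preserved_and_gradient_removed(self):
        # linear background + one bright 3-px-wide spot, large ball
        h = w = 80
        bg = np.linspace(0, 30, w)[None, :] * np.ones((h, 1))
        img = bg.copy()
        img[40:43, 40:43] += 500.0
        out = rolling_ball_subtract(img, 25)
        assert out[41, 41] == pytest.approx(500.0, rel=0.05)
        far = out[:20, :20]
        assert np.abs(far).max() <= 0.05 * 30

    @pytest.mark.parametrize("radius", [2, 3, 5, 8])
    def test_matches_bruteforce_opening(self, radius, rng):
        img = rng.integers(0, 1000, size=(48, 48)).astype(float)
        expected = np.clip(img - grayscale_opening(img, radius), 0, None)
        assert np.array_equal(rolling_ball_subtract(img, radius), expected)

    def test_oversized_radius_warns(self):
        with pytest.warns(UserWarning, match="radius"):
            rolling_ball_subtract(np.ones((10, 10)), 11)


class TestAdaptiveMeanThreshold:
    def test_constant_image_all_background_with_positive_offset(self):
        img = np.full((30, 30), 10.0)
        assert not adaptive_mean_threshold(img, 5, 1.0).any()

    def test_bright_disc_interior_is_foreground(self):
        img = np.zeros((64, 64))
        disc = _disc_mask(img.shape, (32, 32), 5.5)  # 11-px-wide disc
        img[disc] = 400.0
        out = adaptive_mean_threshold(img, 31, 0.0)
        assert out[disc].all()

    def test_huge_negative_offset_selects_everything(self):
        img = np.zeros((20, 20))
        assert adaptive_mean_threshold(img, 5, -1e12).all()

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            adaptive_mean_threshold(np.zeros((10, 10)), 4, 0.0)

    @pytest.mark.parametrize("window", [3, 9, 31])
    def test_matches_bruteforce_local_mean(self, window, rng):
        img = rng.integers(0, 500, size=(64, 64)).astype(float)
        offset = 3.0
        expected = img > local_mean(img, window) + offset
        got = adaptive_mean_threshold(img, window, offset)
        assert np.array_equal(got, expected)


class TestFilterSmallObjects:
    def test_area_below_20_removed_area_20_retained(self):
        # strict '<' semantics at the default threshold
        img = np.zeros((60, 60), dtype=bool)
        img[2:3, 2:7] = True  # area 5
        img[10:11, 10:29] = True  # area 19
        img[30:34, 30:35] = True  # area 20
        out = filter_small_objects(img)
        assert out.sum() == 20
        assert out[30:34, 30:35].all()

    def test_empty_mask_passthrough(self):
        empty = np.zeros((10, 10), dtype=bool)
        assert not filter_small_objects(empty).any()

    def test_idempotent(self, rng):
        img = rng.random((80, 80)) > 0.7
        once = filter_small_objects(img, 10)
        assert np.array_equal(filter_small_objects(once, 10), once)

    def test_label_mask_renumbered_contiguously(self):
        lab = np.zeros((40, 40), dtype=np.int32)
        lab[0:2, 0:3] = 1  # area 6 -> removed at min_area=10
        lab[10:15, 10:15] = 2  # area 25 -> becomes label 1
        lab[30:35, 30:35] = 3  # area 25 -> becomes label 2
        out = filter_small_objects(lab, 10)
        assert sorted(set(out.ravel()) - {0}) == [1, 2]
        assert (out[10:15, 10:15] == 1).all()
        assert (out[30:35, 30:35] == 2).all()


class TestSplitTouchingNuclei:
    def test_single_disc_one_label(self):
        mask = _disc_mask((60, 60), (30, 30), 10)
        lab = split_touching_nuclei(mask)
        assert lab.max() == 1
        assert np.array_equal(lab > 0, mask)

    def test_dumbbell_splits_into_two(self):
        # two discs radius 10, centers 16 px apart: two distance maxima
        mask = _disc_mask((60, 80), (30, 30), 10) | _disc_mask((60, 80), (30, 46), 10)
        lab = split_touching_nuclei(mask)
        assert lab.max() == 2
        assert lab[30, 30] != lab[30, 46]
        assert np.array_equal(lab > 0, mask)
        # split runs along the neck: compare to nearest-centre assignment
        oracle = np.zeros_like(lab)
        rr, cc = np.nonzero(mask)
        d_a = (rr - 30) ** 2 + (cc - 30) ** 2
        d_b = (rr - 30) ** 2 + (cc - 46) ** 2
        oracle[rr, cc] = np.where(d_a <= d_b, lab[30, 30], lab[30, 46])
        agreement = (oracle[mask] == lab[mask]).mean()
        assert agreement >= 0.98

    def test_disjoint_discs_match_connected_components(self):
        mask = _disc_mask((60, 100), (30, 25), 10) | _disc_mask((60, 100), (30, 75), 10)
        lab = split_touching_nuclei(mask)
        assert lab.max() == 2
        assert lab[30, 25] != lab[30, 75]

    def test_empty_mask_gives_empty_labels(self):
        lab = split_touching_nuclei(np.zeros((20, 20), dtype=bool))
        assert lab.max() == 0

    def test_shallow_component_still_seeded(self):
        # a thin bar has distance maxima shallower than the default depth
        mask = np.zeros((20, 40), dtype=bool)
        mask[9:11, 5:35] = True
        lab = split_touching_nuclei(mask, h_depth=5.0)
        assert lab.max() >= 1
        assert (lab[mask] > 0).all()


class TestMakeCellMasks:
    def test_radius_zero_returns_nuclei(self):
        nuc = np.zeros((30, 30), dtype=np.int32)
        nuc[_disc_mask((30, 30), (15, 15), 5)] = 1
        assert np.array_equal(make_cell_masks(nuc, 0), nuc)

    def test_isolated_nucleus_matches_bruteforce_dilation(self):
        nuc = np.zeros((40, 40), dtype=np.int32)
        nuc[_disc_mask((40, 40), (20, 20), 5)] = 1
        got = make_cell_masks(nuc, 8.0)
        assert np.array_equal(got, nearest_seed_dilation(nuc, 8.0))

    def test_contested_pixels_match_exhaustive_nearest_seed(self):
        nuc = np.zeros((40, 50), dtype=np.int32)
        nuc[_disc_mask((40, 50), (20, 18), 4)] = 1
        nuc[_disc_mask((40, 50), (20, 28), 4)] = 2  # 10 px apart, radius 8
        got = make_cell_masks(nuc, 8.0)
        oracle = nearest_seed_dilation(nuc, 8.0)
        assert np.array_equal(got, oracle)
        # union equals the unconstrained dilation of the union
        union_or = nearest_seed_dilation((nuc > 0).astype(np.int32), 8.0)
        assert np.array_equal(got > 0, union_or > 0)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_random_nuclei_match_oracle_exactly(self, seed):
        rng = np.random.default_rng(seed)
        nuc = np.zeros((48, 48), dtype=np.int32)
        for lab in (1, 2, 3):
            r, c = rng.integers(8, 40, size=2)
            nuc[_disc_mask((48, 48), (r, c), int(rng.integers(3, 6)))] = lab
        got = make_cell_masks(nuc, 7.0)
        assert np.array_equal(got, nearest_seed_dilation(nuc, 7.0))


class TestRemoveEdgeCells:
    def _seg(self, nuc, cell):
        return SegmentationResult(nuclear_mask=nuc, cell_mask=cell)

    def test_interior_cells_untouched(self):
        nuc = np.zeros((40, 40), dtype=np.int32)
        nuc[_disc_mask((40, 40), (20, 20), 5)] = 1
        cell = make_cell_masks(nuc, 5)
        out = remove_edge_cells(self._seg(nuc, cell))
        assert out.discarded_edge == 0
        assert np.array_equal(out.nuclear_mask, nuc)

    def test_interior_nucleus_removed_when_cell_mask_touches_edge(self):
        # nucleus 8 px from the border; dilation by 10 reaches column 0
        nuc = np.zeros((40, 40), dtype=np.int32)
        nuc[_disc_mask((40, 40), (20, 8), 4)] = 1
        cell = make_cell_masks(nuc, 10)
        assert (cell[:, 0] > 0).any()
        out = remove_edge_cells(self._seg(nuc, cell))
        assert out.discarded_edge == 1
        assert out.nuclear_mask.max() == 0 and out.cell_mask.max() == 0

    def test_idempotent(self):
        nuc = np.zeros((40, 40), dtype=np.int32)
        nuc[_disc_mask((40, 40), (20, 8), 4)] = 1
        nuc[_disc_mask((40, 40), (20, 28), 4)] = 2
        cell = make_cell_masks(nuc, 10)
        once = remove_edge_cells(self._seg(nuc, cell))
        twice = remove_edge_cells(once)
        assert np.array_equal(once.nuclear_mask, twice.nuclear_mask)
        assert once.discarded_edge == twice.discarded_edge


class TestSegmentField:
    def test_recovers_simulated_nuclei(self, noisy_config, rng):
        cond = noisy_config.conditions["vehicle"]
        cells = sample_field_cells(noisy_config, cond, rng)
        fimg, _ = render_field(cells, noisy_config, rng)
        seg = segment_field(fimg)
        assert abs(seg.n_cells - len(cells)) / len(cells) <= 0.05
        check_mask_algebra(seg)

    def test_touching_pairs_are_split(self, noisy_config):
        cfg = dataclasses.replace(noisy_config, touching_fraction=0.2)
        rng = np.random.default_rng(11)
        cond = cfg.conditions["vehicle"]
        cells = sample_field_cells(cfg, cond, rng)
        fimg, truth = render_field(cells, cfg, rng)
        seg = segment_field(fimg)
        pairs = truth[truth["pair_id"] >= 0].groupby("pair_id")
        assert len(pairs) > 0
        for _, grp in pairs:
            rr = np.round(grp["row"]).astype(int).to_numpy()
            cc = np.round(grp["col"]).astype(int).to_numpy()
            labs = seg.nuclear_mask[rr, cc]
            assert (labs > 0).all(), "pair centre missed"
            assert labs[0] != labs[1], "touching pair not split"

    def test_blank_field_yields_no_labels(self):
        from hcscreen.field import FieldImage

        rng = np.random.default_rng(0)
        img = np.clip(100 + rng.normal(0, 10, (200, 200)), 0, None)
        fimg = FieldImage(channels={"dapi": img})
        seg = segment_field(fimg)
        assert seg.n_cells == 0

    def test_missing_dapi_channel_rejected(self):
        from hcscreen.field import FieldImage

        fimg = FieldImage(channels={"receptor": np.zeros((50, 50))})
        with pytest.raises(ValueError, match="dapi"):
            segment_field(fimg)

    def test_parameters_are_logged(self, noisy_config, rng):
        cond = noisy_config.conditions["vehicle"]
        cells = sample_field_cells(noisy_config, cond, rng)
        fimg, _ = render_field(cells, noisy_config, rng)
        params = SegmentationParams(threshold_offset=25.0)
        seg = segment_field(fimg, params)
        assert seg.params["threshold_offset"] == 25.0
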