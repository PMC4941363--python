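"""Well statistics, normalization, 4PL fitting, clustering, Biolog."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from hcscreen.screen import (
    aggregate_well,
    biolog_analyze,
    build_profile_matrix,
    cluster_profiles,
    compare_cell_counts,
    fit_dose_response,
    normalize_plate,
)
from hcscreen.simulate import BiologConfig, EffectModel, hill_response, simulate_biolog

from .oracles import upgma_heights


def _records(values, well="r01c01"):
    values = np.asarray(values, dtype=float)
    return pd.DataFrame(
        {
            "well": well,
            "receptor_nuc_mean": values,
            "receptor_nuc_integrated": values * 100,
            "ratio_receptor": 2.0,
            "edu_positive": pd.NA,
        }
    )


def _layout_entry(well="r01c01", compound="vehicle", dose=0.0, combo=False):
    return {
        "well": well,
        "compound": compound,
        "dose": dose,
        "unit": "uM",
        "combo_agonist": combo,
        "replicate": 1,
        "timepoint": "24h",
    }


class TestAggregateWell:
    def test_single_cell(self):
        s = aggregate_well(_records([100.0]), _layout_entry())
        assert s["nuclear_level_median"] == 100.0 and s["n_cells"] == 1

    def test_median_of_three(self):
        s = aggregate_well(_records([10.0, 20.0, 30.0]), _layout_entry())
        assert s["nuclear_level_median"] == 20.0

    def test_empty_well_is_flagged_not_fatal(self):
        s = aggregate_well(_records([]).iloc[0:0], _layout_entry())
        assert s["empty"] and s["n_cells"] == 0
        assert np.isnan(s["nuclear_level_median"])


def _well_table():
    rows = []
    for i, (cmpd, dose, combo, level) in enumerate(
        [
            ("vehicle", 0.0, False, 1000.0),
            ("vehicle", 0.0, False, 1050.0),
            ("DHT", 1.0, False, 2000.0),
            ("DHT", 1.0, False, 2050.0),
            ("cmpdX", 10.0, False, 400.0),
        ]
    ):
        rows.append(
            {
                "well": f"r01c{i + 1:02d}",
                "compound": cmpd,
                "dose": dose,
                "dose_unit": "uM",
                "with_agonist": combo,
                "replicate": 1,
                "timepoint": "24h",
                "n_cells": 100,
                "nuclear_level_mean": level,
                "nuclear_level_median": level,
                "nuclear_level_mad": 10.0,
                "ratio_median": 2.0,
                "pct_edu": np.nan,
                "empty": False,
            }
        )
    return pd.DataFrame(rows)


class TestNormalizePlate:
    def test_vehicle_fold_change_is_one_at_the_median(self):
        out = normalize_plate(_well_table())
        veh = out[out["compound"] == "vehicle"]["nuclear_level_median"]
        assert np.median(veh) == pytest.approx(1.0)

    def test_single_vehicle_well_normalizes_itself_to_one(self):
        tbl = _well_table().iloc[[0, 4]].reset_index(drop=True)
        out = normalize_plate(tbl)
        assert out.loc[0, "nuclear_level_median"] == pytest.approx(1.0)

    def test_agonist_well_is_100_percent(self):
        out = normalize_plate(_well_table(), scale="percent_agonist")
        ago = out[out["compound"] == "DHT"]["nuclear_level_median"]
        assert np.median(ago) == pytest.approx(100.0)

    def test_percent_scale_requires_agonist_wells(self):
        tbl = _well_table()
        tbl = tbl[tbl["compound"] != "DHT"]
        with pytest.raises(ValueError, match="agonist"):
            normalize_plate(tbl, scale="percent_agonist")

    def test_missing_vehicle_rejected(self):
        tbl = _well_table()
        tbl = tbl[tbl["compound"] != "vehicle"]
        with pytest.raises(ValueError, match="vehicle"):
            normalize_plate(tbl)

    def test_fold_change_invariant_under_global_rescaling(self):
        tbl = _well_table()
        a = normalize_plate(tbl)
        tbl2 = tbl.copy()
        for col in ("nuclear_level_mean", "nuclear_level_median"):
            tbl2[col] *= 37.5
        b = normalize_plate(tbl2)
        np.testing.assert_allclose(
            a["nuclear_level_median"], b["nuclear_level_median"]
        )


class TestFitDoseResponse:
    DOSES = np.array([1.25, 2.5, 5.0, 10.0, 20.0, 40.0])

    def test_noiseless_4pl_recovered_to_1e4_relative(self):
        m = EffectModel(top=1.0, bottom=0.3, ec50=15.0, hill_slope=1.2)
        fit = fit_dose_response(self.DOSES, hill_response(self.DOSES, m))
        assert fit.converged and not fit.flat
        assert fit.top == pytest.approx(1.0, rel=1e-4)
        assert fit.bottom == pytest.approx(0.3, rel=1e-4)
        assert fit.ic50 == pytest.approx(15.0, rel=1e-4)
        assert fit.hill_slope == pytest.approx(1.2, rel=1e-4)
        assert fit.ic50_in_range

    @pytest.mark.parametrize("seed", range(5))
    def test_random_noiseless_instances_recovered(self, seed):
        rng = np.random.default_rng(seed)
        m = EffectModel(
            top=float(rng.uniform(0.8, 1.5)),
            bottom=float(rng.uniform(0.1, 0.5)),
            ec50=float(rng.uniform(2.0, 30.0)),
            hill_slope=float(rng.uniform(0.6, 2.5)),
        )
        doses = np.concatenate([self.DOSES] * 2)
        fit = fit_dose_response(doses, hill_response(doses, m))
        assert fit.ic50 == pytest.approx(m.ec50, rel=1e-3)

    def test_flat_input_reports_no_activity(self):
        fit = fit_dose_response(self.DOSES, np.ones(6))
        assert fit.flat and not fit.converged
        assert np.isnan(fit.ic50)

    def test_noisy_flat_input_reports_no_activity(self):
        rng = np.random.default_rng(1)
        resp = 1.0 + 0.05 * rng.standard_normal(12)
        fit = fit_dose_response(np.concatenate([self.DOSES] * 2), resp)
        assert fit.flat

    def test_median_ic50_within_20pct_under_5pct_noise(self):
        m = EffectModel(top=1.0, bottom=0.3, ec50=15.0, hill_slope=1.2)
        clean = hill_response(self.DOSES, m)
        rng = np.random.default_rng(7)
        ic50s = []
        for _ in range(100):
            noisy = clean * (1.0 + 0.05 * rng.standard_normal(6))
            fit = fit_dose_response(self.DOSES, noisy)
            if not fit.flat:
                ic50s.append(fit.ic50)
        assert abs(np.median(ic50s) - 15.0) / 15.0 <= 0.20

    def test_zero_dose_anchors_top_plateau(self):
        m = EffectModel(top=1.0, bottom=0.4, ec50=10.0, hill_slope=1.0)
        doses = np.array([0.0, 1.25, 2.5, 5.0, 10.0, 20.0, 40.0])
        fit = fit_dose_response(doses, hill_response(doses, m))
        assert fit.top == pytest.approx(1.0, rel=1e-4)

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            fit_dose_response(np.array([-1, 1, 2, 4, 8, 16.0]), np.ones(6))

    def test_out_of_range_ic50_flagged(self):
        m = EffectModel(top=1.0, bottom=0.3, ec50=500.0, hill_slope=1.5)
        doses = self.DOSES
        fit = fit_dose_response(doses, hill_response(doses, m))
        if not fit.flat:
            assert not fit.ic50_in_range


class TestClusterProfiles:
    def test_three_row_worked_example(self):
        mat = pd.DataFrame([[0.0, 0.0], [3.0, 4.0], [0.0, 1.0]],
                           index=["a", "b", "c"])
        dend = cluster_profiles(mat)
        # distances: d(a,c)=1, d(a,b)=5, d(b,c)=sqrt(18);
        # first merge {a,c} at height 1, then b at (5+sqrt(18))/2
        assert dend.heights[0] == pytest.approx(1.0)
        assert dend.heights[1] == pytest.approx((5.0 + np.sqrt(18.0)) / 2.0)
        assert dend.leaf_order[0] == "b" or dend.leaf_order[-1] == "b"

    def test_identical_rows_merge_first_at_height_zero(self):
        mat = pd.DataFrame([[1.0, 2.0], [5.0, 5.0], [1.0, 2.0]])
        dend = cluster_profiles(mat)
        assert dend.heights[0] == 0.0

    @pytest.mark.parametrize("seed", range(4))
    def test_heights_match_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        mat = pd.DataFrame(rng.random((6, 3)))
        dend = cluster_profiles(mat)
        expected = upgma_heights(mat.to_numpy())
        np.testing.assert_allclose(dend.heights, expected, rtol=1e-12)

    def test_fewer_than_two_rows_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            cluster_profiles(pd.DataFrame([[1.0, 2.0]]))

    def test_masked_values_rejected(self):
        mat = pd.DataFrame([[1.0, np.nan], [0.0, 1.0], [2.0, 2.0]])
        with pytest.raises(ValueError, match="masked"):
            cluster_profiles(mat)

    def test_newick_roundtrips_with_biopython(self, tmp_path):
        from io import StringIO

        from Bio import Phylo

        mat = pd.DataFrame(
            np.random.default_rng(0).random((5, 3)),
            index=[f"cond{i}" for i in range(5)],
        )
        dend = cluster_profiles(mat)
        tree = Phylo.read(StringIO(dend.to_newick()), "newick")
        assert sorted(t.name for t in tree.get_terminals()) == sorted(mat.index)
        # root-to-leaf depth equals the final merge height (ultrametric)
        depths = tree.depths()
        leaf_depths = [d for t, d in depths.items() if t.name]
        np.testing.assert_allclose(leaf_depths, dend.heights[-1], rtol=1e-9)


class TestProfileMatrix:
    def _summaries(self):
        rows = []
        for cl in ("lineA", "lineB", "lineC"):
            for i, (cmpd, combo, val) in enumerate(
                [("vehicle", False, 1.0), ("BPAP", False, 0.5)]
            ):
                rows.append(
                    {
                        "cell_line": cl,
                        "well": f"r01c{i + 1:02d}",
                        "compound": cmpd,
                        "with_agonist": combo,
                        "nuclear_level_median": val,
                    }
                )
        return pd.DataFrame(rows)

    def test_complete_design_builds_dense_matrix(self):
        pm = build_profile_matrix(self._summaries())
        assert pm.values.shape == (2, 3)
        assert not pm.mask.any().any()

    def test_missing_combination_is_masked(self):
        df = self._summaries()
        df = df[~((df["cell_line"] == "lineC") & (df["compound"] == "BPAP"))]
        pm = build_profile_matrix(df)
        assert pm.mask.loc["BPAP", "lineC"]
        assert not pm.mask.loc["vehicle", "lineC"]

    def test_conflicting_duplicates_rejected(self):
        df = self._summaries()
        dup = df.iloc[[0]].copy()
        dup["nuclear_level_median"] = 99.0
        with pytest.raises(ValueError, match="conflicting"):
            build_profile_matrix(pd.concat([df, dup], ignore_index=True))

    def test_engineered_down_regulator_is_row_minimum_in_its_line(self):
        df = self._summaries()
        # BPAP hits only lineB
        df.loc[
            (df["compound"] == "BPAP") & (df["cell_line"] != "lineB"),
            "nuclear_level_median",
        ] = 1.0
        pm = build_profile_matrix(df)
        assert pm.values.loc["BPAP"].idxmin() == "lineB"


class TestBiolog:
    def test_negative_controls_corrected_to_zero(self):
        cfg = BiologConfig(noise_sd=0.0, n_replicates=2)
        veh, trt = simulate_biolog(cfg)
        plate = veh[0]
        nc = np.asarray(plate.negative_control_wells)
        corrected = plate.values - plate.values[nc].mean()
        np.testing.assert_allclose(corrected[nc], 0.0, atol=1e-12)

    def test_z_rows_have_mean_zero_sd_one(self):
        veh, trt = simulate_biolog(BiologConfig(seed=3))
        res = biolog_analyze(veh, trt)
        z = res.zscores.to_numpy()
        np.testing.assert_allclose(z.mean(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(z.std(axis=1, ddof=0), 1.0, atol=1e-9)

    def test_zero_variance_row_flagged_and_zeroed(self):
        from hcscreen.simulate import BiologPlate

        vals = np.full(96, 100.0)
        nc = (0, 1)
        veh = [BiologPlate(values=vals, negative_control_wells=nc,
                           condition="vehicle", replicate=1)]
        trt = [BiologPlate(values=vals, negative_control_wells=nc,
                           condition="treated", replicate=1)]
        with pytest.warns(UserWarning, match="zero-variance"):
            res = biolog_analyze(veh, trt)
        assert len(res.zero_variance_sources) == 94
        assert (res.zscores.to_numpy() == 0).all()

    def test_utilization_loss_gives_negative_treated_z(self):
        mult = np.ones(90)
        mult[:30] = 0.5
        veh, trt = simulate_biolog(BiologConfig(effect_multipliers=mult, seed=5))
        res = biolog_analyze(veh, trt)
        treated_cols = [c for c in res.zscores.columns if c.startswith("treated")]
        affected = res.zscores.iloc[:30][treated_cols].to_numpy()
        assert (affected < 0).mean() > 0.95


class TestCompareCellCounts:
    def _tbl(self, n_treated):
        rows = [
            {"well": "r01c01", "compound": "vehicle", "with_agonist": False,
             "timepoint": "24h", "n_cells": 100},
            {"well": "r01c02", "compound": "vehicle", "with_agonist": False,
             "timepoint": "24h", "n_cells": 102},
            {"well": "r01c03", "compound": "BPAP", "with_agonist": False,
             "timepoint": "24h", "n_cells": n_treated},
        ]
        return pd.DataFrame(rows)

    def test_vehicle_relative_count_is_one(self):
        out = compare_cell_counts(self._tbl(50))
        veh = out[out["compound"] == "vehicle"]["relative_count"]
        assert np.median(veh) == pytest.approx(1.0)

    def test_reduced_density_recovered(self):
        out = compare_cell_counts(self._tbl(40))
        assert out.loc[out["compound"] == "BPAP", "relative_count"].iloc[0] == (
            pytest.approx(40 / 101.0)
        )

    def test_zero_cell_well_flagged(self):
        out = compare_cell_counts(self._tbl(0))
        row = out[out["compound"] == "BPAP"].iloc[0]
        assert row["relative_count"] == 0.0 and row["zero_cells"]

    def test_missing_vehicle_at_timepoint_rejected(self):
        tbl = self._tbl(50)
        tbl.loc[tbl["compound"] == "BPAP", "timepoint"] = "48h"
        with pytest.raises(ValueError, match="vehicle"):
            compare_cell_counts(tbl)
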