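import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phenodist.normalization import (
    NormalizationError,
    NormalizationParams,
    aggregate_to_wells,
    filter_wells,
    normalize_batch,
    normalize_cell_level,
    scale_by_dmso_sd,
    well_cell_counts,
)
from phenodist.plate_model import PlateMap, WellMeta

from conftest import make_batch


class TestWellCellCounts:
    def test_counts(self):
        batch = make_batch({"A1": 3, "A2": 5})
        counts = well_cell_counts(batch)
        assert counts[("P1", "A1")] == 3
        assert counts[("P1", "A2")] == 5

    def test_mapped_but_empty_well_is_zero(self):
        batch = make_batch({"A1": 3, "A2": 0})
        assert well_cell_counts(batch)[("P1", "A2")] == 0

    def test_entry_per_mapped_well(self):
        batch = make_batch({f"A{c}": 2 for c in range(1, 13)})
        assert len(well_cell_counts(batch)) == 12


class TestFilterWells:
    def test_low_count_boundary(self):
        # vehicle median 200; one well at 99 (excluded), one at 100 (kept)
        batch = make_batch(
            {"A1": 200, "A2": 200, "A3": 200, "B1": 99, "B2": 100},
            roles={"B1": "test", "B2": "test"},
        )
        filtered, log = filter_wells(batch)
        reasons = dict(zip(zip(log["plate_id"], log["well"]), log["reason"]))
        assert reasons == {("P1", "B1"): "low_count"}
        kept = {w.well for w in filtered.platemap}
        assert "B2" in kept and "B1" not in kept

    def test_high_reduction_boundary(self):
        # vehicle median 1000: 49% and exactly 50% kept, 51% excluded
        batch = make_batch(
            {"A1": 1000, "A2": 1000, "B1": 510, "B2": 500, "B3": 490},
            roles={"B1": "test", "B2": "test", "B3": "test"},
        )
        _, log = filter_wells(batch)
        reasons = dict(zip(log["well"], log["reason"]))
        assert reasons == {"B3": "high_reduction"}

    def test_vehicle_wells_same_rules(self):
        batch = make_batch({"A1": 1000, "A2": 1000, "A3": 99})
        _, log = filter_wells(batch)
        assert list(log["well"]) == ["A3"]

    def test_all_vehicle_excluded_raises(self):
        batch = make_batch({"A1": 50, "A2": 50, "B1": 500}, roles={"B1": "test"})
        with pytest.raises(NormalizationError, match="no reference"):
            filter_wells(batch)

    def test_no_vehicle_raises(self):
        batch = make_batch({"B1": 500}, roles={"B1": "test"})
        with pytest.raises(NormalizationError):
            filter_wells(batch)


class TestNormalizeCellLevel:
    def _batch_1f(self, vehicle_vals, treated_vals):
        return make_batch(
            {"A1": len(vehicle_vals), "B1": len(treated_vals)},
            feature_values={
                "A1": np.array(vehicle_vals)[:, None],
                "B1": np.array(treated_vals)[:, None],
            },
            n_features=1,
            roles={"B1": "test"},
        )

    def test_median_maps_to_zero(self):
        batch = self._batch_1f([1.0, 2.0, 3.0], [2.0])
        z, _ = normalize_cell_level(batch, NormalizationParams(mad_scale_constant=1.0))
        dmso = z[z["well"] == "A1"]["f0"]
        assert dmso.iloc[1] == 0.0

    def test_hand_computed_mad_unit_constant(self):
        batch = self._batch_1f([1, 2, 3, 4, 5], [6.0])
        z, _ = normalize_cell_level(batch, NormalizationParams(mad_scale_constant=1.0))
        # med=3, rawMAD=1 -> z = (6-3)/1 = 3
        assert z[z["well"] == "B1"]["f0"].iloc[0] == pytest.approx(3.0)

    def test_hand_computed_mad_default_constant(self):
        batch = self._batch_1f([1, 2, 3, 4, 5], [6.0])
        z, _ = normalize_cell_level(batch, NormalizationParams())
        assert z[z["well"] == "B1"]["f0"].iloc[0] == pytest.approx(3.0 / 1.4826)

    def test_constant_feature_dropped(self):
        batch = make_batch(
            {"A1": 3, "B1": 2},
            feature_values={
                "A1": np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]]),
                "B1": np.array([[0.0, 1.0], [1.0, 2.0]]),
            },
            n_features=2,
            roles={"B1": "test"},
        )
        z, dropped = normalize_cell_level(batch)
        assert dropped == ["f1"]
        assert "f1" not in z.columns

    def test_fallback_sd_policy(self):
        # f1 has zero MAD ({5,5,6}: med 5, mad 0) but nonzero SD
        batch = make_batch(
            {"A1": 3, "B1": 1},
            feature_values={
                "A1": np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 6.0]]),
                "B1": np.array([[0.0, 1.0]]),
            },
            n_features=2,
            roles={"B1": "test"},
        )
        z, dropped = normalize_cell_level(
            batch, NormalizationParams(zero_mad_policy="fallback_sd")
        )
        assert dropped == []
        assert "f1" in z.columns


class TestAggregateToWells:
    def _z(self, well_vals):
        rows = []
        for well, vals in well_vals.items():
            for v in vals:
                rows.append({"plate_id": "P1", "well": well, "f0": v})
        return pd.DataFrame(rows)

    def test_odd_median(self):
        m = aggregate_to_wells(self._z({"A1": [1.0, 2.0, 9.0]}))
        assert m.loc[("P1", "A1"), "f0"] == 2.0

    def test_even_midpoint(self):
        m = aggregate_to_wells(self._z({"A1": [1.0, 3.0]}))
        assert m.loc[("P1", "A1"), "f0"] == 2.0

    def test_single_cell(self):
        m = aggregate_to_wells(self._z({"A1": [7.5]}))
        assert m.loc[("P1", "A1"), "f0"] == 7.5

    def test_matches_pandas_groupby(self, rng):
        df = pd.DataFrame(
            {
                "plate_id": rng.choice(["P1", "P2"], 200),
                "well": rng.choice(["A1", "B2", "C3"], 200),
                "f0": rng.standard_normal(200),
                "f1": rng.standard_normal(200),
            }
        )
        ours = aggregate_to_wells(df)
        ref = df.groupby(["plate_id", "well"], sort=False).median()
        pd.testing.assert_frame_equal(ours.sort_index(), ref.sort_index())


class TestScaleByDmsoSd:
    def _medians(self, rows):
        idx = pd.MultiIndex.from_tuples([("P1", w) for w in rows])
        return pd.DataFrame({"f0": list(rows.values())}, index=idx)

    def _platemap(self, vehicle, treated=()):
        wells = [WellMeta("P1", w[0], int(w[1:]), "DMSO", 0.0, "vehicle") for w in vehicle]
        wells += [WellMeta("P1", w[0], int(w[1:]), "chemX", 1.0, "test") for w in treated]
        return PlateMap(wells)

    def test_hand_computed(self):
        med = self._medians({"A1": 0.0, "A2": 2.0, "B1": 2.0})
        pm = self._platemap(["A1", "A2"], ["B1"])
        scaled, _ = scale_by_dmso_sd(med, pm)
        # sd over {0,2} with n-1 denominator = sqrt(2)
        assert scaled.loc[("P1", "B1"), "f0"] == pytest.approx(np.sqrt(2))

    def test_unit_dmso_sd_after_scaling(self, rng):
        idx = pd.MultiIndex.from_tuples([("P1", f"A{c}") for c in range(1, 9)])
        med = pd.DataFrame(rng.standard_normal((8, 4)), index=idx,
                           columns=list("wxyz"))
        pm = self._platemap([f"A{c}" for c in range(1, 9)])
        scaled, _ = scale_by_dmso_sd(med, pm)
        np.testing.assert_allclose(scaled.std(axis=0, ddof=1), 1.0)

    def test_identical_medians_dropped(self):
        idx = pd.MultiIndex.from_tuples([("P1", "A1"), ("P1", "A2")])
        med = pd.DataFrame({"f0": [1.0, 1.0], "f1": [0.0, 1.0]}, index=idx)
        pm = self._platemap(["A1", "A2"])
        scaled, dropped = scale_by_dmso_sd(med, pm)
        assert dropped == ["f0"]
        assert list(scaled.columns) == ["f1"]

    def test_too_few_reference_wells(self):
        med = self._medians({"A1": 0.0})
        with pytest.raises(NormalizationError):
            scale_by_dmso_sd(med, self._platemap(["A1"]))


class TestPipelineProperties:
    def _random_batch(self, seed=0):
        counts = {f"A{c}": 30 for c in range(1, 7)}
        counts.update({f"B{c}": 30 for c in range(1, 7)})
        roles = {f"B{c}": "test" for c in range(1, 7)}
        return make_batch(counts, n_features=4, roles=roles, seed=seed)

    def test_affine_invariance(self):
        batch = self._random_batch()
        params = NormalizationParams(min_cells=1)
        base = normalize_batch(batch, params).profile

        scaled_batch = self._random_batch()
        scaled_batch.cells.data["f1"] = 3.7 * scaled_batch.cells.data["f1"] - 11.0
        out = normalize_batch(scaled_batch, params).profile
        pd.testing.assert_frame_equal(base, out, check_exact=False, atol=1e-10)

    def test_cell_order_permutation_invariance(self, rng):
        batch = self._random_batch()
        params = NormalizationParams(min_cells=1)
        base = normalize_batch(batch, params).profile

        perm = rng.permutation(len(batch.cells.data))
        batch.cells.data = batch.cells.data.iloc[perm].reset_index(drop=True)
        out = normalize_batch(batch, params).profile
        pd.testing.assert_frame_equal(
            base.sort_index(), out.sort_index(), check_exact=False, atol=1e-12
        )

    def test_null_treated_distribution_matches_vehicle(self):
        # identical generative process for vehicle and treated wells
        counts = {f"{r}{c}": 60 for r in "AB" for c in range(1, 13)}
        roles = {f"B{c}": "test" for c in range(1, 13)}
        batch = make_batch(counts, n_features=2, roles=roles, seed=42)
        prof = normalize_batch(batch, NormalizationParams(min_cells=1))
        is_vehicle = (prof.meta["role"] == "vehicle").to_numpy()
        x = prof.profile.to_numpy()[is_vehicle].ravel()
        y = prof.profile.to_numpy()[~is_vehicle].ravel()
        p = stats.mannwhitneyu(x, y).pvalue
        assert p > 0.01


class TestNormalizeBatch:
    def test_profile_contains_vehicle_wells(self):
        batch = make_batch(
            {"A1": 150, "A2": 150, "B1": 150}, roles={"B1": "test"}, n_features=3
        )
        prof = normalize_batch(batch)
        assert ("P1", "A1") in prof.profile.index
        assert set(prof.meta["role"]) == {"vehicle", "test"}

    def test_no_missing_entries(self):
        batch = make_batch(
            {"A1": 150, "A2": 150, "B1": 150}, roles={"B1": "test"}, n_features=3
        )
        prof = normalize_batch(batch)
        assert not prof.profile.isna().any().any()

    def test_write_csv(self, tmp_path):
        batch = make_batch(
            {"A1": 150, "A2": 150, "B1": 150}, roles={"B1": "test"}, n_features=3
        )
        prof = normalize_batch(batch)
        prof.write_csv(tmp_path / "profile.csv")
        prof.write_exclusion_log(tmp_path / "excl.csv")
        back = pd.read_csv(tmp_path / "profile.csv")
        assert {"plate_id", "well", "chemical", "role"}.issubset(back.columns)
        assert len(back) == 3
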