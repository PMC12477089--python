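import numpy as np
import pytest
from scipy import stats

from phenodist import synthetic_data as sd
from phenodist.normalization import NormalizationParams, filter_wells, well_cell_counts


@pytest.fixture(scope="module")
def small_config():
    return sd.SimulationConfig(
        seed=3, plates_per_batch=1, n_features=24, n_categories=8,
        mean_cells=150.0,
    )


class TestLayout:
    def test_96_wells(self, small_config):
        wells = sd.plate_layout(small_config, "P1")
        assert len(wells) == 96

    def test_role_arithmetic(self, small_config):
        wells = sd.plate_layout(small_config, "P1")
        roles = [w.role for w in wells]
        assert roles.count("vehicle") == 8
        assert roles.count("negative_control") == 8
        assert roles.count("cytotoxic_control") == 8
        assert roles.count("test") == 72

    def test_test_chemicals_in_triplicate(self, small_config):
        wells = sd.plate_layout(small_config, "P1")
        per_chem = {}
        for w in wells:
            if w.role == "test":
                per_chem.setdefault(w.chemical, []).append(w)
        assert len(per_chem) == 3
        for chem_wells in per_chem.values():
            assert len(chem_wells) == 24  # 8 concentrations x 3 replicates
            concs = {round(w.concentration, 9) for w in chem_wells}
            assert len(concs) == 8

    def test_half_log_spacing(self):
        s = sd.half_log_series(100.0)
        ratios = s[:-1] / s[1:]
        np.testing.assert_allclose(ratios, 10.0 ** 0.5)

    def test_top_concentration_in_row_a(self, small_config):
        wells = sd.plate_layout(small_config, "P1")
        for w in wells:
            if w.role == "test" and w.row == "A":
                chem = next(c for c in small_config.chemicals if c.name == w.chemical)
                assert w.concentration == pytest.approx(chem.top_conc)


class TestGenerateBatch:
    def test_determinism_byte_identical(self, small_config):
        b1, _, _ = sd.generate_batch(small_config)
        cfg2 = sd.SimulationConfig(
            seed=3, plates_per_batch=1, n_features=24, n_categories=8,
            mean_cells=150.0,
        )
        b2, _, _ = sd.generate_batch(cfg2)
        assert b1.cells.data.to_csv(index=False) == b2.cells.data.to_csv(index=False)

    def test_different_seed_differs(self, small_config):
        b1, _, _ = sd.generate_batch(small_config)
        cfg2 = sd.SimulationConfig(
            seed=4, plates_per_batch=1, n_features=24, n_categories=8,
            mean_cells=150.0,
        )
        b2, _, _ = sd.generate_batch(cfg2)
        assert b1.cells.data.to_csv(index=False) != b2.cells.data.to_csv(index=False)

    def test_zero_noise_inert_equals_vehicle_mean(self):
        cfg = sd.SimulationConfig(
            seed=0, plates_per_batch=1, n_features=12, n_categories=4,
            mean_cells=20.0, zero_noise=True,
        )
        batch, _, _ = sd.generate_batch(cfg)
        df = batch.cells.data
        inert_wells = {w.well for w in batch.platemap
                       if w.chemical == "inert_ctrl"}
        vals = df[df["well"].isin(inert_wells)][batch.feature_names].to_numpy()
        np.testing.assert_array_equal(vals, 0.0)

    def test_catalog_partitions_features(self, small_config):
        _, catalog, _ = sd.generate_batch(small_config)
        feats = [f for c in catalog.categories() for f in catalog.features_in(c)]
        assert sorted(feats) == sorted(small_config.feature_names())
        assert len(catalog.categories()) == 8

    def test_vehicle_wells_pass_qc(self):
        cfg = sd.SimulationConfig(seed=1, plates_per_batch=1, n_features=6,
                                  n_categories=3)
        batch, _, _ = sd.generate_batch(cfg)
        counts = well_cell_counts(batch)
        vehicle = [counts[(w.plate_id, w.well)]
                   for w in batch.platemap.wells_with_role("vehicle")]
        assert all(n >= 100 for n in vehicle)

    def test_cytotoxic_series_reduces_counts(self, small_config):
        batch, _, _ = sd.generate_batch(small_config)
        counts = well_cell_counts(batch)
        cyto = {w.concentration: counts[(w.plate_id, w.well)]
                for w in batch.platemap if w.chemical == "cytotox_ctrl"}
        assert cyto[max(cyto)] < cyto[min(cyto)] * 0.2


class TestNoiseStructure:
    def test_within_category_correlation(self):
        cfg = sd.SimulationConfig(
            seed=0, n_features=12, n_categories=3, rho=0.5
        )
        X = sd._cell_noise(np.random.default_rng(0), 100_000, cfg)
        # features 0-3 share a category at rho = 0.5
        corr = np.corrcoef(X[:, 0], X[:, 1])[0, 1]
        cross = np.corrcoef(X[:, 0], X[:, 5])[0, 1]
        assert corr == pytest.approx(0.5, abs=0.05)
        assert cross == pytest.approx(0.0, abs=0.05)

    def test_unit_marginal_variance_heavy_tails(self):
        cfg = sd.SimulationConfig(
            seed=0, n_features=6, n_categories=2, heavy_tails=True
        )
        X = sd._cell_noise(np.random.default_rng(1), 100_000, cfg)
        np.testing.assert_allclose(X.var(axis=0), 1.0, atol=0.1)

    def test_row_count_gradient_monotone(self):
        plate = sd.generate_dmso_plate(seed=2, mean_cells=2000.0,
                                       n_features=4, n_categories=2,
                                       count_dispersion=500.0)
        counts = well_cell_counts(plate)
        row_means = [
            np.mean([n for (p, w), n in counts.items() if w[0] == r])
            for r in "ABCDEFGH"
        ]
        rho, _ = stats.spearmanr(np.arange(8), row_means)
        assert rho == -1.0


class TestOracle:
    def test_inert_has_no_bmc(self, small_config):
        bmcs = sd.oracle_bmcs(small_config)
        assert bmcs["inert_ctrl"] is None
        assert bmcs["cytotox_ctrl"] is None

    def test_actives_have_bmc_within_range(self, small_config):
        bmcs = sd.oracle_bmcs(small_config)
        for chem in small_config.chemicals:
            if chem.max_shift > 0:
                bmc = bmcs[chem.name]
                assert bmc is not None
                assert bmc <= chem.top_conc

    def test_ac50_scale_equivariance(self):
        def config(scale):
            chems = sd.default_chemicals(24)
            for c in chems:
                c.ac50 *= scale
                c.top_conc *= scale
                if c.cytotox_ec50:
                    c.cytotox_ec50 *= scale
            return sd.SimulationConfig(
                seed=0, plates_per_batch=1, n_features=24, n_categories=8,
                mean_cells=150.0, chemicals=chems,
            )

        b1 = sd.oracle_bmcs(config(1.0))
        b2 = sd.oracle_bmcs(config(2.0))
        for name, v in b1.items():
            if v is not None:
                assert b2[name] == pytest.approx(2 * v, rel=1e-4)

    def test_single_feature_identity_corr_closed_form(self):
        chems = sd.default_chemicals(16)
        for c in chems:
            c.affected_features = ()
            c.max_shift = 0.0
        target = next(c for c in chems if c.name == "chem_a")
        target.affected_features = (0,)
        target.max_shift = 30.0
        target.ac50, target.hill = 1.0, 2.0
        target.ac50_spread = target.hill_spread = 0.0
        cfg = sd.SimulationConfig(
            seed=0, plates_per_batch=2, n_features=16, n_categories=16,
            rho=0.0, mean_cells=300.0, chemicals=chems,
        )
        geom = sd._oracle_geometry(cfg)
        # distance is quadratic in the shift: D(c) = A * shift(c)^2, so the
        # crossing solves E c^h/(ac50^h + c^h) = sqrt(bmr/A) in closed form
        unit = np.zeros(cfg.n_features)
        unit[0] = 1.0 / geom.sd
        t = geom.score(unit) - geom.score(np.zeros(cfg.n_features))
        A = float(np.sum(t * t / geom.eigvals))
        T = np.sqrt(max(geom.bmr_increment - geom.background_offset, 0.0) / A)
        expected = target.ac50 * (T / (target.max_shift - T)) ** (1.0 / target.hill)
        bmc = sd.oracle_bmcs(cfg)["chem_a"]
        assert bmc == pytest.approx(expected, rel=1e-4)

    def test_distance_curve_monotone_for_equal_hills(self):
        chems = sd.default_chemicals(24)
        target = next(c for c in chems if c.name == "chem_a")
        target.ac50_spread = target.hill_spread = 0.0
        cfg = sd.SimulationConfig(
            seed=0, plates_per_batch=1, n_features=24, n_categories=8,
            mean_cells=150.0, chemicals=chems,
        )
        concs = np.geomspace(0.01, 100.0, 30)
        curve = sd.oracle_distance_curve(cfg, target, concs)
        assert np.all(np.diff(curve) >= -1e-9)


class TestTruthRecord:
    def test_written_next_to_batch(self, tmp_path, small_config):
        batch, catalog, truth = sd.generate_batch(small_config)
        sd.write_batch_csvs(batch, catalog, truth, tmp_path)
        assert (tmp_path / "truth.json").exists()
        assert (tmp_path / "platemap.csv").exists()
        assert (tmp_path / "feature_catalog.csv").exists()
        assert (tmp_path / "cells_P1.csv").exists()

    def test_truth_json_contains_oracle(self, tmp_path, small_config):
        import json

        _, _, truth = sd.generate_batch(small_config)
        truth.write_json(tmp_path / "t.json")
        payload = json.loads((tmp_path / "t.json").read_text())
        assert set(payload["oracle_bmcs"]) == {c.name for c in small_config.chemicals}


class TestDmsoPlate:
    def test_96_vehicle_wells(self):
        plate = sd.generate_dmso_plate(seed=0, mean_cells=30.0, n_features=6,
                                       n_categories=3)
        assert len(plate.platemap) == 96
        assert all(w.role == "vehicle" for w in plate.platemap)

    def test_deterministic(self):
        p1 = sd.generate_dmso_plate(seed=5, mean_cells=30.0, n_features=6,
                                    n_categories=3)
        p2 = sd.generate_dmso_plate(seed=5, mean_cells=30.0, n_features=6,
                                    n_categories=3)
        assert p1.cells.data.to_csv(index=False) == p2.cells.data.to_csv(index=False)
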