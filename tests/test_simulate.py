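"""Ground-truth contracts of the plate and qPCR simulators."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import morphoprint as mp


class TestSimulateScreen:
    def test_deterministic_for_fixed_seed(self, small_config):
        t1, l1, _ = mp.simulate_screen(small_config)
        t2, l2, _ = mp.simulate_screen(small_config)
        for a, b in zip(t1, t2):
            pd.testing.assert_frame_equal(a.data, b.data)
        for a, b in zip(l1, l2):
            pd.testing.assert_frame_equal(a.data, b.data)

    def test_different_seed_changes_data(self, small_config):
        t1, _, _ = mp.simulate_screen(small_config)
        t2, _, _ = mp.simulate_screen(dataclasses.replace(small_config, seed=99))
        assert not t1[0].data.equals(t2[0].data)

    def test_shapes_match_design(self, small_config, small_screen):
        tables, layouts, _ = small_screen
        assert len(tables) == small_config.n_replicate_plates
        for t in tables:
            assert len(t.data) == small_config.n_wells * small_config.sites_per_well
            assert len(t.feature_names) == small_config.n_features

    def test_vehicle_wells_from_null_model(self):
        """With no noise, all vehicle wells carry exactly the baseline."""
        cfg = mp.SimulationConfig(
            n_features=20, n_wells=24, sites_per_well=3, seed=0,
            site_noise_sd=0.0, plate_offset_sd=0.0, cell_count_noise_sd=0.0,
            n_reference_compounds=0,
        )
        tables, layouts, truth = mp.simulate_screen(cfg)
        veh = layouts[0].vehicle_wells()
        data = tables[0].data
        null_rows = data[data["well"].isin(veh)]
        for j, name in enumerate(tables[0].feature_names):
            assert np.allclose(null_rows[name], truth.feature_location[j])

    def test_zero_effects_wells_exchangeable_with_vehicle(self):
        """No signatures: treated wells are draws from the vehicle model."""
        cfg = mp.SimulationConfig(
            n_features=20, n_wells=24, sites_per_well=3, seed=1,
            site_noise_sd=0.0, plate_offset_sd=0.0, cell_count_noise_sd=0.0,
            n_reference_compounds=0,
        )
        tables, _, truth = mp.simulate_screen(cfg)
        vals = tables[0].data[tables[0].feature_names].to_numpy()
        assert np.allclose(vals, truth.feature_location, atol=1e-12)

    def test_layout_shift_is_permutation(self, small_screen):
        _, layouts, _ = small_screen
        reference = None
        for lay in layouts:
            treated = sorted(
                lay.data.loc[lay.data["role"] != "vehicle", "compound"]
            )
            if reference is None:
                reference = treated
            assert treated == reference  # every compound exactly once per plate

    def test_vehicle_positions_fixed_across_plates(self, small_screen):
        _, layouts, _ = small_screen
        positions = {tuple(lay.vehicle_wells()) for lay in layouts}
        assert len(positions) == 1

    def test_ground_truth_covers_every_non_vehicle_well(self, small_screen):
        _, layouts, truth = small_screen
        for lay in layouts:
            for cmpd in lay.data.loc[lay.data["role"] != "vehicle", "compound"]:
                assert cmpd in truth.compound_signature

    def test_signature_out_of_range_rejected(self):
        sig = mp.PhenotypeSignature("bad", np.array([100]), np.array([1.0]))
        with pytest.raises(mp.ScreenError, match="feature index"):
            mp.SimulationConfig(n_features=50, signatures=[sig])

    def test_toxicity_reduces_cell_count(self):
        cfg = mp.SimulationConfig(
            n_features=10, n_wells=24, sites_per_well=5, seed=2,
            compounds=[mp.CompoundSpec("toxic", toxicity=0.6)],
            n_reference_compounds=0,
        )
        tables, layouts, _ = mp.simulate_screen(cfg)
        data = tables[0].data
        lay = layouts[0].data
        toxic_wells = lay.loc[lay["compound"] == "toxic", "well"]
        veh_wells = lay.loc[lay["role"] == "vehicle", "well"]
        toxic_mean = data[data["well"].isin(toxic_wells)]["cell_count"].mean()
        veh_mean = data[data["well"].isin(veh_wells)]["cell_count"].mean()
        assert toxic_mean < 0.6 * veh_mean

    def test_concentration_scaling_modulates_effect(self):
        sig = mp.PhenotypeSignature(
            "s", np.arange(5), np.full(5, 4.0), concentration_scaling={1.0: 0.0}
        )
        cfg = mp.SimulationConfig(
            n_features=10, n_wells=24, sites_per_well=3, seed=3,
            site_noise_sd=0.0, plate_offset_sd=0.0,
            signatures=[sig],
            compounds=[
                mp.CompoundSpec("hi", "s", concentration_uM=10.0),
                mp.CompoundSpec("lo", "s", concentration_uM=1.0),
            ],
            n_reference_compounds=0,
        )
        tables, layouts, truth = mp.simulate_screen(cfg)
        data, lay = tables[0].data, layouts[0].data
        f = tables[0].feature_names[0]
        hi_well = lay.loc[lay["compound"] == "hi", "well"].iloc[0]
        lo_well = lay.loc[lay["compound"] == "lo", "well"].iloc[0]
        base = truth.feature_location[0]
        assert data.loc[data["well"] == hi_well, f].iloc[0] > base
        assert data.loc[data["well"] == lo_well, f].iloc[0] == pytest.approx(base)

    def test_irreproducible_features_lose_replicate_correlation(self):
        cfg = mp.SimulationConfig(
            n_features=60, n_wells=48, sites_per_well=5, seed=4,
            irreproducible_fraction=0.5,
        )
        tables, layouts, truth = mp.simulate_screen(cfg)
        wells = [mp.aggregate_sites(t, l) for t, l in zip(tables, layouts)]
        sel = mp.select_robust_features(wells[0], wells[1])
        noisy = set(truth.feature_class[truth.feature_class == "noisy"].index)
        retained_noisy = [f for f in sel.features if f in noisy]
        retained_stable = [f for f in sel.features if f not in noisy]
        assert len(retained_noisy) <= 0.2 * len(noisy)
        assert len(retained_stable) >= 0.5 * (60 - len(noisy))


class TestSimulateReplicatePair:
    def test_programmed_correlation_recovered(self):
        rho = np.array([0.0, 0.5, 0.95])
        r1, r2 = mp.simulate_replicate_pair(2000, rho, seed=5)
        for i, f in enumerate(["f_0001", "f_0002", "f_0003"]):
            r_hat = np.corrcoef(r1[f], r2[f])[0, 1]
            assert r_hat == pytest.approx(rho[i], abs=0.06)

    def test_invalid_correlation_rejected(self):
        with pytest.raises(mp.ScreenError):
            mp.simulate_replicate_pair(10, [1.5], seed=0)


class TestSimulateQpcr:
    def test_zero_noise_unit_fold_change(self):
        table = mp.simulate_qpcr(3, true_fold_change=1.0, ct_noise_sd=0.0, seed=0)
        rel = mp.relative_expression(table, "NRAS", ["GAPDH", "ACTB"])
        assert np.allclose(rel["fold_change"], 1.0)

    def test_zero_noise_programmed_fold_change_exact(self):
        table = mp.simulate_qpcr(3, true_fold_change=0.75, ct_noise_sd=0.0, seed=0)
        rel = mp.relative_expression(table, "NRAS", ["GAPDH", "ACTB"])
        treat = rel.loc[rel["group"] == "treatment", "fold_change"]
        assert np.allclose(treat, 0.75)

    def test_geometric_mean_unbiased_under_noise(self):
        """Log fold changes are Gaussian with mean log(0.75); the geometric
        mean over many seeds must match within Monte-Carlo error."""
        study = mp.benchmarks.qpcr_recovery_study(
            n_seeds=300, base_seed=1, true_fold_change=0.75, ct_noise_sd=0.2
        )
        log_mean = np.log(study["geometric_mean"]).mean()
        # SD of log fold change per sample: noise on target and ref means
        # -> per-seed gmean SD ~ 0.25/sqrt(3); MC error over 300 seeds ~ 0.008
        assert log_mean == pytest.approx(np.log(0.75), abs=0.03)

    def test_negative_noise_rejected(self):
        with pytest.raises(mp.ScreenError):
            mp.simulate_qpcr(3, 1.0, ct_noise_sd=-0.1, seed=0)

    def test_zero_replicates_rejected(self):
        with pytest.raises(mp.ScreenError):
            mp.simulate_qpcr(0, 1.0, seed=0)
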