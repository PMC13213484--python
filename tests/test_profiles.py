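"""Site -> well -> compound aggregation and Z-score fingerprinting."""

import numpy as np
import pandas as pd
import pytest

import morphoprint as mp
from morphoprint.profiles import aggregate_vehicle_wells, dmso_reference


def _table(plate_id, well_values, n_sites=9, feature="feat_a"):
    rows = []
    for well, vals in well_values.items():
        vals = np.broadcast_to(vals, (n_sites,)) if np.isscalar(vals) else vals
        for s, v in enumerate(vals, start=1):
            rows.append({"well": well, "site": s, "cell_count": 100, feature: v})
    return mp.FeatureTable(plate_id=plate_id, data=pd.DataFrame(rows))


def _layout(plate_id, assignment):
    rows = [
        {"well": w, "compound": c, "concentration_uM": 10.0 if c != "DMSO" else 0.0,
         "role": "vehicle" if c == "DMSO" else "treatment"}
        for w, c in assignment.items()
    ]
    return mp.PlateLayout(plate_id=plate_id, data=pd.DataFrame(rows))


class TestAggregateSites:
    def test_constant_sites_return_value(self):
        t = _table("p1", {"A01": 7.5, "A02": 1.0})
        lay = _layout("p1", {"A01": "c1", "A02": "DMSO"})
        prof = mp.aggregate_sites(t, lay)
        assert prof.loc["A01", "feat_a"] == 7.5

    def test_median_of_1_to_9_is_5(self):
        t = _table("p1", {"A01": np.arange(1.0, 10.0), "A02": 1.0})
        lay = _layout("p1", {"A01": "c1", "A02": "DMSO"})
        prof = mp.aggregate_sites(t, lay)
        assert prof.loc["A01", "feat_a"] == 5.0

    def test_missing_site_value_ignored(self):
        vals = np.arange(1.0, 10.0)
        vals[8] = np.nan
        t = _table("p1", {"A01": vals, "A02": 1.0})
        lay = _layout("p1", {"A01": "c1", "A02": "DMSO"})
        prof = mp.aggregate_sites(t, lay)
        assert prof.loc["A01", "feat_a"] == np.median(np.arange(1.0, 9.0))

    def test_all_missing_stays_nan(self):
        t = _table("p1", {"A01": np.full(9, np.nan), "A02": 1.0})
        lay = _layout("p1", {"A01": "c1", "A02": "DMSO"})
        prof = mp.aggregate_sites(t, lay)
        assert np.isnan(prof.loc["A01", "feat_a"])

    def test_well_absent_from_layout_rejected(self):
        t = _table("p1", {"A01": 1.0})
        lay = _layout("p1", {"A02": "DMSO"})
        with pytest.raises(mp.ScreenError, match="layout"):
            mp.aggregate_sites(t, lay)


class TestAggregateReplicates:
    def _well_profiles(self, values_by_plate, compound="c1"):
        plates = []
        for vals in values_by_plate:
            plates.append(
                pd.DataFrame(
                    {
                        "compound": [compound, "DMSO"],
                        "concentration_uM": [10.0, 0.0],
                        "role": ["treatment", "vehicle"],
                        "cell_count": [100.0, 100.0],
                        "feat_a": [vals, 0.0],
                    },
                    index=["A01", "A02"],
                )
            )
        return plates

    def test_identical_plates_passthrough(self):
        agg = mp.aggregate_replicates(self._well_profiles([4.0, 4.0, 4.0]))
        assert agg.loc[("c1", 10.0), "feat_a"] == 4.0

    def test_median_across_plates(self):
        agg = mp.aggregate_replicates(self._well_profiles([1.0, 2.0, 10.0]))
        assert agg.loc[("c1", 10.0), "feat_a"] == 2.0

    def test_plate_order_invariance(self):
        plates = self._well_profiles([1.0, 2.0, 10.0])
        a = mp.aggregate_replicates(plates)
        b = mp.aggregate_replicates(plates[::-1])
        pd.testing.assert_frame_equal(a, b)

    def test_shifted_layouts_equal_unshifted(self, small_config):
        """Matching by compound label makes layout shifting a no-op."""
        import dataclasses

        cfg_shift = small_config
        cfg_flat = dataclasses.replace(small_config, layout_shift=False)
        out = {}
        for key, cfg in [("shift", cfg_shift), ("flat", cfg_flat)]:
            tables, layouts, _ = mp.simulate_screen(cfg)
            wells = [mp.aggregate_sites(t, l) for t, l in zip(tables, layouts)]
            out[key] = mp.aggregate_replicates(wells)
        # same compounds and identical index structure either way
        assert out["shift"].index.equals(out["flat"].index)


class TestFingerprint:
    def test_dmso_median_gives_zero_vector(self, vehicle_profiles):
        profile = vehicle_profiles.iloc[2].copy()  # the median well
        fp = mp.fingerprint(profile, vehicle_profiles, compound="x", concentration=1.0)
        assert np.allclose(fp.z.to_numpy(), 0.0)
        assert fp.induction == 0.0

    def test_hand_computed_robust_z(self, vehicle_profiles):
        """DMSO {1..5}: median 3, MAD 1 -> scale 1.4826; value 6 -> z = 3/1.4826."""
        profile = vehicle_profiles.iloc[0].copy()
        profile["feat_a"] = 6.0
        profile["feat_b"] = 13.0
        fp = mp.fingerprint(profile, vehicle_profiles, compound="x", concentration=1.0)
        assert fp.z["feat_a"] == pytest.approx(3.0 / 1.4826, abs=1e-4)
        assert fp.z["feat_a"] == pytest.approx(2.0235, abs=1e-3)

    def test_zero_dispersion_feature_excluded(self, vehicle_profiles):
        profile = vehicle_profiles.iloc[0]
        fp = mp.fingerprint(profile, vehicle_profiles, compound="x", concentration=1.0)
        assert "feat_c" not in fp.z.index

    def test_sd_scale_switch(self, vehicle_profiles):
        profile = vehicle_profiles.iloc[0].copy()
        profile["feat_a"] = 6.0
        fp = mp.fingerprint(
            profile, vehicle_profiles, scale_method="sd", compound="x", concentration=1.0
        )
        sd = np.std([1, 2, 3, 4, 5], ddof=1)
        assert fp.z["feat_a"] == pytest.approx(3.0 / sd, abs=1e-9)

    def test_affine_equivariance(self, vehicle_profiles):
        """Rescaling a feature across the whole plate leaves z unchanged."""
        profile = vehicle_profiles.iloc[0].copy()
        profile["feat_a"] = 6.0
        fp1 = mp.fingerprint(profile, vehicle_profiles, compound="x", concentration=1.0)
        scaled = vehicle_profiles.copy()
        scaled["feat_a"] = scaled["feat_a"] * 13.0 + 5.0
        profile2 = profile.copy()
        profile2["feat_a"] = profile2["feat_a"] * 13.0 + 5.0
        fp2 = mp.fingerprint(profile2, scaled, compound="x", concentration=1.0)
        assert fp1.z["feat_a"] == pytest.approx(fp2.z["feat_a"], rel=1e-12)

    def test_requires_three_vehicle_wells(self, vehicle_profiles):
        with pytest.raises(mp.ScreenError, match="vehicle"):
            mp.fingerprint(
                vehicle_profiles.iloc[0],
                vehicle_profiles.iloc[:2],
                compound="x",
                concentration=1.0,
            )

    def test_empty_selection_rejected(self, vehicle_profiles):
        with pytest.raises(mp.ScreenError, match="empty"):
            mp.fingerprint(
                vehicle_profiles.iloc[0],
                vehicle_profiles,
                features=[],
                compound="x",
                concentration=1.0,
            )


class TestRelativeCellCount:
    @pytest.mark.parametrize(
        "treated,expected_pct,expected_class",
        [
            (100.0, 100.0, "normal"),
            (84.0, 84.0, "normal"),
            (79.9, 79.9, "reduced"),
            (50.0, 50.0, "reduced"),
            (40.0, 40.0, "growth_arrest"),
        ],
    )
    def test_bands(self, treated, expected_pct, expected_class):
        pct, cls = mp.relative_cell_count(treated, [100.0, 100.0, 100.0])
        assert pct == pytest.approx(expected_pct)
        assert cls == expected_class

    def test_zero_vehicle_median_rejected(self):
        with pytest.raises(mp.ScreenError):
            mp.relative_cell_count(50.0, [0.0, 0.0, 0.0])


class TestVehicleAggregation:
    def test_vehicle_wells_stay_separate(self, small_screen):
        tables, layouts, _ = small_screen
        wells = [mp.aggregate_sites(t, l) for t, l in zip(tables, layouts)]
        veh = aggregate_vehicle_wells(wells)
        assert len(veh) == len(layouts[0].vehicle_wells())
        center, scale = dmso_reference(veh)
        assert (scale > 0).all()
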