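"""Scenario generator: determinism, construction constraints, truth consistency."""

import numpy as np
import pandas as pd
import pytest

from plumewake import synthetic as ps
from plumewake.composite import enhancement, RotatedComposite
from plumewake.grids import oversample
from plumewake.stats import spearman
from plumewake.traffic import rasterize_vkt


def tiny_config(**kw):
    base = dict(
        domain_bounds=(0.0, 0.0, 1.5, 1.5),
        n_facilities=30,
        n_days=4,
        tract_nx=8,
        tract_ny=8,
        seed=11,
    )
    base.update(kw)
    return ps.ScenarioConfig(**base)


class TestConfigValidation:
    def test_fraction_bounds(self):
        with pytest.raises(ValueError):
            tiny_config(swath_missing_frac=1.0)
        with pytest.raises(ValueError):
            tiny_config(missing_docks_frac=-0.1)

    def test_zero_facilities_rejected(self):
        with pytest.raises(ValueError):
            tiny_config(n_facilities=0)

    def test_zero_days_rejected(self):
        with pytest.raises(ValueError):
            tiny_config(n_days=0)


class TestDeterminism:
    def test_same_seed_identical_scenario(self):
        a = ps.generate_scenario(tiny_config(), compute_truth=False)
        b = ps.generate_scenario(tiny_config(), compute_truth=False)
        pd.testing.assert_frame_equal(a.facilities, b.facilities)
        pd.testing.assert_frame_equal(
            a.roads.drop(columns="geometry"), b.roads.drop(columns="geometry")
        )
        pd.testing.assert_frame_equal(a.tracts, b.tracts)
        assert np.array_equal(a.winds.u, b.winds.u)
        for fa, fb in zip(a.no2_daily, b.no2_daily):
            assert np.allclose(fa.masked(), fb.masked(), equal_nan=True)

    def test_different_seed_differs(self):
        a = ps.generate_scenario(tiny_config(), compute_truth=False)
        b = ps.generate_scenario(tiny_config(seed=12), compute_truth=False)
        assert not np.allclose(a.facilities["lon"], b.facilities["lon"])


class TestTracts:
    def test_subgroup_populations_bounded_by_total(self, small_scenario):
        t = small_scenario.tracts
        for sg in ("white", "non_hispanic", "hispanic", "black", "asian_nhpi", "other"):
            assert (t[f"pop_{sg}"] <= t["population_total"]).all()

    def test_hispanic_nonhispanic_partition_total(self, small_scenario):
        t = small_scenario.tracts
        assert (t["pop_hispanic"] + t["pop_non_hispanic"] == t["population_total"]).all()

    def test_facility_counts_match_assignments(self, small_scenario):
        t = small_scenario.tracts.set_index("tract_id")
        counts = small_scenario.facilities["tract_id"].value_counts()
        for tid, n in counts.items():
            assert t.loc[tid, "facility_count"] == n
        assert t["facility_count"].sum() == len(small_scenario.facilities)


class TestFacilities:
    def test_missing_docks_fraction_near_configured(self):
        cfg = tiny_config(n_facilities=800, n_days=1)
        rng = np.random.default_rng(5)
        tracts = ps.generate_tracts(cfg, rng)
        fac = ps.generate_facilities(cfg, tracts, rng)
        frac = fac["loading_docks"].isna().mean()
        # binomial 3-sigma band around 0.407
        assert abs(frac - 0.407) < 3 * np.sqrt(0.407 * 0.593 / 800)

    def test_unbiased_siting_matches_population_weighting(self):
        """With siting_bias 0 the facility-tract subgroup-share distribution
        matches the population-weighted tract distribution."""
        cfg = tiny_config(n_facilities=1500, n_days=1, siting_bias=0.0)
        rng = np.random.default_rng(9)
        tracts = ps.generate_tracts(cfg, rng)
        fac = ps.generate_facilities(cfg, tracts, rng)
        t = tracts.set_index("tract_id")
        share = (t["pop_hispanic"] / t["population_total"]).loc[fac["tract_id"]]
        popw = np.average(
            tracts["pop_hispanic"] / tracts["population_total"],
            weights=tracts["population_total"],
        )
        assert share.mean() == pytest.approx(popw, abs=0.035)

    def test_characteristics_positively_correlated(self, small_scenario):
        fac = small_scenario.facilities
        r, _ = spearman(fac["loading_docks_true"], fac["parking_spaces_true"])
        assert r > 0.3

    def test_empty_tracts_rejected(self):
        with pytest.raises(ValueError):
            ps.generate_facilities(tiny_config(), pd.DataFrame(), np.random.default_rng(0))


class TestWinds:
    def test_constant_forcing(self):
        cfg = tiny_config(wind_constant_uv=(5.0, 0.0))
        winds, daily = ps.generate_wind_fields(cfg, np.random.default_rng(0))
        assert np.all(winds.u == 5.0)
        assert np.all(winds.v == 0.0)
        assert np.allclose(daily, 0.0)

    def test_ar1_zero_gives_independent_hours(self):
        cfg = tiny_config(wind_ar1=0.0, n_days=2)
        winds, _ = ps.generate_wind_fields(cfg, np.random.default_rng(3))
        pert = winds.u[0, :, 3, 3] - winds.u[0, :, 3, 3].mean()
        r = np.corrcoef(pert[:-1], pert[1:])[0, 1]
        assert abs(r) < 0.45  # 24 samples: loose but excludes strong persistence

    def test_speed_distribution_positive(self, small_scenario):
        sp = np.hypot(small_scenario.winds.u, small_scenario.winds.v)
        assert sp.min() >= 0
        assert sp.mean() > 1.0


class TestNo2Fields:
    def test_noise_free_single_facility_peak_displaced_east(self):
        cfg = tiny_config(
            n_facilities=1, noise_cv=0.0, swath_missing_frac=0.0,
            wind_constant_uv=(5.0, 0.0), background_density_coeff=0.0,
            plume_amplitude_per_cluster=0.0,
        )
        scn = ps.generate_scenario(cfg, compute_truth=False)
        fld = scn.no2_daily[0]
        iy, ix = fld.spec.cell_of(scn.facilities["lon"][0], scn.facilities["lat"][0])
        r, c = np.unravel_index(np.argmax(fld.values), fld.values.shape)
        assert r == iy
        assert c - ix == 4  # 4 km east at 1 km cells

    def test_zero_amplitude_gives_pure_background(self):
        cfg = tiny_config(
            plume_amplitude_per_dock=0.0, plume_amplitude_per_cluster=0.0,
            noise_cv=0.0, swath_missing_frac=0.0,
        )
        scn = ps.generate_scenario(cfg, compute_truth=False)
        assert np.allclose(scn.no2_daily[0].values, scn.no2_daily[1].values)
        assert scn.no2_daily[0].values.std() < scn.config.background_base

    def test_swath_masking_fraction(self):
        cfg = tiny_config(swath_missing_frac=0.4, n_days=2)
        scn = ps.generate_scenario(cfg, compute_truth=False)
        frac = 1.0 - scn.no2_daily[0].valid_mask.mean()
        assert frac == pytest.approx(0.4, abs=0.02)

    def test_facility_outside_domain_named_in_error(self):
        cfg = tiny_config()
        scn = ps.generate_scenario(cfg, compute_truth=False)
        fac = scn.facilities.copy()
        fac.loc[0, "lon"] = 99.0
        with pytest.raises(ValueError, match=str(fac.loc[0, "id"])):
            ps.generate_no2_fields(fac, scn.winds, cfg, np.random.default_rng(0), scn.tracts)

    def test_truth_enhancement_consistent_with_statistic(self, small_scenario):
        """Recomputing the statistic on the noise-free fields reproduces the
        recorded truth to well under 1% relative error."""
        from plumewake.composite import PlumeCompositeModel

        res = PlumeCompositeModel(
            small_scenario.no2_daily_noisefree,
            small_scenario.facilities,
            small_scenario.winds,
        ).fit()
        truth = small_scenario.truth.enhancement_pct
        assert res.enhancement_pct == pytest.approx(truth, rel=0.01)


class TestFootprints:
    def test_oversampled_footprints_approximate_field(self):
        cfg = tiny_config(n_facilities=2, noise_cv=0.0, swath_missing_frac=0.0,
                          qa_low_frac=0.0)
        scn = ps.generate_scenario(cfg, compute_truth=False)
        fld = scn.no2_daily[0]
        fps = ps.simulate_footprints(fld, cfg, np.random.default_rng(0))
        grid = fld.spec
        over = oversample(fps, grid, qa_threshold=0.75)
        ok = over.valid_mask
        # footprint means blur the field; agreement is coarse but unbiased
        assert np.nanmean(np.abs(over.values[ok] - fld.values[ok])) < 0.25

    def test_low_qa_fraction_discarded(self):
        cfg = tiny_config(qa_low_frac=0.99)
        scn = ps.generate_scenario(cfg, compute_truth=False)
        fps = ps.simulate_footprints(scn.no2_daily[0], cfg, np.random.default_rng(0))
        n_low = sum(fp.qa < 0.75 for fp in fps)
        assert n_low / len(fps) > 0.95
        over = oversample(fps, scn.grid, qa_threshold=0.75)
        assert over.valid_mask.mean() < 0.1


class TestEmissions:
    def test_sectors_nonnegative_and_ammonia_absent(self, small_scenario):
        assert set(small_scenario.emissions) == set(ps.SECTORS)
        assert "agricultural_ammonia" not in small_scenario.emissions
        for fld in small_scenario.emissions.values():
            assert (fld.values >= 0).all()

    def test_total_is_sum_of_sectors(self, small_scenario):
        tot = ps.total_emissions(small_scenario.emissions)
        acc = sum(f.values for f in small_scenario.emissions.values())
        assert np.allclose(tot.values, acc)

    def test_on_road_tracks_vkt(self, small_scenario):
        vt, _ = rasterize_vkt(small_scenario.roads, small_scenario.grid)
        on_road = small_scenario.emissions["on_road"].values.ravel()
        sub = slice(None, None, 37)  # thin for speed
        r, _ = spearman(on_road[sub], vt.values.ravel()[sub])
        assert r > 0.9


class TestSerialization:
    def test_write_and_read_back(self, small_scenario, tmp_path):
        ps.write_scenario(small_scenario, tmp_path)
        assert (tmp_path / "facilities.csv").exists()
        roads = ps.read_roads_geojson(tmp_path / "roads.geojson")
        assert len(roads) == len(small_scenario.roads)
        tracts = ps.read_tracts_geojson(tmp_path / "tracts.geojson")
        assert len(tracts) == len(small_scenario.tracts)
        assert set(tracts["tract_id"]) == set(small_scenario.tracts["tract_id"])
        import json

        truth = json.loads((tmp_path / "truth.json").read_text())
        assert truth["displacement_km"] == small_scenario.truth.displacement_km
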