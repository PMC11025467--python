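"""Ground-truth recovery and determinism of the synthetic-data generator."""

import numpy as np
import pandas as pd
import pytest

from stemflux import (
    ScenarioConfig,
    ValidationError,
    compute_vpd,
    fluxes_from_bundle,
    generate_campaign_dataset,
    generate_chamber_trace,
    generate_diameter_series,
    generate_micromet,
    zero_growth_partition,
)
from stemflux.chamber_flux import ChamberMeasurement, compute_flux
from stemflux.micromet import validate_micromet_frame


@pytest.fixture(scope="module")
def default_config():
    return ScenarioConfig(seed=7)


class TestMicrometGenerator:
    def test_same_seed_identical_series(self, default_config):
        rng1 = np.random.default_rng(3)
        rng2 = np.random.default_rng(3)
        a = generate_micromet(default_config, 2016, False, rng1)
        b = generate_micromet(default_config, 2016, False, rng2)
        pd.testing.assert_frame_equal(a, b)

    def test_output_passes_micromet_validation(self, default_config):
        rng = np.random.default_rng(3)
        df = generate_micromet(default_config, 2016, False, rng)
        validate_micromet_frame(df)  # no exception, no warnings

    def test_drought_summer_drier_than_wet_summer(self, default_config):
        rng = np.random.default_rng(3)
        wet = generate_micromet(default_config, 2016, False, rng)
        dry = generate_micromet(default_config, 2017, True, rng)
        def summer_min(df):
            month = pd.to_datetime(df["timestamp"]).dt.month
            return df.loc[month.isin([6, 7, 8]), "swc_pct"].min()
        assert summer_min(dry) < summer_min(wet)
        assert summer_min(dry) < 10.0  # severe-drought condition

    def test_saturated_air_gives_zero_vpd(self, default_config):
        rng = np.random.default_rng(3)
        df = generate_micromet(default_config, 2016, False, rng)
        df["rh_pct"] = 100.0
        vpd = compute_vpd(df["ta_c"].to_numpy(), df["rh_pct"].to_numpy())
        assert np.allclose(vpd, 0.0)


class TestDiameterGenerator:
    def test_zero_shrink_zero_noise_partition_recovers_growth_exactly(self):
        cfg = ScenarioConfig(
            seed=5, diameter_noise_um=0.0,
            diel_amp_um={"oak": 0.0, "hornbeam": 0.0},
            sustained_twd_um={"oak": 0.0, "hornbeam": 0.0},
        )
        rng = np.random.default_rng(5)
        met = generate_micromet(cfg, 2016, False, rng)
        series, truth = generate_diameter_series(cfg, met, "oak", 2016, False, rng)
        part = zero_growth_partition(series)
        assert (part["twd"] == 0).all()
        # exact up to the 1e-3 um storage resolution of the series
        assert part["gro"].iloc[-1] == pytest.approx(
            truth["true_annual_growth_um"] - series["diameter"].iloc[0], abs=2e-3
        )

    def test_annual_growth_recovered_within_diel_amplitude(self):
        cfg = ScenarioConfig(seed=11)
        rng = np.random.default_rng(11)
        met = generate_micromet(cfg, 2016, False, rng)
        series, truth = generate_diameter_series(cfg, met, "oak", 2016, False, rng)
        recovered = zero_growth_partition(series)["gro"].iloc[-1]
        g = truth["true_annual_growth_um"]
        noise_bound = 6 * cfg.diameter_noise_um
        assert g - truth["max_diel_amp_um"] - noise_bound <= recovered <= g + noise_bound

    def test_drought_year_cumulative_twd_exceeds_wet_year(self):
        from stemflux import add_moving_averages, cumulative_twd, daily_stats

        cfg = ScenarioConfig(seed=13)
        rng = np.random.default_rng(13)
        results = {}
        for year, drought in cfg.seasons:
            met = generate_micromet(cfg, year, drought, rng)
            series, _ = generate_diameter_series(cfg, met, "oak", year, drought, rng)
            daily = daily_stats(zero_growth_partition(series))
            cum = cumulative_twd(daily, f"{year}-07-01")
            results[year] = cum["twd_cum_um"].iloc[-1]
        assert results[2017] > results[2016]

    def test_drought_year_growth_roughly_halved(self):
        cfg = ScenarioConfig(seed=17, sprout_growth_sigma=0.0)
        rng = np.random.default_rng(17)
        truths = {}
        for year, drought in cfg.seasons:
            met = generate_micromet(cfg, year, drought, rng)
            _, truth = generate_diameter_series(cfg, met, "oak", year, drought, rng)
            truths[year] = truth["true_annual_growth_um"]
        assert truths[2016] == pytest.approx(7500, rel=0.1)  # ~7.1-7.5 mm wet year
        assert truths[2017] < 0.5 * truths[2016]  # halved peaks plus suppression


class TestChamberTraceGenerator:
    GEOM = dict(v2_m3=1e-4, v1_m3=0.002, pressure_pa=101325.0, tair_k=298.15)

    def test_inverse_of_worked_flux_example(self):
        trace = generate_chamber_trace(817.460486, noise_sd_ppm=0.0, **self.GEOM)
        slope = np.diff(trace["co2_ppm"]).mean()
        assert slope == pytest.approx(1.0, rel=1e-4)

    def test_zero_noise_round_trip_is_exact(self):
        true_flux = 312.7
        trace = generate_chamber_trace(true_flux, noise_sd_ppm=0.0, **self.GEOM)
        m = ChamberMeasurement(
            sprout_id="s", plot_id="C-0", species="oak", campaign_date="d",
            time_s=trace["time_s"].to_numpy(), co2_ppm=trace["co2_ppm"].to_numpy(),
            air_pressure=self.GEOM["pressure_pa"],
            air_temperature=self.GEOM["tair_k"], stem_temperature=24.0,
            d1=0.04, d2=0.04, segment_length=1e-4 / (np.pi * 0.02**2),
            system_volume=self.GEOM["v1_m3"],
        )
        est = compute_flux(m)
        assert est.rs_volume == pytest.approx(true_flux, rel=1e-12)

    def test_noisy_traces_unbiased(self, rng):
        true_flux = 200.0
        recovered = []
        for _ in range(300):
            trace = generate_chamber_trace(
                true_flux, noise_sd_ppm=0.5, rng=rng, **self.GEOM
            )
            from stemflux.chamber_flux import R_GAS, fit_trace_slope

            slope = fit_trace_slope(trace["time_s"], trace["co2_ppm"])[0]
            recovered.append(
                slope * self.GEOM["pressure_pa"] * self.GEOM["v1_m3"]
                / (R_GAS * self.GEOM["tair_k"] * self.GEOM["v2_m3"])
            )
        assert np.mean(recovered) == pytest.approx(true_flux, rel=0.01)

    def test_noisy_trace_requires_rng(self):
        with pytest.raises(ValidationError):
            generate_chamber_trace(100.0, noise_sd_ppm=0.5, **self.GEOM)


class TestCampaignDataset:
    def test_default_shape(self, flux_bundle):
        cfg = flux_bundle.config
        assert len(flux_bundle.manifests[2016]) == 4 * 2 * 6 * 6  # plots*species*sprouts*dates
        assert len(flux_bundle.manifests[2017]) == 4 * 2 * 6 * 4
        assert len(flux_bundle.traces) == 480
        for manifest in flux_bundle.manifests.values():
            assert set(manifest["plot_id"]) == set(cfg.plots)
            assert set(manifest["species"]) == set(cfg.species)

    def test_byte_identical_regeneration(self, tmp_path):
        cfg = ScenarioConfig(seed=99, n_sprouts=2)
        a_dir, b_dir = tmp_path / "a", tmp_path / "b"
        generate_campaign_dataset(cfg, out_dir=a_dir)
        generate_campaign_dataset(cfg, out_dir=b_dir)
        a_files = sorted(p.relative_to(a_dir) for p in a_dir.rglob("*") if p.is_file())
        b_files = sorted(p.relative_to(b_dir) for p in b_dir.rglob("*") if p.is_file())
        assert a_files == b_files and len(a_files) > 10
        for rel in a_files:
            assert (a_dir / rel).read_bytes() == (b_dir / rel).read_bytes()

    def test_ground_truth_fluxes_follow_reference_relationship(self, flux_bundle):
        gt = flux_bundle.ground_truth
        man = flux_bundle.manifests[2016]
        cfg = flux_bundle.config
        ratios = []
        for row in man.itertuples():
            true_rs = gt["campaign_fluxes"]["2016"][row.date][row.sprout_id][
                "true_rs_volume"
            ]
            base = cfg.flux_slope[row.species] * row.tstem_c + cfg.flux_intercept[row.species]
            if base > 50:
                ratios.append(true_rs / base)
        # lognormal multipliers are mean-one: ratios centre on 1
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.1)

    def test_drought_window_truth_records_suppression(self, flux_bundle):
        f2017 = flux_bundle.ground_truth["campaign_fluxes"]["2017"]
        assert f2017["2017-07-04"]["suppression_f"] == flux_bundle.config.suppression_f
        assert f2017["2017-06-07"]["suppression_f"] == 1.0

    def test_generated_files_parse_through_module_readers(self, tmp_path):
        import warnings

        from stemflux import RunConfig, run_pipeline

        cfg = RunConfig(
            out_dir=str(tmp_path / "run"), seed=4,
            scenario={"n_sprouts": 1,
                      "campaign_dates": {2016: ["2016-06-07", "2016-08-05"],
                                         2017: ["2017-07-04", "2017-09-04"]}},
            stages=("simulate", "micromet", "flux", "partition"),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("error")  # default config must validate cleanly
            report = run_pipeline(cfg)
        assert report["status"] == "ok"
        for stage in cfg.stages:
            assert report["stages"][stage]["status"] == "ok"
            assert report["stages"][stage]["warnings"] == []

    def test_invalid_config_rejected(self):
        with pytest.raises(ValidationError):
            ScenarioConfig(suppression_f=0.0).validate()
        with pytest.raises(ValidationError):
            ScenarioConfig(trace_noise_ppm=-1.0).validate()
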