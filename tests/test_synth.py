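import warnings

import numpy as np
import pandas as pd
import pytest

from cloudphen import synth
from cloudphen.config import RunConfig, SynthConfig
from cloudphen._circular import circ_dist, circ_mean


class TestLandscapes:
    def test_gradient_spans_range_evenly(self):
        ls = synth.generate_landscapes(8, (200, 450), seed=0)
        r = [lc.transition_dry_rain90 for lc in ls]
        assert r[0] == 200 and r[-1] == 450
        assert np.allclose(np.diff(r), np.diff(r)[0])

    def test_degenerate_range_gives_identical_landscapes(self):
        ls = synth.generate_landscapes(2, (300, 300), seed=0)
        assert all(lc.transition_dry_rain90 == 300 for lc in ls)

    def test_elevation_shuffled_independently_of_rainfall(self):
        a = synth.generate_landscapes(8, (200, 450), seed=1)
        b = synth.generate_landscapes(8, (200, 450), seed=2)
        assert [x.transition_dry_rain90 for x in a] == \
            [x.transition_dry_rain90 for x in b]
        assert [x.elevation for x in a] != [x.elevation for x in b]

    def test_rejects_single_landscape(self):
        with pytest.raises(ValueError):
            synth.generate_landscapes(1, (200, 450))

    def test_wet_peak_within_two_weeks_across_region(self):
        ls = synth.generate_landscapes(8, (200, 450), seed=5)
        peaks = [lc.wet_peak_doy for lc in ls]
        assert max(peaks) - min(peaks) <= 14


class TestRainfall:
    def test_transition_accumulation_calibrated_within_5pct(self):
        lc = synth.generate_landscapes(4, (200, 450), seed=0)[2]
        rain = synth.generate_rainfall(lc, 30, seed=1)
        from cloudphen.climate import seasonal_accumulation
        # trailing-90 window ending 30 June ~ Apr-Jun total
        acc = seasonal_accumulation(rain, (4, 5, 6))
        assert acc.mean() == pytest.approx(lc.transition_dry_rain90, rel=0.05)

    def test_drought_multiplier_reduces_that_years_accumulation(self):
        lc = synth.generate_landscapes(2, (300, 400), seed=0)[0]
        mult = np.ones(5)
        mult[2] = 0.6
        rain = synth.generate_rainfall(lc, 5, mult, seed=3)
        from cloudphen.climate import seasonal_accumulation
        acc = seasonal_accumulation(rain, (4, 5, 6))
        assert acc.iloc[2] < acc.mean()

    def test_seasonal_maximum_near_wet_peak(self):
        lc = synth.generate_landscapes(2, (250, 400), seed=2)[1]
        rain = synth.generate_rainfall(lc, 50, seed=4)
        rain["doy"] = pd.to_datetime(rain["date"]).dt.dayofyear.clip(upper=365)
        clim = rain.groupby("doy")["rain_mm"].mean().rolling(
            31, center=True, min_periods=15).mean()
        assert circ_dist(clim.idxmax(), lc.wet_peak_doy) <= 14

    def test_negative_multiplier_rejected(self):
        lc = synth.generate_landscapes(2, (250, 400), seed=0)[0]
        with pytest.raises(ValueError):
            synth.generate_rainfall(lc, 2, [-0.5, 1.0])

    def test_daytime_rain_capped_at_daylight(self, study):
        r = study["rain"]
        assert (r["daytime_rain_h"] <= r["daylight_h"] + 1e-9).all()

    def test_same_seed_reproduces_byte_identical_table(self):
        lc = synth.generate_landscapes(2, (250, 400), seed=0)[0]
        a = synth.generate_rainfall(lc, 3, seed=9).to_csv()
        b = synth.generate_rainfall(lc, 3, seed=9).to_csv()
        assert a == b


class TestCommunity:
    @pytest.fixture(scope="class")
    def landscapes(self):
        return synth.generate_landscapes(8, (200, 450), seed=0)

    def test_guild_mix_matches_fractions(self, landscapes):
        comm = synth.generate_community(
            landscapes, (0.17, 0.17, 0.66, 0.0), seed=1, n_species=60)
        per_species = comm.drop_duplicates("species")
        counts = per_species.groupby("guild").size()
        assert abs(counts.get("nectarivore", 0) - 0.17 * 60) <= 1
        assert abs(counts.get("frugivore", 0) - 0.17 * 60) <= 1
        assert abs(counts.get("insectivore", 0) - 0.66 * 60) <= 1

    def test_two_regime_rule_follows_biomass_threshold(self, landscapes):
        comm = synth.generate_community(landscapes, seed=2)
        ins = comm[comm["guild"] == "insectivore"]
        assert (ins.loc[ins["biomass_min"] < 43, "regime"] == "post").all()
        assert (ins.loc[ins["biomass_min"] >= 43, "regime"] == "pre").all()
        pre = ins[ins["regime"] == "pre"]["true_peak_doy"]
        post = ins[ins["regime"] == "post"]["true_peak_doy"]
        sep = circ_dist(circ_mean(post.to_numpy()), circ_mean(pre.to_numpy()))
        assert sep == pytest.approx(4.9 * 30.437, abs=25)

    def test_zero_offset_collapses_regimes(self, landscapes):
        comm = synth.generate_community(landscapes, offset_months=0.0, seed=3)
        ins = comm[comm["guild"] == "insectivore"]
        spread = circ_dist(ins["true_peak_doy"],
                           circ_mean(ins["true_peak_doy"].to_numpy()))
        assert np.quantile(spread, 0.9) < 45  # one cluster, not two

    def test_threshold_outside_biomass_range_warns(self, landscapes):
        with pytest.warns(UserWarning, match="unidentifiable"):
            comm = synth.generate_community(landscapes, psi_true=10.0, seed=4)
        assert (comm.loc[comm["guild"] == "insectivore", "regime"]
                == "pre").all()

    def test_more_than_half_of_species_span_multiple_landscapes(self,
                                                                landscapes):
        comm = synth.generate_community(landscapes, seed=5, n_species=60)
        k = comm.groupby("species")["landscape"].nunique()
        assert 0.40 <= (k > 1).mean() <= 0.80

    def test_same_seed_is_deterministic(self, landscapes):
        a = synth.generate_community(landscapes, seed=7).to_csv()
        b = synth.generate_community(landscapes, seed=7).to_csv()
        assert a == b


class TestCaptures:
    @pytest.fixture(scope="class")
    def base(self):
        ls = synth.generate_landscapes(2, (250, 400), seed=0)
        rain = pd.concat([synth.generate_rainfall(lc, 5, seed=i)
                          for i, lc in enumerate(ls)], ignore_index=True)
        visits = synth.generate_visits(ls, 5, seed=1)
        comm = pd.DataFrame([{
            "species": "big", "family": "F", "genus": "G",
            "guild": "insectivore", "landscape": "L1", "regime": "pre",
            "true_peak_doy": 135.0, "true_effort": 0.35,
            "bimodal_flag": False, "secondary_peak_doy": np.nan,
            "timing_slope": 0.0, "effort_slope": 0.0, "abundance": 40.0,
            "biomass_min": 40.0}])
        return ls, rain, visits, comm

    def test_zero_detection_gives_empty_table(self, base):
        _, rain, visits, comm = base
        out = synth.generate_captures(comm, visits, rain, detection=0.0)
        assert out.empty

    def test_empty_schedule_rejected(self, base):
        _, rain, _, comm = base
        with pytest.raises(ValueError):
            synth.generate_captures(comm, rain.iloc[:0], rain)

    def test_molt_overlap_calibration(self, base):
        # ~26% of early-molt and ~2% of late-molt captures retain breeding
        # characters
        _, rain, visits, comm = base
        comm = comm.assign(abundance=120.0)
        caps = synth.generate_captures(comm, visits, rain, seed=5)
        early = caps[caps["phenophase"] == "MOLT1"]
        late = caps[caps["phenophase"].isin(["MOLT2", "MOLT3"])]
        assert len(early) > 300 and len(late) > 300
        assert early["breeding_char"].mean() == pytest.approx(0.26, abs=0.05)
        assert late["breeding_char"].mean() == pytest.approx(0.02, abs=0.02)

    def test_juvenile_capture_lag_centered_on_stage_durations(self, base):
        # juveniles appear on average chick duration + half the juvenile
        # window after the true peak
        _, rain, visits, comm = base
        comm = comm.assign(abundance=120.0)
        caps = synth.generate_captures(comm, visits, rain, seed=6)
        juv = caps[caps["phenophase"].str.startswith("JUV")]
        doy = pd.to_datetime(juv["date"]).dt.dayofyear.to_numpy()
        mean_lag = circ_mean(doy) - 135.0
        assert mean_lag == pytest.approx(30 + 75, abs=25)

    def test_phenophase_order_breed_juvenile_molt(self, base):
        # population-level ordering: breeding evidence first, juveniles
        # later, molt later still
        _, rain, visits, comm = base
        caps = synth.generate_captures(comm.assign(abundance=60.0),
                                       visits, rain, seed=7)
        doy = pd.to_datetime(caps["date"]).dt.dayofyear.to_numpy()
        br = circ_mean(doy[caps["phenophase"] == "BR"])
        juv = circ_mean(doy[caps["phenophase"].str.startswith("JUV")])
        molt = circ_mean(doy[caps["phenophase"].str.startswith("MOLT")])
        assert 0 < (juv - br) % 365 < 180
        assert 0 < (molt - br) % 365 < 180

    def test_determinism_under_seed(self, base):
        _, rain, visits, comm = base
        a = synth.generate_captures(comm, visits, rain, seed=8).to_csv()
        b = synth.generate_captures(comm, visits, rain, seed=8).to_csv()
        assert a == b


class TestVisitsAndResources:
    def test_monthly_schedule_skips_the_gap(self):
        ls = synth.generate_landscapes(2, (250, 400), seed=0)
        v = synth.generate_visits(ls, 3, seed=0)
        months = pd.to_datetime(v["date_start"]).dt.month
        assert not months.isin([3, 4]).any()
        assert months.nunique() == 10

    def test_snapshot_schedule_is_sparser(self):
        ls = synth.generate_landscapes(2, (250, 400), seed=0)
        m = synth.generate_visits(ls, 5, style="monthly", seed=0)
        s = synth.generate_visits(ls, 5, style="snapshot", seed=0)
        assert len(s) < len(m)

    def test_flowers_peak_dry_fruit_peaks_wet(self, study):
        res = study["resources"]
        res = res.assign(month=pd.to_datetime(res["date"]).dt.month)
        fl = res[res["syndrome"] == "flower"].groupby("month")["count"].mean()
        fr = res[res["syndrome"] == "fruit"].groupby("month")["count"].mean()
        assert fl.idxmax() in (5, 6, 7)
        assert fr.idxmax() in (12, 1, 2)

    def test_zero_rain_landscape_has_flat_resources(self):
        ls = synth.generate_landscapes(2, (250, 400), seed=0)
        visits = synth.generate_visits(ls, 3, seed=1)
        rain = pd.concat([synth.generate_rainfall(lc, 3, seed=i)
                          for i, lc in enumerate(ls)], ignore_index=True)
        rain.loc[rain["landscape"] == "L1", "rain_mm"] = 0.0
        res, _ = synth.generate_resources(ls, visits, rain, seed=2)
        res = res.assign(month=pd.to_datetime(res["date"]).dt.month)
        flat = res[(res["landscape"] == "L1") & (res["syndrome"] == "flower")]
        by_month = flat.groupby("month")["count"].mean()
        assert by_month.max() / by_month.min() < 3.0  # noise only
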