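import numpy as np
import pandas as pd
import pytest

from cloudphen import phenology as phen
from cloudphen.config import Durations, FilterTiers, PhenologyConfig
from cloudphen.phenology import (apply_filters, backdate_events,
                                 detect_bimodality, extract_peak,
                                 fit_population_curve, monthly_event_table,
                                 reproductive_effort)
from cloudphen._circular import circ_dist


def _capture(date, phenophase, age_class="adult", breeding_char=None,
             **kw):
    if breeding_char is None:
        breeding_char = phenophase == "BR"
    row = {"capture_id": "C1", "individual_id": "I1", "species": "sp",
           "family": "F", "genus": "G", "guild": "insectivore",
           "landscape": "L1", "date": pd.Timestamp(date),
           "phenophase": phenophase, "age_class": age_class,
           "breeding_char": breeding_char}
    row.update(kw)
    return row


class TestBackdating:
    def test_current_breeding_maps_to_capture_month(self):
        ev = backdate_events(pd.DataFrame([_capture("2016-06-15", "BR")]))
        assert len(ev) == 1
        assert ev["implied_month"].iloc[0] == 6
        assert ev["weight"].iloc[0] == 1.0
        assert ev["event_class"].iloc[0] == "current"

    def test_juvenile_backdated_by_age_class_midpoint_plus_chick(self):
        # JUV1 midpoint 45 d post-fledge + 30 d chick = 75 d before capture:
        # 15 Aug - 75 d = 1 Jun
        ev = backdate_events(pd.DataFrame([_capture("2016-08-15", "JUV1")]))
        assert ev["event_date"].iloc[0] == pd.Timestamp("2016-06-01")
        assert ev["implied_month"].iloc[0] == 6
        assert 0 < ev["weight"].iloc[0] < 1

    def test_prebreeding_birds_emit_nothing(self):
        ev = backdate_events(pd.DataFrame([
            _capture("2016-08-15", "MOLT2", age_class="pre-first-breeding")]))
        assert len(ev) == 0

    def test_early_molt_with_breeding_characters_counts_as_current(self):
        ev = backdate_events(pd.DataFrame([
            _capture("2016-08-15", "MOLT1", breeding_char=True)]))
        assert ev["event_class"].iloc[0] == "current"
        assert ev["implied_month"].iloc[0] == 8

    def test_unknown_code_raises_with_row(self):
        with pytest.raises(ValueError, match="PUPA"):
            backdate_events(pd.DataFrame([_capture("2016-08-15", "PUPA")]))

    def test_none_emits_nothing(self):
        assert len(backdate_events(
            pd.DataFrame([_capture("2016-08-15", "NONE")]))) == 0


def _table(month_events, month_captures):
    """Build a monthly table from dicts month -> value."""
    caps = []
    i = 0
    for m, n in month_captures.items():
        for _ in range(n):
            i += 1
            caps.append(_capture(f"2016-{m:02d}-10", "NONE",
                                 capture_id=f"C{i}"))
    evs = []
    for m, k in month_events.items():
        for _ in range(int(k)):
            i += 1
            evs.append(_capture(f"2016-{m:02d}-12", "BR",
                                capture_id=f"C{i}"))
    caps = pd.DataFrame(caps + evs)
    events = backdate_events(caps)
    return monthly_event_table(events, caps), events, caps


class TestMonthlyTable:
    def test_raw_proportion(self):
        tab, _, _ = _table({6: 4}, {6: 6})
        assert tab.loc[6, "weighted_events"] == pytest.approx(4.0)
        assert tab.loc[6, "exposure"] == pytest.approx(10.0)

    def test_unsampled_month_is_missing_not_zero(self):
        tab, _, _ = _table({6: 2}, {6: 5, 8: 5})
        assert not tab.loc[4, "sampled"]
        assert tab.loc[4, "exposure"] == 0.0

    def test_weights_are_additive(self):
        caps = pd.DataFrame([
            _capture("2016-08-15", "JUV1", capture_id="C1"),
            _capture("2016-08-20", "JUV1", capture_id="C2"),
            _capture("2016-06-10", "NONE", capture_id="C3"),
        ])
        ev = backdate_events(caps)
        tab = monthly_event_table(ev, caps)
        w1 = Durations().juvenile_weights[0]
        assert tab.loc[6, "weighted_events"] == pytest.approx(2 * w1)

    def test_event_mass_is_conserved(self, study):
        cap = study["captures"]
        big = cap.groupby(["species", "landscape"]).size().idxmax()
        sub = cap[(cap["species"] == big[0]) & (cap["landscape"] == big[1])]
        ev = backdate_events(sub)
        tab = monthly_event_table(ev, sub)
        total = tab["weighted_events"].sum() + tab.attrs["orphan_weight"]
        assert total == pytest.approx(ev["weight"].sum(), rel=1e-9)


class TestCurveAndPeak:
    def test_concentrated_events_peak_in_that_month(self):
        tab, _, _ = _table({7: 12}, {m: 10 for m in range(1, 13)})
        c = fit_population_curve(tab)
        assert 6 <= c.peak_month <= 7

    def test_cosine_shaped_events_recover_peak_month(self):
        months = range(1, 13)
        ev = {m: round(20 * (1 + np.cos(2 * np.pi * (m - 7) / 12)) / 2)
              for m in months}
        tab, ev_df, _ = _table(ev, {m: 30 for m in months})
        c = fit_population_curve(tab)
        # the smooth can flatten the very top; the argmax stays inside the
        # peak season and the event-date refinement pins the month
        assert circ_dist(c.peak_month, 6.5, period=12) < 1.5
        refined = phen.refine_peak(ev_df, tab, c.peak_doy)
        assert circ_dist(refined, 6.5 / 12 * 365, period=365) < 20

    def test_uniform_events_are_flagged_flat(self):
        tab, _, _ = _table({m: 5 for m in range(1, 13)},
                           {m: 20 for m in range(1, 13)})
        c = fit_population_curve(tab)
        assert c.flat or c.rate.max() / c.rate.min() < 1.3

    def test_no_events_gives_flagged_curve(self):
        tab, _, _ = _table({}, {m: 10 for m in range(1, 13)})
        c = fit_population_curve(tab)
        assert c.flat and not c.converged

    @pytest.mark.parametrize("peak_doy,guild,expected", [
        (121, "insectivore", 30),   # 1 May from 1 Apr
        (305, "frugivore", 31),     # 1 Nov from 1 Oct
        (152, "nectarivore", 151),  # 1 Jun from 1 Jan
    ])
    def test_linearization_uses_guild_start_dates(self, peak_doy, guild,
                                                  expected):
        grid = np.arange(0.0, 12.0, 0.05)
        rate = np.exp(np.cos(2 * np.pi * (grid - peak_doy / 365 * 12) / 12))
        c = phen.PopulationCurve(grid, rate)
        pk = extract_peak(c, guild)
        assert pk["linearized_day"] == pytest.approx(expected, abs=2)


class TestBimodality:
    @staticmethod
    def _curve(peaks, heights):
        grid = np.arange(0.0, 12.0, 0.05)
        rate = np.zeros_like(grid)
        for p, h in zip(peaks, heights):
            rate += h * np.exp(3 * (np.cos(2 * np.pi * (grid - p) / 12) - 1))
        return phen.PopulationCurve(grid, rate)

    def test_single_peak_is_not_bimodal(self):
        out = detect_bimodality(self._curve([4.5], [1.0]))
        assert not out["bimodal"]

    def test_two_equal_peaks_six_months_apart(self):
        out = detect_bimodality(self._curve([4.5, 10.5], [1.0, 1.0]))
        assert out["bimodal"]
        assert circ_dist(out["secondary_peak_doy"],
                         10.5 / 12 * 365, period=365) < 30 or \
            circ_dist(out["secondary_peak_doy"],
                      4.5 / 12 * 365, period=365) < 30

    def test_small_secondary_below_height_threshold_ignored(self):
        out = detect_bimodality(self._curve([4.5, 10.5], [1.0, 0.1]),
                                min_height_frac=0.25)
        assert not out["bimodal"]

    def test_false_positive_rate_on_unimodal_populations(self, study,
                                                         study_populations):
        truth = study["community"]
        m = study_populations.merge(
            truth, on=["species", "landscape", "guild"])
        uni = m[(~m["bimodal_flag"]) & (m["filter_tier"] >= 2)]
        assert len(uni) >= 30
        assert uni["bimodal"].mean() < 0.05


class TestEffortAndFilters:
    def test_every_capture_breeding_gives_100(self):
        tab, _, _ = _table({6: 10}, {})
        c = fit_population_curve(tab)
        out = reproductive_effort(tab, c)
        assert out["effort_raw_pct"] == pytest.approx(100.0)

    def test_fraction_breeding_recovered(self):
        tab, _, _ = _table({6: 4}, {m: 6 for m in [5, 6, 7, 8, 9, 10]})
        c = fit_population_curve(tab)
        out = reproductive_effort(tab, c)
        assert out["effort_raw_pct"] == pytest.approx(40.0, abs=1e-6)

    def test_halving_breeding_probability_lowers_effort(self):
        hi, _, _ = _table({5: 6, 6: 12, 7: 6}, {m: 20 for m in range(1, 13)})
        lo, _, _ = _table({5: 3, 6: 6, 7: 3}, {m: 20 for m in range(1, 13)})
        e_hi = reproductive_effort(hi, fit_population_curve(hi))
        e_lo = reproductive_effort(lo, fit_population_curve(lo))
        assert e_lo["effort_max_pct"] < e_hi["effort_max_pct"]

    def test_filter_tiers_nest(self):
        tiers = FilterTiers()
        assert apply_filters(3, 12, tiers) == 0
        assert apply_filters(12, 7, tiers) == 2
        assert apply_filters(45, 11, tiers) == 4
        for ev, mo in [(6, 5), (25, 9), (100, 12)]:
            t = apply_filters(ev, mo, tiers)
            for k in range(1, t + 1):
                assert tiers.passes(ev, mo, k)

    def test_higher_tiers_reduce_peak_error_spread(self, study,
                                                   study_populations):
        truth = study["community"]
        m = study_populations.merge(
            truth, on=["species", "landscape", "guild"])
        m = m.dropna(subset=["peak_doy"])
        err = circ_dist(m["peak_doy"], m["true_peak_doy"])
        lo = err[m["filter_tier"] == 1]
        hi = err[m["filter_tier"] >= 3]
        assert len(lo) >= 5 and len(hi) >= 5
        assert np.median(hi) <= np.median(lo)


class TestPopulationPhenology:
    def test_peak_recovery_on_uncoupled_community(self):
        # estimation error alone (no interannual shifts): median |error|
        # under 15 days at >= 30 events
        import cloudphen
        from cloudphen.config import RunConfig
        cfg = RunConfig(seed=31)
        cfg.synth.n_species = 45
        cfg.synth.timing_slope_months = 0.0
        cfg.synth.effort_slope_post_insect = 0.0
        data = cloudphen.simulate_study(cfg)
        pops = phen.population_phenology(data["captures"], data["visits"],
                                         cfg.phenology)
        m = pops.merge(data["community"],
                       on=["species", "landscape", "guild"])
        m = m[(m["n_events"] >= 30) & ~m["bimodal_flag"]].dropna(
            subset=["peak_doy"])
        assert len(m) >= 30
        err = circ_dist(m["peak_doy"], m["true_peak_doy"])
        assert np.median(err) < 15.0

    def test_circular_equivariance_under_date_shift(self):
        import cloudphen
        from cloudphen.config import RunConfig
        cfg = RunConfig(seed=13)
        cfg.synth.n_species = 10
        data = cloudphen.simulate_study(cfg)
        pops = phen.population_phenology(data["captures"], data["visits"],
                                         cfg.phenology)
        shift = 2  # months
        cap2 = data["captures"].copy()
        cap2["date"] = pd.to_datetime(cap2["date"]) + pd.DateOffset(
            months=shift)
        vis2 = data["visits"].copy()
        vis2["date_start"] = pd.to_datetime(vis2["date_start"]) + \
            pd.DateOffset(months=shift)
        pops2 = phen.population_phenology(cap2, vis2, cfg.phenology)
        m = pops.merge(pops2, on=["species", "landscape"],
                       suffixes=("", "_s"))
        m = m.dropna(subset=["peak_doy", "peak_doy_s"])
        m = m[m["n_events"] >= 20]
        assert len(m) >= 8
        d = (m["peak_doy_s"] - m["peak_doy"]) % 365
        med = np.median(d)
        assert abs(med - shift * 30.437) < 10
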