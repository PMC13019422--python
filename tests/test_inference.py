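import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import statsmodels.api as sm

from cloudphen import inference as inf
from cloudphen.inference import (aicc, akaike_weights, classify_regime,
                                 drought_response, fit_guild_model,
                                 segmented_fit, select_climate_window,
                                 select_start_date, spatial_temporal_ratio)
from cloudphen._circular import DAYS_PER_MONTH


class TestAicc:
    def test_hand_computed_value(self):
        # -2*0 + 2*2 + 2*2*3/(10-3) = 4 + 12/7
        assert aicc(0.0, 2, 10) == pytest.approx(4 + 12 / 7)

    def test_large_n_limit_is_aic(self):
        assert aicc(-10.0, 3, 10 ** 7) == pytest.approx(20 + 6, rel=1e-5)

    def test_undefined_for_tiny_samples(self):
        with pytest.raises(ValueError):
            aicc(0.0, 4, 5)

    @given(ll=st.floats(-100, 100), d=st.floats(0.1, 50))
    @settings(max_examples=25, deadline=None)
    def test_strictly_decreasing_in_loglik(self, ll, d):
        assert aicc(ll + d, 3, 50) < aicc(ll, 3, 50)

    def test_duplicate_models_share_weight(self):
        w = akaike_weights([100.0, 100.0, 120.0])
        assert w[0] == pytest.approx(w[1])
        assert w[0] == pytest.approx(0.5, abs=1e-4)


def _pops(n=60, slope=1.0, noise=5.0, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.uniform(200, 450, n)
    return pd.DataFrame({
        "species": [f"s{i % 12}" for i in range(n)],
        "landscape": [f"L{i % 8}" for i in range(n)],
        "linearized_day": 40 + slope * (x - 300) / 10 + rng.normal(0, noise, n),
        "_x": x,
    })


class TestModelSelection:
    def test_true_predictor_beats_null_and_noise(self):
        df = _pops(slope=2.0)
        rng = np.random.default_rng(1)
        tab = select_climate_window(df, {
            "true_window": df["_x"],
            "noise_window": rng.uniform(0, 1, len(df)),
        })
        assert tab.iloc[0]["window"] == "true_window"
        assert tab.iloc[0]["weight"] > 0.5
        assert tab["weight"].sum() == pytest.approx(1.0)

    def test_null_wins_without_signal(self):
        df = _pops(slope=0.0, seed=2)
        tab = select_climate_window(df, {"x": df["_x"]})
        assert tab.iloc[0]["delta"] == 0.0
        assert tab[tab["window"] == "(null)"]["delta"].iloc[0] < 2.0

    def test_start_date_scroll_prefers_season_aligned_origin(self):
        rng = np.random.default_rng(3)
        # insectivore-like peaks in May and October: an April origin keeps
        # the community unwrapped, a July origin splits it
        peaks = np.concatenate([rng.normal(135, 12, 30),
                                rng.normal(285, 12, 30)]) % 365
        tab = select_start_date(peaks)
        assert tab.iloc[0]["start_doy"] in (1, 32, 60, 91)
        july = tab[tab["start_doy"] == 182]["delta"].iloc[0]
        assert july > 2.0


class TestGuildModel:
    def test_matches_ols_without_group_structure(self):
        df = _pops(slope=1.5, seed=4)
        df["species"] = "one"  # single cluster: plain OLS
        m = fit_guild_model(df, "linearized_day", "_x")
        ref = sm.OLS(df["linearized_day"],
                     sm.add_constant(df["_x"])).fit()
        assert m.params["_x"] == pytest.approx(ref.params["_x"], rel=1e-9)

    def test_constant_shift_moves_only_intercept(self):
        df = _pops(seed=5)
        m1 = fit_guild_model(df, "linearized_day", "_x")
        df2 = df.assign(linearized_day=df["linearized_day"] + 100)
        m2 = fit_guild_model(df2, "linearized_day", "_x")
        assert m2.params["_x"] == pytest.approx(m1.params["_x"], rel=1e-9)
        assert m2.params["Intercept"] - m1.params["Intercept"] == \
            pytest.approx(100.0, rel=1e-9)

    def test_interaction_recovers_diverging_slopes(self):
        rng = np.random.default_rng(6)
        n = 120
        x = rng.uniform(-1, 1, n)
        guild = np.where(np.arange(n) % 2 == 0, "a", "b")
        y = np.where(guild == "a", 3 * x, -2 * x) + rng.normal(0, 0.5, n)
        df = pd.DataFrame({"y": y, "x": x, "guild": guild,
                           "species": [f"s{i % 10}" for i in range(n)]})
        m = fit_guild_model(df, "y", "x * C(guild)")
        slope_a = m.params["x"]
        slope_b = slope_a + m.params["x:C(guild)[T.b]"]
        assert slope_a > 0 > slope_b


class TestSegmented:
    def test_noiseless_break_recovered_to_grid_precision(self):
        x = np.linspace(10, 80, 40)
        y = np.where(x <= 43, 2.0 * x, 2.0 * 43 - 1.5 * (x - 43))
        fit = segmented_fit(x, y)
        assert fit.converged and fit.preferred == "segmented"
        assert fit.psi == pytest.approx(43.0, abs=1e-3)
        assert fit.left_slope == pytest.approx(2.0, abs=1e-6)
        assert fit.right_slope == pytest.approx(-1.5, abs=1e-6)

    def test_linear_data_prefers_linear_by_two_aicc(self):
        x = np.linspace(0, 10, 50)
        y = 3 * x + 1.0  # exactly linear: no break exists
        fit = segmented_fit(x, y)
        assert fit.preferred == "linear"
        assert fit.aicc_segmented - fit.aicc_linear >= 2.0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_profile_grid_search_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = np.sort(rng.uniform(0, 100, 30))
        psi0 = rng.uniform(30, 70)
        y = np.where(x <= psi0, x, psi0 + rng.uniform(-3, 3) * (x - psi0)) \
            + rng.normal(0, 1.0, 30)
        fit = segmented_fit(x, y)
        grid = np.arange(x.min() + 1, x.max() - 1, 0.05)
        sses = [inf._hinge_fit(x, y, p)[1] for p in grid]
        psi_grid = grid[int(np.argmin(sses))]
        sse_fit = inf._hinge_fit(x, y, fit.psi)[1]
        assert sse_fit <= min(sses) * 1.001

    def test_breakpoint_ci_coverage(self):
        hits = 0
        n_rep = 150
        for s in range(n_rep):
            rng = np.random.default_rng(1000 + s)
            x = np.sort(rng.uniform(0, 100, 40))
            y = np.where(x <= 43, 1.0 * x, 43 - 1.0 * (x - 43)) \
                + rng.normal(0, 15.0, 40)
            fit = segmented_fit(x, y)
            lo, hi = fit.psi_ci
            if np.isfinite(lo) and lo <= 43 <= hi:
                hits += 1
        assert hits / n_rep >= 0.80

    def test_requires_eight_points(self):
        with pytest.raises(ValueError):
            segmented_fit([1, 2, 3], [1, 2, 3])


class TestRegimesAndTemporal:
    def test_classify_regime_boundaries(self):
        out = classify_regime([10, 70, 200, np.nan])
        assert list(out[:3]) == ["pre", "dry", "post"]
        assert out[3] == "na"

    def test_zero_interannual_variance_gives_zero_slopes(self):
        rows = []
        for p in range(4):
            for y in range(4):
                rows.append({"species": f"s{p}", "landscape": "L1",
                             "year": 2015 + y, "peak_doy": 135.0,
                             "linearized_day": 44.0, "effort_max_pct": 30.0,
                             "event_rate": 0.2, "n_events": 20,
                             "n_captures": 100})
        annual = pd.DataFrame(rows)
        anom = pd.DataFrame([{"landscape": "L1", "year": 2015 + y,
                              "anomaly": 0.0} for y in range(4)])
        dr = drought_response(annual, anom)
        assert dr["pre"]["timing_slope_months"] == 0.0
        assert dr["pre"]["effort_pct_change_dry"] == 0.0

    def test_ratio_flags_zero_temporal_component(self):
        rng = np.random.default_rng(8)
        pops = pd.DataFrame({
            "species": [f"s{i}" for i in range(30)],
            "landscape": "L1",
            "linearized_day": np.r_[rng.normal(44, 8, 15),
                                    rng.normal(194, 8, 15)],
            "bimodal": False,
        })
        drought = {"pre": {"timing_slope_months": 0.0},
                   "post": {"timing_slope_months": 0.0}}
        st_ = spatial_temporal_ratio(pops, drought)
        assert np.isinf(st_["ratio"])
        assert st_["spatial_months"] == pytest.approx(150 / DAYS_PER_MONTH,
                                                      abs=0.6)

    def test_ratio_invariant_to_global_date_shift(self):
        # shift small enough that no population crosses the dry-season
        # boundary of the regime classifier
        rng = np.random.default_rng(9)
        lin = np.r_[rng.normal(35, 3, 15), rng.normal(194, 8, 15)]
        drought = {"pre": {"timing_slope_months": 1.0},
                   "post": {"timing_slope_months": -1.0}}
        base = pd.DataFrame({"species": [f"s{i}" for i in range(30)],
                             "landscape": "L1", "linearized_day": lin,
                             "bimodal": False})
        shifted = base.assign(linearized_day=lin + 10)
        a = spatial_temporal_ratio(base, drought)
        b = spatial_temporal_ratio(shifted, drought)
        assert a["ratio"] == pytest.approx(b["ratio"], rel=1e-9)

    def test_near_identical_landscapes_downweighted(self):
        # a species spanning two near-identical landscapes gets a small
        # gradient-span weight and barely moves the offset estimate
        rng = np.random.default_rng(10)
        lin = np.r_[rng.normal(44, 5, 10), rng.normal(194, 5, 10), [280.0]]
        pops = pd.DataFrame({"species": [f"s{i}" for i in range(21)],
                             "landscape": "L1", "linearized_day": lin,
                             "bimodal": False})
        w = np.r_[np.ones(20), [0.01]]
        off_w, *_ = inf.regime_offset_months(pops, gradient_span=w)
        off_u, *_ = inf.regime_offset_months(pops)
        truth = 150 / DAYS_PER_MONTH
        assert abs(off_w - truth) < abs(off_u - truth)
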