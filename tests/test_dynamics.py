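"""The daily LT10 state machine: increments, transition, full simulation."""

import numpy as np
import pandas as pd
import pytest

import coldhardiness as ch
from coldhardiness.dynamics import PHASE_ACCLIMATION, PHASE_DEACCLIMATION, PHASE_PRE
from coldhardiness.errors import DataError, ParameterError

from _oracles import brute_simulate, random_season_weather

LAT = 31.37


class TestIncrements:
    @pytest.mark.parametrize(
        "csm_prev, csm_ac, expected",
        [
            (0.0, -489.8, 1.0),        # no memory yet: full acclimation rate
            (-489.8, -489.8, 0.0),     # at the critical depth: halted
            (-244.9, -489.8, 0.5),
            (-600.0, -489.8, 0.0),     # beyond critical: still halted
        ],
    )
    def test_slowdown_factor(self, csm_prev, csm_ac, expected):
        assert ch.slowdown_factor(csm_prev, csm_ac) == expected

    def test_slowdown_requires_negative_critical_memory(self):
        with pytest.raises(ParameterError):
            ch.slowdown_factor(-10.0, 0.0)

    def test_acclimation_increment(self):
        assert ch.acclimation_increment(-7.4, 0.0, 0.051, 1.0) == pytest.approx(-0.3774)
        assert ch.acclimation_increment(-5.0, -5.0, 0.051, 1.0) == 0.0
        assert ch.acclimation_increment(-100.0, -90.0, 0.051, 0.0) == 0.0

    def test_growing_degree_days(self):
        assert ch.growing_degree_days([0.0 - 4.0], 0, 0, -4.0) == 0.0
        assert ch.growing_degree_days([5.0, 10.0], 0, 1, -4.0) == pytest.approx(23.0)
        assert ch.growing_degree_days([-10.0, -20.0], 0, 1, -4.0) == 0.0
        with pytest.raises(ParameterError):
            ch.growing_degree_days([5.0, 10.0], 1, 0, -4.0)

    def test_deacclimation_increment_signs(self):
        assert ch.deacclimation_increment(-5.0, -5.0, 3.0, 3.0, 0.032) == 0.0
        # warm day: memory fades (+3) and degree days grow (+14)
        assert ch.deacclimation_increment(-7.0, -10.0, 17.0, 3.0, 0.032) == pytest.approx(0.544)
        # cold snap: memory deepens faster than degree days grow -> reacclimation
        assert ch.deacclimation_increment(-30.0, -10.0, 5.0, 3.0, 0.032) == pytest.approx(-0.576)


class TestOnsetAndTransition:
    def test_onset_is_first_strict_crossing(self):
        assert ch.detect_onset([20.0, 18.0, 16.0], 17.4) == 2
        assert ch.detect_onset([10.0, 18.0], 17.4) == 0
        assert ch.detect_onset([20.0, 18.0], 17.4) is None
        assert ch.detect_onset([16.0, 20.0, 16.0], 17.4, start_index=1) == 2

    def test_threshold_tie_does_not_trigger_onset(self):
        assert ch.detect_onset([17.4, 17.4], 17.4) is None

    def test_empty_series_rejected(self):
        with pytest.raises(DataError):
            ch.detect_onset([], 17.4)

    def test_transition_by_chilling_regardless_of_date(self):
        assert ch.should_transition(-610.0, -605.0, LAT, 350, 661.0)

    def test_no_transition_in_midwinter_with_shallow_memory(self):
        assert not ch.should_transition(-100.0, -605.0, LAT, 350, 661.0)

    def test_transition_by_photoperiod_in_spring(self):
        assert ch.should_transition(-100.0, -605.0, LAT, 85, 654.0)

    def test_and_rule_requires_both_conditions(self):
        assert not ch.should_transition(-610.0, -605.0, LAT, 350, 661.0, rule="and")
        assert ch.should_transition(-610.0, -605.0, LAT, 85, 654.0, rule="and")


def _weather(temps, start="2015-10-01"):
    return pd.DataFrame({"date": pd.date_range(start, periods=len(temps)), "tmean_c": temps})


class TestSimulate:
    def test_all_warm_season_stays_at_baseline(self, yabukita):
        r = ch.simulate(_weather(np.full(180, 20.0)), yabukita, LAT)
        assert np.all(r.daily["lt10_c"] == -2.0)
        assert np.all(r.daily["phase"] == PHASE_PRE)
        assert r.onset_date is None and r.transition_date is None

    def test_constant_cold_matches_hand_recursion(self, yabukita):
        r = ch.simulate(_weather(np.full(10, 10.0)), yabukita, LAT)
        assert r.daily["lt10_c"].iloc[0] == pytest.approx(-2.3774)
        assert r.daily["lt10_c"].iloc[1] == pytest.approx(-2.749, abs=5e-4)
        assert r.onset_date == pd.Timestamp("2015-10-01")

    def test_weather_gap_rejected(self, yabukita):
        w = _weather(np.full(10, 10.0))
        w = pd.concat([w.iloc[:5], w.iloc[6:]], ignore_index=True)
        with pytest.raises(DataError):
            ch.simulate(w, yabukita, LAT)

    def test_lt10_capped_at_baseline_and_diagnostics_bounded(self, yabukita, one_season_weather):
        r = ch.simulate(one_season_weather, yabukita, LAT)
        d = r.daily
        assert np.all(d["lt10_c"] <= yabukita.lt10_ini + 1e-12)
        assert np.all((d["s"] >= 0) & (d["s"] <= 1))
        assert np.all(d["csm_c"] <= 0)
        assert np.all(d["gdd_cday"] >= 0)
        de = d.index[d["phase"] == PHASE_DEACCLIMATION]
        assert np.all(np.diff(d.loc[de, "gdd_cday"]) >= 0)

    def test_phase_sequence_is_monotone(self, yabukita, one_season_weather):
        order = {PHASE_PRE: 0, PHASE_ACCLIMATION: 1, PHASE_DEACCLIMATION: 2}
        r = ch.simulate(one_season_weather, yabukita, LAT)
        codes = r.daily["phase"].map(order).to_numpy()
        assert np.all(np.diff(codes) >= 0)

    def test_seasonal_shape_and_spring_reacclimation_dip(self, yabukita):
        cfg = ch.kagoshima_like(2015, 1, seed=3)
        cold_snap = ch.Spell(start=pd.Timestamp("2016-03-10").date(), length_days=5, offset_c=-12.0)
        base = ch.generate_weather(cfg)
        snap = ch.generate_weather(
            ch.kagoshima_like(2015, 1, seed=3, spells=[cold_snap])
        )
        r0 = ch.simulate(base, yabukita, LAT)
        r1 = ch.simulate(snap, yabukita, LAT)
        # autumn fall, midwinter minimum well below baseline, spring recovery
        lt = r0.daily.set_index("date")["lt10_c"]
        assert lt.min() < -10.0
        assert lt.loc["2016-06-25":].iloc[-1] == pytest.approx(-2.0, abs=0.5)
        # the March cold snap regains hardiness relative to the undisturbed run
        win = slice("2016-03-11", "2016-03-20")
        assert (r1.daily.set_index("date")["lt10_c"].loc[win]
                < lt.loc[win] - 0.05).any()

    def test_colder_series_is_pointwise_hardier_during_acclimation(self, yabukita):
        rng = np.random.default_rng(31)
        ta = 14.0 + rng.normal(0, 2.0, 120)  # below threshold throughout
        ta = np.minimum(ta, 17.0)
        w0, w1 = _weather(ta), _weather(ta - 1.0)
        r0 = ch.simulate(w0, yabukita, LAT)
        r1 = ch.simulate(w1, yabukita, LAT)
        acc = r0.daily["phase"].to_numpy() == PHASE_ACCLIMATION
        acc &= r1.daily["phase"].to_numpy() == PHASE_ACCLIMATION
        assert np.all(r1.daily["lt10_c"].to_numpy()[acc]
                      <= r0.daily["lt10_c"].to_numpy()[acc] + 1e-12)

    @pytest.mark.parametrize("cultivar", ["yabukita", "yutakamidori"])
    def test_matches_brute_force_recursion(self, cultivar, request):
        params = request.getfixturevalue(cultivar)
        rng = np.random.default_rng(99)
        for _ in range(10):
            ta, doy = random_season_weather(rng)
            dates = pd.to_datetime("2014-12-31") + pd.to_timedelta(doy[0] + np.arange(len(ta)), "D")
            w = pd.DataFrame({"date": dates, "tmean_c": ta})
            r = ch.simulate(w, params, LAT)
            lt_o, csm_o, phase_o, onset_o, de_o = brute_simulate(
                ta, w["date"].dt.dayofyear.to_numpy(), params, LAT
            )
            np.testing.assert_allclose(r.daily["lt10_c"], lt_o, rtol=1e-9, atol=1e-9)
            np.testing.assert_allclose(r.daily["csm_c"], csm_o, rtol=1e-9, atol=1e-9)
            assert list(r.daily["phase"]) == phase_o

    def test_season_start_date_delays_onset(self, yabukita):
        w = _weather(np.full(60, 10.0))
        r = ch.simulate(w, yabukita, LAT, season_start_date="2015-10-20")
        assert r.onset_date == pd.Timestamp("2015-10-20")
        assert np.all(r.daily["lt10_c"].iloc[:19] == -2.0)


class TestSeasonSplitting:
    def test_multi_year_series_splits_at_july_first(self, yabukita):
        w = pd.DataFrame(
            {"date": pd.date_range("2014-07-01", "2017-06-30"), "tmean_c": 20.0}
        )
        chunks = ch.split_seasons(w)
        assert len(chunks) == 3
        assert [c["date"].iloc[0].strftime("%m-%d") for c in chunks] == ["07-01"] * 3
        assert sum(len(c) for c in chunks) == len(w)

    def test_each_season_restarts_from_baseline(self, yabukita, five_season_weather):
        results = ch.simulate_seasons(five_season_weather, yabukita, LAT)
        assert len(results) == 5
        for r in results:
            assert r.daily["lt10_c"].iloc[0] == -2.0
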