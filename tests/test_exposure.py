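"""Exposure detection: heat events, precipitation days, drought spells,
district consolidation, and heat-drought overlap."""

import datetime as dt

import numpy as np
import pytest

from climhealth import (
    DetectionParams,
    DroughtCategory,
    DroughtCategorySeries,
    HeatEvent,
    HeatRun,
    InputError,
    consolidate_district_events,
    count_heavy_precip_days,
    detect_heat_events,
    detect_heat_runs,
    extract_drought_spells,
    overlap_days,
)

from _oracles import (
    oracle_drought_spells,
    oracle_heat_events,
    oracle_heavy_precip_days,
    oracle_overlap_days,
)
from conftest import make_series, random_summer_observations

D = dt.date


def days(start: dt.date, values):
    return {start + dt.timedelta(days=i): v for i, v in enumerate(values)}


class TestHeatEvents:
    def test_three_day_run_is_one_event(self, params):
        # the earliest printed district event: a 3-day late-August window
        obs = days(D(2000, 8, 20), [90.0] * 8 + [96.0, 96.0, 96.0] + [90.0] * 5)
        events = detect_heat_events(make_series("Union", obs), params)
        assert events == [
            HeatEvent("Union", D(2000, 8, 28), D(2000, 8, 30), 96.0)
        ]
        assert events[0].duration_days == 3

    def test_two_days_at_threshold_is_not_an_event(self, params):
        obs = days(D(2005, 7, 1), [90.0, 95.0, 95.0, 90.0])
        assert detect_heat_events(make_series("A", obs), params) == []

    def test_threshold_is_inclusive(self, params):
        exactly = days(D(2005, 7, 1), [95.0, 95.0, 95.0])
        assert len(detect_heat_events(make_series("A", exactly), params)) == 1
        shy = days(D(2005, 7, 1), [94.9] * 120)
        assert detect_heat_events(make_series("A", shy), params) == []

    def test_empty_series_yields_no_events(self, params):
        assert detect_heat_events(make_series("A", {}), params) == []

    def test_unsorted_dates_rejected(self, params):
        import pandas as pd

        frame = pd.DataFrame(
            {
                "date": [D(2005, 7, 2), D(2005, 7, 1)],
                "tmax_f": [96.0, 96.0],
                "precip_in": [0.0, 0.0],
            }
        )
        from climhealth import DailyWeatherSeries

        with pytest.raises(InputError):
            DailyWeatherSeries(county="A", frame=frame)

    def test_missing_day_breaks_run(self, params):
        obs = days(D(2005, 7, 1), [96.0, 96.0])
        obs[D(2005, 7, 3)] = None
        obs.update(days(D(2005, 7, 4), [96.0, 96.0]))
        assert detect_heat_events(make_series("A", obs), params) == []
        runs = detect_heat_runs(make_series("A", obs), params)
        assert [r.length for r in runs] == [2, 2]

    def test_season_clips_events(self, params):
        # hot run straddling Sep 30: only the in-season part can qualify
        obs = days(D(2010, 9, 28), [97.0] * 6)  # Sep 28 .. Oct 3
        events = detect_heat_events(make_series("A", obs), params)
        assert events == [HeatEvent("A", D(2010, 9, 28), D(2010, 9, 30), 97.0)]
        # only two in-season hot days -> nothing qualifies
        obs2 = days(D(2010, 9, 29), [97.0] * 6)
        assert detect_heat_events(make_series("A", obs2), params) == []

    @pytest.mark.parametrize("seed", range(60))
    def test_matches_exhaustive_window_oracle(self, params, seed):
        rng = np.random.default_rng(seed)
        obs = random_summer_observations(rng, n_days=200)
        got = detect_heat_events(make_series("A", obs), params)
        expected = oracle_heat_events(obs)
        assert [(e.start, e.end, e.peak_tmax_f) for e in got] == expected

    @pytest.mark.parametrize("seed", range(20))
    def test_detected_events_are_valid_and_maximal(self, params, seed):
        rng = np.random.default_rng(1000 + seed)
        obs = random_summer_observations(rng, n_days=250)
        for ev in detect_heat_events(make_series("A", obs), params):
            assert ev.duration_days >= params.min_run_days
            for day in ev.days():
                assert obs.get(day) is not None
                assert obs[day] >= params.heat_threshold_f
                assert params.season.contains(day)
            for edge in (ev.start - dt.timedelta(days=1), ev.end + dt.timedelta(days=1)):
                qualifies = (
                    obs.get(edge) is not None
                    and obs[edge] >= params.heat_threshold_f
                    and params.season.contains(edge)
                )
                assert not qualifies

    @pytest.mark.parametrize("seed", range(10))
    def test_monotone_in_threshold_and_min_run(self, seed):
        rng = np.random.default_rng(2000 + seed)
        obs = random_summer_observations(rng, n_days=150)
        series = make_series("A", obs)
        counts = [
            len(detect_heat_events(series, DetectionParams(heat_threshold_f=t)))
            for t in (90.0, 95.0, 100.0)
        ]
        assert counts == sorted(counts, reverse=True)
        counts = [
            len(detect_heat_events(series, DetectionParams(min_run_days=k)))
            for k in (1, 3, 5)
        ]
        assert counts == sorted(counts, reverse=True)


class TestDistrictConsolidation:
    def test_single_event_single_county(self, params):
        ev = HeatEvent("Union", D(2006, 7, 18), D(2006, 7, 21), 97.0)
        run = HeatRun("Union", D(2006, 7, 18), D(2006, 7, 21), 97.0)
        district = consolidate_district_events({"Union": [ev]}, {"Union": [run]}, params)
        assert len(district) == 1
        assert district[0].counties_affected == {"Union"}
        assert district[0].near_threshold == frozenset()

    def test_two_day_run_annotated_near_threshold(self, params):
        # one county's long event, another county two days shy inside it
        ev = HeatEvent("Henderson", D(2007, 7, 31), D(2007, 8, 24), 99.0)
        near = HeatRun("Daviess", D(2007, 8, 2), D(2007, 8, 3), 96.0)
        district = consolidate_district_events(
            {"Henderson": [ev], "Daviess": []},
            {"Henderson": [HeatRun("Henderson", ev.start, ev.end, 99.0)], "Daviess": [near]},
            params,
        )
        assert district[0].counties_affected == {"Henderson"}
        assert district[0].near_threshold == {("Daviess", 2)}

    def test_identical_windows_merge(self, params):
        evs = {
            c: [HeatEvent(c, D(2011, 8, 31), D(2011, 9, 3), 96.0)]
            for c in ("A", "B", "C")
        }
        district = consolidate_district_events(evs, {c: [] for c in evs}, params)
        assert len(district) == 1
        assert district[0].counties_affected == {"A", "B", "C"}

    def test_abutting_events_merge_but_gapped_do_not(self, params):
        a = HeatEvent("A", D(2012, 7, 1), D(2012, 7, 4), 96.0)
        b = HeatEvent("B", D(2012, 7, 5), D(2012, 7, 8), 96.0)  # abuts a
        c = HeatEvent("C", D(2012, 7, 10), D(2012, 7, 13), 96.0)  # 1-day gap
        district = consolidate_district_events(
            {"A": [a], "B": [b], "C": [c]}, {}, params
        )
        assert [(d.start, d.end) for d in district] == [
            (D(2012, 7, 1), D(2012, 7, 8)),
            (D(2012, 7, 10), D(2012, 7, 13)),
        ]
        assert district[0].counties_affected == {"A", "B"}

    def test_affected_county_not_double_counted_as_near(self, params):
        ev = HeatEvent("A", D(2012, 7, 1), D(2012, 7, 4), 96.0)
        short = HeatRun("A", D(2012, 7, 1), D(2012, 7, 2), 96.0)
        district = consolidate_district_events({"A": [ev]}, {"A": [short]}, params)
        assert district[0].near_threshold == frozenset()


class TestHeavyPrecip:
    def test_zero_series_counts_zero(self, params):
        obs = days(D(2012, 1, 1), [80.0] * 30)
        assert count_heavy_precip_days(make_series("A", obs), params, 2012) == 0

    def test_exactly_two_inches_does_not_count(self, params):
        series = make_series("A", {}, precip={D(2012, 4, 1): 2.0})
        assert count_heavy_precip_days(series, params, 2012) == 0

    def test_strictly_over_counts(self, params):
        series = make_series(
            "A", {}, precip={D(2012, 4, 1): 2.5, D(2012, 5, 2): 3.1, D(2012, 6, 3): 0.2}
        )
        assert count_heavy_precip_days(series, params, 2012) == 2
        assert count_heavy_precip_days(series, params, 2011) == 0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_oracle_and_monotone_in_threshold(self, seed):
        rng = np.random.default_rng(3000 + seed)
        precip = {
            D(2012, 1, 1) + dt.timedelta(days=int(i)): float(rng.exponential(1.2))
            for i in range(300)
        }
        series = make_series("A", {}, precip=precip)
        for thr in (0.5, 2.0, 4.0):
            got = count_heavy_precip_days(series, DetectionParams(precip_threshold_in=thr), 2012)
            assert got == oracle_heavy_precip_days(precip, thr, 2012)
        counts = [
            count_heavy_precip_days(series, DetectionParams(precip_threshold_in=t), 2012)
            for t in (0.5, 2.0, 4.0)
        ]
        assert counts == sorted(counts, reverse=True)


def weekly(county, start, labels):
    pairs = [
        (start + dt.timedelta(weeks=i), DroughtCategory.parse(c))
        for i, c in enumerate(labels)
    ]
    return DroughtCategorySeries(county=county, weeks=tuple(pairs))


class TestDroughtSpells:
    def test_all_below_floor_yields_nothing(self, params):
        series = weekly("A", D(2012, 5, 7), ["D1"] * 10)
        assert extract_drought_spells(series, params) == []

    def test_single_spell_with_peak(self, params):
        series = weekly("A", D(2012, 5, 7), ["D1", "D2", "D3", "D2", "D1"])
        spells = extract_drought_spells(series, params)
        assert len(spells) == 1
        spell = spells[0]
        assert spell.n_weeks == 3
        assert spell.start_week == D(2012, 5, 14)
        assert spell.peak_category == DroughtCategory.D3

    def test_week_gap_splits_spell(self, params):
        pairs = [
            (D(2012, 5, 7), DroughtCategory.D2),
            (D(2012, 5, 14), DroughtCategory.D2),
            # missing week 5/21
            (D(2012, 5, 28), DroughtCategory.D3),
        ]
        series = DroughtCategorySeries(county="A", weeks=tuple(pairs))
        spells = extract_drought_spells(series, params)
        assert [(s.start_week, s.n_weeks) for s in spells] == [
            (D(2012, 5, 7), 2),
            (D(2012, 5, 28), 1),
        ]

    @pytest.mark.parametrize("seed", range(60))
    def test_matches_week_scan_oracle(self, params, seed):
        rng = np.random.default_rng(4000 + seed)
        labels = [["NONE", "D0", "D1", "D2", "D3", "D4"][i] for i in rng.integers(0, 6, 80)]
        series = weekly("A", D(2010, 1, 4), labels)
        got = extract_drought_spells(series, params)
        expected = oracle_drought_spells(
            [(w, int(c)) for w, c in series.weeks], min_severity=2
        )
        assert [(s.start_week, s.end_week, int(s.peak_category)) for s in got] == expected


class TestOverlapDays:
    def test_disjoint_events_contribute_nothing(self):
        ev = HeatEvent("A", D(2012, 6, 1), D(2012, 6, 5), 96.0)
        assert overlap_days([ev], (D(2012, 7, 1), D(2012, 8, 31))) == 0

    def test_full_containment_excludes_straddling_events(self):
        inside = HeatEvent("A", D(2012, 7, 15), D(2012, 8, 9), 100.0)
        straddle = HeatEvent("A", D(2012, 6, 27), D(2012, 7, 10), 100.0)
        window = (D(2012, 7, 1), D(2012, 8, 31))
        assert overlap_days([inside, straddle], window, "full_containment") == 26
        assert overlap_days([inside, straddle], window, "per_day") == 26 + 10

    def test_spells_expand_to_weeks_of_days(self):
        from climhealth import DroughtSpell

        spell = DroughtSpell("A", D(2012, 7, 2), D(2012, 7, 23), DroughtCategory.D4)
        ev = HeatEvent("A", D(2012, 7, 2), D(2012, 7, 6), 96.0)
        # spell days cover 7/2 .. 7/29 (4 weeks x 7 days)
        assert overlap_days([ev], [spell]) == 5

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_per_day_oracle(self, seed):
        rng = np.random.default_rng(5000 + seed)
        base = D(2012, 6, 1)
        events = []
        for _ in range(rng.integers(1, 8)):
            start = base + dt.timedelta(days=int(rng.integers(0, 90)))
            end = start + dt.timedelta(days=int(rng.integers(0, 12)))
            events.append(HeatEvent("A", start, end, 96.0))
        w0 = base + dt.timedelta(days=int(rng.integers(0, 45)))
        w1 = w0 + dt.timedelta(days=int(rng.integers(5, 60)))
        period = {w0 + dt.timedelta(days=k) for k in range((w1 - w0).days + 1)}
        for policy in ("full_containment", "per_day"):
            got = overlap_days(events, (w0, w1), policy)
            expected = oracle_overlap_days(
                [(e.start, e.end) for e in events], period, policy
            )
            assert got == expected
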