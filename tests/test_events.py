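"""Independent-event assignment, effort bookkeeping and descriptive RDF stats."""

from datetime import date, datetime, timedelta

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fearscape.events import (
    DetectionRecord,
    assign_events,
    build_occasions,
    compare_site_use,
    effort_from_daily,
    parse_records,
    rdf,
    response_table,
)


def _rec(minutes, site="A", cls="chimpanzee"):
    base = datetime(2017, 7, 10, 10, 0)
    return [DetectionRecord(site, cls, base + timedelta(minutes=m)) for m in minutes]


def _oracle_event_count(minutes, gap=30):
    """Independent check: sorted minute stamps split where the gap >= threshold."""
    t = np.sort(np.asarray(minutes))
    if t.size == 0:
        return 0
    return 1 + int(np.sum(np.diff(t) >= gap))


class TestAssignEvents:
    def test_empty_input(self):
        assert assign_events([]) == []

    def test_rolling_chain(self):
        # 10:00, 10:20, 10:45 chain (gaps 20, 25 < 30); 11:20 starts anew
        evs = assign_events(_rec([0, 20, 45, 80]))
        assert len(evs) == 2
        assert evs[0].n_photos == 3
        assert evs[0].start == datetime(2017, 7, 10, 10, 0)
        assert evs[0].end == datetime(2017, 7, 10, 10, 45)
        assert evs[1].n_photos == 1

    def test_exact_gap_splits(self):
        # the merge rule is strict <, so a 30-min gap separates events
        assert len(assign_events(_rec([0, 30]))) == 2

    def test_order_invariance(self):
        a = assign_events(_rec([45, 0, 80, 20]))
        b = assign_events(_rec([0, 20, 45, 80]))
        assert a == b

    def test_sites_and_classes_independent(self):
        recs = _rec([0, 10]) + _rec([0, 10], site="B") + _rec([5], cls="human")
        evs = assign_events(recs)
        assert len(evs) == 3

    def test_gap_limits(self):
        minutes = [0, 7, 50, 90, 200]
        assert len(assign_events(_rec(minutes), gap_minutes=1e-6)) == len(minutes)
        assert len(assign_events(_rec(minutes), gap_minutes=1e9)) == 1

    def test_invalid_gap(self):
        with pytest.raises(ValueError):
            assign_events(_rec([0]), gap_minutes=0)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.integers(min_value=0, max_value=2000), min_size=1, max_size=50))
    def test_matches_gap_partition_oracle(self, minutes):
        evs = assign_events(_rec(minutes))
        assert len(evs) == _oracle_event_count(minutes)
        assert sum(e.n_photos for e in evs) == len(minutes)

    def test_unparseable_timestamp_rejected(self, caplog):
        df = pd.DataFrame(
            {
                "site_id": ["A", "A"],
                "species_class": ["chimpanzee"] * 2,
                "timestamp": ["2017-07-10T10:00", "not-a-time"],
            }
        )
        recs = parse_records(df)
        assert len(recs) == 1


class TestRdf:
    def test_arithmetic(self):
        assert rdf(16, 320) == 5.0
        assert rdf(0, 250) == 0.0

    def test_invalid_effort(self):
        with pytest.raises(ValueError):
            rdf(3, 0)

    def test_mean_effort_per_site(self):
        # a 21-site effort table totalling 6722 camera-trap days
        effort = np.full(21, 6722 / 21)
        assert effort.sum() == pytest.approx(6722)
        assert round(float(effort.mean()), 2) == 320.10

    def test_rdf_effort_product_recovers_event_total(self, rng):
        events = rng.integers(0, 60, size=21)
        effort = rng.uniform(200, 360, size=21)
        back = sum(rdf(n, e) * e / 100.0 for n, e in zip(events, effort))
        assert back == pytest.approx(events.sum(), abs=1e-9)


class TestOccasions:
    def test_midpoint_rule(self):
        grid = build_occasions(
            [date(2017, 7, 15), date(2017, 7, 30)], date(2017, 7, 9), date(2017, 8, 6)
        )
        assert grid.starts == (date(2017, 7, 9), date(2017, 7, 23))
        assert grid.ends == (date(2017, 7, 22), date(2017, 8, 6))

    def test_24_dates_give_24_occasions(self):
        dates = [date(2017, 7, 15) + timedelta(days=15 * i) for i in range(24)]
        grid = build_occasions(dates, date(2017, 7, 9), date(2018, 7, 5))
        assert grid.n_occasions == 24
        # contiguity and phenology containment hold by construction
        assert grid.occasion_of(date(2017, 7, 15)) == 1

    def test_single_date_errors(self):
        with pytest.raises(ValueError):
            build_occasions([date(2017, 7, 15)], date(2017, 7, 9), date(2017, 8, 6))

    def test_explicit_boundaries_override(self):
        grid = build_occasions(
            [date(2017, 7, 15), date(2017, 7, 30)],
            date(2017, 7, 9),
            date(2017, 8, 6),
            boundaries=[date(2017, 7, 23)],
        )
        assert grid.ends[0] == date(2017, 7, 23)


class TestResponseTable:
    def _grid(self):
        return build_occasions(
            [date(2017, 7, 16), date(2017, 7, 31)], date(2017, 7, 9), date(2017, 8, 7)
        )

    def _effort(self, active_first):
        grid = self._grid()
        rows = []
        for i in range(grid.length_days(1)):
            d = grid.starts[0] + timedelta(days=i)
            rows.append(("A", d.isoformat(), int(i < active_first)))
        for i in range(grid.length_days(2)):
            d = grid.starts[1] + timedelta(days=i)
            rows.append(("A", d.isoformat(), 1))
        return effort_from_daily(pd.DataFrame(rows, columns=["site_id", "date", "active"]), grid)

    def test_na_rule_strictly_more_than_seven(self):
        grid = self._grid()
        occ_len = grid.length_days(1)  # 15 days
        tab_8_inactive = response_table([], self._effort(occ_len - 8), grid)
        tab_7_inactive = response_table([], self._effort(occ_len - 7), grid)
        assert np.isnan(tab_8_inactive.loc["A", 1])
        assert tab_7_inactive.loc["A", 1] == 0.0

    def test_rate_arithmetic(self):
        grid = self._grid()
        base = datetime(2017, 7, 10, 8, 0)
        recs = [
            DetectionRecord("A", "chimpanzee", base + timedelta(hours=5 * k)) for k in range(3)
        ]
        evs = assign_events(recs)
        tab = response_table(evs, self._effort(15), grid)
        assert tab.loc["A", 1] == pytest.approx(3 / 15)


class TestCompareSiteUse:
    @pytest.mark.parametrize(
        "a, b, expected",
        [((1, 2, 3), (2, 4, 9), 1.0), ((1, 2, 3), (9, 4, 2), -1.0), ((3, 1, 2), (2, 3, 1), -0.5)],
    )
    def test_spearman_values(self, a, b, expected):
        assert compare_site_use(a, b)["spearman_rs"] == pytest.approx(expected)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            compare_site_use((1, 1, 1), (1, 2, 3))

    def test_rank_sum_between_strata(self, rng):
        a = rng.uniform(0, 50, 21)
        b = rng.uniform(0, 50, 21)
        labels = ["forest"] * 7 + ["matrix"] * 14
        out = compare_site_use(a, b, stratum=labels)
        assert 0 <= out["wilcoxon_W"] <= 7 * 14
        assert 0 <= out["wilcoxon_p"] <= 1
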