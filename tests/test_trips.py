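"""Dwell-time stop detection, trip extraction, and sequence encoding."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from tests.conftest import make_coded_fixes
from tracklink.landuse import ROAD
from tracklink.trips import (
    build_sequences,
    detect_stops,
    encode_sequence,
    extract_trips,
    split_codes,
    trip_code,
    trips_to_frame,
    frame_to_trips,
)


def test_thirteen_fixes_at_school_form_one_stop():
    # 13 fixes at the 10 s epoch span exactly 120 s
    fixes = make_coded_fixes([(ROAD, 3), ("B", 13), (ROAD, 3)])
    stops = detect_stops(fixes)
    assert len(stops) == 1
    assert stops[0].location_code == "B"
    assert stops[0].duration_s == 120.0


def test_below_threshold_visit_is_travel_not_stop():
    fixes = make_coded_fixes([("A", 20), (ROAD, 4), ("D", 5), (ROAD, 4), ("B", 20)])
    stops = detect_stops(fixes)
    assert [s.location_code for s in stops] == ["A", "B"]
    trips = extract_trips(stops, fixes)
    assert len(trips) == 1
    assert trips[0].code == "Ab"
    # the sub-dwell shop visit belongs to the enclosing trip's span
    lo, hi = trips[0].fix_span
    assert hi - lo + 1 == 13


def test_road_runs_never_become_stops():
    fixes = make_coded_fixes([(ROAD, 100)])
    assert detect_stops(fixes) == []


def test_empty_input_gives_empty_stops():
    assert detect_stops(make_coded_fixes([])) == []


def test_gap_bridging_at_same_location():
    """A 2-minute dropout inside a dwell is bridged; a long one splits."""
    base = make_coded_fixes([("A", 30)])
    short_gap = base.drop(index=range(10, 22)).reset_index(drop=True)  # 120 s hole
    stops = detect_stops(short_gap, gap_tolerance_s=300)
    assert len(stops) == 1

    long_gap = base.copy()
    long_gap.loc[15:, "timestamp"] += pd.Timedelta(seconds=600)
    stops = detect_stops(long_gap, gap_tolerance_s=300)
    assert len(stops) == 2


def test_trip_between_different_stops_with_road_between():
    fixes = make_coded_fixes([("A", 20), (ROAD, 10), ("B", 20)])
    stops = detect_stops(fixes)
    trips = extract_trips(stops, fixes)
    assert [t.code for t in trips] == ["Ab"]
    t = trips[0]
    assert t.depart == stops[0].end and t.arrive == stops[1].start
    assert t.on_road_fraction == 1.0 and not t.off_road


def test_same_location_pair_without_exit_is_not_a_trip():
    fixes = make_coded_fixes([("A", 20), ("A", 20)])
    stops = detect_stops(fixes)
    assert len(stops) == 1  # contiguous same-code fixes are one run
    # force two stops with a long same-location gap: still no exit, no trip
    gap = make_coded_fixes([("A", 20)])
    second = make_coded_fixes([("A", 20)], start="2011-03-14 10:00:00")
    fixes = pd.concat([gap, second], ignore_index=True)
    stops = detect_stops(fixes)
    assert len(stops) == 2
    assert extract_trips(stops, fixes) == []


def test_same_location_trip_emitted_when_fixes_leave_polygon():
    fixes = make_coded_fixes([("A", 20), (ROAD, 8), ("A", 20)])
    stops = detect_stops(fixes)
    trips = extract_trips(stops, fixes)
    assert [t.code for t in trips] == ["Aa"]
    assert extract_trips(stops, fixes, include_same_location=False) == []


def test_mostly_off_road_trip_is_flagged_and_excluded_from_sequences():
    fixes = make_coded_fixes([("A", 20), ("E", 9), (ROAD, 1), ("B", 20)])
    trips = extract_trips(detect_stops(fixes), fixes)
    assert trips[0].off_road and trips[0].on_road_fraction == 0.1
    assert build_sequences(trips) == []
    seqs = build_sequences(trips, include_off_road=True)
    assert seqs[0].code_string == "Ab"


def test_trips_match_brute_force_stop_pair_enumeration(null_cohort):
    """Trips equal a hand enumeration over consecutive stop pairs."""
    from tracklink.landuse import assign_locations

    fixes = assign_locations(
        null_cohort.fixes.reset_index(drop=True), null_cohort.world.landuse, null_cohort.world.places
    )
    stops = detect_stops(fixes)
    trips = extract_trips(stops, fixes)
    codes = fixes["location_code"].to_numpy(object)

    expected = []
    for a, b in zip(stops, stops[1:]):
        if a.participant_id != b.participant_id:
            continue
        inter = codes[a.last_fix + 1 : b.first_fix]
        if a.location_code == b.location_code and not (inter != a.location_code).any():
            continue
        expected.append((a.participant_id, a.location_code, b.location_code, a.end, b.start))
    got = [(t.participant_id, t.origin, t.destination, t.depart, t.arrive) for t in trips]
    assert got == expected
    assert len(trips) > 50


def test_detected_stops_equal_generator_schedule(null_cohort):
    """On noiseless tracks every scheduled episode is recovered as exactly
    one stop with the right code, in order."""
    from tracklink.landuse import assign_locations

    fixes = assign_locations(
        null_cohort.fixes.reset_index(drop=True), null_cohort.world.landuse, null_cohort.world.places
    )
    stops = detect_stops(fixes)
    for pid, sched in null_cohort.schedules.items():
        want = [ep.code for day in sched.days for ep in day]
        got = [s.location_code for s in stops if s.participant_id == pid]
        assert got == want


def test_fewer_stops_when_dwell_threshold_grows():
    fixes = make_coded_fixes(
        [("A", 30), (ROAD, 5), ("D", 8), (ROAD, 5), ("B", 30)]
    )
    for small, large in [(60.0, 120.0), (120.0, 600.0)]:
        assert len(detect_stops(fixes, dwell_s=small)) >= len(
            detect_stops(fixes, dwell_s=large)
        )


def test_stop_and_trip_spans_tile_without_overlap():
    fixes = make_coded_fixes([("A", 20), (ROAD, 6), ("B", 20), (ROAD, 6), ("D", 20)])
    stops = detect_stops(fixes)
    trips = extract_trips(stops, fixes)
    claimed: set[int] = set()
    for s in stops:
        span = set(range(s.first_fix, s.last_fix + 1))
        assert not span & claimed
        claimed |= span
    for t in trips:
        lo, hi = t.fix_span
        span = set(range(lo, hi + 1))
        assert not span & claimed
        claimed |= span
    assert claimed == set(range(len(fixes)))


def test_trip_code_formatting_and_validation():
    assert trip_code("A", "B") == "Ab"
    assert trip_code("B", "D") == "Bd"
    with pytest.raises(ValueError):
        trip_code("A", "J")


def test_encode_and_split_round_trip():
    fixes = make_coded_fixes([("A", 20), (ROAD, 5), ("B", 20), (ROAD, 5), ("D", 20)])
    trips = extract_trips(detect_stops(fixes), fixes)
    code_string = encode_sequence(trips)
    assert code_string == "AbBd"
    assert split_codes(code_string) == [t.code for t in trips]
    assert encode_sequence([]) == ""


def test_trip_frame_round_trip():
    fixes = make_coded_fixes([("A", 20), (ROAD, 5), ("B", 20)])
    trips = extract_trips(detect_stops(fixes), fixes)
    trips[0].mode = "walk"
    again = frame_to_trips(trips_to_frame(trips))
    assert [t.code for t in again] == [t.code for t in trips]
    assert again[0].mode == "walk"
    assert again[0].fix_span == trips[0].fix_span


def test_midnight_spanning_trip_belongs_to_departure_date():
    late = make_coded_fixes([("A", 30), (ROAD, 360), ("B", 30)], start="2011-03-14 23:50:00")
    trips = extract_trips(detect_stops(late), late)
    assert trips[0].date == pd.Timestamp("2011-03-14").date()
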