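"""Stop detection and trip extraction from a coded fix stream.

A *stop* is a maximal run of consecutive fixes sharing one non-ROAD
location code whose span is at least the dwell time (120 s by default, at
the 10 s logging epoch that is 13 consecutive fixes).  Short signal
dropouts at the same location are bridged; a gap longer than the tolerance
closes the run.  A *trip* is the travel between two consecutive stops; it
is encoded as origin letter (uppercase) + destination letter (lowercase),
so Home→School is ``Ab`` and School→Shops is ``Bd``.  Trips whose
intermediate fixes are mostly off the street network are flagged
``off_road`` and left out of the daily alignment sequence, mirroring the
known blind spot of dwell-based trip detection for off-road travel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .landuse import CODE_CATEGORIES, ROAD

DEFAULT_DWELL_S = 120.0
DEFAULT_GAP_TOLERANCE_S = 300.0
DEFAULT_MIN_ON_ROAD_FRACTION = 0.5


def trip_code(origin: str, destination: str) -> str:
    """Two-letter trip code: uppercase origin + lowercase destination."""
    if origin not in CODE_CATEGORIES or destination not in CODE_CATEGORIES:
        raise ValueError(f"invalid trip endpoints {origin!r} -> {destination!r}")
    return origin.upper() + destination.lower()


@dataclass(frozen=True)
class Stop:
    participant_id: str
    location_code: str
    start: pd.Timestamp
    end: pd.Timestamp
    first_fix: int  # positional index into the fix stream
    last_fix: int

    @property
    def duration_s(self) -> float:
        return (self.end - self.start).total_seconds()


@dataclass
class Trip:
    participant_id: str
    date: object  # civil date of the departure instant
    origin: str
    destination: str
    depart: pd.Timestamp
    arrive: pd.Timestamp
    fix_span: tuple[int, int] | None  # inclusive positional range of intermediate fixes
    on_road_fraction: float
    off_road: bool
    mode: str | None = None
    accompaniment: str | None = None

    @property
    def code(self) -> str:
        return trip_code(self.origin, self.destination)


@dataclass
class TripSequence:
    participant_id: str
    date: object
    trips: list[Trip] = field(default_factory=list)

    @property
    def code_string(self) -> str:
        return encode_sequence(self.trips)

    def __len__(self) -> int:
        return len(self.trips)


def encode_sequence(trips: Iterable[Trip] | TripSequence) -> str:
    """Concatenate two-letter trip codes in trip order."""
    if isinstance(trips, TripSequence):
        trips = trips.trips
    return "".join(t.code for t in trips)


def split_codes(code_string: str) -> list[str]:
    """Split a concatenated code string back into two-letter trip codes."""
    if len(code_string) % 2:
        raise ValueError("trip code strings have even length")
    return [code_string[i : i + 2] for i in range(0, len(code_string), 2)]


def detect_stops(
    fixes: pd.DataFrame,
    dwell_s: float = DEFAULT_DWELL_S,
    gap_tolerance_s: float = DEFAULT_GAP_TOLERANCE_S,
) -> list[Stop]:
    """Find dwell-time stops in a coded, time-ordered fix stream.

    Runs of equal codes broken by a time gap larger than
    ``gap_tolerance_s`` are split; runs at ROAD never form stops; runs
    shorter than ``dwell_s`` are treated as travel.
    """
    if len(fixes) == 0:
        return []
    if "location_code" not in fixes.columns:
        raise ValueError("fixes must be location-coded before stop detection")
    pid = fixes["participant_id"].astype(str)
    code = fixes["location_code"]
    ts = fixes["timestamp"]
    dt = ts.diff().dt.total_seconds()
    new_run = (
        pid.ne(pid.shift())
        | code.ne(code.shift())
        | (dt > gap_tolerance_s)
    )
    run_id = new_run.cumsum()
    pos = np.arange(len(fixes))
    stops: list[Stop] = []
    grouped = pd.DataFrame(
        {"pid": pid.to_numpy(), "code": code.to_numpy(), "ts": ts.to_numpy(), "pos": pos}
    ).groupby(run_id.to_numpy(), sort=True)
    for _, grp in grouped:
        c = grp["code"].iloc[0]
        if c == ROAD or c is None or (isinstance(c, float) and np.isnan(c)):
            continue
        start, end = grp["ts"].iloc[0], grp["ts"].iloc[-1]
        if (end - start) / np.timedelta64(1, "s") >= dwell_s:
            stops.append(
                Stop(
                    participant_id=str(grp["pid"].iloc[0]),
                    location_code=str(c),
                    start=pd.Timestamp(start),
                    end=pd.Timestamp(end),
                    first_fix=int(grp["pos"].iloc[0]),
                    last_fix=int(grp["pos"].iloc[-1]),
                )
            )
    stops.sort(key=lambda s: (s.participant_id, s.start))
    return stops


def extract_trips(
    stops: Sequence[Stop],
    fixes: pd.DataFrame,
    min_on_road_fraction: float = DEFAULT_MIN_ON_ROAD_FRACTION,
    include_same_location: bool = True,
) -> list[Trip]:
    """Build trips from consecutive stop pairs of each participant.

    The trip departs when the earlier stop ends and arrives when the later
    stop starts; its intermediate fixes are everything logged in between.
    A pair of stops at the *same* location yields a trip only when at least
    one intermediate fix left that location's polygon (and only when
    ``include_same_location``); these carry codes like ``Aa``.
    """
    codes = fixes["location_code"].to_numpy(object) if len(fixes) else np.array([], object)
    trips: list[Trip] = []
    for prev, nxt in zip(stops, stops[1:]):
        if prev.participant_id != nxt.participant_id:
            continue
        lo, hi = prev.last_fix + 1, nxt.first_fix - 1
        inter = codes[lo : hi + 1]
        if prev.location_code == nxt.location_code:
            if not include_same_location:
                continue
            if not np.any(inter != prev.location_code):
                continue  # never left the polygon: not a movement episode
        frac = float(np.mean(inter == ROAD)) if len(inter) else 0.0
        trips.append(
            Trip(
                participant_id=prev.participant_id,
                date=prev.end.date(),
                origin=prev.location_code,
                destination=nxt.location_code,
                depart=prev.end,
                arrive=nxt.start,
                fix_span=(lo, hi) if hi >= lo else None,
                on_road_fraction=frac,
                off_road=frac < min_on_road_fraction,
            )
        )
    return trips


def build_sequences(
    trips: Iterable[Trip], include_off_road: bool = False
) -> list[TripSequence]:
    """Group trips into per-participant-day sequences, time-ordered.

    Off-road-flagged trips are excluded from sequences unless requested; a
    trip belongs to the civil date of its departure.
    """
    buckets: dict[tuple[str, object], list[Trip]] = {}
    for t in trips:
        if t.off_road and not include_off_road:
            continue
        buckets.setdefault((t.participant_id, t.date), []).append(t)
    seqs = [
        TripSequence(pid, date, sorted(ts, key=lambda t: t.depart))
        for (pid, date), ts in buckets.items()
    ]
    seqs.sort(key=lambda s: (s.participant_id, str(s.date)))
    return seqs


def trips_to_frame(trips: Iterable[Trip]) -> pd.DataFrame:
    """Tabulate trips for CSV output."""
    rows = []
    for t in trips:
        rows.append(
            {
                "participant_id": t.participant_id,
                "date": str(t.date),
                "origin": t.origin,
                "destination": t.destination,
                "code": t.code,
                "depart": t.depart.isoformat(),
                "arrive": t.arrive.isoformat(),
                "fix_first": t.fix_span[0] if t.fix_span else -1,
                "fix_last": t.fix_span[1] if t.fix_span else -1,
                "on_road_fraction": round(t.on_road_fraction, 4),
                "off_road": int(t.off_road),
                "mode": t.mode or "",
                "accompaniment": t.accompaniment or "",
            }
        )
    cols = [
        "participant_id", "date", "origin", "destination", "code", "depart",
        "arrive", "fix_first", "fix_last", "on_road_fraction", "off_road",
        "mode", "accompaniment",
    ]
    return pd.DataFrame(rows, columns=cols)


def frame_to_trips(df: pd.DataFrame) -> list[Trip]:
    trips = []
    for row in df.itertuples(index=False):
        span = None
        if int(row.fix_first) >= 0:
            span = (int(row.fix_first), int(row.fix_last))
        trips.append(
            Trip(
                participant_id=str(row.participant_id),
                date=pd.Timestamp(row.date).date(),
                origin=row.origin,
                destination=row.destination,
                depart=pd.Timestamp(row.depart),
                arrive=pd.Timestamp(row.arrive),
                fix_span=span,
                on_road_fraction=float(row.on_road_fraction),
                off_road=bool(row.off_road),
                mode=(row.mode or None) if isinstance(row.mode, str) else None,
                accompaniment=(row.accompaniment or None)
                if isinstance(row.accompaniment, str)
                else None,
            )
        )
    return trips


def sequences_to_frame(seqs: Iterable[TripSequence]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "participant_id": s.participant_id,
                "date": str(s.date),
                "code_string": s.code_string,
                "n_trips": len(s),
            }
            for s in seqs
        ],
        columns=["participant_id", "date", "code_string", "n_trips"],
    )
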