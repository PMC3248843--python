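"""Ground-truthed synthetic cohorts: maps, schedules, GPS tracks, diaries.

The generator emulates the structure of a child-mobility GPS study: a
small urban neighbourhood laid out as a planar grid of land-parcel blocks
separated by road corridors; children who spend weekdays at home and
school with optional after-school stops and weekends on home-based
outings; GPS units logging every 10 s with positional jitter, occasional
dropouts and occasional quality artifacts; and travel diaries that are
degraded copies of the true trip list (omitted trips, two-link chains
collapsed into one reported trip, blanked fields, researcher-entered
rows, jittered clock times).  Every injected defect is recorded in a
truth ledger so downstream stages can be checked against ground truth.

Coordinates are metres in a local planar frame.  All randomness flows
from one integer seed; per-child substreams are derived deterministically
from it, so a cohort is byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from shapely.geometry import box

from .landuse import LandUseMap, ParticipantPlaces

DEFAULT_EPOCH_S = 10.0
DAY_WINDOW = ("07:00:00", "19:00:00")  # monitored hours per day

#: Movement speeds, m/s.
MODE_SPEED = {"walk": 1.3, "bike": 3.5, "car": 9.0}

#: Diary text by code, invertible through the default diary lexicon.
CODE_TEXT = {
    "A": "Home",
    "B": "School",
    "C": "Friends",
    "D": "Shops",
    "E": "Park",
    "F": "Sports",
    "G": "Church",
    "H": "Medical",
    "I": "Other school",
    "K": "Other",
}

ACCOMPANIMENT_CHOICES = ("parent", "friend", "sibling", "none")
ACCOMPANIMENT_P = (0.45, 0.2, 0.1, 0.25)


@dataclass(frozen=True)
class DegradationProfile:
    """Independent per-trip defect rates applied to a true diary."""

    p_omit_trip: float = 0.0
    p_collapse_chain: float = 0.0
    p_missing_field: float = 0.0
    p_researcher_flag: float = 0.0
    time_jitter_sd_min: float = 0.0

    def __post_init__(self) -> None:
        for name in ("p_omit_trip", "p_collapse_chain", "p_missing_field", "p_researcher_flag"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability, got {p}")


#: Null degradation: the diary is a verbatim copy of the true trips.
NULL_PROFILE = DegradationProfile()

#: Realistic defect rates for the sloppier and tidier halves of a cohort.
LOWER_QUALITY_PROFILE = DegradationProfile(
    p_omit_trip=0.30,
    p_collapse_chain=0.18,
    p_missing_field=0.18,
    p_researcher_flag=0.10,
    time_jitter_sd_min=12.0,
)
HIGHER_QUALITY_PROFILE = DegradationProfile(
    p_omit_trip=0.06,
    p_collapse_chain=0.10,
    p_missing_field=0.02,
    p_researcher_flag=0.005,
    time_jitter_sd_min=6.0,
)


@dataclass
class Episode:
    """One dwell at a known location."""

    loc_key: str  # e.g. "home", "school", "shops", "friend:3:5"
    code: str
    cell: tuple[int, int]  # grid cell (row, col) of the block
    arrive: pd.Timestamp
    depart: pd.Timestamp


@dataclass
class TravelLeg:
    depart: pd.Timestamp
    arrive: pd.Timestamp
    polyline: np.ndarray  # (k, 2) waypoints, metres
    mode: str
    off_road: bool


@dataclass
class ActivitySchedule:
    participant_id: str
    days: list[list[Episode]]
    legs: list[list[TravelLeg]]  # legs[d][i] runs from episode i to i+1 of day d


@dataclass
class SyntheticWorld:
    """A grid neighbourhood plus per-participant home/school parcels."""

    landuse: LandUseMap
    categories: list[str]  # map-file category text per feature
    places: dict[str, ParticipantPlaces]
    grid: "GridGeometry"
    home_cell: dict[str, tuple[int, int]]
    school_cell: dict[str, tuple[int, int]]
    special_cells: dict[str, tuple[int, int]]  # loc_key -> block cell
    residential_cells: list[tuple[int, int]]


@dataclass
class GridGeometry:
    """Alternating block/road lattice: cell (r, c) is a block iff both
    r and c are even; odd rows/columns are continuous road corridors."""

    n_rows: int
    n_cols: int
    block_m: float = 80.0
    road_m: float = 20.0

    def _edges(self, n: int) -> np.ndarray:
        widths = [self.block_m if i % 2 == 0 else self.road_m for i in range(n)]
        return np.concatenate([[0.0], np.cumsum(widths)])

    @property
    def x_edges(self) -> np.ndarray:
        return self._edges(self.n_cols)

    @property
    def y_edges(self) -> np.ndarray:
        return self._edges(self.n_rows)

    def cell_box(self, r: int, c: int):
        xe, ye = self.x_edges, self.y_edges
        return box(xe[c], ye[r], xe[c + 1], ye[r + 1])

    def cell_center(self, r: int, c: int) -> tuple[float, float]:
        xe, ye = self.x_edges, self.y_edges
        return (0.5 * (xe[c] + xe[c + 1]), 0.5 * (ye[r] + ye[r + 1]))

    def is_block(self, r: int, c: int) -> bool:
        return r % 2 == 0 and c % 2 == 0

    def block_cells(self) -> list[tuple[int, int]]:
        return [
            (r, c)
            for r in range(0, self.n_rows, 2)
            for c in range(0, self.n_cols, 2)
        ]

    def road_route(self, a: tuple[int, int], b: tuple[int, int]) -> np.ndarray:
        """Waypoints from block a's centre to block b's centre that stay on
        road corridors except inside the two endpoint blocks."""
        (r1, c1), (r2, c2) = a, b
        x1, y1 = self.cell_center(r1, c1)
        x2, y2 = self.cell_center(r2, c2)

        def road_col(c_from: int, c_to: int) -> int:
            if c_to > c_from:
                return c_from + 1
            if c_to < c_from:
                return c_from - 1
            return c_from + 1 if c_from + 1 < self.n_cols else c_from - 1

        def road_row(r_from: int, r_to: int) -> int:
            if r_to > r_from:
                return r_from + 1
            if r_to < r_from:
                return r_from - 1
            return r_from + 1 if r_from + 1 < self.n_rows else r_from - 1

        vx1 = self.cell_center(r1, road_col(c1, c2))[0]
        vx2 = self.cell_center(r2, road_col(c2, c1))[0]
        hy = self.cell_center(road_row(r2, r1), c2)[1]
        pts = [(x1, y1), (vx1, y1), (vx1, hy), (vx2, hy), (vx2, y2), (x2, y2)]
        out = [pts[0]]
        for p in pts[1:]:
            if p != out[-1]:
                out.append(p)
        return np.asarray(out, dtype=float)

    def straight_route(self, a: tuple[int, int], b: tuple[int, int]) -> np.ndarray:
        return np.asarray([self.cell_center(*a), self.cell_center(*b)], dtype=float)


def _polyline_length(poly: np.ndarray) -> float:
    return float(np.hypot(*np.diff(poly, axis=0).T).sum())


SPECIAL_CATEGORIES = [
    ("shops", "Shops", "D"),
    ("park", "Parks", "E"),
    ("sports", "Sports facilities", "F"),
    ("church", "Church", "G"),
    ("medical", "Medical", "H"),
    ("other_school", "Schools", "I"),
    ("other", "Other", "K"),
]


def make_map(
    participant_ids: Sequence[str],
    seed: int = 0,
    block_m: float = 80.0,
    road_m: float = 20.0,
    n_schools: int = 2,
) -> SyntheticWorld:
    """Build a grid neighbourhood big enough for the cohort.

    Every child gets their own home block (base category residential);
    children are split evenly between ``n_schools`` school blocks; one
    block each is reserved for shops, park, sports, church, medical, a
    school nobody attends, and an 'other' parcel; the rest stay plain
    residential.  Deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    pids = [str(p) for p in participant_ids]
    need = len(pids) + n_schools + len(SPECIAL_CATEGORIES) + 2
    k = int(np.ceil(np.sqrt(need)))
    grid = GridGeometry(2 * k - 1, 2 * k - 1, block_m=block_m, road_m=road_m)

    blocks = grid.block_cells()
    order = rng.permutation(len(blocks))
    blocks = [blocks[i] for i in order]

    school_cells = [blocks.pop() for _ in range(n_schools)]
    special_cells: dict[str, tuple[int, int]] = {}
    for key, _, _ in SPECIAL_CATEGORIES:
        special_cells[key] = blocks.pop()
    home_cell = {pid: blocks.pop() for pid in pids}
    residential_cells = list(blocks) + list(home_cell.values())

    geoms, categories = [], []
    for r in range(grid.n_rows):
        for c in range(grid.n_cols):
            geoms.append(grid.cell_box(r, c))
            if not grid.is_block(r, c):
                categories.append("roads")
            elif (r, c) in school_cells:
                categories.append("schools")
            else:
                for key, cat, _ in SPECIAL_CATEGORIES:
                    if special_cells[key] == (r, c):
                        categories.append(cat)
                        break
                else:
                    categories.append("residential")

    from .landuse import category_to_code

    codes = [category_to_code(cat) for cat in categories]
    landuse = LandUseMap(geoms, codes, crs="local-metric")

    places: dict[str, ParticipantPlaces] = {}
    school_cell_by_pid: dict[str, tuple[int, int]] = {}
    for i, pid in enumerate(pids):
        sc = school_cells[i * n_schools // max(len(pids), 1)]
        school_cell_by_pid[pid] = sc
        places[pid] = ParticipantPlaces(
            pid,
            home_polygon=grid.cell_box(*home_cell[pid]),
            school_polygon=grid.cell_box(*sc),
        )
    return SyntheticWorld(
        landuse=landuse,
        categories=categories,
        places=places,
        grid=grid,
        home_cell=home_cell,
        school_cell=school_cell_by_pid,
        special_cells=special_cells,
        residential_cells=residential_cells,
    )


_DEST_KEYS = ("shops", "park", "friend", "sports", "other_school", "church", "medical", "other")
_DEST_P = (0.24, 0.22, 0.22, 0.10, 0.06, 0.06, 0.05, 0.05)


def _dest_cell(world: SyntheticWorld, pid: str, key: str, rng, exclude) -> tuple[str, str, tuple[int, int]]:
    """Resolve a destination key to (loc_key, code, block cell)."""
    if key == "friend":
        pool = [c for c in world.residential_cells if c != world.home_cell[pid] and c != exclude]
        cell = pool[rng.integers(len(pool))]
        return f"friend:{cell[0]}:{cell[1]}", "C", cell
    cell = world.special_cells[key]
    code = dict((k, code) for k, _, code in SPECIAL_CATEGORIES)[key]
    return key, code, cell


def make_schedule(
    world: SyntheticWorld,
    pid: str,
    days: int,
    start_date: str,
    rng: np.random.Generator,
    p_offroad: float = 0.08,
) -> ActivitySchedule:
    """A week of plausible child activity: school on weekdays, home-based
    outings at weekends, every dwell at least several minutes long."""
    day0 = pd.Timestamp(start_date)
    all_eps: list[list[Episode]] = []
    all_legs: list[list[TravelLeg]] = []
    for d in range(days):
        date = day0 + pd.Timedelta(days=d)
        win_start = pd.Timestamp(f"{date.date()} {DAY_WINDOW[0]}")
        win_end = pd.Timestamp(f"{date.date()} {DAY_WINDOW[1]}")
        home = ("home", "A", world.home_cell[pid])
        if date.dayofweek < 5:
            stops = [home, ("school", "B", world.school_cell[pid])]
            n_extra = rng.choice([0, 1, 2, 3], p=[0.15, 0.30, 0.30, 0.25])
            prev_cell = stops[-1][2]
            for _ in range(n_extra):
                key = rng.choice(_DEST_KEYS, p=_DEST_P)
                loc = _dest_cell(world, pid, key, rng, exclude=prev_cell)
                if loc[2] == prev_cell:
                    continue
                stops.append(loc)
                prev_cell = loc[2]
            stops.append(home)
            depart_first = win_start + pd.Timedelta(minutes=float(rng.uniform(40, 80)))
            dwells = [float(rng.uniform(15, 60)) for _ in range(len(stops) - 2)]
            dwells[0] = float(rng.uniform(390, 420))  # the school day
        else:
            stops = [home]
            prev_cell = home[2]
            n_outings = rng.choice([0, 1, 2, 3], p=[0.10, 0.35, 0.35, 0.20])
            for _ in range(n_outings):
                key = rng.choice(_DEST_KEYS, p=_DEST_P)
                loc = _dest_cell(world, pid, key, rng, exclude=prev_cell)
                if loc[2] != prev_cell:
                    stops.append(loc)
                    prev_cell = loc[2]
                if rng.uniform() < 0.45:  # chain a second stop before returning
                    key2 = rng.choice(_DEST_KEYS, p=_DEST_P)
                    loc2 = _dest_cell(world, pid, key2, rng, exclude=prev_cell)
                    if loc2[2] != prev_cell:
                        stops.append(loc2)
                        prev_cell = loc2[2]
                stops.append(home)
                prev_cell = home[2]
            depart_first = win_start + pd.Timedelta(minutes=float(rng.uniform(90, 180)))
            dwells = [float(rng.uniform(20, 75)) for _ in range(len(stops) - 2)]

        episodes: list[Episode] = []
        legs: list[TravelLeg] = []
        t = win_start
        episodes.append(Episode("home", "A", home[2], win_start, depart_first))
        t = depart_first
        for i, (loc_key, code, cell) in enumerate(stops[1:]):
            prev = episodes[-1]
            off_road = rng.uniform() < p_offroad
            mode = "walk" if off_road else rng.choice(["walk", "car", "bike"], p=[0.5, 0.35, 0.15])
            poly = (
                world.grid.straight_route(prev.cell, cell)
                if off_road
                else world.grid.road_route(prev.cell, cell)
            )
            duration = max(_polyline_length(poly) / MODE_SPEED[mode], 30.0)
            arrive = t + pd.Timedelta(seconds=duration)
            is_last = i == len(stops) - 2
            depart = (
                win_end
                if is_last
                else arrive + pd.Timedelta(minutes=dwells[i])
            )
            if not is_last and depart > win_end - pd.Timedelta(minutes=25):
                # Day is full: cut remaining stops, stay here then end at home.
                if code == "A":
                    episodes.append(Episode(loc_key, code, cell, arrive, win_end))
                    legs.append(TravelLeg(t, arrive, poly, mode, off_road))
                    break
                depart = win_end - pd.Timedelta(minutes=15)
                episodes.append(Episode(loc_key, code, cell, arrive, depart))
                legs.append(TravelLeg(t, arrive, poly, mode, off_road))
                back = world.grid.road_route(cell, home[2])
                bmode = "car"
                bdur = max(_polyline_length(back) / MODE_SPEED[bmode], 30.0)
                barrive = depart + pd.Timedelta(seconds=bdur)
                legs.append(TravelLeg(depart, barrive, back, bmode, False))
                episodes.append(Episode("home", "A", home[2], barrive, win_end))
                break
            episodes.append(Episode(loc_key, code, cell, arrive, depart))
            legs.append(TravelLeg(t, arrive, poly, mode, off_road))
            t = depart
        all_eps.append(episodes)
        all_legs.append(legs)
    return ActivitySchedule(pid, all_eps, all_legs)


def true_trips_frame(
    schedule: ActivitySchedule, rng: np.random.Generator
) -> pd.DataFrame:
    """The ground-truth trip list implied by a schedule, with modes and
    accompaniment drawn once per trip."""
    rows = []
    for day_eps, day_legs in zip(schedule.days, schedule.legs):
        for i, leg in enumerate(day_legs):
            o, dst = day_eps[i], day_eps[i + 1]
            acc = rng.choice(ACCOMPANIMENT_CHOICES, p=ACCOMPANIMENT_P)
            rows.append(
                {
                    "participant_id": schedule.participant_id,
                    "date": str(leg.depart.date()),
                    "seq_index": i + 1,
                    "depart": leg.depart.isoformat(),
                    "origin_code": o.code,
                    "destination_code": dst.code,
                    "mode": leg.mode,
                    "accompaniment": str(acc),
                    "off_road": int(leg.off_road),
                }
            )
    cols = [
        "participant_id", "date", "seq_index", "depart", "origin_code",
        "destination_code", "mode", "accompaniment", "off_road",
    ]
    return pd.DataFrame(rows, columns=cols)


def simulate_track(
    schedule: ActivitySchedule,
    world: SyntheticWorld,
    rng: np.random.Generator,
    epoch_s: float = DEFAULT_EPOCH_S,
    noise_sd_m: float = 3.0,
    dropout: float = 0.01,
    artifact_rate: float = 0.01,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fixes every ``epoch_s`` seconds over the monitored window.

    During an episode the position is the block centre plus Gaussian
    jitter; during travel it moves along the leg's polyline at the leg's
    speed.  Speed/HDOP/satellite fields are populated with clean values;
    a fraction ``artifact_rate`` of fixes get exactly one injected
    threshold violation (speed > 160 km/h, HDOP > 5, or < 4 satellites).
    Returns (fixes, artifact ledger with the violated filter per row).
    """
    frames = []
    for day_eps, day_legs in zip(schedule.days, schedule.legs):
        win_start = day_eps[0].arrive
        win_end = day_eps[-1].depart
        n = int(np.floor((win_end - win_start).total_seconds() / epoch_s)) + 1
        times = win_start + pd.to_timedelta(np.arange(n) * epoch_s, unit="s")
        tsec = np.arange(n) * epoch_s
        x = np.empty(n)
        y = np.empty(n)
        spd = np.zeros(n)

        def sec(ts) -> float:
            return (ts - win_start).total_seconds()

        for ep in day_eps:
            lo = int(np.ceil(sec(ep.arrive) / epoch_s))
            hi = int(np.floor(sec(ep.depart) / epoch_s))
            cx, cy = world.grid.cell_center(*ep.cell)
            x[lo : hi + 1] = cx
            y[lo : hi + 1] = cy
            spd[lo : hi + 1] = 0.0
        for leg in day_legs:
            lo = int(np.floor(sec(leg.depart) / epoch_s)) + 1
            hi = int(np.ceil(sec(leg.arrive) / epoch_s)) - 1
            if hi < lo:
                continue
            total = _polyline_length(leg.polyline)
            speed = total / max((leg.arrive - leg.depart).total_seconds(), 1e-9)
            dist = (tsec[lo : hi + 1] - sec(leg.depart)) * speed
            seg = np.hypot(*np.diff(leg.polyline, axis=0).T)
            cum = np.concatenate([[0.0], np.cumsum(seg)])
            x[lo : hi + 1] = np.interp(dist, cum, leg.polyline[:, 0])
            y[lo : hi + 1] = np.interp(dist, cum, leg.polyline[:, 1])
            spd[lo : hi + 1] = speed * 3.6

        if noise_sd_m > 0:
            x = x + rng.normal(0, noise_sd_m, n)
            y = y + rng.normal(0, noise_sd_m, n)
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": schedule.participant_id,
                    "timestamp": times,
                    "lat": y,
                    "lon": x,
                    "speed": np.round(spd + np.abs(rng.normal(0, 0.3, n)), 2),
                    "hdop": np.round(np.clip(rng.lognormal(0.1, 0.3, n), 0.5, 4.5), 2),
                    "nsat": rng.integers(5, 13, n),
                }
            )
        )
    fixes = pd.concat(frames, ignore_index=True)

    if dropout > 0:
        fixes = fixes.loc[rng.uniform(size=len(fixes)) >= dropout].reset_index(drop=True)

    artifact_rows = []
    if artifact_rate > 0:
        hit = np.flatnonzero(rng.uniform(size=len(fixes)) < artifact_rate)
        kinds = rng.integers(0, 3, len(hit))
        for idx, kind in zip(hit, kinds):
            if kind == 0:
                fixes.loc[idx, "speed"] = round(float(rng.uniform(170, 500)), 2)
                reason = "speed"
            elif kind == 1:
                fixes.loc[idx, "hdop"] = round(float(rng.uniform(5.5, 20)), 2)
                reason = "hdop"
            else:
                fixes.loc[idx, "nsat"] = int(rng.integers(0, 4))
                reason = "satellites"
            artifact_rows.append(
                {
                    "participant_id": schedule.participant_id,
                    "timestamp": fixes.loc[idx, "timestamp"].isoformat(),
                    "violation": reason,
                }
            )
    ledger = pd.DataFrame(artifact_rows, columns=["participant_id", "timestamp", "violation"])
    return fixes, ledger


def degrade_diary(
    true_trips: pd.DataFrame,
    profile: DegradationProfile,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Produce diary rows from true trips, injecting recorded defects.

    Defect order per day: two-link chain collapses (non-overlapping, left
    to right), then omissions, then field blanking, researcher flags and
    clock-time jitter.  Returns (diary rows in the raw diary CSV schema,
    defect ledger with one row per injected defect).
    """
    out_rows = []
    defects = []
    for (pid, date), grp in true_trips.groupby(["participant_id", "date"], sort=True):
        trips = grp.sort_values("seq_index").to_dict("records")
        merged = []
        i = 0
        while i < len(trips):
            t = trips[i]
            if (
                i + 1 < len(trips)
                and t["destination_code"] == trips[i + 1]["origin_code"]
                and rng.uniform() < profile.p_collapse_chain
            ):
                nxt = trips[i + 1]
                merged.append(
                    {
                        **t,
                        "destination_code": nxt["destination_code"],
                        "collapsed": True,
                    }
                )
                defects.append(
                    {
                        "participant_id": pid,
                        "date": date,
                        "type": "chain_collapse",
                        "detail": f"{t['origin_code']}{t['destination_code'].lower()}"
                        f"+{nxt['origin_code']}{nxt['destination_code'].lower()}"
                        f"->{t['origin_code']}{nxt['destination_code'].lower()}",
                    }
                )
                i += 2
            else:
                merged.append({**t, "collapsed": False})
                i += 1

        kept = []
        for t in merged:
            if rng.uniform() < profile.p_omit_trip:
                defects.append(
                    {
                        "participant_id": pid,
                        "date": date,
                        "type": "omission",
                        "detail": f"{t['origin_code']}{t['destination_code'].lower()}",
                    }
                )
            else:
                kept.append(t)

        for k, t in enumerate(kept, start=1):
            mode, acc = t["mode"], t["accompaniment"]
            if rng.uniform() < profile.p_missing_field:
                if rng.uniform() < 0.5:
                    mode = ""
                else:
                    acc = ""
                defects.append(
                    {"participant_id": pid, "date": date, "type": "missing_field", "detail": ""}
                )
            researcher = 0
            if rng.uniform() < profile.p_researcher_flag:
                researcher = 1
                defects.append(
                    {"participant_id": pid, "date": date, "type": "researcher_flag", "detail": ""}
                )
            reported = pd.Timestamp(t["depart"])
            if profile.time_jitter_sd_min > 0:
                reported += pd.Timedelta(
                    minutes=float(rng.normal(0, profile.time_jitter_sd_min))
                )
            out_rows.append(
                {
                    "participant_id": pid,
                    "date": date,
                    "seq_index": k,
                    "time": reported.strftime("%H:%M"),
                    "origin": CODE_TEXT[t["origin_code"]],
                    "destination": CODE_TEXT[t["destination_code"]],
                    "mode": mode,
                    "accompaniment": acc,
                    "researcher_entered": researcher,
                    "collapsed": int(t["collapsed"]),
                }
            )
    cols = [
        "participant_id", "date", "seq_index", "time", "origin", "destination",
        "mode", "accompaniment", "researcher_entered", "collapsed",
    ]
    diary = pd.DataFrame(out_rows, columns=cols)
    ledger = pd.DataFrame(defects, columns=["participant_id", "date", "type", "detail"])
    return diary, ledger


@dataclass
class Cohort:
    """Everything a pipeline run needs, plus ground truth."""

    world: SyntheticWorld
    schedules: dict[str, ActivitySchedule]
    fixes: pd.DataFrame
    true_trips: pd.DataFrame
    diary: pd.DataFrame
    artifact_ledger: pd.DataFrame
    defect_ledger: pd.DataFrame
    arm: dict[str, str]  # participant -> "lower" | "higher"


def simulate_cohort(
    n_children: int = 40,
    days: int = 7,
    seed: int = 7,
    lower_profile: DegradationProfile = LOWER_QUALITY_PROFILE,
    higher_profile: DegradationProfile = HIGHER_QUALITY_PROFILE,
    p_offroad: float = 0.08,
    noise_sd_m: float = 3.0,
    dropout: float = 0.01,
    artifact_rate: float = 0.01,
    epoch_s: float = DEFAULT_EPOCH_S,
    start_date: str = "2011-03-14",
) -> Cohort:
    """Simulate a two-arm cohort (default 40 children x 7 days).

    The first half of the cohort attends school A and keeps sloppier
    diaries (``lower_profile``); the second half attends school B with
    tidier diaries.  One seed reproduces the whole cohort byte-for-byte.
    """
    pids = [f"c{i + 1:02d}" for i in range(n_children)]
    world = make_map(pids, seed=seed)
    arm = {
        pid: ("lower" if i < n_children // 2 else "higher") for i, pid in enumerate(pids)
    }
    schedules: dict[str, ActivitySchedule] = {}
    fix_frames, truth_frames, diary_frames = [], [], []
    artifact_frames, defect_frames = [], []
    for i, pid in enumerate(pids):
        rng = np.random.default_rng([seed % (2**31), i])
        sched = make_schedule(world, pid, days, start_date, rng, p_offroad=p_offroad)
        schedules[pid] = sched
        truth = true_trips_frame(sched, rng)
        fixes, artifacts = simulate_track(
            sched, world, rng,
            epoch_s=epoch_s, noise_sd_m=noise_sd_m,
            dropout=dropout, artifact_rate=artifact_rate,
        )
        profile = lower_profile if arm[pid] == "lower" else higher_profile
        diary, defects = degrade_diary(truth, profile, rng)
        fix_frames.append(fixes)
        truth_frames.append(truth)
        diary_frames.append(diary)
        artifact_frames.append(artifacts)
        defect_frames.append(defects)
    return Cohort(
        world=world,
        schedules=schedules,
        fixes=pd.concat(fix_frames, ignore_index=True),
        true_trips=pd.concat(truth_frames, ignore_index=True),
        diary=pd.concat(diary_frames, ignore_index=True),
        artifact_ledger=pd.concat(artifact_frames, ignore_index=True),
        defect_ledger=pd.concat(defect_frames, ignore_index=True),
        arm=arm,
    )


def write_cohort(cohort: Cohort, outdir) -> dict:
    """Write a cohort to plain-text files; returns the path map."""
    import json
    import os

    from .gps import write_gps_log
    from .landuse import save_landuse, save_places

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "landuse": os.path.join(outdir, "map.geojson"),
        "places": os.path.join(outdir, "places.geojson"),
        "fixes": os.path.join(outdir, "fixes.csv"),
        "diary": os.path.join(outdir, "diary.csv"),
        "true_trips": os.path.join(outdir, "true_trips.csv"),
        "truth": os.path.join(outdir, "truth.json"),
    }
    save_landuse(cohort.world.landuse, paths["landuse"], categories=cohort.world.categories)
    save_places(cohort.world.places, paths["places"])
    write_gps_log(cohort.fixes, paths["fixes"])
    cohort.diary.drop(columns=["collapsed"]).to_csv(paths["diary"], index=False)
    cohort.true_trips.to_csv(paths["true_trips"], index=False)
    truth = {
        "arm": cohort.arm,
        "artifacts": cohort.artifact_ledger.to_dict("records"),
        "defects": cohort.defect_ledger.to_dict("records"),
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh)
    return paths
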