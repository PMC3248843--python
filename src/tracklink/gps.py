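"""GPS fix ingest, quality filtering, and speed derivation.

A fix stream is a pandas DataFrame with columns ``participant_id``,
``timestamp`` (datetime64, local civil time), ``lon``, ``lat`` (WGS84
degrees, or metres east/north when the stream is planar), and optional
quality columns ``speed`` (km/h), ``hdop`` and ``nsat``.

Cleaning removes fixes with speed above 160 km/h, horizontal dilution of
precision (HDOP) above 5, or fewer than 4 visible satellites.  The
comparisons are strict, so a fix sitting exactly on a threshold survives,
and by default a fix missing a quality field is retained by that filter —
filters only act on positive evidence of a bad fix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical fix-stream columns; the last four are optional.
FIX_COLUMNS = (
    "participant_id",
    "timestamp",
    "lat",
    "lon",
    "speed",
    "hdop",
    "nsat",
    "location_code",
)

_MANDATORY = ("timestamp", "lat", "lon")

EARTH_RADIUS_M = 6_371_008.8


@dataclass(frozen=True)
class CleaningThresholds:
    """Removal thresholds for the three GPS quality filters."""

    max_speed_kmh: float = 160.0
    max_hdop: float = 5.0
    min_satellites: int = 4

    def __post_init__(self) -> None:
        if min(self.max_speed_kmh, self.max_hdop, self.min_satellites) <= 0:
            raise ValueError("cleaning thresholds must be strictly positive")


@dataclass
class ReadReport:
    """Fix stream plus ingest bookkeeping."""

    fixes: pd.DataFrame
    n_rows: int = 0
    n_malformed: int = 0
    n_duplicates: int = 0


@dataclass
class CleaningResult:
    """Surviving fixes, removed fixes with reasons, per-filter counts."""

    fixes: pd.DataFrame
    removed: pd.DataFrame
    counts: dict = field(default_factory=dict)


def _empty_fixes() -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "participant_id": pd.Series(dtype=str),
            "timestamp": pd.Series(dtype="datetime64[ns]"),
            "lat": pd.Series(dtype=float),
            "lon": pd.Series(dtype=float),
            "speed": pd.Series(dtype=float),
            "hdop": pd.Series(dtype=float),
            "nsat": pd.Series(dtype=float),
        }
    )
    return df


def read_gps_log(
    path,
    column_map: Mapping[str, str] | None = None,
    timestamp_format: str | None = None,
    planar: bool = False,
) -> ReadReport:
    """Read a delimited GPS log into a canonical, ordered fix stream.

    ``column_map`` maps canonical names (see :data:`FIX_COLUMNS`) to the
    file's column headers; omitted entries default to the canonical name.
    Rows with an unparseable timestamp or out-of-range coordinates are
    dropped and counted; duplicate (participant, timestamp) records keep
    the first occurrence.  With ``planar`` the coordinates are metres in
    a local frame and the degree range check is skipped.
    """
    cmap = dict(column_map or {})
    try:
        raw = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return ReadReport(_empty_fixes())
    for canon in _MANDATORY:
        col = cmap.get(canon, canon)
        if col not in raw.columns:
            raise ValueError(f"mandatory column {canon!r} (file column {col!r}) not found")

    df = pd.DataFrame(index=raw.index)
    for canon in FIX_COLUMNS:
        col = cmap.get(canon, canon)
        if col in raw.columns:
            df[canon] = raw[col]
    if "participant_id" not in df.columns:
        df["participant_id"] = "0"
    df["participant_id"] = df["participant_id"].astype(str)

    n_rows = len(df)
    ts = pd.to_datetime(df["timestamp"], format=timestamp_format, errors="coerce")
    lat = pd.to_numeric(df["lat"], errors="coerce")
    lon = pd.to_numeric(df["lon"], errors="coerce")
    bad = ts.isna() | lat.isna() | lon.isna()
    if not planar:
        bad |= (lat < -90) | (lat > 90) | (lon < -180) | (lon > 180)
    n_malformed = int(bad.sum())
    if n_malformed:
        logger.warning("dropped %d malformed GPS rows", n_malformed)
    df = df.loc[~bad].copy()
    df["timestamp"] = ts[~bad]
    df["lat"] = lat[~bad]
    df["lon"] = lon[~bad]
    for opt in ("speed", "hdop", "nsat"):
        if opt in df.columns:
            df[opt] = pd.to_numeric(df[opt], errors="coerce")
        else:
            df[opt] = np.nan

    df = df.sort_values(["participant_id", "timestamp"], kind="mergesort")
    dup = df.duplicated(["participant_id", "timestamp"], keep="first")
    n_dup = int(dup.sum())
    if n_dup:
        logger.info("collapsed %d duplicate (participant, timestamp) rows", n_dup)
    df = df.loc[~dup].reset_index(drop=True)
    return ReadReport(df, n_rows=n_rows, n_malformed=n_malformed, n_duplicates=n_dup)


def clean_gps(
    fixes: pd.DataFrame,
    thresholds: CleaningThresholds | None = None,
    strict_missing: bool = False,
) -> CleaningResult:
    """Apply the speed / HDOP / satellite-count filters to a fix stream.

    With ``strict_missing`` a fix missing a quality field is removed by
    that filter instead of retained.  Order is preserved; cleaning is
    idempotent.
    """
    thr = thresholds or CleaningThresholds()
    speed = pd.to_numeric(fixes.get("speed"), errors="coerce")
    hdop = pd.to_numeric(fixes.get("hdop"), errors="coerce")
    nsat = pd.to_numeric(fixes.get("nsat"), errors="coerce")

    if strict_missing:
        v_speed = ~(speed <= thr.max_speed_kmh)
        v_hdop = ~(hdop <= thr.max_hdop)
        v_nsat = ~(nsat >= thr.min_satellites)
    else:
        v_speed = speed > thr.max_speed_kmh
        v_hdop = hdop > thr.max_hdop
        v_nsat = nsat < thr.min_satellites
    v_speed = v_speed.fillna(strict_missing).to_numpy(bool)
    v_hdop = v_hdop.fillna(strict_missing).to_numpy(bool)
    v_nsat = v_nsat.fillna(strict_missing).to_numpy(bool)

    removed_mask = v_speed | v_hdop | v_nsat
    reasons = []
    for s, h, n in zip(v_speed[removed_mask], v_hdop[removed_mask], v_nsat[removed_mask]):
        r = [name for flag, name in ((s, "speed"), (h, "hdop"), (n, "satellites")) if flag]
        reasons.append("+".join(r))
    removed = fixes.loc[removed_mask].copy()
    removed["removed_reason"] = reasons
    counts = {
        "speed": int(v_speed.sum()),
        "hdop": int(v_hdop.sum()),
        "satellites": int(v_nsat.sum()),
        "total_removed": int(removed_mask.sum()),
        "total_kept": int((~removed_mask).sum()),
    }
    return CleaningResult(fixes.loc[~removed_mask].copy(), removed, counts)


def haversine_m(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in metres between WGS84 coordinate arrays."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(a, float)) for a in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return EARTH_RADIUS_M * 2 * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def step_distances_m(fixes: pd.DataFrame, planar: bool = False) -> np.ndarray:
    """Distance in metres from each fix to the previous fix of the same
    participant (0 for the first fix of each stream)."""
    lat = fixes["lat"].to_numpy(float)
    lon = fixes["lon"].to_numpy(float)
    if planar:
        d = np.hypot(np.diff(lon, prepend=lon[:1]), np.diff(lat, prepend=lat[:1]))
    else:
        d = np.zeros(len(fixes))
        if len(fixes) > 1:
            d[1:] = haversine_m(lat[:-1], lon[:-1], lat[1:], lon[1:])
    new_stream = fixes["participant_id"].ne(fixes["participant_id"].shift()).to_numpy()
    d[new_stream] = 0.0
    return d


def derive_speed(
    fixes: pd.DataFrame, planar: bool = False, overwrite: bool = False
) -> pd.DataFrame:
    """Fill missing ``speed`` values from displacement over time, in km/h.

    The first fix of each participant's stream gets speed 0.  With
    ``overwrite`` every speed is recomputed, not only the missing ones.
    """
    fixes = fixes.copy()
    if len(fixes) == 0:
        if "speed" not in fixes.columns:
            fixes["speed"] = pd.Series(dtype=float)
        return fixes
    d = step_distances_m(fixes, planar=planar)
    dt = fixes["timestamp"].diff().dt.total_seconds().to_numpy()
    new_stream = fixes["participant_id"].ne(fixes["participant_id"].shift()).to_numpy()
    dt[new_stream] = np.nan
    with np.errstate(invalid="ignore", divide="ignore"):
        derived = np.where(np.isnan(dt), 0.0, d / dt * 3.6)
    if "speed" not in fixes.columns or overwrite:
        fixes["speed"] = derived
    else:
        speed = fixes["speed"].to_numpy(float)
        fixes["speed"] = np.where(np.isnan(speed), derived, speed)
    return fixes


def write_gps_log(fixes: pd.DataFrame, path) -> None:
    """Write a fix stream back to CSV with ISO timestamps."""
    out = fixes.copy()
    out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)
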