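"""Land-use maps and per-fix location coding.

Locations are coded with single letters ``A``–``I`` and ``K`` (``J`` is
skipped): Home=A, School=B, Residential=C, Shops=D, Open space=E, Sports
facilities=F, Church=G, Medical=H, Other schools=I, Other=K.  Fixes on the
street network carry the pseudo-code ``ROAD``, which is used by trip
detection but never appears in a trip code.

The map is a flat collection of polygons, each carrying one code.  Coding a
fix is point-in-polygon containment with a fixed precedence: the
participant's own home parcel (A) beats their own school parcel (B), which
beats every other land-use polygon; among overlapping non-road polygons the
smallest wins; roads lose to everything except the fallback K.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import mapping, shape
from shapely.strtree import STRtree

logger = logging.getLogger(__name__)

#: Location categories keyed by single-letter code (letter J unused).
CODE_CATEGORIES: dict[str, str] = {
    "A": "Home",
    "B": "School",
    "C": "Residential",
    "D": "Shops",
    "E": "Open space",
    "F": "Sports facilities",
    "G": "Church",
    "H": "Medical",
    "I": "Other schools",
    "K": "Other",
}

LOCATION_CODES: tuple[str, ...] = tuple(CODE_CATEGORIES)

#: Pseudo-code for street-network polygons; never part of a trip code.
ROAD = "ROAD"

#: Fallback code for uncategorisable or uncovered locations.
OTHER = "K"

# Map-feature category text -> code.  Keys are casefolded and
# whitespace-normalised before lookup.  "school"/"schools" map to I (other
# schools); a participant's *own* school parcel is promoted to B through
# their ParticipantPlaces entry, and their home parcel to A likewise.
MAP_CATEGORY_CODES: dict[str, str] = {
    "home": "A",
    "residential": "C",
    "residential driveways": "C",
    "retirement home": "C",
    "shops": "D",
    "shop": "D",
    "shopping centre": "D",
    "shopping centres": "D",
    "petrol station": "D",
    "petrol stations": "D",
    "commercial": "D",
    "open space": "E",
    "public open space": "E",
    "unofficial open space": "E",
    "park": "E",
    "parks": "E",
    "beach": "E",
    "beaches": "E",
    "sports": "F",
    "sports facilities": "F",
    "indoor sports facilities": "F",
    "outdoor sports facilities": "F",
    "swimming pool": "F",
    "swimming pools": "F",
    "church": "G",
    "medical": "H",
    "hospital": "H",
    "school": "I",
    "schools": "I",
    "other": "K",
    "industrial": "K",
    "airport": "K",
    "car park": "K",
    "car parks": "K",
    "accommodation": "K",
    "preschool": "K",
    "preschools": "K",
    "tertiary institute": "K",
    "water": "K",
    "road": ROAD,
    "roads": ROAD,
}


def _norm(text: str) -> str:
    return " ".join(str(text).split()).casefold()


def category_to_code(category: str) -> str | None:
    """Map a free-text map category to a location code, or None if unknown."""
    return MAP_CATEGORY_CODES.get(_norm(category))


@dataclass
class LandUseMap:
    """Polygons with one location code each, in a shared planar frame."""

    geometries: list  # shapely geometries
    codes: list[str]
    crs: str = "local-metric"
    _tree: STRtree | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.geometries) != len(self.codes):
            raise ValueError("one code per geometry required")
        for code in self.codes:
            if code != ROAD and code not in CODE_CATEGORIES:
                raise ValueError(f"unknown location code {code!r}")

    @property
    def tree(self) -> STRtree:
        if self._tree is None:
            self._tree = STRtree(self.geometries)
        return self._tree

    def __len__(self) -> int:
        return len(self.geometries)


@dataclass
class ParticipantPlaces:
    """A participant's own home and school land parcels."""

    participant_id: str
    home_polygon: object
    school_polygon: object


def load_landuse(path, category_property: str = "category") -> LandUseMap:
    """Read a land-use polygon map from a GeoJSON FeatureCollection.

    Features whose category text is not recognised are coded K ("Other")
    with a logged warning, mirroring how uncommon locations are aggregated.
    """
    with open(path) as fh:
        doc = json.load(fh)
    geoms, codes = [], []
    unknown = 0
    for feat in doc.get("features", []):
        props = feat.get("properties") or {}
        if category_property not in props:
            raise ValueError(
                f"feature missing required property {category_property!r}"
            )
        code = category_to_code(props[category_property])
        if code is None:
            unknown += 1
            logger.warning(
                "unrecognised land-use category %r -> K", props[category_property]
            )
            code = OTHER
        geoms.append(shape(feat["geometry"]))
        codes.append(code)
    if unknown:
        logger.warning("%d features fell back to code K", unknown)
    crs = doc.get("crs_name", "local-metric")
    return LandUseMap(geoms, codes, crs=crs)


def save_landuse(landuse: LandUseMap, path, categories: Iterable[str] | None = None) -> None:
    """Write a LandUseMap as GeoJSON with a ``category`` property per feature."""
    cats = list(categories) if categories is not None else [
        ROAD.lower() if c == ROAD else CODE_CATEGORIES[c] for c in landuse.codes
    ]
    features = [
        {
            "type": "Feature",
            "properties": {"category": cat},
            "geometry": mapping(geom),
        }
        for geom, cat in zip(landuse.geometries, cats)
    ]
    doc = {
        "type": "FeatureCollection",
        "crs_name": landuse.crs,
        "features": features,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_places(path) -> dict[str, ParticipantPlaces]:
    """Read per-participant home/school parcels from GeoJSON.

    Features need properties ``participant_id`` and ``role`` in
    {"home", "school"}.
    """
    with open(path) as fh:
        doc = json.load(fh)
    homes: dict[str, object] = {}
    schools: dict[str, object] = {}
    for feat in doc.get("features", []):
        props = feat.get("properties") or {}
        pid = str(props["participant_id"])
        role = props["role"]
        geom = shape(feat["geometry"])
        if role == "home":
            homes[pid] = geom
        elif role == "school":
            schools[pid] = geom
        else:
            raise ValueError(f"unknown place role {role!r}")
    places = {}
    for pid in homes.keys() | schools.keys():
        if pid not in homes or pid not in schools:
            raise ValueError(f"participant {pid} lacks a home or school parcel")
        places[pid] = ParticipantPlaces(pid, homes[pid], schools[pid])
    return places


def save_places(places: Mapping[str, ParticipantPlaces], path) -> None:
    features = []
    for pp in places.values():
        for role, geom in (("home", pp.home_polygon), ("school", pp.school_polygon)):
            features.append(
                {
                    "type": "Feature",
                    "properties": {"participant_id": pp.participant_id, "role": role},
                    "geometry": mapping(geom),
                }
            )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def _map_codes_for_points(
    points: np.ndarray, landuse: LandUseMap
) -> tuple[np.ndarray, np.ndarray]:
    """Best land-use code per point, ignoring home/school overrides.

    Precedence among overlapping polygons: non-road before road, then
    smallest area.  Points covered by nothing get K.  Returns
    (codes, covered mask).
    """
    out = np.full(len(points), OTHER, dtype=object)
    covered = np.zeros(len(points), dtype=bool)
    if len(points) == 0 or len(landuse) == 0:
        return out, covered
    pt_idx, poly_idx = landuse.tree.query(points, predicate="intersects")
    covered[np.unique(pt_idx)] = True
    if len(pt_idx) == 0:
        return out, covered
    codes = np.asarray(landuse.codes, dtype=object)[poly_idx]
    areas = shapely.area(np.asarray(landuse.geometries, dtype=object)[poly_idx])
    road_rank = (codes == ROAD).astype(int)
    # Sort so the preferred candidate of each point comes first, then keep it.
    order = np.lexsort((areas, road_rank, pt_idx))
    pt_sorted = pt_idx[order]
    first = np.ones(len(pt_sorted), dtype=bool)
    first[1:] = pt_sorted[1:] != pt_sorted[:-1]
    out[pt_sorted[first]] = codes[order][first]
    return out, covered


def assign_locations(
    fixes: pd.DataFrame,
    landuse: LandUseMap,
    places: Mapping[str, ParticipantPlaces] | None = None,
) -> pd.DataFrame:
    """Assign one location code to every fix.

    Precedence: own home parcel (A) > own school parcel (B) > other
    land-use polygons (smallest non-road polygon first, roads last) > K.
    Returns a copy of ``fixes`` with a ``location_code`` column; the number
    of rows never changes.
    """
    fixes = fixes.copy()
    points = shapely.points(
        fixes["lon"].to_numpy(float), fixes["lat"].to_numpy(float)
    )
    code, covered = _map_codes_for_points(points, landuse)
    uncovered = int((~covered).sum())

    if places:
        pids = fixes["participant_id"].astype(str).to_numpy()
        for pid, pp in places.items():
            sel = np.flatnonzero(pids == str(pid))
            if len(sel) == 0:
                continue
            sub = points[sel]
            in_school = shapely.intersects(pp.school_polygon, sub)
            code[sel[in_school]] = "B"
            in_home = shapely.intersects(pp.home_polygon, sub)
            code[sel[in_home]] = "A"
    if uncovered:
        logger.warning("%d fixes outside all map polygons coded K", uncovered)
    fixes["location_code"] = code
    return fixes
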