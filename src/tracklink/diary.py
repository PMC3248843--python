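"""Travel-diary ingest, standardisation, and quality scoring.

Diaries are self-reported, ordered trip lists.  Free-text origins and
destinations are standardised to the single-letter location categories
through a lexicon, and each trip gets the same two-letter code as a GPS
trip, so that a day's diary becomes a code sequence comparable to the GPS
one.  Reported clock times are stored but never used for matching — the
whole point of sequence-based linkage is that diary times are unreliable.

A participant's diary quality score counts mechanical evidence of a poor
diary: rows with missing data, rows entered or adjusted by a researcher,
and sequence inconsistencies (a trip that does not start where the
previous one ended, e.g. travelling to a park but never recording the trip
back home).  Scores above the threshold (4) classify the participant's
diaries as "lower" quality, the rest as "higher".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .landuse import CODE_CATEGORIES, OTHER

logger = logging.getLogger(__name__)

DEFAULT_QUALITY_THRESHOLD = 4

#: Free-text place -> location code.  Keys casefolded, whitespace-normalised.
DEFAULT_LEXICON: dict[str, str] = {
    "home": "A",
    "school": "B",
    "friends": "C",
    "friend": "C",
    "friends house": "C",
    "friend's house": "C",
    "family": "C",
    "residential": "C",
    "retirement home": "C",
    "neighbour": "C",
    "neighbours": "C",
    "shops": "D",
    "shop": "D",
    "shopping centre": "D",
    "supermarket": "D",
    "dairy": "D",
    "petrol station": "D",
    "petrol stations": "D",
    "park": "E",
    "playground": "E",
    "beach": "E",
    "open space": "E",
    "sports": "F",
    "sports ground": "F",
    "swimming pool": "F",
    "pool": "F",
    "gym": "F",
    "church": "G",
    "doctor": "H",
    "medical": "H",
    "hospital": "H",
    "dentist": "H",
    "other school": "I",
    "another school": "I",
    "other": "K",
    "airport": "K",
    "car park": "K",
    "town": "K",
}

#: Accompaniment answers that mean the child travelled unaccompanied.
INDEPENDENT_TOKENS = frozenset(
    {"none", "alone", "no one", "noone", "nobody", "by myself", "myself", "unaccompanied"}
)

DIARY_COLUMNS = (
    "participant_id",
    "date",
    "seq_index",
    "time",
    "origin",
    "destination",
    "mode",
    "accompaniment",
    "researcher_entered",
)


@dataclass(frozen=True)
class DiaryQuality:
    participant_id: str
    score: int
    category: str  # "lower" | "higher"


def _norm(text) -> str:
    if text is None or (isinstance(text, float) and np.isnan(text)):
        return ""
    return " ".join(str(text).split()).casefold()


def load_lexicon(path) -> dict[str, str]:
    """Read a two-column (text, code) CSV lexicon."""
    df = pd.read_csv(path)
    lex = {}
    for row in df.itertuples(index=False):
        code = str(row[1]).strip().upper()
        if code not in CODE_CATEGORIES:
            raise ValueError(f"lexicon code {code!r} is not a location code")
        lex[_norm(row[0])] = code
    return lex


def load_diary(path, lexicon: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a diary CSV into standardised diary trips.

    Output columns add ``origin_code``, ``destination_code``, ``code``
    (empty when an endpoint is missing), ``missing_field``, ``independent``.
    Unmapped place text falls back to K with a warning; rows whose date
    cannot be parsed are rejected (logged).  Rows with missing fields are
    kept and flagged — they feed the quality score.
    """
    lex = dict(DEFAULT_LEXICON)
    if lexicon:
        lex.update({_norm(k): v for k, v in lexicon.items()})
    try:
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raw = pd.DataFrame(columns=list(DIARY_COLUMNS))
    for col in DIARY_COLUMNS:
        if col not in raw.columns:
            raw[col] = ""

    dates = pd.to_datetime(raw["date"], errors="coerce")
    bad_date = dates.isna()
    if bad_date.any():
        logger.warning("rejected %d diary rows with unparseable dates", int(bad_date.sum()))
    raw = raw.loc[~bad_date].copy()
    dates = dates[~bad_date]

    unmapped = 0

    def to_code(text: str) -> str:
        nonlocal unmapped
        t = _norm(text)
        if not t:
            return ""
        if t in lex:
            return lex[t]
        unmapped += 1
        logger.warning("diary place %r not in lexicon -> K", text)
        return OTHER

    origin_code = raw["origin"].map(to_code)
    destination_code = raw["destination"].map(to_code)
    code = np.where(
        (origin_code != "") & (destination_code != ""),
        origin_code.str.upper() + destination_code.str.lower(),
        "",
    )
    missing = (
        (raw["origin"].map(_norm) == "")
        | (raw["destination"].map(_norm) == "")
        | (raw["mode"].map(_norm) == "")
        | (raw["accompaniment"].map(_norm) == "")
    )
    researcher = raw["researcher_entered"].map(_norm).isin({"1", "true", "yes", "y"})
    acc = raw["accompaniment"].map(_norm)
    independent = acc.isin(INDEPENDENT_TOKENS)

    out = pd.DataFrame(
        {
            "participant_id": raw["participant_id"].astype(str),
            "date": dates.dt.date.astype(str),
            "seq_index": pd.to_numeric(raw["seq_index"], errors="coerce").fillna(0).astype(int),
            "time": raw["time"],
            "origin": raw["origin"],
            "destination": raw["destination"],
            "origin_code": origin_code,
            "destination_code": destination_code,
            "code": code,
            "mode": raw["mode"],
            "accompaniment": raw["accompaniment"],
            "independent": independent,
            "missing_field": missing,
            "researcher_entered": researcher,
        }
    )
    out = out.sort_values(["participant_id", "date", "seq_index"], kind="mergesort")
    if unmapped:
        logger.warning("%d diary places fell back to code K", unmapped)
    return out.reset_index(drop=True)


def count_inconsistencies(diary: pd.DataFrame) -> pd.Series:
    """Per-participant count of within-day sequence breaks.

    A break is a consecutive row pair (by seq_index, same day) where the
    earlier trip's destination differs from the later trip's origin.
    Pairs with a missing endpoint cannot be judged and are skipped.
    """
    counts: dict[str, int] = {pid: 0 for pid in diary["participant_id"].unique()}
    for (pid, _), grp in diary.groupby(["participant_id", "date"], sort=False):
        grp = grp.sort_values("seq_index")
        dest = grp["destination_code"].to_numpy(object)
        orig = grp["origin_code"].to_numpy(object)
        for i in range(len(grp) - 1):
            if dest[i] and orig[i + 1] and dest[i] != orig[i + 1]:
                counts[pid] += 1
    return pd.Series(counts, dtype=int)


def score_quality(
    diary: pd.DataFrame, quality_threshold: int = DEFAULT_QUALITY_THRESHOLD
) -> pd.DataFrame:
    """Score each participant's set of diaries and classify quality.

    score = missing-field rows + researcher-entered rows + sequence
    inconsistencies; scores strictly greater than the threshold are
    "lower" quality, the rest "higher".
    """
    if len(diary) == 0:
        return pd.DataFrame(columns=["participant_id", "score", "category"])
    per = diary.groupby("participant_id", sort=True)
    missing = per["missing_field"].sum()
    researcher = per["researcher_entered"].sum()
    incons = count_inconsistencies(diary).reindex(missing.index).fillna(0)
    score = (missing + researcher + incons).astype(int)
    out = pd.DataFrame(
        {
            "participant_id": score.index.astype(str),
            "score": score.to_numpy(),
            "category": np.where(score.to_numpy() > quality_threshold, "lower", "higher"),
        }
    )
    return out.reset_index(drop=True)


def diary_day_codes(diary: pd.DataFrame) -> dict[tuple[str, str], list[str]]:
    """Per (participant, date) ordered list of two-letter diary trip codes.

    Rows without a full code (missing endpoint) cannot take part in
    alignment and are skipped here; they still count against quality.
    """
    out: dict[tuple[str, str], list[str]] = {}
    for (pid, date), grp in diary.groupby(["participant_id", "date"], sort=True):
        codes = [c for c in grp.sort_values("seq_index")["code"] if c]
        out[(str(pid), str(date))] = codes
    return out
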