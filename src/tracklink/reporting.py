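"""Attribute transfer, match-rate tables, and chi-squared tests.

Once a day's GPS and diary sequences are aligned, the diary's travel mode
and accompaniment are copied onto every fully or partially matched GPS
trip (both members of a chain step inherit the single diary trip's
attributes) and onto the fixes inside each such trip's span.  Reporting is
diary-centric — full, partial and unmatched counts as percentages of all
travel-diary trips — because the diary is the record being explained.
Raw counts are always written next to percentages; percentages are
recomputed from counts with half-up rounding to one decimal.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .align import FULL, PARTIAL, AlignmentResult
from .trips import Trip


def round_half_up(value: float, decimals: int = 1) -> float:
    """Decimal half-up rounding (so 0.25 -> 0.3 at 1 d.p.), as printed."""
    q = decimal.Decimal(10) ** -decimals
    return float(decimal.Decimal(repr(value)).quantize(q, rounding=decimal.ROUND_HALF_UP))


def transfer_attributes(
    alignment: AlignmentResult,
    diary_day: pd.DataFrame,
    gps_trips: Sequence[Trip],
    fixes: pd.DataFrame | None = None,
) -> tuple[list[Trip], pd.DataFrame | None]:
    """Copy mode/accompaniment from matched diary trips onto GPS trips.

    ``diary_day`` holds the day's diary rows in sequence order (only rows
    with a complete code, matching ``alignment.diary_codes``).  Every GPS
    trip in a full or partial pair — chain members included — receives the
    paired diary trip's attributes; unmatched and mismatched GPS trips
    stay unannotated.  If ``fixes`` is given, annotated trips' fix spans
    gain ``mode``/``accompaniment`` columns too.  Raises when the
    alignment does not correspond to the supplied trips/diary (stale
    inputs).
    """
    gps_codes = [t.code for t in gps_trips]
    if gps_codes != list(alignment.gps_codes):
        raise ValueError("alignment does not match the supplied GPS trips")
    day_codes = [c for c in diary_day["code"].tolist() if c]
    if day_codes != list(alignment.diary_codes):
        raise ValueError("alignment does not match the supplied diary rows")
    diary_rows = diary_day.loc[diary_day["code"] != ""].reset_index(drop=True)

    annotated = [replace(t) for t in gps_trips]
    if fixes is not None:
        fixes = fixes.copy()
        for col in ("mode", "accompaniment"):
            if col not in fixes.columns:
                fixes[col] = ""
    for p in alignment.pairs:
        if p.match_class not in (FULL, PARTIAL) or p.diary_index is None:
            continue
        row = diary_rows.iloc[p.diary_index]
        for gi in p.gps_indices:
            annotated[gi].mode = row["mode"] or None
            annotated[gi].accompaniment = row["accompaniment"] or None
            span = annotated[gi].fix_span
            if fixes is not None and span is not None:
                lo, hi = span
                fixes.iloc[lo : hi + 1, fixes.columns.get_loc("mode")] = row["mode"]
                fixes.iloc[lo : hi + 1, fixes.columns.get_loc("accompaniment")] = row[
                    "accompaniment"
                ]
    return annotated, fixes


def summarize_matches(
    alignments: Iterable[AlignmentResult],
    grouping: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Diary-centric match table per group plus a totals row.

    ``grouping`` maps participant_id to a group label (e.g. diary quality
    category); without it everything lands in one group.  Percentages are
    of all travel-diary trips in the group, one decimal, half-up; blank
    (NaN) when a group has no diary trips.
    """
    rows: dict[str, dict] = {}
    for res in alignments:
        label = (grouping or {}).get(str(res.participant_id), "all")
        row = rows.setdefault(
            label,
            {
                "participants": set(),
                "diary_trips": 0,
                "gps_trips": 0,
                "full": 0,
                "partial": 0,
                "unmatched_diary": 0,
                "unmatched_gps": 0,
            },
        )
        row["participants"].add(str(res.participant_id))
        row["diary_trips"] += res.counts["n_diary"]
        row["gps_trips"] += res.counts["n_gps"]
        for key in ("full", "partial", "unmatched_diary", "unmatched_gps"):
            row[key] += res.counts[key]

    out = []
    total = {
        "participants": set(),
        "diary_trips": 0,
        "gps_trips": 0,
        "full": 0,
        "partial": 0,
        "unmatched_diary": 0,
        "unmatched_gps": 0,
    }
    for label in sorted(rows):
        row = rows[label]
        total["participants"] |= row["participants"]
        for key in ("diary_trips", "gps_trips", "full", "partial", "unmatched_diary", "unmatched_gps"):
            total[key] += row[key]
        out.append(_summary_row(label, row))
    out.append(_summary_row("total", total))
    return pd.DataFrame(out)


def _summary_row(label: str, row: dict) -> dict:
    n = row["diary_trips"]

    def pct(x: int) -> float:
        return round_half_up(100.0 * x / n, 1) if n else float("nan")

    return {
        "group": label,
        "n_children": len(row["participants"]),
        "diary_trips": n,
        "gps_trips": row["gps_trips"],
        "full": row["full"],
        "partial": row["partial"],
        "unmatched_diary": row["unmatched_diary"],
        "unmatched_gps": row["unmatched_gps"],
        "pct_full": pct(row["full"]),
        "pct_partial": pct(row["partial"]),
        "pct_unmatched": pct(row["unmatched_diary"]),
        "pct_matched": pct(row["full"] + row["partial"]),
    }


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float

    def display_p(self) -> str:
        """Journal-style p: three significant figures, '< 0.001' floor."""
        if self.p_value < 0.001:
            return "< 0.001"
        return f"{self.p_value:.3g}"


def chi_square_independence(table) -> ChiSquareResult:
    """Pearson chi-squared test of independence on an r x c count table.

    Expected counts come from the row/column marginals; no continuity
    correction (matching the plain Pearson statistic).  Degenerate (all
    zero) rows or columns are refused by name.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    row_sums = obs.sum(axis=1)
    col_sums = obs.sum(axis=0)
    for axis_name, sums in (("row", row_sums), ("column", col_sums)):
        zero = np.flatnonzero(sums == 0)
        if len(zero):
            raise ValueError(f"{axis_name} {int(zero[0])} has zero total")
    res = stats.chi2_contingency(obs, correction=False)
    return ChiSquareResult(float(res.statistic), int(res.dof), float(res.pvalue))


def match_class_table(summary: pd.DataFrame, groups: Sequence[str]) -> np.ndarray:
    """Full / partial / unmatched counts per group as a contingency table."""
    rows = []
    for g in groups:
        sub = summary.loc[summary["group"] == g]
        if len(sub) != 1:
            raise ValueError(f"group {g!r} not present exactly once in summary")
        rows.append(
            [int(sub["full"].iloc[0]), int(sub["partial"].iloc[0]), int(sub["unmatched_diary"].iloc[0])]
        )
    return np.asarray(rows, dtype=int)


def alignments_to_frame(alignments: Iterable[AlignmentResult]) -> pd.DataFrame:
    """One row per aligned pair, CSV-friendly."""
    rows = []
    for res in alignments:
        for p in res.pairs:
            rows.append(
                {
                    "participant_id": res.participant_id,
                    "date": str(res.date),
                    "step": p.step,
                    "match_class": p.match_class,
                    "gps_indices": ";".join(str(i) for i in p.gps_indices),
                    "diary_index": "" if p.diary_index is None else p.diary_index,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["participant_id", "date", "step", "match_class", "gps_indices", "diary_index"],
    )


def day_summary_frame(alignments: Iterable[AlignmentResult]) -> pd.DataFrame:
    """Per participant-day alignment bookkeeping."""
    return pd.DataFrame(
        [
            {
                "participant_id": res.participant_id,
                "date": str(res.date),
                "n_gps": res.counts["n_gps"],
                "n_diary": res.counts["n_diary"],
                "full": res.counts["full"],
                "partial": res.counts["partial"],
                "unmatched_diary": res.counts["unmatched_diary"],
                "unmatched_gps": res.counts["unmatched_gps"],
                "score": res.score,
            }
            for res in alignments
        ],
        columns=[
            "participant_id", "date", "n_gps", "n_diary", "full", "partial",
            "unmatched_diary", "unmatched_gps", "score",
        ],
    )
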