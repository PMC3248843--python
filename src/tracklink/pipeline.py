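"""End-to-end pipeline: clean, code, detect, parse, align, transfer, report.

Each stage reads the previous stage's output, writes plain-text artifacts
into the output directory, and records itself in a manifest (input/output
hashes plus the config hash), so a rerun on identical inputs is verifiably
identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass

import pandas as pd

from . import __version__
from .align import align
from .config import PipelineConfig
from .diary import diary_day_codes, load_diary, load_lexicon, score_quality
from .gps import clean_gps, derive_speed, read_gps_log, write_gps_log
from .landuse import assign_locations, load_landuse, load_places
from .reporting import (
    alignments_to_frame,
    chi_square_independence,
    day_summary_frame,
    match_class_table,
    summarize_matches,
    transfer_attributes,
)
from .trips import (
    build_sequences,
    detect_stops,
    extract_trips,
    sequences_to_frame,
    trips_to_frame,
)

logger = logging.getLogger(__name__)

STAGES = (
    "clean",
    "code-locations",
    "detect-trips",
    "parse-diary",
    "align",
    "transfer",
    "report",
)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class PipelineResult:
    outdir: str
    manifest: dict
    summary: pd.DataFrame
    alignments: list


@dataclass
class LinkageResult:
    """In-memory pipeline outcome for a simulated cohort."""

    alignments: list
    summary: pd.DataFrame
    quality: pd.DataFrame
    trips: list
    sequences: list


def link_cohort(cohort, config: PipelineConfig | None = None) -> LinkageResult:
    """Run the linkage stages in memory on a simulated cohort.

    Same computation as :func:`run_pipeline` minus file I/O: clean,
    code, detect, parse (the diary is re-read through the standardiser),
    align and summarise, grouped by measured diary quality.
    """
    import io

    config = config or PipelineConfig()
    fixes = derive_speed(cohort.fixes, planar=config.planar)
    cleaned = clean_gps(fixes, config.thresholds(), strict_missing=config.strict_missing)
    coded = assign_locations(
        cleaned.fixes.reset_index(drop=True), cohort.world.landuse, cohort.world.places
    )
    stops = detect_stops(coded, dwell_s=config.dwell_s, gap_tolerance_s=config.gap_tolerance_s)
    trips = extract_trips(
        stops,
        coded,
        min_on_road_fraction=config.min_on_road_fraction,
        include_same_location=config.include_same_location,
    )
    seqs = build_sequences(trips, include_off_road=config.include_off_road)

    buf = io.StringIO()
    diary_raw = cohort.diary.drop(columns=["collapsed"], errors="ignore")
    diary_raw.to_csv(buf, index=False)
    buf.seek(0)
    diary = load_diary(buf)
    quality = score_quality(diary, quality_threshold=config.quality_threshold)

    scheme = config.scoring()
    gps_days = {(s.participant_id, str(s.date)): s for s in seqs}
    diary_days = diary_day_codes(diary)
    alignments = []
    for key in sorted(set(gps_days) | set(diary_days)):
        gseq = gps_days.get(key)
        gcodes = [t.code for t in gseq.trips] if gseq else []
        dcodes = diary_days.get(key, [])
        if gcodes or dcodes:
            alignments.append(
                align(gcodes, dcodes, scheme=scheme, allow_chain=config.allow_chain,
                      participant_id=key[0], date=key[1])
            )
    grouping = dict(zip(quality["participant_id"], quality["category"]))
    summary = summarize_matches(alignments, grouping)
    return LinkageResult(alignments, summary, quality, trips, seqs)


def run_pipeline(config: PipelineConfig, outdir: str) -> PipelineResult:
    """Run all stages on the files named in ``config.paths``.

    Required paths: ``fixes``, ``landuse``, ``places``, ``diary``;
    optional ``lexicon``.  Writes every stage's artifacts plus
    ``manifest.json`` into ``outdir``; halts with :class:`PipelineError`
    naming the failing stage, keeping partial outputs for debugging.
    """
    os.makedirs(outdir, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "stages": [],
    }

    def record(stage: str, inputs: list, outputs: list) -> None:
        manifest["stages"].append(
            {
                "stage": stage,
                "inputs": {str(p): _sha256(p) for p in inputs},
                "outputs": {str(p): _sha256(p) for p in outputs},
            }
        )

    def path_of(key: str, stage: str) -> str:
        p = config.paths.get(key)
        if not p or not os.path.exists(p):
            raise PipelineError(stage, f"required input {key!r} missing ({p})")
        return p

    out = lambda name: os.path.join(outdir, name)

    # clean ---------------------------------------------------------------
    stage = "clean"
    try:
        fixes_path = path_of("fixes", stage)
        report = read_gps_log(fixes_path, planar=config.planar)
        fixes = derive_speed(report.fixes, planar=config.planar)
        cleaned = clean_gps(fixes, config.thresholds(), strict_missing=config.strict_missing)
        write_gps_log(cleaned.fixes, out("clean.csv"))
        write_gps_log(cleaned.removed, out("removed.csv"))
        with open(out("clean_report.json"), "w") as fh:
            json.dump(
                {
                    "rows_read": report.n_rows,
                    "malformed": report.n_malformed,
                    "duplicates": report.n_duplicates,
                    **cleaned.counts,
                },
                fh,
                indent=2,
            )
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise PipelineError(stage, str(exc)) from exc
    record(stage, [fixes_path], [out("clean.csv"), out("removed.csv")])

    # code-locations ------------------------------------------------------
    stage = "code-locations"
    try:
        landuse = load_landuse(path_of("landuse", stage))
        places = load_places(path_of("places", stage))
        coded = assign_locations(cleaned.fixes.reset_index(drop=True), landuse, places)
        write_gps_log(coded, out("coded.csv"))
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc
    record(stage, [config.paths["landuse"], config.paths["places"]], [out("coded.csv")])

    # detect-trips --------------------------------------------------------
    stage = "detect-trips"
    try:
        stops = detect_stops(coded, dwell_s=config.dwell_s, gap_tolerance_s=config.gap_tolerance_s)
        trips = extract_trips(
            stops,
            coded,
            min_on_road_fraction=config.min_on_road_fraction,
            include_same_location=config.include_same_location,
        )
        seqs = build_sequences(trips, include_off_road=config.include_off_road)
        trips_to_frame(trips).to_csv(out("trips.csv"), index=False)
        sequences_to_frame(seqs).to_csv(out("sequences.csv"), index=False)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc
    record(stage, [out("coded.csv")], [out("trips.csv"), out("sequences.csv")])

    # parse-diary ---------------------------------------------------------
    stage = "parse-diary"
    try:
        lexicon = None
        if config.paths.get("lexicon"):
            lexicon = load_lexicon(config.paths["lexicon"])
        diary = load_diary(path_of("diary", stage), lexicon=lexicon)
        quality = score_quality(diary, quality_threshold=config.quality_threshold)
        diary.to_csv(out("diary_trips.csv"), index=False)
        quality.to_csv(out("quality.csv"), index=False)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc
    record(stage, [config.paths["diary"]], [out("diary_trips.csv"), out("quality.csv")])

    # align ---------------------------------------------------------------
    stage = "align"
    try:
        scheme = config.scoring()
        gps_days = {
            (s.participant_id, str(s.date)): s for s in seqs
        }
        diary_days = diary_day_codes(diary)
        alignments = []
        for key in sorted(set(gps_days) | set(diary_days)):
            pid, date = key
            gseq = gps_days.get(key)
            gcodes = [t.code for t in gseq.trips] if gseq else []
            dcodes = diary_days.get(key, [])
            if not gcodes and not dcodes:
                continue
            alignments.append(
                align(
                    gcodes,
                    dcodes,
                    scheme=scheme,
                    allow_chain=config.allow_chain,
                    participant_id=pid,
                    date=date,
                )
            )
        alignments_to_frame(alignments).to_csv(out("alignment.csv"), index=False)
        day_summary_frame(alignments).to_csv(out("alignment_days.csv"), index=False)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc
    record(stage, [out("sequences.csv"), out("diary_trips.csv")], [out("alignment.csv")])

    # transfer ------------------------------------------------------------
    stage = "transfer"
    try:
        coded = coded.reset_index(drop=True)
        annotated_trips = []
        fixes_annotated = coded.copy()
        fixes_annotated["mode"] = ""
        fixes_annotated["accompaniment"] = ""
        diary_by_day = dict(tuple(diary.groupby(["participant_id", "date"], sort=False)))
        for res in alignments:
            key = (res.participant_id, res.date)
            gseq = gps_days.get(key)
            day_trips = gseq.trips if gseq else []
            diary_day = diary_by_day.get(
                key, diary.iloc[0:0]
            ).sort_values("seq_index")
            ann, fixes_annotated = transfer_attributes(
                res, diary_day, day_trips, fixes_annotated
            )
            annotated_trips.extend(ann)
        trips_to_frame(annotated_trips).to_csv(out("trips_annotated.csv"), index=False)
        write_gps_log(fixes_annotated, out("fixes_annotated.csv"))
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc
    record(stage, [out("alignment.csv")], [out("trips_annotated.csv"), out("fixes_annotated.csv")])

    # report --------------------------------------------------------------
    stage = "report"
    try:
        grouping = dict(zip(quality["participant_id"], quality["category"]))
        summary = summarize_matches(alignments, grouping)
        summary.to_csv(out("summary.csv"), index=False)
        stats: dict = {}
        groups = [g for g in ("lower", "higher") if (summary["group"] == g).any()]
        if len(groups) == 2:
            table = match_class_table(summary, groups)
            if (table.sum(axis=0) > 0).all():
                chi = chi_square_independence(table)
                stats["quality_by_class"] = {
                    "statistic": round(chi.statistic, 3),
                    "df": chi.df,
                    "p_value": chi.p_value,
                    "p_display": chi.display_p(),
                }
        with open(out("stats.json"), "w") as fh:
            json.dump(stats, fh, indent=2)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc
    record(stage, [out("alignment.csv")], [out("summary.csv"), out("stats.json")])

    with open(out("manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    logger.info("pipeline complete: %d stages", len(manifest["stages"]))
    return PipelineResult(outdir, manifest, summary, alignments)
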