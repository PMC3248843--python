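"""Pipeline configuration: every named constant in one validated place."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from .align import ScoringScheme
from .gps import CleaningThresholds


@dataclass
class PipelineConfig:
    """All tunables of the linkage pipeline, with the study defaults.

    Cleaning: speed > 160 km/h, HDOP > 5, < 4 satellites.  Detection:
    120 s dwell, 300 s same-location gap bridging, trips with under half
    of their fixes on roads flagged off-road.  Diary quality: scores > 4
    are "lower".  Scoring: +2 full, +1 partial, -1 mismatch, -1 gap,
    +2 chain.
    """

    planar: bool = True
    max_speed_kmh: float = 160.0
    max_hdop: float = 5.0
    min_satellites: int = 4
    strict_missing: bool = False
    dwell_s: float = 120.0
    gap_tolerance_s: float = 300.0
    min_on_road_fraction: float = 0.5
    include_same_location: bool = True
    include_off_road: bool = False
    quality_threshold: int = 4
    full_match: float = 2.0
    partial_match: float = 1.0
    mismatch: float = -1.0
    gap: float = -1.0
    chain_pair: float = 2.0
    allow_chain: bool = True
    epoch_s: float = 10.0
    seed: int = 7
    paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        # Delegate range checks to the dataclasses that own the semantics.
        self.thresholds()
        self.scoring()
        if self.dwell_s <= 0 or self.gap_tolerance_s < 0:
            raise ValueError("dwell_s must be positive, gap_tolerance_s non-negative")
        if not 0.0 <= self.min_on_road_fraction <= 1.0:
            raise ValueError("min_on_road_fraction must be in [0, 1]")

    def thresholds(self) -> CleaningThresholds:
        return CleaningThresholds(self.max_speed_kmh, self.max_hdop, self.min_satellites)

    def scoring(self) -> ScoringScheme:
        return ScoringScheme(
            self.full_match, self.partial_match, self.mismatch, self.gap, self.chain_pair
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)
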