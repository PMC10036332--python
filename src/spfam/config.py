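"""Pipeline configuration.

Every tunable named by the annotation stages lives on :class:`PipelineConfig`
so that a run is reproducible from (inputs, config, seed) alone.  Values can
be loaded from a flat YAML mapping and overridden key-by-key.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

#: larger, nonpolar residues used by the elastase S1 fallback rule
DEFAULT_BULKY = frozenset("VILFMW")

#: allowed windows (inclusive) for the five inter-cysteine gaps of a clip
#: domain; a gap of exactly 1 (the CC doublet) is accepted at any slot and
#: exactly one doublet is required
DEFAULT_CLIP_GAPS = ((8, 60), (5, 40), (2, 30), (2, 40), (2, 40))


@dataclass(frozen=True)
class PipelineConfig:
    # catalytic-motif scan
    motif_tolerance: int = 2
    taahc_dial_gap: tuple[int, int] = (20, 120)
    dial_gdsggp_gap: tuple[int, int] = (40, 160)
    # domain delimitation
    nterm_search_window: int = 120
    nterm_fallback_offset: int = 60
    cterm_extension: int = 55
    # chymotrypsin-numbering alignment
    gap_open: float = 11.0
    gap_extend: float = 1.0
    min_alignment_identity: float = 0.15
    # clip detection
    clip_gap_windows: tuple[tuple[int, int], ...] = DEFAULT_CLIP_GAPS
    # S1 specificity
    bulky_set: frozenset[str] = DEFAULT_BULKY
    # duplication clustering
    window_genes: int = 5
    min_identity: float = 0.4
    # expression set logic
    min_others: int | None = None  # None = all comparisons ("commonly")

    def replace(self, **kwargs: Any) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["bulky_set"] = sorted(self.bulky_set)
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs: dict[str, Any] = {}
        for key, value in raw.items():
            if key == "bulky_set":
                kwargs[key] = frozenset(value)
            elif key == "clip_gap_windows":
                kwargs[key] = tuple(tuple(w) for w in value)
            elif key in ("taahc_dial_gap", "dial_gdsggp_gap"):
                kwargs[key] = tuple(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)


DEFAULT_CONFIG = PipelineConfig()
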