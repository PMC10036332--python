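"""Clip-domain detection, architecture strings and category tallies.

A clip domain is a small disulfide-knotted regulatory module found upstream
of the protease domain in many immune-pathway proteases.  It is recognized
here purely from its cysteine skeleton: six cysteines whose five
consecutive gaps fall inside configurable windows, exactly one gap being 1
(the CC doublet).  Proteins are then binned into the four-way
cSP / SP / cSPH / SPH classification, and the full domain layout is
rendered as a compact architecture string (e.g. ``S-7LDLA-2CCP-PD``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .config import DEFAULT_CONFIG, PipelineConfig
from .io_formats import GeneLocus


@dataclass(frozen=True)
class ClipDomain:
    start: int
    end: int  # 0-based half-open, first to last cysteine inclusive
    cys_positions: tuple[int, ...]
    doublet_index: int  # which of the five gaps is the CC doublet

    def __post_init__(self) -> None:
        if len(self.cys_positions) != 6:
            raise ValueError("clip domain requires exactly six cysteines")


@dataclass
class SPAnnotation:
    """Per-protein verdicts collected across all pipeline stages."""

    id: str
    triad_class: str  # SP | SPH | incomplete
    his_ok: bool | None = None
    asp_ok: bool | None = None
    ser_ok: bool | None = None
    p1_residue: str | None = None
    activation_class: str | None = None
    res189: str | None = None
    res216: str | None = None
    res226: str | None = None
    specificity_class: str | None = None
    clip_count: int = 0
    architecture: str = ""
    locus: GeneLocus | None = None
    clips: list[ClipDomain] = field(default_factory=list)

    @property
    def category(self) -> str:
        """cSP / SP / cSPH / SPH / incomplete from triad class and clips."""
        if self.triad_class == "incomplete":
            return "incomplete"
        if self.triad_class == "SP":
            return "cSP" if self.clip_count >= 1 else "SP"
        return "cSPH" if self.clip_count >= 1 else "SPH"


def _gap_ok(gap: int, window: tuple[int, int]) -> bool:
    return window[0] <= gap <= window[1]


def detect_clip_domains(
    sequence: str,
    domain_start: int,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> list[ClipDomain]:
    """Scan the region upstream of the protease domain for clip domains.

    Six consecutive cysteines form a clip when exactly one of their five
    gaps equals 1 (the doublet) and every other gap falls inside its
    positional window.  Selection is greedy left-to-right over maximal
    non-overlapping groups; after a match, scanning resumes after its last
    cysteine.
    """
    region_cys = [i for i, aa in enumerate(sequence[:domain_start]) if aa == "C"]
    windows = config.clip_gap_windows
    clips: list[ClipDomain] = []
    i = 0
    while i + 6 <= len(region_cys):
        group = region_cys[i : i + 6]
        gaps = [b - a for a, b in zip(group, group[1:])]
        doublets = [j for j, g in enumerate(gaps) if g == 1]
        ok = len(doublets) == 1 and all(
            g == 1 or _gap_ok(g, windows[j]) for j, g in enumerate(gaps)
        )
        if ok:
            clips.append(
                ClipDomain(
                    start=group[0],
                    end=group[-1] + 1,
                    cys_positions=tuple(group),
                    doublet_index=doublets[0],
                )
            )
            i += 6  # resume after the last cysteine of the match
        else:
            i += 1
    return clips


def compose_architecture(
    signal_flag: bool,
    external_domains: list[tuple[str, int, int]],
    clips: list[ClipDomain],
    protease_domains: list[tuple[str, int, int]],
) -> str:
    """Render the ordered domain layout as a run-length-encoded string.

    ``protease_domains`` are (label, start, end) with label PD or PLD.
    Domains are sorted by start; runs of identical labels collapse to a
    count prefix; a signal peptide prepends ``S``.  Overlapping spans are
    an error naming the offending pair.
    """
    spans: list[tuple[int, int, str]] = []
    for label, start, end in external_domains:
        spans.append((start, end, label))
    for c in clips:
        spans.append((c.start, c.end, "clip"))
    for label, start, end in protease_domains:
        spans.append((start, end, label))
    spans.sort(key=lambda s: (s[0], s[1]))
    for (s1, e1, l1), (s2, e2, l2) in zip(spans, spans[1:]):
        if s2 < e1:
            raise ValueError(
                f"overlapping domain spans: {l1} [{s1 + 1}, {e1}] and {l2} [{s2 + 1}, {e2}]"
            )
    labels = [label for _, _, label in spans]
    if signal_flag:
        labels.insert(0, "S")
    return encode_architecture(labels)


def encode_architecture(labels: list[str]) -> str:
    parts: list[str] = []
    i = 0
    while i < len(labels):
        j = i
        while j < len(labels) and labels[j] == labels[i]:
            j += 1
        count = j - i
        parts.append(labels[i] if count == 1 else f"{count}{labels[i]}")
        i = j
    return "-".join(parts)


_PART_RE = re.compile(r"^(\d*)([A-Za-z]+)$")


def decode_architecture(architecture: str) -> list[str]:
    """Inverse of :func:`encode_architecture` (round-trip property)."""
    if not architecture:
        return []
    labels: list[str] = []
    for part in architecture.split("-"):
        m = _PART_RE.match(part)
        if not m:
            raise ValueError(f"malformed architecture component {part!r}")
        count = int(m.group(1)) if m.group(1) else 1
        labels.extend([m.group(2)] * count)
    return labels


def tally_categories(annotations: list[SPAnnotation]) -> dict[str, int]:
    """Four-way category counts plus their total (incomplete excluded)."""
    counts = {"cSP": 0, "SP": 0, "cSPH": 0, "SPH": 0}
    for ann in annotations:
        cat = ann.category
        if cat == "incomplete":
            continue
        counts[cat] += 1
    counts["total"] = sum(counts.values())
    return counts
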