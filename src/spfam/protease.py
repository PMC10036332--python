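"""Serine-protease domain detection, numbering and catalytic-triad calling.

The protease(-like) domain is located through its three conserved catalytic
blocks — TAAHC (His57), DIAL (Asp102) and GDSGGP (Ser195).  Each block may
diverge at non-anchor positions up to a mismatch tolerance; the anchor
residue itself is recorded but never required to match, so homologs with a
substituted triad residue (SPHs) are still found.  The domain is then mapped
onto chymotrypsin numbering by pairwise alignment against the bundled mature
bovine chymotrypsin A sequence, and the triad call (SP / SPH / incomplete)
is read off the anchors.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from Bio import Align
from Bio.Align import substitution_matrices

from .config import DEFAULT_CONFIG, PipelineConfig
from .reference import ChymotrypsinReference, load_reference

#: motif name -> (pattern, 0-based offset of the catalytic anchor, canonical anchor)
MOTIFS: dict[str, tuple[str, int, str]] = {
    "TAAHC": ("TAAHC", 3, "H"),
    "DIAL": ("DIAL", 0, "D"),
    "GDSGGP": ("GDSGGP", 2, "S"),
}

MOTIF_ORDER = ("TAAHC", "DIAL", "GDSGGP")

#: pattern marking the mature N-terminus of many family members (e.g. IVGG)
NTERM_RE = re.compile(r"[ILV][ILV]GG")


@dataclass(frozen=True)
class MotifMatch:
    motif_name: str
    start: int
    matched_text: str
    mismatches: int
    anchor_pos: int
    anchor_residue: str

    @property
    def end(self) -> int:
        return self.start + len(self.matched_text)

    @property
    def anchor_matches_canonical(self) -> bool:
        return self.anchor_residue == MOTIFS[self.motif_name][2]


@dataclass(frozen=True)
class NumberingMap:
    """Chymotrypsin-numbered positions mapped onto a domain sequence.

    ``pairs`` maps each canonical position to a 0-based index in the domain
    sequence, or ``None`` where the alignment placed a gap.
    """

    pairs: dict[int, int | None]
    alignment_identity: float
    low_confidence: bool = False

    def get(self, position: int) -> int | None:
        return self.pairs.get(position)


@dataclass
class ProteaseDomain:
    """A delimited protease(-like) domain within a protein.

    ``motifs`` holds the TAAHC/DIAL/GDSGGP matches in order; an entry is
    ``None`` when that catalytic region is absent (truncated sequence).
    ``kind`` (PD vs PLD) is assigned after the triad call.
    """

    start: int
    end: int
    motifs: tuple[MotifMatch | None, MotifMatch | None, MotifMatch | None]
    nterm_motif_start: int | None = None
    numbering: NumberingMap | None = None
    kind: str | None = None  # "PD" | "PLD"

    @property
    def taahc(self) -> MotifMatch | None:
        return self.motifs[0]

    @property
    def dial(self) -> MotifMatch | None:
        return self.motifs[1]

    @property
    def gdsggp(self) -> MotifMatch | None:
        return self.motifs[2]

    @property
    def is_complete(self) -> bool:
        return all(m is not None for m in self.motifs)


@dataclass(frozen=True)
class TriadCall:
    klass: str  # "SP" | "SPH" | "incomplete"
    his_ok: bool | None
    asp_ok: bool | None
    ser_ok: bool | None
    substituted: frozenset[str] = frozenset()


@dataclass(frozen=True)
class MotifTriple:
    taahc: MotifMatch
    dial: MotifMatch
    gdsggp: MotifMatch

    @property
    def span(self) -> tuple[int, int]:
        return (self.taahc.start, self.gdsggp.end)

    @property
    def total_mismatches(self) -> int:
        return self.taahc.mismatches + self.dial.mismatches + self.gdsggp.mismatches

    @property
    def anchor_mismatches(self) -> int:
        return sum(
            0 if m.anchor_matches_canonical else 1
            for m in (self.taahc, self.dial, self.gdsggp)
        )


def scan_motif(sequence: str, motif_name: str, tolerance: int) -> list[MotifMatch]:
    """All placements of one catalytic block with <= tolerance non-anchor
    mismatches.  'X' counts as a mismatch; the anchor is free."""
    pattern, anchor_offset, _ = MOTIFS[motif_name]
    n, m = len(sequence), len(pattern)
    matches: list[MotifMatch] = []
    for start in range(n - m + 1):
        window = sequence[start : start + m]
        mismatches = sum(
            1
            for i, (a, b) in enumerate(zip(window, pattern))
            if i != anchor_offset and a != b
        )
        if mismatches <= tolerance:
            matches.append(
                MotifMatch(
                    motif_name=motif_name,
                    start=start,
                    matched_text=window,
                    mismatches=mismatches,
                    anchor_pos=start + anchor_offset,
                    anchor_residue=window[anchor_offset],
                )
            )
    return matches


def _spacing_ok(triple: MotifTriple, config: PipelineConfig) -> bool:
    gap1 = triple.dial.start - triple.taahc.end
    gap2 = triple.gdsggp.start - triple.dial.end
    lo1, hi1 = config.taahc_dial_gap
    lo2, hi2 = config.dial_gdsggp_gap
    return lo1 <= gap1 <= hi1 and lo2 <= gap2 <= hi2


def find_catalytic_motifs(
    sequence: str, config: PipelineConfig = DEFAULT_CONFIG
) -> list[MotifTriple]:
    """Every ordered, non-overlapping TAAHC/DIAL/GDSGGP triple.

    Candidate triples must satisfy the inter-motif spacing windows.  Where
    candidates overlap, the one with the fewest total non-anchor mismatches
    wins; ties prefer fewer anchor substitutions, then the leftmost placement.
    Multiple surviving triples mean multiple candidate domains.
    """
    taahc = scan_motif(sequence, "TAAHC", config.motif_tolerance)
    dial = scan_motif(sequence, "DIAL", config.motif_tolerance)
    gdsggp = scan_motif(sequence, "GDSGGP", config.motif_tolerance)
    candidates: list[MotifTriple] = []
    for t in taahc:
        for d in dial:
            gap1 = d.start - t.end
            if not (config.taahc_dial_gap[0] <= gap1 <= config.taahc_dial_gap[1]):
                continue
            for g in gdsggp:
                triple = MotifTriple(t, d, g)
                if _spacing_ok(triple, config):
                    candidates.append(triple)
    candidates.sort(
        key=lambda tr: (
            tr.total_mismatches,
            tr.anchor_mismatches,
            tr.taahc.start,
            tr.dial.start,
            tr.gdsggp.start,
        )
    )
    chosen: list[MotifTriple] = []
    for triple in candidates:
        lo, hi = triple.span
        if all(hi <= c.span[0] or lo >= c.span[1] for c in chosen):
            chosen.append(triple)
    chosen.sort(key=lambda tr: tr.taahc.start)
    return chosen


def delimit_domain(
    sequence: str, triple: MotifTriple, config: PipelineConfig = DEFAULT_CONFIG
) -> ProteaseDomain:
    """Fix the domain span around a motif triple (numbering left unset).

    The N-terminus is the nearest [ILV][ILV]GG match upstream of TAAHC
    (within a search window), else a fixed offset before TAAHC; the
    C-terminus extends past the catalytic Ser far enough to cover the
    S1-pocket residues and the chymotrypsin C-terminus.
    """
    window_start = max(0, triple.taahc.start - config.nterm_search_window)
    nterm: int | None = None
    for match in NTERM_RE.finditer(sequence, window_start, triple.taahc.start):
        nterm = match.start()  # last match found = nearest upstream
    start = nterm if nterm is not None else max(0, triple.taahc.start - config.nterm_fallback_offset)
    end = min(len(sequence), triple.gdsggp.anchor_pos + config.cterm_extension)
    return ProteaseDomain(
        start=start,
        end=end,
        motifs=(triple.taahc, triple.dial, triple.gdsggp),
        nterm_motif_start=nterm,
    )


def find_truncated_cassette(
    sequence: str, config: PipelineConfig = DEFAULT_CONFIG
) -> ProteaseDomain | None:
    """Best partial catalytic cassette in a sequence with no full triple.

    Used for truncated gene models: a TAAHC (optionally followed by an
    in-window DIAL) whose remaining motifs would fall beyond the sequence
    end, or a DIAL+GDSGGP pair missing its TAAHC.  Returns a domain whose
    absent motif slots are ``None``, to be classified ``incomplete``.
    """
    taahc = scan_motif(sequence, "TAAHC", config.motif_tolerance)
    dial = scan_motif(sequence, "DIAL", config.motif_tolerance)
    gdsggp = scan_motif(sequence, "GDSGGP", config.motif_tolerance)

    def best(matches: list[MotifMatch]) -> MotifMatch | None:
        return min(
            matches, key=lambda m: (m.mismatches, not m.anchor_matches_canonical, m.start)
        ) if matches else None

    # C-terminal truncation: TAAHC [+ DIAL] present, GDSGGP absent
    for t in sorted(taahc, key=lambda m: (m.mismatches, m.start)):
        partners = [
            d
            for d in dial
            if config.taahc_dial_gap[0] <= d.start - t.end <= config.taahc_dial_gap[1]
        ]
        d = best(partners)
        motifs = (t, d, None)
        domain_start_anchor = t
        start = max(0, domain_start_anchor.start - config.nterm_fallback_offset)
        nterm = None
        for match in NTERM_RE.finditer(
            sequence, max(0, t.start - config.nterm_search_window), t.start
        ):
            nterm = match.start()
        if nterm is not None:
            start = nterm
        return ProteaseDomain(
            start=start, end=len(sequence), motifs=motifs, nterm_motif_start=nterm
        )
    # N-terminal truncation: GDSGGP present without an upstream TAAHC
    g = best(gdsggp)
    if g is not None:
        partners = [
            d
            for d in dial
            if config.dial_gdsggp_gap[0] <= g.start - d.end <= config.dial_gdsggp_gap[1]
        ]
        d = best(partners)
        end = min(len(sequence), g.anchor_pos + config.cterm_extension)
        return ProteaseDomain(start=0, end=end, motifs=(None, d, g))
    if dial:
        d = best(dial)
        return ProteaseDomain(start=0, end=len(sequence), motifs=(None, d, None))
    return None


def _build_aligner(config: PipelineConfig) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -config.gap_open
    aligner.extend_gap_score = -config.gap_extend
    # free end gaps: the domain typically lacks the reference's short
    # N-terminal chain, and may carry C-terminal extensions
    try:
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    except AttributeError:  # older Biopython
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    return aligner


def map_to_chymotrypsin_numbering(
    domain_sequence: str,
    reference: ChymotrypsinReference | None = None,
    config: PipelineConfig = DEFAULT_CONFIG,
    ser_anchor: int | None = None,
) -> NumberingMap:
    """Align a domain to the reference and read off position equivalences.

    ``ser_anchor`` is the domain-relative index of the GDSGGP catalytic Ser;
    when given, position 195 is forced onto it even if the alignment
    disagrees (the motif anchor wins) and the identity is recomputed.
    Identity below the configured floor sets the low-confidence flag; the
    map is still returned.
    """
    if reference is None:
        reference = load_reference()
    aligner = _build_aligner(config)
    alignment = aligner.align(reference.sequence, domain_sequence)[0]
    indices = alignment.indices  # 2 x columns, -1 at gaps
    ref_to_dom: dict[int, int] = {}
    matches = 0
    columns = indices.shape[1]
    for col in range(columns):
        ri, di = int(indices[0, col]), int(indices[1, col])
        if ri >= 0 and di >= 0:
            ref_to_dom[ri] = di
            if reference.sequence[ri] == domain_sequence[di]:
                matches += 1
    pairs: dict[int, int | None] = {
        pos: ref_to_dom.get(idx) for pos, idx in reference.numbering.items()
    }
    if ser_anchor is not None and pairs.get(195) != ser_anchor:
        old = pairs.get(195)
        ref_idx_195 = reference.numbering[195]
        if old is not None and reference.sequence[ref_idx_195] == domain_sequence[old]:
            matches -= 1
        if reference.sequence[ref_idx_195] == domain_sequence[ser_anchor]:
            matches += 1
        pairs[195] = ser_anchor
        # drop neighbours that break monotonicity around the forced anchor
        for pos, idx in pairs.items():
            if pos == 195 or idx is None:
                continue
            if (pos < 195 and idx >= ser_anchor) or (pos > 195 and idx <= ser_anchor):
                pairs[pos] = None
    identity = matches / columns if columns else 0.0
    return NumberingMap(
        pairs=pairs,
        alignment_identity=identity,
        low_confidence=identity < config.min_alignment_identity,
    )


def attach_numbering(
    sequence: str,
    domain: ProteaseDomain,
    reference: ChymotrypsinReference | None = None,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> None:
    """Compute and attach the numbering map for a delimited domain in place."""
    domain_seq = sequence[domain.start : domain.end]
    ser_anchor = (
        domain.gdsggp.anchor_pos - domain.start if domain.gdsggp is not None else None
    )
    domain.numbering = map_to_chymotrypsin_numbering(
        domain_seq, reference=reference, config=config, ser_anchor=ser_anchor
    )


def residue_at_numbered(sequence: str, domain: ProteaseDomain, position: int) -> str | None:
    """Residue of ``sequence`` at a chymotrypsin-numbered position, or None."""
    if domain.numbering is None:
        return None
    idx = domain.numbering.get(position)
    if idx is None:
        return None
    return sequence[domain.start + idx]


def classify_triad(sequence: str, domain: ProteaseDomain) -> TriadCall:
    """SP / SPH / incomplete from the catalytic anchors.

    Each triad residue is read at its motif anchor; when that motif is
    absent but the numbering map covers the canonical position, the mapped
    residue is used.  A triad region absent from the sequence altogether
    makes the call ``incomplete`` (severely truncated gene model).
    """
    canonical = {"TAAHC": ("H", 57, "His57"), "DIAL": ("D", 102, "Asp102"), "GDSGGP": ("S", 195, "Ser195")}
    oks: dict[str, bool | None] = {}
    substituted: set[str] = set()
    incomplete = False
    for motif, slot in zip(MOTIF_ORDER, domain.motifs):
        want, numbered_pos, label = canonical[motif]
        residue: str | None = None
        if slot is not None:
            residue = sequence[slot.anchor_pos]
        else:
            residue = residue_at_numbered(sequence, domain, numbered_pos)
        if residue is None:
            oks[motif] = None
            incomplete = True
        else:
            ok = residue == want
            oks[motif] = ok
            if not ok:
                substituted.add(label)
    if incomplete:
        klass = "incomplete"
    elif oks["TAAHC"] and oks["DIAL"] and oks["GDSGGP"]:
        klass = "SP"
    else:
        klass = "SPH"
    return TriadCall(
        klass=klass,
        his_ok=oks["TAAHC"],
        asp_ok=oks["DIAL"],
        ser_ok=oks["GDSGGP"],
        substituted=frozenset(substituted),
    )
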