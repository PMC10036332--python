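"""Synthetic proteins, gene panels and expression tables with planted truth.

Every generated artifact comes with a record of what was planted — triad
status, P1 residue, S1 residues, clip spans, accessory domains, cluster
memberships, per-comparison verdicts — so each pipeline stage can be scored
exactly without external data.

Two generator guarantees keep planted signals unambiguous: background
segments (signal peptides, linkers, accessory-domain filler, clip-cassette
filler) never contain Cys, so the planted cassettes are the only
six-cysteine patterns; and they never contain Ala, which removes the raw
material for chance catalytic-block look-alikes upstream of the protease
domain.  These are properties of the generator, not assumptions made by
any detector.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io_formats import ExpressionRecord, GeneLocus, ProteinRecord
from .protease import find_catalytic_motifs
from .reference import load_reference

#: background alphabet: 20 canonical residues minus Cys (no spurious clip
#: patterns) and Ala (no spurious catalytic-block matches)
BACKGROUND = "DEFGHIKLMNPQRSTVWY"

#: chymotrypsin-numbered positions the generator may override in the
#: reference-derived domain copy
_TRIAD_POSITIONS = {"his": 57, "asp": 102, "ser": 195}
_TRIAD_BROKEN = {"his": "R", "asp": "N", "ser": "A"}
_S1_POSITIONS = (189, 216, 226)

# independent copies of the classification tables, kept separate from the
# pipeline's own rule code so that recovery tests compare two routes
_ACT_TRYPSIN = set("RK")
_ACT_CHYMO = set("FYL")
_ACT_ELASTASE = set("AGVIMS")
_BULKY = set("VILFMW")


def _truth_activation(p1: str | None) -> str:
    if p1 is None:
        return "missing"
    if p1 in _ACT_TRYPSIN:
        return "trypsin_activated"
    if p1 in _ACT_CHYMO:
        return "chymotrypsin_activated"
    if p1 in _ACT_ELASTASE:
        return "elastase_activated"
    return "other"


def _truth_specificity(s1: tuple[str, str, str]) -> str:
    r189, r216, r226 = s1
    if r189 == "D" and r216 == "G" and r226 in "EAS":
        return "trypsin"
    if r189 in "ST" and r216 == "G" and r226 in "GAS":
        return "chymotrypsin"
    if r216 in _BULKY or r226 in _BULKY:
        return "elastase"
    return "other"


def _rle(labels: list[str]) -> str:
    parts, i = [], 0
    while i < len(labels):
        j = i
        while j < len(labels) and labels[j] == labels[i]:
            j += 1
        parts.append(labels[i] if j - i == 1 else f"{j - i}{labels[i]}")
        i = j
    return "-".join(parts)


@dataclass
class ProteinTruth:
    """Everything planted into one synthetic protein."""

    id: str
    triad_class: str  # SP | SPH
    triad_intact: tuple[bool, bool, bool]
    anchor_residues: tuple[str, str, str]
    p1_residue: str | None
    p1_pos: int | None
    s1_triple: tuple[str, str, str]
    activation_class: str
    specificity_class: str | None  # None for SPHs (never emitted)
    clip_count: int
    clip_spans: list[tuple[int, int]]
    accessory: list[tuple[str, int, int]]
    signal_peptide: bool
    category: str
    architecture: str
    domain_start: int

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _background(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(BACKGROUND), size=n)) if n > 0 else ""


def _clip_cassette(rng: np.random.Generator) -> tuple[str, tuple[int, ...]]:
    """Six cysteines with in-window gaps, exactly one CC doublet."""
    windows = [(8, 30), (5, 20), (2, 15), (2, 20), (2, 20)]
    doublet = int(rng.integers(0, 5))
    gaps = [
        1 if j == doublet else int(rng.integers(lo, hi + 1))
        for j, (lo, hi) in enumerate(windows)
    ]
    seq = "C"
    cys = [0]
    for gap in gaps:
        seq += _background(rng, gap - 1) + "C"
        cys.append(cys[-1] + gap)
    return seq, tuple(cys)


def make_protease(
    seed: int,
    triad_intact: tuple[bool, bool, bool] = (True, True, True),
    p1_residue: str | None = "R",
    s1_triple: tuple[str, str, str] = ("D", "G", "S"),
    n_clips: int = 0,
    accessory_spec: Sequence[str] = (),
    signal_peptide: bool = False,
    protein_id: str = "syn1",
    extra_mutations: int = 0,
) -> tuple[ProteinRecord, ProteinTruth]:
    """Build one synthetic zymogen and record its planted truth.

    Layout: [signal] [accessory domains] [clip cassettes] linker, then the
    planted P1 residue, an IVGG mature N-terminus and a copy of the bundled
    chymotrypsin reference carrying the requested triad and S1 residues at
    their canonical numbered positions.  Deterministic for a given seed.
    ``p1_residue=None`` plants a protein whose mature chain starts at
    position 0, which requires no upstream elements at all.
    """
    if not 0 <= n_clips <= 5:
        raise ValueError("n_clips must be in [0, 5]")
    if p1_residue is None and (signal_peptide or n_clips or list(accessory_spec)):
        raise ValueError(
            "a protein lacking the P1 residue starts at its mature N-terminus "
            "and cannot carry upstream elements"
        )
    rng = np.random.default_rng(seed)
    ref = load_reference()

    # reference-derived domain: chymotrypsin positions 16..245 with overrides
    slice_offset = ref.numbering[16]
    domain = list(ref.sequence[slice_offset:])
    domain[0:4] = list("IVGG")
    anchors = []
    for intact, name in zip(triad_intact, ("his", "asp", "ser")):
        pos = _TRIAD_POSITIONS[name]
        canonical = ref.residue_at(pos)
        residue = canonical if intact else _TRIAD_BROKEN[name]
        domain[ref.numbering[pos] - slice_offset] = residue
        anchors.append(residue)
    for pos, residue in zip(_S1_POSITIONS, s1_triple):
        domain[ref.numbering[pos] - slice_offset] = residue
    if extra_mutations:
        protected = {0, 1, 2, 3}
        for pos in list(_TRIAD_POSITIONS.values()) + list(_S1_POSITIONS):
            protected.add(ref.numbering[pos] - slice_offset)
        for chymo in range(54, 59):  # TAAHC block
            protected.add(ref.numbering[chymo] - slice_offset)
        for chymo in range(102, 106):  # DIAL block
            protected.add(ref.numbering[chymo] - slice_offset)
        for chymo in range(193, 199):  # GDSGGP block
            protected.add(ref.numbering[chymo] - slice_offset)
        free = [i for i in range(len(domain)) if i not in protected]
        for idx in rng.choice(free, size=min(extra_mutations, len(free)), replace=False):
            domain[idx] = str(rng.choice(list(BACKGROUND.replace(domain[idx], ""))))

    domain_str = "".join(domain)
    # offset of the planted TAAHC block within the domain copy
    taahc_offset = ref.numbering[54] - slice_offset

    # Assemble the upstream region, re-drawing it in the rare event that
    # background + cassette residues spell out a chance catalytic-block
    # triple of their own (the generator guarantee that planted cassettes
    # are the only catalytic signals is enforced, not merely probable).
    for _attempt in range(50):
        prefix = ""
        accessory = []
        clip_spans = []
        labels = []
        if signal_peptide:
            prefix += "M" + _background(rng, 17)
        for label in accessory_spec:
            prefix += _background(rng, int(rng.integers(4, 11)))
            start = len(prefix)
            prefix += _background(rng, 40)
            accessory.append((label, start, len(prefix)))
            labels.append(label)
        for _ in range(n_clips):
            prefix += _background(rng, int(rng.integers(4, 11)))
            cassette, cys = _clip_cassette(rng)
            start = len(prefix)
            prefix += cassette
            clip_spans.append((start, start + cys[-1] + 1))
            labels.append("clip")
        if p1_residue is not None:
            prefix += _background(rng, int(rng.integers(6, 16)))
            prefix += p1_residue
        sequence = prefix + domain_str
        triples = find_catalytic_motifs(sequence)
        if len(triples) == 1 and triples[0].taahc.start == len(prefix) + taahc_offset:
            break
    else:  # pragma: no cover - would need 50 consecutive chance collisions
        raise RuntimeError("could not draw an upstream region free of decoy motifs")

    domain_start = len(prefix)
    record = ProteinRecord(
        id=protein_id,
        sequence=sequence,
        external_domains=list(accessory),
        signal_peptide=signal_peptide,
    )

    triad_class = "SP" if all(triad_intact) else "SPH"
    category = (
        ("cSP" if n_clips else "SP") if triad_class == "SP" else ("cSPH" if n_clips else "SPH")
    )
    labels.append("PD" if triad_class == "SP" else "PLD")
    if signal_peptide:
        labels.insert(0, "S")
    truth = ProteinTruth(
        id=protein_id,
        triad_class=triad_class,
        triad_intact=tuple(triad_intact),
        anchor_residues=tuple(anchors),
        p1_residue=p1_residue,
        p1_pos=domain_start - 1 if p1_residue is not None else None,
        s1_triple=tuple(s1_triple),
        activation_class=_truth_activation(p1_residue),
        specificity_class=_truth_specificity(tuple(s1_triple)) if triad_class == "SP" else None,
        clip_count=n_clips,
        clip_spans=clip_spans,
        accessory=accessory,
        signal_peptide=signal_peptide,
        category=category,
        architecture=_rle(labels),
        domain_start=domain_start,
    )
    return record, truth


# ---------------------------------------------------------------------------
# combination sweep and family-census panels


@dataclass(frozen=True)
class ProteinSpec:
    triad_intact: tuple[bool, bool, bool]
    p1_residue: str | None
    s1_triple: tuple[str, str, str]
    n_clips: int
    accessory: tuple[str, ...] = ()
    signal_peptide: bool = True


_ACTIVATION_EXEMPLARS: dict[str, str | None] = {
    "trypsin_activated": "K",
    "chymotrypsin_activated": "F",
    "elastase_activated": "A",
    "other": "W",
    "missing": None,
}

_SPECIFICITY_EXEMPLARS: dict[str, tuple[str, str, str]] = {
    "trypsin": ("D", "G", "S"),
    "chymotrypsin": ("S", "G", "A"),
    "elastase": ("A", "V", "T"),
    "other": ("A", "G", "N"),
}

_SPH_BREAKS = [(False, True, True), (True, False, True), (True, True, False)]


def sweep_specs(replicates: int = 5) -> list[ProteinSpec]:
    """Every category x activation x specificity combination, replicated.

    Clip-bearing categories cannot combine with a missing P1 (a clip sits
    upstream of the cleavage site), and specificity applies only to intact
    triads; all other combinations appear once per replicate with varied
    clip counts and broken-triad residues.
    """
    specs: list[ProteinSpec] = []
    for rep in range(replicates):
        accessory = ("LDLA", "LDLA", "CCP") if rep % 3 == 2 else ()
        for act, p1 in _ACTIVATION_EXEMPLARS.items():
            for clipped in (True, False):
                n_clips = 1 + rep % 3 if clipped else 0
                if p1 is None and clipped:
                    continue  # a clip upstream implies a P1 residue exists
                upstream_ok = p1 is not None
                # intact-triad (SP/cSP) combinations, one per specificity class
                for s1 in _SPECIFICITY_EXEMPLARS.values():
                    specs.append(
                        ProteinSpec(
                            triad_intact=(True, True, True),
                            p1_residue=p1,
                            s1_triple=s1,
                            n_clips=n_clips,
                            accessory=accessory if upstream_ok else (),
                            signal_peptide=upstream_ok,
                        )
                    )
                # broken-triad (SPH/cSPH) combination, rotating the broken residue
                specs.append(
                    ProteinSpec(
                        triad_intact=_SPH_BREAKS[rep % 3],
                        p1_residue=p1,
                        s1_triple=("D", "G", "S"),
                        n_clips=n_clips,
                        accessory=accessory if upstream_ok else (),
                        signal_peptide=upstream_ok,
                    )
                )
    return specs


def generate_panel(
    seed: int, specs: Sequence[ProteinSpec], id_prefix: str = "syn"
) -> tuple[list[ProteinRecord], list[ProteinTruth]]:
    """Instantiate one protein per spec with per-protein derived seeds."""
    seeds = np.random.SeedSequence(seed).generate_state(len(specs))
    records, truths = [], []
    for i, (spec, sub) in enumerate(zip(specs, seeds), start=1):
        rec, truth = make_protease(
            seed=int(sub % (2**31)),
            triad_intact=spec.triad_intact,
            p1_residue=spec.p1_residue,
            s1_triple=spec.s1_triple,
            n_clips=spec.n_clips,
            accessory_spec=spec.accessory,
            signal_peptide=spec.signal_peptide,
            protein_id=f"{id_prefix}{i:03d}",
        )
        records.append(rec)
        truths.append(truth)
    return records, truths


def family_census_specs() -> list[ProteinSpec]:
    """A 177-protein panel with the *O. furnacalis* family composition.

    Categories 29 cSP / 105 SP / 9 cSPH / 34 SPH; clip multiplicities one
    quintuple-, five double- and 23 single-clip cSPs, one triple-, one
    double- and seven single-clip cSPHs; activation classes 114 trypsin- /
    16 chymotrypsin- / 21 elastase-activated, 21 with another P1 residue
    and 5 lacking P1; S1 specificity 80 trypsin / 34 chymotrypsin /
    6 elastase / 14 other among the 134 intact proteases.
    """
    categories = ["cSP"] * 29 + ["SP"] * 105 + ["cSPH"] * 9 + ["SPH"] * 34
    clip_counts = ([5] + [2] * 5 + [1] * 23) + [0] * 105 + ([3] + [2] + [1] * 7) + [0] * 34

    # activation residues hitting 114/16/21/21 plus five missing-P1 slots
    trypsin = (["K", "R"] * 57)[:114]
    chymo = (["F", "Y", "L"] * 6)[:16]
    elastase = (["A", "G", "V", "I", "M", "S"] * 4)[:21]
    other = (["W", "N", "Q", "H", "T", "E", "D", "P"] * 3)[:21]
    p1_by_slot: list[str | None] = [None] * 5 + trypsin + chymo + elastase + other
    assert len(p1_by_slot) == 177

    specificity = (
        [_SPECIFICITY_EXEMPLARS["trypsin"]] * 80
        + [_SPECIFICITY_EXEMPLARS["chymotrypsin"]] * 34
        + [_SPECIFICITY_EXEMPLARS["elastase"]] * 6
        + [_SPECIFICITY_EXEMPLARS["other"]] * 14
    )  # one per intact-triad protein (29 cSP + 105 SP = 134)

    specs: list[ProteinSpec] = []
    sp_slots = [i for i, cat in enumerate(categories) if cat in ("cSP", "SP")]
    sph_rotation = 0
    # missing-P1 slots: five clip-free SP proteins (indices 29..33)
    missing_slots = set(range(29, 34))
    p1_iter = iter(p1_by_slot[5:])
    spec_iter = iter(specificity)
    for i, cat in enumerate(categories):
        intact = cat in ("cSP", "SP")
        if intact:
            s1 = next(spec_iter)
            triad = (True, True, True)
        else:
            s1 = ("D", "G", "S")
            triad = _SPH_BREAKS[sph_rotation % 3]
            sph_rotation += 1
        p1 = None if i in missing_slots else next(p1_iter)
        specs.append(
            ProteinSpec(
                triad_intact=triad,
                p1_residue=p1,
                s1_triple=s1,
                n_clips=clip_counts[i],
                signal_peptide=p1 is not None,
            )
        )
    return specs


# ---------------------------------------------------------------------------
# gene panels for duplication clustering


@dataclass
class PanelTruth:
    clusters: list[set[str]] = field(default_factory=list)


def make_gene_panel(
    seed: int,
    cluster_specs: Sequence[tuple[int, float]] = ((9, 0.05),),
    n_singletons: int = 6,
    gene_length: int = 300,
) -> tuple[list[ProteinRecord], PanelTruth]:
    """Scaffold panels of tandem-duplicate clusters plus unrelated singletons.

    Each cluster spec is (size, per-site mutation rate): members are mutated
    copies of one seed sequence placed adjacently on their own scaffold;
    singletons are independent random sequences appended downstream.
    """
    rng = np.random.default_rng(seed)
    alphabet = list("ACDEFGHIKLMNPQRSTVWY")
    records: list[ProteinRecord] = []
    truth = PanelTruth()

    def random_seq(n: int) -> str:
        return "".join(rng.choice(alphabet, size=n))

    def mutate(seq: str, rate: float) -> str:
        out = list(seq)
        for i in range(len(out)):
            if rng.random() < rate:
                out[i] = str(rng.choice([a for a in alphabet if a != out[i]]))
        return "".join(out)

    gene_no = 0
    for k, (size, rate) in enumerate(cluster_specs, start=1):
        scaffold = f"scaffold_{k}"
        seed_seq = random_seq(gene_length)
        members: set[str] = set()
        pos = 1000
        for _ in range(size):
            gene_no += 1
            gid = f"g{gene_no:03d}"
            members.add(gid)
            records.append(
                ProteinRecord(
                    id=gid,
                    sequence=mutate(seed_seq, rate),
                    locus=GeneLocus(scaffold, pos, pos + 900, "+" if gene_no % 2 else "-"),
                )
            )
            pos += 2000
        # unrelated singletons downstream on the same scaffold
        for _ in range(max(0, n_singletons // max(1, len(cluster_specs)))):
            gene_no += 1
            gid = f"g{gene_no:03d}"
            records.append(
                ProteinRecord(
                    id=gid,
                    sequence=random_seq(gene_length),
                    locus=GeneLocus(scaffold, pos, pos + 900, "+"),
                )
            )
            pos += 2000
        if size >= 2:
            truth.clusters.append(members)
    return records, truth


# ---------------------------------------------------------------------------
# expression tables


def make_expression_table(
    seed: int,
    genes: Sequence[str],
    pairs: Sequence[tuple[str, str]],
    planted: dict[tuple[str, str], dict[str, Sequence[str]]] | None = None,
) -> tuple[list[ExpressionRecord], dict[tuple[str, tuple[str, str]], str]]:
    """Per-gene per-pair statistics with planted up/down verdicts.

    ``planted`` maps a pair to {"up": genes, "down": genes}; everything else
    is null.  Planted effects get |log2 ratio| >= 1.2 with q <= 0.04, nulls
    get q >= 0.05, so the threshold classifier recovers the planted verdicts
    exactly.  Deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    planted = planted or {}
    records: list[ExpressionRecord] = []
    truth: dict[tuple[str, tuple[str, str]], str] = {}
    for pair in pairs:
        up = set(planted.get(pair, {}).get("up", ()))
        down = set(planted.get(pair, {}).get("down", ()))
        overlap = up & down
        if overlap:
            raise ValueError(f"genes planted both up and down in {pair}: {sorted(overlap)}")
        for gene in genes:
            if gene in up or gene in down:
                magnitude = 1.2 + 2.8 * rng.random()
                log2 = magnitude if gene in up else -magnitude
                q = 0.04 * rng.random()
                verdict = "up" if gene in up else "down"
            else:
                log2 = rng.normal(0.0, 0.25)
                q = rng.uniform(0.05, 1.0)
                verdict = "ns"
            records.append(
                ExpressionRecord(gene=gene, comparison=tuple(pair), log2_ratio=float(log2), q_value=float(q))
            )
            truth[(gene, tuple(pair))] = verdict
    return records, truth
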