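"""Zymogen activation-site calling and S1-pocket specificity prediction.

Family members are synthesized as inactive zymogens and switched on by
cleavage of one peptide bond.  The residue on the N-terminal side of that
bond (P1) determines which protease class performs the activation; the
three S1-pocket residues (chymotrypsin numbering 189, 216, 226) determine
the substrate specificity of the enzyme itself.  Both classifications are
small, total rule tables.
"""

from __future__ import annotations

from dataclasses import dataclass

from .config import DEFAULT_CONFIG, PipelineConfig
from .io_formats import ALPHABET
from .protease import NTERM_RE, ProteaseDomain

#: P1 residue -> activating protease class
TRYPSIN_P1 = frozenset("RK")
CHYMOTRYPSIN_P1 = frozenset("FYL")
ELASTASE_P1 = frozenset("AGVIMS")

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class ActivationSite:
    p1_pos: int | None
    p1_residue: str | None
    activation_class: str  # trypsin_activated | chymotrypsin_activated | elastase_activated | other | missing


@dataclass(frozen=True)
class S1Pocket:
    res189: str
    res216: str
    res226: str
    specificity_class: str  # trypsin | chymotrypsin | elastase | other | undetermined


def locate_activation_site(sequence: str, domain: ProteaseDomain) -> ActivationSite:
    """Find the P1 residue of the activation cleavage site.

    The mature N-terminus is taken as the protein position mapped from
    chymotrypsin position 16 (the canonical Ile16); when the alignment left
    16 unmapped, fall back to the [ILV][ILV]GG match used to delimit the
    domain, then to the domain start.  P1 is the residue immediately
    upstream; it is absent when the mature chain starts the protein.
    """
    mature_start: int | None = None
    if domain.numbering is not None:
        idx16 = domain.numbering.get(16)
        if idx16 is not None:
            mature_start = domain.start + idx16
    if mature_start is None and domain.nterm_motif_start is not None:
        mature_start = domain.nterm_motif_start
    if mature_start is None:
        mature_start = domain.start
    if mature_start <= 0:
        return ActivationSite(p1_pos=None, p1_residue=None, activation_class="missing")
    p1_pos = mature_start - 1
    p1 = sequence[p1_pos]
    return ActivationSite(
        p1_pos=p1_pos, p1_residue=p1, activation_class=classify_activation(p1)
    )


def classify_activation(p1_residue: str | None) -> str:
    """Map a P1 residue to its activating protease class.

    Arg/Lys -> trypsin-activated; Phe/Tyr/Leu -> chymotrypsin-activated;
    Ala/Gly/Val/Ile/Met/Ser -> elastase-activated; anything else -> other;
    absent -> missing.
    """
    if p1_residue is None:
        return "missing"
    if len(p1_residue) != 1 or p1_residue not in ALPHABET:
        raise ValueError(f"invalid P1 residue {p1_residue!r}")
    if p1_residue in TRYPSIN_P1:
        return "trypsin_activated"
    if p1_residue in CHYMOTRYPSIN_P1:
        return "chymotrypsin_activated"
    if p1_residue in ELASTASE_P1:
        return "elastase_activated"
    return "other"


def classify_specificity(
    res189: str,
    res216: str,
    res226: str,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> str:
    """Predict S1-pocket substrate specificity from residues 189/216/226.

    Rule order: any gap -> undetermined; Asp189+Gly216+Glu/Ala/Ser226 ->
    trypsin; Ser/Thr189+Gly216+Gly/Ala/Ser226 -> chymotrypsin; a larger
    nonpolar residue at 216 or 226 -> elastase; else other.  The first two
    rules are disjoint (position 189 differs); elastase is deliberately a
    fallback so that e.g. (D, G, A) stays trypsin.
    """
    triple = (res189, res216, res226)
    if "gap" in triple:
        return "undetermined"
    for r in triple:
        if len(r) != 1 or r not in ALPHABET:
            raise ValueError(f"invalid S1 residue {r!r}")
    if res189 == "D" and res216 == "G" and res226 in "EAS":
        return "trypsin"
    if res189 in "ST" and res216 == "G" and res226 in "GAS":
        return "chymotrypsin"
    if res216 in config.bulky_set or res226 in config.bulky_set:
        return "elastase"
    return "other"


def s1_pocket(
    sequence: str,
    domain: ProteaseDomain,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> S1Pocket:
    """Read the S1 residues off the numbering map and classify them."""
    from .protease import residue_at_numbered

    residues = []
    for pos in (189, 216, 226):
        r = residue_at_numbered(sequence, domain, pos)
        residues.append("gap" if r is None else r)
    res189, res216, res226 = residues
    return S1Pocket(
        res189=res189,
        res216=res216,
        res226=res226,
        specificity_class=classify_specificity(res189, res216, res226, config=config),
    )
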