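"""Bundled chymotrypsin reference used for residue numbering.

The family-wide convention for naming positions (His57, Asp102, Ser195,
S1-pocket residues 189/216/226, activation residue Ile16) is the residue
numbering of bovine chymotrypsin(ogen) A.  The package ships the mature
enzyme sequence (the zymogen minus the two activation dipeptides 14-15 and
147-148) plus a two-column table mapping each canonical position to its
0-based index in that sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

from Bio import SeqIO


@dataclass(frozen=True)
class ChymotrypsinReference:
    sequence: str
    #: chymotrypsin position -> 0-based index into ``sequence``
    numbering: dict[int, int]

    def residue_at(self, position: int) -> str:
        return self.sequence[self.numbering[position]]


@lru_cache(maxsize=1)
def load_reference() -> ChymotrypsinReference:
    data = resources.files("spfam.data")
    with resources.as_file(data / "chymotrypsin_a_mature.fasta") as fasta_path:
        record = next(SeqIO.parse(str(fasta_path), "fasta"))
    sequence = str(record.seq)
    numbering: dict[int, int] = {}
    table = (data / "chymotrypsin_numbering.tsv").read_text().splitlines()
    for line in table[1:]:
        pos, idx = line.split("\t")
        numbering[int(pos)] = int(idx)
    if len(numbering) != len(sequence):
        raise RuntimeError("numbering table does not cover the reference sequence")
    return ChymotrypsinReference(sequence=sequence, numbering=numbering)
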