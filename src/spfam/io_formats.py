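"""Readers and writers for the formats the pipeline touches.

Protein FASTA, gene loci (GFF3 or 5-column TSV), external domain tables,
signal-peptide flags, expression statistics tables, and the pipeline's own
per-protein annotation TSV.

Internally all sequence coordinates are 0-based half-open; every file and
error message uses 1-based inclusive positions, which is what a biologist
reading the output expects.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

#: the 20 canonical residues plus X for unknown
ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

#: accessory (non-protease) domain labels accepted in external tables
DOMAIN_LABELS = frozenset(
    {"S", "TM", "LDLA", "Fz", "CCP", "CUB", "TSP", "SR", "Gd", "SEA", "CBD"}
)


@dataclass(frozen=True)
class GeneLocus:
    """Genomic location of a gene: scaffold, 1-based inclusive span, strand."""

    scaffold: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not self.scaffold:
            raise ValueError("scaffold name must be non-empty")
        if self.start > self.end:
            raise ValueError(
                f"locus start {self.start} > end {self.end} on {self.scaffold}"
            )
        if self.strand not in {"+", "-"}:
            raise ValueError(f"unknown strand symbol {self.strand!r}")


@dataclass
class ProteinRecord:
    """One protein sequence plus optional locus and external annotations."""

    id: str
    sequence: str
    locus: GeneLocus | None = None
    external_domains: list[tuple[str, int, int]] = field(default_factory=list)
    signal_peptide: bool | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.id}: empty sequence")
        for pos, residue in enumerate(self.sequence):
            if residue not in ALPHABET:
                raise ValueError(
                    f"{self.id}: non-alphabet residue {residue!r} at position {pos + 1}"
                )
        for label, start, end in self.external_domains:
            if label not in DOMAIN_LABELS:
                raise ValueError(f"{self.id}: unknown domain label {label!r}")
            if not (0 <= start < end <= len(self.sequence)):
                raise ValueError(
                    f"{self.id}: domain {label} span [{start + 1}, {end}] outside sequence"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ExpressionRecord:
    """Per-gene statistics for one ordered pairwise comparison."""

    gene: str
    comparison: tuple[str, str]
    log2_ratio: float
    q_value: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.q_value <= 1.0:
            raise ValueError(f"{self.gene}: q-value {self.q_value} outside [0, 1]")
        if self.comparison[0] == self.comparison[1]:
            raise ValueError(f"{self.gene}: comparison labels must differ")


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA into :class:`ProteinRecord` objects.

    Ids are the first whitespace-delimited header token; sequences are
    uppercased and trailing ``*`` stop characters stripped.  Duplicate ids
    and non-alphabet residues are errors.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise ValueError(f"{path}: duplicate sequence id {entry.id!r}")
        seen.add(entry.id)
        seq = str(entry.seq).upper().rstrip("*")
        records.append(ProteinRecord(id=entry.id, sequence=seq))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as handle:
        for rec in records:
            handle.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                handle.write(rec.sequence[i : i + width] + "\n")


def collapse_isoforms(
    records: Sequence[ProteinRecord], gene_of: Mapping[str, str] | None = None
) -> list[ProteinRecord]:
    """Keep one sequence per gene: the longest, ties to the smallest id.

    ``gene_of`` maps protein id -> gene id; proteins not in the map (or when
    no map is given) are treated as their own gene.  Output preserves the
    first-appearance order of the kept records.
    """
    best: dict[str, ProteinRecord] = {}
    order: list[str] = []
    for rec in records:
        gene = gene_of.get(rec.id, rec.id) if gene_of else rec.id
        cur = best.get(gene)
        if cur is None:
            best[gene] = rec
            order.append(gene)
        elif len(rec.sequence) > len(cur.sequence) or (
            len(rec.sequence) == len(cur.sequence) and rec.id < cur.id
        ):
            # longer wins; on equal length the lexicographically smaller id wins
            best[gene] = rec
    return [best[g] for g in order]


def read_gene_loci(path: str | Path, dialect: str = "tsv") -> dict[str, GeneLocus]:
    """Read gene loci keyed by gene id.

    ``tsv`` dialect: 5 columns (id, scaffold, start, end, strand), header
    optional.  ``gff3`` dialect: ``gene`` features keyed by their ``ID``
    attribute.  Coordinates are kept 1-based inclusive exactly as given.
    """
    path = Path(path)
    loci: dict[str, GeneLocus] = {}
    if dialect == "tsv":
        with open(path) as handle:
            for lineno, line in enumerate(handle, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if fields[0] in {"id", "gene", "gene_id"}:  # header row
                    continue
                if len(fields) < 5:
                    raise ValueError(f"{path}:{lineno}: expected 5 columns, got {len(fields)}")
                gene, scaffold, start, end, strand = fields[:5]
                loci[gene] = GeneLocus(scaffold, int(start), int(end), strand)
    elif dialect == "gff3":
        with open(path) as handle:
            for lineno, line in enumerate(handle, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) != 9:
                    raise ValueError(f"{path}:{lineno}: malformed GFF3 line")
                if fields[2] != "gene":
                    continue
                attrs = dict(
                    kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
                )
                gene = attrs.get("ID")
                if gene is None:
                    raise ValueError(f"{path}:{lineno}: gene feature without ID attribute")
                loci[gene] = GeneLocus(fields[0], int(fields[3]), int(fields[4]), fields[6])
    else:
        raise ValueError(f"unknown loci dialect {dialect!r}")
    return loci


def read_domain_table(path: str | Path) -> dict[str, list[tuple[str, int, int]]]:
    """Read an external domain-annotation TSV: protein id, label, start, end.

    Coordinates in the file are 1-based inclusive; returned spans are 0-based
    half-open.
    """
    out: dict[str, list[tuple[str, int, int]]] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] in {"id", "protein", "protein_id"}:
                continue
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns, got {len(fields)}")
            pid, label, start, end = fields[0], fields[1], int(fields[2]), int(fields[3])
            if label not in DOMAIN_LABELS:
                raise ValueError(f"{path}:{lineno}: unknown domain label {label!r}")
            out.setdefault(pid, []).append((label, start - 1, end))
    return out


def read_signal_flags(path: str | Path) -> dict[str, bool]:
    """Read signal-peptide flags: TSV of protein id, {0,1,true,false,yes,no}."""
    truthy = {"1", "true", "yes", "y"}
    falsy = {"0", "false", "no", "n"}
    out: dict[str, bool] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] in {"id", "protein", "protein_id"}:
                continue
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            flag = fields[1].strip().lower()
            if flag in truthy:
                out[fields[0]] = True
            elif flag in falsy:
                out[fields[0]] = False
            else:
                raise ValueError(f"{path}:{lineno}: unrecognized flag {fields[1]!r}")
    return out


EXPRESSION_COLUMNS = ["gene", "comparison_a", "comparison_b", "log2_ratio", "q_value"]


def read_expression_table(path: str | Path) -> list[ExpressionRecord]:
    """Read a per-gene per-comparison statistics TSV.

    Expected columns: gene, comparison_a, comparison_b, log2_ratio, q_value.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValueError(f"{path}: cannot parse expression table: {exc}") from exc
    missing = [c for c in EXPRESSION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing expression columns {missing}")
    records = []
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        try:
            records.append(
                ExpressionRecord(
                    gene=str(row.gene),
                    comparison=(str(row.comparison_a), str(row.comparison_b)),
                    log2_ratio=float(row.log2_ratio),
                    q_value=float(row.q_value),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return records


def write_expression_table(records: Iterable[ExpressionRecord], path: str | Path) -> None:
    rows = [
        (r.gene, r.comparison[0], r.comparison[1], r.log2_ratio, r.q_value)
        for r in records
    ]
    pd.DataFrame(rows, columns=EXPRESSION_COLUMNS).to_csv(path, sep="\t", index=False)


ANNOTATION_COLUMNS = [
    "id",
    "triad_class",
    "his_ok",
    "asp_ok",
    "ser_ok",
    "p1_residue",
    "activation_class",
    "res189",
    "res216",
    "res226",
    "specificity_class",
    "clip_count",
    "architecture",
    "scaffold",
    "start",
    "end",
    "strand",
]


def write_annotation_table(annotations: Sequence, path: str | Path) -> None:
    """Write per-protein verdicts as a TSV with a fixed column order.

    ``annotations`` are :class:`spfam.clip.SPAnnotation` objects; absent
    values are rendered as ``NA``.
    """

    def na(value) -> str:
        return "NA" if value is None else str(value)

    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(ANNOTATION_COLUMNS)
        for ann in annotations:
            locus = ann.locus
            writer.writerow(
                [
                    ann.id,
                    ann.triad_class,
                    na(ann.his_ok),
                    na(ann.asp_ok),
                    na(ann.ser_ok),
                    na(ann.p1_residue),
                    na(ann.activation_class),
                    na(ann.res189),
                    na(ann.res216),
                    na(ann.res226),
                    na(ann.specificity_class),
                    ann.clip_count,
                    ann.architecture,
                    na(locus.scaffold if locus else None),
                    na(locus.start if locus else None),
                    na(locus.end if locus else None),
                    na(locus.strand if locus else None),
                ]
            )


def read_annotation_table(path: str | Path) -> list[dict]:
    """Read back an annotation TSV as typed dicts (``NA`` -> None)."""

    def parse(col: str, value: str):
        if value == "NA":
            return None
        if col in {"his_ok", "asp_ok", "ser_ok"}:
            return value == "True"
        if col in {"clip_count", "start", "end"}:
            return int(value)
        return value

    rows: list[dict] = []
    with open(path) as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        if reader.fieldnames != ANNOTATION_COLUMNS:
            raise ValueError(f"{path}: unexpected annotation columns {reader.fieldnames}")
        for raw in reader:
            rows.append({col: parse(col, raw[col]) for col in ANNOTATION_COLUMNS})
    return rows
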