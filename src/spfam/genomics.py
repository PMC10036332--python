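"""Tandem duplication clustering from scaffold loci and sequence identity.

Gene-family expansion by unequal crossing over leaves near-identical
paralogs sitting next to each other on a scaffold.  Two genes form a
qualifying duplicate pair when they lie on the same scaffold with at most
``window_genes`` family genes between them and their global-alignment
percent identity reaches ``min_identity``; clusters are the connected
components of the qualifying-pair graph with at least two members.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .config import DEFAULT_CONFIG, PipelineConfig
from .io_formats import ProteinRecord


@dataclass(frozen=True)
class DuplicationCluster:
    scaffold: str
    members: tuple[str, ...]  # gene ids in genomic order
    pairs: tuple[tuple[str, str, float], ...]  # (idA, idB, identity)


def _identity_aligner(config: PipelineConfig) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -config.gap_open
    aligner.extend_gap_score = -config.gap_extend
    return aligner


def pairwise_identity(
    seq_a: str, seq_b: str, config: PipelineConfig = DEFAULT_CONFIG
) -> float:
    """Global-alignment percent identity: matches / alignment columns."""
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    alignment = _identity_aligner(config).align(seq_a, seq_b)[0]
    indices = alignment.indices
    columns = indices.shape[1]
    matches = 0
    for col in range(columns):
        ai, bi = int(indices[0, col]), int(indices[1, col])
        if ai >= 0 and bi >= 0 and seq_a[ai] == seq_b[bi]:
            matches += 1
    return matches / columns if columns else 0.0


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def find_duplication_clusters(
    records: Sequence[ProteinRecord],
    window_genes: int | None = None,
    min_identity: float | None = None,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> list[DuplicationCluster]:
    """Connected components of the qualifying tandem-duplicate pair graph.

    Genomic order within a scaffold is by (start, end, id); a pair
    qualifies when at most ``window_genes`` family genes lie between the
    two and their identity is at least ``min_identity``.  Output is
    independent of input order and sorted by (scaffold, first member).
    """
    if window_genes is None:
        window_genes = config.window_genes
    if min_identity is None:
        min_identity = config.min_identity
    if window_genes < 1:
        raise ValueError("window_genes must be >= 1")
    for rec in records:
        if rec.locus is None:
            raise ValueError(f"gene {rec.id} has no locus")

    by_scaffold: dict[str, list[ProteinRecord]] = {}
    for rec in records:
        by_scaffold.setdefault(rec.locus.scaffold, []).append(rec)

    clusters: list[DuplicationCluster] = []
    for scaffold in sorted(by_scaffold):
        genes = sorted(
            by_scaffold[scaffold], key=lambda r: (r.locus.start, r.locus.end, r.id)
        )
        uf = _UnionFind([g.id for g in genes])
        pair_list: list[tuple[str, str, float]] = []
        for i, a in enumerate(genes):
            for j in range(i + 1, min(len(genes), i + window_genes + 2)):
                b = genes[j]
                # j - i - 1 genes intervene in scaffold order
                identity = pairwise_identity(a.sequence, b.sequence, config=config)
                if identity >= min_identity:
                    uf.union(a.id, b.id)
                    pair_list.append((a.id, b.id, identity))
        components: dict[str, list[str]] = {}
        for g in genes:
            components.setdefault(uf.find(g.id), []).append(g.id)
        for root in components:
            members = components[root]
            if len(members) < 2:
                continue
            member_set = set(members)
            clusters.append(
                DuplicationCluster(
                    scaffold=scaffold,
                    members=tuple(members),  # already in genomic order
                    pairs=tuple(
                        p for p in pair_list if p[0] in member_set and p[1] in member_set
                    ),
                )
            )
    clusters.sort(key=lambda c: (c.scaffold, c.members[0]))
    return clusters


def clusters_to_rows(clusters: Sequence[DuplicationCluster]) -> list[tuple[str, int, str]]:
    """Flatten clusters to (gene, cluster id, scaffold) rows for TSV output."""
    rows = []
    for k, cluster in enumerate(clusters, start=1):
        for gene in cluster.members:
            rows.append((gene, k, cluster.scaffold))
    return rows
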