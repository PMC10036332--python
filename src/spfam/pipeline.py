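"""End-to-end per-protein annotation: motifs -> numbering -> verdicts.

Glues the stage modules together into the single-protein and whole-panel
entry points the CLI and downstream analyses use.
"""

from __future__ import annotations

from typing import Mapping, Sequence

from .clip import SPAnnotation, compose_architecture, detect_clip_domains, tally_categories
from .config import DEFAULT_CONFIG, PipelineConfig
from .io_formats import GeneLocus, ProteinRecord
from .protease import (
    ProteaseDomain,
    attach_numbering,
    classify_triad,
    delimit_domain,
    find_catalytic_motifs,
    find_truncated_cassette,
)
from .reference import ChymotrypsinReference, load_reference
from .zymogen import locate_activation_site, s1_pocket

SUMMARY_SCHEMA_VERSION = 1


def annotate_protein(
    record: ProteinRecord,
    config: PipelineConfig = DEFAULT_CONFIG,
    reference: ChymotrypsinReference | None = None,
) -> SPAnnotation:
    """Run every annotation stage on one protein.

    Multiple catalytic cassettes yield multiple protease domains (PD/PLD
    each); the protein-level triad class is SP when any domain carries an
    intact triad.  Activation is read upstream of the N-terminal-most
    domain, the S1 pocket from the first intact-triad domain, and clips
    are searched upstream of the first domain.  A protein with no complete
    cassette is classified incomplete and excluded from category tallies.
    """
    if reference is None:
        reference = load_reference()
    seq = record.sequence
    triples = find_catalytic_motifs(seq, config)
    domains: list[ProteaseDomain] = []
    calls = []
    if triples:
        for triple in triples:
            domain = delimit_domain(seq, triple, config)
            attach_numbering(seq, domain, reference=reference, config=config)
            call = classify_triad(seq, domain)
            domain.kind = "PD" if call.klass == "SP" else "PLD"
            domains.append(domain)
            calls.append(call)
    else:
        domain = find_truncated_cassette(seq, config)
        if domain is not None:
            attach_numbering(seq, domain, reference=reference, config=config)
            calls.append(classify_triad(seq, domain))
            domain.kind = "PLD"
            domains.append(domain)

    if not domains or all(c.klass == "incomplete" for c in calls):
        ann = SPAnnotation(id=record.id, triad_class="incomplete", locus=record.locus)
        if domains:
            primary = calls[0]
            ann.his_ok, ann.asp_ok, ann.ser_ok = primary.his_ok, primary.asp_ok, primary.ser_ok
        return ann

    # protein-level triad: SP when any domain is enzymatically competent
    sp_indices = [i for i, c in enumerate(calls) if c.klass == "SP"]
    triad_class = "SP" if sp_indices else "SPH"
    primary_idx = sp_indices[0] if sp_indices else next(
        i for i, c in enumerate(calls) if c.klass == "SPH"
    )
    primary_call = calls[primary_idx]
    primary_domain = domains[primary_idx]
    first_domain = domains[0]

    activation = locate_activation_site(seq, first_domain)
    clips = detect_clip_domains(seq, first_domain.start, config)

    ann = SPAnnotation(
        id=record.id,
        triad_class=triad_class,
        his_ok=primary_call.his_ok,
        asp_ok=primary_call.asp_ok,
        ser_ok=primary_call.ser_ok,
        p1_residue=activation.p1_residue,
        activation_class=activation.activation_class,
        clip_count=len(clips),
        clips=clips,
        locus=record.locus,
    )
    if triad_class == "SP":
        pocket = s1_pocket(seq, primary_domain, config)
        ann.res189, ann.res216, ann.res226 = pocket.res189, pocket.res216, pocket.res226
        ann.specificity_class = pocket.specificity_class
    ann.architecture = compose_architecture(
        signal_flag=bool(record.signal_peptide),
        external_domains=record.external_domains,
        clips=clips,
        protease_domains=[(d.kind or "PLD", d.start, d.end) for d in domains],
    )
    return ann


def annotate_proteins(
    records: Sequence[ProteinRecord],
    loci: Mapping[str, GeneLocus] | None = None,
    external_domains: Mapping[str, list[tuple[str, int, int]]] | None = None,
    signal_flags: Mapping[str, bool] | None = None,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> list[SPAnnotation]:
    """Annotate a panel, attaching optional loci/domain/signal side tables."""
    reference = load_reference()
    annotations = []
    for record in records:
        if loci is not None and record.id in loci:
            record.locus = loci[record.id]
        if external_domains is not None and record.id in external_domains:
            record.external_domains = external_domains[record.id]
        if signal_flags is not None and record.id in signal_flags:
            record.signal_peptide = signal_flags[record.id]
        annotations.append(annotate_protein(record, config=config, reference=reference))
    return annotations


def summarize(annotations: Sequence[SPAnnotation], config: PipelineConfig = DEFAULT_CONFIG) -> dict:
    """Census-style summary: category tallies, activation and specificity
    counts, clip histogram, incomplete count."""
    complete = [a for a in annotations if a.triad_class != "incomplete"]
    tallies = tally_categories(list(complete))
    activation: dict[str, int] = {}
    for a in complete:
        key = a.activation_class or "missing"
        activation[key] = activation.get(key, 0) + 1
    specificity: dict[str, int] = {}
    for a in complete:
        if a.triad_class == "SP" and a.specificity_class is not None:
            specificity[a.specificity_class] = specificity.get(a.specificity_class, 0) + 1
    clip_histogram: dict[str, int] = {}
    for a in complete:
        key = str(a.clip_count)
        clip_histogram[key] = clip_histogram.get(key, 0) + 1
    return {
        "schema_version": SUMMARY_SCHEMA_VERSION,
        "n_proteins": len(annotations),
        "n_incomplete": len(annotations) - len(complete),
        "categories": tallies,
        "activation_classes": activation,
        "specificity_classes": specificity,
        "clip_count_histogram": clip_histogram,
        "config": config.to_dict(),
    }
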