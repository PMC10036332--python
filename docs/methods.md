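# Methods

This note records the models, rules and numerical choices behind `spfam`,
and what the synthetic benchmarks do and do not demonstrate.

## Catalytic-motif model

The serine protease domain is identified by its three conserved catalytic
blocks rather than by profile search: TAA**H**C around His57, **D**IAL
around Asp102 and GD**S**GGP around Ser195 (chymotrypsin numbering). Each
block may mismatch the consensus at up to `motif_tolerance` (default 2)
non-anchor positions; the anchor residue itself is recorded but never
required to match, so homologs with a substituted triad residue are found
with the same sensitivity as intact enzymes. `X` counts as a mismatch.

A candidate domain is an ordered triple of blocks whose spacings fall in
`taahc_dial_gap` = [20, 120] and `dial_gdsggp_gap` = [40, 160] residues.
These windows bracket the His57→Asp102→Asp102→Ser195 separations of
chymotrypsin itself (43 and 85 residues in the mature sequence) with room
for the loop-length variation seen across the family; both are
configurable. Where candidate triples overlap, the one with the fewest
total non-anchor mismatches is kept; ties prefer fewer anchor
substitutions relative to canonical H/D/S, then the leftmost placement.
The anchor tie-break matters because anchors are unconstrained: a window
one mismatch away from DIAL can tie the true catalytic window, and
preferring the canonical anchor pins the true window for intact enzymes
while leaving the class call unchanged for homologs (tied candidates both
carry a non-canonical anchor). Non-overlapping surviving triples become
separate domains, supporting multi-domain proteins.

With tolerance 2 the scan is deliberately permissive and will emit chance
triples on arbitrary (non-family) protein sequence; the pipeline's inputs
are sequences already known to carry a protease(-like) domain, as is usual
for gene-family curation, and domain discovery against a whole proteome is
out of scope.

Sequences with no complete triple are checked for a partial cassette
(e.g. TAAHC+DIAL with the sequence ending before GDSGGP) and classified
`incomplete`; they are reported but excluded from category tallies.

## Domain span and numbering

The domain N-terminus is the nearest `[ILV][ILV]GG` match within 120
residues upstream of TAAHC (the conserved mature N-terminal pattern,
IVGG in trypsin), falling back to 60 residues before TAAHC. The
C-terminus extends 55 residues past the catalytic Ser, enough to cover
the chymotrypsin C-terminus (position 245 lies 50 residues after Ser195
in the mature sequence) and in particular the S1 residue 226, 31 residues
after Ser195; a shorter extension would leave the S1 pocket undetermined
for every protein.

Numbering uses a global alignment of the delimited domain against the
bundled mature bovine chymotrypsin A sequence (the canonical zymogen
sequence minus the two activation dipeptides 14–15 and 147–148, 241 aa),
scored with BLOSUM62, gap open 11 / extend 1, and free end gaps — the
domain lacks the reference's 13-residue N-terminal chain and may carry
C-terminal extensions, so end gaps are not evidence of divergence.
Position 195 is forced onto the GDSGGP Ser anchor if the alignment
disagrees (the anchor wins; identity is recomputed and any neighbouring
pairs that would break monotonicity are dropped). Alignment identity
below 0.15 sets a low-confidence flag; the map is still returned.

## Rule tables

Activation (P1 = residue immediately upstream of the mature N-terminus,
itself taken at chymotrypsin position 16 with IVGG-pattern and
domain-start fallbacks): Arg/Lys → trypsin-activated; Phe/Tyr/Leu →
chymotrypsin-activated; Ala/Gly/Val/Ile/Met/Ser → elastase-activated;
the remaining nine residues → other; no upstream residue → missing. The
position-16 rule is a design choice — the canonical Ile16 activation
residue — since no single convention for locating the cleavage site is
universal; it is deterministic and matches zymogen biology.

S1 specificity (SPs only; never emitted for homologs), evaluated in
order: any unmapped residue → undetermined; Asp189 + Gly216 +
Glu/Ala/Ser226 → trypsin; Ser/Thr189 + Gly216 + Gly/Ala/Ser226 →
chymotrypsin; bulky nonpolar residue at 216 or 226 → elastase; else
other. "Bulky nonpolar" is taken as {V, I, L, F, M, W} (configurable):
the literature phrase is not an enumerated set. Elastase is a fallback by
construction — the trypsin and chymotrypsin rules require Gly216, so the
only overlap risk is at 226 and precedence resolves it (e.g. D/G/A is
trypsin). The trypsin and chymotrypsin rules are disjoint because they
demand different residues at 189. Both tables are total: exhaustive
enumeration in the tests confirms every residue (triple) receives exactly
one class.

## Clip domains and architecture

A clip domain is called from six cysteines upstream of the protease
domain whose five consecutive gaps satisfy, in order, [8, 60], [5, 40],
[2, 30], [2, 40], [2, 40] — except that exactly one gap anywhere must
equal 1 (the CC doublet). The descriptive definition ("four cysteines
and one cysteine doublet") fixes neither the windows nor the doublet
slot, so the windows are configurable defaults spanning the ~35–60
residue clip fold, and the doublet may occupy any slot. Scanning is
greedy left-to-right over consecutive-cysteine windows and resumes after
a match's last cysteine, yielding maximal non-overlapping clips (up to
the five-clip multiplicity observed in real family members). The clip
region is anywhere upstream of the protease domain, not merely adjacent.

Architecture strings sort all domains (external accessory domains from
the input table, detected clips, PD/PLD protease domains) by start,
run-length encode repeated labels with a count prefix and prepend `S`
for a signal peptide: `S-7LDLA-2CCP-PD`. Overlapping spans are an error
naming the pair. Decoding is exact (round-trip property tested).

Per-protein category is a function of the triad class and clip count
only: cSP/cSPH with ≥ 1 clip, SP/SPH otherwise. Multi-domain proteins
count as SP when any domain carries an intact triad; activation is read
upstream of the N-terminal-most domain and the S1 pocket from the first
intact domain.

## Duplication clustering

A qualifying duplicate pair lies on one scaffold with at most
`window_genes` = 5 family genes between the two (genomic order by start,
then end, then id) and global-alignment identity ≥ `min_identity` = 0.4.
Clusters are connected components with ≥ 2 members of the qualifying-pair
graph, computed by union-find and verified in tests against an
independent graph-library oracle. The thresholds are an MCScan-like
neighbourhood definition, exposed as configuration and echoed with every
run; published duplicated-gene totals that depend on a specific synteny
tool's defaults are therefore treated as a re-analysis, not a fixed
target. Identity is matches / alignment columns under the same BLOSUM62
scoring as the numbering alignment; unrelated random 200-mers score well
below the 0.4 threshold (checked empirically over seeded pairs).

## Expression filter and set logic

Verdicts follow the standard threshold filter with the printed boundary
semantics: log2(ratio) ≥ 1 (inclusive) with q < 0.05 (strict) is up,
log2(ratio) ≤ −1 with q < 0.05 is down, anything else ns — so q = 0.05
is ns. The pairwise matrix counts verdicts per ordered pair
(row-vs-column orientation). "Commonly regulated" sets take the genes
whose verdict equals the requested direction in at least `min_others`
focal-vs-other comparisons, defaulting to all of them (set
intersection); records stored in the opposite orientation are folded in
by negating the ratio. Producing the statistics themselves (read
mapping, quantification, shrinkage testing) is out of scope: those are
published tools, and the contribution here is the filter and set logic.

## Synthetic data

The generator emits proteins assembled as
`[signal] [accessory]* [clip]* linker P1 IVGG + reference-domain copy`,
where the domain copy is the bundled chymotrypsin reference (positions
16–245) carrying the requested triad residues at 57/102/195 and S1
residues at 189/216/226, plus optional extra point mutations away from
the planted features. Planted truth (triad class, anchors, P1 and its
position, S1 triple, clip spans, accessory spans, category, architecture)
is recorded alongside, using independent copies of the classification
tables so recovery tests compare two routes.

Two generator guarantees keep planted signals unambiguous. Background
segments draw from the canonical alphabet minus Cys (no chance
six-cysteine patterns) and minus Ala (removing most raw material for
chance catalytic-block look-alikes); residual chance triples — possible
because cassette cysteines can complete a TAAHC-like window — are
excluded by rejection: the upstream region is re-drawn until the
assembled protein contains exactly the planted catalytic cassette under
the default scan settings. These are properties of the generated data,
not assumptions in any detector, and they are what "100% recovery on
noise-free constructs" means: the benchmark shows the rules are applied
exactly as specified, not that real, diverged proteins are always
annotated correctly. Real sequences with degraded motifs beyond the
tolerance, unusual domain spacings, or clip domains with out-of-window
cysteine gaps will be missed, and external-domain annotation quality is
inherited from the input table.

Gene panels place mutated copies of a seed gene adjacently on a scaffold
(per-site substitution rate per cluster spec) with unrelated singletons
interleaved; expression tables plant up/down verdicts with margins
(|log2| ≥ 1.2, q ≤ 0.04 for effects; q ≥ 0.05 for nulls) that keep every
verdict strictly inside its decision region, so threshold recovery is
exact by construction. All generators are pure functions of (seed, spec).

## Problem sizes

The standard benchmarks are a 225-protein combination sweep (five
replicates of all 45 valid category × activation × specificity
combinations), a 177-protein census panel matching the published
*O. furnacalis* family composition, duplication panels of ≤ 50 genes and
expression designs of 177 genes × 5 comparisons. The full test suite and
the acceptance script each complete in seconds on one CPU.

## Known limitations

- Motif-based domain discovery is permissive at tolerance 2 and is meant
  for curated family FASTAs, not proteome-wide scanning.
- Clip detection assumes the six clip cysteines are consecutive among
  upstream cysteines; a free cysteine inside a clip would break the
  match (the family's clip consensus has no such cysteine, but gene
  models with N-terminal errors might).
- Signal peptides and accessory domains are inputs, not predictions.
- The duplication analysis is scaffold-local; duplicates split across
  scaffolds are not joined.
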