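# spfam — serine protease family annotation

Insect genomes carry large families of chymotrypsin-like serine proteases
(SPs) and catalytically dead serine protease homologs (SPHs). These enzymes
drive digestion, embryonic patterning and the melanization / Toll immune
cascades, and annotating a newly sequenced genome's SP repertoire is a
recurring, largely rule-driven task. `spfam` packages those rules as a
testable pipeline for anyone curating an SP/SPH gene family from protein
sequences:

- **Catalytic triad calling.** The protease domain is located through its
  three conserved blocks — TAA**H**C (His57), **D**IAL (Asp102) and
  GD**S**GGP (Ser195, chymotrypsin numbering) — allowing up to two
  mismatches per block at non-anchor positions. A protein with all three
  anchor residues intact is an SP; any substitution makes it an SPH; a
  sequence missing a whole triad region is flagged incomplete.
- **Chymotrypsin numbering.** Each domain is globally aligned (BLOSUM62,
  affine gaps, free end gaps) against the bundled mature bovine
  chymotrypsin A sequence so that positions can be named in the family's
  standard coordinates; Ser195 is pinned to the GDSGGP anchor.
- **Zymogen activation.** The mature N-terminus is taken at chymotrypsin
  position 16 (the canonical Ile16); the preceding residue is the P1 of the
  activation cleavage. Arg/Lys ⇒ trypsin-activated, Phe/Tyr/Leu ⇒
  chymotrypsin-activated, Ala/Gly/Val/Ile/Met/Ser ⇒ elastase-activated.
- **S1-pocket specificity** from residues 189/216/226: Asp189 + Gly216 +
  Glu/Ala/Ser226 ⇒ trypsin-like; Ser/Thr189 + Gly216 + Gly/Ala/Ser226 ⇒
  chymotrypsin-like; a bulky nonpolar residue at 216 or 226 ⇒ elastase-like.
- **Clip domains** detected from their cysteine skeleton (six cysteines,
  one CC doublet, in-window spacing) upstream of the protease domain, and
  the four-way cSP / SP / cSPH / SPH census.
- **Architecture strings** (`S-7LDLA-2CCP-PD` and the like) from signal
  flags, external domain tables and the detected clip/protease domains.
- **Tandem duplication clusters** from scaffold loci plus global-alignment
  identity (connected components of the adjacent-similar-pair graph).
- **Differential-expression set logic**: the |log2 ratio| ≥ 1 & q < 0.05
  filter, pairwise up/down count matrices and Venn-style "commonly
  regulated in one stage/tissue vs all others" gene sets.
- **A synthetic-data generator** that plants all of the above with recorded
  ground truth, so every stage is scored exactly without any downloads.

Signal peptides and accessory domains (LDLA, Fz, CCP, CUB, TSP, SR, Gd,
SEA, CBD, TM) are consumed as input tables; the package does not predict
them.

## Worked example

```python
from spfam.simulate import make_protease
from spfam.pipeline import annotate_protein

rec, truth = make_protease(
    seed=1, triad_intact=(True, True, True), p1_residue="R",
    s1_triple=("D", "G", "S"), n_clips=1, signal_peptide=True, protein_id="demo1",
)
ann = annotate_protein(rec)
print(f"{ann.id}: {ann.category}  triad={ann.triad_class}  "
      f"P1={ann.p1_residue} ({ann.activation_class})  "
      f"S1={ann.res189}{ann.res216}{ann.res226} -> {ann.specificity_class}  "
      f"clips={ann.clip_count}  architecture={ann.architecture}")
```

prints

```
demo1: cSP  triad=SP  P1=R (trypsin_activated)  S1=DGS -> trypsin  clips=1  architecture=S-clip-PD
```

i.e. the 307-residue construct is recognized as a clip-domain serine
protease with an intact His/Asp/Ser triad, a trypsin-type activation site
(Arg at P1) and a trypsin-like S1 pocket (Asp189/Gly216/Ser226) — exactly
what the generator planted.

From the shell, the same stages run as subcommands:

```bash
spfam simulate --seed 0 --out sim/          # FASTA + loci + expression + truth.json
spfam annotate sim/proteins.fasta --signal-flags sim/signal_flags.tsv --out ann/
spfam expression sim/expression.tsv --out expr/
```

`annotate` writes a fixed-column TSV of per-protein verdicts plus a
`summary.json` with category tallies, activation and specificity counts and
the clip-count histogram; every run also writes the effective configuration.

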