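"""Catalytic motif scan, domain delimitation, numbering and triad calls."""

import random

import pytest

from spfam.config import PipelineConfig
from spfam.protease import (
    attach_numbering,
    classify_triad,
    delimit_domain,
    find_catalytic_motifs,
    find_truncated_cassette,
    map_to_chymotrypsin_numbering,
    residue_at_numbered,
)
from spfam.simulate import make_protease

# ---------------------------------------------------------------------------
# independent brute-force oracle: enumerate every window placement directly

_ORACLE_MOTIFS = {"TAAHC": ("TAAHC", 3, "H"), "DIAL": ("DIAL", 0, "D"), "GDSGGP": ("GDSGGP", 2, "S")}


def brute_force_triples(seq, tol=2, w1=(20, 120), w2=(40, 160)):
    candidates = {}
    for name, (pat, anchor, canon) in _ORACLE_MOTIFS.items():
        found = []
        for i in range(len(seq) - len(pat) + 1):
            window = seq[i : i + len(pat)]
            mm = sum(1 for k in range(len(pat)) if k != anchor and window[k] != pat[k])
            if mm <= tol:
                found.append((i, mm, 0 if window[anchor] == canon else 1))
        candidates[name] = found
    triples = []
    for ti, tm, ta in candidates["TAAHC"]:
        for di, dm, da in candidates["DIAL"]:
            if not w1[0] <= di - (ti + 5) <= w1[1]:
                continue
            for gi, gm, ga in candidates["GDSGGP"]:
                if not w2[0] <= gi - (di + 4) <= w2[1]:
                    continue
                triples.append((tm + dm + gm, ta + da + ga, ti, di, gi))
    triples.sort()
    chosen = []
    for _, _, ti, di, gi in triples:
        lo, hi = ti, gi + 6
        if all(hi <= c[0] or lo >= c[1] for c in chosen):
            chosen.append((lo, hi, ti, di, gi))
    return sorted((ti, di, gi) for _, _, ti, di, gi in chosen)


def _random_protein(rng, n):
    return "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(n))


def _planted_cassette(rng, taahc="TAAHC", dial="DIAL", gdsggp="GDSGGP"):
    return (
        _random_protein(rng, rng.randint(5, 30))
        + taahc
        + _random_protein(rng, rng.randint(20, 60))
        + dial
        + _random_protein(rng, rng.randint(40, 90))
        + gdsggp
        + _random_protein(rng, rng.randint(5, 30))
    )


class TestMotifScan:
    def test_exact_cassette_yields_one_triple(self):
        rng = random.Random(0)
        seq = _planted_cassette(rng)
        triples = find_catalytic_motifs(seq)
        assert len(triples) == 1
        t = triples[0]
        assert (t.taahc.anchor_residue, t.dial.anchor_residue, t.gdsggp.anchor_residue) == ("H", "D", "S")

    def test_substituted_ser_anchor_still_found(self):
        # GDAGGP: the homolog case — anchor recorded but not required to match
        rng = random.Random(1)
        seq = _planted_cassette(rng, gdsggp="GDAGGP")
        triples = find_catalytic_motifs(seq)
        assert len(triples) == 1
        assert triples[0].gdsggp.anchor_residue == "A"
        assert triples[0].gdsggp.mismatches == 0

    def test_two_planted_cassettes_yield_two_triples(self):
        rng = random.Random(2)
        seq = _planted_cassette(rng) + _planted_cassette(rng)
        triples = find_catalytic_motifs(seq)
        assert len(triples) == 2
        assert brute_force_triples(seq) == [
            (t.taahc.start, t.dial.start, t.gdsggp.start) for t in triples
        ]

    @pytest.mark.parametrize("trial", range(30))
    def test_agrees_with_bruteforce_on_short_sequences(self, trial):
        """Oracle equivalence on sequences <= 200 aa, planted and random."""
        rng = random.Random(1000 + trial)
        if trial % 3 == 0:
            seq = _random_protein(rng, rng.randint(30, 200))
        elif trial % 3 == 1:
            seq = _planted_cassette(rng)[:200]
        else:  # degraded motifs near the tolerance boundary
            seq = _planted_cassette(rng, taahc="TAGHC", dial="DIAF", gdsggp="GDSGAP")[:200]
        got = [(t.taahc.start, t.dial.start, t.gdsggp.start) for t in find_catalytic_motifs(seq)]
        assert sorted(got) == brute_force_triples(seq)

    def test_no_triple_in_featureless_sequence(self):
        assert find_catalytic_motifs("G" * 200) == []


class TestDelimitDomain:
    def test_starts_at_upstream_ivgg(self):
        rng = random.Random(3)
        prefix = "".join(c for c in _random_protein(rng, 30) if c not in "ILV")
        seq = prefix + "IVGG" + _planted_cassette(rng)
        triple = find_catalytic_motifs(seq)[0]
        domain = delimit_domain(seq, triple)
        assert domain.start == len(prefix)
        assert domain.nterm_motif_start == len(prefix)

    def test_fallback_without_nterm_motif(self):
        rng = random.Random(4)
        seq = _planted_cassette(rng)
        seq = seq.replace("IV", "QQ").replace("LL", "QQ").replace("VV", "QQ")
        triples = find_catalytic_motifs(seq)
        domain = delimit_domain(seq, triples[0])
        if domain.nterm_motif_start is None:
            assert domain.start == max(0, triples[0].taahc.start - 60)

    def test_end_clipped_to_sequence_length(self):
        rng = random.Random(5)
        core = _planted_cassette(rng)
        end = core.index("GDSGGP") + 6 + 10  # sequence ends 10 residues past the motif
        seq = core[:end]
        triple = find_catalytic_motifs(seq)[0]
        domain = delimit_domain(seq, triple)
        assert domain.end == len(seq)


class TestNumbering:
    def test_reference_self_alignment_is_identity(self, reference):
        nm = map_to_chymotrypsin_numbering(reference.sequence, reference)
        assert nm.alignment_identity == pytest.approx(1.0)
        assert not nm.low_confidence
        for pos, idx in reference.numbering.items():
            assert nm.pairs[pos] == idx

    def test_single_deletion_shifts_downstream_positions(self, reference):
        # delete one residue upstream of 189: everything after maps one left
        cut = reference.numbering[160]
        edited = reference.sequence[:cut] + reference.sequence[cut + 1 :]
        nm = map_to_chymotrypsin_numbering(edited, reference)
        assert nm.pairs[189] == reference.numbering[189] - 1
        assert nm.pairs[102] == reference.numbering[102]  # upstream unaffected

    def test_monotone_over_non_gap_entries(self, reference):
        rec, _ = make_protease(11, extra_mutations=10)
        nm_positions = sorted(reference.numbering)
        from spfam.pipeline import annotate_protein  # noqa: F401 (exercise full path)

        triple = find_catalytic_motifs(rec.sequence)[0]
        domain = delimit_domain(rec.sequence, triple)
        attach_numbering(rec.sequence, domain, reference=reference)
        mapped = [domain.numbering.pairs[p] for p in nm_positions if domain.numbering.pairs[p] is not None]
        assert mapped == sorted(mapped)

    def test_mutated_domain_maps_triad_to_planted_anchors(self, reference):
        rec, truth = make_protease(12, extra_mutations=10)
        triple = find_catalytic_motifs(rec.sequence)[0]
        domain = delimit_domain(rec.sequence, triple)
        attach_numbering(rec.sequence, domain, reference=reference)
        assert residue_at_numbered(rec.sequence, domain, 57) == truth.anchor_residues[0]
        assert residue_at_numbered(rec.sequence, domain, 102) == truth.anchor_residues[1]
        assert residue_at_numbered(rec.sequence, domain, 195) == truth.anchor_residues[2]
        # 195 is pinned to the GDSGGP anchor
        assert domain.start + domain.numbering.pairs[195] == domain.gdsggp.anchor_pos


class TestTriadCall:
    def _domain(self, seq):
        triple = find_catalytic_motifs(seq)[0]
        domain = delimit_domain(seq, triple)
        attach_numbering(seq, domain)
        return domain

    def test_intact_triad_is_sp(self):
        rec, _ = make_protease(20, triad_intact=(True, True, True))
        call = classify_triad(rec.sequence, self._domain(rec.sequence))
        assert call.klass == "SP"
        assert call.his_ok and call.asp_ok and call.ser_ok
        assert call.substituted == frozenset()

    @pytest.mark.parametrize(
        "intact,expected_sub",
        [
            ((False, True, True), "His57"),
            ((True, False, True), "Asp102"),
            ((True, True, False), "Ser195"),
        ],
    )
    def test_substituted_residue_is_sph(self, intact, expected_sub):
        rec, _ = make_protease(21, triad_intact=intact)
        call = classify_triad(rec.sequence, self._domain(rec.sequence))
        assert call.klass == "SPH"
        assert expected_sub in call.substituted

    def test_truncated_before_ser_region_is_incomplete(self):
        rec, _ = make_protease(22)
        seq = rec.sequence
        cut = find_catalytic_motifs(seq)[0].dial.end + 10  # drop GDSGGP and beyond
        truncated = seq[:cut]
        assert find_catalytic_motifs(truncated) == []
        domain = find_truncated_cassette(truncated)
        assert domain is not None and domain.gdsggp is None
        attach_numbering(truncated, domain)
        call = classify_triad(truncated, domain)
        assert call.klass == "incomplete"

    def test_every_domain_gets_exactly_one_class(self):
        # partition property over a batch of varied constructs
        for seed, intact in enumerate(
            [(True, True, True), (False, True, True), (True, False, True), (True, True, False)]
        ):
            rec, _ = make_protease(30 + seed, triad_intact=intact)
            call = classify_triad(rec.sequence, self._domain(rec.sequence))
            assert call.klass in {"SP", "SPH", "incomplete"}
            assert (call.klass == "SP") == bool(call.his_ok and call.asp_ok and call.ser_ok)


def test_configurable_tolerance_changes_sensitivity():
    rng = random.Random(40)
    seq = _planted_cassette(rng, taahc="TAGHC", dial="DIAF", gdsggp="GDSGAP")
    strict = PipelineConfig(motif_tolerance=0)
    assert find_catalytic_motifs(seq, strict) == []
    assert len(find_catalytic_motifs(seq)) == 1
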