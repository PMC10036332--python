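"""Activation-site P1 rules and S1-pocket specificity rules."""

import itertools

import pytest

from spfam.config import PipelineConfig
from spfam.pipeline import annotate_protein
from spfam.protease import attach_numbering, delimit_domain, find_catalytic_motifs
from spfam.simulate import make_protease
from spfam.zymogen import (
    AMINO_ACIDS,
    CHYMOTRYPSIN_P1,
    ELASTASE_P1,
    TRYPSIN_P1,
    classify_activation,
    classify_specificity,
    locate_activation_site,
)


class TestActivationRules:
    @pytest.mark.parametrize(
        "residue,expected",
        [
            ("K", "trypsin_activated"),
            ("R", "trypsin_activated"),
            ("F", "chymotrypsin_activated"),
            ("S", "elastase_activated"),
            ("W", "other"),
            (None, "missing"),
        ],
    )
    def test_examples(self, residue, expected):
        assert classify_activation(residue) == expected

    def test_rejects_lowercase_and_multi_letter(self):
        with pytest.raises(ValueError):
            classify_activation("k")
        with pytest.raises(ValueError):
            classify_activation("RK")

    def test_classes_partition_the_alphabet(self):
        """The three residue sets are pairwise disjoint and every canonical
        residue lands in exactly one of the four classes."""
        assert TRYPSIN_P1 & CHYMOTRYPSIN_P1 == set()
        assert TRYPSIN_P1 & ELASTASE_P1 == set()
        assert CHYMOTRYPSIN_P1 & ELASTASE_P1 == set()
        classes = {aa: classify_activation(aa) for aa in sorted(AMINO_ACIDS)}
        counts = {c: sum(1 for v in classes.values() if v == c) for c in set(classes.values())}
        assert counts == {
            "trypsin_activated": 2,
            "chymotrypsin_activated": 3,
            "elastase_activated": 6,
            "other": 9,
        }


class TestSpecificityRules:
    @pytest.mark.parametrize(
        "triple,expected",
        [
            (("D", "G", "S"), "trypsin"),
            (("D", "G", "E"), "trypsin"),
            (("S", "G", "A"), "chymotrypsin"),
            (("T", "G", "G"), "chymotrypsin"),
            (("D", "V", "T"), "elastase"),  # bulky 216 wins once trypsin fails
            (("D", "G", "A"), "trypsin"),  # precedence: trypsin before elastase
            (("A", "G", "N"), "other"),
            (("D", "gap", "S"), "undetermined"),
        ],
    )
    def test_examples(self, triple, expected):
        assert classify_specificity(*triple) == expected

    def test_rule_order_is_total_over_all_triples(self):
        """Exhaustive enumeration: every residue triple (plus gap) receives
        exactly one class, and the trypsin/chymotrypsin rules never both
        apply (they differ at position 189)."""
        letters = sorted(AMINO_ACIDS) + ["gap"]
        seen = set()
        for r189, r216, r226 in itertools.product(letters, repeat=3):
            klass = classify_specificity(r189, r216, r226)
            seen.add(klass)
            trypsin_applies = r189 == "D" and r216 == "G" and r226 in "EAS"
            chymo_applies = r189 in "ST" and r216 == "G" and r226 in "GAS"
            assert not (trypsin_applies and chymo_applies)
            if "gap" in (r189, r216, r226):
                assert klass == "undetermined"
        assert seen == {"trypsin", "chymotrypsin", "elastase", "other", "undetermined"}

    def test_bulky_set_is_configurable(self):
        wide = PipelineConfig(bulky_set=frozenset("VILFMWY"))
        assert classify_specificity("A", "Y", "T") == "other"
        assert classify_specificity("A", "Y", "T", config=wide) == "elastase"


class TestLocateActivationSite:
    def _domain(self, seq):
        triple = find_catalytic_motifs(seq)[0]
        domain = delimit_domain(seq, triple)
        attach_numbering(seq, domain)
        return domain

    def test_planted_p1_recovered(self):
        rec, truth = make_protease(50, p1_residue="R", n_clips=1, signal_peptide=True)
        site = locate_activation_site(rec.sequence, self._domain(rec.sequence))
        assert site.p1_residue == "R"
        assert site.p1_pos == truth.p1_pos
        assert site.activation_class == "trypsin_activated"

    def test_domain_at_position_zero_has_no_p1(self):
        rec, _ = make_protease(51, p1_residue=None)
        site = locate_activation_site(rec.sequence, self._domain(rec.sequence))
        assert site.p1_residue is None
        assert site.activation_class == "missing"

    def test_specificity_never_attached_to_sph(self):
        rec, _ = make_protease(52, triad_intact=(True, False, True), s1_triple=("D", "G", "S"))
        ann = annotate_protein(rec)
        assert ann.triad_class == "SPH"
        assert ann.specificity_class is None
        assert ann.res189 is None
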