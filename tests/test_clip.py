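"""Clip-domain detection, architecture strings and category tallies."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spfam.clip import (
    SPAnnotation,
    compose_architecture,
    decode_architecture,
    detect_clip_domains,
    encode_architecture,
    tally_categories,
)
from spfam.pipeline import annotate_protein
from spfam.simulate import make_protease


class TestDetectClips:
    def test_single_planted_cassette(self):
        rec, truth = make_protease(60, n_clips=1, signal_peptide=True)
        clips = detect_clip_domains(rec.sequence, truth.domain_start)
        assert len(clips) == 1
        assert (clips[0].start, clips[0].end) == truth.clip_spans[0]
        assert len(clips[0].cys_positions) == 6
        gaps = [b - a for a, b in zip(clips[0].cys_positions, clips[0].cys_positions[1:])]
        assert gaps.count(1) == 1
        assert gaps[clips[0].doublet_index] == 1

    def test_five_planted_cassettes(self):
        # the extreme observed multiplicity: five clip domains on one protein
        rec, truth = make_protease(61, n_clips=5, signal_peptide=True)
        clips = detect_clip_domains(rec.sequence, truth.domain_start)
        assert [(c.start, c.end) for c in clips] == truth.clip_spans

    def test_no_upstream_cysteines_means_no_clips(self):
        rec, truth = make_protease(62, n_clips=0, signal_peptide=True)
        assert detect_clip_domains(rec.sequence, truth.domain_start) == []

    def test_clips_do_not_overlap_each_other_or_domain(self):
        rec, truth = make_protease(63, n_clips=3, signal_peptide=True)
        clips = detect_clip_domains(rec.sequence, truth.domain_start)
        for a, b in zip(clips, clips[1:]):
            assert a.end <= b.start
        assert all(c.end <= truth.domain_start for c in clips)

    def test_six_cysteines_without_doublet_rejected(self):
        # gaps all in-window but no CC doublet
        region = ""
        for gap in (10, 8, 5, 6, 7):
            region += "C" + "G" * (gap - 1)
        region += "C" + "G" * 5
        assert detect_clip_domains(region + "X", len(region) + 1) == []


class TestArchitecture:
    def test_modsp_like_layout(self):
        # signal + 7 LDLA repeats + 2 CCP + protease domain
        external = [("LDLA", 20 + 30 * i, 45 + 30 * i) for i in range(7)]
        external += [("CCP", 230, 280), ("CCP", 285, 340)]
        assert (
            compose_architecture(True, external, [], [("PD", 360, 600)])
            == "S-7LDLA-2CCP-PD"
        )

    def test_corin_like_layout(self):
        external = [("Fz", 20, 140), ("LDLA", 150, 185), ("LDLA", 190, 225), ("SR", 240, 330)]
        assert (
            compose_architecture(True, external, [], [("PD", 350, 590)])
            == "S-Fz-2LDLA-SR-PD"
        )

    def test_bare_protease_domain(self):
        assert compose_architecture(False, [], [], [("PD", 10, 250)]) == "PD"

    def test_overlapping_spans_error_names_the_pair(self):
        with pytest.raises(ValueError, match="LDLA.*CCP"):
            compose_architecture(False, [("LDLA", 10, 50), ("CCP", 40, 90)], [], [])

    @given(
        st.lists(
            st.sampled_from(["LDLA", "CCP", "clip", "PD", "PLD", "Fz", "SR"]),
            min_size=0,
            max_size=12,
        )
    )
    @settings(max_examples=200, deadline=None)
    def test_run_length_encoding_round_trips(self, labels):
        assert decode_architecture(encode_architecture(labels)) == labels


class TestCategories:
    def test_category_follows_triad_and_clip_count(self):
        cases = [
            ((True, True, True), 1, "cSP"),
            ((True, True, True), 0, "SP"),
            ((True, False, True), 2, "cSPH"),
            ((False, True, True), 0, "SPH"),
        ]
        for seed, (intact, n_clips, expected) in enumerate(cases):
            rec, truth = make_protease(70 + seed, triad_intact=intact, n_clips=n_clips)
            assert truth.category == expected
            assert annotate_protein(rec).category == expected

    def test_tally_sums_to_total(self):
        anns = [
            SPAnnotation(id=f"p{i}", triad_class=tc, clip_count=cc)
            for i, (tc, cc) in enumerate(
                [("SP", 1)] * 3 + [("SP", 0)] * 4 + [("SPH", 2)] * 2 + [("SPH", 0)] * 5
            )
        ]
        counts = tally_categories(anns)
        assert counts == {"cSP": 3, "SP": 4, "cSPH": 2, "SPH": 5, "total": 14}

    def test_incomplete_excluded_from_tally(self):
        anns = [
            SPAnnotation(id="a", triad_class="SP"),
            SPAnnotation(id="b", triad_class="incomplete"),
        ]
        assert tally_categories(anns)["total"] == 1

    def test_empty_input_all_zeros(self):
        assert tally_categories([]) == {"cSP": 0, "SP": 0, "cSPH": 0, "SPH": 0, "total": 0}
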