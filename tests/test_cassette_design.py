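"""Cassette geometry, candidate filtering and combinatorial library tests."""

import itertools

import pytest
from hypothesis import given, strategies as st

from capture_kit._dna import STOP_CODONS, revcomp
from capture_kit.cassette_design import (
    CassetteSpec,
    DesignError,
    GuideSite,
    assemble_cassette,
    capture_guides_for,
    check_frames_v2,
    emit_oligos,
    enumerate_library,
    filter_guide_candidates,
)

A20 = "A" * 20
C20 = "C" * 20


class TestSpec:
    def test_default_geometry(self, spec):
        assert spec.motif_length == 6 + 20 + 15 + 20 + 6 == 67
        assert spec.offset_bp == len(spec.linker) == 15
        # PAM-out: plus-strand NGG right of site_b, CCN (minus-strand NGG)
        # left of site_a
        assert spec.three_flank.startswith("CGG")
        assert spec.five_flank.endswith("CCG")

    def test_linker_offset_mismatch_rejected(self):
        with pytest.raises(DesignError):
            CassetteSpec(linker="GCCACC", offset_bp=15)

    def test_pam_geometry_unsatisfiable_rejected(self):
        with pytest.raises(DesignError, match="PAM-out"):
            CassetteSpec(three_flank="ATTTAG")


class TestFilter:
    @pytest.mark.parametrize(
        "candidate,reason",
        [
            # TAA lands on an in-frame codon (positions 9-11 of the cassette)
            ("AAATAAGGCCGGCCGGCCGG", "stop_codon"),
            # TAG completed across the junction by the first linker base (G)
            ("CCCCCCCCCCCCCCCCCCTA", "stop_codon"),
            # MluI site inside the candidate
            ("GGGGGGGGACGCGTGGGGGG", "forbidden_motif"),
            # BamHI completed across the 5'-flank junction (…CCG|GATCC…)
            ("GATCCAAAAACAAAACAAAA", "forbidden_motif"),
            ("ACGTNCGTACGTACGTACGT", "non_ACGT"),
            ("ACGTACGT", "bad_length"),
        ],
    )
    def test_rejection_reasons(self, spec, candidate, reason):
        report = filter_guide_candidates([candidate], spec, "top")
        assert report.rejected == [(candidate, reason)]
        assert not report.accepted

    def test_homopolymer_c_accepted_without_scoring(self, spec):
        report = filter_guide_candidates([C20], spec, "top")
        assert [s.protospacer for s in report.accepted] == [C20]

    def test_min_score_uses_builtin_heuristic(self, spec):
        # C20 fails both heuristic criteria (GC out of range is false —
        # GC=1.0 is out of [0.3, 0.8] — plus a homopolymer run)
        report = filter_guide_candidates([C20], spec, "top", min_score=60.0)
        assert report.rejected == [(C20, "low_score")]

    def test_external_scores(self, spec):
        scores = {C20: 99.0, A20: 10.0}
        report = filter_guide_candidates(
            [C20, A20], spec, "top", min_score=50.0, scores=scores
        )
        assert [s.protospacer for s in report.accepted] == [C20]
        assert report.rejected == [(A20, "low_score")]

    def test_strict_mode_checks_all_frames(self, spec):
        # TGA only in frame 1 of the insert: accepted in default frame,
        # rejected in strict mode
        cand = "CTGACCCCCCCCCCCCCCCC"
        assert filter_guide_candidates([cand], spec, "top").accepted
        strict = filter_guide_candidates(
            [cand], spec, "top", strict_all_frames=True
        )
        assert strict.rejected == [(cand, "stop_codon")]

    def test_empty_candidate_list_errors(self, spec):
        with pytest.raises(DesignError):
            filter_guide_candidates([], spec, "top")


class TestAssemble:
    def test_concatenation_and_key(self, spec):
        a = GuideSite("a", A20, "top")
        b = GuideSite("b", C20, "bottom")
        cas = assemble_cassette(a, b, spec)
        assert cas.full_sequence == "CGTCCG" + A20 + "GCCACCATGGTCGAC" + C20 + "CGGTAG"
        assert len(cas.full_sequence) == 67
        assert cas.barcode_key == A20 + C20

    def test_pool_mismatch_errors(self, spec, site_a):
        with pytest.raises(DesignError, match="pool mismatch"):
            assemble_cassette(site_a, site_a, spec)


@pytest.fixture(scope="module")
def v2():
    return CassetteSpec(version="v2")


class TestFramesV2:
    def test_clean_region_passes(self, v2):
        report = check_frames_v2("GCCGCCGCCGCC", v2)
        assert report.passes

    def test_slippery_heptamer_detected(self, v2):
        report = check_frames_v2("GCCGCC" + "TTTAAAC" + "GCCGCC", v2)
        assert report.slippery_sites == [6]
        assert not report.passes

    def test_minus1_frame_stop_detected(self, v2):
        # frame 0 reads GGT AGC GGC (clean); the -1 frame reads TAG at pos 2
        report = check_frames_v2("GGTAGCGGC", v2)
        assert report.frame0_stops == []
        assert report.minus1_stops == [2]

    def test_short_region_warns_and_skips_slippery(self, v2):
        with pytest.warns(UserWarning, match="slippery"):
            report = check_frames_v2("GCCGCC", v2)
        assert report.slippery_sites == []

    def test_requires_v2(self, spec):
        with pytest.raises(DesignError):
            check_frames_v2("GCCGCC", spec)


class TestLibrary:
    @staticmethod
    def _pool(pool, seqs):
        return [GuideSite(f"{pool}{i}", s, pool) for i, s in enumerate(seqs)]

    def test_three_by_four(self, spec):
        top = self._pool("top", ["ACGTACGTACGTACGTACGA",
                                 "CCGGCCGGCCGGCCGGCCGG",
                                 "ATCGATCGATCGATCGATCG"])
        bottom = self._pool("bottom", ["TGCATGCATGCATGCATGCA",
                                       "GGCCGGCCGGCCGGCCGGCC",
                                       "CATGCATGCATGCATGCATG",
                                       "AACCAACCAACCAACCAACC"])
        complexity, it = enumerate_library(top, bottom, spec)
        cassettes = list(it)
        assert complexity == 12 == len(cassettes)
        assert len({c.barcode_key for c in cassettes}) == 12
        # barcode_key -> (site_a, site_b) is a bijection
        assert len({(c.site_a.site_id, c.site_b.site_id) for c in cassettes}) == 12

    def test_single_pair(self, spec, site_a, site_b):
        complexity, it = enumerate_library([site_a], [site_b], spec)
        assert complexity == 1 and len(list(it)) == 1

    def test_duplicate_protospacer_errors(self, spec, site_b):
        dup = self._pool("top", [A20, A20])
        with pytest.raises(DesignError, match="duplicate"):
            enumerate_library(dup, [site_b], spec)

    @given(n_top=st.integers(1, 30), n_bottom=st.integers(1, 30))
    def test_complexity_is_product(self, n_top, n_bottom):
        spec = CassetteSpec()
        bases = "ACGT"
        def seqs(n, offset):
            out = []
            for i in range(n):
                idx = i + offset
                out.append(
                    "".join(bases[(idx >> (2 * k)) & 3] for k in range(10)) * 2
                )
            return out
        top = self._pool("top", seqs(n_top, 0))
        bottom = self._pool("bottom", seqs(n_bottom, 1000))
        complexity, _ = enumerate_library(top, bottom, spec)
        assert complexity == n_top * n_bottom


def _anneal_extend(top_oligo: str, bottom_oligo: str, overlap: int) -> str | None:
    """String-level annealing oracle: the 3' ends must be complementary over
    exactly ``overlap`` nt; extension copies each template past the overlap."""
    rc_bottom = revcomp(bottom_oligo)
    if top_oligo[-overlap:] != rc_bottom[:overlap]:
        return None
    return top_oligo + rc_bottom[overlap:]


class TestOligos:
    def test_anneal_extend_reconstructs_all_pairs(self, spec):
        tops = ["ACGTACGTACGTACGTACGA", "CCGGCCGGCCGGCCGGCCGG",
                "ATCGATCGATCGATCGATCG"]
        bottoms = ["TGCATGCATGCATGCATGCA", "GGCCGGCCGGCCGGCCGGCC",
                   "AACCAACCAACCAACCAACC"]
        top_sites = [GuideSite(f"t{i}", s, "top") for i, s in enumerate(tops)]
        bottom_sites = [GuideSite(f"b{i}", s, "bottom") for i, s in enumerate(bottoms)]
        top_o, bottom_o = emit_oligos(top_sites, bottom_sites, spec, 15)
        for (ai, a_seq), (bi, b_seq) in itertools.product(top_o, bottom_o):
            product = _anneal_extend(a_seq, b_seq, 15)
            a = next(s for s in top_sites if s.site_id == ai)
            b = next(s for s in bottom_sites if s.site_id == bi)
            assert product == assemble_cassette(a, b, spec).full_sequence

    def test_full_linker_overlap_boundary(self, spec, site_a, site_b):
        top_o, bottom_o = emit_oligos([site_a], [site_b], spec, 15)
        assert top_o[0][1].endswith(spec.linker)
        assert revcomp(bottom_o[0][1]).startswith(spec.linker)

    def test_overlap_longer_than_linker_errors(self, spec, site_a, site_b):
        with pytest.raises(DesignError):
            emit_oligos([site_a], [site_b], spec, 16)


class TestCaptureGuides:
    def test_example_spacers(self, spec):
        cas = assemble_cassette(
            GuideSite("a", A20, "top"), GuideSite("b", C20, "bottom"), spec
        )
        assert capture_guides_for(cas) == ("T" * 20, C20)

    def test_spacers_hit_exactly_one_pam_adjacent_site(self, cassette):
        """Brute-force scan of both strands for spacer+NGG placements."""
        full = cassette.full_sequence
        spacer_a, spacer_b = capture_guides_for(cassette)

        def pam_adjacent_hits(spacer):
            hits = 0
            for strand in (full, revcomp(full)):
                for i in range(len(strand) - len(spacer) - 2):
                    if (strand[i : i + 20] == spacer
                            and strand[i + 21 : i + 23] == "GG"):
                        hits += 1
            return hits

        assert pam_adjacent_hits(spacer_a) == 1
        assert pam_adjacent_hits(spacer_b) == 1

    def test_shared_site_a_distinct_pairs(self, spec, site_a):
        b1 = GuideSite("b1", "TGCATGCATGCATGCATGCA", "bottom")
        b2 = GuideSite("b2", "CATGCATGCATGCATGCATG", "bottom")
        pair1 = capture_guides_for(assemble_cassette(site_a, b1, spec))
        pair2 = capture_guides_for(assemble_cassette(site_a, b2, spec))
        assert pair1 != pair2 and pair1[0] == pair2[0]


@given(
    st.lists(
        st.text(alphabet="ACGT", min_size=20, max_size=20),
        min_size=2, max_size=6, unique=True,
    )
)
def test_frame_safety_of_accepted_cassettes(seqs):
    """Any cassette built from filter-accepted sites has no stop codon in a
    phase-0 codon overlapping either N20."""
    spec = CassetteSpec()
    top = filter_guide_candidates(seqs, spec, "top").accepted
    bottom = filter_guide_candidates(seqs, spec, "bottom").accepted
    for a in top[:3]:
        for b in bottom[:3]:
            full = assemble_cassette(a, b, spec).full_sequence
            for i in range(0, len(full) - 2, 3):
                codon = full[i : i + 3]
                overlaps_insert = (i + 3 > 6 and i < 26) or (i + 3 > 41 and i < 61)
                if overlaps_insert:
                    assert codon not in STOP_CODONS
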