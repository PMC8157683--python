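"""Candidate construction, N-terminus inference and annotation overlap."""

import numpy as np
import pytest

from psmap.annotation import (
    HYPOTHETICAL,
    KNOWN,
    AnnotationIndex,
    AnnotationRecord,
    classify_annotation_status,
)
from psmap.candidates import (
    Candidate,
    build_candidates,
    classify_candidate,
    infer_start_offset,
    shat,
)
from psmap.genome import GenomeSequence, extract_six_frame_orfs
from psmap.mapping import OrfIndex, map_psms
from psmap.psms import PSMRecord


def psm(peptide, ref, i, s=4.0):
    return PSMRecord(
        psm_id=f"p{i}", spectrum_id=f"s{i}", sample_id="a", peptide=peptide,
        charge=2, evalue=10 ** -s, matched_ref=ref, is_decoy=False,
    )


class TestShat:
    def test_top_three_mean(self):
        assert shat([5, 4, 3, 2, 1]) == (4.0, False)
        assert shat([2, 2, 2]) == (2.0, False)

    def test_fewer_than_k_flagged(self):
        assert shat([3.0, 1.0]) == (2.0, True)

    def test_empty_error(self):
        with pytest.raises(ValueError):
            shat([])

    def test_matches_sort_and_slice_oracle(self):
        rng = np.random.default_rng(5)
        scores = list(rng.normal(3, 2, 100))
        value, flagged = shat(scores)
        assert not flagged
        assert value == pytest.approx(np.mean(sorted(scores, reverse=True)[:3]))


class TestStartInference:
    def test_start_at_met_before_psm(self):
        # ORF aa: T S M K R P K ; PSM covers RPK (offset 4)
        nt = "ACTAGTATGAAACGTCCGAAA"
        assert infer_start_offset(nt, 4) == 2

    def test_psm_starting_at_atg_counts(self):
        assert infer_start_offset("ATGAAACGT", 0) == 0

    def test_no_upstream_start_returns_none(self):
        assert infer_start_offset("ACTAGTAAACGTCCG", 3) is None

    def test_alternative_start_codons_flag(self):
        nt = "GTGAAACGT"
        assert infer_start_offset(nt, 1) is None
        assert infer_start_offset(nt, 1, start_codons=("ATG", "GTG", "TTG")) == 0

    def test_matches_brute_force_scan_on_random_orfs(self):
        """Oracle: enumerate every in-frame ATG and pick the closest one at
        or before the first PSM."""
        rng = np.random.default_rng(42)
        for _ in range(1000):
            n_aa = int(rng.integers(5, 60))
            nt = "".join(rng.choice(list("ACGT"), size=3 * n_aa))
            first = int(rng.integers(0, n_aa))
            atgs = [j for j in range(n_aa) if nt[3 * j : 3 * j + 3] == "ATG"]
            upstream = [j for j in atgs if j <= first]
            expected = max(upstream) if upstream else None
            assert infer_start_offset(nt, first) == expected


def _single_gene_setup(s=4.0, n_psm=6):
    # contig: pad + ATG AAA CGT CCG AAA TAA + pad ; protein MKRPK
    seq = "CCTCCTCCT" + "ATGAAACGTCCGAAA" + "TAA" + "CCTCCTCCT"
    genome = GenomeSequence(contig_id="c", sequence=seq)
    orfs = extract_six_frame_orfs(genome)
    orf = next(o for o in orfs if "MKRPK" in o.aa_sequence)
    psms = [psm("RPK", orf.orf_id, i, s) for i in range(n_psm)]
    hits = map_psms(psms, OrfIndex(orfs))
    return genome, orfs, orf, psms, hits


class TestBuildCandidates:
    def test_start_codon_rule(self):
        genome, orfs, orf, psms, hits = _single_gene_setup()
        (cand,) = build_candidates(orfs, hits, psms, {"c": genome}, min_psm=6)
        # candidate begins at the ATG (position 9), not at the PSM (RPK)
        assert cand.cand_start == 9
        assert cand.cand_end == orf.end
        assert cand.start_found

    def test_no_start_codon_falls_back_to_orf_start(self):
        seq = "CCTCCTCCTAAACGTCCGAAATAACCTCCT"  # no ATG anywhere in frame
        genome = GenomeSequence(contig_id="c", sequence=seq)
        orfs = extract_six_frame_orfs(genome)
        orf = next(o for o in orfs if "KRPK" in o.aa_sequence)
        psms = [psm("RPK", orf.orf_id, i) for i in range(6)]
        hits = map_psms(psms, OrfIndex(orfs))
        (cand,) = build_candidates(orfs, hits, psms, {"c": genome}, min_psm=6)
        assert cand.cand_start == orf.start and not cand.start_found

    def test_min_psm_threshold_skips_orfs(self):
        genome, orfs, orf, psms, hits = _single_gene_setup(n_psm=5)
        assert build_candidates(orfs, hits, psms, {"c": genome}, min_psm=6) == []

    def test_shat_and_counts(self):
        genome, orfs, orf, psms, hits = _single_gene_setup(s=3.0)
        (cand,) = build_candidates(orfs, hits, psms, {"c": genome}, min_psm=6)
        assert cand.n_psm == 6
        assert cand.n_distinct_peptides == 1
        assert cand.shat == pytest.approx(3.0)

    def test_order_invariance(self):
        genome, orfs, orf, psms, hits = _single_gene_setup()
        a = build_candidates(orfs, hits, psms, {"c": genome})
        b = build_candidates(orfs[::-1], hits[::-1], psms[::-1], {"c": genome})
        assert a == b

    def test_candidate_start_never_downstream_of_first_psm(self, std_fixture, std_mapping):
        _, targets, hits = std_mapping
        cands = build_candidates(
            std_fixture.orfs, hits, targets, std_fixture.genome_map, min_psm=6
        )
        assert cands
        by_orf = {}
        for h in hits:
            by_orf.setdefault(h.orf_id, []).append(h)
        for c in cands:
            if c.strand == "+":
                first = min(h.start for h in by_orf[c.orf_id])
                assert c.cand_start <= first
            else:
                last = max(h.end for h in by_orf[c.orf_id])
                assert c.cand_end >= last


class TestAnnotationStatus:
    @pytest.mark.parametrize(
        "tags,level,expected",
        [
            (("hypothetical protein",), None, HYPOTHETICAL),
            (("pseudogene",), None, HYPOTHETICAL),
            (("Putative transporter",), None, HYPOTHETICAL),
            (("frameshifted",), None, HYPOTHETICAL),
            (("internal stop",), None, HYPOTHETICAL),
            (("ABC transporter",), 3, KNOWN),
            (("ABC transporter",), 1, HYPOTHETICAL),
            (("ABC transporter",), 2, HYPOTHETICAL),
            ((), None, KNOWN),
        ],
    )
    def test_tag_and_level_rules(self, tags, level, expected):
        assert classify_annotation_status(tags, level) == expected


def _candidate(start, end, strand="+", frame=None):
    from psmap.genome import frame_label
    return Candidate(
        candidate_id="cand:x", orf_id="x", contig_id="c", strand=strand,
        frame_label=frame if frame is not None else frame_label(strand, start),
        cand_start=start, cand_end=end, psm_ids=("p0",), n_psm=6,
        n_distinct_peptides=2, shat=4.0, shat_flagged=False, start_found=True,
    )


class TestClassifyCandidate:
    def test_identical_to_annotation_is_known_with_zero_start_diff(self):
        ann = AnnotationIndex([AnnotationRecord("g1", "c", "+", 30, 90, status=KNOWN)])
        c = classify_candidate(_candidate(30, 90), ann)
        assert c.category == KNOWN
        assert c.start_diff_frac == 0.0

    def test_frame_shifted_overlap_is_novel_with_same_strand_overlap(self):
        ann = AnnotationIndex([AnnotationRecord("g1", "c", "+", 30, 90, status=KNOWN)])
        c = classify_candidate(_candidate(31, 88, frame=1), ann)
        assert c.category == "novel"
        assert c.overlap_same_strand == ("g1",)
        assert c.start_diff_frac is None

    def test_opposite_strand_overlap_recorded(self):
        ann = AnnotationIndex([AnnotationRecord("g1", "c", "-", 30, 90, status=KNOWN)])
        c = classify_candidate(_candidate(30, 90), ann)
        assert c.category == "novel"
        assert c.overlap_opposite_strand == ("g1",)

    def test_known_wins_over_hypothetical(self):
        ann = AnnotationIndex([
            AnnotationRecord("g1", "c", "+", 30, 90, status=HYPOTHETICAL),
            AnnotationRecord("g2", "c", "+", 30, 90, status=KNOWN),
        ])
        assert classify_candidate(_candidate(30, 90), ann).category == KNOWN

    def test_ten_percent_truncation_gives_minus_point_one(self):
        # annotated protein spans [30, 90); candidate starts 6 bp (10%) in
        ann = AnnotationIndex([AnnotationRecord("g1", "c", "+", 30, 90, status=KNOWN)])
        c = classify_candidate(_candidate(36, 90), ann)
        assert c.start_diff_frac == pytest.approx(-0.10)

    def test_truncation_on_reverse_strand(self):
        ann = AnnotationIndex([AnnotationRecord("g1", "c", "-", 30, 90, status=KNOWN)])
        c = classify_candidate(_candidate(30, 84, strand="-"), ann)
        assert c.start_diff_frac == pytest.approx(-0.10)

    def test_extension_is_positive(self):
        ann = AnnotationIndex([AnnotationRecord("g1", "c", "+", 36, 90, status=KNOWN)])
        c = classify_candidate(_candidate(30, 90), ann)
        assert c.start_diff_frac == pytest.approx(6 / 54)


class TestAnnotationRecovery:
    def test_planted_proteins_classified_known_never_novel(self, std_fixture, std_mapping):
        """PSMs generated inside annotated proteins must classify their
        candidates as annotated (known or hypothetical), never novel."""
        _, targets, hits = std_mapping
        cands = build_candidates(
            std_fixture.orfs, hits, targets, std_fixture.genome_map, min_psm=6
        )
        ann = AnnotationIndex(std_fixture.annotations)
        orf_by_id = {o.orf_id: o for o in std_fixture.orfs}
        from psmap.genome import frame_label

        def planted_in(c):
            orf = orf_by_id[c.orf_id]
            return [
                t for t in std_fixture.truth_proteins
                if t.contig_id == c.contig_id and t.strand == c.strand
                and frame_label(t.strand, t.coding_span[0]) == c.frame_label
                and orf.start <= t.coding_span[0] and t.coding_span[1] <= orf.end
            ]

        n_known = 0
        for c in cands:
            cc = classify_candidate(c, ann)
            genes = planted_in(c)
            if genes and any(t.annotated for t in genes):
                assert cc.category in (KNOWN, HYPOTHETICAL)
                n_known += 1
        assert n_known > 0
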