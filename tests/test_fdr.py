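"""FDR estimators: decoy counting, frame-based, genome-based, protein-level."""

import math

import numpy as np
import pytest
from scipy import stats

from psmap.annotation import AnnotationIndex, AnnotationRecord
from psmap.candidates import Candidate
from psmap.fdr import (
    FDREstimate,
    classify_hit_frame,
    count_frame_hits,
    count_genome_hits,
    estimate_alpha,
    extrapolate_fdr,
    fdr_ann,
    fdr_curve_decoy,
    fdr_curve_genome,
    fdr_decoy,
    fdr_genome,
    protein_fdr,
)
from psmap.genome import GenomeSequence, extract_six_frame_orfs
from psmap.mapping import GenomicHit
from psmap.proteolysis import digest


class TestPointEstimators:
    def test_fdr_decoy(self):
        assert fdr_decoy([5.0] * 100, [5.0], 4.0) == pytest.approx(0.01)
        assert fdr_decoy([5.0] * 10, [], 4.0) == 0.0
        assert fdr_decoy([], [], 4.0) == 0.0
        assert fdr_decoy([1.0], [5.0, 5.0], 4.0) == 1.0  # clamped

    def test_fdr_ann_arithmetic(self):
        assert fdr_ann(0, 100) == 0.0
        assert fdr_ann(5, 5) == pytest.approx(0.6)
        with pytest.raises(ValueError):
            fdr_ann(0, 0)

    def test_fdr_ann_published_counts(self):
        """The consistency check on a deeply annotated single genome:
        829 wrong-frame among 180 059 correct-frame PSMs -> 0.55%."""
        assert round(fdr_ann(829, 180059), 4) == 0.0055

    def test_fdr_genome(self):
        assert fdr_genome(10, 100, 0.0) == pytest.approx(0.1)
        assert fdr_genome(0, 100, 0.3) == 0.0
        assert fdr_genome(10, 100, 0.5) == pytest.approx(0.2)
        with pytest.raises(ValueError):
            fdr_genome(10, 100, 1.0)
        with pytest.raises(ValueError):
            fdr_genome(10, 0, 0.0)
        with pytest.raises(ValueError):
            fdr_genome(101, 100, 0.0)


def hit(start, end, strand="+", contig="c", pid="p0", mult=1):
    return GenomicHit(psm_id=pid, contig_id=contig, strand=strand, start=start,
                      end=end, orf_id="o", offset_aa=0, multiplicity=mult)


class TestFrameCounting:
    @pytest.fixture
    def ann(self):
        # one gene [30, 90) on +, frame 0
        return AnnotationIndex([AnnotationRecord("g1", "c", "+", 30, 90)])

    def test_in_frame_hits_counted_as_N(self, ann):
        hits = [hit(33, 45, pid=f"p{i}") for i in range(4)]
        assert count_frame_hits(hits, ann) == (0, 4)

    def test_planted_wrong_frame_counts(self, ann):
        hits = [hit(33, 45)] + [hit(34, 46, pid=f"w{i}") for i in range(3)] \
            + [hit(33, 45, strand="-", pid="w9")]
        assert count_frame_hits(hits, ann) == (4, 1)

    def test_outside_and_partial_counted_in_neither(self, ann):
        hits = [hit(0, 12), hit(24, 36, pid="p1")]  # outside; straddling
        assert count_frame_hits(hits, ann) == (0, 0)
        assert classify_hit_frame(hits[0], ann) == "outside"
        assert classify_hit_frame(hits[1], ann) == "partial"

    def test_strict_outside_for_n_prime(self, ann):
        hits = [hit(0, 12), hit(24, 36, pid="p1"), hit(33, 45, pid="p2")]
        assert count_genome_hits(hits, ann) == (1, 3)

    def test_ambiguous_exclusion_switch(self, ann):
        hits = [hit(33, 45, mult=2), hit(36, 48, pid="p1")]
        assert count_frame_hits(hits, ann) == (0, 2)
        assert count_frame_hits(hits, ann, exclude_ambiguous=True) == (0, 1)

    def test_fdr_ann_invariant_to_hits_outside_annotation(self, ann):
        hits = [hit(34, 46, pid=f"w{i}") for i in range(3)] + \
               [hit(33, 45, pid=f"c{i}") for i in range(5)]
        base = fdr_ann(*count_frame_hits(hits, ann))
        noisy = hits + [hit(0, 12, pid=f"out{i}") for i in range(10)]
        assert fdr_ann(*count_frame_hits(noisy, ann)) == base

    def test_uniform_false_hits_ratio_near_five_to_one(self, std_fixture, truth_index):
        """Uniformly placed peptides on an annotated genome land in a wrong
        frame about 5 times as often as in the right one."""
        from psmap.mapping import hit_span
        rng = np.random.default_rng(0)
        n = N = 0
        for orf in std_fixture.orfs:
            for off, pep in digest(orf.aa_sequence):
                s, e = hit_span(orf, off, len(pep))
                cls = classify_hit_frame(hit(s, e, strand=orf.strand, contig=orf.contig_id), truth_index)
                if cls == "correct":
                    N += 1
                elif cls == "wrong":
                    n += 1
        assert n / N == pytest.approx(5.0, rel=0.35)


class TestAlpha:
    def _genome_orfs(self):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGT"), size=3000))
        g = GenomeSequence(contig_id="c", sequence=seq)
        return g, extract_six_frame_orfs(g)

    def test_full_annotation_gives_one(self):
        g, orfs = self._genome_orfs()
        ann = AnnotationIndex([AnnotationRecord("g1", "c", "+", 0, g.length)])
        assert estimate_alpha(orfs, ann) == 1.0
        assert estimate_alpha(orfs, ann, mode="length",
                              contig_lengths={"c": g.length}) == 1.0

    def test_empty_annotation_gives_zero(self):
        g, orfs = self._genome_orfs()
        ann = AnnotationIndex([])
        assert estimate_alpha(orfs, ann) == 0.0

    def test_matches_exhaustive_enumeration(self):
        g, orfs = self._genome_orfs()
        ann = AnnotationIndex([AnnotationRecord("g1", "c", "+", 500, 1400),
                               AnnotationRecord("g2", "c", "-", 2000, 2600)])
        # oracle: independent enumeration of digest positions
        from psmap.mapping import hit_span
        inside = total = 0
        for orf in orfs:
            for off, pep in digest(orf.aa_sequence):
                s, e = hit_span(orf, off, len(pep))
                total += 1
                if ann.overlapping("c", s, e):
                    inside += 1
        assert estimate_alpha(orfs, ann) == pytest.approx(inside / total)
        assert 0 < estimate_alpha(orfs, ann) < 1


def cand(orf_id, shat, category=None, same=(), oppo=()):
    return Candidate(
        candidate_id=f"cand:{orf_id}", orf_id=orf_id, contig_id="c", strand="+",
        frame_label=0, cand_start=0, cand_end=30, psm_ids=("p",), n_psm=6,
        n_distinct_peptides=1, shat=shat, shat_flagged=False, start_found=True,
        category=category, overlap_same_strand=same, overlap_opposite_strand=oppo,
    )


class TestProteinFDR:
    def test_no_decoys_zero_everywhere(self):
        est = protein_fdr([cand("a", 3.0), cand("b", 4.0)], [], "classical")
        assert (est.fdr == 0).all() and (est.q == 0).all()

    def test_picked_counts_only_winner(self):
        target = [cand("a", 2.0)]
        decoy = [cand("DECOY_a", 3.0)]
        picked = protein_fdr(target, decoy, "picked")
        classical = protein_fdr(target, decoy, "classical")
        # classical at cutoff 2: decoy and target both counted -> FDR 1
        assert classical.fdr_at(2.0) == 1.0
        # picked drops the losing target: only the decoy remains
        assert picked.inputs["n_target"] == 0
        assert picked.inputs["n_decoy"] == 1

    def test_unpaired_decoy_is_error(self):
        with pytest.raises(ValueError, match="without target"):
            protein_fdr([], [cand("DECOY_zzz", 3.0)], "picked",
                        target_orf_ids={"a", "b"})

    def test_q_monotone_and_bounded(self):
        rng = np.random.default_rng(1)
        targets = [cand(f"t{i}", s) for i, s in enumerate(rng.normal(4, 1, 50))]
        decoys = [cand(f"DECOY_t{i}", s) for i, s in enumerate(rng.normal(1.5, 1, 30))]
        for strategy in ("classical", "picked"):
            est = protein_fdr(targets, decoys, strategy)
            assert ((est.q >= 0) & (est.q <= 1)).all()
            assert (np.diff(est.q) <= 1e-12).all()

    def test_picked_not_above_classical_on_simulation(self):
        """Planted true proteins plus matched decoys: picked is at most
        classical at every cutoff, and both bound the realized FDR."""
        rng = np.random.default_rng(2)
        true_scores = rng.normal(4.5, 0.8, 40)
        false_scores = rng.normal(1.2, 0.5, 15)
        decoy_scores = rng.normal(1.2, 0.5, 15)
        targets = [cand(f"t{i}", s) for i, s in enumerate(true_scores)]
        targets += [cand(f"f{i}", s) for i, s in enumerate(false_scores)]
        decoys = [cand(f"DECOY_x{i}", s) for i, s in enumerate(decoy_scores)]
        picked = protein_fdr(targets, decoys, "picked")
        classical = protein_fdr(targets, decoys, "classical")
        for c in np.union1d(picked.cutoffs, classical.cutoffs):
            assert picked.fdr_at(c) <= classical.fdr_at(c) + 1e-12


class TestPositionalCurves:
    def test_genome_curve_tracks_decoy_curve(self, std_fixture, std_mapping):
        """Positional FDR estimates are proportional to decoy-based ones
        across score cutoffs (rank correlation)."""
        from psmap.mapping import OrfIndex, map_psms
        from psmap.genome import mirror_orfs
        index, targets, hits = std_mapping
        uniq = {p.psm_id: p for p in targets}
        scores = {pid: p.s for pid, p in uniq.items()}
        ann = AnnotationIndex(std_fixture.annotations)
        alpha = estimate_alpha(std_fixture.orfs, ann)
        genome_est = fdr_curve_genome(hits, scores, ann, alpha)
        decoys = [p for p in std_fixture.psms if p.is_decoy]
        decoy_est = fdr_curve_decoy(
            [p.s for p in uniq.values()], [p.s for p in {d.psm_id: d for d in decoys}.values()]
        )
        # compare the two curves on a common score grid
        grid = np.linspace(0.5, 3.0, 25)
        a = [genome_est.fdr_at(c) for c in grid]
        b = [decoy_est.fdr_at(c) for c in grid]
        rho = stats.spearmanr(a, b).statistic
        assert rho > 0.9


class TestExtrapolation:
    def _exp_estimate(self, slope=-1.2, intercept=0.5):
        cutoffs = np.linspace(0.5, 3.0, 26)
        fdr = 10 ** (intercept + slope * cutoffs)
        est = FDREstimate("protein_picked", cutoffs, fdr,
                          inputs={"max_decoy_score": 2.0})
        return est

    def test_exact_decay_recovered(self):
        est = self._exp_estimate()
        ext = extrapolate_fdr(est, (0.5, 2.0))
        assert ext.inputs["slope"] == pytest.approx(-1.2)
        assert ext.inputs["intercept"] == pytest.approx(0.5)

    def test_tail_replaced_continuously(self):
        est = self._exp_estimate()
        est.fdr[est.cutoffs > 2.0] = 0.0  # no decoys beyond shat 2
        est.q = np.minimum.accumulate(est.fdr)
        ext = extrapolate_fdr(est, (0.5, 2.0))
        dense = 10 ** (0.5 + -1.2 * est.cutoffs)
        np.testing.assert_allclose(ext.fdr, dense, rtol=1e-9)

    def test_noisy_decay_slope_within_ci(self):
        rng = np.random.default_rng(4)
        cutoffs = np.linspace(0.5, 2.5, 40)
        noise = rng.normal(0, 0.05, cutoffs.size)
        est = FDREstimate("protein_picked", cutoffs,
                          10 ** (-0.2 - 1.0 * cutoffs + noise),
                          inputs={"max_decoy_score": 2.5})
        ext = extrapolate_fdr(est, (0.5, 2.5))
        fit = stats.linregress(cutoffs, np.log10(est.fdr))
        assert abs(ext.inputs["slope"] - (-1.0)) < 3 * fit.stderr

    def test_too_few_points_error(self):
        est = FDREstimate("x", [1.0, 2.0], [0.1, 0.01])
        with pytest.raises(ValueError, match="3"):
            extrapolate_fdr(est, (0.0, 3.0))
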