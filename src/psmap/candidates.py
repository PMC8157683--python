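"""Candidate proteins from PSM-bearing ORFs.

A candidate is an ORF carrying at least ``min_psm`` mapped PSMs (not
necessarily distinct peptides).  Its C-terminus is the ORF's stop-codon
boundary; its N-terminus is the closest canonical start codon at or before
the first (upstream-most) mapped PSM, falling back to the ORF start when no
in-frame start codon exists upstream.  The aggregate score shat is the mean
of the candidate's three best PSM scores s = -log10(e-value).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .annotation import KNOWN, HYPOTHETICAL, AnnotationIndex, AnnotationRecord
from .genome import GenomeSequence, ORFRecord, orf_nucleotides
from .mapping import GenomicHit
from .psms import PSMRecord

NOVEL = "novel"

#: canonical start codons; GTG/TTG can be added for bacterial alternative starts
DEFAULT_START_CODONS = ("ATG",)


@dataclass(frozen=True)
class Candidate:
    candidate_id: str
    orf_id: str
    contig_id: str
    strand: str
    frame_label: int
    cand_start: int          # 0-based half-open, forward strand
    cand_end: int
    psm_ids: tuple[str, ...]
    n_psm: int
    n_distinct_peptides: int  # unambiguous (multiplicity-1) plain sequences
    shat: float
    shat_flagged: bool       # fewer than top_k scores available
    start_found: bool        # an in-frame canonical start codon was located
    species_id: str = "species0"
    category: str | None = None
    overlap_same_strand: tuple[str, ...] = ()
    overlap_opposite_strand: tuple[str, ...] = ()
    start_diff_frac: float | None = None

    @property
    def length_bp(self) -> int:
        return self.cand_end - self.cand_start

    @property
    def aa_length(self) -> int:
        return self.length_bp // 3


def shat(scores: Sequence[float], top_k: int = 3) -> tuple[float, bool]:
    """Mean of the ``top_k`` best scores; with fewer scores, the mean of all
    (flagged).  Returns (value, flagged)."""
    if len(scores) == 0:
        raise ValueError("shat of empty score list")
    arr = np.sort(np.asarray(scores, dtype=float))[::-1]
    flagged = arr.size < top_k
    return float(arr[: top_k].mean()), flagged


def infer_start_offset(
    orf_nt: str, first_psm_offset_aa: int, start_codons: Sequence[str] = DEFAULT_START_CODONS
) -> int | None:
    """Amino-acid offset of the closest canonical start codon at or before
    the first mapped PSM, scanning the strand-oriented ORF nucleotides.

    The codon at the first PSM's own position counts.  ``None`` when no
    start codon exists in the ORF upstream of (or at) that position.
    """
    codons = set(start_codons)
    for j in range(first_psm_offset_aa, -1, -1):
        if orf_nt[3 * j : 3 * j + 3] in codons:
            return j
    return None


def build_candidates(
    orfs: Iterable[ORFRecord],
    hits: Iterable[GenomicHit],
    psms: Iterable[PSMRecord],
    genomes: Mapping[str, GenomeSequence] | None = None,
    min_psm: int = 6,
    start_codons: Sequence[str] = DEFAULT_START_CODONS,
    top_k: int = 3,
    infer_start: bool = True,
) -> list[Candidate]:
    """One candidate per ORF with >= ``min_psm`` mapped PSMs.

    ``genomes`` (contig_id -> GenomeSequence) is needed for start-codon
    inference; with ``infer_start=False`` (e.g. for mirrored decoy ORFs,
    where genomic starts are meaningless) candidates span the whole ORF.
    The result is deterministic and independent of input ordering.
    """
    orf_by_id = {o.orf_id: o for o in orfs}
    psm_by_id: dict[str, PSMRecord] = {}
    for p in psms:
        psm_by_id.setdefault(p.psm_id, p)
    grouped: dict[str, list[GenomicHit]] = {}
    for h in hits:
        grouped.setdefault(h.orf_id, []).append(h)

    out: list[Candidate] = []
    for orf_id in sorted(grouped):
        orf = orf_by_id.get(orf_id)
        if orf is None:
            raise KeyError(f"hit references unknown ORF {orf_id!r}")
        ohits = grouped[orf_id]
        psm_ids = sorted({h.psm_id for h in ohits})
        if len(psm_ids) < min_psm:
            continue
        scores = [psm_by_id[pid].s for pid in psm_ids]
        value, flagged = shat(scores, top_k=top_k)
        unambiguous_peps = {
            psm_by_id[h.psm_id].peptide for h in ohits if not h.ambiguous
        }
        first_off = min(h.offset_aa for h in ohits)
        j: int | None = None
        if infer_start and genomes is not None:
            nt = orf_nucleotides(orf, genomes[orf.contig_id])
            j = infer_start_offset(nt, first_off, start_codons)
        j_eff = 0 if j is None else j
        if orf.strand == "+":
            cstart, cend = orf.start + 3 * j_eff, orf.end
        else:
            cstart, cend = orf.start, orf.end - 3 * j_eff
        out.append(
            Candidate(
                candidate_id=f"cand:{orf_id}",
                orf_id=orf_id,
                contig_id=orf.contig_id,
                strand=orf.strand,
                frame_label=orf.frame_label,
                cand_start=cstart,
                cand_end=cend,
                psm_ids=tuple(psm_ids),
                n_psm=len(psm_ids),
                n_distinct_peptides=len(unambiguous_peps),
                shat=value,
                shat_flagged=flagged,
                start_found=j is not None,
                species_id=orf.species_id,
            )
        )
    return out


def classify_candidate(candidate: Candidate, index: AnnotationIndex) -> Candidate:
    """Category versus the existing annotation.

    known/hypothetical when an annotated protein overlaps in the same
    strand *and* reading frame (known wins when both kinds overlap);
    novel otherwise.  Overlap lists are filled for both strands regardless
    of frame.  For annotated candidates the strand-oriented start
    difference is reported as a fraction of the annotated protein length
    (0 = identical start; negative = candidate N-terminally shorter),
    computed against the in-frame record with the largest overlap.
    """
    over = index.overlapping(candidate.contig_id, candidate.cand_start, candidate.cand_end)
    same = tuple(r.gene_id for r in over if r.strand == candidate.strand)
    oppo = tuple(r.gene_id for r in over if r.strand != candidate.strand)
    in_frame = [
        r for r in over
        if r.strand == candidate.strand and r.frame_label == candidate.frame_label
    ]
    if not in_frame:
        return replace(
            candidate,
            category=NOVEL,
            overlap_same_strand=same,
            overlap_opposite_strand=oppo,
            start_diff_frac=None,
        )
    category = KNOWN if any(r.status == KNOWN for r in in_frame) else HYPOTHETICAL

    def _overlap_bp(r: AnnotationRecord) -> int:
        return min(r.end, candidate.cand_end) - max(r.start, candidate.cand_start)

    best = max(in_frame, key=lambda r: (_overlap_bp(r), -r.start))
    if candidate.strand == "+":
        diff = best.start - candidate.cand_start
    else:
        diff = candidate.cand_end - best.end
    return replace(
        candidate,
        category=category,
        overlap_same_strand=same,
        overlap_opposite_strand=oppo,
        start_diff_frac=diff / best.length,
    )


def classify_candidates(
    candidates: Iterable[Candidate], index: AnnotationIndex
) -> list[Candidate]:
    return [classify_candidate(c, index) for c in candidates]
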