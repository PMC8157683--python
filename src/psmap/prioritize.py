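"""Decision rules ranking novel candidates for follow-up.

A candidate is *transcribed* when more than 70% of its length lies above
the organism-wide median RNA coverage (median over every genomic position,
zeros included).  An annotated gene overlapping a candidate counts as
*translated* when it is identified by more than 6 unique PSMs.  The default
decision tree over the aggregate score shat:

* shat >= 3.5 and a translated same-strand overlap  -> frameshift or
  annotation error (the overlapping gene model is probably wrong);
* shat >= 3.5 with >= 2 distinct peptides or transcription -> high;
* shat >= 3.5 otherwise -> low;
* 2.5 <= shat < 3.5 with >= 2 distinct peptides -> rescued;
* 2.5 <= shat < 3.5 with a translated opposite-strand overlap -> likely
  false (long antisense overlaps of coding regions are very rare);
* 2.5 <= shat < 3.5 otherwise -> low;
* shat < 2.5 -> rejected.

Every threshold is configurable and every fired rule is recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .annotation import AnnotationIndex
from .candidates import Candidate
from .fdr import FDREstimate
from .mapping import GenomicHit

TIER_HIGH = "high"
TIER_FRAMESHIFT = "frameshift_or_annotation_error"
TIER_RESCUED = "rescued"
TIER_LOW = "low"
TIER_LIKELY_FALSE = "likely_false"
TIER_REJECTED = "rejected"

#: rank order used by the monotonicity property (larger = better or at
#: least not worse); the frameshift call is an actionable finding, not a
#: demotion, and ranks with high.
TIER_RANK = {
    TIER_REJECTED: 0,
    TIER_LIKELY_FALSE: 1,
    TIER_LOW: 2,
    TIER_RESCUED: 3,
    TIER_FRAMESHIFT: 4,
    TIER_HIGH: 4,
}


@dataclass(frozen=True)
class Thresholds:
    min_psm: int = 6
    shat_high: float = 3.5
    shat_low: float = 2.5
    transcribed_frac: float = 0.70
    translated_unique_psms: int = 6   # strict: translated iff count > this
    rescue_distinct_peptides: int = 2
    top_k: int = 3


@dataclass(frozen=True)
class EvidenceContext:
    transcribed: bool | None = None      # None = no coverage available
    frac_above_median: float | None = None
    overlap_same_strand_translated: bool = False
    overlap_opposite_translated: bool = False
    unique_psms_of_overlapping_genes: Mapping[str, int] = field(default_factory=dict)


@dataclass(frozen=True)
class PriorityCall:
    candidate_id: str
    tier: str
    reasons: tuple[str, ...]


def genome_median(coverage: Mapping[str, np.ndarray], contigs: Iterable[str] | None = None) -> float:
    """Median RNA coverage over all genomic positions (zeros included) of
    the given contigs (default: all)."""
    keys = list(contigs) if contigs is not None else sorted(coverage)
    arrays = [np.asarray(coverage[c]) for c in keys]
    if not arrays:
        raise ValueError("no coverage arrays")
    return float(np.median(np.concatenate(arrays)))


def classify_transcription(
    candidate: Candidate,
    coverage: Mapping[str, np.ndarray] | None,
    median: float,
    transcribed_frac: float = 0.70,
) -> tuple[float | None, bool | None]:
    """(frac_above_median, transcribed); strictly-greater comparison, so a
    flat track at the median is not transcription evidence.  Missing
    coverage yields (None, None) and downstream rules treat unknown as not
    transcribed."""
    if coverage is None or candidate.contig_id not in coverage:
        return None, None
    cov = np.asarray(coverage[candidate.contig_id])
    span = cov[candidate.cand_start : candidate.cand_end]
    if span.size == 0:
        return None, None
    frac = float((span > median).mean())
    return frac, frac > transcribed_frac


def count_unique_gene_psms(
    hits: Iterable[GenomicHit], index: AnnotationIndex
) -> dict[str, int]:
    """Unique (unambiguously mapped) PSMs per annotated gene: distinct
    psm_ids with a multiplicity-1 hit fully inside the gene span in the
    gene's strand and frame."""
    per_gene: dict[str, set[str]] = {}
    for h in hits:
        if h.ambiguous:
            continue
        fl = h.start % 3 if h.strand == "+" else (h.start % 3) - 3
        for rec in index.containing(h.contig_id, h.start, h.end):
            if rec.strand == h.strand and rec.frame_label == fl:
                per_gene.setdefault(rec.gene_id, set()).add(h.psm_id)
    return {g: len(s) for g, s in per_gene.items()}


def mark_overlap_translation(
    candidate: Candidate,
    gene_unique_psms: Mapping[str, int],
    translated_unique_psms: int = 6,
) -> tuple[bool, bool, dict[str, int]]:
    """(same_strand_translated, opposite_translated, per-gene counts) for
    the genes overlapping a candidate; translated iff unique PSMs is
    strictly greater than the threshold."""
    counts = {
        g: gene_unique_psms.get(g, 0)
        for g in (*candidate.overlap_same_strand, *candidate.overlap_opposite_strand)
    }
    same = any(
        counts[g] > translated_unique_psms for g in candidate.overlap_same_strand
    )
    oppo = any(
        counts[g] > translated_unique_psms for g in candidate.overlap_opposite_strand
    )
    return same, oppo, counts


def build_context(
    candidate: Candidate,
    coverage: Mapping[str, np.ndarray] | None,
    median: float | None,
    gene_unique_psms: Mapping[str, int],
    thresholds: Thresholds = Thresholds(),
) -> EvidenceContext:
    if coverage is not None and median is not None:
        frac, transcribed = classify_transcription(
            candidate, coverage, median, thresholds.transcribed_frac
        )
    else:
        frac, transcribed = None, None
    same, oppo, counts = mark_overlap_translation(
        candidate, gene_unique_psms, thresholds.translated_unique_psms
    )
    return EvidenceContext(
        transcribed=transcribed,
        frac_above_median=frac,
        overlap_same_strand_translated=same,
        overlap_opposite_translated=oppo,
        unique_psms_of_overlapping_genes=counts,
    )


def prioritize(
    candidate: Candidate,
    context: EvidenceContext,
    thresholds: Thresholds = Thresholds(),
) -> PriorityCall:
    """Assign exactly one tier to a novel candidate; fired rules recorded."""
    reasons: list[str] = []
    s = candidate.shat
    multi = candidate.n_distinct_peptides >= thresholds.rescue_distinct_peptides
    transcribed = context.transcribed is True  # unknown is not evidence
    if s >= thresholds.shat_high:
        reasons.append(f"shat>={thresholds.shat_high}")
        if context.overlap_same_strand_translated:
            reasons.append("same_strand_translated_overlap")
            tier = TIER_FRAMESHIFT
        elif multi or transcribed:
            reasons.append("distinct_peptides" if multi else "transcribed")
            tier = TIER_HIGH
        else:
            reasons.append("no_distinct_peptides_no_transcription")
            tier = TIER_LOW
    elif s >= thresholds.shat_low:
        reasons.append(f"{thresholds.shat_low}<=shat<{thresholds.shat_high}")
        if multi:
            reasons.append("distinct_peptides_rescue")
            tier = TIER_RESCUED
        elif context.overlap_opposite_translated:
            reasons.append("opposite_strand_translated_overlap")
            tier = TIER_LIKELY_FALSE
        else:
            reasons.append("single_peptide")
            tier = TIER_LOW
    else:
        reasons.append(f"shat<{thresholds.shat_low}")
        tier = TIER_REJECTED
    return PriorityCall(candidate_id=candidate.candidate_id, tier=tier, reasons=tuple(reasons))


def shat_cutoff_from_q(estimate: FDREstimate, q_target: float) -> float:
    """Smallest grid cutoff whose q-value is <= the target; replaces the
    fixed shat threshold by a data-driven one."""
    ok = estimate.q <= q_target
    if not ok.any():
        raise ValueError(
            f"q never reaches {q_target}; minimum achievable q = {float(estimate.q.min()):.4g}"
        )
    return float(estimate.cutoffs[ok][0])
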