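"""End-to-end orchestration: ORFs -> PSM filter -> genome mapping ->
candidates -> FDR estimates -> prioritization, with a run manifest of
per-stage counts."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .annotation import AnnotationIndex, AnnotationRecord
from .candidates import (
    Candidate,
    DEFAULT_START_CODONS,
    build_candidates,
    classify_candidates,
)
from .fdr import (
    FDREstimate,
    count_frame_hits,
    count_genome_hits,
    estimate_alpha,
    fdr_ann,
    fdr_genome,
    protein_fdr,
)
from .genome import GenomeSequence, ORFRecord, extract_six_frame_orfs, mirror_orfs
from .mapping import GenomicHit, OrfIndex, map_psms, multiplicity_profile, psm_coverage_track
from .prioritize import (
    PriorityCall,
    Thresholds,
    build_context,
    count_unique_gene_psms,
    genome_median,
    prioritize,
)
from .psms import DECOY_PREFIX, FilterResult, PSMRecord, filter_psms, unique_psms


@dataclass(frozen=True)
class PipelineConfig:
    psm_fdr: float = 0.01
    min_psm: int = 6
    min_orf_len_aa: int = 0
    start_codons: tuple[str, ...] = DEFAULT_START_CODONS
    decoy_prefix: str = DECOY_PREFIX
    thresholds: Thresholds = field(default_factory=Thresholds)
    alpha_mode: str = "tryptic"
    il_equivalent: bool = False


@dataclass
class PipelineResult:
    orfs: list[ORFRecord]
    filter_result: FilterResult
    hits: list[GenomicHit]
    decoy_hits: list[GenomicHit]
    multiplicity: dict[int, float]
    candidates: list[Candidate]            # classified, target
    decoy_candidates: list[Candidate]
    alpha: float
    fdr_estimates: dict[str, float | FDREstimate]
    priorities: list[PriorityCall]
    counts: dict                            # run manifest


def run_pipeline(
    genomes: Sequence[GenomeSequence],
    annotations: Sequence[AnnotationRecord],
    psms: Sequence[PSMRecord],
    coverage: Mapping[str, np.ndarray] | None = None,
    config: PipelineConfig = PipelineConfig(),
) -> PipelineResult:
    genome_map = {g.contig_id: g for g in genomes}
    counts: dict = {"config": {
        "psm_fdr": config.psm_fdr, "min_psm": config.min_psm,
        "start_codons": list(config.start_codons),
        "thresholds": vars(config.thresholds).copy(),
    }}

    # 1. six-frame ORF database (targets + mirrored decoys)
    orfs = [o for g in genomes for o in extract_six_frame_orfs(g, config.min_orf_len_aa)]
    decoy_orfs = mirror_orfs(orfs, config.decoy_prefix)
    counts["n_orfs"] = len(orfs)

    # 2. PSM-level decoy FDR filter
    counts["n_psms_read"] = len({p.psm_id for p in psms})
    fres = filter_psms(psms, config.psm_fdr)
    counts["n_targets_pass"] = len({p.psm_id for p in fres.targets})
    counts["n_decoys_pass"] = len({p.psm_id for p in fres.decoys})
    counts["psm_score_threshold"] = fres.threshold

    # 3. genomic mapping
    index = OrfIndex(orfs, il_equivalent=config.il_equivalent)
    decoy_index = OrfIndex(decoy_orfs, il_equivalent=config.il_equivalent)
    hits = map_psms(fres.targets, index)
    decoy_hits = map_psms(fres.decoys, decoy_index)
    mult = multiplicity_profile(hits) if hits else {}
    counts["n_hits"] = len(hits)
    counts["multiplicity_profile"] = mult

    # 4. candidates
    cands = build_candidates(
        orfs, hits, fres.targets, genome_map,
        min_psm=config.min_psm, start_codons=config.start_codons,
        top_k=config.thresholds.top_k,
    )
    dcands = build_candidates(
        decoy_orfs, decoy_hits, fres.decoys, None,
        min_psm=config.min_psm, top_k=config.thresholds.top_k,
        infer_start=False,
    )
    ann_index = AnnotationIndex(annotations)
    cands = classify_candidates(cands, ann_index)
    counts["n_candidates"] = len(cands)
    counts["n_decoy_candidates"] = len(dcands)
    counts["candidates_by_category"] = {
        cat: sum(1 for c in cands if c.category == cat)
        for cat in ("known", "hypothetical", "novel")
    }

    # 5. FDR estimates
    estimates: dict[str, float | FDREstimate] = {}
    n, N = count_frame_hits(hits, ann_index)
    counts["frame_hits"] = {"n": n, "N": N}
    if n + N:
        estimates["fdr_ann"] = fdr_ann(n, N)
    alpha = estimate_alpha(orfs, ann_index, mode=config.alpha_mode,
                           contig_lengths={g.contig_id: g.length for g in genomes})
    n_prime, N_prime = count_genome_hits(hits, ann_index)
    counts["genome_hits"] = {"n_prime": n_prime, "N_prime": N_prime, "alpha": alpha}
    if N_prime:
        estimates["fdr_genome"] = fdr_genome(n_prime, N_prime, alpha)
    estimates["fdr_decoy_at_threshold"] = fres.fdr_at_threshold
    target_orf_ids = {o.orf_id for o in orfs}
    for strategy in ("classical", "picked"):
        estimates[f"protein_{strategy}"] = protein_fdr(
            cands, dcands, strategy=strategy,
            decoy_prefix=config.decoy_prefix, target_orf_ids=target_orf_ids,
        )

    # 6. prioritization of novel candidates
    gene_psms = count_unique_gene_psms(hits, ann_index)
    medians: dict[str, float] = {}
    if coverage is not None:
        by_species: dict[str, list[str]] = {}
        for g in genomes:
            by_species.setdefault(g.species_id, []).append(g.contig_id)
        for sp, contigs in by_species.items():
            present = [c for c in contigs if c in coverage]
            if present:
                medians[sp] = genome_median(coverage, present)
    priorities = []
    for c in cands:
        if c.category != "novel":
            continue
        ctx = build_context(
            c, coverage, medians.get(c.species_id), gene_psms, config.thresholds
        )
        priorities.append(prioritize(c, ctx, config.thresholds))
    counts["priorities_by_tier"] = {}
    for p in priorities:
        counts["priorities_by_tier"][p.tier] = counts["priorities_by_tier"].get(p.tier, 0) + 1

    return PipelineResult(
        orfs=orfs,
        filter_result=fres,
        hits=hits,
        decoy_hits=decoy_hits,
        multiplicity=mult,
        candidates=cands,
        decoy_candidates=dcands,
        alpha=alpha,
        fdr_estimates=estimates,
        priorities=priorities,
        counts=counts,
    )
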