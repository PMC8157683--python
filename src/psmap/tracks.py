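"""Genome-browser track emission (BED, BED12, bedGraph, GFF3) and the TSV
serialisations that make the pipeline stages re-entrant.

Internal coordinates are 0-based half-open; BED/bedGraph share that
convention, GFF3 is written 1-based inclusive.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .annotation import AnnotationRecord, write_gff3
from .candidates import Candidate
from .mapping import GenomicHit
from .prioritize import (
    PriorityCall,
    TIER_FRAMESHIFT,
    TIER_HIGH,
    TIER_LIKELY_FALSE,
    TIER_LOW,
    TIER_REJECTED,
    TIER_RESCUED,
)
from .fdr import FDREstimate

TIER_COLORS = {
    TIER_HIGH: "0,160,0",
    TIER_FRAMESHIFT: "160,0,160",
    TIER_RESCUED: "0,120,200",
    TIER_LOW: "150,150,150",
    TIER_LIKELY_FALSE: "230,140,0",
    TIER_REJECTED: "200,0,0",
}


def _check_span(contig, start, end, contig_lengths) -> None:
    if start < 0 or (contig_lengths is not None and end > contig_lengths[contig]):
        raise ValueError(f"span [{start},{end}) overflows contig {contig}")


def write_candidate_bed(
    candidates: Sequence[Candidate],
    path,
    tiers: Mapping[str, str] | None = None,
    contig_lengths: Mapping[str, int] | None = None,
) -> None:
    """BED9, itemRgb coloured by priority tier (grey when untiered)."""
    with open(path, "w") as fh:
        for c in candidates:
            _check_span(c.contig_id, c.cand_start, c.cand_end, contig_lengths)
            tier = (tiers or {}).get(c.candidate_id)
            color = TIER_COLORS.get(tier, "120,120,120")
            score = int(min(1000, round(100 * max(c.shat, 0))))
            fh.write(
                f"{c.contig_id}\t{c.cand_start}\t{c.cand_end}\t{c.candidate_id}\t"
                f"{score}\t{c.strand}\t{c.cand_start}\t{c.cand_end}\t{color}\n"
            )


def write_hits_bed12(
    hits: Sequence[GenomicHit], path, contig_lengths: Mapping[str, int] | None = None
) -> None:
    """One BED12 line per hit (single block); the score column carries the
    PSM's mapping multiplicity."""
    with open(path, "w") as fh:
        for h in hits:
            _check_span(h.contig_id, h.start, h.end, contig_lengths)
            fh.write(
                f"{h.contig_id}\t{h.start}\t{h.end}\t{h.psm_id}\t{h.multiplicity}\t"
                f"{h.strand}\t{h.start}\t{h.end}\t0\t1\t{h.end - h.start},\t0,\n"
            )


def write_bedgraph(
    tracks: Mapping[tuple[str, str], np.ndarray], path, header: str | None = None
) -> None:
    """Run-length encoded bedGraph; zero runs are omitted.  Keys are
    (contig, strand) with strand '.' for unstranded tracks; stranded tracks
    are distinguished by a trackline comment per strand."""
    with open(path, "w") as fh:
        if header:
            fh.write(header.rstrip("\n") + "\n")
        for (contig, strand), values in sorted(tracks.items()):
            if strand != ".":
                fh.write(f"# strand={strand}\n")
            values = np.asarray(values)
            if values.size == 0:
                continue
            change = np.flatnonzero(np.diff(values)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [values.size]])
            for a, b in zip(starts, ends):
                v = values[a]
                if v != 0:
                    fh.write(f"{contig}\t{a}\t{b}\t{v}\n")


def read_bedgraph(path, contig_lengths: Mapping[str, int]) -> dict[str, np.ndarray]:
    """Unstranded bedGraph back into dense per-contig arrays."""
    cov = {c: np.zeros(n, dtype=np.int64) for c, n in contig_lengths.items()}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            contig, a, b, v = line.split("\t")[:4]
            cov[contig][int(a):int(b)] = int(float(v))
    return cov


def read_bed(path) -> list[tuple[str, int, int, str, int, str]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            out.append((f[0], int(f[1]), int(f[2]), f[3], int(f[4]), f[5]))
    return out


def candidates_to_gff3(candidates: Sequence[Candidate], path, tiers=None) -> None:
    records = [
        AnnotationRecord(
            gene_id=c.candidate_id,
            contig_id=c.contig_id,
            strand=c.strand,
            start=c.cand_start,
            end=c.cand_end,
        )
        for c in candidates
    ]
    write_gff3(records, path, source="psmap")


# ---------------------------------------------------------------------------
# TSV serialisations


def hits_to_tsv(hits: Sequence[GenomicHit], path) -> None:
    pd.DataFrame(
        [
            {
                "psm_id": h.psm_id, "contig_id": h.contig_id, "strand": h.strand,
                "start": h.start, "end": h.end, "orf_id": h.orf_id,
                "offset_aa": h.offset_aa, "multiplicity": h.multiplicity,
            }
            for h in hits
        ]
    ).to_csv(path, sep="\t", index=False)


def hits_from_tsv(path) -> list[GenomicHit]:
    df = pd.read_csv(path, sep="\t", dtype={"psm_id": str, "contig_id": str,
                                            "strand": str, "orf_id": str})
    return [
        GenomicHit(
            psm_id=r.psm_id, contig_id=r.contig_id, strand=r.strand,
            start=int(r.start), end=int(r.end), orf_id=r.orf_id,
            offset_aa=int(r.offset_aa), multiplicity=int(r.multiplicity),
        )
        for r in df.itertuples(index=False)
    ]


def candidates_to_tsv(candidates: Sequence[Candidate], path) -> None:
    pd.DataFrame(
        [
            {
                "candidate_id": c.candidate_id, "orf_id": c.orf_id,
                "contig_id": c.contig_id, "strand": c.strand,
                "frame_label": c.frame_label, "cand_start": c.cand_start,
                "cand_end": c.cand_end, "n_psm": c.n_psm,
                "n_distinct_peptides": c.n_distinct_peptides,
                "shat": repr(c.shat), "shat_flagged": int(c.shat_flagged),
                "start_found": int(c.start_found), "species_id": c.species_id,
                "category": c.category or "",
                "overlap_same_strand": ";".join(c.overlap_same_strand),
                "overlap_opposite_strand": ";".join(c.overlap_opposite_strand),
                "start_diff_frac": "" if c.start_diff_frac is None else repr(c.start_diff_frac),
                "psm_ids": ";".join(c.psm_ids),
                "homology_label": "",   # filled externally (known/hypothetical/none)
            }
            for c in candidates
        ]
    ).to_csv(path, sep="\t", index=False)


def candidates_from_tsv(path) -> list[Candidate]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for r in df.itertuples(index=False):
        out.append(
            Candidate(
                candidate_id=r.candidate_id, orf_id=r.orf_id, contig_id=r.contig_id,
                strand=r.strand, frame_label=int(r.frame_label),
                cand_start=int(r.cand_start), cand_end=int(r.cand_end),
                psm_ids=tuple(x for x in r.psm_ids.split(";") if x),
                n_psm=int(r.n_psm), n_distinct_peptides=int(r.n_distinct_peptides),
                shat=float(r.shat), shat_flagged=bool(int(r.shat_flagged)),
                start_found=bool(int(r.start_found)), species_id=r.species_id,
                category=r.category or None,
                overlap_same_strand=tuple(x for x in r.overlap_same_strand.split(";") if x),
                overlap_opposite_strand=tuple(x for x in r.overlap_opposite_strand.split(";") if x),
                start_diff_frac=float(r.start_diff_frac) if r.start_diff_frac else None,
            )
        )
    return out


def fdr_to_tsv(estimates: Mapping[str, FDREstimate] | Sequence[FDREstimate], path) -> None:
    if isinstance(estimates, Mapping):
        estimates = list(estimates.values())
    rows = []
    for est in estimates:
        for c, f, q in zip(est.cutoffs, est.fdr, est.q):
            rows.append({"strategy": est.strategy, "cutoff": c, "fdr": f, "q": q})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def priorities_to_tsv(calls: Sequence[PriorityCall], path) -> None:
    pd.DataFrame(
        [{"candidate_id": p.candidate_id, "tier": p.tier, "reasons": ";".join(p.reasons)}
         for p in calls]
    ).to_csv(path, sep="\t", index=False)


def multiplicity_to_tsv(profile: Mapping[int, float], path) -> None:
    pd.DataFrame(
        [{"multiplicity": m, "fraction": f} for m, f in sorted(profile.items())]
    ).to_csv(path, sep="\t", index=False)


def export_tracks(
    outdir,
    candidates: Sequence[Candidate] = (),
    hits: Sequence[GenomicHit] = (),
    coverage: Mapping[str, np.ndarray] | None = None,
    psm_coverage: Mapping[tuple[str, str], np.ndarray] | None = None,
    tiers: Mapping[str, str] | None = None,
    contig_lengths: Mapping[str, int] | None = None,
) -> dict[str, str]:
    """Browser bundle: candidate BED (tier-coloured), per-tier BEDs, hit
    BED12, PSM-coverage bedGraph, novel-candidate GFF3."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    p = outdir / "candidates.bed"
    write_candidate_bed(candidates, p, tiers=tiers, contig_lengths=contig_lengths)
    paths["candidates_bed"] = str(p)

    if tiers:
        for tier in sorted(set(tiers.values())):
            sub = [c for c in candidates if tiers.get(c.candidate_id) == tier]
            p = outdir / f"candidates.{tier}.bed"
            write_candidate_bed(sub, p, tiers=tiers, contig_lengths=contig_lengths)
            paths[f"candidates_bed_{tier}"] = str(p)

    p = outdir / "psm_hits.bed12"
    write_hits_bed12(hits, p, contig_lengths=contig_lengths)
    paths["hits_bed12"] = str(p)

    if psm_coverage is not None:
        p = outdir / "psm_coverage.bedgraph"
        write_bedgraph(psm_coverage, p)
        paths["psm_coverage"] = str(p)

    novel = [c for c in candidates if c.category == "novel"]
    p = outdir / "novel_candidates.gff3"
    candidates_to_gff3(novel, p)
    paths["novel_gff3"] = str(p)
    return paths
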