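"""Mapping peptides of PSMs back to genomic coordinates.

A peptide at amino-acid offset ``j`` of an ORF occupies the genomic span
``[orf.start + 3j, orf.start + 3(j + len))`` on the forward strand and
``[orf.end - 3(j + len), orf.end - 3j)`` on the reverse strand.  Every
occurrence of the peptide anywhere in the ORF database yields one hit, so
mapping ambiguity is discovered even when the search engine reported a
single reference; the number of distinct genomic loci is the PSM's
*multiplicity*.
"""

from __future__ import annotations

from bisect import bisect_right
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genome import ORFRecord
from .psms import PSMRecord

SEPARATOR = "\n"  # never an amino acid, so matches cannot cross ORFs


@dataclass(frozen=True)
class GenomicHit:
    psm_id: str
    contig_id: str
    strand: str
    start: int
    end: int
    orf_id: str
    offset_aa: int
    multiplicity: int = 1

    @property
    def locus(self) -> tuple[str, str, int, int]:
        return (self.contig_id, self.strand, self.start, self.end)

    @property
    def ambiguous(self) -> bool:
        return self.multiplicity > 1


class OrfIndex:
    """Substring index over an ORF database.

    Occurrence search runs on one concatenated string (C-speed ``str.find``)
    with a separator that cannot match an amino acid; results are cached per
    peptide.  With ``il_equivalent=True`` isoleucine and leucine are folded
    together before matching.
    """

    def __init__(self, orfs: Sequence[ORFRecord], il_equivalent: bool = False):
        self.orfs = list(orfs)
        self.by_id: dict[str, ORFRecord] = {o.orf_id: o for o in self.orfs}
        if len(self.by_id) != len(self.orfs):
            raise ValueError("duplicate orf_id in index")
        self.il_equivalent = il_equivalent
        self._starts: list[int] = []
        parts = []
        pos = 0
        for o in self.orfs:
            self._starts.append(pos)
            seq = self._fold(o.aa_sequence)
            parts.append(seq)
            pos += len(seq) + 1
        self._cat = SEPARATOR.join(parts)
        self._cache: dict[str, list[tuple[int, int]]] = {}

    def _fold(self, seq: str) -> str:
        return seq.replace("I", "L") if self.il_equivalent else seq

    def occurrences(self, peptide: str) -> list[tuple[ORFRecord, int]]:
        """All (orf, aa_offset) occurrences of the plain peptide."""
        pep = self._fold(peptide)
        hit_list = self._cache.get(pep)
        if hit_list is None:
            hit_list = []
            pos = self._cat.find(pep)
            while pos != -1:
                i = bisect_right(self._starts, pos) - 1
                hit_list.append((i, pos - self._starts[i]))
                pos = self._cat.find(pep, pos + 1)
            self._cache[pep] = hit_list
        return [(self.orfs[i], off) for i, off in hit_list]


def hit_span(orf: ORFRecord, offset_aa: int, pep_len: int) -> tuple[int, int]:
    """Forward-strand genomic span of a peptide inside an ORF."""
    if orf.strand == "+":
        start = orf.start + 3 * offset_aa
        return start, start + 3 * pep_len
    end = orf.end - 3 * offset_aa
    return end - 3 * pep_len, end


def map_psm(psm: PSMRecord, index: OrfIndex, strict: bool = True) -> list[GenomicHit]:
    """One hit per occurrence of the PSM's peptide in the index.

    With ``strict=True`` the search engine's reported reference must be in
    the index and must actually contain the peptide, guarding against a
    database/index mismatch.
    """
    occ = index.occurrences(psm.peptide)
    if strict:
        if psm.matched_ref not in index.by_id:
            raise KeyError(f"matched_ref {psm.matched_ref!r} not in ORF index")
        if not any(o.orf_id == psm.matched_ref for o, _ in occ):
            raise ValueError(
                f"peptide {psm.peptide!r} absent from matched ORF {psm.matched_ref!r}"
            )
    loci: dict[tuple[str, str, int, int], tuple[ORFRecord, int]] = {}
    for orf, off in occ:
        start, end = hit_span(orf, off, len(psm.peptide))
        loci.setdefault((orf.contig_id, orf.strand, start, end), (orf, off))
    mult = len(loci)
    return [
        GenomicHit(
            psm_id=psm.psm_id,
            contig_id=contig,
            strand=strand,
            start=start,
            end=end,
            orf_id=orf.orf_id,
            offset_aa=off,
            multiplicity=mult,
        )
        for (contig, strand, start, end), (orf, off) in sorted(loci.items())
    ]


def map_psms(
    psms: Iterable[PSMRecord], index: OrfIndex, strict: bool = True
) -> list[GenomicHit]:
    """Map unique PSMs (one per psm_id); peptide lookups are cached."""
    seen: set[str] = set()
    hits: list[GenomicHit] = []
    for p in psms:
        if p.psm_id in seen:
            continue
        seen.add(p.psm_id)
        hits.extend(map_psm(p, index, strict=strict))
    return hits


def hits_by_psm(hits: Iterable[GenomicHit]) -> dict[str, list[GenomicHit]]:
    out: dict[str, list[GenomicHit]] = defaultdict(list)
    for h in hits:
        out[h.psm_id].append(h)
    return dict(out)


def multiplicity_profile(hits: Iterable[GenomicHit]) -> dict[int, float]:
    """Fraction of PSMs mapping to m distinct loci, for each m >= 1.

    Distinct loci are distinct (contig, strand, start) triples; the
    fractions are over PSMs, not over hits, and sum to one.
    """
    loci: dict[str, set[tuple[str, str, int]]] = defaultdict(set)
    for h in hits:
        loci[h.psm_id].add((h.contig_id, h.strand, h.start))
    if not loci:
        raise ValueError("no hits")
    counts: dict[int, int] = defaultdict(int)
    for s in loci.values():
        counts[len(s)] += 1
    n = len(loci)
    return {m: c / n for m, c in sorted(counts.items())}


def psm_coverage_track(
    hits: Iterable[GenomicHit], contig_lengths: Mapping[str, int]
) -> dict[tuple[str, str], np.ndarray]:
    """Per-base PSM coverage by (contig, strand): coverage at base b is the
    number of hits whose span contains b."""
    tracks = {
        (c, s): np.zeros(n + 1, dtype=np.int64)
        for c, n in contig_lengths.items()
        for s in "+-"
    }
    for h in hits:
        d = tracks[(h.contig_id, h.strand)]
        d[h.start] += 1
        d[h.end] -= 1
    return {k: np.cumsum(d[:-1]) for k, d in tracks.items()}
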