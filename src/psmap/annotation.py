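"""Existing protein annotation: GFF3 ingestion, known/hypothetical
classification and interval indexing.

An annotated protein counts as *hypothetical* when its UniProt-style
validation level is 1 ("protein uncertain") or 2 ("protein predicted"), or
when any of a fixed list of free-text tags appears in its attributes;
everything else is *known*.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import gffutils
from intervaltree import IntervalTree

from .genome import frame_label

#: Free-text annotations that mark a protein as hypothetical
#: (matched case-insensitively as substrings of attribute values).
HYPOTHETICAL_TAGS = (
    "frameshifted",
    "internal stop",
    "hypothetical",
    "putative",
    "pseudogene",
)

#: UniProt validation levels interpreted as hypothetical.
HYPOTHETICAL_LEVELS = frozenset({1, 2})

KNOWN = "known"
HYPOTHETICAL = "hypothetical"


@dataclass(frozen=True)
class AnnotationRecord:
    gene_id: str
    contig_id: str
    strand: str
    start: int   # 0-based half-open, forward strand
    end: int
    status: str = KNOWN
    raw_tags: tuple[str, ...] = ()

    @property
    def frame_label(self) -> int:
        # the CDS span has length divisible by 3, so labelling by the
        # forward-strand start is frame-consistent on both strands
        return frame_label(self.strand, self.start)

    @property
    def length(self) -> int:
        return self.end - self.start


def classify_annotation_status(
    raw_tags: Iterable[str], validation_level: int | None = None
) -> str:
    """``hypothetical`` iff validation level is 1 or 2 or any tag from the
    fixed list occurs (case-insensitive substring); else ``known``."""
    if validation_level is not None and validation_level in HYPOTHETICAL_LEVELS:
        return HYPOTHETICAL
    for tag in raw_tags:
        low = tag.lower()
        if any(k in low for k in HYPOTHETICAL_TAGS):
            return HYPOTHETICAL
    return KNOWN


def read_gff3(
    path, validation_levels: Mapping[str, int] | None = None
) -> list[AnnotationRecord]:
    """CDS features of a GFF3 file as annotation records.

    ``validation_levels`` maps gene_id -> UniProt validation level (the
    "validation hash map" companion file); missing ids mean no level.
    """
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    records = []
    for feat in db.features_of_type("CDS", order_by=("seqid", "start")):
        attrs = feat.attributes
        gene_id = (attrs.get("ID") or attrs.get("locus_tag") or attrs.get("Name") or [None])[0]
        if gene_id is None:
            gene_id = f"{feat.seqid}:{feat.start - 1}-{feat.end}:{feat.strand}"
        tags = tuple(v for vals in attrs.values() for v in vals)
        level = (validation_levels or {}).get(gene_id)
        records.append(
            AnnotationRecord(
                gene_id=gene_id,
                contig_id=feat.seqid,
                strand=feat.strand,
                start=feat.start - 1,  # GFF3 is 1-based inclusive
                end=feat.end,
                status=classify_annotation_status(tags, level),
                raw_tags=tags,
            )
        )
    return records


def write_gff3(records: Iterable[AnnotationRecord], path, source: str = "psmap") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in records:
            attrs = [f"ID={r.gene_id}"]
            if r.status == HYPOTHETICAL:
                attrs.append("product=hypothetical protein")
            fh.write(
                f"{r.contig_id}\t{source}\tCDS\t{r.start + 1}\t{r.end}\t.\t"
                f"{r.strand}\t0\t{';'.join(attrs)}\n"
            )


def read_validation_levels(path) -> dict[str, int]:
    """TSV gene_id -> validation level (1..5)."""
    out = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            gene, level = line.split("\t")[:2]
            out[gene] = int(level)
    return out


class AnnotationIndex:
    """Interval index over annotation records, per contig."""

    def __init__(self, records: Sequence[AnnotationRecord]):
        self.records = list(records)
        self._trees: dict[str, IntervalTree] = {}
        for r in self.records:
            self._trees.setdefault(r.contig_id, IntervalTree()).addi(r.start, r.end, r)

    def overlapping(self, contig_id: str, start: int, end: int) -> list[AnnotationRecord]:
        tree = self._trees.get(contig_id)
        if tree is None:
            return []
        recs = [iv.data for iv in tree.overlap(start, end)]
        recs.sort(key=lambda r: (r.start, r.end, r.gene_id))
        return recs

    def containing(self, contig_id: str, start: int, end: int) -> list[AnnotationRecord]:
        """Records whose span fully contains [start, end)."""
        return [r for r in self.overlapping(contig_id, start, end)
                if r.start <= start and end <= r.end]

    def merged_spans(self, contig_id: str) -> list[tuple[int, int]]:
        """Union of annotated intervals on a contig (strand-agnostic)."""
        tree = self._trees.get(contig_id)
        if tree is None:
            return []
        merged = IntervalTree(tree)
        merged.merge_overlaps()
        return sorted((iv.begin, iv.end) for iv in merged)

    def annotated_bp(self, contig_id: str) -> int:
        return sum(e - b for b, e in self.merged_spans(contig_id))
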