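"""Six-frame open reading frame extraction.

An ORF here is a *maximal stop-free codon run* in one of the six reading
frames of a contig ("stop-to-stop"), with no length constraint.  Runs that
touch a contig edge (and therefore lack a bounding stop codon) are retained
and flagged.  All coordinates are 0-based half-open on the forward strand;
reverse-strand ORFs carry forward-strand coordinates plus a strand flag.

The frame label of a span starting at forward coordinate ``k`` is
``k mod 3`` on the forward strand and ``(k mod 3) - 3`` on the reverse
strand.  Because every ORF span has a length divisible by three, labelling
by the start or by the end coordinate is equivalent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq

STOP = "*"
VALID_NT = frozenset("ACGTN")

_TABLE_CACHE: dict[int, tuple[dict[str, str], frozenset[str]]] = {}


def _code(table: int) -> tuple[dict[str, str], frozenset[str]]:
    if table not in _TABLE_CACHE:
        t = CodonTable.unambiguous_dna_by_id[table]
        _TABLE_CACHE[table] = (dict(t.forward_table), frozenset(t.stop_codons))
    return _TABLE_CACHE[table]


@dataclass(frozen=True)
class GenomeSequence:
    """One contig, optionally tagged with a species label for meta-samples."""

    contig_id: str
    sequence: str
    species_id: str = "species0"

    def __post_init__(self) -> None:
        bad = set(self.sequence.upper()) - VALID_NT
        if bad:
            raise ValueError(
                f"contig {self.contig_id}: non-nucleotide characters {sorted(bad)}"
            )
        object.__setattr__(self, "sequence", self.sequence.upper())

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ORFRecord:
    """A maximal stop-free codon run with genomic coordinates.

    ``start``/``end`` are forward-strand, 0-based half-open and exclude the
    bounding stop codon; ``aa_sequence`` therefore has length
    ``(end - start) / 3`` and contains no stop symbol.  ``edge5``/``edge3``
    flag runs whose 5'/3' boundary is the contig edge rather than a stop.
    """

    orf_id: str
    contig_id: str
    strand: str
    frame_label: int
    start: int
    end: int
    aa_sequence: str
    edge5: bool = False
    edge3: bool = False
    species_id: str = "species0"

    @property
    def aa_length(self) -> int:
        return len(self.aa_sequence)


def frame_label(strand: str, start: int) -> int:
    """Frame of a span beginning at forward-strand coordinate ``start``."""
    return start % 3 if strand == "+" else (start % 3) - 3


def translate(nt: str, table: int = 11) -> str:
    """Translate a nucleotide string codon-by-codon (bacterial code 11).

    Stop codons become ``*``; any codon containing N (or other ambiguity)
    becomes ``X`` and is never interpreted as a stop.
    """
    if len(nt) % 3 != 0:
        raise ValueError(f"sequence length {len(nt)} not divisible by 3")
    fwd, stops = _code(table)
    nt = nt.upper()
    out = []
    for i in range(0, len(nt), 3):
        codon = nt[i : i + 3]
        if codon in stops:
            out.append(STOP)
        else:
            out.append(fwd.get(codon, "X"))
    return "".join(out)


def reverse_complement(nt: str) -> str:
    return str(Seq(nt).reverse_complement())


def extract_six_frame_orfs(
    genome: GenomeSequence, min_len_aa: int = 0, table: int = 11
) -> list[ORFRecord]:
    """All stop-to-stop ORFs in the six frames of one contig.

    Every maximal stop-free codon run of at least one codon (and at least
    ``min_len_aa`` residues) is returned exactly once.  Trailing partial
    codons (1-2 nt at the frame end) belong to no ORF.
    """
    if not genome.sequence:
        raise ValueError("empty sequence")
    if min_len_aa < 0:
        raise ValueError("min_len_aa must be >= 0")
    fwd_code, stop_codons = _code(table)
    L = genome.length
    orfs: list[ORFRecord] = []
    for strand in "+-":
        oriented = genome.sequence if strand == "+" else reverse_complement(genome.sequence)
        for off in range(3):
            n_codons = (L - off) // 3
            run_start = off  # oriented coordinate of current run's first base
            run_aa: list[str] = []
            bounded5 = False  # becomes True once a stop has been seen
            for ci in range(n_codons):
                p = off + 3 * ci
                codon = oriented[p : p + 3]
                if codon in stop_codons:
                    if run_aa:
                        orfs.append(
                            _make_orf(genome, strand, run_start, p, "".join(run_aa),
                                      edge5=not bounded5, edge3=False)
                        )
                    bounded5 = True
                    run_start = p + 3
                    run_aa = []
                else:
                    run_aa.append(fwd_code.get(codon, "X"))
            if run_aa:  # run hits the contig edge: no bounding 3' stop
                p = off + 3 * n_codons
                orfs.append(
                    _make_orf(genome, strand, run_start, p, "".join(run_aa),
                              edge5=not bounded5, edge3=True)
                )
    if min_len_aa:
        orfs = [o for o in orfs if o.aa_length >= min_len_aa]
    orfs.sort(key=lambda o: (o.contig_id, o.strand, o.frame_label, o.start))
    return orfs


def _make_orf(
    genome: GenomeSequence, strand: str, ostart: int, oend: int, aa: str,
    edge5: bool, edge3: bool,
) -> ORFRecord:
    L = genome.length
    if strand == "+":
        start, end = ostart, oend
    else:
        start, end = L - oend, L - ostart
    fl = frame_label(strand, start)
    return ORFRecord(
        orf_id=f"{genome.contig_id}:{strand}:f{fl}:{start}",
        contig_id=genome.contig_id,
        strand=strand,
        frame_label=fl,
        start=start,
        end=end,
        aa_sequence=aa,
        edge5=edge5,
        edge3=edge3,
        species_id=genome.species_id,
    )


def orf_nucleotides(orf: ORFRecord, genome: GenomeSequence) -> str:
    """Strand-oriented nucleotide span of an ORF."""
    span = genome.sequence[orf.start : orf.end]
    return span if orf.strand == "+" else reverse_complement(span)


def mirror_orfs(orfs: Iterable[ORFRecord], prefix: str = "DECOY_") -> list[ORFRecord]:
    """Mirrored decoy ORF database: amino-acid sequences reversed, ids
    prefixed, coordinates preserved so target/decoy pairing stays by id."""
    return [
        replace(o, orf_id=prefix + o.orf_id, aa_sequence=o.aa_sequence[::-1])
        for o in orfs
    ]


# ---------------------------------------------------------------------------
# I/O

def read_genome_fasta(path, species_map: dict[str, str] | None = None) -> list[GenomeSequence]:
    genomes = []
    for rec in SeqIO.parse(str(path), "fasta"):
        sp = (species_map or {}).get(rec.id, "species0")
        genomes.append(GenomeSequence(contig_id=rec.id, sequence=str(rec.seq), species_id=sp))
    if not genomes:
        raise ValueError(f"no FASTA records in {path}")
    ids = [g.contig_id for g in genomes]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate contig ids in genome FASTA")
    return genomes


def write_genome_fasta(genomes: Iterable[GenomeSequence], path) -> None:
    with open(path, "w") as fh:
        for g in genomes:
            fh.write(f">{g.contig_id} species={g.species_id}\n")
            for i in range(0, g.length, 70):
                fh.write(g.sequence[i : i + 70] + "\n")


def read_species_map(path) -> dict[str, str]:
    """TSV contig_id -> species_id."""
    out = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            contig, species = line.split("\t")[:2]
            out[contig] = species
    return out


def write_orf_fasta(orfs: Iterable[ORFRecord], path) -> None:
    """ORF database as amino-acid FASTA, coordinates encoded in headers."""
    with open(path, "w") as fh:
        for o in orfs:
            fh.write(
                f">{o.orf_id} contig={o.contig_id} strand={o.strand} "
                f"frame={o.frame_label} start={o.start} end={o.end} "
                f"edge5={int(o.edge5)} edge3={int(o.edge3)} species={o.species_id}\n"
            )
            for i in range(0, len(o.aa_sequence), 70):
                fh.write(o.aa_sequence[i : i + 70] + "\n")


def write_orf_bed(orfs: Iterable[ORFRecord], path) -> None:
    with open(path, "w") as fh:
        for o in orfs:
            fh.write(f"{o.contig_id}\t{o.start}\t{o.end}\t{o.orf_id}\t0\t{o.strand}\n")
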