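"""Synthetic fixtures with known ground truth.

The generator emulates the statistical structure the workflow assumes:
planted protein-coding genes emit PSMs from their own tryptic peptides
with well-scoring e-values, false PSMs land uniformly on the tryptic
positions of the whole six-frame database (so a false PSM is equally
likely in any frame), decoy PSMs mirror the false component on the
reversed ORF database, and RNA coverage raises expressed genes above a
flat Poisson background.  A fraction of the planted genes is withheld
from the emitted GFF3 — these are the "novel" proteins the pipeline is
supposed to rediscover.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .annotation import HYPOTHETICAL, KNOWN, AnnotationRecord, write_gff3
from .genome import (
    GenomeSequence,
    ORFRecord,
    extract_six_frame_orfs,
    mirror_orfs,
    reverse_complement,
    translate,
    write_genome_fasta,
)
from .proteolysis import digest
from .psms import DECOY_PREFIX, PSMRecord, write_psm_table

STOP_CODONS = ("TAA", "TAG", "TGA")
NON_STOP_CODONS = tuple(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in STOP_CODONS
)


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for one synthetic data set (see docs/methods.md for
    the rationale behind each default)."""

    seed: int = 0
    genome_length: int = 30_000          # bp per species contig
    gc_content: float = 0.5
    n_species: int = 1
    n_true_proteins: int = 28            # per species
    protein_length_range: tuple[int, int] = (40, 180)   # aa incl. start Met
    hypothetical_frac: float = 0.3       # of annotated genes
    unannotated_true_frac: float = 0.2   # planted novels withheld from GFF
    psm_per_true_protein: float = 12.0   # Poisson mean
    false_psm_rate: float = 0.25         # expected false fraction of target PSMs
    n_false_psms: int | None = None      # direct override of the false-PSM mean
    true_log10e_loc: float = -4.5        # log10 e-value of true PSMs
    true_log10e_scale: float = 1.0
    false_log10e_loc: float = -1.0       # log10 e-value of false/decoy PSMs
    false_log10e_scale: float = 0.6
    rna_background_mean: float = 2.0     # Poisson background reads per base
    rna_expression_mean: float = 40.0    # per-gene expressed level (Poisson)
    expressed_frac: float = 0.9
    expressed_span_frac: tuple[float, float] = (0.9, 1.0)  # covered gene fraction
    intergenic_bp: int = 150             # minimum spacer between genes
    min_peptide_len: int = 6
    max_peptide_len: int = 50
    cover_start_frac: float = 0.8        # P(force a PSM on the N-terminal peptide)
    enzyme: str = "trypsin"

    def __post_init__(self) -> None:
        for name in ("hypothetical_frac", "unannotated_true_frac",
                     "false_psm_rate", "expressed_frac", "cover_start_frac"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class TruthProtein:
    gene_id: str
    species_id: str
    contig_id: str
    strand: str
    start: int      # CDS incl. stop codon, 0-based half-open forward strand
    end: int
    aa_sequence: str
    annotated: bool
    status: str | None      # known/hypothetical for annotated genes
    expressed: bool
    rna_level: float

    @property
    def cds_start(self) -> int:
        """Start-codon boundary (strand-oriented 5' end, forward coords)."""
        return self.start if self.strand == "+" else self.end - 3

    @property
    def coding_span(self) -> tuple[int, int]:
        """Span excluding the stop codon, matching ORF conventions."""
        if self.strand == "+":
            return self.start, self.end - 3
        return self.start + 3, self.end


@dataclass
class Fixture:
    spec: FixtureSpec
    genomes: list[GenomeSequence]
    annotations: list[AnnotationRecord]   # the emitted (incomplete) GFF
    truth_proteins: list[TruthProtein]    # complete ground truth
    psms: list[PSMRecord]                 # targets and decoys, unfiltered
    psm_truth: dict[str, str]             # psm_id -> gene_id | "false" | "decoy"
    coverage: dict[str, np.ndarray]       # per-contig unstranded RNA coverage
    orfs: list[ORFRecord]

    @property
    def genome_map(self) -> dict[str, GenomeSequence]:
        return {g.contig_id: g for g in self.genomes}


def _random_nt(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


def _random_gene_nt(rng: np.random.Generator, n_aa: int) -> str:
    """ATG + (n_aa - 1) random non-stop codons + random stop codon."""
    body = "".join(rng.choice(NON_STOP_CODONS, size=n_aa - 1))
    return "ATG" + body + str(rng.choice(STOP_CODONS))


def simulate_genome_and_annotation(
    spec: FixtureSpec, rng: np.random.Generator
) -> tuple[list[GenomeSequence], list[AnnotationRecord], list[TruthProtein]]:
    """Plant genes on random contigs; returns the (deliberately incomplete)
    annotation plus the full truth table."""
    lo, hi = spec.protein_length_range
    genomes, annotations, truths = [], [], []
    for sp in range(spec.n_species):
        species = f"species{sp}"
        contig = f"contig{sp}"
        n = spec.n_true_proteins
        aa_lens = rng.integers(lo, hi + 1, size=n)
        gene_bp = (aa_lens + 1) * 3  # incl. stop codon
        spacers_min = (n + 1) * spec.intergenic_bp
        leftover = spec.genome_length - int(gene_bp.sum()) - spacers_min
        if leftover < 0:
            raise ValueError(
                f"infeasible packing: {n} proteins need "
                f"{int(gene_bp.sum()) + spacers_min} bp > {spec.genome_length} bp"
            )
        extra = rng.multinomial(leftover, np.full(n + 1, 1 / (n + 1)))
        spacers = extra + spec.intergenic_bp
        parts: list[str] = []
        pos = 0
        for i in range(n):
            spacer = _random_nt(rng, int(spacers[i]), spec.gc_content)
            parts.append(spacer)
            pos += len(spacer)
            strand = "+" if rng.random() < 0.5 else "-"
            coding = _random_gene_nt(rng, int(aa_lens[i]))
            insert = coding if strand == "+" else reverse_complement(coding)
            start, end = pos, pos + len(insert)
            parts.append(insert)
            pos = end
            annotated = rng.random() >= spec.unannotated_true_frac
            status = None
            if annotated:
                status = HYPOTHETICAL if rng.random() < spec.hypothetical_frac else KNOWN
            expressed = rng.random() < spec.expressed_frac
            level = float(rng.lognormal(np.log(spec.rna_expression_mean), 0.4)) if expressed else 0.0
            truths.append(
                TruthProtein(
                    gene_id=f"{species}_g{i:03d}",
                    species_id=species,
                    contig_id=contig,
                    strand=strand,
                    start=start,
                    end=end,
                    aa_sequence=translate(coding)[:-1],
                    annotated=annotated,
                    status=status,
                    expressed=expressed,
                    rna_level=level,
                )
            )
        parts.append(_random_nt(rng, int(spacers[n]), spec.gc_content))
        sequence = "".join(parts)
        assert len(sequence) == spec.genome_length
        genomes.append(GenomeSequence(contig_id=contig, sequence=sequence, species_id=species))
    for t in truths:
        if t.annotated:
            tags = ("hypothetical protein",) if t.status == HYPOTHETICAL else ("validated protein",)
            annotations.append(
                AnnotationRecord(
                    gene_id=t.gene_id,
                    contig_id=t.contig_id,
                    strand=t.strand,
                    start=t.start,
                    end=t.end,
                    status=t.status,
                    raw_tags=tags,
                )
            )
    return genomes, annotations, truths


def _containing_orf(truth: TruthProtein, orfs_by_key) -> ORFRecord:
    """The six-frame ORF that contains a planted gene's coding span."""
    cstart, cend = truth.coding_span
    from .genome import frame_label
    key = (truth.contig_id, truth.strand, frame_label(truth.strand, cstart))
    for orf in orfs_by_key[key]:
        if orf.start <= cstart and cend <= orf.end:
            return orf
    raise AssertionError(f"no ORF contains planted gene {truth.gene_id}")


def _draw_evalue(rng, loc, scale) -> float:
    return float(10 ** min(rng.normal(loc, scale), 0.0))  # e-value capped at 1


def simulate_psms(
    spec: FixtureSpec,
    orfs: list[ORFRecord],
    truths: list[TruthProtein],
    rng: np.random.Generator,
) -> tuple[list[PSMRecord], dict[str, str]]:
    """True PSMs from planted proteins' tryptic peptides, false PSMs
    uniform over all six-frame tryptic positions, decoy PSMs mirroring the
    false component on the reversed ORF database."""
    orfs_by_key: dict[tuple, list[ORFRecord]] = {}
    for o in orfs:
        orfs_by_key.setdefault((o.contig_id, o.strand, o.frame_label), []).append(o)

    digest_kw = dict(min_len=spec.min_peptide_len, max_len=spec.max_peptide_len,
                     enzyme=spec.enzyme)
    psms: list[PSMRecord] = []
    truth_map: dict[str, str] = {}
    counter = 0

    def emit(peptide: str, ref: str, evalue: float, origin: str) -> None:
        nonlocal counter
        spectrum = f"spec{counter:06d}"
        counter += 1
        rec = PSMRecord(
            psm_id=f"sample0:{spectrum}:{peptide}",
            spectrum_id=spectrum,
            sample_id="sample0",
            peptide=peptide,
            charge=int(rng.integers(2, 4)),
            evalue=evalue,
            matched_ref=ref,
            is_decoy=ref.startswith(DECOY_PREFIX),
            enzyme=spec.enzyme,
        )
        psms.append(rec)
        truth_map.setdefault(rec.psm_id, origin)

    n_true_total = 0
    for t in truths:
        peptides = digest(t.aa_sequence, **digest_kw)
        if not peptides:
            continue
        orf = _containing_orf(t, orfs_by_key)
        k = int(rng.poisson(spec.psm_per_true_protein))
        if k == 0:
            continue
        chosen = [peptides[i] for i in rng.integers(0, len(peptides), size=k)]
        if peptides[0][0] == 0 and rng.random() < spec.cover_start_frac:
            chosen[0] = peptides[0]  # force N-terminal coverage
        for _, pep in chosen:
            emit(pep, orf.orf_id,
                 _draw_evalue(rng, spec.true_log10e_loc, spec.true_log10e_scale),
                 t.gene_id)
            n_true_total += 1

    # uniform pools over all tryptic positions of the 6-frame database
    target_pool = [
        (o.orf_id, pep) for o in orfs for _, pep in digest(o.aa_sequence, **digest_kw)
    ]
    decoy_pool = [
        (o.orf_id, pep)
        for o in mirror_orfs(orfs)
        for _, pep in digest(o.aa_sequence, **digest_kw)
    ]
    rate = spec.false_psm_rate
    if spec.n_false_psms is not None:
        mean_false = float(spec.n_false_psms)
    else:
        mean_false = n_true_total * rate / (1 - rate) if rate < 1 else 0.0
    for pool, origin in ((target_pool, "false"), (decoy_pool, "decoy")):
        k = int(rng.poisson(mean_false)) if mean_false else 0
        if k and not pool:
            raise ValueError("no tryptic positions available for false PSMs")
        for i in rng.integers(0, len(pool), size=k) if k else []:
            ref, pep = pool[int(i)]
            emit(pep, ref,
                 _draw_evalue(rng, spec.false_log10e_loc, spec.false_log10e_scale),
                 origin)
    return psms, truth_map


def simulate_rna_coverage(
    spec: FixtureSpec,
    genomes: list[GenomeSequence],
    truths: list[TruthProtein],
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Poisson background plus per-gene expression over most of each
    expressed gene's span (unstranded, like pooled short-read coverage)."""
    coverage = {
        g.contig_id: rng.poisson(spec.rna_background_mean, size=g.length).astype(np.int64)
        for g in genomes
    }
    lo, hi = spec.expressed_span_frac
    for t in truths:
        if not t.expressed:
            continue
        span = t.end - t.start
        covered = int(span * rng.uniform(lo, hi))
        offset = int(rng.integers(0, span - covered + 1)) if covered < span else 0
        a, b = t.start + offset, t.start + offset + covered
        coverage[t.contig_id][a:b] += rng.poisson(t.rna_level, size=b - a)
    return coverage


def simulate_fixture(spec: FixtureSpec) -> Fixture:
    """Full deterministic fixture from one seed."""
    rng = np.random.default_rng(spec.seed)
    genomes, annotations, truths = simulate_genome_and_annotation(spec, rng)
    orfs = [o for g in genomes for o in extract_six_frame_orfs(g)]
    psms, psm_truth = simulate_psms(spec, orfs, truths, rng)
    coverage = simulate_rna_coverage(spec, genomes, truths, rng)
    return Fixture(
        spec=spec,
        genomes=genomes,
        annotations=annotations,
        truth_proteins=truths,
        psms=psms,
        psm_truth=psm_truth,
        coverage=coverage,
        orfs=orfs,
    )


def write_fixture(fix: Fixture, outdir) -> dict[str, str]:
    """Emit the fixture as plain-text files (FASTA, GFF3, TSVs, bedGraph);
    returns the path map.  The seed is recorded in every header."""
    from .tracks import write_bedgraph

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = fix.spec.seed
    paths = {
        "genome": outdir / "genome.fasta",
        "species_map": outdir / "species_map.tsv",
        "annotation": outdir / "annotation.gff3",
        "psms": outdir / "psms.tsv",
        "coverage": outdir / "coverage.bedgraph",
        "truth_proteins": outdir / "truth_proteins.tsv",
        "truth_psms": outdir / "truth_psms.tsv",
    }
    write_genome_fasta(fix.genomes, paths["genome"])
    with open(paths["species_map"], "w") as fh:
        fh.write(f"# seed={seed}\n")
        for g in fix.genomes:
            fh.write(f"{g.contig_id}\t{g.species_id}\n")
    write_gff3(fix.annotations, paths["annotation"])
    write_psm_table(fix.psms, paths["psms"])
    write_bedgraph({(c, "."): v for c, v in fix.coverage.items()}, paths["coverage"],
                   header=f"# seed={seed}")
    with open(paths["truth_proteins"], "w") as fh:
        fh.write(f"# seed={seed}\n")
        fh.write("gene_id\tspecies_id\tcontig_id\tstrand\tstart\tend\t"
                 "annotated\tstatus\texpressed\trna_level\taa_sequence\n")
        for t in fix.truth_proteins:
            fh.write(
                f"{t.gene_id}\t{t.species_id}\t{t.contig_id}\t{t.strand}\t"
                f"{t.start}\t{t.end}\t{int(t.annotated)}\t{t.status or ''}\t"
                f"{int(t.expressed)}\t{t.rna_level:.3f}\t{t.aa_sequence}\n"
            )
    with open(paths["truth_psms"], "w") as fh:
        fh.write(f"# seed={seed}\npsm_id\torigin\n")
        for pid, origin in fix.psm_truth.items():
            fh.write(f"{pid}\t{origin}\n")
    return {k: str(v) for k, v in paths.items()}
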