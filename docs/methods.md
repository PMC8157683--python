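# Methods

## Model and procedure

`psmap` treats a tandem-MS experiment searched against a six-frame
translation of a (meta-)genome as a set of peptide-spectrum matches
(PSMs), each scored by *s* = −log₁₀(e-value), and asks which unannotated
genomic loci accumulate enough well-scoring PSMs to be called novel
proteins.

**ORF conventions.** An ORF is a maximal stop-free codon run in one of the
six frames ("stop-to-stop"), translated with the bacterial genetic code
(table 11). Coordinates are 0-based half-open on the forward strand
throughout the library; reverse-strand ORFs store forward coordinates plus
a strand flag, and conversion to 1-based GFF3 happens only at I/O. The
ORF span excludes the bounding stop codon, so the amino-acid length is
exactly (end − start)/3; the stop is recoverable as the 3 bp downstream.
Frame labels use the 0-based start coordinate (*k* mod 3, or minus 3 on
the reverse strand); because every span of whole codons has length
divisible by three, labelling by start or end is equivalent. Runs touching
a contig edge lack a bounding stop; they are retained and flagged rather
than dropped, since a real contig boundary says nothing about coding
status. Codons containing N translate to X and are never interpreted as
stop codons; since X matches no residue, peptides can never be matched
across ambiguous sequence — the conservative choice.

**Scores.** The e-value base is 10 (scores are displayed and thresholded
as common logarithms); e-values at or below 10⁻³⁰ are capped so *s* stays
finite. The candidate-level aggregate ŝ is the mean of the three best PSM
scores (top-*k* configurable); with fewer than three PSM scores the mean
of all is used and flagged. Averaging the best few is deliberately robust:
summing would reward many mediocre matches, while the single best value is
noisy.

**Mapping.** Peptides are located by exact substring search over the ORF
database (I/L equivalence available behind a flag, off by default for
reproducibility), and every occurrence — not only the reference the search
engine happened to report — becomes a genomic hit. The number of distinct
(contig, strand, start) loci is the PSM's multiplicity; downstream
unique-peptide counts use only multiplicity-1 hits, keeping ambiguity
visible but never letting it inflate evidence. Repeated observations of a
peptide across samples at one locus are one locus, many PSMs.

**Candidates.** An ORF with at least `min_psm` (default 6) mapped PSMs —
not necessarily distinct peptides — becomes a candidate. Its C-terminus is
the ORF stop; its N-terminus is the closest canonical start codon (ATG by
default; GTG/TTG behind a flag) at or before the first mapped PSM, falling
back to the ORF start. "At or before" includes a start codon coinciding
with the first PSM's own first codon. A candidate is annotated
(known/hypothetical) when an annotated CDS overlaps it on the same strand
in the same frame by at least 1 bp, novel otherwise; when both known and
hypothetical records overlap in frame, known wins. The start difference
against the in-frame record with the largest overlap is reported as a
fraction of the annotated length (negative = candidate N-terminally
shorter). Annotated proteins count as hypothetical when their UniProt-style
validation level is 1–2 or any attribute contains one of: frameshifted,
internal stop, hypothetical, putative, pseudogene (case-insensitive).

**FDR estimation.** Four estimators, usable at PSM and protein level:

* *Decoy counting.* FDR(c) = #decoy(s ≥ c)/#target(s ≥ c); q-values are
  the running minimum of FDR over decreasing stringency, and the PSM
  filter accepts the largest set with q at or below the cutoff (default
  1%). At tied scores decoys are counted together with targets —
  the conservative side of the tie.
* *Annotation frames.* Under the assumption that a false PSM is equally
  likely in any of the six frame/strand combinations, the *n* PSMs inside
  annotated CDS but in one of the five wrong frames imply (6/5)·n false
  positives among the n + N annotation-contained PSMs:
  FDR_ann = (6/5)·n/(N + n). Containment is strict (whole peptide span
  inside the CDS); boundary-straddling hits count in neither tally. This
  estimator is insensitive to PSMs outside the annotation, hence robust to
  incomplete annotations.
* *Genome fraction.* FDR_genome = n′/((1 − α)·N′), with n′ the PSMs
  strictly outside the annotation (zero bp overlap), N′ all counted PSMs,
  and α the chance that a random database peptide lands in the annotation.
  α is estimated by default from the in-silico tryptic positions of all
  six-frame ORFs (each position weighted equally, counting those whose
  genomic span overlaps annotation) — this accounts for very short ORFs
  that cannot receive a peptide at all; a plain annotated-length fraction
  is available for comparison. This estimator assumes the annotation is
  complete and overestimates otherwise (see the worked example).
* *Protein level.* Candidate scores ŝ from a mirrored decoy database
  (reversed amino-acid sequences, ids preserved) built with identical
  `min_psm` and ŝ rules. Classical counting uses all candidates; the
  picked variant counts only the better-scoring member of each
  target/decoy id pair. The cutoff grid is the set of observed ŝ values
  (exact step functions, no binning). Where the decoy database produces no
  hits (large ŝ), log₁₀(FDR) is extrapolated linearly in ŝ from a
  configurable fit interval and the zero tail replaced by the fitted
  value, clamped to [0, 1]. Positional (frame/genome) protein-level
  variants classify each candidate by its placement; they have no picked
  analogue because the false-positive definition is positional.

**Prioritization.** Novel candidates (annotated ones go to a validation
report) receive exactly one tier:

| condition | tier |
|---|---|
| ŝ ≥ 3.5, translated same-strand overlap | frameshift_or_annotation_error |
| ŝ ≥ 3.5, ≥ 2 distinct peptides or transcribed | high |
| ŝ ≥ 3.5 otherwise | low |
| 2.5 ≤ ŝ < 3.5, ≥ 2 distinct peptides | rescued |
| 2.5 ≤ ŝ < 3.5, translated opposite-strand overlap | likely_false |
| 2.5 ≤ ŝ < 3.5 otherwise | low |
| ŝ < 2.5 | rejected |

*Transcribed* means more than 70% of the candidate's length lies strictly
above the organism-wide median RNA coverage (median over every genomic
position, zeros included; missing coverage is "unknown" and is never
treated as evidence). An overlapping annotated gene is *translated* when
identified by strictly more than 6 unique (unambiguously mapped) PSMs.
Opposite-strand translation is treated as evidence against a moderate
candidate because long antisense overlaps of coding regions are very rare
in prokaryotes; at ŝ ≥ 3.5 a translated same-strand overlap in a different
frame instead indicates a frameshift or a wrong gene model. The ŝ
thresholds are configurable and can be replaced data-driven by the ŝ at
which the protein-level q-value reaches a target (`shat_cutoff_from_q`).
The exact branch order encodes the textual rules as a conjunction ("no
distinct peptides AND no transcription evidence" demotes at high ŝ); all
thresholds and the rescue peptide count (default 2, a stricter ≥ 3 preset
is one config change away) live in one `Thresholds` object. Every fired
rule is recorded in the call.

## Synthetic fixtures

The generator plants protein-coding genes (ATG + non-stop codons + stop)
on random contigs and emits FASTA, GFF3, a PSM table, RNA coverage and
truth tables. It emulates the statistical structure the workflow assumes:

* true PSMs are drawn from the planted proteins' tryptic peptides
  (cleavage after K/R except before P, peptide length 6–50, no missed
  cleavages; Asp-N mode available) with log-normal e-values,
  log₁₀ e ~ N(−4.5, 1.0) censored at e = 1;
* false PSMs land uniformly on the tryptic positions of the *whole*
  six-frame database — so a false PSM is equally likely in any frame —
  with log₁₀ e ~ N(−1.0, 0.6); decoy PSMs mirror the false component on
  the reversed ORF database with the same expected count;
* RNA coverage is a Poisson background (mean 2 reads/base) plus a
  per-gene Poisson level (log-normal around 40) over 90–100% of each
  expressed gene's span (90% of genes), unstranded like pooled short-read
  coverage.

Defaults: one species, 30 kb contig, 28 proteins of 40–180 aa separated by
at least 150 bp, 30% of annotated genes tagged hypothetical, 20% of
planted genes withheld from the GFF3 (the "novel" proteins), Poisson(12)
PSMs per true protein with the N-terminal peptide forced in 80% of genes
(so most, but not all, annotated starts are recoverable — the remainder
emulate N-terminal coverage loss), and a false-PSM rate of 25% of target
PSMs. These sizes keep a full pipeline run under a second while leaving
every count (PSMs per ORF, decoy candidates, frame hits) far from
degenerate; calibration experiments in the test suite use 20 replicates at
20 kb/15 proteins with the false rate raised to 80% so that decoy and
false candidates actually occur, and the frame-ratio experiment uses a
densely packed, fully annotated 14 kb genome with 5000 placed false PSMs.

What the generator does **not** emulate: spectra (fixtures start at the
PSM level), missed cleavages and semi-tryptic peptides, modification
localisation, shared peptides between homologous real proteins, codon
bias, operon structure, or strand-specific RNA coverage. Passing tests
therefore demonstrate the correctness and calibration of the mapping and
statistics, not search-engine behaviour on real spectra. One visible
consequence of realistic digestion: uniformly drawn false peptides
slightly favour long ORFs (short wrong-frame ORFs lose length-filtered
tryptic positions at their edges), so the realized wrong:correct frame
ratio sits marginally below 5:1 — the same short-ORF effect that motivates
the tryptic-position estimate of α.

## Numerical choices and degenerate inputs

* FDR values are clamped to [0, 1]; with zero targets above a cutoff the
  FDR is 0 when no decoys pass and 1 otherwise.
* q-values are running minima over the observed cutoff grid; queries
  between grid points resolve to the next observed cutoff above (counts
  are step functions).
* The picked strategy errors on a decoy candidate whose id has no
  counterpart in the target ORF universe (a database mismatch); a missing
  target *candidate* simply scores −∞ and loses the pick.
* `shat` of fewer than `top_k` scores is flagged, not rejected; an empty
  score list is an error.
* Extrapolation requires at least three nonzero-FDR grid points in the
  fit interval and errors on zero score variance.
* Empty ORF runs (adjacent stop codons) produce no record; trailing
  partial codons at frame ends belong to no ORF.
* All randomness flows from a single seeded generator per fixture; output
  files record the seed in their headers, and rerunning any stage with
  identical inputs is byte-identical.

## Known limitations

* Contiguous prokaryotic mapping only — no spliced or chimeric peptides.
* Frameshifted proteins are *detected* (as candidates overlapping a
  translated gene in a different frame) but not assembled into a joint
  gene model across the shift.
* Homology search of candidates is out of scope; the candidate table
  carries a free column for externally supplied homology labels.
* FDR_genome is only meaningful for reasonably complete annotations.
* The multiplicity profile pools loci across species of a meta-sample (a
  per-species breakdown is available from the hits table).
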