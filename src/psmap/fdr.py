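"""False discovery rate estimation at PSM and protein level.

Four strategies are implemented:

* decoy counting: FDR = #decoy / #target above a score cutoff;
* annotation frames: of the PSMs falling inside annotated proteins, the
  ``n`` hits in one of the five incorrect reading frames imply (6/5)n false
  positives among the ``n + N`` annotated-locus PSMs, so
  FDR_ann = (6/5) n / (N + n);
* genome fraction: with the annotation assumed complete and covering an
  (effective) fraction alpha of places a peptide can land, the ``n'`` PSMs
  outside the annotation give FDR_genome = n' / ((1 - alpha) N') with N'
  the total of mapped PSMs;
* protein level over the aggregate score shat, in the classical and the
  picked target-decoy variants, with q-values and optional log-linear
  extrapolation beyond the last decoy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .annotation import AnnotationIndex
from .candidates import Candidate
from .genome import ORFRecord
from .mapping import GenomicHit, hit_span
from .proteolysis import digest

CORRECT_FRAME = "correct"
WRONG_FRAME = "wrong"
PARTIAL = "partial"   # straddles a CDS boundary: neither inside nor strictly outside
OUTSIDE = "outside"   # zero bp overlap with any CDS span


# ---------------------------------------------------------------------------
# Point estimators


def fdr_decoy(
    target_scores: Sequence[float], decoy_scores: Sequence[float], cutoff: float
) -> float:
    """#decoys at or above cutoff over #targets at or above cutoff."""
    t = sum(1 for s in target_scores if s >= cutoff)
    d = sum(1 for s in decoy_scores if s >= cutoff)
    if t == 0:
        return 0.0 if d == 0 else 1.0
    return min(1.0, d / t)


def fdr_ann(n: int, N: int) -> float:
    """(6/5) n / (N + n): annotation-frame FDR estimate."""
    if n < 0 or N < 0:
        raise ValueError("counts must be non-negative")
    if n + N == 0:
        raise ValueError("no PSMs mapped to annotated loci")
    return min(1.0, (6 / 5) * n / (N + n))


def fdr_genome(n_prime: int, N_prime: int, alpha: float) -> float:
    """n' / ((1 - alpha) N'), clamped to [0, 1]."""
    if not 0 <= alpha < 1:
        raise ValueError(f"alpha must be in [0, 1), got {alpha}")
    if N_prime <= 0:
        raise ValueError("N_prime must be positive")
    if n_prime > N_prime:
        raise ValueError("n_prime cannot exceed N_prime")
    return min(1.0, n_prime / ((1 - alpha) * N_prime))


# ---------------------------------------------------------------------------
# Counting hits against the annotation


def classify_hit_frame(hit: GenomicHit, index: AnnotationIndex) -> str:
    """correct / wrong / outside for one genomic locus.

    correct: fully inside an annotated CDS in the same strand and frame;
    wrong: fully inside some CDS span but only in one of the five other
    frame/strand combinations; partial: straddling a CDS boundary (counted
    in neither frame tally, nor as strictly outside); outside: zero bp
    overlap with any CDS.
    """
    containing = index.containing(hit.contig_id, hit.start, hit.end)
    if not containing:
        if index.overlapping(hit.contig_id, hit.start, hit.end):
            return PARTIAL
        return OUTSIDE
    fl = hit.start % 3 if hit.strand == "+" else (hit.start % 3) - 3
    for rec in containing:
        if rec.strand == hit.strand and rec.frame_label == fl:
            return CORRECT_FRAME
    return WRONG_FRAME


def count_frame_hits(
    hits: Iterable[GenomicHit],
    index: AnnotationIndex,
    exclude_ambiguous: bool = False,
) -> tuple[int, int]:
    """(n, N): incorrect-frame and correct-frame PSM counts inside the
    annotation.  Ambiguous PSMs contribute once per locus unless excluded;
    loci outside the annotation are counted in neither."""
    n = N = 0
    for h in hits:
        if exclude_ambiguous and h.ambiguous:
            continue
        cls = classify_hit_frame(h, index)
        if cls == CORRECT_FRAME:
            N += 1
        elif cls == WRONG_FRAME:
            n += 1
    return n, N


def count_genome_hits(
    hits: Iterable[GenomicHit],
    index: AnnotationIndex,
    exclude_ambiguous: bool = False,
) -> tuple[int, int]:
    """(n', N'): loci strictly outside the annotation (zero bp overlap with
    any CDS span), and the total number of counted loci."""
    n_prime = total = 0
    for h in hits:
        if exclude_ambiguous and h.ambiguous:
            continue
        total += 1
        if not index.overlapping(h.contig_id, h.start, h.end):
            n_prime += 1
    return n_prime, total


def estimate_alpha(
    orfs: Sequence[ORFRecord],
    index: AnnotationIndex,
    mode: str = "tryptic",
    contig_lengths: Mapping[str, int] | None = None,
    min_len: int = 6,
    max_len: int = 50,
    enzyme: str = "trypsin",
) -> float:
    """Chance that a randomly drawn peptide from the six-frame database
    falls into an annotated region.

    ``tryptic`` mode enumerates the in-silico digest positions of every
    six-frame ORF, each weighted equally, and counts those whose genomic
    span overlaps the annotation — this accounts for short ORFs to which no
    peptide can map.  ``length`` mode is the plain annotated fraction of the
    genome (requires ``contig_lengths``).
    """
    if mode == "length":
        if contig_lengths is None:
            raise ValueError("length mode needs contig_lengths")
        total = sum(contig_lengths.values())
        annotated = sum(index.annotated_bp(c) for c in contig_lengths)
        return annotated / total if total else 0.0
    if mode != "tryptic":
        raise ValueError(f"unknown alpha mode {mode!r}")
    inside = total = 0
    for orf in orfs:
        for off, pep in digest(orf.aa_sequence, min_len, max_len, enzyme):
            start, end = hit_span(orf, off, len(pep))
            total += 1
            if index.overlapping(orf.contig_id, start, end):
                inside += 1
    return inside / total if total else 0.0


# ---------------------------------------------------------------------------
# FDR curves over a score grid


@dataclass
class FDREstimate:
    """FDR and q-value as step functions of a score cutoff.

    ``cutoffs`` ascend; ``q`` is the running minimum of ``fdr`` over
    increasing cutoff, hence monotone non-increasing.
    """

    strategy: str
    cutoffs: np.ndarray
    fdr: np.ndarray
    q: np.ndarray = field(default=None)  # type: ignore[assignment]
    inputs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.cutoffs = np.asarray(self.cutoffs, dtype=float)
        self.fdr = np.clip(np.asarray(self.fdr, dtype=float), 0.0, 1.0)
        if self.q is None:
            self.q = np.minimum.accumulate(self.fdr)
        else:
            self.q = np.asarray(self.q, dtype=float)

    def _idx(self, score: float) -> int:
        # counts (hence FDR) only change at observed cutoffs: a score
        # between grid points behaves like the next grid point up
        i = int(np.searchsorted(self.cutoffs, score, side="left"))
        return min(i, self.cutoffs.size - 1)

    def fdr_at(self, score: float) -> float:
        if score > self.cutoffs[-1]:
            return float(self.fdr[-1])
        return float(self.fdr[self._idx(score)])

    def q_at(self, score: float) -> float:
        if score > self.cutoffs[-1]:
            return float(self.q[-1])
        return float(self.q[self._idx(score)])


def _counts_at_cutoffs(scores: np.ndarray, grid: np.ndarray) -> np.ndarray:
    s = np.sort(scores)
    return (s.size - np.searchsorted(s, grid, side="left")).astype(float)


def fdr_curve_decoy(
    target_scores: Sequence[float], decoy_scores: Sequence[float]
) -> FDREstimate:
    """Decoy-counting FDR at every observed score (PSM or protein level)."""
    t = np.asarray(target_scores, float)
    d = np.asarray(decoy_scores, float)
    grid = np.unique(np.concatenate([t, d]))
    n_t = _counts_at_cutoffs(t, grid)
    n_d = _counts_at_cutoffs(d, grid)
    fdr = np.where(n_t > 0, n_d / np.maximum(n_t, 1.0), np.where(n_d > 0, 1.0, 0.0))
    return FDREstimate(
        strategy="decoy_psm",
        cutoffs=grid,
        fdr=fdr,
        inputs={"n_target": int(t.size), "n_decoy": int(d.size)},
    )


def _positional_curve(
    scores: np.ndarray, classes: np.ndarray, strategy: str, alpha: float | None
) -> FDREstimate:
    grid = np.unique(scores)
    order = np.argsort(scores)[::-1]
    s_sorted = scores[order]
    cls_sorted = classes[order]
    fdr = np.empty_like(grid)
    for i, c in enumerate(grid):
        k = np.searchsorted(-s_sorted, -c, side="right")  # scores >= c
        sub = cls_sorted[:k]
        if strategy == "ann_frame":
            n = int((sub == WRONG_FRAME).sum())
            N = int((sub == CORRECT_FRAME).sum())
            fdr[i] = (6 / 5) * n / (N + n) if (N + n) else 0.0
        else:  # genome_fraction
            n_out = int((sub == OUTSIDE).sum())
            total = int(sub.size)
            fdr[i] = n_out / ((1 - alpha) * total) if total else 0.0
    return FDREstimate(strategy=strategy, cutoffs=grid, fdr=fdr,
                       inputs={} if alpha is None else {"alpha": alpha})


def fdr_curve_ann(
    hits: Sequence[GenomicHit],
    psm_scores: Mapping[str, float],
    index: AnnotationIndex,
) -> FDREstimate:
    """Annotation-frame FDR as a function of the PSM score cutoff."""
    scores, classes = _hit_arrays(hits, psm_scores, index)
    return _positional_curve(scores, classes, "ann_frame", None)


def fdr_curve_genome(
    hits: Sequence[GenomicHit],
    psm_scores: Mapping[str, float],
    index: AnnotationIndex,
    alpha: float,
) -> FDREstimate:
    """Genome-fraction FDR as a function of the PSM score cutoff."""
    scores, classes = _hit_arrays(hits, psm_scores, index)
    return _positional_curve(scores, classes, "genome_fraction", alpha)


def _hit_arrays(hits, psm_scores, index):
    scores, classes = [], []
    for h in hits:
        scores.append(psm_scores[h.psm_id])
        classes.append(classify_hit_frame(h, index))
    return np.asarray(scores, float), np.asarray(classes, object)


# ---------------------------------------------------------------------------
# Protein-level FDR


def strip_decoy(orf_id: str, prefix: str = "DECOY_") -> str:
    return orf_id[len(prefix):] if orf_id.startswith(prefix) else orf_id


def protein_fdr(
    candidates_target: Sequence[Candidate],
    candidates_decoy: Sequence[Candidate],
    strategy: str = "picked",
    decoy_prefix: str = "DECOY_",
    target_orf_ids: Iterable[str] | None = None,
) -> FDREstimate:
    """Protein-level FDR over the shat grid of all observed candidates.

    classical: FDR(c) = #decoy(shat >= c) / #target(shat >= c).
    picked: target and decoy candidates are paired by ORF id (the decoy
    database mirrors the target one, preserving ids); only the
    better-scoring member of each pair is counted on its side.  A missing
    counterpart scores as -inf, i.e. the present member is counted.
    """
    t_scores = {c.orf_id: c.shat for c in candidates_target}
    d_scores = {strip_decoy(c.orf_id, decoy_prefix): c.shat for c in candidates_decoy}
    if strategy == "picked" and target_orf_ids is not None:
        universe = set(target_orf_ids)
        unpaired = sorted(set(d_scores) - universe)
        if unpaired:
            raise ValueError(f"decoy candidates without target counterpart: {unpaired[:5]}")
    if strategy == "classical":
        t_used = np.array(list(t_scores.values()), float)
        d_used = np.array(list(d_scores.values()), float)
    elif strategy == "picked":
        t_list, d_list = [], []
        for oid in set(t_scores) | set(d_scores):
            t = t_scores.get(oid, -math.inf)
            d = d_scores.get(oid, -math.inf)
            if t >= d and t > -math.inf:
                t_list.append(t)
            if d >= t and d > -math.inf:
                d_list.append(d)
        t_used, d_used = np.array(t_list, float), np.array(d_list, float)
    else:
        raise ValueError(f"unknown protein FDR strategy {strategy!r}")
    grid = np.unique(np.concatenate([t_used, d_used])) if t_used.size + d_used.size else np.array([0.0])
    n_t = _counts_at_cutoffs(t_used, grid)
    n_d = _counts_at_cutoffs(d_used, grid)
    fdr = np.where(n_t > 0, n_d / np.maximum(n_t, 1.0), np.where(n_d > 0, 1.0, 0.0))
    return FDREstimate(
        strategy=f"protein_{strategy}",
        cutoffs=grid,
        fdr=fdr,
        inputs={
            "n_target": int(t_used.size),
            "n_decoy": int(d_used.size),
            "max_decoy_score": float(d_used.max()) if d_used.size else -math.inf,
        },
    )


def protein_fdr_positional(
    candidates: Sequence[Candidate], strategy: str = "ann", alpha: float | None = None
) -> FDREstimate:
    """Annotation-frame / genome-fraction FDR extended to the protein
    level: a candidate's truth class is taken from its genomic placement
    (in-frame annotated, wrong-frame overlap, or outside annotation)."""
    scores, classes = [], []
    for c in candidates:
        if c.category is None:
            raise ValueError("candidates must be classified first")
        scores.append(c.shat)
        if c.category != "novel":
            classes.append(CORRECT_FRAME)
        elif c.overlap_same_strand or c.overlap_opposite_strand:
            classes.append(WRONG_FRAME)
        else:
            classes.append(OUTSIDE)
    est = _positional_curve(
        np.asarray(scores, float),
        np.asarray(classes, object),
        "ann_frame" if strategy == "ann" else "genome_fraction",
        alpha,
    )
    est.strategy = f"protein_{strategy}"
    return est


def extrapolate_fdr(
    estimate: FDREstimate, fit_interval: tuple[float, float] = (1.0, 2.5)
) -> FDREstimate:
    """Replace the zero-FDR tail beyond the last decoy by a log-linear fit.

    log10(FDR) is regressed on the cutoff over grid points inside
    ``fit_interval`` with nonzero FDR (at least three required); cutoffs
    above the highest-scoring decoy get the fitted value, clamped to [0,1].
    """
    lo, hi = fit_interval
    mask = (estimate.cutoffs >= lo) & (estimate.cutoffs <= hi) & (estimate.fdr > 0)
    if mask.sum() < 3:
        raise ValueError(
            f"need >= 3 nonzero-FDR grid points in [{lo}, {hi}], have {int(mask.sum())}"
        )
    x = estimate.cutoffs[mask]
    if np.allclose(x, x[0]):
        raise ValueError("degenerate fit: no variance in score cutoffs")
    y = np.log10(estimate.fdr[mask])
    fit = stats.linregress(x, y)
    max_decoy = estimate.inputs.get("max_decoy_score")
    if max_decoy is not None and math.isfinite(max_decoy):
        tail = estimate.cutoffs > max_decoy
    else:
        tail = estimate.fdr == 0
    fdr = estimate.fdr.copy()
    fdr[tail] = np.clip(10 ** (fit.intercept + fit.slope * estimate.cutoffs[tail]), 0.0, 1.0)
    inputs = dict(estimate.inputs)
    inputs.update(
        extrapolated=True,
        fit_interval=(lo, hi),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
    )
    return FDREstimate(
        strategy=estimate.strategy, cutoffs=estimate.cutoffs.copy(), fdr=fdr, inputs=inputs
    )
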