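"""PSM table ingestion, scoring and decoy-FDR filtering.

A PSM (peptide-spectrum match) row carries an e-value from the search
engine; the per-PSM score is ``s = -log10(e-value)``.  Decoy matches are
recognised by a reference-id prefix (``DECOY_`` by default, the convention
of a concatenated target-decoy search).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: e-values at or below this are capped before taking the logarithm so that
#: s stays finite.
EVALUE_FLOOR = 1e-30

DECOY_PREFIX = "DECOY_"

REQUIRED_COLUMNS = ("spectrum", "peptide", "evalue", "proteins")

_MOD_RE = re.compile(r"[^A-Z]")


def strip_modifications(peptide: str) -> str:
    """Plain amino-acid sequence: modification masses/symbols removed."""
    return _MOD_RE.sub("", peptide.upper())


@dataclass(frozen=True)
class PSMRecord:
    psm_id: str
    spectrum_id: str
    sample_id: str
    peptide: str            # plain sequence used for genomic mapping
    charge: int
    evalue: float
    matched_ref: str
    is_decoy: bool
    enzyme: str = "trypsin"
    peptide_modified: str = ""   # as reported, for provenance only

    @property
    def s(self) -> float:
        return -math.log10(max(self.evalue, EVALUE_FLOOR))


def read_psm_table(
    path,
    decoy_prefix: str = DECOY_PREFIX,
    evalue_floor: float = EVALUE_FLOOR,
) -> list[PSMRecord]:
    """Read the TSV dialect (columns: spectrum, peptide, evalue, proteins,
    optional sample, charge, enzyme).

    Rows whose ``proteins`` field lists several references (``;``-separated)
    expand to one record per reference sharing one ``psm_id``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"PSM table {path} missing required column(s): {missing}")
    records: list[PSMRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        evalue = float(row.evalue)
        if evalue <= 0:
            evalue = evalue_floor
        modified = str(row.peptide)
        plain = strip_modifications(modified)
        if not plain:
            raise ValueError(f"row {i}: empty peptide sequence")
        spectrum = str(row.spectrum)
        sample = str(getattr(row, "sample", "sample0") or "sample0")
        charge = int(getattr(row, "charge", 2) or 2)
        enzyme = str(getattr(row, "enzyme", "trypsin") or "trypsin")
        psm_id = f"{sample}:{spectrum}:{plain}"
        for ref in str(row.proteins).split(";"):
            ref = ref.strip()
            if not ref:
                continue
            records.append(
                PSMRecord(
                    psm_id=psm_id,
                    spectrum_id=spectrum,
                    sample_id=sample,
                    peptide=plain,
                    charge=charge,
                    evalue=evalue,
                    matched_ref=ref,
                    is_decoy=ref.startswith(decoy_prefix),
                    enzyme=enzyme,
                    peptide_modified=modified,
                )
            )
    return records


def write_psm_table(psms: Iterable[PSMRecord], path) -> None:
    """Normalised PSM TSV; ``read_psm_table`` of the output is an identity
    round trip (multi-reference records re-collapse by psm_id)."""
    by_id: dict[str, list[PSMRecord]] = {}
    order: list[str] = []
    for p in psms:
        if p.psm_id not in by_id:
            order.append(p.psm_id)
        by_id.setdefault(p.psm_id, []).append(p)
    rows = []
    for pid in order:
        group = by_id[pid]
        first = group[0]
        rows.append(
            {
                "spectrum": first.spectrum_id,
                "sample": first.sample_id,
                "peptide": first.peptide_modified or first.peptide,
                "charge": first.charge,
                "evalue": repr(first.evalue),
                "proteins": ";".join(g.matched_ref for g in group),
                "enzyme": first.enzyme,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Decoy-based PSM filtering


def unique_psms(psms: Iterable[PSMRecord]) -> list[PSMRecord]:
    """One representative record per psm_id (first reference kept)."""
    seen: dict[str, PSMRecord] = {}
    for p in psms:
        seen.setdefault(p.psm_id, p)
    return list(seen.values())


@dataclass
class FilterResult:
    targets: list[PSMRecord]      # accepted target records (all references)
    decoys: list[PSMRecord]       # decoy records above the same threshold
    threshold: float              # smallest accepted score
    fdr_at_threshold: float
    n_target_in: int
    n_decoy_in: int


def _threshold_scan(target_s: np.ndarray, decoy_s: np.ndarray):
    """FDR and q-value at every candidate cutoff (unique observed scores,
    descending).  FDR(c) = #decoy(s>=c) / #target(s>=c)."""
    grid = np.unique(np.concatenate([target_s, decoy_s]))[::-1]
    ts, ds = np.sort(target_s), np.sort(decoy_s)
    n_t = (ts.size - np.searchsorted(ts, grid, side="left")).astype(float)
    n_d = (ds.size - np.searchsorted(ds, grid, side="left")).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(n_t > 0, n_d / np.maximum(n_t, 1), np.where(n_d > 0, 1.0, 0.0))
    fdr = np.clip(fdr, 0.0, 1.0)
    # q at a cutoff = best FDR achievable at that cutoff or any stricter one
    q = np.minimum.accumulate(fdr[::-1])[::-1]
    return grid, fdr, q


def filter_psms(psms: Sequence[PSMRecord], fdr_cutoff: float = 0.01) -> FilterResult:
    """Targets whose score clears the least stringent cutoff with
    FDR_decoy <= ``fdr_cutoff``; decoys above the same cutoff are returned
    separately for protein-level FDR work downstream."""
    uniq = unique_psms(psms)
    t_scores = np.array([p.s for p in uniq if not p.is_decoy])
    d_scores = np.array([p.s for p in uniq if p.is_decoy])
    if d_scores.size == 0:
        raise ValueError("no decoy PSMs present; FDR_decoy cannot be estimated")
    if t_scores.size == 0:
        return FilterResult([], [], math.inf, 0.0, 0, int(d_scores.size))
    grid, fdr, q = _threshold_scan(t_scores, d_scores)
    ok = q <= fdr_cutoff
    if not ok.any():
        threshold = math.inf
        fdr_at = float(q.min())
    else:
        threshold = float(grid[ok][-1])  # least stringent passing cutoff
        fdr_at = float(fdr[ok][-1])
    targets = [p for p in psms if not p.is_decoy and p.s >= threshold]
    decoys = [p for p in psms if p.is_decoy and p.s >= threshold]
    return FilterResult(
        targets=targets,
        decoys=decoys,
        threshold=threshold,
        fdr_at_threshold=fdr_at,
        n_target_in=int(t_scores.size),
        n_decoy_in=int(d_scores.size),
    )
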