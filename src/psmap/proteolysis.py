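"""In-silico proteolytic digestion (full cleavage, no missed cleavages)."""

from __future__ import annotations


def cleavage_sites(seq: str, enzyme: str = "trypsin") -> list[int]:
    """Positions after which the chain is cut (0-based residue index of the
    last residue of the N-terminal fragment).

    trypsin: after K or R, not before P.  asp-n: before D (i.e. cut after
    the residue preceding a D).
    """
    sites = []
    if enzyme == "trypsin":
        for i, aa in enumerate(seq[:-1]):
            if aa in "KR" and seq[i + 1] != "P":
                sites.append(i)
    elif enzyme == "asp-n":
        for i in range(len(seq) - 1):
            if seq[i + 1] == "D":
                sites.append(i)
    else:
        raise ValueError(f"unknown enzyme {enzyme!r}")
    return sites


def digest(
    seq: str,
    min_len: int = 6,
    max_len: int = 50,
    enzyme: str = "trypsin",
) -> list[tuple[int, str]]:
    """(offset, peptide) pairs of the full digest, filtered by length."""
    bounds = [0] + [s + 1 for s in cleavage_sites(seq, enzyme)] + [len(seq)]
    out = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        if min_len <= b - a <= max_len:
            out.append((a, seq[a:b]))
    return out
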