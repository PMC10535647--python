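"""Degenerate-motif scanning for sortase anchors, cleavage and adhesion motifs.

Motif classes
-------------
``LPXTG_canonical``
    The canonical Gram-positive sortase recognition motif L-P-x-T-G.
``LPXTG_variant``
    The degenerate variant pattern [LMF]-[PA]-x-[TA]-[GAN], induced from
    the anchor variants observed in CEP homologs (LAKTA, LPDTA, FPTTN,
    MPQAG, LPTTN) together with known sortase substrate tolerances
    (L->M, P->A, T->A). Exact canonical matches are excluded.
``cleavage``
    The proposed propeptide autocleavage motif K-V-Y-[YH]-[PA]-[TN]-D,
    cleaved between positions 6 and 7 (before the final Asp).
``RGD`` / ``RGE``
    The cell-adhesion tripeptide and its putatively inactive variant.

All hits are reported left to right with 1-based start positions;
overlapping occurrences are all reported.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from ceparch.seq_io import Region

# Kyte-Doolittle hydropathy scale
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2, "X": 0.0,
}

_CANONICAL = re.compile(r"(?=(LP.TG))")
_VARIANT = re.compile(r"(?=([LMF][PA].[TA][GAN]))")
_CLEAVAGE = re.compile(r"(?=(KVY[YH][PA][TN]D))")
_ADHESION = re.compile(r"(?=(RG[DE]))")


@dataclass(frozen=True)
class MotifHit:
    start: int  # 1-based position of the first motif residue
    matched: str
    motif_class: str
    context_ok: bool = False

    @property
    def end(self) -> int:
        return self.start + len(self.matched) - 1


@dataclass(frozen=True)
class ANValidation:
    """Outcome of the tripartite anchor-domain check for one motif hit."""

    motif_hit: MotifHit
    valid: bool
    hydrophobic_region: Region | None = None
    charged_tail: Region | None = None
    hydropathy_mean: float | None = None
    reasons: tuple[str, ...] = ()


def scan_anchor_motifs(seq: str) -> list[MotifHit]:
    """All canonical LPXTG and degenerate-variant anchor 5-mers in *seq*.

    A 5-mer matching the canonical pattern is classed canonical only;
    the variant class covers the degenerate pattern minus exact canonical
    matches. Hits are returned sorted by position.
    """
    seq = seq.upper()
    hits = [
        MotifHit(m.start() + 1, m.group(1), "LPXTG_canonical")
        for m in _CANONICAL.finditer(seq)
    ]
    canonical_starts = {h.start for h in hits}
    hits += [
        MotifHit(m.start() + 1, m.group(1), "LPXTG_variant")
        for m in _VARIANT.finditer(seq)
        if m.start() + 1 not in canonical_starts
    ]
    return sorted(hits, key=lambda h: h.start)


def scan_cleavage_motif(seq: str) -> list[MotifHit]:
    """All 7-mers matching the propeptide cleavage motif KVY[YH][PA][TN]D.

    The scissile bond lies between motif positions 6 and 7, i.e. cleavage
    occurs immediately before the final Asp of the match.
    """
    return [
        MotifHit(m.start() + 1, m.group(1), "cleavage")
        for m in _CLEAVAGE.finditer(seq.upper())
    ]


def scan_adhesion_motifs(seq: str) -> list[MotifHit]:
    """All RGD / RGE cell-adhesion trimers, classed by their final residue."""
    return [
        MotifHit(m.start() + 1, m.group(1), m.group(1))
        for m in _ADHESION.finditer(seq.upper())
    ]


def cleavage_site(hit: MotifHit) -> int:
    """1-based position of the last residue before the scissile bond."""
    if hit.motif_class != "cleavage":
        raise ValueError("not a cleavage-motif hit")
    return hit.start + 5


def validate_an_domain(seq: str, hit: MotifHit, *,
                       c_window: int = 70, min_hydrophobic_run: int = 15,
                       min_hydropathy: float = 1.0, tail_len: int = 10,
                       min_tail_kr: int = 2) -> ANValidation:
    """Check the tripartite AN-domain structure around an anchor-motif hit.

    A covalent cell-wall anchor domain starts with an LPXTG-like motif,
    continues with a membrane-spanning hydrophobic stretch and ends in a
    short positively charged tail. The hit is valid iff

    (a) the motif starts within the C-terminal window (default 70 aa);
    (b) downstream of the motif some contiguous run of
        ``min_hydrophobic_run`` residues has mean Kyte-Doolittle
        hydropathy >= ``min_hydropathy``;
    (c) the final tail (last <= ``tail_len`` residues) contains at least
        ``min_tail_kr`` Lys/Arg residues.
    """
    seq = seq.upper()
    if seq[hit.start - 1 : hit.start - 1 + len(hit.matched)] != hit.matched:
        raise ValueError("motif hit does not originate from this sequence")
    n = len(seq)
    reasons: list[str] = []
    if hit.start < n - c_window + 1:
        reasons.append(f"motif outside C-terminal window of {c_window} aa")

    downstream_start = hit.start + len(hit.matched)  # 1-based
    hregion: Region | None = None
    hmean: float | None = None
    down = seq[downstream_start - 1 :]
    best = None
    for i in range(0, len(down) - min_hydrophobic_run + 1):
        window = down[i : i + min_hydrophobic_run]
        mean = sum(KYTE_DOOLITTLE[aa] for aa in window) / len(window)
        if best is None or mean > best[1]:
            best = (i, mean)
    if best is not None:
        hmean = best[1]
    if best is None or best[1] < min_hydropathy:
        reasons.append(
            f"no {min_hydrophobic_run}-residue run with mean hydropathy >= {min_hydropathy}"
        )
    else:
        hregion = Region(
            downstream_start + best[0],
            downstream_start + best[0] + min_hydrophobic_run - 1,
            "hydrophobic",
        )

    tail = seq[max(0, n - tail_len):]
    if sum(tail.count(aa) for aa in "KR") < min_tail_kr:
        reasons.append(f"fewer than {min_tail_kr} K/R in the final {tail_len} residues")
    ctail = Region(max(1, n - tail_len + 1), n, "charged_tail") if not reasons else None

    valid = not reasons
    return ANValidation(
        motif_hit=MotifHit(hit.start, hit.matched, hit.motif_class, context_ok=valid),
        valid=valid,
        hydrophobic_region=hregion if valid else hregion,
        charged_tail=ctail if valid else None,
        hydropathy_mean=hmean,
        reasons=tuple(reasons),
    )
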