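"""Amino-acid composition statistics, theoretical pI and composition classifiers.

The theoretical isoelectric point is the pH at which the modeled net charge

    Q(pH) = sum over basic groups of 1 / (1 + 10**(pH - pKa))
          - sum over acidic groups of 1 / (1 + 10**(pKa - pH))

crosses zero, with both termini included. Q is strictly decreasing in pH,
so the root is unique; it is located by bisection on [0, 14].

Composition fractions are computed over non-X residues; an all-X sequence
has no defined composition. His is counted as basic (and hence charged),
which is required to reproduce the residue-class groupings quoted for CEP
propeptides (basic = Arg, Lys, His).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ceparch.seq_io import SequenceRecord

ACIDIC = frozenset("DE")
BASIC = frozenset("RKH")
CHARGED = ACIDIC | BASIC
AROMATIC = frozenset("FYW")
HYDROPHOBIC = frozenset("AVLIMFWC")

# Bjellqvist pKa values (the set behind the ProtParam-style pI): per-group
# pKa for the ionizable side chains plus the free termini.
PKA_TABLES: dict[str, dict[str, float]] = {
    "bjellqvist": {
        "Nterm": 7.5, "Cterm": 3.55,
        "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0,
        "H": 5.98, "K": 10.0, "R": 12.0,
    },
    "emboss": {
        "Nterm": 8.6, "Cterm": 3.6,
        "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1,
        "H": 6.5, "K": 10.8, "R": 12.5,
    },
}

_ACIDIC_GROUPS = ("Cterm", "D", "E", "C", "Y")
_BASIC_GROUPS = ("Nterm", "H", "K", "R")


class UndefinedCompositionError(ValueError):
    """Sequence consists only of X residues."""


@dataclass(frozen=True)
class CompositionProfile:
    """Residue-class fractions and theoretical pI of one region.

    All fractions are over non-X residues. ``charged == acidic + basic``
    holds exactly. ``low_complexity_dominant`` is the set of residues whose
    individual frequency exceeds ``dominance_threshold``.
    """

    length: int
    charged: float
    acidic: float
    basic: float
    proline: float
    glycine: float
    lysine: float
    cysteine: float
    methionine: float
    aromatic: float
    hydrophobic: float
    theoretical_pI: float
    low_complexity_dominant: frozenset[str] = field(default_factory=frozenset)

    def as_dict(self) -> dict[str, float]:
        return {
            "length": self.length,
            "charged": self.charged,
            "acidic": self.acidic,
            "basic": self.basic,
            "proline": self.proline,
            "glycine": self.glycine,
            "lysine": self.lysine,
            "cysteine": self.cysteine,
            "methionine": self.methionine,
            "aromatic": self.aromatic,
            "hydrophobic": self.hydrophobic,
            "theoretical_pI": self.theoretical_pI,
        }


def _residues(seq: SequenceRecord | str) -> str:
    if isinstance(seq, SequenceRecord):
        return seq.residues
    if not seq:
        raise ValueError("empty sequence")
    return seq.upper()


def net_charge(seq: SequenceRecord | str, pH: float, pka_set: str = "bjellqvist") -> float:
    """Modeled net charge Q(pH), termini included, X ignored."""
    residues = _residues(seq).replace("X", "")
    if not residues:
        raise UndefinedCompositionError("all-X sequence has no defined charge")
    pka = PKA_TABLES[pka_set]
    counts = {aa: residues.count(aa) for aa in "DECYHKR"}
    counts["Nterm"] = 1
    counts["Cterm"] = 1
    q = 0.0
    for g in _BASIC_GROUPS:
        q += counts.get(g, 0) / (1.0 + 10.0 ** (pH - pka[g]))
    for g in _ACIDIC_GROUPS:
        q -= counts.get(g, 0) / (1.0 + 10.0 ** (pka[g] - pH))
    return q


def isoelectric_point(seq: SequenceRecord | str, pka_set: str = "bjellqvist",
                      tol: float = 1e-4) -> float:
    """Theoretical pI: the unique zero of Q(pH) on [0, 14], by bisection.

    With the termini always present Q(0) > 0 > Q(14), so a root exists for
    every sequence; bisection runs until ``|Q| < tol``.
    """
    lo, hi = 0.0, 14.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        q = net_charge(seq, mid, pka_set)
        if abs(q) < tol:
            return mid
        if q > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def composition_profile(seq: SequenceRecord | str, pka_set: str = "bjellqvist",
                        dominance_threshold: float = 0.10) -> CompositionProfile:
    """Residue-class fractions plus theoretical pI for a sequence or region."""
    residues = _residues(seq)
    counted = residues.replace("X", "")
    if not counted:
        raise UndefinedCompositionError("all-X sequence has no defined composition")
    n = len(counted)

    def frac(members) -> float:
        return sum(counted.count(aa) for aa in members) / n

    dominant = frozenset(
        aa for aa in set(counted) if counted.count(aa) / n > dominance_threshold
    )
    return CompositionProfile(
        length=len(residues),
        charged=frac(CHARGED),
        acidic=frac(ACIDIC),
        basic=frac(BASIC),
        proline=frac("P"),
        glycine=frac("G"),
        lysine=frac("K"),
        cysteine=frac("C"),
        methionine=frac("M"),
        aromatic=frac(AROMATIC),
        hydrophobic=frac(HYDROPHOBIC),
        theoretical_pI=isoelectric_point(counted, pka_set),
        low_complexity_dominant=dominant,
    )


# ---------------------------------------------------------------------------
# Composition-based classifiers
# ---------------------------------------------------------------------------

#: Reference composition ranges for the two propeptide classes: the
#: intrinsically disordered (ID) propeptides average 20% charged residues
#: (acidic ~15%, basic ~5%, Pro ~7%, lengths 48-147 aa) while the structured
#: propeptides average 25% charged (acidic ~11%, basic ~13%, Pro ~3%,
#: lengths 145-172 aa).  Reported in every classification for transparency.
PROPEPTIDE_REFERENCE = {
    "ID": {"charged": (0.10, 0.32), "acidic_mean": 0.15, "basic_mean": 0.05,
           "proline_mean": 0.07, "length": (48, 147)},
    "structured": {"charged": (0.17, 0.39), "acidic_mean": 0.11, "basic_mean": 0.13,
                   "proline_mean": 0.03, "length": (145, 172)},
}


@dataclass(frozen=True)
class PropeptideCall:
    kind: str  # "ID" or "structured"
    criteria_fired: tuple[str, ...]
    disorder_fraction: float | None
    reference: dict = field(default_factory=lambda: PROPEPTIDE_REFERENCE, repr=False)


def classify_propeptide(profile: CompositionProfile,
                        disorder_fraction: float | None = None) -> PropeptideCall:
    """Classify a propeptide region as intrinsically disordered or structured.

    A structure-derived disorder fraction, when available, dominates
    (>= 0.5 -> ID). Otherwise a 3-way composition vote is taken: high
    proline (>= 5%), acidic excess over basic (>= 5 points) and short
    length (<= 147 aa) each favor ID; two of three call ID.
    """
    if disorder_fraction is not None:
        kind = "ID" if disorder_fraction >= 0.5 else "structured"
        return PropeptideCall(kind, ("disorder_fraction",), disorder_fraction)
    fired = []
    if profile.proline >= 0.05:
        fired.append("proline>=0.05")
    if profile.acidic - profile.basic >= 0.05:
        fired.append("acidic_excess>=0.05")
    if profile.length <= 147:
        fired.append("length<=147")
    kind = "ID" if len(fired) >= 2 else "structured"
    return PropeptideCall(kind, tuple(fired), None)


def classify_w_domain(profile: CompositionProfile) -> str:
    """Charge class of a cell-wall-spanning W domain from its theoretical pI.

    Acidic when pI < 5.5, basic when pI > 9.0, intermediate otherwise.
    """
    if profile.theoretical_pI < 5.5:
        return "acidic"
    if profile.theoretical_pI > 9.0:
        return "basic"
    return "intermediate"


@dataclass(frozen=True)
class SlpaCheck:
    passed: bool
    reasons: tuple[str, ...]


def slpa_check(profile: CompositionProfile) -> SlpaCheck:
    """Test whether a candidate region looks like a Lys-rich SlpA anchor.

    SlpA-type surface-layer attachment domains are rich in lysine (17-32%),
    depleted of acidic residues, and strongly basic (pI > 10). The check
    passes iff Lys >= 17%, acidic <= 5% and pI > 10; each failed criterion
    is reported as a reason.
    """
    reasons = []
    if profile.lysine < 0.17:
        reasons.append(f"lysine below 17% ({profile.lysine:.1%})")
    if profile.acidic > 0.05:
        reasons.append(f"acidic above 5% ({profile.acidic:.1%})")
    if profile.theoretical_pI <= 10.0:
        reasons.append(f"pI not above 10 ({profile.theoretical_pI:.2f})")
    return SlpaCheck(passed=not reasons, reasons=tuple(reasons))
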