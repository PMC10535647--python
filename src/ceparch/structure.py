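"""Coordinate models: parsing, pLDDT disorder calling, superposition, geometry.

Only Cα atoms are modeled. Structure-prediction models store the
per-residue pLDDT confidence (0-100) in the B-factor column, following the
AlphaFold convention; long runs of pLDDT < 50 are read as intrinsic
disorder. The catalytic Asp/His/Ser triad of the subtilase fold is found
geometrically: Cα-Cα distances of approximately 7.5 Å (Asp-His), 8.4 Å
(His-Ser) and 10 Å (Asp-Ser).
"""

from __future__ import annotations

from dataclasses import dataclass

import gemmi
import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from ceparch.seq_io import Region

TRIAD_DISTANCES = {"asp_his": 7.5, "his_ser": 8.4, "asp_ser": 10.0}


class EmptyModelError(ValueError):
    """Structure file yielded no Cα atoms."""


@dataclass
class StructureModel:
    """Per-residue Cα trace with pLDDT.

    ``resi`` holds strictly increasing 1-based residue indices; ``aa`` the
    one-letter codes; ``coords`` an (n, 3) array in Å; ``plddt`` values in
    [0, 100].
    """

    id: str
    resi: np.ndarray
    aa: tuple[str, ...]
    coords: np.ndarray
    plddt: np.ndarray

    def __post_init__(self) -> None:
        self.resi = np.asarray(self.resi, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float)
        self.plddt = np.asarray(self.plddt, dtype=float)
        n = len(self.resi)
        if not (len(self.aa) == n and self.coords.shape == (n, 3) and len(self.plddt) == n):
            raise ValueError("inconsistent per-residue array lengths")
        if n and np.any(np.diff(self.resi) <= 0):
            raise ValueError("residue indices must be strictly increasing")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    def __len__(self) -> int:
        return len(self.resi)

    def subset(self, region: Region) -> "StructureModel":
        mask = (self.resi >= region.start) & (self.resi <= region.end)
        return StructureModel(
            id=f"{self.id}/{region.label or f'{region.start}-{region.end}'}",
            resi=self.resi[mask],
            aa=tuple(a for a, m in zip(self.aa, mask) if m),
            coords=self.coords[mask],
            plddt=self.plddt[mask],
        )


@dataclass(frozen=True)
class Superposition:
    rotation: np.ndarray   # 3x3 proper rotation
    translation: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation

    def to_matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m


@dataclass(frozen=True)
class DisorderSegment:
    region: Region
    mean_plddt: float


@dataclass(frozen=True)
class TriadHit:
    asp_index: int
    his_index: int
    ser_index: int
    d_asp_his: float
    d_his_ser: float
    d_asp_ser: float

    @property
    def total_deviation(self) -> float:
        return (abs(self.d_asp_his - TRIAD_DISTANCES["asp_his"])
                + abs(self.d_his_ser - TRIAD_DISTANCES["his_ser"])
                + abs(self.d_asp_ser - TRIAD_DISTANCES["asp_ser"]))


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

def read_structure(path: str, chain: str | None = None, model_id: str | None = None) -> StructureModel:
    """Read a PDB or mmCIF file into a Cα model (first model, one chain).

    pLDDT is taken from the B-factor field. Residues lacking a Cα atom are
    skipped (their count is reported on the returned model as
    ``n_skipped``); a file with no Cα atoms raises EmptyModelError.
    """
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise EmptyModelError(f"{path}: no models")
    model = st[0]
    if chain is None:
        chains = list(model)
        if not chains:
            raise EmptyModelError(f"{path}: no chains")
        gchain = chains[0]
    else:
        gchain = model[chain]
    resi, aa, coords, plddt = [], [], [], []
    skipped = 0
    for res in gchain:
        ca = res.find_atom("CA", "*")
        if ca is None:
            skipped += 1
            continue
        info = gemmi.find_tabulated_residue(res.name)
        one = info.one_letter_code.upper() if info else "X"
        if not one.isalpha():
            one = "X"
        resi.append(res.seqid.num)
        aa.append(one)
        coords.append([ca.pos.x, ca.pos.y, ca.pos.z])
        plddt.append(ca.b_iso)
    if not resi:
        raise EmptyModelError(f"{path}: no Cα atoms in chain {gchain.name!r}")
    sm = StructureModel(
        id=model_id or st.name or str(path),
        resi=np.array(resi),
        aa=tuple(aa),
        coords=np.array(coords),
        plddt=np.array(plddt),
    )
    sm.n_skipped = skipped
    return sm


def write_pdb(model: StructureModel, path: str) -> None:
    """Write the Cα trace as a minimal PDB file (pLDDT in the B-factor column)."""
    three = {v: k for k, v in _ONE_FROM_THREE.items()}
    with open(path, "w") as fh:
        for i, (ri, aa, xyz, pl) in enumerate(
            zip(model.resi, model.aa, model.coords, model.plddt), start=1
        ):
            resname = three.get(aa, "UNK")
            fh.write(
                f"ATOM  {i:5d}  CA  {resname:<3s} A{ri:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.00:6.2f}{pl:6.2f}"
                f"           C\n"
            )
        fh.write("END\n")


_ONE_FROM_THREE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}


# ---------------------------------------------------------------------------
# pLDDT interpretation
# ---------------------------------------------------------------------------

def disorder_segments(model: StructureModel, threshold: float = 50.0,
                      min_len: int = 20) -> list[DisorderSegment]:
    """Maximal runs of >= min_len consecutive residues with pLDDT < threshold."""
    if len(model) == 0:
        raise ValueError("empty model")
    segments: list[DisorderSegment] = []
    low = model.plddt < threshold
    n = len(model)
    i = 0
    while i < n:
        if not low[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and low[j + 1] and model.resi[j + 1] == model.resi[j] + 1:
            j += 1
        if j - i + 1 >= min_len:
            segments.append(
                DisorderSegment(
                    region=Region(int(model.resi[i]), int(model.resi[j]), "ID"),
                    mean_plddt=float(model.plddt[i : j + 1].mean()),
                )
            )
        i = j + 1
    return segments


def quality_bands(model: StructureModel) -> tuple[float, float, float, float]:
    """Fractions of residues with pLDDT >=90, [70,90), [50,70), <50."""
    if len(model) == 0:
        raise ValueError("empty model")
    p = model.plddt
    n = len(p)
    return (
        float((p >= 90).sum()) / n,
        float(((p >= 70) & (p < 90)).sum()) / n,
        float(((p >= 50) & (p < 70)).sum()) / n,
        float((p < 50).sum()) / n,
    )


def disorder_fraction(model: StructureModel, region: Region | None = None,
                      threshold: float = 50.0) -> float:
    """Fraction of (region) residues below the disorder pLDDT threshold."""
    m = model if region is None else model.subset(region)
    if len(m) == 0:
        raise ValueError("no residues in region")
    return float((m.plddt < threshold).mean())


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------

def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray) -> Superposition:
    """Least-squares rigid superposition of *mobile* onto *reference* (Kabsch).

    Proper rotation is enforced: a reflection in the SVD solution is
    corrected by flipping the sign of the smallest singular direction.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError("point sets must have equal shape")
    if mobile.ndim != 2 or mobile.shape[1] != 3 or mobile.shape[0] < 3:
        raise ValueError("need at least 3 points of dimension 3")
    mc, rc = mobile.mean(axis=0), reference.mean(axis=0)
    a, b = mobile - mc, reference - rc
    h = a.T @ b
    u, s, vt = np.linalg.svd(h)
    sign = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, sign])
    rot = vt.T @ corr @ u.T
    moved = a @ rot.T
    rmsd = float(np.sqrt(((moved - b) ** 2).sum() / len(a)))
    trans = rc - rot @ mc
    return Superposition(rotation=rot, translation=trans, rmsd=rmsd)


def superpose_by_alignment(model_a: StructureModel, model_b: StructureModel,
                           pairing: list[tuple[int, int]]) -> Superposition:
    """Kabsch on Cα pairs given as (residue index in A, residue index in B)."""
    if len(pairing) < 3:
        raise ValueError("need at least 3 residue pairs")
    idx_a = {int(r): k for k, r in enumerate(model_a.resi)}
    idx_b = {int(r): k for k, r in enumerate(model_b.resi)}
    try:
        rows = [(idx_a[i], idx_b[j]) for i, j in pairing]
    except KeyError as exc:
        raise KeyError(f"pairing references missing residue {exc}") from None
    ka, kb = zip(*rows)
    return kabsch_superpose(model_a.coords[list(ka)], model_b.coords[list(kb)])


def alignment_pairing(aln_rows: tuple[str, str],
                      model_a: StructureModel, model_b: StructureModel) -> list[tuple[int, int]]:
    """Residue-index pairs from the gapless columns of a 2-row alignment."""
    ra, rb = aln_rows
    ia = ib = 0
    pairs: list[tuple[int, int]] = []
    for ca, cb in zip(ra, rb):
        if ca != "-" and cb != "-":
            pairs.append((int(model_a.resi[ia]), int(model_b.resi[ib])))
        if ca != "-":
            ia += 1
        if cb != "-":
            ib += 1
    return pairs


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def find_catalytic_triad(model: StructureModel, window: float = 2.0) -> list[TriadHit]:
    """All Asp<His<Ser triples whose Cα distances match the subtilase triad.

    Matches require |d(D,H) - 7.5| <= window, |d(H,S) - 8.4| <= window and
    |d(D,S) - 10| <= window (Å); hits are sorted by total deviation.
    """
    aa = np.array(model.aa)
    d_idx = np.flatnonzero(aa == "D")
    h_idx = np.flatnonzero(aa == "H")
    s_idx = np.flatnonzero(aa == "S")
    hits: list[TriadHit] = []
    for di in d_idx:
        for hi in h_idx:
            if hi <= di:
                continue
            ddh = float(np.linalg.norm(model.coords[di] - model.coords[hi]))
            if abs(ddh - TRIAD_DISTANCES["asp_his"]) > window:
                continue
            for si in s_idx:
                if si <= hi:
                    continue
                dhs = float(np.linalg.norm(model.coords[hi] - model.coords[si]))
                if abs(dhs - TRIAD_DISTANCES["his_ser"]) > window:
                    continue
                dds = float(np.linalg.norm(model.coords[di] - model.coords[si]))
                if abs(dds - TRIAD_DISTANCES["asp_ser"]) > window:
                    continue
                hits.append(
                    TriadHit(
                        asp_index=int(model.resi[di]),
                        his_index=int(model.resi[hi]),
                        ser_index=int(model.resi[si]),
                        d_asp_his=ddh, d_his_ser=dhs, d_asp_ser=dds,
                    )
                )
    return sorted(hits, key=lambda h: h.total_deviation)


def domain_span(coords: np.ndarray) -> float:
    """Physical extent (nm) along the first principal axis of a Cα cloud."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or len(coords) < 2:
        raise ValueError("need at least 2 points")
    centered = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    proj = centered @ vt[0]
    return float(proj.max() - proj.min()) / 10.0


def cluster_domain_structures(domains: list[tuple[str, StructureModel]],
                              cut: float = 3.5) -> list[list[str]]:
    """Group domain models by pairwise superposition RMSD.

    Pairings come from the gapless columns of best pairwise global sequence
    alignments; average-linkage hierarchical clustering is cut at the given
    RMSD (Å). Groups are numbered deterministically by their smallest
    member label.
    """
    from ceparch.phylo import global_align

    if not domains:
        raise ValueError("need at least one domain")
    if len(domains) == 1:
        return [[domains[0][0]]]
    n = len(domains)
    rmsd = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            label_i, mi = domains[i]
            label_j, mj = domains[j]
            aln = global_align("".join(mi.aa), "".join(mj.aa))
            pairs = alignment_pairing((aln.rows[0], aln.rows[1]), mi, mj)
            if len(pairs) < 3:
                rmsd[i, j] = rmsd[j, i] = np.inf
                continue
            sup = superpose_by_alignment(mi, mj, pairs)
            rmsd[i, j] = rmsd[j, i] = sup.rmsd
    finite_max = np.nanmax(np.where(np.isfinite(rmsd), rmsd, 0.0))
    rmsd = np.where(np.isfinite(rmsd), rmsd, finite_max * 10 + 100)
    z = linkage(squareform(rmsd, checks=False), method="average")
    assignment = fcluster(z, t=cut, criterion="distance")
    groups: dict[int, list[str]] = {}
    for (label, _), g in zip(domains, assignment):
        groups.setdefault(g, []).append(label)
    out = [sorted(members) for members in groups.values()]
    return sorted(out, key=lambda g: g[0])
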