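"""Seeded generators for CEP-like sequences, families and toy structures.

Every generator is a pure function of (parameters, seed) and returns its
ground truth alongside the data, so each pipeline stage can be tested for
parameter recovery without any database downloads.

Residue recipes follow the composition statistics reported for the domain
classes they emulate: intrinsically disordered propeptides carry ~20%
charged residues (acidic:basic about 15:5), ~7% Pro and no Cys; structured
propeptides ~24% charged split 11:13 with ~3% Pro; W domains draw from a
low-complexity alphabet (Ala, Pro, Gly, Ser, Thr, Asn, Gln, Asp, Lys)
essentially devoid of Cys, Met and aromatics; SlpA anchors are ~25% Lys
with no acidic residues; AN anchors are a sortase motif followed by a
hydrophobic stretch and a Lys/Arg tail. Unconstrained positions draw from
a uniform background. The catalytic Asp/His/Ser residues are planted
explicitly and the protease-domain background excludes free D/H/S so the
planted triad stays geometrically unambiguous.

Toy structures are Cα point clouds: structured domains are compact clouds
scaled to a target span with high pLDDT; W domains and ID propeptides are
extended low-pLDDT chains; the catalytic triad is planted at the reported
Cα geometry (7.5 / 8.4 / 10 Å). The clouds exercise geometry code; they
are not meant to be protein-like beyond their span/pLDDT/triad contracts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ceparch.architecture import DomainSegment, _ORDER, ATTACHMENT_KINDS, GrammarError
from ceparch.phylo import PhyloTree, TreeNode, DistanceMatrix
from ceparch.seq_io import Region, SequenceRecord
from ceparch.structure import StructureModel

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def _recipe(weights: dict[str, float], background: str) -> tuple[str, np.ndarray]:
    """Fill the probability mass left by *weights* uniformly over *background*."""
    used = sum(weights.values())
    rest = [aa for aa in background if aa not in weights]
    probs = {aa: w for aa, w in weights.items()}
    for aa in rest:
        probs[aa] = (1.0 - used) / len(rest)
    letters = "".join(probs)
    return letters, np.array([probs[aa] for aa in letters])


_NO_C = AMINO_ACIDS.replace("C", "")
RECIPES: dict[str, tuple[str, np.ndarray]] = {
    # ID propeptide: charged 0.20 with acidic:basic = 15:5, Pro 0.07, no Cys
    "propeptide_id": _recipe(
        {"D": 0.075, "E": 0.075, "K": 0.02, "R": 0.02, "H": 0.01, "P": 0.07},
        _NO_C,
    ),
    # structured propeptide: charged ~0.24 split 11:13, Pro 0.03, no Cys
    "propeptide_structured": _recipe(
        {"D": 0.055, "E": 0.055, "K": 0.06, "R": 0.045, "H": 0.025, "P": 0.03},
        _NO_C,
    ),
    # W domain: low-complexity, aromatic/Cys/Met-free; acidic or basic bias
    "w_acidic": (
        "APGSTNQDK",
        np.array([0.15, 0.12, 0.12, 0.14, 0.12, 0.08, 0.09, 0.15, 0.03]),
    ),
    "w_basic": (
        "APGSTNQDK",
        np.array([0.15, 0.12, 0.12, 0.14, 0.12, 0.08, 0.09, 0.02, 0.16]),
    ),
    # SlpA: Lys-rich, acidic-free; L/M/F withheld so no anchor-motif 5-mer
    # can arise inside the anchor domain itself
    "slpa": _recipe({"K": 0.25}, "ASTNGQVIY"),
    # protease domain background: catalytic D/H/S planted, not drawn
    "protease": (
        "ACEFGIKLMNPQRTVWY",
        np.full(17, 1.0 / 17.0),
    ),
    "generic": (AMINO_ACIDS, np.full(20, 0.05)),
}

_HYDROPHOBIC_RUN = "LIVF"  # KD-positive and disjoint from anchor-motif position-2 residues


@dataclass(frozen=True)
class LayoutElement:
    kind: str
    length: int
    params: dict = field(default_factory=dict)


@dataclass(frozen=True)
class CepLayout:
    """An ordered domain plan obeying the CEP architecture grammar."""

    name: str
    elements: tuple[LayoutElement, ...]

    def __post_init__(self) -> None:
        kinds = [e.kind for e in self.elements]
        if len(set(kinds)) != len(kinds):
            raise GrammarError("duplicate kinds in layout")
        order = [_ORDER[k] for k in kinds]
        if any(b <= a for a, b in zip(order, order[1:])):
            raise GrammarError(f"layout {self.name!r} violates the domain grammar")
        if any(e.length <= 0 for e in self.elements):
            raise GrammarError("element lengths must be positive")
        n_attach = sum(1 for k in kinds if k in ATTACHMENT_KINDS)
        if n_attach > 1:
            raise GrammarError("at most one attachment domain")
        if n_attach and "W" not in kinds:
            raise GrammarError("attachment requires a W domain")


def _w_sequence(rng: np.random.Generator, element: LayoutElement,
                recipe_key: str) -> tuple[str, dict]:
    """W-domain residues, optionally built from an imperfect tandem repeat."""
    letters, probs = RECIPES[recipe_key]
    attrs: dict = {}
    repeat = element.params.get("repeat")
    if not repeat:
        seq = "".join(rng.choice(list(letters), size=element.length, p=probs))
        return seq, attrs
    unit_len = repeat["unit_length"]
    copies = repeat.get("copies", 3.0)
    sub_rate = repeat.get("sub_rate", 0.1)
    unit = "".join(rng.choice(list(letters), size=unit_len, p=probs))
    total = int(round(unit_len * copies))
    tiled = (unit * (total // unit_len + 1))[:total]
    out = []
    for ch in tiled:
        if rng.random() < sub_rate:
            out.append(str(rng.choice(list(letters), p=probs)))
        else:
            out.append(ch)
    seq = "".join(out)
    if len(seq) < element.length:
        pad = "".join(rng.choice(list(letters), size=element.length - len(seq), p=probs))
        seq = seq + pad
    attrs.update(repeat_unit=unit, repeat_unit_length=unit_len,
                 repeat_copies=round(len(tiled) / unit_len, 3))
    return seq[: element.length] if len(seq) > element.length else seq, attrs


def generate_cep(layout: CepLayout, seed: int) -> tuple[SequenceRecord, list[DomainSegment]]:
    """Generate one CEP-like precursor plus its ground-truth segments."""
    rng = np.random.default_rng(seed)
    pieces: list[str] = []
    truth: list[DomainSegment] = []
    cursor = 0
    triad_positions: dict[str, int] = {}
    for element in layout.elements:
        kind = element.kind
        attrs: dict = dict(element.params)
        if kind == "PRO":
            ptype = element.params.get("propeptide", "structured")
            key = "propeptide_id" if ptype == "ID" else "propeptide_structured"
            letters, probs = RECIPES[key]
            seq = "".join(rng.choice(list(letters), size=element.length, p=probs))
            attrs["propeptide_type"] = ptype
        elif kind == "W":
            charge = element.params.get("charge_class", "acidic")
            seq, w_attrs = _w_sequence(rng, element, f"w_{charge}")
            attrs.update(w_attrs)
            attrs["w_charge_class"] = charge
        elif kind == "SLPA":
            # tandem pair: one ~half-length unit duplicated with light noise
            letters, probs = RECIPES["slpa"]
            spacer = max(0, element.length - 2 * (element.length // 2))
            half = element.length // 2
            unit = "".join(rng.choice(list(letters), size=half, p=probs))
            second = [
                str(rng.choice(list(letters), p=probs)) if rng.random() < 0.1 else ch
                for ch in unit
            ]
            mid = "".join(rng.choice(list(letters), size=spacer, p=probs))
            seq = unit + mid + "".join(second)
            attrs["tandem_unit_length"] = half
        elif kind == "AN":
            motif = element.params.get("motif", "LPKTG")
            tail_len = 6
            run_len = element.length - len(motif) - tail_len
            if run_len < 15:
                raise GrammarError("AN element too short for motif + hydrophobic run + tail")
            run = "".join(rng.choice(list(_HYDROPHOBIC_RUN), size=run_len))
            tail = "".join(rng.choice(list("KR"), size=tail_len))
            seq = motif + run + tail
            attrs["motif"] = motif
            attrs["motif_start"] = cursor + 1
        elif kind in ("PR1", "PR2"):
            letters, probs = RECIPES["protease"]
            chars = list(rng.choice(list(letters), size=element.length, p=probs))
            if kind == "PR1":
                a_pos = element.length // 3
                h_pos = 2 * element.length // 3
                chars[a_pos] = "D"
                chars[h_pos] = "H"
                triad_positions["asp"] = cursor + a_pos + 1
                triad_positions["his"] = cursor + h_pos + 1
            else:
                s_pos = element.length // 2
                chars[s_pos] = "S"
                triad_positions["ser"] = cursor + s_pos + 1
            seq = "".join(chars)
        else:  # PRE, PA, FN*, H
            letters, probs = RECIPES["generic"]
            seq = "".join(rng.choice(list(letters), size=element.length, p=probs))
        region = Region(cursor + 1, cursor + len(seq), kind)
        truth.append(DomainSegment(region=region, kind=kind, attributes=attrs))
        pieces.append(seq)
        cursor += len(seq)

    if triad_positions and len(triad_positions) == 3:
        for seg in truth:
            if seg.kind == "PR1":
                seg.attributes["catalytic"] = dict(triad_positions)
    record = SequenceRecord(
        id=f"{layout.name}_s{seed}",
        residues="".join(pieces),
        description=f"synthetic CEP precursor ({layout.name}, seed {seed})",
    )
    return record, truth


# ---------------------------------------------------------------------------
# Toy structure generation
# ---------------------------------------------------------------------------

#: planar Cα coordinates realizing the catalytic-triad distance triangle
_TRIAD_LOCAL = np.array([
    [0.0, 0.0, 0.0],            # Asp
    [7.5, 0.0, 0.0],            # His
    [5.7127, 8.2077, 0.0],      # Ser: 10.0 from Asp, 8.4 from His
])

_DISORDERED_KINDS = {"W"}


def _is_disordered(seg: DomainSegment) -> bool:
    if seg.kind in _DISORDERED_KINDS:
        return True
    return seg.kind == "PRO" and seg.attributes.get("propeptide_type") == "ID"


def generate_structure(segments: list[DomainSegment], seed: int,
                       sequence: str | None = None) -> StructureModel:
    """Toy Cα model with domain-wise pLDDT tracks and planted triad geometry.

    Structured segments become compact clouds scaled so the first-principal-
    axis extent equals the span target (``span_nm`` in params, default 4 nm)
    with pLDDT in [80, 95]; disordered segments (W, ID propeptides) become
    extended chains with pLDDT in [20, 45]; anchor/attachment segments get
    intermediate confidence. Catalytic positions recorded on PR1 are planted
    at Cα distances 7.5 / 8.4 / 10 Å.
    """
    rng = np.random.default_rng(seed)
    coords_parts: list[np.ndarray] = []
    plddt_parts: list[np.ndarray] = []
    resi: list[int] = []
    aa: list[str] = []
    cursor_x = 0.0
    triad: dict[str, int] = {}
    for seg in sorted(segments, key=lambda s: s.region.start):
        n = len(seg.region)
        if seg.attributes.get("catalytic"):
            triad = seg.attributes["catalytic"]
        if _is_disordered(seg):
            xs = cursor_x + 3.3 * np.arange(n)
            pts = np.column_stack([xs, rng.normal(0, 0.8, n), rng.normal(0, 0.8, n)])
            pl = rng.uniform(20, 45, n)
            cursor_x = xs[-1] + 3.3 + 10.0
        else:
            span = 10.0 * seg.attributes.get("span_nm", 4.0)
            pts = rng.uniform(-1.0, 1.0, size=(n, 3)) * np.array([1.0, 0.45, 0.45])
            centered = pts - pts.mean(axis=0)
            _, _, vt = np.linalg.svd(centered, full_matrices=False)
            proj = centered @ vt[0]
            extent = proj.max() - proj.min()
            pts = centered * (span / extent)
            pts[:, 0] += cursor_x + span / 2.0
            if seg.kind in ("AN", "SLPA", "PRE"):
                pl = rng.uniform(60, 80, n)
            else:
                pl = rng.uniform(80, 95, n)
            cursor_x += span + 20.0
        coords_parts.append(pts)
        plddt_parts.append(pl)
        resi.extend(range(seg.region.start, seg.region.end + 1))
        if sequence is not None:
            aa.extend(sequence[seg.region.start - 1 : seg.region.end])
        else:
            aa.extend("X" * n)

    coords = np.vstack(coords_parts)
    plddt = np.concatenate(plddt_parts)
    index_of = {r: k for k, r in enumerate(resi)}
    if len(triad) == 3:
        base = coords[index_of[triad["asp"]]].copy()
        for key, row in zip(("asp", "his", "ser"), _TRIAD_LOCAL):
            coords[index_of[triad[key]]] = base + row
        for key, letter in zip(("asp", "his", "ser"), "DHS"):
            aa[index_of[triad[key]]] = letter
    return StructureModel(
        id=f"synthetic_s{seed}",
        resi=np.array(resi),
        aa=tuple(aa),
        coords=coords,
        plddt=plddt,
    )


def noisy_rigid_copy(model: StructureModel, seed: int, sigma: float = 0.5) -> StructureModel:
    """Rigid-transformed copy with isotropic Gaussian coordinate noise."""
    rng = np.random.default_rng(seed)
    # a uniformly random proper rotation from the QR decomposition
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    t = rng.uniform(-50, 50, 3)
    coords = model.coords @ q.T + t + rng.normal(0, sigma, model.coords.shape)
    return StructureModel(
        id=f"{model.id}_copy{seed}", resi=model.resi.copy(), aa=model.aa,
        coords=coords, plddt=model.plddt.copy(),
    )


# ---------------------------------------------------------------------------
# Sequence families down a tree
# ---------------------------------------------------------------------------

def generate_family(tree: PhyloTree, root_seq: str, seed: int) -> dict[str, SequenceRecord]:
    """Evolve *root_seq* down *tree* under a 20-state equal-rates process.

    Along a branch of length d (substitutions/site) each site draws a new
    state uniformly from all 20 with probability 1 - exp(-d*s/(s-1)), the
    exact transition kernel of the s-state Jukes-Cantor chain; the observed
    change probability per branch is therefore ((s-1)/s)*(1-exp(-d*s/(s-1)))
    and distances compose correctly across branches.
    """
    rng = np.random.default_rng(seed)
    s = 20
    letters = np.array(list(AMINO_ACIDS))
    out: dict[str, SequenceRecord] = {}

    def walk(node: TreeNode, seq: np.ndarray) -> None:
        if node.length > 0:
            p_evt = 1.0 - np.exp(-node.length * s / (s - 1))
            mask = rng.random(len(seq)) < p_evt
            seq = seq.copy()
            seq[mask] = rng.choice(letters, size=int(mask.sum()))
        if node.is_leaf:
            out[node.name] = SequenceRecord(
                id=node.name, residues="".join(seq),
                description="synthetic family member",
            )
            return
        for child in node.children:
            walk(child, seq)

    walk(tree.root, np.array(list(root_seq)))
    return out


def random_root_sequence(length: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def random_binary_tree(n_taxa: int, seed: int, min_bl: float = 0.02,
                       max_bl: float = 0.3) -> PhyloTree:
    """Random binary topology with uniform branch lengths, leaves T0..T{n-1}."""
    rng = np.random.default_rng(seed)
    nodes = [TreeNode(name=f"T{i}") for i in range(n_taxa)]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        a.length = float(rng.uniform(min_bl, max_bl))
        b.length = float(rng.uniform(min_bl, max_bl))
        merged = TreeNode(children=[a, b])
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)] + [merged]
    for node in nodes:
        node.length = float(rng.uniform(min_bl, max_bl))
    return PhyloTree(root=TreeNode(children=nodes))


def tree_distance_matrix(tree: PhyloTree) -> DistanceMatrix:
    """Additive leaf-to-leaf path-length matrix of a tree."""
    names = sorted(tree.leaf_names())
    n = len(names)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = tree.path_length(names[i], names[j])
    return DistanceMatrix(tuple(names), d)


# ---------------------------------------------------------------------------
# Layout templates
# ---------------------------------------------------------------------------

def _fn(number: int, length: int = 100) -> LayoutElement:
    return LayoutElement(f"FN{number}", length)


LAYOUTS: dict[str, CepLayout] = {
    layout.name: layout
    for layout in [
        CepLayout("subtilisin_like", (
            LayoutElement("PRE", 29),
            LayoutElement("PRO", 160, {"propeptide": "structured"}),
            LayoutElement("PR1", 160),
            LayoutElement("PR2", 114),
        )),
        CepLayout("scpa_like", (
            LayoutElement("PRE", 31),
            LayoutElement("PRO", 100, {"propeptide": "ID"}),
            LayoutElement("PR1", 260),
            LayoutElement("PA", 150),
            LayoutElement("PR2", 120),
            _fn(1, 150), _fn(2, 180), _fn(3, 110),
            LayoutElement("W", 63, {"charge_class": "acidic",
                                    "repeat": {"unit_length": 17, "copies": 3.7}}),
            LayoutElement("AN", 45, {"motif": "LPTTN"}),
        )),
        CepLayout("cluster_x_like", (
            LayoutElement("PRE", 33),
            LayoutElement("PRO", 154, {"propeptide": "structured"}),
            LayoutElement("PR1", 260),
            LayoutElement("PA", 160),
            LayoutElement("PR2", 120),
            _fn(1, 140), _fn(2, 190), _fn(3, 110),
            _fn(4), _fn(5), _fn(6, 110), _fn(7), _fn(8, 95),
            LayoutElement("H", 220),
            LayoutElement("W", 180, {"charge_class": "acidic",
                                     "repeat": {"unit_length": 60, "copies": 3.0}}),
            LayoutElement("AN", 45, {"motif": "LPKTG"}),
        )),
        CepLayout("slpa_type", (
            LayoutElement("PRE", 32),
            LayoutElement("PRO", 160, {"propeptide": "structured"}),
            LayoutElement("PR1", 260),
            LayoutElement("PA", 150),
            LayoutElement("PR2", 120),
            _fn(1, 140), _fn(2, 170), _fn(3, 110),
            _fn(4), _fn(5), _fn(6), _fn(7), _fn(8), _fn(9), _fn(10, 90),
            LayoutElement("W", 90, {"charge_class": "basic"}),
            LayoutElement("SLPA", 126),
        )),
        CepLayout("no_attachment", (
            LayoutElement("PRE", 30),
            LayoutElement("PRO", 150, {"propeptide": "structured"}),
            LayoutElement("PR1", 280),
            LayoutElement("PA", 190),
            LayoutElement("PR2", 120),
            _fn(1, 140), _fn(2, 160), _fn(3, 110),
            _fn(4), _fn(5), _fn(6), _fn(7), _fn(8),
        )),
        CepLayout("no_pa_slpa", (
            LayoutElement("PRE", 30),
            LayoutElement("PRO", 120, {"propeptide": "ID"}),
            LayoutElement("PR1", 230),
            LayoutElement("PR2", 120),
            _fn(1, 130), _fn(2, 170), _fn(3, 110),
            _fn(4), _fn(5), _fn(6), _fn(7),
            LayoutElement("W", 90, {"charge_class": "acidic",
                                    "repeat": {"unit_length": 39, "copies": 2.3}}),
            LayoutElement("SLPA", 130),
        )),
        CepLayout("short_b_an", (
            LayoutElement("PRE", 30),
            LayoutElement("PRO", 110, {"propeptide": "ID"}),
            LayoutElement("PR1", 250),
            LayoutElement("PA", 140),
            LayoutElement("PR2", 115),
            _fn(1, 140), _fn(2, 170), _fn(3, 110),
            _fn(4), _fn(5),
            LayoutElement("W", 80, {"charge_class": "basic"}),
            LayoutElement("AN", 45, {"motif": "FPTTN"}),
        )),
        CepLayout("long_b_an", (
            LayoutElement("PRE", 30),
            LayoutElement("PRO", 158, {"propeptide": "structured"}),
            LayoutElement("PR1", 255),
            LayoutElement("PA", 145),
            LayoutElement("PR2", 118),
            _fn(1, 135), _fn(2, 175), _fn(3, 105),
            _fn(4), _fn(5), _fn(6), _fn(7), _fn(8), _fn(9), _fn(10, 85),
            LayoutElement("W", 94, {"charge_class": "basic"}),
            LayoutElement("AN", 45, {"motif": "LAKTA"}),
        )),
    ]
}


def truth_boundaries(truth: list[DomainSegment]) -> dict[str, Region]:
    """Structured-core boundaries (annotator inputs) from ground-truth segments."""
    return {
        seg.kind: seg.region
        for seg in truth
        if seg.kind not in ("W", "AN", "SLPA")
    }


def truth_architecture_string(layout: CepLayout) -> str:
    from ceparch.architecture import _architecture_string

    return _architecture_string([e.kind for e in layout.elements])
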