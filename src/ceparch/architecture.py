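"""The CEP domain grammar: assembly, validation and end-to-end annotation.

A CEP precursor follows the ordered grammar

    PRE < PRO < PR1 < [PA] < PR2 < [FN1 FN2 FN3 [FN4..FN10]] < [H] < [W] < [AN | SLPA]

with three hard rules: the protease-associated PA domain sits only between
PR1 and PR2; a precursor carries at most one attachment domain (covalent
AN or non-covalent SlpA, never both); and an attachment domain is always
preceded by a cell-wall-spanning W domain. When fibronectin-like domains
are present, the A-region always contributes exactly three (Fn1-Fn3); the
B-region adds up to seven more (Fn4-Fn10).

The annotator computes the evidence the sequence and (optional) structure
carry — anchor motifs, SlpA composition, disorder-based W calling, tandem
repeats, propeptide class, catalytic triad — while the boundaries of the
structured core domains (PRE/PRO/PR/PA/Fn/H), which derive from profile
databases and manual structural inspection, are accepted as inputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

from ceparch import composition as comp
from ceparch import motifs as mot
from ceparch import repeats as rep
from ceparch.seq_io import Region, SequenceRecord
from ceparch.structure import StructureModel, disorder_fraction, disorder_segments, find_catalytic_triad

DOMAIN_KINDS = (
    "PRE", "PRO", "PR1", "PA", "PR2",
    "FN1", "FN2", "FN3", "FN4", "FN5", "FN6", "FN7", "FN8", "FN9", "FN10",
    "H", "W", "AN", "SLPA",
)
_ORDER = {k: i for i, k in enumerate(DOMAIN_KINDS)}
_ORDER["SLPA"] = _ORDER["AN"]  # the two attachment kinds share the final slot
ATTACHMENT_KINDS = ("AN", "SLPA")
_REQUIRED = ("PRE", "PRO", "PR1", "PR2")


class GrammarError(ValueError):
    """Segment ordering or co-occurrence violates the CEP domain grammar."""


class OverlapError(GrammarError):
    """Two segments of one profile overlap."""


@dataclass(frozen=True)
class DomainSegment:
    region: Region
    kind: str
    attributes: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.kind not in _ORDER:
            raise ValueError(f"unknown domain kind {self.kind!r}")


@dataclass(frozen=True)
class ArchitectureProfile:
    record_id: str
    segments: tuple[DomainSegment, ...]
    architecture_string: str
    propeptide_type: str        # "ID", "structured" or "unknown"
    attachment_mode: str        # "AN", "SlpA" or "none"
    fn_count_A: int
    fn_count_B: int


def _architecture_string(kinds: list[str]) -> str:
    out: list[str] = []
    i = 0
    while i < len(kinds):
        # PR1 directly followed by PR2 (no PA insert) prints as one PR domain
        if kinds[i] == "PR1" and i + 1 < len(kinds) and kinds[i + 1] == "PR2":
            out.append("PR")
            i += 2
            continue
        out.append(kinds[i])
        i += 1
    return "-".join(out)


def assemble_architecture(segments: list[DomainSegment],
                          record_id: str = "") -> ArchitectureProfile:
    """Validate the grammar and derive the canonical architecture profile."""
    if not segments:
        raise GrammarError("no segments")
    segs = sorted(segments, key=lambda s: s.region.start)
    for a, b in zip(segs, segs[1:]):
        if a.region.overlaps(b.region):
            raise OverlapError(
                f"segments {a.kind} ({a.region.start}..{a.region.end}) and "
                f"{b.kind} ({b.region.start}..{b.region.end}) overlap"
            )
    kinds = [s.kind for s in segs]
    if len(set(kinds)) != len(kinds):
        raise GrammarError("duplicate domain kinds in one profile")
    order = [_ORDER[k] for k in kinds]
    for (ka, oa), (kb, ob) in zip(zip(kinds, order), zip(kinds[1:], order[1:])):
        if ob <= oa:
            raise GrammarError(f"{kb} may not follow {ka}")
    present = set(kinds)
    missing = [k for k in _REQUIRED if k not in present]
    if missing:
        raise GrammarError(f"missing mandatory domains: {missing}")
    if "PA" in present:
        i_pa = kinds.index("PA")
        if kinds[i_pa - 1] != "PR1" or kinds[i_pa + 1] != "PR2":
            raise GrammarError("PA must sit between PR1 and PR2")
    attachments = [k for k in kinds if k in ATTACHMENT_KINDS]
    if len(attachments) > 1:
        raise GrammarError("a precursor carries either an AN or a SlpA domain, not both")
    attachment_mode = {"AN": "AN", "SLPA": "SlpA"}.get(
        attachments[0] if attachments else "", "none"
    )
    if attachment_mode != "none":
        if "W" not in present:
            raise GrammarError("an attachment domain must be preceded by a W domain")
        if kinds[-1] not in ATTACHMENT_KINDS or kinds[-2] != "W":
            raise GrammarError("W must immediately precede the attachment domain")
    fn_a = sum(1 for k in kinds if k in ("FN1", "FN2", "FN3"))
    fn_b = sum(1 for k in kinds if k.startswith("FN") and k not in ("FN1", "FN2", "FN3"))
    if (fn_a or fn_b) and fn_a != 3:
        raise GrammarError("when Fn domains are present the A-region has exactly Fn1-Fn3")
    b_numbers = sorted(int(k[2:]) for k in kinds if k.startswith("FN")) if fn_b else []
    if b_numbers and b_numbers != list(range(1, len(b_numbers) + 1)):
        raise GrammarError("Fn domains must be numbered consecutively from Fn1")
    prop_type = "unknown"
    for s in segs:
        if s.kind == "PRO":
            prop_type = s.attributes.get("propeptide_type", "unknown")
    return ArchitectureProfile(
        record_id=record_id,
        segments=tuple(segs),
        architecture_string=_architecture_string(kinds),
        propeptide_type=prop_type,
        attachment_mode=attachment_mode,
        fn_count_A=fn_a,
        fn_count_B=fn_b,
    )


def count_architectures(profiles: list[ArchitectureProfile]) -> tuple[int, dict[str, list[str]]]:
    """Number of distinct architecture strings plus the members of each."""
    if not profiles:
        raise ValueError("need at least one profile")
    groups: dict[str, list[str]] = {}
    for p in profiles:
        groups.setdefault(p.architecture_string, []).append(p.record_id)
    return len(groups), groups


# ---------------------------------------------------------------------------
# End-to-end annotation
# ---------------------------------------------------------------------------

@dataclass
class AnnotationConfig:
    """Tunable evidence thresholds for :func:`annotate`.

    ``boundaries`` maps structured-core kinds (PRE, PRO, PR1, PA, PR2,
    FN1.., H) to their regions; these are inputs, not predictions.
    """

    boundaries: dict[str, Region] = field(default_factory=dict)
    # anchor validation
    c_window: int = 70
    min_hydrophobic_run: int = 15
    min_hydropathy: float = 1.0
    tail_len: int = 10
    min_tail_kr: int = 2
    # disorder calling
    disorder_threshold: float = 50.0
    disorder_min_len: int = 20
    w_gap_tolerance: int = 5    # max residues between W end and attachment start
    # sequence-only W heuristic
    w_lowcomplexity_min: float = 0.8   # charged+polar+P+G+A fraction
    w_aromatic_max: float = 0.02       # aromatic+C+M fraction
    # SlpA window search (sequence-only)
    slpa_min_len: int = 100
    slpa_max_len: int = 150
    # repeats inside W
    repeat_min_unit: int = 5
    repeat_max_unit: int = 80
    repeat_min_copies: float = 1.5
    repeat_min_identity: float = 0.5


_W_FRIENDLY = comp.CHARGED | frozenset("STNQPGA")
_W_AVOID = comp.AROMATIC | frozenset("CM")


def _w_heuristic_ok(residues: str, config: AnnotationConfig) -> bool:
    if len(residues) < 10:
        return False
    n = len(residues)
    friendly = sum(residues.count(a) for a in _W_FRIENDLY) / n
    avoid = sum(residues.count(a) for a in _W_AVOID) / n
    return friendly >= config.w_lowcomplexity_min and avoid <= config.w_aromatic_max


def _find_w_region(record: SequenceRecord, model: StructureModel | None,
                   upstream_limit: int, attach_start: int,
                   config: AnnotationConfig) -> Region | None:
    """Locate the disordered W region ending just before *attach_start*."""
    if model is not None:
        for seg in disorder_segments(model, config.disorder_threshold, config.disorder_min_len):
            if (seg.region.end >= attach_start - 1 - config.w_gap_tolerance
                    and seg.region.start < attach_start):
                start = max(seg.region.start, upstream_limit + 1)
                end = min(seg.region.end, attach_start - 1)
                if end >= start:
                    return Region(start, end, "W")
        return None
    if attach_start - 1 <= upstream_limit:
        return None
    candidate = record.residues[upstream_limit : attach_start - 1]
    if _w_heuristic_ok(candidate, config):
        return Region(upstream_limit + 1, attach_start - 1, "W")
    return None


def _motif_hit_dict(hit: mot.MotifHit) -> dict:
    return {"start": hit.start, "end": hit.end, "matched": hit.matched,
            "motif_class": hit.motif_class}


def annotate(record: SequenceRecord, model: StructureModel | None = None,
             config: AnnotationConfig | None = None) -> ArchitectureProfile:
    """Annotate one precursor: attachment, W, repeats, propeptide class, triad.

    The structured-core boundaries in ``config.boundaries`` are taken as
    given; the function adds the computed C-terminal evidence (AN or SlpA
    attachment, W domain with tandem repeats) and attaches classification
    evidence to the corresponding segments. Absence of evidence leaves
    optional domains absent; it is never a hard failure.
    """
    config = config or AnnotationConfig()
    seq = record.residues
    n = len(seq)
    segments: list[DomainSegment] = [
        DomainSegment(region=replace(r, label=kind), kind=kind)
        for kind, r in config.boundaries.items()
        if kind not in ("W", *ATTACHMENT_KINDS)
    ]
    upstream_limit = max((s.region.end for s in segments), default=0)

    # --- attachment: covalent AN first, then SlpA ---
    w_region: Region | None = None
    attach_seg: DomainSegment | None = None

    validated = []
    for hit in mot.scan_anchor_motifs(seq):
        v = mot.validate_an_domain(
            seq, hit, c_window=config.c_window,
            min_hydrophobic_run=config.min_hydrophobic_run,
            min_hydropathy=config.min_hydropathy,
            tail_len=config.tail_len, min_tail_kr=config.min_tail_kr,
        )
        if v.valid:
            validated.append(v)
    for v in reversed(validated):  # most C-terminal valid hit defines AN start
        w = _find_w_region(record, model, upstream_limit, v.motif_hit.start, config)
        if w is not None:
            w_region = w
            attach_seg = DomainSegment(
                region=Region(v.motif_hit.start, n, "AN"),
                kind="AN",
                attributes={
                    "motif": _motif_hit_dict(v.motif_hit),
                    "hydropathy_mean": v.hydropathy_mean,
                },
            )
            break

    if attach_seg is None:
        if model is not None:
            for seg in disorder_segments(model, config.disorder_threshold,
                                         config.disorder_min_len):
                if seg.region.end <= upstream_limit or seg.region.end >= n - 50:
                    continue
                tail = record.residues[seg.region.end:]
                if not (config.slpa_min_len <= len(tail) <= config.slpa_max_len + 10):
                    continue
                check = comp.slpa_check(comp.composition_profile(tail))
                if check.passed:
                    w_region = Region(max(seg.region.start, upstream_limit + 1),
                                      seg.region.end, "W")
                    attach_seg = DomainSegment(
                        region=Region(seg.region.end + 1, n, "SLPA"),
                        kind="SLPA",
                        attributes={"slpa_reasons": list(check.reasons)},
                    )
                    break
        else:
            best = None
            lo = config.slpa_min_len
            hi = min(config.slpa_max_len, n - upstream_limit - 10)
            for L in range(lo, hi + 1):
                tail = seq[n - L:]
                profile = comp.composition_profile(tail)
                if not comp.slpa_check(profile).passed:
                    continue
                w_cand = seq[upstream_limit : n - L]
                if not _w_heuristic_ok(w_cand, config):
                    continue
                if best is None or profile.lysine > best[1]:
                    best = (L, profile.lysine)
            if best is not None:
                L = best[0]
                w_region = Region(upstream_limit + 1, n - L, "W")
                attach_seg = DomainSegment(
                    region=Region(n - L + 1, n, "SLPA"), kind="SLPA",
                )

    if attach_seg is not None and w_region is not None:
        w_attrs: dict = {}
        w_seq = seq[w_region.start - 1 : w_region.end]
        w_profile = comp.composition_profile(w_seq)
        w_attrs["w_charge_class"] = comp.classify_w_domain(w_profile)
        w_attrs["theoretical_pI"] = w_profile.theoretical_pI
        max_unit = min(config.repeat_max_unit, int(len(w_seq) / config.repeat_min_copies))
        if max_unit >= config.repeat_min_unit:
            hits = rep.find_tandem_repeats(
                w_seq, min_unit=config.repeat_min_unit, max_unit=max_unit,
                min_copies=config.repeat_min_copies,
                min_identity=config.repeat_min_identity,
            )
            w_attrs["repeats"] = [
                {
                    "start": w_region.start + h.region.start - 1,
                    "end": w_region.start + h.region.end - 1,
                    "unit_length": h.unit_length,
                    "copy_number": round(h.copy_number, 3),
                    "mean_identity": round(h.mean_identity, 3),
                    "consensus": h.consensus,
                }
                for h in hits
            ]
        segments.append(DomainSegment(region=w_region, kind="W", attributes=w_attrs))
        segments.append(attach_seg)

    # --- propeptide classification ---
    out_segments: list[DomainSegment] = []
    for s in segments:
        if s.kind == "PRO":
            profile = comp.composition_profile(seq[s.region.start - 1 : s.region.end])
            dfrac = None
            if model is not None:
                try:
                    dfrac = disorder_fraction(model, s.region, config.disorder_threshold)
                except ValueError:
                    dfrac = None
            call = comp.classify_propeptide(profile, dfrac)
            attrs = dict(s.attributes)
            attrs.update(
                propeptide_type=call.kind,
                criteria_fired=list(call.criteria_fired),
                disorder_fraction=dfrac,
            )
            s = DomainSegment(region=s.region, kind="PRO", attributes=attrs)
        if s.kind == "PR1" and model is not None:
            triads = find_catalytic_triad(model)
            if triads:
                best_triad = triads[0]
                attrs = dict(s.attributes)
                attrs["catalytic_triad"] = {
                    "asp": best_triad.asp_index,
                    "his": best_triad.his_index,
                    "ser": best_triad.ser_index,
                    "d_asp_his": round(best_triad.d_asp_his, 3),
                    "d_his_ser": round(best_triad.d_his_ser, 3),
                    "d_asp_ser": round(best_triad.d_asp_ser, 3),
                }
                s = DomainSegment(region=s.region, kind="PR1", attributes=attrs)
        out_segments.append(s)

    return assemble_architecture(out_segments, record_id=record.id)


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def profile_to_dict(profile: ArchitectureProfile) -> dict:
    return {
        "record_id": profile.record_id,
        "architecture_string": profile.architecture_string,
        "propeptide_type": profile.propeptide_type,
        "attachment_mode": profile.attachment_mode,
        "fn_count_A": profile.fn_count_A,
        "fn_count_B": profile.fn_count_B,
        "segments": [
            {
                "kind": s.kind,
                "start": s.region.start,
                "end": s.region.end,
                "attributes": s.attributes,
            }
            for s in profile.segments
        ],
    }


def profile_from_dict(data: dict) -> ArchitectureProfile:
    segments = [
        DomainSegment(
            region=Region(s["start"], s["end"], s["kind"]),
            kind=s["kind"],
            attributes=s.get("attributes", {}),
        )
        for s in data["segments"]
    ]
    return assemble_architecture(segments, record_id=data["record_id"])


def report(profile: ArchitectureProfile) -> tuple[str, str]:
    """Machine-readable (JSON) and human-readable (table) summaries."""
    js = json.dumps(profile_to_dict(profile), indent=2, sort_keys=True)
    lines = [
        f"record        {profile.record_id}",
        f"architecture  {profile.architecture_string}",
        f"propeptide    {profile.propeptide_type}",
        f"attachment    {profile.attachment_mode}",
        f"Fn counts     A-region {profile.fn_count_A}, B-region {profile.fn_count_B}",
        "",
        f"{'kind':<6} {'start':>6} {'end':>6}  evidence",
    ]
    for s in profile.segments:
        ev = "; ".join(f"{k}={v}" for k, v in sorted(s.attributes.items())
                       if k not in ("criteria_fired",))
        lines.append(f"{s.kind:<6} {s.region.start:>6} {s.region.end:>6}  {ev}")
    return js, "\n".join(lines) + "\n"
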