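"""Imperfect tandem-repeat detection in low-complexity protein regions.

Cell-wall-spanning (W) domains of CEP homologs carry imperfect tandem
repeats (unit lengths of 17, 39 and 60 aa are known examples, with
fractional copy numbers such as 3.7 or 2.3 arising from partial terminal
copies). The detector here is a k-mer-seeded consensus grower:

1. candidate periods are proposed from recurrence distances of exact
   k-mers (k capped at the minimum unit length);
2. for each candidate (seed, period) the sequence is cut into consecutive
   period-sized blocks anchored at the seed and a column-majority
   consensus is built;
3. the repeat region grows left and right one block at a time while each
   new copy keeps identity to the consensus at or above ``min_identity``;
   partial terminal blocks are attached the same way and count as their
   aligned fraction of a copy;
4. overlapping candidate hits are resolved by keeping the hit maximizing
   copies x identity; a smaller unit covering essentially the same region
   with near-equal identity is preferred over its multiples.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass

from ceparch.seq_io import Region


class RepeatConfigError(ValueError):
    """Invalid search parameters."""


@dataclass(frozen=True)
class RepeatHit:
    region: Region
    unit_length: int
    copy_number: float
    consensus: str
    mean_identity: float

    @property
    def score(self) -> float:
        return self.copy_number * self.mean_identity


def _consensus(blocks: list[str], p: int) -> str:
    cols = []
    for i in range(p):
        counts = Counter(b[i] for b in blocks if len(b) > i)
        top = max(counts.values())
        # deterministic tie-break: lexicographically smallest majority residue
        cols.append(min(aa for aa, c in counts.items() if c == top))
    return "".join(cols)


def _identity(block: str, consensus: str, from_end: bool = False) -> float:
    ref = consensus[-len(block):] if from_end else consensus[: len(block)]
    return sum(a == b for a, b in zip(block, ref)) / len(block)


def _grow(seq: str, seed: int, p: int, min_identity: float) -> RepeatHit | None:
    """Grow a repeat of period *p* anchored at 0-based position *seed*."""
    n = len(seq)
    blocks = [seq[seed : seed + p]]
    if len(blocks[0]) < p:
        return None
    left, right = seed, seed + p  # [left, right) full-block region

    while right + p <= n:
        cand = seq[right : right + p]
        if _identity(cand, _consensus(blocks, p)) < min_identity:
            break
        blocks.append(cand)
        right += p
    while left - p >= 0:
        cand = seq[left - p : left]
        if _identity(cand, _consensus(blocks, p)) < min_identity:
            break
        blocks.insert(0, cand)
        left -= p

    cons = _consensus(blocks, p)
    start, end = left, right
    # partial terminal copies, counted as their aligned fraction
    tail = seq[right : min(n, right + p)]
    if 0 < len(tail) < p and _identity(tail, cons) >= min_identity:
        end = right + len(tail)
    head = seq[max(0, left - p) : left]
    if 0 < len(head) < p and _identity(head, cons, from_end=True) >= min_identity:
        start = left - len(head)

    matches = 0
    total = 0
    for i in range(start, end):
        offset = (i - left) % p
        matches += seq[i] == cons[offset]
        total += 1
    region_len = end - start
    copies = region_len / p
    return RepeatHit(
        region=Region(start + 1, end, "repeat"),
        unit_length=p,
        copy_number=copies,
        consensus=cons,
        mean_identity=matches / total,
    )


def _covers(small: RepeatHit, big: RepeatHit, frac: float = 0.9) -> bool:
    a, b = small.region, big.region
    overlap = min(a.end, b.end) - max(a.start, b.start) + 1
    return overlap >= frac * len(b)


def find_tandem_repeats(seq: str, min_unit: int = 3, max_unit: int = 80,
                        min_copies: float = 2.0, min_identity: float = 0.5,
                        k: int = 5) -> list[RepeatHit]:
    """Detect imperfect tandem repeats; see the module docstring for the contract.

    Returns non-overlapping hits with ``copy_number >= min_copies``,
    sorted by position.
    """
    seq = seq.upper()
    if min_unit < 3:
        raise RepeatConfigError("min_unit must be >= 3")
    if min_copies <= 0:
        raise RepeatConfigError("min_copies must be positive")
    if max_unit > len(seq) / min_copies:
        raise RepeatConfigError(
            f"max_unit {max_unit} exceeds length/min_copies = {len(seq) / min_copies:.1f}"
        )
    if not (0 < min_identity <= 1):
        raise RepeatConfigError("min_identity must be in (0, 1]")
    k = min(k, min_unit)

    positions: dict[str, list[int]] = defaultdict(list)
    for i in range(len(seq) - k + 1):
        positions[seq[i : i + k]].append(i)
    candidates: set[tuple[int, int]] = set()
    for pos in positions.values():
        for a, b in zip(pos, pos[1:]):
            d = b - a
            if min_unit <= d <= max_unit:
                candidates.add((a, d))

    raw: list[RepeatHit] = []
    seen: set[tuple[int, int, int]] = set()
    for seed, p in sorted(candidates):
        hit = _grow(seq, seed, p, min_identity)
        if hit is None or hit.copy_number < min_copies:
            continue
        key = (hit.region.start, hit.region.end, hit.unit_length)
        if key not in seen:
            seen.add(key)
            raw.append(hit)

    # overlap resolution: greedy by copies x identity, preferring the
    # smallest unit that covers the winner's region at near-equal identity
    raw.sort(key=lambda h: (-h.score, h.unit_length, h.region.start))
    chosen: list[RepeatHit] = []
    remaining = raw[:]
    while remaining:
        best = remaining[0]
        same_span = [
            h for h in remaining
            if _covers(h, best) and h.mean_identity >= best.mean_identity - 0.05
        ]
        pick = min(same_span, key=lambda h: (h.unit_length, -h.score)) if same_span else best
        chosen.append(pick)
        remaining = [h for h in remaining if not h.region.overlaps(pick.region)]
    return sorted(chosen, key=lambda h: h.region.start)
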