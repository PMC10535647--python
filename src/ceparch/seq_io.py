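"""Sequence records, 1-based regions, FASTA I/O and the named-protein registry.

All residue coordinates in this package are 1-based and inclusive at both
ends, following the convention used for protein "aa position" annotations.
Conversion to Python's 0-based slices happens only inside this module.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

#: the 20 standard one-letter amino-acid codes plus the unknown residue X
ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")


class FastaParseError(ValueError):
    """Raised when a FASTA file is empty or contains an illegal residue."""


class RegistryLookupError(KeyError):
    """Raised when a protease name is not present in the registry."""


@dataclass(frozen=True)
class SequenceRecord:
    """An identified protein sequence with optional provenance.

    Parameters
    ----------
    id : str
        Short unique label (e.g. ``"PrtP_Wg2"``).
    residues : str
        Uppercase residues over the 21-letter alphabet (20 standard + X).
    description : str
        Free-text description, may be empty.
    accession : str or None
        Database identifier, if known.
    strain : str or None
        Source strain, if known.
    """

    id: str
    residues: str
    description: str = ""
    accession: str | None = None
    strain: str | None = None

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"record {self.id!r}: residues must be non-empty")
        object.__setattr__(self, "residues", self.residues.upper())
        bad = set(self.residues) - ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id!r}: illegal residue character(s) {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class Region:
    """A labeled residue range, 1-based and inclusive at both ends."""

    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid region: need 1 <= start <= end, got {self.start}..{self.end}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "Region") -> bool:
        return self.start <= other.end and other.start <= self.end


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (possibly multi-record, wrapped) FASTA file.

    Lowercase letters are uppercased silently; any character outside the
    21-letter alphabet raises :class:`FastaParseError` naming the offending
    record and character. An empty file is an error ("no records").
    """
    records: list[SequenceRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = str(rec.seq).upper()
        bad = set(residues) - ALPHABET
        if bad:
            raise FastaParseError(
                f"{path}: record {rec.id!r} contains illegal character(s) {sorted(bad)}"
            )
        if not residues:
            raise FastaParseError(f"{path}: record {rec.id!r} has an empty sequence body")
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        records.append(SequenceRecord(id=rec.id, residues=residues, description=desc))
    if not records:
        raise FastaParseError(f"{path}: no records")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    """Write records as wrapped FASTA; round-trips ids and residues exactly."""
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def slice_region(record: SequenceRecord, region: Region) -> SequenceRecord:
    """Extract ``region.start..region.end`` (1-based, inclusive) from *record*.

    The returned record id is extended with the region label (or coordinates
    when the label is empty).
    """
    if region.end > len(record):
        raise IndexError(
            f"region {region.start}..{region.end} out of range for "
            f"record {record.id!r} of length {len(record)}"
        )
    sub = record.residues[region.start - 1 : region.end]
    tag = region.label or f"{region.start}-{region.end}"
    return SequenceRecord(
        id=f"{record.id}/{tag}",
        residues=sub,
        description=record.description,
        accession=record.accession,
        strain=record.strain,
    )


# ---------------------------------------------------------------------------
# Registry of the named CEP homologs and their database accessions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegistryEntry:
    name: str
    accession_db: str
    accession: str
    species: str
    strain: str | None
    model_id: str | None
    source: str = field(default="database")  # "database" or "plant_collection"


def _load_registry() -> dict[str, RegistryEntry]:
    entries: dict[str, RegistryEntry] = {}
    with resources.files("ceparch.data").joinpath("registry.tsv").open() as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        assert header[0] == "name"
        for row in reader:
            if not row:
                continue
            row = row + [""] * (6 - len(row))
            name, db, acc, species, strain, model = row[:6]
            source = "plant_collection" if acc.startswith("OQ26") else "database"
            entries[name.lower()] = RegistryEntry(
                name=name,
                accession_db=db,
                accession=acc,
                species=species,
                strain=strain or None,
                model_id=model or None,
                source=source,
            )
    return entries


_REGISTRY: dict[str, RegistryEntry] | None = None


def registry_entries() -> list[RegistryEntry]:
    """All registry rows, in file order."""
    global _REGISTRY
    if _REGISTRY is None:
        _REGISTRY = _load_registry()
    return list(_REGISTRY.values())


def paper_registry(name: str) -> RegistryEntry:
    """Look up a protease by name (case-insensitive).

    Raises :class:`RegistryLookupError` listing the known names when the
    protease is unknown.
    """
    global _REGISTRY
    if _REGISTRY is None:
        _REGISTRY = _load_registry()
    try:
        return _REGISTRY[name.lower()]
    except KeyError:
        known = ", ".join(sorted(e.name for e in _REGISTRY.values()))
        raise RegistryLookupError(
            f"unknown protease {name!r}; known names: {known}"
        ) from None


def export_registry_tsv(path: str | Path) -> None:
    """Write the registry as TSV (name, accession_db, accession, species, strain, model_id)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["name", "accession_db", "accession", "species", "strain", "model_id"])
        for e in registry_entries():
            w.writerow([e.name, e.accession_db, e.accession, e.species, e.strain or "", e.model_id or ""])
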