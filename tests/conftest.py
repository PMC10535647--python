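"""Shared fixtures: tiny text fixtures are generated programmatically."""

import textwrap

import pytest

from ceparch.seq_io import SequenceRecord


@pytest.fixture
def tmp_fasta(tmp_path):
    """Factory writing a FASTA file from (id, residues) pairs."""

    def write(pairs, name="test.fasta", wrap=None):
        path = tmp_path / name
        chunks = []
        for rid, seq in pairs:
            body = "\n".join(textwrap.wrap(seq, wrap)) if wrap else seq
            chunks.append(f">{rid}\n{body}\n")
        path.write_text("".join(chunks))
        return path

    return write


@pytest.fixture
def tmp_pdb(tmp_path):
    """Factory writing a minimal Cα-only PDB from (resname, resnum, xyz, bfac)."""

    def write(rows, name="model.pdb"):
        path = tmp_path / name
        lines = []
        for i, (resname, num, (x, y, z), b) in enumerate(rows, start=1):
            lines.append(
                f"ATOM  {i:5d}  CA  {resname:<3s} A{num:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{b:6.2f}           C"
            )
        path.write_text("\n".join(lines) + "\nEND\n")
        return path

    return write


@pytest.fixture
def record():
    return SequenceRecord(id="toy", residues="MKKLLAVSDE")
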