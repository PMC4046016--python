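import numpy as np
import pytest

from mdmi.msa_io import ALPHABET, EncodedAlignment


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_alignment(n, length, n_symbols=21, seed=0):
    """Uniform iid alignment over the first n_symbols codes."""
    gen = np.random.default_rng(seed)
    matrix = gen.integers(0, n_symbols, size=(n, length))
    return EncodedAlignment(matrix, [f"s{i}" for i in range(n)])


def alignment_from_columns(*columns):
    """Alignment whose columns are the given integer code vectors."""
    matrix = np.array(columns).T
    return EncodedAlignment(matrix, [f"s{i}" for i in range(matrix.shape[0])])


@pytest.fixture
def make_random_alignment():
    return random_alignment


@pytest.fixture
def make_alignment():
    return alignment_from_columns


# ---------------------------------------------------------------------------
# toy PDB construction
# ---------------------------------------------------------------------------


def atom_line(serial, name, resname, chain, resseq, x, y, z, element=None, altloc=" "):
    element = element or name[0]
    return (
        f"ATOM  {serial:5d} {name:<4s}{altloc}{resname:>3s} {chain}{resseq:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}          {element:>2s}"
    )


def helix_record(serial, chain, start, end):
    return (
        f"HELIX  {serial:3d} {serial:3d} ALA {chain} {start:4d}  ALA {chain} {end:4d} "
        f" 1                               {end - start + 1:5d}"
    )


def sheet_record(serial, chain, start, end):
    return (
        f"SHEET  {serial:3d}   A 1 ALA {chain}{start:4d}  ALA {chain}{end:4d}  0"
    )


def make_pdb(path, residues, header_records=()):
    """Write a toy PDB file.

    residues: list of (resseq, [(atom_name, x, y, z), ...]) on chain A.
    """
    lines = list(header_records)
    serial = 1
    for resseq, atoms in residues:
        for name, x, y, z in atoms:
            lines.append(atom_line(serial, name, "ALA", "A", resseq, x, y, z))
            serial += 1
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def pdb_builder():
    return make_pdb
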