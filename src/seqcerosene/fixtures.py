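"""Synthetic structures with known geometry for testing every pipeline stage.

All generators build in-memory :class:`Structure` objects with coordinates on
a 0.001 Å grid (the precision of the PDB fixed-column format), and
:func:`structure_to_pdb` serializes any of them to valid PDB text, so tests
can run file-in/file-out and round-trip through the parser exactly.

The geometry is deliberately schematic — collinear chains, ideal helices,
rigid anti-parallel strands — because each fixture exists to make one
property of the color embedding checkable by hand, not to be physically
realistic.
"""

from __future__ import annotations

import numpy as np

from .structure_io import (
    Atom,
    Chain,
    Residue,
    ResidueKind,
    Structure,
    one_letter,
)

__all__ = [
    "make_collinear_chain",
    "make_ideal_helix",
    "make_antiparallel_duplex",
    "make_random_coil",
    "make_pathological",
    "pathological_text",
    "structure_to_pdb",
    "PATHOLOGICAL_CASES",
]

PATHOLOGICAL_CASES = (
    "gly_only",
    "missing_cb",
    "altloc_pair",
    "two_models",
    "hydrogen_only_residue",
    "with_water",
    "with_ligand",
)


def _snap(coord) -> np.ndarray:
    """Snap to the 0.001 Å grid so PDB serialization round-trips exactly."""
    return np.round(np.asarray(coord, dtype=float), 3)


def _ala(chain_id: str, number: int, ca, cb=None) -> Residue:
    ca = _snap(ca)
    atoms = [Atom("CA", "C", ca)]
    atoms.append(Atom("CB", "C", _snap(cb) if cb is not None else ca))
    return Residue(chain_id, number, "", "ALA", ResidueKind.AMINO_ACID, atoms, "A")


def _nuc(chain_id: str, number: int, name3: str, coord) -> Residue:
    atoms = [Atom("C1'", "C", _snap(coord))]
    return Residue(
        chain_id, number, "", name3, ResidueKind.NUCLEOTIDE, atoms,
        one_letter(name3, ResidueKind.NUCLEOTIDE),
    )


def make_collinear_chain(n: int, spacing: float) -> Structure:
    """n alanines with CA=CB on the x-axis at 0, spacing, 2*spacing, ...

    With every representative mode agreeing on the same point, the embedding
    of this fixture is pure arithmetic: centroid (n-1)*spacing/2 on x, raw
    span (n-1)*spacing/2.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    chain = Chain("A", [_ala("A", i + 1, (i * spacing, 0.0, 0.0)) for i in range(n)])
    return Structure(identifier=f"collinear_{n}", chains=[chain])


def make_ideal_helix(n: int, rise: float = 1.5, radius: float = 2.3,
                     twist_deg: float = 100.0) -> Structure:
    """n alanines on an ideal α-helical CA trace (100° twist, 1.5 Å rise),
    CB displaced radially outward."""
    if n < 1:
        raise ValueError("n must be >= 1")
    residues = []
    for i in range(n):
        angle = np.deg2rad(twist_deg * i)
        ca = (radius * np.cos(angle), radius * np.sin(angle), rise * i)
        cb = ((radius + 1.5) * np.cos(angle), (radius + 1.5) * np.sin(angle), rise * i)
        residues.append(_ala("A", i + 1, ca, cb))
    return Structure(identifier=f"helix_{n}", chains=[Chain("A", residues)])


def make_antiparallel_duplex(n: int, spacing: float = 3.4,
                             strand_offset: float = 18.0) -> Structure:
    """Two complementary nucleotide strands running in opposite directions.

    Chain C (all DA) runs along +x, chain D (all DT) along −x at a fixed y
    offset; residue i of chain D shares its x-coordinate with residue
    n+1−i of chain C.  Reading both sequences N-to-C therefore produces
    mirrored color gradients — the anti-parallel color signature.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    strand_c = Chain(
        "C", [_nuc("C", i + 1, "DA", (i * spacing, 0.0, 0.0)) for i in range(n)]
    )
    strand_d = Chain(
        "D",
        [_nuc("D", i + 1, "DT", ((n - 1 - i) * spacing, strand_offset, 0.0))
         for i in range(n)],
    )
    return Structure(identifier=f"duplex_{n}", chains=[strand_c, strand_d])


def make_random_coil(n: int, seed: int, box: float = 40.0,
                     identifier: str | None = None) -> Structure:
    """n alanines with CA=CB uniform in a cube of the given side length."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    coords = rng.uniform(-box / 2, box / 2, size=(n, 3))
    chain = Chain("A", [_ala("A", i + 1, coords[i]) for i in range(n)])
    return Structure(identifier=identifier or f"coil_{n}_{seed}", chains=[chain])


def _gly(chain_id: str, number: int, ca) -> Residue:
    ca = _snap(ca)
    atoms = [
        Atom("N", "N", ca + (-1.0, 0.0, 0.0)),
        Atom("CA", "C", ca),
        Atom("C", "C", ca + (1.0, 0.5, 0.0)),
        Atom("O", "O", ca + (1.5, 1.2, 0.0)),
    ]
    return Residue(chain_id, number, "", "GLY", ResidueKind.AMINO_ACID, atoms, "G")


def pathological_text(case: str) -> str:
    """PDB text exhibiting exactly one parsing/selection pathology."""
    if case == "gly_only":
        return structure_to_pdb(
            Structure("gly_only", [Chain("A", [
                _gly("A", 1, (0, 0, 0)),
                _gly("A", 2, (3.8, 0, 0)),
                _gly("A", 3, (7.6, 2.0, 1.0)),
            ])])
        )
    if case == "missing_cb":
        residue = Residue("A", 1, "", "ALA", ResidueKind.AMINO_ACID, [
            Atom("N", "N", (-1.0, 0.0, 0.0)),
            Atom("CA", "C", (0.0, 0.0, 0.0)),
            Atom("C", "C", (1.0, 0.5, 0.0)),
        ], "A")
        partner = _ala("A", 2, (3.8, 0.0, 0.0), (4.2, 1.4, 0.0))
        return structure_to_pdb(Structure("missing_cb", [Chain("A", [residue, partner])]))
    if case == "altloc_pair":
        return "\n".join([
            "ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.40          C",
            "ATOM      2  CA BALA A   1       5.000   0.000   0.000  0.60          C",
            "ATOM      3  CA  ALA A   2       3.800   0.000   0.000  1.00          C",
            "END",
        ]) + "\n"
    if case == "two_models":
        return "\n".join([
            "MODEL        1",
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00          C",
            "ATOM      2  CA  ALA A   2       3.800   0.000   0.000  1.00          C",
            "ENDMDL",
            "MODEL        2",
            "ATOM      1  CA  ALA A   1       0.100   0.000   0.000  1.00          C",
            "ATOM      2  CA  ALA A   2       3.900   0.000   0.000  1.00          C",
            "ENDMDL",
            "END",
        ]) + "\n"
    if case == "hydrogen_only_residue":
        return "\n".join([
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00          C",
            "ATOM      2  H1  ALA A   2       1.000   0.000   0.000  1.00          H",
            "ATOM      3  H2  ALA A   2       1.500   0.000   0.000  1.00          H",
            "ATOM      4  CA  ALA A   3       7.600   0.000   0.000  1.00          C",
            "END",
        ]) + "\n"
    if case == "with_water":
        return "\n".join([
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00          C",
            "ATOM      2  CA  ALA A   2       3.800   0.000   0.000  1.00          C",
            "HETATM    3  O   HOH A 101      10.000  10.000  10.000  1.00          O",
            "END",
        ]) + "\n"
    if case == "with_ligand":
        return "\n".join([
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00          C",
            "ATOM      2  CA  ALA A   2       3.800   0.000   0.000  1.00          C",
            "HETATM    3  C1  CMP A 201      12.000   0.000   0.000  1.00          C",
            "HETATM    4  C2  CMP A 201      14.000   0.000   0.000  1.00          C",
            "END",
        ]) + "\n"
    raise ValueError(f"unknown pathological case {case!r}; "
                     f"expected one of {PATHOLOGICAL_CASES}")


def make_pathological(case: str, include_waters: bool = False) -> Structure:
    """Parse the pathological PDB text for the case (exercises the parser on
    the pathology rather than bypassing it)."""
    from .structure_io import parse_pdb

    return parse_pdb(pathological_text(case), include_waters=include_waters,
                     identifier=case)


# ---------------------------------------------------------------------------
# minimal PDB writer

def _format_atom_name(name: str) -> str:
    # element-aligned convention: 1-3 character names start in column 14
    if len(name) >= 4:
        return name[:4]
    return f" {name:<3s}"


def structure_to_pdb(structure: Structure) -> str:
    """Serialize to fixed-column PDB text (ATOM/HETATM/TER/END only)."""
    lines: list[str] = []
    serial = 1

    def atom_line(record: str, atom: Atom, residue: Residue) -> str:
        nonlocal serial
        x, y, z = atom.coord
        line = (
            f"{record:<6s}{serial:>5d} {_format_atom_name(atom.name)}"
            f"{atom.altloc or ' ':1s}{residue.name3:>3s} "
            f"{residue.chain_id or ' ':1s}{residue.author_number:>4d}"
            f"{residue.insertion_code or ' ':1s}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
            f"          {atom.element:>2s}"
        )
        serial += 1
        return line

    for chain in structure.chains:
        for residue in chain.residues:
            for atom in residue.atoms:
                lines.append(atom_line("ATOM", atom, residue))
        lines.append(f"TER   {serial:>5d}")
        serial += 1
    for compound in structure.compounds:
        for atom in compound.atoms:
            lines.append(atom_line("HETATM", atom, compound))
    lines.append("END")
    return "\n".join(lines) + "\n"
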