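"""Parsing of PDB-format coordinate files into a chain/residue/compound model.

The parser is deliberately narrow: it consumes the fixed-column
``ATOM``/``HETATM``/``MODEL``/``ENDMDL``/``TER``/``END`` records that carry the
coordinate information the color embedding needs, and ignores everything else
(headers, SEQRES, CONECT, ...).  Only the first ``MODEL`` of an ensemble is
retained, alternate locations are collapsed to a single conformer, and water
molecules are dropped unless explicitly requested.

Entities are split into two classes:

* polymer residues (``ATOM`` records) grouped into :class:`Chain` objects with
  a one-letter sequence, and
* compounds (``HETATM`` groups: ligands, coenzymes, ions, modified residues
  deposited as heteroatoms), kept as individual :class:`Residue` objects.

Author residue numbering and insertion codes are preserved verbatim so that
downstream artifacts (raw tables, PyMOL scripts) can address the original
file.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable

import numpy as np
from Bio.Data.IUPACData import protein_letters_3to1_extended

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "Structure",
    "ResidueKind",
    "PDBParseError",
    "parse_pdb",
    "classify_residue",
    "one_letter",
]


class PDBParseError(ValueError):
    """Raised for unreadable coordinate records or empty structures."""


class ResidueKind(Enum):
    AMINO_ACID = "amino_acid"
    NUCLEOTIDE = "nucleotide"
    HETERO = "hetero"
    WATER = "water"


# Amino-acid 3->1 mapping: the standard table from biopython plus common
# modified residues that occur in deposited structures.
_AMINO_3TO1: dict[str, str] = {
    k.upper(): v for k, v in protein_letters_3to1_extended.items()
}
_AMINO_3TO1.update(
    {
        "MSE": "M",  # selenomethionine
        "CSO": "C",
        "SEP": "S",
        "TPO": "T",
        "PTR": "Y",
        "PCA": "E",
        "HYP": "P",
        "KCX": "K",
        "MLY": "K",
        "M3L": "K",
        "UNK": "X",
    }
)

_NUC_3TO1: dict[str, str] = {
    "DA": "A",
    "DC": "C",
    "DG": "G",
    "DT": "T",
    "DU": "U",
    "DI": "X",
    "A": "A",
    "C": "C",
    "G": "G",
    "U": "U",
    "T": "T",
    "I": "X",
    "N": "X",
    "DN": "X",
}

_WATER_NAMES = {"HOH", "DOD", "WAT"}


@dataclass
class Atom:
    """A single atom record: name, element, position in Å, occupancy, altloc."""

    name: str
    element: str
    coord: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.name!r}: coord must be 3 finite components")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name!r}: occupancy {self.occupancy} outside [0,1]")

    @property
    def is_hydrogen(self) -> bool:
        if self.element:
            return self.element.upper() in ("H", "D")
        stripped = self.name.strip().lstrip("0123456789")
        return stripped[:1].upper() in ("H", "D")


@dataclass
class Residue:
    """A polymer residue or a compound (hetero group)."""

    chain_id: str
    author_number: int
    insertion_code: str
    name3: str
    kind: ResidueKind
    atoms: list[Atom] = field(default_factory=list)
    letter: str = "X"

    @property
    def id(self) -> tuple[str, int, str]:
        return (self.chain_id, self.author_number, self.insertion_code)

    def get_atom(self, name: str) -> Atom | None:
        for atom in self.atoms:
            if atom.name == name:
                return atom
        return None

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    @property
    def sequence(self) -> str:
        return "".join(r.letter for r in self.residues)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Structure:
    identifier: str
    chains: list[Chain] = field(default_factory=list)
    compounds: list[Residue] = field(default_factory=list)
    waters_included: bool = False

    def polymer_residues(self) -> list[Residue]:
        return [r for chain in self.chains for r in chain.residues]

    @property
    def n_entities(self) -> int:
        return len(self.polymer_residues()) + len(self.compounds)


def classify_residue(name3: str) -> ResidueKind:
    """Classify a three-letter residue name. Total: unknown names are hetero."""
    name = name3.strip().upper()
    if name in _WATER_NAMES:
        return ResidueKind.WATER
    if name in _AMINO_3TO1:
        return ResidueKind.AMINO_ACID
    if name in _NUC_3TO1:
        return ResidueKind.NUCLEOTIDE
    return ResidueKind.HETERO


def one_letter(name3: str, kind: ResidueKind) -> str:
    """One-letter code for a polymer residue; unknown names map to 'X'."""
    name = name3.strip().upper()
    if kind is ResidueKind.AMINO_ACID:
        return _AMINO_3TO1.get(name, "X")
    if kind is ResidueKind.NUCLEOTIDE:
        return _NUC_3TO1.get(name, "X")
    raise ValueError(f"{name3!r}: not a polymer residue")


def _parse_float(line: str, lo: int, hi: int, what: str, lineno: int) -> float:
    text = line[lo:hi].strip()
    try:
        value = float(text)
    except ValueError:
        raise PDBParseError(
            f"line {lineno}: malformed {what} field {text!r}"
        ) from None
    if not math.isfinite(value):
        raise PDBParseError(f"line {lineno}: non-finite {what} field {text!r}")
    return value


@dataclass
class _RawAtom:
    record: str
    name: str
    altloc: str
    resname: str
    chain_id: str
    resseq: int
    icode: str
    coord: np.ndarray
    occupancy: float
    element: str


def _parse_atom_line(line: str, lineno: int) -> _RawAtom:
    line = line.rstrip("\n")
    if len(line) < 54:
        raise PDBParseError(f"line {lineno}: coordinate record too short")
    x = _parse_float(line, 30, 38, "x coordinate", lineno)
    y = _parse_float(line, 38, 46, "y coordinate", lineno)
    z = _parse_float(line, 46, 54, "z coordinate", lineno)
    occ_text = line[54:60].strip()
    occupancy = 1.0
    if occ_text:
        occupancy = _parse_float(line, 54, 60, "occupancy", lineno)
        occupancy = min(max(occupancy, 0.0), 1.0)
    resseq_text = line[22:26].strip()
    try:
        resseq = int(resseq_text) if resseq_text else 0
    except ValueError:
        raise PDBParseError(
            f"line {lineno}: malformed residue number {resseq_text!r}"
        ) from None
    return _RawAtom(
        record=line[0:6].strip(),
        name=line[12:16].strip(),
        altloc=line[16:17].strip(),
        resname=line[17:20].strip(),
        chain_id=line[21:22].strip() or "A",
        resseq=resseq,
        icode=line[26:27].strip(),
        coord=np.array([x, y, z]),
        occupancy=occupancy,
        element=line[76:78].strip() if len(line) >= 78 else "",
    )


def _resolve_altlocs(raws: list[_RawAtom]) -> list[Atom]:
    """Collapse alternate locations: per atom name keep the highest-occupancy
    conformer, ties broken by lexicographically smallest altloc character."""
    best: dict[str, _RawAtom] = {}
    order: list[str] = []
    for raw in raws:
        prev = best.get(raw.name)
        if prev is None:
            best[raw.name] = raw
            order.append(raw.name)
        elif raw.occupancy > prev.occupancy or (
            raw.occupancy == prev.occupancy
            and (raw.altloc or "~") < (prev.altloc or "~")
        ):
            # higher occupancy wins; at equal occupancy the smaller altloc wins
            best[raw.name] = raw
    return [
        Atom(
            name=best[n].name,
            element=best[n].element,
            coord=best[n].coord,
            occupancy=best[n].occupancy,
            altloc=best[n].altloc,
        )
        for n in order
    ]


def parse_pdb(
    text: str | Iterable[str],
    include_waters: bool = False,
    identifier: str = "structure",
) -> Structure:
    """Parse PDB-format text into a :class:`Structure`.

    Only the first MODEL is read.  ``ATOM`` records become polymer residues
    grouped into chains; ``HETATM`` groups become compounds, except waters
    (HOH/DOD/WAT), which are dropped unless ``include_waters`` is set (waters
    from either record type are treated alike).  Records after ``END`` are
    ignored.

    Raises
    ------
    PDBParseError
        If no coordinate record is present, or a coordinate field is
        malformed (the message names the offending line number).
    """
    if isinstance(text, str):
        lines = text.splitlines()
    else:
        lines = [ln.rstrip("\n") for ln in text]

    groups: dict[tuple, list[_RawAtom]] = {}
    group_order: list[tuple] = []
    model_index = 0
    seen_first_model = False
    for lineno, line in enumerate(lines, start=1):
        record = line[:6].strip().upper()
        if record == "END":
            break
        if record == "MODEL":
            model_index += 1
            if model_index == 1:
                seen_first_model = True
            continue
        if record == "ENDMDL":
            if seen_first_model:
                break
            continue
        if record not in ("ATOM", "HETATM"):
            continue
        if model_index > 1:
            continue
        raw = _parse_atom_line(line, lineno)
        key = (raw.record, raw.chain_id, raw.resseq, raw.icode, raw.resname)
        if key not in groups:
            groups[key] = []
            group_order.append(key)
        groups[key].append(raw)

    if not group_order:
        raise PDBParseError("empty structure: no ATOM or HETATM records found")

    structure = Structure(identifier=identifier, waters_included=include_waters)
    chain_lookup: dict[str, Chain] = {}
    for key in group_order:
        record, chain_id, resseq, icode, resname = key
        atoms = _resolve_altlocs(groups[key])
        kind = classify_residue(resname)
        is_water = kind is ResidueKind.WATER
        if is_water and not include_waters:
            continue
        # HETATM groups are always compounds, never part of a polymer chain,
        # even when they carry a polymer residue name (e.g. HETATM MSE).
        as_compound = record == "HETATM" or kind is ResidueKind.HETERO or is_water
        if as_compound:
            residue = Residue(
                chain_id=chain_id,
                author_number=resseq,
                insertion_code=icode,
                name3=resname,
                kind=ResidueKind.WATER if is_water else ResidueKind.HETERO,
                atoms=atoms,
                letter=resname,
            )
            if not residue.heavy_atoms():
                continue  # hydrogen-only hetero groups carry no usable position
            structure.compounds.append(residue)
            continue
        if kind is ResidueKind.WATER:  # ATOM-record water, include_waters=True
            kind = ResidueKind.HETERO
            structure.compounds.append(
                Residue(chain_id, resseq, icode, resname, kind, atoms, resname)
            )
            continue
        # ATOM records with unrecognized names are still polymer residues.
        if kind is ResidueKind.HETERO:
            kind = ResidueKind.AMINO_ACID
        residue = Residue(
            chain_id=chain_id,
            author_number=resseq,
            insertion_code=icode,
            name3=resname,
            kind=kind,
            atoms=atoms,
            letter=one_letter(resname, kind),
        )
        chain = chain_lookup.get(chain_id)
        if chain is None:
            chain = Chain(chain_id=chain_id)
            chain_lookup[chain_id] = chain
            structure.chains.append(chain)
        chain.residues.append(residue)

    if not structure.polymer_residues() and not structure.compounds:
        raise PDBParseError("empty structure: all records filtered out")
    return structure
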