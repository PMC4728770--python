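"""Reduction of residues and compounds to single representative coordinates.

Each polymer residue and each compound is stood in for by one 3D point.  For
amino acids four selection modes exist (Cβ with Cα for glycine — the default —
Cα, side-chain centroid, terminal heavy side-chain atom); nucleotides and
compounds always use the all-heavy-atom centroid, whatever the mode.

Residues missing their representative atom degrade gracefully: the terminal
mode walks back along the side-chain topology toward Cα, the Cβ mode falls
back to Cα, and a residue with no heavy atom at all is reported as unmapped
rather than raising.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import NamedTuple

import numpy as np

from .structure_io import Residue, ResidueKind, Structure

__all__ = [
    "RepresentativeMode",
    "RepresentativeSource",
    "EntityRef",
    "RepresentativePoint",
    "representative_coordinate",
    "representative_set",
    "NoRepresentativeCoordinatesError",
]

_BACKBONE = {"N", "CA", "C", "O", "OXT"}

# Per residue type, the preferred terminal heavy side-chain atom followed by
# the fallback path walking back toward CA.  Branched termini are resolved by
# lexicographically smallest atom name; ARG uses CZ as the last unbranched
# side-chain atom before the guanidinium fork.
_TERMINAL_PATH: dict[str, tuple[str, ...]] = {
    "ALA": ("CB",),
    "ARG": ("CZ", "NE", "CD", "CG", "CB"),
    "ASN": ("ND2", "CG", "CB"),
    "ASP": ("OD1", "CG", "CB"),
    "CYS": ("SG", "CB"),
    "GLN": ("NE2", "CD", "CG", "CB"),
    "GLU": ("OE1", "CD", "CG", "CB"),
    "HIS": ("CE1", "ND1", "CG", "CB"),
    "ILE": ("CD1", "CG1", "CB"),
    "LEU": ("CD1", "CG", "CB"),
    "LYS": ("NZ", "CE", "CD", "CG", "CB"),
    "MET": ("CE", "SD", "CG", "CB"),
    "MSE": ("CE", "SE", "CG", "CB"),
    "PHE": ("CZ", "CE1", "CD1", "CG", "CB"),
    "PRO": ("CG", "CB"),
    "SER": ("OG", "CB"),
    "THR": ("CG2", "OG1", "CB"),
    "TRP": ("CH2", "CZ2", "CE2", "CD2", "CG", "CB"),
    "TYR": ("OH", "CZ", "CE1", "CD1", "CG", "CB"),
    "VAL": ("CG1", "CG2", "CB"),
}


class RepresentativeMode(Enum):
    """Selectable representative-atom rule for amino acids."""

    C_BETA_DEFAULT = "cb"
    C_ALPHA = "ca"
    SIDE_CHAIN_CENTROID = "sc-centroid"
    TERMINAL_HEAVY = "terminal"

    @classmethod
    def from_string(cls, value: str) -> "RepresentativeMode":
        for mode in cls:
            if mode.value == value:
                return mode
        raise ValueError(
            f"unknown representative mode {value!r}; "
            f"expected one of {[m.value for m in cls]}"
        )


class RepresentativeSource(Enum):
    NAMED_ATOM = "named_atom"
    CENTROID = "centroid"
    FALLBACK_C_ALPHA = "fallback_c_alpha"
    UNMAPPED = "unmapped"


class EntityRef(NamedTuple):
    """Identity of an entity: author addressing plus its class."""

    chain_id: str
    author_number: int
    insertion_code: str
    name3: str
    is_compound: bool


@dataclass(frozen=True)
class RepresentativePoint:
    entity_ref: EntityRef
    coord: np.ndarray | None
    source: RepresentativeSource

    @property
    def is_mapped(self) -> bool:
        return self.source is not RepresentativeSource.UNMAPPED


class NoRepresentativeCoordinatesError(ValueError):
    """Every entity of the structure is unmapped."""


def _centroid_of(atoms) -> np.ndarray:
    return np.mean([a.coord for a in atoms], axis=0)


def _amino_coordinate(
    residue: Residue, mode: RepresentativeMode
) -> tuple[np.ndarray | None, RepresentativeSource]:
    ca = residue.get_atom("CA")
    is_glycine = residue.name3.upper() == "GLY"

    def ca_fallback():
        if ca is not None and not ca.is_hydrogen:
            return ca.coord, RepresentativeSource.FALLBACK_C_ALPHA
        heavy = residue.heavy_atoms()
        if heavy:
            return _centroid_of(heavy), RepresentativeSource.CENTROID
        return None, RepresentativeSource.UNMAPPED

    if mode is RepresentativeMode.C_ALPHA:
        if ca is not None and not ca.is_hydrogen:
            return ca.coord, RepresentativeSource.NAMED_ATOM
        return ca_fallback()

    if is_glycine:
        # every mode collapses to CA for glycine (no side chain, no CB)
        return ca_fallback()

    if mode is RepresentativeMode.C_BETA_DEFAULT:
        cb = residue.get_atom("CB")
        if cb is not None and not cb.is_hydrogen:
            return cb.coord, RepresentativeSource.NAMED_ATOM
        return ca_fallback()

    side_chain = [a for a in residue.heavy_atoms() if a.name not in _BACKBONE]

    if mode is RepresentativeMode.SIDE_CHAIN_CENTROID:
        if side_chain:
            return _centroid_of(side_chain), RepresentativeSource.CENTROID
        return ca_fallback()

    # terminal heavy side-chain atom
    path = _TERMINAL_PATH.get(residue.name3.upper())
    if path is not None:
        for name in path:
            atom = residue.get_atom(name)
            if atom is not None and not atom.is_hydrogen:
                return atom.coord, RepresentativeSource.NAMED_ATOM
    elif side_chain and ca is not None:
        # unknown residue type: most distal heavy side-chain atom from CA,
        # ties broken by atom name
        atom = max(
            side_chain,
            key=lambda a: (float(np.linalg.norm(a.coord - ca.coord)), a.name),
        )
        return atom.coord, RepresentativeSource.NAMED_ATOM
    return ca_fallback()


def representative_coordinate(
    residue: Residue, mode: RepresentativeMode
) -> RepresentativePoint:
    """Compute the single representative point for one residue or compound.

    Never raises on degenerate input: a residue with no heavy atoms yields a
    point with ``source=UNMAPPED`` and ``coord=None``.
    """
    is_compound = residue.kind in (ResidueKind.HETERO, ResidueKind.WATER)
    ref = EntityRef(
        residue.chain_id,
        residue.author_number,
        residue.insertion_code,
        residue.name3,
        is_compound,
    )
    heavy = residue.heavy_atoms()
    if not heavy:
        return RepresentativePoint(ref, None, RepresentativeSource.UNMAPPED)

    if residue.kind is ResidueKind.AMINO_ACID:
        coord, source = _amino_coordinate(residue, mode)
    else:
        # nucleotides and compounds always use the heavy-atom centroid
        coord, source = _centroid_of(heavy), RepresentativeSource.CENTROID
    return RepresentativePoint(ref, coord, source)


def representative_set(
    structure: Structure, mode: RepresentativeMode
) -> list[RepresentativePoint]:
    """One representative point per polymer residue and compound, in document
    order (chains first, then compounds).

    Unmapped entities are included in the list; callers building the color
    embedding must exclude them from the coordinate set.
    """
    points = [
        representative_coordinate(residue, mode)
        for residue in structure.polymer_residues()
    ]
    points += [representative_coordinate(c, mode) for c in structure.compounds]
    if not points:
        raise NoRepresentativeCoordinatesError(
            f"{structure.identifier}: structure has no residues or compounds"
        )
    if not any(p.is_mapped for p in points):
        raise NoRepresentativeCoordinatesError(
            f"{structure.identifier}: no representative coordinates "
            "(every entity is unmapped)"
        )
    return points
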