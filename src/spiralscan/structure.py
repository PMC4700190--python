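"""Minimal protein coordinate I/O and atom selection.

Coordinates are handled internally in Angstrom (PDB convention).  Parsing and
writing of the fixed-column PDB format is delegated to :mod:`gemmi`; this
module only exposes the small, list-of-atoms container the rest of the
package consumes.
"""

from __future__ import annotations

import dataclasses
import string
from pathlib import Path
from typing import Iterable, Optional, Sequence

import gemmi
import numpy as np

__all__ = [
    "AtomRecord",
    "StructureModel",
    "StructureError",
    "EmptySelectionError",
    "read_structure",
    "write_structure",
    "select_atoms",
    "CHAIN_ALPHABET",
]

#: deterministic chain relabelling order for assembly output
CHAIN_ALPHABET = string.ascii_uppercase + string.ascii_lowercase + string.digits


class StructureError(ValueError):
    """Raised for parse failures and invalid coordinate models."""


class EmptySelectionError(StructureError):
    """Raised when an atom selection matches nothing (distinct from parse errors)."""


@dataclasses.dataclass
class AtomRecord:
    """One atom: author chain/residue numbering plus a Cartesian position in A."""

    chain_id: str
    residue_number: int
    residue_name: str
    atom_name: str
    element: str
    position: np.ndarray  # shape (3,), Angstrom
    het: bool = False

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise StructureError("atom position must be a 3-vector")
        if not np.all(np.isfinite(self.position)):
            raise StructureError(
                f"non-finite coordinates for atom {self.atom_name} "
                f"{self.chain_id}/{self.residue_number}"
            )

    def copy(self) -> "AtomRecord":
        return dataclasses.replace(self, position=self.position.copy())


@dataclasses.dataclass
class StructureModel:
    """An ordered list of atoms with a free-form label."""

    atoms: list[AtomRecord]
    label: str = ""

    def __post_init__(self) -> None:
        self.atoms = list(self.atoms)

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n, 3) coordinate array in Angstrom."""
        if not self.atoms:
            return np.empty((0, 3))
        return np.stack([a.position for a in self.atoms])

    @property
    def chain_ids(self) -> list[str]:
        """Distinct chain IDs in order of first appearance."""
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)

    def residue_numbers(self, chain: Optional[str] = None) -> list[int]:
        nums: dict[int, None] = {}
        for a in self.atoms:
            if chain is None or a.chain_id == chain:
                nums.setdefault(a.residue_number, None)
        return list(nums)

    def with_coords(self, coords: np.ndarray, label: Optional[str] = None) -> "StructureModel":
        """New model with the same atom identities and replaced coordinates."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise StructureError("coordinate array shape does not match atom count")
        atoms = [dataclasses.replace(a, position=coords[i].copy()) for i, a in enumerate(self.atoms)]
        return StructureModel(atoms, label if label is not None else self.label)

    def copy(self) -> "StructureModel":
        return StructureModel([a.copy() for a in self.atoms], self.label)

    def validate(self) -> None:
        """Check the container invariants (non-empty, uniqueness, ordering)."""
        if not self.atoms:
            raise StructureError("empty structure model")
        seen: set[tuple[str, int, str]] = set()
        last_resnum: dict[str, int] = {}
        for a in self.atoms:
            key = (a.chain_id, a.residue_number, a.atom_name)
            if key in seen:
                raise StructureError(f"duplicate atom {key}")
            seen.add(key)
            prev = last_resnum.get(a.chain_id)
            if prev is not None and a.residue_number < prev:
                raise StructureError(
                    f"residue numbers decrease within chain {a.chain_id!r} "
                    f"({prev} -> {a.residue_number})"
                )
            last_resnum[a.chain_id] = a.residue_number


def read_structure(path: str | Path, model_index: int = 1) -> StructureModel:
    """Read ATOM/HETATM records of one MODEL block from a PDB file.

    Parameters
    ----------
    path:
        PDB-format text file.
    model_index:
        1-based MODEL block to read (files without MODEL records have one model).

    Insertion codes are rejected: the scan constructs this package targets are
    engineered sequences without them, and silent renumbering would corrupt
    the author numbering every downstream region definition relies on.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"failed to parse {path}: {exc}") from exc
    if model_index < 1 or model_index > len(st):
        raise StructureError(
            f"model_index {model_index} out of range; file has {len(st)} model(s)"
        )
    model = st[model_index - 1]
    atoms: list[AtomRecord] = []
    for chain in model:
        if len(chain.name) > 1:
            raise StructureError(f"multi-character chain ID {chain.name!r} not supported")
        for residue in chain:
            if residue.seqid.icode not in ("", " ", "\x00"):
                raise StructureError(
                    f"insertion code {residue.seqid.icode!r} at "
                    f"{chain.name}/{residue.seqid.num} not supported"
                )
            seen_names: set[str] = set()
            for atom in residue:
                if atom.name in seen_names:  # altloc duplicates: keep the first
                    continue
                seen_names.add(atom.name)
                atoms.append(
                    AtomRecord(
                        chain_id=chain.name,
                        residue_number=residue.seqid.num,
                        residue_name=residue.name,
                        atom_name=atom.name,
                        element=atom.element.name,
                        position=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        het=residue.het_flag == "H",
                    )
                )
    if not atoms:
        raise StructureError(f"no ATOM/HETATM records in {path}")
    result = StructureModel(atoms, label=path.stem)
    result.validate()
    return result


def write_structure(model: StructureModel, path: str | Path) -> None:
    """Write a model as fixed-column PDB; the output re-parses identically.

    Coordinates are emitted at 3-decimal precision (the format's width), so a
    write/read round trip is exact for coordinates already on that grid.
    """
    if not model.atoms:
        raise StructureError("refusing to write an empty model")
    if len(model.atoms) > 99999:
        raise StructureError("more than 99,999 atoms exceeds the PDB serial field")
    model.validate()
    st = gemmi.Structure()
    st.name = model.label or "model"
    gm = gemmi.Model("1")
    chain_map: dict[str, gemmi.Chain] = {}
    res_map: dict[tuple[str, int], gemmi.Residue] = {}
    for a in model.atoms:
        if a.chain_id not in chain_map:
            chain = gemmi.Chain(a.chain_id)
            gm.add_chain(chain)
            chain_map[a.chain_id] = gm[len(gm) - 1]
        chain = chain_map[a.chain_id]
        rkey = (a.chain_id, a.residue_number)
        if rkey not in res_map:
            res = gemmi.Residue()
            res.name = a.residue_name
            res.seqid = gemmi.SeqId(a.residue_number, " ")
            res.het_flag = "H" if a.het else "A"
            chain.add_residue(res)
            res_map[rkey] = chain[len(chain) - 1]
        res = res_map[rkey]
        atom = gemmi.Atom()
        atom.name = a.atom_name
        atom.element = gemmi.Element(a.element)
        atom.pos = gemmi.Position(*a.position)
        atom.occ = 1.0
        atom.b_iso = 0.0
        res.add_atom(atom)
    st.add_model(gm)
    st.setup_entities()
    st.write_pdb(str(path))


def select_atoms(
    model: StructureModel,
    chain: Optional[str] = None,
    residue_range: Optional[tuple[int, int]] = None,
    atom_names: Optional[Iterable[str]] = None,
    include_het: bool = False,
) -> StructureModel:
    """Subset a model, preserving atom order.

    ``residue_range`` is author numbering, 1-based and inclusive at both ends,
    so ``(55, 72)`` selects 18 residues.  HETATM records are excluded unless
    ``include_het`` is set.
    """
    if residue_range is not None and residue_range[0] > residue_range[1]:
        raise ValueError(f"residue_range start > end: {residue_range}")
    names = set(atom_names) if atom_names is not None else None
    picked = []
    for a in model.atoms:
        if a.het and not include_het:
            continue
        if chain is not None and a.chain_id != chain:
            continue
        if residue_range is not None and not (
            residue_range[0] <= a.residue_number <= residue_range[1]
        ):
            continue
        if names is not None and a.atom_name not in names:
            continue
        picked.append(a.copy())
    if not picked:
        raise EmptySelectionError(
            f"selection matched no atoms (chain={chain!r}, "
            f"residue_range={residue_range}, atom_names={atom_names})"
        )
    return StructureModel(picked, model.label)
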