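"""Structure representation, PDB I/O and geometry utilities.

Internal coordinate unit is the nanometre throughout the package; PDB files
(which store angstroms) are converted on read and write.  A :class:`Structure`
partitions its atoms into a protein part and a ligand part — crystallographic
waters and common monatomic ions are dropped on read, because neither side of
the protein–ligand distance machinery should see them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdb

__all__ = [
    "Atom",
    "Structure",
    "PullAxis",
    "read_pdb",
    "write_pdb",
    "write_frames",
    "read_frames",
    "heavy_atoms",
    "calpha_atoms",
    "min_distance",
    "center_of_mass",
    "ATOMIC_MASSES",
]

ANGSTROM_PER_NM = 10.0

#: Standard atomic masses (u) for the elements that occur in protein–ligand
#: systems; unknown elements fall back to carbon.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "F": 18.998, "CL": 35.45, "BR": 79.904, "I": 126.904,
    "NA": 22.990, "K": 39.098, "MG": 24.305, "ZN": 65.38, "CA": 40.078,
    "FE": 55.845, "SE": 78.971,
}

HEAVY_ELEMENTS = frozenset({"C", "N", "O", "S"})

#: Residue names removed from both partitions on read.
WATER_NAMES = frozenset({"HOH", "WAT", "SOL", "TIP", "TIP3", "TIP4", "SPC"})
ION_NAMES = frozenset({
    "NA", "CL", "K", "MG", "ZN", "CA", "MN", "FE", "CU", "NI", "CO",
    "BR", "IOD", "CS", "LI", "SO4", "PO4",
})


@dataclass(frozen=True)
class Atom:
    """A single atom with coordinates in nm."""

    index: int
    name: str
    element: str
    residue_id: int
    residue_name: str
    chain_id: str
    position: np.ndarray
    is_ligand: bool

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.index}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)
        if not self.element:
            raise ValueError(f"atom {self.index}: element must be non-empty")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() == "H"


class Structure:
    """An ordered collection of atoms split into protein and ligand.

    Array views (``positions``, ``elements`` ...) are the primary access
    path; :meth:`atom` materialises an :class:`Atom` record on demand.
    """

    def __init__(
        self,
        names: np.ndarray,
        elements: np.ndarray,
        residue_ids: np.ndarray,
        residue_names: np.ndarray,
        chain_ids: np.ndarray,
        positions: np.ndarray,
        is_ligand: np.ndarray,
        ligand_selector: str = "",
    ) -> None:
        n = len(names)
        self.names = np.asarray(names, dtype=object)
        self.elements = np.array([str(e).upper() for e in elements], dtype=object)
        self.residue_ids = np.asarray(residue_ids, dtype=int)
        self.residue_names = np.asarray(residue_names, dtype=object)
        self.chain_ids = np.asarray(chain_ids, dtype=object)
        self.positions = np.asarray(positions, dtype=float).reshape(n, 3)
        self.is_ligand = np.asarray(is_ligand, dtype=bool)
        self.ligand_selector = ligand_selector
        self._validate()

    def _validate(self) -> None:
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite coordinates")
        if len(self.calpha_indices()) == 0:
            raise ValueError("structure has no protein C-alpha atom")
        if len(self.ligand_heavy_indices()) == 0:
            raise ValueError("structure has no ligand heavy atom")
        # residue ids must not decrease within a chain
        for chain in np.unique(self.chain_ids.astype(str)):
            mask = self.chain_ids.astype(str) == chain
            rid = self.residue_ids[mask]
            if np.any(np.diff(rid) < 0):
                raise ValueError(f"residue ids decrease within chain {chain!r}")

    def __len__(self) -> int:
        return len(self.names)

    @property
    def n_atoms(self) -> int:
        return len(self)

    def atom(self, i: int) -> Atom:
        return Atom(
            index=i,
            name=str(self.names[i]),
            element=str(self.elements[i]),
            residue_id=int(self.residue_ids[i]),
            residue_name=str(self.residue_names[i]),
            chain_id=str(self.chain_ids[i]),
            position=self.positions[i].copy(),
            is_ligand=bool(self.is_ligand[i]),
        )

    def __iter__(self):
        return (self.atom(i) for i in range(len(self)))

    # -- selections ---------------------------------------------------------

    def protein_indices(self) -> np.ndarray:
        return np.flatnonzero(~self.is_ligand)

    def ligand_indices(self) -> np.ndarray:
        return np.flatnonzero(self.is_ligand)

    def ligand_heavy_indices(self) -> np.ndarray:
        heavy = np.array([e != "H" for e in self.elements])
        return np.flatnonzero(self.is_ligand & heavy)

    def calpha_indices(self) -> np.ndarray:
        is_ca = np.array(
            [n == "CA" and e == "C" for n, e in zip(self.names, self.elements)]
        )
        return np.flatnonzero(is_ca & ~self.is_ligand)

    def protein_residue_count(self) -> int:
        """Number of distinct (chain, residue id) pairs in the protein part."""
        prot = self.protein_indices()
        pairs = {(str(self.chain_ids[i]), int(self.residue_ids[i])) for i in prot}
        return len(pairs)

    def masses(self) -> np.ndarray:
        return np.array(
            [ATOMIC_MASSES.get(e, ATOMIC_MASSES["C"]) for e in self.elements]
        )

    def with_positions(self, positions: np.ndarray) -> "Structure":
        """Copy of this structure with replaced coordinates (nm)."""
        return Structure(
            self.names, self.elements, self.residue_ids, self.residue_names,
            self.chain_ids, positions, self.is_ligand, self.ligand_selector,
        )


@dataclass(frozen=True)
class PullAxis:
    """Pulling direction (unit vector) and a reference origin on the ligand."""

    direction: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        norm = np.linalg.norm(d)
        if norm == 0.0:
            raise ValueError("pull direction must be non-zero")
        object.__setattr__(self, "direction", d / norm)
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def read_pdb(
    path,
    ligand_resname: str | None = None,
    ligand_chain: str | None = None,
    model: int = 1,
) -> Structure:
    """Read a PDB file into a :class:`Structure` (coordinates in nm).

    The ligand is identified explicitly by residue name and/or chain id —
    there is no automatic het-group guessing.  Waters and common monatomic
    ions are excluded from both partitions.  Alternate locations are resolved
    to the highest-occupancy conformer.

    Raises
    ------
    ValueError
        If the selector matches no residue, or the protein part has no
        C-alpha atom.
    """
    if ligand_resname is None and ligand_chain is None:
        raise ValueError("ligand_resname or ligand_chain must be given")
    pdb_file = pdb.PDBFile.read(path)
    arr = pdb.get_structure(pdb_file, model=model, altloc="occupancy")

    resnames = arr.res_name.astype(str)
    chains = arr.chain_id.astype(str)

    lig_mask = np.ones(arr.array_length(), dtype=bool)
    if ligand_resname is not None:
        lig_mask &= resnames == ligand_resname
    if ligand_chain is not None:
        lig_mask &= chains == ligand_chain
    if not lig_mask.any():
        raise ValueError(
            f"ligand selector (resname={ligand_resname!r}, chain={ligand_chain!r}) "
            "matched no atom"
        )

    solvent = np.isin(resnames, list(WATER_NAMES | ION_NAMES)) & ~lig_mask
    keep = ~solvent

    elements = arr.element.astype(str)
    sel = ", ".join(
        s for s in (
            f"resname {ligand_resname}" if ligand_resname else "",
            f"chain {ligand_chain}" if ligand_chain else "",
        ) if s
    )
    return Structure(
        names=arr.atom_name[keep].astype(str),
        elements=elements[keep],
        residue_ids=arr.res_id[keep],
        residue_names=resnames[keep],
        chain_ids=chains[keep],
        positions=arr.coord[keep] / ANGSTROM_PER_NM,
        is_ligand=lig_mask[keep],
        ligand_selector=sel,
    )


def _to_atom_array(structure: Structure) -> struc.AtomArray:
    n = len(structure)
    arr = struc.AtomArray(n)
    arr.coord = structure.positions * ANGSTROM_PER_NM
    arr.atom_name = structure.names.astype(str)
    arr.element = structure.elements.astype(str)
    arr.res_id = structure.residue_ids
    arr.res_name = structure.residue_names.astype(str)
    arr.chain_id = np.array([c[:1] if c else "A" for c in structure.chain_ids.astype(str)])
    arr.hetero = structure.is_ligand
    return arr


def write_pdb(structure: Structure, path) -> None:
    """Write a structure as standard ATOM/HETATM records (angstroms)."""
    pdb_file = pdb.PDBFile()
    pdb.set_structure(pdb_file, _to_atom_array(structure))
    pdb_file.write(path)


def write_frames(structure: Structure, frames: np.ndarray, path) -> None:
    """Write trajectory frames as a multi-model PDB (one MODEL per frame).

    ``frames`` is (n_frames, n_atoms, 3) in nm; atom annotations come from
    the structure.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3 or frames.shape[1] != len(structure):
        raise ValueError("frames must be (n_frames, n_atoms, 3) matching "
                         "the structure")
    template = _to_atom_array(structure)
    stack = struc.from_template(template, frames * ANGSTROM_PER_NM)
    pdb_file = pdb.PDBFile()
    pdb.set_structure(pdb_file, stack)
    pdb_file.write(path)


def read_frames(path) -> np.ndarray:
    """Read a multi-model PDB into a (n_frames, n_atoms, 3) array in nm."""
    pdb_file = pdb.PDBFile.read(path)
    stack = pdb.get_structure(pdb_file)
    return stack.coord / ANGSTROM_PER_NM


# ---------------------------------------------------------------------------
# Atom predicates and geometry
# ---------------------------------------------------------------------------

def heavy_atoms(structure: Structure) -> np.ndarray:
    """Indices of protein heavy atoms (elements C, N, O, S)."""
    mask = np.array([e in HEAVY_ELEMENTS for e in structure.elements])
    return np.flatnonzero(mask & ~structure.is_ligand)


def calpha_atoms(structure: Structure) -> np.ndarray:
    """Indices of protein C-alpha atoms (atom name ``CA``, element C)."""
    return structure.calpha_indices()


def min_distance(
    indices_a: np.ndarray,
    indices_b: np.ndarray,
    structure_or_positions,
) -> float:
    """Minimum Euclidean distance (nm) between two atom-index sets."""
    indices_a = np.asarray(indices_a, dtype=int)
    indices_b = np.asarray(indices_b, dtype=int)
    if indices_a.size == 0 or indices_b.size == 0:
        raise ValueError("min_distance requires two non-empty index sets")
    pos = (
        structure_or_positions.positions
        if isinstance(structure_or_positions, Structure)
        else np.asarray(structure_or_positions, dtype=float)
    )
    a = pos[indices_a]
    b = pos[indices_b]
    d2 = np.sum((a[:, None, :] - b[None, :, :]) ** 2, axis=-1)
    return float(np.sqrt(d2.min()))


def center_of_mass(
    indices: np.ndarray,
    structure: Structure,
    weighting: str = "mass",
    positions: np.ndarray | None = None,
) -> np.ndarray:
    """Weighted mean position (nm) of an atom set.

    ``weighting="mass"`` uses standard atomic masses by element;
    ``weighting="geometric"`` weights every atom equally.  ``positions``
    overrides the structure's coordinates (for trajectory frames).
    """
    indices = np.asarray(indices, dtype=int)
    if indices.size == 0:
        raise ValueError("center_of_mass requires a non-empty index set")
    pos = structure.positions if positions is None else np.asarray(positions, float)
    if weighting == "mass":
        w = structure.masses()[indices]
    elif weighting == "geometric":
        w = np.ones(indices.size)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    return np.average(pos[indices], axis=0, weights=w)
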