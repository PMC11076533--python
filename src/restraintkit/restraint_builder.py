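"""Selection of the six position-restraint modes and restraint-file output.

During constant-velocity pulling a harmonic position restraint is applied to
part of the receptor so the external force ruptures the protein–ligand
interaction instead of dragging or spinning the whole complex.  Six selection
rules ("modes") of decreasing rigidity are supported, all evaluated in a frame
where the pulling direction is the +Z axis:

1. all protein heavy atoms (C, N, O, S);
2. all protein C-alpha atoms;
3. C-alpha atoms farther than ``d_axial`` (default 1.2 nm) from the ligand
   in 3-D minimum distance;
4. C-alpha atoms whose along-axis (Z) separation from the ligand exceeds
   ``d_axial``;
5. mode-4 atoms that are additionally within ``d_radial`` (default 1.2 nm)
   of the ligand in the X-Y plane;
6. mode 5 with the along-axis cutoff raised to 1.8 nm.

Selections nest (3 ⊆ 2 ⊆ 1 and 6 ⊆ 5 ⊆ 4), so atom counts never increase
from mode 1 to mode 2 to mode 3, nor from mode 4 through mode 6.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure_model import (
    PullAxis,
    Structure,
    calpha_atoms,
    center_of_mass,
    heavy_atoms,
)

__all__ = [
    "RestraintSpec",
    "RotationFrame",
    "rotation_to_z",
    "align_pull_axis_to_z",
    "select_mode",
    "write_index_group",
    "read_index_group",
    "write_position_restraints",
    "read_position_restraints",
    "DEFAULT_AXIAL_CUTOFF",
    "MODE6_AXIAL_CUTOFF",
    "DEFAULT_RADIAL_CUTOFF",
    "DEFAULT_FORCE_CONSTANT",
]

DEFAULT_AXIAL_CUTOFF = 1.2   # nm, modes 3-5
MODE6_AXIAL_CUTOFF = 1.8     # nm, mode 6
DEFAULT_RADIAL_CUTOFF = 1.2  # nm, modes 5-6
DEFAULT_FORCE_CONSTANT = 1000.0  # kJ/mol/nm^2 per axis


@dataclass(frozen=True)
class RestraintSpec:
    """A resolved restraint selection: mode, cutoffs and the atom set."""

    mode: int
    selected: np.ndarray
    d_axial: float = DEFAULT_AXIAL_CUTOFF
    d_radial: float = DEFAULT_RADIAL_CUTOFF
    reference: str = "min"
    force_constant: float = DEFAULT_FORCE_CONSTANT

    def __post_init__(self) -> None:
        if self.mode not in range(1, 7):
            raise ValueError(f"mode must be 1-6, got {self.mode}")
        if self.d_axial <= 0 or self.d_radial <= 0 or self.force_constant <= 0:
            raise ValueError("cutoffs and force constant must be positive")
        object.__setattr__(
            self, "selected", np.asarray(self.selected, dtype=int)
        )


@dataclass(frozen=True)
class RotationFrame:
    """The rigid rotation applied to bring the pull axis onto +Z."""

    matrix: np.ndarray
    applied_origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float).reshape(3, 3)
        if not np.allclose(m @ m.T, np.eye(3), atol=1e-10):
            raise ValueError("rotation matrix is not orthonormal")
        if not np.isclose(np.linalg.det(m), 1.0, atol=1e-10):
            raise ValueError("rotation matrix must be proper (det = +1)")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(
            self, "applied_origin", np.asarray(self.applied_origin, dtype=float)
        )

    def apply(self, positions: np.ndarray) -> np.ndarray:
        rel = np.asarray(positions, dtype=float) - self.applied_origin
        return rel @ self.matrix.T + self.applied_origin


def rotation_to_z(direction: np.ndarray) -> np.ndarray:
    """Proper rotation matrix mapping ``direction`` onto (0, 0, 1).

    Rodrigues rotation about the axis direction x z; the antiparallel case
    (direction ~ -z) falls back to a half-turn about X.
    """
    d = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(d)
    if norm == 0.0:
        raise ValueError("pull direction must be non-zero")
    d = d / norm
    z = np.array([0.0, 0.0, 1.0])
    c = float(d @ z)
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        return np.diag([1.0, -1.0, -1.0])
    axis = np.cross(d, z)
    s = np.linalg.norm(axis)
    axis = axis / s
    kmat = np.array([
        [0.0, -axis[2], axis[1]],
        [axis[2], 0.0, -axis[0]],
        [-axis[1], axis[0], 0.0],
    ])
    return np.eye(3) + s * kmat + (1.0 - c) * (kmat @ kmat)


def align_pull_axis_to_z(
    structure: Structure, axis: PullAxis
) -> tuple[Structure, RotationFrame]:
    """Rigidly rotate a structure so the pulling direction becomes +Z.

    The rotation pivots about the axis origin; all interatomic distances are
    preserved.  Returns the rotated structure and the applied frame.
    """
    frame = RotationFrame(rotation_to_z(axis.direction), axis.origin)
    return structure.with_positions(frame.apply(structure.positions)), frame


# ---------------------------------------------------------------------------
# Mode selection
# ---------------------------------------------------------------------------

def _ligand_reference_points(structure: Structure, reference: str) -> np.ndarray:
    if reference == "min":
        return structure.positions[structure.ligand_heavy_indices()]
    if reference == "com":
        com = center_of_mass(structure.ligand_heavy_indices(), structure)
        return com[None, :]
    raise ValueError(f"reference must be 'min' or 'com', got {reference!r}")


def select_mode(
    structure: Structure,
    mode: int,
    d_axial: float | None = None,
    d_radial: float = DEFAULT_RADIAL_CUTOFF,
    reference: str = "min",
) -> np.ndarray:
    """Atom indices restrained under a given mode (structure aligned to +Z).

    Distances to "the ligand" are minima over ligand heavy atoms by default
    (``reference="min"``), or to the ligand centre of mass
    (``reference="com"``).  Cutoff comparisons are strict: an atom exactly at
    the cutoff is not selected by a greater-than rule.
    """
    if mode not in range(1, 7):
        raise ValueError(f"unknown restraint mode {mode}")
    if mode == 1:
        return heavy_atoms(structure)
    ca = calpha_atoms(structure)
    if mode == 2:
        return ca
    if d_axial is None:
        d_axial = MODE6_AXIAL_CUTOFF if mode == 6 else DEFAULT_AXIAL_CUTOFF
    lig = _ligand_reference_points(structure, reference)
    pos = structure.positions[ca]

    delta = pos[:, None, :] - lig[None, :, :]
    if mode == 3:
        dist3d = np.sqrt((delta ** 2).sum(axis=-1)).min(axis=1)
        return ca[dist3d > d_axial]
    axial = np.abs(delta[:, :, 2]).min(axis=1)
    if mode == 4:
        return ca[axial > d_axial]
    radial = np.sqrt(delta[:, :, 0] ** 2 + delta[:, :, 1] ** 2).min(axis=1)
    # modes 5 and 6: far along the axis AND close in the transverse plane
    return ca[(axial > d_axial) & (radial < d_radial)]


def build_restraint(
    structure: Structure,
    mode: int,
    d_axial: float | None = None,
    d_radial: float = DEFAULT_RADIAL_CUTOFF,
    reference: str = "min",
    force_constant: float = DEFAULT_FORCE_CONSTANT,
) -> RestraintSpec:
    """Convenience wrapper returning a full :class:`RestraintSpec`."""
    selected = select_mode(structure, mode, d_axial, d_radial, reference)
    if d_axial is None:
        d_axial = MODE6_AXIAL_CUTOFF if mode == 6 else DEFAULT_AXIAL_CUTOFF
    return RestraintSpec(
        mode=mode, selected=selected, d_axial=d_axial, d_radial=d_radial,
        reference=reference, force_constant=force_constant,
    )


# ---------------------------------------------------------------------------
# Restraint file output (GROMACS-style ndx / position-restraint itp)
# ---------------------------------------------------------------------------

def write_index_group(indices: np.ndarray, name: str, path) -> None:
    """Write an index group as an ``.ndx`` section with 1-based indices."""
    indices = np.asarray(indices, dtype=int)
    if indices.size == 0:
        raise ValueError("refusing to write an empty restraint group")
    one_based = np.sort(indices) + 1
    lines = [f"[ {name} ]"]
    for start in range(0, one_based.size, 15):
        chunk = one_based[start:start + 15]
        lines.append(" ".join(str(i) for i in chunk))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_index_group(path, name: str | None = None) -> np.ndarray:
    """Read a section of an ``.ndx`` file back to 0-based indices."""
    groups: dict[str, list[int]] = {}
    current = None
    with open(path) as fh:
        for line in fh:
            line = line.split(";")[0].strip()
            if not line:
                continue
            if line.startswith("[") and line.endswith("]"):
                current = line[1:-1].strip()
                groups[current] = []
            elif current is not None:
                groups[current].extend(int(tok) for tok in line.split())
    if name is None:
        if len(groups) != 1:
            raise ValueError(f"file has {len(groups)} groups; specify a name")
        name = next(iter(groups))
    if name not in groups:
        raise KeyError(f"group {name!r} not in {sorted(groups)}")
    return np.array(sorted(groups[name]), dtype=int) - 1


def write_position_restraints(
    indices: np.ndarray, force_constant: float, path
) -> None:
    """Write a position-restraint include file (one record per atom).

    Each record is ``index  1  kx  ky  kz`` with the same force constant
    (kJ/mol/nm^2) on all three axes; indices are 1-based.
    """
    indices = np.asarray(indices, dtype=int)
    if indices.size == 0:
        raise ValueError("refusing to write an empty restraint set")
    if force_constant <= 0:
        raise ValueError("force constant must be positive")
    k = force_constant
    lines = ["[ position_restraints ]", "; atom  functype  kx  ky  kz"]
    for i in np.sort(indices) + 1:
        lines.append(f"{i} 1 {k:g} {k:g} {k:g}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_position_restraints(path) -> list[tuple[int, float]]:
    """Parse a position-restraint file to 0-based (index, k) pairs."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.split(";")[0].strip()
            if not line or line.startswith("["):
                continue
            tok = line.split()
            out.append((int(tok[0]) - 1, float(tok[2])))
    return out
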