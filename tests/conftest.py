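"""Shared fixtures: programmatic structures, PDB text and brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest

from restraintkit.structure_model import Structure

# ---------------------------------------------------------------------------
# Structure builders
# ---------------------------------------------------------------------------

PROTEIN_ATOM_POOL = [
    # (name, element) drawn from a generic residue
    ("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O"),
    ("CB", "C"), ("SG", "S"), ("H", "H"), ("HA", "H"),
]


def make_structure(
    positions,
    names,
    elements,
    is_ligand,
    residue_ids=None,
    residue_names=None,
    chain_ids=None,
) -> Structure:
    n = len(names)
    if residue_ids is None:
        residue_ids = np.arange(1, n + 1)
    if residue_names is None:
        residue_names = ["LIG" if l else "ALA" for l in is_ligand]
    if chain_ids is None:
        chain_ids = ["B" if l else "A" for l in is_ligand]
    return Structure(
        names=np.array(names, dtype=object),
        elements=np.array(elements, dtype=object),
        residue_ids=np.asarray(residue_ids),
        residue_names=np.array(residue_names, dtype=object),
        chain_ids=np.array(chain_ids, dtype=object),
        positions=np.asarray(positions, dtype=float),
        is_ligand=np.asarray(is_ligand, dtype=bool),
    )


def random_structure(rng: np.random.Generator, n_residues: int = 8,
                     n_ligand: int = 4, spread: float = 2.0) -> Structure:
    """A random protein-like structure with a multi-atom ligand."""
    names, elements, resids, is_lig, pos = [], [], [], [], []
    rid = 0
    for _ in range(n_residues):
        rid += 1
        n_atoms = rng.integers(3, 7)
        picks = [PROTEIN_ATOM_POOL[1]]  # always a CA
        extra = rng.integers(0, len(PROTEIN_ATOM_POOL), size=n_atoms - 1)
        picks += [PROTEIN_ATOM_POOL[i] for i in extra if PROTEIN_ATOM_POOL[i][0] != "CA"]
        center = rng.uniform(-spread, spread, 3)
        for name, elem in picks:
            names.append(name)
            elements.append(elem)
            resids.append(rid)
            is_lig.append(False)
            pos.append(center + rng.normal(0, 0.15, 3))
    rid += 1
    lig_center = rng.uniform(-spread / 2, spread / 2, 3)
    for i in range(n_ligand):
        names.append(f"C{i + 1}")
        elements.append("C" if i % 3 else "O")
        resids.append(rid)
        is_lig.append(True)
        pos.append(lig_center + rng.normal(0, 0.12, 3))
    return make_structure(pos, names, elements, is_lig, residue_ids=resids)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


# ---------------------------------------------------------------------------
# PDB text
# ---------------------------------------------------------------------------

def pdb_line(serial, name, resname, chain, resid, x, y, z,
             occ=1.0, b=0.0, element=" C", altloc=" ", record="ATOM"):
    """One fixed-column PDB coordinate record (coordinates in angstrom)."""
    nm = name if len(name) >= 4 else f" {name:<3s}"
    return (f"{record:<6s}{serial:>5d} {nm:<4s}{altloc}{resname:>3s} "
            f"{chain}{resid:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
            f"{occ:6.2f}{b:6.2f}          {element:>2s}")


@pytest.fixture
def tiny_pdb(tmp_path):
    """3 glycine residues, one LIG residue, a water and two ions."""
    lines = []
    s = 0
    for rid, zoff in ((1, 0.0), (2, 4.0), (3, 8.0)):
        for name, element, dx in (("N", " N", -1.0), ("CA", " C", 0.0),
                                  ("C", " C", 1.2), ("O", " O", 2.0)):
            s += 1
            lines.append(pdb_line(s, name, "GLY", "A", rid, dx, 0.0, zoff,
                                  element=element))
    for name, element, dx in (("C1", " C", 0.0), ("O1", " O", 1.3)):
        s += 1
        lines.append(pdb_line(s, name, "LIG", "B", 1, dx, 5.0, 4.0,
                              element=element, record="HETATM"))
    s += 1
    lines.append(pdb_line(s, "O", "HOH", "B", 2, 9.0, 9.0, 9.0,
                          element=" O", record="HETATM"))
    s += 1
    lines.append(pdb_line(s, "NA", "NA", "B", 3, -9.0, 9.0, 9.0,
                          element="NA", record="HETATM"))
    s += 1
    lines.append(pdb_line(s, "CA", "CA", "B", 4, -9.0, -9.0, 9.0,
                          element="CA", record="HETATM"))
    path = tmp_path / "tiny.pdb"
    path.write_text("\n".join(lines) + "\nEND\n")
    return path


# ---------------------------------------------------------------------------
# Brute-force oracles (kept deliberately naive and loop-based)
# ---------------------------------------------------------------------------

def oracle_heavy_atoms(structure: Structure) -> set[int]:
    out = set()
    for atom in structure:
        if not atom.is_ligand and atom.element in {"C", "N", "O", "S"}:
            out.add(atom.index)
    return out


def oracle_calpha_atoms(structure: Structure) -> set[int]:
    out = set()
    for atom in structure:
        if not atom.is_ligand and atom.name == "CA" and atom.element == "C":
            out.add(atom.index)
    return out


def oracle_min_distance(idx_a, idx_b, positions) -> float:
    best = np.inf
    for i in idx_a:
        for j in idx_b:
            d = float(np.linalg.norm(positions[i] - positions[j]))
            best = min(best, d)
    return best


def oracle_select_mode(structure: Structure, mode: int,
                       d_axial=None, d_radial=1.2, reference="min") -> set[int]:
    if mode == 1:
        return oracle_heavy_atoms(structure)
    ca = sorted(oracle_calpha_atoms(structure))
    if mode == 2:
        return set(ca)
    if d_axial is None:
        d_axial = 1.8 if mode == 6 else 1.2
    lig_heavy = [a.index for a in structure
                 if a.is_ligand and a.element != "H"]
    if reference == "com":
        masses = structure.masses()
        w = masses[lig_heavy]
        refpts = [np.average(structure.positions[lig_heavy], axis=0, weights=w)]
    else:
        refpts = [structure.positions[i] for i in lig_heavy]
    out = set()
    for i in ca:
        p = structure.positions[i]
        d3 = min(np.linalg.norm(p - q) for q in refpts)
        dz = min(abs(p[2] - q[2]) for q in refpts)
        dr = min(np.hypot(p[0] - q[0], p[1] - q[1]) for q in refpts)
        if mode == 3 and d3 > d_axial:
            out.add(i)
        elif mode == 4 and dz > d_axial:
            out.add(i)
        elif mode in (5, 6) and dz > d_axial and dr < d_radial:
            out.add(i)
    return out


def oracle_contacts(frame, structure: Structure, cutoff=0.6):
    count = 0
    residues = set()
    for a in structure:
        if a.is_ligand or a.element not in {"C", "N", "O", "S"}:
            continue
        for b in structure:
            if not b.is_ligand:
                continue
            if np.linalg.norm(frame[a.index] - frame[b.index]) < cutoff:
                count += 1
                residues.add(a.residue_id)
    return count, residues


def oracle_hydrogen_bonds(frame, donors, hydrogens, acceptors,
                          cutoff=0.35, angle_min=135.0) -> int:
    count = 0
    for d, h in zip(donors, hydrogens):
        for a in acceptors:
            if a == d:
                continue
            if np.linalg.norm(frame[d] - frame[a]) >= cutoff:
                continue
            v1 = frame[d] - frame[h]
            v2 = frame[a] - frame[h]
            cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
            ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
            if ang > angle_min:
                count += 1
    return count


def oracle_rmsd(x, ref) -> float:
    total = 0.0
    for xi, ri in zip(x, ref):
        total += float(np.sum((np.asarray(xi) - np.asarray(ri)) ** 2))
    return float(np.sqrt(total / len(x)))
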