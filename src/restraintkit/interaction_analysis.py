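"""Geometric protein–ligand interaction metrics over trajectory frames.

Contacts, hydrogen bonds, displacement-binned profiles and the pairwise
non-bonded interaction energy IE = V_LJ + V_Coulomb, plus the "potential
length" L0 — the ligand displacement at which the interaction energy has
decayed to zero.  All criteria are geometric:

* contact: a protein heavy atom closer than 0.6 nm to any ligand atom;
* hydrogen bond: donor–acceptor distance < 0.35 nm and donor–hydrogen–
  acceptor angle (at the hydrogen) > 135 degrees;
* non-bonded pair: Lennard-Jones 12-6 with Lorentz–Berthelot combination
  plus Coulomb, strict 1.0 nm pair cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure_model import Structure, heavy_atoms

__all__ = [
    "ContactCriteria",
    "HBondCriteria",
    "NonbondedParams",
    "DisplacementProfile",
    "contacts",
    "contact_residue_census",
    "hydrogen_bonds",
    "find_donors_and_acceptors",
    "bin_by_displacement",
    "interaction_energy",
    "potential_length",
    "COULOMB_KJ_NM_E2",
]

#: Coulomb prefactor 1/(4 pi eps0) in kJ/mol * nm / e^2.
COULOMB_KJ_NM_E2 = 138.935458

KCAL_PER_KJ = 1.0 / 4.184


@dataclass(frozen=True)
class ContactCriteria:
    cutoff: float = 0.6  # nm

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("contact cutoff must be positive")


@dataclass(frozen=True)
class HBondCriteria:
    donor_acceptor_cutoff: float = 0.35  # nm
    angle_min: float = 135.0  # degrees, at the hydrogen

    def __post_init__(self) -> None:
        if self.donor_acceptor_cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if not 0 < self.angle_min < 180:
            raise ValueError("angle_min must be in (0, 180)")


@dataclass(frozen=True)
class NonbondedParams:
    """Per-atom charge (e), LJ sigma (nm) and epsilon (kJ/mol)."""

    charges: np.ndarray
    sigmas: np.ndarray
    epsilons: np.ndarray
    cutoff: float = 1.0  # nm, strict
    relative_permittivity: float = 1.0

    def __post_init__(self) -> None:
        for name in ("charges", "sigmas", "epsilons"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), float))
        if self.cutoff <= 0 or self.relative_permittivity <= 0:
            raise ValueError("cutoff and permittivity must be positive")
        if np.any(self.sigmas < 0) or np.any(self.epsilons < 0):
            raise ValueError("sigma and epsilon must be non-negative")

    def validate_for(self, n_atoms: int) -> None:
        for name in ("charges", "sigmas", "epsilons"):
            arr = getattr(self, name)
            if arr.size != n_atoms:
                raise ValueError(
                    f"{name}: {arr.size} entries for a {n_atoms}-atom system"
                )
        bad = np.flatnonzero(~np.isfinite(self.charges))
        if bad.size:
            raise ValueError(f"missing charge for atom index {bad[0]}")


@dataclass
class DisplacementProfile:
    """A metric averaged in half-open displacement bins [lo, hi)."""

    edges: np.ndarray
    means: np.ndarray   # NaN where a bin holds no frame
    counts: np.ndarray

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def empty_bins(self) -> np.ndarray:
        return self.counts == 0


# ---------------------------------------------------------------------------
# Contacts
# ---------------------------------------------------------------------------

def contacts(
    frame: np.ndarray,
    structure: Structure,
    criteria: ContactCriteria = ContactCriteria(),
) -> tuple[int, set[int]]:
    """Count protein-heavy-atom/ligand-atom pairs closer than the cutoff.

    Returns ``(pair count, residue ids with at least one contact)``.
    ``frame`` is an (n_atoms, 3) coordinate array in nm.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.shape != (len(structure), 3):
        raise ValueError(
            f"frame has shape {frame.shape}, expected ({len(structure)}, 3)"
        )
    prot = heavy_atoms(structure)
    lig = structure.ligand_indices()
    diff = frame[prot][:, None, :] - frame[lig][None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=-1))
    close = dist < criteria.cutoff
    count = int(close.sum())
    touching = prot[close.any(axis=1)]
    residues = {int(structure.residue_ids[i]) for i in touching}
    return count, residues


def contact_residue_census(
    frames,
    structure: Structure,
    criteria: ContactCriteria = ContactCriteria(),
) -> tuple[set[int], int]:
    """Union over frames of residues with at least one ligand contact.

    ``frames`` is an iterable of coordinate arrays (any number of
    trajectories chained together).  Returns ``(residue id set, count)``.
    """
    census: set[int] = set()
    for frame in frames:
        _, res = contacts(frame, structure, criteria)
        census |= res
    return census, len(census)


# ---------------------------------------------------------------------------
# Hydrogen bonds
# ---------------------------------------------------------------------------

def hydrogen_bonds(
    frame: np.ndarray,
    donors: np.ndarray,
    hydrogens: np.ndarray,
    acceptors: np.ndarray,
    criteria: HBondCriteria = HBondCriteria(),
) -> int:
    """Count hydrogen bonds among explicit (donor, hydrogen, acceptor) triples.

    ``donors`` and ``hydrogens`` are parallel arrays (each hydrogen is
    covalently bound to its donor); every acceptor except the donor itself
    is tested against each pair.  A bond requires donor–acceptor distance
    below the cutoff and the angle at the hydrogen above ``angle_min``.
    Both pulling directions (protein donor to ligand acceptor and the
    reverse) are covered by listing donors/acceptors from both molecules.
    """
    frame = np.asarray(frame, dtype=float)
    donors = np.asarray(donors, dtype=int)
    hydrogens = np.asarray(hydrogens, dtype=int)
    acceptors = np.asarray(acceptors, dtype=int)
    if donors.size != hydrogens.size:
        raise ValueError("donors and hydrogens must be parallel arrays")
    if donors.size == 0 or acceptors.size == 0:
        return 0
    d_pos = frame[donors]          # (nd, 3)
    h_pos = frame[hydrogens]
    a_pos = frame[acceptors]       # (na, 3)

    da = a_pos[None, :, :] - d_pos[:, None, :]
    dist_da = np.sqrt((da ** 2).sum(axis=-1))          # (nd, na)
    hd = d_pos[:, None, :] - h_pos[:, None, :]         # (nd, 1, 3)
    ha = a_pos[None, :, :] - h_pos[:, None, :]         # (nd, na, 3)
    norm_hd = np.sqrt((hd ** 2).sum(axis=-1))
    norm_ha = np.sqrt((ha ** 2).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = (hd * ha).sum(axis=-1) / (norm_hd * norm_ha)
    angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))

    self_pair = donors[:, None] == acceptors[None, :]
    ok = (
        (dist_da < criteria.donor_acceptor_cutoff)
        & (angle > criteria.angle_min)
        & ~self_pair
    )
    return int(ok.sum())


def find_donors_and_acceptors(
    structure: Structure,
    frame: np.ndarray | None = None,
    bond_cutoff: float = 0.12,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Infer (donors, hydrogens, acceptors) from geometry.

    N and O atoms are acceptors; an N or O with a hydrogen within
    ``bond_cutoff`` nm is the donor of that hydrogen.  A hydrogen with no
    N/O parent within the cutoff raises, since its triple would be
    ill-defined.
    """
    pos = structure.positions if frame is None else np.asarray(frame, float)
    is_h = np.array([e == "H" for e in structure.elements])
    is_no = np.array([e in ("N", "O") for e in structure.elements])
    h_idx = np.flatnonzero(is_h)
    no_idx = np.flatnonzero(is_no)
    donors, hydrogens = [], []
    for h in h_idx:
        if no_idx.size == 0:
            raise ValueError(f"hydrogen atom {h} has no donor parent")
        d2 = np.sum((pos[no_idx] - pos[h]) ** 2, axis=1)
        j = int(np.argmin(d2))
        if d2[j] > bond_cutoff ** 2:
            raise ValueError(f"hydrogen atom {h} has no donor parent")
        donors.append(int(no_idx[j]))
        hydrogens.append(int(h))
    return (
        np.array(donors, dtype=int),
        np.array(hydrogens, dtype=int),
        no_idx.astype(int),
    )


# ---------------------------------------------------------------------------
# Displacement binning
# ---------------------------------------------------------------------------

def bin_by_displacement(
    values: np.ndarray,
    displacements: np.ndarray,
    edges: np.ndarray,
) -> DisplacementProfile:
    """Average a per-frame metric in half-open displacement bins [lo, hi).

    Frames outside the edge range are ignored; empty bins carry NaN means
    and zero counts rather than zeros.
    """
    values = np.asarray(values, dtype=float)
    displacements = np.asarray(displacements, dtype=float)
    edges = np.asarray(edges, dtype=float)
    if values.size != displacements.size:
        raise ValueError("values and displacements must have equal length")
    if edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("edges must be increasing with at least 2 entries")
    idx = np.searchsorted(edges, displacements, side="right") - 1
    nbins = edges.size - 1
    inside = (idx >= 0) & (idx < nbins)
    counts = np.bincount(idx[inside], minlength=nbins)
    sums = np.bincount(idx[inside], weights=values[inside], minlength=nbins)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return DisplacementProfile(edges=edges, means=means, counts=counts)


# ---------------------------------------------------------------------------
# Interaction energy
# ---------------------------------------------------------------------------

def interaction_energy(
    frame: np.ndarray,
    structure: Structure,
    params: NonbondedParams,
) -> tuple[float, float, float]:
    """Protein–ligand non-bonded energy (IE, V_LJ, V_Coulomb) in kcal/mol.

    Sums Lennard-Jones 12-6 (Lorentz–Berthelot mixing) and Coulomb terms
    over protein/ligand atom pairs strictly inside the pair cutoff.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.shape != (len(structure), 3):
        raise ValueError("frame does not match the structure's atom count")
    params.validate_for(len(structure))
    prot = structure.protein_indices()
    lig = structure.ligand_indices()
    diff = frame[prot][:, None, :] - frame[lig][None, :, :]
    r = np.sqrt((diff ** 2).sum(axis=-1))
    within = r < params.cutoff
    if not within.any():
        return 0.0, 0.0, 0.0
    pi, li = np.nonzero(within)
    rij = r[pi, li]
    qi = params.charges[prot][pi]
    qj = params.charges[lig][li]
    si = params.sigmas[prot][pi]
    sj = params.sigmas[lig][li]
    ei = params.epsilons[prot][pi]
    ej = params.epsilons[lig][li]
    sig = 0.5 * (si + sj)
    eps = np.sqrt(ei * ej)
    sr6 = (sig / rij) ** 6
    v_lj = float(np.sum(4.0 * eps * (sr6 ** 2 - sr6)))
    v_coul = float(np.sum(
        COULOMB_KJ_NM_E2 / params.relative_permittivity * qi * qj / rij
    ))
    v_lj *= KCAL_PER_KJ
    v_coul *= KCAL_PER_KJ
    return v_lj + v_coul, v_lj, v_coul


def potential_length(
    profile: DisplacementProfile,
    epsilon_zero: float = 1.0,
) -> float | None:
    """L0: smallest bin centre beyond which |IE| stays below ``epsilon_zero``.

    Empty bins are ignored.  Returns ``None`` (flagged undefined) when the
    profile never decays below the threshold.
    """
    centers = profile.centers
    means = profile.means
    valid = ~np.isnan(means)
    if not valid.any():
        return None
    below = np.abs(means) < epsilon_zero
    # smallest index where every later valid bin is below threshold
    ok_from_here = np.ones(centers.size, dtype=bool)
    running = True
    for i in range(centers.size - 1, -1, -1):
        if valid[i]:
            running = running and bool(below[i])
        ok_from_here[i] = running
    candidates = np.flatnonzero(ok_from_here & valid & below)
    if candidates.size == 0:
        return None
    return float(centers[candidates[0]])
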