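"""Coarse-grained overdamped-Langevin pulling simulator.

Generates synthetic constant-velocity pulling data with the statistical
structure the ensemble analysis assumes — rupture events, trajectory-to-
trajectory variation, receptor drift when under-restrained — without an MD
engine.  The model:

* the receptor is a bead network: a hemispherical "pocket" shell of beads
  around the ligand, a body lattice beneath it, a lateral collar, and a few
  sidechain-like beads; nearby beads are connected by harmonic
  elastic-network springs;
* the ligand is a single bead bound to the pocket beads by Morse potentials
  (finite rupture force, analytic);
* a subset of beads (the restraint mask, produced by the same mode-selection
  rules used for real structures) is tethered harmonically to its initial
  position;
* the ligand is pulled along +Z by a harmonic spring whose anchor moves at
  constant velocity; the recorded force is the spring force;
* every bead follows overdamped (Brownian) dynamics,
  ``dx = (F/gamma) dt + sqrt(2 kB T dt / gamma) xi`` — friction plus noise
  stand in for bulk water.

Units: nm, ps, kJ/mol (Morse depth is configured in kcal/mol, the unit the
analysis reports), friction gamma in kJ/mol*ps/nm^2.  All randomness flows
from a master seed through a splitmix64 stream, so ensembles are
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from numba import njit

from .restraint_builder import select_mode
from .smd_analysis import KB_KJ_PER_MOL_K, PullEnsemble, PullTrace, write_xvg
from .structure_model import Structure

__all__ = [
    "ToyConfig",
    "ToySystem",
    "ToyTrajectory",
    "default_receptor_geometry",
    "build_toy_system",
    "toy_structure",
    "make_mode_masks",
    "run_pull",
    "generate_ensemble",
    "derive_seeds",
    "load_toy_config",
    "toy_nonbonded_params",
    "KJ_PER_KCAL",
]

KJ_PER_KCAL = 4.184
_MASK64 = (1 << 64) - 1


@dataclass(frozen=True)
class ToyConfig:
    """Configuration of the toy receptor, binding potential and pulling run.

    Defaults mirror the conditions of the pulling protocol being emulated:
    v = 1.0 nm/ns, spring k = 600 kJ/mol/nm^2, 3 ns duration, force
    recorded every 10 fs, snapshots every 10 ps, restraint force constant
    1000 kJ/mol/nm^2, T = 300 K.
    """

    # receptor geometry (None -> default_receptor_geometry)
    receptor_positions: np.ndarray | None = None
    receptor_names: np.ndarray | None = None
    pocket_radius: float = 0.5          # nm, finger-to-ligand pocket scale
    ligand_start: np.ndarray = field(
        default_factory=lambda: np.zeros(3))
    # elastic network
    k_net: float = 400.0                # kJ/mol/nm^2 (0 allowed: no network)
    net_cutoff: float = 0.5             # nm (nearest-neighbour bead network)
    # ligand-pocket binding (Morse)
    morse_depth: float = 4.0            # kcal/mol per bond
    morse_width: float = 8.0            # 1/nm
    binding_cutoff: float = 0.7         # nm, beads bonded to the ligand
    # ligand-receptor excluded volume (harmonic, bounded force)
    repulsion_radius: float = 0.45      # nm
    k_repulsion: float = 3000.0         # kJ/mol/nm^2
    # restraints
    restraint_mask: np.ndarray | None = None  # None -> all receptor beads
    k_restraint: float = 1000.0         # kJ/mol/nm^2
    # pulling schedule
    velocity: float = 1.0               # nm/ns (0 allowed: stationary trap)
    k_spring: float = 600.0             # kJ/mol/nm^2
    duration: float = 3000.0            # ps
    # thermostat / integrator
    temperature: float = 300.0          # K
    gamma: float = 1000.0               # kJ/mol*ps/nm^2
    timestep: float = 0.01              # ps (10 fs)
    record_stride: int = 1              # record force every this many steps
    frame_interval: float = 10.0        # ps between saved coordinate frames
    freeze_ligand: bool = False         # infinite-restraint limit
    box_bound: float = 50.0             # nm, blow-up guard
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.k_restraint, self.k_spring, self.gamma, self.timestep,
               self.morse_depth, self.morse_width, self.duration) <= 0:
            raise ValueError("stiffnesses, Morse parameters, gamma, timestep "
                             "and duration must be positive")
        if self.k_net < 0 or self.velocity < 0 or self.temperature < 0:
            raise ValueError("k_net, velocity and temperature must be >= 0")
        if self.record_stride < 1:
            raise ValueError("record_stride must be >= 1")
        for name in ("receptor_positions", "receptor_names",
                     "restraint_mask", "ligand_start"):
            val = getattr(self, name)
            if val is not None:
                object.__setattr__(self, name, np.asarray(val))

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.timestep))


@dataclass(frozen=True)
class ToySystem:
    """Built bead system: receptor beads + one ligand bead (last index)."""

    positions: np.ndarray       # (n_beads + 1, 3), ligand last
    names: np.ndarray           # "CA"/"CB" for receptor, "C1" for ligand
    bonds: np.ndarray           # (n_bonds, 2) receptor elastic network
    bond_r0: np.ndarray         # rest lengths, nm
    morse_partners: np.ndarray  # receptor bead indices bonded to the ligand
    morse_r0: np.ndarray        # rest lengths, nm
    config: ToyConfig

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]

    @property
    def ligand_index(self) -> int:
        return self.n_beads - 1


@dataclass
class ToyTrajectory:
    """One pulling run: the recorded trace plus coordinate frames."""

    trace: PullTrace
    frames: np.ndarray       # (n_frames, n_beads, 3)
    frame_times: np.ndarray  # ps
    config: ToyConfig
    seed: int


# ---------------------------------------------------------------------------
# Geometry and system construction
# ---------------------------------------------------------------------------

def default_receptor_geometry(
    pocket_radius: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Default ~100-bead receptor around a ligand at the origin.

    The binding site is a "claw" of eight three-bead fingers (base, mid,
    tip) wrapped around the ligand, with the tips curving inward above it
    as an exit gate.  Finger bonds run along the escape wall, so a
    central-force network makes each finger stiff against being dragged
    upward but soft against splaying outward — when the fingers are not
    position-restrained, the gate opens sideways at low force, the way
    flexible active-site residues let a ligand out.  Four lid-loop beads
    above the gate are anchored by near-horizontal bonds, the opposite
    anisotropy: when free they trail the departing ligand upward, so
    protein-ligand interactions persist to larger displacement.  Beneath
    the claw sit four 12-bead body plates (z = -0.95 to -2.15 nm); lateral
    collar and flank arms at the ligand plane and at z = -1.35 nm give the
    six restraint modes strictly decreasing bead counts; six
    sidechain-like "CB" beads (heavy, not C-alpha) hang off the first
    plate.
    """
    beads: list[np.ndarray] = []
    names: list[str] = []
    s = pocket_radius / 0.5  # geometry scales with the pocket radius

    def add(x, y, z, name="CA"):
        beads.append(np.array([x, y, z]) * s)
        names.append(name)

    n_fingers = 8
    for i in range(n_fingers):
        phi = 2 * np.pi * i / n_fingers
        c, sn = np.cos(phi), np.sin(phi)
        add(0.55 * c, 0.55 * sn, -0.52)   # base
        add(0.50 * c, 0.50 * sn, -0.10)   # mid (binds the ligand)
        add(0.32 * c, 0.32 * sn, 0.30)    # tip (gate)
    # lid loops: vertically compliant, they follow the ligand out
    for i in range(4):
        phi = 2 * np.pi * i / 4 + np.pi / 8
        add(0.60 * np.cos(phi), 0.60 * np.sin(phi), 0.35)
    # body plates: ring of 8 under the finger bases + inner ring of 4
    for z in (-0.95, -1.35, -1.75, -2.15):
        for i in range(8):
            phi = 2 * np.pi * i / 8
            add(0.55 * np.cos(phi), 0.55 * np.sin(phi), z)
        for i in range(4):
            phi = 2 * np.pi * i / 4 + np.pi / 4
            add(0.25 * np.cos(phi), 0.25 * np.sin(phi), z)
    # collar arms: lateral, in the ligand plane (mode 3 keeps their outer
    # beads restrained, mode 4 frees them: |dz| is small)
    for i in range(4):
        phi = 2 * np.pi * i / 4
        c, sn = np.cos(phi), np.sin(phi)
        add(0.85 * c, 0.85 * sn, -0.10)
        add(1.25 * c, 1.25 * sn, -0.05)
        add(1.55 * c, 1.55 * sn, 0.0)
    # flank arms at the second plate: outer beads are far from the axis,
    # so mode 5 drops them while mode 4 keeps them
    for i in range(4):
        phi = 2 * np.pi * i / 4 + np.pi / 4
        c, sn = np.cos(phi), np.sin(phi)
        add(0.90 * c, 0.90 * sn, -1.35)
        add(1.25 * c, 1.25 * sn, -1.35)
        add(1.55 * c, 1.55 * sn, -1.35)
    # sidechain-like beads: heavy atoms that are not alpha-carbons
    for i in range(6):
        phi = 2 * np.pi * i / 6 + np.pi / 8
        add(0.85 * np.cos(phi), 0.85 * np.sin(phi), -0.95, name="CB")
    return np.array(beads), np.array(names, dtype=object)


def build_toy_system(config: ToyConfig) -> ToySystem:
    """Deterministically build bead positions, network bonds and Morse bonds.

    Raises if the ligand overlaps a receptor bead (< 0.1 nm).
    """
    if config.receptor_positions is None:
        positions, names = default_receptor_geometry(config.pocket_radius)
    else:
        positions = np.array(config.receptor_positions, dtype=float).reshape(-1, 3)
        if config.receptor_names is not None:
            names = np.asarray(config.receptor_names, dtype=object)
        else:
            names = np.array(["CA"] * len(positions), dtype=object)
    lig = np.asarray(config.ligand_start, dtype=float).reshape(3)
    dist_to_lig = np.linalg.norm(positions - lig, axis=1)
    if np.any(dist_to_lig < 0.1):
        raise ValueError("ligand overlaps a receptor bead (< 0.1 nm)")

    # elastic network: receptor pairs within the cutoff
    n = len(positions)
    bonds, r0 = [], []
    for i in range(n):
        for j in range(i + 1, n):
            d = float(np.linalg.norm(positions[i] - positions[j]))
            if d <= config.net_cutoff:
                bonds.append((i, j))
                r0.append(d)
    bonds_arr = np.array(bonds, dtype=np.int64).reshape(-1, 2)
    morse_partners = np.flatnonzero(dist_to_lig <= config.binding_cutoff)

    all_pos = np.vstack([positions, lig[None, :]])
    all_names = np.concatenate([names, np.array(["C1"], dtype=object)])
    return ToySystem(
        positions=all_pos,
        names=all_names,
        bonds=bonds_arr,
        bond_r0=np.array(r0, dtype=float),
        morse_partners=morse_partners.astype(np.int64),
        morse_r0=dist_to_lig[morse_partners].copy(),
        config=config,
    )


def toy_structure(system: ToySystem) -> Structure:
    """View the bead system as a :class:`Structure` (one residue per bead).

    Receptor beads become protein residues carrying a single CA (or CB)
    carbon; the ligand bead becomes a LIG residue on its own chain, so the
    restraint-mode selectors apply unchanged and selected indices are bead
    indices.
    """
    n = system.n_beads
    lig = system.ligand_index
    is_ligand = np.zeros(n, dtype=bool)
    is_ligand[lig] = True
    return Structure(
        names=system.names,
        elements=np.array(["C"] * n, dtype=object),
        residue_ids=np.concatenate([np.arange(1, n), [1]]),
        residue_names=np.array(["GLY"] * (n - 1) + ["LIG"], dtype=object),
        chain_ids=np.array(["A"] * (n - 1) + ["B"], dtype=object),
        positions=system.positions,
        is_ligand=is_ligand,
        ligand_selector="resname LIG",
    )


def toy_nonbonded_params(system: ToySystem):
    """Non-bonded parameters for toy interaction-energy profiles.

    Emulates a drug-like, nearly neutral ligand: a small net charge
    (+0.1 e on the ligand, compensated across the receptor) so the
    interaction-energy tail is van-der-Waals dominated, with bead-scale
    Lennard-Jones parameters (sigma 0.35 nm, epsilon 1.0 kJ/mol).
    """
    from .interaction_analysis import NonbondedParams

    n = system.n_beads
    charges = np.full(n, -0.1 / (n - 1))
    charges[system.ligand_index] = 0.1
    return NonbondedParams(
        charges=charges,
        sigmas=np.full(n, 0.35),
        epsilons=np.full(n, 1.0),
    )


def make_mode_masks(system: ToySystem, mode: int, **select_kwargs) -> np.ndarray:
    """Restraint mask for a toy system under one of the six modes.

    Applies the same selection rules used for real structures, with beads
    standing in for atoms (CA beads as alpha-carbons, every bead as a heavy
    atom); the returned indices index the system's bead array directly.
    """
    return select_mode(toy_structure(system), mode, **select_kwargs)


# ---------------------------------------------------------------------------
# Integrator
# ---------------------------------------------------------------------------

@njit(cache=True)
def _integrate_chunk(
    pos, noise, noise_scale,
    bonds, bond_r0, k_net,
    morse_partners, morse_r0, depth_kj, width,
    r_rep, k_rep,
    lig, mask, anchor, k_restraint,
    k_spring, anchor_z0, v_nm_ps, t0, dt, gamma,
    freeze_ligand, box_bound,
    rec_force, rec_disp, rec_stride, z_lig0,
):  # pragma: no cover - exercised through run_pull
    n_steps = noise.shape[0]
    inv_gamma = dt / gamma
    n_rec = 0
    for s in range(n_steps):
        t = t0 + s * dt
        # pulling spring (record before the update, at the sample time)
        f_pull = k_spring * (anchor_z0 + v_nm_ps * t - pos[lig, 2])
        if s % rec_stride == 0:
            rec_force[n_rec] = f_pull
            rec_disp[n_rec] = pos[lig, 2] - z_lig0
            n_rec += 1

        forces = np.zeros_like(pos)
        # elastic network
        for b in range(bonds.shape[0]):
            i = bonds[b, 0]
            j = bonds[b, 1]
            dx = pos[j, 0] - pos[i, 0]
            dy = pos[j, 1] - pos[i, 1]
            dz = pos[j, 2] - pos[i, 2]
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            if r > 1e-12:
                f = k_net * (r - bond_r0[b]) / r
                forces[i, 0] += f * dx
                forces[i, 1] += f * dy
                forces[i, 2] += f * dz
                forces[j, 0] -= f * dx
                forces[j, 1] -= f * dy
                forces[j, 2] -= f * dz
        # position restraints
        for m in range(mask.shape[0]):
            i = mask[m]
            forces[i, 0] += k_restraint * (anchor[i, 0] - pos[i, 0])
            forces[i, 1] += k_restraint * (anchor[i, 1] - pos[i, 1])
            forces[i, 2] += k_restraint * (anchor[i, 2] - pos[i, 2])
        # Morse binding: ligand to pocket beads
        for m in range(morse_partners.shape[0]):
            j = morse_partners[m]
            dx = pos[lig, 0] - pos[j, 0]
            dy = pos[lig, 1] - pos[j, 1]
            dz = pos[lig, 2] - pos[j, 2]
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            if r > 1e-12:
                e = np.exp(-width * (r - morse_r0[m]))
                dv_dr = 2.0 * depth_kj * width * (1.0 - e) * e
                f = -dv_dr / r
                forces[lig, 0] += f * dx
                forces[lig, 1] += f * dy
                forces[lig, 2] += f * dz
                forces[j, 0] -= f * dx
                forces[j, 1] -= f * dy
                forces[j, 2] -= f * dz
        # excluded volume: ligand vs every receptor bead (bounded force)
        if k_rep > 0.0:
            for j in range(pos.shape[0]):
                if j == lig:
                    continue
                dx = pos[lig, 0] - pos[j, 0]
                dy = pos[lig, 1] - pos[j, 1]
                dz = pos[lig, 2] - pos[j, 2]
                r = np.sqrt(dx * dx + dy * dy + dz * dz)
                if 1e-12 < r < r_rep:
                    f = k_rep * (r_rep - r) / r
                    forces[lig, 0] += f * dx
                    forces[lig, 1] += f * dy
                    forces[lig, 2] += f * dz
                    forces[j, 0] -= f * dx
                    forces[j, 1] -= f * dy
                    forces[j, 2] -= f * dz
        forces[lig, 2] += f_pull

        # overdamped update
        for i in range(pos.shape[0]):
            if freeze_ligand and i == lig:
                continue
            for d in range(3):
                pos[i, d] += forces[i, d] * inv_gamma \
                    + noise_scale * noise[s, i, d]
                if pos[i, d] > box_bound or pos[i, d] < -box_bound:
                    return s  # blow-up at step s
    return -1


def run_pull(system: ToySystem, config: ToyConfig | None = None,
             seed: int | None = None) -> ToyTrajectory:
    """Run one pulling trajectory; bit-reproducible for a given seed.

    The recorded force is the pulling-spring force F(t) = k (v t - dz(t));
    the recorded displacement is the ligand Z displacement from t = 0.
    Raises on numerical blow-up, naming the failing step.
    """
    cfg = system.config if config is None else config
    if seed is None:
        seed = cfg.seed
    n_steps = cfg.n_steps
    dt = cfg.timestep
    v_nm_ps = cfg.velocity * 1e-3
    noise_scale = np.sqrt(2.0 * KB_KJ_PER_MOL_K * cfg.temperature * dt / cfg.gamma)
    mask = (np.arange(system.n_beads - 1, dtype=np.int64)
            if cfg.restraint_mask is None
            else np.asarray(cfg.restraint_mask, dtype=np.int64))
    pos = system.positions.copy()
    anchor = system.positions.copy()
    lig = system.ligand_index
    z_lig0 = float(pos[lig, 2])
    depth_kj = cfg.morse_depth * KJ_PER_KCAL

    frame_stride = max(1, int(round(cfg.frame_interval / dt)))
    # integrate in chunks of one frame interval; noise drawn per chunk
    rng = np.random.default_rng(seed)
    rec_per_chunk_max = (frame_stride + cfg.record_stride - 1) // cfg.record_stride
    times, forces_out, disps_out = [], [], []
    frames = [pos.copy()]
    frame_times = [0.0]
    step = 0
    while step < n_steps:
        chunk = min(frame_stride, n_steps - step)
        if cfg.temperature > 0:
            noise = rng.standard_normal((chunk, system.n_beads, 3))
        else:
            noise = np.zeros((chunk, system.n_beads, 3))
        if cfg.freeze_ligand:
            noise[:, lig, :] = 0.0
        rec_force = np.empty(rec_per_chunk_max)
        rec_disp = np.empty(rec_per_chunk_max)
        # record times within this chunk (pre-update sampling)
        local = np.arange(0, chunk, cfg.record_stride)
        bad = _integrate_chunk(
            pos, noise, noise_scale,
            system.bonds, system.bond_r0, cfg.k_net,
            system.morse_partners, system.morse_r0, depth_kj, cfg.morse_width,
            cfg.repulsion_radius, cfg.k_repulsion,
            lig, mask, anchor, cfg.k_restraint,
            cfg.k_spring, z_lig0, v_nm_ps, step * dt, dt, cfg.gamma,
            cfg.freeze_ligand, cfg.box_bound,
            rec_force, rec_disp, cfg.record_stride, z_lig0,
        )
        if bad >= 0:
            raise RuntimeError(
                f"numerical blow-up (|coordinate| > {cfg.box_bound} nm) "
                f"at step {step + bad}"
            )
        times.append((step + local) * dt)
        forces_out.append(rec_force[: local.size].copy())
        disps_out.append(rec_disp[: local.size].copy())
        step += chunk
        frames.append(pos.copy())
        frame_times.append(step * dt)

    trace = PullTrace(
        time=np.concatenate(times),
        force=np.concatenate(forces_out),
        displacement=np.concatenate(disps_out),
        velocity=cfg.velocity,
        spring_k=cfg.k_spring,
    )
    return ToyTrajectory(
        trace=trace,
        frames=np.array(frames),
        frame_times=np.array(frame_times),
        config=cfg,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Ensembles
# ---------------------------------------------------------------------------

def _splitmix64(state: int) -> tuple[int, int]:
    state = (state + 0x9E3779B97F4A7C15) & _MASK64
    z = state
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & _MASK64
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & _MASK64
    return (z ^ (z >> 31)) & _MASK64, state


def derive_seeds(master_seed: int, n: int) -> np.ndarray:
    """Derive n distinct per-trajectory seeds (< 2^31) from a master seed.

    A fixed splitmix64 stream, so ensembles reproduce across platforms;
    rare collisions are skipped to guarantee distinctness.
    """
    seeds: list[int] = []
    seen: set[int] = set()
    state = int(master_seed) & _MASK64
    while len(seeds) < n:
        value, state = _splitmix64(state)
        s = value & 0x7FFFFFFF
        if s not in seen:
            seen.add(s)
            seeds.append(s)
    return np.array(seeds, dtype=np.int64)


def load_toy_config(path) -> ToyConfig:
    """Read a :class:`ToyConfig` from a YAML/JSON mapping file.

    Keys are the dataclass field names; unknown keys raise.
    """
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping of config fields")
    valid = {f.name for f in ToyConfig.__dataclass_fields__.values()}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown toy config fields: {sorted(unknown)}")
    return ToyConfig(**data)


def generate_ensemble(
    config: ToyConfig,
    n_traj: int,
    seed: int | None = None,
    out_dir=None,
    keep_frames: bool = False,
    mode: int | None = None,
    write_frame_pdbs: bool = False,
) -> tuple[PullEnsemble, list[np.ndarray]]:
    """Run N independent trajectories from per-trajectory derived seeds.

    Optionally writes force/position files in the XVG-style format the
    analysis reads (``pullf_NNN.xvg`` / ``pullx_NNN.xvg``) and, with
    ``write_frame_pdbs``, the coordinate frames as multi-model PDBs.
    Returns the ensemble and (if requested) the per-trajectory frame
    stacks.
    """
    if n_traj < 1:
        raise ValueError("n_traj must be >= 1")
    master = config.seed if seed is None else seed
    system = build_toy_system(config)
    seeds = derive_seeds(master, n_traj)
    traces: list[PullTrace] = []
    frame_sets: list[np.ndarray] = []
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
    for i, s in enumerate(seeds):
        traj = run_pull(system, config, seed=int(s))
        traces.append(traj.trace)
        if keep_frames:
            frame_sets.append(traj.frames)
        if out_dir is not None:
            meta = f"seed {s} of master {master}"
            write_xvg(out_dir / f"pullf_{i:03d}.xvg", traj.trace.time,
                      traj.trace.force, comment=f"pull force (kJ/mol/nm); {meta}")
            write_xvg(out_dir / f"pullx_{i:03d}.xvg", traj.trace.time,
                      traj.trace.displacement,
                      comment=f"ligand displacement (nm); {meta}")
            if write_frame_pdbs:
                from .structure_model import write_frames

                write_frames(toy_structure(system), traj.frames,
                             out_dir / f"frames_{i:03d}.pdb")
    ensemble = PullEnsemble(traces=traces, mode=mode, label=f"toy-seed-{master}")
    return ensemble, frame_sets
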