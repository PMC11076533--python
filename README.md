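# restraintkit

Restraint-group selection and ensemble analysis for steered molecular
dynamics (SMD) pulling simulations.

## The problem

Constant-velocity SMD pulls a ligand out of a receptor with a harmonic
spring (force F(t) = k·(v·t − z(t))) while harmonic position restraints hold
part of the receptor in place.  *Which* atoms to restrain is an unsettled
modelling choice with real consequences: restraining every heavy atom or
every Cα rigidifies the binding site and inflates the rupture force ⟨F_max⟩,
the pulling work ⟨W_pull⟩ = v·∫F dt and the unbinding barrier ΔG‡, while
restraining too few atoms lets the solvent drift or spin the whole complex
so the spring stretches the protein instead of breaking the protein–ligand
interaction.

`restraintkit` is for simulators who want to make that choice deliberately.
It provides:

* **six restraint modes** of decreasing rigidity, selected in a frame where
  the pulling direction is +Z — (1) all protein heavy atoms; (2) all Cα;
  (3) Cα farther than 1.2 nm from the ligand; (4) Cα whose along-axis
  separation exceeds 1.2 nm; (5) mode 4 intersected with an in-plane radial
  distance < 1.2 nm; (6) mode 5 with the axial cutoff at 1.8 nm — emitted
  as GROMACS-style `.ndx` index groups and position-restraint files;
* **ensemble analysis** of pulling traces: rupture forces (pN), pulling
  work (kcal/mol), running-mean convergence, skew-normal distribution fits,
  and free-energy profiles G(z) with either the mean-work estimator or the
  Jarzynski second-order cumulant G(z) = ⟨W(z)⟩ − Var W(z)/(2k_BT), plus
  RMSD with optional Kabsch superposition;
* **interaction metrics** over trajectory frames: contacts (< 0.6 nm),
  hydrogen bonds (donor–acceptor < 0.35 nm, angle at the hydrogen > 135°),
  displacement-binned profiles, non-bonded interaction energy
  IE = V_LJ + V_Coulomb, and the potential length L0 at which IE decays to
  zero;
* a **toy pulling simulator** — an overdamped-Langevin bead model with an
  elastic-network receptor, Morse-bound ligand and moving spring — that
  generates realistic synthetic pulling data (XVG-style force/position
  files, multi-model PDB coordinate frames) so the entire pipeline can be
  exercised and tested without an MD engine.

See `docs/methods.md` for the model details, defaults and limitations.

## Worked example

Compare the rigid (mode 1) and most flexible (mode 6) restraint masks on
the bundled toy receptor, ten 3-ns trajectories per mode:

```python
import numpy as np
from dataclasses import replace
from restraintkit import ToyConfig, build_toy_system, make_mode_masks, generate_ensemble
from restraintkit.smd_analysis import rupture_force, pulling_work, free_energy_profile

base = ToyConfig()                      # v = 1 nm/ns, k = 600 kJ/mol/nm^2, 3 ns
system = build_toy_system(base)
for mode in (1, 6):
    cfg = replace(base, restraint_mask=make_mode_masks(system, mode))
    ens, _ = generate_ensemble(cfg, 10, seed=7, mode=mode)
    fmax = np.array([rupture_force(t)[0] for t in ens.traces])
    work = np.array([pulling_work(t) for t in ens.traces])
    prof = free_energy_profile(ens, "jarzynski-2nd-cumulant")
    print(f"mode {mode}: <Fmax> = {fmax.mean():6.0f} +/- {fmax.std(ddof=1)/np.sqrt(10):3.0f} pN   "
          f"<W> = {work.mean():5.1f} +/- {work.std(ddof=1)/np.sqrt(10):3.1f} kcal/mol   "
          f"barrier = {prof.barrier:5.1f} kcal/mol")
```

prints

```
mode 1: <Fmax> =   1071 +/-  10 pN   <W> = 123.9 +/- 1.7 kcal/mol   barrier = 108.5 kcal/mol
mode 6: <Fmax> =    692 +/-   9 pN   <W> =  95.3 +/- 2.0 kcal/mol   barrier =  82.9 kcal/mol
```

Fully restraining the receptor raises the mean rupture force by ~55%, the
pulling work by ~30% and the unbinding barrier accordingly: the rigid
binding site forces the ligand to break all of its contacts at once, while
a receptor that is free near the binding site lets gate beads swing aside
and contacts rupture sequentially.  The same analysis applied to real SMD
output is one call away (`read_pull_trace` on `pullf`/`pullx` XVG files).

Selecting restraints for a real structure from the shell:

```sh
restraintkit select --pdb complex.pdb --ligand LIG --mode 3 \
    --axis "0.2 -0.1 0.97" --out mode3
# -> mode3.ndx, mode3_posre.itp; prints the number of selected atoms
```

Other subcommands: `toy` (generate synthetic ensembles), `analyze`
(rupture/work/profile tables from force & position files), `report`
(end-to-end per-mode comparison table).

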