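"""Ensemble analysis of constant-velocity pulling trajectories.

A pulling trajectory records the harmonic-spring force F(t) and the ligand
centre-of-mass displacement z(t) while the spring anchor moves at constant
velocity v.  From an ensemble of N independent trajectories this module
computes:

* the rupture force Fmax (maximum of the recorded spring force) per trace
  and its running mean / skew-normal distribution across the ensemble;
* the external pulling work W = v * integral(F dt) per trace (kcal/mol);
* work-versus-displacement curves and a free-energy profile G(z) along the
  pulling coordinate, with two estimators:

  - ``mean-work``:               G(z) = <W(z)>
  - ``jarzynski-2nd-cumulant``:  G(z) = <W(z)> - Var W(z) / (2 kB T)

  The second is the second-order cumulant expansion of the Jarzynski
  equality; for Gaussian work distributions it is exact.  The unbinding
  barrier is max_z G(z) - G(0), with G(0) = 0 by construction.

* protein RMSD with or without optimal rigid-body (Kabsch) superposition.

Units follow the MD-engine convention: time in ps, force in kJ/mol/nm
(converted to pN for reporting), displacement in nm, work and free energy in
kcal/mol, spring constant in kJ/mol/nm^2, velocity in nm/ns.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, stats
from scipy.spatial.transform import Rotation

__all__ = [
    "PullTrace",
    "PullEnsemble",
    "FreeEnergyProfile",
    "RuptureStats",
    "read_xvg",
    "read_pull_trace",
    "write_xvg",
    "rupture_force",
    "pulling_work",
    "force_to_pN",
    "running_mean",
    "fit_skewed_gaussian",
    "work_vs_displacement",
    "free_energy_profile",
    "rmsd",
    "rupture_stats",
    "ensemble_summary",
    "KB_KJ_PER_MOL_K",
    "KCAL_PER_KJ",
    "PN_PER_KJ_MOL_NM",
]

KB_KJ_PER_MOL_K = 0.008314462618  # Boltzmann constant, kJ/mol/K
KCAL_PER_KJ = 1.0 / 4.184
#: 1 kJ/mol/nm expressed in pN: 1e3 J / N_A / 1e-9 m / 1e-12 N.
PN_PER_KJ_MOL_NM = 1.660539


@dataclass
class PullTrace:
    """One pulling trajectory: time (ps), spring force (kJ/mol/nm),
    ligand displacement along the pull axis (nm, zero at t=0)."""

    time: np.ndarray
    force: np.ndarray
    displacement: np.ndarray
    velocity: float = 1.0   # nm/ns
    spring_k: float = 600.0  # kJ/mol/nm^2

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        self.displacement = np.asarray(self.displacement, dtype=float)
        n = self.time.size
        if n == 0:
            raise ValueError("empty pull trace")
        if self.force.size != n or self.displacement.size != n:
            raise ValueError("time, force and displacement must have equal length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if not np.isclose(self.displacement[0], 0.0, atol=1e-9):
            raise ValueError("displacement must start at 0")

    def __len__(self) -> int:
        return self.time.size


@dataclass
class PullEnsemble:
    """N trajectories sharing pulling velocity and spring constant."""

    traces: list[PullTrace]
    mode: int | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if not self.traces:
            raise ValueError("ensemble must contain at least one trace")
        v0, k0 = self.traces[0].velocity, self.traces[0].spring_k
        for t in self.traces:
            if not (np.isclose(t.velocity, v0) and np.isclose(t.spring_k, k0)):
                raise ValueError("all traces must share velocity and spring constant")

    def __len__(self) -> int:
        return len(self.traces)


@dataclass
class FreeEnergyProfile:
    """Free energy along the pulling coordinate, from work statistics."""

    grid: np.ndarray            # displacement bin centres, nm
    mean_work: np.ndarray       # <W(z)>, kcal/mol
    var_work: np.ndarray        # Var W(z), (kcal/mol)^2
    free_energy: np.ndarray     # G(z), kcal/mol; G(0) = 0
    estimator: str
    temperature: float
    se_free_energy: np.ndarray | None = None  # jackknife SE, kcal/mol

    @property
    def barrier(self) -> float:
        """Unbinding barrier: max G - G(0), kcal/mol."""
        return float(np.max(self.free_energy) - self.free_energy[0])


@dataclass
class RuptureStats:
    """Per-trace rupture forces and their ensemble statistics (pN)."""

    fmax: np.ndarray
    mean: float
    stderr: float
    skewnorm_location: float
    skewnorm_scale: float
    skewnorm_shape: float


# ---------------------------------------------------------------------------
# I/O: XVG-style two-column text
# ---------------------------------------------------------------------------

def read_xvg(path) -> np.ndarray:
    """Read whitespace-separated columns, skipping ``#``/``@`` header lines."""
    with open(path) as fh:
        body = "".join(
            ln for ln in fh if ln.strip() and not ln.lstrip().startswith(("#", "@"))
        )
    if not body:
        raise ValueError(f"no data rows in {path}")
    data = np.loadtxt(io.StringIO(body), ndmin=2)
    return data


def write_xvg(path, time: np.ndarray, values: np.ndarray, comment: str = "") -> None:
    header = ""
    if comment:
        header = "\n".join("# " + ln for ln in comment.splitlines())
    np.savetxt(path, np.column_stack([time, values]), fmt="%.10g",
               header=header, comments="")


def read_pull_trace(
    force_file,
    position_file,
    velocity: float = 1.0,
    spring_k: float = 600.0,
) -> PullTrace:
    """Read force and displacement files and merge them on time.

    Both files are two-column XVG-style text (time ps, value).  Grids that
    do not match exactly are joined by nearest time within half the force
    file's sampling step; position samples outside every tolerance window
    are dropped.
    """
    fdat = read_xvg(force_file)
    xdat = read_xvg(position_file)
    tf, force = fdat[:, 0], fdat[:, 1]
    tx, disp = xdat[:, 0], xdat[:, 1]
    if np.any(np.diff(tf) <= 0) or np.any(np.diff(tx) <= 0):
        raise ValueError("time must be strictly increasing in both files")
    if tf.size == tx.size and np.allclose(tf, tx):
        t, f, d = tf, force, disp
    else:
        step = np.min(np.diff(tf)) if tf.size > 1 else np.inf
        idx = np.searchsorted(tx, tf)
        idx = np.clip(idx, 1, tx.size - 1)
        left, right = tx[idx - 1], tx[idx]
        nearest = np.where(tf - left <= right - tf, idx - 1, idx)
        ok = np.abs(tx[nearest] - tf) <= step / 2
        if not ok.any():
            raise ValueError("force and position time grids do not overlap")
        t, f, d = tf[ok], force[ok], disp[nearest[ok]]
    d = d - d[0]
    return PullTrace(t, f, d, velocity=velocity, spring_k=spring_k)


# ---------------------------------------------------------------------------
# Per-trace quantities
# ---------------------------------------------------------------------------

def rupture_force(trace: PullTrace, as_pN: bool = True) -> tuple[float, float]:
    """(Fmax, time at Fmax).  Ties are broken by earliest time."""
    i = int(np.argmax(trace.force))
    fmax = float(trace.force[i])
    if as_pN:
        fmax = force_to_pN(fmax)
    return fmax, float(trace.time[i])


def pulling_work(trace: PullTrace) -> float:
    """External work of the moving spring, W = v * integral(F dt), kcal/mol."""
    v_nm_per_ps = trace.velocity * 1e-3
    w_kj = v_nm_per_ps * np.trapezoid(trace.force, trace.time)
    return float(w_kj * KCAL_PER_KJ)


def force_to_pN(value_kj_mol_nm) -> float | np.ndarray:
    """Convert a spring force from kJ/mol/nm to pN."""
    return value_kj_mol_nm * PN_PER_KJ_MOL_NM


def running_mean(values: np.ndarray) -> np.ndarray:
    """Partial means: element i is the mean of the first i+1 values."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty sequence")
    return np.cumsum(values) / np.arange(1, values.size + 1)


def fit_skewed_gaussian(samples: np.ndarray) -> tuple[float, float, float]:
    """Maximum-likelihood skew-normal fit: (location, scale, shape).

    Shape near zero recovers a plain Gaussian; positive shape means a right
    tail.  Requires at least 10 non-degenerate samples.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size < 10:
        raise ValueError("need at least 10 samples for a distribution fit")
    if np.std(samples) == 0.0:
        raise ValueError("degenerate (zero-variance) samples")
    shape, loc, scale = stats.skewnorm.fit(samples)
    return float(loc), float(scale), float(shape)


def work_vs_displacement(
    trace: PullTrace, grid: np.ndarray | None = None, bin_width: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative pulling work re-indexed by ligand displacement.

    Returns ``(grid, W)`` in nm and kcal/mol.  The trace's displacement is
    made monotone with a running maximum (thermal back-steps collapse onto
    their first crossing) and the cumulative work is interpolated at each
    grid point.  Grid points beyond the trace's maximum displacement are
    not returned.
    """
    v_nm_per_ps = trace.velocity * 1e-3
    w_t = integrate.cumulative_trapezoid(
        trace.force, trace.time, initial=0.0
    ) * v_nm_per_ps * KCAL_PER_KJ
    z_mono = np.maximum.accumulate(trace.displacement)
    if grid is None:
        grid = np.arange(0.0, z_mono[-1] + 1e-12, bin_width)
    else:
        grid = np.asarray(grid, dtype=float)
        grid = grid[grid <= z_mono[-1] + 1e-12]
    # first-crossing interpolation on the monotone displacement
    w_grid = np.interp(grid, z_mono, w_t)
    return grid, w_grid


# ---------------------------------------------------------------------------
# Ensemble free-energy profile
# ---------------------------------------------------------------------------

def free_energy_profile(
    ensemble: PullEnsemble,
    estimator: str = "jarzynski-2nd-cumulant",
    temperature: float = 300.0,
    bin_width: float = 0.05,
    with_se: bool = False,
    coordinate: str = "trap",
) -> FreeEnergyProfile:
    """Free-energy profile G(z) from an ensemble of pulling traces.

    The grid spans displacement 0 to the largest displacement reached by
    every trace, in steps of ``bin_width`` (nm).  The cumulant estimator
    subtracts Var W / (2 kB T) from the mean work and requires at least two
    traces.  ``with_se`` adds a leave-one-out jackknife standard error of G
    at each grid point.

    ``coordinate`` selects how per-trace work is indexed onto the grid:
    ``"trap"`` (default) uses the spring-anchor position v*t — the
    stiff-spring convention, deterministic and free of re-indexing bias;
    ``"ligand"`` re-indexes by the measured ligand displacement (first
    crossing), which tracks the molecular coordinate but inherits a small
    bias from conditioning on thermal excursions.
    """
    if estimator not in ("mean-work", "jarzynski-2nd-cumulant"):
        raise ValueError(f"unknown estimator {estimator!r}")
    if coordinate not in ("trap", "ligand"):
        raise ValueError(f"unknown coordinate {coordinate!r}")
    n = len(ensemble)
    if estimator == "jarzynski-2nd-cumulant" and n < 2:
        raise ValueError("cumulant estimator needs at least 2 traces")
    if coordinate == "trap":
        v = ensemble.traces[0].velocity * 1e-3  # nm/ps
        if v <= 0:
            raise ValueError("trap coordinate requires positive velocity")
        zmax = min(v * (t.time[-1] - t.time[0]) for t in ensemble.traces)
    else:
        zmax = min(np.max(t.displacement) for t in ensemble.traces)
    grid = np.arange(0.0, zmax + 1e-12, bin_width)
    works = np.empty((n, grid.size))
    for i, tr in enumerate(ensemble.traces):
        if coordinate == "trap":
            w_t = integrate.cumulative_trapezoid(
                tr.force, tr.time, initial=0.0) * v * KCAL_PER_KJ
            works[i] = np.interp(grid, v * (tr.time - tr.time[0]), w_t)
        else:
            _, works[i] = work_vs_displacement(tr, grid=grid)

    def estimate(w: np.ndarray) -> np.ndarray:
        mean = w.mean(axis=0)
        if estimator == "mean-work":
            return mean
        var = w.var(axis=0, ddof=1)
        kbt = KB_KJ_PER_MOL_K * temperature * KCAL_PER_KJ  # kcal/mol
        return mean - var / (2.0 * kbt)

    g = estimate(works)
    g = g - g[0]
    se = None
    if with_se and n >= 3:
        loo = np.empty((n, grid.size))
        for i in range(n):
            sub = np.delete(works, i, axis=0)
            gi = estimate(sub)
            loo[i] = gi - gi[0]
        se = np.sqrt((n - 1) / n * np.sum((loo - loo.mean(axis=0)) ** 2, axis=0))
    return FreeEnergyProfile(
        grid=grid,
        mean_work=works.mean(axis=0),
        var_work=works.var(axis=0, ddof=1) if n > 1 else np.zeros(grid.size),
        free_energy=g,
        estimator=estimator,
        temperature=temperature,
        se_free_energy=se,
    )


# ---------------------------------------------------------------------------
# RMSD
# ---------------------------------------------------------------------------

def rmsd(coords: np.ndarray, ref_coords: np.ndarray, fit: bool = False) -> float:
    """Root-mean-square deviation between two coordinate sets (nm).

    With ``fit=True`` the mobile set is first optimally superposed on the
    reference (Kabsch rotation after centroid removal).
    """
    x = np.asarray(coords, dtype=float)
    ref = np.asarray(ref_coords, dtype=float)
    if x.shape != ref.shape or x.ndim != 2 or x.shape[1] != 3:
        raise ValueError("coordinate arrays must both be (N, 3)")
    if fit:
        xc = x - x.mean(axis=0)
        rc = ref - ref.mean(axis=0)
        rot, _ = Rotation.align_vectors(rc, xc)
        x = rot.apply(xc)
        ref = rc
    return float(np.sqrt(np.mean(np.sum((x - ref) ** 2, axis=1))))


# ---------------------------------------------------------------------------
# Ensemble summaries
# ---------------------------------------------------------------------------

def rupture_stats(ensemble: PullEnsemble) -> RuptureStats:
    """Rupture-force statistics (pN) with a skew-normal distribution fit."""
    fmax = np.array([rupture_force(t)[0] for t in ensemble.traces])
    mean = float(fmax.mean())
    stderr = float(fmax.std(ddof=1) / np.sqrt(fmax.size)) if fmax.size > 1 else 0.0
    if fmax.size >= 10 and fmax.std() > 0:
        loc, scale, shape = fit_skewed_gaussian(fmax)
    else:
        loc, scale, shape = mean, float(fmax.std(ddof=1)) if fmax.size > 1 else 0.0, 0.0
    return RuptureStats(fmax, mean, stderr, loc, scale, shape)


def ensemble_summary(
    ensemble: PullEnsemble,
    estimator: str = "jarzynski-2nd-cumulant",
    temperature: float = 300.0,
) -> pd.DataFrame:
    """One-row summary: <Fmax> +/- SE (pN), <Wpull> +/- SE (kcal/mol),
    barrier (kcal/mol), trace count."""
    rs = rupture_stats(ensemble)
    works = np.array([pulling_work(t) for t in ensemble.traces])
    w_se = float(works.std(ddof=1) / np.sqrt(works.size)) if works.size > 1 else 0.0
    if len(ensemble) >= 2:
        prof = free_energy_profile(ensemble, estimator, temperature)
        barrier = prof.barrier
    else:
        barrier = float("nan")
    return pd.DataFrame([
        {
            "mode": ensemble.mode,
            "label": ensemble.label,
            "n_traces": len(ensemble),
            "fmax_mean_pN": rs.mean,
            "fmax_se_pN": rs.stderr,
            "work_mean_kcal": float(works.mean()),
            "work_se_kcal": w_se,
            "barrier_kcal": barrier,
            "estimator": estimator,
        }
    ])
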