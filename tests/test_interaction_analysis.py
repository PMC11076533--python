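"""Contacts, hydrogen bonds, displacement profiles and interaction energy."""

import numpy as np
import pytest

from conftest import (
    make_structure,
    oracle_contacts,
    oracle_hydrogen_bonds,
    random_structure,
)
from restraintkit.interaction_analysis import (
    COULOMB_KJ_NM_E2,
    ContactCriteria,
    DisplacementProfile,
    HBondCriteria,
    NonbondedParams,
    bin_by_displacement,
    contact_residue_census,
    contacts,
    find_donors_and_acceptors,
    hydrogen_bonds,
    interaction_energy,
    potential_length,
)
from restraintkit.restraint_builder import rotation_to_z


class TestContacts:
    def test_single_pair_inside_cutoff(self):
        s = make_structure(
            [[0, 0, 0], [0, 0, 0.5], [0, 0, 5.0]],
            ["CA", "C1", "CA"], ["C", "C", "C"],
            [False, True, False], residue_ids=[1, 2, 3])
        count, residues = contacts(s.positions, s)
        assert count == 1 and residues == {1}

    def test_everything_far_apart(self):
        s = make_structure(
            [[0, 0, 0], [0, 0, 2.0]],
            ["CA", "C1"], ["C", "C"], [False, True])
        count, residues = contacts(s.positions, s)
        assert count == 0 and residues == set()

    def test_hydrogens_do_not_count_on_protein_side(self):
        s = make_structure(
            [[0, 0, 0], [0, 0, 0.1], [0, 0, 0.4]],
            ["CA", "HA", "C1"], ["C", "H", "C"],
            [False, False, True], residue_ids=[1, 1, 2])
        count, _ = contacts(s.positions, s)
        assert count == 1  # CA only; the protein hydrogen is ignored

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_bruteforce_scan(self, seed):
        s = random_structure(np.random.default_rng(seed), spread=0.8)
        got = contacts(s.positions, s)
        expect = oracle_contacts(s.positions, s)
        assert got[0] == expect[0] and got[1] == expect[1]

    def test_count_monotone_in_cutoff(self, rng):
        s = random_structure(rng, spread=0.8)
        loose = contacts(s.positions, s, ContactCriteria(0.8))[0]
        tight = contacts(s.positions, s, ContactCriteria(0.4))[0]
        assert tight <= loose

    def test_frame_shape_checked(self, rng):
        s = random_structure(rng)
        with pytest.raises(ValueError):
            contacts(s.positions[:-1], s)


class TestContactCensus:
    def test_single_frame_equals_contacts(self, rng):
        s = random_structure(rng, spread=0.8)
        census, n = contact_residue_census([s.positions], s)
        assert census == contacts(s.positions, s)[1]
        assert n == len(census)

    def test_union_is_monotone_in_frames(self, rng):
        s = random_structure(rng, spread=0.8)
        frames = [s.positions + rng.normal(0, 0.1, s.positions.shape)
                  for _ in range(5)]
        prev: set[int] = set()
        for k in range(1, 6):
            census, _ = contact_residue_census(frames[:k], s)
            assert census >= prev
            prev = census


class TestHydrogenBonds:
    def test_collinear_bond_counts(self):
        # D-H...A collinear, |D-A| = 0.30 nm: angle at H is 180 degrees
        frame = np.array([[0, 0, 0], [0, 0, 0.1], [0, 0, 0.3]])
        assert hydrogen_bonds(frame, [0], [1], [2]) == 1

    def test_distance_criterion_strict(self):
        frame = np.array([[0, 0, 0], [0, 0, 0.1], [0, 0, 0.36]])
        assert hydrogen_bonds(frame, [0], [1], [2]) == 0

    def test_angle_criterion(self):
        # acceptor placed to give ~90 degrees at the hydrogen: rejected
        frame = np.array([[0, 0, 0], [0, 0, 0.1], [0.25, 0, 0.1]])
        assert hydrogen_bonds(frame, [0], [1], [2]) == 0

    def test_donor_is_not_its_own_acceptor(self):
        frame = np.array([[0, 0, 0], [0, 0, 0.1]])
        assert hydrogen_bonds(frame, [0], [1], [0]) == 0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_bruteforce_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = 20
        frame = rng.uniform(0, 0.8, (n, 3))
        donors = rng.choice(n, 5, replace=False)
        hydrogens = rng.choice(np.setdiff1d(np.arange(n), donors), 5,
                               replace=False)
        acceptors = rng.choice(n, 8, replace=False)
        got = hydrogen_bonds(frame, donors, hydrogens, acceptors)
        assert got == oracle_hydrogen_bonds(frame, donors, hydrogens, acceptors)

    def test_count_nonincreasing_in_angle_threshold(self, rng):
        n = 30
        frame = rng.uniform(0, 0.6, (n, 3))
        donors, hydrogens = np.arange(5), np.arange(5, 10)
        acceptors = np.arange(10, 20)
        loose = hydrogen_bonds(frame, donors, hydrogens, acceptors,
                               HBondCriteria(angle_min=120))
        strict = hydrogen_bonds(frame, donors, hydrogens, acceptors,
                                HBondCriteria(angle_min=160))
        assert strict <= loose

    def test_parallel_arrays_required(self):
        with pytest.raises(ValueError):
            hydrogen_bonds(np.zeros((3, 3)), [0, 1], [2], [0])

    def test_orphan_hydrogen_rejected(self):
        s = make_structure(
            [[0, 0, 0], [0, 0, 3.0], [1, 1, 1]],
            ["CA", "H1", "O1"], ["C", "H", "O"],
            [False, False, True], residue_ids=[1, 1, 2])
        with pytest.raises(ValueError, match="no donor parent"):
            find_donors_and_acceptors(s)

    def test_donor_detection_by_geometry(self):
        s = make_structure(
            [[2, 2, 2], [0, 0, 0], [0, 0, 0.1], [0.5, 0, 0], [1, 1, 1]],
            ["CA", "N", "H", "O", "O1"], ["C", "N", "H", "O", "O"],
            [False, False, False, False, True],
            residue_ids=[1, 1, 1, 1, 2])
        donors, hydrogens, acceptors = find_donors_and_acceptors(s)
        assert list(donors) == [1] and list(hydrogens) == [2]
        assert set(acceptors) == {1, 3, 4}


class TestDisplacementBinning:
    def test_one_frame_per_bin(self):
        prof = bin_by_displacement([1.0, 2.0, 3.0], [0.05, 0.15, 0.25],
                                   np.array([0.0, 0.1, 0.2, 0.3]))
        assert np.allclose(prof.means, [1, 2, 3])
        assert np.all(prof.counts == 1)

    def test_all_frames_in_one_bin(self):
        prof = bin_by_displacement([1.0, 5.0], [0.01, 0.02],
                                   np.array([0.0, 0.1, 0.2]))
        assert prof.means[0] == pytest.approx(3.0)
        assert np.isnan(prof.means[1]) and prof.counts[1] == 0
        assert list(prof.empty_bins) == [False, True]

    def test_weighted_mean_identity(self, rng):
        values = rng.normal(size=200)
        disp = rng.uniform(0, 1, 200)
        prof = bin_by_displacement(values, disp, np.linspace(0, 1, 11))
        filled = prof.counts > 0
        recon = np.sum(prof.means[filled] * prof.counts[filled]) / prof.counts.sum()
        assert recon == pytest.approx(values.mean(), abs=1e-12)

    def test_half_open_bins(self):
        prof = bin_by_displacement([1.0, 2.0], [0.1, 0.2],
                                   np.array([0.0, 0.1, 0.2]))
        # 0.1 belongs to [0.1, 0.2); 0.2 falls outside the last edge
        assert prof.counts[1] == 1 and prof.counts[0] == 0


class TestInteractionEnergy:
    def _pair(self, r, q=0.5, sigma=0.3, eps=0.5):
        s = make_structure([[0, 0, 0], [0, 0, r]], ["CA", "C1"],
                           ["C", "C"], [False, True])
        params = NonbondedParams(
            charges=np.array([q, q]),
            sigmas=np.array([sigma, sigma]),
            epsilons=np.array([eps, eps]))
        return s, params

    def test_all_zero_parameters(self):
        s, _ = self._pair(0.35)
        params = NonbondedParams(np.zeros(2), np.zeros(2), np.zeros(2))
        assert interaction_energy(s.positions, s, params) == (0.0, 0.0, 0.0)

    def test_pair_exactly_at_cutoff_excluded(self):
        s, params = self._pair(1.0)
        assert interaction_energy(s.positions, s, params) == (0.0, 0.0, 0.0)

    def test_single_pair_closed_form(self):
        r, q, sigma, eps = 0.35, 0.5, 0.3, 0.5
        s, params = self._pair(r, q, sigma, eps)
        ie, v_lj, v_coul = interaction_energy(s.positions, s, params)
        sr6 = (sigma / r) ** 6
        expect_lj = 4 * eps * (sr6 ** 2 - sr6) / 4.184
        expect_coul = COULOMB_KJ_NM_E2 * q * q / r / 4.184
        assert v_lj == pytest.approx(expect_lj, rel=1e-12)
        assert v_coul == pytest.approx(expect_coul, rel=1e-12)
        assert ie == pytest.approx(expect_lj + expect_coul, rel=1e-12)

    def test_lorentz_berthelot_mixing(self):
        s = make_structure([[0, 0, 0], [0, 0, 0.4]], ["CA", "C1"],
                           ["C", "C"], [False, True])
        params = NonbondedParams(np.zeros(2), np.array([0.3, 0.5]),
                                 np.array([0.4, 0.9]))
        _, v_lj, _ = interaction_energy(s.positions, s, params)
        sig, eps = 0.4, np.sqrt(0.36)
        sr6 = (sig / 0.4) ** 6
        assert v_lj == pytest.approx(4 * eps * (sr6 ** 2 - sr6) / 4.184)

    def test_rigid_motion_invariance(self, rng):
        s = random_structure(rng, spread=0.6)
        n = len(s)
        params = NonbondedParams(rng.normal(0, 0.2, n),
                                 rng.uniform(0.25, 0.4, n),
                                 rng.uniform(0.1, 1.0, n))
        base = interaction_energy(s.positions, s, params)
        rot = rotation_to_z(rng.normal(size=3))
        moved = s.positions @ rot.T + rng.normal(size=3)
        assert interaction_energy(moved, s, params) == pytest.approx(base)

    def test_missing_parameters_name_the_atom(self, rng):
        s = random_structure(rng)
        n = len(s)
        charges = np.zeros(n)
        charges[4] = np.nan
        params = NonbondedParams(charges, np.zeros(n), np.zeros(n))
        with pytest.raises(ValueError, match="atom index 4"):
            interaction_energy(s.positions, s, params)


N_PATTERN_SEEDS = 20


@pytest.fixture(scope="module")
def paired_frames():
    """Mode-2 and mode-6 toy trajectories sharing per-seed noise streams."""
    from dataclasses import replace

    from restraintkit.toy_smd_simulator import (
        ToyConfig, build_toy_system, make_mode_masks, run_pull,
        toy_structure, toy_nonbonded_params,
    )
    base = ToyConfig(duration=2500.0, frame_interval=25.0)
    system = build_toy_system(base)
    frames = {2: [], 6: []}
    for mode in (2, 6):
        cfg = replace(base, restraint_mask=make_mode_masks(system, mode))
        sysm = build_toy_system(cfg)
        for seed in range(N_PATTERN_SEEDS):
            frames[mode].append(run_pull(sysm, seed=300 + seed).frames)
    return frames, toy_structure(system), toy_nonbonded_params(system), \
        system.ligand_index


class TestModePatternsOnToyEnsembles:
    """Receptor flexibility widens the interaction footprint: a sparsely
    restrained receptor recruits at least as many contact residues and
    sustains the interaction energy to larger ligand displacement."""

    N_SEEDS = N_PATTERN_SEEDS

    def test_contact_census_grows_with_flexibility(self, paired_frames):
        frames, structure, _, _ = paired_frames
        census = {
            mode: np.array([
                contact_residue_census(f, structure)[1] for f in frames[mode]
            ])
            for mode in (2, 6)
        }
        assert np.all(census[6] >= census[2])
        assert census[6].mean() > census[2].mean()

    def test_potential_length_grows_with_flexibility(self, paired_frames):
        frames, structure, params, lig = paired_frames
        edges = np.arange(0.0, 2.4, 0.1)
        l0 = {2: [], 6: []}
        for mode in (2, 6):
            for fr in frames[mode]:
                disp = fr[:, lig, 2] - fr[0, lig, 2]
                ies = [interaction_energy(f, structure, params)[0] for f in fr]
                prof = bin_by_displacement(ies, disp, edges)
                l0[mode].append(potential_length(prof, epsilon_zero=1.0))
        l2, l6 = np.asarray(l0[2], float), np.asarray(l0[6], float)
        assert np.sum(l6 >= l2) >= self.N_SEEDS * 3 // 4
        assert l6.mean() > l2.mean()


class TestPotentialLength:
    def _profile(self, means):
        edges = np.arange(0, 0.1 * (len(means) + 1) - 1e-12, 0.1)
        counts = np.where(np.isnan(means), 0, 1)
        return DisplacementProfile(edges=edges, means=np.asarray(means, float),
                                   counts=counts)

    def test_zero_interaction_everywhere(self):
        prof = self._profile([0.0, 0.0, 0.0])
        assert potential_length(prof) == pytest.approx(0.05)

    def test_step_function(self):
        prof = self._profile([-8.0, -5.0, -3.0, -2.0, -1.5, 0.1, 0.0, 0.0])
        # first center from which |IE| stays below 1 kcal/mol
        assert potential_length(prof) == pytest.approx(0.55)

    def test_transient_dip_is_not_the_length(self):
        prof = self._profile([-8.0, 0.5, -3.0, 0.2, 0.0])
        assert potential_length(prof) == pytest.approx(0.35)

    def test_never_decaying_profile_is_flagged(self):
        prof = self._profile([-8.0, -6.0, -5.0])
        assert potential_length(prof) is None

    def test_empty_bins_ignored(self):
        prof = self._profile([-8.0, np.nan, 0.2, np.nan, 0.1])
        assert potential_length(prof) == pytest.approx(0.25)
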