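"""Interaction-enthalpy cross term and per-residue decomposition."""

import numpy as np
import pytest

from polybridge.core import AtomRecord, BoxSpec, Selection, Topology, Trajectory
from polybridge.energy import (
    enthalpy_timeseries_report,
    interaction_enthalpy,
    per_residue_decomposition,
)
from polybridge.synth import gen_charged_system


def point_charge_system(charges, positions, sigmas=None, epsilons=None,
                        receptor_count=1, edge=100.0, resnames=None):
    n = len(charges)
    sigmas = sigmas if sigmas is not None else [0.0] * n
    epsilons = epsilons if epsilons is not None else [0.0] * n
    atoms = []
    for i in range(n):
        rec = i < receptor_count
        atoms.append(
            AtomRecord(
                i, "C", "C", "A" if rec else "B",
                i + 1 if rec else i - receptor_count + 1,
                (resnames[i] if resnames else ("RCP" if rec else "LIG")), i,
                partial_charge=charges[i], lj_sigma=sigmas[i], lj_epsilon=epsilons[i],
            )
        )
    top = Topology(atoms)
    traj = Trajectory.from_arrays(
        np.asarray(positions, float)[None, :, :], BoxSpec.cubic(edge), 0.1
    )
    receptor = Selection("receptor", np.arange(receptor_count))
    ligand = Selection("ligand", np.arange(receptor_count, n))
    return top, traj, receptor, ligand


def test_coulomb_closed_form_minus_hundred():
    # opposite unit charges at r = 332.0636/100 Å, no LJ: exactly -100 kcal/mol
    r = 332.0636 / 100.0
    top, traj, rec, lig = point_charge_system(
        [1.0, -1.0], [[0, 0, 0], [r, 0, 0]]
    )
    terms = interaction_enthalpy(traj, top, rec, lig)
    assert terms[0].E_coulomb == pytest.approx(-100.0, rel=1e-12)
    assert terms[0].E_lj == 0.0
    assert terms[0].E_total == terms[0].E_coulomb + terms[0].E_lj


def test_zero_ligand_charges_no_lj_gives_zero():
    rng = np.random.default_rng(1)
    pos = rng.uniform(0, 50, (6, 3))
    top, traj, rec, lig = point_charge_system(
        [0.5, -0.3, 0.0, 0.0, 0.0, 0.0], pos, receptor_count=2
    )
    terms = interaction_enthalpy(traj, top, rec, lig)
    assert terms[0].E_total == 0.0


@pytest.mark.parametrize("seed", range(10))
def test_matches_independent_double_loop_oracle(seed):
    """Vectorized cross energies equal the generator's brute-force double
    loop to 1e-10 relative, Coulomb and LJ separately."""
    sc = gen_charged_system(n_receptor=15, n_ligand=15, n_frames=3, seed=seed)
    terms = interaction_enthalpy(
        sc.trajectory, sc.topology, sc.extras["receptor"], sc.extras["ligand"]
    )
    ec = np.array([t.E_coulomb for t in terms])
    el = np.array([t.E_lj for t in terms])
    assert ec == pytest.approx(sc.manifest["oracle_E_coulomb_kcal"], rel=1e-10)
    assert el == pytest.approx(sc.manifest["oracle_E_lj_kcal"], rel=1e-10)


@pytest.mark.parametrize("seed", range(20))
def test_decomposition_conserves_total(seed):
    """Sum of per-residue contributions equals the mean total to 1e-8."""
    sc = gen_charged_system(n_receptor=10, n_ligand=12, n_frames=2, seed=100 + seed)
    terms = interaction_enthalpy(
        sc.trajectory, sc.topology, sc.extras["receptor"], sc.extras["ligand"]
    )
    mean_total = np.mean([t.E_total for t in terms])
    decomp = per_residue_decomposition(
        sc.trajectory, sc.topology, sc.extras["receptor"], sc.extras["ligand"]
    )
    assert decomp.mean_energy_kcal.sum() == pytest.approx(mean_total, abs=1e-8)


def test_single_residue_pair_half_split():
    r = 3.0
    top, traj, rec, lig = point_charge_system([1.0, -1.0], [[0, 0, 0], [r, 0, 0]])
    decomp = per_residue_decomposition(traj, top, rec, lig)
    total = interaction_enthalpy(traj, top, rec, lig)[0].E_total
    assert len(decomp) == 2
    assert decomp.mean_energy_kcal.tolist() == pytest.approx([total / 2, total / 2])


def test_phospho_like_residue_contributes_more_favorably():
    """A -2 site near a +4 ligand is a strictly larger (more negative)
    contributor than a neutral residue at the same distance."""
    pos = [[0, 0, 0], [10, 0, 0], [5, 0, 0]]
    top, traj, rec, lig = point_charge_system(
        [-2.0, 0.0, 4.0], pos, receptor_count=2,
        resnames=["SEP", "GLY", "SPM"],
    )
    decomp = per_residue_decomposition(traj, top, rec, lig)
    by_res = decomp.set_index("residue_name").mean_energy_kcal
    assert by_res["SEP"] < by_res["GLY"]
    assert by_res["SEP"] < 0


def test_receptor_ligand_symmetry():
    sc = gen_charged_system(n_receptor=8, n_ligand=11, n_frames=2, seed=77)
    fwd = interaction_enthalpy(sc.trajectory, sc.topology, sc.extras["receptor"], sc.extras["ligand"])
    rev = interaction_enthalpy(sc.trajectory, sc.topology, sc.extras["ligand"], sc.extras["receptor"])
    assert [t.E_total for t in fwd] == pytest.approx([t.E_total for t in rev], rel=1e-12)


def test_coulomb_sign_and_charge_scaling():
    r = 20.0
    top, traj, rec, lig = point_charge_system([2.0, 3.0], [[0, 0, 0], [r, 0, 0]])
    like = interaction_enthalpy(traj, top, rec, lig)[0].E_coulomb
    assert like > 0
    top2, traj2, rec2, lig2 = point_charge_system([2.0, -3.0], [[0, 0, 0], [r, 0, 0]])
    assert interaction_enthalpy(traj2, top2, rec2, lig2)[0].E_coulomb < 0
    # multiplying all charges by c scales E_coulomb by c^2
    top4, traj4, rec4, lig4 = point_charge_system([4.0, 6.0], [[0, 0, 0], [r, 0, 0]])
    assert interaction_enthalpy(traj4, top4, rec4, lig4)[0].E_coulomb == pytest.approx(
        4.0 * like, rel=1e-12
    )


def test_distance_dependent_dielectric_screens_by_extra_r():
    r = 10.0
    top, traj, rec, lig = point_charge_system([1.0, -1.0], [[0, 0, 0], [r, 0, 0]])
    plain = interaction_enthalpy(traj, top, rec, lig, dielectric="constant")[0].E_coulomb
    screened = interaction_enthalpy(traj, top, rec, lig, dielectric="r")[0].E_coulomb
    assert screened == pytest.approx(plain / r, rel=1e-12)


def test_missing_charges_reported_with_atom_indices():
    atoms = [
        AtomRecord(0, "C", "C", "A", 1, "RCP", 0, partial_charge=1.0),
        AtomRecord(1, "C", "C", "B", 1, "LIG", 1),  # no charge
    ]
    top = Topology(atoms)
    traj = Trajectory.from_arrays(np.zeros((1, 2, 3)) + [[0, 0, 0], [3, 0, 0]],
                                  BoxSpec.cubic(50.0), 0.1)
    with pytest.raises(ValueError, match=r"missing partial charges.*\[1\]"):
        interaction_enthalpy(traj, top, Selection("r", [0]), Selection("l", [1]))


def test_overlapping_selections_rejected():
    sc = gen_charged_system(n_receptor=4, n_ligand=4, n_frames=1, seed=2)
    with pytest.raises(ValueError, match="overlap"):
        interaction_enthalpy(
            sc.trajectory, sc.topology, sc.extras["receptor"], sc.extras["receptor"]
        )


def test_timeseries_flags():
    from polybridge.energy import EnergyTerms

    zeros = [EnergyTerms(k, 0.0, 0.0) for k in range(200)]
    rep = enthalpy_timeseries_report(zeros, window=50)
    assert rep.plateaus_near_zero and not rep.strongly_negative

    bound = [EnergyTerms(k, -500.0, 0.0) for k in range(200)]
    rep = enthalpy_timeseries_report(bound, window=50)
    assert rep.strongly_negative and not rep.plateaus_near_zero


def test_dissociation_drives_running_mean_toward_zero():
    """Ligand drifting away from the receptor: |running mean| decays."""
    n_frames = 120
    positions = np.zeros((n_frames, 2, 3))
    positions[:, 1, 0] = 3.0 + 0.5 * np.arange(n_frames)  # ligand leaves
    atoms = [
        AtomRecord(0, "C", "C", "A", 1, "RCP", 0, partial_charge=1.0, lj_sigma=0.0, lj_epsilon=0.0),
        AtomRecord(1, "C", "C", "B", 1, "LIG", 1, partial_charge=-1.0, lj_sigma=0.0, lj_epsilon=0.0),
    ]
    top = Topology(atoms)
    traj = Trajectory.from_arrays(positions + 100.0, BoxSpec.cubic(500.0), 0.1)
    terms = interaction_enthalpy(traj, top, Selection("r", [0]), Selection("l", [1]))
    rep = enthalpy_timeseries_report(terms, window=20)
    rm = rep.table.running_mean.to_numpy()
    assert rm[-1] > rm[20]  # toward zero from below
    assert abs(rm[-1]) < abs(rm[20])
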