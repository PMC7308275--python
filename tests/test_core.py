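"""Core geometry, topology and PDB I/O."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from polybridge.core import (
    AtomRecord,
    BoxSpec,
    Selection,
    Topology,
    Trajectory,
    assign_donors_acceptors,
    check_cutoff,
    infer_element,
    minimum_image_displacement,
    minimum_image_distance,
    n_frames_for_duration,
    select,
)
from polybridge.pdbio import (
    PDBParseError,
    read_pdb_topology,
    read_trajectory,
    write_pdb_topology,
    write_trajectory,
)
from polybridge.synth import gen_bridge_scenario

from conftest import make_water


# ---------------------------------------------------------------------------
# boxes and minimum image
# ---------------------------------------------------------------------------

def brute_min_image(d, box):
    """Exhaustive 27-image search."""
    h = np.asarray(box.vectors)
    frac = d @ np.linalg.inv(h)
    d = (frac - np.round(frac)) @ h
    best, best_n = d, d @ d
    for s in itertools.product((-1, 0, 1), repeat=3):
        cand = d + np.array(s, float) @ h
        if cand @ cand < best_n:
            best, best_n = cand, cand @ cand
    return best


def test_box_lengths_angles_roundtrip():
    box = BoxSpec.from_lengths_angles(20, 25, 30, 70, 80, 95)
    a, b, c, al, be, ga = box.lengths_angles
    assert np.allclose([a, b, c, al, be, ga], [20, 25, 30, 70, 80, 95])
    assert box.volume > 0
    assert not box.is_orthorhombic


def test_minimum_image_simple_cases():
    box = BoxSpec.cubic(10.0)
    assert np.allclose(minimum_image_displacement([0, 0, 0], [0, 0, 0], box), 0)
    # wrap-around: from (1,1,1) to (9,1,1) the near image is 2 Å in -x
    assert np.allclose(
        minimum_image_displacement([1, 1, 1], [9, 1, 1], box), [-2, 0, 0]
    )


@pytest.mark.parametrize("trial", range(5))
def test_minimum_image_matches_brute_force_triclinic(trial):
    rng = np.random.default_rng(100 + trial)
    box = BoxSpec.from_lengths_angles(
        *rng.uniform(15, 30, 3), *rng.uniform(60, 120, 3)
    )
    a = rng.uniform(-50, 50, (200, 3))
    b = rng.uniform(-50, 50, (200, 3))
    got = minimum_image_displacement(a, b, box)
    for k in range(len(a)):
        expect = brute_min_image(b[k] - a[k], box)
        assert np.linalg.norm(got[k]) == pytest.approx(np.linalg.norm(expect), abs=1e-9)


@given(
    shift=st.tuples(*[st.integers(-3, 3)] * 3),
    point=st.tuples(*[st.floats(-40, 40)] * 3),
)
@settings(derandomize=True, max_examples=50)
def test_minimum_image_invariant_under_lattice_shifts(shift, point):
    box = BoxSpec.from_lengths_angles(18, 22, 27, 75, 85, 100)
    a = np.zeros(3)
    b = np.asarray(point)
    shifted = b + np.asarray(shift, float) @ box.vectors
    d1 = minimum_image_displacement(a, b, box)
    d2 = minimum_image_displacement(a, shifted, box)
    assert np.linalg.norm(d1) == pytest.approx(np.linalg.norm(d2), abs=1e-8)


def test_cutoff_guard_rejects_ambiguous_cutoffs():
    box = BoxSpec.cubic(10.0)
    check_cutoff(box, 4.9)
    with pytest.raises(ValueError, match="half the minimal box height"):
        check_cutoff(box, 5.0)


# ---------------------------------------------------------------------------
# topology semantics
# ---------------------------------------------------------------------------

def test_molecule_partition_and_donor_acceptor_water():
    atoms, coords, bonds = make_water([0, 0, 0], 0, 0, 1)
    top = assign_donors_acceptors(Topology(atoms, bonds=bonds, species_labels={0: "water"}))
    assert top.donors == {0: [1, 2]}
    assert top.acceptors == {0}
    # partition property: molecule sizes sum to atom count
    assert sum(len(top.atoms_of_molecule(m)) for m in top.molecule_list) == top.n_atoms


def test_protonated_amine_is_donor_and_acceptor():
    atoms = [
        AtomRecord(0, "N1", "N", "S", 1, "SPM", 0),
        AtomRecord(1, "HN1", "H", "S", 1, "SPM", 0),
        AtomRecord(2, "HN2", "H", "S", 1, "SPM", 0),
        AtomRecord(3, "HN3", "H", "S", 1, "SPM", 0),
    ]
    top = assign_donors_acceptors(Topology(atoms, bonds=[(0, 1), (0, 2), (0, 3)]))
    assert top.donors == {0: [1, 2, 3]}
    assert 0 in top.acceptors


def test_phosphate_oxygens_are_acceptors_not_donors():
    # phosphoserine-like terminal group: P bonded to three bare oxygens
    atoms = [
        AtomRecord(0, "P", "P", "A", 1, "SEP", 0),
        AtomRecord(1, "O1P", "O", "A", 1, "SEP", 0),
        AtomRecord(2, "O2P", "O", "A", 1, "SEP", 0),
        AtomRecord(3, "O3P", "O", "A", 1, "SEP", 0),
    ]
    top = assign_donors_acceptors(Topology(atoms, bonds=[(0, 1), (0, 2), (0, 3)]))
    assert top.acceptors == {1, 2, 3}
    assert top.donors == {}


def test_assign_donors_acceptors_idempotent():
    atoms, _, bonds = make_water([0, 0, 0], 0, 0, 1)
    top = Topology(atoms, bonds=bonds)
    once = assign_donors_acceptors(top)
    twice = assign_donors_acceptors(once)
    assert once.donors == twice.donors and once.acceptors == twice.acceptors


def test_element_inference_fallback():
    assert infer_element("CA", "") == "C"
    assert infer_element("CL", "CL") == "Cl"
    assert infer_element("1HG1", "") == "H"
    assert infer_element("OXT", " O") == "O"


def test_selection_rejects_duplicates_and_empty():
    with pytest.raises(ValueError, match="duplicate"):
        Selection("bad", np.array([1, 1, 2]))
    atoms, _, bonds = make_water([0, 0, 0], 0, 0, 1)
    top = Topology(atoms, bonds=bonds)
    with pytest.raises(ValueError, match="matched no atoms"):
        select(top, species=["polyamine"], name="none")


# ---------------------------------------------------------------------------
# trajectory bookkeeping
# ---------------------------------------------------------------------------

def test_frame_count_for_production_run():
    # a 1000 ns run saved every 0.1 ns holds 10,000 frames
    assert n_frames_for_duration(1000.0, 0.1) == 10000


def test_trajectory_requires_uniform_spacing():
    box = BoxSpec.cubic(10.0)
    coords = np.zeros((3, 2, 3))
    traj = Trajectory.from_arrays(coords, box, 0.1)
    assert [f.time for f in traj.frames] == pytest.approx([0.0, 0.1, 0.2])
    from polybridge.core import Frame

    frames = [Frame(coords[0], box, 0.0), Frame(coords[1], box, 0.3)]
    with pytest.raises(ValueError, match="dt_frame"):
        Trajectory(frames, 0.1)


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

WATER_PDB = """CRYST1   20.000   20.000   20.000  90.00  90.00  90.00 P 1           1
HETATM    1 O    HOH W   1       5.000   5.000   5.000  1.00  0.00           O
HETATM    2 H1   HOH W   1       5.960   5.000   5.000  1.00  0.00           H
HETATM    3 H2   HOH W   1       4.760   5.930   5.000  1.00  0.00           H
CONECT    1    2    3
END
"""

TWO_CHAIN_PDB = """CRYST1   30.000   30.000   30.000  90.00  90.00  90.00 P 1           1
ATOM      1 CA   GLY A   1       1.000   1.000   1.000  1.00  0.00           C
ATOM      2 CA   GLY A   2       4.800   1.000   1.000  1.00  0.00           C
TER
ATOM      3 CA   GLY B   1       1.000   9.000   1.000  1.00  0.00           C
ATOM      4 CA   GLY B   2       4.800   9.000   1.000  1.00  0.00           C
TER
END
"""


def test_read_single_water(tmp_path):
    p = tmp_path / "w.pdb"
    p.write_text(WATER_PDB)
    top = read_pdb_topology(p)
    assert top.n_atoms == 3
    assert len(top.molecule_list) == 1
    assert top.species_labels[0] == "water"
    assert top.donors == {0: [1, 2]}
    assert top.acceptors == {0}


def test_two_protein_chains_become_two_molecules(tmp_path):
    p = tmp_path / "c.pdb"
    p.write_text(TWO_CHAIN_PDB)
    top = read_pdb_topology(p)
    assert len(top.molecule_list) == 2
    assert all(top.species_labels[m] == "protein_chain" for m in top.molecule_list)
    assert top.protein_chain_ids() == ["A", "B"]


def test_generated_scenario_roundtrips(tmp_path):
    sc = gen_bridge_scenario({"m": {3, 4, 5}}, n_frames=8, seed=11)
    paths = sc.write(tmp_path)
    top = read_pdb_topology(paths["topology"])
    assert {m: top.species_labels[m] for m in top.molecule_list} == {
        m: sc.topology.species_labels[m] for m in sc.topology.molecule_list
    }
    assert top.donors == sc.topology.donors
    assert top.acceptors == sc.topology.acceptors
    traj = read_trajectory(paths["trajectory"], top, dt_frame=0.1)
    # PDB stores three decimals
    assert np.abs(traj.coords - sc.trajectory.coords).max() < 1e-3
    assert [f.time for f in traj.frames] == pytest.approx([0.1 * k for k in range(8)])


def test_write_read_trajectory_preserves_coordinates(tmp_path, water_box):
    top, traj = water_box
    p = tmp_path / "traj.pdb"
    write_trajectory(p, traj, top)
    back = read_trajectory(p, top, 0.1)
    assert np.abs(back.coords - traj.coords).max() < 1e-3


def test_biotite_parses_written_files(tmp_path, water_box):
    """Cross-check our PDB dialect against an independent reader."""
    bpdb = pytest.importorskip("biotite.structure.io.pdb")
    top, traj = water_box
    p = tmp_path / "sys.pdb"
    write_pdb_topology(p, top, traj.frames[0].coordinates, traj.frames[0].box)
    st_ = bpdb.PDBFile.read(str(p)).get_structure(model=1)
    assert st_.array_length() == top.n_atoms
    assert np.abs(st_.coord - traj.frames[0].coordinates).max() < 1e-3
    assert set(st_.res_name) == {"HOH"}


@pytest.mark.parametrize(
    "content, match",
    [
        ("ATOM      1 O    HOH W   1       not_a_number   5.0   5.0\nEND\n", "line 1"),
        (
            "ATOM      1 CA   GLY A   1       1.000   1.000   1.000  1.00  0.00           C\n"
            "ATOM      1 CB   GLY A   1       2.000   1.000   1.000  1.00  0.00           C\nEND\n",
            "duplicate atom serial",
        ),
        ("", "no ATOM/HETATM"),
    ],
)
def test_topology_parse_errors(tmp_path, content, match):
    p = tmp_path / "bad.pdb"
    p.write_text(content)
    with pytest.raises(PDBParseError, match=match):
        read_pdb_topology(p)


def test_trajectory_atom_count_mismatch_names_model(tmp_path):
    p = tmp_path / "w.pdb"
    p.write_text(WATER_PDB)
    top = read_pdb_topology(p)
    bad = tmp_path / "t.pdb"
    bad.write_text(
        "CRYST1   20.000   20.000   20.000  90.00  90.00  90.00 P 1           1\n"
        "MODEL        1\n"
        "HETATM    1 O    HOH W   1       5.000   5.000   5.000  1.00  0.00           O\n"
        "ENDMDL\nEND\n"
    )
    with pytest.raises(PDBParseError, match="model 0 has 1 atoms"):
        read_trajectory(bad, top, 0.1)


def test_empty_trajectory_file_errors(tmp_path):
    p = tmp_path / "w.pdb"
    p.write_text(WATER_PDB)
    top = read_pdb_topology(p)
    empty = tmp_path / "e.pdb"
    empty.write_text("")
    with pytest.raises(PDBParseError, match="no coordinate frames"):
        read_trajectory(empty, top, 0.1)
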