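import numpy as np
import pytest

from polybridge.core import (
    AtomRecord,
    BoxSpec,
    Topology,
    Trajectory,
    assign_donors_acceptors,
)


def make_water(origin, index0, mol_id, residue_index, chain="W"):
    """Three atoms of one water molecule at ``origin`` (O-H bonds 0.96 Å)."""
    o = np.asarray(origin, float)
    atoms = [
        AtomRecord(index0, "O", "O", chain, residue_index, "HOH", mol_id),
        AtomRecord(index0 + 1, "H1", "H", chain, residue_index, "HOH", mol_id),
        AtomRecord(index0 + 2, "H2", "H", chain, residue_index, "HOH", mol_id),
    ]
    coords = np.array([o, o + [0.96, 0, 0], o + [-0.24, 0.93, 0]])
    bonds = [(index0, index0 + 1), (index0, index0 + 2)]
    return atoms, coords, bonds


@pytest.fixture
def water_box():
    """100 random waters in a 20 Å cube, donors/acceptors assigned."""
    rng = np.random.default_rng(7)
    atoms, coords, bonds = [], [], []
    for k in range(100):
        a, c, b = make_water(rng.uniform(0, 20, 3), 3 * k, k, k + 1)
        atoms += a
        coords.append(c)
        bonds += b
    top = assign_donors_acceptors(
        Topology(atoms, bonds=bonds, species_labels={k: "water" for k in range(100)})
    )
    traj = Trajectory.from_arrays(np.concatenate(coords)[None, :, :], BoxSpec.cubic(20.0), 0.1)
    return top, traj


def brute_force_hbonds(coords, topology, box, distance_cutoff=3.0, angle_cutoff=135.0,
                       intermolecular_only=True):
    """Independent O(n^2) hydrogen-bond oracle: plain double loop over all
    donor/acceptor pairs with an exhaustive 27-image minimum distance."""
    import itertools
    import math

    h = np.asarray(box.vectors)
    shifts = [np.array(s) @ h for s in itertools.product((-1, 0, 1), repeat=3)]

    def min_image(vec):
        best, best_n = None, None
        frac = vec @ np.linalg.inv(h)
        vec = (frac - np.round(frac)) @ h
        for s in shifts:
            cand = vec + s
            n = float(cand @ cand)
            if best_n is None or n < best_n:
                best, best_n = cand, n
        return best

    found = set()
    for d_at, hydrogens in topology.donors.items():
        for a_at in topology.acceptors:
            if a_at == d_at:
                continue
            if intermolecular_only and (
                topology.molecule_ids[d_at] == topology.molecule_ids[a_at]
            ):
                continue
            da = min_image(coords[a_at] - coords[d_at])
            if math.sqrt(float(da @ da)) > distance_cutoff:
                continue
            for h_at in hydrogens:
                hd = min_image(coords[d_at] - coords[h_at])
                ha = min_image(coords[a_at] - coords[h_at])
                cosang = float(hd @ ha) / (
                    math.sqrt(float(hd @ hd)) * math.sqrt(float(ha @ ha))
                )
                angle = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
                if angle >= angle_cutoff:
                    found.add((d_at, h_at, a_at))
    return found
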