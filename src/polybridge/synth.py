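"""Synthetic topologies and trajectories with planted ground truth.

Every analysis stage in this package is exercised against generators
whose outputs have analytically known answers: bridge schedules realized
as exact hydrogen-bond geometry, homogeneous/shell/depleted pair
structures for RDFs, Brownian walkers with a known diffusion constant,
and small charged systems whose pairwise energies are recomputed by an
independent double loop.  The toy "protein chains" are rigid
pseudo-peptides with explicit acceptor sites, not real protein models:
ground truth must be constructible in closed form.

All randomness flows from a single explicitly passed seed; regenerating
a scenario with the same seed reproduces byte-identical files.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .core import (
    AtomRecord,
    BoxSpec,
    Selection,
    Topology,
    Trajectory,
    assign_donors_acceptors,
)
from .pdbio import write_parameter_table, write_pdb_topology, write_trajectory

__all__ = [
    "Scenario",
    "gen_bridge_scenario",
    "random_bridge_schedule",
    "gen_pair_structure",
    "gen_brownian",
    "gen_mobility_contrast",
    "gen_charged_system",
]

OH_BOND = 0.96        # Å, donor-H distance in generated bridgers
BRIDGE_DA = 2.8       # Å, planted donor-acceptor distance
BRIDGE_TILT_DEG = 5.0 # tilt of the H off the D..A axis (angle stays >> 135°)
SITE_SPACING = 8.0    # Å between acceptor sites along a chain
CHAIN_SPACING = 5.6   # Å between adjacent chains (= 2 x BRIDGE_DA)
PARK_CLEARANCE = 15.0 # Å from the chain plane for parked molecules
MAX_SITES = 512


@dataclass
class Scenario:
    """A generated system: topology + trajectory + JSON-able manifest.

    ``extras`` holds in-memory objects that do not serialize (reference
    unwrapped trajectories, ready-made selections).
    """

    topology: Topology
    trajectory: Trajectory
    manifest: dict
    extras: dict = field(default_factory=dict)

    def write(self, out_dir) -> dict[str, str]:
        """Write topology.pdb, traj.pdb, manifest.json (and params.tsv when
        charges are present); returns the path map, also recorded in the
        manifest."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "topology": str(out / "topology.pdb"),
            "trajectory": str(out / "traj.pdb"),
            "manifest": str(out / "manifest.json"),
        }
        box = self.trajectory.frames[0].box
        write_pdb_topology(paths["topology"], self.topology, self.trajectory.frames[0].coordinates, box)
        write_trajectory(paths["trajectory"], self.trajectory, self.topology)
        if not np.all(np.isnan(self.topology.charges)):
            paths["params"] = str(out / "params.tsv")
            write_parameter_table(paths["params"], self.topology)
        manifest = dict(self.manifest)
        manifest["files"] = {k: Path(v).name for k, v in paths.items()}
        with open(paths["manifest"], "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return paths


def _single_atom_topology(
    n_groups: Sequence[tuple[int, str, str, str, str]],
) -> Topology:
    """Topology of single-atom molecules.

    ``n_groups`` is a list of (count, element, atom_name, resname, chain).
    """
    atoms = []
    species = {}
    idx = 0
    mol = 0
    for count, element, name, resname, chain in n_groups:
        for k in range(count):
            atoms.append(
                AtomRecord(idx, name, element, chain, k + 1, resname, mol)
            )
            species[mol] = "other"
            idx += 1
            mol += 1
    return Topology(atoms, species_labels=species)


# ---------------------------------------------------------------------------
# bridge scenarios
# ---------------------------------------------------------------------------

def _rle_events(frames: Sequence[int], dt: float) -> list[dict]:
    """Run-length encoding of a sorted frame set into (start, end, lifetime)."""
    frames = sorted(frames)
    events = []
    if not frames:
        return events
    start = prev = frames[0]
    for f in frames[1:]:
        if f == prev + 1:
            prev = f
            continue
        events.append({"start": start, "end": prev, "lifetime_ns": round((prev - start + 1) * dt, 10)})
        start = prev = f
    events.append({"start": start, "end": prev, "lifetime_ns": round((prev - start + 1) * dt, 10)})
    return events


def gen_bridge_scenario(
    schedule: Mapping[object, Sequence[int]],
    n_chains: int = 2,
    n_frames: int = 1000,
    dt: float = 0.1,
    seed: int = 0,
    n_decoys: int = 3,
    species: str = "water",
) -> Scenario:
    """Trajectory in which each scheduled molecule hydrogen-bonds two
    distinct chains exactly in its scheduled frames.

    Chains are parallel rigid pseudo-peptides carrying acceptor-only
    carbonyl sites.  In a scheduled frame the molecule sits midway
    between its two chains with both hydrogens pointing at the acceptors
    (D..A = 2.8 Å, D-H-A about 175 degrees); otherwise it is parked
    at least 6 Å from every chain.  Decoy molecules never approach the
    chains, and chains never hydrogen-bond each other (they carry no
    donors).
    """
    if n_chains < 2:
        raise ValueError("need at least two chains to bridge")
    keys = sorted(schedule, key=str)
    for k in keys:
        fr = schedule[k]
        if any(f < 0 or f >= n_frames for f in fr):
            raise ValueError(f"schedule for {k!r} has frames outside [0, {n_frames})")
    n_bridgers = len(keys)
    n_sites = max(n_bridgers, 1)
    if n_sites > MAX_SITES:
        raise ValueError(
            f"{n_bridgers} simultaneous bridgers exceed the {MAX_SITES} chain surface sites"
        )
    if species == "water":
        resname, d_el, d_name, h_names = "HOH", "O", "O", ("H1", "H2")
    elif species == "polyamine":
        resname, d_el, d_name, h_names = "SPM", "N", "N1", ("HN1", "HN2")
    else:
        raise ValueError(f"unsupported bridger species {species!r}")

    atoms: list[AtomRecord] = []
    species_labels: dict[int, str] = {}
    bonds: list[tuple[int, int]] = []
    base: list[np.ndarray] = []

    def add_atom(name, element, chain, resi, rname, mol, pos):
        atoms.append(AtomRecord(len(atoms), name, element, chain, resi, rname, mol))
        base.append(np.asarray(pos, float))

    # chains: acceptor carbonyls (C=O) at each site, one molecule per chain
    chain_letters = [chr(ord("A") + c) for c in range(n_chains)]
    acceptor_pos: dict[tuple[int, int], np.ndarray] = {}
    for c in range(n_chains):
        y = CHAIN_SPACING * c
        for s in range(n_sites):
            x = SITE_SPACING * s
            o = np.array([x, y, 0.0])
            add_atom("O", "O", chain_letters[c], s + 1, "GLY", c, o)
            add_atom("C", "C", chain_letters[c], s + 1, "GLY", c, o + np.array([0.0, 0.0, -1.23]))
            bonds.append((len(atoms) - 2, len(atoms) - 1))
            acceptor_pos[(c, s)] = o
        species_labels[c] = "protein_chain"

    y_top = CHAIN_SPACING * (n_chains - 1)
    tilt = math.radians(BRIDGE_TILT_DEG)

    bridger_info = []  # (mol_id, atom indices, bridge pos (3 atoms), park pos)
    mol_id = n_chains
    key_to_mol: dict[str, int] = {}
    for b, key in enumerate(keys):
        pair = b % (n_chains - 1)
        x = SITE_SPACING * b
        lo = acceptor_pos[(pair, b)]
        hi = acceptor_pos[(pair + 1, b)]
        center = 0.5 * (lo + hi)
        u_lo = np.array([0.0, -math.cos(tilt), math.sin(tilt)])
        u_hi = np.array([0.0, math.cos(tilt), math.sin(tilt)])
        bridge_pos = np.array([center, center + OH_BOND * u_lo, center + OH_BOND * u_hi])
        park = np.array([x, y_top + PARK_CLEARANCE, 0.0])
        park_pos = bridge_pos - center + park
        first = len(atoms)
        add_atom(d_name, d_el, "W", b + 1, resname, mol_id, park_pos[0])
        add_atom(h_names[0], "H", "W", b + 1, resname, mol_id, park_pos[1])
        add_atom(h_names[1], "H", "W", b + 1, resname, mol_id, park_pos[2])
        bonds += [(first, first + 1), (first, first + 2)]
        species_labels[mol_id] = "water" if species == "water" else "polyamine"
        bridger_info.append((mol_id, [first, first + 1, first + 2], bridge_pos, park_pos))
        key_to_mol[str(key)] = mol_id
        mol_id += 1

    for d in range(n_decoys):
        x = SITE_SPACING * d
        park = np.array([x, y_top + PARK_CLEARANCE + 10.0, 0.0])
        first = len(atoms)
        add_atom(d_name, d_el, "W", n_bridgers + d + 1, resname, mol_id, park)
        add_atom(h_names[0], "H", "W", n_bridgers + d + 1, resname, mol_id, park + [OH_BOND, 0, 0])
        add_atom(h_names[1], "H", "W", n_bridgers + d + 1, resname, mol_id, park + [-OH_BOND, 0, 0])
        bonds += [(first, first + 1), (first, first + 2)]
        species_labels[mol_id] = "water" if species == "water" else "polyamine"
        mol_id += 1

    top = assign_donors_acceptors(Topology(atoms, bonds=bonds, species_labels=species_labels))

    extent = max(SITE_SPACING * max(n_sites, n_decoys, 1), y_top + PARK_CLEARANCE + 10.0)
    box = BoxSpec.cubic(extent + 20.0)
    base_arr = np.array(base) + 5.0  # keep everything inside the cell
    coords = np.repeat(base_arr[None, :, :], n_frames, axis=0)
    for (mid, atom_idx, bridge_pos, park_pos), key in zip(bridger_info, keys):
        sched = set(schedule[key])
        for f in sched:
            coords[f, atom_idx, :] = bridge_pos + 5.0
    traj = Trajectory.from_arrays(coords, box, dt)

    truth_events = {str(k): _rle_events(schedule[k], dt) for k in keys}
    manifest = {
        "kind": "bridge",
        "seed": seed,
        "dt_ns": dt,
        "n_frames": n_frames,
        "n_chains": n_chains,
        "protein_chains": chain_letters,
        "candidate_species": species_labels[n_chains] if n_bridgers else species,
        "molecule_ids": key_to_mol,
        "schedule": {str(k): sorted(int(f) for f in schedule[k]) for k in keys},
        "events": truth_events,
        "n_events": sum(len(v) for v in truth_events.values()),
        "n_bridging_molecules": sum(1 for v in truth_events.values() if v),
        "lifetimes_ns": sorted(
            ev["lifetime_ns"] for evs in truth_events.values() for ev in evs
        ),
    }
    return Scenario(top, traj, manifest)


def random_bridge_schedule(
    n_molecules: int,
    n_events: int,
    n_frames: int,
    seed: int = 0,
    max_run: int = 20,
) -> dict[str, set[int]]:
    """A feasible random schedule with exactly ``n_events`` maximal runs
    spread over ``n_molecules`` molecules (runs separated by single-frame
    gaps at least)."""
    rng = np.random.default_rng(seed)
    per_mol = [n_events // n_molecules] * n_molecules
    for k in range(n_events % n_molecules):
        per_mol[k] += 1
    schedule: dict[str, set[int]] = {}
    for m, k_events in enumerate(per_mol):
        runs = rng.integers(1, max_run + 1, size=k_events)
        needed = int(runs.sum()) + (k_events - 1)
        if needed > n_frames:
            runs = np.ones(k_events, dtype=int)
            needed = 2 * k_events - 1
            if needed > n_frames:
                raise ValueError(
                    f"{k_events} events cannot fit in {n_frames} frames for one molecule"
                )
        slack = n_frames - needed
        # distribute the slack among the k_events+1 gaps
        cuts = np.sort(rng.integers(0, slack + 1, size=k_events)) if slack else np.zeros(k_events, int)
        frames: set[int] = set()
        pos = 0
        prev_cut = 0
        for run, cut in zip(runs, cuts):
            pos += int(cut) - prev_cut
            prev_cut = int(cut)
            frames.update(range(pos, pos + int(run)))
            pos += int(run) + 1  # at least one empty frame between runs
        schedule[f"mol{m}"] = frames
    return schedule


# ---------------------------------------------------------------------------
# pair structure for RDFs
# ---------------------------------------------------------------------------

def _random_unit_vectors(rng, n) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def gen_pair_structure(
    kind: str,
    n_a: int = 1,
    n_b: int = 200,
    box_edge: float = 30.0,
    n_frames: int = 100,
    r0: float = 5.05,
    exclusion_radius: float = 8.0,
    drift_radii: tuple[float, float] = (12.0, 4.0),
    seed: int = 0,
) -> Scenario:
    """Reference (A) and partner (B) point particles in a cubic box.

    kinds: ``ideal_gas`` (B uniform, resampled per frame), ``shell``
    (every B at exactly r0 from its assigned A), ``depleted`` (B uniform
    but outside ``exclusion_radius`` of every A), ``drift`` (B on a
    shell whose radius moves linearly between ``drift_radii`` over the
    trajectory — a planted non-stationarity).
    """
    if kind not in {"ideal_gas", "shell", "depleted", "drift"}:
        raise ValueError(f"unknown pair-structure kind {kind!r}")
    rng = np.random.default_rng(seed)
    box = BoxSpec.cubic(box_edge)
    if kind in {"shell"} and r0 >= 0.5 * box_edge:
        raise ValueError("shell radius must be below half the box edge")
    if kind == "depleted" and exclusion_radius >= 0.5 * box_edge:
        raise ValueError("exclusion radius must be below half the box edge")

    pos_a = rng.uniform(0, box_edge, size=(n_a, 3))
    frames = np.empty((n_frames, n_a + n_b, 3))
    frames[:, :n_a, :] = pos_a
    assign = np.arange(n_b) % n_a
    for t in range(n_frames):
        if kind == "ideal_gas":
            pos_b = rng.uniform(0, box_edge, size=(n_b, 3))
        elif kind == "shell":
            pos_b = pos_a[assign] + r0 * _random_unit_vectors(rng, n_b)
        elif kind == "drift":
            f = t / max(n_frames - 1, 1)
            r_t = drift_radii[0] + (drift_radii[1] - drift_radii[0]) * f
            pos_b = pos_a[assign] + r_t * _random_unit_vectors(rng, n_b)
        else:  # depleted
            pos_b = np.empty((n_b, 3))
            filled = 0
            while filled < n_b:
                cand = rng.uniform(0, box_edge, size=(4 * n_b, 3))
                d = cand[:, None, :] - pos_a[None, :, :]
                d -= box_edge * np.round(d / box_edge)
                ok = np.all(np.linalg.norm(d, axis=2) > exclusion_radius, axis=1)
                good = cand[ok]
                take = min(len(good), n_b - filled)
                pos_b[filled : filled + take] = good[:take]
                filled += take
        frames[t, n_a:, :] = pos_b

    top = _single_atom_topology(
        [(n_a, "C", "C", "REF", "R"), (n_b, "O", "O", "PRB", "P")]
    )
    traj = Trajectory.from_arrays(frames, box, 0.1)
    manifest = {
        "kind": f"pair_{kind}",
        "seed": seed,
        "n_a": n_a,
        "n_b": n_b,
        "box_edge_A": box_edge,
        "box_volume_A3": box.volume,
        "n_frames": n_frames,
        "rho_b_per_A3": n_b / box.volume,
        "r0_A": r0 if kind in {"shell"} else None,
        "exclusion_radius_A": exclusion_radius if kind == "depleted" else None,
        "drift_radii_A": list(drift_radii) if kind == "drift" else None,
    }
    extras = {
        "selection_a": Selection("reference", np.arange(n_a)),
        "selection_b": Selection("partner", np.arange(n_a, n_a + n_b)),
    }
    return Scenario(top, traj, manifest, extras)


# ---------------------------------------------------------------------------
# Brownian walkers
# ---------------------------------------------------------------------------

def gen_brownian(
    n_molecules: int = 100,
    d_true: float = 1e-5,  # cm²/s
    dt: float = 0.1,       # ns
    n_frames: int = 2000,
    box_edge: float = 60.0,
    wrap: bool = True,
    seed: int = 0,
) -> Scenario:
    """Independent Brownian walkers with known diffusion constant.

    Per-axis displacements are Gaussian with variance 2 D dt.  Both the
    wrapped trajectory (``.trajectory`` when ``wrap``) and the unwrapped
    one (``extras['unwrapped']``) are kept, so unwrap round-trips can be
    checked against ground truth.
    """
    d_a2ns = d_true / 1e-7  # Å²/ns
    sigma = math.sqrt(2.0 * d_a2ns * dt)
    if sigma >= 0.5 * box_edge:
        raise ValueError(
            f"per-frame step sigma {sigma:.1f} Å is not below half the box edge; "
            "reduce D or dt, or enlarge the box"
        )
    rng = np.random.default_rng(seed)
    start = rng.uniform(0, box_edge, size=(1, n_molecules, 3))
    steps = rng.normal(0.0, sigma, size=(n_frames - 1, n_molecules, 3))
    unwrapped = np.concatenate([start, start + np.cumsum(steps, axis=0)])
    wrapped = unwrapped - box_edge * np.floor(unwrapped / box_edge)

    box = BoxSpec.cubic(box_edge)
    top = _single_atom_topology([(n_molecules, "C", "C", "BRW", "M")])
    traj = Trajectory.from_arrays(wrapped if wrap else unwrapped, box, dt)
    manifest = {
        "kind": "brownian",
        "seed": seed,
        "n_molecules": n_molecules,
        "n_frames": n_frames,
        "dt_ns": dt,
        "box_edge_A": box_edge,
        "d_true_cm2_s": d_true,
        "step_sigma_A": sigma,
        "wrapped": wrap,
    }
    extras = {
        "unwrapped": Trajectory.from_arrays(unwrapped, box, dt),
        "molecule_ids": list(range(n_molecules)),
    }
    return Scenario(top, traj, manifest, extras)


def gen_mobility_contrast(
    n_free: int = 50,
    n_tethered: int = 50,
    d_free: float = 1e-5,   # cm²/s
    tether_sigma: float = 0.8,  # Å, jitter about the tether site
    dt: float = 0.1,
    n_frames: int = 1000,
    box_edge: float = 200.0,
    seed: int = 0,
) -> Scenario:
    """Two planted mobility populations: free Brownian walkers and
    walkers confined to fixed sites (MSD plateaus, fitted D near zero).

    Emulates the contrast between a freely diffusing cosolute and one
    electrostatically trapped on a protein surface.
    """
    d_a2ns = d_free / 1e-7
    sigma = math.sqrt(2.0 * d_a2ns * dt)
    rng = np.random.default_rng(seed)
    n = n_free + n_tethered
    start = rng.uniform(0, box_edge, size=(1, n, 3))
    coords = np.empty((n_frames, n, 3))
    steps = rng.normal(0.0, sigma, size=(n_frames - 1, n_free, 3))
    coords[:, :n_free, :] = np.concatenate(
        [start[:, :n_free, :], start[:, :n_free, :] + np.cumsum(steps, axis=0)]
    )
    sites = start[0, n_free:, :]
    coords[:, n_free:, :] = sites[None, :, :] + rng.normal(
        0.0, tether_sigma, size=(n_frames, n_tethered, 3)
    )
    box = BoxSpec.cubic(box_edge)
    top = _single_atom_topology([(n, "C", "C", "BRW", "M")])
    traj = Trajectory.from_arrays(coords, box, dt)
    manifest = {
        "kind": "mobility_contrast",
        "seed": seed,
        "n_free": n_free,
        "n_tethered": n_tethered,
        "d_free_cm2_s": d_free,
        "tether_sigma_A": tether_sigma,
        "dt_ns": dt,
        "n_frames": n_frames,
    }
    extras = {
        "free_molecule_ids": list(range(n_free)),
        "tethered_molecule_ids": list(range(n_free, n)),
    }
    return Scenario(top, traj, manifest, extras)


# ---------------------------------------------------------------------------
# charged systems
# ---------------------------------------------------------------------------

def _oracle_min_image(d: np.ndarray, edge: float) -> np.ndarray:
    """Brute-force 27-image minimum for a cubic cell (oracle-side code,
    intentionally independent of the core geometry routines)."""
    best = None
    best_n = None
    for i in (-1, 0, 1):
        for j in (-1, 0, 1):
            for k in (-1, 0, 1):
                cand = d + edge * np.array([i, j, k], float)
                norm = float(np.dot(cand, cand))
                if best_n is None or norm < best_n:
                    best, best_n = cand, norm
    return best


def gen_charged_system(
    n_receptor: int = 25,
    n_ligand: int = 25,
    n_frames: int = 5,
    box_edge: float = 20.0,
    min_separation: float = 1.5,
    charge_scale: float = 1.0,
    with_lj: bool = True,
    seed: int = 0,
) -> Scenario:
    """Random point charges with LJ parameters split into a receptor
    chain (A) and ligand molecules (B), plus oracle energies.

    The manifest stores per-frame Coulomb and LJ cross energies computed
    by a plain double loop with a brute-force 27-image search — the
    independent reference the vectorized energy module is tested against.
    """
    rng = np.random.default_rng(seed)
    n = n_receptor + n_ligand
    pos = np.empty((n_frames, n, 3))
    for t in range(n_frames):
        placed = 0
        attempts = 0
        while placed < n:
            cand = rng.uniform(0, box_edge, size=3)
            if placed:
                d = cand - pos[t, :placed]
                d -= box_edge * np.round(d / box_edge)
                if np.min(np.linalg.norm(d, axis=1)) < min_separation:
                    attempts += 1
                    if attempts > 1000 * n:
                        raise ValueError("could not place atoms with the requested separation")
                    continue
            pos[t, placed] = cand
            placed += 1

    charges = rng.uniform(-1.0, 1.0, size=n) * charge_scale
    sigmas = rng.uniform(2.5, 3.5, size=n) if with_lj else np.zeros(n)
    epsilons = rng.uniform(0.05, 0.2, size=n) if with_lj else np.zeros(n)

    atoms = []
    species = {}
    for i in range(n):
        rec = i < n_receptor
        atoms.append(
            AtomRecord(
                i, "C", "C",
                "A" if rec else "B",
                (i + 1) if rec else (i - n_receptor + 1),
                "RCP" if rec else "LIG",
                i,
                partial_charge=float(charges[i]),
                lj_sigma=float(sigmas[i]),
                lj_epsilon=float(epsilons[i]),
            )
        )
        species[i] = "other"
    top = Topology(atoms, species_labels=species)
    box = BoxSpec.cubic(box_edge)
    traj = Trajectory.from_arrays(pos, box, 0.1)

    # oracle double loop (constant dielectric, epsilon = 1)
    kq = 332.0636
    e_coul_frames, e_lj_frames = [], []
    for t in range(n_frames):
        ec = 0.0
        el = 0.0
        for i in range(n_receptor):
            for j in range(n_receptor, n):
                d = _oracle_min_image(pos[t, j] - pos[t, i], box_edge)
                r = math.sqrt(float(np.dot(d, d)))
                ec += kq * charges[i] * charges[j] / r
                sij = 0.5 * (sigmas[i] + sigmas[j])
                eij = math.sqrt(epsilons[i] * epsilons[j])
                sr6 = (sij / r) ** 6
                el += 4.0 * eij * (sr6 * sr6 - sr6)
        e_coul_frames.append(ec)
        e_lj_frames.append(el)

    manifest = {
        "kind": "charged",
        "seed": seed,
        "n_receptor": n_receptor,
        "n_ligand": n_ligand,
        "n_frames": n_frames,
        "box_edge_A": box_edge,
        "oracle_E_coulomb_kcal": e_coul_frames,
        "oracle_E_lj_kcal": e_lj_frames,
    }
    extras = {
        "receptor": Selection("receptor", np.arange(n_receptor)),
        "ligand": Selection("ligand", np.arange(n_receptor, n)),
    }
    return Scenario(top, traj, manifest, extras)
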