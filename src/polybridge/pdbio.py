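"""Plain-text PDB topology/trajectory I/O.

The interchange dialect is deliberately narrow: ATOM/HETATM/TER/CONECT/
MODEL/ENDMDL/CRYST1/END records, fixed columns, one CRYST1 box per file
(or per MODEL).  Multi-frame data are multi-MODEL files or concatenated
single-frame PDBs.  Coordinates round-trip to the PDB precision of
1e-3 Å.  Molecule partitioning follows the convention: a protein chain
(delimited by chain ID and TER) is one molecule; non-protein atoms are
grouped by residue, merged across residues by CONECT records.

Error reporting is line- and model-accurate so that malformed fixtures
fail loudly rather than silently misassign atoms.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np

from .core import (
    AtomRecord,
    BoxSpec,
    Frame,
    Selection,
    Topology,
    Trajectory,
    assign_donors_acceptors,
    infer_element,
)

logger = logging.getLogger(__name__)

AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    # phosphorylated residues
    "SEP", "TPO", "PTR", "HIP", "HID", "HIE",
}

#: residue-name -> species label; users may pass an extended copy
DEFAULT_SPECIES_MAP: dict[str, str] = {
    "HOH": "water", "WAT": "water", "TIP3": "water", "SOL": "water",
    "NA": "cation", "NA+": "cation", "SOD": "cation", "K": "cation", "K+": "cation",
    "POT": "cation", "MG": "cation", "ZN": "cation",
    "CL": "anion", "CL-": "anion", "CLA": "anion",
    "SPM": "polyamine", "SPD": "polyamine", "PUT": "polyamine",
}

H_BOND_MAX = 1.2    # Å, hydrogen to its parent heavy atom
HEAVY_BOND_MAX = 1.9  # Å, heavy-heavy within a residue


class PDBParseError(ValueError):
    pass


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def _parse_atom_line(line: str, lineno: int):
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        resname = line[17:21].strip()
        chain = line[21].strip() or "A"
        resseq = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        element = line[76:78].strip() if len(line) >= 78 else ""
    except (ValueError, IndexError) as exc:
        raise PDBParseError(f"malformed ATOM/HETATM record at line {lineno}: {line.rstrip()!r}") from exc
    return serial, name, resname, chain, resseq, (x, y, z), element


def _infer_residue_bonds(coords: np.ndarray, atoms: list[AtomRecord]) -> set[tuple[int, int]]:
    """Covalent-radius heuristic: H to nearest heavy atom within 1.2 Å,
    heavy-heavy pairs within 1.9 Å inside the same residue."""
    bonds: set[tuple[int, int]] = set()
    residues: dict[tuple, list[int]] = {}
    for a in atoms:
        key = (a.chain_id, a.residue_index, a.residue_name, a.molecule_id)
        residues.setdefault(key, []).append(a.atom_index)
    for idxs in residues.values():
        idx = np.array(idxs)
        heavy = idx[[atoms[i].is_heavy for i in idxs]]
        hydro = idx[[not atoms[i].is_heavy for i in idxs]]
        if len(heavy) >= 2:
            d = np.linalg.norm(coords[heavy][:, None] - coords[heavy][None, :], axis=-1)
            ii, jj = np.nonzero((d > 1e-6) & (d <= HEAVY_BOND_MAX))
            for a_, b_ in zip(heavy[ii], heavy[jj]):
                bonds.add((min(a_, b_), max(a_, b_)))
        if len(hydro) and len(heavy):
            d = np.linalg.norm(coords[hydro][:, None] - coords[heavy][None, :], axis=-1)
            nearest = np.argmin(d, axis=1)
            for row, h_i in enumerate(hydro):
                k = nearest[row]
                if d[row, k] <= H_BOND_MAX:
                    a_, b_ = heavy[k], h_i
                    bonds.add((min(a_, b_), max(a_, b_)))
    return bonds


def read_pdb_topology(
    path,
    param_table=None,
    species_map: Mapping[str, str] | None = None,
) -> Topology:
    """Read the first model of a PDB file into a :class:`Topology`.

    Chains are delimited by chain IDs and TER records; protein chains
    become single molecules, non-protein residues become molecules (merged
    by CONECT when present).  Donors/acceptors are assigned from bonds
    (CONECT plus an intra-residue distance heuristic).
    """
    smap = dict(DEFAULT_SPECIES_MAP)
    if species_map:
        smap.update(species_map)

    serial_to_idx: dict[int, int] = {}
    atoms_raw = []  # (serial, name, resname, chain, resseq, xyz, element, segment)
    conect_pairs: list[tuple[int, int]] = []
    segment = 0
    in_model = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                in_model += 1
                if in_model > 1:
                    break
            elif rec in ("ATOM  ", "HETATM"):
                serial, name, resname, chain, resseq, xyz, element = _parse_atom_line(line, lineno)
                if serial in serial_to_idx:
                    raise PDBParseError(f"duplicate atom serial {serial} at line {lineno}")
                serial_to_idx[serial] = len(atoms_raw)
                atoms_raw.append((serial, name, resname, chain, resseq, xyz, element, segment))
            elif rec.startswith("TER"):
                segment += 1
            elif rec == "ENDMDL":
                break
            elif rec == "CONECT":
                fields = line[6:].split()
                if len(fields) >= 2:
                    base = int(fields[0])
                    for other in fields[1:]:
                        conect_pairs.append((base, int(other)))
    if not atoms_raw:
        raise PDBParseError(f"no ATOM/HETATM records found in {path}")

    n = len(atoms_raw)
    coords = np.array([a[5] for a in atoms_raw], dtype=float)
    is_protein = np.array([a[2].upper() in AMINO_ACIDS for a in atoms_raw])

    # molecule partition via union-find
    uf = _UnionFind(n)
    by_chain_seg: dict[tuple, int] = {}
    by_residue: dict[tuple, int] = {}
    for i, (serial, name, resname, chain, resseq, xyz, element, seg) in enumerate(atoms_raw):
        if is_protein[i]:
            key = (chain, seg)
            if key in by_chain_seg:
                uf.union(by_chain_seg[key], i)
            else:
                by_chain_seg[key] = i
        else:
            key = (chain, seg, resseq, resname)
            if key in by_residue:
                uf.union(by_residue[key], i)
            else:
                by_residue[key] = i
    bonds_from_conect: set[tuple[int, int]] = set()
    for s1, s2 in conect_pairs:
        if s1 not in serial_to_idx or s2 not in serial_to_idx:
            raise PDBParseError(f"CONECT refers to unknown serial ({s1}, {s2})")
        i, j = serial_to_idx[s1], serial_to_idx[s2]
        if i != j:
            bonds_from_conect.add((min(i, j), max(i, j)))
            uf.union(i, j)

    roots = [uf.find(i) for i in range(n)]
    root_to_mol: dict[int, int] = {}
    mol_ids = []
    for r in roots:
        if r not in root_to_mol:
            root_to_mol[r] = len(root_to_mol)
        mol_ids.append(root_to_mol[r])

    atoms = []
    for i, (serial, name, resname, chain, resseq, xyz, element, seg) in enumerate(atoms_raw):
        atoms.append(
            AtomRecord(
                atom_index=i,
                atom_name=name,
                element=infer_element(name, element),
                chain_id=chain,
                residue_index=resseq,
                residue_name=resname,
                molecule_id=mol_ids[i],
            )
        )

    # species per molecule from residue names
    species: dict[int, str] = {}
    for i, a in enumerate(atoms):
        m = a.molecule_id
        if m in species:
            continue
        if is_protein[i]:
            species[m] = "protein_chain"
        else:
            species[m] = smap.get(a.residue_name.upper(), "other")

    bonds = bonds_from_conect | _infer_residue_bonds(coords, atoms)
    top = Topology(atoms, bonds=bonds, species_labels=species)
    if param_table is not None:
        top.set_parameters(param_table)
    return assign_donors_acceptors(top)


# ---------------------------------------------------------------------------
# trajectory reading
# ---------------------------------------------------------------------------

def _parse_cryst1(line: str, lineno: int) -> BoxSpec:
    try:
        a = float(line[6:15]); b = float(line[15:24]); c = float(line[24:33])
        al = float(line[33:40]); be = float(line[40:47]); ga = float(line[47:54])
    except ValueError as exc:
        raise PDBParseError(f"malformed CRYST1 record at line {lineno}") from exc
    return BoxSpec.from_lengths_angles(a, b, c, al, be, ga)


def read_trajectory(path, topology: Topology, dt_frame: float = 0.1) -> Trajectory:
    """Read a multi-MODEL PDB (or concatenated single-frame PDBs).

    Frame k is assigned time k * dt_frame.  Every model must contain
    exactly the topology's atom count; a mismatch raises an error naming
    the offending model index.
    """
    frames: list[Frame] = []
    box: BoxSpec | None = None
    current: list[tuple[float, float, float]] = []

    def close_frame() -> None:
        nonlocal current
        if not current:
            return
        if len(current) != topology.n_atoms:
            raise PDBParseError(
                f"model {len(frames)} has {len(current)} atoms, "
                f"topology has {topology.n_atoms}"
            )
        if box is None:
            raise PDBParseError("no CRYST1 record seen before coordinates")
        frames.append(Frame(np.array(current), box, len(frames) * dt_frame))
        current = []

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "CRYST1":
                box = _parse_cryst1(line, lineno)
            elif rec in ("ATOM  ", "HETATM"):
                _, _, _, _, _, xyz, _ = _parse_atom_line(line, lineno)
                current.append(xyz)
            elif rec in ("ENDMDL", "END   ") or line.strip() == "END":
                close_frame()
    close_frame()
    if not frames:
        raise PDBParseError(f"no coordinate frames found in {path}")
    return Trajectory(frames, dt_frame)


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def _format_atom_line(a: AtomRecord, xyz, hetatm: bool) -> str:
    rec = "HETATM" if hetatm else "ATOM  "
    name = a.atom_name
    if len(name) < 4:
        name = " " + name
    serial = (a.atom_index + 1) % 100000
    return (
        f"{rec}{serial:5d} {name:<4s} {a.residue_name:<4s}"
        f"{a.chain_id[:1]:1s}{a.residue_index % 10000:4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"          {a.element[:2]:>2s}\n"
    )


def _cryst1_line(box: BoxSpec) -> str:
    a, b, c, al, be, ga = box.lengths_angles
    return f"CRYST1{a:9.3f}{b:9.3f}{c:9.3f}{al:7.2f}{be:7.2f}{ga:7.2f} P 1           1\n"


def _topology_body(topology: Topology, coords: np.ndarray) -> list[str]:
    lines = []
    prev_mol = None
    prev_protein = False
    for a in topology.atoms:
        is_protein = topology.species_labels.get(a.molecule_id) == "protein_chain"
        if prev_mol is not None and a.molecule_id != prev_mol and prev_protein:
            lines.append("TER\n")
        lines.append(_format_atom_line(a, coords[a.atom_index], hetatm=not is_protein))
        prev_mol, prev_protein = a.molecule_id, is_protein
    if prev_protein:
        lines.append("TER\n")
    return lines


def _conect_lines(topology: Topology) -> list[str]:
    """CONECT records for bonds inside non-protein molecules."""
    neigh: dict[int, list[int]] = {}
    for i, j in sorted(topology.bonds):
        if topology.species_labels.get(topology.atoms[i].molecule_id) == "protein_chain":
            continue
        neigh.setdefault(i, []).append(j)
        neigh.setdefault(j, []).append(i)
    lines = []
    for i in sorted(neigh):
        partners = sorted(neigh[i])
        for k in range(0, len(partners), 4):
            chunk = partners[k : k + 4]
            lines.append(
                "CONECT" + f"{i + 1:5d}" + "".join(f"{p + 1:5d}" for p in chunk) + "\n"
            )
    return lines


def write_pdb_topology(path, topology: Topology, coordinates: np.ndarray, box: BoxSpec) -> None:
    """Write a single-model PDB with CONECT records for non-protein bonds."""
    coords = np.asarray(coordinates, dtype=float)
    if coords.shape != (topology.n_atoms, 3):
        raise ValueError("coordinates shape does not match topology")
    with open(path, "w") as fh:
        fh.write(_cryst1_line(box))
        fh.writelines(_topology_body(topology, coords))
        fh.writelines(_conect_lines(topology))
        fh.write("END\n")


def write_trajectory(path, trajectory: Trajectory, topology: Topology) -> None:
    """Write a multi-MODEL PDB trajectory."""
    if trajectory.n_atoms != topology.n_atoms:
        raise ValueError("trajectory atom count does not match topology")
    with open(path, "w") as fh:
        fh.write(_cryst1_line(trajectory.frames[0].box))
        for k, frame in enumerate(trajectory.frames, start=1):
            fh.write(f"MODEL     {k:4d}\n")
            fh.writelines(_topology_body(topology, frame.coordinates))
            fh.write("ENDMDL\n")
        fh.write("END\n")


def write_parameter_table(path, topology: Topology) -> None:
    """Write the whitespace-separated charge/LJ sidecar table."""
    with open(path, "w") as fh:
        fh.write("# atom_index charge_e sigma_A epsilon_kcal\n")
        for a in topology.atoms:
            q = 0.0 if a.partial_charge is None else a.partial_charge
            s = 0.0 if a.lj_sigma is None else a.lj_sigma
            e = 0.0 if a.lj_epsilon is None else a.lj_epsilon
            fh.write(f"{a.atom_index} {q:.6f} {s:.6f} {e:.6f}\n")
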