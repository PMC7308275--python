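"""Core data model for periodic molecular systems.

Atoms are grouped into molecules (one protein chain = one molecule; one
solvent/ion/polyamine residue or bonded component = one molecule).  All
coordinates are in Angstrom, times in nanoseconds, charges in elementary
charge units.  Periodic cells are general triclinic; the truncated
octahedron used in typical condensed-phase simulations is handled through
its triclinic representation.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: elements eligible as hydrogen-bond donors/acceptors
POLAR_ELEMENTS = frozenset({"N", "O", "S"})

# the 27 integer lattice shifts used for exhaustive image searches
_SHIFTS27 = np.array(
    [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)],
    dtype=float,
)


# ---------------------------------------------------------------------------
# periodic box
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BoxSpec:
    """A triclinic periodic cell given by three lattice vectors (rows, Å)."""

    vectors: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vectors, dtype=float)
        if v.shape != (3, 3):
            raise ValueError(f"box vectors must be 3x3, got shape {v.shape}")
        object.__setattr__(self, "vectors", v)
        if self.volume <= 0:
            raise ValueError("box vectors are not linearly independent (volume <= 0)")

    @classmethod
    def cubic(cls, edge: float) -> "BoxSpec":
        return cls(np.eye(3) * float(edge))

    @classmethod
    def from_lengths_angles(
        cls, a: float, b: float, c: float, alpha: float, beta: float, gamma: float
    ) -> "BoxSpec":
        """Build lattice vectors from lengths (Å) and angles (degrees)."""
        al, be, ga = np.radians([alpha, beta, gamma])
        av = np.array([a, 0.0, 0.0])
        bv = np.array([b * np.cos(ga), b * np.sin(ga), 0.0])
        cx = c * np.cos(be)
        cy = c * (np.cos(al) - np.cos(be) * np.cos(ga)) / np.sin(ga)
        cz_sq = c * c - cx * cx - cy * cy
        if cz_sq <= 0:
            raise ValueError("degenerate cell angles")
        cv = np.array([cx, cy, np.sqrt(cz_sq)])
        return cls(np.array([av, bv, cv]))

    @property
    def volume(self) -> float:
        return float(abs(np.linalg.det(np.asarray(self.vectors))))

    @property
    def lengths_angles(self) -> tuple[float, float, float, float, float, float]:
        v = self.vectors
        a, b, c = (np.linalg.norm(v[i]) for i in range(3))

        def ang(x, y):
            return float(np.degrees(np.arccos(np.dot(x, y) / (np.linalg.norm(x) * np.linalg.norm(y)))))

        return (float(a), float(b), float(c), ang(v[1], v[2]), ang(v[0], v[2]), ang(v[0], v[1]))

    @property
    def min_height(self) -> float:
        """Smallest perpendicular distance between opposite cell faces (Å)."""
        v = self.vectors
        vol = self.volume
        heights = []
        for i in range(3):
            j, k = (i + 1) % 3, (i + 2) % 3
            area = np.linalg.norm(np.cross(v[j], v[k]))
            heights.append(vol / area)
        return float(min(heights))

    @property
    def is_orthorhombic(self) -> bool:
        v = self.vectors
        off = v - np.diag(np.diag(v))
        return bool(np.all(np.abs(off) < 1e-9 * max(1.0, np.abs(v).max())))


def check_cutoff(box: BoxSpec, cutoff: float) -> None:
    """Reject cutoffs for which the single-image convention is ambiguous."""
    if cutoff + 1e-9 >= 0.5 * box.min_height:
        raise ValueError(
            f"cutoff {cutoff:g} Å >= half the minimal box height "
            f"({0.5 * box.min_height:g} Å); minimum-image distances would be ambiguous"
        )


def minimum_image_displacement(a, b, box: BoxSpec) -> np.ndarray:
    """Displacement b - a mapped to the nearest periodic image.

    Accepts arrays with arbitrary leading shape broadcastable over the last
    axis of length 3.  For orthorhombic cells fractional rounding is exact;
    for skewed cells the rounded image is refined over the 27 neighbor
    cells, which is sufficient whenever distances of interest are below
    half the minimal box height (enforced by :func:`check_cutoff` at call
    sites that take a cutoff).
    """
    d = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
    h = np.asarray(box.vectors)
    hinv = np.linalg.inv(h)
    frac = d @ hinv
    frac = frac - np.round(frac)
    base = frac @ h
    if box.is_orthorhombic:
        return base
    shifts = _SHIFTS27 @ h  # (27, 3)
    cand = base[..., None, :] + shifts
    norms = np.einsum("...ij,...ij->...i", cand, cand)
    idx = np.argmin(norms, axis=-1)
    return np.take_along_axis(cand, idx[..., None, None], axis=-2)[..., 0, :]


def minimum_image_distance(a, b, box: BoxSpec) -> np.ndarray:
    d = minimum_image_displacement(a, b, box)
    return np.sqrt(np.einsum("...i,...i->...", d, d))


def wrap_coordinates(coords: np.ndarray, box: BoxSpec) -> np.ndarray:
    """Wrap cartesian coordinates into the primary cell."""
    h = np.asarray(box.vectors)
    frac = np.asarray(coords, float) @ np.linalg.inv(h)
    return (frac - np.floor(frac)) @ h


# ---------------------------------------------------------------------------
# atoms / topology
# ---------------------------------------------------------------------------

@dataclass
class AtomRecord:
    """One atom of the system; indices are 0-based and contiguous."""

    atom_index: int
    atom_name: str
    element: str
    chain_id: str
    residue_index: int
    residue_name: str
    molecule_id: int
    partial_charge: float | None = None
    lj_sigma: float | None = None
    lj_epsilon: float | None = None

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"


def infer_element(atom_name: str, element_field: str = "") -> str:
    """Element from the PDB element column, else from leading letters of the name."""
    e = element_field.strip()
    if e:
        return e[0].upper() + e[1:].lower()
    name = atom_name.strip()
    # strip leading digits (e.g. 1HG1)
    stripped = name.lstrip("0123456789")
    if not stripped:
        return ""
    # bare two-letter ion names; CA/FE are left out (they collide with
    # alpha-carbon / iron-free naming in protein records — use the element
    # column for those)
    two = stripped[:2].upper()
    if two in {"CL", "NA", "MG", "ZN", "BR"} and len(name) <= 2:
        return two[0] + two[1].lower()
    return stripped[0].upper()


class Topology:
    """Atoms plus bonding, molecule partition, species labels and H-bond roles.

    ``species_labels`` maps molecule_id to one of ``protein_chain``,
    ``water``, ``cation``, ``anion``, ``polyamine`` or ``other``.
    """

    def __init__(
        self,
        atoms: Sequence[AtomRecord],
        bonds: Iterable[tuple[int, int]] = (),
        species_labels: Mapping[int, str] | None = None,
    ) -> None:
        self.atoms: list[AtomRecord] = list(atoms)
        for k, a in enumerate(self.atoms):
            if a.atom_index != k:
                raise ValueError(
                    f"atom indices must be contiguous from 0; atom {k} has index {a.atom_index}"
                )
        self.bonds: set[tuple[int, int]] = set()
        n = len(self.atoms)
        for i, j in bonds:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise ValueError(f"invalid bond ({i}, {j})")
            self.bonds.add((min(i, j), max(i, j)))
        self.species_labels: dict[int, str] = dict(species_labels or {})
        self.donors: dict[int, list[int]] = {}
        self.acceptors: set[int] = set()
        self._rebuild_arrays()
        missing = set(self.molecule_ids.tolist()) - set(self.species_labels)
        for m in sorted(missing):
            self.species_labels[m] = "other"

    def _rebuild_arrays(self) -> None:
        at = self.atoms
        self.elements = np.array([a.element for a in at], dtype=object)
        self.atom_names = np.array([a.atom_name for a in at], dtype=object)
        self.chain_ids = np.array([a.chain_id for a in at], dtype=object)
        self.residue_indices = np.array([a.residue_index for a in at], dtype=int)
        self.residue_names = np.array([a.residue_name for a in at], dtype=object)
        self.molecule_ids = np.array([a.molecule_id for a in at], dtype=int)
        self.heavy_mask = np.array([a.is_heavy for a in at], dtype=bool)
        self.charges = np.array(
            [np.nan if a.partial_charge is None else a.partial_charge for a in at], dtype=float
        )
        self.lj_sigma = np.array(
            [np.nan if a.lj_sigma is None else a.lj_sigma for a in at], dtype=float
        )
        self.lj_epsilon = np.array(
            [np.nan if a.lj_epsilon is None else a.lj_epsilon for a in at], dtype=float
        )
        mol_atoms: dict[int, list[int]] = defaultdict(list)
        for k, m in enumerate(self.molecule_ids):
            mol_atoms[int(m)].append(k)
        self._mol_atoms = {m: np.array(v, dtype=int) for m, v in mol_atoms.items()}

    # -- queries ------------------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def molecule_list(self) -> list[int]:
        return sorted(self._mol_atoms)

    def atoms_of_molecule(self, molecule_id: int) -> np.ndarray:
        return self._mol_atoms[int(molecule_id)]

    def molecules_of_species(self, labels: Iterable[str]) -> list[int]:
        want = set(labels)
        return [m for m in self.molecule_list if self.species_labels.get(m) in want]

    def chain_of_molecule(self, molecule_id: int) -> str:
        chains = set(self.chain_ids[self.atoms_of_molecule(molecule_id)])
        if len(chains) != 1:
            raise ValueError(f"molecule {molecule_id} spans chains {sorted(chains)}")
        return chains.pop()

    def protein_chain_ids(self) -> list[str]:
        out = []
        for m in self.molecules_of_species(["protein_chain"]):
            out.append(self.chain_of_molecule(m))
        return sorted(set(out))

    def bonded_hydrogens(self) -> dict[int, list[int]]:
        """Map heavy-atom index -> bonded hydrogen indices."""
        out: dict[int, list[int]] = defaultdict(list)
        for i, j in self.bonds:
            hi, hj = self.atoms[i].is_heavy, self.atoms[j].is_heavy
            if hi and not hj:
                out[i].append(j)
            elif hj and not hi:
                out[j].append(i)
        return {k: sorted(v) for k, v in out.items()}

    def set_parameters(self, table) -> None:
        """Attach partial charges and LJ parameters from a sidecar table.

        ``table`` is a pandas DataFrame or a path to a whitespace-separated
        file with columns atom_index, charge_e, sigma_A, epsilon_kcal.
        """
        import pandas as pd

        if not hasattr(table, "columns"):
            table = pd.read_csv(
                table,
                sep=r"\s+",
                comment="#",
                names=["atom_index", "charge_e", "sigma_A", "epsilon_kcal"],
                header=None,
            )
        for row in table.itertuples(index=False):
            idx = int(row.atom_index)
            if not 0 <= idx < self.n_atoms:
                raise ValueError(f"parameter table refers to unknown atom index {idx}")
            a = self.atoms[idx]
            a.partial_charge = float(row.charge_e)
            a.lj_sigma = float(row.sigma_A)
            a.lj_epsilon = float(row.epsilon_kcal)
        self._rebuild_arrays()


def assign_donors_acceptors(topology: Topology) -> Topology:
    """Annotate hydrogen-bond donors and acceptors in place (idempotent).

    Donors are N/O/S heavy atoms with at least one covalently bonded
    hydrogen; acceptors are all N/O/S heavy atoms (this includes bare
    phosphate oxygens, which carry no hydrogens and are acceptors only).
    Atoms with an unrecognized element are skipped with a warning.
    """
    bonded_h = topology.bonded_hydrogens()
    donors: dict[int, list[int]] = {}
    acceptors: set[int] = set()
    warned = False
    for a in topology.atoms:
        el = a.element.upper()
        if not el:
            if not warned:
                logger.warning("atoms with unknown element excluded from donor/acceptor roles")
                warned = True
            continue
        if el in POLAR_ELEMENTS:
            acceptors.add(a.atom_index)
            hs = bonded_h.get(a.atom_index, [])
            if hs:
                donors[a.atom_index] = hs
    topology.donors = donors
    topology.acceptors = acceptors
    return topology


# ---------------------------------------------------------------------------
# frames / trajectory
# ---------------------------------------------------------------------------

@dataclass
class Frame:
    coordinates: np.ndarray  # (n_atoms, 3) Å
    box: BoxSpec
    time: float  # ns

    def __post_init__(self) -> None:
        c = np.asarray(self.coordinates, dtype=float)
        if c.ndim != 2 or c.shape[1] != 3:
            raise ValueError(f"coordinates must be (n, 3); got {c.shape}")
        self.coordinates = c


class Trajectory:
    """Uniformly spaced frames; ``dt_frame`` is the spacing in ns."""

    def __init__(self, frames: Sequence[Frame], dt_frame: float = 0.1) -> None:
        if not frames:
            raise ValueError("trajectory has no frames")
        self.frames = list(frames)
        self.dt_frame = float(dt_frame)
        n0 = self.frames[0].coordinates.shape[0]
        for k, f in enumerate(self.frames):
            if f.coordinates.shape[0] != n0:
                raise ValueError(f"frame {k} has {f.coordinates.shape[0]} atoms, expected {n0}")
        times = np.array([f.time for f in self.frames])
        if len(times) > 1:
            steps = np.diff(times)
            if np.any(steps <= 0) or np.any(np.abs(steps - self.dt_frame) > 1e-9):
                raise ValueError("frame times must increase by dt_frame (within 1e-9 ns)")

    @classmethod
    def from_arrays(cls, coords: np.ndarray, box: BoxSpec, dt_frame: float = 0.1) -> "Trajectory":
        coords = np.asarray(coords, dtype=float)
        if coords.ndim != 3:
            raise ValueError("coords must be (n_frames, n_atoms, 3)")
        frames = [Frame(coords[k], box, k * dt_frame) for k in range(coords.shape[0])]
        return cls(frames, dt_frame)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_atoms(self) -> int:
        return self.frames[0].coordinates.shape[0]

    @property
    def coords(self) -> np.ndarray:
        """All coordinates stacked as (n_frames, n_atoms, 3)."""
        return np.stack([f.coordinates for f in self.frames])

    @property
    def duration(self) -> float:
        """Time spanned measured in saved intervals: n_frames * dt_frame (ns)."""
        return self.n_frames * self.dt_frame

    def __len__(self) -> int:
        return self.n_frames

    def __getitem__(self, k: int) -> Frame:
        return self.frames[k]

    def sub(self, start: int, stop: int) -> "Trajectory":
        """Contiguous sub-trajectory over frames [start, stop)."""
        if not 0 <= start < stop <= self.n_frames:
            raise ValueError(f"invalid frame range [{start}, {stop})")
        return Trajectory(self.frames[start:stop], self.dt_frame)


def n_frames_for_duration(duration_ns: float, dt_frame: float) -> int:
    """Number of saved frames for a production run of the given length.

    A run of 1000 ns sampled every 0.1 ns yields 10,000 frames.
    """
    if dt_frame <= 0:
        raise ValueError("dt_frame must be positive")
    n = duration_ns / dt_frame
    r = round(n)
    if abs(n - r) > 1e-6:
        raise ValueError(f"duration {duration_ns} ns is not a multiple of dt {dt_frame} ns")
    return int(r)


# ---------------------------------------------------------------------------
# selections
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Selection:
    """A named, ordered, duplicate-free set of atom indices."""

    name: str
    atom_indices: np.ndarray

    def __post_init__(self) -> None:
        idx = np.asarray(self.atom_indices, dtype=int)
        if idx.ndim != 1:
            raise ValueError("atom_indices must be 1-D")
        if len(np.unique(idx)) != len(idx):
            raise ValueError(f"selection {self.name!r} contains duplicate indices")
        object.__setattr__(self, "atom_indices", idx)

    def __len__(self) -> int:
        return len(self.atom_indices)


def select(
    topology: Topology,
    *,
    species: Iterable[str] | None = None,
    chains: Iterable[str] | None = None,
    elements: Iterable[str] | None = None,
    molecule_ids: Iterable[int] | None = None,
    heavy_only: bool = False,
    name: str = "selection",
) -> Selection:
    """Build a Selection by intersecting species/chain/element criteria."""
    mask = np.ones(topology.n_atoms, dtype=bool)
    if species is not None:
        mols = set(topology.molecules_of_species(species))
        mask &= np.isin(topology.molecule_ids, list(mols))
    if chains is not None:
        mask &= np.isin(topology.chain_ids, list(chains))
    if elements is not None:
        want = {e.upper() for e in elements}
        mask &= np.array([e.upper() in want for e in topology.elements])
    if molecule_ids is not None:
        mask &= np.isin(topology.molecule_ids, list(molecule_ids))
    if heavy_only:
        mask &= topology.heavy_mask
    idx = np.nonzero(mask)[0]
    if len(idx) == 0:
        raise ValueError(f"selection {name!r} matched no atoms")
    return Selection(name, idx)
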