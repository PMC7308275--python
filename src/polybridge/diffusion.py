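"""Mean-squared displacement and Einstein-relation diffusion coefficients.

The MSD is computed over molecule centers of geometry from an unwrapped
trajectory, averaging over molecules and multiple time origins.  The
three-dimensional Einstein relation gives D = slope/6, with the slope of
MSD versus lag time taken by least squares over a configurable window
(default 10-50% of the maximum lag, excluding the short-lag ballistic/
noise region and the poorly sampled long-lag tail).  Unit bookkeeping:
slopes are in Å²/ns; 1 Å²/ns = 1e-7 cm²/s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .core import Topology, Trajectory, Frame, minimum_image_displacement

__all__ = [
    "MSDResult",
    "DiffusionEstimate",
    "unwrap_trajectory",
    "molecule_centers",
    "compute_msd",
    "fit_diffusion",
    "block_diffusion",
]

A2_PER_NS_TO_CM2_PER_S = 1e-7


def molecule_centers(
    trajectory: Trajectory, topology: Topology, molecule_ids: Sequence[int]
) -> np.ndarray:
    """Centers of geometry, shape (n_frames, n_molecules, 3)."""
    groups = [topology.atoms_of_molecule(m) for m in molecule_ids]
    coords = trajectory.coords
    return np.stack([coords[:, g, :].mean(axis=1) for g in groups], axis=1)


def unwrap_trajectory(trajectory: Trajectory, topology: Topology) -> Trajectory:
    """Make per-molecule center-of-geometry paths continuous.

    For every molecule the lattice translation minimizing each
    consecutive-frame jump of its center is accumulated and applied to
    all its atoms.  Requires every such jump to be below half the
    minimal box height; larger jumps are ambiguous and raise, suggesting
    a finer saving interval.
    """
    mols = topology.molecule_list
    cogs = molecule_centers(trajectory, topology, mols)
    box = trajectory.frames[0].box
    half = 0.5 * box.min_height
    n_frames = trajectory.n_frames
    shifts = np.zeros((n_frames, len(mols), 3))
    for t in range(1, n_frames):
        raw = cogs[t] - cogs[t - 1]
        wrapped = minimum_image_displacement(np.zeros(3), raw, trajectory.frames[t].box)
        jump = np.linalg.norm(wrapped, axis=1)
        if np.any(jump >= half * (1 - 1e-9)):
            worst = int(np.argmax(jump))
            raise ValueError(
                f"molecule {mols[worst]} moves {jump[worst]:.2f} Å between frames "
                f"{t-1} and {t}, at least half the box height; image assignment is "
                "ambiguous — use a finer saving interval"
            )
        shifts[t] = shifts[t - 1] + (wrapped - raw)

    atom_shift = np.zeros((n_frames, trajectory.n_atoms, 3))
    for k, m in enumerate(mols):
        atom_shift[:, topology.atoms_of_molecule(m), :] = shifts[:, k : k + 1, :]
    new_frames = [
        Frame(f.coordinates + atom_shift[t], f.box, f.time)
        for t, f in enumerate(trajectory.frames)
    ]
    return Trajectory(new_frames, trajectory.dt_frame)


@dataclass
class MSDResult:
    lag_times: np.ndarray  # ns
    msd: np.ndarray        # Å²
    selection_name: str
    n_origins: int         # origins used at the largest lag
    n_molecules: int


def compute_msd(
    trajectory: Trajectory,
    topology: Topology,
    molecule_ids: Sequence[int],
    origin_stride: int = 10,
    max_lag_fraction: float = 0.5,
    selection_name: str = "selection",
) -> MSDResult:
    """MSD of molecule centers over lags up to ``max_lag_fraction`` of the
    trajectory, averaged over time origins spaced ``origin_stride`` frames.

    The input must already be unwrapped.  ``origin_stride`` equal to the
    trajectory length reproduces single-origin behavior.
    """
    if len(molecule_ids) == 0:
        raise ValueError("empty molecule selection")
    cogs = molecule_centers(trajectory, topology, molecule_ids)
    n_frames = cogs.shape[0]
    max_lag = max(1, int(np.floor(n_frames * max_lag_fraction)))
    stride = max(1, int(origin_stride))
    msd = np.zeros(max_lag + 1)
    n_origins_last = 0
    for lag in range(1, max_lag + 1):
        origins = np.arange(0, n_frames - lag, stride)
        disp = cogs[origins + lag] - cogs[origins]
        msd[lag] = float(np.mean(np.einsum("omk,omk->om", disp, disp)))
        n_origins_last = len(origins)
    lags = np.arange(max_lag + 1) * trajectory.dt_frame
    return MSDResult(lags, msd, selection_name, n_origins_last, cogs.shape[1])


@dataclass
class DiffusionEstimate:
    D: float               # cm²/s
    slope: float           # Å²/ns
    slope_stderr: float    # Å²/ns
    fit_range: tuple[float, float]  # ns
    block_label: str

    @property
    def D_1e5(self) -> float:
        """D in units of 1e-5 cm²/s, the conventional reporting scale."""
        return self.D / 1e-5

    @property
    def D_stderr(self) -> float:
        return self.slope_stderr / 6.0 * A2_PER_NS_TO_CM2_PER_S


def fit_diffusion(
    msd: MSDResult,
    fit_window: tuple[float, float] = (0.05, 0.25),
    block_label: str = "all",
) -> DiffusionEstimate:
    """Least-squares slope of MSD vs lag over the window (fractions of the
    maximum lag); D = slope/6 converted to cm²/s.

    A negative fitted slope (possible for confined species at short
    trajectories) is reported as-is with a warning.

    The default window spans 5-25% of the maximum lag: below ~5% the MSD
    is dominated by short-time noise, while beyond ~25% each molecule
    contributes only a handful of independent displacement intervals and
    the per-lag variance grows roughly linearly with lag, inflating the
    variance of the fitted slope severalfold.
    """
    max_lag = msd.lag_times[-1]
    lo, hi = fit_window[0] * max_lag, fit_window[1] * max_lag
    mask = (msd.lag_times >= lo) & (msd.lag_times <= hi)
    if mask.sum() < 5:
        raise ValueError(f"fit window [{lo:g}, {hi:g}] ns contains fewer than 5 lag points")
    res = stats.linregress(msd.lag_times[mask], msd.msd[mask])
    if res.slope < 0:
        warnings.warn("negative MSD slope; D reported as fitted (likely confined species)")
    d = res.slope / 6.0 * A2_PER_NS_TO_CM2_PER_S
    return DiffusionEstimate(
        float(d), float(res.slope), float(res.stderr), (float(lo), float(hi)), block_label
    )


def block_diffusion(
    trajectory: Trajectory,
    topology: Topology,
    molecule_ids: Sequence[int],
    n_blocks: int = 4,
    origin_stride: int = 10,
    max_lag_fraction: float = 0.5,
    fit_window: tuple[float, float] = (0.05, 0.25),
    unwrap: bool = True,
) -> list[DiffusionEstimate]:
    """Diffusion estimates from contiguous equal-length time blocks.

    The full trajectory is unwrapped once, then split, so block
    boundaries do not introduce artificial jumps.
    """
    nf = trajectory.n_frames
    if n_blocks < 1 or n_blocks > nf:
        raise ValueError(f"n_blocks={n_blocks} invalid for {nf} frames")
    traj = unwrap_trajectory(trajectory, topology) if unwrap else trajectory
    size = nf // n_blocks
    out = []
    for k in range(n_blocks):
        start = k * size
        stop = (k + 1) * size if k < n_blocks - 1 else nf
        sub = traj.sub(start, stop)
        t0, t1 = sub.frames[0].time, sub.frames[-1].time + traj.dt_frame
        label = f"{t0:g}-{t1:g} ns"
        msd = compute_msd(
            sub, topology, molecule_ids, origin_stride, max_lag_fraction
        )
        out.append(fit_diffusion(msd, fit_window, block_label=label))
    return out
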