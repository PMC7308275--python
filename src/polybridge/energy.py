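"""Receptor-ligand molecular-mechanics interaction enthalpy and its
per-residue decomposition.

The interaction enthalpy proxy is the gas-phase MM cross term between two
disjoint atom selections, summed pairwise over minimum-image distances
with no cutoff (desk-scale systems):

    ΔH_frame = Σ_ij [ 332.0636 q_i q_j / (ε r_ij)
                      + 4 ε_ij ((σ_ij/r_ij)^12 − (σ_ij/r_ij)^6) ]

with Lorentz-Berthelot combination (arithmetic σ, geometric ε) and the
Coulomb constant in kcal·Å/(mol·e²).  An optional distance-dependent
dielectric ε(r) = r serves as a crude solvent-screening surrogate; no
generalized-Born or SASA solvation terms are computed.  Per-residue
attribution assigns half of each pair energy to the residue of each
partner, which conserves the total exactly.  Negative values are
favorable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import Selection, Topology, Trajectory, minimum_image_displacement

__all__ = [
    "COULOMB_CONSTANT",
    "EnergyTerms",
    "interaction_enthalpy",
    "per_residue_decomposition",
    "enthalpy_timeseries_report",
]

COULOMB_CONSTANT = 332.0636  # kcal·Å/(mol·e²)


@dataclass(frozen=True)
class EnergyTerms:
    frame: int
    E_coulomb: float  # kcal/mol
    E_lj: float       # kcal/mol

    @property
    def E_total(self) -> float:
        return self.E_coulomb + self.E_lj


def _check_selections(topology: Topology, receptor: Selection, ligand: Selection) -> None:
    if set(receptor.atom_indices) & set(ligand.atom_indices):
        raise ValueError("receptor and ligand selections overlap")
    for sel in (receptor, ligand):
        missing = sel.atom_indices[np.isnan(topology.charges[sel.atom_indices])]
        if len(missing):
            raise ValueError(
                f"missing partial charges for atoms {missing.tolist()} in selection {sel.name!r}"
            )


def _pair_energies(coords, box, topology, rec_idx, lig_idx, dielectric, epsilon):
    """Coulomb and LJ pair-energy matrices, shape (n_rec, n_lig)."""
    d = minimum_image_displacement(
        coords[rec_idx][:, None, :], coords[lig_idx][None, :, :], box
    )
    r = np.sqrt(np.einsum("ijk,ijk->ij", d, d))
    q = topology.charges
    qq = COULOMB_CONSTANT * np.outer(q[rec_idx], q[lig_idx])
    if dielectric == "r":
        e_coul = qq / (r * r)
    elif dielectric == "constant":
        e_coul = qq / (epsilon * r)
    else:
        raise ValueError(f"unknown dielectric model {dielectric!r}")
    sig = topology.lj_sigma
    eps = topology.lj_epsilon
    sig_ij = 0.5 * (sig[rec_idx][:, None] + sig[lig_idx][None, :])
    eps_ij = np.sqrt(eps[rec_idx][:, None] * eps[lig_idx][None, :])
    with np.errstate(invalid="ignore"):
        sr6 = (sig_ij / r) ** 6
        e_lj = 4.0 * eps_ij * (sr6 * sr6 - sr6)
    e_lj = np.nan_to_num(e_lj, nan=0.0)  # atoms without LJ parameters contribute nothing
    return e_coul, e_lj


def interaction_enthalpy(
    trajectory: Trajectory,
    topology: Topology,
    receptor: Selection,
    ligand: Selection,
    dielectric: str = "constant",
    epsilon: float = 1.0,
) -> list[EnergyTerms]:
    """Per-frame Coulomb + Lennard-Jones cross energy between the two
    selections, by direct pairwise summation (no cutoff)."""
    _check_selections(topology, receptor, ligand)
    out = []
    for k, frame in enumerate(trajectory.frames):
        e_coul, e_lj = _pair_energies(
            frame.coordinates, frame.box, topology,
            receptor.atom_indices, ligand.atom_indices, dielectric, epsilon,
        )
        out.append(EnergyTerms(k, float(e_coul.sum()), float(e_lj.sum())))
    return out


def per_residue_decomposition(
    trajectory: Trajectory,
    topology: Topology,
    receptor: Selection,
    ligand: Selection,
    dielectric: str = "constant",
    epsilon: float = 1.0,
) -> pd.DataFrame:
    """Mean per-residue contribution to the interaction enthalpy.

    Each pair energy is split half to its receptor residue and half to
    its ligand residue, every frame; residue values are then averaged
    over frames.  The sum over all residues therefore equals the mean
    total energy exactly (to floating-point roundoff).  Returns a
    DataFrame with columns chain, residue_index, residue_name, side,
    mean_energy_kcal, sorted most favorable (most negative) first.
    """
    _check_selections(topology, receptor, ligand)

    def residue_codes(sel):
        keys = [
            (topology.chain_ids[i], int(topology.residue_indices[i]), topology.residue_names[i])
            for i in sel.atom_indices
        ]
        uniq = sorted(set(keys))
        lut = {k: n for n, k in enumerate(uniq)}
        return np.array([lut[k] for k in keys]), uniq

    rec_codes, rec_keys = residue_codes(receptor)
    lig_codes, lig_keys = residue_codes(ligand)
    acc_rec = np.zeros(len(rec_keys))
    acc_lig = np.zeros(len(lig_keys))
    for frame in trajectory.frames:
        e_coul, e_lj = _pair_energies(
            frame.coordinates, frame.box, topology,
            receptor.atom_indices, ligand.atom_indices, dielectric, epsilon,
        )
        e = e_coul + e_lj
        np.add.at(acc_rec, rec_codes, 0.5 * e.sum(axis=1))
        np.add.at(acc_lig, lig_codes, 0.5 * e.sum(axis=0))
    nf = trajectory.n_frames
    rows = []
    for keys, acc, side in ((rec_keys, acc_rec, "receptor"), (lig_keys, acc_lig, "ligand")):
        for (chain, resid, resname), val in zip(keys, acc / nf):
            rows.append(
                {
                    "chain": chain,
                    "residue_index": resid,
                    "residue_name": resname,
                    "side": side,
                    "mean_energy_kcal": float(val),
                }
            )
    return pd.DataFrame(rows).sort_values("mean_energy_kcal").reset_index(drop=True)


@dataclass
class TimeseriesReport:
    table: pd.DataFrame      # frame, E_total, running_mean, running_std
    plateaus_near_zero: bool
    strongly_negative: bool
    last_window_mean: float
    zero_tolerance: float
    negative_threshold: float


def enthalpy_timeseries_report(
    terms: Sequence[EnergyTerms],
    window: int = 100,
    zero_tolerance: float = 5.0,
    negative_threshold: float = -50.0,
) -> TimeseriesReport:
    """Running statistics of the enthalpy series and two behavioral flags.

    ``plateaus_near_zero`` — mean of the final ``window`` frames within
    ``zero_tolerance`` kcal/mol of zero (the dissociated regime);
    ``strongly_negative`` — that mean below ``negative_threshold``
    kcal/mol (the tightly bound regime).  Both thresholds are user
    parameters; the defaults suit the toy systems in this package.
    """
    if len(terms) < window:
        raise ValueError(f"need at least window={window} frames, got {len(terms)}")
    totals = np.array([t.E_total for t in terms])
    s = pd.Series(totals)
    table = pd.DataFrame(
        {
            "frame": np.arange(len(totals)),
            "E_total": totals,
            "running_mean": s.rolling(window, min_periods=1).mean().to_numpy(),
            "running_std": s.rolling(window, min_periods=1).std().to_numpy(),
        }
    )
    last_mean = float(totals[-window:].mean())
    return TimeseriesReport(
        table,
        plateaus_near_zero=abs(last_mean) <= zero_tolerance,
        strongly_negative=last_mean <= negative_threshold,
        last_window_mean=last_mean,
        zero_tolerance=zero_tolerance,
        negative_threshold=negative_threshold,
    )
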