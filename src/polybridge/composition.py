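"""Formal-charge and concentration bookkeeping for system design.

Side-chain charges at pH 7: Lys/Arg +1, Glu/Asp −1; a phosphosite adds
−2 by default (fully deprotonated phosphate; configurable to −1).
Termini are treated as jointly neutral (the zwitterion cancels) unless
accounted for separately by the caller.  Spermine carries +4 and
spermidine +3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.constants import Avogadro

__all__ = [
    "ChargeLedger",
    "NeutralizationResult",
    "chain_net_charge",
    "neutralizing_count",
    "molar_concentration",
    "SPERMINE_CHARGE",
    "SPERMIDINE_CHARGE",
]

SPERMINE_CHARGE = 4
SPERMIDINE_CHARGE = 3


@dataclass(frozen=True)
class ChargeLedger:
    """Charged-residue counts for one protein chain."""

    n_lys: int = 0
    n_arg: int = 0
    n_glu: int = 0
    n_asp: int = 0
    n_phosphosites: int = 0
    phosphosite_charge: int = -2

    def __post_init__(self):
        for name in ("n_lys", "n_arg", "n_glu", "n_asp", "n_phosphosites"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def chain_net_charge(ledger: ChargeLedger, phosphorylated: bool = False) -> int:
    """Net side-chain charge of one chain, in elementary charges.

    Unmodified: (+1)(Lys+Arg) + (−1)(Glu+Asp).  Phosphorylated adds the
    per-site phosphate charge for every phosphosite.
    """
    q = (ledger.n_lys + ledger.n_arg) - (ledger.n_glu + ledger.n_asp)
    if phosphorylated:
        q += ledger.n_phosphosites * ledger.phosphosite_charge
    return q


@dataclass(frozen=True)
class NeutralizationResult:
    count: int       # cosolute copies needed
    remainder: int   # leftover system charge after adding them (e)
    exact: bool


def neutralizing_count(total_protein_charge: int, cosolute_charge: int) -> NeutralizationResult:
    """Cosolute copies needed to neutralize the protein charge.

    Returns ceil(|total| / |cosolute|); the remainder is the residual
    system charge (protein + cosolutes), which lies in (−|q_cosolute|, 0]
    for an oppositely charged cosolute.
    """
    if cosolute_charge == 0:
        raise ValueError("cosolute charge must be nonzero")
    if total_protein_charge * cosolute_charge >= 0 and total_protein_charge != 0:
        raise ValueError(
            "cosolute charge must be opposite in sign to the protein charge to neutralize it"
        )
    if total_protein_charge == 0:
        return NeutralizationResult(0, 0, True)
    count = math.ceil(abs(total_protein_charge) / abs(cosolute_charge))
    remainder = total_protein_charge + count * cosolute_charge
    return NeutralizationResult(count, remainder, remainder == 0)


def molar_concentration(n_copies: int, volume_A3: float) -> float:
    """Concentration in mM of ``n_copies`` solutes in a cell of the given
    volume (Å³).  Eight chains in 1.6e6 Å³ come to about 8.3 mM."""
    if volume_A3 <= 0:
        raise ValueError("volume must be positive")
    volume_l = volume_A3 * 1e-27
    return n_copies / (volume_l * Avogadro) * 1e3
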