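"""Conceptual-DFT global reactivity descriptors from frontier-orbital energies.

Given HOMO and LUMO energies (eV) from any electronic-structure output, the
standard finite-difference descriptors are:

    gap          dE  = E_LUMO - E_HOMO
    electronegativity  chi = -(E_HOMO + E_LUMO) / 2
    global hardness    eta = (E_LUMO - E_HOMO) / 2
    softness           1 / eta
    electrophilicity   omega = chi^2 / (2 eta)

No electronic-structure computation is performed here; orbital energies are
inputs. (The literature symbol for softness collides with the dislocation
density used in the diffraction module, so it is named ``softness``.)
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

__all__ = ["FrontierEnergies", "DescriptorSet", "compute_descriptors", "rank_by_gap"]


@dataclass(frozen=True)
class FrontierEnergies:
    """HOMO/LUMO energies in eV; the HOMO must lie below the LUMO."""

    homo: float
    lumo: float

    def __post_init__(self) -> None:
        if self.homo >= self.lumo:
            raise ValueError(f"require E_HOMO < E_LUMO, got ({self.homo}, {self.lumo})")


@dataclass(frozen=True)
class DescriptorSet:
    gap: float              # eV
    electronegativity: float  # chi, eV
    hardness: float         # eta, eV
    softness: float         # 1/eta, eV^-1
    electrophilicity: float  # omega, eV

    def as_dict(self) -> dict:
        return {
            "gap_eV": self.gap,
            "electronegativity_eV": self.electronegativity,
            "hardness_eV": self.hardness,
            "softness_per_eV": self.softness,
            "electrophilicity_eV": self.electrophilicity,
        }


def compute_descriptors(energies: FrontierEnergies) -> DescriptorSet:
    """Global reactivity descriptors from a HOMO/LUMO pair."""
    eh, el = energies.homo, energies.lumo
    chi = -0.5 * (eh + el)
    eta = 0.5 * (el - eh)
    return DescriptorSet(
        gap=el - eh,
        electronegativity=chi,
        hardness=eta,
        softness=1.0 / eta,
        electrophilicity=chi * chi / (2.0 * eta),
    )


def rank_by_gap(named: Sequence[tuple[str, DescriptorSet]]) -> list[str]:
    """Names ordered by ascending HOMO-LUMO gap (stable on ties).

    A smaller gap implies more facile intramolecular charge transfer, the
    ordering usually quoted when comparing a ligand with its complexes.
    """
    if not named:
        raise ValueError("need at least one descriptor set")
    return [name for name, _ in sorted(named, key=lambda nd: nd[1].gap)]
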