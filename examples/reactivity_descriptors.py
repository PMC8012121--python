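"""Conceptual-DFT reactivity descriptors for the HAAT series.

From each compound's HOMO/LUMO energies: the gap, electronegativity chi,
hardness eta, softness 1/eta, and electrophilicity omega = chi^2/(2 eta),
plus the gap ordering across the series.
"""

from coordchar import FrontierEnergies, compute_descriptors, rank_by_gap
from coordchar.refdata import FRONTIER_ENERGIES

named = []
print("compound   E_H     E_L    gap    chi    eta   soft   omega   (eV)")
for name, (homo, lumo) in FRONTIER_ENERGIES.items():
    ds = compute_descriptors(FrontierEnergies(homo, lumo))
    named.append((name, ds))
    print(f"{name:8s} {homo:6.2f} {lumo:6.2f} {ds.gap:6.2f} "
          f"{ds.electronegativity:6.2f} {ds.hardness:5.2f} {ds.softness:6.2f} "
          f"{ds.electrophilicity:6.2f}")

print(f"\nascending gap order: {' < '.join(rank_by_gap(named))}")
print("A smaller HOMO-LUMO gap means easier intramolecular charge transfer;")
print("the free ligand is the softest and most electrophilic of the series.")
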