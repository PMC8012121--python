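"""Reported characterization data for the HAAT thiosemicarbazone series.

Reference input values for the N-allyl acenaphthaquinone thiosemicarbazone
ligand (HAAT, C16H13N3OS) and its 1:1 Co(II), Ni(II), and Zn(II) acetate
complexes, as used by the examples and the reproduction script: molecular
formulas, observed d-d band positions, the Zn(II) complex powder-diffraction
peak table, frontier-orbital energies, thermogravimetric steps, and bioassay
results. These are inputs to the analysis modules, not outputs of them.
"""

from __future__ import annotations

__all__ = [
    "FORMULAS",
    "DD_BANDS",
    "ZN_XRD_PEAKS",
    "ZN_REPORTED_CELL",
    "FRONTIER_ENERGIES",
    "TGA_STEPS",
    "ASSAYS",
    "CARBOXYLATE_BANDS",
    "XRD_WAVELENGTH",
]

#: Molecular formulas (aliases OAc/EtOH/H2O/AAT/HAAT are registered in
#: :mod:`coordchar.formula`).
FORMULAS: dict[str, str] = {
    "HAAT": "C16H13N3OS",
    "Co(II)": "C20H21N3O4SCo",   # [Co(AAT)(OAc)(EtOH)]
    "Ni(II)": "C20H21N3O6SNi",   # [Ni(HAAT)(OAc)2(H2O)]
    "Zn(II)": "C20H19N3O5SZn",   # [Zn(HAAT)(OAc)2]
}

#: Observed spin-allowed d-d transitions (cm^-1) and the configuration they
#: belong to; the pair observed is (nu2, nu3) for d7 and (nu1, nu2) for d8.
DD_BANDS: dict[str, dict] = {
    "Co(II)": {"configuration": "d7", "nu2": 15085.0, "nu3": 17010.0},
    "Ni(II)": {"configuration": "d8", "nu1": 14750.0, "nu2": 19050.0},
}

#: Zn(II) complex powder pattern: (two_theta deg, fwhm deg, hkl). The hkl
#: indices are annotation carried from the original indexing and are not
#: internally consistent with the reported cell; microstructure analysis
#: uses only the first two columns.
ZN_XRD_PEAKS: list[tuple[float, float, tuple[int, int, int]]] = [
    (6.99, 0.76, (4, 0, 0)),
    (11.90, 1.91, (-4, 0, 3)),
    (15.65, 1.10, (-8, 0, 3)),
    (17.39, 1.90, (8, 0, 2)),
    (20.18, 0.53, (8, 0, 3)),
    (22.09, 0.96, (2, 2, 0)),
    (24.31, 0.72, (2, 1, 0)),
    (31.34, 0.50, (1, 0, 0)),
    (41.84, 1.95, (3, 0, 5)),
]

#: Reported monoclinic cell of the Zn(II) complex (a, b, c in A, beta deg).
ZN_REPORTED_CELL = {"a": 8.405, "b": 10.183, "c": 13.731, "beta": 104.4, "space_group": "P21/c"}

XRD_WAVELENGTH = 1.5406  # Cu K-alpha, A

#: DFT frontier-orbital energies in eV (inputs to the descriptor module).
FRONTIER_ENERGIES: dict[str, tuple[float, float]] = {
    "HAAT": (-6.07, -4.11),
    "Co(II)": (-6.53, -4.04),
    "Ni(II)": (-6.15, -4.02),
    "Zn(II)": (-6.01, -3.98),
}

#: Thermogravimetric steps: (temp range C, found loss %, fragment formulas)
#: plus the final residue. Fragment strings use the registered aliases.
TGA_STEPS: dict[str, dict] = {
    "Co(II)": {
        "steps": [
            ((180, 445), 22.56, ["OAc", "EtOH"]),
            ((445, 620), 60.93, ["C16H12N3S"]),
        ],
        "residue": ("CoO", 16.51),
    },
    "Ni(II)": {
        "steps": [
            ((155, 390), 28.01, ["(OAc)2", "H2O"]),
            ((390, 455), 11.68, ["C3H6N"]),
            ((455, 640), 45.28, ["C13H7N2OS"]),
        ],
        "residue": ("NiO", 15.03),
    },
    "Zn(II)": {
        "steps": [
            ((125, 365), 24.87, ["(OAc)2"]),
            ((365, 620), 58.29, ["C16H13N3OS"]),
        ],
        "residue": ("ZnO", 16.84),
    },
}

#: Carboxylate stretch pairs (nu_asym, nu_sym, cm^-1) of the coordinated
#: acetate ions.
CARBOXYLATE_BANDS: dict[str, tuple[float, float]] = {
    "Co(II)": (1725.0, 1586.0),
    "Ni(II)": (1702.0, 1390.0),
    "Zn(II)": (1722.0, 1568.0),
}

#: HepG2 cytotoxicity (IC50, uM) and selectivity index vs a normal liver line.
ASSAYS: dict[str, dict] = {
    "Doxorubicin": {"ic50": 4.50, "sd": 0.2, "si": 3.28},
    "HAAT": {"ic50": 6.45, "sd": 0.25, "si": 1.14},
    "Co(II)": {"ic50": 67.31, "sd": 1.35, "si": 0.82},
    "Ni(II)": {"ic50": 21.46, "sd": 0.72, "si": 0.93},
    "Zn(II)": {"ic50": 6.39, "sd": 0.18, "si": 1.28},
}
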