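"""Rule-based interpretive conventions for complex characterization.

Three small classifiers that codify conventions used when discussing
thiosemicarbazone metal-acetate complexes and their bioassays:

* acetate binding mode from the carboxylate asymmetric/symmetric stretch
  separation (large separation -> monodentate, small -> bidentate);
* a cytotoxicity class from an IC50 value;
* the selectivity index SI = IC50(normal line) / IC50(cancer line), with
  SI > 2 flagged as high selectivity.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "CarboxylateBands",
    "AcetateMode",
    "acetate_mode",
    "classify_ic50",
    "selectivity_index",
    "IC50_CLASSES",
]


@dataclass(frozen=True)
class CarboxylateBands:
    """Carboxylate stretch positions in cm^-1 (asymmetric above symmetric)."""

    nu_asym: float
    nu_sym: float

    def __post_init__(self) -> None:
        if not self.nu_asym > self.nu_sym > 0:
            raise ValueError("require nu_asym > nu_sym > 0")

    @property
    def separation(self) -> float:
        return self.nu_asym - self.nu_sym


@dataclass(frozen=True)
class AcetateMode:
    mode: str        # "monodentate" | "bidentate"
    separation: float  # cm^-1
    note: str | None = None

    def as_dict(self) -> dict:
        d = {"mode": self.mode, "delta_nu_cm-1": self.separation}
        if self.note:
            d["note"] = self.note
        return d


def acetate_mode(bands: CarboxylateBands, monodentate_threshold: float = 200.0) -> AcetateMode:
    """Acetate coordination mode from the carboxylate band separation.

    Separations above the threshold (default 200 cm^-1) indicate monodentate
    coordination, smaller ones bidentate (chelating/bridging). Free ionic
    acetate sits near 160-170 cm^-1; the classifier does not try to detect
    it and instead attaches a caveat when the separation falls in that band.
    """
    dv = bands.separation
    mode = "monodentate" if dv > monodentate_threshold else "bidentate"
    note = None
    if 160.0 <= dv <= 170.0:
        note = "separation in the 160-170 cm^-1 range typical of free ionic acetate"
    return AcetateMode(mode=mode, separation=dv, note=note)


#: (upper bound exclusive except the last inclusive 100, class label); values
#: in the unprinted gaps between ranges fall to the lower (stronger) class.
IC50_CLASSES: tuple[tuple[float, str], ...] = (
    (11.0, "very strong"),
    (21.0, "strong"),
    (51.0, "moderate"),
    (100.0, "weak"),
)


def classify_ic50(ic50_um: float) -> str:
    """Cytotoxicity class from an IC50 in uM.

    Bins: 1-10 very strong, 11-20 strong, 21-50 moderate, 51-100 weak,
    above 100 noncytotoxic; each bin is inclusive at its left edge and gap
    values (e.g. 10.5) fall to the stronger class below.
    """
    if ic50_um <= 0:
        raise ValueError("IC50 must be positive")
    for upper, label in IC50_CLASSES[:-1]:
        if ic50_um < upper:
            return label
    if ic50_um <= IC50_CLASSES[-1][0]:
        return IC50_CLASSES[-1][1]
    return "noncytotoxic"


def selectivity_index(ic50_normal: float, ic50_cancer: float) -> tuple[float, bool]:
    """SI = IC50(normal) / IC50(cancer); high selectivity iff SI > 2 (strict)."""
    if ic50_normal <= 0 or ic50_cancer <= 0:
        raise ValueError("both IC50 values must be positive")
    si = ic50_normal / ic50_cancer
    return si, si > 2.0
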