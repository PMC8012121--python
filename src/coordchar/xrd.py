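"""Powder-XRD microstructure analysis from peak tables.

Works from a list of (2-theta, FWHM) pairs — no raw-pattern profile fitting —
and derives, per peak:

* Bragg interplanar spacing      d = lambda / (2 sin theta)
* Scherrer crystallite size      D = K lambda / (beta cos theta)
* microstrain                    eps = beta / (4 tan theta)
* dislocation density            delta = 1 / D^2   (Williamson-Smallman)

with beta the FWHM in *degrees of 2-theta* converted to radians, and
theta = 2-theta / 2. Size and strain are computed independently per peak
(no Williamson-Hall separation, no instrumental-broadening subtraction).
Table summaries report unweighted arithmetic means and the min-max size
range. A monoclinic-cell least-squares fit against indexed d-spacings is
provided via the standard 1/d^2 relation.

Defaults: Cu K-alpha wavelength 1.5406 A, Scherrer shape factor K = 0.9.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "CU_KALPHA",
    "SCHERRER_K",
    "DiffractionPeak",
    "MicrostructureRow",
    "MicrostructureSummary",
    "MonoclinicCell",
    "bragg_d",
    "scherrer_size",
    "microstrain",
    "dislocation_density",
    "summarize",
    "monoclinic_inv_d2",
    "fit_monoclinic_cell",
]

CU_KALPHA = 1.5406  # A
SCHERRER_K = 0.9


@dataclass(frozen=True)
class DiffractionPeak:
    """One powder-pattern reflection: position and width in degrees of 2-theta."""

    two_theta: float
    fwhm: float
    hkl: tuple[int, int, int] | None = None
    intensity: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.two_theta < 180:
            raise ValueError(f"two_theta must lie in (0, 180), got {self.two_theta}")
        if self.fwhm <= 0:
            raise ValueError(f"fwhm must be positive, got {self.fwhm}")
        if self.fwhm >= self.two_theta:
            raise ValueError("fwhm must be smaller than the peak position")


@dataclass(frozen=True)
class MicrostructureRow:
    """Per-peak derived quantities."""

    two_theta: float
    fwhm: float
    d: float          # A
    size: float       # nm
    strain: float     # dimensionless
    dislocation: float  # nm^-2

    def __post_init__(self) -> None:
        if min(self.d, self.size, self.strain, self.dislocation) <= 0:
            raise ValueError("all derived quantities must be positive")


@dataclass(frozen=True)
class MonoclinicCell:
    """Monoclinic lattice parameters (a, b, c in A; beta in degrees)."""

    a: float
    b: float
    c: float
    beta: float
    space_group: str | None = None  # annotation only

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell edges must be positive")
        if not 90 <= self.beta < 180:
            raise ValueError("beta must lie in [90, 180) degrees")


def bragg_d(two_theta: float, wavelength: float = CU_KALPHA) -> float:
    """Interplanar spacing in A from a peak position in degrees of 2-theta."""
    if not 0 < two_theta < 180:
        raise ValueError(f"two_theta must lie in (0, 180), got {two_theta}")
    return wavelength / (2.0 * math.sin(math.radians(two_theta / 2.0)))


def scherrer_size(
    two_theta: float,
    fwhm: float,
    wavelength: float = CU_KALPHA,
    K: float = SCHERRER_K,
) -> float:
    """Scherrer crystallite size in nm; fwhm in degrees of 2-theta."""
    if fwhm <= 0:
        raise ValueError("fwhm must be positive")
    theta = math.radians(two_theta / 2.0)
    beta = math.radians(fwhm)
    return K * wavelength / (beta * math.cos(theta)) / 10.0  # A -> nm


def microstrain(two_theta: float, fwhm: float) -> float:
    """Lattice microstrain eps = beta / (4 tan theta), dimensionless."""
    if not 0 < two_theta < 180 or two_theta == 90 * 2:
        raise ValueError("two_theta out of range")
    if fwhm <= 0:
        raise ValueError("fwhm must be positive")
    theta = math.radians(two_theta / 2.0)
    return math.radians(fwhm) / (4.0 * math.tan(theta))


def dislocation_density(size_nm: float) -> float:
    """Dislocation density delta = 1 / D^2 in nm^-2."""
    if size_nm <= 0:
        raise ValueError("crystallite size must be positive")
    return 1.0 / (size_nm * size_nm)


@dataclass(frozen=True)
class MicrostructureSummary:
    rows: tuple[MicrostructureRow, ...]
    mean_size: float
    mean_strain: float
    mean_dislocation: float
    size_range: tuple[float, float]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "two_theta_deg": [r.two_theta for r in self.rows],
                "fwhm_deg": [r.fwhm for r in self.rows],
                "d_A": [r.d for r in self.rows],
                "D_nm": [r.size for r in self.rows],
                "strain": [r.strain for r in self.rows],
                "dislocation_nm-2": [r.dislocation for r in self.rows],
            }
        )
        return df


def summarize(
    peaks: Sequence[DiffractionPeak],
    wavelength: float = CU_KALPHA,
    K: float = SCHERRER_K,
) -> MicrostructureSummary:
    """Per-peak microstructure rows plus unweighted means and the size range."""
    if not peaks:
        raise ValueError("peak list must be non-empty")
    rows = []
    for i, p in enumerate(peaks):
        try:
            size = scherrer_size(p.two_theta, p.fwhm, wavelength, K)
            rows.append(
                MicrostructureRow(
                    two_theta=p.two_theta,
                    fwhm=p.fwhm,
                    d=bragg_d(p.two_theta, wavelength),
                    size=size,
                    strain=microstrain(p.two_theta, p.fwhm),
                    dislocation=dislocation_density(size),
                )
            )
        except ValueError as exc:
            raise ValueError(f"peak row {i}: {exc}") from exc
    sizes = [r.size for r in rows]
    return MicrostructureSummary(
        rows=tuple(rows),
        mean_size=float(np.mean(sizes)),
        mean_strain=float(np.mean([r.strain for r in rows])),
        mean_dislocation=float(np.mean([r.dislocation for r in rows])),
        size_range=(min(sizes), max(sizes)),
    )


def monoclinic_inv_d2(cell: MonoclinicCell, hkl: tuple[int, int, int]) -> float:
    """1/d^2 (A^-2) of reflection hkl in a monoclinic cell.

    1/d^2 = (1/sin^2 beta) [h^2/a^2 + k^2 sin^2(beta)/b^2 + l^2/c^2
            - 2 h l cos(beta)/(a c)]

    For beta = 90 deg this reduces to the orthorhombic form. Negative
    indices are accepted; the expression is even under simultaneous
    (h, l) -> (-h, -l).
    """
    h, k, l = hkl
    beta = math.radians(cell.beta)
    s2, cb = math.sin(beta) ** 2, math.cos(beta)
    return (1.0 / s2) * (
        h * h / cell.a**2
        + k * k * s2 / cell.b**2
        + l * l / cell.c**2
        - 2.0 * h * l * cb / (cell.a * cell.c)
    )


def fit_monoclinic_cell(
    hkls: Sequence[tuple[int, int, int]],
    d_values: Sequence[float],
    initial: MonoclinicCell,
    fix_beta: bool = False,
) -> tuple[MonoclinicCell, np.ndarray]:
    """Least-squares monoclinic cell from indexed d-spacings.

    Minimizes sum (1/d_obs^2 - 1/d_calc^2)^2 over (a, b, c, beta); returns
    the refined cell and the per-peak 1/d^2 residuals. Requires at least
    four indexed peaks (three when beta is held fixed).
    """
    if len(hkls) != len(d_values):
        raise ValueError("hkls and d_values must have equal length")
    n_par = 3 if fix_beta else 4
    if len(hkls) < n_par:
        raise ValueError(f"under-determined: need >= {n_par} indexed peaks, got {len(hkls)}")
    inv_d2_obs = np.array([1.0 / d**2 for d in d_values])

    def unpack(x):
        if fix_beta:
            a, b, c = x
            return MonoclinicCell(a, b, c, initial.beta)
        a, b, c, beta = x
        return MonoclinicCell(a, b, c, beta)

    def resid(x):
        try:
            cell = unpack(x)
        except ValueError:
            return np.full(len(hkls), 1e6)
        return np.array([monoclinic_inv_d2(cell, hkl) for hkl in hkls]) - inv_d2_obs

    x0 = [initial.a, initial.b, initial.c] + ([] if fix_beta else [initial.beta])
    lower = [0.1, 0.1, 0.1] + ([] if fix_beta else [90.0])
    upper = [np.inf] * 3 + ([] if fix_beta else [179.9])
    res = least_squares(resid, x0, bounds=(lower, upper), xtol=1e-15, ftol=1e-15, gtol=1e-15)
    if not res.success:
        raise RuntimeError(f"cell refinement did not converge: {res.message}")
    cell = unpack(res.x)
    return MonoclinicCell(cell.a, cell.b, cell.c, cell.beta, initial.space_group), resid(res.x)
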