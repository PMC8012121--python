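"""Tauc-plot optical band-gap extraction.

An absorption edge obeying alpha * h*nu = A (h*nu - Eg)^r becomes a straight
line when (alpha * h*nu)^(1/r)... — here we follow the convention in which the
*plotted* quantity is (alpha * h*nu)^r with r = 2 for a direct transition and
r = 1/2 for an indirect one, so that the linear portion of the plot against
photon energy extrapolates to the x-axis at the optical band gap Eg.

The linear region is chosen automatically: among all contiguous windows of at
least ``min_window`` points with positive slope, the one maximizing the
coefficient of determination R^2 is selected, ties broken toward the longer
window and then toward the higher-energy window. ``mode="auto"`` runs both
exponents and keeps the one whose best window is more nearly linear.

Absorbance (solution spectra, arbitrary units) is used directly as the
absorption measure; no path-length or thickness normalization is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

__all__ = [
    "EV_NM",
    "AbsorptionSpectrum",
    "TaucResult",
    "tauc_transform",
    "find_linear_region",
    "band_gap",
]

EV_NM = 1239.842  # h*c in eV*nm: energy(eV) = EV_NM / wavelength(nm)

Mode = Literal["direct", "indirect", "auto"]
_MODE_EXPONENT = {"direct": 2.0, "indirect": 0.5}


@dataclass(frozen=True)
class AbsorptionSpectrum:
    """Photon energy (eV, strictly increasing) vs absorption (arb. units)."""

    energy: np.ndarray
    absorbance: np.ndarray
    wavelength: np.ndarray | None = None  # original nm axis, if any

    def __post_init__(self) -> None:
        e = np.asarray(self.energy, dtype=float)
        a = np.asarray(self.absorbance, dtype=float)
        if e.shape != a.shape or e.ndim != 1:
            raise ValueError("energy and absorbance must be 1-D arrays of equal length")
        if e.size < 20:
            raise ValueError(f"spectrum needs >= 20 points, got {e.size}")
        if not np.all(np.diff(e) > 0):
            raise ValueError("energies must be strictly increasing")
        if np.any(a < 0):
            raise ValueError("absorbance must be non-negative")
        object.__setattr__(self, "energy", e)
        object.__setattr__(self, "absorbance", a)

    @classmethod
    def from_wavelength(cls, wavelength_nm, absorbance) -> "AbsorptionSpectrum":
        """Build from a wavelength axis (nm), converting via E = 1239.842 / lambda."""
        wl = np.asarray(wavelength_nm, dtype=float)
        ab = np.asarray(absorbance, dtype=float)
        if np.any(wl <= 0):
            raise ValueError("wavelengths must be positive")
        e = EV_NM / wl
        order = np.argsort(e)
        return cls(e[order], ab[order], wavelength=wl[order])

    def __len__(self) -> int:
        return int(self.energy.size)


@dataclass(frozen=True)
class TaucResult:
    """Extracted optical band gap and the straight-line fit that produced it."""

    eg: float                  # eV
    exponent: float            # r: 2 direct, 0.5 indirect
    window: tuple[int, int]    # [start, stop) indices of the fit window
    slope: float
    intercept: float
    r_squared: float

    @property
    def mode(self) -> str:
        return "direct" if self.exponent == 2.0 else "indirect"

    def as_dict(self) -> dict:
        return {
            "Eg_eV": self.eg,
            "mode": self.mode,
            "exponent": self.exponent,
            "window": list(self.window),
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
        }


def tauc_transform(spectrum: AbsorptionSpectrum, exponent: float) -> np.ndarray:
    """Element-wise (alpha * h*nu)^r; zero absorbance maps to zero."""
    if exponent not in (0.5, 2.0):
        raise ValueError("exponent must be 2 (direct) or 0.5 (indirect)")
    y = spectrum.absorbance * spectrum.energy
    return np.power(y, exponent)


def _window_stats(x: np.ndarray, y: np.ndarray):
    """Slope, intercept and R^2 of least-squares lines over all windows.

    Computed from cumulative sums so every O(n^2) window costs O(1).
    """
    n = x.size
    cx = np.concatenate([[0.0], np.cumsum(x)])
    cy = np.concatenate([[0.0], np.cumsum(y)])
    cxx = np.concatenate([[0.0], np.cumsum(x * x)])
    cxy = np.concatenate([[0.0], np.cumsum(x * y)])
    cyy = np.concatenate([[0.0], np.cumsum(y * y)])

    def stats(i: int, j: int):
        m = j - i
        sx, sy = cx[j] - cx[i], cy[j] - cy[i]
        sxx, sxy, syy = cxx[j] - cxx[i], cxy[j] - cxy[i], cyy[j] - cyy[i]
        vx = sxx - sx * sx / m
        vy = syy - sy * sy / m
        cov = sxy - sx * sy / m
        if vx <= 0:
            return None
        slope = cov / vx
        intercept = (sy - slope * sx) / m
        r2 = 1.0 if vy <= 0 else min(1.0, cov * cov / (vx * vy))
        return slope, intercept, r2

    return stats


def find_linear_region(
    x: np.ndarray, y: np.ndarray, min_window: int = 5
) -> tuple[int, int]:
    """Select the fit window on a transformed Tauc series.

    Exhaustive search over all contiguous windows of length >= ``min_window``
    with positive slope; the window maximizing R^2 wins, ties going to the
    longer window and then to the higher-energy (later-starting) window.
    """
    if min_window < 5:
        raise ValueError("min_window must be >= 5")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < min_window:
        raise ValueError("series shorter than min_window")
    stats = _window_stats(x, y)
    best: tuple[float, int, int] | None = None  # (r2, length, start)
    best_win: tuple[int, int] | None = None
    for i in range(0, n - min_window + 1):
        for j in range(i + min_window, n + 1):
            st = stats(i, j)
            if st is None or st[0] <= 0:
                continue
            key = (round(st[2], 12), j - i, i)
            if best is None or key > best:
                best = key
                best_win = (i, j)
    if best_win is None:
        raise ValueError("no window with positive slope found")
    return best_win


def band_gap(
    spectrum: AbsorptionSpectrum,
    mode: Mode = "auto",
    min_window: int = 5,
) -> TaucResult:
    """Optical band gap from the x-intercept of the Tauc linear region.

    ``mode="auto"`` evaluates both the direct (r = 2) and indirect (r = 1/2)
    constructions and returns the one whose selected window fits better.
    """
    if mode not in ("direct", "indirect", "auto"):
        raise ValueError(f"unknown mode {mode!r}")
    modes = ["direct", "indirect"] if mode == "auto" else [mode]
    results: list[TaucResult] = []
    for m in modes:
        r = _MODE_EXPONENT[m]
        y = tauc_transform(spectrum, r)
        try:
            i, j = find_linear_region(spectrum.energy, y, min_window)
        except ValueError:
            continue
        stats = _window_stats(spectrum.energy, y)(i, j)
        slope, intercept, r2 = stats
        if slope <= 0:
            continue
        eg = -intercept / slope
        if not spectrum.energy[0] <= eg <= spectrum.energy[-1]:
            continue
        results.append(TaucResult(float(eg), r, (i, j), float(slope), float(intercept), float(r2)))
    if not results:
        raise ValueError("no acceptable Tauc fit: no positive-slope window gave an in-span gap")
    return max(results, key=lambda t: t.r_squared)
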