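"""Seeded synthetic-data generators for every analysis stage.

Each generator is the forward model of its analysis stage, so at zero noise
the corresponding solver recovers the generating parameters exactly (within
numerical tolerance); with noise they support seeded recovery studies. Noise
models are deliberately simple: Gaussian relative noise on absorbances and
band positions, Gaussian absolute noise (degrees) on FWHM floored at 0.05
degrees. Identical seeds give identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .formula import (
    ChemicalFormula,
    DecompositionStep,
    average_mass,
    loss_percent,
    parse_formula,
)
from .ligand_field import TransitionSet, forward_d7, forward_d8
from .tauc import AbsorptionSpectrum
from .xrd import CU_KALPHA, SCHERRER_K, DiffractionPeak, MonoclinicCell, monoclinic_inv_d2

__all__ = [
    "gen_tauc_spectrum",
    "gen_xrd_peaks",
    "gen_dd_bands",
    "gen_tga_trace",
    "TgaTrace",
]

_FWHM_FLOOR_DEG = 0.05


def gen_tauc_spectrum(
    eg: float,
    mode: str = "direct",
    amplitude: float = 1.0,
    span: tuple[float, float] = (1.2, 4.0),
    n_points: int = 200,
    noise: float = 0.0,
    seed: int | None = 0,
) -> AbsorptionSpectrum:
    """Synthetic absorption edge with a known optical band gap.

    Inverts the Tauc relation (alpha h nu)^r = A^r (h nu - Eg): above the gap
    alpha = A (h nu - Eg)^(1/r) / (h nu), below it alpha = 0, with r = 2 for a
    direct and 1/2 for an indirect transition. Relative Gaussian noise of
    standard deviation ``noise`` multiplies the absorbance.
    """
    lo, hi = span
    if not lo < eg < hi:
        raise ValueError(f"gap {eg} must lie inside the energy span {span}")
    if hi <= lo:
        raise ValueError("degenerate energy span")
    r = {"direct": 2.0, "indirect": 0.5}[mode]
    e = np.linspace(lo, hi, n_points)
    alpha = np.zeros_like(e)
    above = e > eg
    alpha[above] = amplitude * np.power(e[above] - eg, 1.0 / r) / e[above]
    if noise > 0:
        rng = np.random.default_rng(seed)
        alpha = alpha * (1.0 + noise * rng.standard_normal(alpha.shape))
        alpha = np.clip(alpha, 0.0, None)
    return AbsorptionSpectrum(e, alpha)


def gen_xrd_peaks(
    cell: MonoclinicCell,
    hkls: list[tuple[int, int, int]],
    size_nm: float = 10.0,
    wavelength: float = CU_KALPHA,
    K: float = SCHERRER_K,
    position_noise: float = 0.0,
    fwhm_noise_deg: float = 0.0,
    seed: int | None = 0,
) -> list[DiffractionPeak]:
    """Peak list from a monoclinic cell with size-controlled widths.

    Positions follow Bragg's law on the cell's d-spacings; widths invert the
    Scherrer equation, beta = K lambda / (D cos theta). Relative Gaussian
    noise perturbs positions, absolute Gaussian noise (degrees, floored at
    0.05) perturbs widths.
    """
    rng = np.random.default_rng(seed)
    peaks = []
    for hkl in hkls:
        inv_d2 = monoclinic_inv_d2(cell, hkl)
        d = 1.0 / math.sqrt(inv_d2)
        s = wavelength / (2.0 * d)
        if not 0 < s < 1:
            raise ValueError(f"reflection {hkl} unreachable at wavelength {wavelength}")
        theta = math.asin(s)
        two_theta = math.degrees(2.0 * theta)
        beta_rad = K * wavelength / (size_nm * 10.0 * math.cos(theta))
        fwhm = math.degrees(beta_rad)
        if position_noise > 0:
            two_theta *= 1.0 + position_noise * rng.standard_normal()
        if fwhm_noise_deg > 0:
            fwhm = max(_FWHM_FLOOR_DEG, fwhm + fwhm_noise_deg * rng.standard_normal())
        peaks.append(DiffractionPeak(two_theta=two_theta, fwhm=fwhm, hkl=hkl))
    return peaks


def gen_dd_bands(
    configuration: str,
    Dq: float,
    B: float,
    noise: float = 0.0,
    seed: int | None = 0,
) -> TransitionSet:
    """Spin-allowed d-d band triple from known (Dq, B), optional relative noise."""
    forward = {"d7": forward_d7, "d8": forward_d8}[configuration]
    nu = np.array(forward(Dq, B))
    if noise > 0:
        rng = np.random.default_rng(seed)
        nu = nu * (1.0 + noise * rng.standard_normal(3))
        nu = np.sort(nu)
    return TransitionSet(configuration, nu1=float(nu[0]), nu2=float(nu[1]), nu3=float(nu[2]))


@dataclass(frozen=True)
class TgaTrace:
    steps: tuple[DecompositionStep, ...]
    residue: ChemicalFormula
    residue_percent: float

    def total_percent(self) -> float:
        return sum(s.observed_loss for s in self.steps) + self.residue_percent


def gen_tga_trace(
    parent: ChemicalFormula | str,
    step_fragments: list[list[ChemicalFormula | str]],
    noise: float = 0.0,
    seed: int | None = 0,
    start_temp: float = 150.0,
    step_width: float = 200.0,
) -> TgaTrace:
    """Multi-step decomposition trace from a parent formula and leaving groups.

    Each step loses the given fragments; the residue is the parent minus all
    fragments, so at zero noise the step percentages and residue sum exactly
    to 100. Relative Gaussian noise perturbs the observed step losses.
    """
    parent_f = parent if isinstance(parent, ChemicalFormula) else parse_formula(parent)
    rng = np.random.default_rng(seed)
    remaining = dict(parent_f.elements)
    steps: list[DecompositionStep] = []
    t = start_temp
    for frags in step_fragments:
        frag_fs = [f if isinstance(f, ChemicalFormula) else parse_formula(f) for f in frags]
        for f in frag_fs:
            for s, c in f.elements.items():
                if remaining.get(s, 0) < c:
                    raise ValueError(f"fragment {f.hill()} not contained in remaining parent")
                remaining[s] -= c
        calc = loss_percent(parent_f, frag_fs)
        observed = calc * (1.0 + noise * rng.standard_normal()) if noise > 0 else calc
        steps.append(
            DecompositionStep(
                temp_low=t,
                temp_high=t + step_width,
                observed_loss=observed,
                fragments=list(frag_fs),
                calculated_loss=calc,
            )
        )
        t += step_width
    residue_elements = {s: c for s, c in remaining.items() if c > 0}
    if not residue_elements:
        raise ValueError("fragments consume the entire parent; no residue left")
    residue = ChemicalFormula(residue_elements)
    res_pct = 100.0 * average_mass(residue) / average_mass(parent_f)
    return TgaTrace(steps=tuple(steps), residue=residue, residue_percent=res_pct)
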