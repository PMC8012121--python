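"""Octahedral ligand-field parameter extraction for d7 and d8 ions.

The spin-allowed d-d transitions of octahedral d8 (e.g. Ni(II), ground term
3A2g) and d7 (e.g. Co(II), ground term 4T1g(F)) ions are governed, in the
weak-field Racah parameterization, by the crystal-field splitting Dq and the
interelectronic-repulsion parameter B. Writing Q for the square-root term of
the 2x2 term-interaction secular equation:

d8 (3A2g ground state), Q = sqrt(225 B^2 + 100 Dq^2 - 180 Dq B):
    nu1 = 10 Dq                     (3A2g -> 3T2g)
    nu2 = 15 Dq + 7.5 B - Q/2       (3A2g -> 3T1g(F))
    nu3 = 15 Dq + 7.5 B + Q/2       (3A2g -> 3T1g(P))

d7 (4T1g(F) ground state), Q = sqrt(225 B^2 + 100 Dq^2 + 180 Dq B):
    nu1 = 5 Dq - 7.5 B + Q/2        (4T1g(F) -> 4T2g)
    nu2 = 15 Dq - 7.5 B + Q/2       (4T1g(F) -> 4A2g)
    nu3 = Q                         (4T1g(F) -> 4T1g(P))

so nu1 = 10 Dq (d8) and nu2 - nu1 = 10 Dq (d7) hold identically. The
solvers invert these closed forms from the two observed bands (the usual
situation: the third band is obscured or outside the measured window) and
predict the unobserved one. A two-dimensional numeric root find on the same
forward model serves as an independent cross-check.

All quantities are wavenumbers in cm^-1. Only spin-allowed transitions are
modeled: no spin-orbit coupling and no Racah C parameter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

from scipy.optimize import root

__all__ = [
    "TransitionSet",
    "LigandFieldSolution",
    "LigandFieldError",
    "forward_d8",
    "solve_d8",
    "forward_d7",
    "solve_d7",
    "solve_numeric",
]

Configuration = Literal["d7", "d8"]

#: round-trip residual required of every solution, cm^-1
_RESIDUAL_TOL = 0.1


class LigandFieldError(ValueError):
    """Raised when observed bands admit no physical (Dq, B) solution."""


@dataclass(frozen=True)
class TransitionSet:
    """Observed spin-allowed d-d band positions, cm^-1, labeled nu1..nu3."""

    configuration: Configuration
    nu1: float | None = None
    nu2: float | None = None
    nu3: float | None = None

    def __post_init__(self) -> None:
        if self.configuration not in ("d7", "d8"):
            raise ValueError(f"configuration must be 'd7' or 'd8', got {self.configuration!r}")
        labeled = [(k, v) for k, v in (("nu1", self.nu1), ("nu2", self.nu2), ("nu3", self.nu3)) if v is not None]
        if any(v <= 0 for _, v in labeled):
            raise ValueError("band positions must be positive")
        values = [v for _, v in labeled]
        if any(a >= b for a, b in zip(values, values[1:])):
            raise ValueError("labeled bands must be strictly increasing nu1 < nu2 < nu3")


@dataclass(frozen=True)
class LigandFieldSolution:
    """Recovered (Dq, B) and the full predicted transition triple, cm^-1."""

    configuration: Configuration
    Dq: float
    B: float
    predicted: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.Dq <= 0 or self.B <= 0:
            raise LigandFieldError(f"unphysical parameters Dq={self.Dq:.1f}, B={self.B:.1f}")
        p = self.predicted
        if not (p[0] < p[1] < p[2]):
            raise LigandFieldError(f"predicted bands not strictly increasing: {p}")

    @property
    def ten_dq(self) -> float:
        return 10.0 * self.Dq

    def as_dict(self) -> dict:
        return {
            "configuration": self.configuration,
            "Dq": self.Dq,
            "tenDq": self.ten_dq,
            "B": self.B,
            "predicted_bands": list(self.predicted),
        }


def forward_d8(Dq: float, B: float) -> tuple[float, float, float]:
    """Spin-allowed transition triple of an octahedral d8 ion."""
    if Dq <= 0 or B < 0:
        raise LigandFieldError("require Dq > 0 and B >= 0")
    disc = 225.0 * B * B + 100.0 * Dq * Dq - 180.0 * Dq * B
    if disc < 0:
        raise LigandFieldError(f"negative discriminant for Dq={Dq}, B={B}")
    q = math.sqrt(disc)
    nu1 = 10.0 * Dq
    nu2 = 15.0 * Dq + 7.5 * B - 0.5 * q
    nu3 = 15.0 * Dq + 7.5 * B + 0.5 * q
    return nu1, nu2, nu3


def forward_d7(Dq: float, B: float) -> tuple[float, float, float]:
    """Spin-allowed transition triple of an octahedral d7 ion."""
    if Dq <= 0 or B < 0:
        raise LigandFieldError("require Dq > 0 and B >= 0")
    q = math.sqrt(225.0 * B * B + 100.0 * Dq * Dq + 180.0 * Dq * B)
    nu1 = 5.0 * Dq - 7.5 * B + 0.5 * q
    nu2 = 15.0 * Dq - 7.5 * B + 0.5 * q
    nu3 = q
    return nu1, nu2, nu3


def _check_round_trip(sol: LigandFieldSolution, observed: dict[str, float]) -> None:
    idx = {"nu1": 0, "nu2": 1, "nu3": 2}
    for label, value in observed.items():
        resid = abs(sol.predicted[idx[label]] - value)
        if resid > _RESIDUAL_TOL:
            raise LigandFieldError(
                f"round-trip residual {resid:.3g} cm^-1 on {label} exceeds {_RESIDUAL_TOL}"
            )


def solve_d8(nu1: float, nu2: float) -> LigandFieldSolution:
    """Recover (Dq, B) of a d8 ion from its two lowest spin-allowed bands.

    Dq = nu1 / 10 exactly; B is the root of the linear equation obtained by
    squaring the nu2 closed form; nu3 is predicted from the forward model.
    """
    if not 0 < nu1 < nu2:
        raise LigandFieldError("require 0 < nu1 < nu2")
    Dq = nu1 / 10.0
    # Q = 30 Dq + 15 B - 2 nu2; squaring gives a linear equation in B
    num = 120.0 * Dq * nu2 - 800.0 * Dq * Dq - 4.0 * nu2 * nu2
    den = 1080.0 * Dq - 60.0 * nu2
    if den == 0 or (B := num / den) <= 0:
        raise LigandFieldError(f"no positive Racah B for bands ({nu1}, {nu2})")
    sol = LigandFieldSolution("d8", Dq, B, forward_d8(Dq, B))
    _check_round_trip(sol, {"nu1": nu1, "nu2": nu2})
    return sol


def solve_d7(nu2: float, nu3: float) -> LigandFieldSolution:
    """Recover (Dq, B) of a d7 ion from its two highest spin-allowed bands.

    Substituting 15 Dq - 7.5 B = nu2 - nu3/2 into nu3^2 = 225 B^2 + 100 Dq^2
    + 180 Dq B yields 340 B^2 + (56/3) u B + (4/9) u^2 - nu3^2 = 0 with
    u = nu2 - nu3/2; the positive root is taken and nu1 predicted.
    """
    if not 0 < nu2 < nu3:
        raise LigandFieldError("require 0 < nu2 < nu3")
    u = nu2 - 0.5 * nu3
    a, b, c = 340.0, (56.0 / 3.0) * u, (4.0 / 9.0) * u * u - nu3 * nu3
    disc = b * b - 4.0 * a * c
    if disc < 0:
        raise LigandFieldError(f"no real Racah B for bands ({nu2}, {nu3})")
    B = (-b + math.sqrt(disc)) / (2.0 * a)
    if B <= 0:
        raise LigandFieldError(f"no positive Racah B for bands ({nu2}, {nu3})")
    Dq = (u + 7.5 * B) / 15.0
    sol = LigandFieldSolution("d7", Dq, B, forward_d7(Dq, B))
    _check_round_trip(sol, {"nu2": nu2, "nu3": nu3})
    return sol


def solve_numeric(configuration: Configuration, bands: dict[str, float]) -> LigandFieldSolution:
    """Two-dimensional root find on the forward model; independent of the
    closed-form solvers and used to cross-check them.

    ``bands`` maps two of ``nu1``/``nu2``/``nu3`` to observed positions
    (cm^-1): the pair (nu1, nu2) for d8, (nu2, nu3) for d7.
    """
    forward = {"d7": forward_d7, "d8": forward_d8}[configuration]
    labels = sorted(bands)
    if len(labels) != 2:
        raise LigandFieldError("exactly two observed bands are required")
    idx = {"nu1": 0, "nu2": 1, "nu3": 2}

    def residuals(p):
        Dq, B = p
        if Dq <= 0 or B <= 0:
            return [1e9, 1e9]
        try:
            pred = forward(Dq, B)
        except LigandFieldError:
            return [1e9, 1e9]
        return [pred[idx[l]] - bands[l] for l in labels]

    hi = max(bands.values())
    x0 = [hi / 15.0, hi / 30.0]
    res = root(residuals, x0, method="hybr")
    final = max(abs(r) for r in residuals(res.x))
    if not res.success or final > _RESIDUAL_TOL:
        raise LigandFieldError(f"numeric solver did not converge; final residual {final:.3g} cm^-1")
    Dq, B = res.x
    sol = LigandFieldSolution(configuration, float(Dq), float(B), forward(float(Dq), float(B)))
    _check_round_trip(sol, bands)
    return sol
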