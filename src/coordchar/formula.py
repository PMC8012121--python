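"""Chemical-formula arithmetic for complex characterization.

Parses element-count formula strings (``C16H13N3OS``, ``(OAc)2``,
``[Co(AAT)(OAc)(EtOH)]`` after alias registration), computes average and
monoisotopic molecular masses, elemental mass percentages, and the
thermogravimetric bookkeeping used to rationalize decomposition curves:
per-step mass-loss percentages, residue percentages, and a bounded search
that assigns candidate leaving groups to an observed loss.

Atomic masses come from the NIST isotopic composition table shipped with
:mod:`pyteomics`. The *average* mass of an element is its abundance-weighted
isotopic mass (the standard atomic weight); the *monoisotopic* mass is the
mass of its most abundant isotope. Radical dots and charges sometimes
attached to fragment formulas are ignored: the electron mass is negligible
at the 0.01 u level these calculations work at.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from pyteomics.mass import nist_mass

__all__ = [
    "ChemicalFormula",
    "FormulaError",
    "DecompositionStep",
    "ALIASES",
    "register_alias",
    "parse_formula",
    "average_mass",
    "monoisotopic_mass",
    "element_percents",
    "loss_percent",
    "residue_percent",
    "assign_losses",
]


class FormulaError(ValueError):
    """Raised for malformed formula strings or invalid mass arithmetic."""


def _element_symbols() -> frozenset[str]:
    # pyteomics also carries pseudo-entries such as 'e*' and 'H+'
    return frozenset(s for s in nist_mass if s.isalpha())


_ELEMENTS = _element_symbols()


def _average_atomic_mass(symbol: str) -> float:
    isotopes = nist_mass[symbol]
    num = sum(m * ab for k, (m, ab) in isotopes.items() if k != 0)
    den = sum(ab for k, (m, ab) in isotopes.items() if k != 0)
    if den == 0:  # no stable isotopes with tabulated abundance (e.g. Tc)
        raise FormulaError(f"element {symbol!r} has no tabulated isotopic abundances")
    return num / den


def _monoisotopic_atomic_mass(symbol: str) -> float:
    # entry 0 holds (mass of most abundant isotope, 1.0)
    return nist_mass[symbol][0][0]


@dataclass(frozen=True)
class ChemicalFormula:
    """An element -> count multiset, e.g. ``{C: 16, H: 13, N: 3, O: 1, S: 1}``."""

    elements: Mapping[str, int]

    def __post_init__(self) -> None:
        if not self.elements:
            raise FormulaError("formula must contain at least one element")
        clean: dict[str, int] = {}
        for symbol, count in self.elements.items():
            if symbol not in _ELEMENTS:
                raise FormulaError(f"unknown element symbol {symbol!r}")
            if not isinstance(count, int) or count < 1:
                raise FormulaError(f"count for {symbol} must be a positive integer, got {count!r}")
            clean[symbol] = count
        object.__setattr__(self, "elements", dict(clean))

    def __mul__(self, n: int) -> "ChemicalFormula":
        if not isinstance(n, int) or n < 1:
            raise FormulaError("formula multiplier must be a positive integer")
        return ChemicalFormula({s: c * n for s, c in self.elements.items()})

    __rmul__ = __mul__

    def __add__(self, other: "ChemicalFormula") -> "ChemicalFormula":
        merged = dict(self.elements)
        for s, c in other.elements.items():
            merged[s] = merged.get(s, 0) + c
        return ChemicalFormula(merged)

    def hill(self) -> str:
        """Hill-order string: C first, then H, then the rest alphabetically."""
        parts: list[str] = []
        order = [s for s in ("C", "H") if s in self.elements]
        order += sorted(s for s in self.elements if s not in ("C", "H"))
        for s in order:
            c = self.elements[s]
            parts.append(s if c == 1 else f"{s}{c}")
        return "".join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.hill()


#: Shorthand groups expanded before element counting. User-extensible via
#: :func:`register_alias` or the run configuration.
ALIASES: dict[str, str] = {
    "OAc": "C2H3O2",
    "EtOH": "C2H6O",
    "H2O": "H2O",
    "AAT": "C16H12N3OS",   # deprotonated thiosemicarbazone ligand
    "HAAT": "C16H13N3OS",  # neutral thiosemicarbazone ligand
}


def register_alias(name: str, formula: str) -> None:
    """Register a shorthand group so that e.g. ``(OAc)2`` parses."""
    if not name or not name[0].isalpha():
        raise FormulaError(f"invalid alias name {name!r}")
    counts = _parse(formula, allow_aliases=False)
    ALIASES[name] = ChemicalFormula(counts).hill()


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def _parse(text: str, allow_aliases: bool = True) -> dict[str, int]:
    pos = 0
    counts: dict[str, int] = {}
    stack: list[dict[str, int]] = []
    n = len(text)
    # aliases are matched greedily, longest name first, before element symbols
    alias_names = sorted(ALIASES, key=len, reverse=True) if allow_aliases else []

    def read_int(p: int) -> tuple[int, int]:
        q = p
        while q < n and text[q].isdigit():
            q += 1
        return (int(text[p:q]) if q > p else 1), q

    def add(target: dict[str, int], sym: str, k: int) -> None:
        target[sym] = target.get(sym, 0) + k

    while pos < n:
        ch = text[pos]
        if ch in "([":
            stack.append(counts)
            counts = {}
            pos += 1
            continue
        if ch in ")]":
            if not stack:
                raise FormulaError(f"unbalanced parenthesis in {text!r}")
            mult, pos = read_int(pos + 1)
            inner, counts = counts, stack.pop()
            for s, c in inner.items():
                add(counts, s, c * mult)
            continue
        if ch in " ·.":  # separators: space, middle dot, dot
            pos += 1
            continue
        matched_alias = None
        for name in alias_names:
            if text.startswith(name, pos):
                trail = pos + len(name)
                # alias must not be a prefix of a longer alphabetic token
                if trail >= n or not text[trail].islower():
                    matched_alias = name
                    break
        if matched_alias is not None:
            mult, pos = read_int(pos + len(matched_alias))
            for s, c in _parse(ALIASES[matched_alias], allow_aliases=False).items():
                add(counts, s, c * mult)
            continue
        m = _TOKEN.match(text, pos)
        if m is None:
            raise FormulaError(f"cannot parse formula {text!r} at position {pos}")
        sym = m.group(1)
        if sym not in _ELEMENTS:
            raise FormulaError(f"unknown element symbol {sym!r} in {text!r}")
        count = int(m.group(2)) if m.group(2) else 1
        if count == 0:
            raise FormulaError(f"zero count for element {sym} in {text!r}")
        add(counts, sym, count)
        pos = m.end()
    if stack:
        raise FormulaError(f"unbalanced parenthesis in {text!r}")
    return counts


def parse_formula(text: str) -> ChemicalFormula:
    """Parse an element-count formula string into a :class:`ChemicalFormula`.

    Element symbols are case-sensitive; parenthesized groups take integer
    multipliers (``(OAc)2``); registered aliases (``OAc``, ``EtOH``, ``HAAT``,
    ...) expand before counting. Radical dots/charges are not part of the
    grammar and should be stripped by the caller.
    """
    if not text or not text.strip():
        raise FormulaError("empty formula string")
    return ChemicalFormula(_parse(text.strip()))


def _as_formula(f: ChemicalFormula | str) -> ChemicalFormula:
    return f if isinstance(f, ChemicalFormula) else parse_formula(f)


def average_mass(f: ChemicalFormula | str) -> float:
    """Average (standard-atomic-weight) molecular mass in u."""
    f = _as_formula(f)
    return sum(c * _average_atomic_mass(s) for s, c in f.elements.items())


def monoisotopic_mass(f: ChemicalFormula | str) -> float:
    """Molecular mass built from each element's most abundant isotope, in u."""
    f = _as_formula(f)
    return sum(c * _monoisotopic_atomic_mass(s) for s, c in f.elements.items())


def element_percents(f: ChemicalFormula | str) -> dict[str, float]:
    """Mass percent of each element; values sum to 100."""
    f = _as_formula(f)
    total = average_mass(f)
    return {s: 100.0 * c * _average_atomic_mass(s) / total for s, c in f.elements.items()}


def loss_percent(parent: ChemicalFormula | str, fragments: Iterable[ChemicalFormula | str]) -> float:
    """Calculated mass-loss percent for a decomposition step.

    100 x (sum of fragment average masses) / (parent average mass); the
    fragments' combined mass may not exceed the parent's.
    """
    parent = _as_formula(parent)
    total = sum(average_mass(_as_formula(fr)) for fr in fragments)
    pm = average_mass(parent)
    if total > pm * (1 + 1e-9):
        raise FormulaError(f"fragment mass {total:.2f} exceeds parent mass {pm:.2f}")
    return 100.0 * total / pm


def residue_percent(parent: ChemicalFormula | str, residue: ChemicalFormula | str) -> float:
    """Calculated residue percent: 100 x residue mass / parent mass."""
    parent, residue = _as_formula(parent), _as_formula(residue)
    pm, rm = average_mass(parent), average_mass(residue)
    if rm > pm * (1 + 1e-9):
        raise FormulaError(f"residue mass {rm:.2f} exceeds parent mass {pm:.2f}")
    return 100.0 * rm / pm


@dataclass
class DecompositionStep:
    """One thermogravimetric decomposition step."""

    temp_low: float
    temp_high: float
    observed_loss: float
    fragments: list[ChemicalFormula] = field(default_factory=list)
    calculated_loss: float | None = None

    def __post_init__(self) -> None:
        if not self.temp_low < self.temp_high:
            raise ValueError("temperature range must satisfy low < high")
        if not 0 < self.observed_loss < 100:
            raise ValueError("observed loss must lie strictly between 0 and 100 %")


_MAX_NODES = 10**6


def assign_losses(
    parent: ChemicalFormula | str,
    observed: float,
    pool: Sequence[tuple[ChemicalFormula | str, int]],
    tol: float = 1.0,
) -> list[tuple[ChemicalFormula, ...]]:
    """Find fragment multisets whose calculated loss matches an observed one.

    ``pool`` lists candidate leaving groups with their maximum multiplicities.
    Every multiset (excluding the empty one) whose :func:`loss_percent` lies
    within ``tol`` of ``observed`` is returned, best match first; ties break
    toward fewer fragments, then lexicographic Hill-formula order. The search
    is a depth-first enumeration pruned on cumulative mass, capped at 10^6
    visited nodes.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    if not pool:
        raise ValueError("candidate pool must be non-empty")
    parent = _as_formula(parent)
    pm = average_mass(parent)
    items = [(_as_formula(f), int(mx)) for f, mx in pool]
    if any(mx < 1 for _, mx in items):
        raise ValueError("multiplicities must be >= 1")
    masses = [average_mass(f) for f, _ in items]
    upper = (observed + tol) * pm / 100.0  # cumulative-mass pruning bound

    hits: list[tuple[tuple[ChemicalFormula, ...], float]] = []
    visited = 0

    def dfs(idx: int, chosen: list[ChemicalFormula], mass: float) -> None:
        nonlocal visited
        visited += 1
        if visited > _MAX_NODES:
            raise RuntimeError("assign_losses search exceeded the node cap")
        if idx == len(items):
            if chosen:
                calc = 100.0 * mass / pm
                if abs(calc - observed) <= tol:
                    hits.append((tuple(chosen), calc))
            return
        frag, mx = items[idx]
        fm = masses[idx]
        for k in range(mx + 1):
            new_mass = mass + k * fm
            if new_mass > upper + 1e-12:
                break
            dfs(idx + 1, chosen + [frag] * k, new_mass)

    dfs(0, [], 0.0)

    def sort_key(entry: tuple[tuple[ChemicalFormula, ...], float]):
        frags, calc = entry
        names = tuple(sorted(f.hill() for f in frags))
        return (abs(calc - observed), len(frags), names)

    hits.sort(key=sort_key)
    return [tuple(sorted(frags, key=lambda f: f.hill())) for frags, _ in hits]
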