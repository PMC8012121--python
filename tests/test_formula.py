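"""Formula parsing, mass arithmetic, and thermogravimetric bookkeeping."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coordchar import (
    ChemicalFormula,
    FormulaError,
    assign_losses,
    average_mass,
    element_percents,
    loss_percent,
    monoisotopic_mass,
    parse_formula,
    residue_percent,
)


@pytest.mark.parametrize(
    "text, expected",
    [
        ("C16H13N3OS", {"C": 16, "H": 13, "N": 3, "O": 1, "S": 1}),
        ("H2O", {"H": 2, "O": 1}),
        ("(OAc)2", {"C": 4, "H": 6, "O": 4}),
        ("EtOH", {"C": 2, "H": 6, "O": 1}),
        ("CoO", {"Co": 1, "O": 1}),
        ("C20H21N3O4SCo", {"C": 20, "H": 21, "N": 3, "O": 4, "S": 1, "Co": 1}),
        ("Co(OAc)2", {"Co": 1, "C": 4, "H": 6, "O": 4}),
    ],
)
def test_parse_formula(text, expected):
    assert parse_formula(text).elements == expected


@pytest.mark.parametrize("bad", ["", "  ", "Xx3", "C0H2", "C(H2", "c16"])
def test_parse_formula_rejects_malformed_strings(bad):
    with pytest.raises(FormulaError):
        parse_formula(bad)


@pytest.mark.parametrize(
    "formula, expected, tol",
    [
        ("C16H13N3OS", 295.36, 0.02),
        ("C20H21N3O4SCo", 458.40, 0.02),
        ("C20H21N3O6SNi", 490.16, 0.02),
        ("H2", 2.016, 0.001),
    ],
)
def test_average_mass(formula, expected, tol):
    assert average_mass(formula) == pytest.approx(expected, abs=tol)


@pytest.mark.parametrize(
    "formula, expected, tol",
    [
        ("C13H7N2OS", 239.03, 0.01),
        ("C12H6NO", 180.04, 0.01),
        ("H2O", 18.0106, 0.001),  # 2 x 1.007825 + 15.994915
    ],
)
def test_monoisotopic_mass(formula, expected, tol):
    assert monoisotopic_mass(formula) == pytest.approx(expected, abs=tol)


@pytest.mark.parametrize(
    "formula, element, expected",
    [
        ("C16H13N3OS", "C", 65.07),
        ("C16H13N3OS", "H", 4.44),
        ("C16H13N3OS", "N", 14.23),
        ("C20H19N3O5SZn", "C", 50.17),
        ("C20H19N3O5SZn", "N", 8.78),
    ],
)
def test_element_percents_match_reported_microanalysis(formula, element, expected):
    assert element_percents(formula)[element] == pytest.approx(expected, abs=0.05)


def test_element_percents_single_element():
    assert element_percents("N2") == pytest.approx({"N": 100.0})


_ELEMENT_POOL = ["C", "H", "N", "O", "S", "Co", "Ni", "Zn", "Cl", "Fe"]


@st.composite
def formulas(draw):
    n = draw(st.integers(min_value=1, max_value=5))
    symbols = draw(st.permutations(_ELEMENT_POOL))[:n]
    return ChemicalFormula({s: draw(st.integers(min_value=1, max_value=30)) for s in symbols})


@given(formulas())
@settings(max_examples=100, deadline=None)
def test_element_percents_sum_to_100(f):
    assert sum(element_percents(f).values()) == pytest.approx(100.0, abs=0.01)


@given(formulas(), st.integers(min_value=1, max_value=7))
@settings(max_examples=100, deadline=None)
def test_masses_scale_linearly_and_mono_below_average(f, n):
    assert average_mass(n * f) == pytest.approx(n * average_mass(f), rel=1e-12)
    assert monoisotopic_mass(n * f) == pytest.approx(n * monoisotopic_mass(f), rel=1e-12)
    assert monoisotopic_mass(f) <= average_mass(f) * 1.01


@pytest.mark.parametrize(
    "parent, fragments, expected, tol",
    [
        ("C20H21N3O4SCo", ["OAc", "EtOH"], 22.93, 0.05),
        ("C20H21N3O6SNi", ["(OAc)2", "H2O"], 27.75, 0.1),
        ("C20H19N3O5SZn", ["(OAc)2"], 24.62, 0.1),
        ("C16H13N3OS", ["HCNS", "C3H6"], 34.25, 0.1),  # thioamide + allyl moieties
        ("C20H21N3O4SCo", [], 0.0, 1e-12),
    ],
)
def test_loss_percent(parent, fragments, expected, tol):
    assert loss_percent(parent, fragments) == pytest.approx(expected, abs=tol)


@pytest.mark.parametrize(
    "parent, residue, expected, tol",
    [
        ("C20H21N3O4SCo", "CoO", 16.35, 0.05),
        ("C20H19N3O5SZn", "ZnO", 16.99, 0.1),
        ("C20H21N3O6SNi", "NiO", 15.24, 0.1),
        ("H2O", "H2O", 100.0, 1e-9),
    ],
)
def test_residue_percent(parent, residue, expected, tol):
    assert residue_percent(parent, residue) == pytest.approx(expected, abs=tol)


def test_fragments_heavier_than_parent_rejected():
    with pytest.raises(FormulaError):
        loss_percent("H2O", ["C16H13N3OS"])
    with pytest.raises(FormulaError):
        residue_percent("H2O", "CoO")


# --- fragment-loss assignment ------------------------------------------------


def brute_force_assign(parent, observed, pool, tol):
    """Exhaustive cross-product enumeration; reference for assign_losses."""
    pm = average_mass(parent)
    items = [(parse_formula(f) if isinstance(f, str) else f, mx) for f, mx in pool]
    hits = []
    for combo in itertools.product(*[range(mx + 1) for _, mx in items]):
        if not any(combo):
            continue
        frags = []
        for (f, _), k in zip(items, combo):
            frags.extend([f] * k)
        mass = sum(average_mass(f) for f in frags)
        if mass > pm:
            continue
        calc = 100.0 * mass / pm
        if abs(calc - observed) <= tol:
            hits.append((frags, calc))
    hits.sort(
        key=lambda e: (abs(e[1] - observed), len(e[0]), tuple(sorted(f.hill() for f in e[0])))
    )
    return [tuple(sorted(frags, key=lambda f: f.hill())) for frags, _ in hits]


def test_assign_losses_recovers_reported_first_step():
    hits = assign_losses(
        "C20H21N3O4SCo", 22.56, [("OAc", 1), ("EtOH", 1), ("H2O", 1)], tol=1.0
    )
    assert hits, "expected at least one assignment"
    assert tuple(f.hill() for f in hits[0]) == ("C2H3O2", "C2H6O")


def test_assign_losses_nickel_first_step():
    hits = assign_losses(
        "C20H21N3O6SNi", 28.01, [("OAc", 2), ("H2O", 1), ("EtOH", 1)], tol=1.0
    )
    assert tuple(f.hill() for f in hits[0]) == ("C2H3O2", "C2H3O2", "H2O")


def test_assign_losses_no_positive_mass_subset_matches_zero():
    assert assign_losses("C20H21N3O4SCo", 0.0, [("H2O", 1), ("OAc", 1)], tol=0.01) == []


@pytest.mark.parametrize("observed, tol", [(22.56, 1.0), (28.01, 1.0), (13.0, 2.0), (50.0, 5.0)])
def test_assign_losses_matches_brute_force(observed, tol):
    pool = [("OAc", 2), ("H2O", 3), ("EtOH", 2), ("CO2", 2), ("NH3", 3)]
    parent = "C20H21N3O6SNi"
    got = assign_losses(parent, observed, pool, tol=tol)
    want = brute_force_assign(parent, observed, pool, tol=tol)
    assert [tuple(f.hill() for f in m) for m in got] == [
        tuple(f.hill() for f in m) for m in want
    ]


def test_assign_losses_validates_inputs():
    with pytest.raises(ValueError):
        assign_losses("H2O", 10.0, [], tol=1.0)
    with pytest.raises(ValueError):
        assign_losses("H2O", 10.0, [("H2O", 1)], tol=0.0)
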