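"""Octahedral d7/d8 ligand-field forward models and (Dq, B) solvers."""

import math

import numpy as np
import pytest

from coordchar import (
    LigandFieldError,
    TransitionSet,
    forward_d7,
    forward_d8,
    solve_d7,
    solve_d8,
    solve_numeric,
)


def test_forward_d8_exact_triple():
    # root term: sqrt(225*800^2 + 100*1000^2 - 180*1000*800) = 10000 exactly
    assert forward_d8(1000, 800) == pytest.approx((10000, 16000, 26000))


def test_forward_d8_degenerate_b_zero():
    nu1, nu2, _ = forward_d8(1000, 0)
    assert nu1 == nu2 == pytest.approx(10000)


def test_forward_d7_closed_form_values():
    nu1, nu2, nu3 = forward_d7(800, 700)
    assert nu3 == pytest.approx(math.sqrt(275_050_000))
    assert nu2 == pytest.approx(15.0 * 800 - 7.5 * 700 + nu3 / 2)
    assert nu1 == pytest.approx(nu2 - 8000)


@pytest.mark.parametrize("dq, b", [(800, 700), (1475, 399), (500, 1100), (2000, 300)])
def test_d7_band_difference_is_ten_dq(dq, b):
    nu1, nu2, _ = forward_d7(dq, b)
    assert nu2 - nu1 == pytest.approx(10 * dq, rel=1e-12)


def test_solve_d8_reproduces_reported_nickel_parameters():
    sol = solve_d8(14750, 19050)
    assert sol.Dq == pytest.approx(1476, rel=0.005)
    assert sol.B == pytest.approx(399, rel=0.005)
    assert sol.predicted[2] == pytest.approx(31195, rel=0.005)


def test_solve_d7_reproduces_reported_cobalt_parameters():
    sol = solve_d7(15085, 17010)
    assert sol.B == pytest.approx(729, rel=0.005)
    assert sol.ten_dq == pytest.approx(8020, rel=0.005)
    assert sol.predicted[0] == pytest.approx(7049, rel=0.005)


def test_solve_d8_inverts_forward_example():
    sol = solve_d8(10000, 16000)
    assert sol.Dq == pytest.approx(1000, rel=1e-9)
    assert sol.B == pytest.approx(800, rel=1e-9)


def test_solve_d7_inverts_forward_example():
    sol = solve_d7(15042.3157, 16584.6314)
    assert sol.Dq == pytest.approx(800, rel=1e-4)
    assert sol.B == pytest.approx(700, rel=1e-4)


def test_parameter_recovery_round_trips():
    """forward -> solve recovers 200 seeded (Dq, B) draws to < 1e-4 relative.

    d8 admits any positive (Dq, B); for d7 the quartet-P band lies above
    nu2 only while B > (20/27) Dq, so draws outside that physical region
    are replaced (the ion would not show the assumed band ordering there).
    """
    rng = np.random.default_rng(2024)
    done_d8 = done_d7 = 0
    while done_d8 < 200 or done_d7 < 200:
        dq = rng.uniform(500, 2000)
        b = rng.uniform(300, 1100)
        if done_d8 < 200:
            nu = forward_d8(dq, b)
            sol = solve_d8(nu[0], nu[1])
            assert sol.Dq == pytest.approx(dq, rel=1e-4)
            assert sol.B == pytest.approx(b, rel=1e-4)
            done_d8 += 1
        if done_d7 < 200 and b > (20.0 / 27.0) * dq * 1.001:
            nu = forward_d7(dq, b)
            sol = solve_d7(nu[1], nu[2])
            assert sol.Dq == pytest.approx(dq, rel=1e-4)
            assert sol.B == pytest.approx(b, rel=1e-4)
            done_d7 += 1


def test_numeric_solver_agrees_with_closed_forms():
    for bands, config, closed in [
        ({"nu1": 14750.0, "nu2": 19050.0}, "d8", solve_d8(14750, 19050)),
        ({"nu2": 15085.0, "nu3": 17010.0}, "d7", solve_d7(15085, 17010)),
    ]:
        num = solve_numeric(config, bands)
        assert num.Dq == pytest.approx(closed.Dq, abs=0.01)
        assert num.B == pytest.approx(closed.B, abs=0.01)


def test_numeric_solver_agrees_on_random_draws():
    rng = np.random.default_rng(7)
    for _ in range(100):
        dq = rng.uniform(500, 2000)
        b = rng.uniform(300, 1100)
        nu = forward_d8(dq, b)
        num = solve_numeric("d8", {"nu1": nu[0], "nu2": nu[1]})
        assert num.Dq == pytest.approx(dq, abs=0.01)
        assert num.B == pytest.approx(b, abs=0.01)


@pytest.mark.parametrize("k", [0.5, 2.0, 10.0])
def test_solution_scales_with_band_positions(k):
    base = solve_d7(15085, 17010)
    scaled = solve_d7(15085 * k, 17010 * k)
    assert scaled.Dq == pytest.approx(k * base.Dq, rel=1e-9)
    assert scaled.B == pytest.approx(k * base.B, rel=1e-9)
    base8 = solve_d8(14750, 19050)
    scaled8 = solve_d8(14750 * k, 19050 * k)
    assert scaled8.B == pytest.approx(k * base8.B, rel=1e-9)


def test_inconsistent_band_pairs_rejected():
    with pytest.raises(LigandFieldError):
        solve_d8(16000, 10000)  # reversed order
    with pytest.raises(LigandFieldError):
        solve_d8(10000, 40000)  # no positive B reproduces this pair
    with pytest.raises(LigandFieldError):
        solve_d7(17010, 15085)


def test_transition_set_validation():
    ts = TransitionSet("d8", nu1=14750, nu2=19050)
    assert ts.nu3 is None
    with pytest.raises(ValueError):
        TransitionSet("d8", nu1=19050, nu2=14750)
    with pytest.raises(ValueError):
        TransitionSet("d5", nu1=1.0)
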