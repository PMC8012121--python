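"""Powder-XRD microstructure: Bragg, Scherrer, strain, dislocation, cell fit."""

import math

import numpy as np
import pytest

from coordchar import (
    DiffractionPeak,
    MonoclinicCell,
    bragg_d,
    dislocation_density,
    fit_monoclinic_cell,
    gen_xrd_peaks,
    microstrain,
    monoclinic_inv_d2,
    scherrer_size,
    summarize,
)


@pytest.mark.parametrize(
    "two_theta, expected",
    [(6.99, 12.63), (11.90, 7.43), (15.65, 5.66), (24.31, 3.66), (41.84, 2.16)],
)
def test_bragg_d_matches_reported_spacings(two_theta, expected):
    assert bragg_d(two_theta, 1.5406) == pytest.approx(expected, abs=0.01)


def test_bragg_backscattering_limit():
    assert bragg_d(180 - 1e-9, 1.5406) == pytest.approx(1.5406 / 2)


@pytest.mark.parametrize(
    "two_theta, fwhm, expected, tol",
    [(6.99, 0.76, 10.48, 0.05), (20.18, 0.53, 15.24, 0.1), (11.90, 1.91, 4.19, 0.05)],
)
def test_scherrer_size_matches_reported_values(two_theta, fwhm, expected, tol):
    assert scherrer_size(two_theta, fwhm, 1.5406, 0.9) == pytest.approx(expected, abs=tol)


def test_scherrer_inverse_in_width():
    assert scherrer_size(20.0, 1.0) == pytest.approx(2 * scherrer_size(20.0, 2.0))


@pytest.mark.parametrize(
    "two_theta, fwhm, expected",
    [(6.99, 0.76, 54.2e-3), (24.31, 0.72, 14.6e-3), (11.90, 1.91, 79.8e-3)],
)
def test_microstrain_matches_reported_values(two_theta, fwhm, expected):
    assert microstrain(two_theta, fwhm) == pytest.approx(expected, rel=0.01)


def test_microstrain_linear_in_width():
    assert microstrain(30.0, 0.5) == pytest.approx(0.5 * microstrain(30.0, 1.0))
    assert microstrain(30.0, 1e-9) == pytest.approx(0.0, abs=1e-10)


@pytest.mark.parametrize(
    "size, expected", [(10.48, 9.10e-3), (1.0, 1.0), (4.19, 56.9e-3)]
)
def test_dislocation_density(size, expected):
    assert dislocation_density(size) == pytest.approx(expected, rel=0.01)


def test_summarize_reproduces_reported_averages(zn_peaks):
    s = summarize(zn_peaks, wavelength=1.5406, K=0.9)
    assert s.mean_size == pytest.approx(9.10, abs=0.1)
    assert s.mean_strain == pytest.approx(33.6e-3, rel=0.02)
    assert s.mean_dislocation == pytest.approx(24.8e-3, rel=0.02)
    assert s.size_range[0] == pytest.approx(4.19, abs=0.05)
    for row in s.rows:
        assert row.dislocation == pytest.approx(1.0 / row.size**2, rel=1e-12)


def test_summarize_single_peak_averages_equal_row():
    s = summarize([DiffractionPeak(20.0, 0.5)])
    (row,) = s.rows
    assert s.mean_size == row.size
    assert s.mean_strain == row.strain
    assert s.size_range == (row.size, row.size)


def test_summarize_reports_offending_row():
    class _Corrupt:  # bypasses DiffractionPeak construction-time validation
        two_theta = 200.0
        fwhm = 0.5

    with pytest.raises(ValueError, match="row 1"):
        summarize([DiffractionPeak(20.0, 0.5), _Corrupt()])


def test_peak_validation():
    with pytest.raises(ValueError):
        DiffractionPeak(0.0, 0.5)
    with pytest.raises(ValueError):
        DiffractionPeak(20.0, -0.5)
    with pytest.raises(ValueError):
        DiffractionPeak(0.3, 0.5)


def test_monoclinic_reduces_to_orthorhombic_at_90():
    cell = MonoclinicCell(10.0, 10.0, 10.0, 90.0)
    assert monoclinic_inv_d2(cell, (1, 0, 0)) == pytest.approx(1e-2)
    assert 1 / math.sqrt(monoclinic_inv_d2(cell, (1, 0, 0))) == pytest.approx(10.0)


def test_monoclinic_inv_d2_against_direct_arithmetic():
    a, b, c, beta_deg = 8.405, 10.183, 13.731, 104.4
    h, k, l = 1, 1, 0
    beta = math.radians(beta_deg)
    expected = (
        h**2 / (a**2 * math.sin(beta) ** 2)
        + k**2 / b**2
        + l**2 / (c**2 * math.sin(beta) ** 2)
        - 2 * h * l * math.cos(beta) / (a * c * math.sin(beta) ** 2)
    )
    cell = MonoclinicCell(a, b, c, beta_deg)
    assert monoclinic_inv_d2(cell, (h, k, l)) == pytest.approx(expected, rel=1e-12)


@pytest.mark.parametrize("hkl", [(1, 1, 1), (2, 0, 3), (-4, 0, 3), (3, 2, -1)])
def test_monoclinic_inv_d2_even_under_hl_negation(hkl):
    cell = MonoclinicCell(8.405, 10.183, 13.731, 104.4)
    h, k, l = hkl
    assert monoclinic_inv_d2(cell, hkl) == pytest.approx(
        monoclinic_inv_d2(cell, (-h, k, -l)), rel=1e-12
    )


# a well-conditioned indexing set: axial reflections fix each edge, mixed and
# higher-order h0l reflections fix the monoclinic angle
_HKLS = [(1, 0, 0), (0, 1, 0), (0, 0, 1), (2, 0, 0), (0, 2, 0), (0, 0, 2),
         (1, 1, 0), (0, 1, 1), (-1, 0, 1), (1, 0, 1), (-2, 0, 1), (2, 0, 1),
         (2, 1, 0), (1, 2, 1), (0, 2, 2), (-2, 0, 3)]


def test_cell_fit_recovers_generator_cell_with_noise():
    true = MonoclinicCell(8.405, 10.183, 13.731, 104.4)
    peaks = gen_xrd_peaks(true, _HKLS, size_nm=10, position_noise=0.001, seed=11)
    d_obs = [bragg_d(p.two_theta) for p in peaks]
    fit, resid = fit_monoclinic_cell(
        [p.hkl for p in peaks], d_obs, MonoclinicCell(8.0, 10.0, 14.0, 100.0)
    )
    for got, want in [(fit.a, true.a), (fit.b, true.b), (fit.c, true.c), (fit.beta, true.beta)]:
        assert got == pytest.approx(want, rel=0.005)
    assert len(resid) == len(_HKLS)


def test_cell_fit_exact_on_noise_free_orthorhombic_with_beta_fixed():
    true = MonoclinicCell(8.0, 10.0, 14.0, 90.0)
    peaks = gen_xrd_peaks(true, _HKLS, size_nm=10, seed=0)
    d_obs = [bragg_d(p.two_theta) for p in peaks]
    fit, resid = fit_monoclinic_cell(
        [p.hkl for p in peaks], d_obs, MonoclinicCell(7.0, 11.0, 13.0, 90.0), fix_beta=True
    )
    assert fit.a == pytest.approx(8.0, rel=1e-6)
    assert fit.b == pytest.approx(10.0, rel=1e-6)
    assert fit.c == pytest.approx(14.0, rel=1e-6)
    assert np.max(np.abs(resid)) < 1e-9


def test_cell_fit_underdetermined():
    with pytest.raises(ValueError, match="under-determined"):
        fit_monoclinic_cell(
            [(1, 0, 0), (0, 1, 0), (0, 0, 1)],
            [8.0, 10.0, 14.0],
            MonoclinicCell(8.0, 10.0, 14.0, 104.0),
        )
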