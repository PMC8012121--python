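# Methods

This note records the models behind each module, the defaults and why they
were chosen, what the synthetic-data generators do and do not emulate, and
the numerical choices a user adjusting the package should know about.

## Composition

Average atomic masses are abundance-weighted isotopic masses from the NIST
isotopic-composition table bundled with `pyteomics`; these agree with IUPAC
standard atomic weights to well under 0.05 u for the elements relevant here
(the largest deviation among them is Zn, ~0.03 u). Monoisotopic masses use
each element's most abundant isotope. Radical dots and charges on fragment
formulas are ignored: the electron mass (5×10⁻⁴ u) is far below the 0.01 u
working precision. Formula strings are case-sensitive; the alias registry
(`OAc`, `EtOH`, `H2O`, `AAT`, `HAAT`) is consulted before element tokens, so
`OAc` is always acetate, never oxygen–actinium — users needing an actual
O–Ac formula should write the counts explicitly.

`assign_losses` enumerates fragment multisets depth-first with pruning on
cumulative mass and a 10⁶-node cap, sufficient for any realistic leaving-group
pool (a 12-item pool is ~10³ combinations). Matches are ordered by distance
from the observed loss, then by fewer fragments, then lexicographically by
Hill formula; the empty multiset is never a match, so an observed loss of 0
returns no assignments.

## Ligand field

The octahedral weak-field closed forms for the spin-allowed quartet (d⁷) and
triplet (d⁸) transitions are used; spin–orbit coupling and the Racah C
parameter are outside the model, as is any tetrahedral or lower-symmetry
field. Two identities follow algebraically and are enforced by construction:
ν₁ = 10Dq (d⁸) and ν₂ − ν₁ = 10Dq (d⁷). The solvers invert the closed forms
exactly — d⁸ reduces to a linear equation in B after squaring, d⁷ to a
quadratic — and every solution is round-trip-verified through the forward
model to 0.1 cm⁻¹; squaring can introduce a spurious root, and the round-trip
check is what rejects it. A physically meaningful d⁷ solution additionally
requires B > (20/27)·Dq; below that ratio the ⁴T₁g(P) level would fall below
⁴A₂g and the assumed band ordering breaks, so such band pairs are rejected
rather than silently relabeled.

The independent numeric solver (`solve_numeric`, a 2-D Powell-hybrid root
find on the forward model) exists as a cross-check; when it and the closed
form disagree beyond 0.01 cm⁻¹ the caller sees an error, never an average.

Error propagation is worth knowing: B amplifies band-position error roughly
sevenfold in relative terms near (Dq, B) = (1000, 800) cm⁻¹, so a 1%
uncertainty on the band pair yields a median ~6% uncertainty on B with a tail
past 10%. Reported B values from two-band fits should be read with that in
mind.

## Powder-XRD microstructure

FWHM values are degrees of 2θ and are converted to radians before use; the
Scherrer shape factor defaults to K = 0.9 and the wavelength to Cu Kα
(1.5406 Å), both overridable. Size and strain are computed independently per
peak — no Williamson–Hall separation and no instrumental-broadening
subtraction — and the summary reports unweighted arithmetic means, matching
how such tables are conventionally presented. The dislocation-density column
is dimensionally nm⁻² (δ = 1/D²) and is reported as such.

Monoclinic cell refinement minimizes residuals in 1/d² (linear in the
reciprocal-metric elements, well-behaved for least squares) over (a, b, c, β)
with β bounded to [90°, 180°); at β = 90° the relation reduces to the
orthorhombic form, and an option fixes β there. At least four indexed peaks
are required (three with β fixed). Conditioning matters more than count: an
indexing confined to low orders leaves β and c strongly correlated, while
including higher-order h0l reflections pins the monoclinic angle — the
synthetic validation uses a 16-reflection set spanning axial and mixed orders
for this reason.

## Tauc band gap

The plotted quantity is (αhν)^r with r = 2 for direct and ½ for indirect
transitions (the convention in which a direct edge gives a straight (αhν)²
plot; the opposite exponent convention exists in the literature, so the CLI
help states this one). Absorbance in arbitrary units is used directly as α —
solution spectra carry no meaningful thickness normalization, and the
x-intercept is invariant to scaling α.

The linear region is selected by exhaustive search over all contiguous
windows of at least `min_window` points (default 5): among positive-slope
windows the one maximizing R² wins, ties to the longer window, then to the
higher-energy one. Exhaustive search is O(n²) in the number of points with
O(1) per-window fits from cumulative sums, acceptable through ~10⁴-point
spectra. On noisy data the R² criterion can favor short windows; the
recovered gap is robust in the tested regime (≤1% relative noise), but users
with noisier spectra should raise `min_window`. `mode="auto"` runs both
exponents and keeps the fit with higher R².

## Descriptors and interpretation rules

The descriptor formulas are the standard finite-difference conceptual-DFT
set; orbital energies are taken as given from any electronic-structure
package and nothing is computed about the molecule itself. Softness is named
`softness` rather than its customary symbol to avoid colliding with the
dislocation density. Gap ranking is ascending and stable.

The acetate-mode threshold of 200 cm⁻¹ is the smallest round value
separating the monodentate (Δν ≈ 312 cm⁻¹) and bidentate (Δν ≈ 139–154 cm⁻¹)
regimes in the reference series; it is configurable, and separations in the
160–170 cm⁻¹ band typical of free ionic acetate are flagged with a caveat
rather than auto-classified. IC₅₀ bins are inclusive at their left edges and
gap values (e.g. 10.5 µM) fall to the stronger class; classification uses the
mean, with any stated standard deviation carried as annotation only. The
selectivity flag is strict (SI > 2).

## Synthetic data

Each generator inverts its analysis stage: absorption edges from
α = A(hν − E_g)^{1/r}/hν (zero below the gap, default span 1.2–4.0 eV,
200 points — the visible/near-UV range such solution spectra cover);
diffraction peaks from the monoclinic 1/d² relation with widths from the
inverted Scherrer equation; d–d triples from the forward ligand-field model;
decomposition traces whose residue is the parent minus all fragments, so
percentages sum to 100 exactly at zero noise. Noise models are the simplest
adequate for recovery testing: Gaussian relative noise on absorbance and band
positions, Gaussian absolute noise (degrees) on FWHM floored at 0.05°. All
randomness flows through `numpy.random.default_rng(seed)`; identical
configurations give identical output.

What the generators do **not** emulate — and hence what passing recovery
tests do not establish about real data: instrumental broadening, background
and Kα₁/Kα₂ splitting in powder patterns; solvent baselines, scattering tails
and Urbach tails in absorption spectra; band overlap and charge-transfer
interference in d–d spectra; kinetic smearing and overlapping steps in
thermogravimetry. Recovery results on synthetic inputs bound the algorithmic
error only.

## Problem sizes

The default validation runs use 200-point spectra, 9–16-reflection peak
tables, 200-draw parameter-recovery sweeps, and 100-seed noise studies —
sizes at which every property suite completes in seconds while the
statistics (medians over seeded grids) are stable.

## Known limitations

No raw-pattern peak detection or profile fitting; no automatic indexing; no
Tanabe–Sugano matrix diagonalization for arbitrary dⁿ; no isotope-pattern
simulation; no dose–response fitting. Orbital energies, peak tables and band
positions must be supplied — the package post-processes instrument-derived
numbers, it does not reduce raw instrument output.
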