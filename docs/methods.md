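# Methods

## The problem

A triple-quadrupole mass spectrometer scanned in profile mode has unit
resolution (R_FWHM ≈ 500) and a mass axis that drifts by hundreds of
millidaltons. Two post-acquisition steps nevertheless make formula
assignment possible: (i) an internal-calibrant mass-axis correction, which
recovers millidalton-level mass accuracy, and (ii) spectral-accuracy
scoring, which exploits the *shape* of the unresolved isotope envelope to
discriminate among the formula candidates that survive the mass-tolerance
filter. `specacc` implements both, plus the candidate enumeration and
isotope-pattern machinery they need, and a synthetic-spectrum generator
that provides ground truth for testing.

## Atomic data and mass arithmetic

Isotope masses and abundances are vendored as JSON
(`specacc/data/isotopes.json`, version string `NIST-2021/CODATA-2018`) for
C, H, N, O, Na, P, S, Cl, together with the electron mass
(0.000548579909 Da). Pinning the table makes 4-decimal exact-mass
agreement reproducible regardless of which reference tables other installed
libraries carry; the test suite cross-checks against pyteomics'
independent table to 0.1 mDa.

* Monoisotopic mass: neutral-atom sum over each element's most abundant
  isotope.
* Ion m/z: `(mass(ion composition) − z·mₑ)/|z|`. The electron-mass
  correction (~0.55 mDa) is required for 4-decimal agreement at z = +1.
* RDBE: `1 + Σ nᵢ(vᵢ−2)/2` with C=4, N=3(P=3), O=2(S=2), H=Cl=Na=F=1.
  Sodium is treated as monovalent (like H), so fully saturated protonated
  or sodiated even-electron cations reach the −0.5 floor. For odd-|z| ions
  under this valence model, even-electron ⇔ half-integer RDBE.
* Δm (mass accuracy): (measured − exact) × 1000, reported to 0.1 mDa.

Formulas render in Hill order (C, H, then alphabetical) with the charge as
a trailing sign repeated |z| times; the parser also accepts typeset
variants (underscores, carets, Unicode sub/superscripts). A digit before
the sign always binds to the preceding element count, so `NH4+` is H₄,
z = +1 — rendering multi-charges as repeated signs keeps the notation
round-trippable.

## Candidate enumeration

Depth-first search over elements in order of decreasing atomic mass with
branch-and-bound pruning on the minimum/maximum achievable mass of the
remaining elements. It is exhaustive (verified against a naive Cartesian
scan in the tests) and runs in well under a millisecond for the default
constraint box. Candidates are enumerated directly as ion compositions
(adduct atoms included), filtered by RDBE window and electron parity, and
ordered by |Δm| with Hill-string tie-breaks. A configurable cap
(default 100 000) aborts runaway searches.

The default constraints — C 2–25, H 0–50, N 0–10, O 0–10, Na 0–1, Cl 0–5,
±10 mDa, charge +1, RDBE −0.5 to 20, even-electron — are exposed as the
preset `qqq2018_constraints()`, the standard box for ESI+ small-molecule
work where Na is a ubiquitous adduct former and Cl the only halogen in
play.

## Isotope patterns

Fine-structure distributions are computed by exact convolution: each
element's n-atom distribution via exponentiation-by-squaring of its
single-atom distribution, then convolution across elements. Peaks closer
than 1 µDa are merged (abundance-weighted); intermediate results are pruned
at 10⁻³ × the final threshold (default 10⁻⁸ relative) so pruning never
disturbs the reported pattern. FFT-based methods would gain nothing at the
≤ 50-atom scale and lose exactness. The tests verify the convolution
against brute-force isotopologue expansion for small formulas and check
order-independence of the convolution.

`aggregate_nominal` sums fine structure into M, M+1, … clusters within
±0.3 Th of `mono + k` — unambiguous for CHNONaClPS chemistry below
m/z 1000, where intra-cluster spacing is ≤ 13 mDa and inter-cluster
spacing ~1.003 Da.

Profile rendering places a unit-area Gaussian at each centroid, scaled by
abundance, with FWHM from the line-shape model; the integral equals the
summed abundances to 0.1 %. The default grid step of 0.01 Th gives ≥ 40
samples per FWHM at R ≈ 500; rendering touches only the ±10σ neighbourhood
of each centroid, so long acquisition grids stay cheap.

## Line-shape model and calibration

The line shape is Gaussian with FWHM(m) = a + b·m. The default anchors
b = 1/500 (FWHM ≈ 0.44 Th at m/z 222), the single resolving-power anchor
available for this instrument class; both parameters are re-fitted from
calibrant peaks in every calibration.

**Calibrant detection.** Each calibrant is sought within ±0.5 Th of its
expected ion m/z (wide enough for pre-calibration errors of several hundred
mDa). A calibrant whose apex is below a signal floor (default 5× the
spectrum-wide median intensity) is flagged missed rather than contributing
a bogus position — low-signal calibrants are a known source of large
calibrated-mass shifts.

**Centroid estimator.** Intensity-weighted mean over the contiguous run of
samples above 50 % of the apex, with three refinements that the naive
estimator needs at this resolution:

* the run stops at a valley only when intensity rebounds by > 15 % of the
  peak prominence above the running minimum — a plain "stop on any uptick"
  rule truncates at the first noise wiggle near the apex and quantises the
  centroid to the 10-mDa grid;
* the run is symmetrised about the apex, so the flank of a partially
  resolved neighbour cannot extend one side of it;
* weights are the intensity *excess over half-maximum*, making the result
  insensitive to whether edge samples just clear the threshold.

The standalone `centroid()` peak picker adds one more pass: each peak is
re-centroided after subtracting the Gaussian reconstruction of every other
peak, which removes the few-mTh pull that a ten-fold taller neighbour one
line width away exerts (M+1 next to M at R ≈ 500).

**Mass-axis fit.** Least-squares polynomial of order min(n−1, 2) through
(measured, true) centroid pairs; two calibrants give a linear map, three an
exact quadratic interpolation. Order is capped at 2 because 3–4 calibrants
are typical and a cubic would interpolate noise. The fitted map must be
monotone over its validity range (calibrant span ± 25 %); applying it
outside that range flags the output as extrapolated. Per-calibrant
residuals are stored in the model and round-trip bit-exactly through JSON.

**Width fit.** Each calibrant's FWHM comes from a four-parameter Gaussian
fit (amplitude, centre, σ, constant offset) restricted to the peak's own
valley-bounded run above 35 % of the apex. Two numerical choices matter
here: the offset floats in the fit because any fixed estimate taken from
below-half samples is biased by the peak's own tails; and the 35 % cut is
deliberate — at R ≈ 500 the M/M+1 valley bottoms out near 20 % of the apex,
so a lower cut (or a fixed ±1 Th window) sweeps the M+1 isotope into the
fit and biases FWHM several percent low, which then distorts every SA
score. With ≥ 2 calibrants a straight line FWHM = a + b·m is fitted through
the per-peak widths; one calibrant gives a constant model. Peaks with
fewer than 5 samples above half maximum are rejected (grid too coarse).

**Applying the model.** The m/z axis is mapped through the polynomial and
the intensities are linearly interpolated onto a uniform grid at the native
median step; the resampling conserves integrated intensity to well under
0.1 %. Rather than reshaping the measured data onto an idealised target
function, the *theoretical* patterns are later rendered in the fitted
instrument shape — the comparison happens in the instrument's own space,
with identical SA semantics and none of the instability of deconvolution.

## Spectral accuracy and ranking

For each candidate: render its isotope pattern in the fitted shape on the
observed grid of a window centred at the candidate's exact monoisotopic
m/z (post-calibration residuals are far smaller than the window), subtract
the baseline from both sides, and compute

SA = 100 · (1 − ‖o − s·t‖₂/‖o‖₂),  s = max(0, ⟨o,t⟩/⟨t,t⟩),

clipped at 0. SA is scale-invariant in both arguments and reaches 100 only
for a perfect fit. An all-zero observed window yields an *undefined* SA
marker (not 0); such candidates sink to the bottom of the ranking, flagged.

Baseline handling is the median of the lowest decile of window intensities,
floored at zero — robust when isotope peaks occupy most of the window, and
applied **identically to the observed and the theoretical window**. The
symmetric treatment matters: at R ≈ 500 the theoretical profile has a
non-zero floor from overlapping peak tails, and subtracting a floor from
only the observed side leaves a constant-offset residual that swamps the
small SA differences between near-isobaric candidates.

Ranking is SA-descending with ties broken by smaller |Δm| and then Hill
string. Δm is recomputed per candidate from the observed monoisotopic
centroid within ±0.3 Th of the candidate's exact m/z. The default window
(−0.5, +3.5) Da spans M..M+3; narrowing it (e.g. to +2.5 Da) excludes an
interference sitting in the M+3 region, which is exactly the intervention
the windowed design exists for.

## Synthetic data generator

`simulate_spectrum` renders the full isotope pattern of each species in the
configured shape, shifts every centroid through a polynomial mass-axis
distortion (raw = true + d(true), order ≤ 2), adds a constant baseline and
seeded additive Gaussian noise, and clips at zero. Species given as bare
m/z values become single interference peaks. `simulate_acquisition_series`
derives per-scan seeds deterministically from a master seed, so a fixed
seed is bit-reproducible and averaging n scans shows the expected √n noise
reduction.

Default conditions mirror routine ESI+ acquisition on a Quattro-class
instrument: scan range m/z 150–350, grid step 0.01 Th, R_FWHM ≈ 500,
~100 acquisitions per sample. Test scenarios use quadratic distortions
reaching ~0.38 Th (the magnitude of the worst drift such instruments show
before correction), per-scan analyte SNR ≈ 100, and — for the
low-abundance scenario — noise placing the analyte's M+2 at roughly 3× the
averaged background, i.e. "just above" it.

What the generator does **not** model: ionisation efficiency and matrix
suppression, detector (counting) statistics, peak asymmetry, scan-to-scan
mass jitter, and chromatography. Consequently, passing tests demonstrate
the correctness of the calibration/scoring machinery under the stated
noise model, not performance in complex matrices; on real data the
absolute SA values and ranks will be less favourable (interferences and
ion suppression dominate there).

## Numerical choices and degenerate inputs

* Pruning threshold 10⁻⁸ relative; M..M+3 cluster abundances for all test
  ions change by < 0.01 percentage points when tightened to 10⁻¹⁰.
* Tolerance boundaries are inclusive (|Δm| ≤ tolerance).
* Duplicate measured calibrant positions, single-pair axis fits,
  non-monotone fitted maps, empty element boxes, zero-charge ions, and
  centroid-mode mzML input all raise explicit errors; an empty SA window
  returns an undefined-SA marker; rendering a pattern entirely outside the
  requested window returns a flagged all-zero spectrum.
* Negative-mode ions are supported by symmetry (electrons added per
  negative charge) but exercised only lightly by the tests; all reference
  chemistry is ESI+.

## Known limitations

* The Gaussian-only line shape has no asymmetry term; a skewed instrument
  function is fitted as well as a symmetric model can (the fit succeeds,
  with residuals).
* SA discrimination between near-isobaric candidates whose patterns differ
  by < 1 % (e.g. CₙHₘN₇O vs Cₙ₊₂Hₘ₊₅NO₃Na) is genuinely marginal at
  R ≈ 500 and can be decided by noise; this mirrors the instrument's real
  limitation rather than a software one.
* The mzML reader covers the profile-MS1 subset (32/64-bit float arrays,
  none/zlib compression); chromatograms, MSⁿ and vendor raw formats are
  out of scope.
* Average (isotope-weighted) masses are deliberately not implemented;
  everything is monoisotopic.
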