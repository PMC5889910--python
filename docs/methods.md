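# Methods

## Scope and model assumptions

The package treats a quenching titration as a set of steady-state
fluorescence intensities `F([Q])` at fixed protein concentration, with a
single unquenched reference `F0`. Three standard results are computed,
each with its own assumptions:

**Stern–Volmer constant.** `F0/F = 1 + K_SV [Q]` holds exactly for purely
collisional quenching and is used as a linear summary regardless of
mechanism (its slope is what titration tables report). The intercept is
pinned at exactly 1 by default — the value the equation dictates at
`[Q] = 0` — so the estimator is the one-parameter least squares
`K_SV = Σ q (y − 1) / Σ q²` on `y = F0/F`. A free-intercept two-parameter
fit is available as a diagnostic (`fix_intercept=False`); on exact data
the two coincide. A negative fitted slope means fluorescence
*enhancement*; it is flagged on the result rather than raised, because a
titration that enhances is an answer, not a malfunction.

**Quenching classification.** `K_q = K_SV / τ0` with the conventional
biopolymer lifetime `τ0 = 10⁻⁸ s`. Classification is *static* iff `K_q`
strictly exceeds the diffusion-controlled limit `2.0 × 10¹⁰ M⁻¹ s⁻¹`; a
value exactly at the threshold is labelled dynamic (the criterion is
"higher than", and a collisional rate *at* the diffusion limit is
physically possible). Both `τ0` and the threshold are parameters.

**Binding constant and site number.** The double-log form
`log₁₀((F0−F)/F) = log₁₀ K + n log₁₀ [Q]` assumes static quenching of `n`
independent identical sites and is fitted by ordinary least squares in
log space — the linearisation practitioners plot. Points with `F ≥ F0`
have no defined logarithm and carry no quenching information; they are
excluded and their indices recorded on the result, rather than aborting,
because real titrations put noisy points above `F0` at low `[Q]`. The
zero-quencher row never enters this fit (log 0).

**Free energy.** `ΔG = −RT ln K` with `R = 8.314 J mol⁻¹ K⁻¹`, computed
with the natural logarithm rather than the `−2.303 RT log₁₀ K` form so no
truncation of the 2.303 factor enters. The default temperature is
298.15 K (25 °C); tabulated literature values of this kind typically
back-calculate at 298 K, so the temperature is an explicit parameter
everywhere it matters.

## CD analysis

Ellipticity in millidegrees is converted to mean residue ellipticity
`MRE = θ_obs / (10 · n_res · C_p · l)` with `C_p` molar protein
concentration and `l` the path length in cm; for 20 µM HSA (585 residues,
1 cm) the denominator is 0.117. Helix content uses the Chen–Yang
single-wavelength calibration `% helix = (−MRE₂₂₂ − 2340)/30300 × 100`.
The sign convention matters: the 222 nm band of a folded helix is
*negative*, and `−MRE₂₂₂` is the increasing measure of helicity; the
calibration is only self-consistent in that form. θ at 222 nm is read by
linear interpolation between the bracketing grid points. Percentages
outside [0, 100] are returned as computed and flagged out-of-range, never
clamped — a "−8 % helix" reading is diagnostic of a denatured or blank
input and silently clamping it would hide that.

Full secondary-structure deconvolution (β-sheet, turn, coil via
CONTIN-class algorithms) is out of scope; only the α-helix fraction is
quantified.

## UV analysis

Peak position within a window (default 270–300 nm) is located at the grid
argmax and refined by the vertex of the parabola through the three
surrounding points (correct for uneven grids); on a 1 nm grid this
resolves shifts well below 0.1 nm for smooth bands. Flat maxima tie-break
toward the longer wavelength with a warning. Hyperchromism is evaluated
at the *reference* spectrum's peak wavelength,
`100 · (A_spec(λmax_ref) − A_ref(λmax_ref)) / A_ref(λmax_ref)`, so
amplitude growth is reported separately from the shift; evaluating each
spectrum at its own maximum would conflate the two. Difference spectra
subtract on the exact common grid when grids match, otherwise on the
finer grid restricted to the overlap with linear resampling. No
baseline or scatter correction is applied.

## Synthetic data generator

The generator emulates the study conditions of an HSA binding titration:
5 µM protein excited at 295 nm with emission near 340 nm, quencher on a
0.5–10 µM grid (9 points: 0.5, 1, 1.5, 2, 3, 4, 5, 7.5, 10 µM); 20 µM
protein, 190–250 nm, 1 cm path for CD; 240–320 nm with a 280 nm band for
UV. Defaults for the truth parameters (`K = 3.74 × 10⁶ M⁻¹`, `n = 1.1`,
`K_SV = 5.37 × 10⁵ M⁻¹`) are the strong-binder regime such titrations
report.

* Static mode inverts the double-log model exactly:
  `F = F0 / (1 + K [Q]^n)`, so the analyzer must recover `(K, n)` to
  numerical precision at zero noise.
* Dynamic mode generates on the Stern–Volmer line itself.
* Noise is multiplicative Gaussian on intensities (photomultiplier
  shot-noise proxy), default 1 % when enabled, seeded via
  `numpy.random.default_rng`; identical (truth, seed, grid) gives
  bit-identical output. `F0` is reported noise-free, as the
  zero-quencher reference is conventionally averaged until stable.
* CD columns are a fixed three-Gaussian template (positive band at
  193 nm, negative at 208 and 222 nm; σ = 9, 10, 10 nm) rescaled so the
  *linearly interpolated* θ(222 nm) on the caller's grid maps to exactly
  the requested helix percentage — the generator and analyzer share the
  same read-out convention, so the round trip is exact on any grid, and
  only the 222 nm value is contractually meaningful.
* UV columns couple shift and amplitude to the bound fraction
  `f_b = K[Q]^n / (1 + K[Q]^n)`: center `280 + shift · f_b`, amplitude
  `∝ (1 + hyperchromism/100 · f_b)`. This coupling is a modelling
  convenience for end-to-end tests, not a physical claim.

What the generator does *not* emulate: inner-filter effects, dilution
during titration (intensities are treated as uncorrected, matching
common practice), FRET, lifetime distributions, wavelength-dependent
noise, and baseline drift. Passing recovery tests therefore demonstrate
the estimators' correctness and noise behaviour, not robustness to those
instrumental artefacts.

## Attainable recovery precision

At 1 % multiplicative noise on the 9-point 0.5–10 µM grid, the site
number `n` is recovered with median error ≈ 0.005–0.03 across
`K ∈ [5×10⁵, 5×10⁶] M⁻¹`, `n ∈ [1.0, 1.2]`. The binding constant is
harder: because the intercept of the log-log line sits ~5.5 decades
outside the sampled `log₁₀[Q]` range, slope noise is amplified into
`log₁₀ K`, and the median relative error in `K` is ≈ 4–15 % depending on
where in the regime the truth lies (worst where `K[Q]^n` is smallest and
the quenching signal at low `[Q]` is comparable to the noise). This floor
is information-theoretic, not an estimator artefact: an exact
maximum-likelihood nonlinear fit for the multiplicative noise model gives
a regime-median of ≈ 6–7 %, only modestly better than the log-space OLS.
The test suite asserts a 5 % median bound for `K` in this regime as an
aspirational acceptance property; it documents the gap rather than
relaxing the bound, and the companion `n` bound (0.05) holds with a wide
margin.

## Numerical choices

* All concentrations are mol/L internally; units are a property of I/O
  (`M`, `mM`, `uM`, `nM` exact power-of-ten factors).
* CSV writers use `%.17g` and readers `float_precision="round_trip"`, so
  write→read round trips are bit-exact.
* "Exact" round-trip tolerances are 1e-8 relative, reflecting
  double-precision linear algebra through `polyfit`/`lstsq`.
* Brute-force grid-search cross-checks of the binding fit allow the
  discrete argmin to sit a few grid cells from the continuous optimum
  along the correlated (log₁₀ K, n) ridge; the fit is additionally
  required to have an SSE no worse than the best grid point.
* Degenerate inputs: fewer than 3 usable points raise; duplicate
  concentrations raise; zero/negative intensities raise with the row
  named; flat peak windows warn and tie-break long.
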