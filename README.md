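# bindspec

Spectroscopic analysis of small-molecule binding to proteins, built around
the workflow used to characterise drug candidates binding human serum
albumin (HSA): fluorescence quenching titrations, far-UV circular
dichroism, and UV–visible absorbance. It is aimed at wet-lab scientists
who have titration tables or spectra as CSV exports and want binding
constants, quenching classification, free energies, and secondary-structure
changes with reproducible, testable arithmetic — plus a seeded synthetic
generator so the whole pipeline can be validated by parameter recovery.

## The model

A quenching titration records fluorescence `F` at fixed protein
concentration and increasing quencher `[Q]`, with `F0` the unquenched
intensity. The package implements:

* **Stern–Volmer analysis** — `F0/F = 1 + K_SV [Q]`. The slope `K_SV`
  (M⁻¹) measures quenching efficiency; `K_q = K_SV / τ0` with
  `τ0 = 10⁻⁸ s` (biopolymer lifetime) is compared to the
  diffusion-controlled limit `2.0 × 10¹⁰ M⁻¹ s⁻¹`: values strictly above
  it imply *static* quenching (ground-state complex), otherwise *dynamic*
  (collisional).
* **Double-log binding fit** — `log₁₀((F0−F)/F) = log₁₀ K + n log₁₀ [Q]`,
  giving the binding constant `K` (M⁻¹) and the number of binding sites
  `n` for independent identical sites.
* **Gibbs free energy** — `ΔG = −RT ln K` (identical to the
  `−2.303 RT log₁₀ K` form), `R = 8.314 J mol⁻¹ K⁻¹`.
* **CD helix content** — observed ellipticity (mdeg) is converted to mean
  residue ellipticity `MRE = θ_obs / (10 · n_res · C_p · l)` and scored at
  222 nm by the Chen–Yang calibration
  `% α-helix = (−MRE₂₂₂ − 2340) / 30300 × 100`.
* **UV signatures** — bathochromic (red) shift of the 280 nm band and
  hyperchromism, with three-point parabolic peak refinement so nm-scale
  shifts are resolved below the grid spacing.
* **Beer–Lambert** protein concentration from A280
  (`ε₂₈₀ = 36500 M⁻¹ cm⁻¹` for HSA).

## Worked example

Simulate a noisy titration with known ground truth and analyse it:

```
$ bindspec simulate quench --seed 3 --k 3.74e6 --n 1.1 --noise 0.01 --out synth.csv
wrote synth.csv (+ .truth.json)
$ bindspec quench --input synth.csv --temp 298 --out row.json
Ksv = 1.161e+06 M^-1 (11.6 x 1e5 M^-1)
Kq  = 1.161e+14 M^-1 s^-1 (116 x 1e12) -> static
K   = 4.716e+06 M^-1, n = 1.12
dG  = -38.07 kJ/mol at 298.0 K
```

`Kq` far above `2e10 M⁻¹ s⁻¹` classifies the quenching as static, i.e.
the ligand forms a ground-state complex with the protein. The recovered
binding constant `K = 4.7e6 M⁻¹` and `n = 1.12` sit within the sampling
scatter of the true values (`3.74e6`, `1.1`) at 1 % intensity noise — see
`docs/methods.md` for the attainable recovery precision. `ΔG < 0`
confirms spontaneous association. The same works for CD:

```
$ bindspec simulate cd --out cd.csv
$ bindspec cd --input cd.csv --out helix.json
0 M: 67.03% alpha-helix
0.02 M: 64.07% alpha-helix
0.04 M: 62.23% alpha-helix
...
```

a free protein that is 67 % helical and progressively unfolds as ligand
is added. The library API mirrors the CLI
(`bindspec.analyze_titration`, `bindspec.helix_series`,
`bindspec.peak_summary`, `bindspec.generate_quenching`, ...).

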