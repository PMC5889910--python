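"""Seeded synthetic titration generators with known ground truth.

Raw spectra for serum-albumin quenching studies are rarely deposited, so
every analysis stage here is validated by parameter recovery instead:
each generator runs the corresponding binding model *forward* from known
parameters, and a matching analyzer must invert it.

* Fluorescence (static binding): ``F = F0 / (1 + K [Q]^n)`` — the exact
  inverse of the double-log binding regression.
* Fluorescence (dynamic): ``F = F0 / (1 + Ksv [Q])`` — the Stern-Volmer
  line itself.
* Far-UV CD: a three-Gaussian-band template (positive ~193 nm, negative
  ~208 and ~222 nm) scaled per column so that the 222 nm ellipticity
  reproduces a requested helix percentage exactly.
* UV absorbance: a Gaussian 280 nm band whose displacement and amplitude
  grow with the bound fraction ``fb = K [Q]^n / (1 + K [Q]^n)``.

Noise is multiplicative Gaussian on fluorescence intensities (a
shot-noise proxy) and additive in millidegrees on CD; both are
reproducible under a seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cd import CHEN_YANG, HelixCalibration, mre_for_helix, theta_from_mre
from .errors import ValidationError
from .io import ProteinSpec, SpectrumTable, TitrationSeries

__all__ = [
    "SyntheticTruth",
    "generate_quenching",
    "generate_cd",
    "generate_uv",
    "bound_fraction",
    "HSA_TITRATION_GRID_M",
]

#: Quencher grid (mol/L) typical of an HSA titration: 0.5-10 uM in the
#: steps used for a 5 uM protein emission titration.
HSA_TITRATION_GRID_M = np.array([0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 5.0, 7.5, 10.0]) * 1e-6


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth parameters a synthetic dataset was generated from."""

    mode: str = "static_binding"  # or "dynamic"
    k_true: float = 3.74e6  # binding constant, M^-1 (static mode)
    n_true: float = 1.1  # binding sites (static mode)
    ksv_true: float = 5.37e5  # Stern-Volmer constant, M^-1 (dynamic mode)
    f0_true: float = 1000.0  # unquenched intensity, AU
    noise_rel: float = 0.0  # relative Gaussian noise SD
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("static_binding", "dynamic"):
            raise ValidationError("mode must be 'static_binding' or 'dynamic'")
        if self.mode == "static_binding" and self.k_true <= 0:
            raise ValidationError("k_true must be positive")
        if self.mode == "dynamic" and self.ksv_true <= 0:
            raise ValidationError("ksv_true must be positive")
        if self.f0_true <= 0:
            raise ValidationError("f0_true must be positive")
        if self.noise_rel < 0:
            raise ValidationError("noise_rel must be nonnegative")


def generate_quenching(
    truth: SyntheticTruth, concentrations: np.ndarray | None = None
) -> TitrationSeries:
    """Forward-simulate a quenching titration from known parameters.

    Static mode generates ``F = F0 / (1 + K [Q]^n)``; dynamic mode
    ``F = F0 / (1 + Ksv [Q])``.  Multiplicative noise ``F (1 + eps)``,
    ``eps ~ N(0, noise_rel)``, is applied per point, deterministically
    under ``truth.seed``.  F0 itself is reported noise-free (the
    zero-quencher reference is conventionally averaged until stable).
    """
    q = HSA_TITRATION_GRID_M if concentrations is None else np.asarray(concentrations, float)
    if np.any(q <= 0):
        raise ValidationError("quencher concentrations must be positive")
    if len(np.unique(q)) != len(q):
        raise ValidationError("quencher concentrations must be distinct")

    if truth.mode == "static_binding":
        f = truth.f0_true / (1.0 + truth.k_true * q ** truth.n_true)
    else:
        f = truth.f0_true / (1.0 + truth.ksv_true * q)

    if truth.noise_rel > 0:
        rng = np.random.default_rng(truth.seed)
        f = f * (1.0 + rng.normal(0.0, truth.noise_rel, size=f.shape))
        f = np.clip(f, np.finfo(float).tiny, None)

    return TitrationSeries(
        quencher_conc=q,
        intensity=f,
        f0=truth.f0_true,
        emission_wavelength=340.0,
        excitation_wavelength=295.0,
    )


# CD band template: (center nm, sigma nm, relative amplitude).  Signs give
# the characteristic alpha-helical far-UV shape; widths produce realistic
# band overlap.  Only the 222 nm value is contractually exact.
_CD_BANDS = ((193.0, 9.0, 1.6), (208.0, 10.0, -1.0), (222.0, 10.0, -1.0))


def _cd_template(wavelength: np.ndarray) -> np.ndarray:
    s = np.zeros_like(wavelength, dtype=float)
    for center, sigma, amp in _CD_BANDS:
        s += amp * np.exp(-0.5 * ((wavelength - center) / sigma) ** 2)
    return s


def generate_cd(
    helix_percents,
    concentrations,
    protein: ProteinSpec,
    path_cm: float = 1.0,
    noise_mdeg: float = 0.0,
    seed: int = 0,
    wavelength: np.ndarray | None = None,
    cal: HelixCalibration = CHEN_YANG,
) -> SpectrumTable:
    """Synthesize far-UV CD spectra hitting given helix percentages.

    Each column is the band template rescaled so that the ellipticity
    read at 222 nm — by the same linear interpolation the analyzer uses —
    converts to exactly the requested helix percentage before noise.
    """
    helix = np.asarray(helix_percents, dtype=float)
    conc = np.asarray(concentrations, dtype=float)
    if helix.shape != conc.shape:
        raise ValidationError("helix_percents and concentrations must have equal length")
    if np.any((helix < 0) | (helix > 100)):
        raise ValidationError("helix percentages must lie in [0, 100]")
    if wavelength is None:
        wavelength = np.arange(190.0, 250.5, 0.5)
    wavelength = np.asarray(wavelength, dtype=float)

    template = _cd_template(wavelength)
    t222 = float(np.interp(222.0, wavelength, template))
    if t222 >= 0:
        raise ValidationError("wavelength grid must resolve the negative 222 nm band")

    rng = np.random.default_rng(seed)
    cols = np.empty((len(wavelength), len(helix)))
    for j, h in enumerate(helix):
        theta222 = theta_from_mre(
            mre_for_helix(float(h), cal), protein.n_residues, protein.concentration, path_cm
        )
        cols[:, j] = template * (theta222 / t222)
    if noise_mdeg > 0:
        cols = cols + rng.normal(0.0, noise_mdeg, size=cols.shape)
    return SpectrumTable(
        wavelength=wavelength,
        signal=cols,
        signal_kind="ellipticity",
        concentrations=conc,
    )


def bound_fraction(q, k: float, n: float) -> np.ndarray:
    """Fraction of protein bound at quencher concentration(s) ``q``,
    ``fb = K q^n / (1 + K q^n)`` for the single-site-class model."""
    q = np.asarray(q, dtype=float)
    kq = k * q ** n
    return kq / (1.0 + kq)


def generate_uv(
    shift_nm: float,
    hyperchromism_percent: float,
    concentrations,
    k_true: float = 3.74e6,
    n_true: float = 1.1,
    wavelength: np.ndarray | None = None,
    peak_center: float = 280.0,
    sigma_nm: float = 8.0,
    base_amplitude: float = 0.5,
) -> SpectrumTable:
    """Synthesize UV absorbance spectra with binding-coupled shift/growth.

    Column ``c`` is a Gaussian band centred at ``280 + shift_nm * fb(c)``
    with amplitude ``base * (1 + hyperchromism/100 * fb(c))``, where the
    bound fraction fb follows the single-site binding model.  A zero
    concentration gives the unperturbed reference band.
    """
    if not np.isfinite(shift_nm):
        raise ValidationError("shift_nm must be finite")
    conc = np.asarray(concentrations, dtype=float)
    if np.any(conc < 0):
        raise ValidationError("concentrations must be nonnegative")
    if wavelength is None:
        wavelength = np.arange(240.0, 320.5, 0.5)
    wavelength = np.asarray(wavelength, dtype=float)

    fb = np.where(conc > 0, bound_fraction(np.maximum(conc, 1e-300), k_true, n_true), 0.0)
    cols = np.empty((len(wavelength), len(conc)))
    for j in range(len(conc)):
        center = peak_center + shift_nm * fb[j]
        amp = base_amplitude * (1.0 + hyperchromism_percent / 100.0 * fb[j])
        cols[:, j] = amp * np.exp(-0.5 * ((wavelength - center) / sigma_nm) ** 2)
    return SpectrumTable(
        wavelength=wavelength,
        signal=cols,
        signal_kind="absorbance",
        concentrations=conc,
    )
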