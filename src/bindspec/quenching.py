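"""Fluorescence quenching analysis.

Implements the Stern-Volmer treatment of a quenching titration:

* linear Stern-Volmer fit, ``F0/F = 1 + Ksv [Q]``, giving the quenching
  constant Ksv (M^-1);
* the bimolecular quenching rate constant ``Kq = Ksv / tau0`` and its
  comparison against the diffusion-controlled limit (~2e10 M^-1 s^-1) to
  classify quenching as static (ground-state complex) or dynamic
  (collisional);
* the double-log (modified Stern-Volmer) regression
  ``log10((F0-F)/F) = log10 K + n log10 [Q]`` giving the binding constant K
  and the number of binding sites n;
* the standard Gibbs free energy of association, ``dG = -R T ln K``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InsufficientDataError, ValidationError
from .io import TitrationSeries

__all__ = [
    "TAU0_BIOPOLYMER",
    "STATIC_QUENCHING_THRESHOLD",
    "GAS_CONSTANT",
    "SternVolmerResult",
    "BindingFit",
    "GibbsResult",
    "TitrationAnalysis",
    "stern_volmer_fit",
    "bimolecular_rate",
    "classify_quenching",
    "modified_sv_fit",
    "gibbs_free_energy",
    "analyze_titration",
]

#: Unquenched fluorophore lifetime assumed for biopolymers, seconds.
TAU0_BIOPOLYMER = 1e-8

#: Diffusion-controlled collisional limit of Kq, M^-1 s^-1.  A fitted Kq
#: strictly above this cannot be purely collisional, implying static
#: quenching via ground-state complex formation.
STATIC_QUENCHING_THRESHOLD = 2.0e10

#: Molar gas constant R, J mol^-1 K^-1.
GAS_CONSTANT = 8.314


@dataclass
class SternVolmerResult:
    """Outcome of a linear Stern-Volmer fit."""

    ksv: float  # Stern-Volmer constant, M^-1
    intercept: float  # fitted or fixed at 1 (dimensionless)
    kq: float  # bimolecular quenching rate constant, M^-1 s^-1
    tau0: float  # fluorophore lifetime used, s
    r_squared: float
    classification: str  # "static" or "dynamic"
    threshold: float  # classification threshold, M^-1 s^-1
    enhancement_warning: bool = False  # negative slope: enhancement, not quenching

    @property
    def ksv_1e5(self) -> float:
        """Ksv in units of 1e5 M^-1 (as binding tables conventionally print)."""
        return self.ksv / 1e5

    @property
    def kq_1e12(self) -> float:
        """Kq in units of 1e12 M^-1 s^-1."""
        return self.kq / 1e12


@dataclass
class BindingFit:
    """Outcome of the double-log binding regression."""

    k: float  # binding constant, M^-1
    n_sites: float  # number of binding sites (slope), dimensionless
    log10_k: float
    r_squared: float
    n_points_used: int
    excluded_points: list[int] = field(default_factory=list)


@dataclass
class GibbsResult:
    """Standard free energy of binding at a stated temperature."""

    delta_g: float  # J/mol
    temperature: float  # K
    gas_constant: float = GAS_CONSTANT  # J mol^-1 K^-1

    @property
    def delta_g_kj(self) -> float:
        return self.delta_g / 1000.0


@dataclass
class TitrationAnalysis:
    """One titration analysed end to end: Ksv, Kq, K, n and dG together."""

    stern_volmer: SternVolmerResult
    binding: BindingFit | None
    gibbs: GibbsResult | None
    errors: list[str] = field(default_factory=list)


def _r_squared(y: np.ndarray, y_hat: np.ndarray) -> float:
    ss_res = float(np.sum((y - y_hat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res == 0.0 else 0.0
    return 1.0 - ss_res / ss_tot


def stern_volmer_fit(
    series: TitrationSeries,
    fix_intercept: bool = True,
    tau0: float = TAU0_BIOPOLYMER,
    threshold: float = STATIC_QUENCHING_THRESHOLD,
) -> SternVolmerResult:
    """Fit ``F0/F = 1 + Ksv [Q]`` by least squares.

    With ``fix_intercept`` (default) the intercept is pinned at exactly 1,
    the form the equation dictates, and only the slope is estimated;
    otherwise an ordinary two-parameter line is fitted as a diagnostic.
    A negative fitted slope flags fluorescence enhancement rather than
    raising.
    """
    if len(series) < 3:
        raise InsufficientDataError("Stern-Volmer fit needs >= 3 nonzero-quencher points")
    q = series.quencher_conc
    y = series.f0 / series.intensity

    if fix_intercept:
        ksv = float(np.dot(q, y - 1.0) / np.dot(q, q))
        intercept = 1.0
    else:
        coeffs, *_ = np.linalg.lstsq(np.column_stack([q, np.ones_like(q)]), y, rcond=None)
        ksv, intercept = float(coeffs[0]), float(coeffs[1])

    r2 = _r_squared(y, intercept + ksv * q)
    kq = bimolecular_rate(ksv, tau0)
    classification = classify_quenching(kq, threshold) if kq >= 0 else "dynamic"
    return SternVolmerResult(
        ksv=ksv,
        intercept=intercept,
        kq=kq,
        tau0=tau0,
        r_squared=r2,
        classification=classification,
        threshold=threshold,
        enhancement_warning=ksv < 0,
    )


def bimolecular_rate(ksv: float, tau0: float = TAU0_BIOPOLYMER) -> float:
    """Bimolecular quenching rate constant, ``Kq = Ksv / tau0`` (M^-1 s^-1)."""
    if tau0 <= 0:
        raise ValidationError("tau0 must be positive")
    if not math.isfinite(ksv):
        raise ValidationError("ksv must be finite")
    return ksv / tau0


def classify_quenching(
    kq: float, threshold: float = STATIC_QUENCHING_THRESHOLD
) -> str:
    """Classify quenching as ``"static"`` iff Kq strictly exceeds the
    diffusion-controlled threshold, else ``"dynamic"``."""
    if kq < 0:
        raise ValidationError("kq must be nonnegative")
    return "static" if kq > threshold else "dynamic"


def modified_sv_fit(series: TitrationSeries) -> BindingFit:
    """Double-log binding fit: regress log10((F0-F)/F) on log10 [Q].

    The slope estimates the number of binding sites n and the intercept
    log10 of the binding constant K.  Points with F >= F0 (no net
    quenching, typically noise at low quencher) are excluded and their
    indices recorded.
    """
    f0 = series.f0
    usable = series.intensity < f0
    excluded = [int(i) for i in np.flatnonzero(~usable)]
    if int(usable.sum()) < 3:
        raise InsufficientDataError(
            f"double-log fit needs >= 3 points with F < F0; have {int(usable.sum())}"
        )
    q = series.quencher_conc[usable]
    f = series.intensity[usable]
    x = np.log10(q)
    y = np.log10((f0 - f) / f)
    slope, intercept = np.polyfit(x, y, 1)
    r2 = _r_squared(y, intercept + slope * x)
    return BindingFit(
        k=float(10.0 ** intercept),
        n_sites=float(slope),
        log10_k=float(intercept),
        r_squared=r2,
        n_points_used=int(usable.sum()),
        excluded_points=excluded,
    )


def gibbs_free_energy(k: float, temperature: float = 298.15) -> GibbsResult:
    """Standard free energy of binding, ``dG = -R T ln K`` in J/mol.

    Mathematically identical to the -2.303 R T log10 K form but free of
    the truncation in the 2.303 factor.
    """
    if k <= 0:
        raise ValidationError("binding constant must be positive")
    if temperature <= 0:
        raise ValidationError("temperature must be positive")
    return GibbsResult(
        delta_g=-GAS_CONSTANT * temperature * math.log(k),
        temperature=temperature,
    )


def analyze_titration(
    series: TitrationSeries,
    tau0: float = TAU0_BIOPOLYMER,
    temperature: float = 298.15,
    threshold: float = STATIC_QUENCHING_THRESHOLD,
    fix_intercept: bool = True,
) -> TitrationAnalysis:
    """Run all three fits on one titration and return the combined record.

    Component failures downstream of the Stern-Volmer fit (e.g. too few
    quenched points for the binding regression) are collected in
    ``errors`` rather than raised, so a partially analysable titration
    still yields its Stern-Volmer diagnostics.
    """
    sv = stern_volmer_fit(
        series, fix_intercept=fix_intercept, tau0=tau0, threshold=threshold
    )
    binding: BindingFit | None = None
    gibbs: GibbsResult | None = None
    errors: list[str] = []
    try:
        binding = modified_sv_fit(series)
        gibbs = gibbs_free_energy(binding.k, temperature=temperature)
    except (InsufficientDataError, ValidationError) as exc:
        errors.append(str(exc))
    return TitrationAnalysis(stern_volmer=sv, binding=binding, gibbs=gibbs, errors=errors)
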