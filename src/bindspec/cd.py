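"""Circular dichroism analysis: mean residue ellipticity and helix content.

The observed far-UV ellipticity (millidegrees) is normalised per residue,
molar concentration and path length to the mean residue ellipticity

    MRE = theta_obs / (10 * n_residues * Cp * l)   [deg cm^2 dmol^-1]

and the alpha-helix content follows the Chen-Yang single-wavelength
calibration at 222 nm,

    % helix = (-MRE_222 - 2340) / 30300 * 100,

where 2340 deg cm^2 dmol^-1 is the residual -MRE of a fully disordered
chain and 30300 the span to a 100% helical one.  The negative 222 nm band
deepens with helicity, so -MRE_222 is the increasing measure of helix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import RangeError, ValidationError
from .io import ProteinSpec, SpectrumTable

__all__ = [
    "MREParams",
    "HelixCalibration",
    "HelixSeries",
    "CHEN_YANG",
    "mre_from_theta",
    "theta_from_mre",
    "helix_fraction",
    "mre_for_helix",
    "helix_series",
]


@dataclass(frozen=True)
class MREParams:
    """Inputs of the ellipticity-to-MRE conversion."""

    theta_obs: float  # observed ellipticity, millidegrees
    n_residues: int  # residue count (585 for HSA)
    c_protein: float  # molar protein concentration, mol/L
    path_cm: float  # cuvette path length, cm

    def __post_init__(self) -> None:
        if self.n_residues < 1:
            raise ValidationError("n_residues must be >= 1")
        if self.c_protein <= 0:
            raise ValidationError("protein concentration must be positive")
        if self.path_cm <= 0:
            raise ValidationError("path length must be positive")


@dataclass(frozen=True)
class HelixCalibration:
    """Linear calibration mapping -MRE_222 to percent alpha-helix."""

    baseline: float = 2340.0  # -MRE_222 of a 0% helical chain, deg cm^2 dmol^-1
    span: float = 30300.0  # -MRE_222 range from 0% to 100% helix

    def __post_init__(self) -> None:
        if self.span <= 0:
            raise ValidationError("calibration span must be positive")


#: Default 222 nm helix calibration constants.
CHEN_YANG = HelixCalibration()


@dataclass
class HelixSeries:
    """Per-concentration helix content along a ligand titration."""

    ligand_conc: list[float]
    helix_percent: list[float]
    mre_222: list[float]
    out_of_range: list[bool] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.ligand_conc)
        if not (len(self.helix_percent) == len(self.mre_222) == n):
            raise ValidationError("helix series fields must have equal lengths")
        if not self.out_of_range:
            self.out_of_range = [not (0.0 <= h <= 100.0) for h in self.helix_percent]


def mre_from_theta(p: MREParams) -> float:
    """Mean residue ellipticity from observed millidegrees; sign preserved."""
    return p.theta_obs / (10.0 * p.n_residues * p.c_protein * p.path_cm)


def theta_from_mre(
    mre: float, n_residues: int, c_protein: float, path_cm: float
) -> float:
    """Inverse of :func:`mre_from_theta`: millidegrees from MRE."""
    if c_protein <= 0 or path_cm <= 0:
        raise ValidationError("concentration and path length must be positive")
    return mre * 10.0 * n_residues * c_protein * path_cm


def helix_fraction(mre_222: float, cal: HelixCalibration = CHEN_YANG) -> float:
    """Percent alpha-helix from MRE at 222 nm.

    Values outside [0, 100] are returned as-is (callers flag rather than
    clamp them; an out-of-range value is diagnostic of a denatured or
    noisy spectrum, not an error).
    """
    if not math.isfinite(mre_222):
        raise ValidationError("mre_222 must be finite")
    return (-mre_222 - cal.baseline) / cal.span * 100.0


def mre_for_helix(helix_percent: float, cal: HelixCalibration = CHEN_YANG) -> float:
    """MRE at 222 nm that yields the given helix percentage (inverse map)."""
    return -(cal.baseline + cal.span * helix_percent / 100.0)


def _interp_at(wavelength: np.ndarray, signal: np.ndarray, target: float) -> float:
    if not (wavelength[0] <= target <= wavelength[-1]):
        raise RangeError(
            f"{target} nm outside measured range "
            f"[{wavelength[0]}, {wavelength[-1]}] nm"
        )
    return float(np.interp(target, wavelength, signal))


def helix_series(
    spectra: SpectrumTable,
    protein: ProteinSpec,
    path_cm: float = 1.0,
    cal: HelixCalibration = CHEN_YANG,
    c_protein: float | None = None,
) -> HelixSeries:
    """Helix content per column of an ellipticity spectrum table.

    For each ligand concentration the ellipticity is read at 222 nm by
    linear interpolation between the bracketing grid points, converted to
    MRE, and scored with the 222 nm calibration.  Output is ordered by
    concentration.
    """
    if spectra.signal_kind != "ellipticity":
        raise ValidationError("helix_series expects an ellipticity table")
    cp = protein.concentration if c_protein is None else c_protein
    if cp <= 0:
        raise ValidationError("protein concentration must be positive")
    order = np.argsort(spectra.concentrations, kind="stable")
    conc, mre222, helix = [], [], []
    for i in order:
        theta = _interp_at(spectra.wavelength, spectra.column(int(i)), 222.0)
        mre = mre_from_theta(
            MREParams(
                theta_obs=theta,
                n_residues=protein.n_residues,
                c_protein=cp,
                path_cm=path_cm,
            )
        )
        conc.append(float(spectra.concentrations[i]))
        mre222.append(mre)
        helix.append(helix_fraction(mre, cal))
    return HelixSeries(ligand_conc=conc, helix_percent=helix, mre_222=mre222)
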