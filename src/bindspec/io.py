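"""Tabular I/O, experiment constants, and concentration bookkeeping.

All concentrations are carried internally in mol/L; display units are a
reporting concern.  CSV dialects are deliberately minimal: comma-separated
with a header row, optional ``# key: value`` comment lines for metadata.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

__all__ = [
    "UNIT_FACTORS",
    "ProteinSpec",
    "TitrationSeries",
    "SpectrumTable",
    "HSA",
    "read_titration_csv",
    "read_spectrum_csv",
    "write_spectrum_csv",
    "write_titration_csv",
    "concentration_from_absorbance",
    "write_report",
    "read_report",
]

#: Multiplicative factors converting a concentration unit to mol/L.
UNIT_FACTORS = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "nM": 1e-9}

REPORT_SCHEMA = "bindspec/1"


@dataclass(frozen=True)
class ProteinSpec:
    """Identity and optical constants of the protein under study.

    Parameters
    ----------
    name : str
        Protein name, e.g. ``"HSA"``.
    n_residues : int
        Number of amino acid residues (585 for human serum albumin);
        enters the mean-residue-ellipticity conversion.
    epsilon_280 : float
        Molar extinction coefficient at 280 nm, M^-1 cm^-1.
    concentration : float
        Working molar concentration, mol/L.
    """

    name: str
    n_residues: int
    epsilon_280: float
    concentration: float = 0.0

    def __post_init__(self) -> None:
        if self.n_residues < 1:
            raise ValidationError("n_residues must be >= 1")
        if self.epsilon_280 <= 0:
            raise ValidationError("epsilon_280 must be positive")
        if self.concentration < 0:
            raise ValidationError("concentration must be nonnegative")


#: Human serum albumin with its standard extinction coefficient and size.
HSA = ProteinSpec(name="HSA", n_residues=585, epsilon_280=36500.0)


@dataclass
class TitrationSeries:
    """A fluorescence quenching titration at a fixed emission wavelength.

    ``quencher_conc`` holds the nonzero quencher concentrations (mol/L,
    strictly increasing) and ``intensity`` the fluorescence read at each;
    ``f0`` is the unquenched intensity at zero quencher.
    """

    quencher_conc: np.ndarray
    intensity: np.ndarray
    f0: float
    emission_wavelength: float | None = None
    excitation_wavelength: float | None = None

    def __post_init__(self) -> None:
        self.quencher_conc = np.asarray(self.quencher_conc, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.quencher_conc.shape != self.intensity.shape:
            raise ValidationError("quencher_conc and intensity lengths differ")
        if self.f0 <= 0:
            raise ValidationError("f0 must be positive")
        if np.any(self.intensity <= 0):
            bad = int(np.flatnonzero(self.intensity <= 0)[0])
            raise ValidationError(f"nonpositive intensity at row {bad}")
        if np.any(self.quencher_conc < 0):
            raise ValidationError("quencher concentrations must be nonnegative")
        order = np.argsort(self.quencher_conc, kind="stable")
        self.quencher_conc = self.quencher_conc[order]
        self.intensity = self.intensity[order]
        if np.any(np.diff(self.quencher_conc) <= 0):
            raise ValidationError("duplicate quencher concentrations")

    def __len__(self) -> int:
        return len(self.quencher_conc)

    def scaled(self, factor: float) -> "TitrationSeries":
        """Return a copy with all intensities (including F0) rescaled."""
        return TitrationSeries(
            quencher_conc=self.quencher_conc.copy(),
            intensity=self.intensity * factor,
            f0=self.f0 * factor,
            emission_wavelength=self.emission_wavelength,
            excitation_wavelength=self.excitation_wavelength,
        )


@dataclass
class SpectrumTable:
    """A set of spectra sharing one wavelength grid.

    ``signal`` is a 2-D array with one column per ligand concentration;
    ``signal_kind`` is one of ``absorbance``, ``fluorescence``,
    ``ellipticity``.
    """

    wavelength: np.ndarray
    signal: np.ndarray
    signal_kind: str
    concentrations: np.ndarray = field(default_factory=lambda: np.array([]))

    _KINDS = ("absorbance", "fluorescence", "ellipticity")

    def __post_init__(self) -> None:
        self.wavelength = np.asarray(self.wavelength, dtype=float)
        self.signal = np.atleast_2d(np.asarray(self.signal, dtype=float))
        if self.signal.shape[0] != self.wavelength.shape[0]:
            self.signal = self.signal.T
        if self.signal.shape[0] != self.wavelength.shape[0]:
            raise ValidationError("signal columns must match wavelength length")
        if np.any(np.diff(self.wavelength) <= 0):
            raise ValidationError("wavelength grid must be strictly increasing")
        if self.signal_kind not in self._KINDS:
            raise ValidationError(f"signal_kind must be one of {self._KINDS}")
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.concentrations.size == 0:
            self.concentrations = np.full(self.signal.shape[1], np.nan)
        if self.concentrations.shape[0] != self.signal.shape[1]:
            raise ValidationError("one concentration per signal column required")
        if np.any(self.concentrations < 0):
            raise ValidationError("concentrations must be nonnegative")

    @property
    def n_columns(self) -> int:
        return self.signal.shape[1]

    def column(self, i: int) -> np.ndarray:
        return self.signal[:, i]


def _parse_comment_metadata(path: Path) -> dict[str, str]:
    """Pull ``# key: value`` pairs from leading comment lines."""
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, value = body.partition(":")
                meta[key.strip().lower()] = value.strip()
    return meta


def read_titration_csv(path: str | Path, units: str | None = None) -> TitrationSeries:
    """Read a quenching titration from CSV.

    Expects columns ``conc`` and ``intensity``.  The zero-concentration row
    supplies F0 and is removed from the quencher arrays (its logarithm is
    undefined in the double-log binding fit); alternatively a ``# f0:``
    comment line may supply F0 explicitly.  ``units`` names the
    concentration unit (``M``/``mM``/``uM``/``nM``); if omitted, a
    ``# units:`` comment line is consulted, else mol/L is assumed.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    meta = _parse_comment_metadata(path)
    if units is None:
        units = meta.get("units", "M")
    if units not in UNIT_FACTORS:
        raise ValidationError(f"unknown concentration unit {units!r}")
    try:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    missing = {"conc", "intensity"} - set(df.columns)
    if missing:
        raise FormatError(f"missing columns {sorted(missing)} in {path}")

    conc = df["conc"].to_numpy(dtype=float) * UNIT_FACTORS[units]
    intensity = df["intensity"].to_numpy(dtype=float)
    if np.any(intensity <= 0):
        bad = int(np.flatnonzero(intensity <= 0)[0])
        raise ValidationError(f"nonpositive intensity at row {bad}")
    if len(np.unique(conc)) != len(conc):
        raise ValidationError("duplicate concentrations in titration file")

    zero = conc == 0.0
    if "f0" in meta:
        f0 = float(meta["f0"])
        if np.any(zero):
            raise FormatError("both an F0 header and a zero-concentration row present")
    elif np.count_nonzero(zero) == 1:
        f0 = float(intensity[zero][0])
    else:
        raise FormatError(
            "titration needs exactly one zero-concentration row or a '# f0:' header"
        )
    return TitrationSeries(
        quencher_conc=conc[~zero],
        intensity=intensity[~zero],
        f0=f0,
        emission_wavelength=float(meta["emission_nm"]) if "emission_nm" in meta else None,
        excitation_wavelength=float(meta["excitation_nm"]) if "excitation_nm" in meta else None,
    )


def write_titration_csv(series: TitrationSeries, path: str | Path, units: str = "M") -> None:
    """Write a titration to CSV (inverse of :func:`read_titration_csv`)."""
    if units not in UNIT_FACTORS:
        raise ValidationError(f"unknown concentration unit {units!r}")
    factor = UNIT_FACTORS[units]
    conc = np.concatenate([[0.0], series.quencher_conc / factor])
    intensity = np.concatenate([[series.f0], series.intensity])
    with open(path, "w") as fh:
        fh.write(f"# units: {units}\n")
        if series.emission_wavelength is not None:
            fh.write(f"# emission_nm: {series.emission_wavelength}\n")
        if series.excitation_wavelength is not None:
            fh.write(f"# excitation_nm: {series.excitation_wavelength}\n")
        pd.DataFrame({"conc": conc, "intensity": intensity}).to_csv(
            fh, index=False, float_format="%.17g"
        )


def read_spectrum_csv(
    path: str | Path, signal_kind: str, units: str | None = None
) -> SpectrumTable:
    """Read a multi-column spectrum table.

    Layout: a ``wavelength_nm`` column plus one signal column per ligand
    concentration, the column headers being the concentration values.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    meta = _parse_comment_metadata(path)
    if units is None:
        units = meta.get("units", "M")
    if units not in UNIT_FACTORS:
        raise ValidationError(f"unknown concentration unit {units!r}")
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    if "wavelength_nm" not in df.columns:
        raise FormatError(f"missing 'wavelength_nm' column in {path}")
    conc_cols = [c for c in df.columns if c != "wavelength_nm"]
    if not conc_cols:
        raise FormatError(f"no signal columns in {path}")
    try:
        concentrations = np.array([float(c) for c in conc_cols]) * UNIT_FACTORS[units]
    except ValueError as exc:
        raise FormatError("spectrum column headers must be concentration values") from exc
    return SpectrumTable(
        wavelength=df["wavelength_nm"].to_numpy(dtype=float),
        signal=df[conc_cols].to_numpy(dtype=float),
        signal_kind=signal_kind,
        concentrations=concentrations,
    )


def write_spectrum_csv(table: SpectrumTable, path: str | Path, units: str = "M") -> None:
    """Write a spectrum table to CSV (inverse of :func:`read_spectrum_csv`)."""
    if units not in UNIT_FACTORS:
        raise ValidationError(f"unknown concentration unit {units!r}")
    factor = UNIT_FACTORS[units]
    data = {"wavelength_nm": table.wavelength}
    for i, c in enumerate(table.concentrations):
        data[repr(float(c) / factor)] = table.signal[:, i]
    with open(path, "w") as fh:
        fh.write(f"# units: {units}\n")
        pd.DataFrame(data).to_csv(fh, index=False, float_format="%.17g")


def concentration_from_absorbance(
    a280: float, protein: ProteinSpec, path_cm: float = 1.0
) -> float:
    """Protein molarity from A280 via the Beer-Lambert law.

    Returns ``a280 / (epsilon_280 * path_cm)`` in mol/L.
    """
    if path_cm <= 0:
        raise ValidationError("path length must be positive")
    if a280 < 0:
        raise ValidationError("absorbance must be nonnegative")
    return a280 / (protein.epsilon_280 * path_cm)


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        d = {f.name: _to_jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
        d["_kind"] = type(obj).__name__
        return d
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not math.isfinite(obj):
        return repr(obj)
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    return obj


def write_report(result, path: str | Path, provenance: dict | None = None) -> None:
    """Serialize a fit/series result to a versioned JSON report.

    The report carries every fitted parameter with its units plus the
    constants used, and round-trips through :func:`read_report`.
    """
    doc = {"schema": REPORT_SCHEMA, "result": _to_jsonable(result)}
    if provenance:
        doc["provenance"] = _to_jsonable(provenance)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_report(path: str | Path):
    """Read a JSON report back into its result object."""
    from . import cd, quenching  # local import avoids a cycle

    registry = {
        cls.__name__: cls
        for cls in (
            quenching.SternVolmerResult,
            quenching.BindingFit,
            quenching.GibbsResult,
            quenching.TitrationAnalysis,
            cd.HelixSeries,
        )
    }

    def revive(node):
        if isinstance(node, dict):
            node = {k: revive(v) for k, v in node.items()}
            kind = node.pop("_kind", None)
            if kind is not None:
                cls = registry[kind]
                fields = {f.name for f in dataclasses.fields(cls)}
                return cls(**{k: v for k, v in node.items() if k in fields})
            return node
        if isinstance(node, list):
            return [revive(v) for v in node]
        if node in ("nan", "inf", "-inf"):
            return float(node)
        return node

    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("schema") != REPORT_SCHEMA:
        raise FormatError(f"unsupported report schema {doc.get('schema')!r}")
    return revive(doc["result"])
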