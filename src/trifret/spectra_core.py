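"""Fluorophore reference spectra: data model, I/O, resampling.

A :class:`FluorophoreRecord` bundles everything downstream FRET arithmetic
needs about one fluorophore: a unit-area emission density ``f(λ)`` (1/nm), a
molar extinction spectrum ``ε(λ)`` (M⁻¹·cm⁻¹), the fluorescence quantum
yield ``Q`` and the unquenched excited-state lifetime ``τ`` (ns).

All inter-spectrum arithmetic (overlap integrals, forward spectral
simulation) happens on a common 1 nm working grid spanning 300–800 nm;
spectra are zero outside their measured range, as physical spectra are.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "WavelengthGrid",
    "FluorophoreRecord",
    "WORKING_GRID",
    "load_spectrum",
    "resample",
    "synthetic_fluorophores",
]


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform wavelength grid [start, stop] with the given step, in nm."""

    start: float
    stop: float
    step: float

    def __post_init__(self) -> None:
        if not self.start < self.stop:
            raise ValueError(f"grid start must be below stop, got [{self.start}, {self.stop}]")
        if not self.step > 0:
            raise ValueError(f"grid step must be positive, got {self.step}")

    @property
    def n_points(self) -> int:
        return int(np.floor((self.stop - self.start) / self.step)) + 1

    def points(self) -> np.ndarray:
        return self.start + self.step * np.arange(self.n_points)


#: Common working grid for all inter-spectrum arithmetic: finer than any
#: bundled spectrum, so interpolation/integration error is negligible.
WORKING_GRID = WavelengthGrid(300.0, 800.0, 1.0)


@dataclass(frozen=True)
class FluorophoreRecord:
    """Spectra and photophysics of one fluorophore on a common wavelength axis.

    ``emission`` is a unit-area density (integrates to 1 over ``wavelengths``);
    ``extinction`` stays in absolute M⁻¹·cm⁻¹ so overlap integrals carry the
    conventional units.
    """

    name: str
    wavelengths: np.ndarray  # nm, strictly increasing
    emission: np.ndarray  # 1/nm, unit area
    extinction: np.ndarray  # M^-1 cm^-1
    quantum_yield: float
    lifetime_ns: float
    maturation_note: str = ""

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        em = np.asarray(self.emission, dtype=float)
        ex = np.asarray(self.extinction, dtype=float)
        if wl.ndim != 1 or len(wl) < 2:
            raise ValueError("need at least two wavelength samples")
        if np.any(np.diff(wl) <= 0):
            raise ValueError(f"{self.name}: wavelengths must be strictly increasing")
        if len(em) != len(wl) or len(ex) != len(wl):
            raise ValueError(f"{self.name}: spectra and wavelength axis length mismatch")
        if np.any(em < 0) or np.any(ex < 0):
            raise ValueError(f"{self.name}: spectra must be non-negative")
        if not 0.0 <= self.quantum_yield <= 1.0:
            raise ValueError(f"{self.name}: quantum yield must lie in [0, 1]")
        if not self.lifetime_ns > 0:
            raise ValueError(f"{self.name}: lifetime must be positive")
        area = np.trapezoid(em, wl)
        if abs(area - 1.0) > 1e-6:
            raise ValueError(f"{self.name}: emission density must integrate to 1 (got {area:.8f})")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "emission", em)
        object.__setattr__(self, "extinction", ex)

    @property
    def emission_peak_nm(self) -> float:
        """Wavelength of maximum emission; orders members on the energy ladder."""
        return float(self.wavelengths[int(np.argmax(self.emission))])

    def emission_at(self, wavelength_nm) -> np.ndarray:
        return np.interp(wavelength_nm, self.wavelengths, self.emission, left=0.0, right=0.0)

    def extinction_at(self, wavelength_nm) -> np.ndarray:
        return np.interp(wavelength_nm, self.wavelengths, self.extinction, left=0.0, right=0.0)


def _normalize_emission(wavelengths: np.ndarray, values: np.ndarray) -> np.ndarray:
    area = np.trapezoid(values, wavelengths)
    if area <= 0:
        raise ValueError("emission spectrum has zero area; cannot normalize")
    return values / area


def _read_spectrum_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    for col in ("wavelength_nm", "value"):
        if col not in df.columns:
            raise ValueError(f"{path}: spectrum CSV needs columns wavelength_nm,value")
    wl = df["wavelength_nm"].to_numpy(dtype=float)
    val = df["value"].to_numpy(dtype=float)
    if np.any(np.diff(wl) <= 0):
        raise ValueError(f"{path}: wavelengths must be strictly increasing (duplicates rejected)")
    if np.any(val < 0):
        raise ValueError(f"{path}: negative spectral values rejected")
    return wl, val


def load_spectrum(
    emission_path: str | Path,
    extinction_path: str | Path,
    metadata: dict | str | Path,
) -> FluorophoreRecord:
    """Load a fluorophore from two spectrum CSVs plus scalar photophysics.

    Parameters
    ----------
    emission_path, extinction_path
        CSV files with header ``wavelength_nm,value``. Emission is
        renormalized to unit area on its native grid; extinction is kept in
        M⁻¹·cm⁻¹. If the metadata provides ``extinction_max``, the extinction
        column is treated as a shape and rescaled so its maximum equals it.
    metadata
        Mapping (or path to a JSON file) with keys ``name``,
        ``quantum_yield``, ``lifetime_ns`` and optionally ``extinction_max``.
    """
    if not isinstance(metadata, dict):
        metadata = json.loads(Path(metadata).read_text())
    missing = {"name", "quantum_yield", "lifetime_ns"} - set(metadata)
    if missing:
        raise ValueError(f"metadata missing required fields: {sorted(missing)}")

    wl_em, em = _read_spectrum_csv(emission_path)
    wl_ex, ex = _read_spectrum_csv(extinction_path)
    # Put both spectra on the union grid so one record carries one axis.
    wl = np.union1d(wl_em, wl_ex)
    em = np.interp(wl, wl_em, em, left=0.0, right=0.0)
    ex = np.interp(wl, wl_ex, ex, left=0.0, right=0.0)
    if "extinction_max" in metadata and ex.max() > 0:
        ex = ex * float(metadata["extinction_max"]) / ex.max()
    return FluorophoreRecord(
        name=str(metadata["name"]),
        wavelengths=wl,
        emission=_normalize_emission(wl, em),
        extinction=ex,
        quantum_yield=float(metadata["quantum_yield"]),
        lifetime_ns=float(metadata["lifetime_ns"]),
        maturation_note=str(metadata.get("maturation_note", "")),
    )


def resample(record: FluorophoreRecord, grid: WavelengthGrid) -> FluorophoreRecord:
    """Resample a record onto a target grid.

    Linear interpolation inside the source range, zero outside (no
    extrapolation); the emission density is renormalized to unit area on the
    new grid. Raises if the grids are disjoint.
    """
    wl = grid.points()
    src = record.wavelengths
    if wl[-1] < src[0] or wl[0] > src[-1]:
        raise ValueError(
            f"target grid [{wl[0]}, {wl[-1]}] nm does not overlap "
            f"source grid [{src[0]}, {src[-1]}] nm"
        )
    em = np.interp(wl, src, record.emission, left=0.0, right=0.0)
    ex = np.interp(wl, src, record.extinction, left=0.0, right=0.0)
    return replace(
        record,
        wavelengths=wl,
        emission=_normalize_emission(wl, em),
        extinction=ex,
    )


def _gaussian(x: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((x - center) / sigma) ** 2)


# Synthetic Gaussian stand-ins for the mTurquoise2 / mVenus / mRFP triple.
# Peaks follow the published band positions; widths and amplitudes are
# representative of bright monomeric fluorescent proteins. These are test
# fixtures — real digitized spectra can be supplied via load_spectrum.
_SYNTHETIC_PARAMS = {
    "mTRQ2": dict(em_peak=474.0, em_sigma=18.0, abs_peak=434.0, abs_sigma=20.0,
                  eps_max=30000.0, quantum_yield=0.93, lifetime_ns=3.99,
                  note="synthetic Gaussian stand-in; slow-maturing cyan donor"),
    "mVEN": dict(em_peak=528.0, em_sigma=18.0, abs_peak=515.0, abs_sigma=26.0,
                 eps_max=92200.0, quantum_yield=0.57, lifetime_ns=3.0,
                 note="synthetic Gaussian stand-in; fast-maturing yellow intermediate "
                      "(broadened absorption mimics the vibronic blue shoulder)"),
    "mRFP": dict(em_peak=607.0, em_sigma=20.0, abs_peak=584.0, abs_sigma=22.0,
                 eps_max=50000.0, quantum_yield=0.25, lifetime_ns=2.0,
                 note="synthetic Gaussian stand-in; red terminal acceptor"),
}


def synthetic_fluorophores(grid: WavelengthGrid = WORKING_GRID) -> dict[str, FluorophoreRecord]:
    """Bundled synthetic Gaussian stand-ins for the donor/intermediate/terminal triple.

    Emission peaks at 474 / 528 / 607 nm mimic a cyan donor, yellow
    intermediate acceptor and red terminal acceptor. Used by the test suite
    and the scene generator so nothing needs downloading.
    """
    wl = grid.points()
    out: dict[str, FluorophoreRecord] = {}
    for name, p in _SYNTHETIC_PARAMS.items():
        em = _gaussian(wl, p["em_peak"], p["em_sigma"])
        ex = p["eps_max"] * _gaussian(wl, p["abs_peak"], p["abs_sigma"])
        out[name] = FluorophoreRecord(
            name=name,
            wavelengths=wl,
            emission=_normalize_emission(wl, em),
            extinction=ex,
            quantum_yield=p["quantum_yield"],
            lifetime_ns=p["lifetime_ns"],
            maturation_note=p["note"],
        )
    return out
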