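"""Simulated multispectral data from hyperspectral spectra.

Degrades hyperspectral reflectance to a broadband sensor's spectral
resolution by weighting the hyperspectral bands with a Gaussian spectral
response per target band (sigma set from the band's FWHM) and renormalising
the weights over the actual — possibly masked — grid, so excluded wavelengths
never contribute.  Spatial properties of the data are untouched.

Two band sets ship as editable config: ``sim13`` (nominal Sentinel-2 MSI
centres/FWHM) and ``sim8`` (nominal Landsat 8 OLI, panchromatic excluded).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .spectra import (
    WAVELENGTH_MAX,
    WAVELENGTH_MIN,
    SpectraError,
    SpectralDataset,
    WavelengthGrid,
)

_DATA_DIR = Path(__file__).parent / "data"

#: sigma = FWHM / FWHM_TO_SIGMA for a Gaussian profile
FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class BandDefinition:
    """One broadband channel: centre wavelength and FWHM in nm."""

    name: str
    centre: float
    fwhm: float

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise SpectraError(f"band {self.name}: fwhm must be positive")
        if not (WAVELENGTH_MIN <= self.centre <= WAVELENGTH_MAX):
            raise SpectraError(f"band {self.name}: centre outside plausible range")

    @property
    def sigma(self) -> float:
        return self.fwhm / FWHM_TO_SIGMA


@dataclass(frozen=True)
class SpectralResponse:
    """Unit-sum Gaussian weights of one band over a wavelength grid."""

    band: BandDefinition
    grid: WavelengthGrid
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if w.shape != (len(self.grid),):
            raise SpectraError("weights length != grid length")
        if w.min() < 0 or abs(w.sum() - 1.0) > 1e-12:
            raise SpectraError("weights must be nonnegative and sum to 1")


@dataclass(frozen=True)
class BandSet:
    """An ordered collection of broadband channels (e.g. a satellite sensor)."""

    name: str
    bands: tuple[BandDefinition, ...]

    def __post_init__(self) -> None:
        centres = [b.centre for b in self.bands]
        if sorted(centres) != centres:
            raise SpectraError("bands must be ordered by centre wavelength")
        names = [b.name for b in self.bands]
        if len(set(names)) != len(names):
            raise SpectraError("duplicate band names")

    def __len__(self) -> int:
        return len(self.bands)

    @property
    def centres(self) -> np.ndarray:
        return np.array([b.centre for b in self.bands])


def gaussian_srf(band: BandDefinition, grid: WavelengthGrid) -> SpectralResponse:
    """Gaussian spectral response of ``band`` sampled on ``grid``.

    Weights are proportional to exp(-(lambda - centre)^2 / (2 sigma^2)) with
    sigma = FWHM / (2 sqrt(2 ln 2)) and normalised to unit sum over the grid.
    A band whose +-3 sigma support misses the grid entirely is rejected.
    """
    wl = grid.wavelengths
    support = (wl >= band.centre - 3 * band.fwhm) & (wl <= band.centre + 3 * band.fwhm)
    if not support.any():
        raise SpectraError(
            f"band {band.name} ({band.centre} nm) has no support on the grid")
    z = (wl - band.centre) / band.sigma
    w = np.exp(-0.5 * z * z)
    w /= w.sum()
    # renormalised truncation can leave tiny far-tail weights; they are
    # numerically negligible by construction of the Gaussian
    return SpectralResponse(band=band, grid=grid, weights=w)


def simulate_multispectral(dataset: SpectralDataset, bandset: BandSet) -> SpectralDataset:
    """Resample a hyperspectral dataset to a broadband sensor's bands.

    Each simulated band value is the SRF-weighted mean of the hyperspectral
    reflectance, a convex combination, so values stay within the spectrum's
    range.  Sample ids, labels and coordinates carry over unchanged.
    """
    srf_matrix = np.stack(
        [gaussian_srf(b, dataset.grid).weights for b in bandset.bands])
    simulated = dataset.reflectance @ srf_matrix.T
    grid = WavelengthGrid(bandset.centres)
    return SpectralDataset(grid, simulated, dataset.meta.copy())


def load_bandset(path: str | Path) -> BandSet:
    """Read a band-set config (``name`` + per-band name/centre_nm/fwhm_nm)."""
    doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    bands = tuple(
        BandDefinition(name=str(b["name"]), centre=float(b["centre_nm"]),
                       fwhm=float(b["fwhm_nm"]))
        for b in doc["bands"])
    return BandSet(name=str(doc["name"]), bands=bands)


def builtin_bandset(name: str) -> BandSet:
    """A shipped band set: ``sim13`` (Sentinel-2-like) or ``sim8`` (OLI-like)."""
    path = _DATA_DIR / f"{name}.yaml"
    if not path.exists():
        raise SpectraError(f"no shipped band set named {name!r}")
    return load_bandset(path)
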