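"""Data model and I/O for reflectance spectra and labelled spectral datasets.

A :class:`SpectralDataset` bundles a shared wavelength grid, a samples x bands
reflectance matrix, and a per-sample metadata table (patch membership,
coordinates, category labels at one or more thematic resolutions).  Spectral
libraries are read and written as delimited text in a *wide* dialect
(``wavelength_nm`` column plus one column per sample) or a *long* dialect
(``sample_id, wavelength_nm, reflectance``), with a sidecar metadata table
joined on ``sample_id``.  A minimal ENVI-convention cube reader/writer is
provided for flat binary band-sequential/interleaved data.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

WAVELENGTH_MIN = 300.0
WAVELENGTH_MAX = 2600.0

#: metadata columns with reserved meaning; anything prefixed ``label_`` is a
#: thematic-resolution label column
META_COLUMNS = ("sample_id", "patch_id", "type_id", "farm_id", "x", "y", "month")


class SpectraError(ValueError):
    """Raised on invalid spectral data or malformed input files."""


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing wavelength positions in nanometres."""

    wavelengths: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        if wl.ndim != 1 or wl.size < 2:
            raise SpectraError("grid needs at least 2 wavelengths")
        if not np.all(np.diff(wl) > 0):
            raise SpectraError("grid not increasing")
        if wl[0] < WAVELENGTH_MIN or wl[-1] > WAVELENGTH_MAX:
            raise SpectraError(
                f"wavelengths outside [{WAVELENGTH_MIN}, {WAVELENGTH_MAX}] nm"
            )

    def __len__(self) -> int:
        return int(self.wavelengths.size)

    def __eq__(self, other) -> bool:
        return isinstance(other, WavelengthGrid) and np.array_equal(
            self.wavelengths, other.wavelengths
        )

    def index_of(self, wavelength_nm: float) -> int:
        """Index of the band whose centre is nearest ``wavelength_nm``.

        Ties between two equally near centres go to the lower wavelength.
        """
        d = np.abs(self.wavelengths - wavelength_nm)
        return int(np.argmin(d))  # argmin takes the first (lower-wavelength) tie

    def indices_in(self, lo: float, hi: float) -> np.ndarray:
        """Indices of bands with centre in the closed interval [lo, hi]."""
        if lo > hi:
            raise SpectraError(f"empty region [{lo}, {hi}]")
        wl = self.wavelengths
        return np.nonzero((wl >= lo) & (wl <= hi))[0]

    @property
    def is_uniform(self) -> bool:
        d = np.diff(self.wavelengths)
        return bool(np.allclose(d, d[0], rtol=1e-9, atol=1e-9))


@dataclass(frozen=True)
class Spectrum:
    """A single reflectance spectrum on a wavelength grid.

    Reflectance is a unitless fraction; small negatives (down to -0.05) are
    tolerated as atmospheric-correction artefacts, values up to 1.5 as
    specular/bright-target artefacts.
    """

    grid: WavelengthGrid
    reflectance: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.reflectance, dtype=float)
        object.__setattr__(self, "reflectance", r)
        if r.shape != (len(self.grid),):
            raise SpectraError("reflectance length != grid length")
        if not np.all(np.isfinite(r)):
            raise SpectraError("non-finite reflectance")
        if r.min() < -0.05 or r.max() > 1.5:
            raise SpectraError("reflectance outside [-0.05, 1.5]")

    def at(self, wavelength_nm: float) -> float:
        """Reflectance of the nearest band to ``wavelength_nm``."""
        return float(self.reflectance[self.grid.index_of(wavelength_nm)])


@dataclass
class SpectralDataset:
    """Labelled spectra sharing one wavelength grid.

    ``meta`` holds one row per sample with at least ``sample_id`` and
    ``patch_id``; thematic-resolution labels live in ``label_<name>`` columns.
    """

    grid: WavelengthGrid
    reflectance: np.ndarray  # (n_samples, n_bands)
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        if self.reflectance.ndim != 2:
            raise SpectraError("reflectance must be 2-D (samples x bands)")
        if self.reflectance.shape[1] != len(self.grid):
            raise SpectraError("band count != grid length")
        if len(self.meta) != self.reflectance.shape[0]:
            raise SpectraError("metadata rows != sample count")
        if "sample_id" not in self.meta.columns:
            raise SpectraError("metadata lacks sample_id")
        if self.meta["sample_id"].duplicated().any():
            raise SpectraError("duplicate sample_id")
        if "patch_id" not in self.meta.columns:
            raise SpectraError("metadata lacks patch_id")
        if not self.label_columns():
            raise SpectraError("no label_<resolution> column present")
        self.meta = self.meta.reset_index(drop=True)

    # -- accessors ---------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return int(self.reflectance.shape[0])

    @property
    def sample_ids(self) -> list[str]:
        return list(self.meta["sample_id"].astype(str))

    def label_columns(self) -> list[str]:
        return [c for c in self.meta.columns if c.startswith("label_")]

    def labels(self, resolution: str) -> np.ndarray:
        col = f"label_{resolution}"
        if col not in self.meta.columns:
            raise SpectraError(f"no labels for thematic resolution {resolution!r}")
        return self.meta[col].to_numpy()

    def spectrum(self, i: int) -> Spectrum:
        return Spectrum(self.grid, self.reflectance[i])

    def spectra(self) -> Iterable[Spectrum]:
        for i in range(self.n_samples):
            yield self.spectrum(i)

    def subset(self, mask_or_idx) -> "SpectralDataset":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.nonzero(idx)[0]
        return SpectralDataset(
            self.grid,
            self.reflectance[idx],
            self.meta.iloc[idx].reset_index(drop=True),
        )


@dataclass(frozen=True)
class RegionMask:
    """Wavelength intervals (nm) to exclude, e.g. water-vapour windows."""

    intervals: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        ivs = []
        for lo, hi in self.intervals:
            if not lo < hi:
                raise SpectraError(f"mask interval [{lo}, {hi}] has lo >= hi")
            ivs.append((float(lo), float(hi)))
        # normalise: sort and merge overlaps
        ivs.sort()
        merged: list[list[float]] = []
        for lo, hi in ivs:
            if merged and lo <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], hi)
            else:
                merged.append([lo, hi])
        object.__setattr__(self, "intervals", tuple((a, b) for a, b in merged))

    def contains(self, wavelengths: np.ndarray) -> np.ndarray:
        wl = np.asarray(wavelengths, dtype=float)
        inside = np.zeros(wl.shape, dtype=bool)
        for lo, hi in self.intervals:
            inside |= (wl >= lo) & (wl <= hi)
        return inside


#: Default exclusion mask for the atmospheric water-vapour absorption windows
#: where airborne reflectance is unusable.  The exact windows removed by any
#: given campaign vary; this is a configurable convention, not a measured value.
WATER_VAPOUR_MASK = RegionMask(((1340.0, 1460.0), (1790.0, 1960.0), (2400.0, 2600.0)))


def mask_regions(dataset: SpectralDataset, mask: RegionMask) -> SpectralDataset:
    """Remove all bands whose centre falls inside any mask interval."""
    drop = mask.contains(dataset.grid.wavelengths)
    keep = ~drop
    if not keep.any() or keep.sum() < 2:
        raise SpectraError("no bands remain after masking")
    if drop.any():
        logger.info("mask_regions: removed %d of %d bands", drop.sum(), drop.size)
    grid = WavelengthGrid(dataset.grid.wavelengths[keep])
    return SpectralDataset(grid, dataset.reflectance[:, keep], dataset.meta.copy())


# ---------------------------------------------------------------------------
# delimited spectral-library I/O
# ---------------------------------------------------------------------------

def _sniff_sep(path: Path) -> str:
    head = Path(path).read_text(encoding="utf-8").splitlines()[0]
    return "\t" if head.count("\t") >= head.count(",") else ","


def _normalise_reflectance(values: np.ndarray) -> np.ndarray:
    # percent-scale libraries (0-100) are detected by max > 2 and rescaled
    if np.nanmax(values) > 2.0:
        logger.info("reflectance looks percent-scaled (max=%.3g); dividing by 100",
                    np.nanmax(values))
        return values / 100.0
    return values


def load_spectral_table(
    path: str | Path,
    metadata_path: str | Path | None = None,
    dialect: str = "auto",
) -> SpectralDataset:
    """Load a delimited spectral library (wide or long dialect).

    Wide: a ``wavelength_nm`` column plus one column per sample.  Long:
    columns ``sample_id, wavelength_nm, reflectance``.  ``dialect='auto'``
    distinguishes them by the presence of a ``reflectance`` column.  A sidecar
    metadata table is joined on ``sample_id``; samples without a metadata row
    are rejected by id.
    """
    path = Path(path)
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep)
    if dialect == "auto":
        dialect = "long" if {"sample_id", "reflectance"} <= set(df.columns) else "wide"

    if dialect == "long":
        required = {"sample_id", "wavelength_nm", "reflectance"}
        if not required <= set(df.columns):
            raise SpectraError(f"long table needs columns {sorted(required)}")
        pivot = df.pivot(index="wavelength_nm", columns="sample_id",
                         values="reflectance").sort_index()
        # preserve first-appearance order of samples
        order = list(dict.fromkeys(df["sample_id"]))
        wavelengths = pivot.index.to_numpy(dtype=float)
        refl = pivot[order].to_numpy(dtype=float).T
        sample_ids = [str(s) for s in order]
    elif dialect == "wide":
        if "wavelength_nm" not in df.columns:
            raise SpectraError("wide table needs a wavelength_nm column")
        wavelengths = df["wavelength_nm"].to_numpy(dtype=float)
        sample_ids = [c for c in df.columns if c != "wavelength_nm"]
        refl = df[sample_ids].to_numpy(dtype=float).T
    else:
        raise SpectraError(f"unknown dialect {dialect!r}")

    if not np.all(np.diff(wavelengths) > 0):
        raise SpectraError("grid not increasing")
    if np.isnan(refl).any():
        raise SpectraError("missing reflectance values")
    refl = _normalise_reflectance(refl)
    grid = WavelengthGrid(wavelengths)

    if metadata_path is not None:
        meta = pd.read_csv(metadata_path, sep=_sniff_sep(Path(metadata_path)))
        meta["sample_id"] = meta["sample_id"].astype(str)
        missing = [s for s in sample_ids if s not in set(meta["sample_id"])]
        if missing:
            raise SpectraError(f"metadata missing for samples: {missing}")
        meta = meta.set_index("sample_id").loc[sample_ids].reset_index()
    else:
        meta = pd.DataFrame({
            "sample_id": sample_ids,
            "patch_id": ["p0"] * len(sample_ids),
            "label_default": ["unlabelled"] * len(sample_ids),
        })
    return SpectralDataset(grid, refl, meta)


def save_spectral_table(
    dataset: SpectralDataset,
    path: str | Path,
    metadata_path: str | Path | None = None,
    dialect: str = "wide",
    sep: str = ",",
) -> None:
    """Write a dataset in the wide or long spectral-library dialect."""
    path = Path(path)
    ids = dataset.sample_ids
    if dialect == "wide":
        df = pd.DataFrame({"wavelength_nm": dataset.grid.wavelengths})
        for i, sid in enumerate(ids):
            df[sid] = dataset.reflectance[i]
    elif dialect == "long":
        wl = dataset.grid.wavelengths
        df = pd.DataFrame({
            "sample_id": np.repeat(ids, len(wl)),
            "wavelength_nm": np.tile(wl, len(ids)),
            "reflectance": dataset.reflectance.ravel(),
        })
    else:
        raise SpectraError(f"unknown dialect {dialect!r}")
    df.to_csv(path, sep=sep, index=False)
    if metadata_path is not None:
        dataset.meta.to_csv(metadata_path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# ENVI-convention cube I/O (flat binary + text header)
# ---------------------------------------------------------------------------

_ENVI_DTYPES = {4: np.float32, 5: np.float64}
_ENVI_CODES = {np.dtype(np.float32): 4, np.dtype(np.float64): 5}


def _parse_envi_header(text: str) -> dict:
    fields: dict[str, str] = {}
    # join brace-delimited multi-line values first
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    for line in text.splitlines():
        if "=" not in line:
            continue
        key, _, value = line.partition("=")
        fields[key.strip().lower()] = value.strip()
    return fields


def load_envi_cube(header_path: str | Path,
                   data_path: str | Path | None = None) -> SpectralDataset:
    """Read a flat-binary ENVI-convention cube into a per-pixel dataset.

    Supports BSQ/BIL/BIP interleaves and float32/float64 data.  Pixel
    coordinates come from ``map info`` when present, otherwise from pixel
    indices.  The header must declare a wavelength list.
    """
    header_path = Path(header_path)
    if data_path is None:
        data_path = header_path.with_suffix(".dat")
    data_path = Path(data_path)

    fields = _parse_envi_header(header_path.read_text(encoding="utf-8"))
    try:
        samples = int(fields["samples"])
        lines = int(fields["lines"])
        bands = int(fields["bands"])
        dcode = int(fields["data type"])
    except KeyError as exc:
        raise SpectraError(f"ENVI header missing field {exc}") from exc
    if "wavelength" not in fields:
        raise SpectraError("ENVI header lacks wavelength list")
    wl = np.array([float(v) for v in
                   fields["wavelength"].strip("{} ").split(",") if v.strip()])
    if wl.size != bands:
        raise SpectraError("wavelength list length != bands")
    if dcode not in _ENVI_DTYPES:
        raise SpectraError(f"unsupported ENVI data type {dcode}")
    interleave = fields.get("interleave", "bsq").lower()

    raw = np.fromfile(data_path, dtype=_ENVI_DTYPES[dcode])
    if raw.size != samples * lines * bands:
        raise SpectraError(
            f"data size {raw.size} != samples*lines*bands = {samples * lines * bands}")
    if interleave == "bsq":
        cube = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        cube = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    elif interleave == "bip":
        cube = raw.reshape(lines, samples, bands)
    else:
        raise SpectraError(f"unknown interleave {interleave!r}")

    refl = cube.reshape(lines * samples, bands).astype(float)
    cols, rows = np.meshgrid(np.arange(samples), np.arange(lines))
    x = cols.ravel().astype(float)
    y = rows.ravel().astype(float)
    if "map info" in fields:
        mi = [v.strip() for v in fields["map info"].strip("{} ").split(",")]
        # map info = {proj, ref_col, ref_row, easting, northing, xsize, ysize, ...}
        try:
            easting, northing = float(mi[3]), float(mi[4])
            xsize, ysize = float(mi[5]), float(mi[6])
            x = easting + x * xsize
            y = northing - y * ysize
        except (IndexError, ValueError):
            logger.warning("unparseable map info %r; using pixel indices", mi)
    meta = pd.DataFrame({
        "sample_id": [f"px_{i}" for i in range(lines * samples)],
        "patch_id": ["p0"] * (lines * samples),
        "x": x,
        "y": y,
        "label_default": ["unlabelled"] * (lines * samples),
    })
    return SpectralDataset(WavelengthGrid(wl), refl, meta)


def save_envi_cube(
    dataset: SpectralDataset,
    header_path: str | Path,
    data_path: str | Path | None = None,
    lines: int | None = None,
    samples: int | None = None,
    interleave: str = "bsq",
    dtype=np.float64,
) -> None:
    """Write a dataset as a flat-binary ENVI-convention cube.

    The dataset's samples are laid out row-major into a ``lines x samples``
    raster; defaults to a single line.
    """
    header_path = Path(header_path)
    if data_path is None:
        data_path = header_path.with_suffix(".dat")
    n = dataset.n_samples
    if lines is None and samples is None:
        lines, samples = 1, n
    elif lines is None:
        lines = n // samples
    elif samples is None:
        samples = n // lines
    if lines * samples != n:
        raise SpectraError("lines*samples != sample count")
    bands = len(dataset.grid)
    cube = dataset.reflectance.reshape(lines, samples, bands)
    interleave = interleave.lower()
    if interleave == "bsq":
        arr = cube.transpose(2, 0, 1)
    elif interleave == "bil":
        arr = cube.transpose(0, 2, 1)
    elif interleave == "bip":
        arr = cube
    else:
        raise SpectraError(f"unknown interleave {interleave!r}")
    arr.astype(dtype).tofile(data_path)
    wl_str = ", ".join(f"{w:g}" for w in dataset.grid.wavelengths)
    header = (
        "ENVI\n"
        f"samples = {samples}\n"
        f"lines = {lines}\n"
        f"bands = {bands}\n"
        f"data type = {_ENVI_CODES[np.dtype(dtype)]}\n"
        f"interleave = {interleave}\n"
        "byte order = 0\n"
        f"wavelength = {{ {wl_str} }}\n"
    )
    header_path.write_text(header, encoding="utf-8")
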