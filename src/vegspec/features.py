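"""Spectral covariates for vegetation classification.

Derives, from each reflectance spectrum, the covariate families used to
discriminate grassland communities:

* smoothed first derivatives (Savitzky-Golay local polynomial fits, valid on
  uneven wavelength grids) at every band;
* position/value of the reflectance minimum in the chlorophyll-absorption
  region 660-750 nm;
* positions/values of first-derivative extrema in five diagnostic regions
  (495-550, 550-650, 970-1090, 1110-1205, 1205-1285 nm);
* red-edge derivative peaks (local maxima in 690-750 nm), their heights,
  positions and ratios;
* vegetation indices from a configurable registry (NDVI, PRI, ARI, mARI, WBI,
  NDLI, CAI, RGRI, RVSI shipped);
* for simulated multispectral data: band reflectances and all pairwise band
  ratios.

Covariates are assembled into a per-sample table; covariates that are
undefined for a sample (e.g. a missing red-edge peak) are imputed with the
column median, computed on the training partition only when a split is
declared.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .spectra import SpectraError, SpectralDataset, Spectrum, WavelengthGrid

logger = logging.getLogger(__name__)

DEFAULT_EXTREMA_REGIONS: tuple[tuple[float, float], ...] = (
    (495.0, 550.0),
    (550.0, 650.0),
    (970.0, 1090.0),
    (1110.0, 1205.0),
    (1205.0, 1285.0),
)
DEFAULT_MIN_REFL_REGION = (660.0, 750.0)
DEFAULT_PEAK_REGION = (690.0, 750.0)

_DATA_DIR = Path(__file__).parent / "data"


# ---------------------------------------------------------------------------
# Savitzky-Golay first derivative
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DerivativeSpectrum:
    """First derivative of reflectance with wavelength (per nm)."""

    grid: WavelengthGrid
    d1: np.ndarray

    def __post_init__(self) -> None:
        d1 = np.asarray(self.d1, dtype=float)
        object.__setattr__(self, "d1", d1)
        if d1.shape != (len(self.grid),):
            raise SpectraError("derivative length != grid length")
        if not np.all(np.isfinite(d1)):
            raise SpectraError("non-finite derivative")


class SavgolDerivative:
    """Savitzky-Golay first-derivative operator for a fixed grid.

    For every band a polynomial of degree ``polyorder`` is least-squares
    fitted to the ``window`` nearest bands (centred where possible, one-sided
    at the grid ends, always the full window length) against the *actual*
    wavelengths, and the fitted polynomial's derivative is evaluated at the
    band centre.  On a uniform grid this reproduces the classical
    Savitzky-Golay convolution; on uneven grids the per-window fit is exact
    where fixed convolution coefficients would not be.

    The operator is linear; it is materialised once per grid as a sparse-ish
    weight matrix and applied to any number of spectra.
    """

    def __init__(self, grid: WavelengthGrid, window: int, polyorder: int):
        if window % 2 == 0:
            raise SpectraError("sg window must be odd")
        if window <= polyorder:
            raise SpectraError("sg window must exceed polyorder")
        n = len(grid)
        if window > n:
            raise SpectraError("sg window exceeds grid length")
        self.grid = grid
        self.window = window
        self.polyorder = polyorder
        wl = grid.wavelengths
        half = window // 2
        weights = np.zeros((n, window))
        starts = np.empty(n, dtype=int)
        for i in range(n):
            lo = min(max(i - half, 0), n - window)
            starts[i] = lo
            dl = wl[lo:lo + window] - wl[i]
            vander = np.vander(dl, polyorder + 1, increasing=True)
            # derivative at the band centre = linear coefficient of the fit
            weights[i] = np.linalg.pinv(vander)[1]
        self._weights = weights
        self._starts = starts

    def apply_matrix(self, reflectance: np.ndarray) -> np.ndarray:
        """First derivative of each row of an (n_samples, n_bands) matrix."""
        refl = np.atleast_2d(np.asarray(reflectance, dtype=float))
        n = len(self.grid)
        if refl.shape[1] != n:
            raise SpectraError("reflectance width != grid length")
        out = np.empty_like(refl)
        idx = self._starts[:, None] + np.arange(self.window)[None, :]
        # gather windows: (n_samples, n_bands, window) would be large; loop bands
        for i in range(n):
            out[:, i] = refl[:, idx[i]] @ self._weights[i]
        return out

    def __call__(self, spectrum: Spectrum) -> DerivativeSpectrum:
        if spectrum.grid != self.grid:
            raise SpectraError("spectrum grid differs from operator grid")
        d1 = self.apply_matrix(spectrum.reflectance[None, :])[0]
        return DerivativeSpectrum(self.grid, d1)


def savgol_first_derivative(spectrum: Spectrum, window: int,
                            polyorder: int) -> DerivativeSpectrum:
    """Smoothed first derivative of a spectrum (see :class:`SavgolDerivative`)."""
    return SavgolDerivative(spectrum.grid, window, polyorder)(spectrum)


# ---------------------------------------------------------------------------
# scalar spectral features
# ---------------------------------------------------------------------------

def min_reflectance_feature(
    spectrum: Spectrum,
    region: tuple[float, float] = DEFAULT_MIN_REFL_REGION,
) -> tuple[float, float]:
    """Wavelength and value of the reflectance minimum in ``region``.

    Ties go to the lowest wavelength.
    """
    idx = spectrum.grid.indices_in(*region)
    if idx.size == 0:
        raise SpectraError(f"no bands in region {region}")
    vals = spectrum.reflectance[idx]
    k = idx[int(np.argmin(vals))]
    return float(spectrum.grid.wavelengths[k]), float(spectrum.reflectance[k])


def region_extrema_features(
    deriv: DerivativeSpectrum,
    regions: Sequence[tuple[float, float]] = DEFAULT_EXTREMA_REGIONS,
) -> list[dict]:
    """Per region: argmin/argmax of the first derivative and their values.

    Ties go to the lowest wavelength.  Regions with no bands are skipped with
    a warning (reported in the returned records' absence).
    """
    out = []
    for lo, hi in regions:
        idx = deriv.grid.indices_in(lo, hi)
        if idx.size == 0:
            logger.warning("extrema region [%g, %g] has no bands; skipped", lo, hi)
            continue
        vals = deriv.d1[idx]
        imin = idx[int(np.argmin(vals))]
        imax = idx[int(np.argmax(vals))]
        wl = deriv.grid.wavelengths
        out.append({
            "region": (lo, hi),
            "min_pos": float(wl[imin]), "min_val": float(deriv.d1[imin]),
            "max_pos": float(wl[imax]), "max_val": float(deriv.d1[imax]),
        })
    return out


@dataclass(frozen=True)
class RedEdgePeak:
    """A local maximum of the first derivative on the red edge."""

    position: float  # nm
    height: float    # derivative value, per nm
    index: int       # 1-based rank by ascending wavelength

    def __post_init__(self) -> None:
        if self.height <= 0:
            raise SpectraError("red-edge peak height must be positive")


def detect_red_edge_peaks(
    deriv: DerivativeSpectrum,
    region: tuple[float, float] = DEFAULT_PEAK_REGION,
    max_peaks: int = 3,
) -> list[RedEdgePeak]:
    """Strict local maxima of the first derivative inside ``region``.

    A peak satisfies ``d1[i-1] < d1[i] > d1[i+1]`` against its grid
    neighbours; plateau maxima are reported at the plateau's lowest
    wavelength.  When more than ``max_peaks`` maxima exist the tallest are
    retained and re-indexed by ascending wavelength.  Only peaks with
    positive height qualify.
    """
    d1 = deriv.d1
    wl = deriv.grid.wavelengths
    n = d1.size
    # plateau-aware scan via run-length encoding of equal values
    change = np.nonzero(np.diff(d1) != 0)[0]
    starts = np.concatenate(([0], change + 1))          # start index of each run
    ends = np.concatenate((change, [n - 1]))            # end index of each run
    candidates: list[tuple[float, float]] = []
    for s, e in zip(starts, ends):
        if s == 0 or e == n - 1:
            continue  # grid endpoints cannot be interior maxima
        if d1[s - 1] < d1[s] and d1[e] > d1[e + 1]:
            candidates.append((wl[s], d1[s]))
    lo, hi = region
    peaks = [(p, h) for p, h in candidates if lo <= p <= hi and h > 0]
    if len(peaks) > max_peaks:
        peaks = sorted(peaks, key=lambda ph: (-ph[1], ph[0]))[:max_peaks]
    peaks.sort(key=lambda ph: ph[0])
    return [RedEdgePeak(position=p, height=h, index=i + 1)
            for i, (p, h) in enumerate(peaks)]


def red_edge_peak_covariates(
    peaks: Sequence[RedEdgePeak],
    spectrum: Spectrum,
    mode: str,
    peak_region: tuple[float, float] = DEFAULT_PEAK_REGION,
    max_peaks: int = 3,
) -> dict[str, float]:
    """Named covariates from red-edge peaks.

    Airborne mode emits peak heights and pairwise height ratios.  Field
    (hand-held spectroscopy) mode additionally emits peak wavelengths and
    their ratios, plus the local maximum reflectance within the peak region
    and its ratios to the peak heights — hand-held spectra are clean enough
    for positional covariates to be informative.  Missing peaks yield NaN,
    imputed at assembly.
    """
    if mode not in ("airborne", "field"):
        raise SpectraError(f"unknown mode {mode!r}")
    h = {p.index: p.height for p in peaks}
    w = {p.index: p.position for p in peaks}
    out: dict[str, float] = {}
    pairs = [(i, j) for i in range(1, max_peaks + 1)
             for j in range(i + 1, max_peaks + 1)]
    for i in range(1, max_peaks + 1):
        out[f"repk_height_{i}"] = h.get(i, np.nan)
    for i, j in pairs:
        out[f"repk_height_ratio_{i}_{j}"] = (
            h[i] / h[j] if i in h and j in h else np.nan)
    if mode == "field":
        for i in range(1, max_peaks + 1):
            out[f"repk_pos_{i}"] = w.get(i, np.nan)
        for i, j in pairs:
            out[f"repk_pos_ratio_{i}_{j}"] = (
                w[i] / w[j] if i in w and j in w else np.nan)
        idx = spectrum.grid.indices_in(*peak_region)
        maxrefl = float(np.max(spectrum.reflectance[idx])) if idx.size else np.nan
        out["repk_maxrefl"] = maxrefl
        for i in range(1, max_peaks + 1):
            out[f"repk_maxrefl_ratio_{i}"] = (
                maxrefl / h[i] if i in h and np.isfinite(maxrefl) else np.nan)
    return out


# ---------------------------------------------------------------------------
# vegetation-index registry
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"R(\d+(?:\.\d+)?):R(\d+(?:\.\d+)?)|R(\d+(?:\.\d+)?)")


@dataclass(frozen=True)
class IndexDefinition:
    """A vegetation index as an expression over named wavelengths.

    The expression uses ``R<nm>`` for the reflectance of the band nearest
    <nm> and ``mean(R<lo>:R<hi>)`` for the mean reflectance of all bands in
    the closed range; ``log`` is the natural logarithm.
    """

    name: str
    expression: str

    @property
    def single_wavelengths(self) -> tuple[float, ...]:
        return tuple(float(m.group(3)) for m in _TOKEN_RE.finditer(self.expression)
                     if m.group(3) is not None)

    @property
    def range_wavelengths(self) -> tuple[tuple[float, float], ...]:
        return tuple((float(m.group(1)), float(m.group(2)))
                     for m in _TOKEN_RE.finditer(self.expression)
                     if m.group(1) is not None)

    def applicable(self, grid: WavelengthGrid, tolerance_nm: float) -> bool:
        """Whether the grid can resolve every wavelength this index needs.

        Single wavelengths must have a band centre within ``tolerance_nm``;
        ranges must contain at least one band.
        """
        wl = grid.wavelengths
        for lam in self.single_wavelengths:
            if np.min(np.abs(wl - lam)) > tolerance_nm:
                return False
        for lo, hi in self.range_wavelengths:
            if grid.indices_in(lo, hi).size == 0:
                return False
        return True

    def evaluate(self, spectrum: Spectrum) -> float:
        env: dict[str, float] = {}
        counter = [0]

        def sub(m: re.Match) -> str:
            counter[0] += 1
            var = f"_v{counter[0]}"
            if m.group(3) is not None:
                env[var] = spectrum.at(float(m.group(3)))
            else:
                idx = spectrum.grid.indices_in(float(m.group(1)), float(m.group(2)))
                env[var] = (float(np.mean(spectrum.reflectance[idx]))
                            if idx.size else np.nan)
            return var

        expr = _TOKEN_RE.sub(sub, self.expression)
        env.update({"log": np.log, "sqrt": np.sqrt, "abs": abs,
                    "mean": lambda v: v, "__builtins__": {}})
        with np.errstate(all="ignore"):
            try:
                value = float(eval(expr, env))  # noqa: S307 - restricted namespace
            except ZeroDivisionError:
                value = np.nan
        return value if np.isfinite(value) else np.nan


def load_index_registry(path: str | Path | None = None) -> list[IndexDefinition]:
    """Load index definitions from structured config (shipped registry by default)."""
    path = Path(path) if path else _DATA_DIR / "indices.yaml"
    entries = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    defs = [IndexDefinition(name=e["name"], expression=e["expression"])
            for e in entries]
    names = [d.name for d in defs]
    if len(set(names)) != len(names):
        raise SpectraError("duplicate index names in registry")
    return defs


def vegetation_indices(
    spectrum: Spectrum,
    registry: Sequence[IndexDefinition] | None = None,
    tolerance_nm: float = 20.0,
    require_applicable: bool = False,
) -> dict[str, float]:
    """Evaluate every registry index on a spectrum.

    Undefined values (log of a non-positive reflectance, division by zero)
    come back as NaN.  With ``require_applicable`` indices whose wavelengths
    the grid cannot resolve (to ``tolerance_nm``) are omitted — the rule used
    for simulated multispectral band sets.
    """
    if registry is None:
        registry = load_index_registry()
    out: dict[str, float] = {}
    for d in registry:
        if require_applicable and not d.applicable(spectrum.grid, tolerance_nm):
            continue
        value = d.evaluate(spectrum)
        if not np.isfinite(value):
            logger.debug("index %s undefined on this spectrum", d.name)
            value = np.nan
        out[d.name] = value
    return out


def band_ratio_features(spectrum: Spectrum) -> dict[str, float]:
    """All unordered pairwise band ratios R_i / R_j (i < j by wavelength)."""
    wl = spectrum.grid.wavelengths
    r = spectrum.reflectance
    if wl.size < 2:
        raise SpectraError("need at least 2 bands for ratios")
    out: dict[str, float] = {}
    for i in range(wl.size):
        for j in range(i + 1, wl.size):
            name = f"ratio_{wl[i]:g}_{wl[j]:g}"
            out[name] = r[i] / r[j] if r[j] != 0 else np.nan
    return out


# ---------------------------------------------------------------------------
# covariate assembly
# ---------------------------------------------------------------------------

@dataclass
class FeatureConfig:
    """Which covariate families to compute and with what settings.

    ``mode`` selects the families: ``airborne``/``field`` compute derivative,
    extremum, index and red-edge-peak covariates from hyperspectral data
    (field adds the positional peak covariates); ``multispectral`` computes
    band reflectances, pairwise band ratios and the applicable indices.
    """

    mode: str = "airborne"
    sg_window: int = 9
    sg_polyorder: int = 2
    extrema_regions: tuple[tuple[float, float], ...] = DEFAULT_EXTREMA_REGIONS
    min_refl_region: tuple[float, float] = DEFAULT_MIN_REFL_REGION
    peak_region: tuple[float, float] = DEFAULT_PEAK_REGION
    max_peaks: int = 3
    index_tolerance_nm: float = 20.0
    registry_path: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("airborne", "field", "multispectral"):
            raise SpectraError(f"unknown mode {self.mode!r}")
        if self.sg_window % 2 == 0 or self.sg_window <= self.sg_polyorder:
            raise SpectraError("sg_window must be odd and exceed sg_polyorder")


@dataclass
class CovariateTable:
    """Samples x named covariates, with per-column family provenance."""

    table: pd.DataFrame              # index: sample_id
    provenance: dict[str, str]       # column -> family

    def __post_init__(self) -> None:
        if self.table.columns.duplicated().any():
            raise SpectraError("duplicate covariate names")
        missing = set(self.table.columns) - set(self.provenance)
        if missing:
            raise SpectraError(f"columns without provenance: {sorted(missing)}")

    @property
    def n_samples(self) -> int:
        return len(self.table)

    @property
    def columns(self) -> list[str]:
        return list(self.table.columns)

    def values(self) -> np.ndarray:
        return self.table.to_numpy(dtype=float)

    def census(self) -> dict[str, int]:
        """Number of covariates per family."""
        census: dict[str, int] = {}
        for col in self.table.columns:
            fam = self.provenance[col]
            census[fam] = census.get(fam, 0) + 1
        return census

    def save(self, path: str | Path, provenance_path: str | Path | None = None) -> None:
        self.table.to_csv(path)
        if provenance_path is not None:
            pd.DataFrame({"covariate": list(self.provenance),
                          "family": list(self.provenance.values())}
                         ).to_csv(provenance_path, index=False)

    @classmethod
    def load(cls, path: str | Path, provenance_path: str | Path) -> "CovariateTable":
        table = pd.read_csv(path, index_col=0)
        prov = pd.read_csv(provenance_path)
        return cls(table, dict(zip(prov["covariate"], prov["family"])))


def _hyperspectral_rows(dataset: SpectralDataset,
                        config: FeatureConfig) -> tuple[pd.DataFrame, dict[str, str]]:
    op = SavgolDerivative(dataset.grid, config.sg_window, config.sg_polyorder)
    d1_matrix = op.apply_matrix(dataset.reflectance)
    registry = load_index_registry(config.registry_path)
    wl = dataset.grid.wavelengths
    prov: dict[str, str] = {f"d1_{w:g}nm": "derivative" for w in wl}
    rows = []
    for i in range(dataset.n_samples):
        spectrum = dataset.spectrum(i)
        deriv = DerivativeSpectrum(dataset.grid, d1_matrix[i])
        row: dict[str, float] = {f"d1_{w:g}nm": v for w, v in zip(wl, d1_matrix[i])}
        pos, val = min_reflectance_feature(spectrum, config.min_refl_region)
        row["minrefl_pos"] = pos
        row["minrefl_val"] = val
        for rec in region_extrema_features(deriv, config.extrema_regions):
            lo, hi = rec["region"]
            tag = f"{lo:g}_{hi:g}"
            row[f"d1min_pos_{tag}"] = rec["min_pos"]
            row[f"d1min_val_{tag}"] = rec["min_val"]
            row[f"d1max_pos_{tag}"] = rec["max_pos"]
            row[f"d1max_val_{tag}"] = rec["max_val"]
        for name, value in vegetation_indices(
                spectrum, registry, config.index_tolerance_nm).items():
            row[f"vi_{name}"] = value
        peaks = detect_red_edge_peaks(deriv, config.peak_region, config.max_peaks)
        row.update(red_edge_peak_covariates(
            peaks, spectrum, config.mode, config.peak_region, config.max_peaks))
        rows.append(row)
    df = pd.DataFrame(rows, index=pd.Index(dataset.sample_ids, name="sample_id"))
    for col in df.columns:
        if col not in prov:
            if col.startswith(("minrefl_",)):
                prov[col] = "reflectance"
            elif col.startswith(("d1min_", "d1max_")):
                prov[col] = "extremum"
            elif col.startswith("vi_"):
                prov[col] = "index"
            elif "ratio" in col:
                prov[col] = "ratio"
            else:
                prov[col] = "peak"
    return df, prov


def _multispectral_rows(dataset: SpectralDataset,
                        config: FeatureConfig) -> tuple[pd.DataFrame, dict[str, str]]:
    registry = load_index_registry(config.registry_path)
    wl = dataset.grid.wavelengths
    prov: dict[str, str] = {f"R_{w:g}nm": "reflectance" for w in wl}
    rows = []
    for i in range(dataset.n_samples):
        spectrum = dataset.spectrum(i)
        row = {f"R_{w:g}nm": v for w, v in zip(wl, spectrum.reflectance)}
        row.update(band_ratio_features(spectrum))
        for name, value in vegetation_indices(
                spectrum, registry, config.index_tolerance_nm,
                require_applicable=True).items():
            row[f"vi_{name}"] = value
        rows.append(row)
    df = pd.DataFrame(rows, index=pd.Index(dataset.sample_ids, name="sample_id"))
    for col in df.columns:
        if col not in prov:
            prov[col] = "index" if col.startswith("vi_") else "ratio"
    return df, prov


def assemble_covariates(
    dataset: SpectralDataset,
    config: FeatureConfig,
    train_mask: np.ndarray | None = None,
) -> CovariateTable:
    """Build the full covariate table for a dataset.

    Families are selected by ``config.mode``; no pre-selection among
    covariates is applied.  NaN entries (undefined covariates) are imputed
    with the column median — over training rows only when ``train_mask``
    declares a split, so no validation information leaks into the fill
    values.  Columns undefined everywhere (in training) are dropped.
    """
    if config.mode in ("airborne", "field"):
        df, prov = _hyperspectral_rows(dataset, config)
    else:
        df, prov = _multispectral_rows(dataset, config)

    ref = df if train_mask is None else df.loc[np.asarray(train_mask, dtype=bool)]
    medians = ref.median(axis=0, skipna=True)
    dead = [c for c in df.columns if not np.isfinite(medians[c])]
    if dead:
        logger.warning("dropping %d all-undefined covariates: %s...",
                       len(dead), dead[:5])
        df = df.drop(columns=dead)
        for c in dead:
            prov.pop(c, None)
        medians = medians.drop(index=dead)
    df = df.fillna(medians)
    table = CovariateTable(df, prov)
    logger.info("assembled %d covariates for %d samples: %s",
                len(df.columns), len(df), table.census())
    return table


def select_smoothing_level(
    dataset: SpectralDataset,
    resolution: str,
    candidate_windows: Sequence[int],
    config: FeatureConfig | None = None,
    ntree: int = 200,
    downsample_target: int | None = None,
    seed: int = 0,
) -> tuple[int, dict[int, float]]:
    """Choose the SG smoothing window maximising OOB classification accuracy.

    For every candidate window the full covariate table is rebuilt and a
    class-balanced forest fitted; the window with the highest out-of-bag
    accuracy wins, ties going to the smaller window.  Returns the chosen
    window and the per-window accuracy trace.
    """
    from .classify import ForestConfig, balanced_forest_fit, oob_accuracy

    if len(candidate_windows) < 1:
        raise SpectraError("need at least one candidate window")
    labels = dataset.labels(resolution)
    if len(np.unique(labels)) < 2:
        raise SpectraError("need at least two categories")
    config = config or FeatureConfig()
    scores: dict[int, float] = {}
    for window in candidate_windows:
        table = assemble_covariates(dataset, replace(config, sg_window=window))
        fc = ForestConfig(ntree=ntree, downsample_target=downsample_target, seed=seed)
        model = balanced_forest_fit(table, labels, fc)
        scores[window] = oob_accuracy(model)
    best = min(scores, key=lambda w: (-scores[w], w))
    return best, scores
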