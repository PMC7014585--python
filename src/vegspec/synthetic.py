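"""Synthetic grassland scenes with known community structure.

Every pipeline stage needs labelled spectra with controllable class
structure: patches of vegetation categories on a 1 m grid, nested category
labels (community / finest), wide patches whose edge pixels are trimmed
versus narrow patches whose edge pixels mix with a soil background, species
percent-cover plots per patch, and approximately monthly phenology.

The reflectance model is phenomenological, not radiative-transfer: a visible
baseline with a Gaussian green peak and chlorophyll red well, a logistic red
edge rising to a near-infrared plateau, Gaussian water-absorption wells at
1450/1940 nm, a gentle SWIR decline, and optional extra narrow absorption
features.  It produces the canonical grass reflectance shape with a
first-derivative maximum on the red edge, which is all the classification
machinery exercises; it makes no biophysical claims.

Scenes are pure functions of (config, seed): the same pair reproduces
bit-identical output, and the emitted manifest suffices to regenerate it.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.special import expit

from .spectra import SpectraError, SpectralDataset, Spectrum, WavelengthGrid

MONTHS = ("May", "June", "July", "August", "September")


# ---------------------------------------------------------------------------
# archetype reflectance model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ArchetypeParams:
    """Parameters of the smooth vegetation reflectance model (nm / fractions)."""

    base: float = 0.04            # visible baseline reflectance
    green_amp: float = 0.04       # green-peak amplitude above baseline
    green_centre: float = 550.0
    red_depth: float = 0.02       # chlorophyll red-well depth below baseline
    red_centre: float = 670.0
    red_edge_pos: float = 720.0   # logistic inflection, must sit on the red edge
    red_edge_width: float = 12.0  # logistic width (nm)
    nir: float = 0.45             # near-infrared plateau level
    water_1450: float = 0.35      # fractional absorption depth at 1450 nm
    water_1940: float = 0.55      # fractional absorption depth at 1940 nm
    swir_slope: float = 1.2e-4    # plateau decline per nm beyond 1300 nm
    extra_features: tuple[tuple[float, float, float], ...] = ()
    # extra narrow absorptions: (centre_nm, fractional_depth, sigma_nm)

    def __post_init__(self) -> None:
        if not 690.0 <= self.red_edge_pos <= 750.0:
            raise SpectraError("red-edge inflection must lie in [690, 750] nm")


@dataclass(frozen=True)
class Archetype:
    """A vegetation category: spectral parameters plus a species cover profile."""

    name: str
    community: str
    params: ArchetypeParams
    species: dict[str, float] = field(default_factory=dict)  # percent covers


def _gauss(wl, centre, sigma):
    return np.exp(-0.5 * ((wl - centre) / sigma) ** 2)


def spectrum_from_params(wl: np.ndarray, *, base, green_amp, green_centre,
                         red_depth, red_centre, red_edge_pos, red_edge_width,
                         nir, water_1450, water_1940, swir_slope,
                         extra_features=()) -> np.ndarray:
    """Evaluate the reflectance model; parameters broadcast against ``wl``."""
    vis = base + green_amp * _gauss(wl, green_centre, 25.0) \
        - red_depth * _gauss(wl, red_centre, 30.0)
    edge = expit((wl - red_edge_pos) / red_edge_width)
    plateau = nir - swir_slope * np.maximum(wl - 1300.0, 0.0)
    r = vis * (1.0 - edge) + plateau * edge
    r = r * (1.0 - water_1450 * _gauss(wl, 1450.0, 45.0))
    r = r * (1.0 - water_1940 * _gauss(wl, 1940.0, 60.0))
    for centre, depth, sigma in extra_features:
        r = r * (1.0 - depth * _gauss(wl, centre, sigma))
    return np.clip(r, 0.0, 1.0)


def make_archetype(name: str, community: str, params: ArchetypeParams,
                   species: dict[str, float] | None = None,
                   grid: WavelengthGrid | None = None
                   ) -> tuple[Archetype, Spectrum | None]:
    """Validate an archetype and, given a grid, render its clean spectrum."""
    arch = Archetype(name=name, community=community, params=params,
                     species=dict(species or {}))
    spectrum = None
    if grid is not None:
        r = spectrum_from_params(grid.wavelengths,
                                 **_params_as_kwargs(params))
        spectrum = Spectrum(grid, r)
    return arch, spectrum


def _params_as_kwargs(p: ArchetypeParams) -> dict:
    d = dataclasses.asdict(p)
    d["extra_features"] = tuple(tuple(f) for f in d["extra_features"])
    return d


def soil_spectrum(wl: np.ndarray) -> np.ndarray:
    """Bright, featureless soil end-member rising linearly with wavelength."""
    return np.clip(0.10 + 1.2e-4 * (wl - 400.0), 0.0, 1.0)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MonthEffect:
    """Phenology of one acquisition month.

    ``separation`` scales every category's deviation from the across-category
    mean parameters (1 = the baseline separation; < 1 compresses categories
    towards each other, emulating early/late-season convergence).  Deltas
    shift NIR level and red-edge width for all categories alike.
    """

    separation: float = 1.0
    nir_delta: float = 0.0
    red_edge_width_delta: float = 0.0


#: growth peaks mid-season: categories are most distinct in July, least in
#: May/September when swards are short or senescent
DEFAULT_MONTH_EFFECTS: dict[str, MonthEffect] = {
    "May": MonthEffect(0.60, -0.05, 2.0),
    "June": MonthEffect(0.85, 0.00, 0.5),
    "July": MonthEffect(1.00, 0.03, -1.0),
    "August": MonthEffect(0.80, 0.00, 0.5),
    "September": MonthEffect(0.55, -0.07, 3.0),
}


@dataclass
class SyntheticConfig:
    """Everything that defines a scene except the seed."""

    archetypes: list[Archetype]
    grid_start: float = 400.0
    grid_stop: float = 2500.0
    n_bands: int = 622
    wide_patches_per_category: int = 3
    narrow_patches_per_category: int = 3
    wide_shape: tuple[int, int] = (9, 9)
    wide_trim: int = 2              # outer pixels removed from wide patches (m)
    narrow_shape: tuple[int, int] = (3, 12)
    edge_mix_width: float = 2.0     # pixels over which narrow-edge mixing decays
    # matches the 2 m edge zone trimmed from wide patches
    edge_mix_max: float = 0.7       # partner weight at the patch boundary
    level_jitter_rel: float = 0.05  # relative SD on amplitude-like parameters
    pos_jitter_nm: float = 1.5      # SD on position-like parameters
    noise_sd: float = 0.008         # white reflectance noise per band
    smooth_noise_sd: float = 0.004  # spectrally correlated noise component
    smooth_noise_scale_nm: float = 60.0
    plots_per_patch: int = 1        # 4 m^2 cover plots emitted per patch
    cover_jitter: float = 5.0       # percent-cover SD in emitted plots
    slot_gap: int = 3               # empty metres between patch slots
    month_effects: dict[str, MonthEffect] = field(
        default_factory=lambda: dict(DEFAULT_MONTH_EFFECTS))

    def __post_init__(self) -> None:
        if not self.archetypes:
            raise SpectraError("config needs at least one archetype")
        for v in (self.level_jitter_rel, self.pos_jitter_nm, self.noise_sd,
                  self.smooth_noise_sd, self.edge_mix_width):
            if v < 0:
                raise SpectraError("jitter/noise SDs must be >= 0")
        if min(self.wide_shape) <= 2 * self.wide_trim:
            raise SpectraError("wide_shape too small for wide_trim")
        names = [a.name for a in self.archetypes]
        if len(set(names)) != len(names):
            raise SpectraError("duplicate archetype names")

    @property
    def grid(self) -> WavelengthGrid:
        return WavelengthGrid(np.linspace(self.grid_start, self.grid_stop,
                                          self.n_bands))


# -- serialisation (manifest round trip) ------------------------------------

def config_to_dict(config: SyntheticConfig) -> dict:
    d = dataclasses.asdict(config)
    d["month_effects"] = {m: dataclasses.asdict(e)
                          for m, e in config.month_effects.items()}
    return d


def config_from_dict(d: dict) -> SyntheticConfig:
    d = dict(d)
    d["archetypes"] = [
        Archetype(name=a["name"], community=a["community"],
                  params=ArchetypeParams(**{
                      **a["params"],
                      "extra_features": tuple(tuple(f) for f in
                                              a["params"]["extra_features"])}),
                  species=dict(a["species"]))
        for a in d["archetypes"]]
    d["month_effects"] = {m: MonthEffect(**e)
                          for m, e in d["month_effects"].items()}
    d["wide_shape"] = tuple(d["wide_shape"])
    d["narrow_shape"] = tuple(d["narrow_shape"])
    return SyntheticConfig(**d)


# ---------------------------------------------------------------------------
# shipped archetype preset
# ---------------------------------------------------------------------------

def default_archetypes(n_communities: int = 12,
                       n_categories: int = 20) -> list[Archetype]:
    """A deterministic hierarchy preset: communities with sub-categories.

    Communities spread systematically over red-edge position, NIR level,
    green-peak amplitude and water-well depth; the first
    ``n_categories - n_communities`` communities carry a second sub-category
    offset from the first.  Each category is dominated by three species.
    """
    if not 1 <= n_communities <= n_categories <= 2 * n_communities:
        raise SpectraError(
            "need n_communities <= n_categories <= 2*n_communities")
    archetypes: list[Archetype] = []
    n_split = n_categories - n_communities
    for i in range(n_communities):
        f = i / max(1, n_communities - 1)
        params = ArchetypeParams(
            base=0.035 + 0.015 * f,
            green_amp=0.03 + 0.03 * (1 - f),
            red_depth=0.015 + 0.01 * f,
            red_edge_pos=700.0 + 40.0 * f,
            red_edge_width=10.0 + 6.0 * f,
            nir=0.35 + 0.18 * (0.5 + 0.5 * np.cos(2.5 * np.pi * f)),
            water_1450=0.25 + 0.25 * f,
            water_1940=0.45 + 0.2 * (1 - f),
        )
        community = f"C{i + 1:02d}"
        n_sub = 2 if i < n_split else 1
        for s in range(n_sub):
            sub = dataclasses.replace(
                params,
                nir=params.nir * (1.0 + 0.10 * s),
                red_edge_pos=min(750.0, params.red_edge_pos + 4.0 * s),
                water_1450=params.water_1450 * (1.0 - 0.15 * s),
            )
            name = f"{community}{'ab'[s]}" if n_sub > 1 else community
            species = {
                f"sp_{community}_{k}": c
                for k, c in zip("xyz", (60.0 - 10.0 * s, 25.0, 10.0 + 5.0 * s))
            }
            archetypes.append(Archetype(name=name, community=community,
                                        params=sub, species=species))
    return archetypes


def narrow_feature_archetypes(n: int = 3) -> list[Archetype]:
    """Categories that differ only in spectrally narrow features.

    All categories share the broad reflectance shape; they differ in small
    red-edge inflection shifts and in narrow (sigma = 8 nm) absorption lines
    placed between typical broadband channel centres.  Hyperspectral data
    resolve these differences; broadband simulation averages them away — the
    preset for comparing spectral resolutions.
    """
    out = []
    for i in range(n):
        params = ArchetypeParams(
            red_edge_pos=712.0 + 5.0 * i,
            extra_features=(
                (960.0 + 28.0 * i, 0.14, 8.0),
                (1130.0 + 32.0 * i, 0.12, 8.0),
                (1240.0 - 25.0 * i, 0.10, 8.0),
            ),
        )
        name = f"N{i + 1:02d}"
        species = {f"sp_{name}_{k}": c for k, c in zip("xyz", (60.0, 25.0, 10.0))}
        out.append(Archetype(name=name, community=name, params=params,
                             species=species))
    return out


# ---------------------------------------------------------------------------
# scene generation
# ---------------------------------------------------------------------------

@dataclass
class Scene:
    """A generated scene: spectra, cover plots and the reproducibility manifest."""

    dataset: SpectralDataset
    cover: pd.DataFrame              # plots x species percent cover
    plot_categories: pd.Series       # plot id -> finest category
    manifest: dict


_LEVEL_FIELDS = ("base", "green_amp", "red_depth", "nir", "water_1450",
                 "water_1940", "swir_slope")
_POS_FIELDS = ("green_centre", "red_centre", "red_edge_pos")


def _apply_month(archetypes: Sequence[Archetype],
                 effect: MonthEffect) -> list[Archetype]:
    """Scale category separation and apply seasonal offsets."""
    fields = _LEVEL_FIELDS + _POS_FIELDS
    means = {f: float(np.mean([getattr(a.params, f) for a in archetypes]))
             for f in fields}
    out = []
    for a in archetypes:
        updates = {f: means[f] + effect.separation * (getattr(a.params, f) - means[f])
                   for f in fields}
        updates["red_edge_pos"] = float(np.clip(updates["red_edge_pos"],
                                                690.0, 750.0))
        updates["nir"] = max(0.0, updates["nir"] + effect.nir_delta)
        updates["red_edge_width"] = max(
            1.0, a.params.red_edge_width + effect.red_edge_width_delta)
        updates["extra_features"] = tuple(
            (c, max(0.0, d * effect.separation), s)
            for c, d, s in a.params.extra_features)
        out.append(dataclasses.replace(
            a, params=dataclasses.replace(a.params, **updates)))
    return out


def _jitter_params(params: ArchetypeParams, n: int, config: SyntheticConfig,
                   rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Per-pixel parameter draws for ``n`` pixels, broadcastable over bands."""
    cols = lambda v: v[:, None]  # noqa: E731
    out: dict[str, np.ndarray] = {}
    for name in _LEVEL_FIELDS:
        v = getattr(params, name)
        out[name] = cols(np.maximum(
            0.0, v * (1.0 + config.level_jitter_rel * rng.standard_normal(n))))
    for name in _POS_FIELDS:
        v = getattr(params, name)
        out[name] = cols(v + config.pos_jitter_nm * rng.standard_normal(n))
    out["red_edge_pos"] = np.clip(out["red_edge_pos"], 690.0, 750.0)
    out["red_edge_width"] = cols(np.maximum(
        1.0, params.red_edge_width
        * (1.0 + config.level_jitter_rel * rng.standard_normal(n))))
    # extra-feature depths jitter like levels; centres/widths stay fixed
    extras = []
    for c, d, s in params.extra_features:
        depth = np.maximum(0.0, d * (1.0 + config.level_jitter_rel
                                     * rng.standard_normal(n)))
        extras.append((c, cols(depth), s))
    out["extra_features"] = tuple(extras)
    return out


def _pixel_noise(n: int, n_bands: int, spacing_nm: float,
                 config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    noise = config.noise_sd * rng.standard_normal((n, n_bands))
    if config.smooth_noise_sd > 0:
        raw = rng.standard_normal((n, n_bands))
        sigma_bins = max(config.smooth_noise_scale_nm / spacing_nm, 1e-6)
        smooth = gaussian_filter1d(raw, sigma_bins, axis=1, mode="nearest")
        sd = smooth.std()
        if sd > 0:
            noise = noise + config.smooth_noise_sd * smooth / sd
    return noise


def _patch_layout(config: SyntheticConfig,
                  rng: np.random.Generator) -> list[dict]:
    """Assign every patch a slot on a regular slot grid, seeded-shuffled."""
    patches = []
    idx = 0
    for arch in config.archetypes:
        for _ in range(config.wide_patches_per_category):
            patches.append({"patch_id": f"patch{idx:03d}", "category": arch.name,
                            "condition": "wide", "shape": config.wide_shape})
            idx += 1
        for _ in range(config.narrow_patches_per_category):
            patches.append({"patch_id": f"patch{idx:03d}", "category": arch.name,
                            "condition": "narrow", "shape": config.narrow_shape})
            idx += 1
    n = len(patches)
    ncols = int(np.ceil(np.sqrt(n)))
    nrows = int(np.ceil(n / ncols))
    slot_h = max(config.wide_shape[0], config.narrow_shape[0]) + config.slot_gap
    slot_w = max(config.wide_shape[1], config.narrow_shape[1]) + config.slot_gap
    slots = rng.permutation(nrows * ncols)[:n]
    for patch, slot in zip(patches, slots):
        sr, sc = divmod(int(slot), ncols)
        patch["origin"] = (sr * slot_h, sc * slot_w)
        patch["farm_id"] = f"farm_{sr // max(1, nrows // 2)}{sc // max(1, ncols // 2)}"
    return patches


def generate_scene(config: SyntheticConfig, seed: int = 0,
                   month: str | None = None) -> Scene:
    """Generate a labelled scene; a pure function of (config, seed, month).

    Patches are placed on a non-overlapping slot grid.  Wide patches emit
    only their interior pixels (outer ``wide_trim`` metres dropped, as when
    edges are trimmed from ground truth); narrow patches emit all pixels,
    with pixels within ``edge_mix_width`` of the boundary convexly mixed with
    a partner spectrum (weight decaying with distance into the patch).  The
    partner is the clean archetype spectrum of the geometrically nearest
    other patch's category — the mixed-vegetation mechanism that makes
    narrow objects hard — or the soil end-member when no other patch exists;
    the partner category is recorded per pixel in the metadata.
    """
    if month is not None and month not in MONTHS:
        raise SpectraError(f"unknown month {month!r} (use {MONTHS})")
    archetypes = list(config.archetypes)
    if month is not None:
        archetypes = _apply_month(archetypes, config.month_effects[month])
    arch_by_name = {a.name: a for a in archetypes}
    grid = config.grid
    wl = grid.wavelengths
    spacing = float(np.mean(np.diff(wl)))
    soil = soil_spectrum(wl)

    rng = np.random.default_rng(seed)
    patches = _patch_layout(config, rng)

    # clean (unjittered) archetype spectra, used as edge-mixing partners
    clean_arch = {
        a.name: spectrum_from_params(wl, **_params_as_kwargs(a.params))
        for a in archetypes}

    def _nearest_partner(patch) -> str:
        """Category of the geometrically nearest other patch ('' = soil)."""
        oy, ox = patch["origin"]
        best, best_d = "", np.inf
        for other in patches:
            if other["patch_id"] == patch["patch_id"]:
                continue
            d = (other["origin"][0] - oy) ** 2 + (other["origin"][1] - ox) ** 2
            if d < best_d or (d == best_d and other["category"] < best):
                best, best_d = other["category"], d
        return best

    refl_rows, meta_rows = [], []
    cover_rows, plot_cats = {}, {}
    for patch in patches:
        arch = arch_by_name[patch["category"]]
        h, w = patch["shape"]
        oy, ox = patch["origin"]
        rows, cols = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
        rows, cols = rows.ravel(), cols.ravel()
        if patch["condition"] == "wide":
            t = config.wide_trim
            keep = ((rows >= t) & (rows < h - t) & (cols >= t) & (cols < w - t))
        else:
            keep = np.ones(rows.size, dtype=bool)
        rows, cols = rows[keep], cols[keep]
        n_px = rows.size

        prng = np.random.default_rng([seed, 1, int(patch["patch_id"][5:])])
        params = _jitter_params(arch.params, n_px, config, prng)
        clean = spectrum_from_params(wl[None, :], **params)
        noisy = np.clip(clean + _pixel_noise(n_px, wl.size, spacing, config, prng),
                        0.0, 1.0)

        partner_cat = ""
        partner = soil
        if patch["condition"] == "narrow" and config.edge_mix_width > 0:
            dist = np.minimum.reduce([rows, h - 1 - rows, cols, w - 1 - cols])
            mixw = config.edge_mix_max * np.maximum(
                0.0, 1.0 - dist / config.edge_mix_width)
            partner_cat = _nearest_partner(patch)
            if partner_cat:
                partner = clean_arch[partner_cat]
        else:
            mixw = np.zeros(n_px)
        pixels = (1.0 - mixw[:, None]) * noisy + mixw[:, None] * partner[None, :]

        refl_rows.append(pixels)
        for i in range(n_px):
            meta_rows.append({
                "sample_id": f"{patch['patch_id']}_px{rows[i]}_{cols[i]}",
                "patch_id": patch["patch_id"],
                "type_id": arch.name,
                "farm_id": patch["farm_id"],
                "x": float(ox + cols[i]),
                "y": float(oy + rows[i]),
                "month": month or "",
                "condition": patch["condition"],
                "edge_mixed": bool(mixw[i] > 0),
                "mix_weight": float(mixw[i]),
                "mix_partner": partner_cat if mixw[i] > 0 else "",
                "label_community": arch.community,
                "label_finest": arch.name,
            })

        for pi in range(config.plots_per_patch):
            pid = f"{patch['patch_id']}_plot{pi}"
            covers = {}
            for sp, c in arch.species.items():
                covers[sp] = float(np.clip(
                    c + config.cover_jitter * prng.standard_normal(), 0.0, 100.0))
            cover_rows[pid] = covers
            plot_cats[pid] = arch.name

    dataset = SpectralDataset(grid, np.vstack(refl_rows), pd.DataFrame(meta_rows))
    cover = pd.DataFrame.from_dict(cover_rows, orient="index").fillna(0.0)
    cover.index.name = "sample_id"
    cover = cover[sorted(cover.columns)]
    manifest = {
        "generator": "vegspec.synthetic.generate_scene",
        "seed": int(seed),
        "month": month,
        "config": config_to_dict(config),
        "patches": [{k: v for k, v in p.items() if k != "shape"} |
                    {"shape": list(p["shape"])} for p in patches],
        "n_pixels": dataset.n_samples,
    }
    return Scene(dataset=dataset, cover=cover,
                 plot_categories=pd.Series(plot_cats), manifest=manifest)


def scene_from_manifest(manifest: dict) -> Scene:
    """Regenerate a scene from its manifest (bit-identical to the original)."""
    config = config_from_dict(manifest["config"])
    return generate_scene(config, seed=manifest["seed"], month=manifest["month"])


def monthly_series(config: SyntheticConfig, months: Sequence[str],
                   seed: int = 0) -> dict[str, Scene]:
    """One scene per requested month, sharing geometry and pixel randomness.

    Only the archetype parameters change between months (via the configured
    :class:`MonthEffect`); with all effects neutral the spectra are identical
    across months.
    """
    bad = [m for m in months if m not in MONTHS]
    if bad:
        raise SpectraError(f"unknown months {bad} (use {MONTHS})")
    return {m: generate_scene(config, seed=seed, month=m) for m in months}
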