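"""Experiment orchestration: spectral variant x thematic resolution x edge grid.

Runs the full classification chain for every cell of an experiment grid —
build or degrade the spectra (band simulation), assemble covariates, split
patches geographically, fit the class-balanced forest and evaluate with
repeated capped validation — and collects accuracies and kappas in a tidy
result table.  A JSON manifest of the complete configuration and seed is
written alongside, and rerunning from the manifest alone reproduces the
result table exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bandsim import builtin_bandset, simulate_multispectral
from .classify import (
    ForestConfig,
    balanced_forest_fit,
    evaluate,
    geographic_split,
)
from .features import FeatureConfig, assemble_covariates
from .spectra import SpectraError, SpectralDataset
from .synthetic import (
    Scene,
    SyntheticConfig,
    config_from_dict,
    config_to_dict,
    generate_scene,
)

logger = logging.getLogger(__name__)

VARIANTS = ("hyperspectral", "sim13", "sim8")


@dataclass
class ExperimentConfig:
    """One experiment grid over a synthetic scene.

    ``downsample_targets`` maps edge condition to the per-category cap used
    both per tree at training and per repeat at validation (None = no cap).
    """

    synthetic: SyntheticConfig
    variants: tuple[str, ...] = VARIANTS
    resolutions: tuple[str, ...] = ("community", "finest")
    edge_conditions: tuple[str, ...] = ("wide", "narrow")
    month: str | None = None
    ntree: int = 200
    mtry: int | None = None
    downsample_targets: dict[str, int | None] = field(
        default_factory=lambda: {"wide": 1000, "narrow": 300})
    repeats: int = 5
    sg_window: int = 9
    sg_polyorder: int = 2

    def __post_init__(self) -> None:
        if not self.variants or not self.resolutions or not self.edge_conditions:
            raise SpectraError("need >=1 variant, resolution and edge condition")
        bad = [v for v in self.variants if v not in VARIANTS]
        if bad:
            raise SpectraError(f"unknown variants {bad}; use {VARIANTS}")


@dataclass
class ResultTable:
    """Per-repeat rows plus per-cell summary rows."""

    rows: pd.DataFrame      # variant, resolution, edge, repeat, accuracy, kappa, status
    summary: pd.DataFrame   # per cell: mean/min/max of accuracy and kappa

    @property
    def failed(self) -> bool:
        return bool((self.rows["status"] != "ok").any())


def _cell_seed(seed: int, *idx: int) -> int:
    return int(np.random.SeedSequence([seed, *idx]).generate_state(1)[0] % (2**31))


def _variant_dataset(scene_dataset: SpectralDataset, variant: str) -> SpectralDataset:
    if variant == "hyperspectral":
        return scene_dataset
    return simulate_multispectral(scene_dataset, builtin_bandset(variant))


def run_experiment(config: ExperimentConfig, seed: int = 0,
                   out_dir: str | Path | None = None) -> ResultTable:
    """Run every cell of the experiment grid on a freshly generated scene.

    A failing cell is marked ``failed`` in the table and the run continues.
    With ``out_dir``, per-repeat confusion matrices, the result tables and
    the reproducibility manifest are written there.
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    scene = generate_scene(config.synthetic, seed=seed, month=config.month)
    rows = []
    for vi, variant in enumerate(config.variants):
        for ri, resolution in enumerate(config.resolutions):
            for ei, edge in enumerate(config.edge_conditions):
                cell = f"{variant}/{resolution}/{edge}"
                try:
                    cell_rows = _run_cell(scene, config, variant, resolution,
                                          edge, _cell_seed(seed, vi, ri, ei), out)
                    rows.extend(cell_rows)
                    logger.info("cell %s: mean accuracy %.3f", cell,
                                np.mean([r["accuracy"] for r in cell_rows]))
                except Exception as exc:  # noqa: BLE001 - cell isolation
                    logger.error("cell %s failed: %s", cell, exc)
                    rows.append({"variant": variant, "resolution": resolution,
                                 "edge": edge, "repeat": -1,
                                 "accuracy": np.nan, "kappa": np.nan,
                                 "status": f"failed: {exc}"})
    rows_df = pd.DataFrame(rows)
    ok = rows_df[rows_df["status"] == "ok"]
    summary = (ok.groupby(["variant", "resolution", "edge"])[["accuracy", "kappa"]]
               .agg(["mean", "min", "max"]) if len(ok) else pd.DataFrame())
    if isinstance(summary, pd.DataFrame) and len(summary):
        summary.columns = ["_".join(c) for c in summary.columns]
        summary = summary.reset_index()
    result = ResultTable(rows=rows_df, summary=summary)

    if out is not None:
        rows_df.to_csv(out / "results.csv", index=False)
        if len(summary):
            summary.to_csv(out / "summary.csv", index=False)
        manifest = experiment_manifest(config, seed)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2),
                                           encoding="utf-8")
    return result


def _run_cell(scene: Scene, config: ExperimentConfig, variant: str,
              resolution: str, edge: str, cell_seed: int,
              out: Path | None) -> list[dict]:
    meta = scene.dataset.meta
    subset = scene.dataset.subset((meta["condition"] == edge).to_numpy())
    if subset.n_samples == 0:
        raise SpectraError(f"no {edge} pixels in scene")
    data = _variant_dataset(subset, variant)

    split = geographic_split(data, by="type_id")
    train_mask = split.train_mask(data)
    val_mask = split.val_mask(data)
    assert not np.any(train_mask & val_mask), "train/validation overlap"
    if not train_mask.any() or not val_mask.any():
        raise SpectraError("degenerate geographic split")

    mode = "airborne" if variant == "hyperspectral" else "multispectral"
    fconf = FeatureConfig(mode=mode, sg_window=config.sg_window,
                          sg_polyorder=config.sg_polyorder)
    table = assemble_covariates(data, fconf, train_mask=train_mask)

    labels = data.labels(resolution).astype(str)
    target = config.downsample_targets.get(edge)
    forest = ForestConfig(ntree=config.ntree, mtry=config.mtry,
                          downsample_target=target, seed=cell_seed)
    model = balanced_forest_fit(table.table.loc[train_mask],
                                labels[train_mask], forest)
    evaluation = evaluate(model, table.table.loc[val_mask], labels[val_mask],
                          downsample_target=target, repeats=config.repeats,
                          seed=cell_seed)
    rows = []
    for rep, (acc, kap, cm) in enumerate(evaluation.repeats):
        rows.append({"variant": variant, "resolution": resolution, "edge": edge,
                     "repeat": rep, "accuracy": acc, "kappa": kap, "status": "ok"})
        if out is not None:
            cm.to_frame().to_csv(
                out / f"cm_{variant}_{resolution}_{edge}_rep{rep}.csv")
    return rows


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------

def experiment_to_dict(config: ExperimentConfig) -> dict:
    d = dataclasses.asdict(config)
    d["synthetic"] = config_to_dict(config.synthetic)
    d["variants"] = list(config.variants)
    d["resolutions"] = list(config.resolutions)
    d["edge_conditions"] = list(config.edge_conditions)
    return d


def experiment_from_dict(d: dict) -> ExperimentConfig:
    d = dict(d)
    d["synthetic"] = config_from_dict(d["synthetic"])
    d["variants"] = tuple(d["variants"])
    d["resolutions"] = tuple(d["resolutions"])
    d["edge_conditions"] = tuple(d["edge_conditions"])
    d["downsample_targets"] = {k: (None if v is None else int(v))
                               for k, v in d["downsample_targets"].items()}
    return ExperimentConfig(**d)


def experiment_manifest(config: ExperimentConfig, seed: int) -> dict:
    return {"vegspec_version": __version__, "seed": int(seed),
            "experiment": experiment_to_dict(config)}


def rerun_from_manifest(manifest: dict | str | Path,
                        out_dir: str | Path | None = None) -> ResultTable:
    """Re-execute an experiment from its manifest alone."""
    if not isinstance(manifest, dict):
        manifest = json.loads(Path(manifest).read_text(encoding="utf-8"))
    config = experiment_from_dict(manifest["experiment"])
    return run_experiment(config, seed=manifest["seed"], out_dir=out_dir)
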