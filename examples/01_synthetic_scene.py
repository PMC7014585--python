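"""Generate a labelled synthetic grassland scene and inspect its structure.

A scene is a set of 1 m pixels organised in patches of vegetation categories,
with nested labels (community / finest), wide patches (edge pixels trimmed)
and narrow patches (edge pixels mixed with neighbouring vegetation), plus a
species percent-cover table per patch.
"""

from vegspec import SyntheticConfig, default_archetypes, generate_scene

config = SyntheticConfig(
    archetypes=default_archetypes(n_communities=6, n_categories=8),
    n_bands=211,
)
scene = generate_scene(config, seed=42)

meta = scene.dataset.meta
print(f"pixels: {scene.dataset.n_samples}, bands: {len(scene.dataset.grid)}")
print(f"communities: {meta['label_community'].nunique()}, "
      f"finest categories: {meta['label_finest'].nunique()}")
print(meta["condition"].value_counts().to_string())
print(f"edge-mixed pixels: {meta['edge_mixed'].sum()} "
      "(narrow-patch pixels blended with a neighbouring category)")
print(f"cover plots: {len(scene.cover)} x {scene.cover.shape[1]} species")
# every number above is recoverable from scene.manifest alone: the generator
# is a pure function of (config, seed)
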