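"""Run the four-step image analysis on a synthetic scene.

Steps: (1) statistical substrate exclusion, (2) per-pixel forest
classification, (3) lateral modal post-processing, (4) particle detection
and characterization. Prints the recovered particle list next to the
planted ground truth.
"""

import numpy as np

from plastiscan import (
    LabeledSpectraSet,
    PipelineConfig,
    RDFConfig,
    SUBSTRATE,
    default_axis,
    export_csv,
    make_reference_library,
    random_scene_spec,
    run_pipeline,
    synth_scene,
    train_rdf,
)

spec = random_scene_spec(n_particles=8, rows=96, cols=96, seed=42)
img, truth = synth_scene(spec)

X, y = make_reference_library(n_per_class=20, seed=0)
model = train_rdf(LabeledSpectraSet(X, y, default_axis()),
                  RDFConfig(n_trees=40, seed=0))

config = PipelineConfig(substrate_k=6.0, passes=1, min_pixels=2)
table, labels, probs, counts = run_pipeline(img, model, config)

masked = int(np.sum(labels == SUBSTRATE))
print(f"pixels: {img.n_pixels} total, {masked} excluded as substrate, "
      f"{img.n_pixels - masked} classified")
print(f"particles detected: {len(table)} (truth: {len(truth.particles)})")
print(f"per-class counts: {counts}\n")
print(f"{'id':>3} {'class':<6} {'px':>4} {'len_um':>7} {'wid_um':>7} "
      f"{'aspect':>6} {'orient':>6} {'reliab':>6}")
for p in table:
    print(f"{p.id:>3} {p.class_id:<6} {p.n_pixels:>4} {p.length:>7.1f} "
          f"{p.width:>7.1f} {p.aspect_ratio:>6.2f} {p.orientation:>6.1f} "
          f"{p.reliability:>6.2f}")

export_csv(table, "demo_particles.csv")
print()
print("Length/width are principal-axis spans plus one 11 um pixel pitch;")
print("reliability is the mean winning vote fraction of the forest over the")
print("particle's pixels. Full list written to demo_particles.csv.")
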