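"""Generate a two-channel synthetic acquisition and write it to disk.

Produces OME-TIFF stacks for the mitochondrial and ER channels plus a
JSON sidecar with the generating parameters and per-pair ground-truth
moving fractions — the same artifact layout the `cristadyn simulate`
command produces.
"""

import json

import numpy as np

from cristadyn import SceneConfig, generate_scene, save_timelapse

scene = generate_scene(
    SceneConfig(size=256, n_mitochondria=5, frame_count=30, texture_motion_fraction=0.05, seed=99)
)
out = "scratch/simulated_scene"
save_timelapse(scene.mito, f"{out}/mito.ome.tif")
save_timelapse(scene.er, f"{out}/er.ome.tif")
truth = {
    "true_cm_fraction_mean": float(np.nanmean(scene.truth.true_cm_fraction)),
    "true_cm_fraction_per_pair": scene.truth.true_cm_fraction.round(5).tolist(),
}
with open(f"{out}/truth.json", "w") as fh:
    json.dump(truth, fh, indent=2)

print(f"mito channel: {scene.mito.n_frames} frames {scene.mito.frame_shape}")
print(f"ER channel  : {scene.er.n_frames} frames (one per block of 10)")
print(f"ground-truth moving fraction: {truth['true_cm_fraction_mean']:.2%} per frame pair")
print(f"wrote {out}/mito.ome.tif, er.ome.tif, truth.json")
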