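"""Single-channel cristae/shell kinetics on a synthetic time-lapse.

Generates a seeded 30-frame scene in which 7% of the mitochondrial area
toggles its cristae texture per frame, runs the full pipeline
(background subtraction, bleach correction, dual thresholding, shell
closing, change decomposition) and compares the measured moving-area
fractions with the simulator's ground truth.
"""

import numpy as np

from cristadyn import SceneConfig, generate_scene, run_kinetics

scene = generate_scene(
    SceneConfig(size=256, n_mitochondria=5, frame_count=30, texture_motion_fraction=0.07, seed=42)
)
result = run_kinetics(scene.mito, out_dir="scratch/kinetics_example")

true_cm = float(np.nanmean(scene.truth.true_cm_fraction))
print(f"generated cristae motion : 7.00% of mitochondrial area per frame pair")
print(f"realized ground truth    : {true_cm:.2%}")
print(f"pipeline CM estimate     : {result.trace.cm_mean:.2%}")
print(f"pipeline IBM estimate    : {result.trace.ibm_mean:.2%}  (shell is static here)")
print("per-pair CSV written to scratch/kinetics_example/kinetics.csv")
# The CM estimate should sit within a few percent relative of the truth;
# the IBM value is the small residual flicker of the derived shell.
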