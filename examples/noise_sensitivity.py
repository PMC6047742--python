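"""Noise sensitivity of the cristae-kinetics estimator.

On a completely motionless scene any nonzero CM reading is estimator
bias: pixels near intensity-class boundaries (the organelle rim, stripe
transitions) flicker through the local threshold when read noise is
comparable to their classification margin.  This script measures that
flicker floor at increasing noise levels.
"""

from cristadyn import SceneConfig, generate_scene, run_kinetics

print("noise sigma   CM flicker floor   IBM flicker floor")
for sigma in (0.5, 1.0, 1.5, 2.0):
    cfg = SceneConfig(
        size=256,
        n_mitochondria=5,
        frame_count=30,
        texture_motion_fraction=0.0,
        noise_sigma=sigma,
        seed=2,
    )
    trace = run_kinetics(generate_scene(cfg).mito).trace
    print(f"{sigma:>11.1f}   {trace.cm_mean:>16.4%}   {trace.ibm_mean:>17.4%}")
# The floor grows steeply with noise; at the default sigma (1.0, ~0.5%
# of the dynamic range) it is negligible against motion fractions of a
# few percent, at sigma >= 2 it would dominate a 2% signal.
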