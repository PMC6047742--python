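"""Cristae kinetics as a function of ER-contact proximity.

Simulates a dual-channel acquisition (3 blocks of 1 ER frame + 10
mitochondrial frames at 1 Hz) in which cristae motion is halved within
~250 nm of the ER network, then measures the motion fraction inside
nested contact-site dilation bands (5, 10, 20 iterations, count = 3).
"""

from cristadyn import SceneConfig, generate_scene, run_mam

scene = generate_scene(
    SceneConfig(
        size=256,
        n_mitochondria=5,
        frame_count=30,
        texture_motion_fraction=0.07,
        mam_slowdown=0.5,
        seed=7,
    )
)
result = run_mam(scene.as_dual_channel(), out_dir="scratch/mam_example")

print("cristae moving-area fraction by ER proximity (means over frame pairs):")
for level, trace in result.per_level.items():
    print(f"  band({level:2d} iterations): {trace.cm_mean:.2%}")
print(f"  whole mitochondrion : {result.whole_trace.cm_mean:.2%}")
# Bands closest to the ER-mitochondria overlap report the slowest
# cristae motion; the gradient toward the whole-organelle value mirrors
# the generated contact-site deceleration.
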