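# cristadyn

Quantification of inner-mitochondrial-membrane (IMM) dynamics from
live-cell structured-illumination microscopy (SIM) time-lapses.

Mitochondrial cristae — the invaginations of the IMM — remodel on a
seconds timescale, but they sit at or below the resolution limit even of
super-resolution imaging, so their motion cannot be tracked object by
object. `cristadyn` instead measures cristae dynamics as an *area
turnover*: the fraction of the mitochondrial footprint whose thresholded
fine-structure changes between consecutive frames. It separates that
signal from whole-organelle motion, and can stratify it by proximity to
ER–mitochondria contact sites (MAMs). The package is aimed at cell
biologists analyzing reconstructed SIM (or comparable super-resolution)
time-lapses of mitochondrially stained cells, and at anyone who needs a
fully scripted, reproducible replacement for the interactive ImageJ
workflow this kind of analysis is usually built from.

## Method

For a stack of frames I_t (1 Hz), after background subtraction
(sliding-window histogram mode) and photobleaching correction
(mono-exponential fit a·e^{−bt} to frame means):

- **M_t** = global Otsu mask of I_t (the mitochondrial area),
- **L_t** = local-mean threshold mask, radius 2 px (fine IMM texture),
- **S_t** = M_t ∧ L_t, the *IMM-structure* mask,
- **B_t** = shell: S_t closed by count-threshold morphology
  (dilate ×2, erode ×2, count = 2) and hole-filled — the inner boundary
  membrane (IBM) proxy.

Per frame pair, with Δ denoting symmetric difference of consecutive
masks,

    IBM kinetics:  |ΔB_t| / |M_t|
    CM  kinetics:  |ΔS_t \ ΔB_t| / |M_t|

i.e. structure changes not explained by shell changes are attributed to
the cristae membrane (CM), normalized to the mitochondrial area, and
averaged over the time-lapse. For dual-channel runs (pattern: 1 ER frame
+ 10 mitochondrial frames, ×3 at 1 Hz) the overlap M_t ∧ ER defines the
MAM core, which is grown by count-threshold dilation (5/10/20
iterations, count = 3) into nested proximity bands; CM kinetics and the
normalization area are both restricted to each band.

A synthetic-scene generator (`cristadyn.simulate`) renders two-channel
SIM-like time-lapses with exactly known shell motion, cristae-texture
turnover, ER-proximity-dependent slowdown, bleaching and band-limited
noise, so every stage of the pipeline is verifiable without microscopy
data. See `docs/methods.md` for the full model and its limitations.

## Worked example

```bash
python examples/quantify_kinetics.py
```

generates a 30-frame scene in which 7% of the mitochondrial area toggles
its cristae texture per frame (shells static), runs the full pipeline
and prints:

```
generated cristae motion : 7.00% of mitochondrial area per frame pair
realized ground truth    : 6.80%
pipeline CM estimate     : 7.15%
pipeline IBM estimate    : 0.00%  (shell is static here)
per-pair CSV written to scratch/kinetics_example/kinetics.csv
```

The CM estimate recovers the generated turnover (6.80% realized after
binomial sampling; 7.15% measured); the IBM value stays at the noise
floor because the organelles do not move. `examples/mam_proximity.py`
adds the contact-site analysis — with cristae motion halved within
~250 nm of the ER it prints the proximity gradient

```
  band( 5 iterations): 3.98%
  band(10 iterations): 4.65%
  band(20 iterations): 5.46%
  whole mitochondrion : 6.63%
```

— slowest nearest the ER, recovering the generated deceleration. The
other examples cover bleach correction, per-object shape metrics, scene
export and the estimator's noise sensitivity.

For real data the same analyses run from the shell:

```bash
cristadyn quantify stack.tif --out results/
cristadyn mam mito.tif er.tif --out results/      # dual-channel
cristadyn simulate --seed 1 --out scene/          # synthetic scene
cristadyn morphology stack.tif --out shapes.csv
```

Outputs are per-frame-pair CSV tables plus a JSON provenance record;
identical input and configuration reproduce identical bytes.

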