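# ltq — liver trauma quantification from CT

`ltq` is an end-to-end pipeline for detecting and quantifying blunt liver
trauma on 3D contrast-enhanced CT.  Lacerations and intraparenchymal
hematomas appear as hypodense regions inside the enhanced parenchyma; their
volumetric extent — the **liver disruption involvement**

```
LDI(%) = V(trauma) / V(liver) × 100
```

— is a key component of CT-based injury grading, yet is usually judged
visually.  `ltq` computes it automatically and reproducibly:

1. a slice-wise **U-net backbone** (pure numpy, CPU-trainable, fully
   pluggable) proposes initial liver and trauma masks;
2. **liver post-processing** (3D Gaussian smoothing of the mask indicator,
   small-region removal, axial hole filling, largest-component selection)
   produces the final liver segmentation;
3. **trauma post-processing** applies domain knowledge — a component is
   dropped if more than 50% of it lies outside the liver, or if a Welch
   t-test cannot distinguish its intensities from intact parenchyma (the
   defence against fatty liver and congestive hepatopathy false positives)
   — and then refines survivors with a **3D Chan-Vese active contour**
   evolved by a sparse-field level set, clipped to the liver:

   ```
   F(s₁, s₂, S) = µ·A(S) + ν·V(S) + λ₁∫inside |I−s₁|² + λ₂∫outside |I−s₂|²
   ```

   with λ₁ = λ₂ = 1, µ = 0.1, and the contraction bias ν set by grid
   search;
4. **severity quantification** turns the masks into physical volumes and
   the LDI percentage;
5. **evaluation tools** provide Dice/recall/precision/RVD/VOE,
   severity-balanced patient-wise cross-validation folds, and
   regression + Bland-Altman agreement between computed and reference LDI.

A seeded **synthetic CT-phantom generator** (single-component organ,
irregular hypodense trauma blobs hitting an exact target LDI, fatty /
congestive / streak-artifact confounders) makes every stage testable
without patient data.  Everything runs from Python; a thin `ltq` command
covers the common shell workflows (`ltq phantom`, `ltq segment`, `ltq ldi`,
`ltq experiment`).

See [docs/methods.md](docs/methods.md) for the model, numerics and design
choices.

## Worked example

`examples/03_segment_case.py` trains a small liver U-net on six phantoms
and runs the full pipeline on a held-out phantom with 11.99% true
disruption (the trauma mask enters through the pipeline's mask-injection
seam as a perturbed oracle — ground truth dilated by one voxel):

```
$ python examples/03_segment_case.py
liver Dice vs ground truth: 0.961
liver volume:  95.0 cm^3
trauma volume: 10.7 cm^3
computed LDI:  11.28%   (reference: 11.99%)
```

The trained network recovers the liver at Dice 0.96; the exclusion rules
plus Chan-Vese refinement shrink the dilated trauma candidate back to the
lesion, and the computed severity lands within 0.8 points of the
reference.  `examples/04_ldi_agreement.py` repeats this over a 12-phantom
cohort and prints the agreement statistics:

```
regression: computed = 0.983 x reference + 0.105   (r^2 = 0.995)
Bland-Altman: bias -0.11%  limits of agreement [-1.70, +1.48]%
```

A slope near 1 and a bias near 0 mean the pipeline neither inflates nor
shrinks the measured injury burden.  The other examples generate phantom
cohorts (`01`) and demonstrate the Chan-Vese energy descent on a
constructed lesion (`02`).

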