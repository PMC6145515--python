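# weberelastica

Variational restoration of 2-D images corrupted by **multiplicative
(speckle) noise** — the degradation f = g·η, E[η] = 1, characteristic of
coherent imaging (ultrasound, SAR, PET).  Intended for researchers in
biological/medical image analysis who need an edge-preserving,
staircase-free speckle remover with fully reproducible synthetic
benchmarks.

## The model

The core solver minimizes, over strictly positive images g,

```
E(g) = ∬ (β₁ + β₂/g) (α₁ + α₂ κ²) |∇g| dx dy  +  ∬ (log g + f/g) dx dy ,
κ = ∇·(∇g/|∇g|)
```

The regularizer applies **Euler's elastica** (length + squared curvature of
every level line) weighted by the **Weberized** factor β₁ + β₂/g, which
penalizes relative rather than absolute contrast; the data term is the
Gamma-MAP fidelity for multiplicative noise.  The fourth-order
Euler–Lagrange flow

```
∂g/∂t = ∇·U − λ̃(g)(g − f),   λ̃ = β₁ + β₂/g,
U = (α₁ + α₂κ²) ∇g/|∇g| − (2α₂/|∇g|³) (∇⊥g·∇(κ|∇g|)) ∇⊥g
```

is integrated explicitly on a min-mod staggered grid with Neumann
boundaries.  Three classical baselines ship for comparison: Weberized TV
via additive operator splitting (**m1**), a hybrid log-domain split model
with Chambolle duals and split Bregman (**m3**), and TV with a non-convex
edge indicator via ADMM (**m4**).  A speckle simulator (uniform and
L-look gamma), deterministic phantoms, PSNR/line-profile metrics and
multi-seed experiment harnesses complete the pipeline.  See
`docs/methods.md` for the numerics and every parameter.

## Worked example

```python
import weberelastica as we

clean = we.default_shapes_phantom(128, spacing=1.0)     # piecewise-constant card
noisy = we.speckle_uniform(clean, 0.1, seed=7)          # mean-1 speckle, σ² = 0.1
params = we.elastica_preset("shapes128")                # tuned benchmark preset
restored, trace = we.m2_denoise(noisy, params, record_energy=False)
print("noisy   PSNR: %.2f dB" % we.psnr(clean, noisy))
print("restored PSNR: %.2f dB  (%d iterations)" % (we.psnr(clean, restored), trace.iterations))
```

prints

```
noisy   PSNR: 17.88 dB
restored PSNR: 29.98 dB  (3000 iterations)
```

i.e. the elastica flow recovers ~12 dB on the benchmark phantom: speckle in
the flat regions is removed while the disk and rectangle edges stay sharp.
The same pipeline from the shell:

```sh
weberelastica synth --kind shapes --size 128 --spacing 1 clean.png
weberelastica add-noise --sigma2 0.1 --seed 7 clean.png noisy.png
weberelastica denoise --method m2 --preset shapes128 --spacing 1 noisy.png restored.png
weberelastica evaluate clean.png restored.png
# PSNR = 28.6032 dB   (the 8-bit round trip through PNG costs ~1 dB)
```

`weberelastica compare | dt-study | sweep` run the multi-seed method
comparison, the time-step study and the parameter-sensitivity sweep;
`weberelastica run config.yaml` executes a fully manifest-reproducible
pipeline.

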