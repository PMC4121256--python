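# nbseg — narrow-band localized active contours for noisy color images

`nbseg` segments noisy color images with a level-set active contour driven
by **local region statistics**, evolved only on a **narrow band** around the
contour, applied **channel by channel** and combined into region labels.
It is aimed at the kind of segmentation problem that arises in biological
and other scientific imaging: flat-colored objects on contrasting
backgrounds, heavily corrupted by pixel noise, where global-mean methods
latch onto noise specks and gray-conversion methods cannot tell apart
objects of equal brightness but different color.

## The model

Each channel `I : Ω → [0,1]` carries a level-set field φ whose zero
crossing is the contour (interior = {φ < 0}, selected by a smoothed
Heaviside `H_ε`). With global interior/exterior means `u, v` and their
ball-windowed local counterparts `u_x, v_x` (radius r, default 2 px), the
contour evolves on the band {|φ| ≤ w} by

    ∂φ/∂t(x) = δ_ε(φ(x)) [ ((u−u_x)² − (v−v_x)²) · Σ_y B(x,y) δ_ε(φ(y)) + ν κ(x) ]

— the squared gap between local and global means of each phase, plus a
length penalty ν·κ. Local averaging makes the force robust to pixel noise;
the compact Dirac δ_ε and the band confine all motion to the contour
neighborhood. The per-pixel sign tuples of the N channel contours are
packed into labels `Σ sᵢ 2^(N−1−i)`, up to 2³ = 8 regions for RGB.

Two classical baselines ship alongside: the vectorial multiphase
Chan–Vese model (`vcv`, two level sets, four phases) and the channel-wise
two-phase CV model (`stpcv`), plus the overlap metrics
JS / DSC / RFP / RFN and a seeded generator of colored-shape scenes with
pixel-exact ground truth and Gaussian / salt-and-pepper / speckle noise.
See `docs/methods.md` for assumptions, parameter meanings and limitations.

## Worked example

```python
import numpy as np
from nbseg import (EvolutionConfig, NoiseSpec, add_noise, render, scene,
                   segment_image, per_label_overlap)
from nbseg.synthetic import color_truth

spec = scene("fig7")                       # six shapes, three colors, dark bg
image, _ = render(spec)
truth, _ = color_truth(spec)               # labels by color class
noisy = add_noise(image, NoiseSpec("gaussian", 0.08, seed=0))

result = segment_image(noisy, model="nbracm", init="circles:3",
                       cfg=EvolutionConfig())
print("regions:", result.labeling.n_regions)
for label, matched, rep in per_label_overlap(truth, result.labeling.labels):
    print(f"color class {label}: dice={rep.dice:.3f} js={rep.js:.3f}")
```

prints

```
regions: 7
color class 0: dice=0.997 js=0.993
color class 1: dice=0.989 js=0.978
color class 2: dice=0.981 js=0.963
color class 3: dice=0.977 js=0.955
```

i.e. under additive Gaussian noise of variance 0.08 (σ ≈ 0.28 on a 0.8
contrast) every color region is recovered with Dice ≥ 0.97; the extra
predicted regions are thin slivers of boundary pixels where two channel
contours disagree by a pixel.

The same pipeline is available from the shell:

```bash
nbseg synth fig7 --noise gaussian --amount 0.08 -o out/      # render scene
nbseg segment out/fig7.png --model nbracm --init circles:3 -o out/run
nbseg eval out/fig7_truth.png out/run/labels.png -o out/report.csv
nbseg sweep fig11 --radii 1,2,5,9 --noise gaussian --amount 0.1 -o sweep.csv
```

`segment` writes the label map, a colorized preview and a YAML manifest
holding the fully resolved configuration; `sweep` reruns the model at
several localization radii on one shared noisy rendering.

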