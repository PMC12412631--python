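# hdnirs

**Sparse vs. high-density fNIRS array comparison on synthetic data.**

Functional near-infrared spectroscopy (fNIRS) measures cortical
haemodynamics through light attenuation between scalp optodes. Most
commercial systems use a *sparse* grid of non-overlapping 30 mm
source-detector channels; *high-density* (HD) arrays add overlapping,
multidistance channels (8 / 19 / 33 mm) that enable tomographic image
reconstruction at the cost of hardware and setup time. `hdnirs`
implements, end to end and with known ground truth, the machinery needed
to compare the two designs statistically: probe geometry, a
diffusion-approximation forward model, a synthetic block-design
recording generator, the standard preprocessing chain, a Gaussian-basis
GLM with short-separation regression, spatially regularized brain+scalp
image reconstruction, and channel/vertex group statistics including a
cluster-based permutation test.

It is aimed at methods researchers who want a deterministic, desk-scale
test bed for array-design questions — which probe finds an activation,
how well it localizes it, and how analysis choices (regularization,
nuisance regression, cluster correction) shape the answer.

## The model in brief

**Forward model.** Channel sensitivities follow the Rytov form with the
semi-infinite-medium diffusion Green's function `G` (extrapolated
boundary):

```
A[ch, v] = G(r_s, r_v) G(r_v, r_d) / G(r_s, r_d) · dV / D ,
```

sampled on two congruent lateral grids: a superficial scalp surface
(3 mm deep, 10 mm compartment thickness) and a cortical sheet (15 mm
deep, 4 mm thick). Stacking the two wavelengths with the haemoglobin
extinction matrix `E` gives `ΔOD = A [ΔHbO; ΔHbR]` in natural-log
optical density.

**Inverse model.** Because shallow vertices dominate raw sensitivity,
`A` is rescaled column-wise (spatially variant regularization),

```
L_vv = sqrt( (AᵀA)_vv + α_sp · max diag(AᵀA) ),     Â = A L⁻¹ ,
```

and inverted with Tikhonov regularization in channel space,

```
x = L⁻¹ Âᵀ (Â Âᵀ + λ I)⁻¹ y ,     λ = α_meas · max diag(Â Âᵀ) ,
```

with `α_sp = α_meas = 0.001`. A "brain only" variant restricts `A` to
cortical columns and skips `L`.

**Analysis.** Raw intensity → channel pruning (mean < 0.001 or SNR < 5)
→ optical density → spline / Savitzky-Golay motion correction → 0.5 Hz
zero-phase low-pass → modified Beer-Lambert law → per-channel OLS GLM
(26 Gaussians of 1 s width per condition spanning −2…23 s, cubic drift,
best-correlated 8 mm short-separation regressor, motion-block and step
nuisances). The unit of statistics is the *block delta* (mean over
7–18 s post-onset minus −2–0 s baseline); per subject and hemisphere the
extreme-t channel (or the 25 extreme-t image vertices) enters a paired
two-tailed Student's t-test between arrays. Group channel maps are
family-wise corrected with a sign-flip cluster-mass permutation test
(adjacency radius 33 mm, α = 0.05).

## Worked example

```python
import numpy as np
from hdnirs import (build_sparse_layout, build_hd_layout, t_critical,
                    ExperimentConfig, run_experiment)

sparse = build_sparse_layout()
hd = build_hd_layout()
print("sparse:", len(sparse.sources), "sources,", len(sparse.detectors),
      "detectors,", sparse.class_counts())
print("hd:    ", len(hd.sources), "sources,", len(hd.detectors),
      "detectors,", hd.class_counts())
print("group t-critical (n=17):", round(t_critical(17), 2))

config = ExperimentConfig(n_subjects=5, seed=7, spacing=8.0, n_perm=200)
result = run_experiment(config)
img = result.paired.query("space == 'image' and chromophore == 'hbo'")
print(img[["condition", "side", "mean_hd", "mean_sparse",
           "frac_hd_ge_sparse", "p"]].round(3).to_string(index=False))
loc = result.localization.groupby("layout")["loc_error_mm"].mean().round(1)
print("mean peak-localization error (mm):", dict(loc))
```

prints

```
sparse: 17 sources, 24 detectors, {'NN30': 52, 'SS8': 8}
hd:     25 sources, 66 detectors, {'NN19': 108, 'NN33': 91, 'SS8': 8}
group t-critical (n=17): 2.12
  condition  side  mean_hd  mean_sparse  frac_hd_ge_sparse   p
  congruent  left    0.050        0.004                1.0 0.0
  congruent right    0.044        0.004                1.0 0.0
incongruent  left    0.088        0.007                1.0 0.0
incongruent right    0.073        0.006                1.0 0.0
mean peak-localization error (mm): {'hd': 4.7, 'sparse': 8.4}
```

The sparse grid carries the classic 52 long channels (60 with the eight
8 mm short-separation channels); the hexagonal HD array carries 108
19 mm and 91 33 mm channels. Across five simulated subjects who perform
the same block task under both caps, the HD array reconstructs a larger
HbO block delta in the dorsolateral regions of interest for every
subject, condition and hemisphere (paired p ≈ 10⁻³ or below, printed as
0.0 at three decimals), and localizes the injected activation roughly
twice as accurately as the sparse grid — the sparse array's
non-overlapping channels cannot separate cortical from superficial
signal during reconstruction, so its brain-surface images are weak and
poorly focused.

A command-line interface mirrors the library stages:

```sh
hdnirs simulate --layout hd --seed 1 --out rec.snirf
hdnirs preprocess --in rec.snirf --out conc.snirf
hdnirs reconstruct --in conc.snirf --layout hd --out image.csv
hdnirs run-all --n-subjects 17 --seed 0 --out results/
```

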