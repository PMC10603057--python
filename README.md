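# mechphen

Morpho-mechanical phenotyping of adherent cells on elastic substrates.

Fibroblasts sense and respond to the stiffness and ligand density of
their extracellular matrix. `mechphen` implements the computational
chain used to quantify that response in a 2 × 2 × 2 experimental
design — polyacrylamide substrates of 12 kPa (E_P) or 27 kPa (E_H),
collagen I coating at 25 (C_P) or 100 µg/ml (C_H), vimentin wildtype
(VimWT) or knockout (VimKO) cells — observed at 24 h and 48 h:

- **Traction force microscopy.** Bead displacements between a stressed
  frame and the cell-free reference image are estimated by windowed
  cross-correlation PIV with three-point Gaussian subpixel refinement,
  rigid drift correction, and normalized-median outlier filtering.
  Tractions are recovered by Fourier-transform traction cytometry
  (FTTC): on an elastic half-space, û(k) = Ĝ(k)·t̂(k) with the
  Boussinesq Green's tensor

  Ĝ(k) = 2(1+ν)/(E·k³) · [[(1−ν)k² + ν·k_y², −ν·k_x·k_y],
  [−ν·k_x·k_y, (1−ν)k² + ν·k_x²]],

  inverted per mode with optional Tikhonov regularization,
  t̂ = (ĜᵀĜ + λ²I)⁻¹Ĝᵀû. The per-cell summary is the median traction
  magnitude over the cell, averaged over timepoints.
- **Focal-adhesion and 3D morphometry.** Top-hat + Otsu + connected-
  component segmentation of paxillin-like stainings; FA size classes
  small (≤ 0.18 µm²), intermediate (≤ 0.36 µm²), large (> 0.36 µm²);
  cell/nucleus spread area from max-projections and height from the
  occupied z-extent of confocal stacks.
- **Phenotype matrices.** Per property and condition, the Z-score
  z = (x̄ − x̄_c)/σ_c against the control condition E_P-C_P-VimWT;
  cosine-similarity matrices **C** (conditions) and **P** (properties);
  average-linkage clustering on 1 − similarity with silhouette-selected
  k; block reordering of Z.
- **qPCR.** Pfaffl efficiency-corrected relative expression against a
  reference gene (Gapdh), normalized to the control group.
- **Synthetic data.** Seeded generators for every input: balanced
  ground-truth traction scenes and bead-image pairs, FA and 3D
  cell/nucleus images with exact ground truth, condition-structured
  property tables (VimWT responsive, VimKO flat at 24 h,
  stiffness-rescued at 48 h), and Ct tables that invert exactly under
  Pfaffl.

## Worked example

```python
from mechphen.pipeline import PipelineConfig, run_pipeline

report = run_pipeline(PipelineConfig(seed=1), "demo_out")
print(report["tfm"]["E_P"]["traction_pa"])   # 31.263553851887863
print(report["tfm"]["E_H"]["traction_pa"])   # 52.14667306726335
print(report["phenotype"]["24h"]["condition_clusters"])
```

The pipeline simulates one traction scene per stiffness level, renders
bead images, runs PIV + FTTC and reports the median-over-cell traction
in Pa (values above; the two scenes are independent random draws). The
24 h condition clustering splits the seven non-control conditions
exactly by genotype:

```text
{'E_H-C_H-VimKO-24h': 0, 'E_H-C_H-VimWT-24h': 1,
 'E_H-C_P-VimKO-24h': 0, 'E_H-C_P-VimWT-24h': 1,
 'E_P-C_H-VimKO-24h': 0, 'E_P-C_H-VimWT-24h': 1,
 'E_P-C_P-VimKO-24h': 0}
```

while at 48 h the knockout conditions on the stiff substrate join the
wildtype cluster (label 1), leaving only the soft-substrate knockouts
apart — the stiffness-rescue phenotype. The qPCR stage reports, e.g.,
vimentin at 0.0107 ± 0.0006 (mean ± SEM fold change) in VimKO relative
to VimWT.

The same stages are exposed as a CLI (`mechphen run-all`, `simulate`,
`piv`, `tfm`, `features`, `phenotype`, `qpcr`); see `mechphen --help`.

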