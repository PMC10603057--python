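# Methods

## Elasticity model (FTTC)

The substrate is treated as a homogeneous, isotropic, linear-elastic
half-space: thickness effects are ignored (valid when the gel is much
thicker than the displacement decay length) and tractions act on a flat
surface. In Fourier space the Boussinesq surface solution turns the
displacement–traction convolution into a per-mode 2×2 product
û(k) = Ĝ(k)·t̂(k), with Ĝ symmetric positive-definite for k ≠ 0.

Numerical choices:

- **Units.** Tractions in Pa, displacements in µm, wavevectors in
  rad/µm; Young's modulus E in Pa; Poisson ratio ν defaults to 0.5
  (polyacrylamide is nearly incompressible) and is configurable.
- **Zero mode.** The k = 0 component encodes net force and rigid
  translation, which carry no information about internal tractions; it
  is forced to zero in both directions. The forward model refuses
  unbalanced traction fields (net force above 1e-9 of the summed
  traction magnitude) rather than silently projecting them.
- **Nyquist shear coupling.** On even grids the off-diagonal Green's
  entry (odd in each wavevector component) has no Hermitian partner bin
  at the Nyquist frequency; it is zeroed there so that real fields map
  to real fields and the forward and inverse operators are exact
  inverses of each other.
- **Regularization.** Zeroth-order Tikhonov per mode,
  t̂ = (ĜᵀĜ + λ²I)⁻¹Ĝᵀû; λ = 0 by default (the synthetic demo is
  noiseless enough), a good starting point for noisy data is
  λ ≈ 1e-2 · max‖Ĝ‖. No automatic L-curve selection.
- **Padding.** `solve_fttc(pad_factor=...)` can zero-pad before the
  FFT to attenuate periodic wrap-around on fields cropped out of larger
  scenes. The default is no padding: with the periodic forward model
  used throughout, the unpadded inversion is its exact inverse
  (round-trip relative L2 error ~1e-14), whereas pad-and-crop is not an
  inverse of anything and would floor the round trip at the level of
  the wrap-around it suppresses. Padding is therefore an opt-in for
  real cropped data, not part of the self-consistent default.
- **Summary statistic.** Per timepoint, the median traction magnitude
  over the pixels inside the cell mask; the per-cell value is the mean
  of those medians over time, optionally divided by the spread area.

## PIV

Single-pass windowed cross-correlation: 32 px windows at 50% overlap by
default. Each reference window is matched against a search region of
the deformed image extended by a quarter window on every side
(normalized cross-correlation via template matching); the extended
search removes the loss-of-pairs bias that in-place window correlation
suffers at larger shifts. The correlation peak is refined per axis with
a three-point Gaussian (log-parabola) fit, falling back to a parabolic
fit where the log is undefined. Vectors are invalidated when a window
is (near-)flat or the peak sits on the search border; the
normalized-median test (threshold 2.0, noise floor ε = 0.02 µm)
replaces outliers by their valid-neighbor median. Windows are laid out
so the search region fits inside the image, so the vector grid starts
one margin in from the border.

Rigid drift against the cell-free reference is removed beforehand by
phase correlation (subpixel by Fourier upsampling); frames whose
post-alignment Pearson correlation with the reference falls below 0.2
are flagged unalignable and left untouched.

Limitations: no iterative window deformation, so accuracy degrades for
strains that rotate or shear the pattern within a window; displacements
above a quarter window are not searched.

## Image-derived features

FA segmentation: Gaussian denoising (σ = 0.7 px), white top-hat with a
10 px disk (removes structures larger than an FA), global Otsu
threshold, 8-connected labeling, minimum region size 3 px. The Otsu
threshold needs a visible foreground mode; at bead-level SNR below ~10
the region count inflates with noise specks, which is why the
generator-based recovery guarantees are stated at SNR ≥ 10. Size
classes use inclusive upper boundaries on the smaller class: ≤ 0.18 µm²
small, ≤ 0.36 µm² intermediate, > 0.36 µm² large.

Area is foreground pixel count × pixel area on the z-max-projection;
height is the occupied z-extent (first to last slice, inclusive) after
discarding slices below 1% of the peak slice occupancy, a guard against
isolated speckle voxels. The guard implies height is only robust for
objects whose footprint is ≳100 voxels per slice.

## Phenotype matrices and clustering

Z-scores standardize each condition mean by the control condition's
replicate-level mean and standard deviation (ddof = 1), so the control
row is identically zero; a zero control SD is an error, not a silent
NaN. The replicate-level SD (over experimental repeats, N) is the
default normalizer; aggregating cells first would shrink σ_c and
inflate scores.

Cosine similarity — not Pearson: vectors are not centered — is computed
between condition rows (matrix C) and property columns (matrix P). The
control row is excluded from C by default because its zero vector has
undefined direction; it can be included with a pseudocount by callers
that need it. Clustering is agglomerative with average linkage on
d = 1 − S; k is chosen by maximum mean silhouette over k ∈ {2,…,m−1},
smallest k winning ties. When tied merge heights make a two-way cut
unrealizable (all similarities equal), the two children of the
dendrogram root define a deterministic, seed-free split. Orderings are
dendrogram leaf orders stably sorted by cluster label, so clusters are
contiguous blocks; reordering Z is a pure permutation.

## qPCR (Pfaffl)

ratio = E_t^(Ct_t,control − Ct_t,sample) / E_r^(Ct_r,control − Ct_r,sample),
efficiencies in (1, 2] (fold amplification per cycle, default 2.0 when
a table does not state them). Control-group Ct values are aggregated by
arithmetic mean of cycles (not geometric mean of ratios); per-gene
ratios are then divided by the control group's mean ratio so the
control mean is exactly 1, and conditions are reported as mean ± SEM
over samples. Normalization pools the whole control group rather than
normalizing per batch.

## Synthetic data: what it emulates and what it does not

The generators exist so every stage can be exercised and validated
without measured data; they emulate structure, not optics.

- **Traction scenes.** Sums of Gaussian traction patches pointing
  toward the cell center inside an elliptical mask; the in-mask mean is
  subtracted per component, so the net force is exactly zero while the
  field stays zero outside the cell. Default 128×128 grid at 0.2 µm
  spacing, 8 patches, 300 Pa peak.
- **Bead images.** Gaussian spots (σ = 1.5 px) at uniform random
  positions, 0.5 beads/µm² (≈0.02 beads/px² at the default
  calibration), displaced by the bilinearly interpolated field;
  additive Gaussian noise. No photobleaching, drift, aberrations or
  depth effects.
- **FA images and stacks.** Non-overlapping bright ellipses with exact
  rasterized pixel-count ground truth (lognormal areas, mean 0.25 µm²,
  SD 0.15 µm²); 3D masks are extruded footprints built from exactly the
  pixel count matching the requested projected area, so measured area
  and height agree with the request to within one voxel. Real cells
  taper in z and real FAs touch; neither is modeled.
- **Property tables.** 15 properties, three per category (cellular
  morphology, nuclear morphology, cell mechanics, cell migration,
  cell–matrix interactions), with replicate CV 10% and N = 6 per
  condition. Condition means are the control baseline times effect
  multipliers chosen so shifts are 1–3 control SDs: wildtype cells
  respond to stiffness and density; knockouts sit at a flat
  genotype-shifted level at 24 h; at 48 h knockouts on the stiff
  substrate respond like wildtype (the rescue). The absolute scales are
  conventions — no numeric means are claimed, only this relational
  structure — so passing tests demonstrate that the analysis recovers
  planted structure, not that real cells behave this way.
- **Ct tables.** Built by inverting the Pfaffl relation, with the
  reference gene constant across conditions, so zero-noise generation
  followed by quantification is the identity to machine precision.

## Problem sizes

Default test and demo sizes: 128×128 TFM grids (64×64 in the pipeline
smoke test), 50 bead pairs for displacement-recovery statistics, 100
planted-partition instances for cluster recovery, 1,000 random Z draws
for the similarity contracts. The full suite runs in well under a
minute on one core; the acceptance script in a few seconds.

## Known limitations

- Single-pass PIV, infinite-thickness substrate, no 3D TFM.
- No L-curve or GCV selection of λ; the user must pick it for noisy
  data.
- FA analysis reports per-FA areas and per-image fractions; whether a
  study aggregates per cell before statistics is a choice the caller
  makes.
- Hypothesis tests between conditions (Mann–Whitney, Kruskal–Wallis,
  Dunn's) are deliberately out of scope; standard statistics packages
  handle them on the exported tables.
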