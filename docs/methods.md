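# Methods

This note records the models, conventions, numerical choices and known
limitations behind `spectramct`, in the order the pipeline runs.

## Spectral volumes and conventions

A spectral volume is a 4-D array `[x, y, z, bin]` of linear attenuation
coefficients (cm⁻¹) with an `EnergyBinning` (keV edges, optional open top
bin, per-bin usable flags), an isotropic voxel pitch in µm (default 90),
and a display orientation. The five-bin protocol — (7,20), (20,30),
(30,47), (47,73), >73 keV with bins 2–4 usable — is the built-in default;
the lowest bin is excluded for fluorescence-escape artifacts and the open
top bin for quantum noise.

Stored data stays in scanner order. The prone-animal display convention
(the animal's left on the image's right) is applied only in
`extract_slice`, by mirroring the x axis of axial and coronal images;
`insert_slice` inverts it exactly, so slicing partitions the volume.
Negative LAC values from noise are preserved everywhere except at the
final rendering clamp: statistics must see the undershoot.

Canonical storage is a single 4-D NIfTI-1 file plus a JSON sidecar
(`edges_keV`, `open_top`, `usable`, `voxel_size_um`, `orientation`); a
directory of per-bin 3-D NIfTI files is accepted as a reader dialect. Data
are written float64, so write→read round-trips are bit-exact.

## Phantom simulator

The simulator's purpose is to emulate the *structure* of contrast-enhanced
mouse scans — not detector physics. Its defaults are the package's study
conditions and all its randomness is fixed by one seed (per-mouse seeds in
a cohort are `seed + index`).

**Attenuation model.** μ(E) = pe·E⁻³·jump(E) + compton, with jump(E) a
constant factor > 1 at and above a material's K-edge. Bin values are means
of μ(E) over each bin, by trapezoidal integration on a fine grid split at
the K-edge; the open bin is integrated to a configurable cap (default
80 keV, the tube's kVp endpoint). Defaults (pe in cm⁻¹·keV³, compton in
cm⁻¹):

| material      | pe     | compton | K-edge | jump |
|---------------|--------|---------|--------|------|
| soft tissue   | 5200   | 0.18    | —      | —    |
| muscle        | 5200   | 0.18    | —      | —    |
| bone          | 30000  | 0.38    | —      | —    |
| iodine agent  | 20000  | 0.05    | 33 keV | 6    |
| barium agent  | 18000  | 0.04    | 37 keV | 6    |

Tissue/bone amplitudes are stylized fits to water (≈0.38/0.21 cm⁻¹ at
30/60 keV) and cortical bone; elemental K-edge jump ratios are ≈5–6. The
*muscle background is deliberately attenuation-matched to the tumors' base
tissue* so that CNR isolates the agent enhancement — with a denser muscle
background, tumor CNR would change sign channel by channel and stop being
an enhancement measure. Agent rows describe the pure agent; tumor voxels
mix a small volume fraction of it into tissue, so per-voxel material
fractions always sum to 1 (the linearity the tone-invariance tests rely
on).

**Scene.** A body ellipsoid of soft tissue inside an air background, a
bone cylinder (spine), a muscle cylinder providing the background ROI, and
one or two tumor ellipsoids, all scaled to the grid (default 48×48×32).
Two enhancement regimes:

* *diffuse* — agent mixed uniformly at fraction 0.015, giving CNR ≈
  0.5/1.6/0.7 in channels 1–3 at SNR 20, inside the plausible 0–2 range
  for whole-tumor enhancement;
* *punctate* — bright vessel dots: sphere radius 2 voxels, agent fraction
  0.25 inside a dot, dot count Poisson with density `dot_density` dots per
  tumor voxel, centers uniform over the tumor. The default cohort contrast
  is `dot_density` 0.009 (high-vascularity model, ≈25% tumor coverage)
  vs 0.0015 (low-vascularity, ≈5%), chosen so the expected per-channel
  std difference is well above twice its per-mouse sampling std — the
  regime in which a paired test at n = 6 should essentially always detect
  the difference.

**Noise.** Additive zero-mean Gaussian in the LAC domain, independent
across bins, σ_b = (noiseless muscle mean in bin b)/target SNR, so the
measured background SNR matches the target (default 20) in expectation.
Cross-bin noise correlation, projection-domain Poisson statistics,
detector spectral distortion and motion are all *not* modelled; passing
tests therefore validate the analysis code and its statistical behaviour
under the stated noise model, not fidelity to any particular scanner.

## Colorization

`rgb_basic` relabels (I₁,I₂,I₃) as (R,G,B). `rgb_transform` applies an
invertible 3×3 matrix C per pixel; identity C reproduces the basic version
bitwise. The two published weight presets are configuration data
(`session23`: rows [1.5,−1.5,0]/[0,2.5,−2.5]/[0,0,0.34]; `session1`:
[1,−1,0]/[0,2,−2]/[0,0,0.3]) since weights are protocol-specific.
Singularity is rejected at |det C| ≤ 1e-10.

Rendering is clamp-then-scale: negatives (possible for inter-channel
differences) are zeroed first, then a brightness constant is applied and
values clipped to [0,1]. The default brightness rule is automatic — the
99th percentile of positive values maps to 1 — because a fixed, recorded
rule is reproducible where an "adequate intensity" constant would not be;
the constant actually used is always stored in the image provenance and
the run manifest, applied per rendered image.

Tone is reported two ways by design: the unit vector of the *pre-clamp*
transformed pixel (the mathematical object whose uniqueness identifies
materials, exactly scale-invariant) and the HSV hue of the clamped vector
(what a viewer perceives). `tone_uniqueness_check` flags any material pair
whose transformed tones are closer than a threshold, default 3°: the
closest default pair (tissue vs bone) sits at ≈5.1° under `session23` and
≈6.4° under `session1`, so the diagnostic must sit below that while still
catching genuine collisions. The two presets agree to within 8° of tone on
every default signature (a frozen regression bound; measured 1.8–4.9°).

## ROI metrics

Per-channel statistics use only the usable channels and sample standard
deviations (ddof = 1) throughout — the conventional choice for ROI
statistics, recorded in output metadata. CNR keeps its sign. The
right-tailed rank-sum test uses mid-ranks; for min(n,m) ≤ 10 (and at most
5·10⁶ splits) the p-value is the exact permutation tail over all
C(n+m, n) rank splits, otherwise a normal approximation with tie
correction and a 0.5 continuity correction. Reports mark significance at
p < 0.01 by convention; the threshold is configurable.

## Mask refinement

Slicewise manual annotations are smoothed by convolving the binary
indicator with an anisotropic Gaussian — in-plane σ default 1 voxel,
through-plane σ default 2 voxels (through-plane ≥ in-plane realizes the
"directional" emphasis: adjacent slices vote on uncertain boundary
voxels) — and re-thresholding at 0.5, i.e. majority voting. The kernel is
unit-sum and truncated at 3σ, so output ⊆ input dilated by ⌈3σ⌉ per axis,
and a higher threshold always yields a subset mask. No morphological
operators are used. `boundary_roughness` (mean per-slice
perimeter-to-area) quantifies the smoothing in non-annotation views.
A LabelMe-style per-slice polygon JSON dialect is rasterized with standard
polygon filling.

## Discrimination statistics

Tumor features are the per-channel mean and sample std over the *full*
tumor mask; tumors touching the axial grid boundary are flagged as
partially covered, not excluded (quantitative volumes are out of scope for
truncated tumors).

The KS normality check standardizes the differences and compares to
N(0,1), with the asymptotic Kolmogorov p-value of √n·D — mirroring plain
one-sample usage. Because the null parameters are estimated this p-value
is conservative; the Lilliefors correction is available
(`lilliefors=True`) but off by default. Degenerate (constant) inputs are
rejected.

The paired t-test implements the textbook formulas directly, with the
Student-t tail via the regularized incomplete beta function
(`scipy.special.betainc`), which removes any dependence on a stats
backend's t distribution for the core formula; tests cross-check it
against an independent implementation to 1e-8.

Separability uses exact convex-hull disjointness per channel's
(mean, std) plane — decidable and faithful to a scatter-plot claim at
cohort sizes (n ≤ 12 points per side); the headline flag requires channels
1 and 2 jointly separable, and all three channels are reported.

## Statistical calibration of the defaults

Two properties are verified by simulation in the acceptance tests, both at
the generator's default grid (48×48×32), which the simulator is fast
enough to run directly (≈0.2 s per 6-mouse cohort):

* **Null calibration** — with identical tumor models on both sides, the
  paired mean- and std-difference tests each reject at a rate within
  α ± 3 binomial SE across 200 replicate n = 6 cohorts. (At strongly
  reduced grids the Poisson dot counts become small and skew the std
  differences, pushing the small-n t-test's true level toward ≈0.07; the
  default grid keeps the differences close to normal.)
* **Power** — under the default density contrast the std-difference test
  rejects in ≥90% of 100 cohorts (empirically ≈100%).

## Known limitations

* The attenuation model is parametric, not tabulated cross-section data;
  agent concentrations are plausibility choices, not calibrated values.
* Noise is Gaussian and bin-independent; real photon-counting
  reconstructions have correlated, object-dependent noise.
* The rank-sum normal branch underflows to p = 0 for the huge voxel
  samples of whole-ROI comparisons; this is a display convention, not an
  exact zero.
* The KS p-value without the Lilliefors option is conservative by
  construction.
* No projection data, reconstruction, material decomposition or DICOM
  support; volumes enter as reconstructed NIfTI.
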