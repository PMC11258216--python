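# spectramct

Analysis toolbox for **contrast-enhanced spectral photon-counting micro-CT**
of small animals: K-edge-aware RGB color visualization of multi-energy-bin
volumes, ROI contrast/noise metrics, annotation-mask refinement, and paired
first-order statistics for discriminating tumor models — together with a
digital spectral phantom simulator, so the whole chain runs and is tested
without any scan data.

It is written for preclinical imaging groups who reconstruct multi-bin
attenuation volumes (e.g. from a photon-counting micro-CT with five energy
thresholds) and want a fast, quantitative way to visualize and compare
contrast-agent uptake in tumor xenografts.

## The method

A photon-counting scan yields a linear attenuation coefficient (LAC, cm⁻¹)
volume per energy bin. With five bins — (7,20), (20,30), (30,47), (47,73)
and >73 keV — the middle three are the usable analysis channels
(I₁, I₂, I₃); the outer two are dropped for fluorescence-escape and quantum
noise. Each voxel is then a 3-vector **y** = (I₁, I₂, I₃).

**Color visualization.** Placing **y** in RGB space, its direction sets the
color *tone* and its length the brightness, so a concentration change of a
material rescales **y** without changing its tone: materials are identified
by tone. Because similar materials have similar spectra, an invertible 3×3
channel transform *C* magnifies spectral differences before display:

    I_R = 1.5 (I₁ − I₂),  I_G = 2.5 (I₂ − I₃),  I_B = 0.34 I₃

(the `session23` preset; an alternative `session1` preset uses weights
[1, 2, 0.3]). Invertibility of *C* keeps the tone coding unique. Rendering
clamps negatives, applies a recorded brightness constant, and clips to the
[0, 1] true-color window.

**ROI metrics.** With tumor and background-muscle masks:
CNR = (μ_tumor − μ_muscle)/σ_muscle and SNR = μ_muscle/σ_muscle per
channel, plus a right-tailed Wilcoxon rank-sum test of the tumor-vs-muscle
median difference (exact enumeration at small n, tie-corrected normal
approximation otherwise).

**Tumor discrimination.** Per tumor and channel, the mean LAC tracks
average agent uptake (perfusion) and the standard deviation tracks the
heterogeneity of its distribution (effective vascularity for a
non-diffusible nanoparticle agent). With both tumor models implanted in
each mouse, per-mouse paired differences Dᵢ = X_{A,i} − X_{B,i} are tested
with a one-sample Kolmogorov–Smirnov normality check and the paired t-test

    t = D̄ / (S_D /√n) ~ t_{n−1},   S_D = √( Σ(Dᵢ − D̄)² / (n−1) ),

two-sided, α = 0.05, with the Student-t tail computed through the
regularized incomplete beta function. Linear separability of the two
models in each channel's (mean, std) plane is decided exactly by
convex-hull disjointness.

**Phantom simulator.** Materials follow a stylized μ(E) = pe·E⁻³ + Compton
model with a multiplicative K-edge jump (iodine-like edge at 33 keV,
barium-like at 37 keV). Tumors are enhanced either *diffusely* (uniform
agent fraction) or *punctately* (Poisson-count bright vessel dots).
Additive Gaussian noise is calibrated so the background-muscle SNR hits a
target (default 20, inside the 18–25 range typical of such scans).

## Worked example

```bash
spectramct simulate --seed 7 --out demo/scan
spectramct colorize --volume demo/scan/volume.nii --sidecar demo/scan/volume.json \
    --plane axial --index 16 --preset session23 --out demo/png
spectramct roi-metrics --volume demo/scan/volume.nii --sidecar demo/scan/volume.json \
    --tumor-mask demo/scan/mask_tumor_left.nii \
    --muscle-mask demo/scan/mask_muscle.nii --out demo/metrics
```

`demo/metrics/roi_metrics.json` then contains (seed 7):

```json
"snr": {"channel_1": 19.59, "channel_2": 19.92, "channel_3": 19.35},
"cnr": {"channel_1": 0.443, "channel_2": 1.631, "channel_3": 0.667},
"ranksum_right_p": {"channel_1": 0.0, "channel_2": 0.0, "channel_3": 0.0}
```

The measured muscle SNR sits within 3% of the configured target 20. The
diffuse iodine-enhanced tumor shows the K-edge signature: CNR in channels 2
and 3 (energies at/above the 33 keV edge) clearly exceeds channel 1, and
the rank-sum p-values (≈0 at these ROI sizes) confirm the tumor's median
LAC exceeds muscle in every channel. The rendered PNG shows the tumor in
green tones against brownish tissue and yellow bone; the brightness
constant used (≈2.03 here) is recorded in `demo/png/manifest.json`.

A paired cohort runs end to end the same way:

```bash
spectramct simulate-cohort --seed 1 --out demo/cohort
spectramct discriminate --cohort-dir demo/cohort --out demo/report
```

`demo/report/report.json` holds the per-channel KS and paired-t results for
mean and std features and the separability flags.

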