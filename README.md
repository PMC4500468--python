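# canalqsm

Post-processing toolbox for visualizing **vascular cartilage canals** — the
sub-millimeter channels that carry blood vessels through the epiphyseal
(growth) cartilage of the developing skeleton — in high-resolution 3-D
gradient-recalled-echo (GRE) MRI.

Cartilage canals are mildly **paramagnetic** relative to the surrounding
cartilage (relative susceptibility on the order of +0.05 to +0.07 ppm, likely
from deoxygenated blood).  In standard susceptibility-weighted imaging (SWI)
the dipolar phase pattern of such an inclusion is multiplied directly into the
magnitude, which darkens the two phase lobes *straddling* the vessel along B₀
instead of the vessel itself: in any plane containing B₀ the vessel appears
artifactually **split** into two parallel dark lines.  Quantitative
susceptibility mapping (QSM) inverts the dipole field model, restoring the
source to its true location and eliminating the splitting; using the
susceptibility map as an enhancing mask on the magnitude (QSM-weighted
imaging, QSM-WI) combines artifact-free localization with SWI-like contrast.

The package implements the complete chain, plus a susceptibility-phantom
simulator so every claim is testable without scanner data:

| stage | module | method |
|---|---|---|
| phantom | `canalqsm.phantom` | cylinders/spheres of known Δχ, dipole forward model `Δ̂B(k) = D(k) χ̂(k)` with `D(k) = 1/3 − (k·b̂₀)²/K²`, wrapped-phase GRE synthesis with texture, background field and complex noise |
| segmentation | `canalqsm.segmentation` | 7×7×7 box smoothing, threshold at `x̄ − 4σ` of a coarse seed ROI, six-connected erosion |
| SWI | `canalqsm.swi` | homodyne high-pass phase filter (central ½ or ¼ of k-space per dimension), negative phase mask `m = (φ+π)/π` for `φ<0`, applied to the magnitude 4× |
| QSM | `canalqsm.qsm` | Laplacian phase unwrapping (DCT spectral Poisson solver), SHARP background-field removal (9³-voxel spherical-mean kernel, thresholded deconvolution), thresholded k-space division `χ̂ = Δ̂B · g`, `g = sign(1/D)·min(|1/D|, t)` |
| QSM-WI | `canalqsm.qsmwi` | enhancing mask: 1 below `mean − 2·SD` of the canal susceptibilities, linear ramp to 0, applied 4× |
| analysis | `canalqsm.analysis_viz` | canal-ROI growth, susceptibility-vs-truncation sweeps with histograms, thick-slab min/max intensity projections, splitting-profile counter |

The inverse dipole filter `1/(1/3 − k_z²/K²)` has minimum absolute value 3/2;
truncating there (t = 1.5) is the heaviest regularization the kernel admits
and is the default for visualization.  Relaxing t improves quantitative
accuracy at the cost of streaking; canal susceptibility estimates plateau for
t ≈ 10–20.

## Worked example

Run the full chain on the bundled three-canal phantom (96³ voxels at 100 µm,
9.4 T, TE 15 ms; one canal parallel to B₀, one perpendicular, one at 45°, each
Δχ = +0.06 ppm):

```bash
canalqsm run-all --seed 7 --out runs/demo
```

This writes the simulated magnitude/phase pair with ground truth, the
segmentation, the four comparison volumes (masked GRE, SWI, QSM, QSM-WI),
3 mm minimum-intensity projections of each in the axial/coronal/sagittal
planes (16-bit TIFF), the truncation-sweep CSV and a run manifest.  The
manifest from the command above contains

```json
"sweep_t_values":   [0.5,    1.5,    5.0,    10.0,   20.0],
"sweep_mean_chi_ppm": [0.0051, 0.0153, 0.0306, 0.0334, 0.0345]
```

— the mean canal-ROI susceptibility rises steeply with the truncation factor
and flattens above t ≈ 10 (the heavy t = 1.5 setting recovers only a fraction
of the simulated +0.06 ppm, the price paid for streak-free images), while
`sweep.csv` additionally records the growth of the background streaking SD
with t.  Opening `swi_coronal_mip.tiff` next to `qsm_coronal_mip.tiff` shows
the perpendicular canal doubled in the SWI projection and single in QSM.

Per-stage subcommands (`simulate`, `segment`, `swi`, `qsm`, `qsmwi`,
`project`, `sweep`) expose the same functionality on NIfTI volumes with a
YAML acquisition sidecar; run `canalqsm <cmd> --help` for the options.

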