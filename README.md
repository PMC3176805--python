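# restkit

A scriptable Python toolkit for resting-state fMRI (RS-fMRI) analysis:
the classical pipeline that takes preprocessed 4D BOLD data to
voxel-wise maps of spontaneous-activity measures and on to corrected
group-level inference — without a GUI, usable from Python or the shell.

It is aimed at neuroimaging researchers and methods developers who want
the standard resting-state measures as composable, testable library
functions operating on NIfTI-1 / ANALYZE 7.5 volumes.

## What it computes

**Time-course conditioning.** Voxel-wise least-squares linear
detrending (mean preserved); ideal rectangle-window bandpass filtering
in the DFT domain with zero-padding to the shortest 5-smooth FFT
length and remove/restore-trend ("retrend") semantics; nuisance
regression of head-motion, global, white-matter and CSF signals
(OLS residuals + voxel mean); spherical ROI construction in MNI mm and
mean time-course extraction.

**Seed-based functional connectivity.** For seed series *y* and voxel
series *x*, the Pearson correlation

r = Σ(xᵢ−x̄)(yᵢ−ȳ) / √(Σ(xᵢ−x̄)² Σ(yᵢ−ȳ)²),

optionally partial (both series residualized on covariates) and
Fisher z-transformed, z = atanh(r).

**Regional homogeneity (ReHo).** Kendall's coefficient of concordance
of a voxel with its 6/18/26 nearest neighbors (cluster size K = 7, 19,
27) over n time points:

W = (Σᵢ Rᵢ² − n R̄²) / ((1/12) K² (n³ − n)),  R̄ = K(n+1)/2,

where Rᵢ is the rank sum at time point i. W ∈ [0, 1].

**ALFF / fALFF.** ALFF is the mean amplitude (√ of power spectral
density) over a low-frequency band, typically 0.01–0.08 Hz; fALFF is
the ratio of in-band amplitude to the amplitude over the full
(0, Nyquist] range (0–0.25 Hz at TR = 2 s). Maps can be standardized
by their within-mask mean.

**Group statistics.** Voxel-wise one-sample, two-sample (pooled
variance) and paired t-tests, one-way ANOVA/ANCOVA, and across-subject
correlation, with per-subject text covariates and voxel-dependent
image covariates.

**Multiple-comparison correction.** Benjamini–Hochberg FDR (one- or
two-tailed) and Monte-Carlo cluster-extent simulation (the AlphaSim
approach): smooth Gaussian noise in the mask, voxel-wise thresholding,
connected-component labeling, and the corrected alpha per cluster-size
threshold. Cluster reports give voxel counts, volumes in mm³ and MNI
peak coordinates.

**Image calculator.** Elementwise expressions over images (`i1`, …) and
groups (`g1`, …): `g1-1`, `g1.*(i1>100)`, `(i1-mean(g1))./std(g1)`,
`corr(g1,g2,'temporal')`, ….

All test inputs are synthesized by `restkit.synthetic_fixtures` with
recorded ground truth; no external dataset is required.

## Worked example

```python
import numpy as np
from restkit import (FixtureSpec, TimeCourse, make_rs_volume,
                     reho_map, seed_fc_map, standardize_by_mask_mean,
                     critical_stat, kcc)

vol, truth = make_rs_volume(FixtureSpec.default(seed=17))
mask = truth["mask"]
network = truth["components"][0]["mask"]     # planted 0.04 Hz network

seed = TimeCourse(vol.data[network].mean(axis=0), tr=vol.tr)
rmap, _ = seed_fc_map(vol, seed, mask)
print(f"mean r in network:  {rmap.data[network].mean():.3f}")
print(f"mean r elsewhere:   {rmap.data[~network & mask.data].mean():.3f}")

reho = standardize_by_mask_mean(reho_map(vol, mask, neighbors=26), mask)
homog = truth["components"][1]["mask"]       # planted homogeneous region
print(f"standardized ReHo inside/outside: "
      f"{reho.data[homog].mean():.3f} / {reho.data[~homog & mask.data].mean():.3f}")

print(f"critical t (p=0.05 two-sided, df=19): {critical_stat(0.05, 19):.3f}")
print(f"Kendall W, 27 identical courses:      {kcc(np.tile(np.arange(100.), (27,1))):.1f}")
```

Output:

```
mean r in network:  0.886
mean r elsewhere:   0.001
standardized ReHo inside/outside: 5.779 / 0.924
critical t (p=0.05 two-sided, df=19): 2.093
Kendall W, 27 identical courses:      1.0
```

The planted network is recovered by seed correlation (r ≈ 0.9 inside
vs ≈ 0 outside), the coherent region shows elevated regional
homogeneity, t = 2.093 is the familiar two-sided 5% critical value at
19 degrees of freedom, and perfectly concordant time courses attain
Kendall's W = 1.

The same pipeline is available from the shell:

```sh
restkit fixtures --seed 7 -o data/
restkit detrend data/bold.nii work/det.nii
restkit filter work/det.nii work/filt.nii --low 0.01 --high 0.08 --tr 2
restkit reho work/filt.nii work/reho.nii --mask data/brainmask.nii --divide-by-mask-mean --tr 2
restkit alphasim --mask data/brainmask.nii --fwhm 6 --pthr 0.001 --iter 1000 --seed 42 -o work/alphasim.tsv
restkit report work/t.nii --thr 2.093 --min-voxels 13 -o work/clusters.tsv
```

## Scope

Spatial preprocessing (slice timing, realignment, normalization,
smoothing, reslicing) is expected to be done upstream by a dedicated
tool; DICOM handling, ICA, Granger causality and any display
functionality are out of scope. See `docs/methods.md` for the
modeling choices, defaults and limitations.
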