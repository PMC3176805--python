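# Methods

This note documents the models, numerical conventions and design
choices behind restkit, and what the synthetic-data tests do and do
not demonstrate about real data.

## Data model

A 4D dataset is a real array X×Y×Z×T with a 4×4 affine mapping 0-based
voxel indices to mm coordinates (`affine @ [i,j,k,1]`) and a
repetition time TR in seconds. Reported peak coordinates use this
convention throughout. ANALYZE 7.5 files carry no orientation; when a
file supplies none, an RAS-positive diagonal affine is built from the
voxel sizes. TR precedence is: explicit user value > header time
step; a header time step of zero requires an explicit TR.

Masks are binarized at "strictly greater than threshold", default
threshold 0 (any nonzero voxel is in), with an optional threshold
argument for probabilistic maps. Mask grids must match the reference
grid exactly; resampling is deliberately out of scope and a mismatch
is an error, never a silent crop.

Memory is bounded by a block-iteration contract: the grid is cut into
z-slabs of at most `max_voxels_per_block` spatial voxels whose cores
partition the grid. For neighborhood operations, slabs carry a halo of
`overlap` slices; stitching the cores reproduces the whole-volume
result bit for bit (this identity is tested, for ReHo with overlap 1).

## Detrending and the ideal bandpass filter

Detrending fits a least-squares line per voxel series, subtracts it
and adds the original mean back, so the output has zero fitted slope
and an unchanged mean; the operation is idempotent.

The bandpass filter is an ideal rectangle window in the DFT domain:

1. remove the least-squares line (including the mean);
2. zero-pad to the shortest 5-smooth length N ≥ T (smallest integer
   with prime factors in {2,3,5} — the "shortest FFT length"
   zero-padding convention of AFNI's spectral tools, which avoids FFT
   length variability across environments);
3. zero every bin with frequency outside the closed interval
   [low, high]; the DC bin is always zeroed;
4. inverse transform, truncate to T, and add the fitted line back
   ("retrend").

`low = 0` yields a pure low-pass; `high` above the Nyquist frequency
1/(2·TR) yields a pure high-pass. A band containing no nonzero
frequency bin is an error that names the achievable resolution
1/(N_pad·TR).

Two consequences of retrending are worth knowing. First, the full
fitted line is restored, not just the mean: slow drift the user chose
to keep survives filtering. Second, a raw sinusoid sampled over a
finite window carries an incidental nonzero least-squares trend; the
filter removes and restores that trend while band-limiting only the
residual, so exact passband identity holds for signals whose fitted
line is zero. The tests therefore exercise the passband/stopband
contracts with exact-bin sinusoids whose phase is solved analytically
to null the fitted line, and the general case against an independent
DFT-masking oracle.

## Nuisance regression

Per in-mask voxel, the series is replaced by its OLS residual on
[intercept | covariates] plus the original voxel mean. Residuals are
orthogonal to every covariate column; an empty covariate set returns
the input. Rank-deficient designs are rejected with the collinear
columns named. Covariate text files are whitespace- or
comma-delimited, one row per time point, with an optional header line
auto-detected by a non-numeric first row.

Partial correlations are computed as the Pearson correlation of the
two residual series — equivalent to the recursive partial-correlation
formula, which the tests use as the independent oracle. Residuals
whose standard deviation falls at rounding-noise level (≤ 1e-10 of the
input scale) are treated as zero variance and the correlation is
reported undefined rather than returning noise.

## Seed-based functional connectivity

The seed series is the mean over an ROI (sphere in mm, voxel-center
membership, or an explicit mask). Per in-mask voxel the Pearson (or
partial) r is computed; out-of-mask voxels are 0 in the map. Fisher
z = atanh(r) is emitted on request with |r| clipped at 1−1e-7;
clipped and zero-variance voxels are tallied in a QC record. Written
maps never contain NaN.

## ReHo (Kendall's W)

Each course in a cluster is ranked over its n time points (average
ranks on ties — no tie-correction term appears in the denominator;
BOLD values are continuous so ties are measure-zero, and a constant
course simply lowers W through its flat ranks). With rank sums R_i per
time point,

W = (Σ R_i² − n R̄²) / ((1/12) K² (n³ − n)), R̄ = K(n+1)/2.

At mask and grid edges, absent neighbors are dropped and K shrinks
accordingly (minimum 2; voxels below that get 0 and a QC count).
The implementation is vectorized over shifted rank arrays and is
verified exactly against a brute-force rank-sum enumeration in
rational arithmetic (both paths are exact in double precision for the
instance sizes involved, so the comparison is ==, not approximate).

## ALFF / fALFF / power spectrum

With the same 5-smooth zero-padding, amplitude per bin is
√(|DFT|²/N_pad). ALFF is the mean amplitude over bins with
low ≤ f ≤ high, f > 0 — the DC bin is excluded even when the band
starts at 0 Hz, since the mean is not a fluctuation. The absolute
ALFF scale is declared arbitrary up to a constant (it depends on the
FFT normalization); only mask-mean-standardized maps and ratios are
stable contracts, which is why the group pipeline standardizes first.
Averaging amplitudes over bins (rather than summing and dividing by
bandwidth in Hz) was chosen; the two differ by a constant for a fixed
band and padding, so standardized maps are unaffected — but absolute
values should not be compared across implementations.

fALFF is Σ in-band amplitude / Σ amplitude over (0, Nyquist], in
[0, 1]; constant series get 0 with a QC count. fALFF must be computed
on unfiltered data (the ratio is meaningless after bandpass); this is
a caller contract, not something the function can verify.

The power-spectrum utility returns a one-sided periodogram on the
padded length, normalized so that Σ power = Σ (x − x̄)² (Parseval),
with optional line removal first.

## Group statistics

All tests are mass-univariate OLS on the voxel values across subjects.
The two-sample t uses the pooled-variance (equal-variance) formula —
the classical GLM convention — rather than Welch. ANOVA/ANCOVA is a
model comparison: group dummies + covariates vs intercept +
covariates, F with (G−1, N−rank) degrees of freedom; with two groups
and no covariates F = t² exactly. The paired t is the one-sample t of
per-subject differences (fixed A−B convention). Across-subject
correlation with a behavioral regressor supports partial correlation
with q covariates, df = n−2−q.

Image covariates ("voxel-dependent" regressors such as gray-matter
density) enter the design per voxel after per-voxel mean-centering,
keeping the group contrast interpretable; per-voxel rank deficiency
yields statistic 0 and a QC tally. Zero-variance voxels likewise give
0 (or, for a nonzero effect with zero residual variance, a documented
cap of 1e6 instead of infinity); variance at rounding-noise level
(≤ 1e-12 of the data scale) counts as zero. Maps store the signed
statistic; sidedness is applied only at thresholding.

## Multiple-comparison correction

FDR uses the Benjamini–Hochberg step-up rule over in-mask voxels:
largest k with p_(k) ≤ k·q/m; survivors are voxels with p ≤ p_(k).
A signed statistic map may be supplied directly and is converted to
one- or two-tailed p first.

The Monte-Carlo cluster simulation generates, per iteration, unit
Gaussian noise on the grid, smooths it with a Gaussian kernel of the
user-supplied FWHM (smoothness is an input, not estimated from
residuals), re-standardizes within the mask, and thresholds at the
empirical within-mask quantile so that exactly round(p·m) voxels
survive — making the per-voxel rate exact by construction and removing
smoothing-induced variance distortion. Connected components
(default 26-connectivity, matching the K=27 neighborhood convention;
6/18 selectable) are labeled and the maximum cluster size recorded;
the corrected alpha for size s is the fraction of iterations whose
maximum cluster is ≥ s, non-increasing in s by construction. The RNG
is a named, seeded generator and the seed is recorded in the output
header. Bit-compatibility with other AlphaSim implementations is not a
goal (their noise and edge conventions vary); the statistical
properties are what is verified.

Cluster reports list voxel count, volume (count × |det| of the spatial
affine), and the peak (member with maximum |intensity|) in MNI mm.

## Synthetic fixtures

The generator emulates a typical resting-state acquisition: TR = 2 s,
T = 120 volumes, 16×16×16 grid of 3 mm voxels (spectral resolution
≈ 0.004 Hz, so 0.01–0.08 Hz phenomena are resolvable), baseline 100,
unit Gaussian noise, per-voxel linear drifts with slopes in
±0.02/volume, and slow nuisance series (global, white-matter-like,
CSF-like, six motion-like). The default fixture plants a coherent
0.04 Hz "network" (shared phase, amplitude 3 — SNR 3 against unit
noise, comfortably detectable at desk scale) and a second coherent
0.02 Hz region serving as a locally homogeneous (high-ReHo) target.
Phases are randomized across regions so cross-region correlation is
≈ 0 by construction. Group-map fixtures are baseline + effect·region
indicator + N(0, σ²), with a regressor-scaled variant for correlation
designs.

What passing these tests shows: the estimators recover known planted
structure at realistic SNR, and their null calibration is correct
under the stated noise model. What it does not show: robustness to
hemodynamic variability, physiological (cardiac/respiratory) aliasing,
head motion beyond slow confound series, spatial autocorrelation of
real BOLD noise, or registration error. Problem sizes in the tests
(16³–20³ grids, 100–1000 Monte-Carlo iterations, 200-subject
calculator groups) were chosen as the smallest sizes at which the
statistical contracts are sharp.

## Known limitations

- No spatial resampling: inputs must share a grid.
- Equal-variance two-sample t only; no mixed-effects or
  repeated-measures models, no permutation inference, no TFCE or
  Gaussian-random-field thresholds.
- AlphaSim smoothness is user-supplied, not estimated.
- The calculator implements a fixed small grammar, not a general
  expression language; group pairing is by sorted filename order.
- fALFF's no-prefilter contract is the caller's responsibility.
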