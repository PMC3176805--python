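"""The three core resting-state maps: seed-based FC, ReHo, ALFF/fALFF.

Seed-based functional connectivity is the Pearson (or, with nuisance
covariates, partial) correlation between a reference time course and
every in-mask voxel series, optionally Fisher z-transformed.

Regional homogeneity (ReHo) is Kendall's coefficient of concordance W
of a voxel's time course with its 6, 18 or 26 nearest neighbors
(cluster sizes K = 7, 19, 27):

    W = (sum_i R_i^2 - n * Rbar^2) / ((1/12) K^2 (n^3 - n))

where R_i is the rank sum at time point i across the K courses (each
course ranked over its n time points) and Rbar = K(n+1)/2.

ALFF is the mean amplitude (square root of power-spectral density) over
a low-frequency band, typically 0.01-0.08 Hz; fALFF is the ratio of the
in-band amplitude sum to the amplitude sum over the full (0, Nyquist]
range.  Both use the same shortest-5-smooth-length zero-padded DFT as
the ideal filter.  Absolute ALFF scale is arbitrary up to a constant;
only mask-mean-standardized maps and ratios are stable contracts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .nifti_io import Mask, Volume3D, Volume4D
from .preprocess import CovariateSet, FrequencyBand, TimeCourse, _design_matrix, _fit_line, pad_length

__all__ = [
    "MetricMap",
    "pearson_r",
    "partial_r",
    "seed_fc_map",
    "roi_wise_fc",
    "kcc",
    "reho_map",
    "alff_map",
    "falff_map",
    "standardize_by_mask_mean",
    "power_spectrum",
    "fisher_z",
    "NEIGHBOR_OFFSETS",
]

R_CLIP = 1.0 - 1e-7  # |r| clip before atanh


@dataclass
class MetricMap:
    """A 3D metric map plus provenance (metric tag and parameters).

    ``qc`` counts degenerate voxels handled by policy (zero variance,
    clipped |r|, ...), so written volumes never contain NaN.
    """

    volume: Volume3D
    metric: str  # {fc_r, fc_z, reho, alff, falff}
    params: Dict = field(default_factory=dict)
    qc: Dict[str, int] = field(default_factory=dict)

    @property
    def data(self) -> np.ndarray:
        return self.volume.data

    @property
    def affine(self) -> np.ndarray:
        return self.volume.affine


# ---------------------------------------------------------------------------
# correlations


def pearson_r(x: TimeCourse, y: TimeCourse) -> float:
    """Pearson correlation coefficient of two equal-length time courses."""
    xv, yv = np.asarray(x.values), np.asarray(y.values)
    if xv.size != yv.size:
        raise ValueError("time courses must have equal length")
    if xv.size < 3:
        raise ValueError("need at least 3 samples")
    xc, yc = xv - xv.mean(), yv - yv.mean()
    sx, sy = np.sqrt((xc**2).sum()), np.sqrt((yc**2).sum())
    if sx == 0 or sy == 0:
        raise ValueError("zero-variance input: correlation undefined")
    return float(np.clip((xc * yc).sum() / (sx * sy), -1.0, 1.0))


def _residualize(values: np.ndarray, covs: CovariateSet) -> np.ndarray:
    design = _design_matrix(covs)
    beta, *_ = np.linalg.lstsq(design, values, rcond=None)
    return values - design @ beta


def partial_r(x: TimeCourse, y: TimeCourse, covs: CovariateSet) -> float:
    """Partial correlation: Pearson r of the two covariate-residual series."""
    if covs.n_covariates == 0:
        return pearson_r(x, y)
    if len(covs) != len(x):
        raise ValueError("covariate rows must match time-course length")
    xv = np.asarray(x.values, dtype=float)
    yv = np.asarray(y.values, dtype=float)
    rx = _residualize(xv, covs)
    ry = _residualize(yv, covs)
    # residuals at numerical-noise level mean the covariates explain the
    # series exactly: the partial correlation is undefined
    if rx.std() <= 1e-10 * max(xv.std(), 1e-300) or ry.std() <= 1e-10 * max(yv.std(), 1e-300):
        raise ValueError("zero-variance residual: partial correlation undefined")
    return float(np.clip(np.corrcoef(rx, ry)[0, 1], -1.0, 1.0))


def fisher_z(r: np.ndarray) -> np.ndarray:
    """Variance-stabilizing atanh transform, with |r| clipped below 1."""
    return np.arctanh(np.clip(r, -R_CLIP, R_CLIP))


def _corr_with_seed(flat: np.ndarray, seed: np.ndarray) -> Tuple[np.ndarray, int]:
    """Pearson r of each row of ``flat`` with ``seed``; zero-variance rows -> 0."""
    sc = seed - seed.mean()
    ss = np.sqrt((sc**2).sum())
    if ss == 0:
        raise ValueError("seed time course has zero variance")
    fc = flat - flat.mean(axis=1, keepdims=True)
    sf = np.sqrt((fc**2).sum(axis=1))
    degenerate = sf == 0
    sf_safe = np.where(degenerate, 1.0, sf)
    r = (fc @ sc) / (sf_safe * ss)
    r[degenerate] = 0.0
    return np.clip(r, -1.0, 1.0), int(degenerate.sum())


def seed_fc_map(
    vol: Volume4D,
    seed: TimeCourse,
    mask: Mask,
    covs: Optional[CovariateSet] = None,
    fisher: bool = False,
) -> Tuple[MetricMap, Optional[MetricMap]]:
    """Seed-based functional-connectivity map (r, and z if requested).

    Per in-mask voxel: Pearson r between the seed and the voxel series,
    or partial r when covariates are given (both series are residualized
    on [intercept | covariates] first).  Out-of-mask voxels are 0;
    constant voxel series get r = 0 and are tallied in ``qc``.
    """
    if len(seed) != vol.n_timepoints:
        raise ValueError("seed length must equal the number of time points")
    flat = np.asarray(vol.data, dtype=float)[mask.data]
    seed_v = np.asarray(seed.values, dtype=float)
    if covs is not None and covs.n_covariates > 0:
        if len(covs) != vol.n_timepoints:
            raise ValueError("covariate rows must match time points")
        design = _design_matrix(covs)
        beta_s, *_ = np.linalg.lstsq(design, seed_v, rcond=None)
        seed_v = seed_v - design @ beta_s
        beta_f, *_ = np.linalg.lstsq(design, flat.T, rcond=None)
        flat = (flat.T - design @ beta_f).T
    r, n_degenerate = _corr_with_seed(flat, seed_v)
    rmap = np.zeros(vol.spatial_shape)
    rmap[mask.data] = r
    params = {"fisher": fisher, "n_covariates": 0 if covs is None else covs.n_covariates}
    qc = {"zero_variance_voxels": n_degenerate}
    r_metric = MetricMap(vol.spatial_volume3d(rmap), "fc_r", params, qc)
    if not fisher:
        return r_metric, None
    n_clipped = int((np.abs(r) >= R_CLIP).sum())
    zmap = np.zeros(vol.spatial_shape)
    zmap[mask.data] = fisher_z(r)
    z_metric = MetricMap(vol.spatial_volume3d(zmap), "fc_z", params,
                         {**qc, "clipped_r_voxels": n_clipped})
    return r_metric, z_metric


def roi_wise_fc(tcs: Sequence[TimeCourse], covs: Optional[CovariateSet] = None) -> np.ndarray:
    """Pairwise (partial) correlation matrix between ROI time courses."""
    if len(tcs) < 2:
        raise ValueError("need at least 2 ROI time courses")
    n = len(tcs[0])
    if any(len(tc) != n for tc in tcs):
        raise ValueError("all ROI time courses must have equal length")
    k = len(tcs)
    out = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            r = (partial_r(tcs[i], tcs[j], covs) if covs is not None
                 else pearson_r(tcs[i], tcs[j]))
            out[i, j] = out[j, i] = r
    return out


# ---------------------------------------------------------------------------
# Kendall's W / ReHo


def kcc(cluster: np.ndarray) -> float:
    """Kendall's coefficient of concordance W for K time courses x n points.

    Each course is ranked over time (average ranks on ties, no tie
    correction in the denominator); W in [0, 1] with 1 at perfect
    concordance.
    """
    cluster = np.atleast_2d(np.asarray(cluster, dtype=float))
    k, n = cluster.shape
    if k < 2 or n < 2:
        raise ValueError("need K >= 2 time courses and n >= 2 time points")
    ranks = sps.rankdata(cluster, axis=1)
    r_i = ranks.sum(axis=0)  # rank sum per time point
    rbar = k * (n + 1) / 2.0
    num = (r_i**2).sum() - n * rbar**2
    den = (k**2) * (n**3 - n) / 12.0
    return float(num / den)


# offsets by stencil: 6 = faces, 18 = faces+edges, 26 = faces+edges+corners
def _stencil(n_neighbors: int) -> np.ndarray:
    offs = [(i, j, k)
            for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
            if (i, j, k) != (0, 0, 0)]
    order = {6: 1, 18: 2, 26: 3}
    if n_neighbors not in order:
        raise ValueError("neighbors must be 6, 18 or 26")
    return np.array([o for o in offs
                     if abs(o[0]) + abs(o[1]) + abs(o[2]) <= order[n_neighbors]])


NEIGHBOR_OFFSETS = {n: _stencil(n) for n in (6, 18, 26)}


def reho_map(vol: Volume4D, mask: Mask, neighbors: int = 26) -> MetricMap:
    """Regional homogeneity: Kendall's W over each voxel's neighborhood.

    Per in-mask voxel the cluster is the voxel plus its in-mask, in-grid
    neighbors of the chosen stencil (K = 7, 19 or 27 when all are
    present; K shrinks at mask and grid edges, minimum 2).  Voxels whose
    cluster has fewer than 2 usable courses get 0.
    """
    offsets = NEIGHBOR_OFFSETS[neighbors] if neighbors in NEIGHBOR_OFFSETS else _stencil(neighbors)
    n = vol.n_timepoints
    if n < 4:
        raise ValueError("ReHo needs at least 4 time points")
    data = np.asarray(vol.data, dtype=float)
    ranks = sps.rankdata(data, axis=-1)
    m = mask.data
    # accumulate rank sums and member counts over shifted copies
    r_sum = np.where(m[..., None], ranks, 0.0).copy()
    k_eff = m.astype(np.int64).copy()
    shape = m.shape
    for di, dj, dk in offsets:
        src = tuple(slice(max(0, -d), min(s, s - d)) for d, s in zip((di, dj, dk), shape))
        dst = tuple(slice(max(0, d), min(s, s + d)) for d, s in zip((di, dj, dk), shape))
        valid = m[src]
        r_sum[dst] += np.where(valid[..., None], ranks[src], 0.0)
        k_eff[dst] += valid
    k = k_eff.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        rbar = k * (n + 1) / 2.0
        num = (r_sum**2).sum(axis=-1) - n * rbar**2
        den = (k**2) * (n**3 - n) / 12.0
        w = np.where(den > 0, num / den, 0.0)
    usable = m & (k_eff >= 2)
    out = np.where(usable, np.clip(w, 0.0, 1.0), 0.0)
    qc = {"undersized_clusters": int((m & ~usable).sum())}
    return MetricMap(vol.spatial_volume3d(out), "reho",
                     {"neighbors": neighbors, "K": neighbors + 1}, qc)


# ---------------------------------------------------------------------------
# ALFF / fALFF / power spectrum


def _amplitude_spectrum(data: np.ndarray, tr: float) -> Tuple[np.ndarray, np.ndarray]:
    """One-sided amplitude spectrum sqrt(|DFT|^2 / N_pad) along last axis."""
    n = data.shape[-1]
    n_pad = pad_length(n)
    spec = np.fft.rfft(data, n=n_pad, axis=-1)
    amp = np.abs(spec) / np.sqrt(n_pad)
    freqs = np.fft.rfftfreq(n_pad, d=tr)
    return freqs, amp


def alff_map(vol: Volume4D, band: FrequencyBand, mask: Mask) -> MetricMap:
    """Amplitude of low-frequency fluctuation map.

    Per in-mask voxel: mean over in-band DFT bins of the square root of
    power (|DFT|^2 / N_pad).  The DC bin is excluded even when the band
    starts at 0 Hz, so a constant series has ALFF 0.
    """
    if band.high > vol.nyquist + 1e-12:
        raise ValueError(
            f"band.high={band.high} Hz exceeds Nyquist {vol.nyquist:g} Hz for tr={vol.tr}"
        )
    data = np.asarray(vol.data, dtype=float)[mask.data]
    freqs, amp = _amplitude_spectrum(data, vol.tr)
    in_band = (freqs >= band.low) & (freqs <= band.high) & (freqs > 0)
    if not in_band.any():
        n_pad = pad_length(vol.n_timepoints)
        raise ValueError(
            f"no DFT bin in [{band.low}, {band.high}] Hz at resolution "
            f"{1.0 / (n_pad * vol.tr):g} Hz"
        )
    vals = amp[:, in_band].mean(axis=1)
    out = np.zeros(vol.spatial_shape)
    out[mask.data] = vals
    return MetricMap(vol.spatial_volume3d(out), "alff",
                     {"band": (band.low, band.high)}, {})


def falff_map(vol: Volume4D, band: FrequencyBand, mask: Mask) -> MetricMap:
    """Fractional ALFF: in-band amplitude sum over full-range amplitude sum.

    The denominator covers (0, Nyquist]; DC is excluded from both.  The
    input must NOT have been bandpass filtered (the ratio is then
    meaningless), which is the caller's contract.  Values lie in [0, 1];
    constant series get 0 and a QC count.
    """
    data = np.asarray(vol.data, dtype=float)[mask.data]
    freqs, amp = _amplitude_spectrum(data, vol.tr)
    nonzero = freqs > 0
    in_band = nonzero & (freqs >= band.low) & (freqs <= band.high)
    if not in_band.any():
        raise ValueError(f"no DFT bin in [{band.low}, {band.high}] Hz")
    num = amp[:, in_band].sum(axis=1)
    den = amp[:, nonzero].sum(axis=1)
    degenerate = den == 0
    vals = np.where(degenerate, 0.0, num / np.where(degenerate, 1.0, den))
    out = np.zeros(vol.spatial_shape)
    out[mask.data] = np.clip(vals, 0.0, 1.0)
    return MetricMap(vol.spatial_volume3d(out), "falff",
                     {"band": (band.low, band.high)},
                     {"zero_amplitude_voxels": int(degenerate.sum())})


def standardize_by_mask_mean(metric: MetricMap, mask: Mask) -> MetricMap:
    """Divide each in-mask voxel by the in-mask mean (result: mean 1).

    This is the within-subject standardization conventionally applied to
    ReHo and ALFF maps before group statistics.
    """
    vals = metric.data[mask.data]
    mean = vals.mean()
    if mean == 0:
        raise ValueError("mask-mean is zero; cannot standardize")
    out = np.where(mask.data, metric.data / mean, metric.data)
    return MetricMap(
        Volume3D(out, metric.affine.copy()),
        metric.metric,
        {**metric.params, "standardized": True, "mask_mean": float(mean)},
        dict(metric.qc),
    )


def power_spectrum(tc: TimeCourse, detrend_first: bool = False) -> Tuple[np.ndarray, np.ndarray]:
    """One-sided periodogram of a time course on the padded length.

    The mean (and, with ``detrend_first``, the least-squares line) is
    removed before the transform; power is normalized so that the sum
    over bins equals the sum of squared deviations from the mean
    (Parseval).  Returns (frequencies in Hz from 0 to Nyquist, power).
    """
    if len(tc) < 4:
        raise ValueError("need at least 4 samples")
    x = np.asarray(tc.values, dtype=float)
    if detrend_first:
        fitted, _ = _fit_line(x)
        x = x - fitted
    else:
        x = x - x.mean()
    n = x.size
    n_pad = pad_length(n)
    spec = np.fft.rfft(x, n=n_pad)
    power = np.abs(spec) ** 2 / n_pad
    # fold the negative frequencies in (double all but DC and, for even
    # n_pad, the Nyquist bin) so Parseval holds one-sided
    power[1:] *= 2.0
    if n_pad % 2 == 0:
        power[-1] /= 2.0
    freqs = np.fft.rfftfreq(n_pad, d=tc.tr)
    return freqs, power
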