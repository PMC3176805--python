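"""Time-course conditioning for resting-state BOLD data.

Implements the standard preprocessing chain applied before computing
resting-state metrics: least-squares linear detrending, ideal
(rectangle-window) frequency-domain bandpass filtering, nuisance
covariate regression (head motion, global, white-matter and CSF
signals), spherical ROI construction and mean time-course extraction.

The ideal filter works in the discrete Fourier domain: the series is
zero-padded to the shortest 5-smooth length (smallest ``N >= T`` whose
prime factors are all in {2, 3, 5}), transformed, bins outside the band
are zeroed, and the result transformed back.  The least-squares linear
trend is removed before the transform and added back afterwards
("retrend"), so the mean and any slow drift the user chose to keep are
preserved exactly.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .nifti_io import Mask, Volume4D

__all__ = [
    "TimeCourse",
    "FrequencyBand",
    "CovariateSet",
    "SphereROI",
    "detrend",
    "ideal_bandpass",
    "regress_covariates",
    "make_sphere_roi",
    "extract_roi_timecourse",
    "read_covariates",
    "pad_length",
]


@dataclass
class TimeCourse:
    """A single BOLD time course sampled every ``tr`` seconds."""

    values: np.ndarray
    tr: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size < 2:
            raise ValueError("TimeCourse needs at least 2 samples")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("TimeCourse values must be finite")
        if not self.tr > 0:
            raise ValueError("tr must be positive")
        self.tr = float(self.tr)

    def __len__(self) -> int:
        return self.values.size

    @property
    def nyquist(self) -> float:
        return 1.0 / (2.0 * self.tr)


@dataclass
class FrequencyBand:
    """A [low, high] frequency band in Hz.

    ``low = 0`` means low-pass; ``high`` above the Nyquist frequency of
    the series being filtered means high-pass.  The common resting-state
    band is 0.01-0.08 Hz.
    """

    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0 <= self.low < self.high):
            raise ValueError(f"need 0 <= low < high, got [{self.low}, {self.high}]")


@dataclass
class CovariateSet:
    """Temporal nuisance covariates: a T x p matrix with column names.

    Typical columns: six rigid-body motion parameters, the global (whole
    brain) mean signal, white-matter and CSF mean signals.
    """

    matrix: np.ndarray
    names: Sequence[str] = ()

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        if self.matrix.ndim != 2:
            raise ValueError("covariate matrix must be 2D (T x p)")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("covariates must be finite")
        if not self.names:
            self.names = [f"cov{j}" for j in range(self.matrix.shape[1])]
        if len(self.names) != self.matrix.shape[1]:
            raise ValueError("one name per covariate column required")
        if self.matrix.shape[1] > 0:
            zero = np.all(self.matrix == 0, axis=0)
            if zero.any():
                bad = [self.names[j] for j in np.flatnonzero(zero)]
                raise ValueError(f"all-zero covariate column(s): {bad}")

    @classmethod
    def empty(cls, n_timepoints: int) -> "CovariateSet":
        return cls(matrix=np.empty((n_timepoints, 0)), names=[])

    @property
    def n_covariates(self) -> int:
        return self.matrix.shape[1]

    def __len__(self) -> int:
        return self.matrix.shape[0]


@dataclass
class SphereROI:
    """A spherical ROI given by its MNI-mm center and radius in mm."""

    center: Tuple[float, float, float]
    radius: float

    def __post_init__(self) -> None:
        self.center = tuple(float(c) for c in self.center)  # type: ignore[assignment]
        if len(self.center) != 3:
            raise ValueError("center must be an (x, y, z) mm triple")
        if not self.radius > 0:
            raise ValueError("radius must be > 0 mm")


# ---------------------------------------------------------------------------
# detrend


def _fit_line(values: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Least-squares line fit along the last axis; returns (fitted, mean)."""
    n = values.shape[-1]
    t = np.arange(n, dtype=float)
    t_c = t - t.mean()
    denom = (t_c**2).sum()
    mean = values.mean(axis=-1, keepdims=True)
    slope = ((values - mean) * t_c).sum(axis=-1, keepdims=True) / denom
    fitted = mean + slope * t_c
    return fitted, mean


def detrend(tc: TimeCourse) -> TimeCourse:
    """Remove the least-squares linear trend, keeping the original mean.

    A straight line is fitted to the series and subtracted; the original
    mean is then added back, so the output has zero slope and the same
    mean as the input.  Idempotent.
    """
    if len(tc) < 3:
        raise ValueError("detrend needs at least 3 time points")
    fitted, mean = _fit_line(tc.values)
    return TimeCourse(values=tc.values - fitted + mean.ravel(), tr=tc.tr)


def detrend_volume(vol: Volume4D, mask: Optional[Mask] = None) -> Volume4D:
    """Voxel-wise linear detrend of a 4D volume (mean preserved)."""
    data = np.asarray(vol.data, dtype=float)
    fitted, mean = _fit_line(data)
    out = data - fitted + mean
    if mask is not None:
        out = np.where(mask.data[..., None], out, data)
    return Volume4D(data=out, affine=vol.affine.copy(), tr=vol.tr)


# ---------------------------------------------------------------------------
# ideal bandpass


def pad_length(n: int) -> int:
    """Smallest integer >= n whose prime factors are all in {2, 3, 5}.

    This is the "shortest FFT length" zero-padding convention used by
    AFNI's power-spectrum and Fourier-filter tools.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    best = None
    p5 = 1
    while p5 < 6 * n:
        p35 = p5
        while p35 < 6 * n:
            # smallest power of two lifting p35 to >= n
            m = p35
            while m < n:
                m *= 2
            if best is None or m < best:
                best = m
            p35 *= 3
        p5 *= 5
    return int(best)


def _band_bin_mask(n_pad: int, tr: float, band: FrequencyBand) -> np.ndarray:
    """Boolean keep-mask over one-sided DFT bins; DC always dropped.

    A bin at frequency f is kept iff low <= f <= high (closed interval).
    low = 0 keeps everything up to ``high`` (low-pass); high beyond the
    Nyquist keeps everything from ``low`` up (high-pass).
    """
    freqs = np.fft.rfftfreq(n_pad, d=tr)
    keep = (freqs >= band.low) & (freqs <= band.high)
    keep[0] = False  # DC handled by the retrend step
    return keep


def _apply_ideal_filter(data: np.ndarray, tr: float, band: FrequencyBand) -> np.ndarray:
    """Rectangle-window filter along the last axis with retrend."""
    n = data.shape[-1]
    n_pad = pad_length(n)
    keep = _band_bin_mask(n_pad, tr, band)
    if not keep.any():
        nyq = 1.0 / (2 * tr)
        raise ValueError(
            f"no DFT bin in band [{band.low}, {band.high}] Hz "
            f"(Nyquist {nyq:g} Hz, resolution {1.0 / (n_pad * tr):g} Hz)"
        )
    trend, _ = _fit_line(data)
    resid = data - trend
    spec = np.fft.rfft(resid, n=n_pad, axis=-1)
    spec[..., ~keep] = 0
    filt = np.fft.irfft(spec, n=n_pad, axis=-1)[..., :n]
    return filt + trend


def ideal_bandpass(tc: TimeCourse, band: FrequencyBand) -> TimeCourse:
    """Ideal rectangle-window bandpass filter of a time course.

    The series is linearly detrended, zero-padded to the shortest
    5-smooth FFT length, transformed; DFT bins with frequency outside
    the closed interval [low, high] are zeroed; after the inverse
    transform the fitted line (including the mean) is added back.
    """
    out = _apply_ideal_filter(tc.values[None, :], tc.tr, band)[0]
    return TimeCourse(values=out, tr=tc.tr)


def bandpass_volume(vol: Volume4D, band: FrequencyBand,
                    mask: Optional[Mask] = None) -> Volume4D:
    """Voxel-wise ideal bandpass of a 4D volume."""
    data = np.asarray(vol.data, dtype=float)
    out = _apply_ideal_filter(data, vol.tr, band)
    if mask is not None:
        out = np.where(mask.data[..., None], out, data)
    return Volume4D(data=out, affine=vol.affine.copy(), tr=vol.tr)


# ---------------------------------------------------------------------------
# covariate regression


def _design_matrix(covs: CovariateSet) -> np.ndarray:
    return np.column_stack([np.ones(len(covs)), covs.matrix])


def _check_full_rank(design: np.ndarray, names: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify columns linearly dependent on their predecessors
        collinear = []
        for j in range(1, design.shape[1]):
            if np.linalg.matrix_rank(design[:, : j + 1]) <= np.linalg.matrix_rank(design[:, :j]):
                collinear.append(names[j - 1] if j - 1 < len(names) else f"col{j}")
        raise ValueError(f"rank-deficient design; collinear column(s): {collinear}")


def regress_covariates(vol: Volume4D, covs: CovariateSet, mask: Mask) -> Volume4D:
    """Regress nuisance covariates out of every in-mask voxel series.

    Per voxel, the output is the OLS residual of the series on
    ``[intercept | covariates]`` plus the original voxel mean, so
    residuals are orthogonal to every covariate while the baseline
    signal level is retained.  Out-of-mask voxels pass through.
    """
    if len(covs) != vol.n_timepoints:
        raise ValueError(
            f"covariate rows ({len(covs)}) != volume time points ({vol.n_timepoints})"
        )
    if covs.n_covariates == 0:
        return Volume4D(data=np.asarray(vol.data, dtype=float).copy(),
                        affine=vol.affine.copy(), tr=vol.tr)
    design = _design_matrix(covs)
    _check_full_rank(design, covs.names)
    data = np.asarray(vol.data, dtype=float)
    flat = data[mask.data]  # (n_vox, T)
    beta, *_ = np.linalg.lstsq(design, flat.T, rcond=None)
    resid = flat.T - design @ beta  # (T, n_vox)
    out = data.copy()
    out[mask.data] = resid.T + flat.mean(axis=1, keepdims=True)
    return Volume4D(data=out, affine=vol.affine.copy(), tr=vol.tr)


def read_covariates(path: Union[str, os.PathLike]) -> CovariateSet:
    """Read a whitespace- or comma-delimited covariate text file.

    One row per time point (or subject), one column per covariate.  A
    non-numeric first row is treated as a header of column names.
    """
    with open(os.fspath(path)) as fh:
        text = fh.read()
    sep = "," if ("," in text.splitlines()[0] if text.strip() else False) else r"\s+"
    first = text.strip().splitlines()[0] if text.strip() else ""
    tokens = [t for t in first.replace(",", " ").split() if t]

    def _numeric(tok: str) -> bool:
        try:
            float(tok)
            return True
        except ValueError:
            return False

    header = 0 if tokens and not all(_numeric(t) for t in tokens) else None
    df = pd.read_csv(io.StringIO(text), sep=sep, header=header, engine="python")
    names = [str(c) for c in df.columns] if header == 0 else []
    return CovariateSet(matrix=df.to_numpy(dtype=float), names=names)


# ---------------------------------------------------------------------------
# ROI handling


def make_sphere_roi(roi: SphereROI, reference: Union[Volume4D, Mask]) -> Mask:
    """Voxelize a sphere given in mm coordinates on the reference grid.

    A voxel belongs to the ROI iff the Euclidean distance from its
    center's mm coordinate to the sphere center is <= radius.  An ROI
    with no voxel on the grid is an error.
    """
    shape = (reference.spatial_shape if isinstance(reference, Volume4D)
             else reference.data.shape)
    affine = reference.affine
    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    idx = np.stack([ii, jj, kk, np.ones_like(ii)], axis=-1).astype(float)
    mm = idx @ affine.T
    d2 = ((mm[..., :3] - np.asarray(roi.center)) ** 2).sum(axis=-1)
    inside = d2 <= roi.radius**2
    if not inside.any():
        raise ValueError(
            f"sphere at {roi.center} mm radius {roi.radius} mm contains no voxel of the grid"
        )
    return Mask(data=inside, affine=np.asarray(affine, dtype=float).copy())


def extract_roi_timecourse(vol: Volume4D, roi: Mask) -> TimeCourse:
    """Mean time course over the ROI voxels (a 1-voxel ROI returns its series)."""
    if roi.data.shape != vol.spatial_shape:
        raise ValueError(
            f"ROI shape {roi.data.shape} does not match volume grid {vol.spatial_shape}"
        )
    if roi.n_voxels == 0:
        raise ValueError("empty ROI")
    series = np.asarray(vol.data, dtype=float)[roi.data].mean(axis=0)
    return TimeCourse(values=series, tr=vol.tr)
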