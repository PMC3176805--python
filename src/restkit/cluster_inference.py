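"""Multiple-comparison correction and cluster reporting.

Two correction routes are provided.  Benjamini-Hochberg FDR controls
the expected fraction of false positives among suprathreshold voxels by
the step-up rule: with m in-mask p-values sorted ascending, the data
threshold is p_(k) for the largest k with p_(k) <= k*q/m.  The
Monte-Carlo cluster-extent simulation (the "AlphaSim" approach) instead
estimates, under smooth Gaussian noise restricted to the analysis mask,
the probability that a cluster of at least s suprathreshold voxels
occurs anywhere — the corrected alpha for a cluster-size threshold s.

Cluster reporting labels suprathreshold connected components (6-, 18-
or 26-connectivity), filters them by minimum size, and reports voxel
count, volume in mm^3 and the peak's MNI-mm coordinate and intensity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import ndimage, stats as sps

from .group_stats import StatMap
from .nifti_io import Mask, Volume3D, voxel_sizes, voxel_volume_mm3

__all__ = [
    "AlphaSimTable",
    "fdr_threshold",
    "alphasim",
    "cluster_report",
    "critical_stat",
    "connectivity_structure",
]


def connectivity_structure(connectivity: int) -> np.ndarray:
    """3x3x3 binary structuring element for 6/18/26-connectivity."""
    order = {6: 1, 18: 2, 26: 3}
    if connectivity not in order:
        raise ValueError("connectivity must be 6, 18 or 26")
    return ndimage.generate_binary_structure(3, order[connectivity])


# ---------------------------------------------------------------------------
# FDR


def fdr_threshold(
    pmap: Union[Volume3D, StatMap],
    mask: Mask,
    q: float,
    tails: str = "one",
) -> Tuple[float, Mask]:
    """Benjamini-Hochberg FDR threshold over in-mask voxels.

    ``pmap`` is either a 3D map of p-values or a signed :class:`StatMap`
    (then converted to one- or two-tailed p-values per ``tails`` first).
    Returns the data-dependent p threshold (0.0 if nothing survives) and
    the survivor mask (p <= threshold).
    """
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    if mask.n_voxels == 0:
        raise ValueError("empty mask")
    if isinstance(pmap, StatMap):
        p_all = pmap.p_map(tails="two" if tails == "two" else "one")
        affine = pmap.affine
    else:
        p_all = np.asarray(pmap.data, dtype=float)
        affine = pmap.affine
        if p_all.min() < 0 or p_all.max() > 1:
            raise ValueError("p-values must lie in [0, 1]")
    p = p_all[mask.data]
    m = p.size
    order = np.sort(p)
    crit = (np.arange(1, m + 1) / m) * q
    passed = np.flatnonzero(order <= crit)
    if passed.size == 0:
        thr = 0.0
        survivors = np.zeros_like(mask.data)
    else:
        thr = float(order[passed[-1]])
        survivors = mask.data & (p_all <= thr)
    return thr, Mask(data=survivors, affine=np.asarray(affine, dtype=float).copy())


# ---------------------------------------------------------------------------
# AlphaSim


@dataclass
class AlphaSimTable:
    """Monte-Carlo cluster-size null distribution and corrected alphas.

    ``table`` has columns: cluster_size (voxels), frequency (iterations
    whose max cluster equals that size), alpha (fraction of iterations
    whose max cluster size >= that size — the corrected alpha for the
    cluster-extent threshold).  ``params`` records all simulation inputs
    including the seed.
    """

    table: pd.DataFrame
    params: Dict = field(default_factory=dict)

    def minimum_cluster_size(self, alpha: float) -> int:
        """Smallest cluster-extent threshold with corrected alpha <= alpha."""
        ok = self.table[self.table["alpha"] <= alpha]
        if ok.empty:
            raise ValueError(
                f"no simulated cluster size reaches corrected alpha {alpha}"
            )
        return int(ok["cluster_size"].iloc[0])

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            for k, v in sorted(self.params.items()):
                fh.write(f"# {k}: {v}\n")
            self.table.to_csv(fh, sep="\t", index=False)


def _fwhm_to_sigma_vox(fwhm_mm: np.ndarray, affine: np.ndarray) -> np.ndarray:
    sizes = voxel_sizes(affine)
    return np.asarray(fwhm_mm, dtype=float) / (sizes * np.sqrt(8 * np.log(2)))


def alphasim(
    mask: Mask,
    fwhm_mm: Union[float, Sequence[float]],
    voxel_p: float,
    iterations: int = 1000,
    connectivity: int = 26,
    seed: int = 0,
) -> AlphaSimTable:
    """Monte-Carlo estimate of cluster-extent corrected alpha levels.

    Each iteration fills the mask's bounding grid with unit Gaussian
    noise, smooths it with a Gaussian kernel of the given FWHM (mm),
    re-standardizes within the mask, marks the top ``voxel_p`` fraction
    of in-mask voxels (empirical quantile, so the per-voxel rate is
    exact by construction), labels connected components and records the
    largest cluster.  alpha(s) = fraction of iterations whose largest
    cluster has >= s voxels; it is non-increasing in s.
    """
    if iterations < 100:
        raise ValueError("need at least 100 iterations")
    if not 0 < voxel_p < 1:
        raise ValueError("voxel_p must be in (0, 1)")
    fwhm = np.broadcast_to(np.asarray(fwhm_mm, dtype=float), (3,)).copy()
    if (fwhm < 0).any():
        raise ValueError("FWHM must be non-negative")
    structure = connectivity_structure(connectivity)
    sigma = _fwhm_to_sigma_vox(fwhm, mask.affine)
    rng = np.random.default_rng(seed)
    m = mask.data
    n_in = int(m.sum())
    k_thr = max(1, int(round(voxel_p * n_in)))
    max_sizes = np.zeros(iterations, dtype=np.int64)
    for it in range(iterations):
        noise = rng.standard_normal(m.shape)
        if sigma.max() > 0:
            noise = ndimage.gaussian_filter(noise, sigma=sigma)
        vals = noise[m]
        vals = (vals - vals.mean()) / vals.std()
        # empirical within-mask quantile: exactly k_thr voxels survive
        thr = np.partition(vals, n_in - k_thr)[n_in - k_thr]
        supra = np.zeros(m.shape, dtype=bool)
        supra[m] = vals >= thr
        labels, n_lab = ndimage.label(supra, structure=structure)
        if n_lab:
            max_sizes[it] = np.bincount(labels.ravel())[1:].max()
    sizes = np.arange(1, max(1, max_sizes.max()) + 1)
    freq = np.bincount(max_sizes, minlength=sizes.max() + 1)[1:]
    alpha = np.array([(max_sizes >= s).mean() for s in sizes])
    table = pd.DataFrame({"cluster_size": sizes, "frequency": freq, "alpha": alpha})
    params = {
        "fwhm_mm": tuple(fwhm), "voxel_p": voxel_p, "iterations": iterations,
        "connectivity": connectivity, "seed": seed, "mask_voxels": n_in,
        "voxels_per_iteration": k_thr,
    }
    return AlphaSimTable(table=table, params=params)


# ---------------------------------------------------------------------------
# cluster report


def cluster_report(
    stat: Union[StatMap, Volume3D],
    voxel_threshold: float,
    min_cluster_voxels: int = 1,
    connectivity: int = 26,
    sidedness: str = "both",
    mask: Optional[Mask] = None,
) -> pd.DataFrame:
    """Report suprathreshold clusters with sizes and MNI peaks.

    Suprathreshold means value > threshold (``pos``), value < -threshold
    (``neg``) or |value| > threshold (``both``).  Rows are sorted by
    voxel count descending; volume is count times the voxel volume in
    mm^3; the peak is the member voxel with maximum |intensity|, located
    in MNI mm via the affine.
    """
    if not np.isfinite(voxel_threshold):
        raise ValueError("threshold must be finite")
    vol = stat.volume if isinstance(stat, StatMap) else stat
    data = np.asarray(vol.data, dtype=float)
    if sidedness == "pos":
        supra = data > voxel_threshold
    elif sidedness == "neg":
        supra = data < -voxel_threshold
    elif sidedness == "both":
        supra = np.abs(data) > voxel_threshold
    else:
        raise ValueError("sidedness must be 'pos', 'neg' or 'both'")
    if mask is not None:
        supra &= mask.data
    labels, n_lab = ndimage.label(supra, structure=connectivity_structure(connectivity))
    vvol = voxel_volume_mm3(vol.affine)
    rows = []
    for lab in range(1, n_lab + 1):
        idx = np.argwhere(labels == lab)
        count = idx.shape[0]
        if count < min_cluster_voxels:
            continue
        vals = data[tuple(idx.T)]
        peak = idx[np.argmax(np.abs(vals))]
        mm = vol.affine @ np.append(peak, 1.0)
        rows.append({
            "cluster_id": lab,
            "n_voxels": count,
            "volume_mm3": count * vvol,
            "peak_x_mm": mm[0], "peak_y_mm": mm[1], "peak_z_mm": mm[2],
            "peak_intensity": float(vals[np.argmax(np.abs(vals))]),
        })
    df = pd.DataFrame(rows, columns=[
        "cluster_id", "n_voxels", "volume_mm3",
        "peak_x_mm", "peak_y_mm", "peak_z_mm", "peak_intensity",
    ])
    if not df.empty:
        df = df.sort_values("n_voxels", ascending=False, kind="stable").reset_index(drop=True)
        df["cluster_id"] = np.arange(1, len(df) + 1)
    return df


def critical_stat(p: float, df: float, kind: str = "t") -> float:
    """Critical statistic at a two-sided level p (e.g. t for p = 0.05).

    For the t family this is the inverse Student-t CDF at 1 - p/2; the
    viewer uses it to translate a p threshold into a map threshold
    (p = 0.05 at df = 19 gives t = 2.093).
    """
    if not 0 < p < 1:
        raise ValueError("p must be in (0, 1)")
    if kind != "t":
        raise ValueError("only the t family is supported")
    if np.isinf(df):
        return float(sps.norm.ppf(1 - p / 2))
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(sps.t.ppf(1 - p / 2, df))
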