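"""Voxel-wise group inference on 3D metric maps.

Implements the classical mass-univariate GLM battery used on
resting-state metric maps: one-sample, two-sample and paired t-tests,
one-way ANOVA/ANCOVA, and across-subject correlation with a behavioral
regressor.  All designs support per-subject text covariates and
voxel-dependent image covariates (one 3D map per subject entering the
design at each voxel, e.g. gray-matter density).

Conventions: the pooled-variance (equal variance) two-sample t is used,
matching the SPM-style GLM; image covariates are mean-centered per
voxel; maps store the signed statistic and sidedness is applied only at
thresholding.  Zero-variance or rank-deficient voxels emit statistic 0
and are tallied in a QC counter — written maps never contain NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .nifti_io import Mask, Volume3D

__all__ = [
    "StatMap",
    "GroupDesign",
    "one_sample_t",
    "two_sample_t",
    "paired_t",
    "one_way_anova",
    "correlation_map",
]

T_CAP = 1e6  # replaces infinite t at zero residual variance


@dataclass
class StatMap:
    """A 3D statistic map with type, degrees of freedom and QC counts."""

    volume: Volume3D
    stat: str  # {t, F, r}
    df: Tuple[float, ...]  # (df,) for t/r, (df1, df2) for F
    qc: Dict[str, int] = field(default_factory=dict)

    @property
    def data(self) -> np.ndarray:
        return self.volume.data

    @property
    def affine(self) -> np.ndarray:
        return self.volume.affine

    def p_map(self, tails: str = "two") -> np.ndarray:
        """Convert the statistic to p-values (one- or two-tailed)."""
        d = self.data
        if self.stat == "t":
            sf = sps.t.sf(np.abs(d), self.df[0])
            return 2 * sf if tails == "two" else sps.t.sf(d, self.df[0])
        if self.stat == "F":
            return sps.f.sf(d, self.df[0], self.df[1])
        if self.stat == "r":
            df = self.df[0]
            t = d * np.sqrt(df / np.maximum(1 - d**2, 1e-300))
            sf = sps.t.sf(np.abs(t), df)
            return 2 * sf if tails == "two" else sps.t.sf(t, df)
        raise ValueError(f"unknown statistic {self.stat!r}")


@dataclass
class GroupDesign:
    """Optional covariates entering a group-level design.

    ``text_covariates``: subjects x q matrix, rows concatenated across
    groups in group order.  ``image_covariates``: one 3D map per subject
    (same order), entering the design voxel-wise after per-voxel mean
    centering.
    """

    text_covariates: Optional[np.ndarray] = None
    image_covariates: Optional[Sequence[Volume3D]] = None

    def text_matrix(self, n_subjects: int) -> np.ndarray:
        if self.text_covariates is None:
            return np.empty((n_subjects, 0))
        m = np.atleast_2d(np.asarray(self.text_covariates, dtype=float))
        if m.shape[0] != n_subjects:
            raise ValueError(
                f"covariate rows ({m.shape[0]}) != total subjects ({n_subjects})"
            )
        return m

    def image_matrix(self, n_subjects: int, mask: Mask) -> Optional[np.ndarray]:
        """Stack image covariates as (subjects, in-mask voxels), mean-centered."""
        if self.image_covariates is None:
            return None
        if len(self.image_covariates) != n_subjects:
            raise ValueError("one image covariate per subject required")
        stack = np.stack([np.asarray(v.data, dtype=float)[mask.data]
                          for v in self.image_covariates])
        return stack - stack.mean(axis=0, keepdims=True)


def _stack_maps(maps: Sequence[Volume3D], mask: Mask) -> np.ndarray:
    shape = maps[0].data.shape
    for m in maps[1:]:
        if m.data.shape != shape or not np.allclose(m.affine, maps[0].affine):
            raise ValueError("all maps must share grid and affine")
    return np.stack([np.asarray(m.data, dtype=float)[mask.data] for m in maps])


def _to_map(vals: np.ndarray, mask: Mask, template: Volume3D) -> Volume3D:
    out = np.zeros(template.data.shape)
    out[mask.data] = vals
    return Volume3D(out, np.asarray(template.affine, dtype=float).copy())


def one_sample_t(maps: Sequence[Volume3D], mu0: float, mask: Mask) -> StatMap:
    """Voxel-wise one-sample t-test of the subject maps against ``mu0``.

    t = (mean - mu0) / (sd / sqrt(n)), df = n - 1.  Voxels with zero
    cross-subject variance get t = 0 (mean = mu0) or the capped value.
    """
    if len(maps) < 2:
        raise ValueError("need at least 2 subjects")
    y = _stack_maps(maps, mask)
    n = y.shape[0]
    mean = y.mean(axis=0)
    sd = y.std(axis=0, ddof=1)
    # sd at rounding-noise level counts as zero variance
    scale = np.abs(y).max(axis=0)
    zero = sd <= 1e-12 * np.maximum(scale, 1e-300)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mean - mu0) / (sd / np.sqrt(n))
    null_at = np.abs(mean[zero] - mu0) <= 1e-12 * np.maximum(scale[zero], 1e-300)
    t[zero] = np.where(null_at, 0.0, np.sign(mean[zero] - mu0) * T_CAP)
    return StatMap(_to_map(t, mask, maps[0]), "t", (float(n - 1),),
                   {"zero_variance_voxels": int(zero.sum())})


def _glm_t(y: np.ndarray, x: np.ndarray, contrast: np.ndarray) -> Tuple[float, float]:
    """OLS t for a single contrast; returns (t, df). y: (n,), x: (n, p)."""
    n, p = x.shape
    rank = np.linalg.matrix_rank(x)
    if rank < p:
        return np.nan, float(n - rank)
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    df = n - rank
    if df <= 0:
        return np.nan, 0.0
    sigma2 = (resid**2).sum() / df
    xtx_inv = np.linalg.pinv(x.T @ x)
    var = sigma2 * (contrast @ xtx_inv @ contrast)
    if var <= 0:
        return (0.0 if contrast @ beta == 0 else np.sign(contrast @ beta) * T_CAP), df
    return float((contrast @ beta) / np.sqrt(var)), float(df)


def two_sample_t(
    group_a: Sequence[Volume3D],
    group_b: Sequence[Volume3D],
    mask: Mask,
    design: Optional[GroupDesign] = None,
) -> StatMap:
    """Voxel-wise two-sample t-test (pooled variance), A minus B.

    The model per voxel is OLS on [group indicator | intercept | text
    covariates | centered image covariate]; t is the group contrast over
    its standard error, df = n - rank.  Without covariates this equals
    the classical pooled-variance formula.
    """
    na, nb = len(group_a), len(group_b)
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 subjects")
    design = design or GroupDesign()
    y = _stack_maps(list(group_a) + list(group_b), mask)
    n = na + nb
    indicator = np.concatenate([np.ones(na), np.zeros(nb)])
    text = design.text_matrix(n)
    base = np.column_stack([indicator, np.ones(n), text])
    img = design.image_matrix(n, mask)
    contrast = np.zeros(base.shape[1] + (1 if img is not None else 0))
    contrast[0] = 1.0
    n_vox = y.shape[1]
    t = np.empty(n_vox)
    if img is None:
        # shared design: solve all voxels at once
        rank = np.linalg.matrix_rank(base)
        if rank < base.shape[1]:
            raise ValueError("rank-deficient group design (check covariates)")
        beta, *_ = np.linalg.lstsq(base, y, rcond=None)
        resid = y - base @ beta
        df = n - rank
        sigma2 = (resid**2).sum(axis=0) / df
        cvar = contrast @ np.linalg.pinv(base.T @ base) @ contrast
        eff = contrast @ beta
        zero = sigma2 * cvar == 0
        with np.errstate(divide="ignore", invalid="ignore"):
            t = eff / np.sqrt(sigma2 * cvar)
        t[zero] = np.where(eff[zero] == 0, 0.0, np.sign(eff[zero]) * T_CAP)
        qc = {"zero_variance_voxels": int(zero.sum()), "rank_deficient_voxels": 0}
        return StatMap(_to_map(t, mask, group_a[0]), "t", (float(df),), qc)
    # voxel-dependent design
    n_bad = 0
    dfs = np.empty(n_vox)
    for v in range(n_vox):
        x = np.column_stack([base, img[:, v]])
        tv, df = _glm_t(y[:, v], x, contrast)
        if np.isnan(tv):
            tv, n_bad = 0.0, n_bad + 1
        t[v], dfs[v] = tv, df
    df_mode = float(np.median(dfs))
    qc = {"rank_deficient_voxels": n_bad, "zero_variance_voxels": 0}
    return StatMap(_to_map(t, mask, group_a[0]), "t", (df_mode,), qc)


def paired_t(group_a: Sequence[Volume3D], group_b: Sequence[Volume3D],
             mask: Mask) -> StatMap:
    """Paired t-test: one-sample t of per-subject differences A - B vs 0."""
    if len(group_a) != len(group_b):
        raise ValueError(f"paired groups differ in length: {len(group_a)} vs {len(group_b)}")
    diffs = [Volume3D(np.asarray(a.data, dtype=float) - np.asarray(b.data, dtype=float),
                      a.affine) for a, b in zip(group_a, group_b)]
    return one_sample_t(diffs, 0.0, mask)


def one_way_anova(
    groups: Sequence[Sequence[Volume3D]],
    mask: Mask,
    design: Optional[GroupDesign] = None,
) -> StatMap:
    """Voxel-wise one-way ANOVA (ANCOVA with covariates).

    F compares the full model (group dummies + covariates) to the
    reduced model (intercept + covariates); (df1, df2) = (G - 1,
    N - rank_full).  With two groups and no covariates, F = t^2 of the
    two-sample test.
    """
    g = len(groups)
    if g < 2 or any(len(grp) < 2 for grp in groups):
        raise ValueError("need >= 2 groups of >= 2 subjects")
    design = design or GroupDesign()
    all_maps = [m for grp in groups for m in grp]
    n = len(all_maps)
    y = _stack_maps(all_maps, mask)
    sizes = [len(grp) for grp in groups]
    labels = np.repeat(np.arange(g), sizes)
    dummies = np.column_stack([(labels == i).astype(float) for i in range(g)])
    text = design.text_matrix(n)
    img = design.image_matrix(n, mask)
    full_base = np.column_stack([dummies, text])
    red_base = np.column_stack([np.ones(n), text])

    def _rss(x: np.ndarray, yv: np.ndarray) -> Tuple[np.ndarray, int]:
        beta, *_ = np.linalg.lstsq(x, yv, rcond=None)
        resid = yv - x @ beta
        return (resid**2).sum(axis=0), np.linalg.matrix_rank(x)

    n_vox = y.shape[1]
    if img is None:
        rss_full, rank_full = _rss(full_base, y)
        rss_red, rank_red = _rss(red_base, y)
        df1 = rank_full - rank_red
        df2 = n - rank_full
        if df1 <= 0 or df2 <= 0:
            raise ValueError("degenerate ANOVA design")
        with np.errstate(divide="ignore", invalid="ignore"):
            f = ((rss_red - rss_full) / df1) / (rss_full / df2)
        bad = ~np.isfinite(f)
        f[bad] = 0.0
        qc = {"degenerate_voxels": int(bad.sum())}
        return StatMap(_to_map(f, mask, all_maps[0]), "F",
                       (float(df1), float(df2)), qc)
    f = np.empty(n_vox)
    n_bad = 0
    df_pair = (float(g - 1), float(n - (full_base.shape[1] + 1)))
    for v in range(n_vox):
        xf = np.column_stack([full_base, img[:, v]])
        xr = np.column_stack([red_base, img[:, v]])
        rf, rank_f = _rss(xf, y[:, v:v + 1])
        rr, rank_r = _rss(xr, y[:, v:v + 1])
        df1, df2 = rank_f - rank_r, n - rank_f
        if df1 <= 0 or df2 <= 0 or rf[0] == 0:
            f[v], n_bad = 0.0, n_bad + 1
            continue
        f[v] = ((rr[0] - rf[0]) / df1) / (rf[0] / df2)
    return StatMap(_to_map(f, mask, all_maps[0]), "F", df_pair,
                   {"degenerate_voxels": n_bad})


def correlation_map(
    maps: Sequence[Volume3D],
    regressor: np.ndarray,
    mask: Mask,
    design: Optional[GroupDesign] = None,
) -> StatMap:
    """Across-subject (partial) correlation of maps with a regressor.

    Per voxel: Pearson r between the regressor and the subjects' voxel
    values; with q covariates, the partial correlation after
    residualizing both on [intercept | covariates].  df = n - 2 - q.
    """
    n = len(maps)
    if n < 3:
        raise ValueError("need at least 3 subjects")
    reg = np.asarray(regressor, dtype=float).ravel()
    if reg.size != n:
        raise ValueError("regressor length must equal number of subjects")
    if np.ptp(reg) == 0:
        raise ValueError("constant regressor: correlation undefined")
    design = design or GroupDesign()
    text = design.text_matrix(n)
    q = text.shape[1]
    y = _stack_maps(maps, mask)
    if q > 0:
        x = np.column_stack([np.ones(n), text])
        reg = reg - x @ np.linalg.lstsq(x, reg, rcond=None)[0]
        y = y - x @ np.linalg.lstsq(x, y, rcond=None)[0]
    rc = reg - reg.mean()
    yc = y - y.mean(axis=0, keepdims=True)
    sy = np.sqrt((yc**2).sum(axis=0))
    sr = np.sqrt((rc**2).sum())
    zero = sy == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (yc.T @ rc) / (np.where(zero, 1.0, sy) * sr)
    r[zero] = 0.0
    r = np.clip(r, -1.0, 1.0)
    df = n - 2 - q
    if df < 1:
        raise ValueError("not enough subjects for the covariate count")
    return StatMap(_to_map(r, mask, maps[0]), "r", (float(df),),
                   {"zero_variance_voxels": int(zero.sum())})
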