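"""Synthetic resting-state datasets with known ground truth.

Every test input the toolkit needs is generated here rather than
shipped: 4D BOLD-like volumes with planted spectral content (a
"network" of voxels sharing a low-frequency sinusoid with a common
phase, a locally homogeneous high-ReHo region), per-voxel linear
drifts, Gaussian noise, and nuisance signals (a global trend, a
white-matter-like and a CSF-like series, six slow motion-like series);
plus group-level 3D map sets with a planted regional effect.

Defaults emulate a typical resting-state acquisition — TR = 2 s, 120
time points, phenomena in the 0.01-0.08 Hz band — on a 16x16x16 grid
with 3 mm voxels, small enough for seconds-scale tests while keeping
the spectral resolution (~0.004 Hz) fine enough to place signals
squarely in or out of the band.  Everything is deterministic under the
seed, and the returned ground-truth record carries every planted
region, frequency, amplitude and loading.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .nifti_io import Mask, Volume3D, Volume4D

__all__ = ["FixtureSpec", "PlantedComponent", "make_rs_volume", "make_group_maps",
           "default_affine"]


def default_affine(voxel_mm: float = 3.0) -> np.ndarray:
    return np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])


@dataclass
class PlantedComponent:
    """A region-restricted sinusoid: where, at what frequency, how strong.

    ``coherent`` plants one shared phase across the region (a connected
    "network", detectable by seed correlation); incoherent components
    randomize phase per voxel (locally strong spectral power without
    inter-voxel correlation is not representable — use ``coherent=True``
    with per-region phases for homogeneous regions instead).
    """

    region: Tuple[slice, slice, slice]
    frequency_hz: float
    amplitude: float
    coherent: bool = True
    name: str = "component"


@dataclass
class FixtureSpec:
    """Parameters of a synthetic resting-state 4D dataset."""

    shape: Tuple[int, int, int] = (16, 16, 16)
    n_timepoints: int = 120
    tr: float = 2.0
    seed: int = 0
    components: Sequence[PlantedComponent] = field(default_factory=list)
    drift_slope_range: Tuple[float, float] = (-0.02, 0.02)  # units per time point
    noise_sd: float = 1.0
    baseline: float = 100.0
    nuisance_amplitude: float = 0.0  # 0 disables nuisance loadings
    voxel_mm: float = 3.0

    def __post_init__(self) -> None:
        nyq = 1.0 / (2 * self.tr)
        for c in self.components:
            if c.frequency_hz >= nyq:
                raise ValueError(
                    f"planted frequency {c.frequency_hz} Hz >= Nyquist {nyq} Hz"
                )
            if c.amplitude < 0:
                raise ValueError("amplitudes must be >= 0")

    @classmethod
    def default(cls, seed: int = 0, noise_sd: float = 1.0,
                amplitude: float = 3.0) -> "FixtureSpec":
        """The standard two-region fixture: a 0.04 Hz network and a
        locally homogeneous 0.02 Hz region, both inside the band."""
        return cls(
            seed=seed,
            noise_sd=noise_sd,
            components=[
                PlantedComponent(region=(slice(2, 6), slice(2, 6), slice(2, 6)),
                                 frequency_hz=0.04, amplitude=amplitude,
                                 name="network"),
                PlantedComponent(region=(slice(9, 13), slice(9, 13), slice(9, 13)),
                                 frequency_hz=0.02, amplitude=amplitude,
                                 name="homogeneous"),
            ],
        )


def _nuisance_signals(rng: np.random.Generator, n: int, tr: float) -> Dict[str, np.ndarray]:
    """Slow confound series: global, WM-like, CSF-like, 6 motion-like."""
    t = np.arange(n) * tr

    def slow(freqs, scale=1.0):
        sig = sum(rng.normal(0, 1) * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
                  for f in freqs)
        return scale * sig

    out = {
        "global": slow([0.005, 0.015, 0.03]),
        "white_matter": slow([0.01, 0.025]),
        "csf": slow([0.02, 0.05]),
    }
    for k in range(6):
        out[f"motion{k + 1}"] = slow([0.003, 0.008], scale=0.5)
    return out


def make_rs_volume(spec: FixtureSpec) -> Tuple[Volume4D, Dict]:
    """Generate a synthetic 4D resting-state volume and its ground truth.

    The volume is baseline + planted sinusoids (shared phase within each
    coherent region) + per-voxel linear drift + nuisance loadings +
    white Gaussian noise; the truth record lists each component's voxel
    mask, frequency, amplitude and phase, the drift slopes, and the
    nuisance series with their per-voxel loadings.
    """
    rng = np.random.default_rng(spec.seed)
    nx, ny, nz = spec.shape
    n = spec.n_timepoints
    t = np.arange(n) * spec.tr
    data = np.full((nx, ny, nz, n), float(spec.baseline))

    truth: Dict = {"components": [], "tr": spec.tr, "shape": spec.shape,
                   "seed": spec.seed, "noise_sd": spec.noise_sd}
    for comp in spec.components:
        region_mask = np.zeros(spec.shape, dtype=bool)
        region_mask[comp.region] = True
        if comp.coherent:
            phase = rng.uniform(0, 2 * np.pi)
            sig = comp.amplitude * np.sin(2 * np.pi * comp.frequency_hz * t + phase)
            data[region_mask] += sig
            phases = phase
        else:
            n_vox = int(region_mask.sum())
            phases = rng.uniform(0, 2 * np.pi, size=n_vox)
            sig = comp.amplitude * np.sin(
                2 * np.pi * comp.frequency_hz * t[None, :] + phases[:, None])
            data[region_mask] += sig
        truth["components"].append({
            "name": comp.name, "mask": region_mask,
            "frequency_hz": comp.frequency_hz, "amplitude": comp.amplitude,
            "phase": phases, "coherent": comp.coherent,
        })

    lo, hi = spec.drift_slope_range
    slopes = rng.uniform(lo, hi, size=spec.shape)
    data += slopes[..., None] * np.arange(n)
    truth["drift_slopes"] = slopes

    nuisance = _nuisance_signals(rng, n, spec.tr)
    truth["nuisance_signals"] = nuisance
    if spec.nuisance_amplitude > 0:
        loadings = {}
        for name, series in nuisance.items():
            load = rng.normal(0, spec.nuisance_amplitude, size=spec.shape)
            data += load[..., None] * series
            loadings[name] = load
        truth["nuisance_loadings"] = loadings

    if spec.noise_sd > 0:
        data += rng.normal(0, spec.noise_sd, size=data.shape)

    vol = Volume4D(data=data, affine=default_affine(spec.voxel_mm), tr=spec.tr)
    truth["mask"] = Mask(data=np.ones(spec.shape, dtype=bool), affine=vol.affine.copy())
    return vol, truth


def make_group_maps(
    n_subjects: int,
    effect_region: Optional[Mask] = None,
    effect_size: float = 0.0,
    noise_sd: float = 1.0,
    seed: int = 0,
    shape: Tuple[int, int, int] = (12, 12, 12),
    baseline: float = 1.0,
    regressor: Optional[np.ndarray] = None,
) -> Tuple[List[Volume3D], Dict]:
    """Generate per-subject 3D maps with a planted regional effect.

    Subject maps are baseline + effect_size * region indicator +
    N(0, noise_sd^2).  When ``regressor`` is given (one value per
    subject), the regional effect scales with the (standardized)
    regressor instead of being constant, supporting correlation-analysis
    fixtures.  Two-group designs are built by calling this twice with
    different seeds/effects.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    rng = np.random.default_rng(seed)
    affine = default_affine()
    if effect_region is not None:
        region = effect_region.data
        if region.shape != shape:
            shape = region.shape
    else:
        region = np.zeros(shape, dtype=bool)
    if regressor is not None:
        reg = np.asarray(regressor, dtype=float)
        if reg.size != n_subjects:
            raise ValueError("regressor length must equal n_subjects")
        reg_std = (reg - reg.mean()) / (reg.std() if reg.std() > 0 else 1.0)
        per_subject_effect = effect_size * reg_std
    else:
        per_subject_effect = np.full(n_subjects, effect_size)
    maps = []
    for s in range(n_subjects):
        m = np.full(shape, float(baseline))
        m += per_subject_effect[s] * region
        if noise_sd > 0:
            m += rng.normal(0, noise_sd, size=shape)
        maps.append(Volume3D(data=m, affine=affine.copy()))
    truth = {
        "region": region, "effect_size": effect_size, "noise_sd": noise_sd,
        "baseline": baseline, "seed": seed,
        "per_subject_effect": per_subject_effect,
        "mask": Mask(data=np.ones(shape, dtype=bool), affine=affine.copy()),
    }
    return maps, truth
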