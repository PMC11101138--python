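"""Synthetic TMS phantom: mask, focal E-fields, recruitment, full datasets.

Real inputs to the inverse mapping are finite-element E-field simulations on a
subject's motor cortex paired with measured MEP amplitudes. Neither is needed
to exercise the pipeline: this module builds a phantom with the same
statistical structure —

* a sparse, connected, curved-ribbon cortical mask (a motor-strip stand-in
  occupying a few percent of the box);
* smooth, focal, unimodal fields whose peak tracks the coil position, whose
  amplitude grows with stimulator intensity (%RMT) and falls off with the
  coil-to-cortex distance, and which vanish for far-fringe coil placements;
* MEP vectors from a saturating (logistic) recruitment map applied to the
  field mass over per-muscle weight blobs, with additive noise and
  rectification so weak fringe stimulations yield exact zeros.

Stimulation follows the mapping-study design: one pulse per vertex of a
6 x 6 cm grid (1 cm spacing, 7 x 7 = 49 vertices) centred on the map hotspot,
optionally with extra jittered pulses, at each of four intensities
(110-140 %RMT). Field amplitudes are calibrated so masked peaks span from a
few to ~250 mV/m, straddling the 10 mV/m outlier-filter threshold.

All randomness flows from ``PhantomConfig.seed``; with ``noise_sd = 0`` the
generator is a pure function of the config.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .data import (CortexMask, EFieldVolume, MEPVector, StimulationDataset,
                   StimulationRecord, DEFAULT_MUSCLES)

__all__ = [
    "PhantomConfig",
    "MuscleWeightMap",
    "make_phantom_mask",
    "simulate_efield",
    "make_muscle_weight_maps",
    "simulate_mep",
    "generate_dataset",
]

FULL_SIDE_MM = 64.0  # physical box edge; voxel size scales with grid shape


@dataclass
class PhantomConfig:
    """Parameters of the synthetic dataset.

    Defaults are full scale (64^3 voxels at 1 mm); ``test_scale()`` gives the
    16^3 variant used for CPU-friendly runs. Physical extent is the same at
    both scales (the voxel size grows), so the 6 cm grid always fits.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    mask_fraction: float = 0.02
    grid_extent_mm: float = 60.0
    grid_spacing_mm: float = 10.0
    n_jitter: int = 0                       # extra random stimulations per intensity
    intensities: tuple[int, ...] = (110, 120, 130, 140)
    field_sigma_mm: float = 12.0            # focal spread of the field kernel
    field_amp_vm: float = 0.2               # V/m at unit drive, before decay
    coil_standoff_mm: float = 10.0          # coil-to-cortex depth offset
    coil_cutoff_mm: float = 45.0            # farther coils induce no field
    orientation_gain: float = 0.3           # strength of the orientation factor
    m: int = 15
    muscle_sigma_mm: float = 8.0            # width of muscle weight blobs
    drive_ref_vm: float = 0.02              # recruitment drive normalisation
    recruit_slope: float = 4.0
    recruit_threshold_range: tuple[float, float] = (0.8, 2.5)
    mep_gain_uv: float = 800.0              # scale of raw MEP amplitudes
    noise_sd: float = 0.02                  # on the dimensionless sigmoid scale
    rectify_floor: float = 0.04             # detection floor before rectification
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mask_fraction <= 0 or self.mask_fraction >= 0.2:
            raise ValueError("mask_fraction must lie in (0, 0.2)")
        if any(s <= 0 for s in self.shape):
            raise ValueError("shape entries must be positive")
        if list(self.intensities) != sorted(self.intensities):
            raise ValueError("intensities must be sorted ascending")

    @property
    def voxel_size(self) -> float:
        return FULL_SIDE_MM / self.shape[0]

    @classmethod
    def test_scale(cls, **overrides) -> "PhantomConfig":
        kw = dict(shape=(16, 16, 16), mask_fraction=0.05)
        kw.update(overrides)
        return cls(**kw)


@dataclass
class MuscleWeightMap:
    """Normalised per-muscle weight blob over the mask (unit sum)."""

    muscle: str
    grid: np.ndarray
    center_vox: np.ndarray

    def __post_init__(self) -> None:
        if abs(float(self.grid.sum()) - 1.0) > 1e-6:
            raise ValueError("weight map must sum to 1")


def _voxel_coords_mm(shape: tuple[int, int, int], voxel_size: float) -> np.ndarray:
    """(nx*ny*nz, 3) voxel-centre coordinates in mm (0-based indices)."""
    idx = np.indices(shape).reshape(3, -1).T
    return idx * voxel_size


def make_phantom_mask(shape: tuple[int, int, int], mask_fraction: float,
                      seed: int = 0) -> CortexMask:
    """Curved-ribbon mask: a tube around a smooth seeded centerline.

    The tube radius is set by the distance quantile matching ``mask_fraction``,
    so the achieved fraction is close to the target by construction; anisotropy
    (flattened along z) makes it ribbon-like. Single connected component.
    """
    if not 0 < mask_fraction < 0.2:
        raise ValueError("mask_fraction must lie in (0, 0.2)")
    nx, ny, nz = shape
    if min(shape) < 8:
        raise ValueError("shape too small for a connected ribbon mask")
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, 1.0, 200)
    amp = (0.10 + 0.05 * rng.random()) * ny
    phase = rng.uniform(0, 2 * np.pi)
    freq = 1.0 + rng.random()
    cx = (0.15 + 0.7 * t) * nx
    cy = 0.5 * ny + amp * np.sin(2 * np.pi * freq * t / 4 + phase)
    cz = 0.5 * nz + 0.08 * nz * np.sin(2 * np.pi * t + phase / 2)
    centerline = np.stack([cx, cy, cz], axis=1)

    coords = np.indices(shape).reshape(3, -1).T.astype(np.float64)
    z_flatten = 1.8  # ribbon is thinner along z
    scaled = coords.copy()
    scaled[:, 2] *= z_flatten
    line_scaled = centerline.copy()
    line_scaled[:, 2] *= z_flatten
    dist, _ = cKDTree(line_scaled).query(scaled)
    radius = np.quantile(dist, mask_fraction)
    grid = (dist <= radius).reshape(shape).astype(np.uint8)

    labels, n_comp = ndimage.label(grid)
    if n_comp > 1:  # keep the largest component (quantile ties can fragment)
        sizes = ndimage.sum_labels(grid, labels, index=np.arange(1, n_comp + 1))
        grid = (labels == (1 + int(np.argmax(sizes)))).astype(np.uint8)
    achieved = grid.mean()
    if not (0.75 * mask_fraction <= achieved <= 1.25 * mask_fraction):
        raise ValueError(
            f"mask fraction {achieved:.4f} outside +-25% of target {mask_fraction}")
    return CortexMask(grid=grid)


def _local_tangent(mask: CortexMask, center_vox: np.ndarray,
                   radius_vox: float) -> np.ndarray:
    """Principal axis of mask voxels near ``center_vox`` (the ribbon tangent)."""
    pts = np.argwhere(mask.grid > 0).astype(np.float64)
    d = np.linalg.norm(pts - center_vox, axis=1)
    local = pts[d <= radius_vox]
    if len(local) < 3:
        return np.array([1.0, 0.0, 0.0])
    centered = local - local.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    return vt[0]


def simulate_efield(coil_position: np.ndarray, coil_orientation: float,
                    intensity_pct_rmt: int, mask: CortexMask,
                    config: PhantomConfig) -> tuple[EFieldVolume, bool]:
    """Smooth unimodal field under the coil, zero outside the mask.

    ``E(v) = A * s(I) * exp(-d(v)^2 / (2 sigma^2)) * (1 + g*|cos(theta)|)``
    with ``d(v)`` the distance from voxel ``v`` to the coil (mm), ``s``
    linear-increasing in %RMT, and ``theta`` the angle between the coil
    orientation and the local ribbon tangent at the peak (the absolute value
    resolves the tangent's sign ambiguity). The peak voxel is the mask voxel
    nearest the coil. Returns ``(volume, fringe_flag)``: coils farther than
    ``coil_cutoff_mm`` from the mask induce an all-zero field and set the flag.
    """
    vs = config.voxel_size
    coil = np.asarray(coil_position, dtype=np.float64)
    mask_vox = np.argwhere(mask.grid > 0)
    mask_mm = mask_vox * vs
    d_to_mask = np.linalg.norm(mask_mm - coil, axis=1)
    i_near = int(np.argmin(d_to_mask))
    grid = np.zeros(config.shape, dtype=np.float32)
    if d_to_mask[i_near] > config.coil_cutoff_mm:
        return EFieldVolume(grid=grid, voxel_size=vs), True

    s = (intensity_pct_rmt - 100.0) / 40.0
    if s <= 0:
        raise ValueError("intensity must exceed 100 %RMT")
    tangent = _local_tangent(mask, mask_vox[i_near].astype(np.float64),
                             10.0 / vs)
    ori = np.deg2rad(coil_orientation)
    ori_vec = np.array([np.cos(ori), np.sin(ori), 0.0])
    t2 = tangent / (np.linalg.norm(tangent) + 1e-12)
    cos_theta = abs(float(ori_vec @ t2))
    orient_factor = 1.0 + config.orientation_gain * cos_theta

    d2 = np.sum((mask_mm - coil) ** 2, axis=1)
    vals = (config.field_amp_vm * s * orient_factor
            * np.exp(-d2 / (2.0 * config.field_sigma_mm ** 2)))
    grid[tuple(mask_vox.T)] = vals.astype(np.float32)
    return EFieldVolume(grid=grid, voxel_size=vs), False


def make_muscle_weight_maps(m: int, mask: CortexMask, seed: int = 0,
                            sigma_mm: float = 8.0, voxel_size: float = 1.0
                            ) -> list[MuscleWeightMap]:
    """m overlapping Gaussian blobs centred at distinct spots along the ribbon.

    Centres are spread along the ribbon's principal direction (quantiles with
    seeded jitter), emulating overlapping, mosaic-like muscle representations:
    nearby stimulations co-activate several muscles.
    """
    rng = np.random.default_rng(seed)
    mask_vox = np.argwhere(mask.grid > 0).astype(np.float64)
    if len(mask_vox) < m:
        raise ValueError("mask too small for the requested number of muscles")
    centered = mask_vox - mask_vox.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    proj = centered @ vt[0]
    order = np.argsort(proj)
    names = (DEFAULT_MUSCLES if m == len(DEFAULT_MUSCLES)
             else [f"M{i + 1}" for i in range(m)])
    maps: list[MuscleWeightMap] = []
    chosen: list[int] = []
    for k in range(m):
        q = (k + 0.5) / m + rng.uniform(-0.25, 0.25) / m
        j = int(np.clip(round(q * (len(order) - 1)), 0, len(order) - 1))
        idx = int(order[j])
        while idx in chosen:  # force pairwise-distinct centres
            idx = int(order[(j + 1) % len(order)])
            j += 1
        chosen.append(idx)
        center = mask_vox[idx]
        d2 = np.sum(((mask_vox - center) * voxel_size) ** 2, axis=1)
        w = np.exp(-d2 / (2.0 * sigma_mm ** 2))
        grid = np.zeros(mask.grid.shape, dtype=np.float64)
        grid[tuple(mask_vox.astype(int).T)] = w / w.sum()
        maps.append(MuscleWeightMap(muscle=names[k], grid=grid,
                                    center_vox=center))
    return maps


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_mep(efield: EFieldVolume, weight_maps: list[MuscleWeightMap],
                 config: PhantomConfig, rng: np.random.Generator,
                 thresholds: np.ndarray | None = None) -> MEPVector:
    """Saturating recruitment: drive -> logistic -> floor-subtract -> rectify.

    ``drive_k = <w_k, E>`` (V/m, a weighted field average over the muscle's
    blob); the logistic runs on ``drive / drive_ref``; subtracting the
    zero-drive floor makes an unstimulated muscle exactly silent, and the
    ``rectify_floor`` (an EMG detection threshold) plus rectification after
    additive Gaussian noise keep fringe responses sparse (exact zeros).
    """
    if thresholds is None:
        lo, hi = config.recruit_threshold_range
        thresholds = np.linspace(lo, hi, len(weight_maps))
    if len(thresholds) != len(weight_maps):
        raise ValueError("thresholds length must match number of weight maps")
    e = efield.grid.astype(np.float64)
    values = np.empty(len(weight_maps))
    for k, (wm, th) in enumerate(zip(weight_maps, thresholds)):
        drive = float(np.sum(wm.grid * e)) / config.drive_ref_vm
        act = _sigmoid(config.recruit_slope * (drive - th))
        floor = _sigmoid(config.recruit_slope * (-th)) + config.rectify_floor
        eps = rng.normal(0.0, config.noise_sd) if config.noise_sd > 0 else 0.0
        values[k] = config.mep_gain_uv * max(0.0, act - floor + eps)
    names = [wm.muscle for wm in weight_maps]
    return MEPVector(values=values, muscle_names=names)


def generate_dataset(config: PhantomConfig) -> StimulationDataset:
    """Full phantom: grid + jittered stimulations at every intensity.

    With ``n_jitter = 0`` and four intensities this yields 49 x 4 = 196
    records. Reproducible given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    mask = make_phantom_mask(config.shape, config.mask_fraction, seed=config.seed)
    weight_maps = make_muscle_weight_maps(
        config.m, mask, seed=config.seed + 1,
        sigma_mm=config.muscle_sigma_mm, voxel_size=config.voxel_size)
    lo, hi = config.recruit_threshold_range
    thresholds = rng.uniform(lo, hi, size=config.m)

    vs = config.voxel_size
    mask_vox = np.argwhere(mask.grid > 0)
    hotspot_xy = mask_vox.mean(axis=0)[:2] * vs
    half = config.grid_extent_mm / 2.0
    offsets = np.arange(-half, half + 1e-9, config.grid_spacing_mm)
    grid_xy = [(hotspot_xy[0] + dx, hotspot_xy[1] + dy)
               for dx in offsets for dy in offsets]

    mask_mm = mask_vox * vs
    records: list[StimulationRecord] = []
    rid = 0
    for intensity in config.intensities:
        jitter_xy = [(hotspot_xy[0] + rng.uniform(-half, half),
                      hotspot_xy[1] + rng.uniform(-half, half))
                     for _ in range(config.n_jitter)]
        for (x, y) in list(grid_xy) + jitter_xy:
            # coil sits a fixed standoff above the nearest cortex in-plane
            d_xy = np.linalg.norm(mask_mm[:, :2] - [x, y], axis=1)
            z_surface = mask_mm[int(np.argmin(d_xy)), 2]
            coil = np.array([x, y, z_surface + config.coil_standoff_mm])
            orientation = 45.0 + rng.normal(0.0, 10.0)
            efield, _fringe = simulate_efield(coil, orientation, intensity,
                                              mask, config)
            mep = simulate_mep(efield, weight_maps, config, rng,
                               thresholds=thresholds)
            records.append(StimulationRecord(
                id=rid, coil_position=coil, coil_orientation=orientation,
                intensity_pct_rmt=int(intensity), efield=efield, mep=mep))
            rid += 1
    return StimulationDataset(records=records, mask=mask)
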