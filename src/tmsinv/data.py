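"""Domain containers, preprocessing, cross-validation and volume/table I/O.

The unit of analysis is a *stimulation*: one TMS pulse at a given coil
position/orientation and intensity, with the simulated cortical E-field volume
it induced and the 15-muscle MEP amplitude vector it evoked. Preprocessing
follows the pipeline used for network training: drop stimulations whose MEPs
are all zero, drop outlier stimulations whose masked peak E-field is below
10 mV/m, then min-max scale (one global divisor for all E-field voxels, one
per-muscle divisor for the MEPs).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: EMG montage of the 15 recorded hand/arm muscles.
DEFAULT_MUSCLES = [
    "FDI", "3DI", "3Lum", "EI", "AbPB", "AdPB", "ADM", "FDM",
    "FCR", "FCU", "FDS", "EDC", "ECR", "ECU", "BRD",
]

LOW_EFIELD_THRESHOLD = 0.010  # V/m; masked-peak outlier cutoff


class EmptyDatasetError(ValueError):
    pass


class DegenerateScalingError(ValueError):
    pass


@dataclass
class CortexMask:
    """Binary motor-cortex (BA4-like) mask; nonzero on ~2% of the box."""

    grid: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        uniq = np.unique(self.grid)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("mask values must be 0/1")

    @property
    def fraction(self) -> float:
        return float(self.grid.mean())

    @property
    def n_voxels(self) -> int:
        return int(self.grid.sum())


@dataclass
class EFieldVolume:
    """Dense nonnegative E-field intensity grid.

    ``grid`` is in V/m before scaling and dimensionless in [0, 1] after;
    ``voxel_size`` is the isotropic edge length in mm.
    """

    grid: np.ndarray
    voxel_size: float = 1.0
    scaled: bool = False

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float32)
        if self.grid.ndim != 3:
            raise ValueError("E-field grid must be 3D")
        if np.any(self.grid < 0):
            raise ValueError("E-field intensities must be nonnegative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape

    def max(self) -> float:
        return float(self.grid.max())


@dataclass
class MEPVector:
    """Peak-to-peak MEP amplitudes for the recorded muscles (uV raw)."""

    values: np.ndarray
    muscle_names: list[str] = field(default_factory=lambda: list(DEFAULT_MUSCLES))
    scaled: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise ValueError("MEP vector must be 1D")
        if len(self.values) != len(self.muscle_names):
            raise ValueError("MEP length does not match muscle names")
        if np.any(self.values < 0):
            raise ValueError("MEP amplitudes must be nonnegative")

    @property
    def m(self) -> int:
        return len(self.values)

    @property
    def n_active(self) -> int:
        return int(np.count_nonzero(self.values))


@dataclass
class StimulationRecord:
    id: int
    coil_position: np.ndarray        # mm, 3-vector
    coil_orientation: float          # degrees
    intensity_pct_rmt: int           # e.g. 110/120/130/140
    efield: EFieldVolume
    mep: MEPVector


@dataclass
class ScalingParams:
    """Min-max divisors: one global E-field max, per-muscle MEP maxima."""

    efield_global_max: float = np.nan
    mep_per_muscle_max: np.ndarray | None = None

    def to_json(self) -> str:
        return json.dumps({
            "efield_global_max": self.efield_global_max,
            "mep_per_muscle_max": (None if self.mep_per_muscle_max is None
                                   else list(map(float, self.mep_per_muscle_max))),
        })

    @classmethod
    def from_json(cls, text: str) -> "ScalingParams":
        d = json.loads(text)
        mx = d["mep_per_muscle_max"]
        return cls(d["efield_global_max"],
                   None if mx is None else np.asarray(mx, dtype=float))


@dataclass
class FoldSplit:
    fold_id: int
    train_ids: list[int]
    test_ids: list[int]


@dataclass
class StimulationDataset:
    """Aligned collection of stimulation records plus mask and scaling metadata."""

    records: list[StimulationRecord]
    mask: CortexMask
    scaling: ScalingParams = field(default_factory=ScalingParams)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def ids(self) -> list[int]:
        return [r.id for r in self.records]

    def subset(self, ids) -> "StimulationDataset":
        wanted = set(ids)
        return StimulationDataset([r for r in self.records if r.id in wanted],
                                  self.mask, self.scaling)

    def mep_matrix(self) -> np.ndarray:
        return np.stack([r.mep.values for r in self.records])

    def efield_array(self) -> np.ndarray:
        return np.stack([r.efield.grid for r in self.records])


# ---------------------------------------------------------------------------
# preprocessing


def filter_zero_mep(dataset: StimulationDataset) -> StimulationDataset:
    """Drop stimulations that evoked no response in any muscle.

    Keeping them would ask the network to invert points in the null space of
    the cortico-motor map.
    """
    if len(dataset) == 0:
        raise EmptyDatasetError("cannot filter an empty dataset")
    kept = [r for r in dataset.records if np.any(r.mep.values != 0)]
    logger.info("zero-MEP filter removed %d of %d records",
                len(dataset) - len(kept), len(dataset))
    return StimulationDataset(kept, dataset.mask, dataset.scaling)


def filter_low_efield(dataset: StimulationDataset,
                      threshold: float = LOW_EFIELD_THRESHOLD) -> StimulationDataset:
    """Drop outlier stimulations whose masked peak E-field is below ``threshold``.

    Applied on raw (V/m) fields; the boundary is retained (strict ``<`` removal).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if len(dataset) == 0:
        raise EmptyDatasetError("cannot filter an empty dataset")
    mask = dataset.mask.grid
    # compare in the grid's dtype so a stored boundary value (e.g. 10 mV/m in
    # float32) is retained, honouring the strict "<" removal rule
    kept = [r for r in dataset.records
            if (r.efield.grid * mask).max()
            >= np.asarray(threshold, dtype=r.efield.grid.dtype)]
    logger.info("low-E-field filter removed %d of %d records",
                len(dataset) - len(kept), len(dataset))
    return StimulationDataset(kept, dataset.mask, dataset.scaling)


def apply_mask(volume: EFieldVolume, mask: CortexMask) -> EFieldVolume:
    if volume.grid.shape != mask.grid.shape:
        raise ValueError(f"shape mismatch: volume {volume.grid.shape} "
                         f"vs mask {mask.grid.shape}")
    return replace(volume, grid=volume.grid * mask.grid.astype(volume.grid.dtype))


def scale_efields(dataset: StimulationDataset
                  ) -> tuple[StimulationDataset, ScalingParams]:
    """Min-max scale all E-fields by the single dataset-wide masked maximum.

    Voxels outside the cortical mask are set to zero; after scaling exactly the
    voxel(s) attaining the global maximum equal 1.
    """
    if len(dataset) == 0:
        raise EmptyDatasetError("cannot scale an empty dataset")
    mask = dataset.mask.grid
    global_max = max(float((r.efield.grid * mask).max()) for r in dataset.records)
    if global_max <= 0:
        raise DegenerateScalingError("all masked E-field voxels are zero")
    records = []
    for r in dataset.records:
        grid = (r.efield.grid * mask) / global_max
        records.append(replace(
            r, efield=replace(r.efield, grid=grid.astype(np.float32), scaled=True)))
    scaling = replace(dataset.scaling, efield_global_max=global_max)
    return StimulationDataset(records, dataset.mask, scaling), scaling


def scale_meps(dataset: StimulationDataset
               ) -> tuple[StimulationDataset, ScalingParams]:
    """Min-max scale each muscle's activations by that muscle's dataset maximum.

    A muscle never active after filtering has an undefined divisor; its entries
    are mapped to zero (with a warning) so the network input width stays fixed.
    """
    if len(dataset) == 0:
        raise EmptyDatasetError("cannot scale an empty dataset")
    mat = dataset.mep_matrix()
    per_muscle_max = mat.max(axis=0)
    silent = per_muscle_max == 0
    if np.any(silent):
        names = [dataset.records[0].mep.muscle_names[i]
                 for i in np.flatnonzero(silent)]
        logger.warning("muscles never active, mapped to zeros: %s", names)
    divisor = np.where(silent, 1.0, per_muscle_max)
    records = []
    for r, row in zip(dataset.records, mat / divisor):
        records.append(replace(
            r, mep=replace(r.mep, values=row, scaled=True)))
    scaling = replace(dataset.scaling, mep_per_muscle_max=per_muscle_max)
    return StimulationDataset(records, dataset.mask, scaling), scaling


def preprocess(dataset: StimulationDataset,
               low_efield_threshold: float = LOW_EFIELD_THRESHOLD
               ) -> tuple[StimulationDataset, ScalingParams]:
    """Full pipeline: zero-MEP filter, low-field filter, then scaling."""
    ds = filter_zero_mep(dataset)
    ds = filter_low_efield(ds, low_efield_threshold)
    ds, _ = scale_efields(ds)
    ds, scaling = scale_meps(ds)
    return ds, scaling


# ---------------------------------------------------------------------------
# stratified cross-validation


def stratified_kfold(dataset: StimulationDataset, k: int = 10,
                     seed: int = 0) -> list[FoldSplit]:
    """Split into k folds preserving the per-intensity distribution.

    Within each intensity stratum the records are shuffled (seeded) and dealt
    round-robin, so per-fold stratum counts differ by at most one. Deterministic
    given the seed.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    rng = np.random.default_rng(seed)
    strata: dict[int, list[int]] = {}
    for r in dataset.records:
        strata.setdefault(r.intensity_pct_rmt, []).append(r.id)
    fold_test: list[list[int]] = [[] for _ in range(k)]
    for intensity in sorted(strata):
        ids = np.array(strata[intensity])
        if len(ids) < k:
            raise ValueError(
                f"stratum {intensity}%RMT has {len(ids)} records, fewer than k={k}")
        rng.shuffle(ids)
        for j, sid in enumerate(ids):
            fold_test[j % k].append(int(sid))
    all_ids = set(dataset.ids())
    splits = []
    for fold_id, test in enumerate(fold_test):
        train = sorted(all_ids - set(test))
        splits.append(FoldSplit(fold_id, train, sorted(test)))
    return splits


# ---------------------------------------------------------------------------
# I/O


def write_volume(volume: EFieldVolume, path, affine: np.ndarray | None = None) -> None:
    if affine is None:
        affine = np.diag([volume.voxel_size] * 3 + [1.0])
    img = nib.Nifti1Image(volume.grid.astype(np.float32), affine)
    nib.save(img, str(path))


def read_volume(path) -> EFieldVolume:
    try:
        img = nib.load(str(path))
    except Exception as exc:  # noqa: BLE001 - re-raise with file context
        raise ValueError(f"cannot parse NIfTI volume {path}: {exc}") from exc
    grid = np.asarray(img.get_fdata(), dtype=np.float32)
    voxel = float(img.header.get_zooms()[0])
    return EFieldVolume(grid=grid, voxel_size=voxel)


def write_mep_table(meps: list[MEPVector], path) -> None:
    df = pd.DataFrame(np.stack([m.values for m in meps]),
                      columns=meps[0].muscle_names)
    df.to_csv(path, index=False, encoding="utf-8")


def read_mep_table(path) -> list[MEPVector]:
    try:
        df = pd.read_csv(path, encoding="utf-8")
    except Exception as exc:  # noqa: BLE001
        raise ValueError(f"cannot parse MEP table {path}: {exc}") from exc
    if df.shape[1] < 1:
        raise ValueError(f"MEP table {path} has no muscle columns")
    names = list(df.columns)
    return [MEPVector(values=row, muscle_names=names)
            for row in df.to_numpy(dtype=np.float64)]


def write_dataset(dataset: StimulationDataset, out_dir) -> None:
    """Persist a dataset: NIfTI volumes + CSV MEP table + JSON manifest."""
    from pathlib import Path
    out = Path(out_dir)
    (out / "efields").mkdir(parents=True, exist_ok=True)
    for r in dataset.records:
        write_volume(r.efield, out / "efields" / f"stim_{r.id:04d}.nii.gz")
    write_volume(EFieldVolume(dataset.mask.grid.astype(np.float32),
                              voxel_size=dataset.records[0].efield.voxel_size),
                 out / "mask.nii.gz")
    write_mep_table([r.mep for r in dataset.records], out / "meps.csv")
    manifest = {
        "records": [{
            "id": r.id,
            "coil_position": list(map(float, r.coil_position)),
            "coil_orientation": float(r.coil_orientation),
            "intensity_pct_rmt": r.intensity_pct_rmt,
            "scaled": bool(r.efield.scaled),
        } for r in dataset.records],
        "scaling": json.loads(dataset.scaling.to_json()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))


def read_dataset(in_dir) -> StimulationDataset:
    from pathlib import Path
    src = Path(in_dir)
    manifest = json.loads((src / "manifest.json").read_text())
    mask_vol = read_volume(src / "mask.nii.gz")
    mask = CortexMask(grid=(mask_vol.grid > 0.5).astype(np.uint8))
    meps = read_mep_table(src / "meps.csv")
    records = []
    for meta, mep in zip(manifest["records"], meps):
        vol = read_volume(src / "efields" / f"stim_{meta['id']:04d}.nii.gz")
        vol.scaled = bool(meta.get("scaled", False))
        records.append(StimulationRecord(
            id=meta["id"],
            coil_position=np.asarray(meta["coil_position"]),
            coil_orientation=meta["coil_orientation"],
            intensity_pct_rmt=meta["intensity_pct_rmt"],
            efield=vol, mep=mep))
    scaling = ScalingParams.from_json(json.dumps(manifest["scaling"]))
    return StimulationDataset(records=records, mask=mask, scaling=scaling)
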