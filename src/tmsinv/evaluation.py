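"""Reconstruction metrics and their aggregation across folds and strata.

Per stimulation: NRMSE (primary) — the root of the squared-norm ratio
``||pred - gt||^2 / ||gt||^2``; R^2 (secondary) — explained variance over the
cortical-mask voxels; centre of gravity (CoG) and the Euclidean CoG error
(tertiary), the standard TMS-mapping outcome. Aggregates report means with
95%-confidence half-widths (1.96 x SEM) over cross-validation fold means, and
stratified views by stimulation intensity and by the muscle-response profile
(number of active muscles, MEP mean/variance).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["EvaluationRecord", "UndefinedMetricError", "nrmse", "r_squared",
           "center_of_gravity", "cog_error", "evaluate_record", "aggregate",
           "stratify_by_intensity", "mep_profile_analysis",
           "mean_volume_baseline"]


class UndefinedMetricError(ValueError):
    """Raised when a metric's denominator is degenerate (e.g. all-zero GT)."""


def nrmse(pred: np.ndarray, gt: np.ndarray, squared: bool = False) -> float:
    """Normalised RMSE: sqrt(||pred - gt||_2^2 / ||gt||_2^2).

    Scale-invariant (the ratio cancels a common positive factor); 0 iff the
    volumes are identical, 1 when predicting all zeros. ``squared=True``
    returns the squared-norm ratio itself.
    """
    pred = np.asarray(pred, dtype=np.float64)
    gt = np.asarray(gt, dtype=np.float64)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {gt.shape}")
    denom = float((gt ** 2).sum())
    if denom == 0.0:
        raise UndefinedMetricError("NRMSE undefined for an all-zero ground truth")
    ratio = float(((pred - gt) ** 2).sum()) / denom
    return ratio if squared else float(np.sqrt(ratio))


def r_squared(pred: np.ndarray, gt: np.ndarray, mask: np.ndarray) -> float:
    """1 - SS_res / SS_tot over the mask voxels (GT mean taken within the mask)."""
    mask = np.asarray(mask) > 0
    if not mask.any():
        raise ValueError("mask is empty")
    p = np.asarray(pred, dtype=np.float64)[mask]
    g = np.asarray(gt, dtype=np.float64)[mask]
    ss_tot = float(((g - g.mean()) ** 2).sum())
    if ss_tot == 0.0:
        raise UndefinedMetricError("R^2 undefined for a constant ground truth")
    return 1.0 - float(((g - p) ** 2).sum()) / ss_tot


def center_of_gravity(volume: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Intensity-weighted mean voxel coordinate over the mask (0-based, x/y/z)."""
    mask = np.asarray(mask) > 0
    v = np.asarray(volume, dtype=np.float64) * mask
    total = v.sum()
    if total <= 0:
        raise UndefinedMetricError("CoG undefined for zero total intensity")
    coords = np.indices(v.shape, dtype=np.float64)
    return np.array([float((c * v).sum() / total) for c in coords])


def cog_error(gt_volume: np.ndarray, pred_volume: np.ndarray,
              mask: np.ndarray) -> float:
    """Euclidean distance between the two CoGs, in voxel units (symmetric)."""
    a = center_of_gravity(gt_volume, mask)
    b = center_of_gravity(pred_volume, mask)
    return float(np.linalg.norm(a - b))


@dataclass
class EvaluationRecord:
    """Per-stimulation metrics plus the stratifiers used in the analyses."""

    stim_id: int
    nrmse: float
    r2: float
    cog_gt: np.ndarray | None
    cog_pred: np.ndarray | None
    cog_error: float | None          # None when either CoG is undefined
    intensity_pct_rmt: int
    mep_mean: float
    mep_variance: float
    n_active_muscles: int
    fold_id: int = 0
    variant: str = ""


def evaluate_record(stim_id: int, pred: np.ndarray, gt: np.ndarray,
                    mask: np.ndarray, mep: np.ndarray, intensity: int,
                    fold_id: int = 0, variant: str = "",
                    active_eps: float = 0.0) -> EvaluationRecord:
    """All three metrics for one stimulation; CoG skipped when degenerate.

    ``active_eps`` is the threshold above which a scaled MEP counts as active
    (exactly 0 for synthetic data, which produces exact zeros).
    """
    cg = cp = None
    err = None
    try:
        cg = center_of_gravity(gt, mask)
        cp = center_of_gravity(pred, mask)
        err = float(np.linalg.norm(cg - cp))
    except UndefinedMetricError:
        pass
    mep = np.asarray(mep, dtype=np.float64)
    return EvaluationRecord(
        stim_id=stim_id,
        nrmse=nrmse(pred, gt),
        r2=r_squared(pred, gt, mask),
        cog_gt=cg, cog_pred=cp, cog_error=err,
        intensity_pct_rmt=int(intensity),
        mep_mean=float(mep.mean()),
        mep_variance=float(mep.var()),
        n_active_muscles=int(np.count_nonzero(mep > active_eps)),
        fold_id=fold_id, variant=variant)


def records_frame(records: list[EvaluationRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "stim_id": r.stim_id, "nrmse": r.nrmse, "r2": r.r2,
        "cog_error": r.cog_error, "intensity_pct_rmt": r.intensity_pct_rmt,
        "mep_mean": r.mep_mean, "mep_variance": r.mep_variance,
        "n_active_muscles": r.n_active_muscles, "fold_id": r.fold_id,
        "variant": r.variant,
    } for r in records])


def aggregate(records: list[EvaluationRecord],
              group_keys: list[str] | None = None,
              unit: str = "fold") -> pd.DataFrame:
    """Mean and 95% half-width (1.96 x SEM) of NRMSE and R^2 per group.

    With ``unit='fold'`` the SEM is computed over cross-validation fold means
    (the headline-table convention); ``unit='record'`` pools stimulations.
    Single-member groups report ``sem95 = 0`` with ``sem_defined = False``.
    """
    df = records_frame(records)
    group_keys = group_keys or ["variant"]
    if unit == "fold":
        df = (df.groupby(group_keys + ["fold_id"], as_index=False)
              [["nrmse", "r2"]].mean())
    rows = []
    for keys, g in df.groupby(group_keys):
        keys = keys if isinstance(keys, tuple) else (keys,)
        n = len(g)
        row = dict(zip(group_keys, keys))
        row["n"] = n
        row["sem_defined"] = n > 1
        for metric in ("nrmse", "r2"):
            vals = g[metric].to_numpy()
            sem = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
            row[f"{metric}_mean"] = float(vals.mean())
            row[f"{metric}_sem"] = sem          # raw SEM
            row[f"{metric}_sem95"] = 1.96 * sem  # 95% half-width
        rows.append(row)
    return pd.DataFrame(rows)


def stratify_by_intensity(records: list[EvaluationRecord]) -> pd.DataFrame:
    """Per-intensity aggregate (the intensity-effects table shape)."""
    return aggregate(records, group_keys=["variant", "intensity_pct_rmt"])


def mep_profile_analysis(records: list[EvaluationRecord]) -> pd.DataFrame:
    """Box-plot summaries of NRMSE per active-muscle count.

    One row per occupied ``n_active_muscles`` bin (empty bins omitted) with
    the median and quartiles; the per-record table is available via
    ``records_frame``.
    """
    df = records_frame(records)
    rows = []
    for n_act, g in df.groupby("n_active_muscles"):
        q1, med, q3 = np.percentile(g["nrmse"], [25, 50, 75])
        rows.append({"n_active_muscles": int(n_act), "n": len(g),
                     "nrmse_median": float(med), "nrmse_q1": float(q1),
                     "nrmse_q3": float(q3),
                     "mep_mean_mean": float(g["mep_mean"].mean()),
                     "mep_variance_mean": float(g["mep_variance"].mean())})
    return pd.DataFrame(rows)


def mean_volume_baseline(train_volumes: np.ndarray) -> np.ndarray:
    """Voxelwise mean of the training volumes — the no-information predictor."""
    return np.asarray(train_volumes, dtype=np.float64).mean(axis=0)
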