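"""Config-driven experiment: simulate -> preprocess -> CV -> train -> report.

Reproduces the study design at a chosen scale: every variant is trained from a
fresh random initialisation on each cross-validation fold's training set (all
applicable stages re-run per fold) and scored on the fold's test set; the
report aggregates per variant (headline-table shape) and per stimulation
intensity, with full seed provenance.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data import StimulationDataset, preprocess, stratified_kfold
from .evaluation import (EvaluationRecord, aggregate, mep_profile_analysis,
                         records_frame, stratify_by_intensity)
from .model import TMSInverseMapping
from .networks import NetworkConfig
from .phantom import PhantomConfig, generate_dataset
from .training import TrainingConfig

logger = logging.getLogger(__name__)

__all__ = ["ExperimentConfig", "ExperimentReport", "run_experiment",
           "compare_variants"]


@dataclass
class ExperimentConfig:
    """Everything one experiment needs; seeds are recorded in the outputs."""

    scale: str = "test"                       # "test" (16^3) or "full" (64^3)
    variants: tuple[str, ...] = ("a", "b", "c", "d", "e")
    phantom: PhantomConfig | None = None
    training: TrainingConfig | None = None
    k_folds: int = 3
    latent_dim: int | None = None
    l1_weight: float = 1e-4
    data_seed: int = 0
    init_seed: int = 100
    fold_seed: int = 7
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.scale not in ("test", "full"):
            raise ValueError("scale must be 'test' or 'full'")
        if self.phantom is None:
            self.phantom = (PhantomConfig.test_scale(seed=self.data_seed)
                            if self.scale == "test"
                            else PhantomConfig(seed=self.data_seed))
        if self.training is None:
            self.training = (TrainingConfig.test_scale(seed=self.init_seed)
                             if self.scale == "test"
                             else TrainingConfig(seed=self.init_seed))

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        """Load an experiment description from a YAML file.

        Top-level keys mirror the dataclass fields; ``phantom`` and
        ``training`` may be nested mappings of the respective config fields.
        """
        import yaml
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "phantom" in raw and isinstance(raw["phantom"], dict):
            ph = raw["phantom"]
            if "shape" in ph:
                ph["shape"] = tuple(ph["shape"])
            if "intensities" in ph:
                ph["intensities"] = tuple(ph["intensities"])
            raw["phantom"] = PhantomConfig(**ph)
        if "training" in raw and isinstance(raw["training"], dict):
            raw["training"] = TrainingConfig(**raw["training"])
        if "variants" in raw:
            raw["variants"] = tuple(raw["variants"])
        return cls(**raw)


@dataclass
class ExperimentReport:
    config: ExperimentConfig
    records: list[EvaluationRecord]
    variant_table: pd.DataFrame
    intensity_table: pd.DataFrame
    profile_table: pd.DataFrame
    fold_sizes: list[tuple[int, int]]
    n_raw: int = 0
    n_preprocessed: int = 0

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        records_frame(self.records).to_csv(out / "records.csv", index=False)
        self.variant_table.to_csv(out / "variants.csv", index=False)
        self.intensity_table.to_csv(out / "intensity.csv", index=False)
        self.profile_table.to_csv(out / "mep_profile.csv", index=False)
        prov = {
            "scale": self.config.scale,
            "variants": list(self.config.variants),
            "k_folds": self.config.k_folds,
            "seeds": {"data": self.config.data_seed,
                      "init": self.config.init_seed,
                      "fold": self.config.fold_seed},
            "n_raw": self.n_raw, "n_preprocessed": self.n_preprocessed,
            "fold_sizes": self.fold_sizes,
        }
        (out / "provenance.json").write_text(json.dumps(prov, indent=1))


def run_experiment(config: ExperimentConfig,
                   dataset: StimulationDataset | None = None
                   ) -> ExperimentReport:
    """Run the full cross-validated comparison of the requested variants.

    ``dataset`` (raw) may be supplied to reuse one phantom across replicates;
    otherwise it is generated from ``config.phantom``.
    """
    raw = dataset if dataset is not None else generate_dataset(config.phantom)
    n_raw = len(raw)
    processed, _ = preprocess(raw)
    logger.info("preprocessing kept %d of %d stimulations", len(processed), n_raw)
    folds = stratified_kfold(processed, k=config.k_folds, seed=config.fold_seed)

    shape = processed.records[0].efield.shape
    records: list[EvaluationRecord] = []
    fold_sizes = []
    for fold in folds:
        train_ds = processed.subset(fold.train_ids)
        test_ds = processed.subset(fold.test_ids)
        fold_sizes.append((len(train_ds), len(test_ds)))
        for variant in config.variants:
            net_cfg = NetworkConfig(
                input_shape=shape, latent_dim=config.latent_dim,
                l1_weight=config.l1_weight,
                seed=config.init_seed + 1000 * fold.fold_id
                     + ord(variant))  # fresh init per (fold, variant)
            train_cfg = config.training
            model = TMSInverseMapping(train_ds, variant=variant,
                                      network_config=net_cfg,
                                      training_config=train_cfg)
            results = model.fit()
            recs = results.evaluate(test_ds, fold_id=fold.fold_id)
            records.extend(recs)
            logger.info("fold %d variant %s: %d test records",
                        fold.fold_id, variant, len(recs))

    variant_table = aggregate(records, group_keys=["variant"])
    intensity_table = stratify_by_intensity(records)
    profile_table = mep_profile_analysis(records)
    report = ExperimentReport(config, records, variant_table,
                              intensity_table, profile_table, fold_sizes,
                              n_raw=n_raw, n_preprocessed=len(processed))
    if config.out_dir:
        report.save(config.out_dir)
    return report


def compare_variants(report: ExperimentReport | pd.DataFrame) -> pd.DataFrame:
    """Rank variants by mean NRMSE (ascending); ties by R^2 (descending),
    then by variant letter. Adds a pairwise win matrix on NRMSE."""
    table = (report.variant_table if isinstance(report, ExperimentReport)
             else report).copy()
    table = table.sort_values(
        by=["nrmse_mean", "r2_mean", "variant"],
        ascending=[True, False, True]).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    wins = {}
    for _, a in table.iterrows():
        wins[a["variant"]] = {
            b["variant"]: bool(a["nrmse_mean"] < b["nrmse_mean"])
            for _, b in table.iterrows() if b["variant"] != a["variant"]}
    table.attrs["win_matrix"] = wins
    return table
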