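"""Model/Results facade over the inverse-mapping pipeline.

``TMSInverseMapping`` is built from a (preprocessed) stimulation dataset and a
variant choice; ``fit()`` runs the variant's training regime and returns a
``TMSInverseMappingResults`` carrying the trained networks, training traces,
and — after ``evaluate()`` — per-stimulation metrics with a ``summary()``
table, in the style of statsmodels' Model/Results split.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import StimulationDataset, preprocess
from .evaluation import (EvaluationRecord, aggregate, evaluate_record,
                         records_frame)
from .networks import ModelVariant, NetworkConfig, assemble_model
from .training import TrainingConfig, TrainingTrace, train_model

__all__ = ["TMSInverseMapping", "TMSInverseMappingResults"]

VARIANT_NAMES = {
    ModelVariant.AE_DECODER: "AE-Decoder",
    ModelVariant.DIRECT_CONV: "Direct Convolutional",
    ModelVariant.VAE_DECODER: "VAE-Decoder",
    ModelVariant.VAE_SAMPLER_DECODER: "VAE-Sampler-Decoder",
    ModelVariant.DIRECT_VARIATIONAL: "Direct Variational",
}


class TMSInverseMapping:
    """Inverse cortico-motor mapping model: MEP vector -> E-field volume.

    Parameters
    ----------
    dataset
        Preprocessed (filtered, scaled, masked) stimulation dataset.
    variant
        One of the five architectures, by letter ("a".."e") or
        :class:`~tmsinv.networks.ModelVariant`.
    network_config, training_config
        Shapes/sizes and optimisation settings; defaults are derived from the
        dataset's volume shape.
    """

    def __init__(self, dataset: StimulationDataset,
                 variant: ModelVariant | str = ModelVariant.DIRECT_VARIATIONAL,
                 network_config: NetworkConfig | None = None,
                 training_config: TrainingConfig | None = None) -> None:
        if len(dataset) == 0:
            raise ValueError("dataset is empty")
        self.dataset = dataset
        self.variant = ModelVariant(variant)
        shape = dataset.records[0].efield.shape
        self.network_config = network_config or NetworkConfig(input_shape=shape)
        if training_config is None:
            # sub-full-scale volumes get the scale-corrected KL weight and a
            # CPU-sized epoch cap; 64^3 keeps the plain objective
            training_config = (TrainingConfig() if shape[0] >= 64
                               else TrainingConfig.test_scale())
        self.training_config = training_config

    @classmethod
    def from_raw(cls, dataset: StimulationDataset, **kwargs
                 ) -> "TMSInverseMapping":
        """Build from a raw dataset, applying the full preprocessing pipeline."""
        processed, _ = preprocess(dataset)
        return cls(processed, **kwargs)

    def fit(self) -> "TMSInverseMappingResults":
        """Train every stage the variant requires and return the results."""
        bundle = assemble_model(self.variant, self.dataset.mask,
                                self.network_config)
        bundle, traces = train_model(bundle, self.dataset, self.training_config)
        return TMSInverseMappingResults(self, bundle, traces)


class TMSInverseMappingResults:
    """Fitted inverse mapping: trained networks, traces, and metrics."""

    def __init__(self, model: TMSInverseMapping, bundle, traces) -> None:
        self.model = model
        self.bundle = bundle
        self.traces: dict[str, TrainingTrace] = traces
        self.records: list[EvaluationRecord] = []

    def predict(self, mep: np.ndarray, n_samples: int = 1) -> np.ndarray:
        return self.bundle.predict(mep, n_samples=n_samples)

    def evaluate(self, test_dataset: StimulationDataset,
                 fold_id: int = 0) -> list[EvaluationRecord]:
        """Score reconstructions on held-out stimulations; appends to records.

        Stimulations with an all-zero ground-truth field are flagged and
        skipped (their metrics are undefined).
        """
        mask = test_dataset.mask.grid
        out: list[EvaluationRecord] = []
        for r in test_dataset.records:
            gt = r.efield.grid
            if float(gt.max()) <= 0:
                continue
            pred = self.bundle.predict(r.mep.values)
            out.append(evaluate_record(
                r.id, pred, gt, mask, r.mep.values, r.intensity_pct_rmt,
                fold_id=fold_id, variant=self.model.variant.value))
        self.records.extend(out)
        return out

    def records_frame(self) -> pd.DataFrame:
        return records_frame(self.records)

    def summary(self) -> str:
        """Plain-text summary: architecture, training, held-out metrics."""
        m = self.model
        lines = [
            "TMS inverse mapping results",
            "=" * 45,
            f"variant:        ({m.variant.value}) {VARIANT_NAMES[m.variant]}",
            f"input volume:   {m.network_config.input_shape}",
            f"latent dim:     {m.network_config.latent_dim}",
            f"n stimulations: {len(m.dataset)}",
        ]
        for stage, trace in self.traces.items():
            final = trace.losses[-1]
            lines.append(
                f"{stage} stage:  {len(trace.losses)} epochs, final loss "
                f"{final.total:.5f} (mse {final.mse_term:.5f}, "
                f"kl {final.kl_term:.5f}, l1 {final.l1_term:.5f})")
        if self.records:
            agg = aggregate(self.records, group_keys=["variant"])
            row = agg.iloc[0]
            lines += [
                "-" * 45,
                f"held-out stimulations: {len(self.records)}",
                f"NRMSE: {row['nrmse_mean']:.3f} +- {row['nrmse_sem95']:.3f}",
                f"R^2:   {row['r2_mean']:.3f} +- {row['r2_sem95']:.3f}",
            ]
        return "\n".join(lines)
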