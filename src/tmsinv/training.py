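"""Two-stage / single-stage training regimes, schedule, freezing, inference.

Two-stage variants (a, c, d) first learn the latent field code by autoencoding
the E-field volumes (forward stage), then freeze the decoder and train the MEP
mapper against it (reverse stage). Single-stage variants (b, e) train mapper
and decoder jointly in one reverse stage. Optimisation is Adadelta (initial
learning rate 1) in mini-batches of 8; when the training loss plateaus for 5
epochs the learning rate is multiplied by 0.7, and after 20 epochs without a
relative improvement of at least 1e-5 training stops. An epoch "improves" when
``loss <= best * (1 - min_improvement)`` — the same criterion drives both the
scheduler and the stopping rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .data import StimulationDataset
from .engine import Adadelta, VariationalSampler
from .losses import LossReport, mse_loss
from .networks import (NetworkBundle, SamplerPipeline,
                       SINGLE_STAGE_VARIANTS, TWO_STAGE_VARIANTS)

__all__ = ["TrainingConfig", "ScheduleState", "TrainingTrace",
           "lr_schedule_step", "early_stop_check", "train_forward_stage",
           "train_reverse_stage", "train_model", "predict", "RegimeError",
           "StageStateError"]


class RegimeError(ValueError):
    """A stage was requested for a variant that does not have it."""


class StageStateError(RuntimeError):
    """Reverse stage requested before the decoder was trained and frozen."""


@dataclass
class TrainingConfig:
    batch_size: int = 8
    learning_rate: float = 1.0
    plateau_patience: int = 5      # epochs of plateau before an lr drop
    plateau_factor: float = 0.7
    stop_patience: int = 20        # stalled epochs before early stop
    min_improvement: float = 1e-5  # relative improvement factor
    max_epochs: int = 500
    kl_weight: float = 1.0         # beta on the KL term (1 = the plain objective)
    mse_per_voxel: bool = False    # per-voxel mean instead of per-sample norms
    seed: int = 0

    def __post_init__(self) -> None:
        if self.plateau_patience <= 0 or self.stop_patience <= 0:
            raise ValueError("patience values must be positive")
        if not 0 < self.plateau_factor < 1:
            raise ValueError("plateau_factor must lie in (0, 1)")

    @classmethod
    def test_scale(cls, **overrides) -> "TrainingConfig":
        """Settings for 16^3 CPU runs.

        The KL term is reweighted by the voxel-count ratio (16/64)^3 so the
        MSE:KL balance of the objective matches the full-scale (64^3) one,
        where both terms enter unweighted; without this, shrinking the volume
        shrinks only the reconstruction term and the posterior collapses.
        """
        kw = dict(max_epochs=50, kl_weight=(16 / 64) ** 3)
        kw.update(overrides)
        return cls(**kw)


@dataclass(frozen=True)
class ScheduleState:
    """Pure state of the plateau scheduler / early-stopping rule."""

    lr: float = 1.0
    best_loss: float = np.inf
    plateau_count: int = 0
    stall_count: int = 0


def lr_schedule_step(state: ScheduleState, epoch_loss: float,
                     config: TrainingConfig | None = None) -> ScheduleState:
    """Advance the scheduler by one epoch; pure function of (state, loss).

    An epoch counts as improved when the loss beats the best seen by the
    relative ``min_improvement`` factor; ``plateau_patience`` consecutive
    non-improving epochs multiply the lr by ``plateau_factor`` and reset the
    plateau counter (the stall counter keeps running for early stopping).
    """
    config = config or TrainingConfig()
    improved = epoch_loss <= state.best_loss * (1.0 - config.min_improvement)
    if improved:
        return replace(state, best_loss=epoch_loss, plateau_count=0,
                       stall_count=0)
    plateau = state.plateau_count + 1
    lr = state.lr
    if plateau >= config.plateau_patience:
        lr *= config.plateau_factor
        plateau = 0
    return replace(state, lr=lr, plateau_count=plateau,
                   stall_count=state.stall_count + 1)


def early_stop_check(state: ScheduleState, epoch_loss: float,
                     config: TrainingConfig | None = None) -> bool:
    """True exactly when the last ``stop_patience`` epochs all stalled.

    ``state`` is the schedule state *after* ``lr_schedule_step`` consumed
    ``epoch_loss``.
    """
    config = config or TrainingConfig()
    del epoch_loss  # already folded into state by lr_schedule_step
    return state.stall_count >= config.stop_patience


@dataclass
class TrainingTrace:
    """Per-epoch loss terms, learning rate and frozen-component checksums."""

    losses: list[LossReport] = field(default_factory=list)
    lrs: list[float] = field(default_factory=list)
    frozen_checksums: dict[str, list[str]] = field(default_factory=dict)
    stopped_epoch: int | None = None

    @property
    def epoch_losses(self) -> list[float]:
        return [l.total for l in self.losses]


def _stage_sampler(bundle: NetworkBundle, stage: str) -> VariationalSampler | None:
    if stage == "forward":
        enc = bundle.encoder
        return enc.sampler if isinstance(enc, SamplerPipeline) else None
    return bundle.sampler


def _run_stage(bundle: NetworkBundle, stage: str, inputs: np.ndarray,
               targets: np.ndarray, config: TrainingConfig) -> TrainingTrace:
    net = bundle.forward_net() if stage == "forward" else bundle.reverse_net()
    sampler = _stage_sampler(bundle, stage)
    if sampler is not None:
        sampler.kl_weight = config.kl_weight
    params = bundle.trainable_params(stage)
    if not params:
        raise StageStateError("no trainable parameters in this stage")
    opt = Adadelta(params, lr=config.learning_rate)
    state = ScheduleState(lr=config.learning_rate)
    trace = TrainingTrace(
        frozen_checksums={n: [] for n, f in bundle.frozen.items() if f})
    n = inputs.shape[0]
    shuffle_rng = np.random.default_rng(config.seed)
    # weights are checkpointed every improving epoch; the kept model is the
    # best-loss one, not whatever the final (possibly unstable) epoch left
    best_loss = np.inf
    best_params = [p.value.copy() for p in params]

    for epoch in range(config.max_epochs):
        net.set_training(True)
        if sampler is not None:
            sampler.sample = True
        order = shuffle_rng.permutation(n)
        sums = np.zeros(3)  # mse, kl, l1 accumulated over batches
        n_batches = 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb, yb = inputs[idx], targets[idx]
            pred = net.forward(xb)
            mse = mse_loss(pred, yb, per_voxel=config.mse_per_voxel)
            kl = sampler.kl_value if sampler is not None else 0.0
            l1 = bundle.mask_layer.l1_value
            denom = pred.size if config.mse_per_voxel else len(idx)
            grad = (2.0 / denom) * (pred - yb).astype(pred.dtype)
            net.backward(grad)
            if bundle.config.l1_on_weights and not bundle.frozen["decoder"]:
                w = bundle.config.l1_weight
                for p in bundle.decoder.params():
                    p.grad += w * np.sign(p.value)
                    l1 += w * float(np.abs(p.value).sum())
            opt.step()
            opt.zero_grad()
            sums += (mse, kl, l1)
            n_batches += 1
        mse_e, kl_e, l1_e = sums / n_batches
        report = LossReport(total=mse_e + kl_e + l1_e, mse_term=mse_e,
                            kl_term=kl_e, l1_term=l1_e)
        trace.losses.append(report)
        for name in trace.frozen_checksums:
            trace.frozen_checksums[name].append(bundle.checksum(name))
        if report.total < best_loss:
            best_loss = report.total
            best_params = [p.value.copy() for p in params]
        state = lr_schedule_step(state, report.total, config)
        opt.lr = state.lr
        trace.lrs.append(state.lr)
        if early_stop_check(state, report.total, config):
            trace.stopped_epoch = epoch
            break
    for p, best in zip(params, best_params):
        p.value[...] = best
    return trace


def _volumes(dataset: StimulationDataset) -> np.ndarray:
    return dataset.efield_array().astype(np.float32)[:, None]


def _meps(dataset: StimulationDataset) -> np.ndarray:
    return dataset.mep_matrix().astype(np.float32)


def train_forward_stage(bundle: NetworkBundle, dataset: StimulationDataset,
                        config: TrainingConfig
                        ) -> tuple[NetworkBundle, TrainingTrace]:
    """Autoencode the masked E-fields; freeze the decoder afterwards.

    Applies to the two-stage variants only (a with plain MSE; c, d with
    MSE + KL). For (d) the learned variational sampler is carried over into
    the reverse path, where it is re-trained.
    """
    if bundle.variant not in TWO_STAGE_VARIANTS:
        raise RegimeError(
            f"variant {bundle.variant.value} is single-stage; it has no "
            "forward (autoencoding) stage")
    vols = _volumes(dataset)
    trace = _run_stage(bundle, "forward", vols, vols, config)
    bundle.freeze("decoder")
    return bundle, trace


def train_reverse_stage(bundle: NetworkBundle, dataset: StimulationDataset,
                        config: TrainingConfig
                        ) -> tuple[NetworkBundle, TrainingTrace]:
    """Train the MEP mapper (and, for single-stage variants, the decoder).

    For a/c/d the decoder must already be trained and frozen; for b/e the
    decoder trains jointly here. The mapper is frozen on completion.
    """
    if bundle.variant in TWO_STAGE_VARIANTS and not bundle.frozen["decoder"]:
        raise StageStateError(
            f"variant {bundle.variant.value} requires a trained, frozen "
            "decoder before the reverse stage")
    trace = _run_stage(bundle, "reverse", _meps(dataset), _volumes(dataset),
                       config)
    bundle.freeze("mapper")
    if bundle.variant in SINGLE_STAGE_VARIANTS:
        bundle.freeze("decoder")
    return bundle, trace


def train_model(bundle: NetworkBundle, dataset: StimulationDataset,
                config: TrainingConfig
                ) -> tuple[NetworkBundle, dict[str, TrainingTrace]]:
    """Run every stage the variant requires, in order."""
    traces: dict[str, TrainingTrace] = {}
    if bundle.variant in TWO_STAGE_VARIANTS:
        bundle, traces["forward"] = train_forward_stage(bundle, dataset, config)
    bundle, traces["reverse"] = train_reverse_stage(bundle, dataset, config)
    return bundle, traces


def predict(bundle: NetworkBundle, mep: np.ndarray,
            n_samples: int = 1) -> np.ndarray:
    """Masked [0, 1] volume reconstructed from one MEP vector (mean inference)."""
    if not bundle.frozen["mapper"]:
        raise StageStateError("reverse stage must complete before inference")
    return bundle.predict(mep, n_samples=n_samples)
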