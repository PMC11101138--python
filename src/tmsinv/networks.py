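"""The five inverse-imaging architectures and their building blocks.

All variants share a convolutional decoder that maps a coarse spatial latent
code (side L/4) back to the full volume (side L), ending in a bounded ReLU so
reconstructions stay in the normalised [0, 1] field range, followed by the
cortical mask. They differ in how the code is produced:

====================  =======================================================
AE_DECODER (a)        two-stage; deterministic conv encoder learns the code by
                      autoencoding, then a convolutional MEP mapper (with
                      batch norm) is trained against the frozen decoder.
DIRECT_CONV (b)       single-stage; the convolutional mapper and the decoder
                      train jointly, no encoder.
VAE_DECODER (c)       two-stage; a variational encoder (Gaussian latent
                      bottleneck) learns the code, then a fully-connected
                      deterministic mapper trains against the frozen decoder.
VAE_SAMPLER_DECODER   two-stage; like (c) but the learned variational sampler
(d)                   is carried over into the reverse path and re-trained
                      on top of the MEP mapper.
DIRECT_VARIATIONAL    single-stage; a variational MEP mapper (posterior
(e)                   conditioned on y) and the decoder train jointly.
====================  =======================================================

Cube sides must be divisible by 4 (two 2x poolings). Encoder channel widths
are 32 then 64 (3^3 kernels) with a final single-channel 1^3 convolution;
the decoder mirrors them (64 then 32).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .data import CortexMask
from .engine import (BatchNorm, BoundedReLU, Conv3d, Flatten, Layer, Linear,
                     MaskLayer, MaxPool3d, Parameter, ReLU, Reshape,
                     Sequential, Upsample3d, VariationalSampler,
                     parameter_checksum)

__all__ = ["ModelVariant", "NetworkConfig", "NetworkBundle", "bounded_relu",
           "reparameterize", "build_encoder", "build_decoder", "build_mapper",
           "assemble_model", "TWO_STAGE_VARIANTS", "SINGLE_STAGE_VARIANTS"]


class ModelVariant(str, Enum):
    AE_DECODER = "a"
    DIRECT_CONV = "b"
    VAE_DECODER = "c"
    VAE_SAMPLER_DECODER = "d"
    DIRECT_VARIATIONAL = "e"


TWO_STAGE_VARIANTS = frozenset({ModelVariant.AE_DECODER,
                                ModelVariant.VAE_DECODER,
                                ModelVariant.VAE_SAMPLER_DECODER})
SINGLE_STAGE_VARIANTS = frozenset({ModelVariant.DIRECT_CONV,
                                   ModelVariant.DIRECT_VARIATIONAL})


def bounded_relu(x):
    """min(1, max(0, x)) elementwise."""
    return np.clip(x, 0.0, 1.0)


def reparameterize(mu: np.ndarray, logvar: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    """z = mu + exp(logvar / 2) * eps, eps ~ N(0, I)."""
    eps = rng.standard_normal(np.shape(mu))
    return mu + np.exp(0.5 * np.asarray(logvar)) * eps


@dataclass
class NetworkConfig:
    """Shapes and sizes of one model instance.

    ``latent_dim`` is the length of the variational code z (tuned by inner CV
    in the original study, not printed; 512 at full scale, 64 at test scale
    are this package's defaults). ``l1_weight`` is the activity-l1 penalty on
    the pre-mask reconstruction.
    """

    input_shape: tuple[int, int, int] = (64, 64, 64)
    m: int = 15
    latent_dim: int | None = None
    mapper_hidden: int = 256
    mapper_conv_channels: int = 16
    l1_weight: float = 1e-4
    l1_on_weights: bool = False  # penalise decoder weights instead of activity
    seed: int = 0

    def __post_init__(self) -> None:
        side = self.input_shape[0]
        if any(s != side for s in self.input_shape):
            raise ValueError("input volumes must be cubes")
        if side % 4 != 0:
            raise ValueError("cube side must be divisible by 4")
        if self.latent_dim is None:
            # 512 at full scale; 8 at test scale, selected by the inner
            # train-validate CV procedure re-run on synthetic data
            self.latent_dim = 512 if side >= 64 else 8

    @property
    def code_side(self) -> int:
        return self.input_shape[0] // 4

    @property
    def code_size(self) -> int:
        return self.code_side ** 3


class SamplerPipeline(Layer):
    """pre-network -> variational sampler -> reshape to the spatial code."""

    def __init__(self, pre: Sequential, sampler: VariationalSampler,
                 code_side: int) -> None:
        self.pre = pre
        self.sampler = sampler
        self.reshape = Reshape((1, code_side, code_side, code_side))

    def params(self) -> list[Parameter]:
        return self.pre.params() + self.sampler.params()

    def set_training(self, flag: bool) -> None:
        self.training = flag
        for sub in (self.pre, self.sampler, self.reshape):
            sub.set_training(flag)

    def set_skip_param_grad(self, flag: bool) -> None:
        self.skip_param_grad = flag
        for sub in (self.pre, self.sampler, self.reshape):
            sub.set_skip_param_grad(flag)

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.reshape.forward(self.sampler.forward(self.pre.forward(x)))

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return self.pre.backward(self.sampler.backward(self.reshape.backward(gy)))

    def encode_distribution(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(mu, logvar) of the Gaussian posterior for input ``x``."""
        h = self.pre.forward(x)
        return self.sampler.mu_layer.forward(h), self.sampler.lv_layer.forward(h)


def build_encoder(input_shape: tuple[int, int, int], variational: bool = False,
                  latent_dim: int = 64, rng: np.random.Generator | None = None,
                  dtype=np.float32) -> Layer:
    """conv32 -> pool -> conv64 -> pool -> conv(1ch, 1^3); code side = L/4.

    With ``variational=True`` the spatial code is flattened into a Gaussian
    latent bottleneck of length ``latent_dim`` (and projected back to the
    code's size so the decoder input is unchanged).
    """
    side = input_shape[0]
    if side % 4 != 0:
        raise ValueError("cube side must be divisible by 4")
    rng = rng or np.random.default_rng()
    convs = Sequential([
        Conv3d(1, 32, 3, rng=rng, dtype=dtype), ReLU(), MaxPool3d(),
        Conv3d(32, 64, 3, rng=rng, dtype=dtype), ReLU(), MaxPool3d(),
        Conv3d(64, 1, 1, rng=rng, dtype=dtype),
    ])
    if not variational:
        return convs
    s3 = (side // 4) ** 3
    pre = Sequential(convs.layers + [Flatten()])
    sampler = VariationalSampler(s3, latent_dim, s3, rng=rng, dtype=dtype)
    return SamplerPipeline(pre, sampler, side // 4)


def build_decoder(code_side: int, output_shape: tuple[int, int, int],
                  rng: np.random.Generator | None = None,
                  dtype=np.float32) -> Sequential:
    """conv64 -> upsample -> conv32 -> upsample -> conv(1ch, 1^3) -> bounded ReLU."""
    if code_side * 4 != output_shape[0]:
        raise ValueError(f"decoder cannot map code side {code_side} "
                         f"to output side {output_shape[0]}")
    rng = rng or np.random.default_rng()
    # small positive output bias: the bounded ReLU has zero gradient at 0, and
    # sparse targets otherwise lock a zero-initialised output at the boundary
    return Sequential([
        Conv3d(1, 64, 3, rng=rng, dtype=dtype), ReLU(), Upsample3d(),
        Conv3d(64, 32, 3, rng=rng, dtype=dtype), ReLU(), Upsample3d(),
        Conv3d(32, 1, 1, rng=rng, dtype=dtype, bias_init=0.1), BoundedReLU(),
    ])


def build_mapper(variant: ModelVariant, m: int, config: NetworkConfig,
                 sampler: VariationalSampler | None = None,
                 rng: np.random.Generator | None = None,
                 dtype=np.float32) -> Layer:
    """MEP vector (length m) -> spatial latent code for the decoder.

    Convolutional mappers (a, b) lift the vector to a 2x-resolution grid and
    convolve/pool it down (batch norm after the convolution); the
    fully-connected mapper (c) is deterministic; variational mappers (d, e)
    end in the Gaussian sampler (for d, the one carried over from the forward
    path).
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    rng = rng or np.random.default_rng()
    s = config.code_side
    hid = config.mapper_hidden
    if variant in (ModelVariant.AE_DECODER, ModelVariant.DIRECT_CONV):
        # three FC layers lift the vector to a 4x-resolution grid; two
        # conv-BN-ReLU-pool sets bring it down to the code resolution
        ch = config.mapper_conv_channels
        return Sequential([
            Linear(m, hid, rng=rng, dtype=dtype), ReLU(),
            Linear(hid, hid, rng=rng, dtype=dtype), ReLU(),
            Linear(hid, (4 * s) ** 3, rng=rng, dtype=dtype),
            Reshape((1, 4 * s, 4 * s, 4 * s)),
            Conv3d(1, ch, 3, rng=rng, dtype=dtype),
            BatchNorm(ch, dtype=dtype), ReLU(), MaxPool3d(),
            Conv3d(ch, ch, 3, rng=rng, dtype=dtype),
            BatchNorm(ch, dtype=dtype), ReLU(), MaxPool3d(),
            Conv3d(ch, 1, 1, rng=rng, dtype=dtype),
        ])
    if variant is ModelVariant.VAE_DECODER:
        return Sequential([
            Linear(m, hid, rng=rng, dtype=dtype), ReLU(),
            Linear(hid, hid, rng=rng, dtype=dtype), ReLU(),
            Linear(hid, s ** 3, rng=rng, dtype=dtype),
            Reshape((1, s, s, s)),
        ])
    if variant in (ModelVariant.VAE_SAMPLER_DECODER,
                   ModelVariant.DIRECT_VARIATIONAL):
        pre = Sequential([
            Linear(m, hid, rng=rng, dtype=dtype), ReLU(),
            Linear(hid, hid, rng=rng, dtype=dtype), ReLU(),
            Linear(hid, s ** 3, rng=rng, dtype=dtype),
        ])
        if sampler is None:
            sampler = VariationalSampler(s ** 3, config.latent_dim, s ** 3,
                                         rng=rng, dtype=dtype)
        return SamplerPipeline(pre, sampler, s)
    raise ValueError(f"unknown variant {variant!r}")


@dataclass
class NetworkBundle:
    """One assembled model: components, frozen-stage bookkeeping, prediction."""

    variant: ModelVariant
    config: NetworkConfig
    encoder: Layer | None
    mapper: Layer
    decoder: Sequential
    mask_layer: MaskLayer
    rng: np.random.Generator
    frozen: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("encoder", "mapper", "decoder"):
            self.frozen.setdefault(name, False)

    @property
    def sampler(self) -> VariationalSampler | None:
        """The variational sampler active on the reverse/inference path."""
        if isinstance(self.mapper, SamplerPipeline):
            return self.mapper.sampler
        return None

    def component(self, name: str) -> Layer | None:
        return {"encoder": self.encoder, "mapper": self.mapper,
                "decoder": self.decoder}[name]

    def forward_net(self) -> Sequential:
        """Autoencoding path X -> code -> X̂ (two-stage variants only)."""
        if self.encoder is None:
            raise ValueError(f"variant {self.variant.value} has no forward "
                             "(autoencoding) path")
        return Sequential([self.encoder, self.decoder, self.mask_layer])

    def reverse_net(self) -> Sequential:
        """Inverse-imaging path y -> code -> X̂ (all variants; inference path)."""
        return Sequential([self.mapper, self.decoder, self.mask_layer])

    def freeze(self, name: str) -> None:
        self.frozen[name] = True
        comp = self.component(name)
        if comp is not None:
            comp.set_skip_param_grad(True)  # grads would never be applied

    def checksum(self, name: str) -> str:
        comp = self.component(name)
        return parameter_checksum(comp.params()) if comp is not None else ""

    def trainable_params(self, stage: str) -> list[Parameter]:
        comps = (["encoder", "decoder"] if stage == "forward"
                 else ["mapper", "decoder"])
        out: list[Parameter] = []
        for name in comps:
            comp = self.component(name)
            if comp is not None and not self.frozen[name]:
                out.extend(comp.params())
        return out

    def set_inference_mode(self, sample: bool = False) -> None:
        net = self.reverse_net()
        net.set_training(False)
        if self.sampler is not None:
            self.sampler.sample = sample

    def predict(self, mep: np.ndarray, n_samples: int = 1) -> np.ndarray:
        """Reconstruct the masked volume for one MEP vector.

        Mean (deterministic) inference by default; ``n_samples > 1`` averages
        Monte-Carlo draws from the variational posterior instead.
        """
        mep = np.asarray(mep, dtype=np.float32).reshape(1, -1)
        if mep.shape[1] != self.config.m:
            raise ValueError(f"expected MEP of length {self.config.m}")
        net = self.reverse_net()
        net.set_training(False)
        sampler = self.sampler
        if sampler is not None and n_samples > 1:
            sampler.sample = True
            vols = [net.forward(mep)[0, 0] for _ in range(n_samples)]
            sampler.sample = False
            return np.mean(vols, axis=0)
        if sampler is not None:
            sampler.sample = False
        return net.forward(mep)[0, 0]


def assemble_model(variant: ModelVariant | str, mask: CortexMask,
                   config: NetworkConfig) -> NetworkBundle:
    """Wire the components for one of the five variants.

    Two-stage variants (a, c, d) get an encoder for the autoencoding forward
    stage; (d) shares its variational sampler between the forward and reverse
    paths. Single-stage variants (b, e) have no encoder. Weights are
    Glorot-uniform from ``config.seed``.
    """
    variant = ModelVariant(variant)
    rng = np.random.default_rng(config.seed)
    side = config.input_shape[0]
    decoder = build_decoder(config.code_side, config.input_shape, rng=rng)
    activity_l1 = 0.0 if config.l1_on_weights else config.l1_weight
    mask_layer = MaskLayer(mask.grid[None, None], l1_weight=activity_l1)

    encoder: Layer | None = None
    sampler = None
    if variant is ModelVariant.AE_DECODER:
        encoder = build_encoder(config.input_shape, variational=False, rng=rng)
    elif variant in (ModelVariant.VAE_DECODER, ModelVariant.VAE_SAMPLER_DECODER):
        encoder = build_encoder(config.input_shape, variational=True,
                                latent_dim=config.latent_dim, rng=rng)
        if variant is ModelVariant.VAE_SAMPLER_DECODER:
            sampler = encoder.sampler  # carried over into the reverse path
    mapper = build_mapper(variant, config.m, config, sampler=sampler, rng=rng)
    return NetworkBundle(variant=variant, config=config, encoder=encoder,
                         mapper=mapper, decoder=decoder, mask_layer=mask_layer,
                         rng=rng)


def save_bundle(bundle: NetworkBundle, out_dir) -> None:
    """Checkpoint: JSON manifest + one weight blob per component."""
    import json
    from pathlib import Path
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "variant": bundle.variant.value,
        "input_shape": list(bundle.config.input_shape),
        "m": bundle.config.m,
        "latent_dim": bundle.config.latent_dim,
        "mapper_hidden": bundle.config.mapper_hidden,
        "mapper_conv_channels": bundle.config.mapper_conv_channels,
        "l1_weight": bundle.config.l1_weight,
        "seed": bundle.config.seed,
        "frozen": bundle.frozen,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    for name in ("encoder", "mapper", "decoder"):
        comp = bundle.component(name)
        if comp is not None:
            arrays = {f"p{i}": p.value for i, p in enumerate(comp.params())}
            np.savez(out / f"{name}.npz", **arrays)


def load_bundle(in_dir, mask: CortexMask) -> NetworkBundle:
    """Rebuild a bundle from a checkpoint directory (inverse of save_bundle)."""
    import json
    from pathlib import Path
    src = Path(in_dir)
    try:
        manifest = json.loads((src / "manifest.json").read_text())
    except Exception as exc:  # noqa: BLE001
        raise ValueError(f"corrupted checkpoint {src}: {exc}") from exc
    cfg = NetworkConfig(
        input_shape=tuple(manifest["input_shape"]), m=manifest["m"],
        latent_dim=manifest["latent_dim"],
        mapper_hidden=manifest["mapper_hidden"],
        mapper_conv_channels=manifest["mapper_conv_channels"],
        l1_weight=manifest["l1_weight"], seed=manifest["seed"])
    bundle = assemble_model(manifest["variant"], mask, cfg)
    for name in ("encoder", "mapper", "decoder"):
        comp = bundle.component(name)
        if comp is None:
            continue
        path = src / f"{name}.npz"
        if not path.exists():
            raise ValueError(f"corrupted checkpoint: missing {path.name}")
        blobs = np.load(path)
        params = comp.params()
        if len(blobs.files) != len(params):
            raise ValueError(f"corrupted checkpoint: {name} parameter count "
                             f"mismatch ({len(blobs.files)} != {len(params)})")
        for i, p in enumerate(params):
            p.value[...] = blobs[f"p{i}"]
    bundle.frozen.update(manifest["frozen"])
    return bundle
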