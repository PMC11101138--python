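# Methods

## The inverse-imaging model

A TMS pulse at coil position/orientation **c** and intensity *I* (in %RMT)
induces a cortical E-field volume X̃ ∈ ℝ^(l×l×l) (nonzero only inside the
binary motor-cortex mask) and evokes a 15-muscle MEP vector ỹ. The forward
map is modelled as ỹ = f(X̃) + ε with white Gaussian residuals; the package
estimates the inverse f⁻¹: ỹ → X̂ with five 3D convolutional architectures
that share a decoder and differ in how the latent code z (interpreted as the
subject's cortico-motor mapping) is produced:

* **(a) AE-Decoder** — two-stage: a deterministic conv encoder/decoder is
  trained to autoencode E-fields (loss L₁ = MSE + l1); the decoder is then
  frozen and a convolutional MEP mapper (batch-normalised) is trained to hit
  its code (L₁).
* **(b) Direct Convolutional** — the same mapper and decoder trained jointly
  in a single stage (L₁), no encoder.
* **(c) VAE-Decoder** — forward stage is a variational autoencoder
  (L₂ = MSE + KL[Q(z|X)‖N(0,I)]); reverse stage trains a fully-connected
  deterministic mapper against the frozen decoder (L₁).
* **(d) VAE-Sampler-Decoder** — like (c), but the learned Gaussian sampler is
  carried over into the reverse path and re-trained on top of the mapper
  (L₂ in both stages).
* **(e) Direct Variational** — single stage: a variational MEP mapper
  (posterior Q(z|y)) and the decoder train jointly with
  L₃ = MSE + KL[Q(z|y)‖N(0,I)].

Shared geometry: encoder = two (3³ conv → ReLU → 2³ max-pool) blocks with 32
then 64 channels plus a single-channel 1³ conv, so a cube of side L yields a
spatial code of side L/4; the decoder mirrors it (64, 32 channels,
nearest-neighbour 2× upsampling) and ends in a bounded ReLU
(min(1, max(0, x))) so reconstructions live in the min-max-scaled [0, 1]
range, followed by multiplication with the cortical mask. Mappers use three
fully-connected layers; the convolutional mappers (a, b) additionally lift to
a 4×-resolution grid and apply two conv–batchnorm–ReLU–pool blocks. The
variational bottleneck flattens the code, emits (μ, log σ²) of length *n*,
samples z = μ + σ⊙ε, and projects back to the code size.

The MSE follows the per-sample squared-norm convention,
(1/N)Σᵢ‖X̂ᵢ−X̃ᵢ‖₂², and the KL term is batch-averaged to match; an l1
activity penalty (weight 10⁻⁴) on the pre-mask reconstruction encourages the
sparsity the masked volumes have. A per-voxel-mean MSE and a weight-l1
variant are available as config switches.

## Training regime

Adadelta (initial learning rate 1, ρ = 0.95, ε = 10⁻⁶) on mini-batches of 8,
reshuffled each epoch from the run seed. An epoch *improves* when the
training loss beats the best seen by a relative 10⁻⁵; five consecutive
non-improving epochs multiply the learning rate by 0.7, twenty stop training.
Weights are checkpointed at every improving epoch and the best-loss weights
are restored at the end of a stage, so a late unstable epoch cannot degrade
the kept model. After the forward stage the decoder is frozen (bit-identical
thereafter, audited by SHA-256 checksums every epoch); after the reverse
stage the mapper is frozen and the model is ready for inference. Inference
uses the posterior mean (deterministic); Monte-Carlo averaging over posterior
samples is available.

Numerical choices worth knowing:

* **Bounded-ReLU boundary gradient.** The exact gradient of min(1, max(0, x))
  is zero outside (0, 1); with sparse targets the whole output can saturate
  at 0 early in training, leaving no gradient at all (a dead end we observed
  reproducibly). The backward pass therefore passes the gradient through a
  saturated unit only when it would pull the unit back into the active range
  (a straight-through subgradient); it equals the exact gradient everywhere
  else. The decoder's output bias starts at 0.1 for the same reason.
* **Variational stability.** log σ² is clamped to ±10 (gradient masked
  outside), and the log-variance head's bias starts at −5 so early sampling
  noise does not drown the signal path.
* **KL weight at reduced scale.** The objectives are used unweighted
  (β = 1) at the full 64³ scale. The reconstruction term scales with voxel
  count while the KL term does not, so at the 16³ test scale the balance of
  the full-scale objective is preserved by weighting KL with the voxel-count
  ratio (16/64)³ = 1/64 (`TrainingConfig.test_scale`). Without this the
  posterior collapses and the variational variants degenerate to constant
  outputs.
* **Latent length n.** Not derivable from first principles; chosen by the
  inner train-validate cross-validation procedure (lowest validation NRMSE)
  re-run on synthetic data: n = 512 at full scale, n = 8 at test scale.
* **Pooling geometry.** Pool/upsample windows are 2³ with stride 2 — the
  only choice consistent with the stated inter-block dimensions
  (64 → 32 → 16).

## Synthetic phantom

The generator emulates the statistical structure of a TMS motor-mapping
session without any subject data:

* **Mask**: a curved-ribbon tube around a smooth seeded centerline,
  flattened along z, thresholded at the distance quantile matching the target
  fraction (2% of the box at 64³, 5% at 16³ where 2% would be too few voxels
  to be connected); single connected component by construction.
* **Fields**: E(v) = A·s(I)·exp(−d(v)²/2σ²)·(1 + γ|cos θ|) on mask voxels,
  where d(v) is the voxel-to-coil distance (mm), s(I) = (I−100)/40 rises
  linearly over 110–140 %RMT, and θ is the angle between coil orientation and
  the local ribbon tangent (PCA of nearby mask voxels; the absolute value
  resolves the tangent's sign ambiguity). A = 0.2 V/m, σ = 12 mm, coil
  standoff 10 mm: masked peaks span roughly 4–250 mV/m, deliberately
  straddling the 10 mV/m outlier-filter threshold. Coils farther than 45 mm
  from the mask induce no field (fringe stimulations).
* **Stimulation design**: one pulse per vertex of a 7×7 grid (1 cm spacing,
  6×6 cm) centred on the mask centroid, at each intensity, plus optional
  jittered extras — 196 records by default. Physical extent is fixed at
  64 mm, so the voxel size grows at reduced grid sizes (4 mm at 16³).
* **Recruitment**: muscle k's drive is ⟨w_k, E⟩ with w_k a normalised
  Gaussian blob (σ = 8 mm) centred at one of 15 distinct, overlapping sites
  spread along the ribbon. MEP_k = G·max(0, sig(4(d/d₀ − θ_k)) − floor_k + ε)
  with d₀ = 0.02 V/m, per-muscle thresholds θ_k ~ U(0.8, 2.5), gain
  G = 800 µV, noise ε ~ N(0, 0.02) and floor_k = sig(−4θ_k) + 0.04 (the last
  term an EMG detection floor). Zero drive maps to exactly zero; fringe
  stimulations yield sparse or all-zero MEP vectors (≈12% all-zero at
  default settings), and MEP mean/variance rise with intensity.

What the phantom does **not** emulate: anatomically realistic BA4 geometry
and field physics (no FEM), EMG cross-talk, inter-subject variability,
session drift. Passing tests on the phantom therefore demonstrate that the
pipeline recovers fields whose forward map matches its generative
assumptions — not clinical-grade accuracy on real data.

## Evaluation

Per stimulation: NRMSE = sqrt(‖X̂−X̃‖₂²/‖X̃‖₂²) (the squared-ratio form is
available behind a flag), R² over mask voxels with the ground-truth mean
taken within the mask, and the CoG error — the Euclidean distance between
intensity-weighted mean voxel coordinates (0-based voxel units; multiply by
the voxel size for mm). Records with an all-zero ground truth are flagged
and excluded; an all-zero prediction leaves the CoG error undefined for that
record. Aggregates report mean ± 1.96·SEM over cross-validation fold means
(per-record pooling available), stratified by variant, intensity, and
active-muscle count ("active" = scaled MEP > 0 exactly, as the generator
produces exact zeros; real-data mode exposes an ε threshold).

## Scaled-down study sizes

CPU-sized defaults used by the tests and the acceptance script: 16³ volumes,
196 stimulations, 2–3 cross-validation folds, 30–50 epochs, latent 8. These
sizes were chosen so a full variant comparison runs in minutes on one core
while every qualitative behaviour of interest (baseline-beating recovery,
worse errors at sparse muscle activation, the Direct Variational model's
edge over the AE-Decoder) is expressed; the 64³ full-scale configuration is
available through the same configs.

## Known limitations

* The optimiser follows the Adadelta-with-plateau-schedule recipe; at tiny
  scales it converges slowly, so capped-epoch runs are not at the true
  plateau.
* Variant ordering between closely matched architectures is noisy at test
  scale; only the a-vs-e contrast is stable enough to assert across seeds.
* The engine is single-threaded numpy; full-scale (64³) training is feasible
  but slow (hours, not minutes).
* CoG error is reported in voxel units by default; remember the 4 mm voxels
  at test scale when comparing to mm-scale numbers.
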