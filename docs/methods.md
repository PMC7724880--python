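# Methods

## Problem and data model

The supervision signal is a binary association matrix R (m drugs × n
diseases) under the implicit-feedback convention: R_ij = 1 is a verified
association, R_ij = 0 means *unverified* — absent evidence, not evidence of
absence. Side-information enters as two symmetric similarity matrices with
values in [0, 1] and unit diagonal (drug–drug, e.g. from chemical
fingerprints; disease–disease, e.g. from phenotype text mining). How the
similarities were computed is deliberately out of scope: they are opaque
inputs, validated only for symmetry, range and id alignment.

## Model

Scoring a pair (i, j) combines:

1. **Neighborhood path.** N(j) = drugs with a known association to disease
   j, target drug excluded to prevent label leakage (at inference N(j) is
   taken from the *training* positives). Preferences are inner products of
   latent drug factors, attention weights are their softmax, and the
   representation o_ij pools trainable per-drug memory vectors c_n. The
   memory dimension is independent of the latent dimension. An empty N(j)
   yields o_ij = 0, so the predictor degrades to the latent path alone —
   exactly what the cold-start scenario needs.
2. **Latent path.** One denoising autoencoder per side encodes the
   association row/column together with the similarity row into a latent
   factor, and decodes back to both spaces. Corruption is masking noise
   (each input entry zeroed independently with probability ρ);
   reconstruction targets are always the clean inputs. Masking is the
   standard corruption for sparse binary rows, and ρ = 0 recovers a plain
   autoencoder for ablation.
3. **Fusion.** σ(η hᵀ(drug_i ⊙ disease_j) + (1−η) Wᵀ o_ij + b). η = 1
   ignores the memory entirely, η = 0 ignores the factor interaction; both
   identities are asserted by tests.

The joint objective is L = L_r + φ L_d + ψ L_p: summed binary cross-entropy
over training pairs plus the two autoencoder losses

    L_d = Σ_i α‖s_i − ŝ_i‖² + (1−α)‖sim_i − sim̂_i‖² + λ Σ‖weights‖² ,

and its disease mirror with β, δ. The L2 penalty covers the four weight
matrices of each side (encoder W₁, V₁ and both decoder heads W₂, V₂);
biases are unregularized.

## Parameters and defaults

| parameter | meaning | default | note |
|---|---|---|---|
| `latent_dim` (d) | latent factor dimension | 64 | searched in {16…256} |
| `memory_dim` (l) | memory vector dimension | 64 | independent of d; searched in {16…256} |
| `eta` (η) | latent vs neighborhood balance | 0.7 | best-performing reported value |
| `alpha`, `beta` | association vs similarity reconstruction balance | 0.5 | searched in {0.1…0.9} |
| `lambda`, `delta` | per-side L2 weight | 0.001 | smallest grid value; least distorting |
| `phi`, `psi` (φ, ψ) | autoencoder-loss weights in the total objective | 0.1 | keeps the prediction loss dominant |
| `mask_rate` (ρ) | input corruption probability | 0.3 | standard denoising level |
| `neg_ratio` | sampled negatives per positive, per epoch | 1 | standard implicit-feedback practice |
| `learning_rate` | Adam step size | 0.001 | from the grid {0.0001, 0.001, 0.05, 0.01} |
| `epochs` / `batch_size` | optimization length / minibatch | 100 / 256 | |

`grid_search` enumerates the full default grids (112 500 configurations)
or any subset, selecting by validation metric with ties broken by the
earliest configuration in lexicographic key order.

## Training procedure

Adam (β₁ = 0.9, β₂ = 0.999) on analytically derived gradients of the full
objective — attention softmax, memory pooling, both autoencoders and the
fusion layer are differentiated by hand and verified against central finite
differences to 1e−5 relative. Each epoch: resample negatives (uniformly
without replacement from the zero cells, seeded by (seed, epoch)), redraw
corruption masks, shuffle, sweep minibatches. Every minibatch step combines
that batch's prediction loss with the *full* autoencoder losses, which act
as a per-step regularizer; the per-epoch trace records the full objective
on the epoch's complete batch after its updates. Training is joint from the
start (no autoencoder pretraining phase). With a validation set, early
stopping monitors validation AUC with patience 10 and restores the best
parameters.

Numerical choices: the prediction loss is computed from logits via
softplus, so it cannot overflow; standalone score-space BCE clips scores to
[1e−12, 1 − 1e−12]; softmax subtracts the row maximum; weights initialize
from N(0, 0.1²) (the memory table likewise) and biases at zero, all from a
seeded generator. Run single-threaded, training is bit-deterministic in the
seed.

A pair sampled as a training negative in some epoch may also serve as a
test negative under the evaluation protocol below — unavoidable when test
negatives are *all* unverified pairs; the overlap is a property of the
protocol, not a leak of test positives.

## Evaluation protocols

* **Ten-fold CV** partitions the positive *pairs* (not drugs) into
  near-equal seeded folds; test negatives are all zero cells. AUC uses the
  midrank convention for ties; AUPR is the step-wise sum Σ (R_k − R_{k−1})
  P_k over descending score thresholds with equal scores grouped; HR@k
  ranks each held-out positive among *all* diseases unassociated with its
  drug in training (full ranking — deterministic and stricter than sampled
  candidate lists), ties broken by ascending disease index.
* **Cold start** moves every singleton drug's only association to the test
  set and zeroes its row, emulating a drug with no usable history.

## Synthetic data

The generator plants nonnegative factors U (m × r) and V (n × r) (absolute
Gaussians, so cosine similarities are naturally in [0, 1]), scores pairs by
row-normalized UVᵀ, and marks exactly round(sparsity · m · n) top-scoring
pairs as associations — deterministic thresholding, so realized sparsity is
exact and the true scores separate positives perfectly. Similarities are
cosine matrices of the same factors plus symmetric N(0, sd²) noise
(default sd 0.05), clipped to [0, 1] with the diagonal reset to 1. The
cold-start variant post-edits rows so an exact number of drugs are
singletons and no other drug is.

This emulates the structural assumptions the model itself makes ("similar
drugs treat similar diseases", low-rank global structure). It does **not**
emulate the provenance noise of real similarity measures, the skewed degree
distributions of curated association databases, or biases in which pairs
get verified; passing tests therefore demonstrate correct mechanics and
recoverability of planted structure, not clinical performance. Benchmark
results on the published datasets require downloading those datasets and
are not reproduced here.

Reference problem sizes used by the test suite and the acceptance script —
200 drugs × 100 diseases at rank 8 and sparsity 0.05 for cross-validation
and cold start — were chosen as the smallest instances on which the planted
structure is comfortably recoverable while keeping a full 10-fold run
cheap on one CPU.

## Known limitations

* Test negatives equal *all* unverified pairs, so AUPR values are small by
  construction under realistic sparsity; compare models, not absolute
  AUPR, in that regime.
* The memory is defined only over drugs in the neighbor role; there is no
  symmetric disease-side memory.
* Neighbor sets are not capped; diseases with very many known drugs make
  the attention flat and the per-pair cost linear in |N(j)|.
* One encoding layer and two decoding heads per side; stacked encoders are
  out of scope.
* The CLI's `predict` requires ids present at training time; truly unseen
  entities need retraining with their similarity rows included.
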