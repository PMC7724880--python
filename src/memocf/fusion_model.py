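"""Fused neighborhood + latent-factor predictor and its joint training.

The predicted association probability of a pair (drug i, disease j) is

    r^_ij = F_out( eta * h.T (drug_i (*) disease_j)
                   + (1 - eta) * W.T o_ij + b )

where drug_i / disease_j are the autoencoder latent factors, (*) is the
elementwise product, o_ij is the attention-pooled memory representation of
disease j's neighbor drugs, and eta in [0, 1] balances the latent-factor
path against the neighborhood path (eta=1 ignores the memory, eta=0 ignores
the factors).  Training minimizes the joint objective

    L = L_r + phi * L_d + psi * L_p

with L_r the binary cross-entropy over known positives plus sampled
negatives and L_d / L_p the drug / disease denoising-autoencoder losses.

Gradients of the whole objective are derived analytically and applied with
Adam; the implementation is plain numpy and, run single-threaded, is fully
deterministic for a given seed.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .dataset_io import (
    AssociationMatrix,
    DatasetBundle,
    SimilarityMatrix,
    validate_dataset,
)
from .latent_autoencoder import (
    ACTIVATIONS,
    AELossWeights,
    AutoencoderParams,
    _sigmoid,
)
from .neighborhood_memory import (
    MemoryTable,
    attention_weights,
    neighbor_set,
    neighborhood_representation,
    preference_scores,
)

__all__ = [
    "FusionParams",
    "TrainingConfig",
    "Architecture",
    "TrainingBatch",
    "TrainedModel",
    "TrainingError",
    "DEFAULT_GRIDS",
    "predict_score",
    "predict_scores",
    "bce_loss",
    "total_loss",
    "sample_negatives",
    "init_model",
    "train",
    "loss_and_grads",
    "grid_search",
    "grid_size",
    "save_model",
    "load_model",
]

_SCORE_CLIP = 1e-12


class TrainingError(RuntimeError):
    """Raised when optimization produces a non-finite loss."""


@dataclass
class FusionParams:
    """Output-layer parameters h, W, b and the balance weight eta."""

    h: np.ndarray
    w_out: np.ndarray
    b_out: np.ndarray  # length-1 array so the optimizer can update in place
    eta: float = 0.7
    out_activation: str = "sigmoid"

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=float)
        self.w_out = np.asarray(self.w_out, dtype=float)
        self.b_out = np.atleast_1d(np.asarray(self.b_out, dtype=float))
        if not 0.0 <= self.eta <= 1.0:
            raise ValueError("eta must lie in [0, 1]")
        if self.out_activation != "sigmoid":
            raise ValueError("only the logistic output activation is supported")


@dataclass(frozen=True)
class Architecture:
    """Dimensions and activations of the network."""

    latent_dim: int = 64
    memory_dim: int = 64
    eta: float = 0.7
    activation_enc: str = "relu"
    activation_dec: str = "sigmoid"


@dataclass(frozen=True)
class TrainingConfig:
    """Joint-objective weights and optimization settings.

    ``phi``/``psi`` weight the drug/disease autoencoder losses in the total
    objective; ``neg_ratio`` negatives are sampled per positive, afresh each
    epoch; corruption uses ``mask_rate``.  ``patience`` only applies when a
    validation set is passed to :func:`train` (early stopping on validation
    AUC).
    """

    ae_weights: AELossWeights = field(default_factory=AELossWeights)
    phi: float = 0.1
    psi: float = 0.1
    neg_ratio: int = 1
    learning_rate: float = 0.001
    epochs: int = 100
    seed: int = 0
    batch_size: int = 256
    mask_rate: float = 0.3
    patience: int = 10

    def __post_init__(self) -> None:
        if self.phi < 0 or self.psi < 0:
            raise ValueError("phi and psi must be nonnegative")
        if self.neg_ratio <= 0:
            raise ValueError("neg_ratio must be a positive integer")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs <= 0:
            raise ValueError("epochs must be positive")
        if self.seed < 0:
            raise ValueError("seed must be nonnegative")
        if not 0.0 <= self.mask_rate <= 1.0:
            raise ValueError("mask_rate must lie in [0, 1]")


@dataclass
class TrainingBatch:
    """Index-aligned drug/disease/label arrays for a set of training pairs."""

    drug_idx: np.ndarray
    disease_idx: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.drug_idx = np.asarray(self.drug_idx, dtype=int)
        self.disease_idx = np.asarray(self.disease_idx, dtype=int)
        self.labels = np.asarray(self.labels, dtype=float)
        if not (len(self.drug_idx) == len(self.disease_idx) == len(self.labels)):
            raise ValueError("batch arrays must have equal length")
        if self.labels.size and not np.isin(self.labels, (0.0, 1.0)).all():
            raise ValueError("labels must be binary")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def pairs(self) -> List[Tuple[int, int, int]]:
        return [
            (int(i), int(j), int(r))
            for i, j, r in zip(self.drug_idx, self.disease_idx, self.labels)
        ]

    @classmethod
    def concat(cls, a: "TrainingBatch", b: "TrainingBatch") -> "TrainingBatch":
        return cls(
            np.concatenate([a.drug_idx, b.drug_idx]),
            np.concatenate([a.disease_idx, b.disease_idx]),
            np.concatenate([a.labels, b.labels]),
        )


@dataclass
class TrainedModel:
    """All parameters plus the frozen training associations (neighbor source).

    ``drug_latents`` / ``disease_latents`` cache the clean-input latent
    factors so inference does not re-encode every call; they are refreshed
    from the stored similarity matrices whenever parameters change.
    """

    drug_ae: AutoencoderParams
    disease_ae: AutoencoderParams
    memory: MemoryTable
    fusion: FusionParams
    training_associations: AssociationMatrix
    drug_sim: SimilarityMatrix
    disease_sim: SimilarityMatrix
    drug_latents: Optional[np.ndarray] = None
    disease_latents: Optional[np.ndarray] = None

    def refresh_latents(self) -> None:
        """Recompute cached latent factors from clean (uncorrupted) inputs."""
        r = np.asarray(self.training_associations.values, dtype=float)
        g_dr = ACTIVATIONS[self.drug_ae.activation_enc][0]
        g_di = ACTIVATIONS[self.disease_ae.activation_enc][0]
        self.drug_latents = g_dr(
            r @ self.drug_ae.W1.T
            + self.drug_sim.values @ self.drug_ae.V1.T
            + self.drug_ae.b_enc
        )
        self.disease_latents = g_di(
            r.T @ self.disease_ae.W1.T
            + self.disease_sim.values @ self.disease_ae.V1.T
            + self.disease_ae.b_enc
        )


# ---------------------------------------------------------------------------
# parameter plumbing

_AE_FIELDS = ("W1", "V1", "b_enc", "W2", "b_rec_assoc", "V2", "b_rec_sim")


def _param_items(model: TrainedModel) -> List[Tuple[str, np.ndarray]]:
    items: List[Tuple[str, np.ndarray]] = []
    for prefix, ae in (("dr", model.drug_ae), ("di", model.disease_ae)):
        for name in _AE_FIELDS:
            items.append((f"{prefix}.{name}", getattr(ae, name)))
    items.append(("mem", model.memory.values))
    items.append(("fus.h", model.fusion.h))
    items.append(("fus.w_out", model.fusion.w_out))
    items.append(("fus.b_out", model.fusion.b_out))
    return items


class _Adam:
    """Adaptive-moment gradient descent, updating parameter arrays in place."""

    def __init__(self, params: Sequence[np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: Sequence[np.ndarray]) -> None:
        self.t += 1
        bc1 = 1.0 - self.beta1 ** self.t
        bc2 = 1.0 - self.beta2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


@dataclass
class _TrainData:
    r: np.ndarray  # (m, n) float copy of the associations
    drug_sim: np.ndarray
    disease_sim: np.ndarray
    nbrs: List[np.ndarray]  # per disease: sorted drug indices with R[i, j] = 1


def _prepare_data(bundle: DatasetBundle) -> _TrainData:
    r = np.asarray(bundle.associations.values, dtype=float)
    nbrs = [np.flatnonzero(r[:, j]) for j in range(r.shape[1])]
    return _TrainData(r, bundle.drug_sim.values, bundle.disease_sim.values, nbrs)


def _neighbor_segments(nbrs, ib, jb):
    """Flatten per-pair neighbor sets (target drug excluded) for vector ops."""
    flat, pair_of_seg, lengths = [], [], []
    for t in range(len(ib)):
        nb = nbrs[jb[t]]
        pos = np.searchsorted(nb, ib[t])
        if pos < len(nb) and nb[pos] == ib[t]:
            nb = np.delete(nb, pos)
        if len(nb):
            flat.append(nb)
            pair_of_seg.append(t)
            lengths.append(len(nb))
    if not flat:
        return None
    lengths = np.asarray(lengths)
    starts = np.concatenate([[0], np.cumsum(lengths)[:-1]])
    pair_of_seg = np.asarray(pair_of_seg)
    seg_pos = np.repeat(np.arange(len(lengths)), lengths)
    return np.concatenate(flat), starts, seg_pos, pair_of_seg[seg_pos], pair_of_seg


def _batch_neighborhood(z, memory, nbrs, ib, jb, want_backward=False):
    """Attention-pooled memory vectors for a batch of pairs (vectorized)."""
    b = len(ib)
    o = np.zeros((b, memory.shape[1]))
    seg = _neighbor_segments(nbrs, ib, jb)
    if seg is None:
        return o, None
    flat_nbr, starts, seg_pos, seg_pair, pair_of_seg = seg
    p_flat = np.einsum("ij,ij->i", z[flat_nbr], z[ib[seg_pair]])
    mx = np.maximum.reduceat(p_flat, starts)
    e = np.exp(p_flat - mx[seg_pos])
    denom = np.add.reduceat(e, starts)
    q_flat = e / denom[seg_pos]
    o_seg = np.add.reduceat(q_flat[:, None] * memory[flat_nbr], starts, axis=0)
    o[pair_of_seg] = o_seg
    cache = (flat_nbr, starts, seg_pos, seg_pair, pair_of_seg, q_flat)
    return o, cache


# ---------------------------------------------------------------------------
# objective and gradients


def loss_and_grads(
    model: TrainedModel,
    data: _TrainData,
    batch: TrainingBatch,
    cfg: TrainingConfig,
    masks: Optional[Dict[str, np.ndarray]] = None,
    want_grads: bool = True,
):
    """Full joint objective L_r + phi L_d + psi L_p and its analytic gradients.

    ``masks`` holds the epoch's corruption masks (1 = keep); ``None`` means
    no corruption.  Returns ``(loss, parts, grads, scores)`` where ``parts``
    is a dict with the three components and ``grads`` maps parameter names
    (as in the internal parameter list) to arrays, or ``None`` when
    ``want_grads`` is false.
    """
    dr, di, fus = model.drug_ae, model.disease_ae, model.fusion
    mem = model.memory.values
    eta = fus.eta
    w = cfg.ae_weights
    r, dsim, psim = data.r, data.drug_sim, data.disease_sim

    def mk(key, base):
        return base if masks is None else base * masks[key]

    s_dr, sim_dr = mk("dr_s", r), mk("dr_sim", dsim)
    s_di, sim_di = mk("di_s", r.T), mk("di_sim", psim)

    g_enc_dr, dg_enc_dr = ACTIVATIONS[dr.activation_enc]
    f_dec_dr, df_dec_dr = ACTIVATIONS[dr.activation_dec]
    g_enc_di, dg_enc_di = ACTIVATIONS[di.activation_enc]
    f_dec_di, df_dec_di = ACTIVATIONS[di.activation_dec]

    a_dr = s_dr @ dr.W1.T + sim_dr @ dr.V1.T + dr.b_enc
    z = g_enc_dr(a_dr)
    p2_dr = z @ dr.W2.T + dr.b_rec_assoc
    shat_dr = f_dec_dr(p2_dr)
    p3_dr = z @ dr.V2.T + dr.b_rec_sim
    simhat_dr = f_dec_dr(p3_dr)

    a_di = s_di @ di.W1.T + sim_di @ di.V1.T + di.b_enc
    u = g_enc_di(a_di)
    p2_di = u @ di.W2.T + di.b_rec_assoc
    shat_di = f_dec_di(p2_di)
    p3_di = u @ di.V2.T + di.b_rec_sim
    simhat_di = f_dec_di(p3_di)

    def sq(x):
        return float((x ** 2).sum())

    ld = (
        w.alpha * sq(shat_dr - r)
        + (1.0 - w.alpha) * sq(simhat_dr - dsim)
        + w.lam * (sq(dr.W1) + sq(dr.V1) + sq(dr.W2) + sq(dr.V2))
    )
    lp = (
        w.beta * sq(shat_di - r.T)
        + (1.0 - w.beta) * sq(simhat_di - psim)
        + w.delta * (sq(di.W1) + sq(di.V1) + sq(di.W2) + sq(di.V2))
    )

    ib, jb, rb = batch.drug_idx, batch.disease_idx, batch.labels
    zi, uj = z[ib], u[jb]
    lat = (zi * uj) @ fus.h
    o, cache = _batch_neighborhood(z, mem, data.nbrs, ib, jb)
    logit = eta * lat + (1.0 - eta) * (o @ fus.w_out) + fus.b_out[0]
    scores = _sigmoid(logit)
    lr_loss = float(np.logaddexp(0.0, logit).sum() - (rb * logit).sum())
    loss = lr_loss + cfg.phi * ld + cfg.psi * lp
    parts = {"prediction": lr_loss, "drug_ae": ld, "disease_ae": lp}
    if not want_grads:
        return loss, parts, None, scores

    grads = {name: np.zeros_like(arr) for name, arr in _param_items(model)}
    g = scores - rb
    grads["fus.b_out"][0] = g.sum()
    grads["fus.h"][:] = eta * (g[:, None] * zi * uj).sum(axis=0)
    grads["fus.w_out"][:] = (1.0 - eta) * (g[:, None] * o).sum(axis=0)
    dz = np.zeros_like(z)
    du = np.zeros_like(u)
    np.add.at(dz, ib, (eta * g)[:, None] * (fus.h * uj))
    np.add.at(du, jb, (eta * g)[:, None] * (fus.h * zi))

    if cache is not None:
        flat_nbr, starts, seg_pos, seg_pair, pair_of_seg, q_flat = cache
        d_o_seg = ((1.0 - eta) * g[pair_of_seg])[:, None] * fus.w_out
        d_o_flat = d_o_seg[seg_pos]
        np.add.at(grads["mem"], flat_nbr, q_flat[:, None] * d_o_flat)
        d_q = (mem[flat_nbr] * d_o_flat).sum(axis=1)
        sdot = np.add.reduceat(q_flat * d_q, starts)
        d_p = q_flat * (d_q - sdot[seg_pos])
        per_seg = np.add.reduceat(d_p[:, None] * z[flat_nbr], starts, axis=0)
        np.add.at(dz, ib[pair_of_seg], per_seg)
        np.add.at(dz, flat_nbr, d_p[:, None] * z[ib[seg_pair]])

    # drug-side autoencoder backward (scaled by phi)
    dshat = (cfg.phi * 2.0 * w.alpha) * (shat_dr - r)
    dp2 = dshat * df_dec_dr(p2_dr, shat_dr)
    grads["dr.W2"][:] = dp2.T @ z + (cfg.phi * 2.0 * w.lam) * dr.W2
    grads["dr.b_rec_assoc"][:] = dp2.sum(axis=0)
    dsimhat = (cfg.phi * 2.0 * (1.0 - w.alpha)) * (simhat_dr - dsim)
    dp3 = dsimhat * df_dec_dr(p3_dr, simhat_dr)
    grads["dr.V2"][:] = dp3.T @ z + (cfg.phi * 2.0 * w.lam) * dr.V2
    grads["dr.b_rec_sim"][:] = dp3.sum(axis=0)
    dz += dp2 @ dr.W2 + dp3 @ dr.V2
    da = dz * dg_enc_dr(a_dr, z)
    grads["dr.W1"][:] = da.T @ s_dr + (cfg.phi * 2.0 * w.lam) * dr.W1
    grads["dr.V1"][:] = da.T @ sim_dr + (cfg.phi * 2.0 * w.lam) * dr.V1
    grads["dr.b_enc"][:] = da.sum(axis=0)

    # disease-side autoencoder backward (scaled by psi)
    dshat = (cfg.psi * 2.0 * w.beta) * (shat_di - r.T)
    dp2 = dshat * df_dec_di(p2_di, shat_di)
    grads["di.W2"][:] = dp2.T @ u + (cfg.psi * 2.0 * w.delta) * di.W2
    grads["di.b_rec_assoc"][:] = dp2.sum(axis=0)
    dsimhat = (cfg.psi * 2.0 * (1.0 - w.beta)) * (simhat_di - psim)
    dp3 = dsimhat * df_dec_di(p3_di, simhat_di)
    grads["di.V2"][:] = dp3.T @ u + (cfg.psi * 2.0 * w.delta) * di.V2
    grads["di.b_rec_sim"][:] = dp3.sum(axis=0)
    du += dp2 @ di.W2 + dp3 @ di.V2
    da = du * dg_enc_di(a_di, u)
    grads["di.W1"][:] = da.T @ s_di + (cfg.psi * 2.0 * w.delta) * di.W1
    grads["di.V1"][:] = da.T @ sim_di + (cfg.psi * 2.0 * w.delta) * di.V1
    grads["di.b_enc"][:] = da.sum(axis=0)

    return loss, parts, grads, scores


# ---------------------------------------------------------------------------
# losses exposed as standalone operations


def bce_loss(batch: Union[TrainingBatch, np.ndarray], scores: np.ndarray) -> float:
    """Summed binary cross-entropy, with scores clipped away from {0, 1}."""
    labels = batch.labels if isinstance(batch, TrainingBatch) else np.asarray(batch, float)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have equal length")
    s = np.clip(scores, _SCORE_CLIP, 1.0 - _SCORE_CLIP)
    return float(-(labels * np.log(s) + (1.0 - labels) * np.log(1.0 - s)).sum())


def total_loss(bce: float, drug_ae_loss: float, disease_ae_loss: float,
               cfg: TrainingConfig) -> float:
    """Joint objective L = L_r + phi * L_d + psi * L_p."""
    return float(bce + cfg.phi * drug_ae_loss + cfg.psi * disease_ae_loss)


def sample_negatives(
    a: AssociationMatrix, neg_ratio: int, seed: int, epoch: int = 0
) -> TrainingBatch:
    """Uniform sample (without replacement) of unobserved pairs as negatives.

    The sample is deterministic given ``(seed, epoch)``, so resampling each
    epoch is reproducible.
    """
    if neg_ratio <= 0:
        raise ValueError("neg_ratio must be positive")
    zeros = np.argwhere(a.values == 0)
    k = neg_ratio * a.n_associations
    if k > len(zeros):
        raise ValueError(
            f"cannot sample {k} negatives from {len(zeros)} unobserved pairs"
        )
    rng = np.random.default_rng(np.random.SeedSequence([seed, epoch, 7919]))
    sel = rng.choice(len(zeros), size=k, replace=False)
    return TrainingBatch(zeros[sel, 0], zeros[sel, 1], np.zeros(k))


# ---------------------------------------------------------------------------
# prediction


def predict_score(model: TrainedModel, drug_i: int, disease_j: int) -> float:
    """Score one pair by explicit composition of the three modules."""
    a = model.training_associations
    if not 0 <= drug_i < a.n_drugs:
        raise IndexError(f"drug index {drug_i} out of range")
    if not 0 <= disease_j < a.n_diseases:
        raise IndexError(f"disease index {disease_j} out of range")
    if model.drug_latents is None or model.disease_latents is None:
        model.refresh_latents()
    z = model.drug_latents[drug_i]
    uj = model.disease_latents[disease_j]
    nbrs = neighbor_set(a, disease_j, exclude_drug=drug_i)
    if len(nbrs):
        p = preference_scores(z, model.drug_latents[nbrs])
        q = attention_weights(p)
        o = neighborhood_representation(q, model.memory.values[nbrs]).values
    else:
        o = np.zeros(model.memory.l_mem)
    fus = model.fusion
    logit = (
        fus.eta * float(fus.h @ (z * uj))
        + (1.0 - fus.eta) * float(fus.w_out @ o)
        + float(fus.b_out[0])
    )
    return float(_sigmoid(np.asarray(logit)))


def predict_scores(
    model: TrainedModel, drug_idx: np.ndarray, disease_idx: np.ndarray
) -> np.ndarray:
    """Vectorized scores for many pairs (same model as :func:`predict_score`)."""
    if model.drug_latents is None or model.disease_latents is None:
        model.refresh_latents()
    ib = np.asarray(drug_idx, dtype=int)
    jb = np.asarray(disease_idx, dtype=int)
    z, u, fus = model.drug_latents, model.disease_latents, model.fusion
    nbrs = [
        np.flatnonzero(model.training_associations.values[:, j])
        for j in range(model.training_associations.n_diseases)
    ]
    lat = (z[ib] * u[jb]) @ fus.h
    o, _ = _batch_neighborhood(z, model.memory.values, nbrs, ib, jb)
    logit = fus.eta * lat + (1.0 - fus.eta) * (o @ fus.w_out) + fus.b_out[0]
    return _sigmoid(logit)


# ---------------------------------------------------------------------------
# training


def init_model(
    bundle: DatasetBundle, arch: Optional[Architecture] = None, seed: int = 0
) -> TrainedModel:
    """Seeded Gaussian initialization (sd 0.1 weights, zero biases)."""
    arch = arch or Architecture()
    a = bundle.associations
    m, n = a.n_drugs, a.n_diseases
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0]))
    drug_ae = AutoencoderParams.initialize(
        n, m, arch.latent_dim, rng, arch.activation_enc, arch.activation_dec
    )
    disease_ae = AutoencoderParams.initialize(
        m, n, arch.latent_dim, rng, arch.activation_enc, arch.activation_dec
    )
    memory = MemoryTable.initialize(m, arch.memory_dim, rng)
    fusion = FusionParams(
        h=rng.normal(0.0, 0.1, size=arch.latent_dim),
        w_out=rng.normal(0.0, 0.1, size=arch.memory_dim),
        b_out=np.zeros(1),
        eta=arch.eta,
    )
    model = TrainedModel(
        drug_ae, disease_ae, memory, fusion, a, bundle.drug_sim, bundle.disease_sim
    )
    model.refresh_latents()
    return model


def _draw_masks(rng: np.random.Generator, rate: float, m: int, n: int):
    if rate == 0.0:
        return None
    return {
        "dr_s": (rng.random((m, n)) >= rate).astype(float),
        "dr_sim": (rng.random((m, m)) >= rate).astype(float),
        "di_s": (rng.random((n, m)) >= rate).astype(float),
        "di_sim": (rng.random((n, n)) >= rate).astype(float),
    }


def _rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    # midrank AUC; local copy to keep the evaluation module import-free here
    from scipy.stats import rankdata

    pos = labels > 0.5
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    ranks = rankdata(scores)
    return (ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def train(
    bundle: DatasetBundle,
    arch: Optional[Architecture] = None,
    cfg: Optional[TrainingConfig] = None,
    validation: Optional[Tuple[np.ndarray, np.ndarray]] = None,
) -> Tuple[TrainedModel, List[float]]:
    """Jointly train autoencoders, memory and fusion layer; returns loss trace.

    Each epoch resamples ``neg_ratio`` negatives per positive and fresh
    corruption masks, then sweeps shuffled minibatches with Adam; every
    update combines the minibatch prediction loss with the full
    side-information losses.  The trace records the full epoch objective
    after each epoch's updates.  With ``validation=(pairs, labels)`` training
    stops early when validation AUC has not improved for ``cfg.patience``
    epochs and the best parameters are restored.  Deterministic for a fixed
    ``cfg.seed`` (single-threaded).
    """
    arch = arch or Architecture()
    cfg = cfg or TrainingConfig()
    problems = validate_dataset(bundle)
    if problems:
        raise ValueError(f"invalid dataset bundle: {problems}")
    a = bundle.associations
    if a.n_associations == 0:
        raise ValueError("training requires at least one known association")

    data = _prepare_data(bundle)
    model = init_model(bundle, arch, cfg.seed)
    items = _param_items(model)
    opt = _Adam([arr for _, arr in items], lr=cfg.learning_rate)
    pos = np.argwhere(a.values == 1)
    m, n = a.n_drugs, a.n_diseases

    trace: List[float] = []
    best_auc, best_state, since_best = -np.inf, None, 0
    for epoch in range(cfg.epochs):
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, epoch + 1]))
        negs = sample_negatives(a, cfg.neg_ratio, cfg.seed, epoch)
        ib = np.concatenate([pos[:, 0], negs.drug_idx])
        jb = np.concatenate([pos[:, 1], negs.disease_idx])
        rb = np.concatenate([np.ones(len(pos)), negs.labels])
        perm = rng.permutation(len(ib))
        ib, jb, rb = ib[perm], jb[perm], rb[perm]
        masks = _draw_masks(rng, cfg.mask_rate, m, n)

        bs = cfg.batch_size or len(ib)
        for start in range(0, len(ib), bs):
            sl = slice(start, start + bs)
            batch = TrainingBatch(ib[sl], jb[sl], rb[sl])
            loss, _, grads, _ = loss_and_grads(model, data, batch, cfg, masks)
            if not np.isfinite(loss):
                raise TrainingError(f"non-finite loss at epoch {epoch}")
            opt.step([grads[name] for name, _ in items])

        epoch_batch = TrainingBatch(ib, jb, rb)
        epoch_loss, _, _, _ = loss_and_grads(
            model, data, epoch_batch, cfg, masks, want_grads=False
        )
        if not np.isfinite(epoch_loss):
            raise TrainingError(f"non-finite loss at epoch {epoch}")
        trace.append(float(epoch_loss))

        if validation is not None:
            model.refresh_latents()
            val_pairs, val_labels = validation
            val_scores = predict_scores(model, val_pairs[:, 0], val_pairs[:, 1])
            val_auc = _rank_auc(val_scores, np.asarray(val_labels, dtype=float))
            if val_auc > best_auc:
                best_auc, since_best = val_auc, 0
                best_state = [arr.copy() for _, arr in items]
            else:
                since_best += 1
                if since_best >= cfg.patience:
                    break

    if best_state is not None:
        for (_, arr), saved in zip(items, best_state):
            arr[:] = saved
    model.refresh_latents()
    return model, trace


# ---------------------------------------------------------------------------
# grid search

#: search grids used when none are supplied
DEFAULT_GRIDS: Dict[str, List] = {
    "memory_dim": [16, 32, 64, 128, 256],
    "latent_dim": [16, 32, 64, 128, 256],
    "eta": [0.1, 0.3, 0.5, 0.7, 0.9],
    "alpha": [0.1, 0.3, 0.5, 0.7, 0.9],
    "beta": [0.1, 0.3, 0.5, 0.7, 0.9],
    "lambda": [0.1, 0.01, 0.001],
    "delta": [0.1, 0.01, 0.001],
    "lr": [0.0001, 0.001, 0.05, 0.01],
}

_ARCH_KEYS = {"latent_dim", "memory_dim", "eta", "activation_enc", "activation_dec"}
_WEIGHT_KEYS = {"alpha": "alpha", "beta": "beta", "lambda": "lam", "delta": "delta"}
_CFG_KEYS = {
    "lr": "learning_rate",
    "phi": "phi",
    "psi": "psi",
    "neg_ratio": "neg_ratio",
    "epochs": "epochs",
    "batch_size": "batch_size",
    "mask_rate": "mask_rate",
}


def apply_config(
    arch: Architecture, cfg: TrainingConfig, conf: Dict
) -> Tuple[Architecture, TrainingConfig]:
    """Overlay a flat config dict (external key names) onto arch + cfg."""
    arch_kw = {k: v for k, v in conf.items() if k in _ARCH_KEYS}
    if arch_kw:
        arch = replace(arch, **arch_kw)
    w_kw = {_WEIGHT_KEYS[k]: v for k, v in conf.items() if k in _WEIGHT_KEYS}
    if w_kw:
        cfg = replace(cfg, ae_weights=replace(cfg.ae_weights, **w_kw))
    c_kw = {_CFG_KEYS[k]: v for k, v in conf.items() if k in _CFG_KEYS}
    if c_kw:
        cfg = replace(cfg, **c_kw)
    known = _ARCH_KEYS | set(_WEIGHT_KEYS) | set(_CFG_KEYS) | {"seed"}
    unknown = set(conf) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "seed" in conf:
        cfg = replace(cfg, seed=conf["seed"])
    return arch, cfg


def grid_size(grids: Dict[str, List]) -> int:
    """Cardinality of the Cartesian product of the grids."""
    size = 1
    for v in grids.values():
        size *= len(v)
    return size


def grid_search(
    bundle: DatasetBundle,
    grids: Optional[Dict[str, List]] = None,
    validation_split=None,
    metric: Union[str, Callable] = "auc",
    arch: Optional[Architecture] = None,
    cfg: Optional[TrainingConfig] = None,
    max_configs: Optional[int] = None,
    seed: int = 0,
):
    """Exhaustive (optionally subsampled) search over hyperparameter grids.

    ``validation_split`` must expose ``train_positives``, ``test_positives``
    and ``test_negatives`` as (k, 2) index arrays; each candidate config is
    trained on the split's training associations and scored on the held-out
    pairs.  ``metric`` is ``"auc"`` or a callable ``(model, split) -> float``.
    Ties are broken in favor of the earliest configuration in lexicographic
    key order.  Returns ``(best_config, results)``.
    """
    grids = grids if grids is not None else DEFAULT_GRIDS
    if not grids or any(len(v) == 0 for v in grids.values()):
        raise ValueError("grids must be nonempty")
    if validation_split is None:
        raise ValueError("grid_search requires a validation split")
    arch = arch or Architecture()
    cfg = cfg or TrainingConfig()

    a = bundle.associations
    train_vals = np.zeros_like(a.values)
    tp = np.asarray(validation_split.train_positives, dtype=int)
    train_vals[tp[:, 0], tp[:, 1]] = 1
    train_assoc = AssociationMatrix(train_vals, a.drug_ids, a.disease_ids)
    train_bundle = DatasetBundle(train_assoc, bundle.drug_sim, bundle.disease_sim)

    test_pos = np.asarray(validation_split.test_positives, dtype=int)
    test_neg = np.asarray(validation_split.test_negatives, dtype=int)
    val_pairs = np.concatenate([test_pos, test_neg])
    val_labels = np.concatenate([np.ones(len(test_pos)), np.zeros(len(test_neg))])

    keys = sorted(grids)
    configs = [dict(zip(keys, combo)) for combo in itertools.product(*(grids[k] for k in keys))]
    if max_configs is not None and max_configs < len(configs):
        rng = np.random.default_rng(seed)
        pick = np.sort(rng.choice(len(configs), size=max_configs, replace=False))
        configs = [configs[int(i)] for i in pick]

    results = []
    best_conf, best_val = None, -np.inf
    for conf in configs:
        c_arch, c_cfg = apply_config(arch, cfg, conf)
        model, _ = train(train_bundle, c_arch, c_cfg)
        if callable(metric):
            value = float(metric(model, validation_split))
        elif metric == "auc":
            scores = predict_scores(model, val_pairs[:, 0], val_pairs[:, 1])
            value = _rank_auc(scores, val_labels)
        else:
            raise ValueError(f"unknown metric {metric!r}")
        results.append({**conf, "metric": value})
        if value > best_val:
            best_val, best_conf = value, conf
    return best_conf, results


# ---------------------------------------------------------------------------
# model archive (directory of text matrices + JSON manifest)


def save_model(model: TrainedModel, directory: Union[str, Path]) -> None:
    """Write every parameter matrix as CSV plus a JSON manifest of scalars."""
    from .dataset_io import write_matrix

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, arr in _param_items(model):
        np.savetxt(directory / f"{name.replace('.', '_')}.csv", np.atleast_2d(arr),
                   delimiter=",")
    # MatrixMarket keeps shape and id order even for drugs with no edges
    write_matrix(model.training_associations, directory / "associations.mtx", "mtx")
    write_matrix(model.drug_sim, directory / "drug_sim.csv")
    write_matrix(model.disease_sim, directory / "disease_sim.csv")
    manifest = {
        "eta": model.fusion.eta,
        "out_activation": model.fusion.out_activation,
        "activation_enc": model.drug_ae.activation_enc,
        "activation_dec": model.drug_ae.activation_dec,
        "latent_dim": model.drug_ae.d,
        "memory_dim": model.memory.l_mem,
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def load_model(directory: Union[str, Path]) -> TrainedModel:
    """Read a model archive written by :func:`save_model`."""
    from .dataset_io import read_association_edges, read_similarity_matrix

    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())

    def arr(name, shape=None):
        x = np.loadtxt(directory / f"{name.replace('.', '_')}.csv", delimiter=",",
                       ndmin=2)
        return x.ravel() if shape == "vec" else x

    assoc = read_association_edges(directory / "associations.mtx", "mtx")
    drug_sim = read_similarity_matrix(directory / "drug_sim.csv", "drug")
    disease_sim = read_similarity_matrix(directory / "disease_sim.csv", "disease")

    def ae(prefix):
        return AutoencoderParams(
            W1=arr(f"{prefix}.W1"),
            V1=arr(f"{prefix}.V1"),
            b_enc=arr(f"{prefix}.b_enc", "vec"),
            W2=arr(f"{prefix}.W2"),
            b_rec_assoc=arr(f"{prefix}.b_rec_assoc", "vec"),
            V2=arr(f"{prefix}.V2"),
            b_rec_sim=arr(f"{prefix}.b_rec_sim", "vec"),
            activation_enc=manifest["activation_enc"],
            activation_dec=manifest["activation_dec"],
        )

    fusion = FusionParams(
        h=arr("fus.h", "vec"),
        w_out=arr("fus.w_out", "vec"),
        b_out=arr("fus.b_out", "vec"),
        eta=manifest["eta"],
        out_activation=manifest["out_activation"],
    )
    model = TrainedModel(
        ae("dr"), ae("di"), MemoryTable(arr("mem")), fusion,
        assoc, drug_sim, disease_sim,
    )
    model.refresh_latents()
    return model
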