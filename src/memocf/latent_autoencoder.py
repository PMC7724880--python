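"""Denoising autoencoders extracting drug and disease latent factors.

Each side (drug, disease) owns one autoencoder with a single encoding layer
and two decoding heads.  The drug encoder consumes the drug's association
row s_i (over diseases) together with its similarity row (over drugs):

    drug_i  = g(W1 s~_i + V1 sim~_i + b_enc)
    s^_i    = f(W2 drug_i + b_rec_assoc)        # association head
    sim^_i  = f(V2 drug_i + b_rec_sim)          # similarity head

with corrupted inputs (tilde) during training and clean reconstruction
targets.  The disease side mirrors this with association columns and the
disease similarity matrix.  Corruption is dropout-style masking: each entry
is independently zeroed with probability ``mask_rate``; mask_rate 0 recovers
a plain autoencoder.  The per-side loss balances the two reconstruction
residuals with a weight in [0, 1] and L2-regularizes the four weight
matrices (biases are not regularized).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, Tuple

import numpy as np

__all__ = [
    "ACTIVATIONS",
    "AutoencoderParams",
    "CorruptionConfig",
    "AELossWeights",
    "corrupt",
    "encode",
    "decode_association",
    "decode_similarity",
    "ae_loss",
]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


# name -> (f, f' as a function of (pre-activation, output))
ACTIVATIONS: Dict[str, Tuple[Callable, Callable]] = {
    "relu": (lambda x: np.maximum(x, 0.0), lambda x, y: (x > 0).astype(float)),
    "identity": (lambda x: np.asarray(x, dtype=float), lambda x, y: np.ones_like(x)),
    "sigmoid": (_sigmoid, lambda x, y: y * (1.0 - y)),
    "tanh": (np.tanh, lambda x, y: 1.0 - y * y),
}


@dataclass
class AutoencoderParams:
    """Weights of one side's encoder and its two decoder heads.

    Shapes for the drug side with m drugs, n diseases, latent dimension d:
    W1 (d, n), V1 (d, m), b_enc (d,), W2 (n, d), b_rec_assoc (n,),
    V2 (m, d), b_rec_sim (m,).  The disease side swaps m and n.
    """

    W1: np.ndarray
    V1: np.ndarray
    b_enc: np.ndarray
    W2: np.ndarray
    b_rec_assoc: np.ndarray
    V2: np.ndarray
    b_rec_sim: np.ndarray
    activation_enc: str = "relu"
    activation_dec: str = "sigmoid"

    def __post_init__(self) -> None:
        for name in ("W1", "V1", "b_enc", "W2", "b_rec_assoc", "V2", "b_rec_sim"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        d = self.W1.shape[0]
        if not (
            self.V1.shape[0] == d
            and self.b_enc.shape == (d,)
            and self.W2.shape == (self.b_rec_assoc.shape[0], d)
            and self.V2.shape == (self.b_rec_sim.shape[0], d)
        ):
            raise ValueError("autoencoder parameter shapes are mutually inconsistent")
        for act in (self.activation_enc, self.activation_dec):
            if act not in ACTIVATIONS:
                raise ValueError(f"unknown activation {act!r}")

    @property
    def d(self) -> int:
        return self.W1.shape[0]

    @classmethod
    def initialize(
        cls,
        assoc_len: int,
        sim_len: int,
        d: int,
        rng: np.random.Generator,
        activation_enc: str = "relu",
        activation_dec: str = "sigmoid",
        scale: float = 0.1,
    ) -> "AutoencoderParams":
        return cls(
            W1=rng.normal(0.0, scale, size=(d, assoc_len)),
            V1=rng.normal(0.0, scale, size=(d, sim_len)),
            b_enc=np.zeros(d),
            W2=rng.normal(0.0, scale, size=(assoc_len, d)),
            b_rec_assoc=np.zeros(assoc_len),
            V2=rng.normal(0.0, scale, size=(sim_len, d)),
            b_rec_sim=np.zeros(sim_len),
            activation_enc=activation_enc,
            activation_dec=activation_dec,
        )


@dataclass(frozen=True)
class CorruptionConfig:
    """Masking-noise configuration: zero each entry with probability mask_rate."""

    mask_rate: float
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mask_rate <= 1.0:
            raise ValueError("mask_rate must lie in [0, 1]")


@dataclass(frozen=True)
class AELossWeights:
    """Balance and regularization weights of the two autoencoder losses.

    ``alpha``/``beta`` trade association-row against similarity-row
    reconstruction on the drug/disease side; ``lam``/``delta`` scale the
    L2 penalty on that side's four weight matrices.
    """

    alpha: float = 0.5
    beta: float = 0.5
    lam: float = 0.001
    delta: float = 0.001

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError("beta must lie in [0, 1]")
        if self.lam < 0 or self.delta < 0:
            raise ValueError("regularization weights must be nonnegative")


def corrupt(x: np.ndarray, cfg: CorruptionConfig) -> np.ndarray:
    """Dropout-style corruption; deterministic under a fixed seed."""
    x = np.asarray(x, dtype=float)
    rng = np.random.default_rng(cfg.seed)
    mask = rng.random(x.shape) >= cfg.mask_rate
    return x * mask


def encode(
    s_tilde: np.ndarray, sim_tilde: np.ndarray, p: AutoencoderParams
) -> np.ndarray:
    """Latent factor g(W1 s~ + V1 sim~ + b_enc)."""
    s_tilde = np.asarray(s_tilde, dtype=float)
    sim_tilde = np.asarray(sim_tilde, dtype=float)
    if s_tilde.shape[-1] != p.W1.shape[1] or sim_tilde.shape[-1] != p.V1.shape[1]:
        raise ValueError(
            f"input lengths ({s_tilde.shape[-1]}, {sim_tilde.shape[-1]}) do not "
            f"match encoder weights ({p.W1.shape[1]}, {p.V1.shape[1]})"
        )
    g = ACTIVATIONS[p.activation_enc][0]
    return g(s_tilde @ p.W1.T + sim_tilde @ p.V1.T + p.b_enc)


def decode_association(latent: np.ndarray, p: AutoencoderParams) -> np.ndarray:
    """Reconstruction of the association vector, f(W2 z + b)."""
    latent = np.asarray(latent, dtype=float)
    if latent.shape[-1] != p.d:
        raise ValueError(f"latent length {latent.shape[-1]} != d={p.d}")
    f = ACTIVATIONS[p.activation_dec][0]
    return f(latent @ p.W2.T + p.b_rec_assoc)


def decode_similarity(latent: np.ndarray, p: AutoencoderParams) -> np.ndarray:
    """Reconstruction of the similarity vector, f(V2 z + b)."""
    latent = np.asarray(latent, dtype=float)
    if latent.shape[-1] != p.d:
        raise ValueError(f"latent length {latent.shape[-1]} != d={p.d}")
    f = ACTIVATIONS[p.activation_dec][0]
    return f(latent @ p.V2.T + p.b_rec_sim)


def ae_loss(
    s: np.ndarray,
    s_hat: np.ndarray,
    sim: np.ndarray,
    sim_hat: np.ndarray,
    weights: AELossWeights,
    params: AutoencoderParams,
    side: str = "drug",
) -> float:
    """Balanced squared reconstruction error plus L2 weight penalty.

    Targets are the CLEAN inputs (denoising convention).  For the drug side
    the balance is ``alpha`` and the penalty weight ``lam``; the disease side
    uses ``beta`` and ``delta``.
    """
    if side not in ("drug", "disease"):
        raise ValueError("side must be 'drug' or 'disease'")
    bal = weights.alpha if side == "drug" else weights.beta
    reg = weights.lam if side == "drug" else weights.delta
    s, s_hat = np.asarray(s, dtype=float), np.asarray(s_hat, dtype=float)
    sim, sim_hat = np.asarray(sim, dtype=float), np.asarray(sim_hat, dtype=float)
    if s.shape != s_hat.shape or sim.shape != sim_hat.shape:
        raise ValueError("reconstruction shapes do not match their targets")
    penalty = sum(
        float((w ** 2).sum()) for w in (params.W1, params.V1, params.W2, params.V2)
    )
    return (
        bal * float(((s - s_hat) ** 2).sum())
        + (1.0 - bal) * float(((sim - sim_hat) ** 2).sum())
        + reg * penalty
    )
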