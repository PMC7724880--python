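"""Attention-weighted neighborhood representation over an external memory.

For a candidate pair (drug i, disease j) the neighborhood module looks at
N(j), the drugs already associated with disease j.  Each neighbor n gets a
preference score p_ijn = <drug_i, drug_n> (inner product of latent factors),
the preferences are softmax-normalized into attention weights q_ij, and the
representation o_ij is the attention-weighted sum of the neighbors' external
memory vectors c_n.  The memory table is a trainable per-drug parameter
matrix whose dimension is independent of the latent dimension.

When scoring a training pair the target drug is removed from its own
neighbor set to prevent label leakage; a disease with no known drugs yields
the zero representation, so the fused predictor degrades gracefully to its
latent-factor path.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np

from .dataset_io import AssociationMatrix

__all__ = [
    "MemoryTable",
    "NeighborContext",
    "NeighborhoodRepresentation",
    "neighbor_set",
    "preference_scores",
    "attention_weights",
    "neighborhood_representation",
]


@dataclass
class MemoryTable:
    """Per-drug external memory vectors c_n, shape (n_drugs, l_mem)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("memory table must be 2-D (one row per drug)")

    @property
    def l_mem(self) -> int:
        return self.values.shape[1]

    @classmethod
    def initialize(cls, n_drugs: int, l_mem: int, rng: np.random.Generator,
                   scale: float = 0.1) -> "MemoryTable":
        """Zero-mean Gaussian initialization (sd ``scale``), seeded via ``rng``."""
        return cls(rng.normal(0.0, scale, size=(n_drugs, l_mem)))


@dataclass
class NeighborContext:
    """Neighbor set with aligned preference and attention vectors."""

    target_drug: int
    disease: int
    neighbor_indices: np.ndarray
    preferences: np.ndarray
    attention: np.ndarray


@dataclass
class NeighborhoodRepresentation:
    """The pooled memory vector o_ij (zero vector iff the neighbor set is empty)."""

    values: np.ndarray


def neighbor_set(
    a: AssociationMatrix, disease_j: int, exclude_drug: Optional[int] = None
) -> np.ndarray:
    """Indices of drugs associated with disease ``j``, ascending, minus the target."""
    if not 0 <= disease_j < a.n_diseases:
        raise IndexError(f"disease index {disease_j} out of range")
    idx = np.flatnonzero(a.values[:, disease_j])
    if exclude_drug is not None:
        idx = idx[idx != exclude_drug]
    return idx


def preference_scores(
    drug_factor_i: np.ndarray, neighbor_factors: np.ndarray
) -> np.ndarray:
    """Inner products of the target drug factor with each neighbor factor."""
    drug_factor_i = np.asarray(drug_factor_i, dtype=float)
    neighbor_factors = np.asarray(neighbor_factors, dtype=float)
    if neighbor_factors.ndim != 2 or neighbor_factors.shape[1] != drug_factor_i.shape[0]:
        raise ValueError(
            f"neighbor factors {neighbor_factors.shape} incompatible with "
            f"target factor of length {drug_factor_i.shape[0]}"
        )
    return neighbor_factors @ drug_factor_i


def attention_weights(p: np.ndarray) -> np.ndarray:
    """Numerically stable softmax of the preference vector (sums to 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("attention over an empty preference vector is undefined")
    if not np.isfinite(p).all():
        raise ValueError("preference vector contains non-finite entries")
    e = np.exp(p - p.max())
    return e / e.sum()


def neighborhood_representation(
    q: np.ndarray, memory_rows: np.ndarray
) -> NeighborhoodRepresentation:
    """Attention-weighted sum of memory rows, o_ij = sum_n q_n c_n."""
    q = np.asarray(q, dtype=float)
    memory_rows = np.asarray(memory_rows, dtype=float)
    if memory_rows.ndim != 2 or memory_rows.shape[0] != q.shape[0]:
        raise ValueError(
            f"{q.shape[0]} weights incompatible with memory rows {memory_rows.shape}"
        )
    if q.size == 0:
        return NeighborhoodRepresentation(np.zeros(memory_rows.shape[1]))
    return NeighborhoodRepresentation(q @ memory_rows)
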