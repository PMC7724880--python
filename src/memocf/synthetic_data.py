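"""Synthetic drug-disease datasets with planted low-rank structure.

The generator emulates the joint structure the model assumes: drugs and
diseases have nonnegative latent factors, the true affinity of a pair is the
(row-normalized) inner product of its factors, observed associations are the
globally top-scoring pairs, and the similarity matrices are cosine
similarities of the same factors perturbed by symmetric noise.  Under this
construction "similar drugs treat similar diseases" holds literally, the
realized sparsity is exact, and ranking by the true score separates
positives from negatives perfectly -- which makes recovery by the model a
meaningful test of the training machinery rather than of the data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .dataset_io import AssociationMatrix, DatasetBundle, SimilarityMatrix

__all__ = ["SynthSpec", "generate_dataset", "generate_cold_start_dataset"]


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of the planted-structure generator.

    ``rank`` is the dimension of the planted factors; ``target_sparsity`` is
    the fraction of pairs set to 1 (realized exactly, by construction);
    ``similarity_noise_sd`` is the standard deviation of the symmetric
    Gaussian perturbation applied to the cosine similarity matrices.
    """

    m_drugs: int
    n_diseases: int
    rank: int
    target_sparsity: float
    similarity_noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m_drugs <= 0 or self.n_diseases <= 0:
            raise ValueError("m_drugs and n_diseases must be positive")
        if self.rank <= 0 or self.rank > min(self.m_drugs, self.n_diseases):
            raise ValueError("rank must satisfy 1 <= rank <= min(m, n)")
        if not 0.0 < self.target_sparsity < 1.0:
            raise ValueError("target_sparsity must lie in (0, 1)")
        if round(self.target_sparsity * self.m_drugs * self.n_diseases) < 1:
            raise ValueError("target_sparsity * m * n must be at least 1")
        if self.similarity_noise_sd < 0:
            raise ValueError("similarity_noise_sd must be nonnegative")


def _cosine_rows(x: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(x, axis=1, keepdims=True)
    g = (x / norms) @ (x / norms).T
    g = np.clip(g, 0.0, 1.0)
    np.fill_diagonal(g, 1.0)
    return g


def _noisy_similarity(g: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    if sd > 0:
        k = g.shape[0]
        iu = np.triu_indices(k, 1)
        noise = rng.normal(0.0, sd, size=iu[0].size)
        g = g.copy()
        g[iu] += noise
        g.T[iu] += noise  # mirror: keeps the matrix exactly symmetric
    g = np.clip(g, 0.0, 1.0)
    np.fill_diagonal(g, 1.0)
    return g


def generate_dataset(spec: SynthSpec) -> Tuple[DatasetBundle, np.ndarray]:
    """Generate a bundle plus the ground-truth score matrix.

    Factors are absolute values of standard normal draws (so cosine
    similarities land in [0, 1] without rescaling); the true score matrix is
    row-normalized ``U @ V.T``; exactly ``round(target_sparsity * m * n)``
    top-scoring pairs become associations.  Identical seeds give identical
    output.
    """
    m, n, r = spec.m_drugs, spec.n_diseases, spec.rank
    rng = np.random.default_rng(spec.seed)
    u = np.abs(rng.normal(size=(m, r)))
    v = np.abs(rng.normal(size=(n, r)))
    scores = u @ v.T
    scores /= scores.sum(axis=1, keepdims=True)

    q = int(round(spec.target_sparsity * m * n))
    order = np.argsort(scores, axis=None)[::-1][:q]
    values = np.zeros(m * n, dtype=np.int8)
    values[order] = 1
    values = values.reshape(m, n)

    drug_sim = _noisy_similarity(_cosine_rows(u), spec.similarity_noise_sd, rng)
    disease_sim = _noisy_similarity(_cosine_rows(v), spec.similarity_noise_sd, rng)

    drug_ids = [f"D{i}" for i in range(m)]
    disease_ids = [f"P{j}" for j in range(n)]
    bundle = DatasetBundle(
        associations=AssociationMatrix(values, drug_ids, disease_ids),
        drug_sim=SimilarityMatrix(drug_sim, drug_ids, "drug"),
        disease_sim=SimilarityMatrix(disease_sim, disease_ids, "disease"),
    )
    return bundle, scores


def generate_cold_start_dataset(spec: SynthSpec, n_singletons: int) -> DatasetBundle:
    """Generate a bundle in which exactly ``n_singletons`` drugs are singletons.

    A singleton drug has exactly one known association, the situation the
    new-drug evaluation protocol removes into the test set.  Rows are
    post-edited: chosen drugs keep only their top-scoring association (one is
    added if the row is empty); every other drug is topped up to at least two
    associations so no further row is a singleton.
    """
    if n_singletons < 0:
        raise ValueError("n_singletons must be nonnegative")
    if n_singletons >= spec.m_drugs:
        raise ValueError("n_singletons must be smaller than m_drugs")
    if spec.n_diseases < 2:
        raise ValueError("need at least 2 diseases to avoid accidental singletons")
    bundle, scores = generate_dataset(spec)
    values = np.array(bundle.associations.values, dtype=np.int8)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    chosen = np.sort(rng.choice(spec.m_drugs, size=n_singletons, replace=False))
    chosen_set = set(int(c) for c in chosen)
    for i in range(spec.m_drugs):
        row = values[i]
        ranked = np.argsort(scores[i])[::-1]  # diseases by true affinity
        if i in chosen_set:
            keep = next(j for j in ranked if row[j] == 1) if row.any() else ranked[0]
            row[:] = 0
            row[keep] = 1
        else:
            need = 2 - int(row.sum())
            for j in ranked:
                if need <= 0:
                    break
                if row[j] == 0:
                    row[j] = 1
                    need -= 1
    return DatasetBundle(
        associations=AssociationMatrix(
            values, bundle.associations.drug_ids, bundle.associations.disease_ids
        ),
        drug_sim=bundle.drug_sim,
        disease_sim=bundle.disease_sim,
    )
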