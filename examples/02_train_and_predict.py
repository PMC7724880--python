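"""Train the hybrid model on a synthetic dataset and score candidate pairs.

The predictor fuses two signals: the elementwise product of the drug and
disease latent factors (global structure, weight eta) and the
attention-pooled external memory of the disease's known drugs (local
structure, weight 1 - eta).
"""

import numpy as np

import memocf as mc

bundle, _ = mc.generate_dataset(mc.SynthSpec(100, 60, 6, 0.05, seed=42))

arch = mc.Architecture(latent_dim=16, memory_dim=16, eta=0.7)
cfg = mc.TrainingConfig(epochs=40, seed=0)
model, trace = mc.train(bundle, arch, cfg)
print(f"joint loss: epoch 1 = {trace[0]:.1f}, epoch {len(trace)} = {trace[-1]:.1f}")

# rank unobserved diseases for one drug
drug = 3
candidates = np.flatnonzero(bundle.associations.values[drug] == 0)
scores = mc.predict_scores(model, np.full(len(candidates), drug), candidates)
top = candidates[np.argsort(-scores)[:5]]
print(f"top-5 candidate diseases for drug {bundle.associations.drug_ids[drug]}:")
for j in top:
    print(f"  {bundle.associations.disease_ids[j]}  score="
          f"{mc.predict_score(model, drug, int(j)):.4f}")
print("(scores are predicted association probabilities in (0, 1))")
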