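# cdmnet — co-training diagnostic classification

`cdmnet` classifies examinees into binary skill-mastery profiles from
their 0/1 item responses.  A diagnostic assessment measures K latent
attributes (skills); an examinee's state is a profile **α** ∈ {0,1}^K,
one of C = 2^K latent classes, and a Q-matrix records which attributes
each item measures.  Classical diagnostic classification models (DCMs)
commit to one response rule: the conjunctive DINA model, where a correct
response needs *all* measured attributes,

P(y_ij = 1 | ξ_ij, s_j, g_j) = (1 − s_j)^{ξ_ij} g_j^{1−ξ_ij},
ξ_ij = ∏_k α_ik^{q_jk},

or the disjunctive DINO model, where *any* measured attribute suffices
(ideal response ω_ij).  s_j and g_j are the item's slip and guess
probabilities.  Choosing the wrong rule, or working from a partly wrong
Q-matrix, costs classification accuracy.

`cdmnet` implements a semi-supervised alternative: fit **both** DINA and
DINO by marginal-maximum-likelihood EM, take their hard class labels
c_DINA and c_DINO as two noisy views of the truth, and train a
multilayer perceptron (I → 200 → 100 → softmax over C classes) whose
class layer **t** feeds three output heads — a DINA-label head and a
DINO-label head, each a learned C × C confusion mixture
P(c = k | X) = Σ_j P(c = k | t_j) P(t_j | X), plus a reconstruction head
X̃ = σ(tᵀW) over the items.  Training minimizes

H(Y₁, c_DINA) + H(Y₂, c_DINO) + λ · H(X, X̃)

by mini-batch SGD with early stopping on a held-out 20% validation
split, and an ensemble of independently initialized members is averaged
on the class-posterior scale.  The averaged posterior's argmax is the
reported profile; it is typically more accurate than either supervising
model and degrades less when the Q-matrix contains errors.

The package also ships the simulation engine used to evaluate all of
this: item-by-class probability matrices Π with controlled item
discrimination (d_i = π_mastery − π_non-mastery), equivalence-class
structure that no named DCM would produce, Q-matrix misspecification,
and a 12-condition replication harness.

## Worked example

```python
import numpy as np
from cdmnet import (
    enumerate_classes, build_qmatrix, build_item_class_matrix,
    simulate_profiles, simulate_responses, fit_dcm,
    NetworkConfig, make_split, train_ensemble,
)
from cdmnet.latent_structure import one_hot_matrix
from cdmnet.evaluate import attribute_accuracy, profile_accuracy

rng = np.random.default_rng(7)
space = enumerate_classes(3)                      # 8 latent classes
Q = build_qmatrix(20, 3, rng)                     # 20-item diagnostic form
pool = build_item_class_matrix(Q, space, "high", rng)
print(f"mean item discrimination: {pool.discrimination().mean():.3f}")

truth = simulate_profiles(1000, space, rng)
data = simulate_responses(pool, truth, rng)

dina = fit_dcm("DINA", data.responses, Q)
dino = fit_dcm("DINO", data.responses, Q)
print(f"DINA profile accuracy: {profile_accuracy(dina.labels, truth):.3f}")
print(f"DINO profile accuracy: {profile_accuracy(dino.labels, truth):.3f}")

split = make_split(1000, rng)
result = train_ensemble(
    data.responses,
    one_hot_matrix(dina.labels, space.C),
    one_hot_matrix(dino.labels, space.C),
    split, lam=0.5, M=25, config=NetworkConfig(), seed=7,
)
print(f"co-trained network profile accuracy: {profile_accuracy(result.labels_whole, truth):.3f}")
```

Output:

```
mean item discrimination: 0.499
DINA profile accuracy: 0.606
DINO profile accuracy: 0.628
co-trained network profile accuracy: 0.654
```

The two single-rule models disagree (neither matches the generating
process, which follows no named DCM response function), and the
co-trained ensemble beats both.  Accuracy here is exact-profile
("class-level") accuracy — all K attributes right — which is why the
numbers look low next to per-attribute accuracy (0.77–0.94 for the same
fit).

The same pipeline is available from the shell:

```bash
cdmnet simulate --items 20 --attributes 3 --n 1000 --seed 7 --out sim
cdmnet train-ann --responses sim_responses.csv --qmatrix sim_qmatrix.csv \
    --members 25 --seed 7 --lambda 0.5 --out ann
cdmnet replicate --conditions 1,9 --reps 20 --members 25 --out results/
```

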