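# Methods

This note documents the generating model, the two estimation stages,
the default parameters and the numerical choices behind `cdmnet`, and
what the synthetic data can and cannot establish.

## Latent structure

K binary attributes define C = 2^K latent classes.  Profiles are
ordered lexicographically with attribute 1 as the most significant bit;
the all-zeros profile is class 1 and the all-ones profile is class C.
The ordering is arbitrary but must be stable: class labels index the
network's class layer and the one-hot targets, so every component uses
this single enumeration.  One-hot codes set position j (1-based) for
label j.

A Q-matrix (I items × K attributes) is valid when every entry is 0/1
and no row is all zeros.  For each item, latent classes partition into
three groups by their restriction to the measured attributes: mastery
(all measured attributes mastered), partial mastery (a proper non-empty
subset) and non-mastery (none).  Classes whose restrictions agree form
item-based equivalence classes.

## Synthetic data generator

Responses are simulated from a general item-by-class matrix Π = [π_ic]
rather than from any named DCM response function, so that neither DINA
nor DINO (nor a saturated model) is "the" correct model.  Per item the
group-level draws are uniform:

| group           | high-discrimination item | low-discrimination item            |
|-----------------|--------------------------|------------------------------------|
| non-mastery π₀  | U[0.15, 0.35]            | U[0.20, 0.40]                      |
| partial π_p     | U[0.40, 0.60]            | U[π₀, π₀ + w], w = 0.15            |
| mastery π₁      | U[0.65, 0.90]            | complex: U[max π_p, π₀ + 0.30]; simple: U[π₀, π₀ + 0.30] |

Mastery and non-mastery equivalence classes share one value per item;
each *partial* equivalence class receives its own independent draw from
the partial interval — deliberate within-interval heterogeneity that no
standard DCM allows.  Draws are rejected and repeated (up to 100 times
per item) until π₁ > every π_p > π₀ strictly; rejection rather than
sorting preserves the marginal distributions conditional on
acceptance.  Item discrimination is d_i = π₁ − π₀; d > 0.3 defines a
highly discriminating item.  High-quality pools mark every item high
(implied mean d ≈ 0.525); mixed pools mark a random half low.  The
partial-interval width w for low items is 0.15 by default with 0.20
exposed as `low_partial_width` — the two values circulate as
alternative readings of the same design and the narrower one is kept as
the default.

Q-matrices for the three study forms (20×3, 20×4, 30×4) are generated,
not transcribed: two identity blocks guarantee each attribute at least
two simple-structure items (a complete Q-matrix, keeping all 2^K
classes identifiable), and the remaining rows split evenly between
random one- and two-attribute items.  Q-matrix misspecification flips
exactly round(0.10 · I · K) entries drawn uniformly without
replacement, rejecting draws that would zero a row or turn off the lone
1 of a simple item.

Examinee profiles are i.i.d. **uniform over the 2^K classes** by
default (`class_weights` accepts anything else).  Uniform is the
assumption-free choice and makes class-level accuracy directly
interpretable, but it is also the *hardest* regime: any concentration
of the population into fewer classes (e.g. correlated attributes from a
thresholded multivariate normal, the other common convention) raises
every method's accuracy.  Absolute accuracy levels reported by the
harness are therefore conservative relative to studies that simulate
correlated attributes; method *comparisons* are unaffected.  Responses
are Bernoulli(π_{i,c}) independent across items and examinees given the
class (local independence); missing responses are out of scope.

## Stage 1: DINA/DINO by EM

Both models reduce a class to a per-item gate — conjunctive ξ for DINA,
disjunctive ω for DINO — with P(y=1|gate) = (1−s)^gate g^(1−gate).
Estimation is marginal-maximum-likelihood EM with full enumeration of
the C classes (C ≤ 1024): the E-step computes posteriors in log space
with max-subtraction; the M-step updates s_j, g_j in closed form from
expected correct/incorrect counts in the gate-1/gate-0 groups and the
class prior from posterior means (priors can be frozen uniform with
`estimate_priors=False`; both conventions circulate).  Defaults:
s = g = 0.2 and uniform priors at start; stop when the largest
parameter change is below 1e-5 or the log-likelihood gain below 1e-8;
at most 1000 iterations, with non-convergence recorded on the fit
rather than raised.  After each M-step parameters are clipped to
[0.001, 0.999] and, if g_j ≥ 1 − s_j, both are shrunk toward the
midpoint of [g_j, 1 − s_j] leaving a 0.001 gap — items stay monotone
(masters outperform non-masters) and class labels cannot reflect.
MAP ties go to the lowest class label.

## Stage 2: the co-training network

Architecture (for I items, C classes): I → 200 → 100 (ReLU) → C
(softmax class layer t), then three heads: two label heads
head_k = Σ_j rowsoftmax(V)[j,·] · t_j with learned C × C confusion
logits V, and a reconstruction head X̃ = σ(tᵀW_r + b_r).  The loss is
the mean over examinees of the two label cross-entropies plus λ times
the item-summed Bernoulli cross-entropy of the reconstruction.  The
label heads absorb the label noise of c_DINA and c_DINO — they learn
how each supervising model confuses classes — while the reconstruction
term acts as an unsupervised latent-class likelihood pulling t toward
class-coherent response patterns.

Choices at points the architecture leaves open:

* **Heads as probability-space mixtures.**  The joint
  P(c = k | X) = Σ_j P(c = k | t_j) P(t_j | X) is computed exactly,
  with P(c = k | t_j) a row-softmax of the confusion logits; plugging a
  soft t into the logit map would coincide only at one-hot t.
* **Identity-logit head initialization.**  Confusion logits start at
  3·I_C plus N(0, 0.01²) noise.  This anchors class j of the latent
  layer to label j of both supervising models; under symmetric random
  initialization each ensemble member would settle on an arbitrary
  permutation of the classes and averaging posteriors across members
  would be meaningless.  Encoder and reconstruction weights use
  zero-mean Gaussians scaled by 1/√fan-in.
* **Reconstruction through a logistic.**  The affine map from t to
  items is passed through σ so the Bernoulli cross-entropy is defined;
  biases are included in every affine map (`use_bias=False` gives the
  purely linear variant).
* **Optimizer defaults** (none are dictated by the method): mini-batch
  SGD, batch 32, learning rate 0.05, momentum 0.9, early-stopping
  patience 20 epochs on the validation value of the full loss, hard cap
  400 epochs (training on these data stops by patience long before the
  cap), λ = 0.5 when fixed, grid {0.1, 0.5, 1.0} for the validation
  test (`select_lambda`, which compares candidates on validation label
  cross-entropy only).  Divergence triggers one retry at half the
  learning rate.  Training runs in single precision by default — the
  inputs are 0/1 and the network is shallow — with `dtype="float64"`
  available (the analytic gradients are verified against central finite
  differences in double precision).
* **One split, shared by everything.**  A single 80/20
  training/validation split per replication is used by λ selection and
  by all ensemble members, so the three reported populations — whole
  sample ("ANN"), training rows ("ANN*"), validation rows ("ANN**") —
  are well defined for the ensemble.  Per-member resplitting would make
  the validation population ill-posed.  DCM labels are computed on the
  full sample before splitting; the split governs only network
  training.
* **Single pass.**  The DCMs are fitted once and the network trained
  once; no iterative relabeling rounds.

Ensemble members differ only in weight initialization and batch order
(seeds spawned from the master seed); posteriors are averaged
arithmetically, and the averaged posterior's argmax per row gives the
labels.  A member that diverges even after its retry is dropped with a
warning and the effective member count recorded.

## Replication harness

Twelve conditions cross items {20, 30} × attributes {3, 4} (30 items
only with 4 attributes) × diagnostic quality {high, mixed} × Q-matrix
accuracy {100%, 90%}, at n = 1000.  Per condition the Q-matrix and Π
are drawn once and held fixed; each replication draws fresh profiles
and responses.  Truth is always generated under the accurate Q; a
90%-condition hands the *estimators* one fixed perturbed Q (a flag
resamples it per replication instead).  Replication seeds derive from
(master seed, items, attributes, quality, replication index) — Q
accuracy deliberately excluded — so the 100% and 90% variants of a
condition score the same simulated examinees and misspecification
drops are paired comparisons.  Reported statistics are
across-replication means and standard deviations of per-attribute and
exact-profile accuracy for DINA, DINO, ANN, ANN* and ANN**; factor
marginals are unweighted means of condition means.

Default harness scale is 20 replications with 25 ensemble members and
λ fixed at 0.5 — chosen so a condition completes in minutes — with the
full-scale settings (100/100/λ-auto) available through the same
parameters.  The test suite runs representative conditions at 6
replications × 10 members, and unit tests use narrow networks
(hidden 24–64 nodes) on n ≤ 400; `scripts/acceptance.py` uses the
default scale.

## Known limitations

* Absolute accuracy levels depend strongly on the unmodeled profile
  distribution (see above) and, within a condition, on the single fixed
  Π draw: across Π draws the Bayes-optimal profile accuracy for the
  20×3 high-quality design varies with a standard deviation of about
  0.04.  Condition-level point values should be read with that
  between-pool variability in mind; the harness's paired design removes
  it from within-condition method comparisons.
* A 90%-accurate Q is a severe intervention under these generator
  settings: most eligible flips add a spurious attribute requirement to
  an item, which distorts the conjunctive model badly.  Drops in
  accuracy under misspecification are correspondingly large, though
  their ordering (network more robust than either supervising model) is
  stable.
* With early stopping selecting each member's weights by validation
  loss, the validation rows gain a mild selection advantage that
  roughly offsets the training rows' fitting advantage: the three
  population accuracies (ANN*/ANN/ANN**) typically differ by less than
  one replication standard deviation, with no reliable ordering.
* EM is a local optimizer; the neutral start (s = g = 0.2, uniform
  priors) has been sufficient on generated data, and a seeded
  multi-start is the obvious extension where it is not.
* Item parameters are estimated only as a by-product; standard errors,
  fit indices and missing-data handling are out of scope.
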