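"""Semi-supervised co-training network for diagnostic classification.

The network maps a binary response pattern X (length I) through two ReLU
hidden layers (widths 200 and 100) to a softmax "class layer" t over the
C = 2^K latent classes — the model's belief about the examinee's true
class.  Three output heads hang off t:

* head 1 — the probability of each DINA label:  P(c_DINA = k | X)
  = sum_j P(c_DINA = k | t = j) P(t = j | X), where the conditional is a
  row-softmax of a learned C x C confusion matrix;
* head 2 — the same construction for the DINO labels;
* reconstruction — per-item Bernoulli probabilities
  sigmoid(t' W + b) of the observed responses.

Training minimizes

    H(Y1, c_DINA) + H(Y2, c_DINO) + lambda * H(X, X_rec)

by mini-batch SGD with momentum, where H is cross-entropy and c_DINA,
c_DINO are the hard labels from the two EM fits.  The two noisy label
views plus the unsupervised reconstruction term let the class layer
settle on a posterior that is more accurate than either supervising
model alone.  Early stopping monitors the full loss on a held-out 20%
validation split; an ensemble of independently initialized members is
averaged on the class-posterior scale.

Classes are anchored to label indices by initializing both confusion
matrices at identity logits, so ensemble members agree on what class j
means and averaging their posteriors is coherent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NetworkConfig",
    "NetworkWeights",
    "TrainSplit",
    "CoTrainResult",
    "make_split",
    "init_weights",
    "forward",
    "loss",
    "loss_and_grads",
    "train_member",
    "select_lambda",
    "train_ensemble",
]

_CLIP = 1e-12


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture and optimizer settings.

    hidden : widths of the two ReLU layers.
    learning_rate, momentum, batch_size : SGD settings.
    max_epochs : hard cap; early stopping normally fires first.
    patience : epochs without validation improvement before stopping.
    use_bias : include bias terms in every affine map (set False for the
        purely linear variant).
    head_init_logit : diagonal logit magnitude anchoring confusion
        matrices at (near-)identity.
    dtype : training precision; single precision is the default (binary
        inputs, shallow net), double is available for gradient checks.
    """

    hidden: tuple = (200, 100)
    learning_rate: float = 0.05
    momentum: float = 0.9
    batch_size: int = 32
    max_epochs: int = 400
    patience: int = 20
    use_bias: bool = True
    head_init_logit: float = 3.0
    init_noise: float = 0.01
    dtype: str = "float32"


@dataclass
class NetworkWeights:
    """All trainable arrays; w1 = encoder (X -> t), w2 = heads (t -> outputs)."""

    W1: np.ndarray  # I x H1
    b1: np.ndarray
    W2: np.ndarray  # H1 x H2
    b2: np.ndarray
    W3: np.ndarray  # H2 x C
    b3: np.ndarray
    V1: np.ndarray  # C x C confusion logits, DINA head
    V2: np.ndarray  # C x C confusion logits, DINO head
    Wr: np.ndarray  # C x I reconstruction
    br: np.ndarray

    _FIELDS = ("W1", "b1", "W2", "b2", "W3", "b3", "V1", "V2", "Wr", "br")

    def arrays(self) -> dict:
        return {k: getattr(self, k) for k in self._FIELDS}

    def copy(self) -> "NetworkWeights":
        return NetworkWeights(**{k: v.copy() for k, v in self.arrays().items()})

    def check_finite(self) -> bool:
        return all(np.isfinite(v).all() for v in self.arrays().values())


@dataclass(frozen=True)
class TrainSplit:
    """Disjoint, exhaustive 80/20 row split (training / validation)."""

    train_idx: np.ndarray
    valid_idx: np.ndarray

    def __post_init__(self):
        tr = np.asarray(self.train_idx)
        va = np.asarray(self.valid_idx)
        if np.intersect1d(tr, va).size:
            raise ValueError("train and validation indices overlap")
        object.__setattr__(self, "train_idx", tr)
        object.__setattr__(self, "valid_idx", va)

    @property
    def n(self) -> int:
        return self.train_idx.size + self.valid_idx.size


def make_split(n: int, rng: np.random.Generator, train_frac: float = 0.8) -> TrainSplit:
    perm = rng.permutation(n)
    n_train = int(round(train_frac * n))
    return TrainSplit(train_idx=np.sort(perm[:n_train]), valid_idx=np.sort(perm[n_train:]))


@dataclass
class CoTrainResult:
    """Ensemble output: averaged class posterior and the three label views."""

    ensemble_posterior: np.ndarray  # n x C
    split: TrainSplit
    n_members: int
    member_val_losses: list
    member_val_trajectories: list
    lam: float

    @property
    def labels_whole(self) -> np.ndarray:
        """ANN population: MAP labels for every examinee."""
        return np.argmax(self.ensemble_posterior, axis=1) + 1

    @property
    def labels_train(self) -> np.ndarray:
        """ANN* population: MAP labels restricted to the training rows."""
        return self.labels_whole[self.split.train_idx]

    @property
    def labels_valid(self) -> np.ndarray:
        """ANN** population: MAP labels restricted to the validation rows."""
        return self.labels_whole[self.split.valid_idx]


def init_weights(I: int, C: int, rng: np.random.Generator, config: NetworkConfig) -> NetworkWeights:
    """Gaussian fan-in init for the encoder; identity-logit init for the heads."""
    H1, H2 = config.hidden
    dt = np.dtype(config.dtype)

    def gauss(fan_in, shape):
        return rng.normal(0.0, 1.0 / np.sqrt(fan_in), size=shape).astype(dt)

    eye = config.head_init_logit * np.eye(C)
    noise = config.init_noise
    return NetworkWeights(
        W1=gauss(I, (I, H1)),
        b1=np.zeros(H1, dt),
        W2=gauss(H1, (H1, H2)),
        b2=np.zeros(H2, dt),
        W3=gauss(H2, (H2, C)),
        b3=np.zeros(C, dt),
        V1=(eye + rng.normal(0.0, noise, (C, C))).astype(dt),
        V2=(eye + rng.normal(0.0, noise, (C, C))).astype(dt),
        Wr=gauss(C, (C, I)),
        br=np.zeros(I, dt),
    )


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def forward(X: np.ndarray, w: NetworkWeights, return_cache: bool = False):
    """Batch forward pass.

    Returns a dict with ``class_posterior`` (t), ``head1``, ``head2`` and
    ``reconstruction``; with ``return_cache=True`` the intermediate
    activations needed for backprop are included.
    """
    X = np.atleast_2d(np.asarray(X, dtype=w.W1.dtype))
    Z1 = X @ w.W1 + w.b1
    A1 = np.maximum(Z1, 0.0)
    Z2 = A1 @ w.W2 + w.b2
    A2 = np.maximum(Z2, 0.0)
    Z3 = A2 @ w.W3 + w.b3
    T = _softmax(Z3)
    M1 = _softmax(w.V1)  # row-stochastic confusion matrices
    M2 = _softmax(w.V2)
    head1 = T @ M1
    head2 = T @ M2
    Zr = T @ w.Wr + w.br
    recon = 1.0 / (1.0 + np.exp(-Zr))
    for name, arr in (("class layer", T), ("head 1", head1), ("head 2", head2), ("reconstruction", recon)):
        if not np.isfinite(arr).all():
            raise FloatingPointError(f"non-finite activations in {name}")
    out = {
        "class_posterior": T,
        "head1": head1,
        "head2": head2,
        "reconstruction": recon,
    }
    if return_cache:
        out["cache"] = {"X": X, "Z1": Z1, "A1": A1, "Z2": Z2, "A2": A2, "M1": M1, "M2": M2}
    return out


def loss(outputs: dict, Y1: np.ndarray, Y2: np.ndarray, X: np.ndarray, lam: float) -> float:
    """Mean per-examinee cost: two label cross-entropies + lambda x reconstruction.

    The reconstruction term is the Bernoulli cross-entropy summed over
    items.  Probabilities are clipped before logs.
    """
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    h1 = np.clip(outputs["head1"], _CLIP, 1 - _CLIP)
    h2 = np.clip(outputs["head2"], _CLIP, 1 - _CLIP)
    xr = np.clip(outputs["reconstruction"], _CLIP, 1 - _CLIP)
    X = np.atleast_2d(X)
    ce1 = -(np.atleast_2d(Y1) * np.log(h1)).sum(axis=1)
    ce2 = -(np.atleast_2d(Y2) * np.log(h2)).sum(axis=1)
    cer = -(X * np.log(xr) + (1 - X) * np.log(1 - xr)).sum(axis=1)
    return float(np.mean(ce1 + ce2 + lam * cer))


def label_cross_entropy(outputs: dict, Y1: np.ndarray, Y2: np.ndarray) -> float:
    """The two label terms only (the lambda-selection criterion)."""
    h1 = np.clip(outputs["head1"], _CLIP, 1 - _CLIP)
    h2 = np.clip(outputs["head2"], _CLIP, 1 - _CLIP)
    ce1 = -(np.atleast_2d(Y1) * np.log(h1)).sum(axis=1)
    ce2 = -(np.atleast_2d(Y2) * np.log(h2)).sum(axis=1)
    return float(np.mean(ce1 + ce2))


def loss_and_grads(
    w: NetworkWeights, Xb: np.ndarray, Y1b: np.ndarray, Y2b: np.ndarray, lam: float
) -> tuple[float, dict]:
    """Batch loss and its analytic gradient for every weight block."""
    out = forward(Xb, w, return_cache=True)
    cache = out["cache"]
    Xb = cache["X"]
    B = Xb.shape[0]
    T = out["class_posterior"]
    M1, M2 = cache["M1"], cache["M2"]
    h1 = np.clip(out["head1"], _CLIP, 1 - _CLIP)
    h2 = np.clip(out["head2"], _CLIP, 1 - _CLIP)
    recon = out["reconstruction"]
    value = loss(out, Y1b, Y2b, Xb, lam)

    # label heads: d/dhead of -Y log(head), averaged over the batch
    Gh1 = -np.atleast_2d(Y1b) / h1 / B
    Gh2 = -np.atleast_2d(Y2b) / h2 / B
    # reconstruction head in logit space: sigmoid + Bernoulli CE
    dZr = lam * (recon - Xb) / B
    dWr = T.T @ dZr
    dbr = dZr.sum(axis=0)

    # gradient wrt the class posterior T
    GT = Gh1 @ M1.T + Gh2 @ M2.T + dZr @ w.Wr.T

    # confusion-logit gradients through the row softmax
    GM1 = T.T @ Gh1
    GM2 = T.T @ Gh2
    dV1 = M1 * (GM1 - (GM1 * M1).sum(axis=1, keepdims=True))
    dV2 = M2 * (GM2 - (GM2 * M2).sum(axis=1, keepdims=True))

    # class-layer softmax, then plain backprop through the ReLU stack
    dZ3 = T * (GT - (GT * T).sum(axis=1, keepdims=True))
    A2, A1 = cache["A2"], cache["A1"]
    dW3 = A2.T @ dZ3
    db3 = dZ3.sum(axis=0)
    dA2 = dZ3 @ w.W3.T
    dZ2 = dA2 * (cache["Z2"] > 0)
    dW2 = A1.T @ dZ2
    db2 = dZ2.sum(axis=0)
    dA1 = dZ2 @ w.W2.T
    dZ1 = dA1 * (cache["Z1"] > 0)
    dW1 = Xb.T @ dZ1
    db1 = dZ1.sum(axis=0)

    grads = {
        "W1": dW1, "b1": db1, "W2": dW2, "b2": db2, "W3": dW3, "b3": db3,
        "V1": dV1, "V2": dV2, "Wr": dWr, "br": dbr,
    }
    return value, grads


def _evaluate(w: NetworkWeights, X, Y1, Y2, idx, lam) -> float:
    out = forward(X[idx], w)
    return loss(out, Y1[idx], Y2[idx], X[idx], lam)


def _sgd_train(X, Y1, Y2, split: TrainSplit, lam, config: NetworkConfig, rng, lr):
    n, I = X.shape
    C = Y1.shape[1]
    w = init_weights(I, C, rng, config)
    vel = {k: np.zeros_like(v) for k, v in w.arrays().items()}
    bias_keys = {"b1", "b2", "b3", "br"}
    tr = split.train_idx
    best_val = np.inf
    best_w = w.copy()
    best_epoch = 0
    stall = 0
    trajectory = []
    for epoch in range(1, config.max_epochs + 1):
        order = tr[rng.permutation(tr.size)]
        for start in range(0, order.size, config.batch_size):
            idx = order[start : start + config.batch_size]
            _, grads = loss_and_grads(w, X[idx], Y1[idx], Y2[idx], lam)
            for k, arr in w.arrays().items():
                if not config.use_bias and k in bias_keys:
                    continue
                vel[k] = config.momentum * vel[k] - lr * grads[k]
                arr += vel[k]
        val = _evaluate(w, X, Y1, Y2, split.valid_idx, lam)
        trajectory.append(val)
        if not np.isfinite(val):
            raise FloatingPointError("validation loss diverged")
        if val < best_val:
            best_val = val
            best_w = w.copy()
            best_epoch = epoch
            stall = 0
        else:
            stall += 1
            if stall >= config.patience:
                break
    return best_w, best_val, best_epoch, trajectory


def train_member(
    X: np.ndarray,
    Y1: np.ndarray,
    Y2: np.ndarray,
    split: TrainSplit,
    lam: float,
    config: NetworkConfig,
    seed: int,
) -> dict:
    """Train one ensemble member with early stopping on the validation loss.

    SGD sees only the training rows; after every epoch the full cost is
    evaluated on the validation rows and the weights from the best
    validation epoch are kept.  On divergence, training restarts once
    with the learning rate halved.  Deterministic given (seed, config).

    Returns a dict with ``weights``, ``posterior`` (n x C class posterior
    for ALL rows under the best weights), ``best_val_loss``,
    ``best_epoch`` and the per-epoch ``val_trajectory``.
    """
    dt = np.dtype(config.dtype)
    X = np.asarray(X, dtype=dt)
    Y1 = np.asarray(Y1, dtype=dt)
    Y2 = np.asarray(Y2, dtype=dt)
    for lr_scale in (1.0, 0.5):
        rng = np.random.default_rng(seed)
        try:
            best_w, best_val, best_epoch, trajectory = _sgd_train(
                X, Y1, Y2, split, lam, config, rng, config.learning_rate * lr_scale
            )
            break
        except FloatingPointError:
            if lr_scale == 0.5:
                raise
    posterior = forward(X, best_w)["class_posterior"].astype(np.float64)
    return {
        "weights": best_w,
        "posterior": posterior,
        "best_val_loss": best_val,
        "best_epoch": best_epoch,
        "val_trajectory": trajectory,
    }


def select_lambda(
    X: np.ndarray,
    Y1: np.ndarray,
    Y2: np.ndarray,
    split: TrainSplit,
    grid=(0.1, 0.5, 1.0),
    config: NetworkConfig = NetworkConfig(),
    seed: int = 0,
) -> float:
    """Pick the reconstruction weight by a validation test.

    One member is trained per candidate on the same split and seed; the
    winner minimizes the validation cross-entropy of the two label heads
    (the reconstruction term is excluded so candidates are compared on
    the classification criterion alone).  Ties go to the earliest
    candidate in grid order.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("lambda grid must be non-empty")
    if len(grid) == 1:
        return float(grid[0])
    best_lam, best_ce = None, np.inf
    for lam in grid:
        member = train_member(X, Y1, Y2, split, lam, config, seed)
        out = forward(np.asarray(X, dtype=np.float64)[split.valid_idx], member["weights"])
        ce = label_cross_entropy(out, Y1[split.valid_idx], Y2[split.valid_idx])
        if ce < best_ce - 1e-12:
            best_ce = ce
            best_lam = lam
    return float(best_lam)


def train_ensemble(
    X: np.ndarray,
    Y1: np.ndarray,
    Y2: np.ndarray,
    split: TrainSplit,
    lam: float,
    M: int,
    config: NetworkConfig = NetworkConfig(),
    seed: int = 0,
) -> CoTrainResult:
    """Train M members and average their class posteriors.

    Members share the data split but differ in weight initialization and
    batch order (seeds derived per member).  A member that fails even
    after its learning-rate retry is dropped with a warning; the result
    records the effective member count.
    """
    if M < 1:
        raise ValueError("need at least one ensemble member")
    n = np.asarray(X).shape[0]
    C = Y1.shape[1]
    total = np.zeros((n, C))
    val_losses = []
    trajectories = []
    ok = 0
    ss = np.random.SeedSequence(seed)
    member_seeds = [int(s) % (2**31) for s in ss.generate_state(M)]
    for m in range(M):
        try:
            member = train_member(X, Y1, Y2, split, lam, config, member_seeds[m])
        except FloatingPointError as err:  # pragma: no cover - defensive
            import warnings

            warnings.warn(f"ensemble member {m} dropped: {err}")
            continue
        total += member["posterior"]
        val_losses.append(member["best_val_loss"])
        trajectories.append(member["val_trajectory"])
        ok += 1
    if ok == 0:
        raise RuntimeError("all ensemble members failed")
    return CoTrainResult(
        ensemble_posterior=total / ok,
        split=split,
        n_members=ok,
        member_val_losses=val_losses,
        member_val_trajectories=trajectories,
        lam=float(lam),
    )
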