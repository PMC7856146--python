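"""Marginal-maximum-likelihood EM for the DINA and DINO models.

Both models reduce an examinee's latent class to a per-item ideal
response: the conjunctive DINA gate requires mastery of ALL attributes an
item measures (indicator xi), the disjunctive DINO gate is satisfied by
ANY of them (indicator omega).  Given the gate, the response is noisy
with item slip s_j (a capable examinee misses) and guess g_j (an
incapable one succeeds):

    P(y_j = 1 | gate, s_j, g_j) = (1 - s_j)^gate * g_j^(1 - gate)

The fitter runs EM on the marginal likelihood with full enumeration of
the C = 2^K latent classes: the E-step computes each examinee's posterior
over classes in log space; the M-step has closed-form updates for s_j,
g_j from expected correct/incorrect counts in the gate-1 and gate-0
groups, and for the class prior from posterior means.  Hard labels
(c_DINA, c_DINO) are the row-wise maximum-a-posteriori classes; they are
the supervision handed to the co-training network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .latent_structure import (
    LatentClassSpace,
    QMatrix,
    enumerate_classes,
    ideal_response_matrix,
    one_hot_matrix,
)

__all__ = ["ItemParams", "DcmFit", "response_prob", "fit", "classify"]

_PARAM_FLOOR = 0.001


@dataclass(frozen=True)
class ItemParams:
    """Per-item slip and guess probabilities; monotone items keep g < 1 - s."""

    slip: np.ndarray
    guess: np.ndarray

    def __post_init__(self):
        s = np.asarray(self.slip, dtype=np.float64)
        g = np.asarray(self.guess, dtype=np.float64)
        if s.shape != g.shape:
            raise ValueError("slip and guess must have equal length")
        if ((s <= 0) | (s >= 1) | (g <= 0) | (g >= 1)).any():
            raise ValueError("slip and guess must lie strictly in (0, 1)")
        if (g >= 1 - s).any():
            raise ValueError("monotonicity violated: need g_j < 1 - s_j for every item")
        object.__setattr__(self, "slip", s)
        object.__setattr__(self, "guess", g)


@dataclass
class DcmFit:
    """Result of one EM fit: parameters, posterior and hard class labels."""

    model: str
    params: ItemParams
    class_priors: np.ndarray
    posterior: np.ndarray  # n x C
    labels: np.ndarray  # n, 1-based MAP classes
    loglik_trace: list = field(default_factory=list)
    n_iter: int = 0
    converged: bool = True
    space: LatentClassSpace | None = None

    @property
    def loglik(self) -> float:
        return self.loglik_trace[-1]

    def to_json_dict(self) -> dict:
        return {
            "model": self.model,
            "slip": self.params.slip.tolist(),
            "guess": self.params.guess.tolist(),
            "class_priors": self.class_priors.tolist(),
            "loglik": self.loglik,
            "n_iter": self.n_iter,
            "converged": self.converged,
        }

    def labels_to_csv(self, path) -> None:
        pd.DataFrame(
            {
                f"c_{self.model}": self.labels,
                "max_posterior": self.posterior.max(axis=1),
            }
        ).to_csv(path, index_label="examinee")


def response_prob(indicator, s, g):
    """P(y = 1 | gate) = 1 - s when the gate fires, g otherwise."""
    s = np.asarray(s, dtype=np.float64)
    g = np.asarray(g, dtype=np.float64)
    if ((s <= 0) | (s >= 1)).any() or ((g <= 0) | (g >= 1)).any():
        raise ValueError("slip and guess must lie strictly in (0, 1)")
    indicator = np.asarray(indicator)
    return np.where(indicator == 1, 1.0 - s, g)


def _class_log_likelihood(X: np.ndarray, eta: np.ndarray, s: np.ndarray, g: np.ndarray) -> np.ndarray:
    """n x C matrix of log P(x_row | class) under local independence."""
    p = np.where(eta == 1, 1.0 - s[None, :], g[None, :])  # C x I
    logp = np.log(p)
    log1mp = np.log1p(-p)
    return X @ logp.T + (1.0 - X) @ log1mp.T


def _enforce_monotone(s: np.ndarray, g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    s = np.clip(s, _PARAM_FLOOR, 1 - _PARAM_FLOOR)
    g = np.clip(g, _PARAM_FLOOR, 1 - _PARAM_FLOOR)
    bad = g >= 1 - s
    if bad.any():
        # shrink both toward the midpoint of [g, 1-s], leaving a 0.001 gap
        mid = (g[bad] + (1 - s[bad])) / 2.0
        g[bad] = np.clip(mid - _PARAM_FLOOR, _PARAM_FLOOR, 1 - _PARAM_FLOOR)
        s[bad] = np.clip(1 - (mid + _PARAM_FLOOR), _PARAM_FLOOR, 1 - _PARAM_FLOOR)
    return s, g


def fit(
    model: str,
    X: np.ndarray,
    Q: QMatrix,
    *,
    max_iter: int = 1000,
    param_tol: float = 1e-5,
    loglik_tol: float = 1e-8,
    init_slip: float = 0.2,
    init_guess: float = 0.2,
    estimate_priors: bool = True,
) -> DcmFit:
    """Fit DINA or DINO by EM on the marginal likelihood.

    Parameters
    ----------
    model : {"DINA", "DINO"}
    X : (n, I) binary response matrix.
    Q : Q-matrix with I rows.
    estimate_priors : update the class prior from posterior means each
        M-step (default); if False the prior stays uniform.

    EM stops when the largest absolute parameter change is below
    ``param_tol`` or the log-likelihood gain is below ``loglik_tol``.
    Non-convergence within ``max_iter`` sets ``converged=False`` rather
    than raising.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != Q.n_items:
        raise ValueError("X must be n x I with I matching the Q-matrix")
    if not np.isin(X, (0.0, 1.0)).all():
        raise ValueError("responses must be binary")
    model = model.upper()
    space = enumerate_classes(Q.n_attributes)
    eta = ideal_response_matrix(space, Q, model)  # C x I
    C = space.C
    n = X.shape[0]

    s = np.full(Q.n_items, init_slip, dtype=np.float64)
    g = np.full(Q.n_items, init_guess, dtype=np.float64)
    priors = np.full(C, 1.0 / C)

    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step
        logjoint = _class_log_likelihood(X, eta, s, g) + np.log(priors)[None, :]
        lse = logsumexp(logjoint, axis=1)
        trace.append(float(lse.sum()))
        R = np.exp(logjoint - lse[:, None])  # n x C posterior

        # M-step: expected gate-group counts per item
        w1 = R @ eta.astype(np.float64)  # n x I, posterior mass on gate-1 classes
        n1 = w1.sum(axis=0)
        r1 = (X * w1).sum(axis=0)
        n0 = n - n1
        r0 = (X * (1.0 - w1)).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            s_new = np.where(n1 > 0, 1.0 - r1 / np.maximum(n1, 1e-300), s)
            g_new = np.where(n0 > 0, r0 / np.maximum(n0, 1e-300), g)
        s_new, g_new = _enforce_monotone(s_new, g_new)
        priors_new = R.mean(axis=0) if estimate_priors else priors

        delta = max(
            np.abs(s_new - s).max(),
            np.abs(g_new - g).max(),
            np.abs(priors_new - priors).max(),
        )
        s, g, priors = s_new, g_new, priors_new
        if delta < param_tol:
            converged = True
            break
        if len(trace) >= 2 and trace[-1] - trace[-2] < loglik_tol and trace[-1] >= trace[-2]:
            converged = True
            break

    # final E-step with converged parameters
    logjoint = _class_log_likelihood(X, eta, s, g) + np.log(priors)[None, :]
    lse = logsumexp(logjoint, axis=1)
    trace.append(float(lse.sum()))
    R = np.exp(logjoint - lse[:, None])

    labels = np.argmax(R, axis=1) + 1  # argmax takes the lowest index on ties
    return DcmFit(
        model=model,
        params=ItemParams(slip=s, guess=g),
        class_priors=priors,
        posterior=R,
        labels=labels,
        loglik_trace=trace,
        n_iter=it,
        converged=converged,
        space=space,
    )


def classify(fit_result: DcmFit) -> tuple[np.ndarray, np.ndarray]:
    """MAP labels and their one-hot matrix (ties go to the lowest label)."""
    labels = np.argmax(fit_result.posterior, axis=1) + 1
    return labels, one_hot_matrix(labels, fit_result.posterior.shape[1])
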