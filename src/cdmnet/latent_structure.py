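"""Attribute-profile bookkeeping for diagnostic classification.

A diagnostic assessment measures K binary skills ("attributes"); an
examinee's latent state is an attribute profile in {0,1}^K, so there are
C = 2^K latent classes.  The Q-matrix records which attributes each item
measures.  This module owns the canonical class enumeration, one-hot
label codes, the conjunctive (DINA) and disjunctive (DINO) ideal-response
indicators, and controlled Q-matrix misspecification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "QMatrix",
    "LatentClassSpace",
    "enumerate_classes",
    "one_hot",
    "ideal_response_dina",
    "ideal_response_dino",
    "ideal_response_matrix",
    "perturb_qmatrix",
]


@dataclass(frozen=True)
class QMatrix:
    """Binary item-by-attribute incidence matrix.

    Rows are items, columns are attributes; entry (i, k) = 1 means item i
    measures attribute k.  Every item must measure at least one attribute.
    """

    entries: np.ndarray
    item_ids: tuple = ()
    attribute_ids: tuple = ()

    def __post_init__(self):
        entries = np.asarray(self.entries, dtype=np.int8)
        if entries.ndim != 2 or entries.shape[0] < 1 or entries.shape[1] < 1:
            raise ValueError("Q-matrix must be a 2-D items x attributes array")
        if not np.isin(entries, (0, 1)).all():
            raise ValueError("Q-matrix entries must be 0 or 1")
        if (entries.sum(axis=1) == 0).any():
            raise ValueError("every item must measure at least one attribute")
        object.__setattr__(self, "entries", entries)
        if not self.item_ids:
            object.__setattr__(
                self, "item_ids", tuple(f"item{i + 1}" for i in range(entries.shape[0]))
            )
        if not self.attribute_ids:
            object.__setattr__(
                self, "attribute_ids", tuple(f"attr{k + 1}" for k in range(entries.shape[1]))
            )
        if len(self.item_ids) != entries.shape[0]:
            raise ValueError("item_ids length does not match row count")
        if len(self.attribute_ids) != entries.shape[1]:
            raise ValueError("attribute_ids length does not match column count")

    @property
    def n_items(self) -> int:
        return self.entries.shape[0]

    @property
    def n_attributes(self) -> int:
        return self.entries.shape[1]

    def is_simple(self) -> np.ndarray:
        """Boolean vector: item measures exactly one attribute."""
        return self.entries.sum(axis=1) == 1

    @classmethod
    def from_csv(cls, path) -> "QMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(
            entries=df.to_numpy(),
            item_ids=tuple(str(i) for i in df.index),
            attribute_ids=tuple(str(c) for c in df.columns),
        )

    def to_csv(self, path) -> None:
        pd.DataFrame(
            self.entries, index=list(self.item_ids), columns=list(self.attribute_ids)
        ).to_csv(path)


@dataclass(frozen=True)
class LatentClassSpace:
    """All 2^K attribute profiles in a fixed, reproducible order.

    Profiles are ordered lexicographically with attribute 1 as the most
    significant bit; the all-zeros profile gets label 1 and the all-ones
    profile gets label C.  Labels are 1-based integers.
    """

    K: int
    profiles: np.ndarray = field(repr=False)

    @property
    def C(self) -> int:
        return 2 ** self.K

    @property
    def labels(self) -> np.ndarray:
        return np.arange(1, self.C + 1)

    def profile_of(self, label: int) -> np.ndarray:
        if not 1 <= label <= self.C:
            raise ValueError(f"label {label} outside 1..{self.C}")
        return self.profiles[label - 1]

    def label_of(self, profile) -> int:
        profile = np.asarray(profile, dtype=np.int64)
        powers = 2 ** np.arange(self.K - 1, -1, -1)
        return int(profile @ powers) + 1

    def profile_strings(self) -> list[str]:
        return ["".join(str(b) for b in row) for row in self.profiles]


def enumerate_classes(K: int) -> LatentClassSpace:
    """Enumerate all 2^K attribute profiles.

    Parameters
    ----------
    K : int
        Number of attributes, 1 <= K <= 10 (C = 2^K classes must stay
        enumerable).
    """
    if not 1 <= K <= 10:
        raise ValueError(f"attribute count K={K} outside supported range 1..10")
    C = 2 ** K
    # integer c-1 in binary, attribute 1 = most significant bit
    bits = (np.arange(C)[:, None] >> np.arange(K - 1, -1, -1)) & 1
    return LatentClassSpace(K=K, profiles=bits.astype(np.int8))


def one_hot(label: int, C: int) -> np.ndarray:
    """One-hot code for a 1-based class label: position `label` is 1."""
    if not 1 <= label <= C:
        raise ValueError(f"label {label} outside 1..{C}")
    v = np.zeros(C, dtype=np.int8)
    v[label - 1] = 1
    return v


def one_hot_matrix(labels: np.ndarray, C: int) -> np.ndarray:
    """Row-wise one-hot encoding of a vector of 1-based labels."""
    labels = np.asarray(labels)
    if labels.min() < 1 or labels.max() > C:
        raise ValueError("labels outside 1..C")
    out = np.zeros((labels.size, C), dtype=np.float64)
    out[np.arange(labels.size), labels - 1] = 1.0
    return out


def _check_lengths(profile, q_row):
    profile = np.asarray(profile)
    q_row = np.asarray(q_row)
    if profile.shape != q_row.shape:
        raise ValueError("profile and q-vector lengths differ")
    return profile, q_row


def ideal_response_dina(profile, q_row) -> int:
    """Conjunctive ideal response xi: 1 iff ALL measured attributes are mastered."""
    profile, q_row = _check_lengths(profile, q_row)
    return int(np.all(profile >= q_row))


def ideal_response_dino(profile, q_row) -> int:
    """Disjunctive ideal response omega: 1 iff ANY measured attribute is mastered."""
    profile, q_row = _check_lengths(profile, q_row)
    return int(np.any((profile == 1) & (q_row == 1)))


def ideal_response_matrix(space: LatentClassSpace, Q: QMatrix, model: str) -> np.ndarray:
    """C x I matrix of ideal responses for every (class, item) pair."""
    A = space.profiles.astype(np.int64)  # C x K
    q = Q.entries.astype(np.int64)  # I x K
    measured_mastered = A @ q.T  # counts of mastered-and-measured
    required = q.sum(axis=1)  # per item
    if model.upper() == "DINA":
        eta = (measured_mastered == required[None, :]).astype(np.int8)
    elif model.upper() == "DINO":
        eta = (measured_mastered > 0).astype(np.int8)
    else:
        raise ValueError(f"unknown model {model!r}; expected 'DINA' or 'DINO'")
    return eta


def perturb_qmatrix(Q: QMatrix, fraction: float, rng: np.random.Generator) -> QMatrix:
    """Flip a fixed fraction of Q-matrix entries to emulate expert misspecification.

    Exactly ``round(fraction * I * K)`` entries are flipped, sampled uniformly
    without replacement, under the constraint that no item may end up
    measuring zero attributes — in particular the single 1 of a
    simple-structure item can never be turned off.  Draws violating the
    constraint are rejected and resampled (bounded retries).
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be strictly between 0 and 1")
    I, K = Q.entries.shape
    n_flip = int(round(fraction * I * K))
    if n_flip == 0:
        return QMatrix(Q.entries.copy(), Q.item_ids, Q.attribute_ids)
    simple_row = Q.entries.sum(axis=1) == 1
    max_attempts = 10 * I * K
    for _ in range(max_attempts):
        flat = rng.choice(I * K, size=n_flip, replace=False)
        new = Q.entries.copy()
        rows, cols = np.unravel_index(flat, (I, K))
        # the lone 1 of a simple-structure item may never be turned off
        if (simple_row[rows] & (Q.entries[rows, cols] == 1)).any():
            continue
        new[rows, cols] = 1 - new[rows, cols]
        if (new.sum(axis=1) > 0).all():
            return QMatrix(new, Q.item_ids, Q.attribute_ids)
    raise RuntimeError(
        f"could not flip {n_flip} entries without creating an all-zero q-vector "
        f"after {max_attempts} attempts"
    )
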