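"""Simulation engine: item-by-class probability matrices and binary responses.

Data are generated from a general item-by-latent-class matrix Pi (I items
x C classes) rather than from a named diagnostic model's response
function.  For each item the latent classes fall into three groups with
respect to the item's q-vector — mastery (all measured attributes
mastered), partial mastery (a proper, non-empty subset) and non-mastery
(none) — and the item response probabilities (IRPs) are drawn uniformly
within group-specific intervals that control the item's discriminating
power d_i = pi(mastery) - pi(non-mastery):

====================  ==================  ============================
latent group          high discrimination  low discrimination
====================  ==================  ============================
non-mastery pi_0      U[0.15, 0.35]        U[0.20, 0.40]
partial pi_p          U[0.40, 0.60]        U[pi_0, pi_0 + w], w = 0.15
mastery pi_1          U[0.65, 0.90]        U[max pi_p, pi_0 + 0.30]  (complex)
                                           U[pi_0,    pi_0 + 0.30]  (simple)
====================  ==================  ============================

Mastery and non-mastery equivalence classes share a single IRP per item;
each partial-mastery equivalence class (distinct restriction of the
profile to the measured attributes) gets its own independent draw from
the partial interval, which injects within-interval heterogeneity no
standard diagnostic model would allow.  Draws are rejected and repeated
until mastery > every partial > non-mastery strictly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .latent_structure import LatentClassSpace, QMatrix, enumerate_classes

__all__ = [
    "ItemByClassMatrix",
    "SimulatedDataset",
    "build_qmatrix",
    "build_item_class_matrix",
    "item_discrimination",
    "simulate_profiles",
    "simulate_responses",
]

#: d_i above this is a highly discriminating item; at or below, low.
HIGH_DISCRIMINATION_THRESHOLD = 0.3

_MAX_REDRAWS = 100


@dataclass(frozen=True)
class ItemByClassMatrix:
    """Pi: I x C matrix of item response probabilities per latent class."""

    pi: np.ndarray
    qmatrix: QMatrix
    space: LatentClassSpace
    quality_tag: tuple  # "high" | "low" per item

    def __post_init__(self):
        pi = np.asarray(self.pi, dtype=np.float64)
        if pi.shape != (self.qmatrix.n_items, self.space.C):
            raise ValueError("Pi shape inconsistent with Q-matrix and class space")
        if not ((pi > 0) & (pi < 1)).all():
            raise ValueError("all IRPs must lie strictly in (0, 1)")
        object.__setattr__(self, "pi", pi)

    @property
    def n_items(self) -> int:
        return self.pi.shape[0]

    def discrimination(self) -> np.ndarray:
        """Per-item d_i = pi(all attributes mastered) - pi(none mastered)."""
        return self.pi[:, -1] - self.pi[:, 0]

    def to_csv(self, path) -> None:
        pd.DataFrame(
            self.pi,
            index=list(self.qmatrix.item_ids),
            columns=self.space.profile_strings(),
        ).to_csv(path)


@dataclass(frozen=True)
class SimulatedDataset:
    """Binary responses with their generating truth."""

    responses: np.ndarray  # n x I, {0,1}
    true_labels: np.ndarray  # n, 1-based class labels
    pi_matrix: ItemByClassMatrix
    seed_record: dict = field(default_factory=dict)

    @property
    def true_profiles(self) -> np.ndarray:
        return self.pi_matrix.space.profiles[self.true_labels - 1]

    @property
    def n(self) -> int:
        return self.responses.shape[0]

    def export(self, prefix) -> None:
        """Write responses, truth and a manifest next to `prefix`."""
        space = self.pi_matrix.space
        items = list(self.pi_matrix.qmatrix.item_ids)
        pd.DataFrame(self.responses, columns=items).to_csv(f"{prefix}_responses.csv", index_label="examinee")
        strings = space.profile_strings()
        pd.DataFrame(
            {
                "label": self.true_labels,
                "profile": [strings[c - 1] for c in self.true_labels],
            }
        ).to_csv(f"{prefix}_truth.csv", index_label="examinee")
        with open(f"{prefix}_manifest.json", "w") as fh:
            json.dump({"n": int(self.n), "K": space.K, **self.seed_record}, fh, indent=2)


def build_qmatrix(n_items: int, n_attributes: int, rng: np.random.Generator) -> QMatrix:
    """Construct a plausible diagnostic-form Q-matrix.

    Each attribute is measured in isolation by at least two items (an
    identity block appears twice, giving a complete Q-matrix, which keeps
    the latent classes identifiable); the remaining items are split evenly
    between additional single-attribute and two-attribute items with
    attributes drawn at random.  Row order is shuffled.
    """
    K = n_attributes
    if n_items < 2 * K:
        raise ValueError(f"need at least {2 * K} items for {K} attributes")
    rows = [np.eye(K, dtype=np.int8)[k] for k in range(K)] * 2
    remainder = n_items - 2 * K
    n_single = remainder - remainder // 2
    for i in range(remainder):
        row = np.zeros(K, dtype=np.int8)
        if i < n_single:
            row[rng.integers(K)] = 1
        else:
            row[rng.choice(K, size=2, replace=False)] = 1
        rows.append(row)
    entries = np.asarray(rows)
    return QMatrix(entries[rng.permutation(n_items)])


def _equivalence_codes(space: LatentClassSpace, q_row: np.ndarray) -> np.ndarray:
    """Integer code of each class's profile restricted to the measured attributes."""
    measured = np.flatnonzero(q_row)
    sub = space.profiles[:, measured].astype(np.int64)
    powers = 2 ** np.arange(len(measured) - 1, -1, -1)
    return sub @ powers


def _draw_item_irps(
    q_row: np.ndarray,
    space: LatentClassSpace,
    high: bool,
    rng: np.random.Generator,
    low_partial_width: float,
) -> np.ndarray:
    """One row of Pi: group-wise uniform draws, rejected until strictly monotone."""
    m = int(q_row.sum())
    codes = _equivalence_codes(space, q_row)
    mastery_code = 2 ** m - 1
    partial_codes = [c for c in range(1, mastery_code) ]
    for _ in range(_MAX_REDRAWS):
        if high:
            pi_non = rng.uniform(0.15, 0.35)
            pi_partial = {c: rng.uniform(0.40, 0.60) for c in partial_codes}
            pi_mast = rng.uniform(0.65, 0.90)
            if pi_mast - pi_non < HIGH_DISCRIMINATION_THRESHOLD:
                continue
        else:
            pi_non = rng.uniform(0.20, 0.40)
            pi_partial = {
                c: rng.uniform(pi_non, pi_non + low_partial_width) for c in partial_codes
            }
            if m == 1:  # simple item: no partial group
                pi_mast = rng.uniform(pi_non, pi_non + 0.30)
            else:
                pi_mast = rng.uniform(max(pi_partial.values()), pi_non + 0.30)
        values = [pi_non] + list(pi_partial.values()) + [pi_mast]
        if pi_mast <= pi_non:
            continue
        if pi_partial and not (
            all(pi_mast > p for p in pi_partial.values())
            and all(p > pi_non for p in pi_partial.values())
        ):
            continue
        if not all(0 < v < 1 for v in values):
            continue
        row = np.empty(space.C)
        row[codes == 0] = pi_non
        row[codes == mastery_code] = pi_mast
        for c in partial_codes:
            row[codes == c] = pi_partial[c]
        return row
    raise RuntimeError(
        f"could not draw monotone IRPs for q-vector {q_row.tolist()} "
        f"within {_MAX_REDRAWS} attempts"
    )


def build_item_class_matrix(
    Q: QMatrix,
    space: LatentClassSpace | None = None,
    quality: str = "high",
    rng: np.random.Generator | None = None,
    low_partial_width: float = 0.15,
) -> ItemByClassMatrix:
    """Draw the item-by-class matrix Pi for a full item pool.

    ``quality="high"`` marks every item highly discriminating;
    ``quality="mixed"`` marks a random half of the items low.
    ``low_partial_width`` is the width of the partial-mastery interval for
    low items (0.15 by default; 0.20 is an alternative reading of the
    generating rules).
    """
    if space is None:
        space = enumerate_classes(Q.n_attributes)
    if rng is None:
        rng = np.random.default_rng()
    if quality not in ("high", "mixed"):
        raise ValueError("quality must be 'high' or 'mixed'")
    I = Q.n_items
    tags = np.full(I, "high", dtype=object)
    if quality == "mixed":
        tags[rng.choice(I, size=I // 2, replace=False)] = "low"
    pi = np.empty((I, space.C))
    for i in range(I):
        pi[i] = _draw_item_irps(
            Q.entries[i], space, high=(tags[i] == "high"), rng=rng,
            low_partial_width=low_partial_width,
        )
    return ItemByClassMatrix(pi=pi, qmatrix=Q, space=space, quality_tag=tuple(tags))


def item_discrimination(row: np.ndarray, q_row: np.ndarray, space: LatentClassSpace) -> float:
    """d_i: IRP of the full-mastery class minus IRP of the no-mastery class.

    The all-ones and all-zeros profiles belong to the item's mastery and
    non-mastery groups for every q-vector, so their IRPs represent the
    group values.
    """
    row = np.asarray(row, dtype=np.float64)
    if row.shape != (space.C,):
        raise ValueError("IRP row length does not match class count")
    if np.asarray(q_row).shape != (space.K,):
        raise ValueError("q-vector length does not match attribute count")
    return float(row[-1] - row[0])


def classify_discrimination(d: float) -> str:
    """'high' if d > 0.3, else 'low'."""
    return "high" if d > HIGH_DISCRIMINATION_THRESHOLD else "low"


def simulate_profiles(
    n: int,
    space: LatentClassSpace,
    rng: np.random.Generator,
    class_weights: np.ndarray | None = None,
) -> np.ndarray:
    """Draw n true class labels i.i.d. (uniform over the 2^K classes by default)."""
    if n < 1:
        raise ValueError("need at least one examinee")
    if class_weights is None:
        return rng.integers(1, space.C + 1, size=n)
    w = np.asarray(class_weights, dtype=np.float64)
    if w.shape != (space.C,) or (w < 0).any() or w.sum() <= 0:
        raise ValueError("class_weights must be a nonnegative length-C vector")
    return rng.choice(space.C, size=n, p=w / w.sum()) + 1


def simulate_responses(
    pi_matrix: ItemByClassMatrix,
    labels: np.ndarray,
    rng: np.random.Generator,
    seed_record: dict | None = None,
) -> SimulatedDataset:
    """Bernoulli responses, independent across items given the true class."""
    labels = np.asarray(labels)
    if labels.min() < 1 or labels.max() > pi_matrix.space.C:
        raise ValueError("labels outside 1..C")
    probs = pi_matrix.pi[:, labels - 1].T  # n x I
    responses = (rng.random(probs.shape) < probs).astype(np.int8)
    return SimulatedDataset(
        responses=responses,
        true_labels=labels.copy(),
        pi_matrix=pi_matrix,
        seed_record=seed_record or {},
    )
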