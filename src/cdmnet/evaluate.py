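"""Accuracy metrics and the replication harness for the 12-condition study.

The study crosses test length (20 or 30 items), attribute count (3 or 4,
with 30 items only for 4 attributes), test diagnostic quality (high or
mixed) and Q-matrix accuracy (100% or 90% correct entries), at n = 1000
examinees per replication.  Truth is always generated under the accurate
Q-matrix and its item-by-class matrix; a 90%-accurate condition hands the
estimators a perturbed copy.  Each replication simulates fresh responses
from the condition's fixed Pi, fits DINA and DINO by EM, trains the
co-training ensemble, and scores five label sets against truth: DINA,
DINO, and the network on the whole sample (ANN), its training 80%
(ANN*), and its validation 20% (ANN**).

Replication seeds are derived from the master seed and the data-side
factors only, so the accurate-Q and 90%-Q variants of a condition see
identical simulated datasets and their accuracy drops are paired
comparisons.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cotrain_ann import NetworkConfig, make_split, select_lambda, train_ensemble
from .dcm_em import fit as fit_dcm
from .latent_structure import enumerate_classes, one_hot_matrix, perturb_qmatrix
from .simulate import build_item_class_matrix, build_qmatrix, simulate_profiles, simulate_responses

__all__ = [
    "ConditionSpec",
    "AccuracyReport",
    "CONDITION_FACTORS",
    "FACTOR_LEVELS",
    "condition_spec",
    "attribute_accuracy",
    "profile_accuracy",
    "run_condition",
    "aggregate",
    "run_study",
]

#: condition id -> (items, attributes, quality, q_accuracy); n = 1000 throughout
CONDITION_FACTORS = {
    1: (20, 3, "high", 1.00),
    2: (20, 3, "high", 0.90),
    3: (20, 3, "mixed", 1.00),
    4: (20, 3, "mixed", 0.90),
    5: (20, 4, "high", 1.00),
    6: (20, 4, "high", 0.90),
    7: (20, 4, "mixed", 1.00),
    8: (20, 4, "mixed", 0.90),
    9: (30, 4, "high", 1.00),
    10: (30, 4, "high", 0.90),
    11: (30, 4, "mixed", 1.00),
    12: (30, 4, "mixed", 0.90),
}

#: marginal factor levels over condition ids
FACTOR_LEVELS = {
    "quality=high": [c for c, f in CONDITION_FACTORS.items() if f[2] == "high"],
    "quality=mixed": [c for c, f in CONDITION_FACTORS.items() if f[2] == "mixed"],
    "q_accuracy=1.0": [c for c, f in CONDITION_FACTORS.items() if f[3] == 1.00],
    "q_accuracy=0.9": [c for c, f in CONDITION_FACTORS.items() if f[3] == 0.90],
    "all": list(CONDITION_FACTORS),
}

METHODS = ("DINA", "DINO", "ANN", "ANN*", "ANN**")


@dataclass(frozen=True)
class ConditionSpec:
    """One cell of the study design plus harness settings."""

    items: int
    attributes: int
    quality: str  # "high" | "mixed"
    q_accuracy: float  # 1.00 or 0.90
    n: int = 1000
    replications: int = 20
    members: int = 25
    lam: float = 0.5
    lambda_grid: tuple | None = None  # when set, lambda is selected per replication
    master_seed: int = 0
    network: NetworkConfig = field(default_factory=NetworkConfig)
    condition_id: int | None = None
    resample_misspecified_q: bool = False

    def __post_init__(self):
        if self.quality not in ("high", "mixed"):
            raise ValueError("quality must be 'high' or 'mixed'")
        if self.attributes == 3 and self.items == 30:
            raise ValueError("the 30-item form exists only for 4 attributes")


def condition_spec(condition_id: int, **overrides) -> ConditionSpec:
    """Spec for one of the 12 study conditions by its design id (1..12)."""
    try:
        items, attributes, quality, q_accuracy = CONDITION_FACTORS[condition_id]
    except KeyError:
        raise ValueError(f"unknown condition {condition_id}; valid ids are 1..12") from None
    return ConditionSpec(
        items=items, attributes=attributes, quality=quality, q_accuracy=q_accuracy,
        condition_id=condition_id, **overrides,
    )


@dataclass
class AccuracyReport:
    """Across-replication accuracy summary for one method in one condition."""

    method: str
    attribute_mean: np.ndarray  # K
    attribute_sd: np.ndarray
    profile_mean: float
    profile_sd: float
    per_replication_profile: np.ndarray
    per_replication_attribute: np.ndarray  # R x K


def attribute_accuracy(est_profiles: np.ndarray, true_profiles: np.ndarray) -> np.ndarray:
    """Per-attribute proportion of examinees with matching mastery status."""
    est_profiles = np.asarray(est_profiles)
    true_profiles = np.asarray(true_profiles)
    if est_profiles.shape != true_profiles.shape:
        raise ValueError("estimated and true profile arrays differ in shape")
    return (est_profiles == true_profiles).mean(axis=0)


def profile_accuracy(est_labels: np.ndarray, true_labels: np.ndarray) -> float:
    """Proportion of examinees whose whole profile (class label) matches truth."""
    est_labels = np.asarray(est_labels)
    true_labels = np.asarray(true_labels)
    if est_labels.shape != true_labels.shape:
        raise ValueError("estimated and true label vectors differ in shape")
    return float((est_labels == true_labels).mean())


def _data_seed(spec: ConditionSpec, tag: int) -> list:
    # q_accuracy deliberately absent: paired datasets across Q-accuracy levels
    qcode = 0 if spec.quality == "high" else 1
    return [spec.master_seed, spec.items, spec.attributes, qcode, tag]


def _derived_int(seq: list) -> int:
    return int(np.random.SeedSequence(seq).generate_state(1)[0] % (2**31))


def run_condition(spec: ConditionSpec, progress=None) -> dict:
    """Run one condition and return {method: AccuracyReport}.

    The Q-matrix and item-by-class matrix are built once and held fixed;
    every replication draws new examinees and responses from them.  When
    ``q_accuracy < 1`` the estimation side receives a perturbed Q-matrix
    (one perturbation per condition by default; set
    ``resample_misspecified_q`` to redraw it per replication).
    """
    space = enumerate_classes(spec.attributes)
    C = space.C
    rng_pool = np.random.default_rng(_data_seed(spec, 1))
    Q_true = build_qmatrix(spec.items, spec.attributes, rng_pool)
    Pi = build_item_class_matrix(Q_true, space, spec.quality, rng_pool)

    fraction = round(1.0 - spec.q_accuracy, 10)
    if fraction > 0 and not spec.resample_misspecified_q:
        Q_est = perturb_qmatrix(Q_true, fraction, np.random.default_rng(_data_seed(spec, 2)))
    else:
        Q_est = Q_true

    prof = {m: [] for m in METHODS}
    attr = {m: [] for m in METHODS}
    for r in range(spec.replications):
        rng = np.random.default_rng(_data_seed(spec, 1000 + r))
        labels_true = simulate_profiles(spec.n, space, rng)
        data = simulate_responses(Pi, labels_true, rng)
        X = data.responses

        if fraction > 0 and spec.resample_misspecified_q:
            Q_est = perturb_qmatrix(
                Q_true, fraction, np.random.default_rng(_data_seed(spec, 5000 + r) + [17])
            )

        dina = fit_dcm("DINA", X, Q_est)
        dino = fit_dcm("DINO", X, Q_est)
        Y1 = one_hot_matrix(dina.labels, C)
        Y2 = one_hot_matrix(dino.labels, C)

        split = make_split(spec.n, rng)
        ann_seed = _derived_int(_data_seed(spec, 3000 + r))
        lam = spec.lam
        if spec.lambda_grid is not None:
            lam = select_lambda(X, Y1, Y2, split, spec.lambda_grid, spec.network, ann_seed)
        result = train_ensemble(X, Y1, Y2, split, lam, spec.members, spec.network, ann_seed)

        true_prof = data.true_profiles
        estimates = {
            "DINA": (dina.labels, slice(None)),
            "DINO": (dino.labels, slice(None)),
            "ANN": (result.labels_whole, slice(None)),
            "ANN*": (result.labels_train, split.train_idx),
            "ANN**": (result.labels_valid, split.valid_idx),
        }
        for method, (est, rows) in estimates.items():
            truth_labels = labels_true[rows]
            prof[method].append(profile_accuracy(est, truth_labels))
            attr[method].append(
                attribute_accuracy(space.profiles[est - 1], true_prof[rows])
            )
        if progress is not None:
            progress(spec, r)

    reports = {}
    for method in METHODS:
        p = np.asarray(prof[method])
        a = np.asarray(attr[method])
        reports[method] = AccuracyReport(
            method=method,
            attribute_mean=a.mean(axis=0),
            attribute_sd=a.std(axis=0, ddof=1) if len(p) > 1 else np.zeros(a.shape[1]),
            profile_mean=float(p.mean()),
            profile_sd=float(p.std(ddof=1)) if len(p) > 1 else 0.0,
            per_replication_profile=p,
            per_replication_attribute=a,
        )
    return reports


def aggregate(condition_values: dict, conditions) -> float:
    """Unweighted mean of condition-level values over the given condition ids."""
    missing = [c for c in conditions if c not in condition_values]
    if missing:
        raise ValueError(f"cannot aggregate; missing conditions: {missing}")
    return float(np.mean([condition_values[c] for c in conditions]))


def reports_to_frame(condition_id: int, reports: dict) -> pd.DataFrame:
    """Long-format summary: one row per method x statistic."""
    rows = []
    for method, rep in reports.items():
        for stat, attr_vals, cls_val in (
            ("mean", rep.attribute_mean, rep.profile_mean),
            ("sd", rep.attribute_sd, rep.profile_sd),
        ):
            row = {"condition": condition_id, "method": method, "statistic": stat}
            row.update({f"attribute{k + 1}": v for k, v in enumerate(attr_vals)})
            row["class"] = cls_val
            rows.append(row)
    return pd.DataFrame(rows)


def run_study(
    condition_ids,
    out_dir=None,
    progress=None,
    **overrides,
) -> dict:
    """Run several conditions; optionally write per-condition and summary files.

    Returns {"reports": {cid: {method: AccuracyReport}},
             "marginals": {factor-level: {method: mean profile accuracy}}}.
    Marginals are only computed over factor levels fully covered by
    ``condition_ids``.
    """
    all_reports = {}
    for cid in condition_ids:
        spec = condition_spec(cid, **overrides)
        all_reports[cid] = run_condition(spec, progress=progress)

    marginals = {}
    for level, members in FACTOR_LEVELS.items():
        if all(c in all_reports for c in members):
            per_method = {}
            for method in METHODS:
                values = {c: all_reports[c][method].profile_mean for c in members}
                per_method[method] = aggregate(values, members)
            marginals[level] = per_method

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        frames = []
        for cid, reports in all_reports.items():
            frame = reports_to_frame(cid, reports)
            frame.to_csv(out_dir / f"condition_{cid:02d}.csv", index=False)
            frames.append(frame)
        pd.concat(frames, ignore_index=True).to_csv(out_dir / "summary.csv", index=False)
        with open(out_dir / "marginals.json", "w") as fh:
            json.dump(marginals, fh, indent=2)
    return {"reports": all_reports, "marginals": marginals}
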