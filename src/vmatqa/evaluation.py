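"""Prediction metrics, ROC/AUC, the 90% action limit, and dataset splitting.

RMSE, MAE and MAPE follow the usual definitions (MAPE in percent); AUC uses
the rank (Mann-Whitney) formulation with ties counted one-half, which equals
trapezoidal integration of the full ROC curve.  A field passes QA iff its
gamma passing rate strictly exceeds the 0.90 action limit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from sklearn import metrics as skm

ACTION_LIMIT = 0.90
CRITERIA = ("3%/3mm", "3%/2mm", "2%/2mm", "1%/1mm")


@dataclass
class PredictionSet:
    y: np.ndarray
    y_hat: np.ndarray
    criterion: str = ""

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.y_hat = np.asarray(self.y_hat, dtype=float)
        if self.y.shape != self.y_hat.shape or self.y.ndim != 1:
            raise ValueError("y and y_hat must be equal-length vectors")
        if len(self.y) < 1:
            raise ValueError("empty prediction set")


def rmse(ps: PredictionSet) -> float:
    return float(np.sqrt(np.mean((ps.y - ps.y_hat) ** 2)))


def mae(ps: PredictionSet) -> float:
    return float(np.mean(np.abs(ps.y - ps.y_hat)))


def mape(ps: PredictionSet) -> float:
    """Mean absolute percentage error, in percent."""
    if np.any(ps.y == 0):
        raise ValueError("MAPE undefined: actual value of 0 present")
    return float(100.0 * np.mean(np.abs((ps.y - ps.y_hat) / ps.y)))


def roc_auc(labels: np.ndarray, scores: np.ndarray):
    """AUC (rank formulation, ties = 1/2) and the full ROC curve points."""
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present for ROC/AUC")
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    ranks = sps.rankdata(scores)
    auc = (ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
    fpr, tpr, thr = skm.roc_curve(labels, scores, drop_intermediate=False)
    return float(auc), (fpr, tpr, thr)


def classify_pass(gpr: float | np.ndarray) -> np.ndarray | bool:
    """Pass iff GPR strictly exceeds the 90% universal action limit."""
    out = np.asarray(gpr, dtype=float) > ACTION_LIMIT
    return bool(out) if out.ndim == 0 else out


@dataclass
class SplitAssignment:
    train: np.ndarray  # field indices
    val: np.ndarray
    test: np.ndarray
    seed: int
    plan_split: dict[str, list] = field(default_factory=dict)


def split_dataset(plan_ids, seed: int, fractions=(0.70, 0.15, 0.15),
                  unit: str = "plan", stratify_by=None) -> SplitAssignment:
    """Random 70/15/15 split at plan level (all fields of a plan share a split).

    ``unit='field'`` splits fields independently instead.  ``stratify_by``
    (optional, one label per unit in sorted-unit order) splits each stratum
    separately; off by default — the reference protocol is a pure random
    plan-level split.
    """
    plan_ids = np.asarray(plan_ids)
    rng = np.random.default_rng(seed)
    if unit == "plan":
        units = np.unique(plan_ids)
    elif unit == "field":
        units = np.arange(len(plan_ids))
    else:
        raise ValueError("unit must be 'plan' or 'field'")
    if len(units) < 3:
        raise ValueError("need at least 3 plans to split")

    def _partition(members):
        perm = rng.permutation(members)
        n = len(members)
        n_train = int(round(fractions[0] * n))
        n_val = int(round(fractions[1] * n))
        return (perm[:n_train], perm[n_train:n_train + n_val],
                perm[n_train + n_val:])

    if stratify_by is None:
        tr, va, te = _partition(units)
    else:
        strata = np.asarray(stratify_by)
        if len(strata) != len(units):
            raise ValueError("stratify_by must give one label per unit")
        parts = [[], [], []]
        for s in np.unique(strata):
            for bucket, part in zip(parts, _partition(units[strata == s])):
                bucket.append(part)
        tr, va, te = (np.concatenate(b) if b else np.array([], dtype=int)
                      for b in parts)
    if unit == "plan":
        idx = np.arange(len(plan_ids))
        pick = lambda group: idx[np.isin(plan_ids, group)]
        return SplitAssignment(
            train=pick(tr), val=pick(va), test=pick(te), seed=seed,
            plan_split={"train": tr.tolist(), "val": va.tolist(), "test": te.tolist()},
        )
    return SplitAssignment(train=np.sort(tr), val=np.sort(va), test=np.sort(te),
                           seed=seed)


def evaluate_predictions(
    y: np.ndarray, y_hat: np.ndarray, pass_scores: np.ndarray | None = None
) -> dict:
    """Per-criterion MAE/MAPE/RMSE (and AUC when scores are given) for one split.

    ``y``/``y_hat``: (N, 4) GPR arrays on [0, 1], columns ordered as
    :data:`CRITERIA`; ``pass_scores``: (N, 4) pass probabilities.
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    y_hat = np.atleast_2d(np.asarray(y_hat, dtype=float))
    report: dict = {}
    for k, crit in enumerate(CRITERIA):
        ps = PredictionSet(y[:, k], y_hat[:, k], criterion=crit)
        entry = {"MAE": mae(ps), "MAPE": mape(ps), "RMSE": rmse(ps)}
        if pass_scores is not None:
            labels = classify_pass(y[:, k]).astype(int)
            if len(np.unique(labels)) == 2:
                auc, _ = roc_auc(labels, np.asarray(pass_scores)[:, k])
                entry["AUC"] = auc
            else:
                entry["AUC"] = None
        report[crit] = entry
    return report


def report_to_json(report: dict, path) -> None:
    with open(path, "w") as f:
        json.dump(report, f, indent=1, sort_keys=True)


def report_from_json(path) -> dict:
    with open(path) as f:
        return json.load(f)
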