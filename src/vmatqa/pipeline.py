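"""End-to-end orchestration: cohort -> split -> z-score -> train -> report.

Standardization statistics are fitted on the training split only and reused
verbatim for validation and test; the split is made at plan level so no
plan's fields straddle splits.
"""

from __future__ import annotations

import numpy as np

from .evaluation import SplitAssignment, evaluate_predictions, split_dataset
from .mpc import ZScoreStats, zscore_fit_transform
from .nn.autograd import get_default_dtype
from .nn.models import ModelConfig, predict_arrays, train
from .synthetic import SyntheticCohort


def standardize_features(
    cohort: SyntheticCohort, split: SplitAssignment,
) -> tuple[dict[str, np.ndarray], dict[str, ZScoreStats]]:
    """Z-score C/R/D (per feature) and L (per metric over all train days)
    with training-split statistics; calendar encodings pass through."""
    tr = split.train
    out: dict[str, np.ndarray] = {}
    stats: dict[str, ZScoreStats] = {}
    for key in ("C", "R", "D"):
        x = getattr(cohort, key)
        _, st = zscore_fit_transform(x[tr])
        out[key], _ = zscore_fit_transform(x, st)
        stats[key] = st
    L = cohort.L
    _, stL = zscore_fit_transform(L[tr].reshape(-1, L.shape[-1]))
    out["L"], _ = zscore_fit_transform(L, stL)
    stats["L"] = stL
    out["cal"] = cohort.calendar
    dt = get_default_dtype()
    return {k: np.asarray(v, dtype=dt) for k, v in out.items()}, stats


def run_training(
    cohort: SyntheticCohort,
    cfg: ModelConfig,
    model_name: str = "informer_cnn",
    split_seed: int = 0,
    split_unit: str = "plan",
    verbose: bool = False,
):
    """Split, standardize, train, and evaluate one model.

    Returns (model, history, report) where the report carries per-criterion
    MAE/MAPE/RMSE and AUC for the validation and test splits.
    """
    split = split_dataset(cohort.plan_ids, seed=split_seed, unit=split_unit)
    arrays, stats = standardize_features(cohort, split)
    model, history = train(arrays, cohort.labels, split, cfg,
                           model_name=model_name, verbose=verbose)
    report = {"model": model_name, "split_seed": split_seed}
    for name, idx in (("validation", split.val), ("test", split.test)):
        if len(idx) == 0:
            report[name] = None
            continue
        sub = {k: v[idx] for k, v in arrays.items()}
        gpr_hat, pass_prob = predict_arrays(model, sub)
        report[name] = evaluate_predictions(
            cohort.labels[idx], np.clip(gpr_hat, 1e-4, 1.0), pass_prob)
    report["noise_floor_mae"] = cohort.noise_floor_mae.tolist()
    return model, history, report, split, stats
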