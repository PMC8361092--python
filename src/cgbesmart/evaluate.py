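"""Dataset splitting, trisection cross-validation, and benchmarking metrics.

Splits are always by site, never by position, so no target sequence leaks
between partitions.  The benchmarking metrics are Pearson correlation and
RMSE between observed and predicted efficiencies, either pooled over all
(site, position) pairs or averaged per protospacer position (the convention
used for endogenous-site evaluation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_tables import ValidationError


@dataclass
class SplitPlan:
    """Site-level partition into train / val / test."""

    assignment: dict[str, str]
    seed: int

    def sites(self, part: str) -> list[str]:
        return [s for s, p in self.assignment.items() if p == part]


def _largest_remainder(n: int, fractions: tuple[float, ...]) -> list[int]:
    exact = [n * f for f in fractions]
    counts = [int(e) for e in exact]
    for _ in range(n - sum(counts)):
        remainders = [e - c for e, c in zip(exact, counts)]
        i = int(np.argmax(remainders))
        counts[i] += 1
        exact[i] = counts[i]  # zero its remainder
    return counts


def split_613(
    site_ids: list[str],
    seed: int,
    fractions: tuple[float, float, float] = (0.6, 0.1, 0.3),
) -> SplitPlan:
    """Seeded 6:1:3 train/validation/test split (largest-remainder rounding)."""
    if len(site_ids) < 10:
        raise ValidationError(f"need >= 10 sites to split, got {len(site_ids)}")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValidationError("split fractions must sum to 1")
    rng = np.random.default_rng(seed)
    order = list(site_ids)
    rng.shuffle(order)
    n_train, n_val, n_test = _largest_remainder(len(order), fractions)
    assignment = {}
    for i, sid in enumerate(order):
        if i < n_train:
            assignment[sid] = "train"
        elif i < n_train + n_val:
            assignment[sid] = "val"
        else:
            assignment[sid] = "test"
    return SplitPlan(assignment, seed)


def split_41(site_ids: list[str], seed: int) -> SplitPlan:
    """4:1 train/validation preset (used when testing on endogenous data)."""
    return split_613(site_ids, seed, fractions=(0.8, 0.2, 0.0))


def trisection_cv(site_ids: list[str], seed: int) -> list[SplitPlan]:
    """Three folds; each site is tested exactly once; within each fold 10% of
    the training portion is held out for validation."""
    if len(site_ids) < 15:
        raise ValidationError(f"need >= 15 sites for trisection, got {len(site_ids)}")
    rng = np.random.default_rng(seed)
    order = list(site_ids)
    rng.shuffle(order)
    sizes = _largest_remainder(len(order), (1 / 3, 1 / 3, 1 / 3))
    folds = []
    start = 0
    for s in sizes:
        folds.append(order[start : start + s])
        start += s
    plans = []
    for i, test_fold in enumerate(folds):
        train_pool = [s for j, f in enumerate(folds) if j != i for s in f]
        fold_rng = np.random.default_rng([seed, i])
        pool = list(train_pool)
        fold_rng.shuffle(pool)
        n_val = max(int(round(0.1 * len(pool))), 1)
        assignment = {s: "test" for s in test_fold}
        assignment.update({s: "val" for s in pool[:n_val]})
        assignment.update({s: "train" for s in pool[n_val:]})
        plans.append(SplitPlan(assignment, seed))
    return plans


def pearson_r(a: np.ndarray, b: np.ndarray) -> float:
    return float(stats.pearsonr(a, b).statistic)


def benchmark(
    predicted,
    observed,
    mode: str = "pooled",
    positions=None,
) -> dict:
    """Pearson R and RMSE between predicted and observed efficiencies.

    ``mode='pooled'``: single R and RMSE over all aligned pairs.
    ``mode='per_position_average'``: R per protospacer position, then the
    unweighted mean (RMSE still pooled); positions whose observed or
    predicted vector has zero variance (or fewer than 3 pairs) are skipped
    and reported.
    """
    pred = np.asarray(predicted, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if pred.shape != obs.shape:
        raise ValidationError("predicted/observed shapes differ")
    if pred.size == 0:
        raise ValidationError("zero overlapping pairs")
    rmse = float(np.sqrt(np.mean((pred - obs) ** 2)))

    if mode == "pooled":
        if pred.size < 3:
            raise ValidationError("need >= 3 pairs for a correlation")
        if np.std(pred) == 0 or np.std(obs) == 0:
            return {"pearson_r": float("nan"), "rmse": rmse, "n": int(pred.size),
                    "skipped": ["zero variance"]}
        return {"pearson_r": pearson_r(pred, obs), "rmse": rmse,
                "n": int(pred.size), "skipped": []}

    if mode != "per_position_average":
        raise ValidationError(f"unknown benchmark mode {mode!r}")
    if positions is None:
        raise ValidationError("per_position_average mode needs positions")
    pos = np.asarray(positions)
    per_position: dict[int, float] = {}
    skipped: list[int] = []
    for p in sorted(set(pos.tolist())):
        m = pos == p
        if m.sum() < 3 or np.std(pred[m]) == 0 or np.std(obs[m]) == 0:
            skipped.append(int(p))
            continue
        per_position[int(p)] = pearson_r(pred[m], obs[m])
    if not per_position:
        raise ValidationError("no position had a defined correlation")
    mean_r = float(np.mean(list(per_position.values())))
    return {
        "pearson_r": mean_r,
        "rmse": rmse,
        "n": int(pred.size),
        "per_position_r": per_position,
        "skipped": skipped,
    }


def predictions_frame_to_pairs(
    predicted: pd.DataFrame, observed: pd.DataFrame
) -> pd.DataFrame:
    """Inner-join predicted and observed on (site_id, position)."""
    merged = predicted.merge(
        observed, on=["site_id", "position"], suffixes=("_pred", "_obs")
    )
    if merged.empty:
        raise ValidationError("zero overlapping (site, position) pairs")
    return merged
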