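"""Model validation and variable selection.

Validation follows the standard presence/background protocol: threshold-free
discrimination by AUC (Mann-Whitney form), better-than-chance testing by the
partial-ROC ratio restricted to the high-sensitivity region, and subsampling
replicates for cross-validation. Variable selection reconstructs the
reiterative jackknife: repeatedly drop the variable with the lowest
single-variable training gain, then enforce a pairwise correlation cap on
background values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geo import ClimateStack, OccurrenceSet, extract_values, sample_background
from .maxent import ModelSettings

__all__ = [
    "ReplicateSet",
    "VariableSelectionReport",
    "auc",
    "partial_auc_ratio",
    "subsample_replicates",
    "jackknife_importance",
    "select_variables",
]


def auc(presence_scores, background_scores) -> float:
    """Mann-Whitney AUC: P(presence score > background score), ties count 1/2."""
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if p.size == 0 or b.size == 0:
        raise ValueError("both score lists must be non-empty")
    from scipy.stats import rankdata
    ranks = rankdata(np.concatenate([p, b]))
    u = ranks[:p.size].sum() - p.size * (p.size + 1) / 2.0
    return float(u / (p.size * b.size))


def _roc_points(presence_scores, background_scores):
    """(FPR, TPR) step-curve points from (0,0) to (1,1), FPR ascending."""
    p = np.asarray(presence_scores, float)
    b = np.asarray(background_scores, float)
    thresholds = np.unique(np.concatenate([p, b]))[::-1]
    tpr = [(p >= t).mean() for t in thresholds]
    fpr = [(b >= t).mean() for t in thresholds]
    fpr = np.concatenate([[0.0], fpr, [1.0]])
    tpr = np.concatenate([[0.0], tpr, [1.0]])
    order = np.lexsort((tpr, fpr))
    return fpr[order], tpr[order]


def _partial_roc_ratio(presence_scores, background_scores, omission_e):
    """Partial-ROC ratio over sensitivity >= 1 - E against the chance diagonal."""
    fpr, tpr = _roc_points(presence_scores, background_scores)
    sens_floor = 1.0 - omission_e
    # FPR at which the curve first reaches the sensitivity floor
    if tpr[0] >= sens_floor:
        fpr_star = fpr[0]
    else:
        idx = np.searchsorted(tpr, sens_floor, side="left")
        idx = min(idx, len(tpr) - 1)
        lo, hi = idx - 1, idx
        if tpr[hi] == tpr[lo]:
            fpr_star = fpr[hi]
        else:
            frac = (sens_floor - tpr[lo]) / (tpr[hi] - tpr[lo])
            fpr_star = fpr[lo] + frac * (fpr[hi] - fpr[lo])
    grid = np.linspace(fpr_star, 1.0, 512)
    curve = np.interp(grid, fpr, tpr)
    model_area = float(np.trapezoid(np.maximum(curve, sens_floor), grid))
    null_area = float((1.0 - fpr_star ** 2) / 2.0)
    if null_area <= 0:
        return float("nan")
    return model_area / null_area


def partial_auc_ratio(presence_scores, background_scores, omission_E: float = 0.05,
                      n_boot: int = 100, resample_fraction: float = 0.5, seed=None):
    """Bootstrap partial-ROC ratio; returns ``(mean ratio, p_value)``.

    Each replicate resamples ``resample_fraction`` of the presences with
    replacement and computes the ROC area over sensitivity >= 1 - E divided
    by the chance-diagonal area over the same region; ``p`` is the fraction
    of replicates with ratio <= 1 (mean ratio > 1 means better than chance).
    """
    if not (0 < omission_E < 0.5):
        raise ValueError("omission_E must lie in (0, 0.5)")
    p = np.asarray(presence_scores, float)
    b = np.asarray(background_scores, float)
    n_res = int(round(resample_fraction * p.size))
    if n_res < 1:
        raise ValueError(f"too few presences ({p.size}) to resample "
                         f"a fraction of {resample_fraction}")
    rng = np.random.default_rng(seed)
    ratios = np.empty(n_boot)
    for i in range(n_boot):
        sample = p[rng.integers(0, p.size, size=n_res)]
        ratios[i] = _partial_roc_ratio(sample, b, omission_E)
    return float(np.nanmean(ratios)), float(np.mean(ratios <= 1.0))


@dataclass
class ReplicateSet:
    """Train/test index splits for subsampling cross-validation."""

    splits: list  # [(train_idx, test_idx), ...]
    n_points: int
    test_fraction: float
    seed: object = None

    def __len__(self):
        return len(self.splits)

    def __iter__(self):
        return iter(self.splits)

    def to_frame(self):
        rows = [{"replicate": i, "role": role, "index": int(k)}
                for i, (tr, te) in enumerate(self.splits)
                for role, idx in (("train", tr), ("test", te)) for k in idx]
        return pd.DataFrame(rows)


def subsample_replicates(n_points: int, n_replicates: int, test_fraction: float,
                         seed) -> ReplicateSet:
    """Independent uniform train/test splits; deterministic given seed."""
    if not (0 < test_fraction < 1):
        raise ValueError("test_fraction must be in (0, 1)")
    n_test = int(round(test_fraction * n_points))
    if n_test < 1 or n_test >= n_points:
        raise ValueError(f"test_fraction {test_fraction} gives impossible test "
                         f"size {n_test} of {n_points}")
    rng = np.random.default_rng(seed)
    splits = []
    for _ in range(n_replicates):
        perm = rng.permutation(n_points)
        test = np.sort(perm[:n_test])
        train = np.sort(perm[n_test:])
        splits.append((train, test))
    return ReplicateSet(splits, n_points, test_fraction, seed)


def jackknife_importance(presence_values, background_values, variables=None,
                         settings: ModelSettings | None = None) -> pd.DataFrame:
    """Per-variable training gain with the variable alone and without it.

    Gain is ``ln(n_background)`` minus the unpenalized negative log-likelihood
    part of the fitted objective (the MaxEnt "training gain"); an
    uninformative variable has gain_alone near zero, and dropping a redundant
    variable barely lowers the all-variable gain.
    """
    presence_values = pd.DataFrame(presence_values)
    background_values = pd.DataFrame(background_values)
    if variables is None:
        variables = list(presence_values.columns)
    if len(variables) < 2:
        raise ValueError("jackknife needs at least 2 variables")
    settings = settings or ModelSettings()
    rows = []
    for v in variables:
        try:
            alone = settings.fit(presence_values[[v]], background_values[[v]])
            others = [w for w in variables if w != v]
            without = settings.fit(presence_values[others], background_values[others])
        except Exception as exc:  # fit failure context
            raise RuntimeError(f"jackknife fit failed for variable {v!r}: {exc}") from exc
        rows.append({"variable": v, "gain_alone": alone.training_gain,
                     "gain_without": without.training_gain})
    return pd.DataFrame(rows).set_index("variable")


@dataclass
class VariableSelectionReport:
    """Audit trail of the reiterative jackknife + correlation filtering."""

    iterations: list  # list of per-iteration jackknife DataFrames
    removed: list = field(default_factory=list)  # (variable, reason)
    correlation_matrix: pd.DataFrame = None
    final_variables: list = field(default_factory=list)

    def removal_table(self):
        return pd.DataFrame(self.removed, columns=["variable", "reason"])


def select_variables(stack: ClimateStack, training_occurrences: OccurrenceSet,
                     r_threshold: float = 0.8, target_k: int = 4,
                     settings: ModelSettings | None = None,
                     n_background: int = 2000, seed=0) -> VariableSelectionReport:
    """Reiterative jackknife variable selection with a correlation cap.

    Starting from all stack variables: fit, compute the jackknife table, and
    drop the variable with the lowest single-variable gain until ``target_k``
    remain; then, on background-cell values, repeatedly drop the lower-gain
    member of any pair with ``|Pearson r| > r_threshold``. Every step is
    recorded in the returned report.
    """
    if target_k < 1:
        raise ValueError("target_k must be >= 1")
    if not (0 < r_threshold <= 1):
        raise ValueError("r_threshold must be in (0, 1]")
    if len(stack.names) < target_k:
        raise ValueError(f"stack has {len(stack.names)} variables; target_k={target_k}")
    settings = settings or ModelSettings()
    presence_all = extract_values(stack, training_occurrences)
    n_background = min(n_background, stack.n_unmasked)
    background_all, _ = sample_background(stack, n_background, seed)
    current = list(stack.names)
    report = VariableSelectionReport(iterations=[])
    gains = None
    while len(current) > target_k:
        table = jackknife_importance(presence_all[current], background_all[current],
                                     current, settings)
        report.iterations.append(table)
        gains = table["gain_alone"]
        worst = gains.idxmin()
        report.removed.append((worst, f"lowest gain_alone ({gains[worst]:.4f})"))
        current = [v for v in current if v != worst]
    # final jackknife for gain ranking inside the correlation filter
    if len(current) >= 2:
        table = jackknife_importance(presence_all[current], background_all[current],
                                     current, settings)
        report.iterations.append(table)
        gains = table["gain_alone"]
    corr = background_all[current].corr(method="pearson")
    report.correlation_matrix = corr
    while len(current) >= 2:
        corr = background_all[current].corr(method="pearson")
        worst_pair, worst_r = None, r_threshold
        for i, a in enumerate(current):
            for b in current[i + 1:]:
                if abs(corr.loc[a, b]) > worst_r:
                    worst_pair, worst_r = (a, b), abs(corr.loc[a, b])
        if worst_pair is None:
            break
        a, b = worst_pair
        drop = a if gains[a] <= gains[b] else b
        report.removed.append((drop, f"|r|={worst_r:.3f} with "
                               f"{b if drop == a else a} > {r_threshold}"))
        current = [v for v in current if v != drop]
    report.final_variables = current
    return report
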