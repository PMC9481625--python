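"""Schoener's D niche overlap and randomization tests.

Overlap between two alleles' fitted suitability distributions is measured by
Schoener's D = 1 - 0.5 * sum |p_i - q_i| over cells (geographic space) or
over a Latin-hypercube sample of climate space (environmental space), with
each surface first normalized to unit mass. Two permutation tests probe its
significance:

* the **niche identity test** pools the two alleles' occurrence records and
  repeatedly repartitions them at random into groups of the original sizes,
  refitting both models — a one-sided test for D lower than exchangeable;
* the **background similarity test** replaces one allele's records by random
  points from its available background region, a two-sided test of whether
  the observed overlap differs from what the landscapes alone would give.

Both tests refit every replicate with the observed models' settings
(no per-replicate re-tuning) and use the add-one permutation p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.stats import qmc

from .geo import ClimateStack, OccurrenceSet, extract_values, sample_background
from .maxent import MaxentNicheModel, MaxentResults, ModelSettings, SuitabilitySurface

__all__ = [
    "OverlapResult",
    "schoener_d",
    "schoener_d_geographic",
    "schoener_d_environment",
    "identity_test",
    "background_test",
]


def schoener_d(p, q) -> float:
    """D between two non-negative weight vectors, normalized to unit mass."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("weight vectors must share a shape")
    ps, qs = p.sum(), q.sum()
    if ps <= 0 or qs <= 0:
        raise ValueError("zero total mass in a suitability vector")
    return float(1.0 - 0.5 * np.abs(p / ps - q / qs).sum())


def schoener_d_geographic(surface_a: SuitabilitySurface,
                          surface_b: SuitabilitySurface) -> float:
    """D over the shared unmasked cells of two co-registered surfaces."""
    if not surface_a.same_grid(surface_b):
        raise ValueError("surfaces are not on the same grid")
    shared = surface_a.mask & surface_b.mask
    if not shared.any():
        raise ValueError("surfaces share no unmasked cells")
    return schoener_d(surface_a.values[shared], surface_b.values[shared])


def _pooled_ranges(results_a: MaxentResults, results_b: MaxentResults):
    ranges = {}
    for res in (results_a, results_b):
        exp = res.model.expansion
        for v, lo, hi in zip(exp.variables, exp.mins, exp.maxs):
            if v in ranges:
                ranges[v] = (min(ranges[v][0], lo), max(ranges[v][1], hi))
            else:
                ranges[v] = (float(lo), float(hi))
    return ranges


def schoener_d_environment(results_a: MaxentResults, results_b: MaxentResults,
                           variable_ranges: dict | None = None,
                           n_points: int = 10_000, seed=0) -> float:
    """D in continuous climate space, sampled by Latin hypercube.

    Points are drawn over the hyper-rectangle of pooled training ranges
    (overridable via ``variable_ranges``); both models score them on the raw
    scale with clamping, and the score vectors are normalized before D.
    """
    if n_points < 100:
        raise ValueError("n_points < 100 gives an unstable estimate")
    if variable_ranges is None:
        variable_ranges = _pooled_ranges(results_a, results_b)
    variables = sorted(variable_ranges)
    for res in (results_a, results_b):
        missing = [v for v in res.model.expansion.variables if v not in variables]
        if missing:
            raise ValueError(f"ranges lack model variables {missing}")
    sampler = qmc.LatinHypercube(d=len(variables), seed=np.random.default_rng(seed))
    unit = sampler.random(n_points)
    lo = np.array([variable_ranges[v][0] for v in variables])
    hi = np.array([variable_ranges[v][1] for v in variables])
    pts = pd.DataFrame(qmc.scale(unit, lo, hi), columns=variables)
    sa = results_a.predict(pts[results_a.model.expansion.variables],
                           output_scale="raw", clamp=True)
    sb = results_b.predict(pts[results_b.model.expansion.variables],
                           output_scale="raw", clamp=True)
    return schoener_d(sa, sb)


@dataclass
class OverlapResult:
    """Observed D with its permutation null distribution and p-value."""

    observed: float
    null: np.ndarray
    p_value: float
    sidedness: str  # one-sided-lower | two-sided
    space: str  # geographic | environmental
    settings: dict = field(default_factory=dict)
    seed: object = None

    def __post_init__(self):
        self.null = np.asarray(self.null, dtype=float)
        self.observed = float(self.observed)
        self.p_value = float(self.p_value)
        if not (0.0 <= self.observed <= 1.0):
            raise ValueError("D must lie in [0, 1]")
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError("permutation p-value must lie in (0, 1]")

    @property
    def n_reps(self):
        return len(self.null)

    def to_dict(self):
        return {"observed_d": float(self.observed),
                "null_d": [float(x) for x in self.null],
                "p_value": float(self.p_value),
                "sidedness": self.sidedness, "space": self.space,
                "settings": self.settings, "seed": self.seed}

    def save(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def _fit_and_surface(presence_values, background_values, stack, settings):
    res = settings.fit(presence_values, background_values)
    return res.predict_surface(stack, output_scale="raw")


def _observed_d(occ_a, occ_b, stack, settings, background_values):
    pres_a = extract_values(stack, occ_a)
    pres_b = extract_values(stack, occ_b)
    sa = _fit_and_surface(pres_a, background_values, stack, settings)
    sb = _fit_and_surface(pres_b, background_values, stack, settings)
    return schoener_d_geographic(sa, sb), pres_a, pres_b


def identity_test(occ_a: OccurrenceSet, occ_b: OccurrenceSet, stack: ClimateStack,
                  model_settings: ModelSettings | None = None, n_reps: int = 100,
                  seed=0, n_background: int = 2000) -> OverlapResult:
    """One-sided niche identity test.

    The pooled occurrence records are randomly repartitioned into groups of
    the observed sizes ``n_reps`` times, both models refit with identical
    settings, and D recomputed on the raw geographic surfaces. The p-value
    is add-one corrected: ``p = (1 + #{D_null <= D_obs}) / (n_reps + 1)``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    settings = model_settings or ModelSettings()
    rng = np.random.default_rng(seed)
    n_background = min(n_background, stack.n_unmasked)
    background_values, _ = sample_background(stack, n_background, rng.integers(2 ** 31))
    observed, pres_a, pres_b = _observed_d(occ_a, occ_b, stack, settings,
                                           background_values)
    pooled = pd.concat([pres_a, pres_b], ignore_index=True)
    na = len(pres_a)
    null = np.empty(n_reps)
    for rep in range(n_reps):
        for attempt in range(3):
            perm = rng.permutation(len(pooled))
            try:
                sa = _fit_and_surface(pooled.iloc[perm[:na]], background_values,
                                      stack, settings)
                sb = _fit_and_surface(pooled.iloc[perm[na:]], background_values,
                                      stack, settings)
                null[rep] = schoener_d_geographic(sa, sb)
                break
            except Exception:
                if attempt == 2:
                    raise
    p = (1.0 + np.sum(null <= observed)) / (n_reps + 1.0)
    return OverlapResult(observed, null, p, "one-sided-lower", "geographic",
                         settings={**settings.to_dict(),
                                   "n_background": n_background,
                                   "n_reps": n_reps}, seed=seed)


def background_test(occ_a: OccurrenceSet, occ_b: OccurrenceSet, stack: ClimateStack,
                    background_region_b: ClimateStack | None = None,
                    model_settings: ModelSettings | None = None,
                    n_reps: int = 100, seed=0, n_background: int = 2000) -> OverlapResult:
    """Two-sided background similarity test (randomizing the second group).

    Each replicate replaces group b's records with points drawn uniformly
    from the unmasked cells of its background region (default: the whole
    study mask), refits that model, and recomputes D. Two-sided p-value:
    ``2 * min(P_lower, P_upper)`` with add-one correction, capped at 1. The
    symmetric direction is obtained by a second call with arguments swapped.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    settings = model_settings or ModelSettings()
    region = background_region_b if background_region_b is not None else stack
    nb = len(occ_b)
    if region.n_unmasked < nb:
        raise ValueError("background region smaller than the occurrence set")
    rng = np.random.default_rng(seed)
    n_background = min(n_background, stack.n_unmasked)
    background_values, _ = sample_background(stack, n_background, rng.integers(2 ** 31))
    observed, pres_a, _ = _observed_d(occ_a, occ_b, stack, settings,
                                      background_values)
    sa = _fit_and_surface(pres_a, background_values, stack, settings)
    null = np.empty(n_reps)
    for rep in range(n_reps):
        for attempt in range(3):
            try:
                rand_b, _ = sample_background(region, nb, rng.integers(2 ** 31))
                sb = _fit_and_surface(rand_b, background_values, stack, settings)
                null[rep] = schoener_d_geographic(sa, sb)
                break
            except Exception:
                if attempt == 2:
                    raise
    p_lower = (1.0 + np.sum(null <= observed)) / (n_reps + 1.0)
    p_upper = (1.0 + np.sum(null >= observed)) / (n_reps + 1.0)
    p = min(1.0, 2.0 * min(p_lower, p_upper))
    return OverlapResult(observed, null, p, "two-sided", "geographic",
                         settings={**settings.to_dict(),
                                   "n_background": n_background,
                                   "n_reps": n_reps,
                                   "randomized_group": "b"}, seed=seed)
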