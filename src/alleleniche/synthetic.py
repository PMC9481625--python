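"""Synthetic worlds with known niche structure.

Generates spatially autocorrelated, partially correlated climate layers
(Gaussian-smoothed white noise, standardized over the study mask) and allele
presence records drawn from known product-Gaussian response surfaces, so
that every downstream stage — model fitting, overlap testing, projection —
can be checked against ground truth.

The default world mirrors the study conditions of the bank-vole haemoglobin
system: two allele classes ("HbS", cold/wet optimum; "HbF", warm/dry
optimum) with 40 and 57 records at 94 distinct sites (three sites carry both
types), thinned-compatible spacing, and a "future" stack equal to the
present stack plus a +2 standardized-unit shift on the temperature-like
layer so that the warm allele's favourable area must expand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import gaussian_filter

from .geo import ClimateStack, OccurrenceSet, haversine_km
from .maxent import SuitabilitySurface

__all__ = [
    "NicheTruth",
    "SyntheticWorld",
    "generate_climate_stack",
    "true_suitability",
    "sample_occurrences",
    "make_world",
    "make_default_world",
    "DEFAULT_VARIABLES",
]

DEFAULT_VARIABLES = ["BIO4", "BIO10", "BIO13", "BIO15"]


@dataclass
class NicheTruth:
    """Product-Gaussian climate response: s = exp(-sum_v (z_v - mu_v)^2 / 2 sigma_v^2)."""

    allele: str
    optima: dict  # variable -> mu (standardized climate units)
    breadths: dict  # variable -> sigma > 0

    def __post_init__(self):
        if not self.optima:
            raise ValueError("niche must use at least one variable")
        if set(self.optima) != set(self.breadths):
            raise ValueError("optima and breadths must cover the same variables")
        for v, s in self.breadths.items():
            if not s > 0:
                raise ValueError(f"breadth for {v} must be strictly positive")

    @property
    def variables(self):
        return sorted(self.optima)

    def to_dict(self):
        return {"allele": self.allele,
                "optima": {k: float(v) for k, v in self.optima.items()},
                "breadths": {k: float(v) for k, v in self.breadths.items()}}


def generate_climate_stack(n_vars: int, n_rows: int, n_cols: int,
                           smoothing_scale: float, inter_var_correlation: float,
                           seed, var_names=None, correlated_pair=(0, 1),
                           xllcorner=-6.0, yllcorner=50.0, cellsize=0.1,
                           mask=None) -> ClimateStack:
    """Smoothed, standardized, optionally correlated synthetic climate layers.

    Each layer is an independent white-noise field smoothed with a Gaussian
    kernel of width ``smoothing_scale`` (cells) and standardized to zero
    mean, unit variance over the mask. ``inter_var_correlation`` mixes the
    designated pair of layers (first two by default) to that target Pearson
    correlation; other layers stay independent. Deterministic given seed.
    """
    if n_vars < 2:
        raise ValueError("need at least 2 variables")
    if n_rows <= 0 or n_cols <= 0:
        raise ValueError("grid dimensions must be positive")
    if smoothing_scale < 0:
        raise ValueError("smoothing_scale must be >= 0")
    if abs(inter_var_correlation) >= 1:
        raise ValueError("|inter_var_correlation| must be < 1")
    rng = np.random.default_rng(seed)
    if var_names is None:
        var_names = [f"VAR{i + 1}" for i in range(n_vars)]
    if len(var_names) != n_vars:
        raise ValueError("var_names length must equal n_vars")
    if mask is None:
        mask = np.ones((n_rows, n_cols), dtype=bool)
    layers = []
    for _ in range(n_vars):
        noise = rng.standard_normal((n_rows, n_cols))
        if smoothing_scale > 0:
            noise = gaussian_filter(noise, sigma=smoothing_scale, mode="reflect")
        mu = noise[mask].mean()
        sd = noise[mask].std()
        layers.append((noise - mu) / sd)
    if inter_var_correlation != 0.0:
        i, j = correlated_pair
        rho = inter_var_correlation
        mixed = rho * layers[i] + np.sqrt(1.0 - rho ** 2) * layers[j]
        mu = mixed[mask].mean()
        sd = mixed[mask].std()
        layers[j] = (mixed - mu) / sd
    data = np.stack(layers)
    data[:, ~mask] = np.nan
    return ClimateStack(list(var_names), data, xllcorner, yllcorner, cellsize, mask)


def true_suitability(stack: ClimateStack, niche: NicheTruth) -> SuitabilitySurface:
    """Ground-truth suitability surface of a product-Gaussian niche; values in (0, 1]."""
    missing = [v for v in niche.variables if v not in stack.names]
    if missing:
        raise KeyError(f"niche variables {missing} not in stack {stack.names}")
    expo = np.zeros((stack.nrows, stack.ncols))
    for v in niche.variables:
        z = stack.layer(v)
        expo = expo + (z - niche.optima[v]) ** 2 / (2.0 * niche.breadths[v] ** 2)
    s = np.exp(-expo)
    s[~stack.mask] = np.nan
    return SuitabilitySurface(s, "truth", stack.xllcorner, stack.yllcorner,
                              stack.cellsize, provenance=f"truth:{niche.allele}")


def sample_occurrences(surface: SuitabilitySurface, n: int, min_distance_km: float,
                       seed, allele: str = "A", exclude_cells=None,
                       avoid_points=None, max_rejects=None) -> OccurrenceSet:
    """Draw presence points proportional to suitability, without replacement.

    Cells are drawn one at a time with probability proportional to their
    suitability; each point sits at its cell centre. With a positive
    ``min_distance_km`` a draw closer than that (great-circle) to any point
    already accepted — or to any of ``avoid_points`` — is rejected and
    redrawn; after ``max_rejects`` rejections (default ``1000 * n``) sampling
    fails, naming the distance constraint. Deterministic given seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    mask = surface.mask
    rows, cols = np.nonzero(mask)
    s = surface.values[rows, cols].astype(float)
    if exclude_cells is not None:
        banned = set(map(tuple, exclude_cells))
        keep = np.array([(r, c) not in banned for r, c in zip(rows, cols)])
        rows, cols, s = rows[keep], cols[keep], s[keep]
    if len(rows) < n:
        raise ValueError(f"surface has only {len(rows)} candidate cells; need {n}")
    if not np.any(s > 0):
        raise ValueError("suitability surface has no positive mass")
    # cell-centre coordinates (row 0 = north)
    nrows = surface.values.shape[0]
    yur = surface.yllcorner + nrows * surface.cellsize
    lon = surface.xllcorner + (cols + 0.5) * surface.cellsize
    lat = yur - (rows + 0.5) * surface.cellsize
    if max_rejects is None:
        max_rejects = 1000 * n
    avoid_lon = np.array([p[0] for p in (avoid_points or [])], dtype=float)
    avoid_lat = np.array([p[1] for p in (avoid_points or [])], dtype=float)
    available = np.ones(len(rows), dtype=bool)
    chosen = []
    rejects = 0
    while len(chosen) < n:
        p = np.where(available, s, 0.0)
        total = p.sum()
        if total <= 0:
            raise RuntimeError(
                f"ran out of cells satisfying the {min_distance_km} km "
                f"minimum-distance constraint after {len(chosen)} points")
        idx = rng.choice(len(rows), p=p / total)
        if min_distance_km > 0:
            ok = True
            if chosen:
                d = haversine_km(lon[idx], lat[idx],
                                 lon[np.array(chosen)], lat[np.array(chosen)])
                ok = bool(np.all(d >= min_distance_km))
            if ok and len(avoid_lon):
                d = haversine_km(lon[idx], lat[idx], avoid_lon, avoid_lat)
                ok = bool(np.all(d >= min_distance_km))
            if not ok:
                available[idx] = False  # too close; never admissible again
                rejects += 1
                if rejects > max_rejects:
                    raise RuntimeError(
                        f"exceeded {max_rejects} rejections enforcing the "
                        f"{min_distance_km} km minimum-distance constraint")
                continue
        available[idx] = False
        chosen.append(idx)
    chosen = np.array(chosen)
    table = pd.DataFrame({"longitude": lon[chosen], "latitude": lat[chosen],
                          "allele": allele})
    return OccurrenceSet(table, provenance=f"synthetic:{allele}")


@dataclass
class SyntheticWorld:
    """A complete ground-truth scenario: stacks, niches, surfaces, occurrences."""

    present: ClimateStack
    future: ClimateStack | None
    niches: dict  # allele -> NicheTruth
    true_surfaces: dict  # allele -> SuitabilitySurface (present stack)
    occurrences: OccurrenceSet
    seed: int
    future_shifts: dict = field(default_factory=dict)

    @property
    def alleles(self):
        return sorted(self.niches)

    def write(self, directory):
        """Persist the world as plain text: ASCII grids, CSV occurrences, YAML truth."""
        directory = Path(directory)
        (directory / "present").mkdir(parents=True, exist_ok=True)
        self.present.write(directory / "present")
        if self.future is not None:
            (directory / "future").mkdir(exist_ok=True)
            self.future.write(directory / "future")
        self.occurrences.write(directory / "occurrences.csv")
        truth = {"seed": int(self.seed),
                 "future_shifts": {k: float(v) for k, v in self.future_shifts.items()},
                 "niches": {a: n.to_dict() for a, n in self.niches.items()}}
        with open(directory / "truth.yaml", "w") as fh:
            yaml.safe_dump(truth, fh, sort_keys=False)
        for allele, surf in self.true_surfaces.items():
            surf.write(directory / f"true_suitability_{allele}.asc")


def make_world(seed, n_rows=100, n_cols=100, var_names=None,
               smoothing_scale=6.0, inter_var_correlation=0.5,
               niches=None, n_per_allele=None, min_distance_km=10.0,
               n_shared_sites=0, future_shifts=None, mask=None) -> SyntheticWorld:
    """Assemble a synthetic world; all randomness derives from ``seed``.

    ``n_shared_sites`` forces that many sites to carry both allele labels
    (sampled first, from the geometric mean of the two true surfaces), the
    remainder of each allele's records being drawn from its own surface away
    from already-placed points of the same allele.
    """
    if var_names is None:
        var_names = list(DEFAULT_VARIABLES)
    ss = np.random.SeedSequence(seed)
    child = ss.spawn(8)
    stack = generate_climate_stack(len(var_names), n_rows, n_cols,
                                   smoothing_scale, inter_var_correlation,
                                   child[0], var_names=var_names, mask=mask)
    if niches is None:
        niches = default_niches()
    if n_per_allele is None:
        n_per_allele = {a: 40 for a in niches}
    alleles = sorted(niches)
    surfaces = {a: true_suitability(stack, niches[a]) for a in alleles}
    sets = []
    shared_coords = []
    if n_shared_sites > 0:
        if len(alleles) != 2:
            raise ValueError("shared sites require exactly two alleles")
        a, b = alleles
        joint = np.sqrt(surfaces[a].values * surfaces[b].values)
        joint_surf = SuitabilitySurface(joint, "truth", stack.xllcorner,
                                        stack.yllcorner, stack.cellsize)
        shared = sample_occurrences(joint_surf, n_shared_sites, min_distance_km,
                                    child[1], allele="shared")
        shared_coords = list(zip(shared.table["longitude"], shared.table["latitude"]))
    used_cells = []
    if shared_coords:
        srow, scol, _ = stack.cell_of(np.array([c[0] for c in shared_coords]),
                                      np.array([c[1] for c in shared_coords]))
        used_cells = list(zip(srow, scol))
    for i, allele in enumerate(alleles):
        n_own = n_per_allele[allele] - n_shared_sites
        # exclude cells already used by any allele so only the designated
        # shared sites carry both labels
        own = sample_occurrences(surfaces[allele], n_own, min_distance_km,
                                 child[2 + i], allele=allele,
                                 exclude_cells=used_cells or None,
                                 avoid_points=shared_coords or None)
        orow, ocol, _ = stack.cell_of(own.table["longitude"].to_numpy(),
                                      own.table["latitude"].to_numpy())
        used_cells = used_cells + list(zip(orow, ocol))
        if shared_coords:
            extra = pd.DataFrame({"longitude": [c[0] for c in shared_coords],
                                  "latitude": [c[1] for c in shared_coords],
                                  "allele": allele})
            own = OccurrenceSet(pd.concat([own.table, extra], ignore_index=True),
                                provenance=own.provenance)
        sets.append(own)
    occ = OccurrenceSet.concat(sets, provenance=f"synthetic-world(seed={seed})")
    future = None
    if future_shifts:
        future = stack.shifted(future_shifts)
    return SyntheticWorld(stack, future, dict(niches), surfaces, occ,
                          seed=seed if isinstance(seed, int) else 0,
                          future_shifts=dict(future_shifts or {}))


def default_niches():
    """Divergent cold/wet vs warm/dry niches on the temperature- and
    precipitation-like layers, mirroring the two haemoglobin types."""
    return {
        "HbS": NicheTruth("HbS", {"BIO10": -1.0, "BIO13": 0.8},
                          {"BIO10": 0.9, "BIO13": 1.2}),
        "HbF": NicheTruth("HbF", {"BIO10": 1.0, "BIO13": -0.8},
                          {"BIO10": 0.9, "BIO13": 1.2}),
    }


def make_default_world(seed=0) -> SyntheticWorld:
    """The standard study-condition fixture.

    100x100 grid, four partially correlated smoothed layers; two alleles
    with 40 (HbS) and 57 (HbF) records at 94 distinct sites (3 dual-type);
    future stack = present + 2 standardized units on BIO10.
    """
    return make_world(seed, n_rows=100, n_cols=100,
                      var_names=list(DEFAULT_VARIABLES),
                      smoothing_scale=6.0, inter_var_correlation=0.5,
                      niches=default_niches(),
                      n_per_allele={"HbS": 40, "HbF": 57},
                      min_distance_km=10.0, n_shared_sites=3,
                      future_shifts={"BIO10": 2.0})
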