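"""Projection to new climates, threshold classification and favourability maps.

Fitted models are projected onto other climate stacks (future scenarios),
scenario members are averaged cell-wise, suitability is classified by the
three training-presence thresholds (minimum, 5th and 10th percentile of
predicted suitability at the training records), and the two alleles'
surfaces are compared cell by cell to map which allele the climate favours.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil

import numpy as np

from .geo import GeometryError, OccurrenceSet, write_ascii_grid
from .maxent import MaxentResults, SuitabilitySurface
from .geo import ClimateStack

__all__ = [
    "ThresholdSet",
    "CategoricalMap",
    "FavourabilityMap",
    "project",
    "average_surfaces",
    "training_thresholds",
    "classify_suitability",
    "relative_favourability",
]

SUITABILITY_CLASSES = {0: "unsuitable", 1: "marginal", 2: "moderate", 3: "high"}


@dataclass
class ThresholdSet:
    """Omission thresholds on the surface's output scale: mtp <= p5 <= p10."""

    mtp: float  # minimum training presence (marginal)
    p5: float   # 5th percentile training presence (moderate)
    p10: float  # 10th percentile training presence (high)
    scale: str = "cloglog"

    def __post_init__(self):
        if not (self.mtp <= self.p5 <= self.p10):
            raise ValueError("thresholds must satisfy mtp <= p5 <= p10")

    def as_tuple(self):
        return (self.mtp, self.p5, self.p10)


def project(results: MaxentResults, new_stack: ClimateStack, clamp: bool = True,
            output_scale: str = "cloglog"):
    """Project a fitted model; returns ``(surface, clamping_mask)``.

    The clamping mask flags unmasked cells whose climate falls outside the
    model's training range (empty whenever the new stack stays in range).
    """
    surface = results.predict_surface(new_stack, output_scale=output_scale,
                                      clamp=clamp)
    clamping_mask = results.clamping_mask(new_stack)
    return surface, clamping_mask


def average_surfaces(surfaces) -> SuitabilitySurface:
    """Cell-wise arithmetic mean of co-registered same-scale surfaces.

    A cell masked in any member is masked in the mean (e.g. averaging the
    four GCM members of one emissions scenario).
    """
    surfaces = list(surfaces)
    if not surfaces:
        raise ValueError("need at least one surface")
    first = surfaces[0]
    for s in surfaces[1:]:
        if not first.same_grid(s):
            raise ValueError("surfaces are not on the same grid")
        if s.scale != first.scale:
            raise ValueError(f"output scales differ: {first.scale} vs {s.scale}")
    stackvals = np.stack([s.values for s in surfaces])
    mean = stackvals.mean(axis=0)  # NaN wherever any member is masked
    prov = f"mean({len(surfaces)} surfaces)"
    return SuitabilitySurface(mean, first.scale, first.xllcorner, first.yllcorner,
                              first.cellsize, provenance=prov)


def training_thresholds(surface: SuitabilitySurface,
                        training_presences: OccurrenceSet) -> ThresholdSet:
    """Minimum / 5th / 10th percentile training-presence thresholds.

    Percentiles use the nearest-rank definition: the value at 1-based index
    ``ceil(q * n)`` of the ascending sorted presence suitabilities.
    """
    lon, lat = training_presences.coords()
    vals = np.sort(surface.values_at(lon, lat))
    n = len(vals)
    if n < 1:
        raise GeometryError("no training presences on the surface")

    def nearest_rank(q):
        return float(vals[max(ceil(q * n), 1) - 1])

    return ThresholdSet(mtp=float(vals[0]), p5=nearest_rank(0.05),
                        p10=nearest_rank(0.10), scale=surface.scale)


@dataclass
class CategoricalMap:
    """Integer-coded classification on a raster grid with its code table."""

    codes: np.ndarray  # int grid; -1 off mask
    code_table: dict
    xllcorner: float
    yllcorner: float
    cellsize: float
    provenance: str = ""

    @property
    def mask(self):
        return self.codes >= 0

    def area_fraction(self, code) -> float:
        """Fraction of unmasked cells carrying ``code`` (name or int)."""
        if isinstance(code, str):
            inv = {v: k for k, v in self.code_table.items()}
            code = inv[code]
        m = self.mask
        return float((self.codes[m] == code).mean())

    def write(self, path):
        write_ascii_grid(path, np.where(self.mask, self.codes.astype(float), np.nan),
                         self.xllcorner, self.yllcorner, self.cellsize)


def classify_suitability(surface: SuitabilitySurface,
                         thresholds: ThresholdSet) -> CategoricalMap:
    """Classify each cell: >= p10 high, >= p5 moderate, >= mtp marginal, else unsuitable.

    All bounds are inclusive, so a cell exactly at p10 is 'high'.
    """
    v = surface.values
    codes = np.full(v.shape, -1, dtype=int)
    m = surface.mask
    codes[m] = 0
    codes[m & (v >= thresholds.mtp)] = 1
    codes[m & (v >= thresholds.p5)] = 2
    codes[m & (v >= thresholds.p10)] = 3
    return CategoricalMap(codes, dict(SUITABILITY_CLASSES), surface.xllcorner,
                          surface.yllcorner, surface.cellsize,
                          provenance=f"classified({surface.provenance})")


@dataclass
class FavourabilityMap:
    """Per-cell winner between two alleles, with percent-of-area summary."""

    winner: np.ndarray  # int grid: 1 = allele_a, 2 = allele_b, -1 off mask
    allele_a: str
    allele_b: str
    percent: dict = field(default_factory=dict)  # allele -> % of unmasked area
    n_ties: int = 0
    provenance: str = ""
    xllcorner: float = 0.0
    yllcorner: float = 0.0
    cellsize: float = 1.0

    @property
    def mask(self):
        return self.winner >= 0

    def write(self, path):
        write_ascii_grid(path, np.where(self.mask, self.winner.astype(float), np.nan),
                         self.xllcorner, self.yllcorner, self.cellsize)


def relative_favourability(surface_a: SuitabilitySurface,
                           surface_b: SuitabilitySurface,
                           allele_a: str = "a", allele_b: str = "b") -> FavourabilityMap:
    """Which allele's climate suitability wins at each cell.

    The winner holds the strictly greater value; exact ties go to allele_a
    and are counted in ``n_ties``. Percents are over the shared unmasked
    cells and sum to 100.
    """
    if not surface_a.same_grid(surface_b):
        raise ValueError("surfaces are not on the same grid")
    if surface_a.scale != surface_b.scale:
        raise ValueError("surfaces must share an output scale")
    shared = surface_a.mask & surface_b.mask
    winner = np.full(surface_a.values.shape, -1, dtype=int)
    a_wins = surface_a.values >= surface_b.values
    winner[shared & a_wins] = 1
    winner[shared & ~a_wins] = 2
    n_ties = int((shared & (surface_a.values == surface_b.values)).sum())
    n = int(shared.sum())
    pct_a = float(100.0 * (winner[shared] == 1).sum() / n)
    pct_b = float(100.0 * (winner[shared] == 2).sum() / n)
    return FavourabilityMap(winner, allele_a, allele_b,
                            percent={allele_a: pct_a, allele_b: pct_b},
                            n_ties=n_ties,
                            provenance=f"{surface_a.provenance} vs {surface_b.provenance}"
                                       f" ({surface_a.scale})",
                            xllcorner=surface_a.xllcorner,
                            yllcorner=surface_a.yllcorner,
                            cellsize=surface_a.cellsize)
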