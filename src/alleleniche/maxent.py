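"""Maximum-entropy presence/background niche model.

The model estimates a Gibbs distribution over landscape cells,

    q_lambda(x) = exp(lambda . f(x)) / Z,

where ``f`` expands raw climate values into bounded features (linear,
quadratic, pairwise-product and hinge classes, all scaled into [0, 1] on the
training range) and ``Z`` normalizes over a background sample of the
landscape. Coefficients minimize the L1-regularized negative mean presence
log-likelihood

    J(lambda) = -(1/m) sum_i lambda . f(x_i) + ln Z + sum_j beta_j |lambda_j|,

with per-feature penalties ``beta_j = reg_multiplier * w_class(m) * s_j /
sqrt(m)`` (``s_j`` the feature's standard deviation over the m presences,
``w_class`` the published per-class weight schedule). The problem is convex;
it is solved by L-BFGS-B on the positive/negative split ``lambda = a - b``.

Output scales follow the MaxEnt 3.4 conventions: *raw* (the normalized Gibbs
density), *cumulative* (sum of raw over cells no more suitable), and
*cloglog* ``1 - exp(-e^H * raw)`` with ``H`` the entropy of the fitted raw
distribution over the training background.

Usage parallels statsmodels::

    model = MaxentNicheModel(presence_values, background_values,
                             feature_classes="LQ")
    res = model.fit()
    print(res.summary())
    surface = res.predict(stack, output_scale="cloglog")
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import minimize
from scipy.special import logsumexp

from .geo import ClimateStack, write_ascii_grid, read_ascii_grid

__all__ = [
    "FeatureExpansion",
    "MaxentNicheModel",
    "MaxentResults",
    "SuitabilitySurface",
    "TuningResult",
    "ConvergenceWarning",
    "build_features",
    "fit_maxent",
    "tune_model",
    "auto_feature_classes",
    "parse_feature_classes",
]

FEATURE_CLASSES = ("linear", "quadratic", "product", "hinge")
_CLASS_CODE = {"L": "linear", "Q": "quadratic", "P": "product", "H": "hinge"}

# Published per-class regularization schedules: weight interpolated on the
# number of presences m (linear/quadratic/product share one table).
_LQP_BREAKS = np.array([0.0, 10.0, 30.0, 100.0])
_LQP_WEIGHTS = np.array([1.0, 1.0, 0.2, 0.05])
_HINGE_WEIGHT = 0.5


class ConvergenceWarning(UserWarning):
    pass


def parse_feature_classes(classes):
    """Normalize 'LQH'-style codes or iterables into a set of class names."""
    if isinstance(classes, str):
        out = set()
        for ch in classes.upper():
            if ch not in _CLASS_CODE:
                raise ValueError(f"unknown feature class code {ch!r}")
            out.add(_CLASS_CODE[ch])
        return out
    out = set(classes)
    bad = out - set(FEATURE_CLASSES)
    if bad:
        raise ValueError(f"unknown feature classes {sorted(bad)}")
    return out


def auto_feature_classes(n_presences: int):
    """MaxEnt 3.4-style default feature classes by presence count."""
    if n_presences < 10:
        return {"linear"}
    if n_presences < 15:
        return {"linear", "quadratic"}
    if n_presences < 80:
        return {"linear", "quadratic", "hinge"}
    return {"linear", "quadratic", "hinge", "product"}


def _class_weight(feature_class: str, m: int) -> float:
    if feature_class == "hinge":
        return _HINGE_WEIGHT
    return float(np.interp(m, _LQP_BREAKS, _LQP_WEIGHTS))


@dataclass
class FeatureExpansion:
    """Maps raw climate values into bounded model features.

    Scaling and clamping use the stored per-variable training min/max; hinge
    knots sit at evenly spaced interior positions of the scaled [0, 1] range.
    """

    variables: list
    classes: set
    mins: np.ndarray
    maxs: np.ndarray
    n_hinge_knots: int = 8
    feature_names: list = field(default_factory=list)
    feature_classes: list = field(default_factory=list)

    @classmethod
    def from_training(cls, values: pd.DataFrame, classes, n_hinge_knots: int = 8):
        classes = parse_feature_classes(classes)
        if "hinge" in classes and n_hinge_knots < 2:
            raise ValueError("n_hinge_knots must be >= 2 when hinge features are requested")
        values = pd.DataFrame(values)
        if not np.isfinite(values.to_numpy()).all():
            raise ValueError("training values must be finite")
        mins = values.min(axis=0).to_numpy(dtype=float)
        maxs = values.max(axis=0).to_numpy(dtype=float)
        flat = [v for v, lo, hi in zip(values.columns, mins, maxs) if hi <= lo]
        if flat:
            raise ValueError(f"zero-variance variable(s) over training data: {flat}")
        exp = cls(list(values.columns), classes, mins, maxs, n_hinge_knots)
        exp._build_names()
        return exp

    def _build_names(self):
        names, fclasses = [], []
        for v in self.variables:
            if "linear" in self.classes:
                names.append(f"lin:{v}")
                fclasses.append("linear")
        for v in self.variables:
            if "quadratic" in self.classes:
                names.append(f"quad:{v}")
                fclasses.append("quadratic")
        if "product" in self.classes:
            for a, b in itertools.combinations(self.variables, 2):
                names.append(f"prod:{a}*{b}")
                fclasses.append("product")
        if "hinge" in self.classes:
            for v in self.variables:
                for k in self.knots:
                    names.append(f"hingeF:{v}@{k:.4f}")
                    fclasses.append("hinge")
                for k in self.knots:
                    names.append(f"hingeR:{v}@{k:.4f}")
                    fclasses.append("hinge")
        self.feature_names = names
        self.feature_classes = fclasses

    @property
    def knots(self):
        """Interior hinge knots on the scaled [0, 1] range."""
        return np.linspace(0.0, 1.0, self.n_hinge_knots + 2)[1:-1]

    @property
    def n_features(self):
        return len(self.feature_names)

    def scale(self, values: pd.DataFrame, clamp: bool = True):
        v = pd.DataFrame(values)[self.variables].to_numpy(dtype=float)
        z = (v - self.mins) / (self.maxs - self.mins)
        if clamp:
            z = np.clip(z, 0.0, 1.0)
        return z

    def out_of_range(self, values: pd.DataFrame):
        """Boolean row mask: any variable outside the training range."""
        v = pd.DataFrame(values)[self.variables].to_numpy(dtype=float)
        return np.any((v < self.mins) | (v > self.maxs), axis=1)

    def transform(self, values, clamp: bool = True) -> np.ndarray:
        """Feature matrix (n_rows, n_features) for raw climate values."""
        z = self.scale(values, clamp=clamp)
        cols = []
        if "linear" in self.classes:
            cols.append(z)
        if "quadratic" in self.classes:
            cols.append(z ** 2)
        if "product" in self.classes:
            prods = [z[:, i] * z[:, j]
                     for i, j in itertools.combinations(range(z.shape[1]), 2)]
            if prods:
                cols.append(np.column_stack(prods))
        if "hinge" in self.classes:
            ks = self.knots
            hmat = []
            for i in range(z.shape[1]):
                x = z[:, i][:, None]
                hmat.append(np.maximum(0.0, (x - ks) / (1.0 - ks)))  # forward
                hmat.append(np.maximum(0.0, (ks - x) / ks))  # reverse
            cols.append(np.hstack(hmat))
        F = np.hstack(cols)
        assert F.shape[1] == self.n_features
        return F

    def to_dict(self):
        return {
            "variables": list(self.variables),
            "classes": sorted(self.classes),
            "mins": [float(x) for x in self.mins],
            "maxs": [float(x) for x in self.maxs],
            "n_hinge_knots": int(self.n_hinge_knots),
        }

    @classmethod
    def from_dict(cls, d):
        exp = cls(list(d["variables"]), set(d["classes"]),
                  np.asarray(d["mins"], float), np.asarray(d["maxs"], float),
                  int(d["n_hinge_knots"]))
        exp._build_names()
        return exp


def build_features(values, classes, n_hinge_knots: int = 8):
    """Expand raw climate values; returns ``(feature_matrix, FeatureExpansion)``."""
    exp = FeatureExpansion.from_training(values, classes, n_hinge_knots)
    return exp.transform(values, clamp=True), exp


# ---------------------------------------------------------------------------
# Suitability surfaces
# ---------------------------------------------------------------------------

@dataclass
class SuitabilitySurface:
    """Per-cell suitability on a raster grid, tagged with its output scale."""

    values: np.ndarray  # (nrows, ncols), NaN off-mask
    scale: str  # raw | cumulative | cloglog
    xllcorner: float
    yllcorner: float
    cellsize: float
    provenance: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.scale not in ("raw", "cumulative", "cloglog", "truth"):
            raise ValueError(f"unknown output scale {self.scale!r}")

    @property
    def mask(self):
        return ~np.isnan(self.values)

    def mask_values(self):
        return self.values[self.mask]

    def same_grid(self, other: "SuitabilitySurface"):
        import math
        return (self.values.shape == other.values.shape
                and math.isclose(self.xllcorner, other.xllcorner, abs_tol=1e-9)
                and math.isclose(self.yllcorner, other.yllcorner, abs_tol=1e-9)
                and math.isclose(self.cellsize, other.cellsize, rel_tol=1e-12))

    def values_at(self, lon, lat):
        """Surface values at points (cells located by the half-open convention)."""
        from .geo import GeometryError
        stacklike = ClimateStack(["s"], self.values[None, :, :],
                                 self.xllcorner, self.yllcorner, self.cellsize)
        row, col, inside = stacklike.cell_of(lon, lat)
        if not np.all(inside):
            raise GeometryError("point outside surface grid")
        vals = self.values[row, col]
        if np.any(np.isnan(vals)):
            raise GeometryError("point on masked cell of surface")
        return vals

    def write(self, path):
        write_ascii_grid(path, self.values, self.xllcorner, self.yllcorner, self.cellsize)

    @classmethod
    def read(cls, path, scale, provenance=""):
        values, header = read_ascii_grid(path)
        return cls(values, scale, header["xllcorner"], header["yllcorner"],
                   header["cellsize"], provenance=provenance)


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class MaxentNicheModel:
    """Presence/background maximum-entropy niche model.

    Parameters
    ----------
    presence_values, background_values : DataFrame
        Raw climate values (one column per variable) at presence records and
        at the background sample. The background must be strictly larger than
        the presence set. The feature scaling range is the pooled min/max.
    feature_classes : str | set | None
        ``"LQH"``-style code or set of class names; ``None`` selects classes
        automatically from the presence count.
    reg_multiplier : float
        Global multiplier on the per-feature L1 penalties.
    n_hinge_knots : int
        Hinge knots per variable (forward and reverse), evenly spaced.
    """

    def __init__(self, presence_values, background_values, feature_classes=None,
                 reg_multiplier: float = 1.0, n_hinge_knots: int = 8, seed=None):
        self.presence_values = pd.DataFrame(presence_values).reset_index(drop=True)
        self.background_values = pd.DataFrame(background_values).reset_index(drop=True)
        m, n = len(self.presence_values), len(self.background_values)
        if m < 2:
            raise ValueError("need at least 2 presences")
        if n <= m:
            raise ValueError("background must be strictly larger than the presence set")
        if feature_classes is None:
            feature_classes = auto_feature_classes(m)
        self.reg_multiplier = float(reg_multiplier)
        self.seed = seed
        pooled = pd.concat([self.presence_values, self.background_values], ignore_index=True)
        self.expansion = FeatureExpansion.from_training(
            pooled, feature_classes, n_hinge_knots)
        self.F_presence = self.expansion.transform(self.presence_values)
        self.F_background = self.expansion.transform(self.background_values)
        if np.all(self.F_presence == self.F_presence[0], axis=None) and m > 1:
            raise ValueError("degenerate presence set: all presence feature rows identical")
        self._beta = self._penalties()

    @classmethod
    def from_occurrences(cls, stack: ClimateStack, occurrences, n_background: int,
                         seed, **kwargs):
        """Build a model from an occurrence set and a climate stack.

        Extracts climate at the occurrence points and draws a uniform
        background sample of ``n_background`` unmasked cells.
        """
        from .geo import extract_values, sample_background
        pres = extract_values(stack, occurrences)
        bg, _ = sample_background(stack, n_background, seed)
        return cls(pres, bg, seed=seed, **kwargs)

    @property
    def n_presences(self):
        return len(self.presence_values)

    @property
    def n_background(self):
        return len(self.background_values)

    def _penalties(self):
        m = self.n_presences
        s = self.F_presence.std(axis=0, ddof=0)
        # floor the deviation so features constant on presences stay penalized
        s = np.maximum(s, 1e-3)
        w = np.array([_class_weight(c, m) for c in self.expansion.feature_classes])
        return self.reg_multiplier * w * s / np.sqrt(m)

    # -- fitting ------------------------------------------------------------
    def objective(self, lam):
        """Regularized objective J(lambda); convex in lambda."""
        lam = np.asarray(lam, dtype=float)
        eta_b = self.F_background @ lam
        smooth = -(self.F_presence @ lam).mean() + logsumexp(eta_b)
        active = lam != 0  # avoids inf * 0 under infinite regularization
        return smooth + float(self._beta[active] @ np.abs(lam[active]))

    def fit(self, tol: float = 1e-5, max_iter: int = 500) -> "MaxentResults":
        """Fit by L-BFGS-B on the positive/negative coefficient split.

        ``tol`` bounds both the relative objective improvement and the
        projected-gradient norm at termination; the returned results carry a
        ``converged`` flag and the per-iteration objective path.
        """
        p = self.expansion.n_features
        emp_mean = self.F_presence.mean(axis=0)
        beta = self._beta
        if not np.isfinite(self.reg_multiplier):
            lam = np.zeros(p)
            return self._results(lam, converged=True, n_iter=0,
                                 objective_path=[self.objective(lam)])
        Fb = self.F_background

        def split_obj(theta):
            a, b = theta[:p], theta[p:]
            lam = a - b
            eta = Fb @ lam
            lse = logsumexp(eta)
            w = np.exp(eta - lse)
            model_mean = w @ Fb
            f = -float(emp_mean @ lam) + lse + float(beta @ (a + b))
            g_smooth = model_mean - emp_mean
            grad = np.concatenate([g_smooth + beta, -g_smooth + beta])
            return f, grad

        path = []

        def cb(theta):
            a, b = theta[:p], theta[p:]
            path.append(self.objective(a - b))

        x0 = np.zeros(2 * p)
        path.append(self.objective(np.zeros(p)))
        res = minimize(split_obj, x0, jac=True, method="L-BFGS-B",
                       bounds=[(0.0, None)] * (2 * p), callback=cb,
                       options={"maxiter": max_iter, "ftol": tol * 1e-3,
                                "gtol": tol, "maxfun": 20 * max_iter})
        lam = res.x[:p] - res.x[p:]
        lam[np.abs(lam) < 1e-12] = 0.0
        converged = bool(res.success) or "CONVERG" in str(res.message).upper()
        if not converged:
            warnings.warn(f"MaxEnt fit did not converge in {max_iter} iterations: "
                          f"{res.message}", ConvergenceWarning)
        return self._results(lam, converged=converged, n_iter=res.nit,
                             objective_path=path)

    def _results(self, lam, converged, n_iter, objective_path):
        eta_b = self.F_background @ lam
        log_z = float(logsumexp(eta_b))
        logp = eta_b - log_z
        p = np.exp(logp)
        entropy = float(-(p @ logp))
        return MaxentResults(self, lam, log_z, entropy, converged, n_iter,
                             objective_path)


class MaxentResults:
    """Fitted MaxEnt model: coefficients, normalizer, entropy, diagnostics."""

    def __init__(self, model: MaxentNicheModel, lam, log_z, entropy,
                 converged, n_iter, objective_path):
        self.model = model
        self.params = pd.Series(lam, index=model.expansion.feature_names, name="lambda")
        self.log_z = log_z  # over the training background
        self.entropy = entropy  # nats; in [0, ln(n_background)]
        self.converged = converged
        self.n_iter = n_iter
        self.objective_path = list(objective_path)

    # -- basic quantities ---------------------------------------------------
    @property
    def z(self):
        """Background normalizer sum_bg exp(lambda . f)."""
        return float(np.exp(self.log_z))

    @property
    def beta(self):
        return pd.Series(self.model._beta, index=self.params.index, name="beta")

    @property
    def n_active(self):
        """Number of features with nonzero coefficient (AICc's K)."""
        return int((np.abs(self.params.to_numpy()) > 1e-10).sum())

    @property
    def training_gain(self):
        """ln(n_background) minus the unpenalized NLL part of the objective."""
        lam = self.params.to_numpy()
        nll = -(self.model.F_presence @ lam).mean() + self.log_z
        return float(np.log(self.model.n_background) - nll)

    def empirical_means(self):
        return pd.Series(self.model.F_presence.mean(axis=0), index=self.params.index)

    def model_means(self):
        lam = self.params.to_numpy()
        eta = self.model.F_background @ lam
        w = np.exp(eta - logsumexp(eta))
        return pd.Series(w @ self.model.F_background, index=self.params.index)

    def kkt_gaps(self):
        """|empirical mean - model mean| per feature; at the optimum each gap
        is <= beta_j (with equality on active features, up to solver tolerance)."""
        return (self.empirical_means() - self.model_means()).abs()

    def max_kkt_violation(self):
        return float((self.kkt_gaps() - self.beta).max())

    # -- prediction ---------------------------------------------------------
    def _eta(self, values, clamp=True):
        F = self.model.expansion.transform(values, clamp=clamp)
        return F @ self.params.to_numpy()

    def predict(self, values, output_scale: str = "cloglog", clamp: bool = True):
        """Per-row suitability scores for raw climate values.

        raw is normalized to the *training* background (sums to 1 over it);
        cloglog applies ``1 - exp(-e^H raw)``. Cumulative scores require a
        prediction domain — use :meth:`predict_surface`.
        """
        eta = self._eta(values, clamp=clamp)
        raw = np.exp(eta - self.log_z)
        if output_scale == "raw":
            return raw
        if output_scale == "cloglog":
            return 1.0 - np.exp(-np.exp(self.entropy) * raw)
        raise ValueError("per-row prediction supports 'raw' and 'cloglog' scales")

    def predict_surface(self, stack: ClimateStack, output_scale: str = "cloglog",
                        clamp: bool = True) -> SuitabilitySurface:
        """Suitability surface over a stack's unmasked cells.

        raw is renormalized to sum to 1 over the prediction domain; cloglog
        rescales raw to the training-background size before the transform, so
        the uniform model maps to ``1 - e^-1`` on any domain.
        """
        for v in self.model.expansion.variables:
            if v not in stack.names:
                raise KeyError(f"stack lacks model variable {v!r}")
        values = stack.values_table()[self.model.expansion.variables]
        eta = self._eta(values, clamp=clamp)
        eta = eta - eta.max()
        w = np.exp(eta)
        raw = w / w.sum()
        n_domain = len(raw)
        if output_scale == "raw":
            out = raw
        elif output_scale == "cloglog":
            scaled = raw * n_domain / self.model.n_background
            out = 1.0 - np.exp(-np.exp(self.entropy) * scaled)
        elif output_scale == "cumulative":
            order = np.argsort(raw, kind="stable")
            sorted_raw = raw[order]
            csum = np.cumsum(sorted_raw)
            # ties: cumulative(x) = sum of raw over cells with raw <= raw(x)
            idx = np.searchsorted(sorted_raw, raw, side="right") - 1
            out = csum[idx]
        else:
            raise ValueError(f"unknown output scale {output_scale!r}")
        grid = np.full((stack.nrows, stack.ncols), np.nan)
        rows, cols = stack.mask_indices()
        grid[rows, cols] = out
        prov = f"maxent(K={self.n_active},m={self.model.n_presences})"
        if not clamp:
            n_out = int(self.model.expansion.out_of_range(values).sum())
            prov += f"|unclamped({n_out} cells out of training range)"
        return SuitabilitySurface(grid, output_scale, stack.xllcorner,
                                  stack.yllcorner, stack.cellsize, provenance=prov)

    def clamping_mask(self, stack: ClimateStack):
        """Boolean grid marking unmasked cells with values outside the training range."""
        values = stack.values_table()[self.model.expansion.variables]
        flags = self.model.expansion.out_of_range(values)
        grid = np.zeros((stack.nrows, stack.ncols), dtype=bool)
        rows, cols = stack.mask_indices()
        grid[rows, cols] = flags
        return grid

    # -- information criteria -----------------------------------------------
    def aicc(self, presence_values=None, landscape=None):
        """Small-sample AIC from the landscape-normalized raw likelihood.

        ``lnL = sum_i ln raw(x_i)`` with raw normalized over the landscape
        (a ClimateStack or a DataFrame of cell values; defaults to the
        training background). ``K`` counts nonzero coefficients. Returns NaN
        (invalid candidate) when ``n <= K + 1``.
        """
        if presence_values is None:
            presence_values = self.model.presence_values
        presence_values = pd.DataFrame(presence_values)
        if len(presence_values) == 0:
            raise ValueError("AICc needs at least one presence")
        if landscape is None:
            land_values = self.model.background_values
        elif isinstance(landscape, ClimateStack):
            land_values = landscape.values_table()
        else:
            land_values = pd.DataFrame(landscape)
        eta_land = self._eta(land_values)
        log_z_land = logsumexp(eta_land)
        eta_pres = self._eta(presence_values)
        lnl = float((eta_pres - log_z_land).sum())
        n = len(presence_values)
        k = self.n_active
        if n <= k + 1:
            return float("nan")
        return 2 * k - 2 * lnl + 2 * k * (k + 1) / (n - k - 1)

    # -- reporting ----------------------------------------------------------
    def summary(self):
        m = self.model
        active = self.params[self.params.abs() > 1e-10]
        lines = [
            "Maximum-entropy niche model",
            "=" * 60,
            f"presences: {m.n_presences}    background: {m.n_background}",
            f"feature classes: {','.join(sorted(m.expansion.classes))}"
            f"    features: {m.expansion.n_features} ({self.n_active} active)",
            f"regularization multiplier: {m.reg_multiplier}",
            f"converged: {self.converged} in {self.n_iter} iterations",
            f"ln Z = {self.log_z:.6f}    entropy H = {self.entropy:.6f} nats",
            f"training gain = {self.training_gain:.6f}",
            "-" * 60,
            f"{'feature':<28}{'lambda':>12}{'beta':>10}",
        ]
        for name, lam in active.items():
            lines.append(f"{name:<28}{lam:>12.5f}{self.beta[name]:>10.5f}")
        if active.empty:
            lines.append("(no active features)")
        return "\n".join(lines)

    # -- serialization ------------------------------------------------------
    def to_dict(self):
        return {
            "expansion": self.model.expansion.to_dict(),
            "lambda": {k: float(v) for k, v in self.params.items() if abs(v) > 0},
            "beta": {k: float(v) for k, v in self.beta.items()},
            "log_z": float(self.log_z),
            "entropy": float(self.entropy),
            "n_presences": self.model.n_presences,
            "n_background": self.model.n_background,
            "reg_multiplier": self.model.reg_multiplier,
            "converged": bool(self.converged),
        }

    def save(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class ModelSettings:
    """A reusable bundle of fitting choices, applied identically across fits
    (e.g. to the two alleles, or to every permutation replicate of a test)."""

    feature_classes: object = None  # None -> auto by presence count
    reg_multiplier: float = 1.0
    n_hinge_knots: int = 8
    tol: float = 1e-5
    max_iter: int = 500

    def fit(self, presence_values, background_values) -> "MaxentResults":
        model = MaxentNicheModel(presence_values, background_values,
                                 feature_classes=self.feature_classes,
                                 reg_multiplier=self.reg_multiplier,
                                 n_hinge_knots=self.n_hinge_knots)
        return model.fit(tol=self.tol, max_iter=self.max_iter)

    def to_dict(self):
        fc = self.feature_classes
        if isinstance(fc, (set, frozenset)):
            fc = ",".join(sorted(fc))
        return {"feature_classes": fc, "reg_multiplier": self.reg_multiplier,
                "n_hinge_knots": self.n_hinge_knots, "tol": self.tol,
                "max_iter": self.max_iter}


def fit_maxent(presence_values, background_values, feature_classes=None,
               reg_multiplier: float = 1.0, tol: float = 1e-5,
               max_iter: int = 500, **kwargs) -> MaxentResults:
    """One-call fit: build the model and run the optimizer."""
    model = MaxentNicheModel(presence_values, background_values,
                             feature_classes=feature_classes,
                             reg_multiplier=reg_multiplier, **kwargs)
    return model.fit(tol=tol, max_iter=max_iter)


# ---------------------------------------------------------------------------
# AICc tuning
# ---------------------------------------------------------------------------

@dataclass
class TuningResult:
    table: pd.DataFrame
    best_classes: str
    best_multiplier: float
    best_results: MaxentResults


def tune_model(presence_values, background_values,
               candidate_feature_sets=("L", "LQ", "LQH"),
               candidate_multipliers=(0.5, 1.0, 2.0, 4.0),
               landscape=None, seed=None, tol=1e-6, max_iter=500) -> TuningResult:
    """Grid search over feature-class sets and regularization multipliers.

    The winner minimizes AICc over valid candidates (``n > K + 1``); ties are
    broken by fewer active coefficients, then by the lower multiplier. The
    full per-candidate table is returned for audit.
    """
    rows = []
    fits = {}
    for classes in candidate_feature_sets:
        for mult in candidate_multipliers:
            res = fit_maxent(presence_values, background_values,
                             feature_classes=classes, reg_multiplier=mult,
                             tol=tol, max_iter=max_iter)
            score = res.aicc(landscape=landscape)
            valid = np.isfinite(score)
            rows.append({"feature_classes": classes if isinstance(classes, str)
                         else ",".join(sorted(classes)),
                         "reg_multiplier": mult, "k": res.n_active,
                         "aicc": score, "valid": valid,
                         "converged": res.converged})
            fits[(rows[-1]["feature_classes"], mult)] = res
    table = pd.DataFrame(rows)
    valid = table[table["valid"]]
    if valid.empty:
        raise ValueError("all tuning candidates invalid (n <= K + 1 throughout)")
    best = valid.sort_values(
        ["aicc", "k", "reg_multiplier"], kind="stable").iloc[0]
    key = (best["feature_classes"], best["reg_multiplier"])
    return TuningResult(table, key[0], float(key[1]), fits[key])
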