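"""Lightweight ensemble niche modelling with thresholded habitat areas.

Given presence/absence occurrence points and a stack of environmental
raster layers on a regular lon/lat grid, this module fits an ensemble of
suitability learners on bootstrap resamples, evaluates them with AUC
(ROC), the True Skill Statistic and Cohen's kappa, projects the weighted
ensemble onto any grid with the same layer names (enabling transfer to a
second region), and converts the probability surface into suitable-habitat
areas above probability thresholds by counting qualifying cells and
multiplying by the median spherical cell area.

One reference learner is provided — a ridge-penalized logistic suitability
model — behind a registry so other learners can plug in; the scientific
content here is the evaluation, ensembling, projection and area
arithmetic, not any particular learner family.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit
from scipy.stats import rankdata

__all__ = [
    "EARTH_RADIUS_KM",
    "EnvGrid",
    "OccurrenceSet",
    "EvalMetrics",
    "ProjectionResult",
    "read_asc",
    "write_asc",
    "read_grid_dir",
    "extract_covariates",
    "RidgeLogisticLearner",
    "LEARNER_REGISTRY",
    "fit_reference_learner",
    "fit_ensemble",
    "evaluate",
    "ensemble_predict",
    "project",
    "estimate_area",
    "cell_areas_km2",
    "variable_importance",
]

EARTH_RADIUS_KM = 6371.0
DEFAULT_THRESHOLDS = (0.2, 0.5, 0.8)


class EnmError(ValueError):
    """Invalid niche-modelling input."""


# ---------------------------------------------------------------------------
# rasters

@dataclass
class EnvGrid:
    """Named stack of environmental layers on a regular lon/lat grid.

    ``layers`` maps name → 2-D array (row 0 = northernmost); nodata cells
    are NaN and shared across layers via ``nodata_mask``.
    """

    layers: dict
    xllcorner: float
    yllcorner: float
    cellsize: float

    def __post_init__(self):
        if not self.layers:
            raise EnmError("grid needs at least one layer")
        if self.cellsize <= 0:
            raise EnmError("cellsize must be > 0")
        shapes = {a.shape for a in self.layers.values()}
        if len(shapes) != 1:
            raise EnmError(f"layers disagree in shape: {sorted(shapes)}")

    @property
    def shape(self):
        return next(iter(self.layers.values())).shape

    @property
    def layer_names(self):
        return tuple(sorted(self.layers))

    @property
    def nodata_mask(self) -> np.ndarray:
        """True where any layer is nodata."""
        return np.any(np.stack([np.isnan(a) for a in self.layers.values()]), axis=0)

    def cell_index(self, lon: float, lat: float) -> tuple[int, int]:
        """Nearest-cell index with half-open convention (west/north edges inclusive)."""
        nrows, ncols = self.shape
        col = math.floor((lon - self.xllcorner) / self.cellsize)
        ytop = self.yllcorner + nrows * self.cellsize
        row = math.floor((ytop - lat) / self.cellsize)
        # the grid's extreme south/east boundary belongs to the last cell
        if lat == self.yllcorner:
            row = nrows - 1
        if lon == self.xllcorner + ncols * self.cellsize:
            col = ncols - 1
        if not (0 <= row < nrows and 0 <= col < ncols):
            raise EnmError(f"point ({lon}, {lat}) outside grid bounds")
        return row, col


def read_asc(path) -> tuple[np.ndarray, dict]:
    """Read one ESRI ASCII grid (.asc); nodata becomes NaN."""
    header_keys = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value")
    header = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines[:6]:
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in header_keys:
            header[parts[0].lower()] = float(parts[1])
            n_header += 1
        else:
            break
    data = np.loadtxt(lines[n_header:])
    data = np.atleast_2d(data)
    if "ncols" not in header or "nrows" not in header:
        raise EnmError(f"{path}: missing ncols/nrows header")
    if data.shape != (int(header["nrows"]), int(header["ncols"])):
        raise EnmError(f"{path}: data shape {data.shape} disagrees with header")
    nodata = header.get("nodata_value")
    if nodata is not None:
        data = np.where(np.isclose(data, nodata), np.nan, data)
    return data, header


def write_asc(array: np.ndarray, path, xllcorner: float, yllcorner: float,
              cellsize: float, nodata_value: float = -9999.0) -> None:
    """Write a 2-D array as an ESRI ASCII grid; NaN written as nodata."""
    arr = np.where(np.isnan(array), nodata_value, array)
    nrows, ncols = arr.shape
    with open(path, "w") as fh:
        fh.write(
            f"ncols {ncols}\nnrows {nrows}\n"
            f"xllcorner {xllcorner}\nyllcorner {yllcorner}\n"
            f"cellsize {cellsize}\nNODATA_value {nodata_value}\n"
        )
        for row in arr:
            fh.write(" ".join(f"{v:.6g}" for v in row) + "\n")


def read_grid_dir(directory) -> EnvGrid:
    """Read every .asc in a directory as one multi-layer grid (name = stem)."""
    from pathlib import Path

    paths = sorted(Path(directory).glob("*.asc"))
    if not paths:
        raise EnmError(f"no .asc layers found in {directory}")
    layers, header0 = {}, None
    for p in paths:
        data, header = read_asc(p)
        if header0 is None:
            header0 = header
        for key in ("xllcorner", "yllcorner", "cellsize"):
            if not math.isclose(header[key], header0[key]):
                raise EnmError(f"{p.name}: {key} disagrees with other layers")
        layers[p.stem] = data
    return EnvGrid(layers, header0["xllcorner"], header0["yllcorner"], header0["cellsize"])


# ---------------------------------------------------------------------------
# occurrences

@dataclass
class OccurrenceSet:
    """Presence/absence points with per-point extracted covariates."""

    lon: np.ndarray
    lat: np.ndarray
    labels: np.ndarray  # 1 = presence, 0 = absence
    covariates: pd.DataFrame  # columns = layer names, rows align with points
    flagged_nodata: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.flagged_nodata is None:
            self.flagged_nodata = np.zeros(len(self.labels), dtype=bool)

    @property
    def fitting_mask(self) -> np.ndarray:
        return ~self.flagged_nodata

    def fitting_data(self) -> tuple[np.ndarray, np.ndarray]:
        m = self.fitting_mask
        return self.covariates.loc[m].to_numpy(float), self.labels[m]


def extract_covariates(grid: EnvGrid, points: pd.DataFrame) -> OccurrenceSet:
    """Nearest-cell covariate extraction for (lon, lat, label) points.

    Points on nodata cells are flagged and excluded from fitting (count
    logged as a warning); an error is raised only if no point falls inside
    the grid.
    """
    labels = points["label"].map({"presence": 1, "absence": 0, 1: 1, 0: 0}).to_numpy()
    if np.any(pd.isna(labels)):
        raise EnmError("labels must be 'presence'/'absence' (or 1/0)")
    names = grid.layer_names
    rows = []
    flagged = np.zeros(len(points), dtype=bool)
    inside = 0
    for i, (lon, lat) in enumerate(zip(points["lon"], points["lat"])):
        try:
            r, c = grid.cell_index(float(lon), float(lat))
        except EnmError:
            flagged[i] = True
            rows.append([np.nan] * len(names))
            continue
        inside += 1
        vals = [grid.layers[nm][r, c] for nm in names]
        if any(np.isnan(v) for v in vals):
            flagged[i] = True
        rows.append(vals)
    if inside == 0:
        raise EnmError("all points fall outside the grid")
    if flagged.any():
        warnings.warn(f"{int(flagged.sum())} points on nodata/outside cells excluded from fitting",
                      stacklevel=2)
    cov = pd.DataFrame(rows, columns=list(names))
    return OccurrenceSet(points["lon"].to_numpy(float), points["lat"].to_numpy(float),
                         labels.astype(int), cov, flagged)


# ---------------------------------------------------------------------------
# learners

class RidgeLogisticLearner:
    """Ridge-penalized logistic suitability model.

    Covariates are standardized internally; the L2 penalty (``alpha``, not
    applied to the intercept) keeps the fit defined under separation and
    collinear layers.  Deterministic given data.
    """

    def __init__(self, alpha: float = 1.0):
        self.alpha = float(alpha)
        self.coef_ = None
        self.intercept_ = None
        self.feature_names_ = None
        self._mean = None
        self._std = None

    def fit(self, X: np.ndarray, y: np.ndarray, feature_names=None):
        X = np.asarray(X, float)
        y = np.asarray(y, float)
        if set(np.unique(y)) - {0.0, 1.0}:
            raise EnmError("labels must be binary 0/1")
        if y.min() == y.max():
            raise EnmError("both classes are required to fit a suitability model")
        self._mean = X.mean(axis=0)
        std = X.std(axis=0)
        self._std = np.where(std > 0, std, 1.0)
        Z = (X - self._mean) / self._std
        n, p = Z.shape

        def nll(beta):
            eta = beta[0] + Z @ beta[1:]
            # log(1 + e^eta) − y·eta, numerically stable
            val = np.sum(np.logaddexp(0.0, eta) - y * eta) + 0.5 * self.alpha * beta[1:] @ beta[1:]
            mu = expit(eta)
            grad = np.empty(p + 1)
            grad[0] = np.sum(mu - y)
            grad[1:] = Z.T @ (mu - y) + self.alpha * beta[1:]
            return val, grad

        res = minimize(nll, np.zeros(p + 1), jac=True, method="L-BFGS-B",
                       options={"maxiter": 500})
        self.intercept_ = float(res.x[0])
        self.coef_ = res.x[1:]
        self.feature_names_ = list(feature_names) if feature_names is not None else None
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if self.coef_ is None:
            raise EnmError("learner is not fitted")
        Z = (np.asarray(X, float) - self._mean) / self._std
        return expit(self.intercept_ + Z @ self.coef_)

    @property
    def raw_coefficients(self) -> np.ndarray:
        """Coefficients on the original covariate scale."""
        return self.coef_ / self._std


#: pluggable registry: name → zero-argument factory returning an unfitted learner
LEARNER_REGISTRY = {"ridge_logistic": RidgeLogisticLearner}


def fit_reference_learner(occ: OccurrenceSet, seed: int | None = None,
                          learner: str = "ridge_logistic", **kwargs):
    """Fit one registry learner on the occurrence set (nodata points excluded)."""
    X, y = occ.fitting_data()
    model = LEARNER_REGISTRY[learner](**kwargs)
    return model.fit(X, y, feature_names=list(occ.covariates.columns))


def fit_ensemble(occ: OccurrenceSet, k: int = 20, seed: int = 0,
                 learner: str = "ridge_logistic", **kwargs):
    """k learners on bootstrap resamples; returns (learners, tss_weights).

    Each member is fitted on a with-replacement resample of the fitting
    points (redrawn until both classes are present) and weighted by its
    TSS on the full fitting set, floored at 0.
    """
    X, y = occ.fitting_data()
    rng = np.random.default_rng(seed)
    learners, weights = [], []
    for _ in range(k):
        for _attempt in range(100):
            idx = rng.integers(0, len(y), size=len(y))
            if y[idx].min() != y[idx].max():
                break
        else:
            raise EnmError("could not draw a bootstrap sample with both classes")
        model = LEARNER_REGISTRY[learner](**kwargs)
        model.fit(X[idx], y[idx], feature_names=list(occ.covariates.columns))
        m = evaluate(model.predict_proba(X), y)
        learners.append(model)
        weights.append(max(m.tss, 0.0))
    return learners, np.asarray(weights)


# ---------------------------------------------------------------------------
# evaluation

@dataclass(frozen=True)
class EvalMetrics:
    auc: float
    tss: float
    kappa: float
    threshold_star: float  # score threshold maximizing TSS


def _confusion_metrics(scores, labels, t):
    pred = scores >= t
    pos, neg = labels == 1, labels == 0
    tp, fn = np.sum(pred & pos), np.sum(~pred & pos)
    tn, fp = np.sum(~pred & neg), np.sum(pred & neg)
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    tss = sens + spec - 1.0
    n = len(labels)
    po = (tp + tn) / n
    pe = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / n**2
    kappa = (po - pe) / (1.0 - pe) if pe < 1.0 else 0.0
    return tss, kappa


def evaluate(scores: np.ndarray, labels: np.ndarray) -> EvalMetrics:
    """AUC (Mann–Whitney, ties ½), max-TSS and kappa at the TSS-optimal threshold.

    The threshold grid is the sorted unique scores — exact for these
    step-function metrics.  Both classes must be present.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos, neg = labels == 1, labels == 0
    n1, n0 = int(pos.sum()), int(neg.sum())
    if n1 == 0 or n0 == 0:
        raise EnmError("evaluation requires both classes")
    ranks = rankdata(scores)
    auc = (ranks[pos].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
    best = (-np.inf, 0.0, 0.5)
    for t in np.unique(scores):
        tss, kappa = _confusion_metrics(scores, labels, t)
        if tss > best[0]:
            best = (tss, kappa, float(t))
    return EvalMetrics(auc=float(auc), tss=float(best[0]), kappa=float(best[1]),
                       threshold_star=best[2])


# ---------------------------------------------------------------------------
# ensembling, projection, areas

def ensemble_predict(learners, X: np.ndarray, weights=None) -> np.ndarray:
    """Weighted mean of member probabilities (default: equal weights)."""
    if not learners:
        raise EnmError("need at least one learner")
    if weights is None:
        weights = np.ones(len(learners))
    weights = np.asarray(weights, float)
    if np.any(weights < 0) or weights.sum() <= 0:
        raise EnmError("weights must be >= 0 and not all zero")
    probs = np.stack([m.predict_proba(X) for m in learners])
    return probs.T @ (weights / weights.sum())


@dataclass
class ProjectionResult:
    """Probability surface on a grid plus per-threshold habitat areas."""

    probability: np.ndarray  # NaN on nodata
    grid: EnvGrid
    areas_km2: dict  # threshold -> area


def cell_areas_km2(grid: EnvGrid) -> np.ndarray:
    """Spherical cell areas per row: R²·Δλ·|sin φ_top − sin φ_bottom|."""
    nrows, ncols = grid.shape
    dlam = math.radians(grid.cellsize)
    lat_top = grid.yllcorner + (nrows - np.arange(nrows)) * grid.cellsize
    lat_bot = lat_top - grid.cellsize
    row_area = EARTH_RADIUS_KM**2 * dlam * np.abs(
        np.sin(np.radians(lat_top)) - np.sin(np.radians(lat_bot))
    )
    return np.repeat(row_area[:, None], ncols, axis=1)


def estimate_area(proj: ProjectionResult, threshold: float) -> float:
    """Habitat area: cells with p > threshold × median cell area (km²).

    The median cell area is taken over non-nodata cells of the projection
    grid, matching an equal-area-per-cell approximation.
    """
    if not 0.0 < threshold < 1.0:
        raise EnmError("threshold must be in (0, 1)")
    p = proj.probability
    valid = ~np.isnan(p)
    count = int(np.sum(p[valid] > threshold))
    if count == 0:
        return 0.0
    median_cell = float(np.median(cell_areas_km2(proj.grid)[valid]))
    return count * median_cell


def project(learners, grid: EnvGrid, weights=None,
            thresholds=DEFAULT_THRESHOLDS, training_layer_names=None) -> ProjectionResult:
    """Apply the ensemble cell-wise to a grid (same layer names as training).

    Works for any grid carrying the training layers — including a second
    region — so a model fitted in one range can be transferred.  Nodata
    propagates to the probability surface.
    """
    names = training_layer_names
    if names is None:
        names = getattr(learners[0], "feature_names_", None) or grid.layer_names
    missing = [nm for nm in names if nm not in grid.layers]
    if missing:
        raise EnmError(f"projection grid lacks layers: {missing}")
    nrows, ncols = grid.shape
    stack = np.stack([grid.layers[nm] for nm in names], axis=-1).reshape(-1, len(names))
    valid = ~np.any(np.isnan(stack), axis=1)
    prob = np.full(nrows * ncols, np.nan)
    if valid.any():
        prob[valid] = ensemble_predict(learners, stack[valid], weights)
    result = ProjectionResult(prob.reshape(nrows, ncols), grid, {})
    result.areas_km2 = {t: estimate_area(result, t) for t in thresholds}
    return result


def variable_importance(learner, occ: OccurrenceSet, seed: int = 0, reps: int = 10) -> dict:
    """Permutation importance: 1 − Pearson r between baseline and permuted predictions.

    Each covariate is permuted independently ``reps`` times; importances
    are the mean over repetitions, clipped to [0, 1].  Constant baseline
    predictions give importance 0 with a warning.
    """
    X, _ = occ.fitting_data()
    rng = np.random.default_rng(seed)
    base = learner.predict_proba(X)
    names = list(occ.covariates.columns)
    if np.std(base) == 0:
        warnings.warn("constant predictions: all importances set to 0", stacklevel=2)
        return {nm: 0.0 for nm in names}
    out = {}
    for j, nm in enumerate(names):
        vals = []
        for _ in range(reps):
            Xp = X.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            perm = learner.predict_proba(Xp)
            if np.std(perm) == 0:
                vals.append(1.0)
                continue
            r = np.corrcoef(base, perm)[0, 1]
            vals.append(1.0 - r)
        out[nm] = float(np.clip(np.mean(vals), 0.0, 1.0))
    return out
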