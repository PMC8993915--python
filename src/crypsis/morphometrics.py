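"""Discriminant morphometrics for cryptic-species diagnosis.

The measurement system is the 19-variable scheme used in taxonomic
revisions of *Lasius* ants: absolute head/appendage lengths in mm
(``CL``, ``CW``, ``CS``, ``SL``, ``EYE``, ``GuHL``, ``dClAn``, ``MP6``,
``PnHL``, ``PoOc``, ``PLF``), the pubescence distance ``sqPDCL`` in µm,
six setae counts (``nGen``, ``nGu``, ``nHT``, ``nOcc``, ``nSc``, ``nSt``)
and the categorical offset-mandibular-denticle state ``MaDe``.

The module provides

- derived size-corrected ratios (``CL/CW``, ``GuHL/CS``, ...) as used in
  group-comparison tables,
- the standard taxonomic indices CI = 100·HW/HL and SI = 100·SL/HW,
- the frozen published diagnostic function :data:`PUBLISHED_D` whose sign
  separates the Nearctic cryptic species (negative) from its Palearctic
  look-alikes (positive),
- two-group linear discriminant fitting, AIC-based stepwise logistic
  variable selection, Wilcoxon/Fisher group comparison, and PCA on the
  reduced variable set.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MEASUREMENT_VARS",
    "LENGTH_VARS",
    "COUNT_VARS",
    "RATIO_DEFS",
    "MorphoSpecimen",
    "StandardMeasurements",
    "DiscriminantModel",
    "GroupComparisonRow",
    "PUBLISHED_D",
    "read_morpho_csv",
    "compute_derived_ratios",
    "standard_indices",
    "apply_discriminant",
    "score_table",
    "fit_lda",
    "stepwise_select",
    "group_compare",
    "pca_morpho",
]

#: lengths measured in mm
LENGTH_VARS = ("CL", "CS", "CW", "dClAn", "EYE", "GuHL", "MP6", "PLF", "PnHL", "PoOc", "SL")
#: setae counts (non-negative integers)
COUNT_VARS = ("nGen", "nGu", "nHT", "nOcc", "nSc", "nSt")
#: the full 19-variable measurement scheme
MEASUREMENT_VARS = tuple(sorted(LENGTH_VARS + COUNT_VARS + ("sqPDCL", "MaDe"), key=str.lower))

GROUPS = ("nearctic", "palearctic", "unknown")

#: derived size-corrected ratios: name -> (numerator, denominator)
RATIO_DEFS = {
    "CL/CW": ("CL", "CW"),
    "SL/CS": ("SL", "CS"),
    "EYE/CS": ("EYE", "CS"),
    "GuHL/CS": ("GuHL", "CS"),
    "dClAn/CS": ("dClAn", "CS"),
    "MP6/CS": ("MP6", "CS"),
    "PnHL/CS": ("PnHL", "CS"),
    "PoOc/CL": ("PoOc", "CL"),
}


class MorphometricsError(ValueError):
    """Invalid measurement data."""


def _is_missing(v) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v))


@dataclass
class MorphoSpecimen:
    """One specimen's raw measurements plus group label.

    Lengths are in mm except ``sqPDCL`` (µm); counts are raw integers;
    missing values are ``None``/NaN and are allowed (flagged downstream).
    """

    specimen_id: str
    group: str = "unknown"
    measurements: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.group not in GROUPS:
            raise MorphometricsError(f"unknown group label {self.group!r}; expected one of {GROUPS}")
        for var in LENGTH_VARS + ("sqPDCL",):
            v = self.measurements.get(var)
            if not _is_missing(v) and v is not None and v <= 0:
                raise MorphometricsError(f"{self.specimen_id}: {var} must be > 0, got {v}")
        for var in COUNT_VARS:
            v = self.measurements.get(var)
            if not _is_missing(v) and v is not None:
                if v < 0 or int(v) != v:
                    raise MorphometricsError(
                        f"{self.specimen_id}: {var} must be a non-negative integer, got {v}"
                    )
        # CS is derivable as the mean of head length and width
        cs, cl, cw = (self.measurements.get(k) for k in ("CS", "CL", "CW"))
        if not any(map(_is_missing, (cs, cl, cw))):
            if abs(cs - (cl + cw) / 2.0) > 1e-9 + 1e-6 * cs:
                warnings.warn(
                    f"{self.specimen_id}: CS={cs} deviates from (CL+CW)/2={(cl + cw) / 2}",
                    stacklevel=2,
                )

    def __getitem__(self, var):
        return self.measurements.get(var)

    @classmethod
    def from_series(cls, row: pd.Series) -> "MorphoSpecimen":
        meas = {
            k: (None if pd.isna(v) else v)
            for k, v in row.items()
            if k not in ("specimen_id", "group")
        }
        return cls(str(row["specimen_id"]), str(row.get("group", "unknown")), meas)


def read_morpho_csv(path) -> pd.DataFrame:
    """Read a per-specimen measurement table (one row per specimen).

    Expected header: ``specimen_id``, ``group`` and the 19 measurement
    codes; units mm except sqPDCL (µm) and raw counts.
    """
    df = pd.read_csv(path)
    if "specimen_id" not in df.columns:
        raise MorphometricsError("morphometric CSV must have a 'specimen_id' column")
    if "group" not in df.columns:
        df["group"] = "unknown"
    bad = set(df["group"].dropna()) - set(GROUPS)
    if bad:
        raise MorphometricsError(f"unknown group labels {sorted(bad)}; expected {GROUPS}")
    # validate each row (raises on impossible values)
    for _, row in df.iterrows():
        MorphoSpecimen.from_series(row)
    return df


def _cs_value(spec) -> float | None:
    """CS, filled as (CL+CW)/2 when not supplied."""
    cs = spec["CS"]
    if not _is_missing(cs):
        return cs
    cl, cw = spec["CL"], spec["CW"]
    if _is_missing(cl) or _is_missing(cw):
        return None
    return (cl + cw) / 2.0


def compute_derived_ratios(spec: MorphoSpecimen) -> dict:
    """Size-corrected ratios for one specimen.

    Missing numerator or denominator yields ``None`` for that ratio
    (flagged, not an exception); non-positive lengths were already
    rejected at construction.
    """
    values = dict(spec.measurements)
    values["CS"] = _cs_value(spec)
    out = {}
    for name, (num, den) in RATIO_DEFS.items():
        a, b = values.get(num), values.get(den)
        out[name] = None if (_is_missing(a) or _is_missing(b)) else a / b
    return out


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class StandardMeasurements:
    """Standard taxonomic measurements of a type specimen (mm)."""

    HL: float
    HW: float
    SL: float
    EL: float | None = None
    EW: float | None = None
    ProW: float | None = None
    ML: float | None = None
    HTL: float | None = None

    def __post_init__(self):
        for name in ("HL", "HW", "SL"):
            if getattr(self, name) <= 0:
                raise MorphometricsError(f"{name} must be > 0")


def standard_indices(m: StandardMeasurements) -> tuple[int, int]:
    """Cephalic and scape indices: CI = round(100·HW/HL), SI = round(100·SL/HW).

    Rounding is half-up to integers, the convention of printed taxonomic
    descriptions.
    """
    return _round_half_up(100.0 * m.HW / m.HL), _round_half_up(100.0 * m.SL / m.HW)


@dataclass(frozen=True)
class DiscriminantModel:
    """A linear diagnostic score D = Σ coef_i·x_i + intercept.

    ``decision_rule`` fixes the sign convention: negative D diagnoses the
    nearctic group, positive the palearctic group, D = 0 is ambiguous.
    """

    variables: tuple
    coefficients: tuple
    intercept: float
    decision_rule: str = "negative_is_nearctic"

    def __post_init__(self):
        if len(self.variables) != len(self.coefficients):
            raise MorphometricsError("variables and coefficients must align")

    def score(self, values: dict) -> float:
        total = self.intercept
        for var, coef in zip(self.variables, self.coefficients):
            v = values.get(var) if isinstance(values, dict) else values[var]
            if _is_missing(v):
                raise MorphometricsError(f"missing required variable {var!r}")
            total += coef * float(v)
        return total


#: The published species-diagnostic function (measurements in mm, counts raw);
#: negative D diagnoses the Nearctic cryptic species.
PUBLISHED_D = DiscriminantModel(
    variables=("GuHL", "dClAn", "MP6", "nSt"),
    coefficients=(-43.792, 113.436, 75.68, -0.431),
    intercept=-10.075,
)


def apply_discriminant(model: DiscriminantModel, spec) -> tuple[float, str]:
    """Evaluate a discriminant model on one specimen.

    Returns ``(D, label)`` with label ``nearctic`` iff D < 0,
    ``palearctic`` iff D > 0 and ``ambiguous`` at exactly 0.
    """
    values = spec.measurements if isinstance(spec, MorphoSpecimen) else spec
    d = model.score(values)
    label = "nearctic" if d < 0 else ("palearctic" if d > 0 else "ambiguous")
    return d, label


def score_table(df: pd.DataFrame, model: DiscriminantModel = PUBLISHED_D) -> pd.DataFrame:
    """Apply a discriminant model row-wise; returns specimen_id, D, label."""
    rows = []
    for _, row in df.iterrows():
        d, label = apply_discriminant(model, {v: row[v] for v in model.variables})
        rows.append((row["specimen_id"], d, label))
    return pd.DataFrame(rows, columns=["specimen_id", "D", "label"])


def fit_lda(df: pd.DataFrame, variables, group_col: str = "group") -> DiscriminantModel:
    """Two-group linear discriminant analysis with a midpoint boundary.

    The direction is S_pooled⁻¹(μ_pal − μ_nea) and the intercept places the
    decision boundary at the midpoint of the projected group means, so the
    nearctic group scores negative.  Raw coefficient scale is arbitrary up
    to positive factors; only classifications are comparable across fits.
    """
    variables = tuple(variables)
    sub = df.dropna(subset=list(variables) + [group_col])
    groups = [g for g in ("nearctic", "palearctic") if (sub[group_col] == g).any()]
    if len(groups) < 2:
        raise MorphometricsError("both groups must be non-empty")
    X1 = sub.loc[sub[group_col] == "nearctic", list(variables)].to_numpy(float)
    X2 = sub.loc[sub[group_col] == "palearctic", list(variables)].to_numpy(float)
    if len(X1) < 2 or len(X2) < 2:
        raise MorphometricsError("need >= 2 specimens per group")
    mu1, mu2 = X1.mean(axis=0), X2.mean(axis=0)
    if np.allclose(mu1, mu2):
        raise MorphometricsError("identical group means: discriminant direction undefined")
    S = ((len(X1) - 1) * np.cov(X1, rowvar=False) + (len(X2) - 1) * np.cov(X2, rowvar=False)) / (
        len(X1) + len(X2) - 2
    )
    S = np.atleast_2d(S)
    try:
        w = np.linalg.solve(S, mu2 - mu1)
    except np.linalg.LinAlgError as exc:
        raise MorphometricsError(
            "singular pooled covariance; reduce the variable set (collinear measurements)"
        ) from exc
    # w points from the nearctic toward the palearctic mean, so nearctic
    # specimens project below the midpoint boundary (negative D)
    intercept = -float(w @ (mu1 + mu2) / 2.0)
    return DiscriminantModel(variables, tuple(float(c) for c in w), intercept)


def _logit_aic(endog, exog) -> float:
    """AIC of a logistic fit; penalized fallback under perfect separation."""
    import statsmodels.api as sm

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(endog, exog).fit(disp=0, maxiter=200)
            if np.isfinite(res.llf) and res.mle_retvals.get("converged", True):
                return float(-2 * res.llf + 2 * exog.shape[1])
        except Exception:
            pass
    # perfect separation (or non-convergence): ridge-penalized likelihood
    warnings.warn("separation in logistic step; using penalized likelihood", stacklevel=3)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.Logit(endog, exog).fit_regularized(method="l1", alpha=1.0, disp=0, maxiter=500)
    return float(-2 * res.llf + 2 * exog.shape[1])


def stepwise_select(df: pd.DataFrame, candidate_variables, group_col: str = "group"):
    """Bidirectional stepwise logistic selection minimizing AIC.

    Starts from the intercept-only model; at each round considers every
    single addition and removal and takes the move with the lowest AIC
    (ties broken alphabetically by variable name); stops when no move
    improves.  Deterministic given the data.
    """
    candidates = sorted(candidate_variables)
    sub = df.dropna(subset=candidates + [group_col])
    y = (sub[group_col] == "palearctic").to_numpy(int)
    if y.min() == y.max():
        raise MorphometricsError("stepwise selection needs both group labels")
    X = sub[candidates].to_numpy(float)
    # standardize for numeric stability; AIC ordering is unaffected
    X = (X - X.mean(axis=0)) / np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
    cols = {v: X[:, i] for i, v in enumerate(candidates)}

    def aic_of(subset):
        exog = np.column_stack([np.ones(len(y))] + [cols[v] for v in subset])
        return _logit_aic(y, exog)

    selected: list[str] = []
    best_aic = aic_of(selected)
    while True:
        moves = []
        for v in candidates:
            if v not in selected:
                moves.append((aic_of(selected + [v]), "add", v))
        for v in selected:
            moves.append((aic_of([u for u in selected if u != v]), "drop", v))
        if not moves:
            break
        moves.sort(key=lambda t: (t[0], t[2]))
        aic, action, var = moves[0]
        if aic >= best_aic - 1e-9:
            break
        best_aic = aic
        if action == "add":
            selected.append(var)
        else:
            selected.remove(var)
    return selected


@dataclass
class GroupComparisonRow:
    """One variable's per-group summary and test in a comparison table."""

    variable: str
    nearctic_median: float
    nearctic_range: tuple
    palearctic_median: float
    palearctic_range: tuple
    p_value: float
    test: str  # 'wilcoxon' or 'fisher'
    n_dropped: int = 0


def _fisher_made(a: pd.Series, b: pd.Series) -> tuple[float, int]:
    """Fisher's exact test on MaDe collapsed to present/absent."""

    def collapse(s):
        s = s.dropna()
        s = s[~s.astype(str).str.lower().isin({"unknown", "?"})]
        present = s.astype(str).str.lower().isin({"present", "1", "yes", "true"}) | (
            pd.to_numeric(s, errors="coerce") > 0
        )
        return int(present.sum()), int((~present).sum())
    (p1, a1), (p2, a2) = collapse(a), collapse(b)
    dropped = len(a) + len(b) - (p1 + a1 + p2 + a2)
    _, p = stats.fisher_exact([[p1, a1], [p2, a2]], alternative="two-sided")
    return float(p), dropped


def group_compare(df: pd.DataFrame, variables=None, group_col: str = "group"):
    """Per-variable medians/ranges and two-group tests.

    Numeric variables get a two-sided Wilcoxon rank-sum test (exact when
    sample sizes permit and there are no ties, normal approximation with
    continuity correction otherwise); the categorical ``MaDe`` gets
    Fisher's exact test on the present/absent collapse.  No multiplicity
    adjustment is applied.  Median uses linear interpolation between order
    statistics for even n.
    """
    if variables is None:
        variables = [v for v in MEASUREMENT_VARS if v in df.columns]
    g1 = df[df[group_col] == "nearctic"]
    g2 = df[df[group_col] == "palearctic"]
    if g1.empty or g2.empty:
        raise MorphometricsError("both groups must be non-empty")
    rows = []
    for var in variables:
        if var == "MaDe":
            p, dropped = _fisher_made(g1[var], g2[var])
            rows.append(
                GroupComparisonRow(var, math.nan, (math.nan, math.nan), math.nan,
                                   (math.nan, math.nan), p, "fisher", dropped)
            )
            continue
        a = pd.to_numeric(g1[var], errors="coerce").dropna().to_numpy(float)
        b = pd.to_numeric(g2[var], errors="coerce").dropna().to_numpy(float)
        dropped = (len(g1) - len(a)) + (len(g2) - len(b))
        if len(a) == 0 or len(b) == 0:
            continue
        if np.ptp(np.concatenate([a, b])) == 0:
            warnings.warn(f"{var}: all values tied across both groups; p = 1", stacklevel=2)
            p = 1.0
        else:
            p = float(
                stats.mannwhitneyu(a, b, alternative="two-sided", use_continuity=True).pvalue
            )
        rows.append(
            GroupComparisonRow(
                var,
                float(np.median(a)), (float(a.min()), float(a.max())),
                float(np.median(b)), (float(b.min()), float(b.max())),
                p, "wilcoxon", dropped,
            )
        )
    return rows


def comparison_to_frame(rows) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "variable": [r.variable for r in rows],
            "nearctic_median": [r.nearctic_median for r in rows],
            "nearctic_min": [r.nearctic_range[0] for r in rows],
            "nearctic_max": [r.nearctic_range[1] for r in rows],
            "palearctic_median": [r.palearctic_median for r in rows],
            "palearctic_min": [r.palearctic_range[0] for r in rows],
            "palearctic_max": [r.palearctic_range[1] for r in rows],
            "p_value": [r.p_value for r in rows],
            "test": [r.test for r in rows],
        }
    )


def pca_morpho(df: pd.DataFrame, variables=("GuHL", "dClAn", "MP6", "nSt")):
    """PCA of the (standardized) reduced variable set.

    Returns ``(scores, loadings, explained)`` where loadings columns are
    orthonormal principal axes and ``explained`` are variance fractions
    summing to 1.  Complete cases only; errors if fewer specimens than
    variables.
    """
    variables = list(variables)
    sub = df.dropna(subset=variables)
    X = sub[variables].to_numpy(float)
    if X.shape[0] < X.shape[1]:
        raise MorphometricsError("fewer complete specimens than variables")
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        zero = [v for v, s in zip(variables, sd) if s == 0]
        raise MorphometricsError(f"constant variables cannot be standardized: {zero}")
    Z = (X - X.mean(axis=0)) / sd
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    scores = U * s
    explained = s**2 / np.sum(s**2)
    return scores, Vt.T, explained
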