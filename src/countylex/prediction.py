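"""Omnibus prediction comparison: ridge regression vs traditional covariates.

A language-only feature set (all dictionary and topic scores) and a
"traditional" set (socioeconomic/health covariates only) are each fit with
ridge regression under k-fold cross-validation, on identical folds so the
comparison is paired.  Model skill is the Pearson correlation between the
assembled out-of-fold predictions and the outcome; the two skills — which
are dependent correlations sharing the outcome variable — are compared with
Steiger's (1980) z for dependent correlations.

The ridge penalty is chosen per outer fold by an inner grid search on the
training data only, and feature standardization is fit on training folds
only, so no information leaks from a test fold into model selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import Ridge
from sklearn.model_selection import KFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .core_io import ValidationError, get_logger

log = get_logger("countylex.prediction")

__all__ = [
    "PredictionResult",
    "ModelComparison",
    "DEFAULT_PENALTY_GRID",
    "ridge_cv",
    "compare_dependent_correlations",
    "power_note",
]

#: Logarithmic ridge-penalty grid over six decades.  The top is capped well
#: below the intercept-only regime: a near-constant predictor is not a
#: weaker model under the CV-correlation metric but a degenerate one, with
#: a systematically *negative* held-out correlation of about
#: -sqrt(k/(n(k-1))) under the null (each fold's intercept is the mean of
#: the counties the fold excludes).
DEFAULT_PENALTY_GRID = tuple(np.logspace(-4, 2, 7))


@dataclass
class PredictionResult:
    """Out-of-fold ridge predictions and their correlation with the outcome."""

    model_id: str
    fold_assignments: dict[str, int]
    predictions: dict[str, float]
    cv_r: float
    n: int
    lambdas: list[float]


@dataclass
class ModelComparison:
    """Steiger's z comparison of two dependent prediction-outcome correlations."""

    r_a: float
    r_b: float
    r_ab: float
    z: float
    p: float
    n: int


# --------------------------------------------------------------------------
# ridge with nested cross-validation
# --------------------------------------------------------------------------


def ridge_cv(
    features: pd.DataFrame,
    outcome: pd.Series,
    k: int = 10,
    penalty_grid: tuple[float, ...] = DEFAULT_PENALTY_GRID,
    seed: int = 0,
    model_id: str = "model",
    inner_folds: int = 5,
) -> PredictionResult:
    """k-fold cross-validated ridge regression with per-fold penalty search.

    ``features`` is a county x variable matrix indexed by fips; ``outcome``
    a fips-indexed series.  For each outer fold, the penalty minimizing
    inner-CV mean squared error on the training portion is selected, a
    standardize+ridge pipeline refit on the full training portion, and the
    held-out counties predicted.  Every county is predicted exactly once
    out-of-fold; ``cv_r`` is computed once on the assembled vector.
    """
    joined = features.join(outcome.rename("__y__"), how="inner").dropna()
    dropped = len(features) - len(joined)
    if dropped:
        log.info("ridge_cv(%s): join/NaN dropped %d count(ies)", model_id, dropped)
    n = len(joined)
    if k < 2:
        raise ValidationError("k must be >= 2")
    if k > n:
        raise ValidationError(f"k={k} exceeds n={n}")
    y = joined["__y__"].to_numpy(dtype=float)
    if y.std() == 0:
        raise ValidationError("constant outcome")
    X = joined.drop(columns="__y__").to_numpy(dtype=float)
    fips = list(joined.index)

    outer = KFold(n_splits=k, shuffle=True, random_state=seed)
    preds = np.full(n, np.nan)
    fold_of = np.full(n, -1, dtype=int)
    lambdas: list[float] = []
    for fold, (train, test) in enumerate(outer.split(X)):
        Xtr, ytr = X[train], y[train]
        best = _inner_select(Xtr, ytr, penalty_grid, inner_folds, seed + fold + 1)
        pipe = make_pipeline(StandardScaler(), Ridge(alpha=best))
        pipe.fit(Xtr, ytr)
        preds[test] = pipe.predict(X[test])
        fold_of[test] = fold
        lambdas.append(float(best))
    assert not np.isnan(preds).any()
    cv_r = float(np.corrcoef(preds, y)[0, 1])
    return PredictionResult(
        model_id=model_id,
        fold_assignments=dict(zip(fips, fold_of.tolist())),
        predictions=dict(zip(fips, preds.tolist())),
        cv_r=cv_r,
        n=n,
        lambdas=lambdas,
    )


def _inner_select(
    X: np.ndarray, y: np.ndarray, grid: tuple[float, ...], folds: int, seed: int
) -> float:
    """Penalty with lowest inner-CV mean squared error on training data."""
    folds = min(folds, len(y))
    inner = KFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(inner.split(X))
    errors = []
    for alpha in grid:
        sse = 0.0
        for train, val in splits:
            pipe = make_pipeline(StandardScaler(), Ridge(alpha=alpha))
            pipe.fit(X[train], y[train])
            sse += float(((pipe.predict(X[val]) - y[val]) ** 2).sum())
        errors.append(sse)
    return grid[int(np.argmin(errors))]


# --------------------------------------------------------------------------
# dependent-correlation comparison
# --------------------------------------------------------------------------


def _steiger_z(r_a: float, r_b: float, r_ab: float, n: int) -> tuple[float, float]:
    """Steiger's (1980) z for two correlations sharing one variable.

    Uses the pooled mean correlation in the covariance term:
    rbar = (r_a + r_b)/2, psi = r_ab(1 - 2 rbar^2) - rbar^2 (1 - 2 rbar^2
    - r_ab^2)/2, sbar = psi / (1 - rbar^2)^2, and
    z = (z_a - z_b) sqrt((n-3) / (2 - 2 sbar)).
    """
    for name, r in (("r_a", r_a), ("r_b", r_b), ("r_ab", r_ab)):
        if not -1 < r < 1:
            raise ValidationError(f"{name}={r} must be strictly inside (-1, 1)")
    if n < 4:
        raise ValidationError("n must be >= 4")
    rbar = (r_a + r_b) / 2
    psi = r_ab * (1 - 2 * rbar**2) - rbar**2 * (1 - 2 * rbar**2 - r_ab**2) / 2
    sbar = psi / (1 - rbar**2) ** 2
    z = (np.arctanh(r_a) - np.arctanh(r_b)) * np.sqrt((n - 3) / (2 - 2 * sbar))
    p = 2 * stats.norm.sf(abs(z))
    return float(z), float(p)


def compare_dependent_correlations(
    pred_a: dict[str, float] | pd.Series,
    pred_b: dict[str, float] | pd.Series,
    outcome: dict[str, float] | pd.Series,
) -> ModelComparison:
    """Compare two models' prediction-outcome correlations on shared counties.

    Both prediction vectors correlate with the same outcome, so the two
    skills are dependent; Steiger's z accounts for their covariance through
    the inter-prediction correlation.  Identical prediction vectors give
    z = 0, p = 1 (not an error).
    """
    a = pd.Series(pred_a, dtype=float)
    b = pd.Series(pred_b, dtype=float)
    y = pd.Series(outcome, dtype=float)
    common = a.index.intersection(b.index).intersection(y.index)
    if len(common) < 10:
        raise ValidationError(f"need >= 10 common counties, got {len(common)}")
    av, bv, yv = (s.loc[common].to_numpy() for s in (a, b, y))
    n = len(common)
    r_a = float(np.corrcoef(av, yv)[0, 1])
    r_b = float(np.corrcoef(bv, yv)[0, 1])
    if np.allclose(av - av.mean(), bv - bv.mean()) or np.isclose(
        abs(float(np.corrcoef(av, bv)[0, 1])), 1.0
    ):
        return ModelComparison(r_a=r_a, r_b=r_b, r_ab=1.0, z=0.0, p=1.0, n=n)
    r_ab = float(np.corrcoef(av, bv)[0, 1])
    z, p = _steiger_z(r_a, r_b, r_ab, n)
    return ModelComparison(r_a=r_a, r_b=r_b, r_ab=r_ab, z=z, p=p, n=n)


def power_note(n: int, r_a: float, r_b: float, r_ab: float) -> tuple[float, float]:
    """Analytic (z, p) for a stated correlation configuration at sample size n.

    Answers "what p-value would Steiger's test give for exactly these
    correlations at this n" — the quantity behind power arguments that a
    barely sub-threshold p at enormous n is evidence *for* the null.
    """
    if r_a == r_b:
        return 0.0, 1.0
    return _steiger_z(r_a, r_b, r_ab, n)
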