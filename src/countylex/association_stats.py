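"""Correlation machinery for the county-level audit.

Pearson correlations with Fisher-z confidence intervals, regression-based
partial correlations, Bonferroni family-wise thresholds, batch screening of
many language variables against one outcome, and Welch's two-sample t.

Conventions
-----------
* p-values are two-sided throughout.
* The simple Pearson p comes from ``t = r * sqrt((n-2)/(1-r^2))`` on n-2
  degrees of freedom; the CI from Fisher's z, ``tanh(atanh r ± z_(ci)/
  sqrt(n-3))``.
* Partial correlations residualize both variables on an intercept plus the
  covariates by least squares and correlate the residuals; inference uses
  the same machinery with effective sample size n' = n - k (k covariates),
  so k = 0 reduces bit-identically to the simple case.
* Missing values are dropped pairwise-complete per variable (not listwise
  across a batch), with the per-variable n reported.
* Cohen's d uses the pooled SD even alongside Welch's t.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import ValidationError, get_logger

log = get_logger("countylex.association_stats")

__all__ = [
    "AssociationResult",
    "TTestResult",
    "ScreenResult",
    "pearson",
    "partial_correlation",
    "bonferroni_threshold",
    "screen",
    "welch_t",
]


@dataclass
class AssociationResult:
    """A (partial) correlation with its sample size, CI, p and threshold."""

    predictor_id: str
    outcome_id: str
    n: int
    r: float
    partial: bool
    covariates: list[str]
    p: float
    ci_low: float
    ci_high: float
    alpha_threshold: float
    significant: bool

    def __post_init__(self) -> None:
        if not -1 <= self.r <= 1:
            raise ValidationError(f"r={self.r} outside [-1, 1]")
        if self.n < 4 + len(self.covariates):
            raise ValidationError(
                f"n={self.n} too small for {len(self.covariates)} covariates"
            )


@dataclass
class TTestResult:
    """Welch two-sample t with Satterthwaite df and pooled-SD Cohen's d."""

    t: float
    df: float
    p: float
    d: float
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int


@dataclass
class ScreenResult:
    """Batch screening output: simple+partial results and skipped variables."""

    results: list[AssociationResult]
    skipped: list[tuple[str, str]] = field(default_factory=list)
    n_joined: int = 0
    n_dropped: int = 0

    def any_significant(self) -> bool:
        return any(r.significant for r in self.results)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.results])


# --------------------------------------------------------------------------
# scalar correlation inference
# --------------------------------------------------------------------------


def _pairwise_complete(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    ok = np.isfinite(x) & np.isfinite(y)
    dropped = int((~ok).sum())
    if dropped:
        log.info("dropping %d incomplete pair(s)", dropped)
    return x[ok], y[ok], dropped


def _r_inference(
    r: float, n_eff: int, ci_level: float
) -> tuple[float, float, float]:
    """(p, ci_low, ci_high) for a correlation at effective sample size n_eff."""
    if n_eff < 4:
        raise ValidationError(f"effective n={n_eff} < 4")
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n_eff - 2) / (1 - r**2))
        p = 2 * stats.t.sf(abs(t), df=n_eff - 2)
    zcrit = stats.norm.ppf(0.5 + ci_level / 2)
    if abs(r) == 1.0:
        lo = hi = r
    else:
        z = np.arctanh(r)
        half = zcrit / np.sqrt(n_eff - 3)
        lo, hi = np.tanh(z - half), np.tanh(z + half)
    return float(p), float(lo), float(hi)


def pearson(
    x: np.ndarray,
    y: np.ndarray,
    ci_level: float = 0.95,
    predictor_id: str = "x",
    outcome_id: str = "y",
    alpha_threshold: float = 0.05,
) -> AssociationResult:
    """Sample Pearson r with Fisher-z CI and t-based two-sided p.

    Pairs with any non-finite value are dropped first (pairwise-complete).
    Zero variance in either vector is an error naming the variable.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("x and y must have equal length")
    x, y, _ = _pairwise_complete(x, y)
    n = len(x)
    if n < 4:
        raise ValidationError(f"need n >= 4 complete pairs, got {n}")
    if x.std() == 0:
        raise ValidationError(f"zero variance in {predictor_id!r}")
    if y.std() == 0:
        raise ValidationError(f"zero variance in {outcome_id!r}")
    r = float(np.corrcoef(x, y)[0, 1])
    r = float(np.clip(r, -1.0, 1.0))
    p, lo, hi = _r_inference(r, n, ci_level)
    return AssociationResult(
        predictor_id=predictor_id,
        outcome_id=outcome_id,
        n=n,
        r=r,
        partial=False,
        covariates=[],
        p=p,
        ci_low=lo,
        ci_high=hi,
        alpha_threshold=alpha_threshold,
        significant=p < alpha_threshold,
    )


def _residualize(v: np.ndarray, design: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(design, v, rcond=None)
    return v - design @ beta


def partial_correlation(
    x: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None,
    ci_level: float = 0.95,
    predictor_id: str = "x",
    outcome_id: str = "y",
    covariate_names: list[str] | None = None,
    alpha_threshold: float = 0.05,
) -> AssociationResult:
    """Partial r of x and y given covariates, via least-squares residuals.

    Both variables are residualized on [1, covariates]; the residual Pearson
    r carries inference at effective n' = n - k.  With no covariates this is
    bit-identical to :func:`pearson`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if covariates is None or (hasattr(covariates, "size") and covariates.size == 0):
        return pearson(x, y, ci_level, predictor_id, outcome_id, alpha_threshold)
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    k = C.shape[1]
    names = covariate_names or [f"c{i}" for i in range(k)]
    ok = np.isfinite(x) & np.isfinite(y) & np.isfinite(C).all(axis=1)
    x, y, C = x[ok], y[ok], C[ok]
    n = len(x)
    if n <= k + 3:
        raise ValidationError(f"need n > k + 3 (n={n}, k={k})")
    design = np.column_stack([np.ones(n), C])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValidationError("covariate matrix is rank-deficient")
    rx = _residualize(x, design)
    ry = _residualize(y, design)
    if np.allclose(rx, 0, atol=1e-10 * max(1.0, float(np.abs(x).max()))):
        raise ValidationError(
            f"{predictor_id!r} has zero residual variance given the covariates"
        )
    if np.allclose(ry, 0, atol=1e-10 * max(1.0, float(np.abs(y).max()))):
        raise ValidationError(
            f"{outcome_id!r} has zero residual variance given the covariates"
        )
    r = float(np.clip(np.corrcoef(rx, ry)[0, 1], -1.0, 1.0))
    p, lo, hi = _r_inference(r, n - k, ci_level)
    return AssociationResult(
        predictor_id=predictor_id,
        outcome_id=outcome_id,
        n=n,
        r=r,
        partial=True,
        covariates=list(names),
        p=p,
        ci_low=lo,
        ci_high=hi,
        alpha_threshold=alpha_threshold,
        significant=p < alpha_threshold,
    )


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise significance threshold alpha / m."""
    if m < 1:
        raise ValidationError("m must be >= 1")
    if not 0 < alpha < 1:
        raise ValidationError("alpha must be in (0, 1)")
    return alpha / m


# --------------------------------------------------------------------------
# batch screening
# --------------------------------------------------------------------------


def _vectorized_r_p(Y: np.ndarray, x: np.ndarray, n_eff: int) -> tuple[np.ndarray, np.ndarray]:
    """Columnwise r and two-sided p of Y's columns against x (complete data)."""
    xc = x - x.mean()
    Yc = Y - Y.mean(axis=0)
    denom = np.sqrt((xc**2).sum() * (Yc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Yc.T @ xc) / denom
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n_eff - 2) / (1 - r**2))
    p = np.where(np.abs(r) == 1.0, 0.0, 2 * stats.t.sf(np.abs(t), df=n_eff - 2))
    return r, p


def screen(
    scores: pd.DataFrame,
    outcome: pd.Series,
    covariates: pd.DataFrame | None,
    alpha: float = 0.05,
    m: int | None = None,
    ci_level: float = 0.95,
    outcome_id: str = "outcome",
) -> ScreenResult:
    """Screen many language variables against one outcome with FWER control.

    ``scores`` is long-form (fips, variable_id, value); ``outcome`` and the
    covariate columns are indexed by fips.  Each variable gets a simple and a
    covariate-adjusted result; a variable is flagged significant only when
    both p-values beat the Bonferroni threshold alpha/m (m defaults to the
    number of variables).  Results are sorted by \\|simple r\\| descending;
    per-variable failures become skipped rows, never abort the batch.
    """
    wide = scores.pivot_table(index="fips", columns="variable_id", values="value")
    joined = wide.join(outcome.rename("__outcome__"), how="inner")
    if covariates is not None and len(covariates.columns):
        joined = joined.join(covariates, how="inner")
        cov_names = list(covariates.columns)
    else:
        cov_names = []
    n_dropped = len(wide) - len(joined)
    if n_dropped:
        log.info("screen: inner join dropped %d count(ies)", n_dropped)
    variables = [c for c in wide.columns]
    m = m or len(variables)
    threshold = bonferroni_threshold(alpha, m)

    y = joined["__outcome__"].to_numpy(dtype=float)
    C = joined[cov_names].to_numpy(dtype=float) if cov_names else None
    X = joined[variables].to_numpy(dtype=float)

    results: list[AssociationResult] = []
    skipped: list[tuple[str, str]] = []

    complete = (
        np.isfinite(X).all()
        and np.isfinite(y).all()
        and (C is None or np.isfinite(C).all())
    )
    if complete and y.std() > 0:
        order = _screen_fast(
            variables, X, y, C, cov_names, threshold, ci_level, outcome_id,
            results, skipped,
        )
    else:
        for var in variables:
            x = joined[var].to_numpy(dtype=float)
            try:
                simple = pearson(x, y, ci_level, var, outcome_id, threshold)
                adj = partial_correlation(
                    x, y, C, ci_level, var, outcome_id, cov_names, threshold
                )
            except ValidationError as exc:
                skipped.append((var, _skip_reason(exc)))
                continue
            sig = simple.p < threshold and adj.p < threshold
            simple.significant = sig
            adj.significant = sig
            results.extend([simple, adj])
    simple_r = {r.predictor_id: abs(r.r) for r in results if not r.partial}
    results.sort(
        key=lambda r: (-simple_r.get(r.predictor_id, abs(r.r)), r.predictor_id, r.partial)
    )
    return ScreenResult(
        results=results, skipped=skipped, n_joined=len(joined), n_dropped=n_dropped
    )


def _skip_reason(exc: ValidationError) -> str:
    msg = str(exc)
    return "zero variance" if "zero variance" in msg or "residual variance" in msg else msg


def _screen_fast(
    variables, X, y, C, cov_names, threshold, ci_level, outcome_id,
    results, skipped,
):
    """Vectorized complete-data path: columnwise simple and partial r/p."""
    n = len(y)
    sd = X.std(axis=0)
    good = sd > 0
    for j in np.flatnonzero(~good):
        skipped.append((variables[j], "zero variance"))
    Xg = X[:, good]
    names = [v for v, g in zip(variables, good) if g]
    r_s, p_s = _vectorized_r_p(Xg, y, n)

    if C is not None:
        k = C.shape[1]
        design = np.column_stack([np.ones(n), C])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise ValidationError("covariate matrix is rank-deficient")
        proj = design @ np.linalg.pinv(design)
        ry = y - proj @ y
        RX = Xg - proj @ Xg
        rsd = RX.std(axis=0)
        zero_resid = rsd <= 1e-12 * np.maximum(1.0, np.abs(Xg).max(axis=0))
        r_a, p_a = _vectorized_r_p(RX, ry, n - k)
    else:
        k = 0
        zero_resid = np.zeros(len(names), dtype=bool)
        r_a, p_a = r_s, p_s

    zcrit = stats.norm.ppf(0.5 + ci_level / 2)

    def _ci(r, n_eff):
        if abs(r) == 1.0:
            return r, r
        half = zcrit / np.sqrt(n_eff - 3)
        z = np.arctanh(r)
        return float(np.tanh(z - half)), float(np.tanh(z + half))

    for i, var in enumerate(names):
        if zero_resid[i]:
            skipped.append((var, "zero variance"))
            continue
        sig = p_s[i] < threshold and p_a[i] < threshold
        lo_s, hi_s = _ci(r_s[i], n)
        results.append(AssociationResult(
            predictor_id=var, outcome_id=outcome_id, n=n, r=float(r_s[i]),
            partial=False, covariates=[], p=float(p_s[i]),
            ci_low=lo_s, ci_high=hi_s, alpha_threshold=threshold,
            significant=bool(sig),
        ))
        lo_a, hi_a = _ci(r_a[i], n - k)
        results.append(AssociationResult(
            predictor_id=var, outcome_id=outcome_id, n=n, r=float(r_a[i]),
            partial=True, covariates=list(cov_names), p=float(p_a[i]),
            ci_low=lo_a, ci_high=hi_a, alpha_threshold=threshold,
            significant=bool(sig),
        ))


# --------------------------------------------------------------------------
# Welch's t
# --------------------------------------------------------------------------


def welch_t(a: np.ndarray, b: np.ndarray) -> TTestResult:
    """Welch's two-sample t with Satterthwaite df and pooled-SD Cohen's d."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValidationError("each group needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        raise ValidationError("zero variance in both groups")
    se2a, se2b = va / na, vb / nb
    se = np.sqrt(se2a + se2b)
    t = (a.mean() - b.mean()) / se
    df = (se2a + se2b) ** 2 / (se2a**2 / (na - 1) + se2b**2 / (nb - 1))
    p = 2 * stats.t.sf(abs(t), df=df)
    s_pooled = np.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2))
    d = (a.mean() - b.mean()) / s_pooled if s_pooled > 0 else np.nan
    return TTestResult(
        t=float(t), df=float(df), p=float(p), d=float(d),
        mean_a=float(a.mean()), mean_b=float(b.mean()), n_a=na, n_b=nb,
    )
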