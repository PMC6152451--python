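"""Audit procedures for county-level mortality associations.

These are the checks a skeptical reader runs against an ecological
correlation claim:

* ``suppression_filter`` — apply the CDC-style release rule (a county's
  data exist only when its average annual deaths reach a threshold, default
  10/year) and report what was dropped.  Because small counties need a high
  *rate* to clear a fixed *count* threshold, the rule preferentially keeps
  high-rate small counties: selection bias by construction.
* ``selection_bias_test`` — split counties at the median population and
  Welch-test the cause-specific rates of the two halves.
* ``latitude_split`` — re-estimate the language/mortality partial
  correlations separately in the northern and southern halves (median
  centroid latitude); a real nationwide mechanism should not evaporate in
  one half.
* ``range_factor`` / ``percent_lower`` / ``rate_ratio`` — descriptive
  ratios that expose coding variability and small-denominator instability.
* ``crud_scan`` — all pairwise correlations among cause-specific rates,
  quantifying how easily aggregate variables correlate with everything
  (the "crud factor").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .association_stats import (
    AssociationResult,
    TTestResult,
    partial_correlation,
    pearson,
    welch_t,
)
from .core_io import CountyRecord, ValidationError, get_logger

log = get_logger("countylex.robustness_checks")

__all__ = [
    "SplitResult",
    "suppression_filter",
    "selection_bias_test",
    "latitude_split",
    "range_factor",
    "percent_lower",
    "rate_ratio",
    "crud_scan",
]


@dataclass
class SplitResult:
    """A two-group split with its per-group statistics.

    ``groups`` maps fips -> group label; the two labels partition the input
    counties, and for median splits of distinct values the group sizes
    differ by at most one.
    """

    split_variable: str
    split_value: float
    groups: dict[str, str]
    group_stats: dict[str, list[AssociationResult]] = field(default_factory=dict)
    ttest: TTestResult | None = None


def _rate(county: CountyRecord, cause: str) -> float:
    entry = county.mortality.get(cause)
    return np.nan if entry is None else entry.rate


# --------------------------------------------------------------------------
# suppression and selection bias
# --------------------------------------------------------------------------


def suppression_filter(
    counties: list[CountyRecord], cause: str, threshold: float = 10.0
) -> tuple[list[CountyRecord], list[tuple[CountyRecord, str]]]:
    """Apply the minimum average-annual-deaths release rule (inclusive).

    A county is kept iff ``deaths / years >= threshold`` for the cause;
    counties without data for the cause are dropped with reason "no data".
    Returns (kept, dropped-with-reasons).
    """
    kept: list[CountyRecord] = []
    dropped: list[tuple[CountyRecord, str]] = []
    for county in counties:
        entry = county.mortality.get(cause)
        if entry is None:
            dropped.append((county, "no data"))
        elif entry.deaths_per_year >= threshold:
            kept.append(county)
        else:
            dropped.append((
                county,
                f"mean annual deaths {entry.deaths_per_year:.2f} < {threshold}",
            ))
    log.info(
        "suppression_filter(%s, >=%g/yr): kept %d, dropped %d",
        cause, threshold, len(kept), len(dropped),
    )
    return kept, dropped


def selection_bias_test(
    counties: list[CountyRecord], cause: str
) -> tuple[TTestResult, SplitResult]:
    """Welch t of cause-specific rates: below-median vs at-or-above-median population.

    The split is at the median 2010-style population; at-median counties go
    to the larger-population group ("below the median" read verbatim).  A
    positive t means the small-county group has the higher mean rate — the
    signature of count-threshold selection.
    """
    with_data = [c for c in counties if not np.isnan(_rate(c, cause))]
    if len(with_data) < 4:
        raise ValidationError("need >= 4 counties with data for the cause")
    pops = np.array([c.population for c in with_data], dtype=float)
    if np.all(pops == pops[0]):
        raise ValidationError("degenerate split: all populations equal")
    median = float(np.median(pops))
    below = [c for c in with_data if c.population < median]
    above = [c for c in with_data if c.population >= median]
    if len(below) < 2 or len(above) < 2:
        raise ValidationError("each population group needs n >= 2")
    rates_below = np.array([_rate(c, cause) for c in below])
    rates_above = np.array([_rate(c, cause) for c in above])
    tt = welch_t(rates_below, rates_above)
    split = SplitResult(
        split_variable="population",
        split_value=median,
        groups={
            **{c.fips: "below" for c in below},
            **{c.fips: "above" for c in above},
        },
        ttest=tt,
    )
    return tt, split


# --------------------------------------------------------------------------
# geographic split
# --------------------------------------------------------------------------


def latitude_split(
    counties: list[CountyRecord],
    scores: pd.DataFrame,
    cause: str,
    covariate_names: list[str],
    ci_level: float = 0.95,
) -> SplitResult:
    """Partial correlations per language variable, north vs south of the median latitude.

    Counties with centroid latitude strictly above the median go north, at
    or below go south (the at-median county joins the southern group).
    Counties without a centroid are excluded with a log entry.
    """
    with_lat = [c for c in counties if not np.isnan(c.centroid_lat)]
    if len(with_lat) < len(counties):
        log.info(
            "latitude_split: excluding %d count(ies) without centroids",
            len(counties) - len(with_lat),
        )
    if len(with_lat) < 8:
        raise ValidationError("need >= 8 counties with centroids")
    lats = np.array([c.centroid_lat for c in with_lat])
    if np.all(lats == lats[0]):
        raise ValidationError("degenerate split: all centroids at the same latitude")
    median = float(np.median(lats))
    north = [c for c in with_lat if c.centroid_lat > median]
    south = [c for c in with_lat if c.centroid_lat <= median]

    groups = {**{c.fips: "north" for c in north}, **{c.fips: "south" for c in south}}
    result = SplitResult(
        split_variable="centroid_lat", split_value=median, groups=groups
    )
    for label, group in (("north", north), ("south", south)):
        outcome = pd.Series(
            {c.fips: _rate(c, cause) for c in group}, name=cause
        )
        covs = pd.DataFrame(
            {
                name: {c.fips: c.covariates.get(name, np.nan) for c in group}
                for name in covariate_names
            }
        )
        stats_list: list[AssociationResult] = []
        for var, grp in scores.groupby("variable_id"):
            joined = (
                grp.set_index("fips")["value"].rename("score").to_frame()
                .join(outcome, how="inner")
            )
            if covariate_names:
                joined = joined.join(covs, how="inner")
            joined = joined.dropna()
            if len(joined) <= len(covariate_names) + 3:
                log.info(
                    "latitude_split[%s]: variable %s has too few counties, skipped",
                    label, var,
                )
                continue
            stats_list.append(
                partial_correlation(
                    joined["score"].to_numpy(),
                    joined[cause].to_numpy(),
                    joined[covariate_names].to_numpy() if covariate_names else None,
                    ci_level=ci_level,
                    predictor_id=str(var),
                    outcome_id=cause,
                    covariate_names=covariate_names,
                )
            )
        result.group_stats[label] = stats_list
    return result


# --------------------------------------------------------------------------
# descriptive ratios
# --------------------------------------------------------------------------


def range_factor(counties: list[CountyRecord], cause: str) -> float:
    """max/min cause-specific rate over counties with data (post-suppression set)."""
    rates = np.array([
        _rate(c, cause) for c in counties if not np.isnan(_rate(c, cause))
    ])
    if len(rates) < 2:
        raise ValidationError("need >= 2 counties with rates")
    if rates.min() <= 0:
        raise ValidationError("minimum rate is zero; range factor undefined")
    return float(rates.max() / rates.min())


def percent_lower(rate_a: float, rate_b: float) -> float:
    """How much lower rate_a is than rate_b, in percent: 100*(b-a)/b."""
    if rate_b <= 0:
        raise ValidationError("reference rate must be > 0")
    return 100.0 * (rate_b - rate_a) / rate_b


def rate_ratio(count_a: float, pop_a: float, count_b: float, pop_b: float) -> float:
    """Per-inhabitant rate of B relative to A: (count_b/pop_b)/(count_a/pop_a).

    A zero count in A gives an infinite ratio (signalled as ``inf``, not an
    exception): with tiny denominators, one or two occurrences swing the
    per-inhabitant rate arbitrarily.
    """
    if pop_a <= 0 or pop_b <= 0:
        raise ValidationError("populations must be > 0")
    if count_a < 0 or count_b < 0:
        raise ValidationError("counts must be >= 0")
    if count_a == 0:
        return float("inf")
    return (count_b / pop_b) / (count_a / pop_a)


# --------------------------------------------------------------------------
# crud scan
# --------------------------------------------------------------------------


def crud_scan(
    counties: list[CountyRecord], causes: list[str], ci_level: float = 0.95
) -> tuple[pd.DataFrame, list[AssociationResult]]:
    """All pairwise Pearson correlations among cause-specific rate vectors.

    Returns a symmetric cause x cause correlation matrix (diagonal 1, absent
    entries NaN) plus the long-form upper-triangle results with CIs.
    Pairwise-complete deletion per pair.
    """
    if len(causes) < 2:
        raise ValidationError("need >= 2 causes")
    rates = {
        cause: np.array([_rate(c, cause) for c in counties]) for cause in causes
    }
    matrix = pd.DataFrame(np.eye(len(causes)), index=causes, columns=causes)
    long_form: list[AssociationResult] = []
    for i, ca in enumerate(causes):
        for cb in causes[i + 1 :]:
            try:
                res = pearson(
                    rates[ca], rates[cb], ci_level, predictor_id=ca, outcome_id=cb
                )
            except ValidationError as exc:
                log.info("crud_scan: %s vs %s absent (%s)", ca, cb, exc)
                matrix.loc[ca, cb] = matrix.loc[cb, ca] = np.nan
                continue
            matrix.loc[ca, cb] = matrix.loc[cb, ca] = res.r
            long_form.append(res)
    return matrix, long_form
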