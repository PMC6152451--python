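"""Synthetic county studies with known ground truth.

Every downstream stage of the audit pipeline is exercised against data from
this module, where the latent quantities are known exactly:

* counties whose populations are log-uniform over several orders of
  magnitude (real US county populations span five);
* a standard-normal latent "language valence" factor ``lambda`` per county;
* Poisson death counts whose log expected rate correlates with ``lambda``
  at a configurable target (including zero), subject to a CDC-style
  >= 10 deaths/year release rule downstream;
* word counts in which dictionary-word emission is a logistic function of
  ``lambda`` on top of a Zipf background, so the county dictionary score is
  monotone in the latent factor;
* paired region -> color choropleth assignments whose per-region interval
  differences realize exactly a requested count of green/yellow/red
  discrepancy classes.

Age adjustment is modeled as the identity: synthetic populations carry no
age structure, so rates are crude-rate arithmetic
(``deaths / population * 100,000 / years``).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np

from .core_io import (
    CountyRecord,
    LanguageDictionary,
    MortalityEntry,
    ValidationError,
    WordCountTable,
    get_logger,
)
from .map_discrepancy import (
    CLASS_BOUNDS,
    ColorScale,
    RegionColorMap,
    classify,
)

log = get_logger("countylex.synthetic_data")

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "generate_counties",
    "generate_mortality",
    "generate_word_counts",
    "generate_map_pair",
    "generate_study",
]

# Continental-US bounding box for synthetic centroids.
LAT_RANGE = (25.0, 49.0)
LON_RANGE = (-125.0, -67.0)

#: Zipf background exponent for non-dictionary word frequencies (documented
#: constant, not a config knob).
ZIPF_EXPONENT = 1.0

#: Slope of the logistic link from the latent factor to the dictionary-word
#: emission probability.  Small enough that the logistic stays near-linear
#: over lambda in [-3, 3], so the dictionary score is close to linear in
#: lambda while remaining strictly monotone.
DICT_LOGISTIC_SLOPE = 0.3


@dataclass
class SyntheticConfig:
    """Study-design knobs for a synthetic county study.

    Defaults emulate an AHD-like setting: baseline rate 50 deaths per
    100,000/year over a 2-year observation window, populations spanning
    10^2–10^7, about one collected token per inhabitant, and a vocabulary in
    which 5% of word types belong to the scored dictionary.
    """

    n_counties: int
    seed: int = 0
    pop_log10_range: tuple[float, float] = (2.0, 7.0)
    baseline_rate: float = 50.0
    rate_dispersion: float = 0.3
    rho_language_outcome: float = 0.0
    #: income and education load negatively on the risk-language factor by
    #: default — the socioeconomic confounding the covariate-adjusted
    #: analyses are there to remove.
    covariate_loadings: dict[str, float] = field(
        default_factory=lambda: {"income": -0.3, "education": -0.3}
    )
    vocab_size: int = 2000
    dict_word_fraction: float = 0.05
    tokens_per_capita: float = 1.0
    years: float = 2.0

    def __post_init__(self) -> None:
        if self.n_counties < 4:
            raise ValidationError("n_counties must be >= 4")
        if not -1 <= self.rho_language_outcome <= 1:
            raise ValidationError("rho_language_outcome must be in [-1, 1]")
        if self.rate_dispersion < 0:
            raise ValidationError("rate_dispersion must be >= 0")
        if not 0 < self.dict_word_fraction < 1:
            raise ValidationError("dict_word_fraction must be in (0, 1)")
        if self.pop_log10_range[0] > self.pop_log10_range[1]:
            raise ValidationError("pop_log10_range must be (min, max)")
        if self.tokens_per_capita < 0:
            raise ValidationError("tokens_per_capita must be >= 0")
        if self.years <= 0:
            raise ValidationError("years must be > 0")


@dataclass
class SyntheticTruth:
    """Latent parameters persisted alongside the outputs for recovery tests."""

    lam: dict[str, float]
    true_rate: dict[str, float] = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    def lam_vector(self, fips: Sequence[str]) -> np.ndarray:
        return np.array([self.lam[f] for f in fips])


# --------------------------------------------------------------------------
# counties
# --------------------------------------------------------------------------


def generate_counties(cfg: SyntheticConfig) -> tuple[list[CountyRecord], SyntheticTruth]:
    """Draw counties: populations, centroids, latent factor, covariates.

    Populations are log-uniform over ``pop_log10_range``; centroids uniform
    over a continental-US box; each covariate is ``loading * lambda`` plus
    independent Gaussian noise (variance chosen so the covariate has unit
    variance on its latent scale), mapped onto a natural measurement scale.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_counties
    lam = rng.standard_normal(n)
    lo, hi = cfg.pop_log10_range
    pops = np.floor(10 ** rng.uniform(lo, hi, n)).astype(np.int64)
    pops = np.maximum(pops, 1)
    lats = rng.uniform(*LAT_RANGE, n)
    lons = rng.uniform(*LON_RANGE, n)

    cov_latent: dict[str, np.ndarray] = {}
    for cov, loading in cfg.covariate_loadings.items():
        if not -1 <= loading <= 1:
            raise ValidationError(f"covariate loading for {cov!r} outside [-1, 1]")
        noise = rng.standard_normal(n)
        cov_latent[cov] = loading * lam + np.sqrt(1 - loading**2) * noise

    fips = [f"{i + 1:05d}" for i in range(n)]
    counties = []
    for i, f in enumerate(fips):
        covariates: dict[str, float] = {}
        for cov, z in cov_latent.items():
            if cov == "income":
                covariates[cov] = float(np.clip(52_000 + 12_000 * z[i], 5_000, None))
            else:
                # fraction-valued covariates: squash the latent score to (0,1)
                covariates[cov] = float(1 / (1 + np.exp(-(z[i] * 0.8 - 1.2))))
        counties.append(
            CountyRecord(
                fips=f,
                name=f"Synth County {i + 1}",
                state="SY",
                population=int(pops[i]),
                centroid_lat=float(lats[i]),
                centroid_lon=float(lons[i]),
                covariates=covariates,
            )
        )
    truth = SyntheticTruth(
        lam=dict(zip(fips, lam.tolist())), config=asdict(cfg)
    )
    return counties, truth


# --------------------------------------------------------------------------
# mortality
# --------------------------------------------------------------------------


def _calibrated_mixture(
    lam: np.ndarray, noise: np.ndarray, rho: float
) -> np.ndarray:
    """Unit-variance mixture whose population correlation with ``lam`` is ``rho``.

    Under the linear-Gaussian structure (standard-normal latent factor,
    independent standard-normal noise) the mixing weight that hits the
    target on the log scale has the closed form ``rho`` itself:
    corr(lam, rho*lam + sqrt(1-rho^2)*noise) = rho.  Sample correlations
    fluctuate around the target with the usual ~1/sqrt(n) error, which the
    downstream calibration suites rely on being genuine.
    """
    if lam.std() == 0:
        raise ValidationError("degenerate latent factor (zero variance)")
    return rho * lam + np.sqrt(1 - rho**2) * noise


def generate_mortality(
    counties: list[CountyRecord],
    truth: SyntheticTruth,
    cfg: SyntheticConfig,
    cause: str = "I25.1",
) -> list[CountyRecord]:
    """Fill Poisson mortality for one cause; records the true rates in truth.

    Expected rate: ``mu_f = baseline_rate * exp(rate_dispersion * eta_f)``
    where ``eta`` is a unit-variance mixture of the latent factor and
    independent noise whose population correlation with lambda is
    ``rho_language_outcome``.  Observed deaths are
    ``Poisson(mu_f * pop_f / 100,000 * years)`` and the reported rate is the
    crude rate per 100,000 per year.
    """
    # stable per-cause stream (zlib.crc32 is deterministic across processes)
    rng = np.random.default_rng((cfg.seed, 1, zlib.crc32(cause.encode())))
    fips = [c.fips for c in counties]
    lam = truth.lam_vector(fips)
    n = len(counties)
    if cfg.rate_dispersion == 0:
        log_mu = np.full(n, np.log(cfg.baseline_rate))
    else:
        eta = _calibrated_mixture(
            lam, rng.standard_normal(n), cfg.rho_language_outcome
        )
        log_mu = np.log(cfg.baseline_rate) + cfg.rate_dispersion * eta
    mu = np.exp(log_mu)
    pops = np.array([c.population for c in counties], dtype=float)
    expected_deaths = mu * pops / 100_000 * cfg.years
    deaths = rng.poisson(expected_deaths)
    for i, county in enumerate(counties):
        rate = deaths[i] / pops[i] * 100_000 / cfg.years
        county.mortality[cause] = MortalityEntry(
            cause=cause, deaths=int(deaths[i]), years=cfg.years, rate=float(rate)
        )
        truth.true_rate[county.fips] = float(mu[i])
    return counties


# --------------------------------------------------------------------------
# word counts
# --------------------------------------------------------------------------


def _default_dictionary(cfg: SyntheticConfig) -> LanguageDictionary:
    k = max(1, round(cfg.dict_word_fraction * cfg.vocab_size))
    return LanguageDictionary(
        id="synthetic_dict",
        label="Synthetic risk dictionary",
        valence="risk",
        words=frozenset(f"d{i:05d}" for i in range(k)),
    )


def generate_word_counts(
    counties: list[CountyRecord],
    truth: SyntheticTruth,
    cfg: SyntheticConfig,
    dictionary: LanguageDictionary | None = None,
) -> tuple[WordCountTable, LanguageDictionary]:
    """Emit per-county word counts whose dictionary share tracks ``lambda``.

    County token totals are Poisson(tokens_per_capita * population).  A
    county's probability of emitting a dictionary word is
    ``sigmoid(logit(dict_word_fraction) + slope * lambda)``; the remaining
    probability mass goes to background words under a Zipf(1) law.  Within
    the dictionary the same Zipf law shares out the dictionary mass.
    """
    rng = np.random.default_rng((cfg.seed, 2))
    if dictionary is None:
        dictionary = _default_dictionary(cfg)
    dict_words = sorted(dictionary.words)
    n_bg = max(1, cfg.vocab_size - len(dict_words))
    bg_words = [f"w{i:05d}" for i in range(n_bg)]
    vocab = dict_words + bg_words

    fips = [c.fips for c in counties]
    lam = truth.lam_vector(fips)
    pops = np.array([c.population for c in counties], dtype=float)
    totals = rng.poisson(cfg.tokens_per_capita * pops)

    if totals.sum() == 0:
        empty = np.zeros((len(fips), len(vocab)), dtype=np.int64)
        return WordCountTable(empty, fips, vocab), dictionary

    base = cfg.dict_word_fraction
    logit = np.log(base / (1 - base)) + DICT_LOGISTIC_SLOPE * lam
    p_dict = 1 / (1 + np.exp(-logit))  # per-county dictionary emission prob

    zipf_d = 1 / np.arange(1, len(dict_words) + 1) ** ZIPF_EXPONENT
    zipf_d /= zipf_d.sum()
    zipf_b = 1 / np.arange(1, n_bg + 1) ** ZIPF_EXPONENT
    zipf_b /= zipf_b.sum()
    # county x vocab emission probabilities
    probs = np.concatenate(
        [p_dict[:, None] * zipf_d[None, :], (1 - p_dict)[:, None] * zipf_b[None, :]],
        axis=1,
    )
    counts = rng.multinomial(totals, probs)
    return WordCountTable(counts, fips, vocab, totals=totals), dictionary


# --------------------------------------------------------------------------
# paired choropleth maps
# --------------------------------------------------------------------------


def generate_map_pair(
    n_regions: int,
    scale: ColorScale,
    discrepancy_spec: Mapping[str, int],
    seed: int = 0,
) -> tuple[RegionColorMap, RegionColorMap, dict[str, dict]]:
    """Two region->color assignments realizing exact discrepancy-class counts.

    ``discrepancy_spec`` maps class names (green/yellow/red) to region
    counts; regions beyond the spec total are left as no-data (background).
    The truth dict records each region's two intervals, their difference and
    its class.  Raises on infeasible specs (e.g. a red region — interval
    difference >= 6 — on a scale narrower than 7 colors).
    """
    m = len(scale.colors)
    rng = np.random.default_rng(seed)
    unknown = set(discrepancy_spec) - set(CLASS_BOUNDS)
    if unknown:
        raise ValidationError(f"unknown discrepancy classes: {sorted(unknown)}")
    total = sum(discrepancy_spec.values())
    if total > n_regions:
        raise ValidationError(
            f"requested {total} classed regions but only {n_regions} regions"
        )

    # 1-based ids, aligned with make_tile_masks labels (label i -> r000i)
    region_ids = [f"r{i + 1:04d}" for i in range(n_regions)]
    assign_a: dict[str, tuple[int, int, int]] = {}
    assign_b: dict[str, tuple[int, int, int]] = {}
    truth: dict[str, dict] = {}
    idx = 0
    for cls in ("green", "yellow", "red"):
        count = int(discrepancy_spec.get(cls, 0))
        if count == 0:
            continue
        lo, hi = CLASS_BOUNDS[cls]
        hi = m - 1 if hi is None else min(hi, m - 1)
        if lo > m - 1:
            raise ValidationError(
                f"class {cls!r} needs an interval difference >= {lo}, "
                f"impossible on a {m}-color scale"
            )
        for _ in range(count):
            delta = int(rng.integers(lo, hi + 1))
            ia = int(rng.integers(1, m - delta + 1))
            ib = ia + delta
            if rng.random() < 0.5:
                ia, ib = ib, ia
            rid = region_ids[idx]
            assign_a[rid] = scale.colors[ia - 1]
            assign_b[rid] = scale.colors[ib - 1]
            truth[rid] = {
                "interval_a": ia,
                "interval_b": ib,
                "delta": delta,
                "class": classify(delta),
            }
            idx += 1
    background = next(iter(scale.background))
    for rid in region_ids[idx:]:
        assign_a[rid] = background
        assign_b[rid] = background
        truth[rid] = {"interval_a": None, "interval_b": None, "delta": None,
                      "class": "nodata"}
    return (
        RegionColorMap(colors=assign_a),
        RegionColorMap(colors=assign_b),
        truth,
    )


# --------------------------------------------------------------------------
# whole-study convenience
# --------------------------------------------------------------------------


def generate_study(
    cfg: SyntheticConfig, cause: str = "I25.1"
) -> tuple[list[CountyRecord], WordCountTable, LanguageDictionary, SyntheticTruth]:
    """Counties + mortality + word counts in one call (single seed)."""
    counties, truth = generate_counties(cfg)
    generate_mortality(counties, truth, cfg, cause=cause)
    table, dictionary = generate_word_counts(counties, truth, cfg)
    return counties, table, dictionary, truth
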