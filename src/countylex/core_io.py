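"""Domain types, readers/writers, validation, configuration and logging.

The package audits county-level associations between social-media language
and cause-specific mortality.  Everything downstream operates on the types
defined here:

* :class:`CountyRecord` — one county: identifiers, population, centroid,
  socioeconomic/health covariates, and per-cause mortality entries.
* :class:`WordCountTable` — a sparse county x word token-count matrix with
  per-county token totals.
* :class:`LanguageDictionary` / :class:`TopicModel` — themed word lists with
  a valence, and topic -> word-weight maps.
* :class:`AnalysisConfig` — run-wide settings (seed, alpha, comparison count,
  covariates, suppression threshold, CI level).

FIPS codes are the sole join key across tables: 5-character, zero-padded
strings.  Joins everywhere in the package are inner joins, and each stage
logs how many counties the join dropped.  Missing numeric cells are explicit
``NaN`` absences, never silently imputed to zero — a zero word count is a
real observation, a missing one is not.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import sparse

__all__ = [
    "MortalityEntry",
    "CountyRecord",
    "WordCountTable",
    "LanguageDictionary",
    "TopicModel",
    "AnalysisConfig",
    "CountylexError",
    "ValidationError",
    "get_logger",
    "read_county_table",
    "write_county_table",
    "read_dictionary",
    "write_dictionary",
    "read_word_counts",
    "write_word_counts",
    "read_topic_weights",
    "load_config",
]

# --------------------------------------------------------------------------
# logging / errors
# --------------------------------------------------------------------------

_LOG_FORMAT = "%(asctime)s %(name)s %(levelname)s: %(message)s"


def get_logger(name: str = "countylex") -> logging.Logger:
    """Package logger; handlers are configured once, at first use."""
    logger = logging.getLogger(name)
    root = logging.getLogger("countylex")
    if not root.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(logging.Formatter(_LOG_FORMAT))
        root.addHandler(handler)
        root.setLevel(logging.INFO)
    return logger


log = get_logger("countylex.core_io")


class CountylexError(Exception):
    """Base class for all package errors."""


class ValidationError(CountylexError):
    """An input violated a documented invariant."""


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

#: Valid dictionary valences (direction of the hypothesised association).
VALENCES = ("risk", "protective")


@dataclass(frozen=True)
class MortalityEntry:
    """Cause-specific mortality for one county.

    ``cause`` is an opaque ICD-10 code string; range codes such as
    ``"X60-X84"`` are a single key, never expanded.  ``deaths / years`` is
    the mean annual death count the suppression rule operates on; ``rate``
    is the age-adjusted rate per 100,000 persons per year, consumed as given.
    """

    cause: str
    deaths: int
    years: float
    rate: float

    def __post_init__(self) -> None:
        if self.deaths < 0:
            raise ValidationError(f"deaths must be >= 0, got {self.deaths}")
        if not self.years > 0:
            raise ValidationError(f"years must be > 0, got {self.years}")
        if not np.isnan(self.rate) and self.rate < 0:
            raise ValidationError(f"rate must be >= 0, got {self.rate}")

    @property
    def deaths_per_year(self) -> float:
        return self.deaths / self.years


@dataclass
class CountyRecord:
    """One county's identifiers, population, centroid, covariates, mortality.

    Covariate values may be ``NaN`` (explicitly absent).  Fraction-valued
    covariates (education, obesity, smoking, diabetes, hypertension) must lie
    in [0, 1] when present; income is in USD per household.
    """

    fips: str
    name: str
    state: str
    population: int
    centroid_lat: float = np.nan
    centroid_lon: float = np.nan
    covariates: dict[str, float] = field(default_factory=dict)
    mortality: dict[str, MortalityEntry] = field(default_factory=dict)

    #: covariates constrained to [0, 1]
    FRACTION_COVARIATES = (
        "education",
        "obesity",
        "smoking",
        "diabetes",
        "hypertension",
    )

    def __post_init__(self) -> None:
        if len(self.fips) != 5 or not self.fips.isdigit():
            raise ValidationError(
                f"fips must be a 5-digit zero-padded string, got {self.fips!r}"
            )
        if len(self.state) != 2:
            raise ValidationError(f"state must be a 2-letter code, got {self.state!r}")
        if self.population < 1:
            raise ValidationError(
                f"county {self.fips}: population must be >= 1, got {self.population}"
            )
        if not np.isnan(self.centroid_lat) and not -90 <= self.centroid_lat <= 90:
            raise ValidationError(
                f"county {self.fips}: centroid_lat out of range: {self.centroid_lat}"
            )
        for cov in self.FRACTION_COVARIATES:
            v = self.covariates.get(cov, np.nan)
            if not np.isnan(v) and not 0 <= v <= 1:
                raise ValidationError(
                    f"county {self.fips}: covariate {cov!r}={v} outside [0, 1]"
                )


class WordCountTable:
    """Sparse county x word token counts with per-county totals.

    Backed by a CSR matrix over explicit FIPS and vocabulary indexes; the
    mapping interface (:meth:`get`, :meth:`total`) gives the sparse-map view
    with 0 as the default for absent pairs.  Totals may exceed the column
    sums (out-of-vocabulary tokens); they must never be smaller.
    """

    def __init__(
        self,
        counts: sparse.spmatrix | np.ndarray,
        fips: Sequence[str],
        vocab: Sequence[str],
        totals: Sequence[int] | None = None,
    ) -> None:
        mat = sparse.csr_matrix(counts, dtype=np.int64)
        if mat.shape != (len(fips), len(vocab)):
            raise ValidationError(
                f"counts shape {mat.shape} does not match "
                f"{len(fips)} counties x {len(vocab)} words"
            )
        if mat.nnz and mat.data.min() < 0:
            raise ValidationError("negative word count")
        for w in vocab:
            if w != w.lower() or any(c.isspace() for c in w):
                raise ValidationError(f"word {w!r} must be lowercase, no whitespace")
        if len(set(fips)) != len(fips):
            raise ValidationError("duplicate fips in word-count table")
        if len(set(vocab)) != len(vocab):
            raise ValidationError("duplicate word in vocabulary")
        self.matrix = mat
        self.fips = list(fips)
        self.vocab = list(vocab)
        self._fips_index = {f: i for i, f in enumerate(self.fips)}
        self._word_index = {w: j for j, w in enumerate(self.vocab)}
        col_sums = np.asarray(mat.sum(axis=1)).ravel()
        if totals is None:
            self.totals = col_sums.astype(np.int64)
        else:
            self.totals = np.asarray(totals, dtype=np.int64)
            if self.totals.shape != (len(self.fips),):
                raise ValidationError("totals length does not match county count")
            if np.any(self.totals < col_sums):
                bad = self.fips[int(np.argmax(self.totals < col_sums))]
                raise ValidationError(
                    f"county {bad}: total tokens smaller than sum of word counts"
                )

    # -- mapping interface --------------------------------------------------

    def get(self, fips: str, word: str) -> int:
        """Count for a (county, word) pair; absent pairs are 0."""
        i = self._fips_index.get(fips)
        j = self._word_index.get(word)
        if i is None or j is None:
            return 0
        return int(self.matrix[i, j])

    def total(self, fips: str) -> int:
        """Total tokens for a county (may exceed the in-vocabulary sum)."""
        return int(self.totals[self._fips_index[fips]])

    @property
    def n_counties(self) -> int:
        return len(self.fips)

    def word_columns(self, words: Iterable[str]) -> np.ndarray:
        """Column indexes of the given words, skipping out-of-vocabulary ones."""
        return np.array(
            [self._word_index[w] for w in words if w in self._word_index], dtype=int
        )

    # -- conversion ---------------------------------------------------------

    def to_long_frame(self) -> pd.DataFrame:
        coo = self.matrix.tocoo()
        return pd.DataFrame(
            {
                "fips": [self.fips[i] for i in coo.row],
                "word": [self.vocab[j] for j in coo.col],
                "count": coo.data,
            }
        ).sort_values(["fips", "word"], ignore_index=True)

    @classmethod
    def from_long_frame(
        cls, frame: pd.DataFrame, totals: Mapping[str, int] | None = None
    ) -> "WordCountTable":
        if (frame["count"] < 0).any():
            row = frame.index[frame["count"] < 0][0]
            raise ValidationError(f"negative count at row {row}")
        fips = sorted(frame["fips"].unique())
        vocab = sorted(frame["word"].unique())
        fi = {f: i for i, f in enumerate(fips)}
        wi = {w: j for j, w in enumerate(vocab)}
        mat = sparse.coo_matrix(
            (
                frame["count"].to_numpy(),
                (
                    frame["fips"].map(fi).to_numpy(),
                    frame["word"].map(wi).to_numpy(),
                ),
            ),
            shape=(len(fips), len(vocab)),
        )
        tot = None if totals is None else [totals[f] for f in fips]
        return cls(mat, fips, vocab, totals=tot)


@dataclass(frozen=True)
class LanguageDictionary:
    """A themed word list with a valence (risk or protective factor)."""

    id: str
    label: str
    valence: str
    words: frozenset[str]

    def __post_init__(self) -> None:
        if self.valence not in VALENCES:
            raise ValidationError(
                f"valence must be one of {VALENCES}, got {self.valence!r}"
            )
        if not self.words:
            raise ValidationError(f"dictionary {self.id!r} has an empty word set")
        object.__setattr__(self, "words", frozenset(w.lower() for w in self.words))


@dataclass(frozen=True)
class TopicModel:
    """Topic -> (word -> weight) maps; weights are nonnegative, used as given."""

    weights: dict[str, dict[str, float]]

    def __post_init__(self) -> None:
        for topic, wmap in self.weights.items():
            if not any(v > 0 for v in wmap.values()):
                raise ValidationError(f"topic {topic!r} has no positive-weight word")
            if any(v < 0 for v in wmap.values()):
                raise ValidationError(f"topic {topic!r} has a negative weight")


@dataclass
class AnalysisConfig:
    """Run-wide analysis settings; defaults are materialized explicitly.

    ``suppression_threshold`` is the minimum average annual death count for a
    county to be released at all (the CDC-style inclusion rule, default 10
    deaths/year); ``n_comparisons`` is the family size for the Bonferroni
    threshold.
    """

    seed: int = 0
    alpha: float = 0.05
    n_comparisons: int = 1
    covariate_names: list[str] = field(
        default_factory=lambda: ["income", "education"]
    )
    suppression_threshold: float = 10.0
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValidationError(f"alpha must be in (0,1), got {self.alpha}")
        if self.n_comparisons < 1:
            raise ValidationError("n_comparisons must be >= 1")
        if not 0 < self.ci_level < 1:
            raise ValidationError(f"ci_level must be in (0,1), got {self.ci_level}")

    def config_hash(self) -> str:
        payload = repr(sorted(self.__dict__.items())).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


# --------------------------------------------------------------------------
# county table I/O
# --------------------------------------------------------------------------

#: Default column names, matching the dialect of the original study's
#: principal data file (county key column "cnty").
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "fips": "cnty",
    "name": "name",
    "state": "state",
    "population": "population",
    "centroid_lat": "lat",
    "centroid_lon": "lon",
}

_COVARIATE_COLUMNS = (
    "income",
    "education",
    "obesity",
    "smoking",
    "diabetes",
    "hypertension",
)


def _file_digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:12]


def read_county_table(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> list[CountyRecord]:
    """Read a county outcome CSV into :class:`CountyRecord` rows.

    Mortality columns follow the pattern ``<cause>_deaths``, ``<cause>_years``,
    ``<cause>_rate`` (e.g. ``I25.1_rate``); any trio present builds a
    :class:`MortalityEntry`.  Missing numeric cells stay absent (NaN), FIPS
    codes are zero-padded to five characters, and a duplicated FIPS is a hard
    error.
    """
    path = Path(path)
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, dtype={cmap["fips"]: str})
    if cmap["fips"] not in df.columns:
        raise ValidationError(f"{path}: key column {cmap['fips']!r} not found")
    log.info("read %s (%d rows, digest %s)", path.name, len(df), _file_digest(path))

    fips = df[cmap["fips"]].str.strip().str.zfill(5)
    dup = fips[fips.duplicated()]
    if len(dup):
        raise ValidationError(
            f"{path}: duplicate fips code(s): {sorted(dup.unique())}"
        )

    cause_codes = sorted(
        {c[: -len("_rate")] for c in df.columns if c.endswith("_rate")}
    )

    def _num(row_idx: int, col: str) -> float:
        if col not in df.columns:
            return np.nan
        raw = df.at[row_idx, col]
        if pd.isna(raw) or (isinstance(raw, str) and not raw.strip()):
            return np.nan
        try:
            return float(raw)
        except (TypeError, ValueError):
            raise ValidationError(
                f"{path}: unparseable numeric value {raw!r} "
                f"at row {row_idx}, column {col!r}"
            ) from None

    records: list[CountyRecord] = []
    for idx in df.index:
        pop = _num(idx, cmap["population"])
        if np.isnan(pop):
            raise ValidationError(
                f"{path}: missing population at row {idx}"
            )
        mortality: dict[str, MortalityEntry] = {}
        for cause in cause_codes:
            rate = _num(idx, f"{cause}_rate")
            deaths = _num(idx, f"{cause}_deaths")
            years = _num(idx, f"{cause}_years")
            if np.isnan(rate) and np.isnan(deaths):
                continue  # cause absent for this county, not zero
            mortality[cause] = MortalityEntry(
                cause=cause,
                deaths=0 if np.isnan(deaths) else int(deaths),
                years=1.0 if np.isnan(years) else years,
                rate=rate,
            )
        records.append(
            CountyRecord(
                fips=fips.at[idx],
                name=str(df.at[idx, cmap["name"]]) if cmap["name"] in df.columns else "",
                state=str(df.at[idx, cmap["state"]]) if cmap["state"] in df.columns else "XX",
                population=int(pop),
                centroid_lat=_num(idx, cmap["centroid_lat"]),
                centroid_lon=_num(idx, cmap["centroid_lon"]),
                covariates={c: _num(idx, c) for c in _COVARIATE_COLUMNS if c in df.columns},
                mortality=mortality,
            )
        )
    return records


def write_county_table(counties: Sequence[CountyRecord], path: str | Path) -> None:
    """Write counties to CSV in the dialect :func:`read_county_table` reads."""
    causes = sorted({c for rec in counties for c in rec.mortality})
    covs = sorted({c for rec in counties for c in rec.covariates})
    rows = []
    for rec in counties:
        row: dict[str, object] = {
            "cnty": rec.fips,
            "name": rec.name,
            "state": rec.state,
            "population": rec.population,
            "lat": rec.centroid_lat,
            "lon": rec.centroid_lon,
        }
        for c in covs:
            row[c] = rec.covariates.get(c, np.nan)
        for cause in causes:
            entry = rec.mortality.get(cause)
            row[f"{cause}_deaths"] = entry.deaths if entry else np.nan
            row[f"{cause}_years"] = entry.years if entry else np.nan
            row[f"{cause}_rate"] = entry.rate if entry else np.nan
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# --------------------------------------------------------------------------
# dictionary I/O (LIWC-style category files)
# --------------------------------------------------------------------------


def read_dictionary(path: str | Path) -> LanguageDictionary:
    """Read a LIWC-style category file.

    Format: a header line ``#id<TAB>label<TAB>valence`` followed by one word
    per line.  Words are lowercased and deduplicated; an empty category is an
    error.
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines or not lines[0].startswith("#"):
        raise ValidationError(f"{path}: missing '#id\\tlabel\\tvalence' header")
    header = lines[0][1:].split("\t")
    if len(header) != 3:
        raise ValidationError(f"{path}: header must have id, label, valence")
    dict_id, label, valence = (h.strip() for h in header)
    words = {w.strip().lower() for w in lines[1:] if w.strip()}
    if not words:
        raise ValidationError(f"{path}: dictionary {dict_id!r} is empty")
    return LanguageDictionary(id=dict_id, label=label, valence=valence, words=frozenset(words))


def write_dictionary(dictionary: LanguageDictionary, path: str | Path) -> None:
    lines = [f"#{dictionary.id}\t{dictionary.label}\t{dictionary.valence}"]
    lines.extend(sorted(dictionary.words))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# --------------------------------------------------------------------------
# word counts & topics
# --------------------------------------------------------------------------


def read_word_counts(
    path: str | Path, totals_path: str | Path | None = None
) -> WordCountTable:
    """Read a long CSV ``fips,word,count`` into a :class:`WordCountTable`.

    Totals default to the per-county sums; an optional two-column totals CSV
    (``fips,total``) overrides them, e.g. when the table omits
    out-of-vocabulary tokens.
    """
    df = pd.read_csv(path, dtype={"fips": str})
    for col in ("fips", "word", "count"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    df["fips"] = df["fips"].str.zfill(5)
    df["word"] = df["word"].str.lower()
    totals = None
    if totals_path is not None:
        tdf = pd.read_csv(totals_path, dtype={"fips": str})
        totals = dict(zip(tdf["fips"].str.zfill(5), tdf["total"].astype(int)))
    return WordCountTable.from_long_frame(df, totals=totals)


def write_word_counts(table: WordCountTable, path: str | Path) -> None:
    table.to_long_frame().to_csv(path, index=False)


def read_topic_weights(path: str | Path) -> TopicModel:
    """Read a long CSV ``topic,word,weight`` into a :class:`TopicModel`."""
    df = pd.read_csv(path, dtype={"topic": str})
    weights: dict[str, dict[str, float]] = {}
    for topic, grp in df.groupby("topic"):
        weights[str(topic)] = dict(
            zip(grp["word"].str.lower(), grp["weight"].astype(float))
        )
    return TopicModel(weights=weights)


def write_topic_weights(topics: TopicModel, path: str | Path) -> None:
    rows = [
        {"topic": t, "word": w, "weight": v}
        for t, wmap in topics.weights.items()
        for w, v in wmap.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------


def load_config(path: str | Path | None = None, **overrides) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from YAML, with keyword overrides.

    Every field is materialized explicitly; unknown keys are an error so a
    typo never silently becomes a default.
    """
    data: dict = {}
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
    data.update(overrides)
    known = set(AnalysisConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    cfg = AnalysisConfig(**data)
    log.info("config loaded: seed=%d hash=%s", cfg.seed, cfg.config_hash())
    return cfg
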