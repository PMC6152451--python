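"""County-level language variables from word counts.

A dictionary score is the fraction of a county's tokens that belong to a
themed word list (relative frequency, in [0, 1]); a topic score is the
weighted sum of the county's word relative frequencies under a topic's
word-weight vector.  Dominance measures how much of a dictionary's pooled
occurrences a single word accounts for — the lever behind single-word
ablation analyses (drop one dominant word, watch the association move).
The vocabulary audit flags watchlist words that never appear in the data at
all, the signature of upstream censorship of the token stream.

Scores are plain relative frequencies by default; an arcsinh(sqrt(.))
variance-stabilizing transform is available behind a switch but never
applied implicitly.  Tokens match by exact string equality after
lowercasing; no stemming or wildcard expansion.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .core_io import (
    LanguageDictionary,
    TopicModel,
    ValidationError,
    WordCountTable,
    get_logger,
)

log = get_logger("countylex.language_scoring")

__all__ = [
    "CountyScore",
    "dictionary_score",
    "topic_score",
    "dominance_share",
    "ablate_word",
    "vocabulary_audit",
    "scores_to_frame",
]


@dataclass(frozen=True)
class CountyScore:
    """One county's value on one language variable.

    ``n_tokens`` is the county token total used as the denominator.
    Dictionary scores lie in [0, 1]; topic scores are nonnegative.
    """

    fips: str
    variable_id: str
    value: float
    n_tokens: int


def scores_to_frame(scores: list[CountyScore]) -> pd.DataFrame:
    """Long DataFrame (fips, variable_id, value, n_tokens) from score lists."""
    return pd.DataFrame([s.__dict__ for s in scores])


def _stabilize(values: np.ndarray) -> np.ndarray:
    return np.arcsinh(np.sqrt(values))


def dictionary_score(
    counts: WordCountTable,
    dictionary: LanguageDictionary,
    stabilize: bool = False,
) -> list[CountyScore]:
    """Relative frequency of dictionary words per county.

    value = (sum of the county's counts over dictionary words) / county
    token total.  Counties with zero total tokens are omitted and logged —
    a score cannot be formed, and 0 would be a different claim.
    """
    if not dictionary.words:
        raise ValidationError("empty dictionary")
    cols = counts.word_columns(dictionary.words)
    if cols.size:
        dict_sums = np.asarray(counts.matrix[:, cols].sum(axis=1)).ravel()
    else:
        dict_sums = np.zeros(counts.n_counties)
    totals = counts.totals.astype(float)
    zero = totals == 0
    if zero.any():
        log.info(
            "dictionary_score(%s): omitting %d zero-token count%s",
            dictionary.id, int(zero.sum()), "y" if zero.sum() == 1 else "ies",
        )
    values = np.divide(dict_sums, totals, out=np.zeros_like(totals), where=~zero)
    if stabilize:
        values = _stabilize(values)
    return [
        CountyScore(
            fips=f,
            variable_id=dictionary.id,
            value=float(values[i]),
            n_tokens=int(totals[i]),
        )
        for i, f in enumerate(counts.fips)
        if not zero[i]
    ]


def topic_score(
    counts: WordCountTable, topics: TopicModel, topic_id: str
) -> list[CountyScore]:
    """Weighted sum of word relative frequencies under one topic.

    value = sum_w (count[f, w] / total[f]) * weight(topic, w).  Weights are
    used as supplied, un-normalized.
    """
    if topic_id not in topics.weights:
        raise ValidationError(f"unknown topic id {topic_id!r}")
    wmap = topics.weights[topic_id]
    present = [(w, wt) for w, wt in wmap.items() if w in counts._word_index]
    totals = counts.totals.astype(float)
    zero = totals == 0
    if zero.any():
        log.info("topic_score(%s): omitting %d zero-token counties",
                 topic_id, int(zero.sum()))
    if present:
        cols = np.array([counts._word_index[w] for w, _ in present])
        wts = np.array([wt for _, wt in present])
        sums = counts.matrix[:, cols].toarray() @ wts
    else:
        sums = np.zeros(counts.n_counties)
    values = np.divide(sums, totals, out=np.zeros_like(totals), where=~zero)
    return [
        CountyScore(
            fips=f, variable_id=topic_id, value=float(values[i]),
            n_tokens=int(totals[i]),
        )
        for i, f in enumerate(counts.fips)
        if not zero[i]
    ]


def dominance_share(
    counts: WordCountTable, dictionary: LanguageDictionary, word: str
) -> float:
    """Percentage of the dictionary's pooled occurrences owed to one word.

    Counts are pooled across counties first ("of all word occurrences"),
    not averaged over per-county shares.
    """
    word = word.lower()
    if word not in dictionary.words:
        raise ValidationError(f"word {word!r} is not in dictionary {dictionary.id!r}")
    cols = counts.word_columns(dictionary.words)
    pooled = float(counts.matrix[:, cols].sum()) if cols.size else 0.0
    if pooled == 0:
        raise ValidationError(
            f"dictionary {dictionary.id!r} has zero total occurrences"
        )
    j = counts._word_index.get(word)
    word_total = float(counts.matrix[:, j].sum()) if j is not None else 0.0
    return 100.0 * word_total / pooled


def ablate_word(dictionary: LanguageDictionary, word: str) -> LanguageDictionary:
    """Dictionary without one word; the id records the ablation.

    Ablating an absent word returns an identical word set (warning logged);
    removing the last word is an error.
    """
    word = word.lower()
    if word not in dictionary.words:
        log.warning(
            "ablate_word: %r not in dictionary %s; word set unchanged",
            word, dictionary.id,
        )
        return replace(dictionary, id=f"{dictionary.id}-minus-{word}")
    remaining = dictionary.words - {word}
    if not remaining:
        raise ValidationError(
            f"ablating {word!r} would empty dictionary {dictionary.id!r}"
        )
    return replace(
        dictionary, id=f"{dictionary.id}-minus-{word}", words=frozenset(remaining)
    )


def vocabulary_audit(
    counts: WordCountTable, watchlist: list[str]
) -> pd.DataFrame:
    """Presence report per watchlist word.

    Columns: word, present, total_occurrences, n_counties (counties with at
    least one occurrence).  A word absent from the entire table — when its
    near-synonyms are common — is the fingerprint of upstream filtering.
    """
    rows = []
    for word in watchlist:
        w = word.lower()
        j = counts._word_index.get(w)
        if j is None:
            rows.append({"word": w, "present": False,
                         "total_occurrences": 0, "n_counties": 0})
        else:
            col = counts.matrix[:, j]
            rows.append({
                "word": w,
                "present": bool(col.sum() > 0),
                "total_occurrences": int(col.sum()),
                "n_counties": int((col > 0).sum()),
            })
    return pd.DataFrame(rows, columns=["word", "present", "total_occurrences", "n_counties"])
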