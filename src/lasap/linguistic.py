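"""Keyword-frequency linguistic features.

Transcripts are tokenized, term frequencies are counted per participant,
keywords are screened by corpus frequency and lexicon (topic) membership,
and redundancy among the surviving counts is removed with PCA fitted on
training data only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from sklearn.decomposition import PCA

from .blocks import FeatureBlock

logger = logging.getLogger(__name__)

__all__ = [
    "Transcript",
    "KeywordLexicon",
    "TermMatrix",
    "PCAReducer",
    "read_transcripts",
    "build_term_matrix",
    "screen_keywords",
    "fit_pca",
    "apply_pca",
]


@dataclass
class Transcript:
    """One participant's tokenized interview response."""

    participant_id: str
    tokens: list[str]


@dataclass
class KeywordLexicon:
    """Keyword -> topic map (keywords may be multi-word phrases).

    ``topic_process`` optionally maps each topic to one of the three
    family-resilience processes (belief systems, organizational patterns,
    communication patterns); it is carried as metadata only.
    """

    entries: dict[str, str]
    topic_process: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.entries and len(set(self.entries)) != len(self.entries):
            raise ValueError("duplicate keywords in lexicon")

    def __contains__(self, keyword: str) -> bool:
        return keyword in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def topics(self) -> list[str]:
        return sorted(set(self.entries.values()))

    @classmethod
    def from_yaml(cls, path) -> "KeywordLexicon":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        if isinstance(payload, dict) and "keywords" in payload:
            return cls(dict(payload["keywords"]), dict(payload.get("topic_process", {})))
        return cls(dict(payload))

    def to_yaml(self, path) -> None:
        payload: dict = {"keywords": dict(self.entries)}
        if self.topic_process:
            payload["topic_process"] = dict(self.topic_process)
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, allow_unicode=True, sort_keys=True)


@dataclass
class TermMatrix:
    """Participant x vocabulary nonnegative count matrix."""

    counts: np.ndarray
    vocabulary: list[str]
    participant_ids: list[str]

    def __post_init__(self) -> None:
        self.counts = np.atleast_2d(np.asarray(self.counts))
        if self.counts.shape != (len(self.participant_ids), len(self.vocabulary)):
            raise ValueError("count matrix shape does not match ids/vocabulary")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    def to_block(self) -> FeatureBlock:
        return FeatureBlock(
            self.counts.astype(float), list(self.vocabulary), list(self.participant_ids), "linguistic"
        )

    def restrict(self, terms: list[str]) -> "TermMatrix":
        index = {t: j for j, t in enumerate(self.vocabulary)}
        cols = [index[t] for t in terms]
        return TermMatrix(self.counts[:, cols], list(terms), list(self.participant_ids))


def tokenize(text: str) -> list[str]:
    """Default tokenizer: lowercase whitespace split."""
    return text.lower().split()


def read_transcripts(path) -> list[Transcript]:
    """Read a transcript TSV with columns ``id`` and ``text``."""
    frame = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if not {"id", "text"}.issubset(frame.columns):
        raise ValueError("transcript TSV needs columns 'id' and 'text'")
    return [Transcript(str(r.id), tokenize(r.text)) for r in frame.itertuples()]


def _count_terms(tokens: list[str], vocabulary: list[str]) -> np.ndarray:
    """Count vocabulary occurrences with greedy longest phrase match.

    Multi-word vocabulary entries are matched greedily left to right and
    consume their tokens, so a phrase hit never double-counts its words.
    """
    phrases: dict[str, list[tuple[str, ...]]] = {}
    for term in vocabulary:
        parts = tuple(term.split())
        phrases.setdefault(parts[0], []).append(parts)
    for head in phrases:
        phrases[head].sort(key=len, reverse=True)
    index = {t: j for j, t in enumerate(vocabulary)}
    counts = np.zeros(len(vocabulary), dtype=int)
    i = 0
    while i < len(tokens):
        matched = False
        for parts in phrases.get(tokens[i], ()):
            if tuple(tokens[i : i + len(parts)]) == parts:
                counts[index[" ".join(parts)]] += 1
                i += len(parts)
                matched = True
                break
        if not matched:
            i += 1
    return counts


def build_term_matrix(
    corpus: list[Transcript], vocabulary: list[str] | None = None
) -> TermMatrix:
    """Count term frequencies per participant.

    When ``vocabulary`` is omitted it is the sorted set of all tokens in
    the corpus; when given (possibly containing multi-word phrases),
    counting is restricted to it.  Empty transcripts yield all-zero rows
    and are logged, not dropped.
    """
    if not corpus:
        raise ValueError("empty corpus")
    ids = [t.participant_id for t in corpus]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate participant ids: {dupes}")
    if vocabulary is None:
        vocabulary = sorted({tok for t in corpus for tok in t.tokens})
    rows = []
    for t in corpus:
        if not t.tokens:
            logger.warning("empty transcript for participant %s", t.participant_id)
        rows.append(_count_terms(t.tokens, list(vocabulary)))
    return TermMatrix(np.vstack(rows) if rows else np.zeros((0, len(vocabulary))), list(vocabulary), ids)


def screen_keywords(
    tm: TermMatrix, lexicon: KeywordLexicon, min_total: int = 2
) -> list[str]:
    """Select terms with corpus-wide count >= ``min_total`` that belong to the lexicon.

    Vocabulary order is preserved.  The default threshold of 2 keeps terms
    that appear at least twice across the screening corpus.
    """
    if min_total < 1:
        raise ValueError("min_total must be >= 1")
    if len(lexicon) == 0:
        raise ValueError("empty lexicon")
    totals = np.asarray(tm.counts).sum(axis=0)
    return [t for t, c in zip(tm.vocabulary, totals) if c >= min_total and t in lexicon]


@dataclass
class PCAReducer:
    """PCA fitted on a training block; retains the smallest number of
    components whose cumulative explained variance reaches the target
    fraction."""

    training_means: np.ndarray
    components: np.ndarray  # (retained, n_features), orthonormal rows
    explained_variance: np.ndarray  # all eigenvalues, descending
    retained: int
    variance_fraction: float

    @property
    def input_dim(self) -> int:
        return self.components.shape[1]


def fit_pca(training_block: FeatureBlock, variance_fraction: float = 0.95) -> PCAReducer:
    """Fit a PCA redundancy reducer on training rows only."""
    X = training_block.values
    if X.shape[0] < 2:
        raise ValueError("need at least 2 training rows")
    if not 0 < variance_fraction <= 1:
        raise ValueError("variance_fraction must be in (0, 1]")
    if np.allclose(X.var(axis=0), 0):
        raise ValueError("constant (zero-variance) block: PCA undefined")
    pca = PCA(svd_solver="full")
    pca.fit(X)
    cumulative = np.cumsum(pca.explained_variance_ratio_)
    retained = int(np.searchsorted(cumulative, variance_fraction - 1e-12) + 1)
    retained = min(retained, pca.components_.shape[0])
    return PCAReducer(
        training_means=pca.mean_.copy(),
        components=pca.components_.copy(),
        explained_variance=pca.explained_variance_.copy(),
        retained=retained,
        variance_fraction=float(variance_fraction),
    )


def apply_pca(reducer: PCAReducer, block: FeatureBlock) -> FeatureBlock:
    """Center by the training means and project onto the retained components."""
    if block.n_features != reducer.input_dim:
        raise ValueError(
            f"block has {block.n_features} features, reducer expects {reducer.input_dim}"
        )
    scores = (block.values - reducer.training_means) @ reducer.components[: reducer.retained].T
    names = [f"pc{k + 1}" for k in range(reducer.retained)]
    return FeatureBlock(scores, names, list(block.participant_ids), "linguistic")
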