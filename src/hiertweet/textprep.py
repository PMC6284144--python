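"""Corpus -> nonnegative term-document matrix.

The preparation pipeline applied to every tweet is: clean and tokenize
(URLs, @-mentions and the leading retweet marker removed, case folded,
punctuation stripped), remove stopwords, Porter-stem each token, then emit
contiguous N-grams over the stemmed tokens.  Document vectors are raw term
frequencies or tf-idf (``count * log(n_docs / docfreq)``), optionally
scaled to unit Euclidean norm per document — the conventional weighting
for NMF document clustering, which needs columns on a comparable scale for
balanced splits.

Stemming happens *before* N-gram joining, so inflectional variants of a
phrase ("aids epidemic" / "aids epidemics") collapse onto one bigram term.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import scipy.sparse as sp
from sklearn.feature_extraction.text import ENGLISH_STOP_WORDS

from .corpus import Corpus
from .porter import porter_stem

__all__ = [
    "PrepOptions",
    "Vocabulary",
    "TermDocMatrix",
    "DEFAULT_STOPWORDS",
    "clean_and_tokenize",
    "extract_ngrams",
    "prepare_terms",
    "build_matrix",
    "save_matrix",
    "load_matrix",
]

# Standard English list plus Twitter-collection artifacts.
DEFAULT_STOPWORDS = frozenset(ENGLISH_STOP_WORDS) | {"rt", "amp", "http", "https"}

_URL = re.compile(r"(?:https?://|www\.)\S+", re.IGNORECASE)
_MENTION = re.compile(r"@\w+")
_LEADING_RT = re.compile(r"^\s*rt\b:?\s*", re.IGNORECASE)
_HASHTAG = re.compile(r"#\w+")
_WORD = re.compile(r"[a-z0-9]+")


@dataclass(frozen=True)
class PrepOptions:
    """Text-preparation settings.

    ``ngram_min``/``ngram_max`` bound the N in N-gram extraction (default
    unigrams + bigrams).  ``min_term_docfreq`` prunes terms occurring in
    fewer documents.  tf-idf weighting with unit-norm documents is the
    default vectorization.
    """

    ngram_min: int = 1
    ngram_max: int = 2
    stopwords: frozenset[str] = DEFAULT_STOPWORDS
    min_term_docfreq: int = 3
    keep_hashtags: bool = True
    weighting: Literal["tf", "tfidf"] = "tfidf"
    normalize_docs: bool = True

    def __post_init__(self) -> None:
        if self.ngram_min < 1:
            raise ValueError("ngram_min must be >= 1")
        if self.ngram_max < self.ngram_min:
            raise ValueError("ngram_max must be >= ngram_min")
        if self.min_term_docfreq < 1:
            raise ValueError("min_term_docfreq must be >= 1")


@dataclass
class Vocabulary:
    """Ordered term list with its row-index map and document frequencies."""

    terms: list[str]
    docfreq: np.ndarray
    index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.index = {t: i for i, t in enumerate(self.terms)}
        if len(self.index) != len(self.terms):
            raise ValueError("terms are not unique")

    def __len__(self) -> int:
        return len(self.terms)


@dataclass
class TermDocMatrix:
    """Sparse nonnegative terms x documents matrix with its vocabulary.

    Rows follow ``vocabulary.terms``; columns follow ``doc_ids``.  All
    stored values are nonnegative and no row is entirely zero.
    """

    values: sp.csc_matrix
    vocabulary: Vocabulary
    doc_ids: list[str]
    weighting: str
    dropped_doc_ids: list[str] = field(default_factory=list)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def clean_and_tokenize(text: str, keep_hashtags: bool = True) -> list[str]:
    """Case-folded word tokens with URLs, @-mentions and a leading "RT"
    marker removed; hashtags kept (sans '#') or dropped; punctuation
    stripped; standalone numerals retained."""
    s = _URL.sub(" ", text)
    s = _LEADING_RT.sub(" ", s)
    s = _MENTION.sub(" ", s)
    if keep_hashtags:
        s = s.replace("#", " ")
    else:
        s = _HASHTAG.sub(" ", s)
    return _WORD.findall(s.casefold())


def extract_ngrams(tokens: list[str], ngram_min: int, ngram_max: int) -> list[str]:
    """All contiguous n-grams for n in [ngram_min, ngram_max], in order of
    first emission, words joined by single spaces."""
    if ngram_min > ngram_max:
        raise ValueError("ngram_min must be <= ngram_max")
    out: list[str] = []
    for n in range(ngram_min, ngram_max + 1):
        for i in range(len(tokens) - n + 1):
            out.append(" ".join(tokens[i : i + n]))
    return out


def prepare_terms(text: str, options: PrepOptions) -> list[str]:
    """Full per-document pipeline: tokenize -> drop stopwords -> stem ->
    N-grams.  Returns the term occurrence list (with repeats)."""
    tokens = clean_and_tokenize(text, keep_hashtags=options.keep_hashtags)
    tokens = [t for t in tokens if t not in options.stopwords]
    stems = [porter_stem(t) for t in tokens]
    return extract_ngrams(stems, options.ngram_min, options.ngram_max)


def build_matrix(corpus: Corpus, options: PrepOptions | None = None) -> TermDocMatrix:
    """Build the term-document matrix for a corpus.

    Terms below ``min_term_docfreq`` are pruned; with tf-idf weighting a
    term present in every document weights to zero and is pruned as well.
    Documents whose column becomes all-zero are dropped and reported in
    ``dropped_doc_ids``.

    Raises
    ------
    ValueError
        If the corpus is empty or no document survives preparation.
    """
    if options is None:
        options = PrepOptions()
    if not corpus.tweets:
        raise ValueError("corpus is empty")

    doc_terms = [prepare_terms(t.text, options) for t in corpus.tweets]
    doc_ids = [t.id for t in corpus.tweets]

    # Deterministic vocabulary: sorted unique terms passing the docfreq cut.
    df_all: dict[str, int] = {}
    for terms in doc_terms:
        for term in set(terms):
            df_all[term] = df_all.get(term, 0) + 1
    kept = sorted(t for t, df in df_all.items() if df >= options.min_term_docfreq)
    if not kept:
        raise ValueError("no term passes min_term_docfreq; corpus too small?")
    index = {t: i for i, t in enumerate(kept)}

    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    for j, terms in enumerate(doc_terms):
        counts: dict[int, int] = {}
        for term in terms:
            i = index.get(term)
            if i is not None:
                counts[i] = counts.get(i, 0) + 1
        for i, c in counts.items():
            rows.append(i)
            cols.append(j)
            vals.append(float(c))
    mat = sp.csc_matrix(
        (vals, (rows, cols)), shape=(len(kept), len(doc_ids)), dtype=np.float64
    )

    n_docs = len(doc_ids)
    docfreq = np.asarray((mat > 0).sum(axis=1)).ravel().astype(np.int64)
    if options.weighting == "tfidf":
        idf = np.log(n_docs / docfreq.astype(np.float64))
        mat = sp.diags(idf) @ mat
        mat.eliminate_zeros()

    # Prune rows zeroed by weighting (idf of an everywhere-present term is 0).
    row_nnz = np.asarray((mat != 0).sum(axis=1)).ravel()
    keep_rows = row_nnz > 0
    mat = mat[keep_rows]
    terms_final = [t for t, k in zip(kept, keep_rows) if k]
    docfreq = docfreq[keep_rows]

    # Drop documents emptied by pruning/weighting, reporting them.
    col_norms = np.sqrt(np.asarray(mat.multiply(mat).sum(axis=0)).ravel())
    keep_cols = col_norms > 0
    dropped = [d for d, k in zip(doc_ids, keep_cols) if not k]
    mat = mat[:, keep_cols]
    doc_ids = [d for d, k in zip(doc_ids, keep_cols) if k]
    if not doc_ids:
        raise ValueError("all documents empty after preparation")

    if options.normalize_docs:
        inv = 1.0 / col_norms[keep_cols]
        mat = mat @ sp.diags(inv)

    return TermDocMatrix(
        values=sp.csc_matrix(mat),
        vocabulary=Vocabulary(terms=terms_final, docfreq=docfreq),
        doc_ids=doc_ids,
        weighting=options.weighting,
        dropped_doc_ids=dropped,
    )


def save_matrix(tdm: TermDocMatrix, prefix: str | Path) -> None:
    """Write ``<prefix>.mtx`` (MatrixMarket) plus ``<prefix>.terms.txt`` and
    ``<prefix>.docs.txt`` sidecars (one entry per line, UTF-8)."""
    prefix = Path(prefix)
    from scipy.io import mmwrite

    mmwrite(str(prefix.with_suffix(".mtx")), tdm.values)
    prefix.with_suffix(".terms.txt").write_text(
        "\n".join(tdm.vocabulary.terms) + "\n", encoding="utf-8"
    )
    prefix.with_suffix(".docs.txt").write_text(
        "\n".join(tdm.doc_ids) + "\n", encoding="utf-8"
    )


def load_matrix(prefix: str | Path, weighting: str = "tfidf") -> TermDocMatrix:
    """Read a matrix written by :func:`save_matrix`."""
    from scipy.io import mmread

    prefix = Path(prefix)
    mat = sp.csc_matrix(mmread(str(prefix.with_suffix(".mtx"))))
    terms = prefix.with_suffix(".terms.txt").read_text(encoding="utf-8").splitlines()
    docs = prefix.with_suffix(".docs.txt").read_text(encoding="utf-8").splitlines()
    docfreq = np.asarray((mat != 0).sum(axis=1)).ravel().astype(np.int64)
    return TermDocMatrix(
        values=mat,
        vocabulary=Vocabulary(terms=terms, docfreq=docfreq),
        doc_ids=docs,
        weighting=weighting,
    )
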