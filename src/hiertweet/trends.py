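"""Two-timepoint topic-frequency trends and the UNAIDS theme codebook.

*Frequency* of a topic term is tweet-level containment: the number of
documents whose prepared term set contains the term, not the number of
token occurrences.  Terms reaching a minimum frequency (default 35 tweets)
form the frequency table for a timepoint; tables from two timepoints are
compared either on raw counts or on rates per 10,000 unique tweets — the
normalized mode is the default because the corpora being compared can
differ in size severalfold.

The codebook maps a cluster's top terms to a named theme, each theme tied
to one UNAIDS core action principle and one of the three commitment areas
(Prevention, Treatment or Care, Support).  Matching is a deterministic
largest-keyword-overlap rule; the expert qualitative coding that produced
such themes in the first place is *not* automated here.  Comparing the
degree level (tree depth) of a theme's node between two years quantifies
shifts in its prominence: a positive depth delta means the theme moved
deeper, i.e. became less prominent.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Optional

import pandas as pd

from .corpus import Corpus
from .porter import porter_stem
from .textprep import PrepOptions, prepare_terms

__all__ = [
    "CORE_ACTIONS",
    "COMMITMENTS",
    "CodebookEntry",
    "Codebook",
    "ThemeAssignment",
    "TrendRecord",
    "default_codebook",
    "read_codebook",
    "write_codebook",
    "topic_frequency",
    "frequency_table",
    "compare_periods",
    "apply_codebook",
    "theme_depth_table",
]

CORE_ACTIONS = frozenset(
    {
        "Decrease Vulnerability of Acquiring HIV/AIDS",
        "Access to Services",
        "Expand Programs",
        "Safeguard Human Rights",
        "Partnerships and Alliances",
        "Eliminate Stigma and Discrimination",
    }
)

COMMITMENTS = frozenset({"Prevention", "Treatment or Care", "Support"})


@dataclass(frozen=True)
class CodebookEntry:
    theme: str
    keywords: frozenset[str]  # stemmed unigram keywords
    core_action: str
    commitment: str


@dataclass
class Codebook:
    entries: list[CodebookEntry]

    def __post_init__(self) -> None:
        names = [e.theme for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("theme names must be unique")
        for e in self.entries:
            if e.core_action not in CORE_ACTIONS:
                raise ValueError(f"unknown core action {e.core_action!r}")
            if e.commitment not in COMMITMENTS:
                raise ValueError(f"unknown commitment {e.commitment!r}")

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class ThemeAssignment:
    theme: str
    core_action: str
    commitment: str
    overlap: int


@dataclass(frozen=True)
class TrendRecord:
    topic_term: str
    freq_a: int
    freq_b: int
    rate_a: float  # per 10,000 unique tweets
    rate_b: float
    direction: Literal["increase", "decrease", "stable", "new", "absent"]


# ---------------------------------------------------------------------------
# Default codebook: themes from the published World AIDS Day 2014/2015
# tweet-theme framework, with their representative cluster words.
# ---------------------------------------------------------------------------

_DEFAULT_ROWS: list[tuple[str, str, str, str]] = [
    # (theme, core action, commitment, raw keywords both years)
    ("Informational Resources from Governmental Organizations",
     "Decrease Vulnerability of Acquiring HIV/AIDS", "Prevention",
     "infographics, aids.gov, white house"),
    ("Halt Infections",
     "Decrease Vulnerability of Acquiring HIV/AIDS", "Prevention",
     "accessible, affordable, vaccine partnerships, epidemic, averted"),
    ("AIDS-Free Generation",
     "Decrease Vulnerability of Acquiring HIV/AIDS", "Prevention",
     "close the gap, aids free gen, children"),
    ("Prevent HIV/AIDS",
     "Decrease Vulnerability of Acquiring HIV/AIDS", "Prevention",
     "aids prevention, hiv facts"),
    ("Treatment for HIV/AIDS",
     "Access to Services", "Treatment or Care",
     "access, children, pregnant women services, closing the gap, treat, people"),
    ("Save Lives: Infected and At Risk",
     "Access to Services", "Treatment or Care",
     "cure, treatment for all"),
    ("Impact of the HIV/AIDS Pandemic",
     "Access to Services", "Treatment or Care",
     "millions, lives, end, children, can avert, infections, save, world"),
    ("Efforts for Targeted HIV/AIDS Eradication",
     "Expand Programs", "Treatment or Care",
     "facts, wipe homophobia, today, save, join, treatment for all"),
    ("Fast Track the End of the Pandemic",
     "Expand Programs", "Treatment or Care",
     "today, end, epidemic, unaids, fast track, treatment, response, assessing"),
    ("Spread HIV/AIDS Awareness",
     "Safeguard Human Rights", "Support",
     "cure, love, sending, support, fight, amfar, awareness, spread, end aids"),
    ("Recognition of the Pandemic",
     "Safeguard Human Rights", "Support",
     "unaware, united states, hiv, aware, disease"),
    ("Honor People Living with HIV/AIDS",
     "Safeguard Human Rights", "Support",
     "honor, memory, continuing, lost, affected, living, people, positive, statement"),
    ("Expression of HIV/AIDS Solidarity and Consciousness",
     "Safeguard Human Rights", "Support",
     "wear, ribbon, close the gap, tee shirt ribbon"),
    ("Combat HIV/AIDS",
     "Safeguard Human Rights", "Support",
     "fight, today, support, cure, love, helping"),
    ("Support PLWH",
     "Safeguard Human Rights", "Support",
     "sending, support, fight, cure, living, and people"),
    ("Commitment to End the Pandemic",
     "Partnerships and Alliances", "Support",
     "renew, vow, longer, statements, discrimination, make"),
    ("Celebrities or Industries",
     "Partnerships and Alliances", "Support",
     "mac cosmetics viva glam, mac aids fund, kasper, rappers, victoria beckham"),
    ("Reduce Stigma",
     "Eliminate Stigma and Discrimination", "Support",
     "lgbt, facts, stigma, end"),
    ("Discrimination of PLWH",
     "Eliminate Stigma and Discrimination", "Support",
     "discrimination, living, people"),
]


def _stem_keywords(raw: str, prep: PrepOptions) -> frozenset[str]:
    unigram = PrepOptions(
        ngram_min=1,
        ngram_max=1,
        stopwords=prep.stopwords,
        min_term_docfreq=1,
        keep_hashtags=prep.keep_hashtags,
        weighting="tf",
        normalize_docs=False,
    )
    return frozenset(prepare_terms(raw, unigram))


def default_codebook(prep: PrepOptions | None = None) -> Codebook:
    """The packaged theme codebook; keywords are stemmed through the same
    pipeline as corpus text so matching is consistent."""
    prep = prep or PrepOptions()
    return Codebook(
        entries=[
            CodebookEntry(
                theme=theme,
                keywords=_stem_keywords(raw, prep),
                core_action=action,
                commitment=commitment,
            )
            for theme, action, commitment, raw in _DEFAULT_ROWS
        ]
    )


def write_codebook(codebook: Codebook, path: str | Path) -> None:
    """One record per theme: theme, keywords (space-separated), core
    action, commitment — tab-delimited."""
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["theme", "keywords", "core_action", "commitment"])
        for e in codebook.entries:
            writer.writerow(
                [e.theme, " ".join(sorted(e.keywords)), e.core_action, e.commitment]
            )


def read_codebook(path: str | Path) -> Codebook:
    entries = []
    with Path(path).open(newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            entries.append(
                CodebookEntry(
                    theme=row["theme"],
                    keywords=frozenset(row["keywords"].split()),
                    core_action=row["core_action"],
                    commitment=row["commitment"],
                )
            )
    return Codebook(entries=entries)


# ---------------------------------------------------------------------------
# Frequencies and trends
# ---------------------------------------------------------------------------

def _doc_term_sets(corpus: Corpus, prep: PrepOptions) -> list[set[str]]:
    return [set(prepare_terms(t.text, prep)) for t in corpus.tweets]


def topic_frequency(corpus: Corpus, term: str, prep: PrepOptions | None = None) -> int:
    """Number of tweets whose prepared term set contains ``term`` (a tweet
    repeating the term still counts once)."""
    prep = prep or PrepOptions()
    return sum(1 for terms in _doc_term_sets(corpus, prep) if term in terms)


def frequency_table(
    corpus: Corpus,
    prep: PrepOptions | None = None,
    min_count: int = 35,
) -> list[tuple[str, int]]:
    """All terms with tweet-level frequency >= ``min_count``, sorted by
    frequency descending then lexicographically."""
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    prep = prep or PrepOptions()
    counts: dict[str, int] = {}
    for terms in _doc_term_sets(corpus, prep):
        for term in terms:
            counts[term] = counts.get(term, 0) + 1
    kept = [(t, c) for t, c in counts.items() if c >= min_count]
    kept.sort(key=lambda tc: (-tc[1], tc[0]))
    return kept


def compare_periods(
    table_a: Iterable[tuple[str, int]],
    table_b: Iterable[tuple[str, int]],
    n_unique_a: int,
    n_unique_b: int,
    mode: Literal["raw", "normalized"] = "normalized",
    stable_band: float = 0.25,
) -> list[TrendRecord]:
    """Classify each term's frequency shift between two timepoints.

    Rates are per 10,000 unique tweets.  In ``normalized`` mode a term
    increases when its rate grows by more than ``stable_band`` (fractional),
    decreases when it shrinks by more, and is stable otherwise; ``raw``
    mode applies the same band to the counts.  Terms present in only one
    table are classified ``new`` (b only) or ``absent`` (a only).
    """
    if stable_band < 0:
        raise ValueError("stable_band must be >= 0")
    if n_unique_a < 1 or n_unique_b < 1:
        raise ValueError("unique-tweet counts must be positive")
    fa = dict(table_a)
    fb = dict(table_b)
    records: list[TrendRecord] = []
    for term in sorted(set(fa) | set(fb)):
        ca, cb = fa.get(term), fb.get(term)
        rate_a = 1e4 * (ca or 0) / n_unique_a
        rate_b = 1e4 * (cb or 0) / n_unique_b
        if ca is None:
            direction = "new"
        elif cb is None:
            direction = "absent"
        else:
            va, vb = (ca, cb) if mode == "raw" else (rate_a, rate_b)
            if vb > va * (1.0 + stable_band):
                direction = "increase"
            elif vb < va * (1.0 - stable_band):
                direction = "decrease"
            else:
                direction = "stable"
        records.append(
            TrendRecord(
                topic_term=term,
                freq_a=ca or 0,
                freq_b=cb or 0,
                rate_a=rate_a,
                rate_b=rate_b,
                direction=direction,
            )
        )
    return records


def trends_to_frame(records: list[TrendRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "topic_term": r.topic_term,
                "freq_a": r.freq_a,
                "freq_b": r.freq_b,
                "rate_a": r.rate_a,
                "rate_b": r.rate_b,
                "direction": r.direction,
            }
            for r in records
        ]
    )


# ---------------------------------------------------------------------------
# Codebook application and theme-depth comparison
# ---------------------------------------------------------------------------

def apply_codebook(
    node_top_terms: list[str],
    codebook: Codebook,
    min_overlap: int = 2,
) -> Optional[ThemeAssignment]:
    """The theme whose keyword set overlaps the node's top terms the most,
    provided the overlap reaches ``min_overlap``.  A tie between themes
    yields no assignment (flagged for manual review via a warning)."""
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    if not codebook.entries:
        raise ValueError("codebook is empty")
    # Keyword sets hold stems.  A node word matches directly if it is
    # already a stem, otherwise through its own stem — the Porter mapping
    # is not idempotent, so already-stemmed pipeline terms must never be
    # stemmed a second time.  Multiword terms contribute each component.
    words = {w for t in node_top_terms for w in t.split()}

    def overlap_with(keywords: frozenset[str]) -> int:
        matched = set()
        for w in words:
            if w in keywords:
                matched.add(w)
            else:
                stem = porter_stem(w)
                if stem in keywords:
                    matched.add(stem)
        return len(matched)

    best: list[CodebookEntry] = []
    best_overlap = 0
    for e in codebook.entries:
        ov = overlap_with(e.keywords)
        if ov > best_overlap:
            best, best_overlap = [e], ov
        elif ov == best_overlap and ov > 0:
            best.append(e)
    if best_overlap < min_overlap:
        return None
    if len(best) > 1:
        names = ", ".join(sorted(e.theme for e in best))
        warnings.warn(
            f"codebook tie at overlap {best_overlap} between: {names}; "
            "node left unassigned for manual review",
            stacklevel=2,
        )
        return None
    e = best[0]
    return ThemeAssignment(
        theme=e.theme,
        core_action=e.core_action,
        commitment=e.commitment,
        overlap=best_overlap,
    )


def _assign_tree_themes(tree, codebook: Codebook, min_overlap: int) -> dict[str, int]:
    """theme -> degree level for every assignable node of a topic tree."""
    depths: dict[str, int] = {}
    conflicts: list[str] = []
    for nid in sorted(tree.nodes):
        node = tree.nodes[nid]
        assignment = apply_codebook(node.top_terms, codebook, min_overlap)
        if assignment is None:
            continue
        if assignment.theme in depths and depths[assignment.theme] != node.depth:
            conflicts.append(
                f"{assignment.theme!r} assigned at depths "
                f"{depths[assignment.theme]} and {node.depth}"
            )
        elif assignment.theme in depths:
            conflicts.append(f"{assignment.theme!r} assigned to multiple nodes")
        else:
            depths[assignment.theme] = node.depth
    if conflicts:
        raise ValueError("conflicting theme assignments: " + "; ".join(conflicts))
    return depths


def theme_depth_table(
    tree_a,
    tree_b,
    codebook: Codebook,
    min_overlap: int = 2,
) -> pd.DataFrame:
    """Per-theme degree levels in two trees and their shift.

    ``delta = depth_b - depth_a`` where both are present: positive delta
    means the theme sits deeper in the second tree, a *decrease* in
    prominence by that many levels.  Themes found in only one tree carry a
    missing value in the other column.

    Raises
    ------
    ValueError
        If a theme is assigned to multiple nodes within one tree.
    """
    da = _assign_tree_themes(tree_a, codebook, min_overlap)
    db = _assign_tree_themes(tree_b, codebook, min_overlap)
    rows = []
    for theme in sorted(set(da) | set(db)):
        a, b = da.get(theme), db.get(theme)
        rows.append(
            {
                "theme": theme,
                "depth_a": a,
                "depth_b": b,
                "delta": (b - a) if (a is not None and b is not None) else None,
            }
        )
    frame = pd.DataFrame(rows, columns=["theme", "depth_a", "depth_b", "delta"])
    return frame.astype({"depth_a": "Int64", "depth_b": "Int64", "delta": "Int64"})
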