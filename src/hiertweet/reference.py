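"""Published World AIDS Day 2014/2015 tweet-theme hierarchy summary.

The original World AIDS Day analyses reported, for each expert-coded
theme, the degree level (tree depth) of its node in the 2014 and the 2015
binary topic hierarchy together with representative cluster words.  The
raw tweet streams behind those trees are not redistributable, but the
printed summary is enough to exercise and demonstrate the theme-depth
comparison: this module encodes it and can materialize it as summary
:class:`~hiertweet.hiernmf2.TopicTree` objects whose nodes carry the
reported depth and cluster words.

Depths use the convention root = degree level 1.  A ``None`` depth means
the theme was absent from that year's hierarchy.
"""

from __future__ import annotations

import numpy as np

from .hiernmf2 import TopicNode, TopicTree
from .textprep import PrepOptions, prepare_terms

__all__ = ["WAD_THEME_LEVELS", "reference_tree"]

# theme -> (2014 degree level or None, 2015 degree level or None,
#           2014 cluster words, 2015 cluster words)
WAD_THEME_LEVELS: dict[str, tuple[int | None, int | None, str, str]] = {
    "Informational Resources from Governmental Organizations": (
        1, 2, "infographics aids.gov", "white house aids.gov"),
    "Halt Infections": (
        4, 5, "accessible affordable vaccine partnerships", "epidemic averted"),
    "AIDS-Free Generation": (
        5, 4, "close the gap", "aids free gen children"),
    "Prevent HIV/AIDS": (
        4, None, "aids prevention hiv facts", ""),
    "Treatment for HIV/AIDS": (
        5, 3, "access children pregnant women services closing the gap",
        "treat people"),
    "Save Lives: Infected and At Risk": (
        4, 1, "cure", "treatment for all"),
    "Impact of the HIV/AIDS Pandemic": (
        None, 3, "", "millions lives end children can avert infections save world"),
    "Efforts for Targeted HIV/AIDS Eradication": (
        1, 1, "facts wipe homophobia today", "save join treatment for all"),
    "Fast Track the End of the Pandemic": (
        3, 6, "today end epidemic",
        "unaids fast track treatment response assessing"),
    "Spread HIV/AIDS Awareness": (
        4, 2, "cure love sending support fight amfar", "awareness spread end aids"),
    "Recognition of the Pandemic": (
        5, 3, "unaware united states hiv", "aware disease"),
    "Honor People Living with HIV/AIDS": (
        4, 1, "honor memory continuing lost affected",
        "living people positive statement"),
    "Expression of HIV/AIDS Solidarity and Consciousness": (
        4, 2, "wear ribbon close the gap", "tee shirt ribbon"),
    "Combat HIV/AIDS": (
        2, 5, "fight today support cure love", "fight helping"),
    "Support PLWH": (
        3, 2, "sending support fight cure", "support living and people"),
    "Commitment to End the Pandemic": (
        4, 2, "renew vow longer", "statements discrimination make"),
    "Celebrities or Industries": (
        2, 5, "mac cosmetics viva glam mac aids fund", "kasper rappers victoria beckham"),
    "Reduce Stigma": (
        2, 2, "lgbt facts", "stigma end"),
    "Discrimination of PLWH": (
        None, 3, "", "discrimination living people"),
}


def reference_tree(year: int, prep: PrepOptions | None = None) -> TopicTree:
    """A summary tree for ``year`` (2014 or 2015): one node per theme
    present that year, at its reported degree level, whose top terms are
    the stemmed representative cluster words.

    The result is a *summary*: nodes carry no document sets and no
    parent/child links (only depth matters for theme-depth comparison).
    """
    if year not in (2014, 2015):
        raise ValueError("year must be 2014 or 2015")
    prep = prep or PrepOptions()
    unigram = PrepOptions(
        ngram_min=1, ngram_max=1, stopwords=prep.stopwords,
        min_term_docfreq=1, keep_hashtags=prep.keep_hashtags,
        weighting="tf", normalize_docs=False,
    )
    nodes: dict[int, TopicNode] = {}
    nid = 0
    for theme, (d14, d15, w14, w15) in WAD_THEME_LEVELS.items():
        depth, words = (d14, w14) if year == 2014 else (d15, w15)
        if depth is None:
            continue
        terms = prepare_terms(words, unigram)
        nodes[nid] = TopicNode(
            node_id=nid,
            parent_id=None,
            child_ids=[],
            doc_indices=np.empty(0, dtype=np.int64),
            topic_vector=np.empty(0),
            top_terms=list(dict.fromkeys(terms)),
            split_score=None,
            depth=depth,
        )
        nid += 1
    return TopicTree(
        nodes=nodes,
        root_id=0,
        max_leaves=len(nodes),
        min_node_docs=2,
        seed=0,
        terms=[],
    )
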