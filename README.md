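# hiertweet

Hierarchical rank-2 NMF topic trees and two-timepoint trend analysis for
short health-related social-media corpora.

## The problem

Infoveillance studies mine public sentiment from tweet streams collected
around health observances — for example, World AIDS Day, when HIV/AIDS
advocacy peaks worldwide.  Given two single-day corpora of English tweets
from consecutive years, the analysis questions are: what themes are people
tweeting about, how are those themes organized hierarchically, and which
themes gained or lost prominence between the two years?  `hiertweet`
implements that pipeline end to end for epidemiologists and digital-health
researchers:

1. **Corpus accounting** — ingest exported tweet files (CSV or JSON-lines),
   keep one language, collapse retweets onto their originals, and summarize
   each corpus by its unique-tweet count and *reach* (summed follower
   counts over all messages).
2. **Text preparation** — clean and tokenize (URLs, @-mentions, retweet
   markers, punctuation removed), drop stopwords, Porter-stem, extract
   N-grams, and build a tf-idf term-document matrix with unit-norm
   document columns.
3. **Hierarchical rank-2 NMF (HierNMF2)** — recursively bisect the corpus
   into a binary topic tree.  Each candidate split fits a rank-2
   factorization `A ≈ WH` (`W`: terms × 2, `H`: 2 × documents, both
   nonnegative) by alternating **exact** rank-2 nonnegative least squares;
   documents follow their dominant `H` row.  A node-splitting score —
   the product of modified NDCG values that discount top terms shared
   between the two children — decides which frontier leaf to split next,
   so the tree structure is detected automatically and need not be
   balanced.  A node's depth is its *degree level* (root = 1): lower
   means more prominent.
4. **Trends and themes** — per-term tweet-level frequencies (a topic's
   frequency is the number of tweets containing it, not token counts),
   frequency tables at a minimum count of 35 tweets, increase / decrease /
   stable classification between timepoints (raw counts or rates per
   10,000 unique tweets), and a deterministic keyword codebook mapping
   clusters to named themes under the UNAIDS core action principles and
   the Prevention / Treatment or Care / Support commitment areas.
5. **Synthetic corpora** — real World AIDS Day streams are not
   redistributable, so a generator plants a known topic hierarchy (anchor
   words per leaf topic, Zipfian background vocabulary, retweet
   duplication, heavy-tailed follower counts) and recovery is scored by
   adjusted Rand index and purity.

## Worked example

Simulate two "years" of tweets and run the whole pipeline:

```sh
hiertweet simulate --n-docs 400 --seed 1 --label wad2014 --out corpora
hiertweet simulate --n-docs 800 --seed 2 --label wad2015 --out corpora
hiertweet run --input-a corpora/wad2014.csv --input-b corpora/wad2015.csv \
              --max-leaves 4 --seed 7 --out-dir out
hiertweet render --tree out/tree_a.json --format text
```

which prints (stderr log, then the rendered tree):

```
[hiertweet:corpus_a] 560 messages, 400 unique
[hiertweet:cluster_a] 571 terms x 400 docs -> 4 leaves
[hiertweet:corpus_b] 1120 messages, 800 unique
[hiertweet:cluster_b] 1417 terms x 800 docs -> 4 leaves

node 0 (depth 1, 400 docs): worldaidsdai, topic1anchor0, hivawar, ...
  node 1 (depth 2, 91 docs): topic2anchor0, topic2anchor1, t2w05, ...
  node 2 (depth 2, 309 docs): topic0anchor1, topic1anchor0, ...
    node 3 (depth 3, 99 docs): topic3anchor1, topic3anchor0, t3w01, ...
    node 4 (depth 3, 210 docs): topic1anchor0, topic1anchor1, ...
      node 5 (depth 4, 99 docs): topic0anchor1, topic0anchor0, t0w09, ...
      node 6 (depth 4, 111 docs): topic1anchor0, topic1anchor1, t1w17, ...
```

The 560 messages are 400 unique documents plus 160 retweet duplicates;
each leaf isolates one planted topic (its anchor words head the top-term
list).  Comparing the clustering against the planted labels:

```sh
hiertweet evaluate --predicted out/labels_a.tsv \
                   --planted corpora/wad2014.labels.tsv
# {"ari": 1.0, "purity": 1.0}
```

`out/trends.tsv` classifies every frequent term (`new` here because the
background branch words only cross the 35-tweet threshold in the larger
second corpus):

```
topic_term  freq_a  freq_b  rate_a  rate_b  direction
branch0w0   0       36      0.0     450.0   new
branch0w1   0       58      0.0     725.0   new
```

Comparing theme prominence between the two encoded published World AIDS
Day hierarchies with the packaged codebook:

```python
from hiertweet.reference import reference_tree
from hiertweet.trends import default_codebook, theme_depth_table

table = theme_depth_table(reference_tree(2014), reference_tree(2015),
                          default_codebook())
```

```
                          theme  depth_a  depth_b  delta
                Combat HIV/AIDS        2        5      3
         Discrimination of PLWH     <NA>        3   <NA>
Impact of the HIV/AIDS Pandemic     <NA>        3   <NA>
               Prevent HIV/AIDS        4     <NA>   <NA>
    Recognition of the Pandemic        5        3     -2
```

A positive delta means the theme moved deeper — *Combat HIV/AIDS* dropped
3 degree levels (lost prominence), *Prevent HIV/AIDS* disappeared in the
second year, and *Discrimination of PLWH* newly emerged at degree 3.

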