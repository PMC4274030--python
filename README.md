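# seqdiv

Diversity-aware re-ranking and diversity measures for protein sequence
similarity search results.

BLAST and PSI-BLAST return the database sequences most similar to a query —
and those hits are usually also highly similar to *each other*. For
exploratory tasks (finding all regions of a query with detectable homology,
surveying the functional neighbourhood of a protein) a user is better served
by a small subset of hits that are individually significant but mutually
different. `seqdiv` post-processes a finished search report into such a
diversity-ranked subset, and provides measures to quantify how diverse a
result set is.

## What it computes

All operations work on a **query-anchored star alignment**: each high-scoring
pair (HSP) of the report becomes one row over a shared column space (every
query position, plus columns for insertions the hits open in the query).
Positions a fragment does not touch are marked with a distinct *non-aligned*
symbol `.`, separate from the alignment gap `-`.

**Greedy diversification.** Starting from the top hit, repeatedly add the
fragment most different from the set chosen so far, under one of two Div
functions:

- *bit*: fragments are binary masks b of aligned query columns; a candidate
  scores the average Hamming distance `mean_{c∈chosen} Σ_j b_j ⊕ c_j`
  (average linkage; single/complete available).
- *entropy*: a candidate scores the column-wise Shannon entropy of
  chosen ∪ {candidate}, computed over residues (20 amino acids + gap +
  non-aligned) and over bits {0,1}, each normalized by its uniform-column
  maximum `n_columns · log₂ |alphabet|` and averaged.

The selection is incremental: the top-k ranking is always a prefix of the
top-(k+1) ranking.

**Rao quadratic-entropy sequence diversity.** Per column,
`H = Σ_i Σ_j p_i p_j d_ij` with p the column symbol frequencies and d a
dissimilarity matrix derived from BLOSUM62 (per-row score-deficit transform
scaled to [0, 19], symmetrized by averaging; gap at distance 9.5 from
residues by default and non-aligned at twice that). The set's diversity is
the mean of H over columns: 0 iff all rows are identical, at most the
largest pairwise distance (19).

**Query coverage.** Fraction of query positions aligned by at least one
chosen fragment, and the coverage curve over ranking prefixes.

**Functional dissimilarity.** Wang semantic similarity of GO
molecular-function annotations (S-value propagation with is-a weight 0.8,
best-match-average protein aggregation); a result set's functional
dissimilarity is the mean of 1 − similarity over protein pairs.

## Worked example

The package ships a deterministic fixture generator that mimics a typical
redundant report: near-identical hits clustered on one query region, plus a
few fragments tiling the rest.

```sh
seqdiv fixture --seed 4 --query-length 120 --n-redundant 6 --n-tilers 2 \
    --tile-overlap 0 --mutation-rate 0.05 \
    --query-out query.fasta --hits-out hits.tsv
seqdiv diversify --query query.fasta --hits hits.tsv \
    --method bit -k 4 --alignment-out star.fasta --output ranked.tsv
cat ranked.tsv
```

```
new_rank  original_rank  subject_id    method  selection_score  qstart  qend  evalue  score
1         1              redundant_01  bit                      1       60    1e-29   198.0
2         7              tiler_01      bit     90.0             61      90    1e-23   186.0
3         8              tiler_02      bit     75.0             91      120   1e-22   184.0
4         2              redundant_02  bit     60.0             1       60    1e-28   196.0
```

The seed is the report's top hit (covering query positions 1–60). The next
two picks are the tilers from the bottom of the report — `tiler_01` wins
step 2 with selection score 90, its Hamming distance to the seed (60 mask
positions where only the seed aligns + 30 where only the tiler does) — so
the top-3 already cover the whole query, which the original order only
manages at rank 8. Evaluating the whole set:

```sh
seqdiv evaluate --measure rao --alignment star.fasta
```

```
measure  value             n_rows  n_columns  gap_distance
rao      5.93308894519832  8       120        9.5
```

i.e. an average per-column quadratic entropy of 5.93 on the 0–19 scale of
the BLOSUM62-derived distances — well above 0 (all rows identical) because
the tilers disagree with the cluster about which half of the query they
align.

The same operations are available as a library:

```python
import seqdiv as sd

query, hits = sd.generate_fixture(sd.FixtureSpec(seed=4))
star = sd.build_star_alignment(query, hits)
ranking = sd.diversify(star.fragments, k=4, method="entropy")
sd.rao_diversity(star.rows(), sd.default_distance_matrix())
```

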