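# Methods

## Problem setting

A protein similarity search (blastp, PSI-BLAST) against a large database
returns hits ordered by statistical significance. Because databases are
redundant and homologous families are deep, the top of the list is typically
dominated by near-duplicates of a single alignment. `seqdiv` treats
*diversification* as a post-processing step: re-rank the finished report so
that a short prefix of the new order contains fragments that are similar to
the query but mutually different — covering different query regions, or the
same region with different residues.

The unit of diversification is the **aligned fragment** (one HSP), not the
full database sequence: a subject with two HSPs contributes two independent
fragments, because each aligned region carries its own information about the
query.

## Star alignment

All fragments are projected into one coordinate system anchored on the
query: one column per query position, plus insertion columns where some hit
aligns extra subject residues between two query positions. When several hits
insert different numbers of residues after the same position, the column
block takes the longest run and shorter runs are left-aligned and padded
with gaps — a deterministic, input-order-independent rule.

Rows use three symbol classes: amino acids, the alignment gap `-` (inside
the fragment's HSP span), and the non-aligned symbol `.` (outside the span).
Keeping `.` distinct from `-` matters for the diversity measure below: a
region the aligner chose to bridge with a gap is evidence of relatedness; a
region the fragment never touched is not. Input coordinates are 1-based
inclusive (BLAST convention); internally everything is 0-based.

A fragment's bit mask has 1 wherever its row holds an amino acid, 0 at gaps
and non-aligned columns.

## Greedy diversification

Selection is greedy: seed with the report's first fragment (the search
tool's best hit, whose relevance we keep), then repeatedly score every
unchosen fragment against the chosen set and append the argmax, until k
fragments are chosen. Ties go to the lower original rank, preserving the
search tool's relevance order; this also makes the output invariant to input
permutations. The greedy loop is incremental by construction, so a top-k
ranking is a prefix of any longer one, and k is only a stopping point.

Two Div functions are shipped:

- **Bit diversification** — the mean Hamming (XOR) distance between the
  candidate's bit mask and each chosen mask (average linkage). Single and
  complete linkage (min/max) are available behind a flag, but average
  linkage is the default as it gives the most stable behaviour on
  cluster-plus-tiler inputs.
- **Entropy diversification** — the total per-column Shannon entropy of
  chosen ∪ {candidate}, computed twice: over the residue alphabet (20 amino
  acids + gap + non-aligned, 22 symbols) and over the bit alphabet {0, 1}.
  Each total is normalized by its uniform-column upper bound,
  `n_columns · log₂ |alphabet|`, and the two ratios are averaged. The
  normalization makes the two scales commensurable; since both use the same
  bound structure the ranking is unaffected by whether totals or per-column
  means are used. Logarithms are base 2 throughout (the normalized ratios
  are base-independent). The query row itself is excluded: it is constant
  across candidates and would shift every score equally.

Numerical note: both entropy flavours run through one scalar column-entropy
routine, so two candidates that are column permutations of each other score
bit-for-bit identically and ties resolve by rank rather than by floating-
point rounding.

## Rao quadratic-entropy diversity

To *evaluate* a result set (not to drive selection — the simpler Div
functions above are deliberately cheaper), the package uses Rao's quadratic
entropy per column, `H = Σ_i Σ_j p_i p_j d_ij`, averaged over columns. It is
zero iff every column is uniform and bounded by the maximum pairwise
distance in d, and unlike plain Shannon entropy it weights disagreements by
how different the disagreeing symbols are.

### BLOSUM62 distance transform

The symbol distances come from BLOSUM62. A substitution score a_ij is first
turned into a raw per-row distance

    r_ij = (s − 1) · (a_ii − a_ij) / (a_ii − min_k a_ik),   s = 20,

the candidate's score deficit relative to the self-score, scaled so every
row spans [0, s − 1] = [0, 19]. Raw distances are asymmetric (each row is
normalized by its own range), so the final matrix is the average
(r_ij + r_ji)/2. This yields a symmetric dissimilarity matrix with zero
diagonal whose maximum is exactly 19, attained at residue pairs that are
mutually most dissimilar (e.g. W–N, D–W); the row-wise scaling expresses
that a score of −4 against tryptophan (self-score 11) and the same −4
against asparagine (self-score 6) are both "as dissimilar as this residue
gets". The transform accepts any substitution matrix whose rows peak on the
diagonal.

Two symbols are appended: the gap at a configurable distance from every
residue — default half the matrix maximum, 9.5 — and the non-aligned symbol
at twice the gap distance, so that "never aligned here" is maximally distant
(19) while an aligner-introduced gap stays intermediate. The gap/non-aligned
mutual distance is set to the gap distance (the intermediate value); their
diagonal is zero. All three choices are parameters of
`extend_with_special_symbols`.

## Query coverage

Coverage is the fraction of *query* positions (insertion columns excluded)
aligned by at least one fragment of a chosen subset; the coverage curve
reports it per ranking prefix, optionally dropping the first hit for
searches where the query itself is in the database. On
redundant-cluster-plus-tiler inputs the diversified rankings reach full
coverage with prefixes no longer — usually much shorter — than the original
order needs.

## Functional dissimilarity (GO)

Functional diversity is measured on molecular-function GO annotations with
Wang et al.'s semantic similarity. For a term A, semantic contributions
propagate from A up its ancestor DAG: S_A(A) = 1 and
S_A(t) = max_{t′ child of t} w_e · S_A(t′), evaluated children-before-
parents so diamonds take the best path rather than the sum; SV(A) = Σ S_A.
Term similarity is the shared semantic mass
Σ_{t common} (S_A(t) + S_B(t)) / (SV(A) + SV(B)). Edge weights default to
the published 0.8 (is-a) and 0.6 (part-of); molecular function effectively
uses only is-a. Protein similarity aggregates the cross-term matrix by
best-match average (max and plain average are selectable), and a result
set's functional dissimilarity is the mean of 1 − similarity over unordered
protein pairs; proteins without molecular-function annotations are excluded
before pairing. GAF input skips NOT-qualified rows and can optionally drop
IEA evidence.

## Synthetic fixtures

`generate_fixture` emulates the redundancy structure the diversifiers
target: a query of 120 residues (single-domain scale); 10 near-identical
fragments covering its first half, mutated at 5% per residue (cluster
members differing by a few substitutions, as near-duplicate database entries
do); and 4 fragments tiling the second half with 10% overlap. The report
order places the cluster first with monotonically decreasing scores,
mimicking a relevance ranking. A separate unstructured generator produces
random spans with substitutions, subject-side deletions and insertions for
property tests. What the fixtures do **not** emulate: realistic BLOSUM
substitution statistics, e-value distributions, compositional bias, or
multi-domain architectures — so passing tests demonstrate algorithmic
correctness and the qualitative coverage behaviour, not retrieval quality on
real databases.

All randomness flows from one seeded NumPy generator; identical spec and
seed give byte-identical outputs, which the CLI tests assert end-to-end.

## Problem sizes and tolerances

Oracle-equivalence checks run the greedy selections on 200 random fixtures
of up to 15 fragments over queries of up to 40 residues against brute-force
per-step argmax re-implementations, asserting identical orders; Rao
diversity is checked against a brute-force double loop at 1e-9 absolute.
Coverage dominance is asserted across 100 seeded cluster-plus-tiler
fixtures. These sizes exercise every code path (insertions, ties,
degenerate single-fragment sets) while keeping the whole suite in seconds.

## Known limitations

- Nucleotide and translated search modes are untested; the alphabet is
  the 20 amino acids (+ X in queries).
- HSPs of one subject are never merged; users who want per-subject
  diversification should pre-aggregate.
- The entropy normalization bound (uniform columns) is attainable only for
  sets of ≥ alphabet-size rows, so normalized scores are conservative for
  small sets; rankings are unaffected.
- Wang similarity is computed exactly (no caching across proteins beyond a
  call), which is fine at result-set scale but not for genome-wide
  all-vs-all use.
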