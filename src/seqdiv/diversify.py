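"""Greedy diversification of search results.

Both methods re-rank the aligned fragments by repeatedly appending the
candidate that is most different from the set chosen so far, seeded with
the first fragment of the original report (the search tool's top hit).
The selection is incremental: the top-k ranking is a prefix of the
top-(k+1) ranking, so k only bounds how far the loop runs.

*Bit diversification* treats each fragment as the binary mask of query
columns it aligns and scores a candidate by the average Hamming (XOR)
distance to the chosen set (average linkage; single/complete linkage are
available for comparison).

*Entropy diversification* scores a candidate by the Shannon entropy of the
star-alignment columns of the chosen set plus the candidate, computed both
at the residue level (20 amino acids + gap + non-aligned) and at the bit
level ({0, 1}); each total entropy is normalized by its uniform-column
upper bound, number of columns × log2(alphabet size), and the two
normalized entropies are averaged.  Logarithms are base 2 throughout; the
normalized ratios are base-independent.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .star import AMINO_ACIDS, GAP, NONALIGNED, AlignedFragment, SeqDivError

#: residue-level entropy alphabet: 20 amino acids, gap, non-aligned
RESIDUE_ALPHABET = tuple(AMINO_ACIDS) + (GAP, NONALIGNED)

LINKAGES = ("average", "single", "complete")
METHODS = ("bit", "entropy")


class ContractViolation(SeqDivError):
    """An operation was called outside its stated preconditions."""


def xor_difference(a, b) -> int:
    """Hamming distance between two equal-length binary vectors."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ContractViolation(
            f"bit vectors differ in length: {a.shape} vs {b.shape}"
        )
    return int(np.count_nonzero(a != b))


def bit_div(
    candidate: AlignedFragment,
    chosen: list[AlignedFragment],
    linkage: str = "average",
) -> float:
    """Difference between a candidate and the chosen set, on the bit masks.

    Average linkage (the default) is the mean Hamming distance to the
    chosen fragments; single/complete linkage take the min/max instead.
    """
    if not chosen:
        raise ContractViolation("chosen set is empty; the greedy loop seeds first")
    if linkage not in LINKAGES:
        raise ContractViolation(f"unknown linkage {linkage!r}")
    dists = [xor_difference(candidate.bits, c.bits) for c in chosen]
    if linkage == "average":
        return float(np.mean(dists))
    if linkage == "single":
        return float(min(dists))
    return float(max(dists))


def column_entropy(column, base: float = 2.0) -> float:
    """Shannon entropy of one alignment column.

    ``column`` is any iterable of symbols; probabilities are the empirical
    frequencies in the column.  A column uniform in one symbol has entropy
    zero; symbols absent from the column contribute nothing.
    """
    counts = Counter(column)
    n = sum(counts.values())
    if n == 0:
        raise ContractViolation("empty column")
    log = math.log2 if base == 2.0 else lambda x: math.log(x, base)
    return -sum((c / n) * log(c / n) for c in counts.values())


def _total_entropies(rows: list[AlignedFragment]) -> tuple[float, float]:
    """Sum of per-column entropies at residue level and at bit level.

    Both flavours go through the same scalar column routine so that
    candidates which are permutations of one another score bit-for-bit
    identically and ties resolve by rank, not by rounding.
    """
    n_cols = len(rows[0].symbols)
    e_aa = sum(
        column_entropy([r.symbols[j] for r in rows]) for j in range(n_cols)
    )
    bit_rows = [[int(b) for b in r.bits] for r in rows]
    e_bit = sum(
        column_entropy([br[j] for br in bit_rows]) for j in range(n_cols)
    )
    return e_aa, e_bit


def entropy_div(
    candidate: AlignedFragment,
    chosen: list[AlignedFragment],
    query=None,
) -> float:
    """Normalized joint entropy of the chosen set plus the candidate.

    Returns the average of the residue-level and bit-level total column
    entropies of ``chosen + [candidate]``, each normalized by its maximum
    (columns × log2 of the alphabet size).  Higher means the candidate
    makes the set more diverse.  The query defines the column space only;
    its constant row would shift every candidate equally and is excluded.
    """
    if not chosen:
        raise ContractViolation("chosen set is empty; the greedy loop seeds first")
    rows = list(chosen) + [candidate]
    n_cols = len(candidate.symbols)
    e_aa, e_bit = _total_entropies(rows)
    max_aa = n_cols * math.log2(len(RESIDUE_ALPHABET))
    max_bit = n_cols * 1.0  # log2(2)
    return (e_aa / max_aa + e_bit / max_bit) / 2.0


@dataclass
class DiversifiedRanking:
    """Ordered selection produced by the greedy loop.

    ``selection_scores[i]`` is the winning Div value at step ``i``; the
    seed (step 0) is not scored and carries NaN.
    """

    order: list[AlignedFragment]
    selection_scores: list[float]
    method: str
    linkage: str = "average"
    extras: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.order)

    def to_frame(self) -> pd.DataFrame:
        """Ranked table in the package's TSV layout."""
        return pd.DataFrame(
            {
                "new_rank": np.arange(1, len(self.order) + 1),
                "original_rank": [f.original_rank for f in self.order],
                "subject_id": [f.subject_id for f in self.order],
                "method": self.method,
                "selection_score": self.selection_scores,
                "qstart": [f.qstart for f in self.order],
                "qend": [f.qend for f in self.order],
                "evalue": [f.evalue for f in self.order],
                "score": [f.score for f in self.order],
            }
        )


def diversify(
    fragments: list[AlignedFragment],
    k: int,
    method: str = "bit",
    linkage: str = "average",
) -> DiversifiedRanking:
    """Greedy diverse top-k selection over aligned fragments.

    Seeds with the fragment of lowest original rank, then repeatedly scans
    every unchosen fragment, scores it against the chosen set with the
    requested Div function, and appends the argmax until ``min(k, n)``
    fragments are selected.  Ties in the argmax go to the lower original
    rank (the search tool's relevance order).  ``k`` larger than the input
    simply ranks everything.
    """
    if k < 1:
        raise ContractViolation(f"k must be >= 1, got {k}")
    if not fragments:
        raise ContractViolation("no fragments to diversify")
    if method not in METHODS:
        raise ContractViolation(f"unknown method {method!r}")

    remaining = sorted(fragments, key=lambda f: f.original_rank)
    chosen = [remaining.pop(0)]
    scores = [math.nan]
    while remaining and len(chosen) < k:
        best_i = 0
        best_score = -math.inf
        for i, cand in enumerate(remaining):
            if method == "bit":
                s = bit_div(cand, chosen, linkage=linkage)
            else:
                s = entropy_div(cand, chosen)
            # strict > keeps the earliest (lowest original rank) on ties
            if s > best_score:
                best_score = s
                best_i = i
        chosen.append(remaining.pop(best_i))
        scores.append(best_score)
    return DiversifiedRanking(
        order=chosen, selection_scores=scores, method=method, linkage=linkage
    )
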