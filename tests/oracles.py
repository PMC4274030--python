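"""Independent brute-force re-implementations used as test oracles.

Plain-Python, loop-based evaluations of the greedy selection, the column
entropies and the quadratic-entropy diversity; deliberately kept free of
any code from the package under test (beyond reading fragment fields).
"""

import math
from collections import Counter

RESIDUE_ALPHABET_SIZE = 22  # 20 amino acids + gap + non-aligned


def hamming(a, b):
    assert len(a) == len(b)
    return sum(1 for x, y in zip(a, b) if int(x) != int(y))


def bit_score(candidate, chosen, linkage="average"):
    dists = [hamming(candidate.bits, c.bits) for c in chosen]
    if linkage == "single":
        return min(dists)
    if linkage == "complete":
        return max(dists)
    return sum(dists) / len(dists)


def shannon(symbols):
    counts = Counter(symbols)
    n = len(symbols)
    return -sum((c / n) * math.log2(c / n) for c in counts.values())


def entropy_score(candidate, chosen):
    rows = [f.symbols for f in chosen] + [candidate.symbols]
    bit_rows = [[int(b) for b in f.bits] for f in chosen] + [
        [int(b) for b in candidate.bits]
    ]
    m = len(rows[0])
    e_aa = sum(shannon([r[j] for r in rows]) for j in range(m))
    e_bit = sum(shannon([r[j] for r in bit_rows]) for j in range(m))
    return (e_aa / (m * math.log2(RESIDUE_ALPHABET_SIZE)) + e_bit / m) / 2


def greedy(fragments, k, score_fn):
    """Step-by-step argmax selection; ties keep the earliest candidate
    in original-rank order."""
    remaining = sorted(fragments, key=lambda f: f.original_rank)
    chosen = [remaining.pop(0)]
    while remaining and len(chosen) < k:
        best_i, best_s = 0, -math.inf
        for i, f in enumerate(remaining):
            s = score_fn(f, chosen)
            if s > best_s:
                best_i, best_s = i, s
        chosen.append(remaining.pop(best_i))
    return chosen


def rao_brute(rows, dist_fn):
    """Mean per-column Σ_i Σ_j p_i p_j d(i,j) by explicit double loop
    over all ordered symbol pairs."""
    m = len(rows)
    n_cols = len(rows[0])
    total = 0.0
    for j in range(n_cols):
        column = [r[j] for r in rows]
        h = 0.0
        for a in set(column):
            for b in set(column):
                pa = column.count(a) / m
                pb = column.count(b) / m
                h += pa * pb * dist_fn(a, b)
        total += h
    return total / n_cols
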