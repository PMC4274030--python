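"""Diversity measures for evaluating a result set.

The sequence-level measure is Rao's quadratic entropy: for each star-
alignment column, H = Σ_i Σ_j p_i p_j d_ij over the symbols present, with
p the empirical column frequencies and d a symbol dissimilarity matrix;
the diversity of the set is the mean of H over columns.  It is zero iff
every column is uniform, and bounded above by the largest pairwise
distance in d.

The dissimilarity matrix is derived from BLOSUM62.  A substitution score
s(i,j) is turned into a raw per-row distance

    r(i,j) = (s - 1) * (a_ii - a_ij) / (a_ii - min_k a_ik),   s = 20,

i.e. the score deficit relative to the self-score, scaled so each row
spans [0, 19].  Raw distances are asymmetric (each row is scaled by its
own range); the final matrix averages r(i,j) and r(j,i), giving a
symmetric dissimilarity with zero diagonal whose maximum is exactly 19 —
attained by residue pairs that are mutually most dissimilar.

Two extra symbols join the 20 amino acids: the alignment gap ``-`` at a
configurable distance from every residue (default: half the matrix
maximum, 9.5), and the non-aligned symbol ``.`` at twice the gap distance
— a fragment that says nothing about a query region is farther from a
residue than a gap the aligner chose to open.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from importlib import resources

import numpy as np
from Bio.Align import substitution_matrices

from .star import AMINO_ACIDS, GAP, NONALIGNED, StarAlignment
from .diversify import ContractViolation


@dataclass(frozen=True)
class SymbolDistanceMatrix:
    """Symmetric, zero-diagonal dissimilarities over an ordered symbol set."""

    symbols: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1] or d.shape[0] != len(self.symbols):
            raise ContractViolation("distance matrix shape does not match symbols")
        if not np.allclose(d, d.T):
            raise ContractViolation("distance matrix is not symmetric")
        if not np.allclose(np.diag(d), 0.0):
            raise ContractViolation("distance matrix diagonal is not zero")
        if (d < 0).any():
            raise ContractViolation("distances must be non-negative")
        object.__setattr__(self, "d", d)

    @property
    def index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.symbols)}

    def distance(self, a: str, b: str) -> float:
        idx = self.index
        try:
            return float(self.d[idx[a], idx[b]])
        except KeyError as exc:
            raise ContractViolation(f"symbol {exc.args[0]!r} not in matrix") from exc

    @property
    def max_distance(self) -> float:
        return float(self.d.max())


@dataclass(frozen=True)
class DiversityScore:
    """Rao quadratic-entropy diversity of an aligned result set."""

    value: float
    n_rows: int
    n_columns: int


def load_blosum62() -> substitution_matrices.Array:
    """The bundled BLOSUM62 substitution matrix (plain-text NCBI layout)."""
    with resources.files("seqdiv").joinpath("data/blosum62.txt").open() as fh:
        return substitution_matrices.read(fh)


def blosum_to_distance(matrix=None) -> SymbolDistanceMatrix:
    """Convert a substitution (similarity) matrix into amino-acid distances.

    Defaults to the bundled BLOSUM62.  See the module docstring for the
    transform; the result covers the 20 canonical amino acids only — use
    :func:`extend_with_special_symbols` to add gap/non-aligned rows.
    """
    if matrix is None:
        matrix = load_blosum62()
    missing = [a for a in AMINO_ACIDS if a not in matrix.alphabet]
    if missing:
        raise ContractViolation(f"substitution matrix lacks residues {missing}")
    n = len(AMINO_ACIDS)
    sim = np.empty((n, n))
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            sim[i, j] = matrix[a, b]
    diag = np.diag(sim)
    if (diag <= sim.min(axis=1)).any():
        raise ContractViolation("substitution matrix rows must peak on the diagonal")
    scale = (n - 1) / (diag - sim.min(axis=1))
    raw = scale[:, None] * (diag[:, None] - sim)
    d = (raw + raw.T) / 2.0
    np.fill_diagonal(d, 0.0)  # exact zeros despite float averaging
    return SymbolDistanceMatrix(symbols=tuple(AMINO_ACIDS), d=d)


def extend_with_special_symbols(
    m: SymbolDistanceMatrix, gap_distance: float | None = None
) -> SymbolDistanceMatrix:
    """Add gap and non-aligned rows/columns to an amino-acid distance matrix.

    Gap-vs-residue distances are ``gap_distance`` (default: half the matrix
    maximum); non-aligned-vs-residue distances are twice that;
    gap-vs-non-aligned is ``gap_distance`` (intermediate); the diagonal
    stays zero.
    """
    if gap_distance is None:
        gap_distance = m.max_distance / 2.0
    if gap_distance <= 0:
        raise ContractViolation(f"gap_distance must be > 0, got {gap_distance}")
    n = len(m.symbols)
    d = np.zeros((n + 2, n + 2))
    d[:n, :n] = m.d
    d[n, :n] = d[:n, n] = gap_distance  # gap vs residues
    d[n + 1, :n] = d[:n, n + 1] = 2.0 * gap_distance  # non-aligned vs residues
    d[n, n + 1] = d[n + 1, n] = gap_distance
    return SymbolDistanceMatrix(symbols=m.symbols + (GAP, NONALIGNED), d=d)


def default_distance_matrix(gap_distance: float | None = None) -> SymbolDistanceMatrix:
    """BLOSUM62-derived distances extended with gap/non-aligned symbols."""
    return extend_with_special_symbols(blosum_to_distance(), gap_distance)


def column_probability(column, symbol: str) -> float:
    """Empirical frequency of ``symbol`` in one alignment column."""
    column = list(column)
    if not column:
        raise ContractViolation("empty column")
    return column.count(symbol) / len(column)


def rao_column_entropy(column, d: SymbolDistanceMatrix) -> float:
    """Quadratic entropy Σ_i Σ_j p_i p_j d_ij of one column."""
    column = list(column)
    if not column:
        raise ContractViolation("empty column")
    counts = Counter(column)
    n = len(column)
    idx = d.index
    syms = list(counts)
    for s in syms:
        if s not in idx:
            raise ContractViolation(f"symbol {s!r} not in distance matrix")
    p = np.array([counts[s] / n for s in syms])
    sub = d.d[np.ix_([idx[s] for s in syms], [idx[s] for s in syms])]
    return float(p @ sub @ p)


def rao_diversity(rows, d: SymbolDistanceMatrix) -> DiversityScore:
    """Mean per-column quadratic entropy of a set of aligned rows.

    ``rows`` may be fragments (their ``symbols`` are used) or plain
    strings; all rows must have equal length.
    """
    strings = [r if isinstance(r, str) else r.symbols for r in rows]
    if not strings:
        raise ContractViolation("need at least one row")
    n_cols = len(strings[0])
    if any(len(s) != n_cols for s in strings):
        raise ContractViolation("ragged rows: all rows must have equal length")
    value = float(
        np.mean(
            [rao_column_entropy([s[j] for s in strings], d) for j in range(n_cols)]
        )
    )
    return DiversityScore(value=value, n_rows=len(strings), n_columns=n_cols)


# ---------------------------------------------------------------------------
# query coverage


def _query_bits(fragment, star: StarAlignment | None):
    bits = np.asarray(fragment.bits, dtype=bool)
    if star is not None:
        bits = bits[star.query_column_mask]
    return bits


def coverage(chosen, star: StarAlignment | None = None, L: int | None = None) -> float:
    """Fraction of query positions aligned by at least one chosen fragment.

    Insertion columns are excluded: when ``star`` is given its query-column
    mask restricts the bit masks to real query positions; otherwise the
    bit masks are assumed to already live on query positions of length
    ``L`` (or their own length).
    """
    chosen = list(chosen)
    if not chosen:
        return 0.0
    masks = [_query_bits(f, star) for f in chosen]
    if L is None:
        L = len(masks[0])
    covered = np.zeros(L, dtype=bool)
    for m in masks:
        covered |= m[:L]
    return float(covered.sum() / L)


def coverage_curve(
    ranking, star: StarAlignment | None = None, exclude_first: bool = False
):
    """Coverage as a function of the fraction of the result set used.

    ``ranking`` is a DiversifiedRanking or any fragment sequence in rank
    order.  Returns a list of ``(fraction_used, coverage)`` pairs, one per
    prefix length; coverage is monotone non-decreasing.  ``exclude_first``
    drops the top-ranked entry before computing prefixes, for searches
    where the first hit is the query itself.
    """
    order = list(getattr(ranking, "order", ranking))
    if exclude_first:
        order = order[1:]
    if not order:
        raise ContractViolation("ranking is empty")
    masks = [_query_bits(f, star) for f in order]
    L = len(masks[0])
    covered = np.zeros(L, dtype=bool)
    curve = []
    for i, m in enumerate(masks, 1):
        covered |= m
        curve.append((i / len(masks), float(covered.sum() / L)))
    return curve


def prefixes_to_full_coverage(ranking, star: StarAlignment | None = None) -> int | None:
    """Smallest prefix length reaching the ranking's maximal coverage.

    Returns the number of fragments needed for the prefix coverage to
    reach the coverage of the whole set (full coverage when the set tiles
    the query).  None for an empty ranking.
    """
    curve = coverage_curve(ranking, star)
    target = curve[-1][1]
    for i, (_, cov) in enumerate(curve, 1):
        if cov >= target:
            return i
    return None
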