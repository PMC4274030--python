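"""Deterministic synthetic search-result fixtures.

The generator emulates the canonical redundancy pattern of a real
similarity search: a *redundant cluster* of near-identical fragments all
aligned to the same query region (the top of a typical report), followed
by a handful of *tilers* — fragments that together tile the rest of the
query with a controlled overlap.  On such a set a relevance-ordered
ranking wastes its prefix on the cluster, while a diversity-aware ranking
pulls the tilers forward; this is exactly the situation the greedy
diversifiers are designed for, reduced to desk scale.

All randomness comes from one seeded generator; the same spec and seed
give byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .star import AMINO_ACIDS, QueryRecord, RawHit, SeqDivError


class FixtureSpecError(SeqDivError):
    """The fixture specification is inconsistent (e.g. query too short)."""


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic query + result set.

    query_length
        residues in the query (default 120, a single-domain protein).
    n_redundant
        near-identical fragments clustered on the first ~half of the
        query (default 10).
    n_tilers
        fragments tiling the remaining query region (default 4).
    tile_overlap
        overlap between neighbouring tiles as a fraction of tile length
        (default 0.1).
    mutation_rate
        per-residue substitution probability within redundant fragments
        (default 0.05, near-identical cluster members).
    cluster_fraction
        fraction of the query covered by the redundant cluster (0.5);
        zero when ``n_redundant`` is zero so tilers span the whole query.
    """

    query_length: int = 120
    n_redundant: int = 10
    n_tilers: int = 4
    tile_overlap: float = 0.1
    mutation_rate: float = 0.05
    cluster_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.query_length < 1:
            raise FixtureSpecError("query_length must be >= 1")
        if self.n_redundant < 0 or self.n_tilers < 0:
            raise FixtureSpecError("counts must be >= 0")
        for name in ("tile_overlap", "mutation_rate", "cluster_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise FixtureSpecError(f"{name} must be in [0, 1], got {v}")


def _random_residues(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=n))


def _mutate(rng: np.random.Generator, s: str, rate: float) -> str:
    out = []
    for c in s:
        if rate > 0 and rng.random() < rate:
            choices = [a for a in AMINO_ACIDS if a != c]
            out.append(choices[rng.integers(len(choices))])
        else:
            out.append(c)
    return "".join(out)


def _tile_bounds(start: int, end: int, n: int, overlap: float):
    """1-based inclusive windows covering [start, end] with fractional overlap.

    Consecutive windows advance by (length − overlap·length), so the union
    is always contiguous; at zero overlap the windows partition the span
    exactly.
    """
    span = end - start + 1
    if n > span:
        raise FixtureSpecError(
            f"query too short: cannot tile {span} positions with {n} fragments"
        )
    if n == 1:
        return [(start, end)]
    w = max(1, round(span / (n - (n - 1) * overlap)))
    o = round(w * overlap)
    step = max(1, w - o)
    bounds = []
    for i in range(n):
        s = min(start + i * step, end)
        e = min(s + w - 1, end)
        bounds.append((s, e))
    bounds[-1] = (bounds[-1][0], end)
    return bounds


def generate_fixture(spec: FixtureSpec) -> tuple[QueryRecord, list[RawHit]]:
    """Build a query and a rank-ordered result set from a spec.

    The report order mimics a relevance ranking: redundant cluster
    members first (highest scores, lowest e-values), tilers after.  All
    fragments are gapless local alignments of the query.
    """
    rng = np.random.default_rng(spec.seed)
    query = QueryRecord(
        id=f"synthetic_query_{spec.seed}",
        residues=_random_residues(rng, spec.query_length),
    )
    L = spec.query_length
    cluster_end = (
        max(1, round(L * spec.cluster_fraction)) if spec.n_redundant else 0
    )

    hits: list[RawHit] = []
    rank = 0

    def add(subject_id: str, qstart: int, qend: int, subject: str) -> None:
        nonlocal rank
        rank += 1
        hits.append(
            RawHit(
                subject_id=subject_id,
                original_rank=rank,
                qstart=qstart,
                qend=qend,
                aligned_query=query.residues[qstart - 1 : qend],
                aligned_subject=subject,
                score=round(200.0 - 2.0 * rank, 1),
                evalue=float(f"{10.0 ** (-30 + rank):.3g}"),
            )
        )

    region = query.residues[:cluster_end]
    for i in range(spec.n_redundant):
        add(
            f"redundant_{i + 1:02d}",
            1,
            cluster_end,
            _mutate(rng, region, spec.mutation_rate),
        )

    if spec.n_tilers:
        tile_start = cluster_end + 1 if cluster_end < L else 1
        for i, (s, e) in enumerate(
            _tile_bounds(tile_start, L, spec.n_tilers, spec.tile_overlap)
        ):
            add(
                f"tiler_{i + 1:02d}",
                s,
                e,
                _mutate(rng, query.residues[s - 1 : e], spec.mutation_rate),
            )
    if not hits:
        raise FixtureSpecError("spec produces no fragments")
    return query, hits


def random_fixture(
    rng: np.random.Generator, max_fragments: int = 15, max_length: int = 40
) -> tuple[QueryRecord, list[RawHit]]:
    """An unstructured random fixture for property tests and oracles.

    Fragments get random spans, random substitutions, and occasional
    insertions relative to the query, so star alignments with insertion
    columns are exercised too.
    """
    L = int(rng.integers(8, max_length + 1))
    query = QueryRecord(id="rnd", residues=_random_residues(rng, L))
    n = int(rng.integers(1, max_fragments + 1))
    hits = []
    for rank in range(1, n + 1):
        qstart = int(rng.integers(1, L + 1))
        qend = int(rng.integers(qstart, L + 1))
        aligned_q = list(query.residues[qstart - 1 : qend])
        aligned_s = list(_mutate(rng, "".join(aligned_q), 0.2))
        # occasional subject-side deletion (gap in subject)
        if len(aligned_q) > 2 and rng.random() < 0.3:
            j = int(rng.integers(1, len(aligned_s) - 1))
            aligned_s[j] = "-"
        # occasional insertion (gap in query)
        if rng.random() < 0.3:
            j = int(rng.integers(1, len(aligned_q) + 1))
            aligned_q.insert(j, "-")
            aligned_s.insert(j, _random_residues(rng, 1))
        hits.append(
            RawHit(
                subject_id=f"s{rank}",
                original_rank=rank,
                qstart=qstart,
                qend=qend,
                aligned_query="".join(aligned_q),
                aligned_subject="".join(aligned_s),
                score=float(100 - rank),
                evalue=1e-5 * rank,
            )
        )
    return query, hits
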