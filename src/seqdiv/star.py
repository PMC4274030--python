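"""Query-anchored star alignment of local search hits.

A BLAST/PSI-BLAST report is a list of high-scoring pairs (HSPs), each a
pairwise local alignment between the query and a database sequence.  All
diversification and diversity measurement in this package operates on a
*star alignment*: a shared column coordinate system consisting of every
query position plus one column per insertion the hits open in the query.
Each HSP ("aligned fragment") becomes one row over these columns, and the
query itself is the center row.

Three symbols appear in a row besides the amino acids:

``-`` (GAP)
    a column inside the fragment's HSP span where the alignment opened a
    gap in the subject (or an insertion column the fragment does not use).
``.`` (NONALIGNED)
    a column outside the fragment's HSP span; the fragment says nothing
    about the query there.  Distinct from a gap on purpose: the Rao
    diversity measure assigns it twice the gap distance.

Coordinates are 1-based inclusive on input (BLAST convention) and 0-based
half-open internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Blast import NCBIXML

GAP = "-"
NONALIGNED = "."
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: residues accepted in a query sequence (X = unknown)
QUERY_ALPHABET = frozenset(AMINO_ACIDS + "X")


class SeqDivError(Exception):
    """Base class for all errors raised by this package."""


class ReportParseError(SeqDivError):
    """The search report is syntactically malformed."""


class UnusableReportError(SeqDivError):
    """The report parses but lacks the aligned sequence strings."""


class CoordinateError(SeqDivError):
    """Hit coordinates are inconsistent or exceed the query length."""


@dataclass(frozen=True)
class QueryRecord:
    """The searched query sequence."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise CoordinateError("query sequence is empty")
        bad = set(self.residues.upper()) - QUERY_ALPHABET
        if bad:
            raise CoordinateError(
                f"query {self.id!r} contains non-amino-acid symbols: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class RawHit:
    """One HSP from a search report, before projection onto the query.

    ``qstart``/``qend`` are 1-based inclusive query coordinates;
    ``aligned_query``/``aligned_subject`` are the gapped alignment strings
    of equal length.
    """

    subject_id: str
    original_rank: int
    qstart: int
    qend: int
    aligned_query: str
    aligned_subject: str
    score: float
    evalue: float

    def __post_init__(self) -> None:
        if len(self.aligned_query) != len(self.aligned_subject):
            raise CoordinateError(
                f"hit {self.subject_id!r}: aligned query and subject lengths differ"
            )
        if self.qstart < 1 or self.qend < self.qstart:
            raise CoordinateError(
                f"hit {self.subject_id!r}: bad query coordinates "
                f"{self.qstart}..{self.qend}"
            )
        n_res = sum(1 for c in self.aligned_query if c != GAP)
        if n_res != self.qend - self.qstart + 1:
            raise CoordinateError(
                f"hit {self.subject_id!r}: aligned_query has {n_res} residues "
                f"but coordinates span {self.qend - self.qstart + 1}"
            )
        if self.evalue < 0:
            raise CoordinateError(f"hit {self.subject_id!r}: negative e-value")


@dataclass(frozen=True)
class AlignedFragment:
    """One search hit projected onto the star-alignment column space.

    ``bits[j] == 1`` iff ``symbols[j]`` is an amino acid, i.e. the fragment
    aligns a subject residue to that column; gap and non-aligned columns
    are 0.
    """

    subject_id: str
    symbols: str
    bits: np.ndarray
    original_rank: int
    score: float
    evalue: float
    qstart: int
    qend: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "bits", np.asarray(self.bits, dtype=np.uint8))

    @property
    def row_id(self) -> str:
        """Unique row label (a subject may contribute several HSPs)."""
        return f"{self.subject_id}|{self.original_rank}"


@dataclass
class StarAlignment:
    """The query plus all fragments over a shared column coordinate system.

    ``columns`` holds one descriptor per column: ``(p, 0)`` is query
    position ``p`` (1-based) and ``(p, k)`` with ``k >= 1`` is the k-th
    insertion column after position ``p`` (``p == 0`` for insertions before
    the first position).
    """

    query: QueryRecord
    columns: list[tuple[int, int]]
    query_row: str
    fragments: list[AlignedFragment] = field(default_factory=list)

    @property
    def n_columns(self) -> int:
        return len(self.columns)

    @property
    def query_column_mask(self) -> np.ndarray:
        """Boolean mask selecting the real query positions (offset-0 columns)."""
        return np.array([off == 0 for _, off in self.columns], dtype=bool)

    def rows(self) -> list[str]:
        return [f.symbols for f in self.fragments]


# ---------------------------------------------------------------------------
# report parsing


def parse_blast_xml(stream) -> list[RawHit]:
    """Read a BLAST XML report (outfmt 5) into a flat list of hits.

    Every HSP becomes its own :class:`RawHit` (a subject with several HSPs
    contributes several fragments); ``original_rank`` follows report order.
    """
    try:
        records = list(NCBIXML.parse(stream))
    except ValueError as exc:
        raise ReportParseError(f"not a BLAST XML report: {exc}") from exc
    except Exception as exc:  # expat errors carry the offending element/line
        raise ReportParseError(f"malformed BLAST XML: {exc}") from exc
    hits: list[RawHit] = []
    rank = 0
    for record in records:
        for alignment in record.alignments:
            subject_id = alignment.hit_id or alignment.hit_def.split()[0]
            for hsp in alignment.hsps:
                if not hsp.query or not hsp.sbjct:
                    raise UnusableReportError(
                        f"hit {subject_id!r}: report lacks Hsp_qseq/Hsp_hseq "
                        "aligned strings"
                    )
                rank += 1
                hits.append(
                    RawHit(
                        subject_id=subject_id,
                        original_rank=rank,
                        qstart=hsp.query_start,
                        qend=hsp.query_end,
                        aligned_query=hsp.query,
                        aligned_subject=hsp.sbjct,
                        score=float(hsp.bits if hsp.bits is not None else hsp.score),
                        evalue=float(hsp.expect),
                    )
                )
    return hits


#: tabular columns this package understands; qseq/sseq are the aligned strings
TABULAR_DEFAULT_COLUMNS = (
    "sseqid",
    "qstart",
    "qend",
    "evalue",
    "bitscore",
    "qseq",
    "sseq",
)

_REQUIRED_TABULAR = {"qstart", "qend", "qseq", "sseq"}


def parse_blast_tabular(stream, column_spec=TABULAR_DEFAULT_COLUMNS) -> list[RawHit]:
    """Read BLAST tabular output whose columns are named by ``column_spec``.

    The custom tabular format must include ``qstart qend qseq sseq``
    (e.g. ``-outfmt "6 sseqid qstart qend evalue bitscore qseq sseq"``);
    the standard 12-column outfmt 6 lacks the aligned strings and is
    rejected, because fragment projection is impossible without them.
    """
    column_spec = tuple(column_spec)
    missing = _REQUIRED_TABULAR - set(column_spec)
    if missing:
        raise UnusableReportError(
            f"tabular column spec lacks required columns: {sorted(missing)}"
        )
    col = {name: i for i, name in enumerate(column_spec)}
    hits: list[RawHit] = []
    rank = 0
    for lineno, line in enumerate(stream, 1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < len(column_spec):
            raise ReportParseError(
                f"line {lineno}: expected {len(column_spec)} columns, "
                f"got {len(fields)}"
            )
        rank += 1
        hits.append(
            RawHit(
                subject_id=fields[col["sseqid"]] if "sseqid" in col else f"hit{rank}",
                original_rank=rank,
                qstart=int(fields[col["qstart"]]),
                qend=int(fields[col["qend"]]),
                aligned_query=fields[col["qseq"]],
                aligned_subject=fields[col["sseq"]],
                score=float(fields[col["bitscore"]]) if "bitscore" in col else 0.0,
                evalue=float(fields[col["evalue"]]) if "evalue" in col else 0.0,
            )
        )
    return hits


def read_query_fasta(path_or_stream) -> QueryRecord:
    """Read the (single) query sequence from a FASTA file."""
    records = list(SeqIO.parse(path_or_stream, "fasta"))
    if not records:
        raise ReportParseError("query FASTA contains no sequences")
    rec = records[0]
    return QueryRecord(id=rec.id, residues=str(rec.seq).upper())


# ---------------------------------------------------------------------------
# star-alignment construction


def _insertion_runs(hit: RawHit):
    """Yield (anchor query position, run length) for every gap run in the
    aligned query, plus the per-position subject symbols.

    Returns (placements, runs) where placements maps a 1-based query
    position to the subject symbol aligned there, and runs maps an anchor
    position p to the list of subject symbols inserted after p.
    """
    placements: dict[int, str] = {}
    runs: dict[int, list[str]] = {}
    qpos = hit.qstart - 1  # last consumed query position, 1-based
    for qc, sc in zip(hit.aligned_query, hit.aligned_subject):
        if qc == GAP:
            runs.setdefault(qpos, []).append(sc)
        else:
            qpos += 1
            placements[qpos] = sc
    return placements, runs


def build_star_alignment(query: QueryRecord, hits: list[RawHit]) -> StarAlignment:
    """Project all hits onto a single query-anchored coordinate system.

    The column set is every query position plus, for each query position
    ``p``, as many insertion columns as the longest insertion run any hit
    opens after ``p`` (shorter runs are left-aligned and padded with GAP).
    Fragment rows carry NONALIGNED outside their HSP span — never GAP.
    """
    L = len(query)
    per_hit = []
    max_run: dict[int, int] = {}
    for hit in hits:
        if hit.qend > L:
            raise CoordinateError(
                f"hit {hit.subject_id!r}: qend {hit.qend} exceeds query length {L}"
            )
        placements, runs = _insertion_runs(hit)
        per_hit.append((hit, placements, runs))
        for p, symbols in runs.items():
            max_run[p] = max(max_run.get(p, 0), len(symbols))

    columns: list[tuple[int, int]] = []
    for k in range(1, max_run.get(0, 0) + 1):
        columns.append((0, k))
    for p in range(1, L + 1):
        columns.append((p, 0))
        for k in range(1, max_run.get(p, 0) + 1):
            columns.append((p, k))
    col_index = {c: i for i, c in enumerate(columns)}

    query_row = "".join(
        query.residues[p - 1] if off == 0 else GAP for p, off in columns
    )

    fragments: list[AlignedFragment] = []
    for hit, placements, runs in per_hit:
        row = [NONALIGNED] * len(columns)
        placed: list[int] = []
        for p, sc in placements.items():
            i = col_index[(p, 0)]
            row[i] = sc.upper() if sc != GAP else GAP
            placed.append(i)
        for p, symbols in runs.items():
            for k, sc in enumerate(symbols, 1):
                i = col_index[(p, k)]
                row[i] = sc.upper() if sc != GAP else GAP
                placed.append(i)
        # inside the HSP span, unused insertion columns are gaps
        lo, hi = min(placed), max(placed)
        for i in range(lo, hi + 1):
            if row[i] == NONALIGNED:
                row[i] = GAP
        symbols_str = "".join(row)
        bits = np.fromiter(
            (1 if c not in (GAP, NONALIGNED) else 0 for c in symbols_str),
            dtype=np.uint8,
            count=len(symbols_str),
        )
        fragments.append(
            AlignedFragment(
                subject_id=hit.subject_id,
                symbols=symbols_str,
                bits=bits,
                original_rank=hit.original_rank,
                score=hit.score,
                evalue=hit.evalue,
                qstart=hit.qstart,
                qend=hit.qend,
            )
        )
    return StarAlignment(
        query=query, columns=columns, query_row=query_row, fragments=fragments
    )


# ---------------------------------------------------------------------------
# interchange format: aligned FASTA with '.'/'-' semantics


def write_star_fasta(star: StarAlignment, handle) -> None:
    """Write the star alignment as aligned FASTA (query first).

    Fragment headers carry ``rank``, ``score``, ``evalue``, ``qstart`` and
    ``qend`` as key=value pairs so a round trip is lossless.
    """
    close = False
    if isinstance(handle, str):
        handle = open(handle, "w")
        close = True
    try:
        handle.write(f">{star.query.id} query\n{star.query_row}\n")
        for f in star.fragments:
            handle.write(
                f">{f.subject_id} rank={f.original_rank} score={f.score:g} "
                f"evalue={f.evalue:g} qstart={f.qstart} qend={f.qend}\n"
                f"{f.symbols}\n"
            )
    finally:
        if close:
            handle.close()


def read_star_fasta(handle) -> StarAlignment:
    """Re-read an alignment written by :func:`write_star_fasta`."""
    if isinstance(handle, str):
        with open(handle) as fh:
            return read_star_fasta(fh)
    records = list(SeqIO.parse(handle, "fasta"))
    if not records:
        raise ReportParseError("star-alignment FASTA is empty")
    qrec = records[0]
    query_row = str(qrec.seq)
    residues = query_row.replace(GAP, "")
    query = QueryRecord(id=qrec.id, residues=residues)
    columns: list[tuple[int, int]] = []
    p = 0
    offset = 0
    for c in query_row:
        if c == GAP:
            offset += 1
            columns.append((p, offset))
        else:
            p += 1
            offset = 0
            columns.append((p, 0))
    fragments = []
    for rec in records[1:]:
        meta = dict(
            kv.split("=", 1) for kv in rec.description.split()[1:] if "=" in kv
        )
        symbols = str(rec.seq)
        if len(symbols) != len(columns):
            raise ReportParseError(
                f"row {rec.id!r} length {len(symbols)} != {len(columns)} columns"
            )
        bits = np.fromiter(
            (1 if c not in (GAP, NONALIGNED) else 0 for c in symbols),
            dtype=np.uint8,
            count=len(symbols),
        )
        fragments.append(
            AlignedFragment(
                subject_id=rec.id,
                symbols=symbols,
                bits=bits,
                original_rank=int(meta.get("rank", len(fragments) + 1)),
                score=float(meta.get("score", 0.0)),
                evalue=float(meta.get("evalue", 0.0)),
                qstart=int(meta.get("qstart", 1)),
                qend=int(meta.get("qend", len(residues))),
            )
        )
    return StarAlignment(
        query=query, columns=columns, query_row=query_row, fragments=fragments
    )


def hits_to_tabular(hits: list[RawHit], handle) -> None:
    """Write hits in the custom tabular format this package reads back."""
    close = False
    if isinstance(handle, str):
        handle = open(handle, "w")
        close = True
    try:
        for h in hits:
            handle.write(
                f"{h.subject_id}\t{h.qstart}\t{h.qend}\t{h.evalue:g}\t"
                f"{h.score:g}\t{h.aligned_query}\t{h.aligned_subject}\n"
            )
    finally:
        if close:
            handle.close()
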