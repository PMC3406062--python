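"""Global pairwise alignment, percent identity and reference-database search.

Identity convention used throughout the package: the fraction of columns
with identical bases among the alignment columns outside the terminal-gap
spans.  Internal gap columns count as mismatches; terminal gaps (free by
default, see :class:`AlignmentParams`) are excluded from the denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._gotoh import OP_DIAG, OP_LEFT, OP_UP, _align_kernel

__all__ = [
    "AlignmentParams",
    "Alignment",
    "RefDb",
    "MatchResult",
    "global_align",
    "percent_identity",
    "aligning_fraction",
    "pairwise_identity",
    "best_match",
    "search_databases",
    "match_profile",
    "match_single_cells",
    "reverse_complement",
    "encode",
    "DB_CATEGORIES",
]

DB_CATEGORIES = frozenset(
    {"comprehensive", "sequenced_all", "sequenced_human", "cultured_named", "cultured_unnamed"}
)

_IUPAC = b"ACGTRYSWKMBDHVN"
_VALID = np.zeros(256, dtype=bool)
_VALID[np.frombuffer(_IUPAC, dtype=np.uint8)] = True

_RC = {"A": "T", "C": "G", "G": "C", "T": "A", "R": "Y", "Y": "R", "S": "S",
       "W": "W", "K": "M", "M": "K", "B": "V", "V": "B", "D": "H", "H": "D",
       "N": "N"}


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring for affine-gap global alignment.

    A gap run of length L costs ``gap_open + (L - 1) * gap_extend``.  With
    ``end_gaps_free`` terminal gaps score zero (semi-global alignment), so a
    sub-region amplicon is not penalized for being shorter than a full-length
    reference.
    """

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -2.0
    gap_extend: float = -1.0
    end_gaps_free: bool = True

    def __post_init__(self) -> None:
        if self.gap_open >= 0 or self.gap_extend >= 0:
            raise ValueError("gap penalties must be negative")
        if self.match <= self.mismatch:
            raise ValueError("match score must exceed mismatch score")


DEFAULT_PARAMS = AlignmentParams()


@dataclass
class Alignment:
    """A pairwise global alignment: gapped strings plus terminal-gap spans.

    ``lead_cols`` / ``trail_cols`` count the alignment columns before the
    first and after the last substitution column; these are the terminal-gap
    spans excluded from identity and aligning-fraction denominators.
    """

    aligned_a: str
    aligned_b: str
    score: float
    lead_cols: int
    trail_cols: int

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings must have equal length")

    @property
    def length(self) -> int:
        return len(self.aligned_a)


@dataclass(frozen=True)
class RefDb:
    """A categorized 16S reference collection (ordered records)."""

    name: str
    category: str
    records: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if self.category not in DB_CATEGORIES:
            raise ValueError(
                f"unknown database category {self.category!r}; "
                f"expected one of {sorted(DB_CATEGORIES)}"
            )

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class MatchResult:
    query_id: str
    db_name: str
    ref_id: str
    identity: float
    aligning_fraction: float


def encode(seq: str) -> np.ndarray:
    """Uppercase a DNA string and encode it as a uint8 array, validating IUPAC."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8).copy()
    if arr.size == 0:
        raise ValueError("empty sequence")
    if not _VALID[arr].all():
        bad = chr(arr[~_VALID[arr]][0])
        raise ValueError(f"non-IUPAC character {bad!r} in sequence")
    return arr


def reverse_complement(seq: str) -> str:
    return "".join(_RC[c] for c in reversed(seq.upper()))


def _ops_stats(ops: np.ndarray, a: np.ndarray, b: np.ndarray):
    """Per-alignment tallies from the op path.

    Returns (lead, trail, n_ident, n_counted, n_a_in, n_b_in) where n_a_in /
    n_b_in count each sequence's bases inside the non-terminal region.
    """
    L = ops.shape[0]
    diag = ops == OP_DIAG
    idx = np.flatnonzero(diag)
    if idx.size == 0:
        return L, 0, 0, 0, 0, 0
    lead = int(idx[0])
    trail = int(L - idx[-1] - 1)
    ai = np.cumsum(ops != OP_LEFT) - 1  # index into a per column (valid on non-LEFT)
    bi = np.cumsum(ops != OP_UP) - 1
    ident = int(np.count_nonzero(a[ai[idx]] == b[bi[idx]]))
    mid = slice(lead, L - trail)
    n_counted = L - lead - trail
    n_a_in = int(np.count_nonzero(ops[mid] != OP_LEFT))
    n_b_in = int(np.count_nonzero(ops[mid] != OP_UP))
    return lead, trail, ident, n_counted, n_a_in, n_b_in


def _align_codes(a: np.ndarray, b: np.ndarray, params: AlignmentParams):
    return _align_kernel(
        a, b, float(params.match), float(params.mismatch),
        float(params.gap_open), float(params.gap_extend), params.end_gaps_free,
    )


def global_align(a: str, b: str, params: AlignmentParams = DEFAULT_PARAMS) -> Alignment:
    """Optimal affine-gap global alignment of two DNA sequences.

    Traceback ties prefer substitution columns, then gaps in ``b``, then gaps
    in ``a``, so the result is deterministic.
    """
    ca, cb = encode(a), encode(b)
    score, ops = _align_codes(ca, cb, params)
    lead, trail, *_ = _ops_stats(ops, ca, cb)
    ia = ib = 0
    out_a = []
    out_b = []
    sa, sb = a.upper(), b.upper()
    for op in ops:
        if op == OP_DIAG:
            out_a.append(sa[ia]); ia += 1
            out_b.append(sb[ib]); ib += 1
        elif op == OP_UP:
            out_a.append(sa[ia]); ia += 1
            out_b.append("-")
        else:
            out_a.append("-")
            out_b.append(sb[ib]); ib += 1
    return Alignment("".join(out_a), "".join(out_b), float(score), lead, trail)


def percent_identity(aln: Alignment) -> float:
    """Identical columns / columns outside the terminal-gap spans, in [0, 1].

    The denominator is floored at the shorter (ungapped) sequence length.
    For homologous or contained pairs this is a no-op; for unrelated pairs it
    prevents the free-end-gap optimum -- a tiny perfect overlap with nearly
    everything in terminal gaps -- from reporting a spuriously high identity.
    """
    lo, hi = aln.lead_cols, aln.length - aln.trail_cols
    len_a = sum(1 for c in aln.aligned_a if c != "-")
    len_b = sum(1 for c in aln.aligned_b if c != "-")
    denom = max(hi - lo, min(len_a, len_b))
    if denom <= 0:
        raise ValueError("alignment has no columns outside terminal gaps")
    n_id = 0
    for x, y in zip(aln.aligned_a[lo:hi], aln.aligned_b[lo:hi]):
        if x == y and x != "-":
            n_id += 1
    return n_id / denom


def aligning_fraction(aln: Alignment, query_length: int) -> float:
    """Fraction of query (sequence ``a``) bases inside the aligned region."""
    if query_length <= 0:
        raise ValueError("query_length must be positive")
    lo, hi = aln.lead_cols, aln.length - aln.trail_cols
    n_in = sum(1 for c in aln.aligned_a[lo:hi] if c != "-")
    return min(n_in / query_length, 1.0)


def pairwise_identity(
    a, b, params: AlignmentParams = DEFAULT_PARAMS, with_fraction: bool = False
):
    """Fast identity between two sequences (strings or pre-encoded arrays).

    This is the hot path used by clustering and database search; it skips
    building the gapped strings.  With ``with_fraction`` also returns the
    aligning fraction of ``a``.

    The pair is aligned in a canonical orientation so the identity value is
    exactly symmetric in its two arguments (co-optimal degenerate alignments
    of unrelated pairs would otherwise make it orientation-dependent).
    """
    ca = a if isinstance(a, np.ndarray) else encode(a)
    cb = b if isinstance(b, np.ndarray) else encode(b)
    swapped = (ca.shape[0], ca.tobytes()) > (cb.shape[0], cb.tobytes())
    first, second = (cb, ca) if swapped else (ca, cb)
    _, ops = _align_codes(first, second, params)
    _, _, n_ident, n_counted, n_a_in, n_b_in = _ops_stats(ops, first, second)
    denom = max(n_counted, min(ca.shape[0], cb.shape[0]))
    ident = n_ident / denom if denom else 0.0
    if with_fraction:
        n_query_in = n_b_in if swapped else n_a_in
        return ident, min(n_query_in / ca.shape[0], 1.0)
    return ident


def match_profile(query, ref, params: AlignmentParams = DEFAULT_PARAMS) -> np.ndarray:
    """Boolean per-query-position match indicators against ``ref``.

    Position p is True when the query base is aligned to an identical
    reference base.  Used by the chimera model.
    """
    cq = query if isinstance(query, np.ndarray) else encode(query)
    cr = ref if isinstance(ref, np.ndarray) else encode(ref)
    _, ops = _align_codes(cq, cr, params)
    prof = np.zeros(cq.shape[0], dtype=bool)
    qi = np.cumsum(ops != OP_LEFT) - 1
    ri = np.cumsum(ops != OP_UP) - 1
    diag = np.flatnonzero(ops == OP_DIAG)
    hits = diag[cq[qi[diag]] == cr[ri[diag]]]
    prof[qi[hits]] = True
    return prof


def best_match(
    query_id: str,
    query,
    db: RefDb,
    params: AlignmentParams = DEFAULT_PARAMS,
) -> MatchResult:
    """Best hit of a query in one database: max identity, first record wins ties."""
    if len(db) == 0:
        raise ValueError(f"reference database {db.name!r} is empty")
    cq = query if isinstance(query, np.ndarray) else encode(query)
    best_id = -1.0
    best_frac = 0.0
    best_ref = ""
    for ref_id, ref_seq in db.records:
        ident, frac = pairwise_identity(cq, encode(ref_seq), params, with_fraction=True)
        if ident > best_id:
            best_id, best_frac, best_ref = ident, frac, ref_id
    return MatchResult(query_id, db.name, best_ref, best_id, best_frac)


def search_databases(
    queries: Sequence[tuple[str, str]],
    dbs: Mapping[str, RefDb],
    params: AlignmentParams = DEFAULT_PARAMS,
) -> pd.DataFrame:
    """All-queries-vs-all-databases best-hit table (one row per query x db)."""
    rows = []
    for qid, qseq in queries:
        cq = encode(qseq)
        for db in dbs.values():
            m = best_match(qid, cq, db, params)
            rows.append((m.query_id, m.db_name, db.category, m.ref_id,
                         m.identity, m.aligning_fraction))
    return pd.DataFrame(
        rows,
        columns=["query_id", "db_name", "category", "ref_id", "identity",
                 "aligning_fraction"],
    )


def match_single_cells(
    cell_reads: Mapping[str, Sequence[tuple[str, str]]],
    otu_db: RefDb,
    id_threshold: float,
    params: AlignmentParams = DEFAULT_PARAMS,
    search_reverse_complement: bool = True,
) -> pd.DataFrame:
    """Assign each single cell to its best OTU.

    Per read the best OTU is found by identity (both strands when
    ``search_reverse_complement``); per cell the read with the highest
    aligning fraction is used (ties: higher identity, then read order).
    """
    rows = []
    for cell_id, reads in cell_reads.items():
        if not reads:
            raise ValueError(f"cell {cell_id!r} has no reads")
        picked = None
        for order, (read_id, seq) in enumerate(reads):
            candidates = [seq]
            if search_reverse_complement:
                candidates.append(reverse_complement(seq))
            hit = None
            for s in candidates:
                m = best_match(read_id, s, otu_db, params)
                if hit is None or m.identity > hit.identity:
                    hit = m
            key = (hit.aligning_fraction, hit.identity, -order)
            if picked is None or key > picked[0]:
                picked = (key, hit)
        hit = picked[1]
        rows.append((cell_id, hit.query_id, hit.ref_id, hit.identity,
                     hit.aligning_fraction, hit.identity >= id_threshold))
    return pd.DataFrame(
        rows,
        columns=["cell_id", "read_id", "otu_id", "identity",
                 "aligning_fraction", "above_threshold"],
    )
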