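"""Greedy abundance-ordered consensus clustering of amplicon reads into OTUs.

Reads are dereplicated and visited from most to least abundant (ties broken
by sequence order).  Each sequence joins the first existing cluster whose
*current consensus* it matches at or above the identity threshold, otherwise
it founds a new cluster.  Consensus sequences are column-majority votes over
members aligned to the cluster seed.  After the greedy pass all consensi are
recomputed and a single re-recruitment pass re-assigns every sequence; small
clusters are then dissolved into the unincorporated pool.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import align
from ._gotoh import OP_DIAG, OP_LEFT, OP_UP
from .align import Alignment, AlignmentParams, encode
from .io import ReadSet, write_fasta

__all__ = [
    "ClusterParams",
    "Otu",
    "cluster_reads",
    "consensus_sequence",
    "incorporation_summary",
    "rank_abundance",
    "write_cluster_outputs",
]

_PREFILTER_K = 12
# lowest threshold at which a shared 12-mer is guaranteed between any two
# sequences matching at >= threshold over >= 12 alignment columns
_PREFILTER_MIN_THRESHOLD = 2 * _PREFILTER_K / (2 * _PREFILTER_K + 1)
_PREFILTER_MIN_LEN = 100

_CODE4 = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _CODE4[_b] = _i


@dataclass(frozen=True)
class ClusterParams:
    identity_threshold: float = 0.97
    min_cluster_size: int = 2
    kmer_prefilter: bool = True

    def __post_init__(self) -> None:
        if not 0.5 < self.identity_threshold <= 1.0:
            raise ValueError("identity_threshold must be in (0.5, 1]")
        if self.min_cluster_size < 1:
            raise ValueError("min_cluster_size must be >= 1")


@dataclass
class Otu:
    otu_id: str
    region: str
    consensus: str
    n_reads: int
    per_sample_counts: dict[str, int]
    member_read_ids: list[str]

    def __post_init__(self) -> None:
        if not self.consensus:
            raise ValueError("OTU consensus must be nonempty")
        if self.n_reads != sum(self.per_sample_counts.values()):
            raise ValueError("n_reads does not match per-sample counts")
        if self.n_reads != len(self.member_read_ids):
            raise ValueError("n_reads does not match member count")


def consensus_sequence(alignments: Sequence[Alignment],
                       weights: Sequence[float] | None = None) -> str:
    """Column-majority consensus over members aligned to a common seed.

    Each alignment must have the seed as sequence ``a`` and a member as
    sequence ``b``.  Per seed position the weighted majority symbol wins,
    ties go to the seed base, and positions whose majority is a gap are
    deleted.  Insertions relative to the seed are ignored.
    """
    if not alignments:
        raise ValueError("need at least one member alignment")
    if weights is None:
        weights = [1.0] * len(alignments)
    seed = alignments[0].aligned_a.replace("-", "")
    L = len(seed)
    votes = np.zeros((L, 5), dtype=float)
    sym = "ACGT-"
    for aln, w in zip(alignments, weights):
        if aln.aligned_a.replace("-", "") != seed:
            raise ValueError("all alignments must share the same seed sequence")
        pos = 0
        for ca, cb in zip(aln.aligned_a, aln.aligned_b):
            if ca == "-":  # insertion relative to seed
                continue
            votes[pos, sym.index(cb) if cb in "ACGT" else 4] += w
            pos += 1
    return _consensus_from_votes(votes, encode(seed))


def _consensus_from_votes(votes: np.ndarray, seed_codes: np.ndarray) -> str:
    seed4 = _CODE4[seed_codes]
    out = []
    sym = "ACGT-"
    for pos in range(votes.shape[0]):
        col = votes[pos]
        top = int(col.argmax())
        sb = int(seed4[pos])
        if 0 <= sb <= 3 and col[sb] >= col[top]:
            top = sb
        if top == 4:
            continue
        out.append(sym[top])
    if not out:  # degenerate; never expected with real members
        return "".join(sym[c] if c <= 3 else "N" for c in seed4)
    return "".join(out)


def _kmer_codes(codes: np.ndarray, k: int = _PREFILTER_K) -> np.ndarray:
    """Unique 2-bit-packed k-mer codes; windows with non-ACGT bases dropped."""
    vals = _CODE4[codes].astype(np.int64)
    n = vals.shape[0] - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    acc = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=bool)
    for i in range(k):
        win = vals[i : i + n]
        acc = (acc << 2) | np.where(win > 3, 0, win)
        bad |= win > 3
    return np.unique(acc[~bad])


class _Cluster:
    __slots__ = ("seed_codes", "consensus", "consensus_codes", "members",
                 "n_reads", "refresh_at")

    def __init__(self, seed_codes: np.ndarray, count: int, member: int):
        self.seed_codes = seed_codes
        self.consensus_codes = seed_codes
        self.consensus = seed_codes.tobytes().decode("ascii")
        self.members = [member]
        self.n_reads = count
        self.refresh_at = 2 * count


def _member_votes(seed_codes: np.ndarray, member_codes: np.ndarray, weight: float,
                  votes: np.ndarray, params: AlignmentParams) -> None:
    _, ops = align._align_codes(seed_codes, member_codes, params)
    si = np.cumsum(ops != OP_LEFT) - 1
    mi = np.cumsum(ops != OP_UP) - 1
    diag = ops == OP_DIAG
    up = ops == OP_UP
    np.add.at(votes, (si[diag], _CODE4[member_codes[mi[diag]]]), weight)
    np.add.at(votes, (si[up], 4), weight)


def _recompute_consensus(cluster: _Cluster, derep, params: AlignmentParams) -> None:
    votes = np.zeros((cluster.seed_codes.shape[0], 5), dtype=float)
    for idx in cluster.members:
        _, codes, _, count = derep[idx]
        _member_votes(cluster.seed_codes, codes, count, votes, params)
    cluster.consensus = _consensus_from_votes(votes, cluster.seed_codes)
    cluster.consensus_codes = encode(cluster.consensus)


def cluster_reads(
    reads: ReadSet,
    params: ClusterParams = ClusterParams(),
    aln_params: AlignmentParams = align.DEFAULT_PARAMS,
) -> tuple[list[Otu], list[str]]:
    """Cluster a single-region read set; returns (otus, unincorporated read ids)."""
    if len(reads) == 0:
        raise ValueError("read set is empty")
    regions = reads.regions
    if len(regions) > 1:
        raise ValueError(f"mixed region tags in read set: {sorted(regions)}")
    region = next(iter(regions))

    # dereplicate
    groups: dict[str, list[str]] = {}
    for rid, seq in reads.records:
        groups.setdefault(seq.upper(), []).append(rid)
    derep = [
        (seq, encode(seq), rids, len(rids))
        for seq, rids in sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    ]

    use_prefilter = (
        params.kmer_prefilter
        and params.identity_threshold >= _PREFILTER_MIN_THRESHOLD
    )
    thr = params.identity_threshold
    clusters: list[_Cluster] = []
    kmer_index: dict[int, list[int]] = {}
    derep_kmers: list[np.ndarray] = [
        _kmer_codes(codes) if use_prefilter else np.empty(0, dtype=np.int64)
        for _, codes, _, _ in derep
    ]

    def candidates(di: int, codes: np.ndarray) -> list[int]:
        if not use_prefilter or codes.shape[0] < _PREFILTER_MIN_LEN:
            return list(range(len(clusters)))
        seen: set[int] = set()
        for code in derep_kmers[di]:
            hits = kmer_index.get(int(code))
            if hits:
                seen.update(hits)
        return sorted(seen)

    def index_cluster(ci: int) -> None:
        if not use_prefilter:
            return
        for code in _kmer_codes(clusters[ci].consensus_codes):
            kmer_index.setdefault(int(code), []).append(ci)

    # greedy pass
    assignment = np.full(len(derep), -1, dtype=np.int64)
    for di, (seq, codes, rids, count) in enumerate(derep):
        placed = -1
        for ci in candidates(di, codes):
            cl = clusters[ci]
            if align.pairwise_identity(codes, cl.consensus_codes, aln_params) >= thr:
                placed = ci
                break
        if placed < 0 and use_prefilter:
            # short sequences bypass the index entirely (handled in candidates);
            # additionally check clusters whose consensus is too short to index
            for ci, cl in enumerate(clusters):
                if cl.consensus_codes.shape[0] >= _PREFILTER_MIN_LEN:
                    continue
                if align.pairwise_identity(codes, cl.consensus_codes, aln_params) >= thr:
                    placed = ci
                    break
        if placed >= 0:
            cl = clusters[placed]
            cl.members.append(di)
            cl.n_reads += count
            assignment[di] = placed
            if cl.n_reads >= cl.refresh_at and len(cl.members) > 1:
                _recompute_consensus(cl, derep, aln_params)
                cl.refresh_at = 2 * cl.n_reads
                index_cluster(placed)
        else:
            cl = _Cluster(codes, count, di)
            clusters.append(cl)
            assignment[di] = len(clusters) - 1
            index_cluster(len(clusters) - 1)

    # stabilize: recompute every consensus, then one re-recruitment pass
    for cl in clusters:
        if len(cl.members) > 1:
            _recompute_consensus(cl, derep, aln_params)
    if use_prefilter:
        kmer_index.clear()
        for ci in range(len(clusters)):
            index_cluster(ci)

    members_final: list[list[int]] = [[] for _ in clusters]
    unassigned: list[int] = []
    for di, (seq, codes, rids, count) in enumerate(derep):
        placed = -1
        for ci in candidates(di, codes):
            if align.pairwise_identity(codes, clusters[ci].consensus_codes,
                                       aln_params) >= thr:
                placed = ci
                break
        if placed < 0 and use_prefilter:
            for ci, cl in enumerate(clusters):
                if cl.consensus_codes.shape[0] >= _PREFILTER_MIN_LEN:
                    continue
                if align.pairwise_identity(codes, cl.consensus_codes, aln_params) >= thr:
                    placed = ci
                    break
        if placed >= 0:
            members_final[placed].append(di)
        else:
            unassigned.append(di)

    # rebuild clusters, recompute consensi, dissolve small clusters
    meta = reads.meta
    otus: list[Otu] = []
    unincorporated: list[str] = []
    for di in unassigned:
        unincorporated.extend(derep[di][2])
    n_kept = 0
    for ci, member_idx in enumerate(members_final):
        if not member_idx:
            continue
        n_reads = sum(derep[di][3] for di in member_idx)
        if n_reads < params.min_cluster_size:
            for di in member_idx:
                unincorporated.extend(derep[di][2])
            continue
        cl = clusters[ci]
        cl.members = member_idx
        if len(member_idx) > 1:
            _recompute_consensus(cl, derep, aln_params)
        read_ids = [rid for di in member_idx for rid in derep[di][2]]
        counts: dict[str, int] = {}
        for rid in read_ids:
            sample = meta.at[rid, "sample_id"]
            counts[sample] = counts.get(sample, 0) + 1
        n_kept += 1
        otus.append(
            Otu(
                otu_id=f"otu_{n_kept:04d}",
                region=region,
                consensus=cl.consensus,
                n_reads=n_reads,
                per_sample_counts=counts,
                member_read_ids=read_ids,
            )
        )
    return otus, unincorporated


def incorporation_summary(n_incorporated: int, n_total: int) -> float:
    """Percent of reads incorporated into OTUs, truncated to one decimal.

    Truncation (not rounding) reproduces how the published survey tables
    report this quantity.
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_incorporated <= n_total:
        raise ValueError("n_incorporated must be between 0 and n_total")
    return (1000 * n_incorporated // n_total) / 10


def rank_abundance(otus: Sequence[Otu], n_total_reads: int) -> pd.DataFrame:
    """Rank-abundance table with the cumulative incorporated fraction."""
    if not otus:
        raise ValueError("no OTUs")
    if n_total_reads <= 0:
        raise ValueError("n_total_reads must be positive")
    ordered = sorted(otus, key=lambda o: (-o.n_reads, o.otu_id))
    n = np.array([o.n_reads for o in ordered], dtype=float)
    return pd.DataFrame(
        {
            "rank": np.arange(1, len(ordered) + 1),
            "otu_id": [o.otu_id for o in ordered],
            "n_reads": [o.n_reads for o in ordered],
            "cumulative_fraction": np.cumsum(n) / n_total_reads,
        }
    )


def write_cluster_outputs(outdir: str | Path, otus: Sequence[Otu],
                          unincorporated: Sequence[str], n_total: int) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    paths["otus_fasta"] = outdir / "otus.fasta"
    write_fasta(paths["otus_fasta"], [(o.otu_id, o.consensus) for o in otus])

    rows = [(rid, o.otu_id) for o in otus for rid in o.member_read_ids]
    rows += [(rid, "") for rid in unincorporated]
    paths["membership"] = outdir / "membership.tsv"
    pd.DataFrame(rows, columns=["read_id", "otu_id"]).to_csv(
        paths["membership"], sep="\t", index=False
    )

    samples = sorted({s for o in otus for s in o.per_sample_counts})
    table = pd.DataFrame(0, index=[o.otu_id for o in otus], columns=samples, dtype=int)
    for o in otus:
        for s, c in o.per_sample_counts.items():
            table.at[o.otu_id, s] = c
    paths["otu_table"] = outdir / "otu_table.tsv"
    table.rename_axis("otu_id").to_csv(paths["otu_table"], sep="\t")

    n_inc = sum(o.n_reads for o in otus)
    region = otus[0].region if otus else ""
    summary = pd.DataFrame(
        [
            ("region", region),
            ("n_reads_total", n_total),
            ("n_reads_incorporated", n_inc),
            ("percent_incorporated", incorporation_summary(n_inc, n_total)),
            ("n_otus", len(otus)),
        ],
        columns=["metric", "value"],
    )
    paths["summary"] = outdir / "summary.tsv"
    summary.to_csv(paths["summary"], sep="\t", index=False)
    return paths
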