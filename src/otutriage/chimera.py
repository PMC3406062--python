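"""Two-parent (bimera) chimera screening of OTU consensus sequences.

The model: given per-query-position match indicators against two candidate
parents, the bimera identity is the best achievable fraction of matching
positions when the query prefix up to a breakpoint is explained by one
parent and the suffix by the other.  An OTU is flagged when the bimera
model beats the best single parent by a configurable identity gain.

Reference mode draws candidate parents from a chimera-free database; de novo
mode draws them from other OTUs, restricted to those sufficiently more
abundant than the query OTU (the abundance-skew rule).  A pipeline combines
both verdicts with a logical OR.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import align
from .align import AlignmentParams, RefDb, match_profile
from .cluster import Otu

__all__ = [
    "ChimeraParams",
    "ChimeraVerdict",
    "bimera_identity",
    "flag_reference_mode",
    "flag_denovo_mode",
    "combine_flags",
    "screen_otus",
    "write_verdicts",
]


@dataclass(frozen=True)
class ChimeraParams:
    top_k_parents: int = 4
    min_divergence_gain: float = 0.02
    abskew: float = 2.0
    min_model_identity: float = 0.90

    def __post_init__(self) -> None:
        if self.top_k_parents < 2:
            raise ValueError("top_k_parents must be >= 2")
        if self.abskew < 1:
            raise ValueError("abskew must be >= 1")


@dataclass
class ChimeraVerdict:
    otu_id: str
    flagged_ref: bool
    flagged_denovo: bool
    best_single_identity: float
    best_model_identity: float
    parents: tuple[str, str] | None
    breakpoint: int | None


def _bimera_from_profiles(prof_a: np.ndarray, prof_b: np.ndarray) -> tuple[float, int, bool]:
    """Max over breakpoints and parent orders of the two-segment match fraction.

    Returns (model_identity, breakpoint, swapped) where breakpoint i means
    query positions [0, i) come from the first parent of the winning order and
    ``swapped`` says that order was (b, a).  Ties prefer the (a, b) order,
    then the smallest breakpoint.
    """
    L = prof_a.shape[0]
    pa = np.concatenate(([0], np.cumsum(prof_a)))
    pb = np.concatenate(([0], np.cumsum(prof_b)))
    ab = pa + (pb[L] - pb)  # prefix from a, suffix from b, per breakpoint
    ba = pb + (pa[L] - pa)
    i_ab = int(ab.argmax())
    i_ba = int(ba.argmax())
    if ab[i_ab] >= ba[i_ba]:
        return float(ab[i_ab]) / L, i_ab, False
    return float(ba[i_ba]) / L, i_ba, True


def bimera_identity(
    query: str,
    parent_a: str,
    parent_b: str,
    aln_params: AlignmentParams = align.DEFAULT_PARAMS,
) -> tuple[float, int]:
    """Best two-segment model identity of query against two parents.

    Identity here is measured per query position (fraction of the L query
    bases aligned to an identical parent base), so the model with breakpoint
    0 or L degenerates exactly to a single parent.
    """
    prof_a = match_profile(query, parent_a, aln_params)
    prof_b = match_profile(query, parent_b, aln_params)
    ident, bp, _ = _bimera_from_profiles(prof_a, prof_b)
    return ident, bp


def _screen_against_parents(
    otu_id: str,
    query: str,
    parents: Sequence[tuple[str, str]],
    params: ChimeraParams,
    aln_params: AlignmentParams,
    mode: str,
) -> ChimeraVerdict:
    """Shared core of both modes: top-k parent selection + pairwise bimera test."""
    cq = align.encode(query)
    profiles = []
    for pid, pseq in parents:
        prof = match_profile(cq, align.encode(pseq), aln_params)
        profiles.append((pid, prof, prof.mean()))
    profiles.sort(key=lambda t: -t[2])
    top = profiles[: params.top_k_parents]
    best_single = top[0][2] if top else 0.0

    best_model = best_single
    best_pair = None
    best_bp = None
    for (ida, prof_a, _), (idb, prof_b, _) in combinations(top, 2):
        ident, bp, swapped = _bimera_from_profiles(prof_a, prof_b)
        if ident > best_model:
            best_model = ident
            best_pair = (idb, ida) if swapped else (ida, idb)
            best_bp = bp
    flagged = (
        best_model >= params.min_model_identity
        and best_model - best_single >= params.min_divergence_gain
    )
    return ChimeraVerdict(
        otu_id=otu_id,
        flagged_ref=flagged if mode == "ref" else False,
        flagged_denovo=flagged if mode == "denovo" else False,
        best_single_identity=float(best_single),
        best_model_identity=float(best_model),
        parents=best_pair if flagged else None,
        breakpoint=best_bp if flagged else None,
    )


def flag_reference_mode(
    otu_id: str,
    query: str,
    refdb: RefDb,
    params: ChimeraParams = ChimeraParams(),
    aln_params: AlignmentParams = align.DEFAULT_PARAMS,
) -> ChimeraVerdict:
    if len(refdb) == 0:
        raise ValueError(f"reference database {refdb.name!r} is empty")
    return _screen_against_parents(otu_id, query, refdb.records, params,
                                   aln_params, "ref")


def flag_denovo_mode(
    otu: Otu,
    all_otus: Sequence[Otu],
    params: ChimeraParams = ChimeraParams(),
    aln_params: AlignmentParams = align.DEFAULT_PARAMS,
) -> ChimeraVerdict:
    """De novo mode: candidate parents are OTUs passing the abundance-skew rule."""
    eligible = [
        (o.otu_id, o.consensus)
        for o in all_otus
        if o.otu_id != otu.otu_id and o.n_reads >= params.abskew * otu.n_reads
    ]
    if not eligible:
        return ChimeraVerdict(otu.otu_id, False, False, 0.0, 0.0, None, None)
    return _screen_against_parents(otu.otu_id, otu.consensus, eligible, params,
                                   aln_params, "denovo")


def combine_flags(ref: ChimeraVerdict, denovo: ChimeraVerdict) -> bool:
    """The either-mode OR rule."""
    if ref.otu_id != denovo.otu_id:
        raise ValueError(
            f"verdicts refer to different OTUs: {ref.otu_id!r} vs {denovo.otu_id!r}"
        )
    return ref.flagged_ref or denovo.flagged_denovo


def screen_otus(
    otus: Sequence[Otu],
    refdb: RefDb,
    params: ChimeraParams = ChimeraParams(),
    aln_params: AlignmentParams = align.DEFAULT_PARAMS,
    reference_only: bool = False,
) -> pd.DataFrame:
    """Screen all OTUs in both modes (or reference mode only for non-survey data)."""
    rows = []
    for otu in otus:
        ref_v = flag_reference_mode(otu.otu_id, otu.consensus, refdb, params,
                                    aln_params)
        if reference_only:
            dn_v = ChimeraVerdict(otu.otu_id, False, False, 0.0, 0.0, None, None)
        else:
            dn_v = flag_denovo_mode(otu, otus, params, aln_params)
        chimeric = combine_flags(ref_v, dn_v)
        winner = ref_v if ref_v.flagged_ref else dn_v
        rows.append(
            (
                otu.otu_id,
                chimeric,
                ref_v.flagged_ref,
                dn_v.flagged_denovo,
                max(ref_v.best_single_identity, dn_v.best_single_identity),
                max(ref_v.best_model_identity, dn_v.best_model_identity),
                winner.parents[0] if winner.parents else "",
                winner.parents[1] if winner.parents else "",
                # positions are reported 1-based; breakpoint i means the model
                # switches parents after query base i
                winner.breakpoint if winner.breakpoint is not None else "",
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "otu_id", "chimeric", "flagged_ref", "flagged_denovo",
            "best_single_identity", "best_model_identity",
            "parent_a", "parent_b", "breakpoint",
        ],
    )


def write_verdicts(path: str | Path, verdicts: pd.DataFrame) -> None:
    verdicts.to_csv(path, sep="\t", index=False)
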