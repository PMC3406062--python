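"""Sequencing-priority triage of non-chimeric OTUs.

An OTU's class is driven by two axes: its best identity to 16S sequences of
whole-genome-sequenced, human-derived strains, and the fraction of samples
in which it occurs at its most prevalent body site.  Identity bands are
half-open: [0, 90) high, [90, 98) medium, [98, 100] low; anything below the
prevalence floor is low priority regardless of identity.  Matches to
sequenced databases of environmental origin never demote an OTU.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .align import MatchResult

__all__ = [
    "TriageThresholds",
    "PriorityRecord",
    "sequenced_identity",
    "assign_priority",
    "cultured_status",
    "triage_table",
    "most_wanted_report",
    "build_priority_records",
    "PRIORITY_CLASSES",
]

PRIORITY_CLASSES = ("high", "medium", "low")

SEQUENCED_HUMAN = "sequenced_human"
CULTURED = ("cultured_named", "cultured_unnamed")
COMPREHENSIVE = "comprehensive"


@dataclass(frozen=True)
class TriageThresholds:
    high_identity_max: float = 90.0  # percent
    low_identity_min: float = 98.0  # percent
    prevalence_min: float = 0.20  # fraction of samples at the best site
    cultured_identity_min: float = 98.0  # percent

    def __post_init__(self) -> None:
        if not self.high_identity_max < self.low_identity_min:
            raise ValueError("high_identity_max must be below low_identity_min")
        if not 0 < self.prevalence_min < 1:
            raise ValueError("prevalence_min must be in (0, 1)")


@dataclass
class PriorityRecord:
    otu_id: str
    region: str
    sequenced_identity: float  # percent
    cultured_identity: float  # percent
    comprehensive_identity: float  # percent
    max_prevalence: float
    max_site: str
    priority_class: str
    cultured: bool


def sequenced_identity(
    matches: Sequence[MatchResult], categories: Mapping[str, str]
) -> float:
    """Max best-hit identity (percent) over sequenced-human databases only.

    Databases of other categories -- including comprehensive collections and
    sequenced environmental strains -- are ignored, so a close environmental
    match cannot demote an OTU.
    """
    values = [
        m.identity for m in matches
        if categories.get(m.db_name) == SEQUENCED_HUMAN
    ]
    if not values:
        raise ValueError("no sequenced-human database among the matches")
    return 100.0 * max(values)


def assign_priority(seq_id: float, max_prev: float, t: TriageThresholds) -> str:
    """Priority class from sequenced-human identity (percent) and prevalence."""
    if max_prev < t.prevalence_min:
        return "low"
    if seq_id < t.high_identity_max:
        return "high"
    if seq_id < t.low_identity_min:
        return "medium"
    return "low"


def cultured_status(
    matches: Sequence[MatchResult],
    categories: Mapping[str, str],
    t: TriageThresholds,
) -> tuple[bool, float]:
    """(cultured, identity percent) over the named + unnamed culture databases."""
    values = [
        m.identity for m in matches if categories.get(m.db_name) in CULTURED
    ]
    if not values:
        raise ValueError("no cultured database among the matches")
    ident = 100.0 * max(values)
    return ident >= t.cultured_identity_min, ident


def build_priority_records(
    matches: pd.DataFrame,
    prevalence: Mapping[str, tuple[str, float]],
    regions: Mapping[str, str],
    chimeric: Iterable[str] = (),
    thresholds: TriageThresholds = TriageThresholds(),
) -> list[PriorityRecord]:
    """Assemble per-OTU records from the search table and prevalence profile.

    ``matches`` is the table from :func:`otutriage.align.search_databases`;
    ``prevalence`` maps otu_id -> (max_site, max_prevalence); ``chimeric``
    OTUs are excluded before triage.
    """
    chimeric = set(chimeric)
    categories = dict(
        matches[["db_name", "category"]].drop_duplicates().itertuples(index=False)
    )
    records = []
    for otu_id, sub in matches.groupby("query_id", sort=True):
        if otu_id in chimeric:
            continue
        hits = [
            MatchResult(otu_id, r.db_name, r.ref_id, r.identity, r.aligning_fraction)
            for r in sub.itertuples(index=False)
        ]
        seq_id = sequenced_identity(hits, categories)
        cultured, cult_id = cultured_status(hits, categories, thresholds)
        comp = [
            m.identity for m in hits if categories.get(m.db_name) == COMPREHENSIVE
        ]
        max_site, max_prev = prevalence.get(otu_id, ("", 0.0))
        records.append(
            PriorityRecord(
                otu_id=otu_id,
                region=regions.get(otu_id, ""),
                sequenced_identity=seq_id,
                cultured_identity=cult_id,
                comprehensive_identity=100.0 * max(comp) if comp else float("nan"),
                max_prevalence=max_prev,
                max_site=max_site,
                priority_class=assign_priority(seq_id, max_prev, thresholds),
                cultured=cultured,
            )
        )
    return records


def triage_table(records: Sequence[PriorityRecord]) -> pd.DataFrame:
    """Class x region count table with a combined column and a TOTAL row."""
    regions = sorted({r.region for r in records})
    table = pd.DataFrame(0, index=list(PRIORITY_CLASSES) + ["total"],
                         columns=regions + ["combined"], dtype=int)
    for r in records:
        table.at[r.priority_class, r.region] += 1
        table.at[r.priority_class, "combined"] += 1
        table.at["total", r.region] += 1
        table.at["total", "combined"] += 1
    return table.rename_axis("priority_class")


def most_wanted_report(records: Sequence[PriorityRecord]) -> pd.DataFrame:
    """High-priority OTUs ranked by prevalence, then by distance to references."""
    high = [r for r in records if r.priority_class == "high"]
    high.sort(key=lambda r: (-r.max_prevalence, r.sequenced_identity, r.otu_id))
    return pd.DataFrame(
        [
            (r.otu_id, r.region, r.max_site, r.max_prevalence,
             r.sequenced_identity, r.cultured, r.comprehensive_identity)
            for r in high
        ],
        columns=["otu_id", "region", "max_site", "max_prevalence",
                 "sequenced_identity", "cultured", "comprehensive_identity"],
    )


def write_triage_outputs(
    outdir: str | Path,
    records: Sequence[PriorityRecord],
) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    full = pd.DataFrame(
        [
            (r.otu_id, r.region, r.sequenced_identity, r.cultured_identity,
             r.comprehensive_identity, r.max_site, r.max_prevalence,
             r.priority_class, r.cultured)
            for r in records
        ],
        columns=["otu_id", "region", "sequenced_identity", "cultured_identity",
                 "comprehensive_identity", "max_site", "max_prevalence",
                 "priority_class", "cultured"],
    )
    paths["triage"] = outdir / "triage.tsv"
    full.to_csv(paths["triage"], sep="\t", index=False)

    paths["class_counts"] = outdir / "class_counts.tsv"
    triage_table(records).to_csv(paths["class_counts"], sep="\t")

    paths["most_wanted"] = outdir / "most_wanted.tsv"
    most_wanted_report(records).to_csv(paths["most_wanted"], sep="\t", index=False)

    # scatter inputs: identity vs prevalence, and sequenced vs cultured identity
    paths["identity_prevalence"] = outdir / "identity_prevalence.tsv"
    full[["otu_id", "region", "sequenced_identity", "comprehensive_identity",
          "max_prevalence", "priority_class"]].to_csv(
        paths["identity_prevalence"], sep="\t", index=False
    )
    paths["sequenced_cultured"] = outdir / "sequenced_cultured.tsv"
    full[["otu_id", "region", "sequenced_identity", "cultured_identity",
          "priority_class", "cultured"]].to_csv(
        paths["sequenced_cultured"], sep="\t", index=False
    )
    return paths
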