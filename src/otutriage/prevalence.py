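"""OTU x sample table, per-body-site prevalence and mean relative abundance."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "OtuTable",
    "PrevalenceRecord",
    "build_otu_table",
    "prevalence_by_site",
    "mean_relative_abundance",
    "write_prevalence",
]


@dataclass
class OtuTable:
    """Non-negative integer counts (OTU rows x sample columns) plus sample sites.

    ``sample_sites`` maps sample_id -> body_site for every column.
    """

    counts: pd.DataFrame
    sample_sites: pd.Series

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        missing = [s for s in self.counts.columns if s not in self.sample_sites.index]
        if missing:
            raise ValueError(f"samples without a body site, e.g. {missing[0]!r}")


@dataclass
class PrevalenceRecord:
    otu_id: str
    per_site_prevalence: dict[str, float]
    max_site: str
    max_prevalence: float
    mean_relative_abundance: float


def build_otu_table(membership: Mapping[str, str], metadata: pd.DataFrame) -> OtuTable:
    """Tally reads per (OTU, sample) from a read -> OTU map.

    ``metadata`` is indexed by read_id with sample_id and body_site columns.
    Reads mapped to the empty string (unincorporated) are skipped.
    """
    for rid in membership:
        if rid not in metadata.index:
            raise ValueError(f"read {rid!r} is not present in the metadata")
    pairs = [
        (otu, metadata.at[rid, "sample_id"])
        for rid, otu in membership.items()
        if otu
    ]
    samples = metadata["sample_id"].unique()
    sites = (
        metadata.drop_duplicates("sample_id")
        .set_index("sample_id")["body_site"]
    )
    if not pairs:
        counts = pd.DataFrame(0, index=pd.Index([], name="otu_id"),
                              columns=samples, dtype=int)
        return OtuTable(counts, sites)
    frame = pd.DataFrame(pairs, columns=["otu_id", "sample_id"])
    counts = (
        frame.groupby(["otu_id", "sample_id"]).size().unstack(fill_value=0)
        .reindex(columns=samples, fill_value=0)
        .sort_index()
    )
    return OtuTable(counts.astype(int), sites)


def prevalence_by_site(table: OtuTable, presence_min: int = 1) -> list[PrevalenceRecord]:
    """Per OTU and body site: fraction of the site's samples with enough reads.

    The site attaining the maximum prevalence is recorded; ties go to the
    lexicographically first site.  Sites with zero samples are excluded with
    a warning.
    """
    if presence_min < 1:
        raise ValueError("presence_min must be >= 1")
    sites = table.sample_sites.loc[table.counts.columns]
    empty = sorted(set(table.sample_sites.unique()) - set(sites.unique()))
    if empty:
        warnings.warn(f"body sites with no samples excluded: {empty}")
    present = table.counts >= presence_min
    by_site = present.T.groupby(sites).mean().T  # OTU x site prevalence
    by_site = by_site[sorted(by_site.columns)]
    mra = mean_relative_abundance(table)
    records = []
    for otu_id, row in by_site.iterrows():
        max_site = row.idxmax()  # first (lexicographically) on ties
        records.append(
            PrevalenceRecord(
                otu_id=otu_id,
                per_site_prevalence=row.to_dict(),
                max_site=str(max_site),
                max_prevalence=float(row[max_site]),
                mean_relative_abundance=mra.get(otu_id, 0.0),
            )
        )
    return records


def mean_relative_abundance(table: OtuTable) -> dict[str, float]:
    """Per OTU, the mean over non-empty samples of its within-sample fraction."""
    colsums = table.counts.sum(axis=0)
    keep = colsums > 0
    if not keep.any():
        raise ValueError("all samples are empty")
    if (~keep).any():
        warnings.warn(
            f"{int((~keep).sum())} empty sample(s) dropped from relative abundance"
        )
    rel = table.counts.loc[:, keep].div(colsums[keep], axis=1)
    return rel.mean(axis=1).to_dict()


def write_prevalence(path: str | Path, records: Sequence[PrevalenceRecord]) -> None:
    if not records:
        pd.DataFrame(
            columns=["otu_id", "max_site", "max_prevalence", "mean_relative_abundance"]
        ).to_csv(path, sep="\t", index=False)
        return
    sites = sorted(records[0].per_site_prevalence)
    rows = []
    for r in records:
        row = {"otu_id": r.otu_id, "max_site": r.max_site,
               "max_prevalence": r.max_prevalence,
               "mean_relative_abundance": r.mean_relative_abundance}
        for s in sites:
            row[f"prevalence_{s}"] = r.per_site_prevalence[s]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
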