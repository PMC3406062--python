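"""File formats: FASTA reads/databases, TSV metadata, database manifests."""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .align import DB_CATEGORIES, RefDb

META_COLUMNS = ["read_id", "sample_id", "subject_id", "body_site", "region"]


@dataclass
class ReadSet:
    """Amplicon reads plus their per-read sample metadata.

    ``meta`` is indexed by read_id with columns sample_id, subject_id,
    body_site and region; every read must have a metadata row.
    """

    records: list[tuple[str, str]]
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [rid for rid, _ in self.records if rid not in self.meta.index]
        if missing:
            raise ValueError(f"reads missing from metadata, e.g. {missing[0]!r}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def regions(self) -> set[str]:
        return set(self.meta.loc[[rid for rid, _ in self.records], "region"])


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    recs = (SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records)
    SeqIO.write(recs, str(path), "fasta")


def read_metadata(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata is missing columns {missing}")
    return meta.set_index("read_id")


def write_metadata(path: str | Path, meta: pd.DataFrame) -> None:
    meta.reset_index().rename(columns={"index": "read_id"}).to_csv(
        path, sep="\t", index=False
    )


def load_read_set(reads_path: str | Path, meta_path: str | Path) -> ReadSet:
    return ReadSet(read_fasta(reads_path), read_metadata(meta_path))


def write_db_manifest(path: str | Path, dbs: Mapping[str, RefDb],
                      fasta_paths: Mapping[str, str]) -> None:
    rows = [(db.name, db.category, fasta_paths[name]) for name, db in dbs.items()]
    pd.DataFrame(rows, columns=["db_name", "category", "fasta_path"]).to_csv(
        path, sep="\t", index=False
    )


def load_ref_dbs(manifest_path: str | Path) -> dict[str, RefDb]:
    """Load reference databases from a manifest TSV.

    Columns: db_name, category (one of the five recognized categories) and
    fasta_path, resolved relative to the manifest's directory.
    """
    manifest_path = Path(manifest_path)
    table = pd.read_csv(manifest_path, sep="\t", dtype=str)
    for col in ("db_name", "category", "fasta_path"):
        if col not in table.columns:
            raise ValueError(f"db manifest is missing column {col!r}")
    dbs: dict[str, RefDb] = {}
    for row in table.itertuples(index=False):
        if row.category not in DB_CATEGORIES:
            raise ValueError(
                f"database {row.db_name!r} has unknown category {row.category!r}"
            )
        fasta = Path(row.fasta_path)
        if not fasta.is_absolute():
            fasta = manifest_path.parent / fasta
        dbs[row.db_name] = RefDb(row.db_name, row.category,
                                 tuple(read_fasta(fasta)))
    return dbs


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
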