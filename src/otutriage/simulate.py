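"""Synthetic amplicon communities with planted ground truth.

Generates random source sequences (stand-ins for real taxa), samples reads
per body site with configurable abundance and presence structure, plants
per-read point errors and two-parent chimeras, and builds tiered reference
databases at controlled divergence from the sources.  Everything planted is
recorded in a truth table so each downstream stage can be scored against
known answers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import align
from .align import RefDb
from .io import META_COLUMNS, ReadSet, write_db_manifest, write_fasta
from .triage import TriageThresholds, assign_priority

__all__ = [
    "SourcePool",
    "SimulationDesign",
    "TruthTable",
    "generate_source_pool",
    "mutate_sequence",
    "simulate_samples",
    "generate_reference_databases",
    "attribute_otus",
    "standard_community",
    "demo_community",
    "write_simulation",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE4 = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _CODE4[_b] = _i


@dataclass
class SourcePool:
    """Named source sequences, mutually divergent so they map 1:1 to OTUs."""

    sources: list[tuple[str, str]]
    seed: int

    def __len__(self) -> int:
        return len(self.sources)

    @property
    def ids(self) -> list[str]:
        return [sid for sid, _ in self.sources]

    def sequence(self, source_id: str) -> str:
        for sid, seq in self.sources:
            if sid == source_id:
                return seq
        raise KeyError(source_id)


@dataclass
class SimulationDesign:
    body_sites: list[str]
    samples_per_site: int
    reads_per_sample: int
    prevalence_plan: dict[str, dict[str, float]]  # source -> site -> probability
    abundance_model: str = "geometric"  # or "power"
    abundance_param: float = 0.3
    error_rate: float = 0.01
    indel_rate: float = 0.001
    chimera_rate: float = 0.0
    region: str = "V1-V3"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.body_sites or self.samples_per_site <= 0 or self.reads_per_sample <= 0:
            raise ValueError("design must have at least one site, sample and read")
        if not 0 <= self.chimera_rate < 0.5:
            raise ValueError("chimera_rate must be in [0, 0.5)")
        for rate in (self.error_rate, self.indel_rate):
            if not 0 <= rate < 1:
                raise ValueError("error rates must be in [0, 1)")
        for src, per_site in self.prevalence_plan.items():
            for site, p in per_site.items():
                if not 0 <= p <= 1:
                    raise ValueError(f"presence probability out of range for {src}/{site}")
        if self.abundance_model not in ("geometric", "power"):
            raise ValueError("abundance_model must be 'geometric' or 'power'")


@dataclass
class TruthTable:
    """Planted ground truth: per-read origin and per-source annotations."""

    read_origins: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["read_id", "sample_id", "source_id", "parent_a", "parent_b",
                     "breakpoint"]
        )
    )
    site_prevalence: dict[str, dict[str, float]] = field(default_factory=dict)
    presence_prob: dict[str, dict[str, float]] = field(default_factory=dict)
    total_reads: dict[str, int] = field(default_factory=dict)
    db_identity: dict[str, dict[str, float]] = field(default_factory=dict)
    db_category: dict[str, str] = field(default_factory=dict)
    planted_class: dict[str, str] = field(default_factory=dict)

    def planted_sequenced_identity(self, source_id: str) -> float:
        """Percent identity to the closest sequenced-human database entry."""
        values = [
            per_source[source_id]
            for db, per_source in self.db_identity.items()
            if self.db_category.get(db) == "sequenced_human" and source_id in per_source
        ]
        return 100.0 * max(values) if values else 0.0

    def planted_max_prevalence(self, source_id: str) -> float:
        per_site = self.site_prevalence.get(source_id, {})
        return max(per_site.values()) if per_site else 0.0

    def finalize_classes(self, thresholds: TriageThresholds = TriageThresholds()) -> None:
        """Derive planted priority classes from planted identity and prevalence.

        Uses *realized* values (identity actually achieved by mutation,
        prevalence actually achieved by sampling) so that planted classes are
        self-consistent with the triage rules by construction.
        """
        for source_id in self.site_prevalence:
            self.planted_class[source_id] = assign_priority(
                self.planted_sequenced_identity(source_id),
                self.planted_max_prevalence(source_id),
                thresholds,
            )

    @property
    def n_chimeric_reads(self) -> int:
        return int((self.read_origins["source_id"] == "").sum())


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


def generate_source_pool(
    n_sources: int,
    length: int,
    min_divergence: float = 0.10,
    seed: int = 0,
) -> SourcePool:
    """Random source sequences with all pairwise identities < 1 - min_divergence."""
    if n_sources < 1:
        raise ValueError("n_sources must be >= 1")
    if length < 50:
        raise ValueError("length must be >= 50")
    rng = np.random.default_rng(seed)
    ceiling = 1.0 - min_divergence
    accepted: list[str] = []
    attempts = 0
    max_attempts = 50 * n_sources
    while len(accepted) < n_sources:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not generate {n_sources} sources with pairwise identity "
                f"< {ceiling:.2f} after {max_attempts} attempts"
            )
        attempts += 1
        cand = _random_sequence(rng, length)
        if all(align.pairwise_identity(cand, other) < ceiling for other in accepted):
            accepted.append(cand)
    width = max(2, len(str(n_sources)))
    return SourcePool(
        [(f"src_{i + 1:0{width}d}", seq) for i, seq in enumerate(accepted)], seed
    )


def mutate_sequence(
    seq: str,
    divergence: float,
    indel_fraction: float = 0.0,
    seed: int = 0,
) -> tuple[str, float]:
    """Mutate a sequence to a target divergence; returns (mutant, realized identity).

    ``round(divergence * len)`` positions are altered; a fraction of the
    events are single-base indels, the rest substitutions to a different
    base.  The realized identity is measured with the package's own global
    alignment, so substitution-only mutants report 1 - n_sub/len up to
    end-effects of the free-end-gap alignment.
    """
    if not 0 <= divergence <= 0.5:
        raise ValueError("divergence must be in [0, 0.5]")
    if not 0 <= indel_fraction <= 1:
        raise ValueError("indel_fraction must be in [0, 1]")
    if divergence == 0:
        return seq, 1.0
    rng = np.random.default_rng(seed)
    codes = _CODE4[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]
    if (codes > 3).any():
        raise ValueError("sequence must contain only A/C/G/T")
    L = codes.shape[0]
    n_events = int(round(divergence * L))
    n_indels = int(round(indel_fraction * n_events))
    n_subs = n_events - n_indels

    positions = rng.choice(L, size=n_subs, replace=False)
    mutated = codes.copy()
    mutated[positions] = (mutated[positions] + rng.integers(1, 4, size=n_subs)) % 4

    out = list(mutated)
    for _ in range(n_indels):
        pos = int(rng.integers(0, len(out)))
        if rng.random() < 0.5 and len(out) > 1:
            del out[pos]
        else:
            out.insert(pos, int(rng.integers(0, 4)))
    mutant = "".join("ACGT"[c] for c in out)
    realized = align.pairwise_identity(seq, mutant)
    return mutant, float(realized)


def _abundance_weights(design: SimulationDesign, n: int) -> np.ndarray:
    ranks = np.arange(1, n + 1, dtype=float)
    if design.abundance_model == "geometric":
        p = design.abundance_param
        w = p * (1 - p) ** (ranks - 1)
    else:
        w = ranks ** (-design.abundance_param)
    return w / w.sum()


def _apply_read_errors(codes4: np.ndarray, rng: np.random.Generator,
                       error_rate: float, indel_rate: float) -> np.ndarray:
    out = codes4
    if error_rate > 0:
        mask = rng.random(out.shape[0]) < error_rate
        n = int(mask.sum())
        if n:
            out = out.copy()
            out[mask] = (out[mask] + rng.integers(1, 4, size=n)) % 4
    if indel_rate > 0:
        mask = rng.random(out.shape[0]) < indel_rate
        if mask.any():
            parts = list(out)
            for pos in np.flatnonzero(mask)[::-1]:
                if rng.random() < 0.5 and len(parts) > 1:
                    del parts[pos]
                else:
                    parts.insert(int(pos), int(rng.integers(0, 4)))
            out = np.array(parts, dtype=codes4.dtype)
    return out


def simulate_samples(
    pool: SourcePool, design: SimulationDesign
) -> tuple[ReadSet, TruthTable]:
    """Draw reads per sample with planted errors and chimeras.

    Returns the read set (reads + per-read metadata) and a truth table whose
    realized per-site prevalence counts samples in which a source contributed
    at least one non-chimeric read.
    """
    if len(pool) == 0:
        raise ValueError("source pool is empty")
    rng = np.random.default_rng(design.seed)
    source_ids = pool.ids
    seqs4 = {
        sid: _CODE4[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
        for sid, seq in pool.sources
    }
    weights = _abundance_weights(design, len(pool))
    plan = design.prevalence_plan

    records: list[tuple[str, str]] = []
    meta_rows: list[tuple[str, str, str, str, str]] = []
    origin_rows: list[tuple[str, str, str, str, str, int]] = []
    presence_tally = {sid: {site: 0 for site in design.body_sites} for sid in source_ids}
    total_reads = {sid: 0 for sid in source_ids}
    read_no = 0

    for site in design.body_sites:
        for s in range(design.samples_per_site):
            sample_id = f"{site}_{s + 1:03d}"
            subject_id = f"subj_{site}_{s + 1:03d}"
            present_mask = np.array(
                [rng.random() < plan.get(sid, {}).get(site, 0.0) for sid in source_ids]
            )
            if not present_mask.any():
                present_mask[int(np.argmax(weights))] = True
            present = [sid for sid, m in zip(source_ids, present_mask) if m]
            w = weights[present_mask]
            w = w / w.sum()

            n_reads = design.reads_per_sample
            n_chim = 0
            if design.chimera_rate > 0 and len(present) >= 2:
                n_chim = int(rng.binomial(n_reads, design.chimera_rate))
            counts = rng.multinomial(n_reads - n_chim, w)

            contributed = set()
            for sid, count in zip(present, counts):
                for _ in range(count):
                    read_no += 1
                    rid = f"read_{read_no:07d}"
                    codes = _apply_read_errors(
                        seqs4[sid], rng, design.error_rate, design.indel_rate
                    )
                    records.append((rid, "".join("ACGT"[c] for c in codes)))
                    meta_rows.append((rid, sample_id, subject_id, site, design.region))
                    origin_rows.append((rid, sample_id, sid, "", "", -1))
                    total_reads[sid] += 1
                if count > 0:
                    contributed.add(sid)
            for _ in range(n_chim):
                read_no += 1
                rid = f"read_{read_no:07d}"
                ia, ib = rng.choice(len(present), size=2, replace=False, p=w)
                pa, pb = present[int(ia)], present[int(ib)]
                ca, cb = seqs4[pa], seqs4[pb]
                L = min(ca.shape[0], cb.shape[0])
                lo, hi = int(np.ceil(0.2 * L)), int(np.floor(0.8 * L))
                bp = int(rng.integers(lo, hi))
                codes = np.concatenate([ca[:bp], cb[bp:]])
                codes = _apply_read_errors(codes, rng, design.error_rate,
                                           design.indel_rate)
                records.append((rid, "".join("ACGT"[c] for c in codes)))
                meta_rows.append((rid, sample_id, subject_id, site, design.region))
                origin_rows.append((rid, sample_id, "", pa, pb, bp))
            for sid in contributed:
                presence_tally[sid][site] += 1

    meta = pd.DataFrame(meta_rows, columns=META_COLUMNS).set_index("read_id")
    truth = TruthTable(
        read_origins=pd.DataFrame(
            origin_rows,
            columns=["read_id", "sample_id", "source_id", "parent_a", "parent_b",
                     "breakpoint"],
        ),
        site_prevalence={
            sid: {
                site: presence_tally[sid][site] / design.samples_per_site
                for site in design.body_sites
            }
            for sid in source_ids
        },
        presence_prob={sid: dict(plan.get(sid, {})) for sid in source_ids},
        total_reads=total_reads,
    )
    return ReadSet(records, meta), truth


def generate_reference_databases(
    pool: SourcePool,
    divergence_plan: Mapping[str, Mapping[str, float]],
    seed: int = 0,
    categories: Mapping[str, str] | None = None,
    truth: TruthTable | None = None,
    indel_fraction: float = 0.0,
) -> dict[str, RefDb]:
    """Build reference databases as mutated copies of the sources.

    ``divergence_plan`` maps db_name -> {source_id -> divergence}; sources
    omitted from a database's map are absent from it.  ``categories`` maps
    db_name -> category (defaults to the db name itself).  Realized
    identities are recorded in ``truth`` when given.
    """
    categories = dict(categories) if categories else {
        name: name for name in divergence_plan
    }
    cats = {categories[name] for name in divergence_plan}
    for required in ("sequenced_human", "cultured_named"):
        if required not in cats:
            raise ValueError(f"divergence plan must include a {required!r} database")
    known = set(pool.ids)
    rng = np.random.default_rng(seed)
    dbs: dict[str, RefDb] = {}
    for db_name in divergence_plan:
        per_source = divergence_plan[db_name]
        unknown = set(per_source) - known
        if unknown:
            raise ValueError(f"unknown source id(s) in plan for {db_name!r}: "
                             f"{sorted(unknown)}")
        recs = []
        realized: dict[str, float] = {}
        for sid, seq in pool.sources:
            if sid not in per_source:
                continue
            mutant, ident = mutate_sequence(
                seq, per_source[sid], indel_fraction,
                seed=int(rng.integers(0, 2**31)),
            )
            recs.append((f"{db_name}|{sid}", mutant))
            realized[sid] = ident
        dbs[db_name] = RefDb(db_name, categories[db_name], tuple(recs))
        if truth is not None:
            truth.db_identity[db_name] = realized
            truth.db_category[db_name] = categories[db_name]
    return dbs


def attribute_otus(otus, truth: TruthTable) -> pd.DataFrame:
    """Majority-origin label per OTU: a source id or 'chimera', with purity."""
    origin = truth.read_origins.set_index("read_id")["source_id"]
    rows = []
    for otu in otus:
        labels = origin.loc[otu.member_read_ids].replace("", "chimera")
        top = labels.value_counts()
        rows.append((otu.otu_id, top.index[0], top.iloc[0] / len(labels),
                     otu.n_reads))
    return pd.DataFrame(rows, columns=["otu_id", "label", "purity", "n_reads"])


def _banded_plan(pool: SourcePool, rng: np.random.Generator, sites: list[str]):
    """Divergence + prevalence structure spanning the three identity bands."""
    n = len(pool)
    n_band = n // 3
    bands = (["high"] * n_band + ["medium"] * n_band
             + ["low"] * (n - 2 * n_band))
    div_ranges = {"high": (0.12, 0.20), "medium": (0.04, 0.08), "low": (0.0, 0.01)}

    seq_human: dict[str, float] = {}
    hmp_strains: dict[str, float] = {}
    cultured_named: dict[str, float] = {}
    cultured_unnamed: dict[str, float] = {}
    sequenced_all: dict[str, float] = {}
    comprehensive: dict[str, float] = {}
    prevalence_plan: dict[str, dict[str, float]] = {}

    for i, sid in enumerate(pool.ids):
        band = bands[i]
        lo, hi = div_ranges[band]
        d = float(rng.uniform(lo, hi))
        seq_human[sid] = d
        if band == "low":
            hmp_strains[sid] = 0.0
        # cultured divergence never exceeds sequenced divergence, so sequenced
        # taxa are always cultured (the diagonal property)
        if band == "low" or i % 3 == 0:
            cultured_named[sid] = min(d, 0.005)
        else:
            cultured_named[sid] = d
        cultured_unnamed[sid] = 0.25
        sequenced_all[sid] = 0.0
        comprehensive[sid] = 0.005

        home = sites[i % len(sites)]
        if (i // len(sites)) % 2 == 0:  # prevalent source
            prevalence_plan[sid] = {
                site: 0.7 if site == home else 0.05 for site in sites
            }
        else:  # sparse source
            prevalence_plan[sid] = {site: 0.08 for site in sites}

    plan = {
        "gold_human": seq_human,
        "hmp_strains": hmp_strains,
        "gold_all": sequenced_all,
        "silva_like": comprehensive,
        "gg_named": cultured_named,
        "gg_unnamed": cultured_unnamed,
    }
    categories = {
        "gold_human": "sequenced_human",
        "hmp_strains": "sequenced_human",
        "gold_all": "sequenced_all",
        "silva_like": "comprehensive",
        "gg_named": "cultured_named",
        "gg_unnamed": "cultured_unnamed",
    }
    return plan, categories, prevalence_plan


def standard_community(
    seed: int = 1,
    n_sources: int = 60,
    n_sites: int = 5,
    samples_per_site: int = 40,
    reads_per_sample: int = 200,
    length: int = 250,
    error_rate: float = 0.01,
    indel_rate: float = 0.001,
    chimera_rate: float = 0.05,
) -> dict:
    """The parameter-recovery fixture: sources spanning all identity bands
    and both prevalence regimes, with planted errors and chimeras."""
    pool = generate_source_pool(n_sources, length, 0.10, seed)
    rng = np.random.default_rng(seed + 1)
    sites = [f"site_{c}" for c in "abcdefghij"[:n_sites]]
    plan, categories, prevalence_plan = _banded_plan(pool, rng, sites)
    design = SimulationDesign(
        body_sites=sites,
        samples_per_site=samples_per_site,
        reads_per_sample=reads_per_sample,
        prevalence_plan=prevalence_plan,
        abundance_model="power",
        abundance_param=0.3,
        error_rate=error_rate,
        indel_rate=indel_rate,
        chimera_rate=chimera_rate,
        seed=seed + 2,
    )
    reads, truth = simulate_samples(pool, design)
    dbs = generate_reference_databases(pool, plan, seed + 3, categories, truth)
    truth.finalize_classes()
    return {"pool": pool, "design": design, "reads": reads, "truth": truth,
            "dbs": dbs}


def demo_community(seed: int = 7) -> dict:
    """A small community (seconds to run end-to-end) for demos and smoke tests."""
    return standard_community(
        seed=seed, n_sources=12, n_sites=3, samples_per_site=8,
        reads_per_sample=60, length=180, chimera_rate=0.05,
    )


def write_simulation(outdir: str | Path, community: dict) -> dict[str, Path]:
    """Write reads, metadata, databases + manifest, truth tables and config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pool: SourcePool = community["pool"]
    reads: ReadSet = community["reads"]
    truth: TruthTable = community["truth"]
    dbs: Mapping[str, RefDb] = community["dbs"]
    design: SimulationDesign = community["design"]

    paths: dict[str, Path] = {}
    paths["reads"] = outdir / "reads.fasta"
    write_fasta(paths["reads"], reads.records)
    paths["metadata"] = outdir / "metadata.tsv"
    reads.meta.reset_index().to_csv(paths["metadata"], sep="\t", index=False)
    paths["sources"] = outdir / "sources.fasta"
    write_fasta(paths["sources"], pool.sources)

    fasta_paths = {}
    for name, db in dbs.items():
        p = outdir / f"refdb_{name}.fasta"
        write_fasta(p, db.records)
        fasta_paths[name] = p.name
        paths[f"refdb_{name}"] = p
    paths["db_manifest"] = outdir / "db_manifest.tsv"
    write_db_manifest(paths["db_manifest"], dbs, fasta_paths)

    paths["truth_reads"] = outdir / "truth_reads.tsv"
    truth.read_origins.to_csv(paths["truth_reads"], sep="\t", index=False)

    src_rows = []
    for sid in pool.ids:
        row = {
            "source_id": sid,
            "planted_class": truth.planted_class.get(sid, ""),
            "sequenced_identity": truth.planted_sequenced_identity(sid),
            "max_prevalence": truth.planted_max_prevalence(sid),
            "total_reads": truth.total_reads.get(sid, 0),
        }
        for site, prev in truth.site_prevalence.get(sid, {}).items():
            row[f"prevalence_{site}"] = prev
        src_rows.append(row)
    paths["truth_sources"] = outdir / "truth_sources.tsv"
    pd.DataFrame(src_rows).to_csv(paths["truth_sources"], sep="\t", index=False)

    cfg = {
        "pool": {"n_sources": len(pool), "seed": pool.seed},
        "design": {
            "body_sites": design.body_sites,
            "samples_per_site": design.samples_per_site,
            "reads_per_sample": design.reads_per_sample,
            "abundance_model": design.abundance_model,
            "abundance_param": design.abundance_param,
            "error_rate": design.error_rate,
            "indel_rate": design.indel_rate,
            "chimera_rate": design.chimera_rate,
            "region": design.region,
            "seed": design.seed,
        },
    }
    paths["config"] = outdir / "simulation_config.yaml"
    paths["config"].write_text(yaml.safe_dump(cfg, sort_keys=True))
    return paths
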