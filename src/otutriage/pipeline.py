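"""Stage orchestration: simulate -> cluster -> chimera -> search -> prevalence
-> triage, with a run manifest and deterministic seeding."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import simulate as sim
from .align import AlignmentParams, RefDb, search_databases
from .chimera import ChimeraParams, screen_otus, write_verdicts
from .cluster import ClusterParams, Otu, cluster_reads, write_cluster_outputs
from .io import file_digest, load_read_set, load_ref_dbs, read_metadata
from .prevalence import build_otu_table, prevalence_by_site, write_prevalence
from .triage import TriageThresholds, build_priority_records, write_triage_outputs

log = logging.getLogger("otutriage")

__all__ = ["PipelineConfig", "run_pipeline", "load_config", "demo_config",
           "load_otus"]


@dataclass
class PipelineConfig:
    outdir: str
    seed: int = 1
    non_hmp_mode: bool = False
    simulate: dict[str, Any] | None = None
    paths: dict[str, str] = field(default_factory=dict)
    cluster: ClusterParams = field(default_factory=ClusterParams)
    chimera: ChimeraParams = field(default_factory=ChimeraParams)
    alignment: AlignmentParams = field(default_factory=AlignmentParams)
    triage: TriageThresholds = field(default_factory=TriageThresholds)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()


def load_config(path: str | Path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return config_from_dict(raw)


def config_from_dict(raw: Mapping[str, Any]) -> PipelineConfig:
    return PipelineConfig(
        outdir=raw.get("outdir", "otutriage_run"),
        seed=int(raw.get("seed", 1)),
        non_hmp_mode=bool(raw.get("non_hmp_mode", False)),
        simulate=raw.get("simulate"),
        paths=dict(raw.get("paths", {})),
        cluster=ClusterParams(**raw.get("cluster", {})),
        chimera=ChimeraParams(**raw.get("chimera", {})),
        alignment=AlignmentParams(**raw.get("alignment", {})),
        triage=TriageThresholds(**raw.get("triage", {})),
    )


def demo_config(outdir: str = "otutriage_demo") -> PipelineConfig:
    """A self-contained configuration that simulates a small community."""
    return PipelineConfig(outdir=outdir, seed=7, simulate={"preset": "demo"})


def _simulate_inputs(config: PipelineConfig, outdir: Path) -> dict[str, Path]:
    params = dict(config.simulate or {})
    preset = params.pop("preset", "demo")
    params.setdefault("seed", config.seed)
    if preset == "demo":
        community = sim.demo_community(seed=params["seed"])
    elif preset == "standard":
        community = sim.standard_community(**params)
    else:
        raise ValueError(f"unknown simulate preset {preset!r}")
    return sim.write_simulation(outdir / "inputs", community)


def load_otus(otus_fasta: str | Path, membership_tsv: str | Path,
              metadata_tsv: str | Path) -> tuple[list[Otu], list[str]]:
    """Rebuild Otu objects from stage files (for standalone subcommands)."""
    from .io import read_fasta

    consensi = dict(read_fasta(otus_fasta))
    membership = pd.read_csv(membership_tsv, sep="\t", dtype=str).fillna("")
    meta = read_metadata(metadata_tsv)
    otus = []
    unincorporated = list(membership.loc[membership["otu_id"] == "", "read_id"])
    for otu_id, sub in membership[membership["otu_id"] != ""].groupby("otu_id"):
        rids = list(sub["read_id"])
        counts: dict[str, int] = {}
        for rid in rids:
            s = meta.at[rid, "sample_id"]
            counts[s] = counts.get(s, 0) + 1
        region = meta.at[rids[0], "region"]
        otus.append(Otu(otu_id, region, consensi[otu_id], len(rids), counts, rids))
    return otus, unincorporated


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns the manifest (also written to manifest.json)."""
    t_start = time.monotonic()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    stages: list[dict] = []

    current_stage = "setup"

    def stage(name: str):
        nonlocal current_stage
        current_stage = name
        log.info("stage %s started", name)
        return {"name": name, "t0": time.monotonic()}

    def done(rec: dict, **info):
        rec["seconds"] = round(time.monotonic() - rec.pop("t0"), 3)
        rec.update(info)
        stages.append(rec)
        log.info("stage %s finished in %.1fs %s", rec["name"], rec["seconds"], info)

    try:
        if config.simulate is not None:
            rec = stage("simulate")
            sim_paths = _simulate_inputs(config, outdir)
            config.paths = {
                "reads": str(sim_paths["reads"]),
                "metadata": str(sim_paths["metadata"]),
                "db_manifest": str(sim_paths["db_manifest"]),
            }
            outputs.update({f"inputs/{k}": v for k, v in sim_paths.items()})
            done(rec, n_files=len(sim_paths))

        for key in ("reads", "metadata", "db_manifest"):
            if key not in config.paths:
                raise ValueError(f"config.paths is missing {key!r}")
            if not Path(config.paths[key]).exists():
                raise FileNotFoundError(config.paths[key])

        rec = stage("load")
        reads = load_read_set(config.paths["reads"], config.paths["metadata"])
        dbs = load_ref_dbs(config.paths["db_manifest"])
        done(rec, n_reads=len(reads), n_dbs=len(dbs))

        rec = stage("cluster")
        otus, unincorporated = cluster_reads(reads, config.cluster, config.alignment)
        outputs.update(write_cluster_outputs(outdir, otus, unincorporated, len(reads)))
        done(rec, n_otus=len(otus), n_unincorporated=len(unincorporated))

        rec = stage("chimera")
        chimera_db = _chimera_reference(dbs)
        verdicts = screen_otus(otus, chimera_db, config.chimera, config.alignment,
                               reference_only=config.non_hmp_mode)
        outputs["chimera_verdicts"] = outdir / "chimera_verdicts.tsv"
        write_verdicts(outputs["chimera_verdicts"], verdicts)
        chimeric = set(verdicts.loc[verdicts["chimeric"], "otu_id"])
        done(rec, n_chimeric=len(chimeric), reference_db=chimera_db.name,
             reference_only=config.non_hmp_mode)

        rec = stage("search")
        matches = search_databases(
            [(o.otu_id, o.consensus) for o in otus], dbs, config.alignment
        )
        outputs["matches"] = outdir / "matches.tsv"
        matches.to_csv(outputs["matches"], sep="\t", index=False)
        done(rec, n_matches=len(matches))

        rec = stage("prevalence")
        membership = {rid: o.otu_id for o in otus for rid in o.member_read_ids}
        membership.update({rid: "" for rid in unincorporated})
        table = build_otu_table(membership, reads.meta)
        prev_records = prevalence_by_site(table)
        outputs["prevalence"] = outdir / "prevalence.tsv"
        write_prevalence(outputs["prevalence"], prev_records)
        done(rec, n_records=len(prev_records))

        rec = stage("triage")
        prevalence_map = {
            r.otu_id: (r.max_site, r.max_prevalence) for r in prev_records
        }
        regions = {o.otu_id: o.region for o in otus}
        records = build_priority_records(matches, prevalence_map, regions,
                                         chimeric, config.triage)
        outputs.update(write_triage_outputs(outdir, records))
        done(rec, n_records=len(records),
             n_high=sum(1 for r in records if r.priority_class == "high"))
    except Exception as exc:
        raise RuntimeError(
            f"pipeline aborted in stage {current_stage!r}: {exc}"
        ) from exc

    manifest = {
        "config": config.to_dict(),
        "config_digest": config.digest(),
        "stages": stages,
        "total_seconds": round(time.monotonic() - t_start, 3),
        "outputs": {
            key: {"path": str(p), "sha256": file_digest(p)}
            for key, p in sorted(outputs.items(), key=lambda kv: str(kv[1]))
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _chimera_reference(dbs: Mapping[str, RefDb]) -> RefDb:
    """Pick the chimera-free reference: sequenced genomes, preferring the
    all-organisms collection."""
    for category in ("sequenced_all", "sequenced_human"):
        for db in dbs.values():
            if db.category == category:
                return db
    raise ValueError("no sequenced database available for reference-mode screening")
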