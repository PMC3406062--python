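# otutriage

A tested re-implementation of a "most wanted" prioritization pipeline for 16S
amplicon surveys: cluster reads into consensus OTUs, screen consensus
sequences for two-parent chimeras, compute global-alignment percent identity
against tiered reference collections, profile per-body-site prevalence, and
triage OTUs into high / medium / low sequencing-priority classes. A
synthetic-community module generates read sets, metadata and reference
databases with planted ground truth (divergence bands, prevalence structure,
chimeras), so the whole pipeline is validated end-to-end without any
external data.

## Package layout

| module | role |
| --- | --- |
| `otutriage.simulate` | synthetic communities with planted truth (source pools, mutation at controlled divergence, per-site prevalence plans, planted bimeras, tiered reference databases) |
| `otutriage.cluster` | greedy abundance-ordered consensus clustering at a fixed identity threshold; incorporation and rank-abundance summaries |
| `otutriage.chimera` | two-parent (bimera) chimera model; reference mode, de novo mode with abundance skew, either-mode OR rule |
| `otutriage.align` | affine-gap global alignment (free end gaps), percent identity, best-hit database search, aligning fraction, single-cell-to-OTU matching |
| `otutriage.prevalence` | OTU × sample table, per-body-site prevalence, arg-max habitat, mean relative abundance |
| `otutriage.triage` | priority classes from sequenced-human identity bands (90/98%) and the 20% prevalence floor; cultured status; ranked most-wanted report |
| `otutriage.pipeline` / `otutriage.cli` | stage orchestration, YAML config, run manifest with digests, `otutriage` console command |

## CLI

Run the self-contained demo (simulates a small community, then runs every
stage):

```sh
otutriage -v run-all --outdir demo_out
```

Outputs under `demo_out/`: `otus.fasta`, `membership.tsv`, `otu_table.tsv`,
`summary.tsv`, `chimera_verdicts.tsv`, `matches.tsv`, `prevalence.tsv`,
`triage.tsv`, `class_counts.tsv`, `most_wanted.tsv` plus the simulated
inputs (reads, metadata, reference FASTAs + `db_manifest.tsv`, truth tables)
and a `manifest.json` with per-file SHA-256 digests. Re-running with the
same config reproduces identical outputs.

Each stage is also a standalone, re-entrant subcommand operating on files:

```sh
otutriage simulate   --outdir sim --preset standard --seed 1
otutriage cluster    --reads sim/reads.fasta --metadata sim/metadata.tsv --outdir out
otutriage chimera    --otus out/otus.fasta --membership out/membership.tsv \
                     --metadata sim/metadata.tsv --db-manifest sim/db_manifest.tsv \
                     --out out/chimera_verdicts.tsv
otutriage search     --otus out/otus.fasta --db-manifest sim/db_manifest.tsv --out out/matches.tsv
otutriage prevalence --membership out/membership.tsv --metadata sim/metadata.tsv --out out/prevalence.tsv
otutriage triage     --matches out/matches.tsv --prevalence out/prevalence.tsv \
                     --verdicts out/chimera_verdicts.tsv --metadata sim/metadata.tsv \
                     --membership out/membership.tsv --outdir out
```

`otutriage demo-config` prints a ready-to-edit YAML configuration; pass it
to `run-all --config`. `--non-hmp-mode` restricts chimera screening to
reference mode only.

## Notes

- Identity convention: identical columns / columns outside terminal-gap
  spans, internal gaps count as mismatches, and the denominator is floored
  at the shorter ungapped sequence length (so degenerate free-end overlaps
  between unrelated sequences report near-zero identity rather than 100%).
- Priority bands are half-open: identity [0, 90) high, [90, 98) medium,
  [98, 100] low; any OTU below 20% prevalence at every body site is low
  priority. Matches to sequenced *environmental* collections never demote.
- Read-level scratch output and experiments belong under `scratch/` (not
  part of the deliverable).
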