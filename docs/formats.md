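# File formats

All tabular artifacts are tab-separated with a header row.  Coordinates
are 1-based inclusive.  Chromosomes are written as `1`..`22`, `X`;
internally `X` is stored as 23.

## Probe matrix (`matrix.tsv`)

| column | content |
| --- | --- |
| `probe_id` | unique probe identifier |
| `chromosome` | `1`..`22`, `X` |
| `position` | genomic position, bp |
| *sample...* | one column per sample: log2 ratio (blank = missing) |

Rows are sorted by (chromosome, position) on read.

## Clinical table (`clinical.tsv`, also the packaged patient fixture)

Columns: `sample_id`, `age`, `stage_group` (`early`/`advanced`),
`figo_stage` (as printed), `histology` (`C`/`E`/`M`/`S`), `grade`
(1-3), `chemo` (`yes`/`no`), `staging`, `status` (`Alive`/`Dead`),
`os_months`, `progression` (`yes`/`no`), `pfs_months`, `cluster`
(`A`/`B`/`unassigned`).

## Truth segments (`truth.tsv`, simulator output)

`sample`, `chromosome`, `start`, `end`, `state` — per-sample constant
runs of the true copy-number state (−1 loss, 0 normal, 1 gain,
2 amplification); `start`/`end` are probe indices within the
chromosome, 1-based inclusive, tiling each chromosome.

## Segments (`segments.tsv`)

`sample`, `chromosome`, `start`, `end` (genomic positions of the first
and last probe), `n_probes`, `mean` (log2).

## Calls (`calls.tsv`)

`probe_id`, `chromosome`, `position`, then per sample four columns:
`<sample>.call` (−1/0/1, or −9 = uncalled), `<sample>.p_loss`,
`<sample>.p_normal`, `<sample>.p_gain` (merged three-state posterior;
the gain column includes the amplification share).

## Regions (`regions.tsv`)

`chromosome`, `start`, `end` (genomic positions), `n_probes`, then one
column per sample with the region's representative hard call.

## Dendrogram (`dendrogram.nwk`)

Newick; branch lengths are differences of merge heights
(1 − similarity).  `clusters.tsv` holds the two-cluster labels:
`sample`, `cluster`.

## Results (`results.json`, `qc.json`)

JSON.  `results.json` embeds the full pipeline configuration, package
version, seed, per-stage wall-clock seconds, the fitted mixture, the
region summary, the group-comparison block (per-region frequencies,
chi-square p/q, genome-wide odds test) and the survival block.
`qc.json` holds per-sample MAD values, the threshold and exclusions.
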