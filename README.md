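# eracr

Integration of ERα ChIP-seq and ATAC-seq peak sets: condition-specific
accessibility groups, ERα-bound active chromatin regions (ACR), PWM motif
enrichment, and Fox-motif co-occurrence statistics — plus a seeded synthetic
data generator that plants all of the analyzed rates as recoverable ground
truth.

## What it does

Given per-sample peak files (one per clone × Dox × E2 × assay), a genome
FASTA and a motif library, the pipeline:

1. **intervals** — reads BED6/ENCODE narrowPeak peak files into validated,
   sorted interval sets (0-based half-open throughout) and provides the
   overlap/merge/summit-window algebra used everywhere else.
2. **condition_groups** — classifies consensus regions by their presence
   pattern across the four Dox × E2 conditions: condition-specific labels
   and the ERα-dependent groups (`E2minus_ERa`, `E2plus_ERa`, `E2ind_ERa`).
3. **motif** — JASPAR/MEME PWM loading (via Biopython), both-strand
   log2-odds scanning with a max-score threshold fraction, ERE half/full-site
   classification (palindromic half-site pair with a fixed spacer),
   hypergeometric enrichment (`-log10 p` scores, BH-adjusted values carried
   alongside), cross-clone differential enrichment, and top-k reporting.
4. **acr** — defines ACR regions as ChIP peaks overlapping ATAC peaks
   (ChIP coordinates retained), partitions them across clones
   (common / clone-specific / shared-subset), computes per-motif rates and
   the rate-variability (`max/min ≥ 3`, `max ≥ 15%`) and high-enrichment
   (`p ≤ 1e-20`) selection filters.
5. **fox_analysis** — Fox-motif fraction of ChIP peaks, ERE-free fraction
   among Fox-positive peaks, per-direction WT/K303R sharing, and
   chromatin-opening rates stratified by clone partition and ERE label,
   always with numerators/denominators.
6. **sample_similarity** — "DBA-lite" consensus presence/score matrix across
   all samples and a PCA projection.
7. **reporter_assay** — dual-luciferase fold-change normalization
   (per-well firefly/Renilla ratios relative to a reference condition).
8. **synthetic** — deterministic scenario generator: random genome,
   non-overlapping 200-bp loci whose backgrounds are rejection-sampled to be
   free of spurious motif hits, planted motif instances, per-sample
   narrowPeak files, and a truth manifest (`verify_manifest` re-checks every
   planted base and rate).

## CLI

```bash
# generate a synthetic scenario with planted ground truth
eracr generate --seed 11 --out scratch/scenario

# run the full analysis pipeline on a sample sheet
eracr all --config run_config.json
# or individual stages
eracr groups --config run_config.json
eracr fox    --config run_config.json
```

`run_config.json` minimally contains:

```json
{
  "sample_sheet": "samples.tsv",
  "genome": "scratch/scenario/genome.fa",
  "out_dir": "scratch/out"
}
```

The sample sheet is a TSV with columns `clone dox e2 assay path format`
(clones: `control/WT/Y537S/K303R`; dox/e2: `plus/minus`; assay:
`ATAC/ChIP`; format: `bed6/narrowPeak`). `eracr.synthetic.write_sample_sheet`
emits one for a generated scenario. Thresholds (overlap `min_bp`, scan
`threshold_fraction`, differential `delta_min`, rate filters `ratio_min` /
`rate_min`, enrichment `p_max`, summit `flank`) are RunConfig fields with
sensible defaults.

Outputs: condition-group TSVs, ACR table + motif-rate tables + selection
summary JSON, enrichment/differential TSVs, a Fox report JSON (fractions,
sharing, stratified opening — each with counts), PCA coordinates, and a
provenance JSON. All analysis stages are deterministic; randomness lives
only in the generator.

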