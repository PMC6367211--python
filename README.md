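# cofun-instab

Tools for finding gene modules associated with genomic instability and for
quantifying copy-number aberrations in single cells:

1. **Instability association** — rank genes by the Spearman correlation
   between their expression and a per-sample genomic-instability score
   (Fisher-z standardized), and select the top-N positively associated
   genes (default N = 250).
2. **Co-functionality network** — build a gene co-regulation matrix from
   expression (or load one precomputed), score each query gene against
   every gene set in a GMT database (one Spearman coefficient per set =
   its *functional likelihood vector*), correlate likelihood vectors
   between genes, threshold the resulting network (default weight > 0.5)
   and report connected-component gene clusters.
3. **Single-cell SCNA counting** — from per-cell, per-bin integer
   copy-number states, call focal vs whole-chromosome deviations against
   the control population's modal state, count them per cell, and compare
   conditions with a Kruskal–Wallis test plus Dunn's post-hoc z-tests
   (Bonferroni-adjusted).
4. **Synthetic data** — generators for both pipelines with full ground
   truth: dosage-driven expression with a planted co-annotated gene
   module, and diploid single-cell profiles with planted focal segments
   and whole-chromosome aneuploidies.

## CLI

One executable, `cofun-instab`, with subcommands:

```sh
# synthetic inputs (truth records written as JSON)
cofun-instab simulate expression --seed 7 --outdir sim/
cofun-instab simulate cn --seed 7 --outdir sim/

# association ranking (+ top-250 gene list)
cofun-instab associate --expr sim/expression.tsv --scores sim/instability.tsv \
    --out assoc.tsv --top 250

# co-functionality network and clusters
cofun-instab cofun --expr sim/expression.tsv --gmt sim/gene_sets.gmt \
    --genes assoc.top.txt --tau 0.5 --out net.tsv --clusters clusters.tsv

# per-cell focal / whole-chromosome aberration counts + group comparison
cofun-instab scna --calls sim/cn_calls.tsv --control CTRL --frac 0.9 \
    --out counts.tsv --stats stats.json

# full pipelines from a JSON config, with a SHA-256 manifest of outputs
cofun-instab run discovery --config config.json --seed 7 --outdir out/
cofun-instab run scna --config config.json --seed 7 --outdir out/
```

Config files are JSON mirroring `cofun_instab.pipeline.RunConfig`; unknown
keys are hard errors. Defaults reproduce the anchored settings
(`top_n=250`, `tau=0.5`, whole-chromosome fraction 0.9). Reruns with the
same config and seed are byte-identical (checked via manifest checksums).

## File formats

- Expression: TSV, header row of sample IDs, first column gene IDs.
- Instability scores: two-column TSV (`sample_id`, `score`).
- Gene sets: standard GMT (`name TAB description TAB genes...`).
- Copy-number calls: BED-like TSV (`chrom  start  end  cell_id  condition
  state`), **0-based half-open** coordinates; pass `--one-based` for
  callers that emit 1-based starts. Integer states, identical bin grid
  across cells.
- Writers prepend a `#` header with tool version and parameters; readers
  skip `#` lines.

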