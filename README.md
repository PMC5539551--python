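# crustscreen

Contamination screening and community analysis for low-biomass 16S rRNA
amplicon OTU tables, built around comparison with a sequenced background
control library.

Deep-subsurface (and other low-biomass) amplicon libraries are easily
swamped by seawater-, reagent- and handling-derived reads. `crustscreen`
ingests post-clustering OTU count tables and:

1. **filters** putatively spurious rare OTUs (fixed minimum total count,
   default ≥ 5 reads, or a fraction of the pooled total, default 0.005%);
2. **bins** every OTU against a designated background control library into
   four provenance groups — *control only*, *samples only*, *≥10×
   sample-enriched* and *control:sample* — using enrichment ratios on
   per-library relative abundances;
3. **screens** the table down to the *samples only* fraction, dropping the
   control column, all control-overlapping OTUs, and any sample that is both
   tracer-microsphere positive and dominated (≥ 99% of reads) by
   control-overlapping OTUs;
4. **summarises** the surviving communities: taxonomic composition at any
   rank (counts and fractions), OTUs shared between ≥ 2 samples ranked by
   abundance, and presence/absence Jaccard similarity between samples;
5. **quantifies** biomass from qPCR replicate panels: detection calls
   (every sample replicate must exceed every extraction- and PCR-negative
   replicate by more than a factor, default 2), background subtraction by
   the larger negative-control mean, copies-per-gram scaling, and
   conversion to cell densities (× sediment density ÷ rRNA operons per
   cell);
6. **simulates** complete datasets with known ground truth — endemic,
   seawater and reagent source pools mixed per sample with a
   biomass-dependent contaminant fraction φ = κ/(κ+B) — so the whole
   pipeline is verifiable end to end without any external data.

## CLI

```bash
crustscreen simulate --seed 7 --out sim/                 # synthetic dataset + truth.json
crustscreen screen --otu-table sim/otu_table.tsv \
    --taxonomy sim/taxonomy.tsv --metadata sim/metadata.tsv \
    --control-id CONTROL --out run/
crustscreen summarize --otu-table run/screened_otu_table.tsv \
    --taxonomy sim/taxonomy.tsv --rank class --out summaries/
crustscreen quantify --qpcr qpcr.csv --out quant.tsv
crustscreen run --config config.yaml                     # full pipeline + manifest
```

Accepted formats: plain TSV OTU×sample count matrices (either orientation,
auto-detected) or mothur `.shared` files; mothur-style taxonomy files
(bootstrap annotations stripped, unclassified ranks normalised); tab-separated
sample metadata; CSV/TSV qPCR replicate tables. A `config.yaml` for
`crustscreen run` looks like:

```yaml
otu_table: sim/otu_table.tsv
taxonomy: sim/taxonomy.tsv      # optional
metadata: sim/metadata.tsv      # optional
qpcr: qpcr.csv                  # optional
control_id: CONTROL             # omit + screening_enabled: false for pass-through
out: run/
screen:
  ratio_threshold: 10           # enrichment threshold T
  ratio_comparison: GE          # GE or GT at exactly T
  rare_count_min: 5
quant:
  detection_factor: 2
  operons_per_cell: 4
  sediment_density: 2.5
  elution_volume: 100           # µL, enables copies/g and cells/cm³
  extracted_mass: 1             # g
```

Every run writes deterministic TSVs (`bins.tsv`, `sample_summary.tsv`,
`screened_otu_table.tsv`, `composition_*.tsv`, `jaccard.tsv`,
`shared_otus.tsv`, `quant_results.tsv`) and a `manifest.json` with the
config hash and per-stage record counts.

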