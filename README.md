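# microscape

Spatial single-cell analysis of multiplexed tissue imaging data (CyCIF /
ORION-style single-cell feature tables), plus single-sample gene-set scoring
of spatially resolved microregion count matrices.

The package implements the desk-scale analysis chain:

- **gating** — per-marker piecewise-linear rescaling of raw intensities onto
  [0, 1] through (low, 0) / (gate, 0.5) / (high, 1) anchors; positivity is
  strictly > 0.5; hierarchical boolean phenotype rules (first match wins,
  children scoped to their parent label, fallback `Other`), with a shipped
  tumor / immune / endothelial / CD8 T-state hierarchy.
- **regions** — tumor-boundary reconstruction (DBSCAN + alpha-shape concave
  hulls) and per-cell microanatomical region assignment with precedence
  tumor > necrotic > perivascular > peritumoral > distal; per-type regional
  composition and cell densities (cells/mm²).
- **cellstate** — multivariate proliferation index (MPI ∈ {+1, 0, −1} from
  KI67/CCNA2/CCNB1 vs p21/p27, arrest dominant), quiescent-cell (QCC) flags,
  and per-group compositions with binomial standard deviations.
- **spatial** — Gaussian-KDE density maps (≥ 50 cells, 98th-percentile clip,
  10th-percentile mask), adaptively filtered Delaunay graphs, 50 μm
  neighborhood composition, nearest-neighbor distances, subtype ratios.
- **signatures** — median-of-ratios size-factor normalization, log10(x+1),
  rank-weighted single-sample enrichment scores (running-sum statistic,
  α = 0.25), min-max/z score scaling, compartment-stratified two-sided
  Pearson tests, and Mann-Whitney U comparisons (exact for small samples).
- **synth** — seeded synthetic tissues (tumor nests, vessel corridors,
  debris-flagged necrotic zones, two-component log-normal marker
  intensities, cell-cycle co-expression ladders) and negative-binomial
  microregion count matrices with planted signature activity, all with
  ground truth for end-to-end testing.
- **io / cli** — CSV/TSV/YAML/GeoJSON/GMT I/O, a run manifest with input
  checksums, and a `microscape` command-line interface.

## CLI

```sh
# simulate a tissue, gate it, phenotype it
microscape simulate --n-cells 5000 --seed 1 --out sim/
microscape gate --cells sim/cells.csv --gates sim/gates.yaml --out gated.csv
microscape phenotype --cells gated.csv --out typed.csv

# regions, per-cell state, spatial statistics
microscape regions --cells typed.csv --out regions_out/
microscape state --cells typed.csv --group-col true_domain --out state_out/
microscape spatial kde --cells typed.csv --phenotype Tumor --out kde
microscape spatial neighbors --cells typed.csv --target Tumor --out comp.csv

# microregion signature scoring
microscape simulate-mr --seed 1 --out mr/
microscape signatures normalize --counts mr/counts.tsv --out mr/norm
microscape signatures score --expr mr/norm_log_normalized.tsv --gmt mr/gene_sets.gmt --out mr/scores.tsv

# everything end to end from a YAML config
microscape run --config config.yaml --seed 1 --out out/
```

A minimal `config.yaml`:

```yaml
out_dir: out
seed: 1
simulate: {n_cells: 5000, tumor_fraction: 0.4}
```

Supply `cell_table:` + `gates:` (and optionally `rules:`, `annotations:`,
`counts:` + `mr_metadata:` + `gene_sets:`) to run on real data instead of a
simulation.

## Conventions

Coordinates are micrometers, origin top-left, y increasing downward; tables
are UTF-8 CSV/TSV with headers; polygons are GeoJSON with CCW outer rings in
μm; gene sets are GMT.
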