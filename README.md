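# lightmeta

Cross-study meta-analysis of high-light (HL) stress transcriptomes in
*Arabidopsis thaliana* photosynthetic tissue. The package is for
plant-stress researchers who have a compendium of bulk RNA-seq count
matrices from heterogeneous HL experiments (different intensities,
durations, tissues, ages) and want the analyses a single experiment
cannot give: which genes respond *reproducibly*, how the short-term
(≤ 90 min) and long-term (≥ 2 h) transcriptional programs differ, and
which transcription factors (TFs) plausibly drive them.

## What it computes

1. **Per-condition differential expression** from raw counts: low-CPM
   filtering, TMM normalisation, common negative-binomial dispersion by
   conditional maximum likelihood, a two-group conditional NB exact
   test, Benjamini–Hochberg FDR. DEGs: FDR ≤ 0.05 and |log2FC| ≥ 0.5.
2. **Condition space**: condition-level CPM profiles, UPGMA clustering
   on 1 − |Pearson r| (outlier-experiment screening), and a categorical
   taxonomy (duration, intensity, age, tissue groups).
3. **Vote counting**: the core meta-analytic statistic is the per-gene
   frequency of up/down calls across the short and long condition
   groups,

       freq(g, group, dir) = #{conditions in group where g is dir} / #group,

   from which frequent DEGs (detected in ≥ 50 % of conditions), the
   four upper-quartile temporal categories (short-up, short-down,
   long-up, long-down, with combined-pattern labels), and
   consistency-selected robust genes (≥ 50 % one-directional; ≥ 80 %
   for TFs) are derived.
4. **GO over-representation**: hypergeometric upper tail with BH
   q-values, gates q ≤ 1e-5 and ≥ 3 % representation.
5. **Consensus gene regulatory networks** per tissue × duration group:
   soft-thresholded unsigned topological-overlap modules with a
   minimum-correlation gate, intersected with permutation-tested
   random-forest TF→target importances (top-density candidates,
   pooled permutation null, p < 0.05), clustered and GO-annotated.
6. **Synthetic studies**: a negative-binomial multi-experiment
   generator with planted temporal DEG classes, planted TF→target
   regulation and a planted enriched GO term, so every stage is tested
   against known ground truth.

See `docs/methods.md` for models, conventions and limitations.

## Worked example

Simulate a compendium (4 experiments × 3 stress conditions, 3 planted
regulons) and run all three steps:

```bash
lightmeta run-all --simulate --seed 7 --outdir demo \
    --n-genes 400 --n-experiments 4 --conditions-per-experiment 3 \
    --replicates 2 --deg-fraction 0.25 --n-tfs 8 --edges-per-tf 2 \
    --config demo_config.yaml
```

with `demo_config.yaml` containing a desk-scale network profile:

```yaml
n_trees: 50
n_shuffle: 10
min_module_size: 10
```

The run prints per-stage progress and ends with

```
complete: 7 stage(s) in demo
```

`demo/` then contains, among others:

| file | content |
|---|---|
| `study.csv` | simulated counts + metadata (the input format) |
| `degs.tsv` | per (gene, condition) logFC / logCPM / p / FDR / direction |
| `condition_dendrogram.nwk` | UPGMA tree over conditions (Newick) |
| `condition_labels.tsv` | duration/intensity/age/tissue taxonomy |
| `frequency_leaf.tsv` | per-gene vote-counting profiles |
| `categories_leaf.tsv` | upper-quartile temporal categories + pattern labels |
| `enrichment_leaf.tsv` | GO terms passing q ≤ 1e-5 and ≥ 3 % representation |
| `grn_edges_leaf_short.tsv` | consensus TF→target edges with importance, r, p |
| `manifest.json` | config snapshot, seed, per-stage checksums and counts |

The manifest of the run above reports 865 DEG calls among 4 800
(gene, condition) records, 102 genes passing the five-condition
filter, 88 genes entering the four temporal categories, and consensus
networks of 17 (short) and 11 (long) edges. The edge tables carry one
row per retained TF→target edge:

```
regulator   target      importance  correlation  perm_pvalue  cluster
AT1G00020   AT2G00510   0.465512    -0.642521    0.00452659   4
AT3G00020   AT5G00500   0.427414    0.638461     0.00829876   2
AT5G00010   AT1G00190   0.412584    0.675125     0.0116937    5
```

`importance` is the (per-target normalised) random-forest impurity
reduction, `correlation` the signed Pearson r of the pair. Note this
demo profile is deliberately tiny (6 conditions per duration group,
50 trees, 10 permutation rounds): it demonstrates the workflow and the
artifact formats, not recovery power — at this scale most retained
edges reflect the planted stress-axis coexpression rather than the
planted regulons. The powered evaluation (30 conditions, 200 trees,
100 rounds), where planted-edge recall is at or near 1.0 with
precision ≈ 0.6, is what `scripts/acceptance.py` recomputes.

The same stages run individually (`lightmeta simulate|deg|cluster|
classify|enrich|grn`) and resume from each other's outputs; on real
data, point `deg`/`cluster` at your own counts+metadata CSV with
`--study` (layout documented in `lightmeta.io`). Outlier experiments
identified on the dendrogram are excluded with
`--exclude-experiments ID1,ID2`, and the intensity inclusion window is
`--min-intensity/--max-intensity`.

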