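# Methods

`lightmeta` re-analyses compendia of bulk RNA-seq experiments in which
*Arabidopsis thaliana* photosynthetic tissue was exposed to high light
(HL; 500–2000 µmol·m⁻²·s⁻¹ photons, seconds to days). The pipeline has
three analytic layers — per-condition differential expression,
cross-condition vote counting, and consensus network inference — plus a
synthetic-study generator that makes every layer testable without
downloading data. This note records the models, the tunables, and the
design choices made where the design was genuinely open.

## Differential expression

Counts for gene *g* in library *s* are modelled as negative binomial
with mean µ and variance µ + φµ² (common dispersion φ per experiment).
The per-experiment workflow:

1. **Expression filter.** A gene is dropped iff its CPM (library-size
   normalised only) is below `cpm_filter` (default 1.0) in *strictly
   more than* ⌊n/2⌋ of the experiment's libraries.
2. **TMM normalisation.** The reference library is the one whose
   upper-quartile count fraction is closest to the mean across
   libraries. Per library, the factor is 2 to the weighted mean of
   M-values (log2 expression ratios against the reference) after
   trimming 30 % of M-values and 5 % of A-values from each tail;
   weights are inverse asymptotic binomial variances; genes with a zero
   in either library of a pair are excluded; factors are rescaled to
   geometric mean 1.
3. **Common dispersion.** Libraries are scaled (and rounded) to their
   geometric-mean effective size; φ maximises the summed conditional
   NB log-likelihood given per-gene totals within each replicate group,
   by bounded scalar search over log₁₀ φ ∈ [−6, 1]. A degenerate input
   (no within-group variation anywhere) returns the 1e-6 floor with a
   warning. Tagwise (per-gene) shrinkage is deliberately out of scope:
   a single φ keeps the exact test checkable by enumeration.
4. **Exact test.** Scaled counts are summed within the control and
   stress groups; the group sums are treated as NB with dispersion
   φ/n_group. Conditional on the two-group total *s*, the two-sided
   p-value sums all outcome probabilities not exceeding that of the
   observed split ("small probabilities" rule), enumerated exactly over
   0…s; for φ < 1e-8 the conditional law is the Poisson-limit binomial.
   This deterministic scaling+rounding is an *approximation* to
   quantile-adjusted conditional inference; byte-equality with any
   existing tool is not claimed — equality with the stated model is
   enforced against an enumeration oracle in the tests.
5. **Fold changes.** log2FC = log2((y_b/n_b + p₀)/(y_a/n_a + p₀)) with
   prior p₀ = 0.125 reads per million of the common library size. The
   depth-proportional prior makes log2FC exactly invariant when every
   count and library size is rescaled. logCPM = log2(mean CPM + 2).
6. **Calling.** Benjamini–Hochberg within each condition;
   up: FDR ≤ 0.05 ∧ log2FC ≥ 0.5; down: FDR ≤ 0.05 ∧ log2FC ≤ −0.5
   (all comparisons inclusive). Non-significant records are kept with
   direction `ns` so downstream universes are well defined.

Contrasts: when an experiment has controls at more than one sampling
time, each stress condition is tested against the control sharing its
duration (time-matched); otherwise all stress conditions share the
pooled common control. A stress condition lacking a timed control falls
back to the common control with a warning.

## Condition space

Replicate libraries are averaged to condition-level **linear** CPM
profiles (the correlation analysis runs on linear CPM; a log option
exists because linear-scale correlation is unusual practice — it is
dominated by the most abundant transcripts). Conditions are compared by
1 − |Pearson r| over genes with mean CPM ≥ 3; this dissimilarity is not
a metric (no triangle inequality), which UPGMA tolerates. UPGMA heights
are raw average distances (no halving). The categorical taxonomy:

* duration: short ≤ 90 min; medium 2–16 h; long_days 1–3 days. The
  two-way split used by the meta-analysis is short ≤ 90 min vs long
  ≥ 2 h; durations in the (90 min, 2 h) gap join the long group
  (configurable; no such condition exists in practice). One source
  describes short as "20 s–90 min", another as "2–60 min" for leaves;
  the 90-min boundary is implemented.
* intensity: moderate [500, 950), intensive [950, 1500), severe
  [1500, 2000]. The published ranges leave gaps (900→1000, 1330→1700);
  the cut points 950 and 1500 bisect them and are configurable.
* age: juvenile < 21 d, mature 21–30 d, old > 30 d.

## Vote counting and classification

For each gene detected as a DEG in ≥ `min_condition_count` (default 5)
stress conditions, the frequency profile counts the fraction of short
(and long) conditions where it is up (or down). On top of it:

* **Frequent DEGs**: detected in ≥ ⌈50 %⌉ of all conditions; assigned
  up/down by the sign of the median log2FC over detected conditions
  (median |log2FC| ≥ 0.5), middle band unclassified.
* **Temporal categories**: for each of short-up/short-down/long-up/
  long-down, the threshold is the 0.75 quantile (linear interpolation)
  of that category's frequencies *among genes with nonzero frequency
  there* — computed over all genes the 75th percentile is typically 0
  and the category would explode; a flag restores the all-genes mode.
  Boundary genes (frequency exactly at the threshold) are included.
  Genes in one category keep its name; two categories produce combined
  labels ("short–long upregulated" and the five analogues); three or
  more are labelled "frequent".
* **Robust consistency selection**: a gene is consistently up in a
  group when its up-frequency there is ≥ 0.5 (≥ 0.8 for transcription
  factors, which are numerous enough to warrant the stricter gate). If
  both directions qualify at a threshold of exactly 0.5, the larger
  frequency wins and an exact tie excludes the gene.

## GO over-representation

Upper-tail hypergeometric test per term: population = genes that passed
the expression filter *and* carry ≥ 1 GO term, successes = term size in
that universe, draws = target size. q-values are BH-adjusted p-values
(not the Storey estimator). Terms pass at q ≤ 1e-5 **and**
representation (overlap/target size) ≥ 3 %, both inclusive. The GO
mapping is used flat — no ancestor propagation along the GO graph; a
pre-propagated mapping can be supplied to emulate tools that propagate
internally, so borderline terms may differ from such tools.

## Consensus network inference

Run per tissue × duration group on log2(CPM+1) over all libraries of
the group's conditions (not condition means). The gene set is the
group's classified up/down genes plus the regulator pool — TFs called
as DEGs in at least one of the group's conditions (classification alone
almost never retains TFs, whose responses are condition-specific rather
than consistently directional). CPM here uses TMM effective library sizes
computed over the full transcriptome of those libraries; without the
composition correction, coordinated shifts in responsive genes leak a
spurious common axis into every gene's profile.

**Coexpression side.** Unsigned adjacency |r|^β. β is the smallest
power in 1…20 whose scale-free fit R² (signed by the slope of the
log-log degree-distribution regression) reaches 0.8, *excluding* powers
whose mean connectivity drops below 2 — an effectively edgeless network
fits a power law vacuously, and on desk-scale data the unconstrained
rule oscillated between β = 1 and β = 19. When no admissible power
reaches 0.8 the admissible power with the best fit is used (β = 6 only
if the whole grid is degenerate). The unsigned TOM is
t_ij = (Σ_k a_ik a_kj + a_ij)/(min(k_i,k_j) + 1 − a_ij); modules are a
static cut of the average-linkage tree on 1 − TOM at height 0.99
(configurable; a dynamic cut is out of scope), clusters below
`min_module_size` = 30 are unassigned. A gene pair is a coexpression
edge iff both genes share a non-zero module and |r| ≥ `min_correlation`
(0.30 for leaves, 0.55/0.5/0.6 variants for other subsets, per
configuration).

**Regulation side.** For every target, a random-forest regression of
its standardised expression on all TF expressions (K = √p candidate
features per split, bootstrap sampling, importance = total
sum-of-squares reduction, normalised to 1 per target; TFs may be
targets of other TFs but never of themselves). The forest is an
in-package numba kernel — the permutation null recomputes importances
hundreds of times and a general-purpose implementation is an order of
magnitude too slow for that; the tests cross-check it against
scikit-learn's forest (same top regulator, importance correlation
> 0.95). The candidate set is the top ⌈density × #TFs × #targets⌉
edges; the null pools importances from `n_shuffle` recomputations with
every TF's expression vector independently permuted across libraries;
empirical p-values carry the +1 correction and edges are retained at
p < 0.05. Defaults follow the published configuration (1000 trees,
1000 shuffles, density 0.065 leaf / 0.002 seedling); the test profile
uses 200/100.

**Consensus.** A directed TF→target edge survives iff its unordered
pair is a coexpression edge and the directed edge passed the
permutation test. Clusters are connected components of the undirected
skeleton, numbered by descending node count; nodes are labelled
up/down from the classified sets, or "mixed" when a gene is in both or
carries the "frequent" pattern; clusters are annotated with their top
three enriched GO terms against the filtered annotated universe.

Because the candidate set is *selected* as the top importances, most
candidates beat the pooled permutation null by construction; the
false-positive control of the consensus comes from the intersection
with the coexpression gate. On a null study (no planted regulation) the
consensus network is empty or nearly so.

## Synthetic studies

`simulate_study` emulates a multi-experiment compendium: gene baseline
abundances log-normal (log-mean 4, log-sd 1.5), library sizes
log-normal around 10⁷ reads (log-sd 0.2), NB counts at dispersion φ
(default 0.1 for DE-layer studies, 0.05 for network studies), a
per-gene × per-experiment batch effect (log-sd `batch_sd`), stress
conditions on a duration grid spanning 2 min–3 days and intensities
500–2000, one control group per experiment. Planted structure:

* temporal DEG classes (short/long/short-long × up/down, cycled over a
  `deg_fraction` of genes) shift stress means by ±`lfc_magnitude` log2
  units in the matching duration group(s);
* TF→target regulation: each TF receives a condition-level activity
  (log-sd 0.7) of which a fraction 0.2 is a latent stress axis shared
  by all TFs; target log-means follow their regulator's realised
  activity linearly (sign per edge, signs balanced 50/50). The shared
  axis is what lets the classified genes form ≥ 30-gene coexpression
  modules at all — ten independent four-gene regulons never could —
  while cross-regulon correlations (≈ 0.2) stay below the 0.3 edge
  gate. Balanced signs keep the compositional swing of total output
  second-order, mirroring the near-balanced up/down counts seen in real
  HL compendia;
* one optional outlier experiment with an extreme batch shift (log-sd
  2.0) to exercise dendrogram-based outlier detection;
* `simulate_go` plants one GO term covering a chosen fraction of a DEG
  class (plus 1 % background leakage) over a uniform background
  term map.

What the generator does **not** emulate: read-level artifacts, gene
length and GC bias, isoform structure, tagwise dispersion variation,
correlated batch effects across genes, unbalanced designs, or real GO
topology. Passing tests therefore demonstrate statistical correctness
and recovery under the stated model, not performance on any real
compendium.

## Problem sizes and numerics

The test and acceptance profiles use 10 000-gene single-experiment
studies for calibration (3v3 null, 5v5 planted), a 1 500-gene
20-condition compendium for vote-counting recovery, and 1 000-gene
30-condition studies with 10 TFs × 3 targets for network recovery
(network run on the 10 TFs + 100 candidate targets). Network recovery
is reported pooled over two replicate studies because a single draw of
this size carries several points of Monte-Carlo noise in precision.
Numerical conventions: quantiles by linear interpolation; average
ranks for TMM trimming ties; exact-test tie comparisons with 1e-10
log-space tolerance so symmetric splits yield p = 1; dispersion search
tolerance 1e-4 on log₁₀ φ; empirical p-values never 0 (+1 correction).

## Known limitations

* Common (not tagwise) dispersion; multi-factor designs and GLM/QL
  testing are out of scope.
* The exact test's scaling+rounding approximation differs from
  quantile-adjusted implementations in third-party tools; agreement is
  with the stated model, verified by enumeration.
* The static module cut is cruder than dynamic tree cutting; very
  close modules may merge.
* 1 − |r| clustering on linear CPM is dominated by abundant genes — a
  faithful reproduction of the published protocol rather than a
  recommendation.
* GO enrichment without DAG propagation understates ancestor terms.
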