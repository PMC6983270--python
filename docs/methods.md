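# Methods

## The model

A cell's marker-gene expression vector `y` is modeled as a convex
combination of reference cell-state signatures: `y ≈ S·x` with `x ≥ 0` and
`Σx = 1`. The weight vector `x` — the deconvolution cell profile (DCP) —
is the fractional contribution estimate of each reference state. A singlet
should concentrate its DCP on one reference; a heterotypic doublet spreads
it over the two states of its parent cells. The pipeline:

1. **Label standardization / optional cell-cycle removal.** Cluster labels
   become 1..K integers (order of first appearance along the cell axis,
   preserving the clustered-heatmap ordering). Optionally, gene clusters
   enriched for cell-cycle genes (one-sided hypergeometric against the
   marker-table universe, BH-adjusted across gene clusters, adjusted
   p ≤ 0.05) are dropped: cycling subpopulations split one cell type into
   several clusters and corrupt the references. Off by default.
2. **Cluster merging.** Pairwise Pearson correlation `r_ij` of per-cluster
   signatures (per-gene centroid by default, marginal medoid as the robust
   alternative) is binarized at `ρ_T = mean(r_ij) + ρ′·sd(r_ij)`, the mean
   and *sample* sd taken over the off-diagonal upper triangle. If any pair
   passes, Markov clustering (MCL) on the binary matrix defines the merged
   references, whose signatures are recomputed from the pooled member cells.
   Redundant clusters must merge because synthetic doublets built between
   near-identical clusters look like singlets and inflate the call rate.
3. **Synthetic doublets.** For every pair of merged references,
   `num_doubs` profiles per weight class: the 50/50 average of two sampled
   cells ("even"), plus 70/30 ("one") and 30/70 ("two") unless
   `only50`. Cells are sampled uniformly with replacement.
4. **Remove.** Every real cell, every synthetic profile, and every
   reference signature is deconvolved against the references. A cell whose
   DCP is more similar to a synthetic set's mean DCP than to any reference
   centroid DCP is a putative doublet. Similarity is Pearson correlation
   for n > 2 references and negative Euclidean distance for n = 2 (length-2
   DCPs sum to 1, making Pearson degenerate at ±1); exact ties resolve
   toward singlet.
5. **Recluster.** Putative doublets group by their two largest DCP
   components ("a|b", ids sorted; weight-class suffix ".even/.one/.two"
   appended in weighted mode). They leave their original clusters.
6. **Rescue.** Per doublet cluster, genes *uniquely expressed* there are
   counted: overall one-way ANOVA p ≤ 0.05, Tukey-adjusted contrast
   against **every** retained cluster p ≤ 0.05, and strictly highest mean
   in the doublet cluster. Clusters with ≥ U unique genes are rescued
   wholesale (all-or-none, matching the cluster-level semantics of the
   procedure); the rest are final doublets. Genuine transitional states
   carry genes expressed nowhere else and survive; true doublets, being
   mixtures, have no expression their parents lack.

## Numerical choices

* **Deconvolution solver.** The simplex-constrained least-squares problem
  is solved exactly by a primal active-set method: equality-constrained
  least squares on the free variable set via the KKT system (solved with
  `lstsq`, so rank-deficient signature matrices degrade gracefully with a
  warning), bound activation by ratio test, release by most-negative
  multiplier. Tiny negative weights in (−1e−9, 0) are clipped and the
  vector renormalized. A `zscore-columns` scale mode is exposed because
  deconvolution packages differ in internal column scaling; the default
  (`none`) is the simpler behavior and the one the tests characterize.
* **ρ_T statistics.** Mean and sample sd over the off-diagonal upper
  triangle only; including the unit diagonal would bias ρ_T upward when
  clusters are few. With exactly two clusters there is a single pair, the
  sample sd is undefined, and no merging occurs (matching the observed
  behavior of sd-based thresholds on length-1 samples).
* **MCL.** Column-stochastic flow matrix with self-loops; expansion 2,
  inflation 2, ≤ 100 iterations, convergence at max-norm change < 1e−6;
  values < 1e−12 pruned. Clusters are read from attractor rows; attractor
  supports sharing an attractor merge; a node attracted by several
  clusters goes to the lowest-indexed one. Non-convergence raises.
* **Aggregated ANOVA.** The rescue tests run on 1,000-gene chunks and use
  only per-cluster total sums (TS) and sums of squares (TSS):
  `SS_between = Σ TS_g²/n_g − (ΣTS)²/N`, `SS_within = Σ(TSS_g − TS_g²/n_g)`,
  so memory stays bounded for full-transcriptome matrices and results are
  bitwise independent of chunk boundaries. Tukey–Kramer p-values come from
  the studentized range distribution with the pooled MSE. Zero
  within-group variance gives p = 0 for a nonzero between-group difference
  and p = 1 otherwise; all-equal genes get F = 0, p = 1 and can never be
  unique. The expensive studentized-range integral is evaluated only for
  genes that can still qualify as unique (overall test significant, focal
  mean strictly highest); the unscreened path is retained and tested
  against direct per-gene computation.
* **Determinism.** One global seed drives every stochastic stage; multi-run
  consensus spawns per-run seeds from a `SeedSequence` of the global seed.
  Two runs with the same seed produce byte-identical tabular outputs.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `rhop` (ρ′) | 1.0 | scaling of the merge threshold; typical range 0.5–1.5, lower merges more |
| `only50` | off | even-weight synthetics only (specificity-biased); default adds 70/30 + 30/70 (sensitivity-biased) |
| `num_doubs` | 100 | synthetic doublets per pair and weight class; for datasets over ~1,000 cells, ~10% of the cell count is a better guide |
| `min_uniq` (U) | 4 | unique genes needed to rescue a doublet cluster; 30 when testing the full gene list (`use_full`) |
| `centroid/medoid` | centroid | medoids only advisable when doublets materially shift cluster means |
| `remove_cc` | off | cell-cycle gene-cluster removal (needs gene clusters) |
| `n_runs` | 1 | runs for the all-runs consensus doublet set (consensus raises specificity) |

The significance level of the rescue tests is fixed at 0.05 and the ANOVA
chunk size at 1,000 genes; neither is a tuning knob.

## What the synthetic fixtures emulate — and what they do not

The generator (`decondoublet.simulate`) produces cluster-structured
log-normalized expression: per-cluster disjoint marker blocks lifted by
`marker_effect` (default 3.0) over a low background, additive Gaussian
noise in log space (`noise_sd` 0.5), and a per-cell lognormal
transcriptional-activity factor (`activity_sd` 1.25 on the log2 scale).
The activity factor is essential to the study conditions: a real doublet's
two cells differ in total transcriptional output, so even a doublet formed
from equal cell numbers shows uneven effective contributions — the reason
weighted 30/70 synthetics detect doublets that even-weight synthetics
miss. A heterotypic doublet therefore mixes two independently
activity-scaled cells (log-space weighted average); a homotypic doublet
mixes two cells of one cluster; a transitional cell is a *single* cell
co-expressing two programs under *one* activity factor, plus a block of
`n_unique_genes` expressed nowhere else. Doublet and transitional cells
enter the input labeling under their first parent cluster — upstream
clustering has failed to isolate them, which is the regime the detector
targets. A negative-binomial count mode (counts → CPM → log2) probes
robustness to count-space mixing.

What passing these fixtures does **not** show about real data: there is no
ambient RNA, no dropout structure beyond the activity factor, no batch or
donor effects, markers are perfectly disjoint, and clusters are far better
separated than in tissue. Fixture sensitivities near 100% are an upper
bound; published benchmarks on experimentally demultiplexed PBMCs put
realistic sensitivity for deconvolution-based calling near 40–60% at
~80% specificity, largely because homotypic doublets (invisible to this
method and to its alternatives) count against recall there.

## Design choices where the design was open

* Cells are sampled **with replacement** when building synthetics, so
  small clusters remain usable.
* Synthetic mixing happens in the provided (log-normalized) value space;
  the fixture's spiked doublets are formed the same way for core tests.
* Rescue granularity is the whole doublet cluster (all-or-none). A
  per-cell unique-gene filter within rescued clusters is described only
  qualitatively in the literature and is not implemented.
* The enrichment statistic for cell-cycle screening is pinned to the
  one-sided hypergeometric test with the marker-table universe, one test
  per gene cluster, BH across clusters. The gene set ships as a bundled,
  user-overridable GMT (a curated KEGG-cell-cycle-derived symbol list;
  mouse symbols by case convention) so no network access is needed.
* The tab-delimited input dialect is pinned (see `io_formats`): upstream
  tools never formalized it, so byte-compatibility with other
  implementations' readers is not guaranteed.
* Problem sizes in the shipped tests and the acceptance script (two
  populations × 500 cells, 50-gene marker blocks, 100 spiked doublets,
  100 synthetics per set, 20-run consensus) were chosen as the smallest
  configuration in which all of the method's contrasts — weighted vs even
  synthetics, homotypic invisibility, transitional rescue — are clearly
  expressed.

## Known limitations

* Homotypic doublets are undetectable by construction (their DCPs look
  like singlets); the fixture asserts this rather than fighting it.
* Multiplets of more than two cells are out of scope.
* Performance depends on accurate upstream clustering and sane ρ′; badly
  merged or unmerged references over- or under-call doublets.
* With exactly two references the n = 2 Euclidean branch makes the
  remove step depend on absolute DCP distances, which is sensitive to
  reference DCPs not being exactly unit vectors.
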