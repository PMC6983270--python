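# decondoublet

Deconvolution-based detection of heterotypic doublets in single-cell
RNA-seq, with rescue of transitional and mixed-lineage cell states.

## The problem

Droplet and well-based scRNA-seq platforms co-capture two cells in a single
library at appreciable rates. Doublets between *distinct* cell types
(heterotypic) produce hybrid expression profiles that masquerade as novel
cell states and corrupt downstream clustering and trajectory analysis. The
difficulty is that genuine biology also produces hybrid profiles:
transitional states and multi-lineage progenitors co-express the programs
of two lineages. A detector that removes everything hybrid-looking throws
those cells away.

`decondoublet` addresses both sides. For each cell it computes a
**deconvolution cell profile (DCP)** — the solution of

```
minimize ‖S·x − y‖²   subject to   x ≥ 0,  Σᵢ xᵢ = 1
```

where `y` is the cell's marker-gene expression and `S` the matrix of
(merged) cluster centroid signatures. The DCP `x` estimates the fractional
contribution of each reference cell state and sums to 1. Cells whose DCP is
closer to the mean DCP of **synthetic doublets** (weighted averages of
sampled cell pairs, 50/50 and optionally 70/30 + 30/70) than to any real
cluster's centroid DCP are flagged (*remove*), grouped by their two top
contributing clusters (*recluster*), and then returned to singlet status if
their group expresses at least `U` genes significantly and uniquely —
one-way ANOVA plus Tukey-adjusted contrasts against every retained cluster,
with a strictly higher mean (*rescue*).

Before any of this, transcriptionally similar input clusters are merged:
pairwise Pearson correlations `r_ij` of the cluster signatures are
binarized at the data-driven threshold `ρ_T = mean(r_ij) + ρ′·sd(r_ij)` and
Markov clustering on the binary matrix defines the merged references.

The intended users are scRNA-seq analysts with clustered output from an
unsupervised workflow (ICGS-style marker/groups files, or Seurat-style
exports) who want doublets removed without losing transitional biology.

## Worked example

Simulate a ground-truth fixture (two populations of 500 cells with
disjoint 50-gene marker blocks, plus 10% spiked even-weight heterotypic
doublets), run the detector, and score it:

```bash
decondoublet simulate --seed 7 --out fixture/
decondoublet run --expression fixture/expression.txt \
    --groups fixture/groups.txt --out run/ --seed 7
```

The run prints (stderr log abridged):

```
"rho_T": Infinity,            # 2 input clusters: merging threshold undefined, no merge
"n_putative_doublets": 167,
"n_rescued": 0,
"n_final_doublets": 167
final doublets: 167 / 1100 cells -> run/
```

Scoring against the simulated truth:

```bash
awk -F'\t' 'NR>1{print $1}' run/Final_doublets_groups.txt > calls.txt
awk -F'\t' 'NR>1{print $1"\t"($2=="singlet"?0:1)}' fixture/truth.tsv > truth.txt
decondoublet evaluate --calls calls.txt --truth truth.txt --mode single
```

```
TP      FP      TN      FN      sensitivity     specificity     f1
100     67      933     0       100.0           93.3            0.75
```

All 100 spiked doublets are recovered; the 67 false positives are
predominantly cells whose per-cell transcriptional activity makes their DCP
doublet-like, the known failure mode of deconvolution-based detection.
Running with `--only50` (even-weight synthetics only) trades sensitivity
for specificity: 98.0 / 98.3 on the same fixture.

Other subcommands: `seurat-prep` converts Seurat-style exports,
`sweep-rhop` tabulates the merge partition across a range of ρ′, and
`evaluate --mode {union,intersection,consensus}` combines call sets from
several tools or runs.

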