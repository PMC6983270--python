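"""Ground-truth synthetic scRNA-seq fixtures for end-to-end testing.

The generator emulates cluster-structured log-normalized expression with
per-cluster marker-gene blocks: each singlet carries its own cluster's
markers lifted by ``marker_effect`` over a low background, with additive
Gaussian noise in log space. Heterotypic doublets are weighted mixtures of
two sampled singlets from distinct clusters (mirroring how real doublets
superimpose two transcriptomes in log-normalized data); homotypic doublets
mix two cells of one cluster. An optional transitional population carries a
hybrid profile of two parent clusters plus a block of genes expressed
nowhere else — the signature that lets the rescue step tell a genuine
mixed-lineage state from a doublet.

Doublet and transitional cells enter the cell-cluster labeling under their
first parent cluster: upstream clustering has, by construction, failed to
recognize them as separate populations, which is precisely the regime the
detector targets. Truth labels for every cell are returned alongside.

An alternative negative-binomial count mode (counts -> CPM -> log2) is
included to probe robustness to count-space doublet formation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import AnnotatedExpression

__all__ = ["SimulationParams", "simulate_dataset"]


@dataclass
class SimulationParams:
    """Fixture geometry and noise model.

    Defaults give two clearly separated populations of 500 cells each with
    disjoint 50-gene marker blocks and a 10% spiked even-weight heterotypic
    doublet load (the detector assumes accurate upstream clustering, so the
    default geometry keeps clusters unambiguous: marker lift 3.0 vs noise
    sd 0.5 in log space).
    """

    n_clusters: int = 2
    cells_per_cluster: int = 500
    n_marker_genes_per_cluster: int = 50
    n_background_genes: int = 50
    marker_effect: float = 3.0
    noise_sd: float = 0.5
    base_level: float = 0.5
    activity_sd: float = 1.25  # sd of per-cell log2 transcriptional activity
    doublet_rate: float = 0.1
    # mapping weight-of-first-parent -> probability
    doublet_weight_distribution: dict = field(default_factory=lambda: {0.5: 1.0})
    homotypic_fraction: float = 0.0
    transitional_cluster: bool = False
    n_unique_genes: int = 10
    n_transitional_cells: int = 50
    mode: str = "lognormal"  # or "counts"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.doublet_rate <= 1 and 0 <= self.homotypic_fraction <= 1):
            raise ValueError("rates must lie in [0, 1]")
        if min(self.n_clusters, self.cells_per_cluster,
               self.n_marker_genes_per_cluster) < 1:
            raise ValueError("counts must be positive")
        if self.doublet_rate > 0 and self.n_clusters < 2:
            raise ValueError("heterotypic doublets need at least 2 clusters")
        total = sum(self.doublet_weight_distribution.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("doublet weight probabilities must sum to 1")
        if self.mode not in ("lognormal", "counts"):
            raise ValueError(f"unknown mode {self.mode!r}")


def _marker_gene_names(params: SimulationParams) -> tuple[list, pd.Series]:
    genes, clusters = [], []
    for c in range(1, params.n_clusters + 1):
        for i in range(params.n_marker_genes_per_cluster):
            genes.append(f"mk{c}_{i}")
            clusters.append(c)
    if params.transitional_cluster:
        for i in range(params.n_unique_genes):
            genes.append(f"uq_{i}")
            clusters.append(params.n_clusters + 1)
    return genes, pd.Series(clusters, index=genes)


def _base_profile(
    cluster: int, params: SimulationParams, n_genes: int,
    marker_slices: dict, rng: np.random.Generator,
) -> np.ndarray:
    """Cluster signal + log-space Gaussian noise, before activity scaling."""
    prof = np.full(n_genes, params.base_level)
    lo, hi = marker_slices[cluster]
    prof[lo:hi] += params.marker_effect
    prof += rng.normal(0.0, params.noise_sd, size=n_genes)
    return np.clip(prof, 0.0, None)


def _apply_activity(
    log_prof: np.ndarray, params: SimulationParams, rng: np.random.Generator,
) -> np.ndarray:
    """Scale the cell's linear expression by a per-cell activity factor.

    Cells differ widely in total transcriptional output / capture depth;
    this is what makes the effective contributions of a doublet's two cells
    uneven even when their transcripts mix 50/50 by cell count. A zero stays
    a zero (log2(s * 0 + 1) = 0).
    """
    if params.activity_sd == 0:
        return log_prof
    s = 2.0 ** rng.normal(0.0, params.activity_sd)
    return np.log2(s * (2.0 ** log_prof - 1.0) + 1.0)


def simulate_dataset(
    params: SimulationParams,
) -> tuple[AnnotatedExpression, pd.DataFrame, AnnotatedExpression]:
    """Generate (marker table, truth table, full table) from the parameters.

    The truth table is indexed by cell with columns ``kind`` (singlet /
    heterotypic_doublet / homotypic_doublet / transitional), ``parent_a``,
    ``parent_b`` and ``weight``. The number of spiked doublets is
    ``round(doublet_rate * number of singlets)``. Byte-identical output for
    a given seed.
    """
    rng = np.random.default_rng(params.seed)
    marker_genes, gene_cluster = _marker_gene_names(params)
    bg_genes = [f"bg_{i}" for i in range(params.n_background_genes)]
    all_genes = marker_genes + bg_genes
    n_genes = len(all_genes)

    marker_slices = {}
    for c in range(1, params.n_clusters + 1):
        lo = (c - 1) * params.n_marker_genes_per_cluster
        marker_slices[c] = (lo, lo + params.n_marker_genes_per_cluster)
    uq_lo = params.n_clusters * params.n_marker_genes_per_cluster
    uq_hi = uq_lo + (params.n_unique_genes if params.transitional_cluster else 0)

    def draw_cell(cluster: int) -> np.ndarray:
        """One cell's observed profile: signal + noise + its own activity."""
        return _apply_activity(
            _base_profile(cluster, params, n_genes, marker_slices, rng),
            params, rng,
        )

    profiles: list[np.ndarray] = []
    labels: list[int] = []
    truth_rows: list[dict] = []
    names: list[str] = []

    n_singlets = params.n_clusters * params.cells_per_cluster
    for c in range(1, params.n_clusters + 1):
        for i in range(params.cells_per_cluster):
            profiles.append(draw_cell(c))
            labels.append(c)
            names.append(f"cell_s{c}_{i}")
            truth_rows.append(
                {"kind": "singlet", "parent_a": c, "parent_b": c, "weight": 1.0}
            )

    n_doublets = int(round(params.doublet_rate * n_singlets))
    weights = sorted(params.doublet_weight_distribution)
    probs = [params.doublet_weight_distribution[w] for w in weights]
    for i in range(n_doublets):
        homo = rng.random() < params.homotypic_fraction
        if homo:
            a = int(rng.integers(1, params.n_clusters + 1))
            b = a
        else:
            a, b = rng.choice(
                np.arange(1, params.n_clusters + 1), size=2, replace=False
            )
            a, b = int(a), int(b)
        w = float(rng.choice(weights, p=probs))
        # two cells, each with its own activity, mixed in log space
        prof = w * draw_cell(a) + (1.0 - w) * draw_cell(b)
        profiles.append(prof)
        labels.append(a)
        names.append(f"cell_d_{i}")
        truth_rows.append(
            {
                "kind": "homotypic_doublet" if homo else "heterotypic_doublet",
                "parent_a": a, "parent_b": b, "weight": w,
            }
        )

    if params.transitional_cluster:
        if params.n_clusters < 2:
            raise ValueError("a transitional cluster needs two parent clusters")
        for i in range(params.n_transitional_cells):
            # one genuine cell co-expressing both programs: a single
            # activity factor applied after mixing the signals
            base = 0.5 * _base_profile(1, params, n_genes, marker_slices, rng) \
                + 0.5 * _base_profile(2, params, n_genes, marker_slices, rng)
            lift = params.marker_effect + rng.normal(
                0.0, params.noise_sd, size=params.n_unique_genes
            )
            base[uq_lo:uq_hi] = np.clip(lift, 0.0, None)
            prof = _apply_activity(base, params, rng)
            lift = params.marker_effect + rng.normal(
                0.0, params.noise_sd, size=params.n_unique_genes
            )
            prof[uq_lo:uq_hi] = np.clip(lift, 0.0, None)
            profiles.append(prof)
            labels.append(1)
            names.append(f"cell_t_{i}")
            truth_rows.append(
                {"kind": "transitional", "parent_a": 1, "parent_b": 2,
                 "weight": 0.5}
            )

    mat = np.column_stack(profiles)
    if params.transitional_cluster:
        # unique genes are expressed nowhere outside the transitional cells
        non_trans = np.array(
            [row["kind"] != "transitional" for row in truth_rows]
        )
        mat[uq_lo:uq_hi, non_trans] = 0.0
    if params.mode == "counts":
        mat = _to_count_space(mat, rng)

    values = pd.DataFrame(mat, index=all_genes, columns=names)
    cell_cluster = pd.Series(labels, index=names)
    truth = pd.DataFrame(truth_rows, index=names)
    truth.index.name = "cell"

    # order cells so same-cluster cells are contiguous
    order: list = []
    for c in range(1, params.n_clusters + 1):
        order.extend([nm for nm, lab in zip(names, labels) if lab == c])
    values = values[order]
    cell_cluster = cell_cluster.loc[order]
    truth = truth.loc[order]

    marker_ae = AnnotatedExpression(
        values.loc[marker_genes], cell_cluster, gene_cluster
    )
    full_ae = AnnotatedExpression(values, cell_cluster)
    return marker_ae, truth, full_ae


def _to_count_space(log_mat: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Resample profiles as negative-binomial counts, then CPM + log2."""
    mean = 2.0 ** log_mat - 1.0
    mean = np.clip(mean, 1e-6, None)
    dispersion = 0.2
    r = 1.0 / dispersion
    p = r / (r + mean)
    counts = rng.negative_binomial(r, p).astype(float)
    lib = counts.sum(axis=0, keepdims=True)
    lib[lib == 0] = 1.0
    cpm = counts / lib * 1e6
    return np.log2(cpm + 1.0)
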