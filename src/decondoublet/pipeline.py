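"""End-to-end orchestration: preprocess -> merge -> synthetics ->
deconvolution -> remove -> recluster -> rescue -> outputs.

A single global seed drives every stochastic stage; with ``n_runs > 1`` the
pipeline is repeated with per-run seeds spawned deterministically from the
global one and an all-runs consensus doublet set (cells called in every
run) is additionally reported.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import calls as calls_mod
from . import deconvolution as deconv
from .evaluation import consensus_runs
from .io_formats import AnnotatedExpression, OutputBundle, read_icgs, write_outputs
from .merge import merge_clusters
from .preprocess import bundled_cell_cycle, read_gmt, remove_cell_cycle, standardize_labels
from .synthetics import generate_synthetics

__all__ = ["RunConfig", "PipelineResult", "detect_doublets", "run_pipeline"]


@dataclass
class RunConfig:
    """All knobs of one pipeline run (defaults match the recommended use)."""

    expression_path: str | None = None
    groups_path: str | None = None
    full_expression_path: str | None = None
    output_dir: str | None = None
    rhop: float = 1.0
    only50: bool = False
    num_doubs: int = 100
    min_uniq: int | None = None  # default 4, or 30 when use_full
    use_full: bool = False
    mode: str = "centroid"       # or "medoid"
    scale_mode: str = "none"
    remove_cc: bool = False
    species: str = "Hs"
    cc_gmt: str | None = None
    mcl_inflation: float = 2.0
    seed: int = 0
    n_runs: int = 1

    def resolved_min_uniq(self) -> int:
        if self.min_uniq is not None:
            return self.min_uniq
        return 30 if self.use_full else 4


@dataclass
class PipelineResult:
    calls: calls_mod.DoubletCalls
    bundle: OutputBundle
    rescue: calls_mod.RescueReport
    log: dict
    consensus_doublets: set | None = None
    run_doublet_sets: list | None = None


def detect_doublets(
    ae: AnnotatedExpression,
    full_ae: AnnotatedExpression | None = None,
    config: RunConfig | None = None,
) -> PipelineResult:
    """Run the core detection on an in-memory expression table."""
    cfg = config or RunConfig()
    log: dict = {"config": {k: v for k, v in asdict(cfg).items()}}

    ae, label_map = standardize_labels(ae)
    log["label_map"] = {str(k): v for k, v in label_map["cells"].items()}
    if cfg.remove_cc:
        gene_sets = (
            read_gmt(cfg.cc_gmt) if cfg.cc_gmt else bundled_cell_cycle(cfg.species)
        )
        ae, cc_report = remove_cell_cycle(ae, gene_sets)
        log["cell_cycle_removed_clusters"] = [
            str(c) for c in cc_report.loc[cc_report["removed"], "gene_cluster"]
        ]

    decision, refs = merge_clusters(
        ae, rho_prime=cfg.rhop, mode=cfg.mode, inflation=cfg.mcl_inflation
    )
    log["rho_T"] = float(decision.rho_T)
    log["merge_partition"] = {str(k): v for k, v in decision.partition.items()}
    log["n_merged_clusters"] = len(refs.merged_ids)

    merged_labels = ae.cell_cluster.map(decision.partition)
    merged_ae = AnnotatedExpression(ae.values, merged_labels, ae.gene_cluster)

    synth = generate_synthetics(
        merged_ae, refs, num_doubs=cfg.num_doubs, only50=cfg.only50, seed=cfg.seed
    )
    cell_dcps = deconv.dcp_table(merged_ae.values, refs, scale_mode=cfg.scale_mode)
    ref_dcps = deconv.reference_dcps(refs, scale_mode=cfg.scale_mode)
    synth_dcps, synth_means = deconv.synthetic_mean_dcps(
        synth, refs, scale_mode=cfg.scale_mode
    )

    calls = calls_mod.remove_step(
        cell_dcps, ref_dcps, synth_means, merged_ae.cell_cluster
    )
    log["n_putative_doublets"] = int(
        (calls.table["state"] == "putative_doublet").sum()
    )
    calls = calls_mod.recluster_step(calls, cell_dcps, only50=cfg.only50)
    full_for_rescue = None
    if cfg.use_full:
        if full_ae is None:
            raise ValueError("use_full requires the full expression matrix")
        full_for_rescue = AnnotatedExpression(
            full_ae.values, merged_labels, full_ae.gene_cluster
        )
    calls, rescue = calls_mod.rescue_step(
        calls, merged_ae, U=cfg.resolved_min_uniq(),
        full_expression=full_for_rescue,
    )
    log["n_rescued"] = int((calls.table["state"] == "rescued_singlet").sum())
    log["n_final_doublets"] = int(
        (calls.table["state"] == "final_doublet").sum()
    )

    doublets = calls.final_doublets
    non_doublets = calls.non_doublets
    table = calls.table
    bundle = OutputBundle(
        drs_doublet_table=table[
            ["original_cluster", "best_match", "similarity", "state"]
        ].assign(
            is_putative_doublet=table["state"].isin(
                ["putative_doublet", "rescued_singlet", "final_doublet"]
            )
        ),
        drs_results=cell_dcps,
        final_doublets_groups=table.loc[doublets, ["final_label", "state"]],
        final_nondoublets_groups=table.loc[non_doublets, ["final_label", "state"]],
        final_doublets_exp=merged_ae.values[doublets],
        final_nondoublets_exp=merged_ae.values[non_doublets],
        synthetic_dcps=synth_dcps,
    )
    return PipelineResult(calls=calls, bundle=bundle, rescue=rescue, log=log)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """File-based pipeline run, optionally repeated for a consensus call set."""
    if config.expression_path is None or config.groups_path is None:
        raise ValueError("expression_path and groups_path are required")
    loaded = read_icgs(
        config.expression_path, config.groups_path, config.full_expression_path
    )
    if config.full_expression_path is not None:
        ae, full_ae = loaded
    else:
        ae, full_ae = loaded, None

    if config.n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    run_seeds = _spawn_seeds(config.seed, config.n_runs)
    results = []
    for rs in run_seeds:
        cfg = RunConfig(**{**asdict(config), "seed": int(rs), "n_runs": 1})
        results.append(detect_doublets(ae, full_ae, cfg))
    primary = results[0]
    if config.n_runs > 1:
        sets = [set(r.calls.final_doublets) for r in results]
        primary.consensus_doublets = consensus_runs(sets)
        primary.run_doublet_sets = sets
        primary.log["n_consensus_doublets"] = len(primary.consensus_doublets)
    primary.log["run_seeds"] = [int(s) for s in run_seeds]

    if config.output_dir is not None:
        os.makedirs(config.output_dir, exist_ok=True)
        write_outputs(primary.bundle, config.output_dir)
        if primary.consensus_doublets is not None:
            pd.Series(
                sorted(primary.consensus_doublets), name="cell"
            ).to_csv(
                os.path.join(config.output_dir, "Consensus_doublets.txt"),
                sep="\t", index=False,
            )
        with open(os.path.join(config.output_dir, "run.log"), "w") as fh:
            json.dump(primary.log, fh, indent=2, default=str)
    return primary


def _spawn_seeds(seed: int, n: int) -> list[int]:
    if n == 1:
        return [seed]
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(n) % (2**31 - 1)]
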