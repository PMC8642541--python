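"""End-to-end orchestration of the analysis chain.

Chains the stages on in-memory objects: DEG calling per organ, module
discovery per organ, module unification, GTOM clustering with median
cluster-expression profiles and betweenness hub ranking, gene-set
enrichment, and CRN inference.  Used by the command-line ``run-all`` and by
scripted analyses; every stage is also callable on its own through the
stage modules.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import degcall, modcluster, modisco, synthio
from .config import PipelineConfig
from .crn import CRNConfig, CRNResult, infer_crn
from .network import InteractionNetwork

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_pipeline", "simulate_inputs"]


@dataclass
class PipelineResult:
    degs: dict[str, degcall.DEGResult]
    modules: dict[str, modisco.RegulatoryModule]
    combined: modcluster.CombinedModule
    partition: modcluster.ClusterPartition | None
    cluster_expr: modcluster.ClusterExpression | None
    centrality: pd.DataFrame | None
    enrichment: pd.DataFrame | None
    crn: CRNResult | None
    summary: dict = field(default_factory=dict)


def simulate_inputs(config: PipelineConfig, seed: int | None = None):
    """Generate the synthetic study described by ``config.synth``."""
    s = config.synth
    return synthio.simulate_study(
        n_background=s.n_background,
        background_density=s.background_density,
        clique_sizes=list(s.clique_sizes),
        n_per_cell=s.n_per_cell,
        baseline_mean=s.baseline_mean,
        n_decoys=s.n_decoys,
        decoy_size=s.decoy_size,
        seed=config.seed if seed is None else seed,
        effect_size=s.effect_size,
        organ_effect=s.organ_effect,
        noise_sd=s.noise_sd,
        deg_rate_in=s.deg_rate_in,
        deg_rate_out=s.deg_rate_out,
    )


def run_pipeline(
    network: InteractionNetwork,
    expr: pd.DataFrame,
    meta: pd.DataFrame,
    genesets: dict[str, set[str]] | None,
    config: PipelineConfig,
) -> PipelineResult:
    """Run every stage downstream of the inputs and collect the results."""
    t0 = time.perf_counter()
    organs = sorted(set(meta["organ"]))
    background = frozenset(network.nodes & set(expr.index))
    master = np.random.SeedSequence(config.seed)
    organ_seeds = dict(zip(organs, master.spawn(len(organs))))
    (crn_seed,) = master.spawn(1)

    degs: dict[str, degcall.DEGResult] = {}
    modules: dict[str, modisco.RegulatoryModule] = {}
    for organ in organs:
        res = degcall.call_degs(expr, meta, organ, config.p_threshold, config.lfc_threshold)
        degs[organ] = res
        logger.info("%s: %d DEGs", organ, res.n_degs)
        module, _, _ = modisco.discover_module(
            network,
            deg_set=res.deg_set & background,
            background=background,
            organ_label=organ,
            n_iterations=config.iterations,
            min_size=config.min_clique_size,
            n_random_sets=config.random_sets,
            alpha=config.alpha,
            n_boot=config.bootstraps,
            rng=np.random.default_rng(organ_seeds[organ]),
            smoothing=config.smoothing,
        )
        modules[organ] = module
        logger.info(
            "%s module: %d nodes, %d edges, %d significant cliques",
            organ, len(module.nodes), len(module.edges), module.n_significant_cliques,
        )

    combined = modcluster.combine_modules(list(modules.values()), deg_results=degs)

    partition = cluster_expr = centrality = enrichment = crn_result = None
    if len(combined.nodes) >= 2:
        dissim = modcluster.gtom_dissimilarity(combined.nodes, combined.edges, m=config.gtom_m)
        partition = modcluster.cluster_proteins(
            dissim, k=config.k, cut_height=config.cut_height, linkage=config.linkage
        )
        cluster_expr = modcluster.cluster_expression_profile(partition, expr, meta)
        centrality = modcluster.betweenness_ranking(
            combined.nodes, combined.edges, top_n=config.top_n_hubs
        )
        if genesets:
            enrichment = modcluster.cluster_geneset_enrichment(
                partition, genesets, background=set(network.nodes)
            )
        if partition.n_clusters >= 2:
            crn_result = infer_crn(
                cluster_expr,
                meta,
                CRNConfig(
                    k_folds=min(config.k_folds, expr.shape[1]),
                    n_runs=config.n_runs,
                    lambda_grid_size=config.lambda_grid_size,
                    lambda_min_ratio=config.lambda_min_ratio,
                    nonzero_tol=config.nonzero_tol,
                    seed=int(crn_seed.generate_state(1)[0] % (2**31)),
                ),
            )

    summary = {
        "organs": organs,
        "n_background_genes": len(background),
        "degs": {o: degs[o].n_degs for o in organs},
        "modules": {
            o: {
                "n_nodes": len(m.nodes),
                "n_edges": len(m.edges),
                "n_significant_cliques": m.n_significant_cliques,
                "node_stability": m.node_stability,
                "edge_stability": m.edge_stability,
            }
            for o, m in modules.items()
        },
        "combined": {
            "n_nodes": len(combined.nodes),
            "n_edges": len(combined.edges),
            "n_shared": combined.n_shared,
        },
        "n_clusters": partition.n_clusters if partition else 0,
    }
    logger.info("pipeline complete in %.1f s", time.perf_counter() - t0)
    return PipelineResult(
        degs=degs,
        modules=modules,
        combined=combined,
        partition=partition,
        cluster_expr=cluster_expr,
        centrality=centrality,
        enrichment=enrichment,
        crn=crn_result,
        summary=summary,
    )
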