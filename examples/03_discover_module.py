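"""Discover a regulatory module by randomized maximal-clique sampling.

Samples maximal cliques from random seed proteins, scores each unique
clique's DEG enrichment with a Fisher exact test calibrated against random
gene sets, unifies the significant cliques into the regulatory module, and
quantifies bootstrap stability.
"""

import numpy as np

import modcrn

network, expr, meta, _, truth = modcrn.simulate_study(seed=42, n_per_cell=3)
degs = modcrn.call_degs(expr, meta, "lung")
background = frozenset(network.nodes & set(expr.index))

module, cliques, records = modcrn.discover_module(
    network,
    deg_set=degs.deg_set & background,
    background=background,
    organ_label="lung",
    n_iterations=20_000,
    n_random_sets=1_000,
    alpha=0.01,
    n_boot=50,
    rng=np.random.default_rng(7),
)

planted = set().union(*truth.planted_cliques)
print(f"sampled {sum(cliques.values())} cliques, {len(cliques)} unique (size >= 3)")
print(f"significant cliques at alpha=0.01: {module.n_significant_cliques}")
print(f"module: {len(module.nodes)} proteins, {len(module.edges)} interactions")
print(f"  of which planted: {len(module.nodes & planted)}/{len(module.nodes)}")
print(f"bootstrap stability: node {module.node_stability:.3f}, edge {module.edge_stability:.3f}")
# Stability near 1.0 means the module barely changes when the clique multiset
# is resampled with replacement — the discovery is reproducible, not a fluke
# of the randomized sampler.
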