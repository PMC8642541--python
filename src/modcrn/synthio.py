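"""Synthetic study generator with planted ground truth.

Emulates the structure of the motivating two-organ treatment study: a sparse
background interaction network containing planted cliques, and a log2-scale
expression matrix over two organs x two groups (control vs treated) x a
configurable number of biological replicates.  Treatment-responsive genes
concentrate in planted modules and carry an additive log2 treatment effect;
all genes carry an additive organ effect and i.i.d. Gaussian noise.

The generative model for gene g in sample m is

    x(g, m) = baseline + organ_effect * [m from liver]
            + effect_size * [m treated] * [g responsive] + N(0, noise_sd^2)

Responsiveness is Bernoulli per gene: probability ``deg_rate_in`` for genes
inside a responsive planted module, ``deg_rate_out`` elsewhere.

A single master seed spawns independent substreams per operation, so
re-running one stage never perturbs the draws of another.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .network import InteractionNetwork

__all__ = ["SyntheticTruth", "generate_ppin", "generate_expression", "generate_genesets", "simulate_study"]

ORGANS = ("liver", "lung")
TREATMENTS = ("control", "treated")


@dataclass
class SyntheticTruth:
    """Planted ground truth of a synthetic study.

    ``planted_cliques`` are node-disjoint cliques wired into the network;
    ``responsive_modules`` (a subset) carry the treatment effect.  Effect
    sizes are in log2 units.  ``responsive_genes`` is populated once
    expression has been generated.
    """

    planted_cliques: list[frozenset[str]]
    responsive_modules: list[frozenset[str]]
    effect_size: float = 2.0
    organ_effect: float = 1.0
    noise_sd: float = 0.5
    deg_rate_in: float = 0.7
    deg_rate_out: float = 0.05
    responsive_genes: frozenset[str] | None = None

    def __post_init__(self) -> None:
        for c in self.planted_cliques:
            if len(c) < 3:
                raise ValueError(f"planted clique of size {len(c)} < 3")
        planted = set(map(frozenset, self.planted_cliques))
        if not set(map(frozenset, self.responsive_modules)) <= planted:
            raise ValueError("responsive_modules must be a subset of planted_cliques")
        for name in ("deg_rate_in", "deg_rate_out"):
            r = getattr(self, name)
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"{name}={r} outside [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _node_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"p{i:0{width}d}" for i in range(1, n + 1)]


def generate_ppin(
    n_background: int,
    background_density: float,
    clique_sizes: list[int],
    seed: int | np.random.SeedSequence,
    *,
    n_responsive: int | None = None,
    **truth_params,
) -> tuple[InteractionNetwork, SyntheticTruth]:
    """Generate a background Erdős–Rényi network with planted, node-disjoint cliques.

    ``n_background`` is the total node count (it must cover the planted
    cliques).  Planted cliques are fully wired; every remaining node pair is
    wired independently with probability ``background_density``.  Edge
    confidence scores are drawn uniform on [0.7, 1.0] so every edge passes
    the pipeline's default confidence filter.  ``n_responsive`` selects how
    many planted cliques carry the treatment effect (default: all).
    Additional keyword arguments are forwarded to :class:`SyntheticTruth`.
    """
    if any(s < 3 for s in clique_sizes):
        raise ValueError("planted clique sizes must be >= 3")
    if not 0.0 <= background_density <= 1.0:
        raise ValueError("background_density must be in [0, 1]")
    total_planted = sum(clique_sizes)
    if n_background < total_planted:
        raise ValueError(
            f"n_background={n_background} < sum of clique sizes {total_planted}"
        )
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)

    nodes = _node_ids(n_background)
    cliques: list[frozenset[str]] = []
    pos = 0
    clique_of: dict[str, int] = {}
    for ci, size in enumerate(clique_sizes):
        members = nodes[pos : pos + size]
        pos += size
        cliques.append(frozenset(members))
        for n in members:
            clique_of[n] = ci

    edges: dict[tuple[str, str], float] = {}
    # planted cliques fully wired
    for members in cliques:
        ordered = sorted(members)
        for i, u in enumerate(ordered):
            for v in ordered[i + 1 :]:
                edges[(u, v)] = 0.0
    # background pairs (everything not inside one planted clique)
    n = n_background
    iu, ju = np.triu_indices(n, k=1)
    same = np.zeros(iu.shape[0], dtype=bool)
    cid = np.full(n, -1)
    for idx, node in enumerate(nodes):
        cid[idx] = clique_of.get(node, -1)
    same = (cid[iu] == cid[ju]) & (cid[iu] >= 0)
    draw = rng.random(iu.shape[0]) < background_density
    for a, b in zip(iu[draw & ~same], ju[draw & ~same]):
        edges[(nodes[a], nodes[b])] = 0.0
    # scores uniform [0.7, 1.0], assigned in canonical edge order for determinism
    keys = sorted(edges)
    scores = rng.uniform(0.7, 1.0, size=len(keys))
    for key, s in zip(keys, scores):
        edges[key] = float(s)

    if n_responsive is None:
        responsive = list(cliques)
    else:
        responsive = list(cliques[:n_responsive])
    truth = SyntheticTruth(planted_cliques=cliques, responsive_modules=responsive, **truth_params)
    net = InteractionNetwork.from_scored_edges(edges, extra_nodes=nodes)
    return net, truth


def generate_expression(
    truth: SyntheticTruth,
    network: InteractionNetwork,
    n_per_cell: int = 3,
    baseline_mean: float = 8.0,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Simulate log2 expression for every network node over the 2x2 design.

    Returns ``(expr, meta, truth)`` where ``truth`` is a copy carrying the
    drawn ``responsive_genes``.  Samples are laid out organ-major:
    ``liver_control_1 .. lung_treated_<n>``.
    """
    if n_per_cell < 1:
        raise ValueError("n_per_cell must be >= 1")
    planted_nodes = set().union(*truth.planted_cliques) if truth.planted_cliques else set()
    if not planted_nodes <= network.nodes:
        raise ValueError("truth refers to nodes absent from the network")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)

    genes = network.sorted_nodes()
    responsive_pool = set().union(*truth.responsive_modules) if truth.responsive_modules else set()
    p_resp = np.where(
        np.isin(genes, sorted(responsive_pool)), truth.deg_rate_in, truth.deg_rate_out
    )
    responsive = rng.random(len(genes)) < p_resp
    responsive_genes = frozenset(g for g, r in zip(genes, responsive) if r)

    samples, organ_col, treat_col = [], [], []
    for organ in ORGANS:
        for treatment in TREATMENTS:
            for rep in range(1, n_per_cell + 1):
                samples.append(f"{organ}_{treatment}_{rep}")
                organ_col.append(organ)
                treat_col.append(treatment)
    is_liver = np.array([o == "liver" for o in organ_col], dtype=float)
    is_treated = np.array([t == "treated" for t in treat_col], dtype=float)

    values = (
        baseline_mean
        + truth.organ_effect * is_liver[None, :]
        + truth.effect_size * is_treated[None, :] * responsive[:, None].astype(float)
        + rng.normal(0.0, truth.noise_sd, size=(len(genes), len(samples)))
    )
    expr = pd.DataFrame(values, index=genes, columns=samples)
    meta = pd.DataFrame({"organ": organ_col, "treatment": treat_col}, index=pd.Index(samples, name="sample"))
    return expr, meta, replace(truth, responsive_genes=responsive_genes)


def generate_genesets(
    truth: SyntheticTruth,
    network: InteractionNetwork,
    n_decoys: int = 5,
    decoy_size: int = 10,
    seed: int | np.random.SeedSequence = 0,
) -> dict[str, set[str]]:
    """One gene set per planted clique plus random decoy sets from network nodes.

    Set names encode origin: ``planted_clique_<i>`` / ``decoy_<i>``.
    """
    if decoy_size < 1:
        raise ValueError("decoy_size must be >= 1")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    nodes = network.sorted_nodes()
    width = max(2, len(str(max(len(truth.planted_cliques), n_decoys))))
    sets: dict[str, set[str]] = {}
    for i, clique in enumerate(truth.planted_cliques, start=1):
        sets[f"planted_clique_{i:0{width}d}"] = set(clique)
    for i in range(1, n_decoys + 1):
        members = rng.choice(nodes, size=min(decoy_size, len(nodes)), replace=False)
        sets[f"decoy_{i:0{width}d}"] = set(members.tolist())
    return sets


def simulate_study(
    n_background: int = 300,
    background_density: float = 0.02,
    clique_sizes: list[int] | None = None,
    n_per_cell: int = 3,
    baseline_mean: float = 8.0,
    n_decoys: int = 5,
    decoy_size: int = 10,
    seed: int = 0,
    **truth_params,
):
    """Generate a full synthetic study bundle under one master seed.

    Returns ``(network, expr, meta, genesets, truth)``.  The master seed
    spawns one independent substream per generator, so each stage's draws are
    stable regardless of the others.
    """
    if clique_sizes is None:
        clique_sizes = [6] * 8
    ss_ppin, ss_expr, ss_gmt = np.random.SeedSequence(seed).spawn(3)
    network, truth = generate_ppin(
        n_background, background_density, clique_sizes, ss_ppin, **truth_params
    )
    expr, meta, truth = generate_expression(
        truth, network, n_per_cell=n_per_cell, baseline_mean=baseline_mean, seed=ss_expr
    )
    genesets = generate_genesets(
        truth, network, n_decoys=n_decoys, decoy_size=decoy_size, seed=ss_gmt
    )
    return network, expr, meta, genesets, truth
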