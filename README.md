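# modcrn

Regulatory-module discovery and cluster-regulatory-network inference for
two-organ treatment studies on protein–protein interaction networks.

## The problem

A systemic treatment (for instance, infusing mesenchymal stromal cells after
liver surgery) perturbs gene expression in several organs at once.  Given a
confidence-scored protein–protein interaction network (PPIN), per-organ
expression profiles of treated and control animals, and nothing else, the
question is: **which parts of the interactome respond to the treatment, and
which of those responses are organ-independent?**

`modcrn` implements the full in-silico inference chain for that question:

1. **DEG calling** — per organ, a gene is differentially expressed when a
   two-sided Welch test gives raw *p* < 0.05 and |log2 fold change| ≥ 0.5.
2. **Regulatory-module discovery** — the PPIN (edges with confidence < 0.7
   removed) is fragmented into maximal cliques by a randomized sampler: each
   iteration grows a clique from a random seed protein by uniformly chosen
   common neighbours until maximal.  Each unique clique *C* is scored by a
   one-sided Fisher exact test on the 2×2 table (C∩DEG, C∖DEG; DEG∖C, rest),
   and the Fisher *p* is calibrated against the same test applied to random
   gene sets of size |DEG| drawn from the measured background:
   *p*<sub>perm</sub> = (1 + #{r : p(C, random<sub>r</sub>) ≤ p(C, DEG)}) / (R+1).
   The union of cliques with *p*<sub>perm</sub> < 0.01 — nodes plus all
   within-clique edges — is the organ's regulatory module, and its
   reproducibility is measured by bootstrap resampling of the clique
   multiset (mean fraction of module nodes/edges recovered).
3. **Module unification and clustering** — organ modules are unified; the
   combined module is partitioned by average-linkage hierarchical clustering
   of the generalized topological overlap dissimilarity
   d<sub>ij</sub> = 1 − (l<sub>ij</sub> + a<sub>ij</sub>)/(min(k<sub>i</sub>,k<sub>j</sub>) + 1 − a<sub>ij</sub>);
   each cluster gets a median expression profile, hubs are ranked by
   betweenness centrality, and clusters are annotated against gene sets
   (Fisher + Benjamini–Hochberg).
4. **Cluster regulatory network (CRN)** — each cluster profile x<sub>i</sub> is
   modelled as x̂<sub>i</sub>(m) = Σ<sub>j≠i</sub> β<sub>ij</sub>x<sub>j</sub>(m) + β<sub>i,C+1</sub>·treatment(m) + β<sub>i,C+2</sub>·organ(m)
   with an L1 constraint on β, the penalty chosen by 12-fold
   cross-validation; the procedure is repeated with fresh fold
   randomizations and an edge is reported with the **frequency** of runs in
   which it was selected.

A synthetic-study generator (`modcrn.synthio`) plants cliques in a sparse
background network and treatment-responsive genes inside them, so every
stage of the chain is verifiable against known ground truth without any
external download.

## Worked example

```bash
python examples/03_discover_module.py
```

prints, for a synthetic study with eight planted 6-cliques:

```
sampled 3397 cliques, 51 unique (size >= 3)
significant cliques at alpha=0.01: 3
module: 18 proteins, 45 interactions
  of which planted: 18/18
bootstrap stability: node 1.000, edge 1.000
```

Every protein in the discovered module lies in a planted clique (perfect
precision), three planted cliques cleared the permutation threshold under
this seed's responsive-gene draw, and the module is fully stable under
clique-multiset bootstrap.  The other examples cover simulation
(`01`), DEG calling (`02`), unification/clustering/hubs (`04`) and CRN
inference (`05` — the treatment variable attaches to the two planted
clusters in 100% of runs and to at most 3% of null clusters).

The same chain is available from the shell:

```bash
modcrn run-all --seed 11 --out results/demo
```

which writes the simulated inputs, per-organ DEG tables and modules, the
cluster partition with median profiles and centrality ranking, the gene-set
enrichment table, the CRN edge-frequency table, and a resolved config for
provenance.  Reruns with the same seed are byte-identical.

## Layout

- `src/modcrn/` — library: `synthio` (generator), `degcall`, `modisco`
  (clique sampling + permutation significance + stability), `modcluster`
  (GTOM, profiles, hubs, enrichment), `lasso` + `crn` (repeated-CV sparse
  regression), `io`, `config`, `pipeline`, `cli`.
- `examples/` — one narrative script per capability.
- `docs/methods.md` — model assumptions, parameter defaults, numerical
  choices, and known limitations.
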