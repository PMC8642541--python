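# Methods

This note documents the models, parameter choices, numerical decisions and
limitations of `modcrn`.  Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Differential expression

Expression values are assumed log2-scale after upstream summarization, so
the log2 fold change is the plain difference of group means (treated minus
control).  The per-gene test is a two-sided Welch *t*-test; a gene is a DEG
when raw *p* < 0.05 **and** |log2FC| ≥ 0.5 (strict `<` on *p*, `≥` on the
fold change).  No multiple-testing correction is applied at this stage: the
DEG list is an intermediate whose false positives are absorbed by the
permutation calibration of module discovery, which compares every clique
against random gene sets of the same size as the DEG list — an inflated
list inflates the null panels identically.  Genes with zero variance in
both groups are degenerate for the *t*-test; they receive *p* = 0 when the
means differ and *p* = 1 otherwise, which preserves the direction of
evidence without a distributional claim.

The Welch test is a deliberate stand-in for an empirical-Bayes moderated
statistic: it honours the same result contract (per-gene log2FC, *p*,
flag), so a moderated test can be swapped in behind `call_degs` without
touching downstream stages.  With only 3 biological replicates per cell the
Welch test is noticeably less powerful than a moderated one; the synthetic
default effect size (2 log2 units over 0.5-sd noise, i.e. 4σ) is large
enough that this does not matter for the planted genes.

## Regulatory-module discovery

**Clique sampling.** Exhaustive maximal-clique enumeration is infeasible on
genome-scale PPINs, so the community structure is approximated by sampling:
each iteration starts from a uniformly drawn seed protein and repeatedly
adds one node chosen uniformly at random among the nodes adjacent to every
current member, until none exists.  The result is maximal by construction,
and uniform candidate selection is the minimal assumption for an otherwise
unspecified randomization.  Cliques below size 3 are discarded;
deduplication is by canonical sorted node tuple with sampling multiplicity
retained.  The reference parameterization for a full-size network
(≈13.5k proteins) is 2,000,000 iterations; the bundled synthetic
configuration uses 15,000 iterations on a 300-node network, which saturates
the unique-clique set many times over (the sampler provably covers every
maximal clique of a graph with n ≤ 15 within 10,000 iterations in the test
suite's exhaustive comparison).

**Enrichment significance.** Each unique clique gets a one-sided Fisher
exact *p* (hypergeometric upper tail) for its DEG overlap against the
statistical background, defined as network nodes ∩ measured genes.  The
Fisher *p* alone is biased by clique size and background composition, so it
is calibrated against an empirical null: one shared panel of R random gene
sets of size |DEG| (R = 10,000 at reference scale; 500–1,000 in the scaled
configurations), and

permutation p = (1 + #{r : p(C, random_r) ≤ p(C, DEG)}) / (R + 1).

Ties count against the observed clique and the add-one smoothing keeps the
p-value away from zero; this is the standard valid-permutation-p
convention.  A strict-inequality variant without tie counting
(`tie_policy="strict"`) is available because some discovery tools use it;
it is anti-conservative — on the synthetic benchmark it admits triangles
with 2 responsive members of 3, trading precision for recall.  Because all
random sets share one size, the p-value comparison is implemented as the
exact equivalent overlap comparison, avoiding floating-point tie artifacts.
Significance is permutation *p* < α with α = 0.01.

A calibration consequence worth knowing: with the synthetic defaults
(8 planted 6-cliques, responsiveness 0.7 inside / 0.05 outside, 500 nodes)
the DEG list is ≈57 genes, and a clique with 3 responsive members has a
valid permutation *p* of ≈0.02 — above α.  Significance therefore requires
≥4 responsive members, which caps expected node recall of planted cliques
at P(Bin(6, 0.7) ≥ 4) ≈ 0.74 while keeping node precision near 1.  This is
a property of the test at these rates, not of the sampler; the acceptance
script reports the measured recall and precision.

**Assembly and stability.** The module is the union of significant cliques:
nodes plus all within-clique pairs (each pair is a network edge because
cliques are complete).  The full induced subgraph on the module nodes is
deliberately *not* taken — edges outside any significant clique carry no
enrichment evidence.  Stability: the enumerated clique multiset is
bootstrap-resampled with replacement to its original total count,
significance and assembly are re-run, and the mean fraction of
reference-module nodes/edges present across bootstraps is reported.  A
clique's permutation *p* does not depend on its multiplicity, so the
bootstrap re-scoring reduces exactly to presence (drawn at least once);
the implementation exploits this, and the test suite checks the resulting
inclusion probabilities against the closed-form multinomial model.  An
empty reference module reports stability (1.0, 1.0) with a warning — there
is nothing to destabilize.  Module similarity between two modules is
(shared nodes + shared edges)/(union nodes + union edges), the
graph-edit-distance–style score; two empty modules score 1.

## Combined module, GTOM clustering, hubs

Organ modules are unified by plain node/edge union; nodes present in
modules of two or more organs are flagged `both` (the organ-independent
candidates).  Clustering uses the generalized topological overlap measure
on the **unweighted** combined-module graph (module edges carry no weights
after assembly): for order m = 1,

t_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij),  d = 1 − t,

with l_ij the shared-neighbour count; for m ≥ 2 the adjacency is first
replaced by the m-step reachability indicator.  The default order is m = 1;
m = 2 is available when one-step overlap is too sparse.  Hierarchical
clustering uses average linkage (the standard companion of topological
overlap; complete and single are available).  When neither a cluster count
k nor a cut height is supplied, k maximizes the mean silhouette width over
k ∈ [2, min(30, ⌊n/3⌋)], smallest k on ties — a deterministic default for
studies that do not state their cut.  Cluster IDs are dense integers from
1, assigned by each cluster's lexicographically smallest member so
partitions are stable across runs.

Cluster expression is the per-sample median over member proteins; members
missing from the expression matrix are dropped with a warning and a fully
unmeasured cluster is an error.  The z-scaled copy (per-cluster, across
samples, n−1 denominator) is what a heatmap should show.  Hub ranking uses
unnormalized shortest-path betweenness with even splitting across
equal-length paths, ties broken lexicographically by protein ID; weights
are ignored for the same reason GTOM is unweighted.  Cluster annotation is
a one-sided Fisher test per (cluster, gene set) with Benjamini–Hochberg
adjustment across the whole table; it is a generic gene-set mechanism (GMT
input), not an ontology pipeline.

## Cluster regulatory network

The model for target cluster i has no intercept; centering the response
and all predictors per fit (binary indicators included) is algebraically
equivalent to an unpenalized intercept and prevents mean shifts from
masquerading as sparsity.  The treatment and organ indicators are penalized
exactly like cluster predictors.  The constrained L1 formulation is solved
in the equivalent penalized (Lagrangian) form, so "λ" throughout means the
penalty weight, not the budget.  Constant predictor columns (e.g. the organ
indicator in a single-organ design) are dropped with a warning.

**Solver.** Cyclic coordinate descent with soft-thresholding on precomputed
Gram statistics, warm-started along a descending log-spaced grid of 100
penalties from the analytic λ_max = max_j |⟨x_j, y⟩|/M (standardized
predictors, centered response) down to λ_max·10⁻⁴.  Final fits converge at
max coefficient change < 10⁻⁷ (cap 10⁵ sweeps).  Cross-validation path
fits use a looser tolerance (10⁻⁴, 25-sweep cap) with glmnet-style
active-set iteration: with p ≈ n designs and tiny penalties the minimizer
is not unique and strict coefficient-change convergence stalls without
affecting the held-out error curve anywhere near the selected penalty, and
the repeated-CV loop performs tens of thousands of path fits.  The inner
kernel is numba-compiled.  The solver is cross-checked in the test suite
against a normal-equations OLS oracle at λ→0, the soft-threshold closed
form on an exactly orthonormal design, and an independent coordinate
descent implementation.

**Penalty selection.** k-fold cross-validation (default k = 12) with
random, organ×treatment-stratified fold assignment.  The default selection
rule is **λ-1se** — the largest penalty whose mean CV error is within one
standard error (computed across folds) of the minimum — matching the
coefficient-extraction default of the reference LASSO implementation this
procedure emulates; minimum-CV selection is available as
`lambda_rule="min"`.  The 1se rule is the right default here because
repeated CV re-randomizes *folds*, never the data: a null cluster whose
profile has a chance correlation with the treatment indicator (|r| up to
≈0.4 at 24 samples) is selected by the min-CV rule in essentially every
run, saturating its edge frequency.  The 1se rule suppresses most, but not
all, such dataset-level chance structure — with ~18 null clusters at
n = 24, the strongest chance correlate can still exceed the one-SE bar and
acquire a high frequency.  This is an inherent small-sample property of
repeated CV on a fixed dataset (the reference R implementation reproduces
it), and it is why CRN edge frequencies should be read as stability
evidence *given this dataset*, not as false-positive-controlled p-values.

**Repetition.** Fold assignment is the only stochastic element per run
(reference: 1000 repetitions; scaled configurations use 50–200).  With
k equal to the sample count the folds are leave-one-out, every run is
identical, and the tool warns that frequencies degenerate to {0, 1}.
Frequencies are reported directed (source → target cluster), with the
diagonal undefined; treatment and organ rows sit alongside the cluster
rows.

## Synthetic-study generator

The generator emulates the structure of a two-organ, control-vs-treated
microarray study: a sparse Erdős–Rényi background (default 300 nodes,
density 0.02) containing node-disjoint planted cliques (default eight
6-cliques); expression x(g,m) = baseline + organ_effect·[liver] +
effect_size·[treated]·[g responsive] + N(0, noise_sd²) with defaults
baseline 8, organ effect 1, treatment effect 2, noise sd 0.5 — i.e. a 4σ
treatment effect, the regime where DEG calling is essentially noiseless and
downstream stages are tested on their own merits; responsiveness is
Bernoulli(0.7) inside responsive modules and Bernoulli(0.05) outside.
Replicates default to 3 per organ×group for expression-level work and 6 for
CRN work (24 samples, so 12-fold CV is genuinely randomized).  Edge
confidences are uniform on [0.7, 1.0], so the default confidence filter
keeps everything — the filter itself is exercised by the IO tests instead.
A single master seed spawns one independent substream per generator, so
regenerating one artifact never perturbs another, and all outputs are
bit-reproducible.

What the generator does **not** emulate: degree-preserving background
topology (module discovery does not model degree), per-gene organ effects,
batch effects, probe-level noise, overlapping planted modules, and
correlated noise between genes.  Consequently, passing tests demonstrate
correctness of the inference chain under a clean additive model — they do
not certify performance on real microarray data with correlated noise and
annotation loss.

## Input conventions

Network input is a STRING-style edge list; integer scores in [0, 1000] are
auto-detected and divided by 1000, floats in [0, 1] pass through, and
mixing the dialects in one file is an error.  Duplicate unordered pairs
keep the maximum score; self-loops are dropped with their node retained
(note the edge-list output format carries connected nodes only, so
isolated nodes do not survive a write/read cycle).  All identifiers are
opaque case-sensitive strings — no species or ID mapping.  Every writer has
a matching reader and round-trips exactly (floats via `repr`, re-parsed
with round-trip precision).  The organ indicator of the CRN equals 1 for
`liver` when that label is present, otherwise for the lexicographically
first organ label.

## Scaled configurations

`PipelineConfig` defaults carry the full-study reference values
(2,000,000 iterations, 10,000 random sets, 100 bootstraps, 1000 CV
repetitions); `PipelineConfig.synthetic_defaults()` — what the CLI uses
when no config is given — scales them to the bundled 300-node study
(15,000 / 500 / 20 / 50) so a complete `run-all` finishes in well under a
minute on one CPU while every stage still operates far from its sampling
limits at that network size.  The acceptance script's recovery benchmarks
use 500 nodes, 50,000 iterations, 1,000 random sets and 200 CV repetitions.

## Known limitations

- The clique sampler's coverage guarantee is empirical (exhaustive checks
  up to n = 15, soundness up to n = 25); on large networks, rare cliques
  reachable only through low-probability growth orders can be missed.
- Permutation significance shares one random-set panel per organ across
  cliques; p-values of overlapping cliques are therefore correlated, which
  is intentional (it mirrors one shared null) but means the significant
  set is not a multiplicity-controlled family.
- Cluster-count selection by silhouette is a documented reconstruction for
  studies that do not state their cut criterion; with a stated k or cut
  height, supply it.
- CRN edge frequencies quantify selection stability under fold
  randomization only — see the penalty-selection discussion above.
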