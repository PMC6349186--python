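# Methods notes

## Model and assumptions

`cernapath` treats a disease condition as perturbing localized regions of
curated pathways, where the perturbation is visible through two signals:
differential expression of member genes, and competing-endogenous (ceRNA)
coupling between member transcripts.  The underlying assumptions are

* ceRNA partners share an improbably large set of targeting miRNAs
  (hypergeometric excess over independent targeting) **and** are positively
  co-expressed, since competition for a common miRNA pool couples their
  free-transcript levels;
* pathway topology matters: two perturbed genes close together in the
  gene-product graph are better evidence of a perturbed region than the
  same genes far apart;
* a subpathway needs at least 5 nodes to be a biologically interpretable
  unit rather than a scatter of hits.

## Statistics

**miRNA-sharing test.**  For genes with K_a and K_b targeting miRNAs out
of a universe of N, the shared count under the null is hypergeometric;
the reported value is the upper tail P(X ≥ s).  The tested family (all
pairs with s ≥ 3) is BH-adjusted *before* the co-pathway filter — testing
the full family and filtering afterwards is the conservative ordering.

**Permutation DE.**  d = (x̄₁ − x̄₂)/(s + s₀) with s the pooled SE of the
mean difference and s₀ the median of per-gene s values (configurable
percentile).  Permuted |d*| values are pooled across genes into a single
null; p = (1 + #{|d*| ≥ |d|}) / (1 + total).  The add-one smoothing keeps
p > 0, which matters downstream because Φ⁻¹(1 − P) must stay finite.
When fewer distinct label assignments than requested permutations exist,
all distinct assignments are enumerated.  This deliberately replaces the
original SAM machinery (s₀ by coefficient-of-variation minimisation,
delta-threshold FDR) with a simpler moderated statistic yielding the
per-gene FDR-adjusted p-values the ce-score needs; users with SAM or
limma output can load it verbatim through `load_external_de`.

**ce-score.**  P_DE = min of the two node-level DE FDR values (a node's
value is the minimum over its member genes; 1 if none is DE), P^cor = the
minimum correlation p over cross-node ceRNA pairs (1 if the nodes are not
ceRNA partners), P = P_DE·P^cor, z = Φ⁻¹(1 − P), score = exp(−d)·z.
The score-combination form is configurable (`score_form`): the compact
printed form exp(−dz) read literally as exp(−d·z) *decreases* with z,
contradicting the intended monotonicity (stronger evidence or shorter
distance ⇒ larger score), so the default is the only parse consistent
with that behaviour, exp(−d)·z.  For z < 0 (P > 0.5) the default form
still ranks weak pairs below strong ones at every distance.

Numerical choices: P is clamped into [1e-300, 1 − 1e-16] before the
normal quantile; a pair with P = 1 exactly (neither node DE, no ceRNA
link) receives score −∞ and is excluded from the ω pool and from
qualification.  ω is the 0.75 linear-interpolation quantile of the finite
scores pooled over *all* pathways; pair admission uses strict `> ω`.

**Node sets and merging.**  A qualifying pair contributes the union of
nodes on **all** of its shortest paths (a node x lies on some shortest
u–v path iff d(u,x) + d(x,v) = d(u,v)).  Sets sharing a node merge to a
fixed point via union-find, which is order-independent; ties in reported
ordering are broken by node-sorted, size-descending canonical order, and
subpathway ids `<pathway>_<k>` number the surviving sets in that order.
Lowering ω can only add qualifying pairs, so node sets are monotone
non-shrinking in decreasing ω.

**Enrichment.**  Subpathways are scored by the upper-tail hypergeometric
P(X ≥ r) for r signature genes among t subpathway genes, with the
signature being the ceRNA ∪ DE set intersected with the background (all
genes on the reconstructed graphs).  The verbatim "summed" counting
(n_ce + n_DE, r_ce + r_DE) double-counts genes that are both ceRNA and
DE and can leave the hypergeometric support; it is available as
`count_mode="sum"` (tail mass 0 beyond the support), but the default
`union` mode keeps the distribution valid.

**Survival.**  Univariate Cox coefficients are maximised by Newton on
the Breslow partial likelihood (|Δβ| < 1e-8); Breslow rather than Efron
tie handling is an explicit choice.  Monotone separation or
non-convergence flags the gene and assigns β = 0 so one pathological
covariate cannot dominate a signature.  Risk = Σ βᵢ·Exp(i); the median
split sends ties to the low-risk group, giving a deterministic
⌈n/2⌉ / ⌊n/2⌋ split.  In-sample evaluation (β fitted and tested on the
same cohort) is anti-conservative for arbitrary signatures; the honest
protocol — used throughout the tests — trains β on one cohort and
evaluates the log-rank split on an independent cohort.

## Synthetic data generator

`ScenarioSpec` defaults define the reference study condition: 3 pathways
of 20 nodes (random spanning tree plus extra edges at density 0.08), a
planted 6-node region in pathway 0, miRNA universe of 386, 150 mRNAs,
8 targets per miRNA, a 12-miRNA block shared by all planted genes,
expression equicorrelation 0.8 among planted genes, a 2 σ disease-group
mean shift for planted genes and for 12 background DE genes placed in
the non-planted pathways, 50 samples per group, and exponential survival
with hazard ∝ exp(0.5·u) where u is the standardised mean planted-gene
expression (baseline hazard 0.1, exponential censoring rate 0.025,
≈ 15–20 % censored).

Design notes:

* The planted region is generated as a *complete* subgraph.  A tightly
  interconnected dysregulated complex is the scenario the method is
  designed to find, and it makes the ground truth unambiguous for
  Jaccard scoring.  Real KEGG regions are sparser; recovery on real maps
  will be correspondingly noisier.
* Background DE genes give the ω pool realistic competition: without
  them every scored pair would involve planted nodes and the 75 %
  threshold would sit inside the planted score distribution.
* Non-planted miRNA targeting is uniform, so the sharing test sees a
  calibrated null.
* Two cohorts over the same pathway structure and planted region are
  obtained by fixing `seed` and varying `expression_seed`.

What passing tests on this generator do **not** show: probe-level noise,
batch effects, correlated null genes, KEGG-scale maps (hundreds of nodes,
multi-gene entries), or starBase-like heavy-tailed miRNA degree
distributions.  The generator is a correctness instrument, not a
realism benchmark.

## Problem sizes used in the shipped checks

Recovery and robustness run the full workflow on the default scenario
(60 pathway genes, 100 samples, 1000 permutations) over 10–20 scenario
seeds; calibration uses 200-gene null matrices over 20 seeds and
~50 000 null gene pairs for the sharing test; survival recovery uses
n = 500 for coefficient recovery and two independent 200-sample cohorts
for signature evaluation.  These sizes make the entire suite run in well
under a minute while leaving the statistical bands (3·SE) meaningful.

## Robustness harness

Following the removal-experiment design, 5–30 % of called DE genes (5 %
steps, 20 repetitions) are removed — a removed gene leaves the DE list
and all its ceRNA pairs — and location + significance are re-run.  An
original significant subpathway counts as recovered when a new
significant subpathway matches its node set with Jaccard ≥ 0.5.  Within
a repetition the removal sets are nested (one shuffled ordering per
repetition, prefixes removed), a common-random-numbers choice that
reduces the variance of the fraction-to-fraction comparison without
changing the expectation at any single fraction.

## Known limitations

* ceRNA inference uses target sharing + positive correlation only; no
  conditional/sensitivity-correlation or miRNA-expression-aware scoring.
* Graphs are undirected and unweighted; KGML arrow direction and
  relation subtype semantics beyond compound mediation are dropped.
* The enrichment test treats genes as exchangeable; gene-length or
  degree biases in real annotations are not modelled.
* Exact subpathway numbering is a package convention; only the node-set
  content is meaningful across implementations.
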