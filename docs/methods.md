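# Methods

## The analysis model

The package targets perturbation-panel transcriptomics: one tissue profiled
under T treatments (2–3 replicates each) plus pooled controls, on the order
of 40 arrays and a few thousand measured genes after filtering. Co-expression
across such a panel is dominated by co-*response*: two genes correlate mainly
because they move together under the same subset of treatments. The chain is

signatures → batch residualization → correlation → soft threshold →
TOM → average linkage → dynamic tree cut → intramodular hubs → enrichment.

### Differential-expression signatures

A gene enters a treatment's signature when all three hold against controls:
fold change of group means ≥ `fc_up` (1.2) or ≤ `fc_down` (0.83); two-sided
t-test p ≤ `p_max` (0.05); absolute mean difference ≥ `min_abs_diff`
(10 intensity units, sensible only on a linear RMA-like scale — a
`log2_input` flag back-transforms first). No multiplicity correction is
applied at this stage: the filter's joint structure, not the p-value alone,
controls the false-positive load, and the network only needs a candidate
union. The t-test defaults to Welch because group sizes of 2–3 make the
pooled-variance assumption unverifiable; a pooled switch exists
(`equal_var`). Two-replicate groups are allowed. Degenerate zero-variance
cases use the convention p = 1 on equal means, p = 0 otherwise.

Signatures are computed on the raw matrix; residualized values feed only the
network. A `residualize_before_de` switch supports the other order.

### Robust batch residualization

Per gene, an intercept + batch-indicator model is fitted by Huber
M-estimation (tuning constant 1.345, MAD scale centred at the median,
IRLS from the OLS start, convergence 1e-13 relative). The implementation is
vectorized across genes; statsmodels' RLM is used in the tests as an
independent route to the same estimate. Because every batch level has its
own coefficient, adding a constant to all samples of one batch leaves the
residuals unchanged (verified to 1e-8 absolute) — exactly the invariance
batch correction must provide. Constant covariate columns are absorbed by
the intercept; genuinely collinear designs are rejected with the offending
columns named.

### Soft threshold and scale-free diagnostics

The unsigned adjacency is `a_ij = |cor_ij|^β`. Unsigned is the right default
here because perturbation responses come with both signs (a module may
contain both up- and down-regulated responders) and the power is odd in the
reference analyses. For each integer β in 1..20 the connectivity vector
`k_i = Σ_{j≠i} a_ij` is binned into `n_bins` (10) equal-width bins; empty
bins are dropped; the occupancy fraction p(k) is regressed on the bin-mean
k: log10 p ~ log10 k (plain) and log10 p ~ log10 k + k (truncated). The
selected β is the smallest with truncated R² > 0.75 *and* a decreasing
distribution (negative slope in both models). The sign requirement matters:
the three-parameter truncated model will happily score a humped, distinctly
non-scale-free distribution above 0.9, and without the sign convention the
smallest-β rule collapses to β = 1. When nothing qualifies the argmax of
the truncated R² is returned with a warning flag; on panels this small that
fallback can be poor, which is why the pipeline accepts a fixed β (7 is the
conventional choice for this design) as an alternative.

R² values are clamped to [0, 1]. A distribution concentrated in fewer than
three occupied bins is a degenerate-fit error.

### Topological overlap and module detection

`TOM_ij = (ℓ_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij)`, `ℓ_ij = Σ_{u≠i,j}
a_iu a_uj`, diagonal 1; computed by matrix product, tested to 1e-12 against
a cubic-loop oracle. Genes are clustered by UPGMA on `d = 1 − TOM`
(scipy linkage behind the module's surface).

The dendrogram is cut by a height-based dynamic procedure. An initial
static cut at `cut_height_fraction` (0.99) of the dendrogram *height range*
delimits maximal candidate branches. Each candidate is accepted as a module
when

* it has at least `min_size` (20) leaves,
* its **core scatter** — mean pairwise dissimilarity over its tightest
  `min(min_size, 2 + √n)` members — stays below
  `base + mcs·(h_cut − base)`, where `base` is the 5th percentile of merge
  heights and `mcs` ∈ {0.64, 0.73, 0.82, 0.91} indexed by `deep_split`
  (default 2), and
* its own top merge does not split it into two module-sized,
  well-separated sub-branches.

A branch failing the tests is replaced by its two children and re-tested;
leaves ending in no accepted branch are grey. "Well-separated" means either
both children hang at least `0.375·(1−mcs)·(h_cut − base)` below the merge,
or the mean between-children dissimilarity exceeds the larger within-child
mean by that amount. Three design points deserve a note, all established on
planted-module fixtures with known truth:

* the cut height is a fraction of the height *range*, not a merge-height
  quantile — with few modules, fewer than 1% of merges are between-module,
  and a quantile cut slices into module interiors;
* acceptance is scored on the branch core, because peripheral members of a
  genuine module otherwise push the scatter over threshold and the module
  dissolves into grey;
* the split test (rather than an outright gap *rejection*) prevents one
  failed criterion from cascading into a fully grey assignment, while still
  descending through merges of two genuinely distinct modules.

Accepted modules are named from the conventional colour palette (turquoise,
blue, brown, …) in decreasing size order, ties broken by the smallest member
gene ID; overflow gets indexed names. No eigengene-based module merging is
performed. The cut is deterministic for fixed input.

### Hubs and enrichment

`k.in(g)` is the sum of g's adjacency to the other members of its module;
grey genes keep k.in = 0 and are never selected. Hub candidates are the top
`ceil(fraction × module size)` genes per module of interest (default
fraction 0.10; per-module overrides, e.g. 0.20 where annotation coverage is
poor; optional restriction to annotated genes, with the quota still counted
against the full module). Ceiling guarantees a non-empty selection for any
module at or above the size floor.

Enrichment of a gene list against a GMT collection is the one-sided
hypergeometric upper tail P(X ≥ overlap) at the observed margins;
Benjamini–Hochberg q-values are computed within each scan. The enrichment
universe defaults to all genes on the matrix (a config can restrict it to
genes covered by at least one set). Pathway-overlap significance between two
treatments is the same tail probability on set *names*, with the number of
sets in the collection as the default universe.

## The synthetic-data generator

`generate_expression` draws a genes × samples panel from

x_gs = baseline_g + amp·√(c_g)·f_{b(g),s} + noise_sd·√(1−c_g)·e_gs + batch_s + de_gs

* `baseline_g = baseline_mean · exp(N(0, 0.3))` — log-normal-style
  intensities around 100, a linear RMA-like scale;
* `f_bs` — one standard-normal latent factor per planted module per sample;
  `amp = noise_sd` (unit amplitude when `noise_sd = 0`, so full cohesion
  gives exactly unit correlation);
* `c_g = 1 − (1 − c)·v_g`, `v_g ~ U(1, 3)` clipped to [0, 1] — gene-level
  cohesion spread below the nominal `module_cohesion` c, so modules have
  genuine hubs (high `c_g`) and peripheries; `hub_rank` in the ground truth
  is the descending `c_g` order. The spread (up to 3×) is wide enough that
  intramodular connectivity recovers the planted ranking from ~40 arrays
  (rank correlation ≈ 0.8 at c = 0.8);
* `batch_s ~ N(0, batch_sd)` per batch level (default three interleaved
  batches standing in for culture/processing/array dates);
* `de_gs = ±baseline_g·(m − 1)` (down-shifts use `1/m − 1`) in treated
  samples of affected genes. In `de_mode="module"` each planted module is
  assigned one treatment round-robin and a treatment's affected genes are
  drawn from its modules first (spilling into the background only when the
  quota exceeds the pool), with the response *direction drawn once per
  module-treatment pair* — a module is a co-regulated unit, and per-gene
  random signs would cancel the planted correlation. `de_mode="random"`
  scatters DE genes uniformly.

Intensities are clipped at 1e-3 to stay positive. Everything flows from one
`numpy` Generator seeded by `config.seed`; identical config + seed is
bitwise reproducible.

`study_config` mirrors the motivating design at desk scale: 8 growth-factor
arms (AMH, FGF2, BMP4, GDNF, FGF7, KITLG, LIF, PDGF), three replicates each
except GDNF with two, 15 controls (38 arrays), 2,000 genes, 16 planted
modules with sizes drawn in 20–194, ~10% of genes affected per treatment at
multiplier 1.5, noise_sd 10, batch_sd 5, cohesion 0.8.

**What the generator does not emulate:** probe-level effects and RMA
preprocessing, heteroskedastic intensity-dependent noise, correlated batch ×
treatment confounding, or annotation structure. Passing tests therefore
demonstrate that the chain recovers block-structured co-response planted in
linear-scale intensities — not that it is robust to array-level artefacts.

## Problem sizes and numerical choices

The test suite and the acceptance script run at 300–2,000 genes and 18–38
samples; the recovery benchmark (five equal modules of 400 genes, cohesion
0.8, β = 7) scores mean adjusted Rand index ≥ 0.99 over ten draws. These
sizes make every matrix dense and exact — no sparse approximations are
implemented, and above ~50k genes the O(n³) TOM product would need one.
Fold-change boundaries are compared inclusively (≥/≤) in double precision;
the three-gene and perfect-power-law reference values in the tests are exact
closed forms. All tie-breaks (hub ranks, colour assignment) fall back to
gene-ID order, so outputs are stable across platforms.

## Known limitations

* Only the unsigned adjacency is implemented; signed/hybrid variants are
  out of scope.
* The dynamic cut is the height-based variant; no PAM-like reassignment of
  grey genes, so grey counts run higher than a hybrid cut would give.
* Auto-β on small, strongly modular panels can find no qualifying power
  (the degree distribution never becomes decreasing before contrast is
  lost); the warning flag and fixed-β path exist for exactly that case.
* Enrichment treats gene sets as flat lists; no topology-aware pathway
  scoring.
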