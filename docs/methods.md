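# Methods

This note describes the models implemented in `guildquant`, the parameters
that matter, what the synthetic-data generators do and do not emulate, and
the numerical and design choices made where the method left room.

## The impact coefficient

The contribution of a group of equivalent sequences *s* — all query
sequences assigned to one (taxon, implementation, context) — is

    k_s = A_s · (d_obs,s / d_exp,s) · u_s

* `A_s` — summed normalized abundance of the member queries, in TPM.
* `d_obs,s` — observed richness: the number of distinct unique sequences
  (query identifiers after upstream dereplication; an exact-string dedup
  can be applied upstream for unclustered inputs).
* `u_s` — univocity of the cluster the sequences fall in, in [0, 1]. This
  package uses the binary case only: functional clusters carry u = 1,
  non-functional u = 0. Continuous efficiencies (e.g. from kinetic data)
  would slot into the same term but are not estimated here.
* `d_exp,s` — the richness expected from abundance alone (below).

Identities that the implementation preserves exactly (they are asserted on
randomized inputs in the test suite): k = A when d_obs = d_exp and u = 1;
u = 0 forces k = 0; recomputing A·(d_obs/d_exp)·u reproduces the stored k
bit for bit.

Groups falling in *incertae* (undefined) tree regions receive a missing k,
deliberately distinct from the zero k of non-functional groups: the former
are unclassifiable, the latter are classified as not performing the
function.

## Expected richness

Sampling reads from a large, unsaturated pool of sequence variants yields
more distinct variants the more reads are drawn, so raw d_obs would mostly
restate abundance. Abundance and richness follow a power law per gene,

    d_exp = c · A^γ,

fitted by ordinary least squares of log d_obs on log A. One model is
fitted per gene (guild marker), pooled over all groups and contexts of
that gene: per-group constants would make d_obs/d_exp identically one and
empty the richness term of content. Pooling across contexts is the
default for the same reason — the fit is a property of the gene's sequence
space, not of one layer.

Natural logarithms are used internally; (c, γ) are reported on the linear
scale, so the base is immaterial (it is recorded in the model object for
reproducibility, and base-2/base-10 fits return the same constants).
Groups with A = 0 carry no information about the law and are excluded from
the fit but counted in the model's diagnostics. Fewer than three usable
groups, or an abundance column with no spread, refuse to fit. Fitted
models on synthetic power-law groups with multiplicative lognormal noise
(σ_log = 0.1, n = 100) recover γ within ±0.05 with R² above 0.8 — the
regime the method expects on real per-gene tables; a poor R² is a warning
that the richness correction is not meaningful for that gene.

Fold changes between environments divide summed k by default. A pooled
mode is also provided (sum A and d_obs over the selection's functional
groups and re-apply the coefficient); it is off by default because
summation is the interpretable "total contribution" reading and keeps the
grand total conserved under any partition.

## Discovering implementations: leaf-trait enrichment

Reference-tree regions whose sequences work alike are discovered from leaf
metadata (environmental preferences of the organisms carrying the
sequences: temperature, salinity, pH optima and ranges; binary traits such
as motility are treated as 0/1 numerics under the same test).

For every internal node and trait, the observed mean over the node's
data-bearing leaves is compared to a null distribution obtained by
shuffling the trait values among all data-bearing leaves tree-wide
(missing values are never permuted into existence) and recomputing the
node mean per shuffle; 20 000 shuffles by default. The z score uses the
permutation mean and sample SD; the one-tailed p value uses the
(b+1)/(B+1) estimator, so it can never be zero at finite B, with ties
counted as at-least-as-extreme (a small relative tolerance absorbs float
summation-order noise when a shuffle reproduces the observed subset). A
node is significant when |z| ≥ 3 — equivalently one-tailed P < 0.003 —
and at least `min_leaves` (default 4, below which a node mean is too
unstable for a 3σ call) leaves carry data. Both tails are tested: a clade
may be significantly low-salinity as well as high. Constant traits give
z = 0 and are never significant. Given a seed, results are deterministic
and invariant to leaf input order. On trees with ≤ 8 data-bearing leaves
the permutation p matches exhaustive enumeration over all assignments
within Monte-Carlo error (tested), and under i.i.d. traits the realized
|z| ≥ 3 rate is at or slightly below the nominal 0.003 (sampling without
replacement from a finite value set has slightly lighter tails than the
normal).

Per trait, the *most general* significant nodes — significant while their
parent is not (the root qualifies if significant) — become implementation
candidates. When different traits select overlapping (in a tree: nested or
identical) nodes, the node covering more leaves wins, ties breaking by
trait order; identical selections merge into one cluster. The surviving
nodes partition the leaves into implementation labels plus *incertae*.

Two properties of the tree-wide randomization null are worth knowing:

* The z is computed per (node, trait). An across-trait mean z per node is
  easy to compute from the results table but is not used for selection,
  because traits are on different scales and a strong single-trait signal
  is already ecologically meaningful.
* Ancestors of a genuinely shifted clade are themselves enriched (they
  contain the shifted leaves), so "most general" tends to climb as far up
  as the signal stays above 3σ. A clade covering half of a 64-leaf tree
  under the root is recovered as most-general essentially always (tested
  over 20 seeds); a 16-leaf clade buried mid-tree is reliably *significant*
  (z ≥ 3), but its parent usually is too, and the parent is then the
  most-general node. This is a property of the statistic, not a bug; it is
  why the package reports both `significant` and `most_general`.

Univocity itself is propagated differently: from leaf-level experimental
evidence (functional / non-functional / ambiguous), the largest
monophyletic nodes whose evidenced leaves are unanimous become clusters
with u = 1 or u = 0. Mixed or unevidenced regions stay *incertae* — a
cluster never contains contradictory evidence.

## The taxonomy null model for gene divergence

Whether implementations merely restate taxonomy is tested by comparing
node-wise divergence in the target gene tree against two phylomarker
trees (16S rRNA and *rplB* style). All distances are patristic
(path-length) distances between leaves, normalized by each tree's diameter
so they lie in [0, 1] and every downstream statistic is invariant to a
global rescaling of branch lengths (the normalization constant is a
choice; the diameter bounds the scale and matches distances reported as
fractions of the tree depth). For each internal node of the target tree
with at least two organisms present in all three trees, the mean over
organism pairs of the normalized distance is computed in each tree.
Organisms with several gene copies (multiple target-tree leaves) are
summarized by the minimum leaf-pair distance — the most convergent copy —
configurable to the mean; distances are averaged over organism pairs, not
leaf pairs, so multi-copy organisms are not over-weighted.

The two phylomarkers track the same organismal history, so their points
fall on a line. That line — OLS of marker 2 on marker 1 (the marker-1 axis
is the reference axis; a total-least-squares variant would be symmetric
but is not what the plotted band represents) — plus a ±3σ band, with σ the
residual SD (ddof = 2), is the null envelope. A target node outside the
band is flagged: below the line, convergence (sequences more similar than
taxonomy predicts — the signature of shared environmental adaptation or
horizontal transfer); above, excess divergence. The test is two-sided. A
degenerate envelope (σ = 0, e.g. identical marker trees) flags any nonzero
residual.

Known limitation: the band is a single pooled σ, while node-mean residuals
are heteroskedastic (small nodes average few pairs and fluctuate more) and
correlated (nested nodes share organism pairs and branches). Under the
idealized null — points scattered independently around the line — the
band flags the nominal ~0.3% (tested by simulation). In tree-level
simulations where markers and target are independently rate-jittered
copies of one phylogeny, the realized flag rate at small nodes is several
times higher; flags at nodes with few organisms should therefore be read
together with their `n_organisms` (the package reports it per point).

## Synthetic data: what is emulated, what is not

The generators produce every input the pipeline consumes, with planted
ground truth, and are first-class tested code:

* **Trees** — Yule (pure-birth) topologies with exponential waiting times
  as branch lengths; leaves `L000…`, internal nodes `n0…`, byte-identical
  per seed.
* **Traits** — Gaussian baseline (SD 1), planted clades shifted by a fixed
  effect (5 SD in the bundled scenarios — a strong, clean signal), values
  missing completely at random.
* **Placements** — each query draws a home cluster, spreads its
  like-weight-ratio mass over up to 3 edges inside that cluster
  (Dirichlet-concentrated, concentration 20 by default; infinite
  concentration gives single-edge placements), and draws a lognormal TPM
  per context (σ_log = 1: per-group abundances spanning orders of
  magnitude, as metagenomic tables do). Ground-truth k is evaluated with
  the generator's richness constants (default c = 2, γ = 0.5), which the
  quantify command can take as a fixed model (`--model-c/--model-gamma`) —
  a refitted model would differ from the generating constants by sampling
  noise, and fixing published constants is also the right workflow for a
  gene whose law is already characterized. The bundled 2× layer-contrast
  scenario uses a flat richness law (γ = 0) with the same query set
  observed in both layers, so the abundance contrast passes through to k
  exactly; with γ > 0 a 2× abundance contrast yields 2^(1−γ) in k by
  construction.
* **Marker/target triples** — markers are per-branch lognormally
  rate-jittered copies of a base tree (jitter SD 0.1 by default);
  convergence events prune a leaf distant from a second leaf (above the
  0.6 distance quantile) and regraft it as that leaf's sister with short
  branches. Because a tree metric cannot shrink one pairwise distance in
  isolation, the planted signal is inherited by every ancestor of the new
  cherry (attenuating as ~2Δ/m for an m-organism ancestor); the generator
  therefore records both the cherry nodes (`truth_nodes`, where recall is
  measured) and the full affected set (`affected_nodes`, outside which any
  flag is a false positive), and prefers regraft sites whose ancestors
  grow large quickly so the signal stays local.

Not emulated: sequences themselves (no alignments, no HMM scores — the
simulation operates at the placement/abundance level), placement
uncertainty structure of real aligners (LWR mass never leaks outside the
home cluster, so classification accuracy on synthetic data is an upper
bound), taxonomically structured abundance covariance, trait values
missing not-at-random (cultured organisms are a biased subset in real
trait tables), and reference-tree reconstruction error. Passing tests on
synthetic data therefore demonstrate correctness of the computations and
calibration of the statistics under their stated assumptions, not
robustness to upstream annotation or placement artifacts.

## Numerical and interface choices

* Quality filter: the placement-quality score is the winning cluster's
  summed like-weight ratio ("confidence"); the default threshold is 0.5
  and the mean confidence of kept queries is reported alongside the
  discard percentage.
* Edge→cluster mapping: a jplace edge belongs to the cluster of its child
  node; edges above every cluster root are *incertae*. Argmax ties break
  toward the cluster holding the single best-supported edge, then
  lexicographically (and are logged).
* Consensus taxonomy: longest common prefix of the semicolon-ranked leaf
  paths below a node; query taxonomy is read at the best edge of the
  winning cluster; grouping truncates to a configurable rank depth,
  falling back to the deepest resolved rank.
* Placed queries missing from the abundance table are an error by default
  (`"drop"` discards them with a warning): a context-less query cannot be
  attributed to any (taxon, implementation, context) group.
* Tree IO preserves underscores and internal labels; unlabeled internal
  nodes get stable preorder ids (`n<i>`) that all output tables share.
* Every command writes its resolved configuration next to its outputs and
  is byte-reproducible given the same inputs and seed.

## Problem sizes used in the bundled checks

The test suite and the acceptance script run at deliberately desk-scale
sizes — 48–201-leaf trees, 120–150 queries, 500 null traits, 20 seeds for
Monte-Carlo medians, 2 000–20 000 permutations — chosen so the full
statistical battery (exhaustive 8-leaf enumeration, type-I calibration on
100 000 node-trait results, 20-seed divergence medians) completes in well
under a minute each while keeping every estimate's Monte-Carlo error far
below the margins being tested.
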