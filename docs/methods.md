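# Methods

## Correlation network

The network is built on Spearman's rank correlation because count margins in
16S data are heavy-tailed and nonlinear monotone associations are the norm;
rank correlation is invariant to the margins, which also makes the simulator
analytically tractable (below). Ties get mid-ranks; p-values use the
two-sided t approximation t = R·√((n−2)/(1−R²)) with n−2 degrees of freedom,
which is adequate at the target sample size (n = 29) and standard in the
field. |R| = 1 maps to p = 0. An exact permutation p-value is available for
n ≤ 8 (`p_method="exact"`), where the t approximation is crudest.

Edge criteria are |R| ≥ 0.6 and p ≤ 0.05, both inclusive, on **raw**
p-values: thresholded co-occurrence networks of this type select on the
uncorrected significance level, and the package reproduces that convention.
Benjamini–Hochberg adjustment is available behind `adjust="bh"` but off by
default. Constant OTU vectors (no rank information) are skipped with a
logged warning rather than failing the run. Nodes left isolated by
thresholding are dropped by default; a filtered table of ~347 OTUs typically
yields a somewhat smaller network for exactly this reason.

Low-abundance filtering removes OTUs with fewer than `min_total = 30` reads
summed over all samples — about one read per sample in a 29-sample design,
i.e. singleton removal.

Whole-network statistics: average degree 2E/V, density 2E/(V(V−1)), mean
local clustering coefficient C_i = 2n/(k_i(k_i−1)) (C_i = 0 for degree < 2),
diameter and average path length over the largest connected component when
the graph is disconnected (the component count is reported alongside so the
convention is visible), and the P/N ratio = positive/negative edge counts
with 0 negatives → "Inf" and 0/0 → "NA". Community structure (modularity,
community count) uses greedy modularity maximisation on the unsigned graph;
the method name is recorded in the output because different community
algorithms give materially different counts and no single choice is
canonical.

## MCODE

The cluster detector follows the canonical three-stage MCODE design. Vertex
weighting defaults to the core-density form — k_max × density of the highest
k-core of the closed neighbourhood — because the frequently quoted "weight =
clustering coefficient" description is an abridgement that changes behaviour;
the abridged form is kept as an explicit `simple_clustering` mode. The two
modes genuinely differ: two 5-cliques joined by a bridge edge merge into one
cluster under core-density weighting (all ten vertices weigh 4.0) but split
into two 4-cliques under C_i weighting (bridge endpoints weigh 0.6 and fall
below the 0.8 cutoff).

Seed expansion is breadth-first with inclusive threshold
weight ≥ (1−vwp)·weight(seed), vwp default 0.2, depth counted in BFS layers
(`max_depth` 100); a vertex belongs to at most one cluster; zero-weight
vertices never seed. Post-processing discards candidates without a 2-core
(`kcore_filter` ≥ 2), haircut iteratively strips members with fewer than two
intra-cluster connections, and fluff (off by default) adds boundary vertices
whose closed-neighbourhood density exceeds `fluff_density_cutoff`. All
tie-breaks (equal weights, equal scores) use lexicographic node labels, so
output is deterministic.

Cluster score is density × size. Published MCODE front-ends print scores
whose exact formula varies between implementations; scores here are
self-consistent for ranking but not comparable across tools.

MCODE sees only unsigned topology. Sign analysis is deliberately downstream:
a guild is first a *dense* region; whether it is internally cooperative is a
separate question answered by the guilds module.

## Guild analysis

Sub-guilds are the connected components of the positive-edge subgraph
(union-find). The two-block structure of a balanced guild is an *emergent*
result, not an assumption: the code reports k groups plus the list of
frustrated edges (negative edges inside a group; positive edges between
final groups cannot occur under union-find). A brute-force
frustration-minimising bipartition (≤ 20 nodes) is provided as an
independent cross-check; on clusters whose groups are positively connected
the two constructions agree, and the test suite verifies this. For graphs
with no positive edges the union-find convention yields singleton groups —
an all-negative triangle is reported as three singletons with zero
frustration rather than forced into two blocks.

Roles: any within-group negative edge makes a node *anomalous*; otherwise a
negative edge to another group makes it a *guard*; otherwise *civilian*. On
a balanced partition this guarantees both endpoints of every negative edge
are guards. Percentages are rounded half-up to one decimal. Dominant-phylum
ties report all tied phyla with a flag.

Phylum grouping: labels parse on the **last** underscore into (name,
number); names map to phyla through an explicit two-column table (a packaged
default covers the oral reference taxa), unmapped names become UNKNOWN, and
everything outside Actinobacteria/Firmicutes/Bacteroidetes is grouped as
"Others" for composition and pair summaries. Phylum-pair summaries count
edges with one endpoint in each phylum; same-phylum edges appear only as
diagonal entries when requested.

## Synthetic data

The generator emulates the data shape the analysis assumes: a 29-sample
count table over 367 OTUs — two antagonistic blocks of 21 and 34 members
(14 and 16 of them guards), 292 independent background OTUs, and 20 rare
OTUs whose expected totals (15 reads) fall below the abundance filter — so
that ~347 OTUs survive filtering in expectation. Counts come from a Gaussian
copula: latent multivariate normal → normal CDF → inverse negative-binomial
CDF per OTU (means log-uniform, 20–150 for block members and 2–50 for
background; common dispersion 1.0). Because Spearman depends only on ranks,
a planted latent correlation ρ yields population rank correlation
ρ_S = (6/π)·asin(ρ/2) regardless of margins — the tests verify this identity
at n = 5000. All randomness flows from a single seed.

The latent correlation is a three-factor loading model: civilians of block b
load √ρ_within on their block factor; guards load p = 0.72 on their own
block factor, −s = −0.30 on the opposite one, and ±β on a shared antagonism
factor with β² chosen so the guard–guard cross-block correlation equals
`rho_between_guards` exactly (default −0.8). This is PSD by construction.
The naive alternative — ρ_within on all within-block pairs, ρ_between on
guard pairs, zero elsewhere — is far from PSD at these sizes (minimum
eigenvalue ≈ −6.7), and no PSD matrix can combine strong within-block
correlation, strong negative guard–guard cross correlation and exactly zero
guard–civilian cross correlation: with many mutually correlated civilians a
guard orthogonal to the opposite block's civilians can reach at most ≈ −0.45
against its guards, below the detection threshold. The factor model instead
accepts documented side-correlations (guard–civilian within ≈ 0.64,
guard–guard within ≈ 0.98, guard–civilian cross ≈ −0.27, civilian–civilian
cross = 0), all either above the edge threshold with margin or safely below
it. `planted_profile()` reports the achieved values; `repair_psd()`
(eigenvalue clipping + diagonal renormalisation, error when any entry moves
more than 0.05) remains available for user-supplied matrices.

What the simulator does **not** model: compositional closure (the analysis
operates on raw counts, so neither does the generator), varying sequencing
depth per sample, phylogenetically structured correlation, or overdispersion
heterogeneity across taxa. Passing recovery tests therefore demonstrate that
the inference chain is correct under its own assumptions, not that those
assumptions hold in any particular real dataset.

## Problem sizes and power

At n = 29 the |R| ≥ 0.6 threshold has limited power (a true ρ_S = 0.78 pair
is detected ~96% of the time; weaker pairs much less), so end-to-end
recovery tests run in "power mode" at n = 200 samples, where planted guard
edges (ρ_S ≈ −0.78) are detected essentially always and measured guard
recall/precision and partition ARI are 1.0. The 29-sample setting is used
for shape/realism checks and for the false-positive-rate test (200
replicates of a small configuration; null-pair edge rate < 1%). MCODE on
the unequal 21/34 blocks places the dominant block plus the antagonist
guards in the top cluster (the larger block's core-density weights exceed
the expansion cutoff computed from any smaller-block seed and vice versa),
with the remaining civilians in the next cluster; recovery is therefore
asserted as cluster purity plus coverage of the planted union by the
detected clusters, alongside exact guard/partition recovery.

## Reproducibility

Simulation, clustering and reporting are deterministic given the spec seed
and parameters; CLI outputs serialise floats at 6 significant digits and
each run directory carries a manifest with the configuration hash, package
version and per-stage counts, so reruns are byte-identical.
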