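# Methods

This note documents the models, defaults and numerical choices behind
`graftnet`, and what the synthetic experiments do and do not demonstrate.

## Study design emulated

The platform targets a two-part proteomic study of experimental vein-graft
disease: (i) a *static* multigroup comparison of 4-week graft tissue layers —
control vein (IVC), neointima (NEO), adventitia (ADV) and wild-type grafts
(WT) — and (ii) a *kinetic* comparison of whole grafts against paired IVC
controls at four timepoints (day 1, day 3, week 2, week 4) with three
biological replicates per timepoint. The standalone generators default to
this design at its original scale (1357 quantified proteins, T = 4,
3 replicates); the end-to-end bundle (`graftnet synth`) runs the same design
scaled to a 300-node interactome so a full pipeline run takes seconds.

## Static stage

**Normalization.** Label-free area-under-curve abundances are scaled per
sample so every sample's median equals the global median of per-sample
medians. This preserves within-sample rank order and missingness.

**Testing.** All tests run on log2 abundances. Missing values are excluded
per protein; zero abundances are treated as missing on the log scale (with a
warning) because a label-free zero cannot be distinguished from
non-detection. The filter is a one-way fixed-effects ANOVA per protein;
groups contributing fewer than two observed values to a protein are excluded
from that protein's test, proteins with fewer than two usable groups are
skipped, proteins constant across all samples are dropped — each with a
warning. Benjamini-Hochberg adjustment (statsmodels step-up) converts p to q;
the retention gate defaults to q ≤ 0.05. Two-group comparisons use the Welch
t test (reduces to the pooled test under equal variances; `F = t²` holds for
two equal-variance groups).

**Bipartition.** Retained proteins are z-scored per row and cut into two
clusters by Ward/Euclidean agglomerative clustering; the cluster with the
higher mean z over control-condition samples is the control-predominant
cluster, the other the lesion-predominant cluster. The linkage choice is
ours; any method that separates the two planted directions gives the same
partition on clearly differential proteins.

## Kinetic stage

Replicates are averaged per timepoint, each (protein, condition) trajectory
is divided by its sum (fractional abundance; all-zero or incomplete profiles
are excluded with a warning), and vein-graft and control profiles are pooled
into a single clustering step so shared trends land in shared clusters.

The cluster model is a finite mixture of T-variate Gaussians with diagonal
covariance, fitted by EM with a variance floor of 1e-8, k-means++
initialization, and the best of `restarts` (default 8) seeded runs by final
log-likelihood. The log-likelihood is non-decreasing across EM iterations
(asserted with numerical slack); empty components are re-seeded from the
worst-fit profile; non-convergence within 300 iterations returns the best
iterate with a warning. The EM loop is written in-package because the
assertion of per-step monotonicity and deterministic empty-cluster reseeding
are part of the contract. Default K = 30 mirrors the original 30-cluster
analysis; the synthetic bundle uses K = 10, matching its 10 planted
templates.

Phase labels derive from centroids: *flat* if max − min < `flat_range`
(default 0.10 on the fractional scale, where a perfectly flat profile is
0.25 per timepoint at T = 4 — the original analysis classified flat trends
visually, so the threshold is ours), else *early* if the centroid peaks at
D1/D3, *late* if at W2/W4. Condition filtering keeps, per phase, only the
proteins whose vein-graft profile lies in a cluster of that phase; control
profiles and flat clusters contribute nothing.

## Pathway networks and target calls

Enrichment is the upper-tail hypergeometric probability with the population
set to the measured proteome (not the union of the gene-set collection): the
query is drawn from what was quantified. Sets are intersected with the
universe before testing; BH runs across all tested sets; the pipeline's node
gate defaults to q ≤ 0.001 (the network-comparison convention), the library
default is 0.05. Pathway nodes carry their dataset-overlap size; edges join
pathways whose overlaps share proteins (weight = number shared, threshold ≥ 1).

Centralities (betweenness with pair normalization (n−1)(n−2)/2, closeness
(n−1)/Σd, degree/(n−1)) are computed per connected component on the
unweighted graph; edge weights are annotation only. Components with fewer
than three nodes have betweenness 0; isolated nodes score 0 on all three.
Pathway ranking is by betweenness with deterministic tie-breaks (closeness,
degree, then lexicographic id).

Within a top-ranked pathway, the members present in the interactome induce a
subgraph (no first-neighbor expansion — the most conservative reading), each
member gets the same three centralities plus dense ranks, and the *consensus
central protein* is the minimizer of the Borda score (sum of the three
ranks; ties broken by betweenness value, then id, and flagged). Borda
aggregation formalizes the visual consensus of three pairwise centrality
scatter plots: it reproduces unanimity exactly and is deterministic.

## Network proximity

The closeness of modules A and B is the symmetrized closest distance
`½(⟨min_b d(a,b)⟩_a + ⟨min_a d(a,b)⟩_b)` in shortest-path hops (shared
members contribute 0; unreachable sources are excluded with a warning). The
separation score `s = ⟨d_AB⟩ − (⟨d_AA⟩+⟨d_BB⟩)/2`, with within-set and self
distances taken to the nearest *other* member (so s(A,A) = 0), is offered as
an alternative.

The null replaces both modules with random node sets drawn from matching
degree bins (nodes sorted by degree, contiguous bins grown to
`min_bin_size`; default 5 for synthetic graphs under 500 nodes, 25
otherwise), preserving each module's degree-bin multiset exactly. The two
replacement sets are drawn disjoint from each other: only shared members can
produce an exact-zero distance, and a null that produces zeros at a high
rate would put a large atom in the empirical p distribution. The
`random`-class module generator draws its observed pairs through the same
sampler, making observed and null draws exchangeable by construction.
Empirical p uses the (r+1)/(n+1) pseudocount (never 0), z uses the null mean
and sd (ddof = 1; degenerate nulls report z as missing), BH runs over all
module pairs of the matrix as one family, and cells with p_emp > 0.05 are
flagged blank following the display convention.

**Discreteness of the empirical p.** The closest distance is a mean of
integer hop minima, so ties between the observed and null values occur with
non-trivial probability, and a pseudocount p that counts ties as successes
is conservative by exactly that tie mass. The calibration experiment
(empirical p uniform for sampler-drawn pairs) therefore uses a sparse
attachment-1 scale-free interactome and `min_bin_size` 25, which give the
statistic wide support (tie mass of a few per mill to a few percent); on a
denser graph with fine bins the same machinery is exchangeable (the mid-p
variant of the experiment is uniform) but the pseudocount p is visibly
super-uniform. This is a property of discrete Monte-Carlo p-values, not of
the sampler; in practice it errs on the conservative side.

## Synthetic data

Every generator is a pure function of its parameters and seed; identical
reruns are byte-identical, and truth objects are sufficient to score every
downstream stage.

*Kinetic*: per protein and condition a trend template is drawn uniformly
(defaults: 10 well-separated fractional templates at T = 4 — sharp and
extreme single peaks per timepoint, a flat profile, a rising ramp), and each
replicate abundance is `scale · max(template + N(0, noise_sd), 0)` with a
log-normal per-profile scale. Gaussian noise on the fractional scale with
clipping at zero is the simplest model that stresses the clustering without
heavy tails; `noise_sd` defaults to 0.03, roughly a 3-percentage-point
per-timepoint jitter. At zero noise the fractional profiles equal their
templates exactly.

*Static*: log-normal abundances (base log2 level N(20, 2)), planted
differential proteins shifted by ±`effect_log2` (default 2) in the lesion
conditions, i.i.d. N(0, `noise_sd`) log2 noise (default 0.25 — a
moderate-precision label-free setting).

*Interactome*: preferential-attachment (Barabási–Albert) graph — connected,
scale-free, with exactly `attachment · (n − attachment)` edges. *Pathways*:
breadth-first neighborhoods around seeded nodes, at least three of which are
centered on the designated hub so it sits on many shared-protein edges.
*Modules*: overlapping pairs share ≥ 30% of members by construction,
neighboring pairs grow disjointly from adjacent seeds, random pairs come
from the degree-binned null sampler.

*Bundle*: the end-to-end study links the truths — the planted up-in-lesion
differential set is the union of the hub-containing pathways (so the lesion
cluster enriches them and the hub is recoverable as the consensus target),
and an equal-sized random up-in-control set gives the bipartition two real
clusters. The bundle config scales the run for speed: 300 nodes, K = 10,
4 EM restarts, `n_rand` 100, `min_bin_size` 5.

What the synthetic experiments do **not** show: robustness to
mass-spectrometry artifacts (batch effects, peptide-level variance,
missing-not-at-random dropout, isobaric interference), to incomplete or
biased interactomes, or to pathway annotation redundancy. Real gene-set
collections have heavily overlapping, nested sets; the planted collections
are comparatively clean, so real-data centrality rankings will be noisier
than the recovery experiments suggest.

## Numerical and reproducibility choices

Identifiers are uppercased at every boundary; missing is distinct from zero;
TSV (no quoting, UTF-8) is the canonical table dialect and all emitted
tables are sorted, so outputs are byte-stable. One global seed derives all
stage seeds by fixed offsets (kinetics +101, proximity +202; per-pair
proximity seeds spawn from a `SeedSequence`), so changing one stage's
parameters does not shift another's randomness. The run manifest records the
config snapshot (basenames only), package version, sha256 of every output
and all collected warnings — dropped proteins, unreachable nodes, absent
module members — because silent analysis decisions of this kind are exactly
what a discovery platform must surface.
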