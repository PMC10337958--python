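# Methods

## Model and procedure

The package treats a cohort's microbiome as a binary co-abundance
network: nodes are OTUs, edges are OTU pairs whose relative abundances
co-vary across the cohort's samples more than chance allows. The
analysis makes no attempt to infer directed or causal interactions, and
no per-sample network is ever estimated — single samples are
characterised only by how much their presence bends the cohort-level
network (leave-one-out impact).

### Edge significance (shuffle Z-score)

For each OTU pair, the observed Pearson correlation `C` of relative
abundances is standardised against a Monte-Carlo null in which every
OTU's abundance vector is resampled from its own empirical distribution,
independently of all others:

    W = (C − mean(C_shuffle)) / std(C_shuffle).

The default resampling is a permutation of each OTU's observed values
(preserves the marginal exactly); resampling with replacement is
available as an option. Pairs with `W` below a threshold (default 1) are
discarded, the survivors ranked by signed Pearson value, and a fixed
number of top edges kept (default 500). Ranking by signed `r` means
strong negative correlations never enter the network; a `rank_abs`
option exists for sensitivity analyses. Fixing the edge count removes
the edge-number confound when comparing networks of different cohorts;
`network_size_sweep` shows how the unfixed size varies with the
threshold, which differs between cohorts even at a fixed `W`.

Implementation note: `reconstruct_network` evaluates the null jointly —
one seeded stream, each realization permutes every OTU column
independently and the whole correlation matrix is computed at once. Each
realization is a valid independent draw of the per-pair null, so the
per-pair moments are the same as with per-pair streams, at ~30× less
cost — which the leave-one-out procedures (n + 1 reconstructions per
cohort) rely on. The standalone `shuffle_null_for_pair` uses a
spawn-keyed substream per pair instead, so either route is reproducible.
Before shuffling, columns are put in a canonical order (sorted OTU ids)
and each column's values are sorted, making the reconstructed edge set
exactly invariant to the input order of samples and OTUs.

### Degenerate inputs and ties

OTUs that are exactly constant across a cohort's samples have no defined
correlation; such pairs are excluded before ranking (constancy is judged
by zero range, not a floating-point variance test). Pairs whose null
standard deviation is zero are likewise excluded. Ties at the ranking
cutoff are broken by the lexicographic order of the sorted OTU-id pair,
so the edge set is deterministic.

### Network comparison and its null

Similarity of two networks is the Jaccard index of their edge sets.
The null ensemble redraws both edge sets uniformly over all C(n, 2)
node pairs (not degree-preserving — the shuffled networks represent
fully independent networks of the same size), and the empirical p-value
is the inclusive fraction of realizations with a Jaccard at least the
observed value, reported as `< 1/n_realizations` when none reaches it.
For m and m' edges on n nodes the null mean is close to the
hypergeometric ratio E|∩| / (m + m' − E|∩|) with E|∩| = m·m'/C(n,2);
for 108 nodes and 500-edge networks this is ≈ 0.0452.

Group-level significance of a *difference between similarities* (for
example, reference-vs-before against reference-vs-after) needs a
distribution of Jaccard values per cohort pair. The package's
construction for this — `bootstrap_similarity_distribution` — resamples
each cohort's subjects with replacement (default B = 100), rebuilds
both networks and records the Jaccard per replicate, then a rank-sum
test can be applied. This is this package's own device; p-values
produced this way are not comparable with any externally reported ones.

### Leave-one-out impact

Direct impact of sample k is `1 − J(B^n, B^{n−k})`; indirect impact is
`J(A^m, B^{n−k}) − J(A^m, B^n)` for a reference cohort A (by convention
the healthy group at the matching timepoint). Both networks of a
profile use the same parameters and master seed, and `B^n` (and `A^m`)
is reconstructed once and reused across all k, so the profile is
deterministic and invariant to sample listing order. Both `B^n` and
`B^{n−k}` keep the same fixed edge count; the shift in correlation
estimates from removing one sample *is* the signal. Per-sample
significance uses a one-sample Wilcoxon signed-rank test of the
differences {score_j − score_k, j ≠ k} against zero, one-sided towards
k being higher; this construction is the package's own documented
choice for an otherwise open design question.

### Community baseline

The root Jensen–Shannon divergence uses base-2 logarithms (so values
lie in [0, 1]; the base is a convention choice that rescales distances
but leaves every rank-based statistic unchanged) and renormalises both
vectors over the taxa present in *both* samples before the divergence
is taken. This shared-support form differs from the more common
union-support JSD; the latter is available via `shared_support=False`.
PCoA is classical metric scaling: double-centre −D²/2, eigendecompose,
keep the requested number of non-negative eigenvalues; explained
fractions are computed over the positive spectrum and the total
magnitude of any negative eigenvalues (the non-Euclidean part of rJSD
matrices) is reported alongside. Group tests are two-sided Wilcoxon
rank-sum; per-taxon differential-abundance screens apply the rank-sum
test per OTU with Bonferroni correction.

## Synthetic cohorts

`generate_cohort` draws correlated standard normals with target
correlation `rho` on the planted OTU pairs and zero elsewhere (nearest-
PSD repair by eigenvalue clipping; if the repair moves a planted
correlation by more than 0.05 the requested structure is infeasible and
an error says so), maps them through per-OTU log-normals, closes each
sample to relative abundances and draws multinomial counts at a fixed
read depth.

Defaults (chosen once as the package's study conditions): 30 samples,
108 OTUs, read depth 50 000, per-OTU log-locations drawn N(0, 1.0²) and
a common log-scale of 0.8 — abundances spanning a few orders of
magnitude with heavy tails, as in real 16S data. Planted structure is
expressed as disjoint blocks of mutually correlated OTUs
(`block_planted_edges`), because a uniform-`rho` block correlation
matrix is positive definite for any `rho` in (0, 1), whereas an
arbitrary random edge set at realistic density quickly has no valid
correlation matrix at useful `rho`.

`study_scale_fixture` assembles a four-cohort study — 30 + 30 healthy
and 27 + 27 affected samples at two timepoints over 108 shared OTUs,
with 9 blocks of 11 (495 planted pairs ≈ the 500-edge network size).
The healthy cohorts share one structure at both timepoints; the
affected W0 cohort shares a configurable fraction of the healthy blocks
and its W2 cohort is rewired again relative to its own W0 structure,
emulating a between-timepoint perturbation.

Outlier samples are disrupted either by permuting the sample's values
across OTU labels (`permute`, with an optional strength = fraction of
labels touched) or by redrawing the sample from a shifted planted
network (`swap`). Label permutation preserves the sample's value
multiset — its library size exactly, and its abundance *distribution*
— while destroying which taxa the values belong to, hence its
co-abundance pattern.

### What the generator does and does not emulate

It reproduces compositionality, sequencing-depth noise, heavy-tailed
abundance distributions and a controllable correlation structure. It
does not model phylogenetic relatedness, zero-inflation beyond what the
multinomial induces, batch effects, or within-subject temporal
autocorrelation (the two timepoints of a group are independent draws
from their planted structures). Passing tests therefore demonstrate the
machinery's behaviour under known ground truth, not performance claims
about any real cohort.

### The outlier-contrast experiment

The demonstration that network impact flags a correlation-disrupted
sample that community distances miss lives in a deliberately chosen
regime: 27 subjects, 9 blocks of 11 at rho = 0.7, per-OTU log-location
spread 0.45. The contrast genuinely requires *moderate* abundance
heterogeneity. With identical per-OTU distributions a label-permuted
sample is statistically indistinguishable from the others marginally
*and* contributes so little leverage that neither view detects it
reliably; with strong heterogeneity (spread ≥ 0.5 in natural logs) the
permuted sample becomes compositionally aberrant and the rJSD view
flags it too. The chosen spread sits where the permuted sample still
looks compositionally plausible (mean rJSD to the cohort rarely the
maximum) while its misplaced values create enough leverage in pair
correlations for the leave-one-out network impact to rank it first.
Detection power in this regime is high but not perfect: across
replicate families the network argmax finds the outlier in roughly
70–100% of runs, always far above the 1/27 chance level, while the
community view stays near chance.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run entirely on generated
data: the shuffled-network null at the full 108-node/500-edge scale
(1000 realizations), planted-edge recovery at 30 samples × 108 OTUs
with 1000 shuffles, and the outlier contrast as 10 replicates of a
27-sample cohort (each replicate is 28 network reconstructions). These
sizes keep a complete run in the low minutes while matching the scale
the method is intended for; unit tests use smaller cohorts of the same
shape.

## Known limitations

* **Compositional closure is not corrected.** Correlations are computed
  on relative abundances exactly as the method prescribes — no log-ratio
  or SparCC-style correction. Closure makes even latently independent
  taxa weakly positively correlated (a shared random denominator), and
  for heavy-tailed, dominance-structured compositions the permutation
  null of Pearson r is itself heavier-tailed than normal at n ≈ 30.
  Consequently the W ≥ 2 tail on "independent" synthetic cohorts sits
  near 0.04 rather than the normal-theory 0.023; on near-symmetric,
  balanced compositions (where the independence premise actually holds)
  it matches the normal tail within binomial bounds. Users should read
  W as a ranking statistic, not a calibrated p-value.
* The fixed-500-edge convention makes networks comparable but means the
  weakest included edges are near-arbitrary when few pairs pass the W
  threshold; the recorded shortfall and the threshold sweep make this
  visible.
* Jaccard overlap ignores all graph topology beyond edge identity;
  modularity, centrality or degree structure are out of scope.
* The bootstrap similarity distributions and the signed-rank impact
  test are this package's own constructions for under-determined steps;
  their p-values are internally consistent but not comparable across
  implementations.
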