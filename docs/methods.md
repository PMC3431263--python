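# Methods

## Scope and data model

The package analyses two (or more) isogenic metastatic/parental models,
each described by per-feature differential statistics on one or more omic
layers, against a single global interaction network and a pathway
collection. The network is undirected and unweighted: interaction
databases annotate direction and mechanism, but the topological statistic
below uses connectivity only, and an undirected model is the simplest one
consistent with shortest-path scoring. Identifiers are upper-cased
everywhere so gene symbols from different layers join reliably; features
absent from the network are dropped with a logged count rather than
imputed.

## Differential selection

A feature is called up-regulated when its differential p-value is below
`p_max` (default 0.05) and its linear fold change is at least `fc_min`
(default 2.0); down-calls mirror the rule on the reciprocal fold. The fold
comparison is inclusive (`>= 2`) by default — protocols state the same rule
both as "2-fold or greater" and "greater than 2-fold", and the inclusive
reading is taken as operative; a flag switches to the strict comparison
for sensitivity analysis. Probe-level array statistics are out of scope:
the pipeline consumes per-feature (log2 fold change, p-value) tables.

The sequon scanner enumerates candidate N-glycosylation sites as 1-based
positions of Asn-Xaa-Ser/Thr motifs, overlapping occurrences included.
Proline at Xaa is allowed by default (the literal motif rule); the
well-known depletion of glycosylation at Asn-Pro-Ser/Thr is available as
an opt-in exclusion. No neural glycosylation-potential score is computed —
the scanner only enumerates candidate sites.

## Spectral-count quantification

Label-free quantification compares two samples per model. Counts are
scaled so each sample's library total equals the mean of the two totals;
the normalization target is a documented choice (any common target gives
the same fold changes; the mean keeps values on the scale of the data).
Scaled values are floored at 1.0 so proteins absent from one sample yield
finite fold changes; the fold change is metastatic over parental on the
floored values. Significance uses the two-sided Fisher exact test on the
*raw integer* counts against the library totals (exact tests require
integers; the floor affects only fold changes), with two-sidedness by the
standard minimum-likelihood rule, followed by Benjamini–Hochberg step-up
correction. Replicate rows for one protein are pooled by summation before
testing. Differential calls then apply the threshold rule to the corrected
p-value and fold change.

The Fisher test assumes counts are proportions of a fixed sampling depth;
biological overdispersion makes it anti-conservative, which is why the
synthetic generator draws counts from a negative binomial (below) — the
2-fold requirement is what keeps moderate overdispersion from flooding the
calls.

## Topological significance scoring

For a seed set S (one model's up- or down-regulated features mapped onto
the network) and any node v, the observed statistic is

    T(v; S) = sum over unordered pairs {s,t} of S, v not in {s,t}, of
              sigma_st(v),

the number of tied shortest s–t paths whose interior contains v, computed
from per-seed BFS distance/path-count arrays (sigma_st(v) =
sigma_s(v) * sigma_t(v) when d(s,v) + d(v,t) = d(s,t)). Counting *all*
tied paths removes tie-breaking nondeterminism. Seeds themselves are
scored on the pairs they do not belong to, so a seed can be a
(non-hidden) significant node.

The null distribution re-draws, for each of R resamples (default 100), a
degree-matched replacement for every seed: nodes are binned by
floor(log2(degree)) and each seed is replaced by a uniform draw from its
bin, without replacement within a resample (bins too small to supply
enough distinct nodes are widened to neighboring bins). Logarithmic bins
keep the matching stable on heavy-tailed degree distributions. The
empirical p-value uses the permutation pseudocount
p = (1 + #{T_null >= T_obs}) / (R + 1), so p >= 1/(R+1) and a node is
significant when p < alpha (default 0.05, uncorrected — the procedure
reports a flat significance level by design). Identical seeds give
identical outputs: all randomness flows through one seeded generator, and
the resample-drawing routine is a public function so independent
re-implementations can share its stream.

This null is what operationalizes hub penalization: a hub's generic path
participation appears in its own null (the same node is re-scored against
random degree-matched seed sets), so only connectivity *specific* to the
observed seeds is rewarded. Two consequences are worth noting. First,
nodes with zero observed participation have p = 1 exactly (every null
value is >= 0), so p-values are informative only for participating nodes;
calibration diagnostics should condition on T_obs > 0 or work at the
decision (significance) level. Second, the p-value is discrete with
resolution 1/(R+1); R = 100 suffices for alpha = 0.05 and is the default
trade-off against runtime.

Hidden nodes are significant nodes absent from the model's direct
differential sets; the hidden fraction is |hidden| / |significant| (0 when
nothing is significant).

## Pathway over-representation and common pathways

For a query set Q (direct differential features, or topological
significant nodes) and pathway P within universe U, the p-value is the
upper hypergeometric tail P(X >= |Q ∩ P|) with X ~ Hypergeom(|U|, |P|,
|Q|). The universe defaults to all collection/network features. FDR is
Benjamini–Hochberg across the collection, significance at FDR < 0.05, and
rows are ranked by (p, name) so top-k lists are reproducible under ties.
Common pathways between two models are the names in both top-k significant
lists, ordered by summed rank. Up- and down-regulated sets are analyzed
separately throughout, never pooled.

The random-set calibration draws n_sets uniform feature sets (excluding a
supplied differential list), pushes each through scoring and enrichment —
falling back to enriching the random set itself when no node is
significant — and reports, per target pathway, the fraction of sets where
the target lands in the top-k *ranked* rows. The membership criterion is
rank-based rather than significance-based so that the statistic measures
"how often would this pathway headline a top-10 list from noise", which is
also the only reading under which a degenerate whole-universe pathway
(p = 1 always) attains FDR 1. Random-set size should match the size of the
real query it calibrates (the pipeline default, 24, matches the
significant-node counts of the default scenario).

## Concordance

Concordance between models A and B on one layer:

    category % = 100 * |common| / min(|A|, |B|)          (per direction)
    overall %  = 100 * (common_up + common_down)
                 / (min(A_up, B_up) + min(A_down, B_down))

rounded half-up to integer percent. The per-category minimum denominator
is the only rule consistent with all published overall figures when the
two models' set sizes straddle each other, and it makes the statistic
symmetric in model order and bounded by 100%.

## RPPA panel test

Antibody-level tables collapse to one value per protein by keeping the
antibody with the largest *absolute* log2 difference (ties broken by
antibody name); the absolute value preserves down-regulation information.
Up-regulation is a strict log2 > 0.3 call (linear fold 2^0.3 = 1.23,
chosen because RPPA fold changes are compressed relative to other
platforms). With N panel proteins, K up-calls, n pathway proteins on the
panel and k up-called pathway proteins, the enrichment p-value is the
upper cumulative tail

    p = sum_{i >= k} C(K, i) C(N-K, n-i) / C(N, n),

the only reading of "cumulative" consistent with testing enrichment (and
verified in the tests against a summed-PMF oracle). Counts are integral;
a k derived from a reported percentage is round(pct * n).

## Synthetic scenario generator

The generator emulates the study design rather than any specific dataset:

- **Network**: preferential-attachment graph with exact node and edge
  counts (default 300 nodes, 900 edges) — a connected attachment tree plus
  degree-weighted extra edges, giving the heavy-tailed degrees of real
  interactomes at desk scale.
- **Pathways**: 20 pathways of 12 members over the network universe; the
  first 3 are "planted" as the shared biology.
- **Hidden regulators**: 8 members of each planted pathway, 4 assigned to
  the up direction and 4 to the down direction. Each regulator is wired to
  every seed of its direction in *both* models (half of each model's total
  seed set). Splitting regulators by direction keeps their degree modest
  (~20 in a 300-node graph): wiring a regulator to all four seed groups
  would make it a global hub whose degree-matched null absorbs its own
  signal — the penalization working as designed, but destroying the
  planted contrast.
- **Seeds**: 16 per model (8 up, 8 down), drawn outside every planted
  pathway, with 25% of each direction shared between models — so the
  direct profiles overlap weakly (the generated direct concordance, ~25%,
  is in the regime of real cross-model comparisons) while the topological
  layer converges on the same regulators.
- **Expression**: seed features get log2 fold changes of ±(2.0 ± N(0,0.3))
  and p ~ 10^-U(3,6); null features get log2fc ~ N(0, 0.35) and p ~
  U(0,1), so with no planted seeds the p-values are exactly uniform and
  the false-call rate of the threshold rule equals its nominal level.
- **Spectral counts**: log-normal baseline abundances scaled to an
  expected library of 7,500 spectra per sample (the scale of a MudPIT
  run), negative-binomial noise with var = mu + 0.01 mu^2, and per-model
  spiked proteins at 5-fold. The dispersion default is deliberately mild:
  var/mu ≈ 1.7 at the default depth — genuinely overdispersed, but below
  the level at which the Fisher + 2-fold rule (which ignores biological
  variance by construction) would flood the calls with false positives.
  Larger dispersions are available as an explicit stress setting.
- **RPPA**: 120 proteins probed by 242 antibodies, a 24-protein target
  pathway containing the first planted pathway, and planted up-calls of
  35 and 14 proteins (11 and 6 inside the pathway) — the canonical
  validation-panel shape. Planted-up protein levels are drawn above 0.35
  and all others below 0.25, with ±0.04 antibody noise, so the 0.3
  threshold recovers the planted calls exactly.

Everything flows through one seeded generator: a configuration plus seed
reproduces every file byte for byte, and the truth file attributes every
planted effect.

What the generator does *not* emulate: real gene symbols or annotation
structure, correlated noise between features, probe-level array artifacts,
peptide-to-protein inference ambiguity, or batch effects. Passing tests on
this scenario demonstrate that the *procedures* behave as specified under
their stated assumptions — not that any particular biological dataset
would yield the same pathway identities.

## Problem sizes and runtime

Default analyses run on 100–500-node networks with ~10–50 seeds and
R = 100 resamples; a full pipeline run (direct + topological + random-set
calibration + RPPA) completes in well under a minute on one CPU, and the
complete test suite in under two minutes. Scoring cost is
O(R · |S| · |E|) BFS work; the implementation uses CSR adjacency arrays
and frontier-vectorized BFS.

## Known limitations

- The topological score is a resampling procedure; p-values have
  resolution 1/(R+1) and no multiplicity correction is applied (by
  contract). With many candidate nodes, alpha = 0.05 implies the usual
  false-positive expectation among non-participating nodes' complements.
- Degree-matching widens bins when a bin cannot supply enough distinct
  nodes, which weakens matching in tiny or extremely skewed graphs.
- The concordance statistic depends only on set cardinalities and
  intersections; it does not model identifier mapping ambiguity.
- The Fisher spectral-count test ignores biological replicates beyond
  pooling; genuinely replicated designs are better served by count models
  with dispersion estimation, outside this package's scope.
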