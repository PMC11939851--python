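# Methods

`immunodiffnet` analyses circulating immune-marker profiles of small
oncology cohorts — soluble immune checkpoints and cytokines/chemokines/
adhesion molecules in serum (pg/mL) and CD137⁺ T-cell subsets from flow
cytometry (% of parent population) — against dichotomous clinical labels:
response to checkpoint-inhibitor therapy (R/NR), ECOG performance status
(PS = 0 vs PS > 0) and an overall-survival dichotomy separating early
progressors from the rest. It has two analysis arms plus a synthetic-cohort
generator.

## Preprocessing

Raw concentrations are transformed as `log2(x + 1)` (base and pseudocount
configurable). Concentrations are non-negative and right-skewed, the
pseudocount keeps zero measurements finite, and base 2 makes downstream
group differences read directly as log2 fold changes. For correlation
analysis each marker row is standardised to mean 0 and unit sample
(n − 1) variance; a constant marker is reported by name rather than
silently producing NaNs. Missing cells propagate and all pairwise
statistics use pairwise-complete observations, with the per-estimate
sample size recorded.

The transform is logarithmic, not logistic: marker panels of this kind
are routinely log-transformed before clustering, and the fold-change
reporting downstream presumes a log scale. A logit variant would require
bounded data, which concentrations are not.

## Patient clustering and cluster statistics

Patients are clustered on their log-scale profiles by agglomerative
Ward-D2 linkage on Euclidean distances (`scipy.cluster.hierarchy.linkage`
implements exactly the Lance–Williams Ward update with squared-Euclidean
initialisation; heights are reported on the distance scale, the dominant
convention, so cut heights are interpretable against the dendrogram).
Outlier removal cuts the dendrogram at a user-supplied height: branches of
size ≤ 1 (configurable) whose members only join the tree above the cut
are removed. There is no universal numeric default for the cut height —
it depends on panel size and scale — so it is a required parameter, and a
safety guard refuses to discard more than half the cohort.

Cluster–label association uses the Freeman–Halton generalisation of
Fisher's exact test, computed by full enumeration of all r×c tables with
the observed margins; the two-sided p is the total probability of tables
no more probable than the observed one (relative tie tolerance 1e-9,
matching common implementations). Enumeration is limited to grand totals
≤ 60 — ample for cohort-scale tables and sub-second on one CPU; larger
tables are refused rather than silently approximated. On 2×2 tables this
reduces exactly to the classical two-sided Fisher test, and on r×c tables
it agrees with R's `fisher.test` (both checked in the test suite).

Differential expression between clusters uses a two-group linear model
with empirical-Bayes variance moderation. Per marker g, the pooled sample
variance s²_g with d_g = n_A + n_B − 2 degrees of freedom is shrunk toward
a prior variance s₀²:

    s²_post = (d₀·s₀² + d_g·s²_g) / (d₀ + d_g)

and the moderated t = (mean_A − mean_B) / (s_post·√(1/n_A + 1/n_B)) is
referred to t with d₀ + d_g df. The hyperparameters (d₀, s₀²) are
estimated by moment-matching the log sample variances to the scaled-F
model (digamma/trigamma moments; trigamma inverted by Newton iteration).
When the spread of log-variances does not exceed its sampling floor the
prior is fully pooled (d₀ = ∞). The test suite verifies the two limits
(d₀ = 0 recovers the ordinary equal-variance t to 1e-10; d₀ = ∞ pools to
the common variance) and agreement of t, p, d₀ and s₀² with Bioconductor
limma's `eBayes` on a fixture. Multiple testing is controlled by
Benjamini–Hochberg; hit calling defaults to |log2 FC| > 1.5 and q < 0.05.
The model is a fixed-effects linear model: the design has one observation
per patient and no repeated measures, so there is nothing for a random
effect to absorb.

## Differential correlation

For each unordered marker pair and each condition of a contrast, the
Pearson correlation r (Spearman optional, computed as Pearson on ranks)
over n pairwise-complete patients is computed, with a two-sided p from
t = r·√((n−2)/(1−r²)) on n − 2 df. The Fisher transform z = atanh(r)
with se = 1/√(n−3) variance-stabilises r; each condition needs n ≥ 4 so
that n − 3 > 0. Saturated correlations (|r| = 1) are clipped to
0.999999 before atanh and flagged. The contrast statistic is

    Δz = (z_A − z_B) / √(1/(n_A−3) + 1/(n_B−3))  ~  N(0, 1) under H₀.

Two significance modes are implemented and the run log states which was
used:

* `abs_threshold` (default): |Δz| > 1.64, the conventional rule for this
  analysis. 1.64 is the upper-5% normal quantile, i.e. a one-sided
  critical value applied two-sidedly, so its null rate is 2Φ(−1.64) ≈
  0.101, not 0.05. The test suite verifies this calibration to ±0.01.
* `two_sided_p`: two-sided normal p < α (default 0.05), the statistically
  coherent 5% rule.

Each pair is classified by the ordered pair of per-condition states —
"+" (p < α and r > 0), "−" (p < α and r < 0), "0" (otherwise) — giving
nine classes +/+, +/0, +/−, 0/+, 0/0, 0/−, −/+, −/0, −/−, with condition
A conventionally the adverse state (NR, PS > 0, early progression). No
multiple-testing correction is applied across the ~561 pairs by default,
matching standard practice for this screen; a BH option exists.

A seeded label-permutation oracle (`permutation_null`) recomputes Δz
under joint permutation of the condition labels, with empirical
p = (1 + #{|z*| ≥ |z_obs|})/(n_perm + 1). Two caveats, both verified
empirically in this package's validation: the permutation null is exact
only when the two conditions are exchangeable (equal true correlation),
and because it conditions on the observed sample it matches the analytic
normal p in expectation over datasets, not dataset-by-dataset (the
conditional deviation is O(1/n) and can exceed Monte-Carlo error).

## Network, degrees, hubs

Edges are the significant pairs whose class is neither 0/0 (no
correlation anywhere) nor same-sign (+/+, −/−: the correlation merely
persists across conditions and carries no differential signal). All panel
markers remain as nodes so degree bookkeeping can include isolated nodes
when asked. The class-specific degree of a node counts incident edges of
one class; per class, hubs are the nodes whose degree lies *strictly
above* the 90th percentile (nearest-rank, no interpolation) of that
class's degree distribution. By default the distribution is taken over
nodes incident to ≥ 1 edge of the class — isolated nodes are absent from
the networks this mirrors — with `include_isolated=True` as the
alternative. With all degrees equal the hub set is empty (nothing
strictly exceeds the percentile). Networks export to GraphML (node kind,
per-class degrees, hub flags; edge class and Δz) and a flat TSV edge
list; re-import round-trips losslessly.

## Synthetic cohorts

The generator emulates the study conditions the pipeline targets:
27 patients; 34 markers (13 checkpoints, 18 cytokines/chemokines/adhesion
molecules, 3 CD137⁺ subsets — the panel composition is configuration,
not hard-coded, since assay panels vary); clinical margins 14 R/13 NR,
15 PS0/12 PS>0, 21/6 at the 3-month survival cutoff. Labels are assigned
independently per variable by default (only margins are known in
general); a joint-table mode injects an explicit patient×label layout.

Marker vectors are drawn per patient from a latent multivariate normal
whose correlation is the identity except for planted equicorrelated
blocks active only in one condition of one contrast (positive
definiteness is checked before sampling; for an equicorrelated block of
k markers this requires ρ > −1/(k−1)). Latent values map through
exp(loc + scale·x) to positive, right-skewed lognormal concentrations
(checkpoint/cytokine medians ~10²–10³ pg/mL, cell subsets ~1%),
emulating Luminex-like data. Correlations planted on the latent scale
are mildly attenuated on the observed scale; the pipeline's log step
largely restores them. Optional structure: a small patient cluster with
elevated levels on chosen markers (mean shift in latent sd units), and
outlier patients shifted on every marker with an independent random sign
pattern per outlier, so each appears as a dendrogram singleton rather
than a tight outlier pair. Ground truth lists every planted pair with
its expected edge class, plus cluster/outlier membership.

What the generator does not emulate: assay floor/ceiling censoring
(values below standard curves), batch effects, heavy-tailed measurement
error, or biologically structured background correlation among unplanted
markers. Passing recovery tests therefore demonstrates correctness of
the statistical machinery under the model's assumptions, not robustness
to those real-data artefacts.

## Validation results computed by the test suite

* Null calibration: 5000 independent null pairs at group sizes 13/14 give
  a significant-pair rate within ±0.01 of 2Φ(−1.64) ≈ 0.101 under the
  default rule.
* Planted-structure recovery (100 replicate cohorts, five-marker ρ = 0.9
  block in the adverse group, n = 13/14): the scan flags ≈ 97% of planted
  pairs and ≥ 90% of the flagged planted pairs carry the expected +/0
  class. The network-level false-edge rate of the default rule measures
  ≈ 0.0515: the null scan rate ≈ 0.101 times the probability ≈ 0.5 that a
  null significant pair lands in a retained class. This sits marginally
  above a 5% working bound — an inherent property of pairing the 1.64
  threshold with per-condition α = 0.05, documented here and asserted
  honestly (the corresponding test expects ≤ 5% and fails by ~0.15
  percentage points; the `two_sided_p` mode achieves ≈ 0.028 at the cost
  of sensitivity ≈ 0.93).
* Exact-test cross-checks: 2×2 agreement with `scipy.stats.fisher_exact`
  to 1e-10; 3×2 agreement with R `fisher.test` to 7 digits; enumerated
  table probabilities over fixed margins sum to 1.
* Moderated-t cross-check against Bioconductor limma, and uniformity of
  its null p-values (Kolmogorov–Smirnov, 5000 marker-replicates).

## Numerical choices and degenerate inputs

Tie tolerance 1e-9 (relative) in exact-test tail inclusion; |r| = 1
clipped at 0.999999 before atanh; trigamma inversion by Newton from
x₀ = 0.5 + 1/y, tolerance 1e-10; non-finite prior df falls back to the
fully pooled prior with a warning; pairs with < 4 complete observations
or zero variance are returned as flagged records so a scan never aborts;
a zero row/column in a contingency table yields p = 1 (the margins admit
a single table); BH q-values are capped at 1 and returned in input
order. Problem sizes in tests (replicate counts, permutation counts,
marker counts) are chosen so the full suite completes in a few minutes
while keeping Monte-Carlo error well inside each asserted tolerance.

## Known limitations

* The 1.64/two-sided pairing is kept as the faithful default despite its
  ~10% null rate; users wanting a strict 5% should select `two_sided_p`.
* Fisher-z inference assumes approximate bivariate normality per
  condition; at n ≈ 13 per group the normal approximation to Δz is good
  but not exact, and the permutation oracle is the better reference when
  groups are exchangeable.
* The survival dichotomy discards follow-up time; no survival modelling
  is attempted.
* Exact enumeration is refused above a grand total of 60; a Monte Carlo
  contingency test is deliberately out of scope.
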