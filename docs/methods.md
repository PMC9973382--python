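# Methods

This note records the models, conventions and design choices behind
`panhallmark`, and what the synthetic-data validation does and does not
establish.

## Single-sample enrichment scoring

For one sample, genes are ranked by expression with average ranks for
ties and the ranks divided by the number of genes N ("rank"
normalization). Walking the genes in decreasing rank order, a
signature's enrichment score is the area under the running enrichment
statistic

    ES = Σ_i [ P_hit(i) − P_miss(i) ],

where `P_hit` accumulates signature genes weighted by `|r_i|^w`
(default weight w = 0.75) and `P_miss` is the uniform ECDF over
non-signature genes. Signatures overlapping the expression genes by
fewer than `min_overlap = 5` genes are dropped. Because only ranks
enter, scores are invariant to any per-sample strictly increasing
transform of expression — this is asserted bit-level in the tests, and
the score itself is checked against an independent brute-force
evaluation of the sum to 1e−12 relative error.

Two output conventions are exposed: the raw area score (default), and a
permutation-normalized variant that divides each signature's ES by the
mean |ES| over random gene-label assignments of the same set size.
Downstream statistics are rank-based within signature, so the choice
does not affect the association results; the convention used is
recorded in the score matrix's parameter block. The permutation null
is computed from one sample's rank profile: after rank normalization
all samples share the same rank multiset up to ties, so the null
depends only on set size.

Near-constant signatures are removed by an explicit rule rather than by
inspection: a signature is dropped when the median across subtypes of
its within-subtype IQR falls below a configurable floor.

## Driver curation

Variant classifications 3'Flank, 3'UTR, 5'Flank, 5'UTR, Intron, RNA and
Silent count as synonymous; everything else (including unknown terms)
is nonsynonymous. Within each group — the filter runs at both tumor-type
and subtype granularity, and passes are unioned into gene–tumor-type
combinations — the outlier threshold is `Q3 + 3·IQR` of the per-gene
nonsynonymous mutated-tumor counts over the supplied gene list, with
quantiles linearly interpolated between order statistics (the default
convention of most statistical environments; the routine is isolated in
`_stats.quantile` so it is swappable). "Above the threshold" is strict
(>), the minimum count is ≥ 3, and the tumor-suppressor silent-fraction
rule uses silent / (all mutations of the gene in the group) < 0.20.
Two ambiguities are resolved explicitly: the silent-fraction
denominator is all mutations of that gene in that group, and the
outlier distribution is formed over the supplied driver list (not the
whole exome); both choices are deliberate and local to one function.

Focal peaks are filtered to q ≤ 0.01 and width ≥ 250 kb, merged within
chromosome and direction whenever any base overlaps (transitively), and
assigned the nearest gene from a user-supplied BED-like table; peaks
with no mappable gene keep a coordinate-derived id rather than being
dropped. Arm calls use the canonical 39 autosomal arms (acrocentric
p-arms excluded); each arm expands into an Amp and a Del binary column
(+1 → (1,0), −1 → (0,1), 0 → (0,0), missing → missing in both). The
aneuploidy score is the number of altered arms (0–39), "high" means
> 15, and whole-genome doubling is assigned at average ploidy ≥ 3.
Segment-based arm calls (for array-CGH cohorts, e.g. mouse models) mark
segments amplified at log2 ratio > 0.1 and deleted below −0.1, and call
an arm altered when more than 50% of its bases change in one direction;
if both directions exceed the fraction the call is neutral with a
warning. In subtype arm-percentage matrices the larger of %amp and %del
is kept with deletions negated; exact ties resolve to amplification
(arbitrary but fixed and documented).

## Cross-tumor-type association and permutation FDR

The scan tests every (alteration, signature, qualifying tumor type)
with a two-sided Wilcoxon rank-sum test: exact enumeration when both
groups have ≤ 12 observations and the pooled values contain no ties,
otherwise the normal approximation with tie and continuity correction.
The location estimate is the Hodges–Lehmann median of all pairwise
differences, signed altered − wildtype. Alterations must qualify in at
least two tumor types; groups with fewer than two samples on a side are
skipped.

A tumor type counts toward a direction when p ≤ the class threshold
(1e−3 for mutations and focal CNAs, 1e−7 for arm events) and the
estimate has the matching sign; pairs whose larger directional count is
below 2 are non-candidates. For each candidate, every permutation
replicate shuffles the alteration labels independently within each
qualifying tumor type (preserving the per-type alteration frequency),
recounts the significant same-direction types, and the FDR is the
fraction of replicates reaching at least the observed count (`≥`,
conservative; an optional (b+1)/(n+1) pseudocount is off by default so
that an FDR of 0 is representable). BH adjustment runs within an
alteration class, covering both directions in one family. The default
replicate number is 10,000, configurable upward.

One deliberate approximation: replicate direction uses the sign of the
rank-sum location U − mn/2 instead of recomputing the Hodges–Lehmann
median per replicate. For continuous scores the two signs agree; the
shortcut is what makes 10^4 replicates per candidate tractable (the
replicate rank sums are a single ranks × masks matrix product per
tumor type, and replicate p-values use the same exact-table or
normal-approximation convention as the observed scan).

Subtype independence is confirmed with a Gaussian GLM
`signature ~ alteration + subtype` (identity link) per tumor type;
alterations constant within every subtype are flagged inestimable
rather than fitted. Enrichment of binary events in a sample status
(e.g. arm deletions in TP53-mutant tumors) uses the chi-square test
with Yates correction and odds ratios with the Haldane–Anscombe 0.5
correction when any 2×2 cell is zero.

## Clustering

Subtype profiles are per-subtype feature means over tumor types with at
least 100 samples and subtypes with strictly more than 10, rows
median-centered. Columns are clustered on `d = 1 − Pearson r` with a
Ward criterion implemented through the Lance–Williams recurrence. Both
classic variants are available — "wardD" runs the recurrence on d,
"wardD2" (default) on d² with square-root merge heights; wardD2
reproduces scipy's `linkage(..., 'ward')` exactly, which serves as the
reference in tests. Clusters are the groups whose merges lie strictly
below the cut height, so a cut at 0 gives singletons and a cut above
the tallest merge gives one cluster. Because the underlying analysis
environment's Ward variant is ambiguous, absolute cut heights are
configuration values, not constants. Marker detection uses a one-vs-rest
Welch t statistic with a label-permutation null ((b+1)/(B+1)
convention, default B = 10,000) and BH q-values within a cluster; this
is a documented approximation of permutation-t "SAM-style" marker
calling, whose exact internals are not public.

## Plackett–Luce event timing

Within a tumor, events are ordered by descending CCF (dense ranks;
equal CCFs form tie groups); tumors with fewer than two events are
dropped. The Plackett–Luce model gives each event a positive worth and
generates a ranking by repeatedly choosing the next-earliest event with
probability proportional to worth. Maximum-likelihood worths come from
MM (minorization–maximization) iterations; the log-likelihood is
asserted non-decreasing at every step, convergence is a maximum
relative worth change below `tol`, and worths are normalized to sum 1.
Tie groups are split uniformly at random (seeded; fresh split per
bootstrap replicate) — unbiased under exchangeability; the tie-aware
extended likelihood is out of scope. A pseudo-observation of one
complete ranking and its reverse at weight ε = 0.1 guarantees a
strongly connected comparison graph and a finite MLE; ε → 0 behavior on
dominated pairs is tested. The "timing estimate" of an event is its
rank position in the descending-worth order; 95% CIs come from 1,000
(configurable) tumor-level bootstrap resamples with replacement,
refitting per replicate and taking the 2.5th/97.5th percentiles of rank
position. Events absent in a tumor are treated as missing at random,
not as late.

## Survival

Signature high/low groups are defined per tumor type (or dataset-wide)
as score ≥ the third quartile, inclusive, with the same interpolated
quantile convention as curation; groups under 4 samples are skipped.
Kaplan–Meier curves and the log-rank chi-square are computed after
administrative censoring at 10 years (configurable) via lifelines. The
Cox workflow fits each candidate covariate alone (likelihood-ratio p),
passes those under the gate into one multivariate model, and reports
HR with 95% CI per term; ties use the Efron approximation, and the gate
has no default because it legitimately differs between cohorts (0.2 and
0.1 in the motivating analyses). Near-duplicate covariates (|r| >
0.999) are flagged and deduplicated before the multivariate fit.

## Synthetic cohorts

The generator emulates exactly the structure the association framework
assumes. Gene g's log-expression is Normal(μ_g, σ_g) per sample with
μ_g ~ U(2, 8) and σ_g ~ U(0.25, 1.0) on the natural-log scale (so
expression is log-normal and rank-based scoring is exercised
realistically); signatures are disjoint gene blocks unless supplied.
Alterations are Bernoulli(frequency) independently per sample, and a
planted effect multiplies each signature gene of an altered sample in
an affected tumor type by exp(±δ·σ_g) — a mean shift of δ within-group
SDs on the log scale. Survival times are exponential with hazard
`baseline·exp(Σβx)` and administrative censoring; event orderings are
drawn sequentially from a Plackett–Luce model with per-event missingness.
One seed drives everything through deterministically spawned
sub-streams, so identical (config, seed) is bit-identical.

What the generator does **not** emulate: gene–gene correlation beyond
signature blocks, tumor-type-specific expression baselines, mutual
exclusivity or co-occurrence of alterations (an optional coupling hook
exists but is off by default), segmentation noise, or non-exponential
hazards. Passing tests therefore demonstrate correctness of the
statistics and the machinery under the stated model — calibration of
the permutation FDR under the null, power against planted effects,
estimator consistency — not robustness to every pathology of real
cohorts.

## Problem sizes and numerical choices

The validation suite uses desk-scale versions of the study conditions,
chosen once: association calibration/power cohorts of 10 tumor types ×
100 samples with 20 alterations × 10 signatures and 10,000 permutation
replicates; timing recovery with worths 8:4:2:1 over 100 tumors at 20%
missingness; Cox recovery with true HR 2 at n = 600 per seed over 100
seeds. Floats are serialized with 12 significant digits, which is what
makes pipeline reruns byte-identical. Degenerate inputs error early
with named causes (empty signature files, inverted intervals,
out-of-alphabet arm calls, zero-variance cluster columns, all-censored
survival groups), and boundary semantics are pinned in tests: threshold
p exactly at the cutoff counts, count-3 at threshold-3 does not, ≥ Q3
is inclusive, subtypes need strictly more than 10 samples.

## Known limitations

The permutation FDR inherits a selection effect: candidates are chosen
for being extreme (count ≥ 2), so under a global null the rare
candidate that does arise will tend to receive a very small FDR; the
framework controls discoveries through the rarity of candidates, not
through the conditional FDR of selected pairs. The multiSAM-style
marker test and the permutation-normalized ES are documented
approximations of conventions whose reference implementations are not
fully specified. GISTIC, segmentation and variant calling are consumed,
never re-implemented; homolog mapping is table-driven relabeling only.
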