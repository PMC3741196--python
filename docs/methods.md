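# Methods

This note documents the statistical procedure implemented by `tissuevote`,
its assumptions, the tunable parameters, the synthetic-data model used for
validation, and the numerical and design choices made where the procedure
left room for them.

## Problem and overall procedure

Given several expression datasets — each a probe-set × sample matrix of
log2 intensities with a sample→tissue assignment — the task is to label
every gene as *specific* (preferentially expressed in exactly one tissue),
*2-selective* (exactly two) or *ubiquitous*, together with a confidence
(support band) and a consistency measure (coverage). The pipeline is
high-level integration: methods are applied to each dataset separately and
only their verdicts are merged, which allows mixing platforms and
technologies without joint normalisation.

Stages: (1) per-probe-set detection by 2–3 methods, (2) per-probe-set
consensus vote, (3) per-gene, per-dataset inner score over probe sets,
(4) cross-dataset total score and final verdict.

## Input model and vocabulary grouping

Intensities are assumed log2-scale and finite; missing values are rejected
rather than imputed, because none of the detectors defines missing-data
behaviour. Tissue terms are compared case-insensitively after whitespace
trimming; the vocabulary file's spelling is normative. Grouping merges
tissues that share a group term. For a replicate-free dataset the merged
column is the element-wise maximum over the grouped columns — the grouped
tissue is represented by its strongest signal, which is conservative for
specificity detection (a gene specific to a sub-tissue stays visible). For
a replicate-bearing dataset the samples of grouped tissues are pooled under
the group term, preserving replicate structure for the Bayes detector;
max-merging across replicate indices would fabricate mixed pseudo-replicates.
An empty group term drops the tissue; grouping that leaves fewer than three
tissues is an error, since no detector is meaningful below that.

## Detectors

### ROKU-SPM

The profile is centred by a one-step Tukey biweight (tuning constant 5,
epsilon guard 1e-4 on the MAD). The guard makes the estimator degenerate
gracefully on profiles whose MAD is 0: gross outliers receive weight
exactly 0, so e.g. (1,1,1,10) centres at exactly 1. Shannon entropy of the
normalised absolute deviations gates specific vs ubiquitous; a flat profile
returns the maximal entropy log2(n) by convention. Candidate tissues are
located by a one-sided AIC outlier search: over the prefixes U of the
descending ranking with |U| ≤ 2 (including the empty set), minimise
m·ln(RSS/m) + 2(|U|+1), where RSS is the residual sum of squares of the m
non-outlier values around their mean; RSS is floored at 1e-12 inside the
logarithm and ties prefer fewer outliers. SPM then confirms the candidates:
one outlier needs SPM ≥ spm1, a pair needs pairwise SPM ≥ spm2. Failed
checks degrade to the next weaker call (a pair failing spm2 falls back to a
specific call if the top outlier passes spm1; otherwise ubiquitous). The
order — entropy gate, then outliers, then SPM confirmation — is this
package's concrete choice.

SPM is computed on linear-scale intensities by default (`spm_scale:
linear` exponentiates the log2 input; `log2` uses values as-is), matching
the measure's origin in linear expression databases.

Parameters: `h_max` (bits; grid default 1..log2(n) in 0.25 steps), `spm1`,
`spm2` (both in (0,1]; grid 0.5..0.95 in 0.05 steps).

### Decision function

On the descending-sorted profile, for k ∈ {1, 2}: gap g_k = x(k) − x(k+1),
specificity fraction sp_k = g_k / (x(1) − x(n)) (0 when the range is 0),
decision value d_k = g_k / sd(x(k+1..n)) with the sample sd (ddof 1). A
zero-spread low group with a positive gap gives d = +∞; an entirely
constant profile is ubiquitous. At least 4 tissues are required so the low
group has a spread. Parameters: `g_min` (log2 units; grid 0.5..4 step 0.5),
`sp_min` (grid 0.1..0.9 step 0.1), `d_min` (grid 1..5 step 0.5).

### Encompassing-prior Bayes factor

Replicated data only (every tissue ≥ 2 samples). Model: per-tissue normal
likelihood with a shared diffuse normal-inverse-gamma prior, μ_j ~ N(m0,
σ²/κ0), σ² ~ InvGamma(a0, b0), with m0 = 0, κ0 = 1e-4, a0 = b0 = 1/2.
The half-unit shape keeps the prior heavy-tailed but proper: near-improper
shapes (e.g. 1e-3) produce numerically infinite draws whose ties break the
exchangeability of the prior constraint fraction, which must equal 1/J at
c = 0 by symmetry (verified within Monte-Carlo error in the tests).

Tissues are ranked by sample mean (descending; ties broken by panel
order). The specificity constraint is μ(1) > c·s(2..J) + max_{j≥2} μ(j),
the 2-selectivity constraint requires μ(1) and μ(2) to exceed
c·s(3..J) + max_{j≥3} μ(j); s(·) is the standard deviation of the *sample
means* of the lower-ranked tissues — the between-tissue variability, which
dominates replicate noise in tissue panels and is what the margin is meant
to capture. Both the ranking and s are fixed by the data; only μ is drawn.
BF = (posterior constraint fraction) / (prior constraint fraction), each
estimated from `n_draws` Monte-Carlo draws (floor 10⁴) under one seeded
generator per call; a zero prior count is floored at half a draw so
overwhelming but finite evidence is reported rather than a division error.

Because the top tissue is selected by the same data the posterior is
conditioned on, exchangeable (null) data yields BF slightly above 1 on
average, not below; the margin c·s reduces but need not invert this. The
decision boundary is therefore not BF = 1 but the simulation-calibrated
thresholds: `calibrate_bf_thresholds` simulates exchangeable null panels
and returns the smallest (bf1, bf2) whose null exceedance rate is at most
the target false-positive rate (default 0.05), deterministically under a
seed. Typical calibrated values at c = 1 are bf1 ≈ 4–5.

Parameters: `c` (margin, multiples of the between-tissue sd; grid
{0, 0.5, 1, 2}), `bf1`, `bf2` (from calibration), `n_draws`, `seed`.

## Consensus vote

The vote over 2–3 method calls is order-invariant (patterns are multisets)
and tissue-aware: a call supports a tissue it contains. Rules, in order:
ubiquitous calls strictly outnumbering informative ones win; among
informative calls, a pair named by a unique ≥50% majority wins as
2-selective; otherwise the tissue with the uniquely largest support wins as
specific — requiring at least two supporters unless specific calls are in
the majority, where a single uncontested specific call suffices (so a
specific + ubiquitous two-method vote stays specific, while one informative
call of three loses). Ties between distinct tissues mean no tissue has
strong support: ubiquitous. These rules reproduce the full 16-row vote
table under every permutation (exhaustively tested) and extend it to the
tissue-mismatch cases the table leaves open: disagreeing specific calls tie
to ubiquitous; partially overlapping pairs resolve to the shared tissue
when it has two supporters; three disjoint tissues yield ubiquitous.

## Inner score, total score, verdict

Rule 1: if at least 50% of a gene's probe sets in a dataset are informative
and share a tissue, ubiquitous probe sets are non-informative and dropped.
"At least 50%" is an exact rational comparison (1 of 2 counts). Rule 2: a
*single* candidate condition — a tissue with ≥50% specific calls among the
retained probe sets, or a pair with ≥50% 2-selective calls — scores 1, or
0.5 + 0.5 for the pair. When several candidate conditions tie at the bar
(e.g. one specific(Liver) and one 2-selective(Liver, Kidney) retained call,
each at exactly 50%) the evidence is split and the score falls back to
contribution averaging: a specific call contributes 1 to its tissue, a
2-selective call 0.5 to each of its tissues, averaged over retained calls
(Liver (1 + 0.5)/2 = 0.75, Kidney 0.25 in the example). The alternative
frequency reading — the fraction of retained calls mentioning the tissue —
is available as `rule2_frequency="mention"`; it is not the default because
it can exceed the per-gene unit budget (Liver would score 1.0 in the same
example). Under the default, inner scores sum to at most 1 per gene.

The total score per tissue is the arithmetic mean of the inner scores over
the datasets in which the gene is represented — not over all datasets.
A gene present in a single dataset with inner score 1 therefore reaches
total score 1 (strong support at coverage 1), and present-but-ubiquitous
datasets still dilute the average with zeros. Coverage reports
(datasets present, datasets total) separately, so consistency is not
conflated with confidence.

The final category is the majority among the per-dataset verdicts implied
by the inner-score rules, counting informative datasets only, with ties
going to specific (the stronger claim, which the support band then
qualifies). Reported tissues are the top-scoring one (specific) or top two
(2-selective), ties broken alphabetically for determinism. Support bands
follow the category-dependent score edges listed in the README; a
2-selective top score above 0.5 (possible only under mixed specific/pair
evidence) is reported as strong. Genes whose top score falls below every
band are below-threshold regardless of category.

## Training and evaluation

The penalty for a training gene is s = |τ − 1| (annotated specific) or
s = τ (annotated ubiquitous), where τ is the number of tissues in the
gene's call; the objective is the sum over the training set and is 0
exactly when every specific gene gets one tissue and every ubiquitous gene
none. Note the penalty does not check *which* tissue — the annotated tissue
is used at evaluation time, not during fitting, mirroring the original
optimisation design. Multi-probe-set training genes are consolidated by the
consensus vote (2–3 probe sets) or the inner-score verdict (more). The grid
search returns the first minimum in grid order; the default grids list
stricter settings first, so a tie never selects a more permissive setting.
2-selective training genes are not used: the training sets contain only
specific and ubiquitous genes.

`cross_evaluate` applies each training set's fitted parameters to every
gene set: a specific gene agrees when the predicted tissue set contains its
annotated tissue, a ubiquitous gene agrees when no tissue is predicted
(below-threshold predictions count as no tissue, matching the convention
that an empty cell means "no tissue with strong support"). The result is
the all-against-all percentage matrix.

## Synthetic studies

`generate_study` emulates a multi-platform tissue atlas: per dataset,
baseline intensities are Normal(baseline, noise_sd) per tissue × replicate
on the log2 scale (multiplicative noise on the linear scale — the standard
microarray intensity model); planted genes add the effect size Δ to their
target tissue(s) wherever the panel contains them; a configured fraction of
probe sets is discordant (no elevation) to exercise Rule 1.

Defaults define the standard validation study: 4 datasets, 500 genes in
proportions 0.45 / 0.15 / 0.40 (specific / 2-selective / ubiquitous), Δ = 3
log2 units against noise sd 1, 10% discordant probe sets, 1–3 probe sets
per gene, 20-tissue panels drawn from a fixed 60-term list with a
12-tissue shared core, and replicate structure (1, 3, 1, 3) so two datasets
support the Bayes detector. Baseline 8 log2 units sits mid-range for
intensity data. Target tissues are drawn from the shared core so every
platform can in principle detect them (`targets_from_core=False` draws from
the panel union instead, producing genes whose tissue is missing from some
panels). Genes are present on every platform; partial-coverage behaviour is
exercised through explicit fixtures rather than the generator. The training
set sampled from the truth table (20 specific + 10 ubiquitous genes)
mirrors the size and composition of curated training sets used in practice.

What the generator does *not* model: probe-level hybridisation artifacts,
batch effects, platform-specific normalisation differences, correlated
tissues, or genes absent from individual platforms. Passing tests therefore
demonstrate the correctness and statistical behaviour of the rules and
detectors under an idealised intensity model, not performance on any
particular real platform.

Under these defaults the grid-search-trained pipeline recovers 96.9% of
planted specific genes (218/225) at support ≥ medium with 0.5% (1/200) of
planted ubiquitous genes called specific (computed by
`tests/test_acceptance.py`; thresholds ≥ 90% and ≤ 5%).

## Numerical choices and determinism

- All randomness flows through `numpy.random.default_rng` with explicit
  seeds; every CLI command and fit is reproducible under `--seed`.
- Ranking ties (equal means) break by tissue-panel order; score ties break
  alphabetically; grid ties keep the earliest (strictest) grid point.
- Support-band edges use an absolute tolerance of 1e-9 so that scores
  assembled from exact halves and quarters compare as printed.
- The AIC's RSS is floored at 1e-12; the biweight MAD carries a 1e-4 guard;
  the Bayes prior count is floored at half a draw.
- Problem sizes in the test suite (500-gene studies, 10⁴–10⁵ Monte-Carlo
  draws, 40–100 calibration simulations) were chosen as the smallest sizes
  at which the statistical assertions are stable at their stated
  tolerances.

## Known limitations

- The consensus extensions for tissue-mismatch patterns and the
  specific-vs-2-selective majority at gene level are this package's rules;
  the original vote table does not define them.
- The Bayes factor's null behaviour depends on the prior; only the
  calibrated thresholds, not BF = 1, separate the hypotheses.
- No categories beyond 2-selective are emitted (3-selective and higher are
  out of scope).
- The inner score treats probe sets exchangeably; platform-specific probe
  quality is not modelled.
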