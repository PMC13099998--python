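# Methods

## Setting and data model

The toolkit analyses long-format annotation tables: one record per
(item, rater, question), where each rater has a role (`crowd`, `expert`,
`model`, `consensus`) and each question is either *single-option* (one label
from a codebook of size k) or *multi-option* (a non-empty label set).
Absence is always an explicit codebook label (`"None"`,
`"Non-applicable"`), never an empty set — this keeps "the rater judged that
nothing applies" distinguishable from "the rater gave no answer" (a missing
row), and it makes under-detection of the absence category a measurable
bias like any other label.

## Consensus rules

Single-option: majority vote; ties go to the label of the earliest coder in
ascending-`rater_id` order. The tie-break needs *some* fixed coder order to
be reproducible; ascending id is declared once and never depends on the
data. Multi-option: a label enters the consensus when at least
`threshold` (default 2) of the coders chose it; if no label qualifies, the
fallback is the union of all chosen labels, so the reference never goes
empty. The sensitivity variants `union_only`, `intersection_only` and
`threshold_only` apply the plain set operation; `threshold_only`
deliberately has no fallback and may produce an empty consensus, in which
case no consensus record is emitted for that item.

## Agreement coefficients

Proportion agreement and mean per-item Jaccard are raw overlap measures.
The two chance-corrected coefficients:

**Gwet's AC1.** `(P_o − p_e) / (1 − p_e)` with
`p_e = (1/(k−1)) Σ_q π_q(1−π_q)`, `π_q` the mean of the two raters' usage
proportions of category q. Two deliberate choices: (i) the chance term is
the standard AC1 form — the agreement literature contains variant printings
of this formula that are not bounded by 1 and do not reproduce AC1's known
values, so the implementation pins itself to the hand-derived worked
example (P_o = 0.8, π = 0.8 ⇒ AC1 = 0.48/0.68) in the test suite; (ii) the
sum runs over *all* k codebook categories, not only the observed ones
(unused categories contribute 0 to the sum but inflate k−1), so a rare
category that happens not to appear in a subsample does not silently change
the coefficient's definition.

**Krippendorff's alpha (two raters).** `α = 1 − D_o/D_e` with
`D_o = (1/n) Σ_i d(a_i, b_i)` and `D_e` the mean of d over all
`2n(2n−1)/2` unordered pairs of the pooled responses — the canonical
pooled estimator, with no additional finite-sample correction. When all
pooled values are identical, `D_e = 0` and α is reported as 1 with a
degeneracy flag rather than an error: the raters agree perfectly, the
coefficient is simply uninformative about chance. The distance is
pluggable: 0/1 nominal (which reduces α to standard nominal alpha, verified
against an independently coded reference), Jaccard distance, Passonneau's
`d_P` (0 equal, 1/3 subset, 2/3 partial overlap, 1 disjoint), or MASI
`d_P · (1 − J)`. MASI is symmetric, bounded in [0,1], zero iff the sets are
equal and one iff disjoint, but it is *not* a metric (the triangle
inequality can fail); α only needs the former properties.

Computation reduces the pooled responses to unique values with counts; for
label sets the unique-by-unique distance matrix is evaluated with bitmask
popcount arithmetic (codebooks up to 64 labels), so α at n = 1000 on a
26-label task costs a few milliseconds. An explicit all-pairs enumeration
oracle lives in the test suite and must agree to 1e−12.

All pairwise results are computed on the intersection of the two raters'
item sets (listwise within pair), so expert comparisons automatically run
on the expert subsample while crowd/model comparisons use the full panel.

## Option bias

For each label, the bias is `rate_model − rate_reference` over the shared
items; positive = over-detection. The default test is the unpaired pooled
two-proportion z-test — chosen because the quantity of interest is a rate
difference, and because it is the conventional reading of "two-tailed
z-test" for selection rates; a paired McNemar-style variant (z on the
discordant counts) is available for users who want to exploit the shared
items. Stars at p < .05/.01/.001 come from the raw p-values;
Benjamini–Hochberg-adjusted values are emitted as an extra column but do
not drive the stars. Labels offered only to human coders (an `"Other"`
option) are excluded from model bias tables via the schema's
`ai_excluded` set. A caveat the test suite respects: when model and
reference errors are both driven by the same latent truth, the unpaired
z-test is conservative (the shared truth induces positive correlation
between the two rates); exact 5% type-I calibration holds when the two
series' label selections are independent across raters, which is how the
calibration test constructs its null panels.

## Bootstrap exchangeability

Each of B (default 1000) iterations draws one vector of item indices with
replacement and applies it to *every* rater — the coupling is what makes
the within-iteration min/max comparison meaningful. Per iteration the model
and each expert are scored against the consensus (held fixed, not
re-derived per resample: consensus is an item-level attribute, so
resampling items re-selects consensus values with them) using AC1 for
single-option and MASI-α for multi-option questions. Reported: the
proportion of iterations with `min_expert ≤ model ≤ max_expert`, the model's
median coefficient, and a 2.5/97.5 percentile interval. Degenerate
iterations (coefficient undefined after resampling) are recorded as
missing and excluded; valid + missing always equals B. Note the statistic
is only informative when the expert envelope has width — three clones of
one expert produce a zero-width range that nothing can fall inside.

## Synthetic panels

The generator is a latent-truth/independent-noise model: each item has a
true response per question; each rater is an independent channel.
Single-option: the truth is kept with probability `1 − ε_single`, otherwise
replaced by a uniformly random wrong label. Multi-option: each true label
is dropped with probability `ε_miss`, each absent label added with
probability `clamp(ε_add + bias_offset(label))`; an empty result falls back
to the none-label. Per-label `bias_offsets` are the mechanism behind
over-/under-detection in the bias analysis. This generative family is the
simplest one under which the downstream analyses (counting consensus,
chance-corrected agreement, rate-difference bias tests) are all
well-posed.

Default panel (`default_panel_config`): 1000 items; six questions with
k = 2, 3, 9, 10, 11, 26 (three single-, three multi-option, the two
marketing-style questions carrying a human-only `"Other"` label); three
crowd raters covering every item (so each item has exactly 3 crowd
responses per question); three experts sharing one contiguous 40% subsample
(400 items at the default size); four model raters covering everything.
Label prevalence is skewed (geometrically decaying weights, a lump on the
absence label); multi-label set sizes follow {1: .5, 2: .3, 3: .2}
(mean 1.7). Noise defaults: crowd ε_single = .12, experts .06, models .10,
with multi-question miss/add rates scaled as 2ε and ε/4. Experts are
deliberately heterogeneous (0.7×, 1×, 1.8× the base rate): real expert
panels show wide inter-expert variability, and the exchangeability envelope
is degenerate without it. Model raters carry small positive bias offsets on
a salient promotional label per multi question, emulating systematic
over-detection.

Two things the generator does not emulate: correlated errors across raters
(real coders share item-level ambiguity, which inflates observed agreement
relative to independent noise at equal error rates) and item-difficulty
heterogeneity. Consequently passing tests demonstrate the estimators'
correctness and calibration under exchangeable independent noise, not that
any particular real panel will reach the same coefficient values. For multi
questions the per-label `prevalence` values act as sampling *weights* for
without-replacement member draws, so they are proportional to, but not
equal to, marginal selection probabilities; the marginal-control test
therefore checks single-option marginals exactly and multi-option mean set
size.

## Calibration scenarios

`random_like` draws both raters independently (sizes from the task's
empirical size distribution, members uniform) — its mean α defines the
chance floor, verified to bracket 0. `near_perfect` copies rater 1 and,
with probability `ε_cal` (default 0.05) per item, swaps one label for a
random outsider; at `ε_cal = 0` it returns α = 1 exactly. `near_disagreement`
draws a same-size set from the complement of rater 1's set; when the
codebook is too small for full disjointness the overlap is minimized. The
three means order near_perfect > random_like > near_disagreement, which is
asserted, not assumed. Summaries (mean, sd, 2.5/97.5 percentiles) are
reported per scenario × metric; sd is missing at R = 1.

## Stratified deltas

Agreement is computed within each of two item strata for a rater pair; the
null distribution of the delta comes from permuting stratum labels across
the pair's overlap (group sizes preserved), with
`p = (1 + #{|null| ≥ |obs|}) / (P + 1)` — the add-one smoothing keeps p in
(0, 1]. The permutation pool is put in a canonical order so swapping the
two strata negates the delta but leaves p unchanged. A permutation test was
chosen because agreement coefficients have no convenient closed-form
sampling distribution, especially with MASI-α on sparse sets.

## Numerical and design notes

- All randomness flows through `numpy.random.default_rng` seeded from
  explicit integers or spawned `SeedSequence` children; identical configs
  give byte-identical outputs, which the pipeline test asserts at the file
  level.
- Problem sizes in the test suite (e.g. 200-item panels × 50 seeds for the
  noise-monotonicity check, B = 200 for the bootstrap ordering check) were
  fixed as the smallest scales at which the asserted orderings are stable
  across seeds by a wide margin; the stated tolerances are unchanged from
  their definitions.
- Distance callables other than the named ones fall back to a per-unique-
  pair Python loop; correctness is identical, only speed differs.
- Known limitations: no multi-rater (> 2) alpha; no probabilistic consensus
  (Dawid–Skene); bias analysis reports rate deltas only, not confusion
  structure; the CLI's heatmap export is plain CSV, rendering is left to
  the user.
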