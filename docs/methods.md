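# Methods

This note documents the models, default parameters and design choices behind
`screensim`, and what its synthetic validation does and does not establish.

## Screening data model

A review dataset couples four layers: candidate records (title + abstract),
title–abstract decisions by a *senior* and a *second* reviewer, the set of
records included in the final report (the gold standard against which any
screening workflow is judged), and study-level characteristics (design, risk
of bias, publication year, journal impact factor) for final-report records.
Reviewer decisions are binary: `relevant` merges the include and unsure
labels, because either advances a record to full-text screening and the two
cannot be distinguished retrospectively in screening exports; no borderline
state is modeled. Identity is a caller-supplied record id; ids generated
from RIS files without one are content hashes so regeneration is stable.

## Synthetic corpus generator

The generator is first-class, tested code: it defines the conditions under
which the pipeline is validated.

**Texts.** A two-component multinomial bag-of-words. The background
(irrelevant) distribution is Zipf (exponent 1.1) over a `vocab_size`-word
vocabulary; the topic distribution places the same Zipf mass on a seeded
permutation of the vocabulary. The relevant-class distribution is
`a·topic + (1−a)·background` with `a = 1 − exp(−topic_separation)`, so
separation 0 makes the classes textually identical (held-out AUC ≈ 0.5,
verified by test) and separation ≳ 3 makes them essentially separable for a
linear model. Each relevant document additionally mixes back toward the
background with per-record weight `hardness` (default base 0.25); hardness is
the single dial through which difficulty and characteristic effects enter.

**Rates and reviewers.** Defaults follow the across-review medians of
retrospective screening data: 3,000 records, 9% relevant at title–abstract,
2% in the final report (drawn from the true-relevant at the conditional rate
2/9), titles ~12 tokens, abstracts ~120. Reviewer decisions are Bernoulli
corruptions of the latent truth. Published screening data do not report
reviewer error rates (single-reviewer miss rates spanned 0–43% across
reviews), so the defaults — senior 0.95 sensitivity / 0.98 specificity,
second 0.90 / 0.96 — encode only the qualitative ordering that the senior
reviewer is the stronger screener; they are modeling choices, not estimates
of any real reviewer.

**Characteristics.** Final-report records receive design (60% trial, 27%
observational, the remainder qualitative/mixed-methods/reviews), risk of bias
(15% low, 62% high-or-unclear, 23% unknown), publication year ~ N(2008, 7²)
and a log-normal impact factor (μ=0.85, σ=1.1, approximating a heavy-tailed
mean ≈ 4.9). Each category carries a hardness multiplier (defaults: 2.0 for
observational, 1.6 for reviews and for low risk of bias, 1.0 otherwise); the
record's text is re-drawn with `base_hardness × multipliers`, which is what
couples characteristics to downstream misprediction. Unit multipliers give
the null model (categories independent of text).

**Determinism.** Every generator op draws from `default_rng([seed, op_id])`
— one stream per op — so attaching a later stage never perturbs earlier
draws, and all generators are pure functions of their spec.

## Relevance classifier

Online screening tools do not document their internals, so the predictor is
an explicit surrogate: tf-idf over lower-cased unigrams+bigrams of
title+abstract (idf = ln((1+n)/(1+df)) + 1, L2-normalized rows), fitted on
the full corpus — the retrospective setting is transductive — and an
L2-penalized logistic model with **balanced class weights** (each class
contributes half the total loss). Balancing matters: at ~9% prevalence an
unweighted fit ranks perfectly but calibrates relevant records below the
fixed 0.5 hard-prediction threshold, gutting recall; a screening tool's
operating point errs toward inclusion, and balanced weighting is the
standard way to encode that. The hard threshold stays at 0.5 (tools are used
with their hard predictions, not custom thresholds), and a probability
exactly at threshold is called relevant.

Reviewer term priors ("dual supervision") enter as the mean of the Gaussian
penalty: the objective is `Σ wᵢ·logloss + ||w − w₀||²/(2C)` with `w₀` built
from the tagged terms (±weight). A pure optimizer initialization would be
inert under a convex loss; the prior-mean form makes tagging a term actually
pull predictions, monotonically in the weight (property-tested). The fit is
a SciPy L-BFGS minimization of that objective (deterministic); at `w₀ = 0`
it agrees with scikit-learn's balanced `LogisticRegression` to ~1e-3, which
a unit test enforces as an independent cross-check.

**Training protocol.** Records are labeled in seeded random order with the
senior reviewer's decisions: 200 initially, extended in batches of 100 up to
300 while the set lacks at least one relevant and one irrelevant label; at
the cap without both classes, predictions are declared unavailable rather
than degraded. Vendor guidance of ≥10 includes / ≥40 excludes is surfaced as
a warning, not a gate, since it is advice rather than a hard requirement.

## Workflow simulators and effort accounting

All four simulators share the either-relevant-advances rule and an exact
ledger. For the liberal-accelerated ML workflow, training records are
counted as dual-screened (2T), the senior screens the P predicted-relevant
records, the second reviewer screens the senior's E_sp exclusions among them
plus all I predicted-irrelevant records: total `2T + P + E_sp + I`, savings
`2N − total`. This accounting reproduces the one published row whose ledger
can be back-solved (N=2928, T=200, P=319, E_sp=192 → savings 2536, 43%).
The ML second-screener workflow has the second reviewer screen all N and the
senior screen T + P, giving savings `N − T − P`; with a senior who never
overrides a relevant prediction its missed set coincides with the
liberal-accelerated one (tested). Consensus steps are not modeled — the
liberal-accelerated design omits them by construction. Conservation
(`savings + screenings = 2N`) is asserted for every workflow.

## Metrics

Proportion missed = 100·missed/final-report; workload savings percentage
uses the dual baseline 2N as denominator (the only convention consistent
across all published per-review rows); time savings at 0.5 min/record and an
8-hour day. Display rounding is half-up; day counts below 1 render as
"< 1 d" — the rule consistent with every published row (e.g. 0.66 days
prints as "< 1 d", so the cut is at 1 day, not 0.5). Median/IQR quantiles
interpolate linearly at position `1 + (n−1)p`, the rule that reproduces the
published cross-review summaries; raw (unrounded) values are returned and
rounding is applied only at display.

## Exact tests

2×2 tables use Fisher's exact test (SciPy). The r×c generalization
(Freeman–Halton) is implemented here by full enumeration of tables with the
observed margins: a table counts toward p when its multivariate
hypergeometric probability is ≤ the observed table's, with the same 1e-7
relative slack mainstream implementations use for ties. Two-column tables —
the common case — enumerate recursively over the small rows and vectorize
the largest, which keeps the 802-record 5×2 design table (~9×10⁵ feasible
tables) under a tenth of a second. Above a `max_tables` budget (default
10⁷) a seeded Monte-Carlo estimate over margin-preserving random tables is
returned with its binomial standard error; it is property-tested to agree
with enumeration within 3 SE. The 2×2 reduction agrees with Fisher to 1e-9
over random tables. The pooled-variance (not Welch) unpaired t-test is used
for continuous publication characteristics, from raw values or (n, mean, sd)
summaries; pooled is the form whose CI half-width matches the published
summary-statistics example.

## Meta-analysis sensitivity

DerSimonian–Laird random effects with normal (z) intervals — the era-default
estimator for the reviews this models; the moment equations are implemented
directly and cross-checked against `statsmodels.combine_effects` in a test.
`leave_out_compare` re-pools after removing chosen studies and flags a
significance change strictly as the 95% CI's zero-crossing status flipping,
plus a direction flag; removing every study yields an explicit
"undefined" comparison object, not a zero. Estimator calibration is
validated by parameter recovery on synthetic study sets: bias of the pooled
estimate within 3 Monte-Carlo SEs (k=100, small SEs, 150 replicates) and
z-test type-I error inside the binomial 3-SD band around 5% (k=10, τ²=0,
1,000 replicates).

## Problem sizes used in validation

The packaged separable corpus is 2,000 records (separation 4.0, seed 42);
classifier recall on its non-training true-relevant records is ≥95% by
acceptance test (measured 100%). Prevalence and reviewer-error checks use
5,000–10,000 records at 3-SD binomial tolerances; characteristic-coupling
effects are demonstrated at 5,000 records with moderate separation. These
sizes sit inside the 451–12,156-record range the generator emulates.

## Limitations

Synthetic texts are bags of symbolic tokens: no syntax, no citation
networks, no near-duplicate records, no multilingual abstracts — so passing
tests show the pipeline's logic and statistics are correct under the stated
generative model, not that any particular classifier will achieve these
recalls on real corpora. The classifier is a declared surrogate for
proprietary screening tools; published per-review prediction counts are
treated as validation inputs, never re-predicted. Reviewer errors are
independent Bernoulli draws, ignoring correlated blind spots between
reviewers, and the published antipsychotics meta-analyses cannot be
reproduced exactly because study-level data are not printed; the leave-out
machinery is instead validated on synthetic sets constructed to flip
significance by design.
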