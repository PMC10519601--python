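# Methods

This note documents the models and procedures the package implements, the
parameters that matter, what the synthetic generator does and does not
emulate, and the numerical and design choices made where the design was
genuinely open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model

A *post* is one forum message — submission or comment, undistinguished
downstream — with an opaque id and author, a community (subreddit) name, a
UTC epoch timestamp (no valid post predates the platform's 2005 inception),
and unicode text. Submissions' titles are folded into the body with one
newline. Corpora are line-delimited JSON so processing streams; user
attributes (mean age in years; gender coded 0 = feminine, 1 = masculine,
matching the upstream inference convention) arrive as a TSV and may be
missing per user. Deleted-post placeholders are treated as ordinary text.

## Cohort mining

Membership is decided per author over the union of their posts: included iff
at least one bipolar-diagnosis statement matches, no exclusion phrase
matches, and no psychotic-disorder statement matches. Exclusion is
user-level (any post, any time) and therefore monotone: adding posts can
only remove a user, never add one, and membership is invariant to post
order. A major-depressive-disorder statement does not exclude — a large
fraction of people eventually diagnosed with BD first receive a depression
diagnosis — while a psychotic-disorder comorbidity (a DSM-5 exclusion
criterion outside the usual diagnostic trajectory) does.

Matching is case-insensitive regular-expression search over
whitespace-normalised text, anchored at word boundaries. The shipped pattern
file is a documented, deliberately small seed built from the canonical
quoted statement forms; production pattern sets behind published cohorts are
much larger and not public, so the file is replaceable wholesale
(`--patterns`), and the pattern file — not the shipped default — is the
source of truth when supplied. No statement-ordering or per-post length
constraint is applied at this stage.

## Context classification

The subreddit taxonomy (CSV: name, ≤4 topic levels, `is_mh`, `is_bd`;
`is_bd ⇒ is_mh` enforced) is the positive filter: a post's context is MH iff
its normalised (lower-cased, trimmed) subreddit name is an entry flagged
`is_mh`. Names absent from the taxonomy count as non-MH — in real corpora
only a few percent of posts fall outside topic-assigned communities, and the
binary MH/non-MH context is all that downstream analyses consume. The
bundled 18-row fixture taxonomy (including the four canonical BD
communities) exists for tests and synthetic runs; real taxonomies are passed
as input.

## Dictionary scoring

Tokens are whitespace-separated, lower-cased, with leading/trailing
punctuation stripped; internal apostrophes survive ("don't" is one token),
pure-punctuation fragments are dropped, numerals count. The exact tokeniser
behind commercial dictionary tools is not public, so these rules are this
package's documented convention.

A category score is 100 × (tokens matching the category) / (all tokens).
Entries are literal words or stems with a trailing `*` wildcard (prefix
match). A token may score in several categories but counts at most once per
category; the denominator includes non-dictionary tokens. Texts with fewer
than 25 tokens are excluded from analysis (percentage estimates on short
texts are unreliable; the threshold is the field's convention and is a
parameter, `min_wc`). Scores are permutation-invariant, bounded in [0, 100],
and the score of a concatenation is the word-count-weighted mean of the
parts — properties the test suite checks exactly, alongside equivalence with
a brute-force nested-loop matcher.

The bundled lexicon (~70 entries over five categories: posemo, anxiety,
anger, sadness, first-person singular) is an open, shippable seed grown from
each category's canonical example vocabulary. It is *not* a substitute for a
full licensed dictionary in coverage; any `.dic`-format dictionary is read
natively (`read_dic`, five target categories retained, others ignored) and
slots in unchanged.

## User aggregation and samples

Per cohort user: unfiltered MH / non-MH post counts; counts and unweighted
means of ≥25-word posts per context (post-weighted, not token-weighted,
matching the convention of averaging post-level scores); `active_days =
max(1, ceil((last − first)/86 400 s))` in UTC with the floor covering
single-post users; `activity` = unfiltered posts / active days. The binary
outcome `posted_in_MH` is 1 iff the user has ≥1 MH post of any length.

* **Posting partition** — classes (both / only MH / only non-MH) on
  *unfiltered* counts, since the partition precedes the language analysis;
  strata: both-context users with ≥4 posts in each ("active contributors",
  the ≥4 threshold adopted from prior forum studies), single-context users
  with ≥8 posts, and the <8-post remainder by class.
* **Paired sample** — users with ≥4 scored (≥25-word) posts in each context.
* **Regression sample** — the paired-sample users (outcome 1) against users
  with *zero* MH posts and ≥8 scored non-MH posts (outcome 0); users missing
  age or gender are dropped listwise. Regression predictors use non-MH means
  only, keeping the mood measure comparable between groups; the test suite
  asserts MH-context means never leak into the design matrix.

## Inferential statistics

**Paired comparison.** Dependent t-test on per-user MH − non-MH mean scores;
two-sided p from t with n − 1 df; Bonferroni `p_bonf = min(1, 5p)` for the
five categories. Cohen's d is reported in two variants because published
paired effect sizes are often not identifiable to one variant from summary
tables: `d_z = mean(diff)/sd(diff)` and
`d_av = mean(diff)/√((sd₁² + sd₂²)/2)` (the variant recomputable from
printed group means/SDs). Magnitude labels follow the extended conventional
thresholds (0.01/0.2/0.5/0.8/1.2/2.0). Degenerate inputs are explicit:
identical vectors give the null result (t = 0, p = 1, d = 0); a constant
nonzero difference raises rather than returning an infinite statistic.

**Logistic regression.** Binomial GLM with logit link, fitted by IRLS from a
zero start; convergence when |ΔLL| < 1e−8 (error after 100 iterations).
Standard errors from the inverse observed information at the optimum; z and
two-sided normal p-values (the GLM convention — Satterthwaite-type df
approximations do not apply to this model class); Wald CIs at ±1.96 SE; odds
ratios by exponentiation. Rank-deficient designs raise an error naming a
minimal set of collinear columns (greedy QR-style scan). Perfect separation
is detected by the likelihood climbing toward zero or coefficients diverging
(>10³) during iteration — deliberately *not* by single extreme fitted
probabilities or raw coefficient magnitude, which are legitimate when a
covariate's scale is small (the synthetic `activity` covariate, ~0.08
posts/day, legitimately takes coefficients in the tens). The score equation
Xᵀ(y − p̂) = 0 holds to 1e−6 at the reported optimum, and the fit matches
both the closed-form 2×2-table log odds ratio and an independent
implementation (statsmodels) to 1e−6 in tests.

**Model comparison.** `AIC = 2k − 2LL`, `BIC = k·ln(n) − 2LL` with k
counting the intercept; LRT `X² = 2(LL_full − LL_nested)` with df = Δk
against the χ² upper tail, rejecting non-nested inputs. Pseudo-R²:
"Hosmer–Lemeshow" is implemented as the likelihood-ratio index
`1 − LL/LL₀` (McFadden's formula, under the name common in applied
reporting — the formula is what reproduces published triples from printed
log-likelihoods and outcome prevalence, which the acceptance suite checks);
Cox–Snell `1 − exp(2(LL₀ − LL)/n)`; Nagelkerke rescales Cox–Snell by its
maximum. The null LL comes from the intercept-only closed form on the same
sample.

**Gender effect and robustness.** `relative_probability` reports the percent
change in predicted probability between gender codes at a covariate profile
(default: sample means) — the profile is an explicit parameter, since any
single published percentage depends on an unstated profile choice. The
gender-balanced rerun down-samples the majority gender to the minority count
*within each outcome group* and refits. Note a structural consequence: this
balancing makes gender independent of the outcome by construction, so the
gender coefficient itself necessarily collapses toward zero; the robustness
question — and the stability check in the tests — concerns the substantive
mood and control coefficients only.

## Synthetic generator

What it emulates: users with a latent group (MH poster, 76%, vs not, 24%,
with 9% of MH posters never posting outside MH communities — shares chosen
to mirror the partition reported for real cohorts); gender (55% feminine)
and age (normal, mean 32, SD 9, floor 16) independent of group; exactly one
diagnosis-statement post per user, placed where the user posts (MH community
for MH posters), always shorter than 25 words so it never enters scored
means; per-context post counts 1 + Poisson(9) (default mean 10); post
lengths 26 + Poisson(mean − 26) so every emission post passes the 25-word
filter (a flag enables shorter posts for filter tests); token streams i.i.d.
categorical — each token is one of five single-category signature words with
its cell's emission probability, else a neutral filler — so every cell's
expected score is exactly 100 × its emission probability, giving closed-form
binomial oracles throughout. Default emission rates are the published
per-100-token score levels: MH context (3.48, 0.67, 0.75, 0.81, 8.82)/100
for (posemo, anxiety, anger, sadness, i); non-MH (3.64, 0.37, 0.78, 0.45,
6.39)/100 for MH posters, with non-posters slightly lower on
posemo/anxiety/sadness — reproducing the qualitative within-user and
between-group structure. Posting windows (uniform 30–700 days) are drawn
independently of post volume so the activity controls carry no structural
group signal; MH posters still genuinely produce more posts in total, which
is real structure, not an artifact. Contamination (exclusion phrases,
psychotic statements) is planted per user with configured probabilities and
recorded in the ground truth. One `numpy` generator seeded once drives all
draws in a fixed order, so a seed pins the corpus byte for byte.

What it does not emulate, hence what passing tests do not show about real
data: linguistic realism (tokens come from a controlled vocabulary, so
lexicon *coverage* is never stressed); heavy-tailed post-count and
word-count distributions; throwaway/single-post accounts (every synthetic
user has ≥2 posts); topic drift, negation, sarcasm; correlation of age or
gender with posting behaviour (the default corpus carries a null gender
effect — planted-coefficient regression tests use a direct design-matrix
simulator instead); non-stationarity over a user's history.

`simulate_logistic_sample` complements the corpus generator for regression
tests: predictors drawn at realistic scales (scores in percent, raw
active-day counts) and a Bernoulli outcome with specified log-odds, used for
parameter recovery (n = 5 000, 20 seeds, every coefficient within 3 reported
SEs of truth) and type-I-error calibration of the LRT.

## Problem sizes and defaults

The default study conditions are 500 synthetic users (~9 000 posts, ~60
tokens per post), 5%/3% exclusion/psychotic contamination in the `analysis/`
drivers; calibration uses 1 000 Monte-Carlo replicates (paired t at 20
users × 4 posts × 50 tokens per context; LRT at n = 250 with null mood
effects), chosen so the full suite and the acceptance script each complete
in minutes on one CPU while keeping Monte-Carlo error bands (±3 SE ≈ ±0.021
on a 0.05 rate) informative. At the 390-user default regression sample the
small planted between-group mood differences are not significant — the
corresponding published analyses rest on samples of ~10⁴ users — so
end-to-end tests assert direction and calibration, not significance, for
those effects.

## Known limitations

* The shipped lexicon and pattern sets are honest seeds, not full
  dictionaries; results on real corpora depend on supplying the real
  resources as inputs.
* `active_days` counts ceil-of-span UTC days with a floor of 1; other
  endpoint conventions would shift `activity` slightly for short histories.
* Unlisted subreddits are non-MH by definition; a corpus dominated by
  communities missing from the taxonomy will understate MH posting.
* The regression is cross-sectional with listwise deletion of missing
  attributes; no mixed-effects, longitudinal, or imputation machinery.
* Self-reported diagnosis statements cannot be verified; the pipeline
  measures disclosure, not diagnosis.
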