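# Methods

This note records the models, conventions, and numerical choices behind
`repostflow`, in the order the pipeline runs. It documents decisions a
reader would otherwise have to reverse-engineer from the code.

## Data model

Datasets are three tab-separated tables (users, directed follower edges,
events). Timestamps are integer epoch seconds UTC; event order is the
total order (timestamp, event id), so repeated reads and writes are
byte-stable. A repost references the *original* post only — the
who-from-whom chain is never an input, mirroring what platform APIs
expose, and is inferred downstream. Duplicate (user, post) reposts keep
the earliest occurrence with a warning; reposts must be strictly later
than their original, and reads fail on unknown users or posts rather
than silently dropping rows.

## Influence scoring

The h index is the largest *h* with at least *h* posts of ≥ *h* reposts;
the g index is the largest *g* with the top *g* posts totalling ≥ *g²*
reposts, capped at the number of posts (Egghe's convention; the cap
preserves h ≤ g ≤ n_posts and gives a single 100-repost post g = 1, not
10 — an uncapped variant is available). hg = √(h·g). Both indices are
validated against exhaustive search in the tests.

Categories are assigned by position in the hg distribution, ranked
descending. Because hg is discrete, ties are ubiquitous (typically a
large mass at exactly 0), and equal scores must receive equal
categories. The convention used is the **mid-rank percentile**: a tie
block spanning 0-based ranks [a, b) gets fraction ((a+b−1)/2 + 0.5)/N.
Consequences: with all-distinct scores the category populations match
the nominal quantile widths exactly (1000 distinct users → exactly 10
very_high); a fully tied population sits at the 50th percentile and is
assigned `low` — a tied mass never occupies a top percentile. At
moderate scale this can leave interior categories empty when the hg = 0
block spans their band; empty categories surface as undefined (flagged)
rows, never as zeros. The degenerate single-user input is assigned
`very_high`. Scores are computed over all users in the user table,
including never-posters (who score 0), and only reposts inside the
observed log count.

## Cascade reconstruction

Parent attribution for a repost by X at time t considers the original
author (sharing at the post's timestamp) and every earlier non-official
reposter whom X follows; the parent is the candidate with the latest
share time strictly before t, ties broken by user id. "Temporally
closest" means closest to the *repost*, i.e. the share most recently on
X's feed — the reading consistent with how chronological timelines
surface content. Official accounts are dropped as reposters but retained
as roots. When X follows no prior sharer the node attaches to the root
and is flagged `fallback` (alternatives: drop the node, or attach to the
most recent prior sharer regardless of edges — both available for
sensitivity analysis; fallback children are never credited in timelines).
Reconstruction is an approximation by construction: the true transmission
edge is unobservable, and the most-recent-prior-share rule is the stated
inference, validated against a brute-force scan in the tests.

## Virtual timelines and CRP

Three rules filter exposures: (1) only users with ≥ 1 repost of
*anything* in the window act as viewers (dormancy filter — the purpose
is removing inactive accounts, so any repost qualifies); (2) official
accounts never appear as senders; (3) a followee share timestamped at or
after the viewer's own repost of that post is suppressed (the boundary
is configurable; the default treats an exactly simultaneous share as
"after"). Views are timeline appearances — true impressions are
unknowable and no impression model is attempted. Original posts by
followees are not timeline entries; only reposts are, so CRP measures
secondary spread specifically.

CRP per group pools raw counts (Σ credited / Σ viewed), never averages
per-user ratios, so the pooled CRP over all categories equals total
credited over total viewed by construction. Popularity strata are
cumulative minimum-size filters (≥ 1000 contains ≥ 5000), with the
"< 1000" complement expressible via an exclusive upper bound; cascade
size is the final constructed-cascade size (official reposters excluded),
not the size at view time. Zero-view cells are emitted flagged
`defined=False`.

## First-reposter subtree metrics

The earliest reposter (ties by user id) seeds the subtree of all their
cascade descendants. Structural virality is the mean pairwise tree
distance, computed by the linear-time per-edge decomposition
Σ s·(n−s) / C(n,2) rather than all-pairs search (the two agree on 500
random trees in the tests); it is undefined below two nodes. Max depth
is the longest root-to-node path in edges. Category summaries default to
cascades strictly larger than the size threshold and report
normal-approximation 95% CIs of the mean (bootstrap percentile CIs
behind a flag); with n < 2 the CI is undefined and flagged.

## Case-control regression

Positives are credited exposures sampled independently at
`positive_fraction` (default 0.001, with 0.01 a documented alternative);
negatives are uncredited exposures drawn uniformly without replacement
at twice the positive count (configurable), restricted to posts and
viewers present in the positive set. Hour-of-day uses local time (UTC
offset default +9 h) bucketed as morning [05–11), noon [11–17), night
[17–23), midnight [23–05); influence is reference-coded against `low`,
hours are sum-contrast coded (the redundant fourth level is reported as
minus the sum of the fitted three), and both follower counts — follow-graph
in-degrees — are log(x+1)-transformed then z-scored over the sample,
with a zero-variance guard. Because case-control sampling distorts the
base rate, coefficients are relative contrasts only.

The model — binomial GLMM with logit link and crossed random intercepts
for source post and viewer topic — is fitted with statsmodels'
`BinomialBayesMixedGLM`. The default backend is the Laplace-type
posterior mode (`fit_map`), whose point estimates and standard errors
match lme4's zero-quadrature `glmer` fits to the third decimal on shared
data (asserted in a test via `Rscript`) and whose 2-SE intervals show
~95% empirical coverage on self-generated data. The mean-field
variational backend (`fit_vb`) is retained but its posterior sds
understate uncertainty and should not feed significance tests. A joint
Wald test over several terms uses the marginal sds (diagonal
covariance), adequate for the calibration checks it serves. Per-user
random intercepts are deliberately absent: at one repost per (user,
post) the data cannot identify them.

## Synthetic diffusion model

The simulator provides ground truth the observational design lacks. Its
defaults define the validation conditions used in the test suite:

| parameter | default | meaning |
|---|---|---|
| n_users | 2000 | population |
| pa_out_degree | 3 | preferential followees per arriving node |
| random_follow_rate | 2.0 | mean extra uniform-random followees (Poisson) |
| influence_degree_corr | 0.7 | corr(log influence, log follower count) |
| official_fraction | 0.02 | probability a user is official |
| n_topics | 10 | categorical profile topics |
| observation_days | 14 | window length |
| post_rate | 0.12/day | mean originals per user (log-normal across users, σ = 1) |
| appeal_scale | 1.0 | sd of per-post appeal on the log-odds scale |
| prestige_weight | 1.0 | ground-truth bias (0 = null model) |
| base_logit | −4.0 | baseline per-exposure repost log-odds |
| circadian_amplitude | 0.5 | sinusoidal log-odds modulation, peak 20:00 |
| decay_rate | 0.15/h | log-odds attenuation with post age |
| delay_mean_hours | 0.25 | exponential exposure-to-repost delay |

The follower graph combines directed preferential attachment (arriving
nodes follow high-follower accounts, yielding heavy-tailed follower
counts) with uniform-random extra followees. The random component
matters structurally: without it the earliest, best-followed nodes
follow only one another, always share first in any cascade, and under
most-recent-prior-share attribution systematically lose credit to later
sharers — a graph-rigidity artifact that imprints a spurious *negative*
influence–CRP association even in the null model. With it, the null
model shows no systematic ordering, as it must. The post rate matches
the order of magnitude of large platform logs (~0.12 originals per user
per day); the short repost delay reflects that platform reposts follow
exposure within minutes; per-post log-normal appeal mirrors the large
content-level heterogeneity that motivates the post-level random
intercept in the regression. Latent influence is log-normal and
correlated with, but distinct from, follower count — reach and
per-exposure persuasiveness are related yet separate properties.

What the simulator does *not* emulate: algorithmic feed ranking and
ads, quote posts, follower-graph churn, strategic content selection by
influencers, re-exposure to the same share, and any realistic topic
structure (topics are uniform labels). Passing recovery tests therefore
shows the *pipeline* correctly measures a prestige effect when exposure
is chronological and single-shot; it does not validate those modelling
assumptions against a real platform.

## Validation conditions and problem sizes

The test suite validates at sizes chosen to keep full runs on a single
CPU within minutes while leaving sampling error well below the effects
tested: oracle suites use 1,000 random count vectors, 200 random cascade
instances (≤ 50 reposts), and 500 random trees (≤ 200 nodes);
CRP-recovery runs 20 simulator replicates per arm at the default
conditions above (prestige_weight 1 vs 0), comparing very_high vs low
pooled CRP by one-sided sign test and checking the pooled
category-to-CRP trend; GLMM recovery generates from the model's own
formula at n = 30,000 rows, 200 posts, 10 topics (random-intercept sds
1.0 and 0.3) and measures 2-SE recovery over 80 replicates — enough that
the binomial error of the measured rate (~2.4 points) is small against
the margin between nominal ~95% coverage and the 90% pass bar, which a
20-replicate measurement (±5 points per seed) cannot resolve.

## Known limitations

- Parent attribution is an approximation; the fallback convention
  (root attachment) is a guess where the data are silent, and is flagged
  per node so its influence can be audited.
- Quantile binning on a discrete score makes category boundaries
  data-dependent; at small N entire interior categories can be empty.
- The joint Wald test ignores off-diagonal coefficient covariance.
- The simulator's graph has small, homogeneous out-degree for arriving
  nodes; real following behaviour is heavy-tailed on both sides.
- A single static follower snapshot is assumed; edge churn during the
  observation window is not modelled.
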