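# repostflow

Prestige-biased social learning predicts that people preferentially copy
what prestigious individuals do — including what they *share*. On a
repost-based social platform this becomes a measurable question: when an
influential account reposts someone else's content, is that repost more
likely to be reposted onward than the same kind of exposure coming from an
ordinary account? `repostflow` is a tested, reusable pipeline for answering
that question from a directed follower graph plus a timestamped log of
original posts and reposts. It is aimed at computational social scientists
and cultural-evolution researchers studying information diffusion who need
the full chain — influence scoring, cascade reconstruction, exposure
modelling, and effect estimation — as composable, unit-tested parts, plus a
synthetic diffusion simulator for method validation when platform data
cannot be shared.

## What it computes

**Influence (hg index).** A user's original posts are scored like
publications with reposts as citations: `h` is the largest *h* such that
*h* posts each drew ≥ *h* reposts, `g` is the largest *g* (≤ number of
posts) such that the top *g* posts drew ≥ *g²* reposts in total, and the
hg index is √(h·g). Users are binned into six quantile categories of the
hg distribution — very_high (top 1%), high (1–5%), upper_mid (5–10%),
mid (10–30%), lower_mid (30–50%), low (bottom 50%) — each category
excluding its upper threshold.

**Repost cascades.** Platform APIs say which original post a repost
shares, not whom it was reposted *from*. The who-from-whom tree is
inferred: the candidate parents of a repost by user X at time t are the
original author and earlier non-official reposters whom X follows; the
parent is the candidate whose own share is latest before t. Official
accounts are excluded as reposters (their original posts still root
cascades).

**Virtual timelines and CRP.** Each active user's chronological feed of
followee reposts is reconstructed; every appearance is a *view*, and a
view is *credited* when the viewer later reposted the post with that
sender as cascade parent. The cascading repost probability is

```
CRP = (number of reposted reposts) / (number of viewed reposts)
```

pooled over raw counts within each influence category, optionally
restricted to a window of hours since posting and to posts above a final
popularity threshold. A sharer seen by three followers, two of whom
repost onward, has CRP 2/3 ≈ 0.67.

**Cascade structure.** For popular cascades, the subtree seeded by the
first reposter is summarized by structural virality (mean pairwise tree
distance: ~1 for broadcast stars, large for chains) and maximum depth.

**Regression.** A case-control sample of exposures feeds a logistic
mixed model `is_retweeted ~ sender_influence + repost_hour +
sender_followers_count + user_followers_count + (1|source_tweet_id) +
(1|user_topic)`, isolating the sender-influence contrasts from per-post
appeal and viewer-topic heterogeneity.

**Simulator.** An agent-based diffusion model on a heavy-tailed follower
graph with a ground-truth `prestige_weight`: each exposure converts with
probability `logistic(base + appeal_post + prestige_weight·z(influence_sharer)
+ circadian(t) − decay·age)`. Setting `prestige_weight = 0` gives the
null world where sharer prestige has no causal effect — the pipeline
should (and does) find no category ordering there.

## Worked example

```python
from repostflow.synthetic_data import SimulationConfig, simulate_dataset
from repostflow.cascade_builder import build_all_cascades
from repostflow.virtual_timeline import build_timelines
from repostflow.influence_scoring import score_and_categorize
from repostflow.secondary_spread import crp_by_category

config = SimulationConfig(n_users=2000, observation_days=14,
                          prestige_weight=1.0, seed=7)
users, edges, events = simulate_dataset(config)      # 3,373 posts, 24,321 reposts
cascades = build_all_cascades(events, edges, users)  # 439 cascades
entries = build_timelines(events, edges, users, cascades)
influence = score_and_categorize(events, users)
print(crp_by_category(entries, influence, cascades, events,
                      window=(0.0, 6.0)).to_string(index=False))
```

```
    group     window stratum  viewed  reposted      crp  defined
very_high [0.0,6.0)h     >=0    4446      1722 0.387314     True
     high [0.0,6.0)h     >=0    5571      1942 0.348591     True
upper_mid [0.0,6.0)h     >=0   15227      5111 0.335654     True
      mid [0.0,6.0)h     >=0       0         0      NaN    False
lower_mid [0.0,6.0)h     >=0       0         0      NaN    False
      low [0.0,6.0)h     >=0   51687     13503 0.261246     True
```

Reading the table: within six hours of posting, a view of a repost made
by a very-high-influence sender converted to an onward repost 38.7% of
the time, against 26.1% for bottom-half senders — the prestige gradient
the simulator was configured to produce (`prestige_weight=1`). The
`mid`/`lower_mid` rows are flagged undefined rather than shown as zero:
at this scale the discrete hg distribution leaves those quantile bands
without members (a large tied mass of hg = 0 users falls entirely into
`low`), so no views can be attributed to them. Pooled counts, not means
of per-user ratios, make the `crp` column exactly consistent with the
`viewed`/`reposted` columns.

The same pipeline is scriptable from a shell:

```
repostflow simulate --seed 7 --out-dir data/
repostflow validate --events data/events.tsv --users data/users.tsv --edges data/edges.tsv
repostflow crp --events data/events.tsv --users data/users.tsv \
    --edges data/edges.tsv --window 0:6 --out crp.csv
```

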