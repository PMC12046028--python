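import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from repostflow.cascade_builder import build_all_cascades
from repostflow.influence_scoring import score_and_categorize
from repostflow.regression_stage import (
    EmptySampleError,
    FIXED_TERMS,
    INFLUENCE_LEVELS,
    build_samples,
    encode_features,
    fit_glmm,
    hour_bucket,
    simulate_regression_data,
)
from repostflow.virtual_timeline import build_timelines


@pytest.fixture(scope="module")
def sim_entries(sim_dataset):
    _, users, edges, events = sim_dataset
    cascades = build_all_cascades(events, edges, users)
    entries = build_timelines(events, edges, users, cascades)
    categories = score_and_categorize(events, users)
    return users, edges, entries, categories


def test_negative_count_follows_stated_ratio(sim_entries):
    users, edges, entries, categories = sim_entries
    sample = build_samples(entries, positive_fraction=0.05, negative_ratio=2.0, seed=1)
    n_pos = int(sample["is_retweeted"].sum())
    n_neg = len(sample) - n_pos
    assert n_neg == round(2.0 * n_pos)
    assert n_pos / len(sample) == pytest.approx(1 / 3, abs=0.01)


def test_negative_eligibility_constraints(sim_entries):
    users, edges, entries, categories = sim_entries
    sample = build_samples(entries, positive_fraction=0.05, negative_ratio=2.0, seed=1)
    pos = sample[sample["is_retweeted"] == 1]
    neg = sample[sample["is_retweeted"] == 0]
    assert set(neg["post_id"]) <= set(pos["post_id"])
    assert set(neg["viewer_id"]) <= set(pos["viewer_id"])


def test_sampling_is_deterministic(sim_entries):
    users, edges, entries, categories = sim_entries
    a = build_samples(entries, positive_fraction=0.5, negative_ratio=2.0, seed=9)
    b = build_samples(entries, positive_fraction=0.5, negative_ratio=2.0, seed=9)
    pd.testing.assert_frame_equal(a, b)


def test_no_positives_raises(sim_entries):
    users, edges, entries, categories = sim_entries
    with pytest.raises(EmptySampleError):
        build_samples(entries, positive_fraction=0.0, seed=0)


def test_small_negative_pool_warns():
    entries = pd.DataFrame(
        {
            "viewer_id": ["v1", "v2", "v3"],
            "sender_id": ["s"] * 3,
            "post_id": ["p"] * 3,
            "sender_share_time": [1, 2, 3],
            "credited": [True, True, True],  # every view credited
        }
    )
    with pytest.warns(UserWarning, match="negative pool"):
        sample = build_samples(entries, positive_fraction=1.0, negative_ratio=2.0, seed=0)
    assert (sample["is_retweeted"] == 1).all()


def test_hour_bucket_boundaries():
    # epoch 0 is 09:00 local under the default +9h offset -> morning
    assert hour_bucket(np.array([0]))[0] == "morning"
    local = lambda h: int((h - 9) % 24) * 3600
    assert hour_bucket(np.array([local(5)]))[0] == "morning"
    assert hour_bucket(np.array([local(11)]))[0] == "noon"
    assert hour_bucket(np.array([local(17)]))[0] == "night"
    assert hour_bucket(np.array([local(23)]))[0] == "midnight"
    assert hour_bucket(np.array([local(4)]))[0] == "midnight"  # wraps


def test_encoding_reference_and_sum_contrasts(sim_entries):
    users, edges, entries, categories = sim_entries
    sample = build_samples(entries, positive_fraction=0.2, negative_ratio=2.0, seed=3)
    design = encode_features(sample, users, edges, categories)
    # low is the reference: rows with low senders have all-zero dummies
    low_rows = design[design["sender_influence"] == "low"]
    assert (low_rows[[f"infl_{l}" for l in INFLUENCE_LEVELS]] == 0).all().all()
    # sum contrasts: midnight rows are -1 on every hour column
    mid_rows = design[design["repost_hour"] == "midnight"]
    if len(mid_rows):
        assert (mid_rows[["hour_morning", "hour_noon", "hour_night"]] == -1).all().all()
    # standardized covariates
    assert design["sender_followers_count"].mean() == pytest.approx(0.0, abs=1e-9)
    assert design["sender_followers_count"].std(ddof=0) == pytest.approx(1.0, abs=1e-9)


def test_zero_variance_covariate_guard():
    samples = pd.DataFrame(
        {
            "viewer_id": ["v1", "v2"],
            "sender_id": ["s1", "s2"],
            "post_id": ["p1", "p2"],
            "sender_share_time": [0, 3600],
            "credited": [True, False],
            "is_retweeted": [1, 0],
        }
    )
    users = pd.DataFrame(
        {"user_id": ["v1", "v2", "s1", "s2"], "is_official": [False] * 4,
         "topic": ["t0"] * 4}
    )
    edges = pd.DataFrame({"follower_id": [], "followee_id": []})  # all in-degrees 0
    categories = pd.DataFrame(
        {"user_id": ["v1", "v2", "s1", "s2"], "category": ["low"] * 4}
    )
    with pytest.warns(UserWarning, match="zero variance"):
        design = encode_features(samples, users, edges, categories)
    assert (design["sender_followers_count"] == 0).all()


def test_log1p_transform_of_zero_followers():
    assert np.log1p(0) == 0.0  # transform definition preserved by the guard path


def test_fit_recovers_known_coefficients():
    true = {"infl_very_high": 0.6, "user_followers_count": -0.5}
    df = simulate_regression_data(n_rows=8000, n_posts=100, beta=true, seed=21)
    fit = fit_glmm(df)
    assert fit.converged
    # single-draw smoke check: 3 SE band (systematic coverage is asserted
    # over many seeds elsewhere)
    assert abs(fit.coef("infl_very_high") - 0.6) <= 3 * fit.se("infl_very_high")
    assert abs(fit.coef("user_followers_count") + 0.5) <= 3 * fit.se("user_followers_count")


def test_fit_invariant_to_row_order():
    df = simulate_regression_data(n_rows=3000, n_posts=50, beta={"infl_very_high": 0.6}, seed=2)
    fit1 = fit_glmm(df)
    fit2 = fit_glmm(df.sample(frac=1.0, random_state=0))
    pd.testing.assert_frame_equal(fit1.fixed_effects, fit2.fixed_effects)


def test_single_level_grouping_rejected():
    df = simulate_regression_data(n_rows=500, n_posts=1, seed=0)
    with pytest.raises(ValueError, match="grouping factor"):
        fit_glmm(df)


def test_near_zero_random_variance_estimated_near_zero():
    df = simulate_regression_data(
        n_rows=8000, n_posts=50, post_sd=0.0, topic_sd=0.0, seed=4
    )
    fit = fit_glmm(df)
    assert fit.random_sd["source_tweet_id"] < 0.2
    assert fit.random_sd["user_topic"] < 0.2


def test_implied_hour_level_sums_contrasts_to_zero():
    df = simulate_regression_data(n_rows=4000, n_posts=50, seed=6)
    fit = fit_glmm(df)
    name, beta = fit.implied_hour_level
    assert name == "midnight"
    hour_sum = sum(fit.coef(f"hour_{h}") for h in ("morning", "noon", "night"))
    assert beta == pytest.approx(-hour_sum)


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not available")
def test_fit_matches_lme4_oracle(tmp_path):
    """Independent cross-check against the reference GLMM implementation."""
    true = {"infl_very_high": 0.6, "infl_high": 0.4, "sender_followers_count": -0.17,
            "user_followers_count": -0.57}
    df = simulate_regression_data(n_rows=8000, n_posts=100, beta=true, seed=3)
    df.to_csv(tmp_path / "design.csv", index=False)
    script = tmp_path / "fit.R"
    script.write_text(
        """
        suppressMessages(library(lme4))
        d <- read.csv(file.path(Sys.getenv("OUTDIR"), "design.csv"))
        f <- is_retweeted ~ infl_lower_mid + infl_mid + infl_upper_mid + infl_high +
             infl_very_high + hour_morning + hour_noon + hour_night +
             sender_followers_count + user_followers_count +
             (1 | source_tweet_id) + (1 | user_topic)
        m <- glmer(f, data = d, family = binomial, nAGQ = 0,
                   control = glmerControl(optimizer = "bobyqa"))
        co <- summary(m)$coefficients
        write.csv(data.frame(term = rownames(co), beta = co[, 1], se = co[, 2]),
                  file.path(Sys.getenv("OUTDIR"), "lme4.csv"), row.names = FALSE)
        """
    )
    import os

    env = dict(os.environ, OUTDIR=str(tmp_path))
    proc = subprocess.run(
        ["Rscript", str(script)], capture_output=True, text=True, env=env
    )
    assert proc.returncode == 0, proc.stderr
    ref = pd.read_csv(tmp_path / "lme4.csv")
    ref["term"] = ref["term"].replace({"(Intercept)": "intercept"})

    fit = fit_glmm(df)
    merged = fit.fixed_effects.merge(ref, on="term", suffixes=("", "_r"))
    assert len(merged) == len(fit.fixed_effects)
    assert np.allclose(merged["beta"], merged["beta_r"], atol=0.05)
    assert np.allclose(merged["se"], merged["se_r"], atol=0.02)
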