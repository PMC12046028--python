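"""Case-control sampling and mixed-effects logistic regression of repost outcome.

Exposure records (timeline entries) are subsampled into a case-control
set: a small fraction of all *positive* exposures (credited reposts) is
kept, and negatives (viewed but not reposted) are drawn at
``negative_ratio`` times the positive count, restricted to posts and
viewers that appear in the positive set so the groups remain comparable.

The model is a logistic mixed model

    is_retweeted ~ sender_influence + repost_hour
                   + sender_followers_count + user_followers_count
                   + (1 | source_tweet_id) + (1 | user_topic)

with the sender's influence category reference-coded against ``low``,
the local hour of exposure collapsed to four buckets coded with sum
contrasts, and both follower counts log(x+1)-transformed then
standardised over the sample.  Random intercepts absorb post-specific
appeal and topic-level differences in viewer interests.

Because case-control subsampling distorts the base rate, the intercept
and coefficients are interpretable only as *relative* contrasts, not as
absolute repost probabilities.

Fitting uses a fast approximate maximum a posteriori / variational Bayes
scheme for crossed random intercepts (statsmodels
``BinomialBayesMixedGLM``), comparable in spirit to zero-quadrature
Laplace fits of logistic GLMMs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: Influence levels in reference-coded order (low = baseline, omitted).
INFLUENCE_LEVELS = ["lower_mid", "mid", "upper_mid", "high", "very_high"]

#: Hour buckets as (name, start_hour, end_hour) half-open local-time intervals;
#: midnight wraps around.
DEFAULT_HOUR_BUCKETS = [
    ("morning", 5, 11),
    ("noon", 11, 17),
    ("night", 17, 23),
    ("midnight", 23, 5),
]

HOUR_LEVELS = [b[0] for b in DEFAULT_HOUR_BUCKETS]


class EmptySampleError(ValueError):
    """No positive cases were sampled."""


def build_samples(
    entries: pd.DataFrame,
    positive_fraction: float = 0.001,
    negative_ratio: float = 2.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Case-control subsample of timeline entries.

    Positives (credited entries) are kept independently with probability
    ``positive_fraction``; negatives are drawn uniformly without
    replacement, ``round(negative_ratio * n_positives)`` of them, from
    uncredited entries whose post and viewer both occur in the sampled
    positive set.  Deterministic under ``seed``.  Returns the sampled
    rows with an ``is_retweeted`` column.
    """
    rng = np.random.default_rng(seed)
    positives_pool = entries[entries["credited"]]
    keep = rng.random(len(positives_pool)) < positive_fraction
    positives = positives_pool[keep]
    if len(positives) == 0:
        raise EmptySampleError("no positive cases sampled; increase positive_fraction")

    pos_posts = set(positives["post_id"])
    pos_viewers = set(positives["viewer_id"])
    pool = entries[
        ~entries["credited"]
        & entries["post_id"].isin(pos_posts)
        & entries["viewer_id"].isin(pos_viewers)
    ]
    target = int(round(negative_ratio * len(positives)))
    if len(pool) < target:
        warnings.warn(
            f"negative pool ({len(pool)}) smaller than target ({target}); taking all",
            stacklevel=2,
        )
        negatives = pool
    else:
        idx = rng.choice(len(pool), size=target, replace=False)
        negatives = pool.iloc[np.sort(idx)]

    sample = pd.concat([positives, negatives], ignore_index=True)
    sample["is_retweeted"] = sample["credited"].astype(int)
    return sample


def hour_bucket(
    timestamps: np.ndarray | pd.Series,
    timezone_offset_hours: float = 9.0,
    buckets: list[tuple[str, int, int]] = DEFAULT_HOUR_BUCKETS,
) -> pd.Series:
    """Map epoch seconds to a local-time-of-day bucket name."""
    hours = (np.asarray(timestamps, dtype=float) / 3600.0 + timezone_offset_hours) % 24.0
    out = np.empty(hours.shape, dtype=object)
    for name, lo, hi in buckets:
        if lo < hi:
            mask = (hours >= lo) & (hours < hi)
        else:  # wraps midnight
            mask = (hours >= lo) | (hours < hi)
        out[mask] = name
    return pd.Series(out, index=getattr(timestamps, "index", None))


def _log1p_standardize(x: np.ndarray) -> np.ndarray:
    z = np.log1p(x.astype(float))
    sd = z.std()
    if sd == 0:
        warnings.warn("zero variance after log1p; covariate set to all zeros", stacklevel=3)
        return np.zeros_like(z)
    return (z - z.mean()) / sd


def encode_features(
    samples: pd.DataFrame,
    users: pd.DataFrame,
    edges: pd.DataFrame,
    categories: pd.DataFrame,
    timezone_offset_hours: float = 9.0,
    hour_buckets: list[tuple[str, int, int]] = DEFAULT_HOUR_BUCKETS,
) -> pd.DataFrame:
    """Build the regression design frame from a case-control sample.

    Adds reference-coded influence dummies (``infl_*``, low omitted),
    sum-contrast hour columns (``hour_morning/noon/night``, the midnight
    level coded -1 on all three), standardised log follower counts, the
    outcome, and the two grouping keys ``source_tweet_id`` and
    ``user_topic``.  Follower counts are follow-graph in-degrees.
    """
    df = samples.copy()
    cat = categories.set_index("user_id")["category"]
    df["sender_influence"] = df["sender_id"].map(cat)
    if df["sender_influence"].isna().any():
        raise KeyError("sender without influence category in sample")

    for level in INFLUENCE_LEVELS:
        df[f"infl_{level}"] = (df["sender_influence"] == level).astype(float)

    bucket_names = [b[0] for b in hour_buckets]
    df["repost_hour"] = hour_bucket(df["sender_share_time"], timezone_offset_hours, hour_buckets)
    last = bucket_names[-1]
    for name in bucket_names[:-1]:
        col = (df["repost_hour"] == name).astype(float)
        col[df["repost_hour"] == last] = -1.0
        df[f"hour_{name}"] = col

    indeg = edges["followee_id"].value_counts()
    df["sender_followers_count"] = _log1p_standardize(
        df["sender_id"].map(indeg).fillna(0).to_numpy()
    )
    df["user_followers_count"] = _log1p_standardize(
        df["viewer_id"].map(indeg).fillna(0).to_numpy()
    )

    topic = users.set_index("user_id")["topic"]
    df["user_topic"] = df["viewer_id"].map(topic)
    df["source_tweet_id"] = df["post_id"]
    return df


FIXED_TERMS = (
    [f"infl_{lvl}" for lvl in INFLUENCE_LEVELS]
    + [f"hour_{name}" for name in HOUR_LEVELS[:-1]]
    + ["sender_followers_count", "user_followers_count"]
)


@dataclass
class RegressionFit:
    """Fitted logistic mixed model.

    ``fixed_effects`` has one row per design term (term, beta, se, z, p);
    ``random_sd`` holds the estimated random-intercept standard
    deviations per grouping factor.  Because sum contrasts drop one hour
    level, ``implied_hour_level`` reports the redundant bucket's
    coefficient, -(sum of the fitted hour contrasts), for display
    parity with four-row hour tables.
    """

    fixed_effects: pd.DataFrame
    random_sd: dict[str, float]
    converged: bool
    method: str
    implied_hour_level: tuple[str, float] = ("midnight", np.nan)

    def coef(self, term: str) -> float:
        return float(self.fixed_effects.set_index("term").loc[term, "beta"])

    def se(self, term: str) -> float:
        return float(self.fixed_effects.set_index("term").loc[term, "se"])

    def wald_joint(self, terms: list[str]) -> tuple[float, int, float]:
        """Joint Wald chi-square for several terms (diagonal covariance).

        The variational posterior provides marginal sds only, so the
        statistic treats coefficients as independent; adequate for the
        calibration checks it serves.
        """
        fe = self.fixed_effects.set_index("term")
        z2 = (fe.loc[terms, "beta"] / fe.loc[terms, "se"]) ** 2
        chi2 = float(z2.sum())
        df = len(terms)
        return chi2, df, float(stats.chi2.sf(chi2, df))


def fit_glmm(
    design: pd.DataFrame,
    fixed_terms: list[str] | None = None,
    groups: tuple[str, str] = ("source_tweet_id", "user_topic"),
    outcome: str = "is_retweeted",
    fit_method: str = "map",
) -> RegressionFit:
    """Fit the logistic mixed model with crossed random intercepts.

    ``fit_method``: ``"map"`` (Laplace-approximation posterior mode,
    default; fast and with well-calibrated standard errors) or ``"vb"``
    (mean-field variational Bayes; its posterior sds understate
    uncertainty and should not feed significance tests).  Requires at
    least two
    levels in each grouping factor.  Estimates are invariant to row
    order.  Raises ``RuntimeError`` when the optimizer fails.
    """
    from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM

    if fixed_terms is None:
        fixed_terms = FIXED_TERMS
    for g in groups:
        if design[g].nunique() < 2:
            raise ValueError(f"grouping factor {g!r} needs >= 2 levels")

    # canonical row order so estimates do not depend on input ordering
    design = design.sort_values(list(design.columns), kind="mergesort").reset_index(drop=True)

    formula = f"{outcome} ~ 1 + " + " + ".join(fixed_terms)
    vc_formulas = {g: f"0 + C({g})" for g in groups}
    model = BinomialBayesMixedGLM.from_formula(formula, vc_formulas, design)
    with warnings.catch_warnings():
        # statsmodels flags |gradient| ~ 1e-5 as non-convergence; that is
        # numerically converged for our purposes and checked below
        warnings.filterwarnings("ignore", message="Laplace fitting did not converge")
        if fit_method == "vb":
            result = model.fit_vb()
        elif fit_method == "map":
            result = model.fit_map()
        else:
            raise ValueError(f"unknown fit_method {fit_method!r}")

    k_fe = len(model.exog_names)
    beta = np.asarray(result.fe_mean, dtype=float)
    se = np.asarray(result.fe_sd, dtype=float)
    if not np.all(np.isfinite(beta)) or not np.all(np.isfinite(se)):
        raise RuntimeError("mixed-model fit did not converge (non-finite estimates)")
    z = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
    p = 2 * stats.norm.sf(np.abs(z))
    terms = ["intercept"] + fixed_terms
    fe = pd.DataFrame({"term": terms[:k_fe], "beta": beta, "se": se, "z": z, "p": p})

    vcp_names = list(model.vcp_names)
    vcp_mean = np.asarray(result.vcp_mean, dtype=float)
    random_sd = {name: float(np.exp(m)) for name, m in zip(vcp_names, vcp_mean)}

    hour_terms = [t for t in fixed_terms if t.startswith("hour_")]
    fitted_hours = {t.removeprefix("hour_") for t in hour_terms}
    implied_name = next((h for h in HOUR_LEVELS if h not in fitted_hours), "midnight")
    implied = -float(fe.set_index("term").loc[hour_terms, "beta"].sum()) if hour_terms else np.nan

    return RegressionFit(
        fixed_effects=fe,
        random_sd=random_sd,
        converged=True,
        method=fit_method,
        implied_hour_level=(implied_name, implied),
    )


def simulate_regression_data(
    n_rows: int = 30000,
    n_posts: int = 200,
    n_topics: int = 10,
    beta: dict[str, float] | None = None,
    intercept: float = -0.7,
    post_sd: float = 1.0,
    topic_sd: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate outcomes from the regression model's own formula.

    Rows get random influence levels, hour buckets, and Gaussian
    follower covariates; random intercepts are drawn per post and per
    topic with the given standard deviations; the binary outcome follows
    the logistic model.  Used for parameter-recovery checks
    (generate-then-fit with known coefficients).
    """
    rng = np.random.default_rng(seed)
    if beta is None:
        beta = {}
    df = pd.DataFrame(
        {
            "source_tweet_id": rng.integers(n_posts, size=n_rows).astype(str),
            "user_topic": rng.integers(n_topics, size=n_rows).astype(str),
            "sender_influence": rng.choice(
                INFLUENCE_LEVELS + ["low"], size=n_rows
            ),
            "repost_hour": rng.choice(HOUR_LEVELS, size=n_rows),
            "sender_followers_count": rng.standard_normal(n_rows),
            "user_followers_count": rng.standard_normal(n_rows),
        }
    )
    for level in INFLUENCE_LEVELS:
        df[f"infl_{level}"] = (df["sender_influence"] == level).astype(float)
    for name in HOUR_LEVELS[:-1]:
        col = (df["repost_hour"] == name).astype(float)
        col[df["repost_hour"] == HOUR_LEVELS[-1]] = -1.0
        df[f"hour_{name}"] = col

    eta = np.full(n_rows, intercept)
    for term in FIXED_TERMS:
        eta += beta.get(term, 0.0) * df[term].to_numpy()
    post_re = rng.normal(0, post_sd, size=n_posts)
    topic_re = rng.normal(0, topic_sd, size=n_topics)
    eta += post_re[df["source_tweet_id"].astype(int)]
    eta += topic_re[df["user_topic"].astype(int)]
    df["is_retweeted"] = (rng.random(n_rows) < 1 / (1 + np.exp(-eta))).astype(int)
    return df
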