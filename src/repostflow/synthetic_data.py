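"""Agent-based simulator of repost diffusion with a tunable prestige bias.

The generator produces a directed follower graph with heavy-tailed
follower counts, then runs an event-driven diffusion: each user emits
original posts as a Poisson process, and every time a user shares a post
(originally or as a repost) each of their followers is exposed once and
reposts with probability

    logistic(base_logit + appeal_p + prestige_weight * z(influence_s)
             + circadian(t) - decay_rate * age_hours)

where ``appeal_p`` is a per-post Gaussian draw on the log-odds scale
(log-normal appeal), ``influence_s`` is the *sharer's* latent influence
(standardised as z on the log scale), ``circadian(t)`` is a sinusoid with a
24-hour period, and ``age_hours`` is the time since the original post.
``prestige_weight = 0`` defines the null model in which the sharer's
influence has no causal effect on repost decisions.

Latent influence is a positive heavy-tailed quantity correlated with, but
distinct from, follower count: follower reach and per-exposure persuasive
prestige are related yet separate properties of a user.
"""

from __future__ import annotations

import heapq
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from repostflow.data_io import EVENT_COLUMNS, sort_events

_SECONDS_PER_DAY = 86400
_SECONDS_PER_HOUR = 3600


class ConfigurationError(ValueError):
    """Invalid simulation parameters."""


@dataclass
class SimulationConfig:
    """Parameters of the synthetic diffusion study.

    Defaults describe the study conditions used throughout the test
    suite: a 2,000-user preferential-attachment follower graph observed
    for 14 days, with original-post rates matching the observed order of
    magnitude on the real platform (roughly 0.12 originals per user per
    day) and a unit prestige effect.
    """

    n_users: int = 2000
    graph_model: str = "preferential_attachment"
    pa_out_degree: int = 3  # preferential followees per arriving node
    random_follow_rate: float = 2.0  # mean extra uniform-random followees per user
    influence_degree_corr: float = 0.7  # corr of log influence with log follower count
    official_fraction: float = 0.02
    n_topics: int = 10
    observation_days: int = 14
    post_rate: float = 0.12  # mean originals per user per day
    post_rate_sigma: float = 1.0  # log-normal dispersion of per-user rates
    appeal_scale: float = 1.0  # sd of per-post appeal on the log-odds scale
    prestige_weight: float = 1.0
    base_logit: float = -4.0
    circadian_amplitude: float = 0.5
    circadian_peak_hour: float = 20.0
    decay_rate: float = 0.15  # per-hour log-odds attenuation with exposure age
    delay_mean_hours: float = 0.25  # mean exponential repost delay
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_users < 2:
            raise ConfigurationError("n_users must be >= 2")
        if self.graph_model not in {"preferential_attachment", "configuration"}:
            raise ConfigurationError(f"unknown graph_model {self.graph_model!r}")
        if self.pa_out_degree < 1 or self.pa_out_degree >= self.n_users:
            raise ConfigurationError("pa_out_degree must be in [1, n_users)")
        for name in ("official_fraction",):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be a probability, got {v}")
        if not -1.0 <= self.influence_degree_corr <= 1.0:
            raise ConfigurationError("influence_degree_corr must be in [-1, 1]")
        if self.prestige_weight < 0:
            raise ConfigurationError("prestige_weight must be >= 0")
        for name in ("n_topics", "observation_days"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be a positive integer")
        for name in ("post_rate", "appeal_scale", "post_rate_sigma", "decay_rate",
                     "delay_mean_hours", "random_follow_rate"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")

    @property
    def window_seconds(self) -> int:
        return self.observation_days * _SECONDS_PER_DAY


def _user_ids(n: int) -> list[str]:
    width = max(5, len(str(n - 1)))
    return [f"u{i:0{width}d}" for i in range(n)]


def generate_graph(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate users and directed follower edges.

    ``preferential_attachment``: each arriving node follows
    ``pa_out_degree`` distinct earlier nodes chosen proportionally to
    (follower count + 1), yielding a heavy-tailed follower-count
    (in-degree) distribution.  ``configuration`` draws per-node follower
    counts from a Zipf-like law and wires followers uniformly.

    Latent influence is log-normal with its log correlated (coefficient
    ``influence_degree_corr``) with log follower count.
    """
    rng = np.random.default_rng(config.seed)
    n, m = config.n_users, config.pa_out_degree
    ids = _user_ids(n)

    followers: list[int] = []  # follower index per edge
    followees: list[int] = []
    if config.graph_model == "preferential_attachment":
        # repeated-target list: node j appears in_degree(j)+1 times
        targets = list(range(m))
        for i in range(m, n):
            chosen: set[int] = set()
            while len(chosen) < m:
                pick = targets[rng.integers(len(targets))]
                chosen.add(pick)
            for j in chosen:
                followers.append(i)
                followees.append(j)
                targets.append(j)
            targets.append(i)
    else:  # configuration model on in-degrees
        indeg = np.minimum(rng.zipf(2.2, size=n), n - 1)
        for j in range(n):
            pool = np.delete(np.arange(n), j)
            src = rng.choice(pool, size=int(indeg[j]), replace=False)
            for i in src:
                followers.append(int(i))
                followees.append(j)

    # extra uniform-random followees: real accounts, hubs included, follow
    # across the whole graph, not only their attachment-era neighbours
    if config.random_follow_rate > 0:
        n_extra = rng.poisson(config.random_follow_rate, size=n)
        for i in range(n):
            for j in rng.integers(n, size=n_extra[i]):
                if int(j) != i:
                    followers.append(i)
                    followees.append(int(j))

    edges = pd.DataFrame(
        {"follower_id": [ids[i] for i in followers],
         "followee_id": [ids[j] for j in followees]}
    ).drop_duplicates().reset_index(drop=True)

    indegree = np.zeros(n, dtype=float)
    counts = edges["followee_id"].value_counts()
    for uid, c in counts.items():
        indegree[int(uid[1:])] = c

    log_deg = np.log1p(indegree)
    sd = log_deg.std()
    z_deg = (log_deg - log_deg.mean()) / sd if sd > 0 else np.zeros(n)
    rho = config.influence_degree_corr
    noise = rng.standard_normal(n)
    latent = np.exp(rho * z_deg + np.sqrt(max(0.0, 1 - rho**2)) * noise)

    users = pd.DataFrame(
        {
            "user_id": ids,
            "is_official": rng.random(n) < config.official_fraction,
            "topic": [f"t{k}" for k in rng.integers(config.n_topics, size=n)],
            "latent_influence": latent,
        }
    )
    return users, edges


def _circadian(t_seconds: np.ndarray | float, amplitude: float, peak_hour: float) -> np.ndarray | float:
    hours = (np.asarray(t_seconds, dtype=float) / _SECONDS_PER_HOUR) % 24.0
    return amplitude * np.cos(2 * np.pi * (hours - peak_hour) / 24.0)


def simulate_diffusion(
    users: pd.DataFrame, edges: pd.DataFrame, config: SimulationConfig
) -> pd.DataFrame:
    """Run the diffusion and return a canonical, referentially closed event log.

    Originals arrive as per-user Poisson processes with heterogeneous
    (log-normal) rates averaging ``post_rate`` per day.  Diffusion then
    proceeds recursively: each share exposes the sharer's followers
    exactly once; a user reposts a given post at most once, never their
    own, with an exponential delay after exposure.  Timestamps are
    integer epoch seconds inside the observation window; reposts are
    strictly later than their original post.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n = len(users)
    ids = list(users["user_id"])
    index = {u: i for i, u in enumerate(ids)}

    followers_of: list[np.ndarray] = [np.empty(0, dtype=np.int64) for _ in range(n)]
    grouped = edges.groupby("followee_id")["follower_id"]
    for followee, fs in grouped:
        followers_of[index[followee]] = np.fromiter((index[f] for f in fs), dtype=np.int64)

    latent = users["latent_influence"].to_numpy(dtype=float)
    log_latent = np.log(latent)
    sd = log_latent.std()
    z_inf = (log_latent - log_latent.mean()) / sd if sd > 0 else np.zeros(n)

    # heterogeneous per-user original-post rates, mean post_rate per day
    raw = rng.lognormal(mean=0.0, sigma=config.post_rate_sigma, size=n)
    rates = raw / raw.mean() * config.post_rate if raw.mean() > 0 else raw

    window = config.window_seconds
    n_posts_per_user = rng.poisson(rates * config.observation_days)
    post_rows: list[tuple[int, int]] = []  # (time, author index)
    for i in range(n):
        for t in rng.integers(0, window, size=n_posts_per_user[i]):
            post_rows.append((int(t), i))
    post_rows.sort()

    heap: list[tuple[int, int, int, int, int]] = []  # (t, seq, post_idx, sharer, kind)
    seq = 0
    appeal = rng.normal(0.0, config.appeal_scale, size=len(post_rows))
    post_origin = np.empty(len(post_rows), dtype=np.int64)
    for p, (t, author) in enumerate(post_rows):
        post_origin[p] = t
        heapq.heappush(heap, (t, seq, p, author, 0))
        seq += 1

    pw = config.prestige_weight
    width = max(7, len(str(len(post_rows))))
    post_ids = [f"p{p:0{width}d}" for p in range(len(post_rows))]
    post_author = np.array([a for _, a in post_rows], dtype=np.int64)

    reacted: dict[int, set[int]] = {}  # post -> users who reposted or are scheduled to
    records: list[tuple[str, str, str, str, int]] = []
    for p, (t, author) in enumerate(post_rows):
        records.append(("post", post_ids[p], ids[author], post_ids[p], t))

    repost_seq = 0
    while heap:
        t, _, p, sharer, _kind = heapq.heappop(heap)
        audience = followers_of[sharer]
        if audience.size == 0:
            continue
        age_h = (t - post_origin[p]) / _SECONDS_PER_HOUR
        logit = (
            config.base_logit
            + appeal[p]
            + pw * z_inf[sharer]
            + _circadian(float(t), config.circadian_amplitude, config.circadian_peak_hour)
            - config.decay_rate * age_h
        )
        prob = 1.0 / (1.0 + np.exp(-logit))
        hits = audience[rng.random(audience.size) < prob]
        if hits.size == 0:
            continue
        seen = reacted.setdefault(p, set())
        for v in hits:
            v = int(v)
            if v == post_author[p] or v in seen:
                continue
            delay = max(1, int(round(rng.exponential(config.delay_mean_hours) * _SECONDS_PER_HOUR)))
            t_r = t + delay
            if t_r >= window:
                continue
            seen.add(v)
            heapq.heappush(heap, (t_r, seq, p, v, 1))
            seq += 1
            records.append(("repost", f"q{repost_seq:09d}", ids[v], post_ids[p], t_r))
            repost_seq += 1

    events = pd.DataFrame(records, columns=EVENT_COLUMNS)
    events["timestamp"] = events["timestamp"].astype("int64")
    return sort_events(events)


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Convenience wrapper: graph + diffusion in one call."""
    users, edges = generate_graph(config)
    events = simulate_diffusion(users, edges, config)
    return users, edges, events


def write_dataset(config: SimulationConfig, out_dir: str | Path) -> dict:
    """Write users.tsv, edges.tsv, events.tsv and a provenance JSON."""
    from repostflow.data_io import write_edges, write_events, write_users

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    users, edges, events = simulate_dataset(config)
    write_users(users, out / "users.tsv")
    write_edges(edges, out / "edges.tsv")
    write_events(events, out / "events.tsv")
    provenance = {"config": asdict(config), "n_events": int(len(events))}
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2) + "\n")
    return provenance
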