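"""Canonical data model and tabular I/O shared by every pipeline stage.

Three plain-text tables describe a dataset:

* ``users.tsv`` — columns ``user_id``, ``is_official`` (0/1), ``topic``,
  optional ``latent_influence`` (ground truth, synthetic data only);
* ``edges.tsv`` — columns ``follower_id``, ``followee_id`` (the follower
  sees the followee's activity);
* ``events.tsv`` — columns ``event_type`` (``post``/``repost``),
  ``event_id``, ``user_id``, ``post_id`` (equal to ``event_id`` for
  posts), ``timestamp`` (integer epoch seconds UTC).  A JSONL dialect with
  the same field names is also accepted for events.

Events are kept in a canonical total order: timestamp ascending, ties
broken by ``event_id`` lexicographically.  A repost references the
*original* post directly, as platform APIs report it; the
who-reposted-from-whom chain is not part of the input and is inferred by
:mod:`repostflow.cascade_builder`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

EVENT_COLUMNS = ["event_type", "event_id", "user_id", "post_id", "timestamp"]
USER_COLUMNS = ["user_id", "is_official", "topic"]
EDGE_COLUMNS = ["follower_id", "followee_id"]


class LogFormatError(ValueError):
    """A row of an input table could not be parsed."""


class ReferentialIntegrityError(ValueError):
    """An event references a user or post that does not exist."""


class ChronologyError(ValueError):
    """A repost is not strictly later than its original post."""


@dataclass(frozen=True)
class ValidationReport:
    """Cardinalities and orphan counts of a dataset.

    ``orphans`` counts reposts whose ``post_id`` matches no post plus
    events whose ``user_id`` and edges whose endpoints match no user.  A
    pipeline run should refuse to proceed when ``orphans > 0``.
    """

    n_users: int
    n_posts: int
    n_reposts: int
    orphan_reposts: int
    orphan_event_users: int
    orphan_edge_users: int

    @property
    def orphans(self) -> int:
        return self.orphan_reposts + self.orphan_event_users + self.orphan_edge_users

    def is_clean(self) -> bool:
        return self.orphans == 0


def _read_tsv(path: Path, columns: list[str], dtypes: dict) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype=dtypes)
    except (pd.errors.ParserError, ValueError) as exc:
        raise LogFormatError(f"{path}: {exc}") from exc
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise LogFormatError(f"{path}: missing required columns {missing}")
    return df


def read_users(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    users = _read_tsv(path, USER_COLUMNS, {"user_id": str, "topic": str})
    if users["user_id"].duplicated().any():
        dup = users.loc[users["user_id"].duplicated(), "user_id"].iloc[0]
        raise LogFormatError(f"{path}: duplicate user_id {dup!r}")
    users["is_official"] = users["is_official"].astype(int).astype(bool)
    if "latent_influence" in users.columns:
        users["latent_influence"] = users["latent_influence"].astype(float)
    return users.reset_index(drop=True)


def read_edges(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    edges = _read_tsv(path, EDGE_COLUMNS, {"follower_id": str, "followee_id": str})
    self_loops = edges["follower_id"] == edges["followee_id"]
    if self_loops.any():
        raise LogFormatError(f"{path}: self-loop edge for {edges.loc[self_loops, 'follower_id'].iloc[0]!r}")
    edges = edges.drop_duplicates(subset=EDGE_COLUMNS, keep="first")
    return edges.reset_index(drop=True)


def _read_event_table(path: Path) -> pd.DataFrame:
    if path.suffix.lower() in {".jsonl", ".ndjson", ".json"}:
        rows = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                try:
                    rows.append(json.loads(line))
                except json.JSONDecodeError as exc:
                    raise LogFormatError(f"{path}: line {lineno}: {exc}") from exc
        df = pd.DataFrame(rows, columns=EVENT_COLUMNS if not rows else None)
        missing = [c for c in EVENT_COLUMNS if c not in df.columns]
        if missing:
            raise LogFormatError(f"{path}: missing required fields {missing}")
    else:
        df = _read_tsv(path, EVENT_COLUMNS, {c: str for c in EVENT_COLUMNS[:-1]})
    try:
        df["timestamp"] = df["timestamp"].astype("int64")
    except (ValueError, TypeError) as exc:
        bad = df.index[pd.to_numeric(df["timestamp"], errors="coerce").isna()]
        lineno = int(bad[0]) + 2 if len(bad) else "?"  # +2: header + 1-based
        raise LogFormatError(f"{path}: line {lineno}: non-integer timestamp") from exc
    for c in EVENT_COLUMNS[:-1]:
        df[c] = df[c].astype(str)
    bad_type = ~df["event_type"].isin(["post", "repost"])
    if bad_type.any():
        lineno = int(df.index[bad_type][0]) + 2
        raise LogFormatError(f"{path}: line {lineno}: event_type must be 'post' or 'repost'")
    return df


def sort_events(events: pd.DataFrame) -> pd.DataFrame:
    """Canonical total order: timestamp ascending, then event_id."""
    return events.sort_values(["timestamp", "event_id"], kind="mergesort").reset_index(drop=True)


def read_events(
    event_file: str | Path,
    user_file: str | Path,
    edge_file: str | Path,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Read and validate a full dataset.

    Returns ``(users, edges, events)`` with events in canonical order.
    Duplicate reposts of the same post by the same user keep the earliest
    occurrence (with a warning).  Raises
    :class:`ReferentialIntegrityError` for unknown users or posts and
    :class:`ChronologyError` for reposts not strictly after their
    original.
    """
    users = read_users(user_file)
    edges = read_edges(edge_file)
    events = sort_events(_read_event_table(Path(event_file)))

    if events["event_id"].duplicated().any():
        dup = events.loc[events["event_id"].duplicated(), "event_id"].iloc[0]
        raise LogFormatError(f"{event_file}: duplicate event_id {dup!r}")

    posts = events[events["event_type"] == "post"]
    if not (posts["post_id"] == posts["event_id"]).all():
        raise LogFormatError(f"{event_file}: post rows must have post_id == event_id")

    known_users = set(users["user_id"])
    unknown = set(events["user_id"]) - known_users
    if unknown:
        raise ReferentialIntegrityError(f"events reference unknown user(s): {sorted(unknown)[:5]}")
    unknown_edge = (set(edges["follower_id"]) | set(edges["followee_id"])) - known_users
    if unknown_edge:
        raise ReferentialIntegrityError(f"edges reference unknown user(s): {sorted(unknown_edge)[:5]}")

    reposts = events[events["event_type"] == "repost"]
    post_times = dict(zip(posts["post_id"], posts["timestamp"]))
    missing_posts = set(reposts["post_id"]) - set(post_times)
    if missing_posts:
        raise ReferentialIntegrityError(
            f"reposts reference unknown post_id(s): {sorted(missing_posts)[:5]}"
        )
    if len(reposts):
        origin = reposts["post_id"].map(post_times)
        late = reposts["timestamp"] <= origin
        if late.any():
            bad = reposts[late].iloc[0]
            raise ChronologyError(
                f"repost {bad['event_id']!r} at t={bad['timestamp']} is not strictly "
                f"after its original post {bad['post_id']!r}"
            )
        dup_mask = reposts.duplicated(subset=["user_id", "post_id"], keep="first")
        if dup_mask.any():
            warnings.warn(
                f"dropping {int(dup_mask.sum())} duplicate (user, post) repost(s); keeping earliest",
                stacklevel=2,
            )
            drop_ids = set(reposts.loc[dup_mask, "event_id"])
            events = events[~events["event_id"].isin(drop_ids)].reset_index(drop=True)

    return users, edges, events


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    """Write events in canonical form (sorted, tab-separated, LF endings)."""
    out = sort_events(events)[EVENT_COLUMNS]
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_users(users: pd.DataFrame, path: str | Path) -> None:
    out = users.copy()
    out["is_official"] = out["is_official"].astype(int)
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_edges(edges: pd.DataFrame, path: str | Path) -> None:
    edges[EDGE_COLUMNS].to_csv(path, sep="\t", index=False, lineterminator="\n")


def validate_log(
    events: pd.DataFrame, users: pd.DataFrame, edges: pd.DataFrame
) -> ValidationReport:
    """Count cardinalities and orphaned references without raising."""
    posts = events[events["event_type"] == "post"]
    reposts = events[events["event_type"] == "repost"]
    known_users = set(users["user_id"])
    known_posts = set(posts["post_id"])
    orphan_reposts = int((~reposts["post_id"].isin(known_posts)).sum())
    orphan_event_users = int((~events["user_id"].isin(known_users)).sum())
    orphan_edge_users = int(
        (~edges["follower_id"].isin(known_users)).sum()
        + (~edges["followee_id"].isin(known_users)).sum()
    )
    return ValidationReport(
        n_users=len(users),
        n_posts=len(posts),
        n_reposts=len(reposts),
        orphan_reposts=orphan_reposts,
        orphan_event_users=orphan_event_users,
        orphan_edge_users=orphan_edge_users,
    )
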