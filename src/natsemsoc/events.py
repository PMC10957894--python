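"""Movie event tables: validation, short-event merging, inter-rater
reliability, word-to-event assignment, and the scrambled-ratings null.

An event table is a pandas DataFrame with columns
``movie_id, index, onset, duration, semantic, social`` (optionally
``is_major, rater, notes``).  Ratings live on a 1-10 scale; by the rating
rubric a single event may not score 9 or 10 on *both* the semantic and the
social dimension (the primary purpose of a scene is one or the other).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EVENT_COLUMNS = ["movie_id", "index", "onset", "duration", "semantic", "social"]

RATING_MIN, RATING_MAX = 1.0, 10.0
#: ratings at or above this value mark an event's "primary purpose"
DUAL_MAX_CUTOFF = 9.0
#: inter-rater reliability below this triggers consensus revision
RELIABILITY_THRESHOLD = 0.75


@dataclass
class ValidationReport:
    """Report-only result of :func:`validate_events`."""

    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def add(self, msg: str) -> None:
        self.violations.append(msg)


@dataclass
class ReliabilityResult:
    """Krippendorff's alpha plus the revision decision."""

    alpha: float
    threshold: float = RELIABILITY_THRESHOLD

    @property
    def needs_revision(self) -> bool:
        return self.alpha < self.threshold


def validate_events(table: pd.DataFrame) -> ValidationReport:
    """Check an event table against the machine-checkable rubric constraints.

    Flags non-positive durations, out-of-range ratings, the dual-9/10 rule,
    per-movie ordering, and overlapping consecutive events.  Never raises:
    the result lists every violation found, and is empty iff the table is
    valid.
    """
    report = ValidationReport()
    missing = [c for c in EVENT_COLUMNS if c not in table.columns]
    if missing:
        report.add(f"missing columns: {missing}")
        return report
    for i, row in table.iterrows():
        if not row["duration"] > 0:
            report.add(f"row {i}: non-positive duration {row['duration']}")
        for col in ("semantic", "social"):
            r = row[col]
            if not (RATING_MIN <= r <= RATING_MAX):
                report.add(f"row {i}: {col} rating {r} outside [1, 10]")
        if row["semantic"] >= DUAL_MAX_CUTOFF and row["social"] >= DUAL_MAX_CUTOFF:
            report.add(
                f"row {i}: semantic {row['semantic']} and social {row['social']} "
                "both >= 9 (dual-maximum violation)"
            )
    for movie, grp in table.groupby("movie_id", sort=False):
        onsets = grp["onset"].to_numpy(float)
        ends = onsets + grp["duration"].to_numpy(float)
        if np.any(np.diff(onsets) < 0):
            report.add(f"movie {movie}: events not ordered by onset")
            continue
        overlap = onsets[1:] < ends[:-1] - 1e-9
        for j in np.flatnonzero(overlap):
            report.add(
                f"movie {movie}: event at {onsets[j + 1]:g}s overlaps previous "
                f"event ending {ends[j]:g}s"
            )
    return report


def merge_short_events(table: pd.DataFrame, min_duration: float = 3.0) -> pd.DataFrame:
    """Merge events shorter than ``min_duration`` seconds into their successor.

    A short event is absorbed by the next event in the same movie: merged
    onset is the earlier onset, duration the sum, and the semantic/social
    ratings the arithmetic mean of the pair.  A short event at the end of a
    movie merges backward into its predecessor.  Merging iterates until every
    event is at least ``min_duration`` long (or the movie has one event
    left), so chains of consecutive shorts resolve.  Total rated time is
    conserved.
    """
    if len(table) == 0:
        raise ValueError("cannot merge an empty event table")
    out = []
    for movie, grp in table.groupby("movie_id", sort=False):
        events = grp.sort_values("onset").to_dict("records")
        while len(events) > 1:
            short = [i for i, e in enumerate(events) if e["duration"] < min_duration]
            if not short:
                break
            i = short[0]
            j = i + 1 if i + 1 < len(events) else i - 1
            a, b = events[min(i, j)], events[max(i, j)]
            merged = dict(a)
            merged["onset"] = a["onset"]
            merged["duration"] = a["duration"] + b["duration"]
            merged["semantic"] = (a["semantic"] + b["semantic"]) / 2.0
            merged["social"] = (a["social"] + b["social"]) / 2.0
            events[min(i, j)] = merged
            del events[max(i, j)]
        out.extend(events)
    res = pd.DataFrame(out)
    res["index"] = np.arange(len(res))
    return res.reset_index(drop=True)


def _alpha_metric(values: np.ndarray, level: str) -> np.ndarray:
    """Pairwise squared-difference metric delta(c, k) for the given level."""
    if level == "interval":
        return (values[:, None] - values[None, :]) ** 2
    if level == "ordinal":
        # delta based on cumulative coincidence ranks
        raise NotImplementedError  # replaced below where marginals are known
    raise ValueError(f"unknown measurement level: {level!r}")


def krippendorff_alpha(
    ratings: np.ndarray, level: str = "interval"
) -> ReliabilityResult:
    """Krippendorff's alpha from a rater x item matrix (NaN = missing).

    Uses the coincidence-matrix formulation: every ordered pair of ratings
    within an item contributes with weight 1/(m_u - 1), where m_u is the
    number of ratings for item u.  Items with fewer than two ratings are
    dropped.  ``level`` selects the disagreement metric: ``interval``
    (squared difference, the default — ratings treated as numeric) or
    ``ordinal`` (squared difference of cumulative-frequency ranks).
    """
    ratings = np.asarray(ratings, dtype=float)
    if ratings.ndim != 2 or ratings.shape[0] < 2:
        raise ValueError("need a rater x item matrix with >= 2 raters")
    counts_per_item = np.sum(~np.isnan(ratings), axis=0)
    keep = counts_per_item >= 2
    if keep.sum() < 2:
        raise ValueError("need >= 2 items with >= 2 ratings each")
    ratings = ratings[:, keep]

    values = np.unique(ratings[~np.isnan(ratings)])
    v = len(values)
    idx = {val: i for i, val in enumerate(values)}
    coincidence = np.zeros((v, v))
    for u in range(ratings.shape[1]):
        col = ratings[:, u]
        col = col[~np.isnan(col)]
        m_u = len(col)
        for a in col:
            for b in col:
                coincidence[idx[a], idx[b]] += 1.0 / (m_u - 1)
        # diagonal self-pairings removed: pairs are between distinct raters
        for a in col:
            coincidence[idx[a], idx[a]] -= 1.0 / (m_u - 1)

    n_c = coincidence.sum(axis=1)
    n_total = n_c.sum()

    if level == "interval":
        delta = (values[:, None] - values[None, :]) ** 2
    elif level == "ordinal":
        cum = np.cumsum(n_c)
        rank = cum - n_c / 2.0
        delta = (rank[:, None] - rank[None, :]) ** 2
    else:
        raise ValueError(f"unknown measurement level: {level!r}")

    d_observed = np.sum(coincidence * delta)
    d_expected = np.sum(np.outer(n_c, n_c) * delta) / (n_total - 1)
    if d_expected == 0:
        raise ValueError(
            "expected disagreement is zero (all ratings identical); "
            "alpha is undefined"
        )
    return ReliabilityResult(alpha=1.0 - d_observed / d_expected)


def scramble_ratings(
    table: pd.DataFrame, which: str = "both", seed: int = 0
) -> pd.DataFrame:
    """Permute rating columns across each movie's events (null condition).

    Onsets and durations are untouched, so the scrambled table carries no
    systematic semantic or social signal while preserving the temporal
    structure and the marginal rating distribution.  Deterministic for a
    given seed.
    """
    if which not in ("semantic", "social", "both"):
        raise ValueError(f"unknown rating selection: {which!r}")
    cols = ["semantic", "social"] if which == "both" else [which]
    rng = np.random.default_rng(seed)
    out = table.copy()
    for _, grp in table.groupby("movie_id", sort=False):
        for col in cols:
            perm = rng.permutation(len(grp))
            out.loc[grp.index, col] = grp[col].to_numpy()[perm]
    return out


def assign_words_to_events(
    transcript: pd.DataFrame, table: pd.DataFrame
) -> pd.Series:
    """Map each transcript word to the event containing its onset.

    Events are half-open intervals ``[onset, onset + duration)``, so a word
    at exactly an event's end time belongs to the next event; words falling
    in gaps between events get -1.  Returns a Series of event ``index``
    values aligned with the transcript rows.
    """
    onsets = transcript["onset"].to_numpy(float)
    if np.any(np.diff(onsets) < 0):
        raise ValueError("transcript must be ordered by word onset")
    ev = table.sort_values("onset")
    starts = ev["onset"].to_numpy(float)
    ends = starts + ev["duration"].to_numpy(float)
    indices = ev["index"].to_numpy()
    pos = np.searchsorted(starts, onsets, side="right") - 1
    assigned = np.full(len(onsets), -1, dtype=int)
    ok = (pos >= 0) & (onsets < ends[np.clip(pos, 0, None)])
    assigned[ok] = indices[pos[ok]]
    return pd.Series(assigned, index=transcript.index, name="event_index")


def apply_rating_overrides(
    table: pd.DataFrame, overrides: pd.DataFrame
) -> pd.DataFrame:
    """Apply consensus rating overrides (movie_id, index, semantic, social).

    Represents the human consensus-revision step that follows a
    below-threshold reliability result; the revision itself happens off-line.
    """
    out = table.copy()
    for _, row in overrides.iterrows():
        mask = (out["movie_id"] == row["movie_id"]) & (out["index"] == row["index"])
        if not mask.any():
            warnings.warn(f"override for unknown event {row['movie_id']}/{row['index']}")
            continue
        for col in ("semantic", "social"):
            if col in overrides.columns and not pd.isna(row[col]):
                out.loc[mask, col] = row[col]
    return out
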