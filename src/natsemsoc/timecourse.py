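"""Event-bounded sliding-window predictor series at 1 Hz.

Word-level values (factor scores, or 1 per content word) are summed inside
a window that slides in 1 s steps but never crosses an event boundary: the
window grid restarts at each event's onset, the window is clipped at the
event's end, and a final fragment shorter than the step still yields a
(shorter) window.  Factor series are then residualized on the total word
count per window so that they index word *properties* rather than word
quantity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

WINDOW_S = 5.0
STEP_S = 1.0

SERIES_COLUMNS = [
    "movie_id",
    "event_index",
    "window_start",
    "window_end",
    "value",
    "n_words",
    "empty",
]


@dataclass
class WindowSeries:
    """Ordered per-window samples for one movie."""

    movie_id: str
    samples: pd.DataFrame  # SERIES_COLUMNS

    def __post_init__(self) -> None:
        lengths = self.samples["window_end"] - self.samples["window_start"]
        assert (lengths > 0).all()

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def values(self) -> np.ndarray:
        return self.samples["value"].to_numpy(float)

    def replace_values(self, values: np.ndarray) -> "WindowSeries":
        out = self.samples.copy()
        out["value"] = values
        return WindowSeries(self.movie_id, out)


def window_sums(
    word_values: pd.DataFrame,
    table: pd.DataFrame,
    window: float = WINDOW_S,
    step: float = STEP_S,
) -> WindowSeries:
    """Sum word values in event-bounded sliding windows.

    ``word_values`` has ``onset`` and ``value`` columns; ``table`` is a
    merged, validated event table for one movie.  For each event, windows
    start at ``onset + k*step`` while the start lies before the event's
    end, and span ``[start, min(start + window, event_end))``.  A window's
    value is the sum of word values whose onsets fall in that span; windows
    containing no words carry ``value 0`` and the ``empty`` flag.
    """
    if step <= 0 or window <= 0:
        raise ValueError("window and step must be positive")
    movie_ids = table["movie_id"].unique()
    if len(movie_ids) != 1:
        raise ValueError("window_sums expects a single movie's event table")
    onsets = word_values["onset"].to_numpy(float)
    values = word_values["value"].to_numpy(float)
    order = np.argsort(onsets, kind="stable")
    onsets, values = onsets[order], values[order]

    rows = []
    for _, ev in table.sort_values("onset").iterrows():
        start0, end = float(ev["onset"]), float(ev["onset"] + ev["duration"])
        k = 0
        while start0 + k * step < end - 1e-12:
            w_start = start0 + k * step
            w_end = min(w_start + window, end)
            lo = np.searchsorted(onsets, w_start, side="left")
            hi = np.searchsorted(onsets, w_end, side="left")
            n = hi - lo
            rows.append(
                {
                    "movie_id": ev["movie_id"],
                    "event_index": ev["index"],
                    "window_start": w_start,
                    "window_end": w_end,
                    "value": float(values[lo:hi].sum()) if n else 0.0,
                    "n_words": int(n),
                    "empty": n == 0,
                }
            )
            k += 1
    return WindowSeries(str(movie_ids[0]), pd.DataFrame(rows, columns=SERIES_COLUMNS))


def content_word_counts(
    transcript: pd.DataFrame,
    table: pd.DataFrame,
    overrides: set[str] | None = None,
    window: float = WINDOW_S,
    step: float = STEP_S,
) -> WindowSeries:
    """Count open-class (content) words per event-bounded window.

    ``transcript`` has ``word, onset, pos`` columns.  Words flagged
    open-class count 1; closed-class words count 0.  The ``overrides`` set
    admits words absent from the norm databases (character names, dates,
    movie-specific coinages) as content words regardless of their POS tag.
    Words with no POS and no override are excluded with a warning.
    """
    overrides = overrides or set()
    pos = transcript["pos"] if "pos" in transcript.columns else pd.Series(
        [None] * len(transcript), index=transcript.index
    )
    value = np.zeros(len(transcript))
    untagged = []
    for i, (word, tag) in enumerate(zip(transcript["word"], pos)):
        if word in overrides or tag == "open":
            value[i] = 1.0
        elif tag == "closed":
            value[i] = 0.0
        elif tag is None or (isinstance(tag, float) and np.isnan(tag)):
            untagged.append(word)
    if untagged:
        warnings.warn(
            f"{len(untagged)} words with no POS tag and no override were "
            "excluded from the content-word count"
        )
    wv = pd.DataFrame({"onset": transcript["onset"].to_numpy(float), "value": value})
    series = window_sums(wv, table, window=window, step=step)
    # a zero count is meaningful for the content-word predictor; the empty
    # flag marks windows with *no qualifying content words* for this series
    samples = series.samples.copy()
    samples["empty"] = samples["value"] == 0
    return WindowSeries(series.movie_id, samples)


def residualize(series: WindowSeries, counts: WindowSeries) -> WindowSeries:
    """Regress window values on total word counts; keep the residuals.

    Fitted per movie by OLS with an intercept, using the total number of
    words in each window as the single covariate.  The returned series
    carries the residuals, which are exactly uncorrelated with the counts.
    If the counts are constant the fit is degenerate and the values are
    simply mean-centered, with a warning.
    """
    a = series.samples
    b = counts.samples
    if len(a) != len(b) or not np.allclose(
        a[["window_start", "window_end"]].to_numpy(float),
        b[["window_start", "window_end"]].to_numpy(float),
    ):
        raise ValueError("series and counts must share an identical window grid")
    y = a["value"].to_numpy(float)
    x = b["value"].to_numpy(float)
    if np.ptp(x) == 0:
        warnings.warn("constant word counts: residualization reduces to centering")
        return series.replace_values(y - y.mean())
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return series.replace_values(y - X @ beta)


def drop_empty(series: WindowSeries) -> WindowSeries:
    """Remove empty-flagged windows (no words, or no words with ratings).

    Windows without any rated words would otherwise be modelled as windows
    of *average*-scoring words once values are mean-centered, so factor
    predictors drop them instead of scoring them zero.
    """
    keep = ~series.samples["empty"].to_numpy(bool)
    if not keep.any():
        raise ValueError("every window is empty; nothing to analyse")
    return WindowSeries(series.movie_id, series.samples.loc[keep].reset_index(drop=True))
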