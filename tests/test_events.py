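"""Event-table validation, merging, reliability, scrambling, assignment."""

import numpy as np
import pandas as pd
import pytest

from natsemsoc.events import (
    assign_words_to_events,
    krippendorff_alpha,
    merge_short_events,
    scramble_ratings,
    validate_events,
)

# Example two-coder semantic ratings over ten consecutive events
R1_SEMANTIC = [2, 5, 6, 9, 4, 7, 7, 3, 1, 7]
R2_SEMANTIC = [3, 6, 6, 9, 5, 7, 9, 4, 3, 7]
# pinned against the independent pairwise oracle below
ALPHA_PINNED = 0.8914285714285715


def alpha_pairwise_oracle(mat):
    """Interval alpha from raw rating pairs, bypassing the coincidence matrix."""
    mat = np.asarray(mat, float)
    do_num, n_tot, vals = 0.0, 0, []
    for u in range(mat.shape[1]):
        col = mat[:, u]
        col = col[~np.isnan(col)]
        m = len(col)
        if m < 2:
            continue
        n_tot += m
        vals.extend(col)
        for i in range(m):
            for j in range(m):
                if i != j:
                    do_num += (col[i] - col[j]) ** 2 / (m - 1)
    d_obs = do_num / n_tot
    vals = np.array(vals)
    d_exp = sum((a - b) ** 2 for a in vals for b in vals) / (n_tot * (n_tot - 1))
    return 1.0 - d_obs / d_exp


class TestValidate:
    def test_well_formed_table_is_clean(self, toy_events):
        assert validate_events(toy_events).ok

    def test_dual_maximum_rule(self, toy_events):
        bad = toy_events.copy()
        bad.loc[0, ["semantic", "social"]] = [9.0, 10.0]
        report = validate_events(bad)
        assert any("dual-maximum" in v for v in report.violations)

    def test_nine_on_one_dimension_is_allowed(self, toy_events):
        ok = toy_events.copy()
        ok.loc[0, ["semantic", "social"]] = [9.0, 4.0]
        assert validate_events(ok).ok

    def test_overlap_and_range_violations(self, toy_events):
        bad = toy_events.copy()
        bad.loc[0, "duration"] = 12.0  # overlaps event at t=10
        bad.loc[2, "semantic"] = 11.0
        report = validate_events(bad)
        assert any("overlap" in v for v in report.violations)
        assert any("outside [1, 10]" in v for v in report.violations)


def brute_force_merge(events, min_duration=3.0):
    """Iterative reference merger: repeatedly absorb the first short event."""
    events = [dict(r) for _, r in events.iterrows()]
    while len(events) > 1:
        shorts = [i for i, e in enumerate(events) if e["duration"] < min_duration]
        if not shorts:
            break
        i = shorts[0]
        j = i + 1 if i + 1 < len(events) else i - 1
        a, b = events[min(i, j)], events[max(i, j)]
        merged = dict(a)
        merged["duration"] = a["duration"] + b["duration"]
        merged["semantic"] = (a["semantic"] + b["semantic"]) / 2
        merged["social"] = (a["social"] + b["social"]) / 2
        events[min(i, j)] = merged
        del events[max(i, j)]
    return events


class TestMerge:
    def test_short_first_event_averages_into_successor(self):
        ev = pd.DataFrame(
            {
                "movie_id": "m",
                "index": [0, 1],
                "onset": [0.0, 2.5],
                "duration": [2.5, 10.0],
                "semantic": [4.0, 6.0],
                "social": [2.0, 8.0],
            }
        )
        out = merge_short_events(ev)
        assert len(out) == 1
        row = out.iloc[0]
        assert row["onset"] == 0.0 and row["duration"] == 12.5
        assert row["semantic"] == 5.0 and row["social"] == 5.0

    def test_no_short_events_unchanged(self, toy_events):
        out = merge_short_events(toy_events)
        pd.testing.assert_frame_equal(
            out[["onset", "duration", "semantic", "social"]],
            toy_events[["onset", "duration", "semantic", "social"]],
        )

    def test_chain_merge_matches_brute_force(self):
        durations = [1.0, 1.0, 1.0, 20.0]
        onsets = np.concatenate([[0], np.cumsum(durations)[:-1]])
        ev = pd.DataFrame(
            {
                "movie_id": "m",
                "index": range(4),
                "onset": onsets,
                "duration": durations,
                "semantic": [2.0, 4.0, 6.0, 8.0],
                "social": [1.0, 3.0, 5.0, 7.0],
            }
        )
        out = merge_short_events(ev)
        ref = brute_force_merge(ev)
        assert len(out) == len(ref)
        for (_, got), want in zip(out.iterrows(), ref):
            assert got["duration"] == pytest.approx(want["duration"])
            assert got["semantic"] == pytest.approx(want["semantic"])
            assert got["social"] == pytest.approx(want["social"])
        assert (out["duration"] >= 3.0).all()
        assert out["duration"].sum() == pytest.approx(23.0)

    def test_trailing_short_event_merges_backward(self):
        ev = pd.DataFrame(
            {
                "movie_id": "m",
                "index": [0, 1],
                "onset": [0.0, 10.0],
                "duration": [10.0, 2.0],
                "semantic": [4.0, 8.0],
                "social": [2.0, 6.0],
            }
        )
        out = merge_short_events(ev)
        assert len(out) == 1
        assert out.iloc[0]["duration"] == pytest.approx(12.0)
        assert out.iloc[0]["semantic"] == pytest.approx(6.0)

    def test_total_duration_conserved(self, event_table):
        ev, _ = event_table
        out = merge_short_events(ev)
        assert out["duration"].sum() == pytest.approx(ev["duration"].sum(), abs=1e-9)

    def test_empty_table_raises(self):
        with pytest.raises(ValueError):
            merge_short_events(pd.DataFrame(columns=["movie_id", "duration"]))


class TestKrippendorff:
    def test_perfect_agreement(self):
        mat = np.array([[1, 5, 3, 7, 2, 8, 4, 6, 9, 10]] * 2, float)
        res = krippendorff_alpha(mat)
        assert res.alpha == pytest.approx(1.0)
        assert not res.needs_revision

    def test_two_coder_semantic_ratings_match_oracle(self):
        mat = np.array([R1_SEMANTIC, R2_SEMANTIC], float)
        res = krippendorff_alpha(mat)
        assert res.alpha == pytest.approx(alpha_pairwise_oracle(mat), abs=1e-12)
        assert res.alpha == pytest.approx(ALPHA_PINNED, abs=1e-12)
        assert not res.needs_revision  # 0.89 clears the 0.75 revision bar

    def test_missing_ratings_match_oracle(self):
        mat = np.array(
            [R1_SEMANTIC, R2_SEMANTIC, [4, 5, 6, 7, 8, 2, 3, 4, 5, 6]], float
        )
        mat[0, 3] = np.nan
        mat[2, 7] = np.nan
        assert krippendorff_alpha(mat).alpha == pytest.approx(
            alpha_pairwise_oracle(mat), abs=1e-12
        )

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        mat = rng.integers(1, 11, size=(3, 12)).astype(float)
        base = krippendorff_alpha(mat).alpha
        assert krippendorff_alpha(mat[::-1]).alpha == pytest.approx(base)
        perm = rng.permutation(12)
        assert krippendorff_alpha(mat[:, perm]).alpha == pytest.approx(base)

    def test_shuffled_rater_gives_near_zero_alpha(self):
        rng = np.random.default_rng(1)
        base = rng.integers(1, 11, size=20).astype(float)
        alphas = []
        for _ in range(400):
            shuffled = rng.permutation(base)
            alphas.append(krippendorff_alpha(np.array([base, shuffled])).alpha)
        assert abs(np.mean(alphas)) < 0.05

    def test_identical_constant_ratings_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            krippendorff_alpha(np.full((2, 10), 5.0))

    def test_ordinal_level_perfect_agreement_and_bounds(self):
        mat = np.array([[1, 5, 3, 7, 2, 8, 4, 6, 9, 10]] * 2, float)
        assert krippendorff_alpha(mat, level="ordinal").alpha == pytest.approx(1.0)
        rng = np.random.default_rng(3)
        noisy = np.array([[1, 5, 3, 7, 2, 8, 4, 6, 9, 10],
                          rng.permutation([1, 5, 3, 7, 2, 8, 4, 6, 9, 10])], float)
        a = krippendorff_alpha(noisy, level="ordinal").alpha
        assert -1.0 <= a <= 1.0

    def test_below_threshold_flags_revision(self):
        rng = np.random.default_rng(2)
        mat = rng.integers(1, 11, size=(2, 30)).astype(float)
        res = krippendorff_alpha(mat)
        assert res.needs_revision == (res.alpha < 0.75)


class TestScramble:
    def test_permutation_preserves_multiset_and_timing(self, event_table):
        ev, _ = event_table
        out = scramble_ratings(ev, "both", seed=5)
        for col in ("semantic", "social"):
            assert sorted(out[col]) == sorted(ev[col])
        assert (out["onset"].to_numpy() == ev["onset"].to_numpy()).all()
        assert (out["duration"].to_numpy() == ev["duration"].to_numpy()).all()

    def test_deterministic_given_seed(self, event_table):
        ev, _ = event_table
        a = scramble_ratings(ev, "semantic", seed=9)
        b = scramble_ratings(ev, "semantic", seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_mean_correlation_near_zero(self, event_table):
        ev, _ = event_table
        orig = ev["semantic"].to_numpy(float)
        rs = [
            np.corrcoef(orig, scramble_ratings(ev, "semantic", seed=s)["semantic"])[0, 1]
            for s in range(300)
        ]
        assert abs(np.mean(rs)) < 0.05


class TestAssign:
    def test_onset_at_event_start_and_end(self, toy_events):
        words = pd.DataFrame({"onset": [0.0, 9.999, 10.0, 24.9, 25.0, 40.0]})
        out = assign_words_to_events(words, toy_events)
        # half-open intervals: end time belongs to the next event
        assert list(out) == [0, 0, 1, 1, 2, -1]

    def test_gap_words_unassigned(self):
        ev = pd.DataFrame(
            {
                "movie_id": "m",
                "index": [0, 1],
                "onset": [0.0, 20.0],
                "duration": [5.0, 5.0],
                "semantic": [5.0, 5.0],
                "social": [5.0, 5.0],
            }
        )
        words = pd.DataFrame({"onset": [2.0, 10.0, 21.0]})
        assert list(assign_words_to_events(words, ev)) == [0, -1, 1]

    def test_unordered_transcript_raises(self, toy_events):
        with pytest.raises(ValueError):
            assign_words_to_events(pd.DataFrame({"onset": [5.0, 1.0]}), toy_events)

    def test_every_word_in_at_most_one_event(self, event_table):
        ev, _ = event_table
        rng = np.random.default_rng(11)
        span = ev["onset"].iloc[-1] + ev["duration"].iloc[-1]
        words = pd.DataFrame({"onset": np.sort(rng.uniform(0, span + 10, 500))})
        out = assign_words_to_events(words, ev)
        starts = ev.set_index("index")["onset"]
        durs = ev.set_index("index")["duration"]
        for onset, idx in zip(words["onset"], out):
            # brute-force interval scan
            containing = [
                i
                for i in ev["index"]
                if starts[i] <= onset < starts[i] + durs[i]
            ]
            assert len(containing) <= 1
            assert idx == (containing[0] if containing else -1)
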