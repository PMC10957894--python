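"""Lexical feature pipeline: assembly, imputation, PCA factors, scores,
socialness extrapolation."""

import numpy as np
import pandas as pd
import pytest

from natsemsoc import synthdata as sd
from natsemsoc.lexfeatures import (
    PROPERTIES,
    assemble_word_table,
    extrapolate_social,
    fit_pca_varimax,
    impute_chained,
    score_factors,
    tucker_congruence,
    _varimax,
)


def _norms_from_lexicon(lex):
    return lex.drop(columns=["socialness"])


def _social_from_lexicon(lex, n=50):
    have = lex.dropna(subset=["socialness"]).head(n)
    return pd.DataFrame(
        {"word": have["word"], "mean_rating": have["socialness"], "n_raters": 34}
    ).reset_index(drop=True)


class TestAssemble:
    @pytest.fixture()
    def inputs(self, small_lexicon):
        lex, _ = small_lexicon
        transcript = pd.DataFrame(
            {"word": lex["word"].head(100).tolist() + ["the", "and"],
             "pos": ["open"] * 100 + ["closed"] * 2}
        )
        return transcript, _norms_from_lexicon(lex), _social_from_lexicon(lex)

    def test_complete_word_retained(self, inputs):
        transcript, norms, social = inputs
        table = assemble_word_table(transcript, norms, social)
        full = norms.dropna()
        overlap = set(full["word"]) & set(transcript["word"]) & set(table["word"])
        assert overlap  # fully-normed transcript words survive

    def test_closed_class_excluded(self, inputs):
        transcript, norms, social = inputs
        table = assemble_word_table(transcript, norms, social)
        assert "the" not in set(table["word"])
        assert "and" not in set(table["word"])

    def test_word_missing_eleven_of_twelve_dropped(self, inputs):
        transcript, norms, social = inputs
        norms = norms.copy()
        target = transcript["word"].iloc[0]
        idx = norms["word"] == target
        for p in PROPERTIES:
            if p in norms.columns and p != "n_letters":
                norms.loc[idx, p] = np.nan
        social = social[social["word"] != target]
        table = assemble_word_table(transcript, norms, social)
        assert target not in set(table["word"])

    def test_high_frequency_words_excluded(self, inputs):
        transcript, norms, social = inputs
        table = assemble_word_table(transcript, norms, social, high_freq_quantile=0.5)
        cut = norms["frequency"].quantile(0.5)
        freqs = norms.set_index("word")["frequency"]
        present = [w for w in table["word"] if w in freqs and not pd.isna(freqs[w])]
        assert all(freqs[w] <= cut for w in present)

    def test_socialness_extrapolated_for_unnormed_words(self, small_lexicon):
        lex, _ = small_lexicon
        emb = sd.gen_embeddings(lex, seed=1)
        transcript = pd.DataFrame({"word": lex["word"].head(60), "pos": "open"})
        social = _social_from_lexicon(lex, n=100)
        table = assemble_word_table(
            transcript, _norms_from_lexicon(lex), social, embeddings=emb
        )
        unnormed = table[~table["word"].isin(social["word"])]
        assert unnormed["socialness"].notna().any()
        filled = unnormed["socialness"].dropna()
        assert ((filled >= 1) & (filled <= 5)).all()

    def test_empty_transcript_raises(self, inputs):
        _, norms, social = inputs
        with pytest.raises(ValueError, match="empty"):
            assemble_word_table(pd.DataFrame(columns=["word", "pos"]), norms, social)

    def test_duplicate_norm_words_raise(self, inputs):
        transcript, norms, social = inputs
        dup = pd.concat([norms, norms.head(1)])
        with pytest.raises(ValueError, match="duplicate"):
            assemble_word_table(transcript, dup, social)


@pytest.fixture(scope="module")
def masked():
    lex, _ = sd.gen_lexicon(150, missing_rate=0.0, seed=8)
    rng = np.random.default_rng(9)
    mask = rng.random((150, 12)) < 0.2
    arr = lex[PROPERTIES].to_numpy(float)
    complete = lex.copy()
    arr[mask] = np.nan
    lex = lex.copy()
    lex[PROPERTIES] = arr
    return lex, complete


class TestImpute:

    def test_no_missing_gives_identical_copies(self):
        lex, _ = sd.gen_lexicon(120, missing_rate=0.0, seed=2)
        out = impute_chained(lex, m=3, iters=2, seed=0)
        assert len(out) == 3
        for t in out:
            pd.testing.assert_frame_equal(t, lex)

    def test_observed_cells_unchanged_and_donors_observed(self, masked):
        lex, _ = masked
        out = impute_chained(lex, m=2, iters=3, seed=1)
        obs = lex[PROPERTIES].notna().to_numpy()
        for t in out:
            assert not t[PROPERTIES].isna().any().any()
            filled = t[PROPERTIES].to_numpy()
            orig = lex[PROPERTIES].to_numpy()
            assert np.array_equal(filled[obs], orig[obs])
            # PMM: every imputed cell equals some observed value of the column
            for j, p in enumerate(PROPERTIES):
                donors = set(lex[p].dropna())
                imputed = filled[~obs[:, j], j]
                assert all(v in donors for v in imputed)

    def test_post_imputation_means_close_to_complete_data(self, masked):
        lex, complete = masked
        out = impute_chained(lex, m=3, iters=4, seed=5)
        for p in PROPERTIES:
            pooled_mean = np.mean([t[p].mean() for t in out])
            assert abs(pooled_mean - complete[p].mean()) < 0.1 * complete[p].std()

    def test_deterministic_given_seed(self, masked):
        lex, _ = masked
        a = impute_chained(lex, m=2, iters=2, seed=3)
        b = impute_chained(lex, m=2, iters=2, seed=3)
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x, y)

    def test_fully_missing_property_raises(self, masked):
        lex, _ = masked
        lex = lex.copy()
        lex["arousal"] = np.nan
        with pytest.raises(ValueError, match="fully-missing"):
            impute_chained(lex, m=2, iters=2, seed=0)


class TestVarimax:
    def test_simple_structure_is_fixed_point(self):
        load = np.zeros((8, 2))
        load[:4, 0] = 0.9
        load[4:, 1] = 0.8
        rotated, rotation = _varimax(load)
        assert np.allclose(np.abs(rotated), np.abs(load), atol=1e-6)
        assert np.allclose(rotation.T @ rotation, np.eye(2), atol=1e-10)

    def test_rotation_preserves_total_variance(self, complete_lexicon):
        lex, _ = complete_lexicon
        from sklearn.decomposition import PCA

        z = (lex[PROPERTIES] - lex[PROPERTIES].mean()) / lex[PROPERTIES].std()
        pca = PCA(n_components=4).fit(z.to_numpy())
        load = pca.components_.T * np.sqrt(pca.explained_variance_)
        rotated, _ = _varimax(load)
        assert np.sum(rotated**2) == pytest.approx(np.sum(load**2), abs=1e-8)

    def test_model_rotation_is_orthogonal(self, complete_lexicon):
        lex, _ = complete_lexicon
        model = fit_pca_varimax([lex])
        rtr = model.rotation.T @ model.rotation
        assert np.allclose(rtr, np.eye(4), atol=1e-8)

    def test_recovers_planted_loadings(self, complete_lexicon):
        lex, truth = complete_lexicon
        model = fit_pca_varimax([lex])
        cong = tucker_congruence(
            truth.loadings.to_numpy(), model.loadings.to_numpy()
        )
        assert (cong >= 0.95).all()

    def test_variance_ordering_matches_generator(self, complete_lexicon):
        lex, truth = complete_lexicon
        model = fit_pca_varimax([lex])
        ve = model.variance_explained
        assert (np.diff(ve) <= 1e-12).all()  # ordered by rotated variance
        assert np.all(ve > 0) and ve.sum() <= 1.0

    def test_k_exceeding_properties_raises(self, complete_lexicon):
        lex, _ = complete_lexicon
        with pytest.raises(ValueError):
            fit_pca_varimax([lex], k=13)


class TestScores:
    def test_identical_tables_average_to_single_table_scores(self, complete_lexicon):
        lex, _ = complete_lexicon
        model = fit_pca_varimax([lex])
        one = score_factors(model, [lex])
        three = score_factors(model, [lex, lex.copy(), lex.copy()])
        for f in model.factor_names:
            assert np.allclose(one[f], three[f])

    def test_emotional_strength_nonnegative_and_others_centered(self, complete_lexicon):
        lex, _ = complete_lexicon
        model = fit_pca_varimax([lex])
        scores = score_factors(model, [lex])
        assert scores["EmotionalStrength"].min() >= 0
        assert scores.attrs["emotional_strength_abs_applied"]
        for f in ("WordLength", "SemanticFlexibility", "SocialImpact"):
            assert abs(scores[f].mean()) < 1e-6

    def test_scores_track_true_latents_with_strong_loadings(self):
        # dedicated strong-loading 4-factor generator: regression-score
        # validity rises with loading strength, so recovery >= 0.9 needs
        # higher loadings than the variance-split calibration uses
        rng = np.random.default_rng(4)
        n, load = 3000, 0.92
        latents = rng.standard_normal((n, 4))
        cols = {}
        for i, p in enumerate(PROPERTIES):
            f = i % 4
            cols[p] = load * latents[:, f] + np.sqrt(1 - load**2) * rng.standard_normal(n)
        table = pd.DataFrame(cols)
        table.insert(0, "word", [f"w{i}" for i in range(n)])
        model = fit_pca_varimax([table])
        scores = score_factors(model, [table], abs_emotional=False)
        best = np.abs(np.corrcoef(scores[model.factor_names].T, latents.T)[:4, 4:])
        assert (best.max(axis=1) >= 0.9).all()

    def test_mismatched_columns_raise(self, complete_lexicon):
        lex, _ = complete_lexicon
        model = fit_pca_varimax([lex])
        with pytest.raises(ValueError, match="lacks"):
            score_factors(model, [lex.drop(columns=["arousal"])])


class TestExtrapolate:
    def _embeddings(self, sims):
        """Construct embeddings with chosen cosine similarity to a probe."""
        emb = {"probe": np.array([1.0, 0.0])}
        for i, s in enumerate(sims):
            emb[f"n{i}"] = np.array([s, np.sqrt(max(1 - s**2, 0.0))])
        return emb

    def test_constant_neighbour_ratings(self):
        emb = self._embeddings([0.9, 0.5, 0.3])
        norms = pd.DataFrame(
            {"word": ["n0", "n1", "n2"], "mean_rating": [3.0, 3.0, 3.0]}
        )
        assert extrapolate_social("probe", emb, norms, k=3) == pytest.approx(3.0)

    def test_hand_computed_weighted_mean(self):
        emb = self._embeddings([0.9, 0.8, 0.7])
        norms = pd.DataFrame(
            {"word": ["n0", "n1", "n2"], "mean_rating": [5.0, 3.0, 1.0]}
        )
        out = extrapolate_social("probe", emb, norms, k=3)
        assert out == pytest.approx((4.5 + 2.4 + 0.7) / 2.4, abs=1e-12)

    def test_identical_word_dominates_neighbourhood(self):
        emb = self._embeddings([1.0, 0.5, 0.2, 0.1])
        norms = pd.DataFrame(
            {"word": [f"n{i}" for i in range(4)], "mean_rating": [5.0, 1.0, 1.0, 1.0]}
        )
        out = extrapolate_social("probe", emb, norms, k=3)
        # the similarity-1 neighbour carries the largest weight
        assert out > np.mean([5.0, 1.0, 1.0])

    def test_bounded_by_neighbour_range(self, small_lexicon):
        lex, _ = small_lexicon
        emb = sd.gen_embeddings(lex, seed=5)
        norms = sd.gen_social_norms(lex, n_normed=80, seed=6)
        rng = np.random.default_rng(7)
        for w in rng.choice(lex["word"], 25, replace=False):
            val = extrapolate_social(w, emb, norms, k=10)
            assert norms["mean_rating"].min() <= val <= norms["mean_rating"].max()

    def test_all_nonpositive_similarities_fall_back(self):
        emb = {"probe": np.array([1.0, 0.0]),
               "n0": np.array([-1.0, 0.0]),
               "n1": np.array([-0.9, np.sqrt(1 - 0.81)])}
        norms = pd.DataFrame({"word": ["n0", "n1"], "mean_rating": [2.0, 4.0]})
        with pytest.warns(UserWarning, match="non-positive"):
            assert extrapolate_social("probe", emb, norms, k=2) == pytest.approx(3.0)

    def test_missing_embedding_raises(self):
        with pytest.raises(KeyError):
            extrapolate_social("absent", {"x": np.ones(3)},
                               pd.DataFrame({"word": ["x"], "mean_rating": [3.0]}), k=1)
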