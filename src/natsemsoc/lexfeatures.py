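"""Word-level psycholinguistic features: property-table assembly, chained
multiple imputation, varimax-rotated PCA factors, averaged factor scores,
and embedding-based extrapolation of socialness norms.

The lexical model treats every content word as a point in a 12-dimensional
property space (orthographic/phonological length and neighbourhoods,
frequency, concreteness, semantic neighbourhood density and diversity,
valence, arousal, dominance, and a 1-5 socialness rating).  Missing norms
are multiply imputed; a varimax-rotated PCA reduces the 12 properties to
four interpretable factors (word length, semantic flexibility, emotional
strength, social impact), whose per-word scores — averaged across
imputations — drive the downstream time-course predictors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from statsmodels.imputation.mice import MICEData

#: the 12 critical word properties, in canonical column order
PROPERTIES = [
    "n_letters",
    "n_phonemes",
    "n_phon_neighbors",
    "n_orth_neighbors",
    "frequency",
    "concreteness",
    "sem_neighborhood_density",
    "semantic_diversity",
    "valence",
    "arousal",
    "dominance",
    "socialness",
]

FACTOR_NAMES = ["WordLength", "SemanticFlexibility", "EmotionalStrength", "SocialImpact"]

#: rows missing more than this many of the 12 properties are dropped
MAX_MISSING_PROPERTIES = 10


@dataclass
class FactorModel:
    """Varimax-rotated PCA over the 12 standardized word properties."""

    loadings: pd.DataFrame  # property x factor
    rotation: np.ndarray  # 4x4 orthogonal
    variance_explained: np.ndarray  # per-factor proportion of total variance
    means: pd.Series  # per-property standardization mean
    sds: pd.Series  # per-property standardization sd
    factor_names: list[str]

    def __post_init__(self) -> None:
        rtr = self.rotation.T @ self.rotation
        assert np.allclose(rtr, np.eye(rtr.shape[0]), atol=1e-8)


# ---------------------------------------------------------------------------
# table assembly


def assemble_word_table(
    transcript_words: pd.DataFrame,
    norms: pd.DataFrame,
    social: pd.DataFrame,
    embeddings: dict[str, np.ndarray] | None = None,
    high_freq_quantile: float = 0.95,
    k_neighbors: int = 10,
) -> pd.DataFrame:
    """Build the per-word property table for the unique transcript words.

    ``transcript_words`` needs ``word`` and ``pos`` ('open'/'closed')
    columns; ``norms`` is a word-keyed table of the non-social properties;
    ``social`` holds ``word, mean_rating`` from the socialness norming
    study.  Closed-class words and words above the ``high_freq_quantile``
    of the norm-table frequency distribution are excluded, as are words
    missing more than 10 of the 12 critical properties.  A word without a
    normed socialness rating gets an extrapolated rating from its embedding
    neighbours when an embedding exists; otherwise socialness stays missing
    for the imputation stage.
    """
    if len(transcript_words) == 0:
        raise ValueError("empty transcript: no words to assemble")
    if norms["word"].duplicated().any():
        dupes = norms.loc[norms["word"].duplicated(), "word"].tolist()
        raise ValueError(f"norm table has duplicate words: {dupes[:5]}")
    if social["word"].duplicated().any():
        raise ValueError("social norms table has duplicate words")

    pos_map = (
        transcript_words.drop_duplicates("word").set_index("word")["pos"].to_dict()
    )
    words = [w for w in dict.fromkeys(transcript_words["word"]) if pos_map.get(w) == "open"]

    norm_idx = norms.set_index("word")
    freq_cut = norm_idx["frequency"].quantile(high_freq_quantile)
    social_idx = social.set_index("word")["mean_rating"]

    rows = []
    for word in words:
        props: dict[str, float] = {p: np.nan for p in PROPERTIES}
        if word in norm_idx.index:
            rec = norm_idx.loc[word]
            for p in PROPERTIES:
                if p in rec.index and not pd.isna(rec[p]):
                    props[p] = float(rec[p])
        if not pd.isna(props["frequency"]) and props["frequency"] > freq_cut:
            continue  # high-frequency exclusion
        if word in social_idx.index:
            props["socialness"] = float(social_idx.loc[word])
        elif embeddings is not None and word in embeddings:
            props["socialness"] = extrapolate_social(
                word, embeddings, social, k=k_neighbors
            )
        n_missing = sum(pd.isna(v) for v in props.values())
        if n_missing > MAX_MISSING_PROPERTIES:
            continue
        rows.append({"word": word, **props})
    return pd.DataFrame(rows, columns=["word"] + PROPERTIES)


# ---------------------------------------------------------------------------
# multiple imputation


def impute_chained(
    table: pd.DataFrame, m: int = 5, iters: int = 10, seed: int = 0
) -> list[pd.DataFrame]:
    """Fill missing property cells by chained equations with PMM.

    Runs ``m`` independent chains (predictive mean matching, ``iters``
    burn-in cycles each) and returns ``m`` complete copies of the table.
    Observed cells are never altered, and every imputed value is an
    observed donor value of the same property.  Deterministic given
    ``seed``.
    """
    prop_cols = [c for c in table.columns if c in PROPERTIES]
    data = table[prop_cols].reset_index(drop=True)
    fully_missing = [c for c in prop_cols if data[c].isna().all()]
    if fully_missing:
        raise ValueError(f"cannot impute fully-missing properties: {fully_missing}")
    thin = [c for c in prop_cols if data[c].notna().sum() < 2]
    if thin:
        raise ValueError(f"need >= 2 observed values per property: {thin}")

    completed = []
    has_missing = data.isna().any().any()
    for chain in range(m):
        if not has_missing:
            completed.append(table.copy())
            continue
        state = np.random.get_state()
        try:
            np.random.seed((seed + 1000003 * chain) % (2**32))
            md = MICEData(data.copy())
            md.update_all(iters)
        finally:
            np.random.set_state(state)
        out = table.copy()
        out[prop_cols] = md.data[prop_cols].to_numpy()
        completed.append(out)
    return completed


# ---------------------------------------------------------------------------
# varimax PCA


def _varimax(loadings: np.ndarray, max_iter: int = 500, tol: float = 1e-12):
    """Varimax rotation; returns (rotated loadings, rotation matrix)."""
    p, k = loadings.shape
    rotation = np.eye(k)
    var_old = 0.0
    for _ in range(max_iter):
        rotated = loadings @ rotation
        u, s, vt = np.linalg.svd(
            loadings.T @ (rotated**3 - rotated * (rotated**2).sum(axis=0) / p)
        )
        rotation = u @ vt
        var_new = s.sum()
        if var_new < var_old * (1 + tol):
            break
        var_old = var_new
    return loadings @ rotation, rotation


def _standardize(data: pd.DataFrame):
    means = data.mean()
    sds = data.std(ddof=1)
    return (data - means) / sds, means, sds


def _fit_one(data: pd.DataFrame, k: int):
    """PCA + varimax on one complete table; loadings sign/order normalized."""
    z, means, sds = _standardize(data)
    pca = PCA(n_components=k)
    pca.fit(z.to_numpy())
    # component loadings on the correlation metric: eigvec * sqrt(eigval)
    load = pca.components_.T * np.sqrt(pca.explained_variance_)
    rotated, rotation = _varimax(load)
    # order factors by rotated variance, flip so the dominant loading is +
    ssq = (rotated**2).sum(axis=0)
    order = np.argsort(-ssq)
    rotated = rotated[:, order]
    rotation = rotation[:, order]
    signs = np.sign(rotated[np.argmax(np.abs(rotated), axis=0), np.arange(k)])
    signs[signs == 0] = 1.0
    rotated *= signs
    rotation *= signs
    return rotated, rotation, means, sds


def fit_pca_varimax(tables: list[pd.DataFrame], k: int = 4) -> FactorModel:
    """Fit a varimax-rotated PCA on each imputed table and aggregate.

    Each table is standardized per property (correlation-metric PCA); the
    first ``k`` components are varimax-rotated, ordered by rotated variance
    and sign-fixed so the largest-magnitude loading of each factor is
    positive.  Models from the individual imputations are aligned to the
    first (matching factors by maximal absolute congruence, flipping signs
    as needed) and their loadings averaged element-wise.
    """
    prop_cols = [c for c in tables[0].columns if c in PROPERTIES]
    if k > len(prop_cols):
        raise ValueError(f"k={k} exceeds the {len(prop_cols)} properties")
    for t in tables:
        if t[prop_cols].isna().any().any():
            raise ValueError("imputed tables must be complete")
        nz = (t[prop_cols].std(ddof=1) > 0).sum()
        if nz < k:
            raise ValueError("need >= k properties with non-zero variance")

    fits = [_fit_one(t[prop_cols], k) for t in tables]
    ref = fits[0][0]
    aligned = [ref]
    for rotated, *_ in fits[1:]:
        # greedy congruence matching to the reference factors
        cong = _congruence_matrix(ref, rotated)
        perm = np.full(k, -1)
        for _ in range(k):
            i, j = np.unravel_index(
                np.argmax(np.where(np.isfinite(cong), np.abs(cong), -np.inf)), cong.shape
            )
            perm[i] = j
            cong[i, :] = np.nan
            cong[:, j] = np.nan
        reordered = rotated[:, perm]
        signs = np.sign((ref * reordered).sum(axis=0))
        signs[signs == 0] = 1.0
        aligned.append(reordered * signs)

    mean_load = np.mean(aligned, axis=0)
    ssq = (mean_load**2).sum(axis=0)
    order = np.argsort(-ssq)
    mean_load = mean_load[:, order]
    var_explained = (mean_load**2).sum(axis=0) / len(prop_cols)

    pooled = pd.concat([t[prop_cols] for t in tables])
    means = pooled.mean()
    sds = pooled.std(ddof=1)
    return FactorModel(
        loadings=pd.DataFrame(mean_load, index=prop_cols, columns=FACTOR_NAMES[:k]),
        rotation=_orthonormalize(mean_load),
        variance_explained=var_explained,
        means=means,
        sds=sds,
        factor_names=FACTOR_NAMES[:k],
    )


def _congruence_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Tucker congruence between columns of a and b."""
    na = np.linalg.norm(a, axis=0)
    nb = np.linalg.norm(b, axis=0)
    return (a.T @ b) / np.outer(na, nb)


def _orthonormalize(loadings: np.ndarray) -> np.ndarray:
    """Orthonormal k x k rotation summarizing the factor axes (via QR of
    the normalized loading columns projected onto their own span)."""
    q, _ = np.linalg.qr(loadings.T @ loadings)
    return q


def tucker_congruence(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Per-factor Tucker congruence after greedy sign/order alignment."""
    cong = _congruence_matrix(a, b)
    k = cong.shape[0]
    work = cong.copy()
    out = np.zeros(k)
    for _ in range(k):
        i, j = np.unravel_index(
            np.argmax(np.where(np.isfinite(work), np.abs(work), -np.inf)), work.shape
        )
        out[i] = abs(cong[i, j])
        work[i, :] = np.nan
        work[:, j] = np.nan
    return out


# ---------------------------------------------------------------------------
# factor scores


def score_factors(
    model: FactorModel, tables: list[pd.DataFrame], abs_emotional: bool = True
) -> pd.DataFrame:
    """Regression-method factor scores, averaged over imputations.

    Each complete table is standardized with the model's means/sds; scores
    are the regression estimates ``Z R^{-1} L`` with ``R`` the pooled
    correlation matrix and ``L`` the rotated loadings.  Scores are averaged
    per word across the ``m`` tables.  The EmotionalStrength column is then
    replaced by its absolute value so that it indexes emotional versus
    neutral content rather than positive versus negative valence.
    """
    prop_cols = list(model.loadings.index)
    for t in tables:
        missing = [c for c in prop_cols if c not in t.columns]
        if missing:
            raise ValueError(f"table lacks model properties: {missing}")

    pooled = pd.concat([t[prop_cols] for t in tables])
    z_pooled = (pooled - model.means) / model.sds
    corr = np.corrcoef(z_pooled.to_numpy(), rowvar=False)
    weights = np.linalg.solve(corr, model.loadings.to_numpy())

    all_scores = []
    for t in tables:
        z = ((t[prop_cols] - model.means) / model.sds).to_numpy()
        all_scores.append(z @ weights)
    scores = np.mean(all_scores, axis=0)
    out = pd.DataFrame(scores, columns=model.factor_names, index=tables[0].index)
    if "word" in tables[0].columns:
        out.insert(0, "word", tables[0]["word"].to_numpy())
    if abs_emotional and "EmotionalStrength" in out.columns:
        out["EmotionalStrength"] = out["EmotionalStrength"].abs()
        out.attrs["emotional_strength_abs_applied"] = True
    return out


# ---------------------------------------------------------------------------
# socialness extrapolation


def extrapolate_social(
    word: str,
    embeddings: dict[str, np.ndarray],
    norms: pd.DataFrame,
    k: int = 10,
) -> float:
    """Extrapolate a 1-5 socialness rating from embedding neighbours.

    Cosine similarity is computed between ``word`` and every normed word
    with an embedding; the ``k`` most similar (ties broken alphabetically)
    contribute a similarity-weighted mean of their ratings.  Negative
    similarities are clipped to zero before normalization so the result
    stays inside the neighbours' rating range; if every retained similarity
    is non-positive, the unweighted neighbour mean is returned with a
    warning.
    """
    if word not in embeddings:
        raise KeyError(f"no embedding for {word!r}")
    cand = [(w, r) for w, r in zip(norms["word"], norms["mean_rating"]) if w in embeddings]
    if not cand:
        raise ValueError("no normed word has an embedding")
    if k > len(cand):
        raise ValueError(f"k={k} exceeds the {len(cand)} normed words with embeddings")
    v = np.asarray(embeddings[word], dtype=float)
    sims = []
    for w, r in cand:
        u = np.asarray(embeddings[w], dtype=float)
        sims.append((float(v @ u / (np.linalg.norm(v) * np.linalg.norm(u))), w, r))
    # top-k by similarity, ties broken lexicographically by word
    sims.sort(key=lambda t: (-t[0], t[1]))
    top = sims[:k]
    weights = np.clip([s for s, _, _ in top], 0.0, None)
    ratings = np.array([r for _, _, r in top], dtype=float)
    if weights.sum() <= 0:
        warnings.warn(
            f"all top-{k} similarities non-positive for {word!r}; "
            "falling back to the unweighted neighbour mean"
        )
        return float(ratings.mean())
    return float(np.sum(weights * ratings) / weights.sum())
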