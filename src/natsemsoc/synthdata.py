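"""Synthetic study generator: every input the pipeline consumes, with
ground truth recorded for recovery tests.

The generators emulate the study conditions of a naturalistic movie-fMRI
dataset: a lexicon whose 12 psycholinguistic properties arise from four
latent factors with a ~29/17/16/11% variance split, embeddings whose
cosine neighbourhoods carry socialness, movie event tables with the
printed duration distribution (post-merge median ~16 s, ~4% of pre-merge
events under 3 s) and rating structure (1-10 integer scales, the dual-9/10
exclusion, low-to-moderate semantic/social correlation), transcripts whose
per-event word counts reproduce the printed duration/rating/word-count
correlation ranges, and 4D BOLD built by the pipeline's own forward model
(HRF-convolved regressors scaled by known betas) plus AR(1), spatially
smoothed noise.  Every generator is a pure function of its parameters and
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .firstlevel import BoldImage, Regressor
from .lexfeatures import FACTOR_NAMES, PROPERTIES

#: target proportion-of-variance split of the four lexical factors
VARIANCE_SPLIT = (0.29, 0.17, 0.16, 0.11)

#: property -> (factor index, loading); each property has one parent factor
_LOADING_PLAN = {
    "n_letters": (0, 0.917),
    "n_phonemes": (0, 0.917),
    "n_phon_neighbors": (0, -0.917),
    "n_orth_neighbors": (0, -0.917),
    "frequency": (1, 0.731),
    "sem_neighborhood_density": (1, 0.731),
    "semantic_diversity": (1, 0.731),
    "valence": (2, 0.682),
    "dominance": (2, 0.682),
    "concreteness": (2, -0.682),
    "socialness": (3, 0.619),
    "arousal": (3, 0.619),
}

#: affine output scales per property: (mean, sd, lo, hi, integer)
_SCALES = {
    "n_letters": (7.0, 2.3, 1, None, True),
    "n_phonemes": (6.0, 2.0, 1, None, True),
    "n_phon_neighbors": (8.0, 5.0, 0, None, True),
    "n_orth_neighbors": (6.0, 4.0, 0, None, True),
    "frequency": (4.0, 1.0, 1, 7, False),
    "concreteness": (3.0, 0.8, 1, 5, False),
    "sem_neighborhood_density": (0.5, 0.15, 0, 1, False),
    "semantic_diversity": (1.5, 0.4, 0, 3, False),
    "valence": (5.0, 1.5, 1, 9, False),
    "arousal": (5.0, 1.5, 1, 9, False),
    "dominance": (5.0, 1.5, 1, 9, False),
    "socialness": (3.0, 0.55, 1, 5, False),
}

CLOSED_CLASS = [
    "the", "a", "an", "and", "but", "or", "of", "to", "in", "on", "at",
    "it", "he", "she", "they", "we", "you", "i", "is", "was", "that",
    "this", "with", "for", "not", "his", "her", "as", "be", "have",
]


@dataclass
class SyntheticTruth:
    """Ground truth and calibration record for one generated artifact."""

    seed: int
    loadings: pd.DataFrame | None = None
    variance_split: tuple | None = None
    latents: pd.DataFrame | None = None
    event_latents: pd.DataFrame | None = None
    betas: dict = field(default_factory=dict)
    active_masks: dict = field(default_factory=dict)
    noise: dict = field(default_factory=dict)
    extra: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# lexicon


def gen_lexicon(
    n_words: int = 1000, missing_rate: float = 0.1, seed: int = 0
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Lexicon with a planted 4-factor structure and MCAR missingness.

    Properties are generated as ``loading * latent + unique noise`` on the
    z scale and mapped affinely to realistic norm scales (socialness into
    [1, 5], counts non-negative integers).  The single-parent loading plan
    puts the four factors at ~29/17/16/11% of total variance, matching the
    reported split of the word-property PCA.
    """
    if n_words < 100:
        raise ValueError("n_words must be >= 100")
    if missing_rate >= 0.5:
        raise ValueError("missing_rate must be < 0.5")
    rng = np.random.default_rng(seed)
    latents = rng.standard_normal((n_words, 4))
    z = {}
    for prop in PROPERTIES:
        f, load = _LOADING_PLAN[prop]
        unique_sd = np.sqrt(1.0 - load**2)
        z[prop] = load * latents[:, f] + unique_sd * rng.standard_normal(n_words)

    words = [f"w{i:05d}" for i in range(n_words)]
    table = pd.DataFrame({"word": words})
    for prop in PROPERTIES:
        mean, sd, lo, hi, integer = _SCALES[prop]
        vals = mean + sd * z[prop]
        if integer:
            vals = np.round(vals)
        if lo is not None:
            vals = np.maximum(vals, lo)
        if hi is not None:
            vals = np.minimum(vals, hi)
        table[prop] = vals

    if missing_rate > 0:
        mask = rng.random((n_words, len(PROPERTIES))) < missing_rate
        arr = table[PROPERTIES].to_numpy(float)
        arr[mask] = np.nan
        table[PROPERTIES] = arr

    loadings = np.zeros((len(PROPERTIES), 4))
    for i, prop in enumerate(PROPERTIES):
        f, load = _LOADING_PLAN[prop]
        loadings[i, f] = load
    truth = SyntheticTruth(
        seed=seed,
        loadings=pd.DataFrame(loadings, index=PROPERTIES, columns=FACTOR_NAMES),
        variance_split=VARIANCE_SPLIT,
        latents=pd.DataFrame(latents, columns=FACTOR_NAMES).assign(word=words),
    )
    return table, truth


# ---------------------------------------------------------------------------
# embeddings and social norms


def gen_embeddings(
    lexicon: pd.DataFrame, dim: int = 16, seed: int = 0, noise: float = 0.25
) -> dict[str, np.ndarray]:
    """Embeddings whose cosine neighbourhoods are enriched for socialness.

    Each word's vector interpolates between two orthogonal anchors
    according to its socialness (missing socialness treated as the scale
    midpoint) plus isotropic noise, so words with similar socialness are
    closer in cosine terms than unrelated words.
    """
    if dim < 8:
        raise ValueError("dim must be >= 8")
    rng = np.random.default_rng(seed)
    vecs = {}
    for word, s in zip(lexicon["word"], lexicon["socialness"]):
        s = 3.0 if pd.isna(s) else float(s)
        theta = (s - 1.0) / 4.0 * (np.pi / 2.0)
        base = np.zeros(dim)
        base[0] = np.cos(theta)
        base[1] = np.sin(theta)
        v = base + noise * rng.standard_normal(dim)
        if not v.any():
            v[0] = 1.0
        vecs[word] = v
    return vecs


def gen_social_norms(
    lexicon: pd.DataFrame, n_normed: int = 300, seed: int = 0
) -> pd.DataFrame:
    """Subset of the lexicon posing as the 1-5 socialness norming study."""
    rng = np.random.default_rng(seed)
    have = lexicon.dropna(subset=["socialness"])
    n_normed = min(n_normed, len(have))
    pick = have.sample(n=n_normed, random_state=int(rng.integers(2**31)))
    return pd.DataFrame(
        {
            "word": pick["word"].to_numpy(),
            "mean_rating": np.clip(pick["socialness"].to_numpy(float), 1.0, 5.0),
            "n_raters": 34,
        }
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# events


def gen_events(
    n_events: int = 300,
    seed: int = 0,
    movie_id: str = "sim",
    short_fraction: float = 0.04,
    rating_corr: float = 0.25,
    duration_coupling: float = 0.30,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Event table with the reported duration and rating structure.

    Durations are log-normal (post-merge median ~16 s, clipped into
    [4, 131] s) with ~4% of pre-merge events shorter than 3 s; integer
    semantic and social ratings 1-10 are discretized correlated Gaussians,
    mildly coupled to log duration (longer scenes tend to carry more
    content), respecting the dual-9/10 exclusion.  Events tile the movie
    contiguously from t = 0.
    """
    if not (20 <= n_events <= 1000):
        raise ValueError("n_events outside the supported range [20, 1000]")
    rng = np.random.default_rng(seed)
    short = rng.random(n_events) < short_fraction
    durations = np.where(
        short,
        rng.uniform(1.0, 2.9, n_events),
        np.clip(np.exp(np.log(16.0) + 0.65 * rng.standard_normal(n_events)), 4.0, 131.0),
    )
    onsets = np.concatenate([[0.0], np.cumsum(durations)[:-1]])

    cov = np.array([[1.0, rating_corr], [rating_corr, 1.0]])
    lat = rng.multivariate_normal([0.0, 0.0], cov, size=n_events)
    z_dur = (np.log(durations) - np.log(durations).mean()) / np.log(durations).std()
    lat = duration_coupling * z_dur[:, None] + np.sqrt(1 - duration_coupling**2) * lat
    sem = np.clip(np.round(5.5 + 2.0 * lat[:, 0]), 1, 10)
    soc = np.clip(np.round(5.5 + 2.0 * lat[:, 1]), 1, 10)
    both_max = (sem >= 9) & (soc >= 9)
    # the primary purpose of a scene is either semantic or social: demote
    # the weaker latent to 8
    demote_sem = both_max & (lat[:, 0] <= lat[:, 1])
    demote_soc = both_max & ~demote_sem
    sem[demote_sem] = 8
    soc[demote_soc] = 8

    table = pd.DataFrame(
        {
            "movie_id": movie_id,
            "index": np.arange(n_events),
            "onset": onsets,
            "duration": durations,
            "semantic": sem.astype(float),
            "social": soc.astype(float),
            "is_major": False,
        }
    )
    truth = SyntheticTruth(
        seed=seed,
        event_latents=pd.DataFrame(lat, columns=["semantic_latent", "social_latent"]),
        extra={"short_fraction_target": short_fraction},
    )
    return table, truth


# ---------------------------------------------------------------------------
# transcripts


def gen_transcript(
    events: pd.DataFrame,
    lexicon: pd.DataFrame,
    seed: int = 0,
    words_per_second: float = 0.9,
    open_fraction: float = 0.55,
    sem_coef: float = 0.42,
    soc_coef: float = 0.27,
    noise_sd: float = 0.10,
) -> pd.DataFrame:
    """Transcript whose per-event word counts track duration and ratings.

    The expected word count is ``rate * duration * exp(b_sem z_sem +
    b_soc z_soc + noise)`` with Poisson sampling, calibrated so that the
    empirical correlations of word count with duration, semantic rating
    and social rating fall inside the reported ranges (0.55-0.86,
    0.40-0.76 and 0.32-0.56).  Word onsets are uniform within their
    event; tokens mix open-class draws from the lexicon with a small
    closed-class vocabulary.
    """
    rng = np.random.default_rng(seed)
    sem = events["semantic"].to_numpy(float)
    soc = events["social"].to_numpy(float)
    zs = (sem - sem.mean()) / max(sem.std(), 1e-9)
    zo = (soc - soc.mean()) / max(soc.std(), 1e-9)
    lam = (
        words_per_second
        * events["duration"].to_numpy(float)
        * np.exp(sem_coef * zs + soc_coef * zo + noise_sd * rng.standard_normal(len(events)))
    )
    counts = rng.poisson(lam)

    open_words = lexicon["word"].to_numpy()
    rows = []
    for (_, ev), n in zip(events.iterrows(), counts):
        if n == 0:
            continue
        onsets = np.sort(rng.uniform(ev["onset"], ev["onset"] + ev["duration"], n))
        is_open = rng.random(n) < open_fraction
        toks = np.where(
            is_open,
            rng.choice(open_words, n),
            rng.choice(CLOSED_CLASS, n),
        )
        for t, tok, op in zip(onsets, toks, is_open):
            rows.append(
                {
                    "movie_id": ev["movie_id"],
                    "word": tok,
                    "onset": float(t),
                    "duration": 0.3,
                    "pos": "open" if op else "closed",
                }
            )
    return pd.DataFrame(rows, columns=["movie_id", "word", "onset", "duration", "pos"])


# ---------------------------------------------------------------------------
# BOLD forward model


def sphere_mask(shape: tuple[int, int, int], center, radius: float) -> np.ndarray:
    grid = np.indices(shape).astype(float)
    dist2 = sum((grid[i] - center[i]) ** 2 for i in range(3))
    return dist2 <= radius**2


def gen_bold(
    regressors: list[Regressor],
    beta_maps: dict[str, np.ndarray],
    shape: tuple[int, int, int] = (16, 16, 16),
    tr: float = 1.0,
    ar1: float = 0.3,
    fwhm_mm: float = 4.0,
    noise_sd: float = 1.0,
    voxel_size: float = 2.0,
    seed: int = 0,
) -> tuple[BoldImage, SyntheticTruth]:
    """BOLD forward model: known betas times regressors plus AR(1) noise.

    ``beta_maps`` maps regressor names to 3D beta volumes (missing names
    get zero effect).  Noise is AR(1) over time per voxel, spatially
    smoothed at ``fwhm_mm`` per volume, and rescaled to ``noise_sd``.
    """
    n_t = len(regressors[0].samples)
    data = np.zeros(shape + (n_t,))
    for reg in regressors:
        beta = beta_maps.get(reg.name)
        if beta is None:
            continue
        data += beta[..., None] * reg.samples[None, None, None, :]

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        eps = rng.standard_normal(shape + (n_t,))
        if fwhm_mm > 0:
            sigma_vox = fwhm_mm / (np.sqrt(8 * np.log(2)) * voxel_size)
            eps = ndimage.gaussian_filter(eps, sigma=(sigma_vox,) * 3 + (0,))
        noise = np.empty_like(eps)
        noise[..., 0] = eps[..., 0]
        for t in range(1, n_t):
            noise[..., t] = ar1 * noise[..., t - 1] + eps[..., t]
        noise *= noise_sd / noise.std()
        data += noise

    mask = np.ones(shape, dtype=bool)
    truth = SyntheticTruth(
        seed=seed,
        betas={k: v.copy() for k, v in beta_maps.items()},
        active_masks={k: v != 0 for k, v in beta_maps.items()},
        noise={"ar1": ar1, "fwhm_mm": fwhm_mm, "sd": noise_sd},
    )
    return BoldImage(data, tr, mask, voxel_size), truth
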