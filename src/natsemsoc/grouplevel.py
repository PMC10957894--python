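"""Group-level inference: voxelwise mixed-effects maps over subject images
and Monte-Carlo cluster-extent familywise-error correction.

Each subject contributes one statistic map and watched exactly one movie,
so the group model at every voxel is an intercept-only linear mixed model
with a random movie intercept (the subject intercept is not separately
identifiable from the residual with one observation per subject and is
absorbed by it).  Variance components are estimated by REML with the
movie variance bounded at zero, and the fixed-effect test statistic is
converted to a z value.  Cluster-extent correction simulates smooth
Gaussian null fields inside the analysis mask, thresholds them at the
cluster-forming quantile, and takes the (1 - p_FWE) quantile of the
maximum cluster size as the minimum surviving extent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .firstlevel import SmoothnessEstimate, StatMap

Z_CAP = 40.0

#: faces-only (NN=1) 3D connectivity
FACES_STRUCT = ndimage.generate_binary_structure(3, 1)


@dataclass
class GroupDesign:
    subjects: list[str]
    movies: dict[str, str]  # subject -> movie
    content_type: str = ""

    def __post_init__(self) -> None:
        missing = [s for s in self.subjects if s not in self.movies]
        if missing:
            raise ValueError(f"subjects without a movie assignment: {missing}")

    @property
    def movie_labels(self) -> np.ndarray:
        return np.array([self.movies[s] for s in self.subjects])


@dataclass
class ClusterRule:
    cluster_forming_p: float = 0.01
    fwe_p: float = 0.05
    voxel_size: float = 2.0
    sidedness: str = "two"  # forming threshold applied two-sided

    def __post_init__(self) -> None:
        if not (0 < self.cluster_forming_p < 1 and 0 < self.fwe_p < 1):
            raise ValueError("thresholds must lie in (0, 1)")

    def forming_z(self) -> float:
        if self.sidedness == "two":
            return float(stats.norm.isf(self.cluster_forming_p / 2))
        return float(stats.norm.isf(self.cluster_forming_p))


# ---------------------------------------------------------------------------
# mixed-effects group map


def _reml_profile(
    ybar: np.ndarray, ssw: np.ndarray, n_j: np.ndarray, lam: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Profiled REML pieces at a fixed variance ratio lambda.

    Returns (criterion, mu, Q) per voxel, where the criterion is
    -2 l_REML up to a constant and Q the GLS residual sum of squares.
    """
    n_total = int(n_j.sum())
    w = n_j / (1.0 + lam * n_j)  # (J,)
    sw = w.sum()
    mu = (w @ ybar) / sw  # (V,)
    dev = ybar - mu[None, :]
    q = ssw + (w[:, None] * dev**2).sum(axis=0)
    crit = (
        (n_total - 1) * np.log(np.maximum(q, 1e-300))
        + np.sum(np.log1p(lam * n_j))
        + np.log(sw)
    )
    return crit, mu, q


def fit_group_map(
    maps: list[StatMap],
    design: GroupDesign,
    lambda_grid: np.ndarray | None = None,
) -> StatMap:
    """Voxelwise REML mixed model with a movie random intercept.

    ``maps`` holds one subject-level map per subject, all on a common grid.
    The variance ratio sigma_movie^2 / sigma_resid^2 is profiled on a
    (log-spaced) grid including zero and minimized voxelwise; the
    fixed-effect statistic is referenced against a t distribution (df =
    number of movies - 1 when movie variance is positive, subjects - 1
    otherwise) and converted to a two-sided-equivalent z value, capped at
    +/- 40 for degenerate voxels.
    """
    if len(maps) < 3:
        raise ValueError("need at least 3 subject maps")
    if len(maps) != len(design.subjects):
        raise ValueError("one map per subject required")
    shape = maps[0].data.shape
    for m in maps[1:]:
        if m.data.shape != shape:
            raise ValueError("subject maps must share a common grid")
    mask = maps[0].mask
    Y = np.stack([m.data[mask] for m in maps])  # (S, V)
    movies = design.movie_labels
    uniq, codes = np.unique(movies, return_inverse=True)
    J = len(uniq)
    n_j = np.bincount(codes).astype(float)
    S = len(maps)

    group_sums = np.zeros((J, Y.shape[1]))
    np.add.at(group_sums, codes, Y)
    ybar = group_sums / n_j[:, None]
    ssw = ((Y - ybar[codes]) ** 2).sum(axis=0)

    if lambda_grid is None:
        lambda_grid = np.concatenate([[0.0], np.logspace(-4, 3, 60)])
    if J < 2:
        lambda_grid = np.array([0.0])

    crits = np.empty((len(lambda_grid), Y.shape[1]))
    for i, lam in enumerate(lambda_grid):
        crits[i], _, _ = _reml_profile(ybar, ssw, n_j, float(lam))
    best = np.argmin(crits, axis=0)

    mu = np.empty(Y.shape[1])
    q = np.empty(Y.shape[1])
    lam_hat = lambda_grid[best]
    for i, lam in enumerate(lambda_grid):
        sel = best == i
        if not sel.any():
            continue
        _, mu_i, q_i = _reml_profile(ybar[:, sel], ssw[sel], n_j, float(lam))
        mu[sel], q[sel] = mu_i, q_i

    sigma2 = q / (S - 1)
    w_sum = np.array(
        [np.sum(n_j / (1.0 + lam * n_j)) for lam in lam_hat]
    )
    se = np.sqrt(sigma2 / w_sum)
    # effective df: Satterthwaite-style blend between the movie-level df
    # (J - 1) and the residual df (S - J), weighted by the share c of the
    # intercept variance contributed by the movie component
    if J < 2 or len(lambda_grid) == 1:
        df = np.full(Y.shape[1], float(S - 1))
    else:
        w_sq = np.array(
            [np.sum((n_j / (1.0 + lam * n_j)) ** 2) for lam in lam_hat]
        )
        c = np.clip(lam_hat * w_sq / w_sum, 0.0, 1.0)
        df = 1.0 / (c**2 / max(J - 1, 1) + (1 - c) ** 2 / max(S - J, 1))

    with np.errstate(divide="ignore", invalid="ignore"):
        tval = np.where(se > 0, mu / np.where(se > 0, se, 1.0), np.sign(mu) * np.inf)
    degenerate = ~np.isfinite(tval) | (np.abs(tval) > 1e8)
    if (degenerate & (mu != 0)).any():
        warnings.warn(
            f"{int((degenerate & (mu != 0)).sum())} voxels with zero residual "
            f"variance and nonzero mean; z capped at +/-{Z_CAP}"
        )
    # t -> z preserving the two-sided p-value
    logp = stats.t.logsf(np.abs(np.where(degenerate, 0.0, tval)), df)
    z = np.sign(tval) * stats.norm.isf(np.exp(logp))
    z = np.where(degenerate, np.sign(mu) * Z_CAP, z)
    z = np.clip(z, -Z_CAP, Z_CAP)

    out = np.zeros(shape)
    out[mask] = z
    return StatMap(
        out,
        "z",
        float(np.median(df)),
        mask,
        maps[0].voxel_size,
        {
            "model": "movie random intercept (REML)",
            "n_subjects": S,
            "n_movies": J,
            "mu": mu,
            "se": se,
            "lambda": lam_hat,
        },
    )


# ---------------------------------------------------------------------------
# Monte-Carlo cluster-extent threshold


def _max_cluster_size(field: np.ndarray, mask: np.ndarray, z_crit: float) -> int:
    """Largest sign-separated supra-threshold cluster under NN=1."""
    best = 0
    for signed in (field >= z_crit, field <= -z_crit):
        lab, n = ndimage.label(signed & mask, structure=FACES_STRUCT)
        if n:
            best = max(best, int(np.bincount(lab.ravel())[1:].max()))
    return best


def cluster_size_threshold(
    smoothness: SmoothnessEstimate,
    mask: np.ndarray,
    rule: ClusterRule,
    n_sim: int = 2000,
    seed: int = 0,
) -> int:
    """Minimum cluster extent controlling FWE by Monte-Carlo simulation.

    Simulates ``n_sim`` Gaussian null fields smoothed at the estimated
    FWHM inside the mask, thresholds each (two-sided) at the
    cluster-forming quantile, and records the maximum cluster size.  The
    returned extent is the smallest k such that the fraction of null
    fields with a cluster of at least k voxels does not exceed the
    nominal FWE level.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    sigma_vox = smoothness.fwhm / (np.sqrt(8 * np.log(2)) * rule.voxel_size)
    if smoothness.mean < rule.voxel_size / 2:
        warnings.warn("estimated smoothness below half a voxel; simulating unsmoothed")
        sigma_vox = np.zeros(3)
    rng = np.random.default_rng(seed)
    z_crit = rule.forming_z()
    max_sizes = np.empty(n_sim, dtype=int)
    for s in range(n_sim):
        field = rng.standard_normal(mask.shape)
        if sigma_vox.max() > 0:
            field = ndimage.gaussian_filter(field, sigma=sigma_vox)
        inside = field[mask]
        field = (field - inside.mean()) / inside.std()
        max_sizes[s] = _max_cluster_size(field, mask, z_crit)
    # smallest k with P(max >= k) <= fwe_p
    for k in range(1, max_sizes.max() + 2):
        if np.mean(max_sizes >= k) <= rule.fwe_p:
            return k
    return int(max_sizes.max() + 1)


def apply_cluster_threshold(
    stat_map: StatMap, rule: ClusterRule, k_min: int
) -> tuple[StatMap, pd.DataFrame]:
    """Zero sub-threshold voxels and clusters smaller than ``k_min``.

    The forming threshold is the two-sided quantile of the map's own
    statistic (t with the map's df, or normal for z maps).  Connected
    components are labelled under faces-only adjacency separately for
    positive and negative excursions.  Returns the thresholded map and a
    cluster table (size, peak coordinate, peak value), positives first,
    larger clusters first.
    """
    if k_min < 1:
        raise ValueError("k_min must be >= 1")
    if stat_map.kind == "t":
        crit = float(stats.t.isf(rule.cluster_forming_p / 2, stat_map.df))
    else:
        crit = rule.forming_z()
    data = stat_map.data
    out = np.zeros_like(data)
    rows = []
    for sign in (1.0, -1.0):
        supra = (sign * data >= crit) & stat_map.mask
        lab, n = ndimage.label(supra, structure=FACES_STRUCT)
        for c in range(1, n + 1):
            voxels = lab == c
            size = int(voxels.sum())
            if size < k_min:
                continue
            out[voxels] = data[voxels]
            peak_flat = np.argmax(sign * np.where(voxels, data, -np.inf * sign))
            peak = np.unravel_index(peak_flat, data.shape)
            rows.append(
                {
                    "cluster_size": size,
                    "sign": "positive" if sign > 0 else "negative",
                    "peak_x": peak[0],
                    "peak_y": peak[1],
                    "peak_z": peak[2],
                    "peak_value": float(data[peak]),
                }
            )
    table = pd.DataFrame(
        rows,
        columns=["cluster_size", "sign", "peak_x", "peak_y", "peak_z", "peak_value"],
    ).sort_values(
        ["sign", "cluster_size"], ascending=[False, False]
    ).reset_index(drop=True)
    thresholded = StatMap(
        out,
        stat_map.kind,
        stat_map.df,
        stat_map.mask,
        stat_map.voxel_size,
        {**stat_map.meta, "k_min": k_min, "forming_crit": crit},
    )
    return thresholded, table
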