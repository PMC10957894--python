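"""Subject-level parametric-modulation GLMs on movie BOLD time series.

Window series (word-level predictors) and event ratings (event-level
predictors) are turned into regressors by placing impulses or boxcars on a
fine 0.1 s grid, convolving with a canonical double-gamma hemodynamic
response, and sampling at the TR grid.  Modulator amplitudes are
mean-centered so that "stimulus intensity" is decorrelated from "stimulus
on", and event models carry an unmodulated baseline boxcar plus the other
rating as a nuisance modulator.  Voxelwise OLS yields beta and t maps, and
the residuals give Gaussian-equivalent smoothness (FWHM) estimates used by
the cluster-extent Monte Carlo.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .timecourse import WindowSeries

FINE_DT = 0.1  # convolution grid, s
HRF_PEAK_S = 5.0
HRF_UNDERSHOOT_S = 15.0
HRF_LENGTH_S = 32.0


@dataclass
class Regressor:
    name: str
    samples: np.ndarray  # length n_volumes
    kind: str = "amplitude"  # amplitude | duration | nuisance | baseline

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError(f"regressor {self.name!r} has non-finite samples")


@dataclass
class BoldImage:
    """4D BOLD array with its acquisition metadata."""

    data: np.ndarray  # (x, y, z, t)
    tr: float
    mask: np.ndarray  # (x, y, z) bool
    voxel_size: float = 2.0  # mm, isotropic
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise ValueError("TR must be positive")
        if self.mask.shape != self.data.shape[:3]:
            raise ValueError("mask shape must match the spatial dimensions")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]


@dataclass
class StatMap:
    """3D statistic image with the metadata cluster inference needs."""

    data: np.ndarray
    kind: str  # t | z | beta
    df: float
    mask: np.ndarray
    voxel_size: float = 2.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        inside = self.data[self.mask]
        if inside.size and not np.all(np.isfinite(inside)):
            raise ValueError("statistic values inside the mask must be finite")
        self.data = np.where(self.mask, self.data, 0.0)


@dataclass
class SmoothnessEstimate:
    fwhm: np.ndarray  # (3,) mm

    def __post_init__(self) -> None:
        self.fwhm = np.asarray(self.fwhm, dtype=float)
        if not np.all(np.isfinite(self.fwhm)) or np.any(self.fwhm < 0):
            raise ValueError("FWHM estimates must be finite and non-negative")

    @property
    def mean(self) -> float:
        return float(self.fwhm.mean())


# ---------------------------------------------------------------------------
# HRF and regressor construction


def canonical_hrf(
    dt: float,
    peak: float = HRF_PEAK_S,
    undershoot: float = HRF_UNDERSHOOT_S,
    length: float = HRF_LENGTH_S,
    undershoot_ratio: float = 6.0,
) -> np.ndarray:
    """Double-gamma HRF sampled at ``dt``, unit peak, truncated at 32 s."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    t = np.arange(0.0, length, dt)
    # gamma densities parameterized by their mode (= peak time)
    def gamma_pdf(mode: float, disp: float) -> np.ndarray:
        shape = 1.0 + mode / disp
        return stats.gamma.pdf(t, a=shape, scale=disp)

    h = gamma_pdf(peak, 1.0) - gamma_pdf(undershoot, 1.0) / undershoot_ratio
    return h / h.max()


def _convolve_and_sample(
    fine: np.ndarray, tr: float, n_volumes: int, hrf_kwargs: dict | None = None
) -> np.ndarray:
    kernel = canonical_hrf(FINE_DT, **(hrf_kwargs or {}))
    conv = np.convolve(fine, kernel)[: len(fine)]
    idx = np.round(np.arange(n_volumes) * tr / FINE_DT).astype(int)
    return conv[idx]


def parametric_regressor(
    series: WindowSeries,
    tr: float,
    n_volumes: int,
    name: str = "modulator",
    hrf_kwargs: dict | None = None,
) -> Regressor:
    """Window-series parametric modulator sampled at the TR grid.

    Values are mean-centered over the retained windows, placed as impulses
    at the window-start times on a 0.1 s grid, convolved with the canonical
    HRF and sampled at the TR grid.
    """
    starts = series.samples["window_start"].to_numpy(float)
    scan_len = n_volumes * tr
    if np.any(starts >= scan_len) or np.any(starts < 0):
        raise ValueError("window times extend beyond the scan")
    values = series.values - series.values.mean()
    n_fine = int(np.ceil(scan_len / FINE_DT)) + 1
    fine = np.zeros(n_fine)
    np.add.at(fine, np.round(starts / FINE_DT).astype(int), values)
    return Regressor(name, _convolve_and_sample(fine, tr, n_volumes, hrf_kwargs))


def duration_modulated_regressor(
    table: pd.DataFrame,
    which: str,
    tr: float,
    n_volumes: int,
    hrf_kwargs: dict | None = None,
) -> list[Regressor]:
    """Duration-modulated event model: baseline, modulated, and nuisance.

    Three regressors built from boxcars spanning each event's duration:
    an unmodulated baseline, a boxcar scaled by the mean-centered rating of
    interest (``which`` = 'semantic' or 'social'), and a boxcar scaled by
    the mean-centered *other* rating as a nuisance covariate.
    """
    if which not in ("semantic", "social"):
        raise ValueError("which must be 'semantic' or 'social'")
    other = "social" if which == "semantic" else "semantic"
    scan_len = n_volumes * tr
    n_fine = int(np.ceil(scan_len / FINE_DT)) + 1

    onsets = table["onset"].to_numpy(float)
    durations = table["duration"].to_numpy(float)
    mod = table[which].to_numpy(float)
    nui = table[other].to_numpy(float)
    mod = mod - mod.mean()
    nui = nui - nui.mean()

    def boxcars(amplitudes: np.ndarray) -> np.ndarray:
        fine = np.zeros(n_fine)
        for onset, dur, amp in zip(onsets, durations, amplitudes):
            lo = int(np.round(onset / FINE_DT))
            hi = min(int(np.round((onset + dur) / FINE_DT)), n_fine)
            fine[lo:hi] += amp
        return fine

    return [
        Regressor(
            "baseline",
            _convolve_and_sample(boxcars(np.ones_like(mod)), tr, n_volumes, hrf_kwargs),
            kind="baseline",
        ),
        Regressor(
            f"{which}_modulated",
            _convolve_and_sample(boxcars(mod), tr, n_volumes, hrf_kwargs),
            kind="duration",
        ),
        Regressor(
            f"{other}_nuisance",
            _convolve_and_sample(boxcars(nui), tr, n_volumes, hrf_kwargs),
            kind="nuisance",
        ),
    ]


# ---------------------------------------------------------------------------
# GLM fit


def fit_first_level(
    bold: BoldImage,
    regressors: list[Regressor],
    drift_order: int = 0,
    censor: np.ndarray | None = None,
) -> dict[str, dict[str, StatMap]]:
    """Voxelwise OLS of the BOLD series on the regressor set.

    Polynomial drift columns up to ``drift_order`` are appended (order 0 =
    intercept only; the input is assumed pre-detrended upstream).  An
    optional ``censor`` vector (1 = keep) drops motion-censored volumes.
    Returns ``{regressor_name: {"beta": StatMap, "t": StatMap}}`` for the
    non-baseline/nuisance regressors, with residuals attached under the
    ``"_residuals"`` key of each map's ``meta``.
    """
    n_t = bold.n_volumes
    for r in regressors:
        if len(r.samples) != n_t:
            raise ValueError(f"regressor {r.name!r} length != n_volumes")
    t_norm = np.linspace(-1.0, 1.0, n_t)
    drift = np.column_stack([t_norm**p for p in range(drift_order + 1)])
    X = np.column_stack([r.samples for r in regressors] + [drift])
    names = [r.name for r in regressors] + [f"drift{p}" for p in range(drift_order + 1)]

    keep = np.ones(n_t, dtype=bool) if censor is None else censor.astype(bool)
    X = X[keep]
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the columns whose removal restores full rank
        collinear = []
        for j in range(X.shape[1]):
            others = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(others) == rank:
                collinear.append(names[j])
        raise ValueError(f"rank-deficient design; collinear columns: {collinear}")

    Y = bold.data[bold.mask].T[keep]  # (t, v)
    beta, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    dof = X.shape[0] - X.shape[1]
    sigma2 = (resid**2).sum(axis=0) / dof
    xtx_inv = np.linalg.inv(X.T @ X)

    resid_img = np.zeros(bold.data.shape[:3] + (resid.shape[0],))
    resid_img[bold.mask] = resid.T

    out: dict[str, dict[str, StatMap]] = {}
    interest = [
        (i, r.name) for i, r in enumerate(regressors) if r.kind in ("amplitude", "duration")
    ]
    if not interest:  # fall back to every supplied regressor
        interest = [(i, r.name) for i, r in enumerate(regressors)]
    for i, name in interest:
        se = np.sqrt(sigma2 * xtx_inv[i, i])
        with np.errstate(divide="ignore", invalid="ignore"):
            tval = np.where(se > 0, beta[i] / np.where(se > 0, se, 1.0), 0.0)
        beta_map = np.zeros(bold.data.shape[:3])
        t_map = np.zeros(bold.data.shape[:3])
        beta_map[bold.mask] = beta[i]
        t_map[bold.mask] = tval
        meta = {"_residuals": resid_img, "regressor": name}
        out[name] = {
            "beta": StatMap(beta_map, "beta", dof, bold.mask, bold.voxel_size, meta),
            "t": StatMap(t_map, "t", dof, bold.mask, bold.voxel_size, dict(meta)),
        }
    return out


# ---------------------------------------------------------------------------
# smoothness


def estimate_smoothness(
    residuals: np.ndarray, mask: np.ndarray, voxel_size: float = 2.0
) -> SmoothnessEstimate:
    """Gaussian-equivalent FWHM per axis from first-level residuals.

    Residuals are standardized per voxel over time; along each axis the
    variance of spatial first differences estimates the squared gradient of
    the standardized field, whose reciprocal gives the equivalent Gaussian
    kernel width: ``sigma^2 = d^2 / (2 var_diff)`` for voxel spacing ``d``.
    For fields much smoother than the grid this recovers the width of the
    Gaussian kernel that would produce them from white noise; for white
    noise itself it returns roughly 1.18 voxels.
    """
    if residuals.ndim != 4:
        raise ValueError("residuals must be a 4D (x, y, z, t) array")
    if residuals.shape[3] < 10:
        raise ValueError("need >= 10 time points to estimate smoothness")
    if mask.sum() < 100:
        raise ValueError("mask too small (< 100 voxels) for smoothness estimation")
    sd = residuals.std(axis=3, ddof=1)
    sd[sd == 0] = 1.0
    z = (residuals - residuals.mean(axis=3, keepdims=True)) / sd[..., None]

    fwhm = np.zeros(3)
    for axis in range(3):
        m_pair = mask & np.roll(mask, -1, axis=axis)
        # exclude the wrap-around face
        sl = [slice(None)] * 3
        sl[axis] = slice(-1, None)
        m_pair[tuple(sl)] = False
        if m_pair.sum() < 10:
            fwhm[axis] = 0.0
            continue
        diff = np.roll(z, -1, axis=axis) - z
        var_diff = np.mean(diff[m_pair] ** 2)
        var_z = np.mean(z[mask] ** 2)  # ~ (T-1)/T after per-voxel standardization
        if var_diff <= 0:
            fwhm[axis] = 0.0
            continue
        sigma2 = voxel_size**2 * var_z / (2.0 * var_diff)
        fwhm[axis] = np.sqrt(8.0 * np.log(2.0) * sigma2)
    return SmoothnessEstimate(fwhm)
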