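"""Orchestration: configuration, the three analysis drivers (words,
events, overlap), study simulation, provenance, and the sensitivity power
computation.

The drivers wire the stage modules together exactly as the study design
prescribes: word/event predictors -> subject-level parametric-modulation
GLMs -> mixed-effects group map -> Monte-Carlo cluster-extent FWE
(pre-registered p<.05 and strict p<.01 variants) -> overlap
quantification.  ``simulate_study`` builds a complete synthetic dataset
through the pipeline's own forward model so every driver can run and be
validated without the original neuroimaging data.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import lexfeatures, synthdata
from .events import merge_short_events, scramble_ratings, validate_events
from .firstlevel import (
    BoldImage,
    Regressor,
    SmoothnessEstimate,
    StatMap,
    duration_modulated_regressor,
    estimate_smoothness,
    fit_first_level,
    parametric_regressor,
)
from .grouplevel import (
    ClusterRule,
    GroupDesign,
    apply_cluster_threshold,
    cluster_size_threshold,
    fit_group_map,
)
from .overlapnet import (
    group_overlap_rfx,
    network_dice_report,
    normalize_stat_map,
    overlap_voxels,
    statistical_overlap_map,
)
from .timecourse import WindowSeries, drop_empty, residualize, window_sums

WORD_CONTENT_TYPES = ("content_words", "semantic_flexibility", "social_impact")
EVENT_CONTENT_TYPES = ("semantic_events", "social_events")

_FACTOR_OF_CONTENT = {
    "semantic_flexibility": "SemanticFlexibility",
    "social_impact": "SocialImpact",
}


@dataclass
class PipelineConfig:
    """All tunables of a run, defaulting to the study's values."""

    tr: float = 1.0
    window_s: float = 5.0
    step_s: float = 1.0
    merge_min_duration_s: float = 3.0
    cluster_forming_p: float = 0.01
    fwe_p: float = 0.05
    strict_fwe_p: float = 0.01
    voxel_size_mm: float = 2.0
    n_sim_cluster: int = 1000
    n_sim_cluster_subject: int = 200
    m_imputations: int = 5
    imputation_iters: int = 5
    seed: int = 0

    def rule(self, strict: bool = False) -> ClusterRule:
        return ClusterRule(
            cluster_forming_p=self.cluster_forming_p,
            fwe_p=self.strict_fwe_p if strict else self.fwe_p,
            voxel_size=self.voxel_size_mm,
        )

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


@dataclass
class SyntheticStudy:
    """A complete synthetic dataset plus its ground truth."""

    lexicon: pd.DataFrame
    lexicon_truth: synthdata.SyntheticTruth
    social_norms: pd.DataFrame
    embeddings: dict[str, np.ndarray]
    events: dict[str, pd.DataFrame]  # movie -> raw (pre-merge) events
    transcripts: dict[str, pd.DataFrame]
    bold: dict[str, BoldImage]  # subject -> BOLD
    design: GroupDesign
    n_volumes: dict[str, int]  # movie -> volumes
    truth: synthdata.SyntheticTruth
    config: PipelineConfig


@dataclass
class AnalysisResult:
    """Subject- and group-level outputs of one content analysis."""

    content: str
    subject_tmaps: dict[str, StatMap]
    subject_smoothness: dict[str, SmoothnessEstimate]
    group_z: StatMap
    k_min: int
    thresholded: StatMap
    cluster_table: pd.DataFrame
    strict_k_min: int | None = None
    strict_thresholded: StatMap | None = None
    strict_cluster_table: pd.DataFrame | None = None
    provenance: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# sensitivity power analysis


@dataclass
class SensitivitySpec:
    u: int
    n: int
    alpha: float
    power: float
    f2: float

    @property
    def v(self) -> int:
        return self.n - self.u - 1


def sensitivity_f2(
    u: int, n: int, alpha: float = 0.05, power: float = 0.95
) -> SensitivitySpec:
    """Smallest Cohen's f² detectable by the omnibus F test.

    Solves for the effect size f² = R²/(1-R²) at which an F test with
    numerator df ``u``, denominator df ``v = n - u - 1`` and noncentrality
    ``f² (u + v + 1)`` reaches the target power at level ``alpha``, using
    the exact noncentral F distribution (root found to 1e-6).
    """
    if n <= u + 1:
        raise ValueError("need n > u + 1")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    v = n - u - 1
    crit = stats.f.isf(alpha, u, v)

    def achieved(f2: float) -> float:
        return stats.ncf.sf(crit, u, v, f2 * (u + v + 1)) - power

    hi = 1.0
    while achieved(hi) < 0:
        hi *= 2
        if hi > 1e6:
            raise ValueError("target power unattainable")
    f2 = optimize.brentq(achieved, 1e-12, hi, xtol=1e-6)
    return SensitivitySpec(u=u, n=n, alpha=alpha, power=power, f2=float(f2))


# ---------------------------------------------------------------------------
# predictor construction shared by simulation and analysis


def _word_value_series(
    transcript: pd.DataFrame,
    merged_events: pd.DataFrame,
    word_values: dict[str, float] | None,
    config: PipelineConfig,
) -> WindowSeries:
    """Window sums of per-word values (1/word if ``word_values`` is None)."""
    if word_values is None:
        values = np.ones(len(transcript))
        keep = transcript["pos"].to_numpy() == "open"
    else:
        values = transcript["word"].map(word_values).to_numpy(float)
        keep = ~np.isnan(values)
    wv = pd.DataFrame(
        {"onset": transcript["onset"].to_numpy(float)[keep], "value": values[keep]}
    )
    return window_sums(wv, merged_events, window=config.window_s, step=config.step_s)


def _total_word_counts(
    transcript: pd.DataFrame, merged_events: pd.DataFrame, config: PipelineConfig
) -> WindowSeries:
    wv = pd.DataFrame(
        {"onset": transcript["onset"].to_numpy(float), "value": np.ones(len(transcript))}
    )
    return window_sums(wv, merged_events, window=config.window_s, step=config.step_s)


def build_word_regressor(
    transcript: pd.DataFrame,
    merged_events: pd.DataFrame,
    word_values: dict[str, float] | None,
    config: PipelineConfig,
    n_volumes: int,
    name: str,
    residualize_on_counts: bool = True,
) -> "Regressor":
    """Word-level parametric modulator for one movie.

    Factor predictors (``word_values`` given) are residualized on the
    total word count per window and empty windows dropped; the
    content-word count predictor (``word_values`` None) keeps zero-count
    windows, which are meaningful.
    """
    series = _word_value_series(transcript, merged_events, word_values, config)
    if word_values is not None:
        if residualize_on_counts:
            counts = _total_word_counts(transcript, merged_events, config)
            series = residualize(series, counts)
        series = drop_empty(series)
    return parametric_regressor(series, config.tr, n_volumes, name=name)


# ---------------------------------------------------------------------------
# study simulation


def simulate_study(
    n_subjects: int = 8,
    n_movies: int = 2,
    n_events: int = 60,
    n_words_lexicon: int = 400,
    shape: tuple[int, int, int] = (12, 12, 12),
    effects: dict[str, float] | None = None,
    effect_centers: dict[str, tuple[int, int, int]] | None = None,
    effect_radius: float = 2.5,
    noise_sd: float = 1.0,
    ar1: float = 0.3,
    noise_fwhm_mm: float = 4.0,
    missing_rate: float = 0.1,
    seed: int = 0,
    config: PipelineConfig | None = None,
) -> SyntheticStudy:
    """Generate a full synthetic study through the pipeline's forward model.

    ``effects`` maps content types (``content_words``,
    ``semantic_flexibility``, ``social_impact``, ``semantic_events``,
    ``social_events``) to effect sizes expressed as signal-sd over
    noise-sd; each effect activates a small sphere whose mask is recorded
    in the truth.  Word-level forward regressors are built from the
    lexicon's *true* latent factors, so recovering them via the estimated
    factor scores is a genuine test.
    """
    config = config or PipelineConfig(seed=seed)
    effects = effects or {}
    rng = np.random.default_rng(seed)

    lexicon, lex_truth = synthdata.gen_lexicon(
        n_words_lexicon, missing_rate=missing_rate, seed=seed
    )
    social = synthdata.gen_social_norms(lexicon, seed=seed + 1)
    embeddings = synthdata.gen_embeddings(lexicon, seed=seed + 2)
    latents = lex_truth.latents.set_index("word")

    movies = [f"movie{m:02d}" for m in range(n_movies)]
    events: dict[str, pd.DataFrame] = {}
    transcripts: dict[str, pd.DataFrame] = {}
    n_volumes: dict[str, int] = {}
    movie_regressors: dict[str, dict[str, Regressor]] = {}

    truth = synthdata.SyntheticTruth(seed=seed)
    truth.noise = {"sd": noise_sd, "ar1": ar1, "fwhm_mm": noise_fwhm_mm}

    centers = dict(effect_centers or {})
    for i, content in enumerate(sorted(effects)):
        if content not in centers:
            # well-separated spheres on the grid diagonal
            frac = (i + 1) / (len(effects) + 1)
            centers[content] = tuple(int(round(frac * (s - 1))) for s in shape)
        truth.active_masks[content] = synthdata.sphere_mask(
            shape, centers[content], effect_radius
        )

    for movie in movies:
        ev, _ = synthdata.gen_events(
            n_events, seed=seed + 10 + hash(movie) % 1000, movie_id=movie
        )
        events[movie] = ev
        merged = merge_short_events(ev, config.merge_min_duration_s)
        tr_df = synthdata.gen_transcript(
            merged, lexicon, seed=seed + 20 + hash(movie) % 1000
        )
        transcripts[movie] = tr_df
        total_s = float(merged["onset"].iloc[-1] + merged["duration"].iloc[-1])
        n_vol = int(np.ceil((total_s + 24.0) / config.tr))
        n_volumes[movie] = n_vol

        regs: dict[str, Regressor] = {}
        for content in effects:
            if content in EVENT_CONTENT_TYPES:
                which = "semantic" if content == "semantic_events" else "social"
                base, mod, _ = duration_modulated_regressor(
                    merged, which, config.tr, n_vol
                )
                regs[content] = Regressor(content, mod.samples, kind="duration")
            else:
                if content == "content_words":
                    word_values = None
                else:
                    fac = _FACTOR_OF_CONTENT[content]
                    word_values = latents[fac].to_dict()
                reg = build_word_regressor(
                    tr_df, merged, word_values, config, n_vol, name=content
                )
                regs[content] = reg
        movie_regressors[movie] = regs

    subjects = [f"sub-{i:02d}" for i in range(n_subjects)]
    assignment = {s: movies[i % n_movies] for i, s in enumerate(subjects)}
    design = GroupDesign(subjects=subjects, movies=assignment)

    bold: dict[str, BoldImage] = {}
    for i, sub in enumerate(subjects):
        movie = assignment[sub]
        regs = movie_regressors[movie]
        beta_maps = {}
        for content, reg in regs.items():
            reg_sd = reg.samples.std()
            amp = effects[content] * noise_sd / max(reg_sd, 1e-12)
            beta_maps[content] = np.where(truth.active_masks[content], amp, 0.0)
            truth.betas.setdefault(content, amp)
        img, _ = synthdata.gen_bold(
            list(regs.values()),
            beta_maps,
            shape=shape,
            tr=config.tr,
            ar1=ar1,
            fwhm_mm=noise_fwhm_mm,
            noise_sd=noise_sd,
            voxel_size=config.voxel_size_mm,
            seed=seed + 1000 + i,
        )
        bold[sub] = img

    truth.extra["effect_centers"] = centers
    return SyntheticStudy(
        lexicon=lexicon,
        lexicon_truth=lex_truth,
        social_norms=social,
        embeddings=embeddings,
        events=events,
        transcripts=transcripts,
        bold=bold,
        design=design,
        n_volumes=n_volumes,
        truth=truth,
        config=config,
    )


# ---------------------------------------------------------------------------
# analysis drivers


def _group_and_threshold(
    content: str,
    subject_tmaps: dict[str, StatMap],
    smoothness: dict[str, SmoothnessEstimate],
    design: GroupDesign,
    config: PipelineConfig,
    seed_offset: int = 0,
) -> AnalysisResult:
    maps = [subject_tmaps[s] for s in design.subjects]
    group_z = fit_group_map(maps, design)
    med_fwhm = SmoothnessEstimate(
        np.median(np.stack([smoothness[s].fwhm for s in design.subjects]), axis=0)
    )
    mask = maps[0].mask
    rule = config.rule()
    k_min = cluster_size_threshold(
        med_fwhm, mask, rule, n_sim=config.n_sim_cluster, seed=config.seed + seed_offset
    )
    thresholded, table = apply_cluster_threshold(group_z, rule, k_min)
    strict_rule = config.rule(strict=True)
    strict_k = cluster_size_threshold(
        med_fwhm,
        mask,
        strict_rule,
        n_sim=config.n_sim_cluster,
        seed=config.seed + seed_offset,
    )
    strict_thr, strict_table = apply_cluster_threshold(group_z, strict_rule, strict_k)
    return AnalysisResult(
        content=content,
        subject_tmaps=subject_tmaps,
        subject_smoothness=smoothness,
        group_z=group_z,
        k_min=k_min,
        thresholded=thresholded,
        cluster_table=table,
        strict_k_min=strict_k,
        strict_thresholded=strict_thr,
        strict_cluster_table=strict_table,
        provenance={
            "content": content,
            "config": config.hash(),
            "seed": config.seed,
            "n_subjects": len(design.subjects),
            "median_fwhm_mm": med_fwhm.fwhm.tolist(),
        },
    )


def derive_factor_scores(study: SyntheticStudy) -> pd.DataFrame:
    """Run the full lexical pipeline on a study: assemble, impute, PCA,
    score.  Returns the word-keyed averaged factor-score table."""
    cfg = study.config
    all_words = pd.concat(study.transcripts.values(), ignore_index=True)
    table = lexfeatures.assemble_word_table(
        all_words[["word", "pos"]],
        norms=study.lexicon,
        social=study.social_norms,
        embeddings=study.embeddings,
    )
    imputed = lexfeatures.impute_chained(
        table, m=cfg.m_imputations, iters=cfg.imputation_iters, seed=cfg.seed
    )
    model = lexfeatures.fit_pca_varimax(imputed)
    return lexfeatures.score_factors(model, imputed)


def run_words_analysis(
    study: SyntheticStudy,
    content: str = "content_words",
    scores: pd.DataFrame | None = None,
    out_dir: str | Path | None = None,
) -> AnalysisResult:
    """Word-level analysis for one content type, subject to group level.

    ``content`` is one of ``content_words`` (count of open-class words per
    window), ``semantic_flexibility`` or ``social_impact`` (residualized,
    empty-dropped factor-score window sums).  Pass a precomputed
    ``scores`` table to reuse the lexical stage across content types.
    """
    if content not in WORD_CONTENT_TYPES:
        raise ValueError(f"unknown word content type {content!r}")
    config = study.config
    if content != "content_words":
        if scores is None:
            scores = derive_factor_scores(study)
        word_values = scores.set_index("word")[_FACTOR_OF_CONTENT[content]].to_dict()
    else:
        word_values = None

    regressors_by_movie = {}
    for movie in study.events:
        merged = merge_short_events(study.events[movie], config.merge_min_duration_s)
        regressors_by_movie[movie] = build_word_regressor(
            study.transcripts[movie],
            merged,
            word_values,
            config,
            study.n_volumes[movie],
            name=content,
        )

    subject_tmaps = {}
    smoothness = {}
    for sub in study.design.subjects:
        movie = study.design.movies[sub]
        fit = fit_first_level(study.bold[sub], [regressors_by_movie[movie]])
        tmap = fit[content]["t"]
        subject_tmaps[sub] = tmap
        smoothness[sub] = estimate_smoothness(
            tmap.meta["_residuals"], tmap.mask, config.voxel_size_mm
        )
    result = _group_and_threshold(
        content, subject_tmaps, smoothness, study.design, config
    )
    if out_dir is not None:
        _write_result(result, out_dir)
    return result


def run_events_analysis(
    study: SyntheticStudy,
    which: str = "semantic",
    scrambled: bool = False,
    out_dir: str | Path | None = None,
) -> AnalysisResult:
    """Event-level duration-modulated analysis (or its scrambled null).

    The regression model carries the unmodulated event boxcar, the
    mean-centered rating of interest as the duration-modulated regressor,
    and the other rating as a nuisance modulator.  ``scrambled`` permutes
    the ratings within each movie first, giving the null comparison.
    """
    if which not in ("semantic", "social"):
        raise ValueError("which must be 'semantic' or 'social'")
    config = study.config
    content = f"{which}_events" + ("_scrambled" if scrambled else "")

    regressors_by_movie = {}
    for movie, ev in study.events.items():
        report = validate_events(ev)
        if not report.ok:
            raise ValueError(f"invalid events for {movie}: {report.violations[:3]}")
        merged = merge_short_events(ev, config.merge_min_duration_s)
        if scrambled:
            merged = scramble_ratings(merged, which="both", seed=config.seed + 17)
        regressors_by_movie[movie] = duration_modulated_regressor(
            merged, which, config.tr, study.n_volumes[movie]
        )

    subject_tmaps = {}
    smoothness = {}
    mod_name = f"{which}_modulated"
    for sub in study.design.subjects:
        movie = study.design.movies[sub]
        fit = fit_first_level(study.bold[sub], regressors_by_movie[movie])
        tmap = fit[mod_name]["t"]
        subject_tmaps[sub] = tmap
        smoothness[sub] = estimate_smoothness(
            tmap.meta["_residuals"], tmap.mask, config.voxel_size_mm
        )
    result = _group_and_threshold(
        content, subject_tmaps, smoothness, study.design, config
    )
    if out_dir is not None:
        _write_result(result, out_dir)
    return result


def threshold_subject_maps(
    result: AnalysisResult, config: PipelineConfig, positive_only: bool = True
) -> dict[str, StatMap]:
    """Threshold each subject's t map with its own cluster-size threshold.

    Mirrors the study's subject-level procedure: each subject's residual
    blur estimate feeds the Monte-Carlo cluster simulation, yielding
    subject-specific minimum extents.
    """
    out = {}
    rule = config.rule()
    for sub, tmap in result.subject_tmaps.items():
        k = cluster_size_threshold(
            result.subject_smoothness[sub],
            tmap.mask,
            rule,
            n_sim=config.n_sim_cluster_subject,
            seed=config.seed + (hash(sub) % 10000),
        )
        thr, _ = apply_cluster_threshold(tmap, rule, k)
        if positive_only:
            thr = StatMap(
                np.where(thr.data > 0, thr.data, 0.0),
                thr.kind,
                thr.df,
                thr.mask,
                thr.voxel_size,
                thr.meta,
            )
        out[sub] = thr
    return out


@dataclass
class OverlapAnalysisResult:
    pair: tuple[str, str]
    per_subject: pd.DataFrame  # subject, n_overlap, dice, functional_zero
    overlap_maps: dict[str, StatMap]
    group_overlap_z: StatMap
    thresholded: StatMap
    cluster_table: pd.DataFrame
    provenance: dict = field(default_factory=dict)


def run_overlap_analysis(
    result_a: AnalysisResult,
    result_b: AnalysisResult,
    study: SyntheticStudy,
    out_dir: str | Path | None = None,
) -> OverlapAnalysisResult:
    """Within- and cross-subject overlap between two content analyses.

    Subject maps are thresholded with subject-specific cluster extents;
    binary overlap gives Dice and voxel counts (functional zero below 10
    voxels); normalized-map products feed the random-effects group
    analysis of stable overlap loci.
    """
    config = study.config
    thr_a = threshold_subject_maps(result_a, config)
    thr_b = threshold_subject_maps(result_b, config)

    rows = []
    products = {}
    for sub in study.design.subjects:
        a, b = thr_a[sub], thr_b[sub]
        ov = overlap_voxels(a.data != 0, b.data != 0)
        rows.append(
            {
                "subject": sub,
                "n_overlap": ov.n_overlap_voxels,
                "dice": ov.dice,
                "functional_zero": ov.functional_zero,
            }
        )
        products[sub] = statistical_overlap_map(
            normalize_stat_map(a), normalize_stat_map(b)
        )

    group_z = group_overlap_rfx(
        [products[s] for s in study.design.subjects], study.design
    )
    med_fwhm = SmoothnessEstimate(
        np.median(
            np.stack(
                [result_a.subject_smoothness[s].fwhm for s in study.design.subjects]
            ),
            axis=0,
        )
    )
    rule = config.rule()
    k_min = cluster_size_threshold(
        med_fwhm, group_z.mask, rule, n_sim=config.n_sim_cluster, seed=config.seed + 99
    )
    thresholded, table = apply_cluster_threshold(group_z, rule, k_min)
    result = OverlapAnalysisResult(
        pair=(result_a.content, result_b.content),
        per_subject=pd.DataFrame(rows),
        overlap_maps=products,
        group_overlap_z=thresholded,
        thresholded=thresholded,
        cluster_table=table,
        provenance={
            "pair": [result_a.content, result_b.content],
            "config": config.hash(),
            "seed": config.seed,
            "caveat": group_z.meta.get("caveat"),
        },
    )
    result.group_overlap_z = group_z
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        result.per_subject.to_csv(
            out_dir / f"overlap_{result_a.content}_{result_b.content}.tsv",
            sep="\t",
            index=False,
        )
        with open(out_dir / "provenance_overlap.json", "w") as fh:
            json.dump(result.provenance, fh, indent=2)
    return result


def overlap_suite(
    results: dict[str, AnalysisResult],
    pairs: list[tuple[str, str]],
    study: SyntheticStudy,
    networks: dict[str, np.ndarray] | None = None,
) -> dict:
    """All pre-registered overlap outputs for a set of content analyses.

    Runs the pairwise overlap analysis for every requested pair, builds
    the conjunction of the thresholded group maps, and — when network
    masks are supplied — the long-format Dice report of every result
    against every network at subject and group level.
    """
    from .overlapnet import conjunction_map

    overlaps = {
        pair: run_overlap_analysis(results[pair[0]], results[pair[1]], study)
        for pair in pairs
    }
    conjunction = conjunction_map(
        {name: res.thresholded for name, res in results.items()}
    )
    report = None
    if networks:
        subject_masks = {
            name: {
                sub: thr.data != 0
                for sub, thr in threshold_subject_maps(res, study.config).items()
            }
            for name, res in results.items()
        }
        group_masks = {name: res.thresholded.data != 0 for name, res in results.items()}
        report = network_dice_report(subject_masks, group_masks, networks)
    return {"pairs": overlaps, "conjunction": conjunction, "network_report": report}


def _write_result(result: AnalysisResult, out_dir: str | Path) -> None:
    from . import io as nio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    nio.save_stat_map(result.group_z, out_dir / f"{result.content}_group_z.nii.gz")
    nio.save_stat_map(
        result.thresholded, out_dir / f"{result.content}_thresholded.nii.gz"
    )
    result.cluster_table.to_csv(
        out_dir / f"{result.content}_clusters.tsv", sep="\t", index=False
    )
    with open(out_dir / f"{result.content}_provenance.json", "w") as fh:
        json.dump(result.provenance, fh, indent=2)
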