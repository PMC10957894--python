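"""Readers and writers for the pipeline's file formats.

Tables travel as CSV/TSV, embeddings as word2vec text, images as NIfTI-1.
Generated synthetic bundles are written through the same functions so a
file-based run exercises every reader.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .firstlevel import BoldImage, StatMap
from .timecourse import SERIES_COLUMNS, WindowSeries

_EVENT_FILE_COLS = {
    "onset_s": "onset",
    "duration_s": "duration",
}


def read_events_csv(path: str | Path) -> pd.DataFrame:
    """Event table CSV (movie_id, index, onset_s, duration_s, semantic,
    social[, rater, is_major, notes])."""
    df = pd.read_csv(path)
    return df.rename(columns=_EVENT_FILE_COLS)


def write_events_csv(table: pd.DataFrame, path: str | Path) -> None:
    out = table.rename(columns={v: k for k, v in _EVENT_FILE_COLS.items()})
    out.to_csv(path, index=False)


def read_transcript_tsv(path: str | Path) -> pd.DataFrame:
    """Transcript TSV with word, onset (s), duration (s) and optional pos."""
    return pd.read_csv(path, sep="\t")


def write_transcript_tsv(transcript: pd.DataFrame, path: str | Path) -> None:
    transcript.to_csv(path, sep="\t", index=False)


def read_norms_csv(path: str | Path) -> pd.DataFrame:
    """Word-property norm table; missing cells empty."""
    return pd.read_csv(path)


def write_norms_csv(norms: pd.DataFrame, path: str | Path) -> None:
    norms.to_csv(path, index=False)


def read_embeddings_text(path: str | Path) -> dict[str, np.ndarray]:
    """word2vec text format: header "count dim", then word + floats."""
    vecs: dict[str, np.ndarray] = {}
    with open(path) as fh:
        header = fh.readline().split()
        n, dim = int(header[0]), int(header[1])
        for line in fh:
            parts = line.rstrip("\n").split(" ")
            word = parts[0]
            v = np.array(parts[1:], dtype=float)
            if len(v) != dim:
                raise ValueError(f"embedding for {word!r} has {len(v)} != {dim} dims")
            if not v.any():
                raise ValueError(f"zero vector for {word!r}")
            vecs[word] = v
    if len(vecs) != n:
        raise ValueError(f"header promised {n} words, file had {len(vecs)}")
    return vecs


def write_embeddings_text(vecs: dict[str, np.ndarray], path: str | Path) -> None:
    words = list(vecs)
    dim = len(next(iter(vecs.values())))
    with open(path, "w") as fh:
        fh.write(f"{len(words)} {dim}\n")
        for w in words:
            fh.write(w + " " + " ".join(f"{x:.6g}" for x in vecs[w]) + "\n")


def read_window_series_tsv(path: str | Path) -> WindowSeries:
    df = pd.read_csv(path, sep="\t")
    movie = str(df["movie_id"].iloc[0]) if len(df) else ""
    return WindowSeries(movie, df[SERIES_COLUMNS])


def write_window_series_tsv(series: WindowSeries, path: str | Path) -> None:
    series.samples.to_csv(path, sep="\t", index=False)


def _default_affine(voxel_size: float) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = voxel_size
    return aff


def save_bold(bold: BoldImage, path: str | Path) -> None:
    aff = bold.affine if bold.affine is not None else _default_affine(bold.voxel_size)
    img = nib.Nifti1Image(bold.data.astype(np.float32), aff)
    img.header["pixdim"][4] = bold.tr
    nib.save(img, str(path))


def load_bold(path: str | Path, mask: np.ndarray | None = None) -> BoldImage:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    tr = float(img.header["pixdim"][4]) or 1.0
    voxel = float(img.header["pixdim"][1])
    if mask is None:
        mask = np.ones(data.shape[:3], dtype=bool)
    return BoldImage(data, tr, mask, voxel, np.asarray(img.affine))


def save_stat_map(stat_map: StatMap, path: str | Path) -> None:
    aff = _default_affine(stat_map.voxel_size)
    nib.save(nib.Nifti1Image(stat_map.data.astype(np.float32), aff), str(path))


def load_stat_map(
    path: str | Path, kind: str = "z", df: float = np.inf, mask: np.ndarray | None = None
) -> StatMap:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    voxel = float(img.header["pixdim"][1])
    if mask is None:
        mask = np.ones(data.shape, dtype=bool)
    return StatMap(data, kind, df, mask, voxel)


def load_mask(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj) > 0


def save_mask(mask: np.ndarray, path: str | Path, voxel_size: float = 2.0) -> None:
    nib.save(
        nib.Nifti1Image(mask.astype(np.uint8), _default_affine(voxel_size)), str(path)
    )


def read_censor(path: str | Path) -> np.ndarray:
    """Single-column censor file, 1 = keep."""
    return np.loadtxt(path).astype(bool)


def write_design_matrix_tsv(regressors, path: str | Path) -> None:
    """Export a regressor set as a TSV design matrix (one column each)."""
    pd.DataFrame({r.name: r.samples for r in regressors}).to_csv(
        path, sep="\t", index=False
    )
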