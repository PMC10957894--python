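"""Overlap quantification between thresholded statistic maps.

Within-subject overlap between two analyses (say, social words and content
words) is measured as the Dice coefficient of the binarized thresholded
maps, with fewer than 10 overlapping voxels treated as functionally zero.
For the cross-subject analysis, each subject's thresholded map is
normalized by its maximum statistic (range [0, 1]) and the normalized maps
of the two conditions multiplied voxelwise, so large products mark voxels
responding strongly in *both* conditions; these products feed a second
random-effects group analysis.  Dice against meta-analytic (ALE-derived)
network masks contextualizes where results fall.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .firstlevel import StatMap
from .grouplevel import GroupDesign, fit_group_map

#: fewer overlapping voxels than this is functionally the same as none
FUNCTIONAL_ZERO_VOXELS = 10


@dataclass
class OverlapResult:
    n_overlap_voxels: int
    dice: float

    @property
    def functional_zero(self) -> bool:
        return self.n_overlap_voxels < FUNCTIONAL_ZERO_VOXELS


def _check_grids(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"grid mismatch: {a.shape} vs {b.shape}")


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity 2|A∩B| / (|A| + |B|) between binary masks (0 if both
    are empty)."""
    _check_grids(a, b)
    a = a.astype(bool)
    b = b.astype(bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 0.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def overlap_voxels(a: np.ndarray, b: np.ndarray) -> OverlapResult:
    """Overlap voxel count + Dice, with the functional-zero rule applied."""
    _check_grids(a, b)
    n = int(np.logical_and(a.astype(bool), b.astype(bool)).sum())
    return OverlapResult(n_overlap_voxels=n, dice=dice(a, b))


def normalize_stat_map(stat_map: StatMap) -> StatMap:
    """Divide a thresholded map by its maximum, yielding values in [0, 1].

    Requires the positive-cluster convention (no surviving negative
    values); an empty map comes back all zero with a warning.
    """
    data = stat_map.data
    if (data < 0).any():
        raise ValueError("negative surviving values: expected positive clusters only")
    mx = data.max()
    meta = dict(stat_map.meta)
    if mx == 0:
        warnings.warn("empty thresholded map: normalization returns all zeros")
        meta["empty"] = True
        out = np.zeros_like(data)
    else:
        out = data / mx
    return StatMap(out, stat_map.kind, stat_map.df, stat_map.mask, stat_map.voxel_size, meta)


def statistical_overlap_map(a: StatMap, b: StatMap) -> StatMap:
    """Voxelwise product of two normalized maps.

    Nonzero only where both inputs are nonzero, and never larger than
    either input, so high values mark joint engagement.
    """
    _check_grids(a.data, b.data)
    for m in (a, b):
        if m.data.min() < 0 or m.data.max() > 1:
            raise ValueError("inputs must be normalized maps in [0, 1]")
    meta = {"overlap_of": (a.meta.get("regressor"), b.meta.get("regressor"))}
    return StatMap(a.data * b.data, "beta", min(a.df, b.df), a.mask, a.voxel_size, meta)


def binary_overlap_map(a: StatMap, b: StatMap) -> StatMap:
    """Binary within-subject overlap mask as a 0/1 map (non-default).

    This is the rejected "method 1" for the cross-subject analysis: a
    group model over binary masks aggregates *any* overlap observed
    anywhere rather than consistent overlap strength, and a binary
    outcome calls for a logistic model besides.  Kept for comparison;
    the statistical-overlap product is the default.
    """
    _check_grids(a.data, b.data)
    both = ((a.data != 0) & (b.data != 0)).astype(float)
    meta = {"method": "binary overlap (non-default, rejected method 1)"}
    return StatMap(both, "beta", min(a.df, b.df), a.mask, a.voxel_size, meta)


def group_overlap_rfx(
    overlap_maps: list[StatMap], design: GroupDesign, **kwargs
) -> StatMap:
    """Random-effects group analysis of per-subject overlap products.

    Because the inputs are non-negative and mostly zero, testing the mean
    against zero is one-sided in nature; the output metadata carries that
    caveat ("anti-conservative test").
    """
    out = fit_group_map(overlap_maps, design, **kwargs)
    out.meta["caveat"] = (
        "This is an anti-conservative test: overlap inputs are non-negative, "
        "so the null of zero mean can only be exceeded from above."
    )
    return out


def conjunction_map(maps: dict[str, StatMap]) -> tuple[np.ndarray, dict[int, tuple[str, ...]]]:
    """Label each voxel by the subset of thresholded maps it survives in.

    Returns an integer label volume and a mapping from label to the tuple
    of map names present there; label 0 is background and the label for
    all maps together is the full conjunction.
    """
    if len(maps) < 2:
        raise ValueError("need at least 2 maps for a conjunction")
    names = list(maps)
    shape = maps[names[0]].data.shape
    for m in maps.values():
        _check_grids(m.data, maps[names[0]].data)
    bits = np.zeros(shape, dtype=int)
    for i, name in enumerate(names):
        bits += (maps[name].data != 0).astype(int) << i
    legend = {0: ()}
    for code in np.unique(bits):
        if code == 0:
            continue
        legend[int(code)] = tuple(n for i, n in enumerate(names) if code >> i & 1)
    return bits, legend


def network_dice_report(
    subject_masks: dict[str, dict[str, np.ndarray]],
    group_masks: dict[str, np.ndarray],
    networks: dict[str, np.ndarray],
) -> pd.DataFrame:
    """Long-format Dice table of every (result, network) pair.

    ``subject_masks`` maps result name -> subject id -> binary mask;
    ``group_masks`` maps result name -> binary mask.  Rows carry
    ``level`` ('subject' or 'group'), ``subject`` (empty at group level),
    ``result``, ``network`` and ``dice``.
    """
    rows = []
    for result, per_subject in subject_masks.items():
        for subject, mask in per_subject.items():
            for net_name, net in networks.items():
                rows.append(
                    {
                        "level": "subject",
                        "subject": subject,
                        "result": result,
                        "network": net_name,
                        "dice": dice(mask, net),
                    }
                )
    for result, mask in group_masks.items():
        for net_name, net in networks.items():
            rows.append(
                {
                    "level": "group",
                    "subject": "",
                    "result": result,
                    "network": net_name,
                    "dice": dice(mask, net),
                }
            )
    return pd.DataFrame(rows, columns=["level", "subject", "result", "network", "dice"])
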