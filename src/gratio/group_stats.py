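"""Cohort-level statistics on co-registered quantitative maps.

Given per-subject maps already in a common space, this module computes
voxel-wise group mean / SD / coefficient-of-variation maps, a
reliability mask (CoV < 0.3 by convention), white-matter histograms,
an equidistant anterior–posterior parcellation of the corpus callosum,
probabilistic-atlas tract ROIs (probability >= 50% intersected with the
CoV mask), per-ROI subject-level tables, a one-way ANOVA with one-sided
post-hoc t-tests against a reference tract, and per-ROI Pearson
correlations between subject-mean MT and fiber density.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupStack",
    "GroupSummary",
    "group_summary",
    "cov_threshold_mask",
    "wm_histogram",
    "parcellate_cc",
    "tract_roi",
    "roi_statistics",
    "tract_contrasts",
    "mt_density_correlation",
]

DEFAULT_COV_THRESHOLD = 0.3
DEFAULT_PROB_THRESHOLD = 0.5
MIN_TRACT_VOXELS = 100
DEFAULT_HISTOGRAM_BINS = 64


@dataclass
class GroupStack:
    """Per-subject co-registered 3-D maps for one modality.

    ``maps`` has shape (n_subjects, x, y, z); NaNs mark per-subject
    invalid voxels.  All subjects share ``affine``.
    """

    maps: np.ndarray
    subject_ids: list[str]
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    modality: str = "g"

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        if self.maps.ndim != 4:
            raise ValueError("maps must be (n_subjects, x, y, z)")
        if self.maps.shape[0] < 2:
            raise ValueError("need at least 2 subjects")
        if len(self.subject_ids) != self.maps.shape[0]:
            raise ValueError("subject_ids must match the number of maps")
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def n_subjects(self) -> int:
        return self.maps.shape[0]


@dataclass
class GroupSummary:
    """Voxel-wise cohort mean, sample SD, CoV and valid-subject counts."""

    mean_map: np.ndarray
    sd_map: np.ndarray
    cov_map: np.ndarray
    n_valid_map: np.ndarray
    affine: np.ndarray


def group_summary(stack: GroupStack) -> GroupSummary:
    """Voxel-wise mean, sample SD (ddof=1) and CoV over valid subjects.

    A voxel needs >= 2 valid (finite) subjects; CoV additionally needs a
    strictly positive mean.  Others come back NaN.
    """
    maps = stack.maps
    n_valid = np.isfinite(maps).sum(axis=0)
    enough = n_valid >= 2
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(maps, axis=0)
        sd = np.nanstd(maps, axis=0, ddof=1)
    mean = np.where(enough, mean, np.nan)
    sd = np.where(enough, sd, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = np.where(enough & (mean > 0), sd / mean, np.nan)
    return GroupSummary(
        mean_map=mean, sd_map=sd, cov_map=cov, n_valid_map=n_valid, affine=stack.affine.copy()
    )


def cov_threshold_mask(
    summary: GroupSummary, threshold: float = DEFAULT_COV_THRESHOLD
) -> np.ndarray:
    """Reliability mask: valid voxels with CoV strictly below threshold."""
    with np.errstate(invalid="ignore"):
        return np.isfinite(summary.cov_map) & (summary.cov_map < threshold)


def wm_histogram(
    mean_map: np.ndarray,
    wm_mask: np.ndarray,
    cov_mask: np.ndarray | None = None,
    bins: int = DEFAULT_HISTOGRAM_BINS,
    value_range: tuple[float, float] = (0.0, 1.0),
) -> pd.DataFrame:
    """Histogram of map values over (optionally CoV-restricted) WM voxels.

    Returns a DataFrame with ``bin_left``, ``bin_right`` and ``count``;
    counts sum to the number of finite masked voxels.
    """
    mask = np.asarray(wm_mask, dtype=bool)
    if cov_mask is not None:
        mask = mask & np.asarray(cov_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask for histogram")
    vals = np.asarray(mean_map, dtype=float)[mask]
    vals = vals[np.isfinite(vals)]
    counts, edges = np.histogram(np.clip(vals, *value_range), bins=bins, range=value_range)
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )


def _ap_axis_from_affine(affine: np.ndarray) -> tuple[int, float]:
    """Voxel axis most aligned with world anterior (+y in RAS), and its sign."""
    rot = np.asarray(affine, dtype=float)[:3, :3]
    y_row = rot[1, :]  # world-y contribution of each voxel axis
    axis = int(np.argmax(np.abs(y_row)))
    return axis, float(np.sign(y_row[axis]))


def parcellate_cc(
    cc_mask: np.ndarray,
    affine: np.ndarray,
    n_intervals: int = 8,
    posterior_to_anterior: bool = True,
) -> np.ndarray:
    """Split a corpus-callosum mask into equidistant anterior–posterior slabs.

    The mask's world-space anterior–posterior extent is divided into
    ``n_intervals`` equal-width (mm) intervals; every mask voxel gets a
    label 1..n, ordered posterior-to-anterior by default.  Returns an
    int label volume (0 outside the mask).
    """
    mask = np.asarray(cc_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty corpus-callosum mask")
    idx = np.array(np.where(mask)).T  # (n_vox, 3)
    world = (np.asarray(affine, dtype=float)[:3, :3] @ idx.T).T + np.asarray(affine)[:3, 3]
    y = world[:, 1]  # anterior coordinate in RAS world space
    y_min, y_max = float(y.min()), float(y.max())
    axis, _ = _ap_axis_from_affine(affine)
    voxel_extent = len(np.unique(idx[:, axis]))
    if voxel_extent < n_intervals:
        raise ValueError(
            f"mask spans only {voxel_extent} voxels along the A-P axis; "
            f"cannot form {n_intervals} intervals"
        )
    width = (y_max - y_min) / n_intervals
    bins = np.minimum(((y - y_min) / width).astype(int), n_intervals - 1)
    if not posterior_to_anterior:
        bins = n_intervals - 1 - bins
    labels = np.zeros(mask.shape, dtype=np.int32)
    labels[tuple(idx.T)] = bins + 1
    return labels


def tract_roi(
    prob_map: np.ndarray,
    cov_mask: np.ndarray,
    prob_threshold: float = DEFAULT_PROB_THRESHOLD,
    min_voxels: int = MIN_TRACT_VOXELS,
) -> tuple[np.ndarray, bool]:
    """Tract ROI: probabilistic atlas >= threshold AND the CoV mask.

    Returns ``(mask, too_small)``; ROIs below ``min_voxels`` are flagged
    (the convention is to drop tracts with fewer than 100 voxels).
    """
    prob = np.asarray(prob_map, dtype=float)
    if np.nanmin(prob) < 0 or np.nanmax(prob) > 1:
        raise ValueError("probability map must lie in [0, 1]")
    mask = (prob >= prob_threshold) & np.asarray(cov_mask, dtype=bool)
    return mask, bool(mask.sum() < min_voxels)


def roi_statistics(
    stack: GroupStack, rois: dict[str, np.ndarray], mode: str = "subject-then-group"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subject ROI means/SDs plus group-level summaries.

    Returns ``(table, summary)``.  ``table`` has one row per
    (roi, subject) with the subject's within-ROI mean and SD over that
    subject's valid voxels.  ``summary`` aggregates per ROI: the group
    mean of subject means, the between-subject SD of those means, and —
    in the default ``subject-then-group`` mode — the group mean of the
    within-ROI SDs (the within-ROI spread convention used when
    comparing against ex-vivo samples).
    """
    if mode not in ("subject-then-group", "group-across-roi"):
        raise ValueError(f"unknown mode {mode!r}")
    rows = []
    for roi_id, roi in rois.items():
        roi = np.asarray(roi, dtype=bool)
        if not roi.any():
            raise ValueError(f"ROI {roi_id!r} is empty")
        for s, sid in enumerate(stack.subject_ids):
            vals = stack.maps[s][roi]
            vals = vals[np.isfinite(vals)]
            if vals.size == 0:
                warnings.warn(f"ROI {roi_id!r} entirely invalid for subject {sid}; row dropped")
                continue
            rows.append(
                {
                    "roi_id": roi_id,
                    "subject_id": sid,
                    "mean": float(vals.mean()),
                    "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                    "n_voxels": int(vals.size),
                }
            )
    table = pd.DataFrame(rows)
    if table.empty:
        raise ValueError("no valid (roi, subject) combinations")
    grouped = table.groupby("roi_id")
    summary = pd.DataFrame(
        {
            "group_mean": grouped["mean"].mean(),
            "between_subject_sd": grouped["mean"].std(ddof=1),
            "mean_within_roi_sd": grouped["sd"].mean(),
            "n_subjects": grouped["mean"].size(),
        }
    ).reset_index()
    return table, summary


def tract_contrasts(
    table: pd.DataFrame, reference_tract: str, alpha_level: float = 0.05
) -> dict:
    """One-way ANOVA across tracts plus one-sided post-hoc tests.

    Subject-level tract means are the observations.  The ANOVA asks
    whether any tract differs; each non-reference tract is then tested
    one-sided (smaller than the reference) with a two-sample t-test at
    an uncorrected ``alpha_level``.
    """
    tracts = table["roi_id"].unique().tolist()
    if reference_tract not in tracts:
        raise ValueError(f"reference tract {reference_tract!r} not in table")
    if len(tracts) < 2:
        raise ValueError("need at least 2 tracts")
    groups = {t: table.loc[table.roi_id == t, "mean"].to_numpy() for t in tracts}
    if min(len(v) for v in groups.values()) < 3:
        raise ValueError("need at least 3 subjects per tract")
    if all(np.allclose(v, v[0]) for v in groups.values()):
        raise ValueError("degenerate zero-variance inputs")

    f_stat, anova_p = stats.f_oneway(*groups.values())
    ref = groups[reference_tract]
    posthoc = []
    for t in tracts:
        if t == reference_tract:
            continue
        t_stat, p = stats.ttest_ind(groups[t], ref, alternative="less")
        posthoc.append(
            {
                "tract": t,
                "t_stat": float(t_stat),
                "p_value": float(p),
                "smaller_than_reference": bool(p < alpha_level),
            }
        )
    return {
        "anova_f": float(f_stat),
        "anova_p": float(anova_p),
        "reference_tract": reference_tract,
        "alpha_level": alpha_level,
        "posthoc": pd.DataFrame(posthoc),
    }


def mt_density_correlation(
    mt_table: pd.DataFrame, density_table: pd.DataFrame
) -> pd.DataFrame:
    """Per-ROI Pearson correlation of subject-mean MT vs fiber density.

    Both inputs are ``roi_statistics`` tables (one row per roi/subject).
    Returns one row per ROI with r, the two-sided p-value and n.
    """
    merged = mt_table.merge(
        density_table, on=["roi_id", "subject_id"], suffixes=("_mt", "_density")
    )
    rows = []
    for roi_id, grp in merged.groupby("roi_id"):
        x = grp["mean_mt"].to_numpy()
        y = grp["mean_density"].to_numpy()
        if x.size < 3:
            raise ValueError(f"ROI {roi_id!r}: need at least 3 subjects for a correlation")
        if np.allclose(x, x[0]) or np.allclose(y, y[0]):
            raise ValueError(f"ROI {roi_id!r}: zero variance in MT or density")
        r, p = stats.pearsonr(x, y)
        rows.append({"roi_id": roi_id, "r": float(r), "p_value": float(p), "n_subjects": int(x.size)})
    return pd.DataFrame(rows)
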