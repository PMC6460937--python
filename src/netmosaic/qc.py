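"""Run-level quality control and motion-matched subsampling.

Covers equilibration-volume trimming, the DVARS head-motion index (root
mean square of the voxelwise signal difference between consecutive
volumes), mask-correspondence screening of normalized runs, and the greedy
construction of a motion-matched subsample in which the between-sex DVARS
difference is no longer significant.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ValidationError

__all__ = [
    "BoldRun",
    "MotionSummary",
    "trim_equilibration",
    "compute_dvars",
    "compute_mask_correspondence",
    "sex_motion_test",
    "motion_match",
    "qc_report",
]


@dataclass
class BoldRun:
    """One subject's 4D BOLD series on a common voxel grid."""

    data: np.ndarray          # (x, y, z, t)
    tr_seconds: float
    affine: np.ndarray        # 4 x 4
    mask: np.ndarray          # 3D bool
    subject_id: str = ""

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValidationError("BoldRun data must be 4D (x, y, z, t)")
        if self.mask.shape != self.data.shape[:3]:
            raise ValidationError("mask shape must equal the spatial shape")
        if self.data.shape[-1] < 2:
            raise ValidationError("a run needs at least 2 volumes")
        if self.tr_seconds <= 0:
            raise ValidationError("tr_seconds must be positive")
        if not np.isfinite(self.data[self.mask]).all():
            raise ValidationError("non-finite values inside the mask")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[-1]

    def in_mask_matrix(self) -> np.ndarray:
        """Time x in-mask-voxel data matrix."""
        return self.data[self.mask].T


@dataclass
class MotionSummary:
    subject_id: str
    series: np.ndarray        # length t - 1, non-negative

    @property
    def mean(self) -> float:
        return float(self.series.mean())


def trim_equilibration(run: BoldRun, n_drop: int) -> BoldRun:
    """Drop the first ``n_drop`` volumes (scanner equilibration)."""
    if n_drop < 0:
        raise ValidationError("n_drop must be non-negative")
    if n_drop >= run.n_timepoints:
        raise ValidationError(
            f"cannot drop {n_drop} of {run.n_timepoints} volumes"
        )
    if n_drop == 0:
        return run
    return replace(run, data=run.data[..., n_drop:])


def compute_dvars(run: BoldRun) -> MotionSummary:
    """DVARS series: RMS over in-mask voxels of volume-to-volume change."""
    if not run.mask.any():
        raise ValidationError("empty mask")
    x = run.in_mask_matrix()                       # t x v
    d = np.diff(x, axis=0)
    return MotionSummary(run.subject_id, np.sqrt((d**2).mean(axis=1)))


def compute_mask_correspondence(
    run: BoldRun, group_mask: np.ndarray, cutoff: float = 0.85
) -> tuple[float, bool]:
    """Spatial correspondence of a run with the group mask.

    The run's mean absolute-intensity volume is binarized at a quarter of
    its in-mask median (brain voxels sit well above this; empty background
    well below), and the squared Pearson correlation with the group mask
    is returned (negative correlations clip to zero correspondence).
    Returns ``(fraction, flagged)`` with ``flagged`` set when the fraction
    falls below ``cutoff`` (default 0.85, i.e. the >85% rule).
    """
    if group_mask.shape != run.mask.shape:
        raise ValidationError("group mask shape must match the run grid")
    if not group_mask.any():
        raise ValidationError("group mask is empty")
    mean_abs = np.abs(run.data).mean(axis=-1)
    med = np.median(mean_abs[run.mask])
    binarized = (mean_abs > 0.25 * med).astype(float)
    g = group_mask.astype(float)
    bv, gv = binarized.ravel(), g.ravel()
    if bv.std() == 0 or gv.std() == 0:
        frac = 0.0
    else:
        r = float(np.corrcoef(bv, gv)[0, 1])
        frac = max(r, 0.0) ** 2
    return frac, frac < cutoff


def sex_motion_test(covariates: pd.DataFrame) -> tuple[float, float]:
    """Welch two-sample t-test of mean DVARS by sex -> (t, p)."""
    m = covariates.loc[covariates["sex"] == "M", "dvars"].to_numpy(float)
    f = covariates.loc[covariates["sex"] == "F", "dvars"].to_numpy(float)
    if len(m) == 0 or len(f) == 0:
        raise ValidationError("both sexes must be present")
    t, p = stats.ttest_ind(m, f, equal_var=False)
    if np.isnan(p):  # zero variance in both groups
        p = 1.0 if np.isclose(m.mean(), f.mean()) else 0.0
        t = 0.0 if p == 1.0 else np.inf
    return float(t), float(p)


def motion_match(
    covariates: pd.DataFrame, alpha: float = 0.05
) -> tuple[list[str], list[str]]:
    """Greedy motion matching: remove subjects until DVARS no longer
    differs by sex at level ``alpha``.

    At each step the subject whose removal most reduces the between-sex
    mean DVARS gap is removed. Ties prefer the majority sex within the
    candidate's age bin (so matching never unbalances an age bin when an
    equivalent candidate exists) and then the lowest subject id. Returns
    ``(kept_ids, removed_ids)`` with removals in order.
    """
    df = covariates.copy().reset_index(drop=True)
    removed: list[str] = []
    while True:
        _, p = sex_motion_test(df)
        if p > alpha:
            return df["subject_id"].tolist(), removed
        sexes = df["sex"].to_numpy()
        if (sexes == "M").sum() <= 1 or (sexes == "F").sum() <= 1:
            raise ValidationError(
                f"cannot match without emptying a sex group; best p = {p:.3g}"
            )
        dv = df["dvars"].to_numpy(float)
        best = None  # (gap, minority_flag, subject_id, row_index)
        for i in range(len(df)):
            keep = np.ones(len(df), dtype=bool)
            keep[i] = False
            m = dv[keep & (sexes == "M")]
            f = dv[keep & (sexes == "F")]
            if len(m) == 0 or len(f) == 0:
                continue
            gap = abs(m.mean() - f.mean())
            bin_rows = df["age_bin"] == df.loc[i, "age_bin"]
            same_sex = int((df.loc[bin_rows, "sex"] == sexes[i]).sum())
            other_sex = int(bin_rows.sum()) - same_sex
            minority = 1 if same_sex <= other_sex else 0
            key = (round(gap, 12), minority, df.loc[i, "subject_id"], i)
            if best is None or key < best:
                best = key
        if best is None:
            raise ValidationError(f"no removable subject; best p = {p:.3g}")
        removed.append(best[2])
        df = df.drop(index=best[3]).reset_index(drop=True)


def qc_report(
    runs: list[BoldRun],
    group_mask: np.ndarray,
    cutoff: float = 0.85,
    path: str | Path | None = None,
) -> pd.DataFrame:
    """Per-subject QC table: mean DVARS, mask correspondence, flag."""
    rows = []
    for run in runs:
        corr, flagged = compute_mask_correspondence(run, group_mask, cutoff)
        rows.append(
            {
                "subject_id": run.subject_id,
                "mean_dvars": compute_dvars(run).mean,
                "correspondence": corr,
                "flagged": flagged,
            }
        )
    report = pd.DataFrame(rows)
    if path is not None:
        report.to_csv(path, sep="\t", index=False)
    return report
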