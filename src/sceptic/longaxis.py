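"""Hippocampal long-axis geometry and event-locked time-course extraction.

The hippocampus runs obliquely through the sagittal plane: its long axis is
rotated clockwise relative to the anterior commissure-posterior commissure
(AC-PC) line. This module estimates that rotation from a voxel mask (via
the centroids of the ten most anteroinferior and ten most posterosuperior
voxels per hemisphere), projects voxels onto the rotated axis, bins them
into quantiles of (near-)equal size, aggregates voxelwise statistics per
bin, and extracts event-locked trial time courses from 1 s-sampled activity
series with censoring at the next trial's onset.

World coordinates are RAS mm (x right, y anterior, z superior); a clockwise
rotation of ``theta`` means the axis direction in the (y, z) plane is
(cos theta, -sin theta), i.e. the anterior end of the axis sits inferior.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["VoxelMask", "LongAxisBins", "TrialTimecourse", "long_axis_rotation",
           "quantile_bins", "binwise_stat", "timelock_trials", "timecourse_regression"]


@dataclass(frozen=True)
class VoxelMask:
    """Voxel grid indices with an affine to RAS mm space and per-voxel
    probabilities (e.g. from a probabilistic atlas)."""

    ijk: np.ndarray            # (n, 3) int grid indices
    affine: np.ndarray         # (4, 4)
    probabilities: np.ndarray  # (n,) in [0, 1]
    hemisphere: str = ""

    def __post_init__(self):
        if self.ijk.ndim != 2 or self.ijk.shape[1] != 3:
            raise ValueError("ijk must be (n, 3)")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine must be invertible")
        if self.ijk.shape[0] == 0:
            raise ValueError("empty mask")

    @property
    def world(self) -> np.ndarray:
        """Voxel centers in mm, shape (n, 3)."""
        homog = np.c_[self.ijk, np.ones(len(self.ijk))]
        return (homog @ self.affine.T)[:, :3]

    @classmethod
    def from_nifti(cls, path, threshold: float = 0.5, hemisphere: str = "") -> "VoxelMask":
        """Load a probability image and keep voxels at or above ``threshold``."""
        import nibabel as nib
        img = nib.load(path)
        data = np.asarray(img.get_fdata())
        ijk = np.argwhere(data >= threshold)
        return cls(ijk=ijk, affine=np.asarray(img.affine),
                   probabilities=data[tuple(ijk.T)], hemisphere=hemisphere)


@dataclass(frozen=True)
class LongAxisBins:
    axis_mm: np.ndarray     # per-voxel coordinate along the rotated axis
    labels: np.ndarray      # bin label 1..n_bins (posterior- to anterior-most)
    n_bins: int


@dataclass(frozen=True)
class TrialTimecourse:
    rel_times: np.ndarray   # event-aligned grid, s
    values: np.ndarray      # (n_trials, n_times), NaN where censored


def _extreme_centroids(mask: VoxelMask, n_extreme: int, direction: np.ndarray):
    yz = mask.world[:, 1:3]
    key = yz @ direction
    if len(key) < 2 * n_extreme:
        raise ValueError(f"mask needs >= {2 * n_extreme} voxels")
    order = np.argsort(key)
    post = yz[order[:n_extreme]].mean(axis=0)   # posterosuperior extreme
    ant = yz[order[-n_extreme:]].mean(axis=0)   # anteroinferior extreme
    return ant, post


def long_axis_rotation(mask_l: VoxelMask, mask_r: VoxelMask,
                       n_extreme: int = 10,
                       direction=(1.0, -1.0), n_iter: int = 4) -> float:
    """Clockwise rotation (degrees) of the long axis relative to AC-PC.

    Per hemisphere, the centroids of the ``n_extreme`` most anteroinferior
    and posterosuperior voxels (ordered by projecting (y, z) onto
    ``direction``, default (1, -1): anterior and inferior score high) define
    a two-point line in the sagittal plane; the hemispheres' slopes are
    averaged and converted to a clockwise angle (zero slope = 0 deg).

    Because ordering by a direction oblique to the true axis biases the
    extreme sets sideways, the selection is iterated: after each estimate
    the ordering key is realigned with the estimated axis until stable
    (``n_iter`` passes; the first pass is the anatomical-key estimate).
    """
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    angle = None
    for _ in range(max(1, n_iter)):
        slopes = []
        for mask in (mask_l, mask_r):
            ant, post = _extreme_centroids(mask, n_extreme, d)
            dy = ant[0] - post[0]
            if abs(dy) < 1e-9:
                raise ValueError("degenerate mask: extremes vertically aligned")
            slopes.append((ant[1] - post[1]) / dy)
        new_angle = float(np.degrees(np.arctan(-np.mean(slopes))))
        if angle is not None and abs(new_angle - angle) < 1e-3:
            return new_angle
        angle = new_angle
        theta = np.deg2rad(angle)
        d = np.array([np.cos(theta), -np.sin(theta)])
    return angle


def quantile_bins(mask: VoxelMask, angle_deg: float, n_bins: int = 12) -> LongAxisBins:
    """Project voxels onto the rotated axis and cut into ``n_bins``
    quantiles; counts per bin differ by at most one.

    Label 1 is the posterior-most bin, ``n_bins`` the anterior-most.
    """
    n = len(mask.ijk)
    if n < n_bins:
        raise ValueError(f"{n} voxels < {n_bins} bins")
    theta = np.deg2rad(angle_deg)
    yz = mask.world[:, 1:3]
    axis_mm = yz[:, 0] * np.cos(theta) - yz[:, 1] * np.sin(theta)
    order = stats.rankdata(axis_mm, method="ordinal")  # 1..n
    labels = np.floor((order - 0.5) / n * n_bins).astype(int) + 1
    return LongAxisBins(axis_mm=axis_mm, labels=labels, n_bins=n_bins)


def binwise_stat(statmap: np.ndarray, bins: LongAxisBins) -> pd.Series:
    """Mean statistic per long-axis bin (index = bin label)."""
    statmap = np.asarray(statmap, dtype=float)
    if statmap.shape != bins.labels.shape:
        raise ValueError("statmap must have one value per mask voxel")
    s = pd.Series(statmap).groupby(bins.labels).mean()
    if len(s) < bins.n_bins:
        raise ValueError("empty long-axis bin")
    s.index.name = "bin"
    return s


def timelock_trials(times: np.ndarray, series: np.ndarray,
                    events: np.ndarray, window: tuple[float, float],
                    next_onsets: np.ndarray | None = None,
                    dt: float = 1.0) -> TrialTimecourse:
    """Event-locked windows interpolated onto an evenly spaced grid.

    For each event, the series is linearly interpolated onto
    ``event + arange(window[0], window[1] + dt, dt)``. Samples outside the
    series support, or at or after the corresponding next-trial onset, are
    returned as NaN (censored, never imputed).
    """
    times = np.asarray(times, dtype=float)
    series = np.asarray(series, dtype=float)
    events = np.asarray(events, dtype=float)
    lo, hi = window
    rel = np.arange(lo, hi + dt / 2, dt)
    out = np.full((events.size, rel.size), np.nan)
    for i, ev in enumerate(events):
        abs_t = ev + rel
        ok = (abs_t >= times[0]) & (abs_t <= times[-1])
        if next_onsets is not None and np.isfinite(next_onsets[i]):
            ok &= abs_t < next_onsets[i]
        out[i, ok] = np.interp(abs_t[ok], times, series)
    return TrialTimecourse(rel_times=rel, values=out)


def timecourse_regression(df: pd.DataFrame, y: str, x: str,
                          by=("time", "bin"), alpha: float = 0.05) -> pd.DataFrame:
    """Per-(time, bin) simple regression of activity on a covariate, with
    Benjamini-Yekutieli false-discovery control across all cells."""
    from statsmodels.stats.multitest import multipletests
    rows = []
    for keys, g in df.groupby(list(by)):
        g = g.dropna(subset=[y, x])
        if len(g) < 3 or g[x].std() == 0:
            continue
        res = stats.linregress(g[x], g[y])
        rows.append(dict(zip(by, np.atleast_1d(keys))) |
                    dict(slope=res.slope, se=res.stderr, p=res.pvalue, n=len(g)))
    out = pd.DataFrame(rows)
    if out.empty:
        warnings.warn("no estimable (time, bin) cells")
        return out
    out["p_adj"] = multipletests(out["p"], alpha=alpha, method="fdr_by")[1]
    out["significant"] = out["p_adj"] < alpha
    return out
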