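"""Motion quality control: DVARS, outlier flagging, window cropping, exclusion.

DVARS (the root-mean-square intensity difference between successive volumes)
is a per-volume index of motion/artefact. Volumes whose DVARS exceeds
Q3 + 1.5*IQR of the subject's own series are flagged as motion outliers;
the contiguous ~70% window with the fewest outliers is retained, and
subjects with outliers in more than 10% of the retained window are excluded
entirely. The retained outlier count becomes a nuisance covariate in all
downstream regressions.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from .io import Bold4D, MaskVolume, SubjectMeta

#: retained fraction of the acquisition (1600 of 2300 volumes)
WINDOW_FRACTION = 1600.0 / 2300.0
#: exclusion rule: more than this fraction of the cropped window flagged
EXCLUDE_FRACTION = 0.10


@dataclass
class DvarsSeries:
    """Per-volume DVARS values; index 0 is 0 by convention (undefined)."""

    values: np.ndarray
    mask_used: Union[str, MaskVolume] = "all voxels"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("DVARS values must be a 1D vector")
        if (self.values < 0).any():
            raise ValueError("DVARS values must be non-negative")


@dataclass
class OutlierMask:
    """Per-volume outlier flags. ``flag_outliers`` never flags the first
    volume (DVARS is undefined there); hand-built masks are not constrained."""

    flags: np.ndarray
    threshold: float

    def __post_init__(self):
        self.flags = np.asarray(self.flags, dtype=bool)


@dataclass
class CropResult:
    start: int
    length: int
    outlier_count: int
    excluded: bool


def compute_dvars(b: Bold4D, mask: Optional[MaskVolume] = None) -> DvarsSeries:
    """RMS intensity difference between successive volumes, within a mask.

    ``values[t] = sqrt(mean_v (data[v,t] - data[v,t-1])^2)`` for t >= 1 and
    0 for the first volume.
    """
    if mask is not None:
        if mask.data.shape != b.data.shape[:3]:
            raise ValueError("mask shape does not match BOLD spatial grid")
        ts = b.data[mask.data]  # V x T
    else:
        ts = b.data.reshape(-1, b.n_volumes)
    diffs = np.diff(ts, axis=1)
    values = np.sqrt(np.mean(diffs**2, axis=0))
    values = np.concatenate([[0.0], values])
    return DvarsSeries(values=values, mask_used=mask if mask is not None else "all voxels")


def flag_outliers(d: DvarsSeries) -> OutlierMask:
    """Flag volumes with DVARS above Q3 + 1.5*IQR of the series.

    Quartiles use sorted-data linear interpolation (numpy's default) over
    t >= 1 only; the first volume is never flagged. A constant series yields
    a threshold equal to that constant and zero outliers.
    """
    v = d.values
    if len(v) < 5:
        raise ValueError("need at least 5 volumes to estimate quartiles")
    q1, q3 = np.percentile(v[1:], [25, 75])
    threshold = q3 + 1.5 * (q3 - q1)
    flags = v > threshold
    flags[0] = False
    return OutlierMask(flags=flags, threshold=float(threshold))


def default_window_length(T: int) -> int:
    """Retained window length for an acquisition of T volumes (~70%).

    Exactly 1600 when T = 2300; otherwise the rounded fraction 1600/2300.
    """
    return int(np.rint(WINDOW_FRACTION * T))


def select_window(
    o: OutlierMask,
    window_len: Optional[int] = None,
    exclude_frac: float = EXCLUDE_FRACTION,
) -> CropResult:
    """Find the contiguous window of ``window_len`` volumes with the fewest
    outliers (ties broken by smallest start index) and apply the exclusion
    rule: excluded iff outlier_count > floor(exclude_frac * window_len).
    """
    flags = o.flags
    T = len(flags)
    if window_len is None:
        window_len = default_window_length(T)
    if window_len > T:
        raise ValueError(f"window length {window_len} exceeds series length {T}")
    csum = np.concatenate([[0], np.cumsum(flags)])
    counts = csum[window_len:] - csum[: T - window_len + 1]
    start = int(np.argmin(counts))  # first minimum = smallest start index
    count = int(counts[start])
    excluded = count > math.floor(exclude_frac * window_len)
    return CropResult(start=start, length=int(window_len), outlier_count=count,
                      excluded=excluded)


def apply_qc(b: Bold4D, c: CropResult, meta: SubjectMeta) -> Optional[Bold4D]:
    """Crop the acquisition to the selected window, or drop the subject.

    Writes the retained outlier count into ``meta.motion_outliers`` (it is
    a covariate in all subsequent regressions). Returns the cropped Bold4D,
    or None when the subject is excluded.
    """
    meta.motion_outliers = c.outlier_count
    if c.excluded:
        return None
    cropped = b.data[..., c.start : c.start + c.length]
    return Bold4D(data=cropped, voxel_size=b.voxel_size, tr=b.tr,
                  subject_id=b.subject_id)


def run_qc(
    b: Bold4D,
    meta: SubjectMeta,
    mask: Optional[MaskVolume] = None,
    window_len: Optional[int] = None,
    exclude_frac: float = EXCLUDE_FRACTION,
):
    """Full QC for one subject: DVARS -> outlier flags -> crop/exclude.

    Returns ``(crop_result, dvars, cropped_or_None)``.
    """
    d = compute_dvars(b, mask)
    o = flag_outliers(d)
    c = select_window(o, window_len=window_len, exclude_frac=exclude_frac)
    cropped = apply_qc(b, c, meta)
    return c, d, cropped
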