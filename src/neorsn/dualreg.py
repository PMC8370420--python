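"""Dual regression: group components -> subject time courses -> subject maps.

Stage 1 regresses the full set of group spatial maps (signal *and* noise
components -- artifact components are retained to absorb confound
variance) into each volume of the subject's 4D dataset, yielding one time
course per component. Stage 2 regresses those time courses into the same
dataset voxel by voxel, yielding one spatial beta map per component.
Both stages are ordinary least squares on demeaned regressors.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .io import Bold4D
from .ica import GroupMapSet


@dataclass
class SubjectDR:
    """Per-subject dual-regression outputs (all K components)."""

    timecourses: np.ndarray  # T x K
    beta_maps: np.ndarray  # K x X x Y x Z
    subject_id: str
    variance_normalised: bool = False

    @property
    def K(self) -> int:
        return self.timecourses.shape[1]


def _check_rank(M: np.ndarray, what: str):
    K = M.shape[1]
    s = np.linalg.svd(M, compute_uv=False)
    if s[-1] <= 1e-10 * s[0]:
        # identify near-collinear columns via the small right singular vector
        _, _, Vt = np.linalg.svd(M)
        involved = np.where(np.abs(Vt[-1]) > 0.1)[0].tolist()
        raise ValueError(f"rank-deficient {what}: collinear components {involved}")


def stage1_spatial_regression(b: Bold4D, g: GroupMapSet) -> np.ndarray:
    """Spatial multiple regression of all K group maps into each volume.

    Group maps are demeaned over in-mask voxels; each volume's voxel vector
    is demeaned before the fit. Returns a T x K time-course matrix.
    """
    if g.maps.shape[1:] != b.data.shape[:3]:
        raise ValueError("group-map grid does not match subject grid")
    mask = g.mask
    V = int(mask.sum())
    if g.K >= V:
        raise ValueError(f"K={g.K} must be below the in-mask voxel count {V}")
    M = np.stack([g.maps[k][mask] for k in range(g.K)], axis=1)  # V x K
    M = M - M.mean(axis=0, keepdims=True)
    _check_rank(M, "group-map matrix")
    Y = b.data[mask]  # V x T
    Y = Y - Y.mean(axis=0, keepdims=True)
    coeffs, *_ = np.linalg.lstsq(M, Y, rcond=None)  # K x T
    return coeffs.T


def stage2_temporal_regression(
    b: Bold4D,
    tcs: np.ndarray,
    variance_normalise: bool = False,
    mask: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Temporal multiple regression of the stage-1 time courses into the
    same dataset, voxel by voxel.

    Time courses are demeaned over time and, with ``variance_normalise``,
    scaled to unit variance (betas then read as response per unit
    time-course standard deviation). Returns K beta maps.
    """
    T = b.n_volumes
    if tcs.shape[0] != T:
        raise ValueError("time-course length does not match the data")
    D = tcs - tcs.mean(axis=0, keepdims=True)
    if variance_normalise:
        sd = D.std(axis=0)
        if (sd == 0).any():
            raise ValueError("cannot variance-normalise a constant time course")
        D = D / sd
    _check_rank(D, "time-course matrix")
    if mask is None:
        mask = np.ones(b.data.shape[:3], dtype=bool)
    Y = b.data[mask]  # V x T
    Y = Y - Y.mean(axis=1, keepdims=True)
    coeffs, *_ = np.linalg.lstsq(D, Y.T, rcond=None)  # K x V
    K = tcs.shape[1]
    betas = np.zeros((K,) + b.data.shape[:3])
    for k in range(K):
        betas[k][mask] = coeffs[k]
    return betas


def dual_regress(
    b: Bold4D, g: GroupMapSet, variance_normalise: bool = False
) -> SubjectDR:
    """Run both stages for one subject against a group map set."""
    tcs = stage1_spatial_regression(b, g)
    betas = stage2_temporal_regression(b, tcs, variance_normalise, mask=g.mask)
    return SubjectDR(timecourses=tcs, beta_maps=betas,
                     subject_id=b.subject_id,
                     variance_normalised=variance_normalise)
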