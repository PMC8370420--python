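"""Winner-takes-all functional parcellation from the group map set.

Each signal network's Z-map is Gaussian-smoothed, and every voxel is
assigned to the network with the highest smoothed Z among those exceeding
the threshold (default Z > 1); voxels with no suprathreshold candidate
stay unassigned (label 0). Ties break deterministically to the lowest
component index.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter

from .ica import GroupMapSet

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # ~1/2.3548


@dataclass
class ParcelMap:
    """Integer label grid: 0 = unassigned, k = k-th signal network."""

    labels: np.ndarray
    smoothing_fwhm: float
    z_thr: float
    legend: dict  # label value -> network name


def winner_takes_all(
    g: GroupMapSet,
    smoothing_fwhm: float = 3.0,
    z_thr: float = 1.0,
    voxel_size: Optional[tuple] = None,
) -> ParcelMap:
    """Parcellate the grid by the strongest smoothed suprathreshold network.

    ``smoothing_fwhm`` is in mm and is converted to a per-axis Gaussian
    sigma using the map set's voxel size.
    """
    idx = g.signal_indices
    if not idx:
        raise ValueError("no signal components to parcellate")
    if voxel_size is None:
        voxel_size = g.voxel_size
    sigma = [smoothing_fwhm * FWHM_TO_SIGMA / v for v in voxel_size]
    smoothed = np.stack([
        gaussian_filter(g.maps[k].astype(float), sigma) for k in idx
    ])
    best = np.argmax(smoothed, axis=0)  # first max wins: lowest index
    best_val = np.take_along_axis(smoothed, best[None], axis=0)[0]
    labels = np.where((best_val > z_thr) & g.mask, best + 1, 0).astype(np.int32)
    legend = {i + 1: g.names[k] for i, k in enumerate(idx)}
    return ParcelMap(labels=labels, smoothing_fwhm=float(smoothing_fwhm),
                     z_thr=float(z_thr), legend=legend)


def write_parcellation(p: ParcelMap, path, legend_path=None,
                       voxel_size=(2.15, 2.15, 2.15)):
    import nibabel as nib
    import pandas as pd

    affine = np.diag(list(voxel_size) + [1.0])
    nib.save(nib.Nifti1Image(p.labels.astype(np.int16), affine), str(path))
    if legend_path is not None:
        pd.DataFrame(
            {"label": list(p.legend), "network": list(p.legend.values())}
        ).to_csv(legend_path, sep="\t", index=False)
    return path
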