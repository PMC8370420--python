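"""Group-level network definition by temporal-concatenation spatial ICA.

Each subject's voxel time series are demeaned and variance-normalised,
concatenated in time across subjects, reduced to K dimensions by SVD with
unit-variance whitening, and unmixed by fixed-point negentropy maximisation
(tanh contrast) over the spatial dimension. Raw component maps are
converted to Z-maps by a robust-sigma normalisation (median/MAD), signed so
that each map's skewness is positive (networks are positive activations)
and ordered by explained variance, descending.

Component labelling (signal network vs structured noise) is manual-by-file,
mirroring visual inspection of group maps in practice; a simple heuristic
pre-labeller is available to *suggest* labels.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import Bold4D, MaskVolume

SIGNAL = "signal"
NOISE = "noise"
#: default ICA dimensionality
DEFAULT_DIM = 30


@dataclass
class Whitened:
    """K x V whitened spatial matrix plus what is needed to interpret it."""

    matrix: np.ndarray  # K x V, identity covariance over voxels
    mask: np.ndarray  # 3D bool
    shape: tuple
    voxel_size: tuple
    singular_values: np.ndarray
    var_explained: np.ndarray  # fraction of total variance per retained dim
    dewhiten: np.ndarray  # K x K: whitened coords -> singular-value-scaled PCs
    total_variance: float
    n_subjects: int
    total_timepoints: int


@dataclass
class GroupMapSet:
    """K group-level spatial Z-maps with signal/noise labels."""

    maps: np.ndarray  # K x X x Y x Z
    labels: list
    names: list
    var_explained: np.ndarray
    mask: np.ndarray
    voxel_size: tuple = (2.15, 2.15, 2.15)

    def __post_init__(self):
        if self.maps.ndim != 4:
            raise ValueError("maps must be K x X x Y x Z")
        if not np.isfinite(self.maps).all():
            raise ValueError("non-finite values in group maps")
        if len(self.labels) != self.K or len(self.names) != self.K:
            raise ValueError("labels and names must have one entry per component")

    @property
    def K(self) -> int:
        return self.maps.shape[0]

    @property
    def signal_indices(self) -> list:
        return [i for i, l in enumerate(self.labels) if l == SIGNAL]

    @property
    def n_signal(self) -> int:
        return len(self.signal_indices)

    def flat(self, k: int) -> np.ndarray:
        return self.maps[k][self.mask]


def _stack_normalised(subjects: Sequence[Bold4D], mask: np.ndarray) -> np.ndarray:
    rows = []
    for b in subjects:
        ts = b.data[mask].astype(float)  # V x T
        ts = ts - ts.mean(axis=1, keepdims=True)
        sd = ts.std(axis=1)
        sd[sd == 0] = 1.0
        ts /= sd[:, None]
        rows.append(ts.T)  # T x V
    return np.vstack(rows)


def concat_and_whiten(
    subjects: Sequence[Bold4D], K: int, mask: Optional[MaskVolume] = None
) -> Whitened:
    """Demean/variance-normalise, time-concatenate, SVD-reduce and whiten.

    Returns a K x V matrix whose rows have zero mean and identity
    covariance over voxels (``Y @ Y.T / V = I``).
    """
    if not subjects:
        raise ValueError("no subjects supplied")
    shape = subjects[0].data.shape[:3]
    for b in subjects:
        if b.data.shape[:3] != shape:
            raise ValueError(
                f"grid mismatch: '{b.subject_id}' has {b.data.shape[:3]}, "
                f"expected {shape}"
            )
    m = mask.data if mask is not None else np.ones(shape, dtype=bool)
    X = _stack_normalised(subjects, m)  # Ttot x V
    Ttot, V = X.shape
    if K > min(Ttot, V):
        raise ValueError(f"K={K} exceeds the rank bound min(T={Ttot}, V={V})")

    # SVD via the Gram matrix on the smaller side
    if V <= Ttot:
        G = X.T @ X
        evals, evecs = np.linalg.eigh(G)
        order = np.argsort(evals)[::-1]
        evals = np.clip(evals[order], 0, None)
        s = np.sqrt(evals)
        Vt = evecs[:, order].T  # V x V rows = right singular vectors
    else:
        G = X @ X.T
        evals, evecs = np.linalg.eigh(G)
        order = np.argsort(evals)[::-1]
        evals = np.clip(evals[order], 0, None)
        s = np.sqrt(evals)
        U = evecs[:, order]
        with np.errstate(divide="ignore", invalid="ignore"):
            Vt = (U.T @ X) / np.where(s[:, None] > 0, s[:, None], np.inf)
    if s[K - 1] <= 1e-10 * max(s[0], 1.0):
        raise ValueError(f"K={K} exceeds the numerical rank of the data")

    Y0 = Vt[:K].copy()
    Y0 -= Y0.mean(axis=1, keepdims=True)
    C = Y0 @ Y0.T / V
    w, E = np.linalg.eigh(C)
    W = (E / np.sqrt(np.clip(w, 1e-30, None))) @ E.T
    Winv = (E * np.sqrt(np.clip(w, 1e-30, None))) @ E.T
    Y = W @ Y0
    total_var = float(np.sum(evals))
    return Whitened(
        matrix=Y, mask=m, shape=shape, voxel_size=subjects[0].voxel_size,
        singular_values=s[:K],
        var_explained=evals[:K] / total_var if total_var > 0 else evals[:K],
        dewhiten=np.diag(s[:K]) @ Winv,
        total_variance=total_var,
        n_subjects=len(subjects), total_timepoints=Ttot,
    )


def robust_z(x: np.ndarray) -> np.ndarray:
    """(x - median) / (1.4826 * MAD): sigma from the background voxels."""
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        mad = np.mean(np.abs(x - med)) or 1.0
    return (x - med) / (1.4826 * mad)


def fit_group_ica(
    w: Whitened,
    K: Optional[int] = None,
    seed: int = 0,
    max_iter: int = 1000,
    tol: float = 1e-6,
) -> GroupMapSet:
    """Spatial ICA on the whitened matrix (fixed-point tanh negentropy).

    Raises on non-convergence with restart guidance. Maps come back as
    robust Z-maps, positively skewed, ordered by explained variance.
    """
    from sklearn.decomposition import FastICA
    from sklearn.exceptions import ConvergenceWarning

    if K is None:
        K = w.matrix.shape[0]
    if K > w.matrix.shape[0]:
        raise ValueError("K exceeds the whitened dimensionality")
    Y = w.matrix[:K]
    ica = FastICA(algorithm="parallel", fun="logcosh",
                  whiten=False, max_iter=max_iter, tol=tol, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            S = ica.fit_transform(Y.T)  # V x K spatial sources
        except ConvergenceWarning as exc:
            raise RuntimeError(
                f"ICA did not converge in {max_iter} iterations; "
                "restart with a different seed"
            ) from exc
    A = np.linalg.pinv(ica.components_)  # K_white x K mixing

    # sign: positive skewness; order: explained variance, descending
    for k in range(K):
        if stats.skew(S[:, k]) < 0:
            S[:, k] *= -1.0
            A[:, k] *= -1.0
    # energy of each component's voxel-varying part, mapped back through the
    # whitening into singular-value-scaled PC coordinates
    comp_var = ((w.dewhiten[:K, :K] @ A) ** 2).sum(axis=0) * (S**2).sum(axis=0)
    order = np.argsort(comp_var)[::-1]
    S = S[:, order]
    comp_var = comp_var[order]

    maps = np.zeros((K,) + tuple(w.shape))
    for k in range(K):
        maps[k][w.mask] = robust_z(S[:, k])
    frac = comp_var / w.total_variance if w.total_variance > 0 else comp_var
    return GroupMapSet(
        maps=maps, labels=[SIGNAL] * K,
        names=[f"IC{k + 1:02d}" for k in range(K)],
        var_explained=frac, mask=w.mask, voxel_size=w.voxel_size,
    )


def group_ica(
    subjects: Sequence[Bold4D],
    K: int = DEFAULT_DIM,
    seed: int = 0,
    mask: Optional[MaskVolume] = None,
) -> GroupMapSet:
    """Convenience wrapper: concatenate, whiten and unmix in one call."""
    return fit_group_ica(concat_and_whiten(subjects, K, mask), K=K, seed=seed)


def label_components(g: GroupMapSet, labels) -> GroupMapSet:
    """Attach signal/noise labels from a sequence or a labels TSV.

    The TSV needs columns ``component`` (1-based index) and ``label``;
    an optional ``name`` column overrides component names. Downstream
    stages treat signal components as networks and keep noise components
    only as confound regressors.
    """
    names = list(g.names)
    if isinstance(labels, (str, Path)):
        df = pd.read_csv(labels, sep="\t")
        if "component" not in df.columns or "label" not in df.columns:
            raise ValueError("labels file needs 'component' and 'label' columns")
        lab = [None] * g.K
        for _, row in df.iterrows():
            idx = int(row["component"]) - 1
            if not (0 <= idx < g.K):
                raise ValueError(f"component index {idx + 1} out of range 1..{g.K}")
            lab[idx] = str(row["label"])
            if "name" in df.columns and pd.notna(row.get("name")):
                names[idx] = str(row["name"])
        for i, l in enumerate(lab):
            if l is None:
                raise ValueError(f"missing label for component {i + 1}")
        labels = lab
    labels = list(labels)
    if len(labels) != g.K:
        raise ValueError(f"got {len(labels)} labels for {g.K} components")
    bad = [l for l in labels if l not in (SIGNAL, NOISE)]
    if bad:
        raise ValueError(f"unknown label tokens: {sorted(set(bad))}")
    return replace(g, labels=labels, names=names)


def suggest_labels(g: GroupMapSet, edge_fraction_thr: float = 0.35) -> list:
    """Heuristic label suggestions: components whose suprathreshold voxels
    concentrate on the mask edge look like artifacts. Suggestions only --
    labelling stays a manual decision."""
    from scipy.ndimage import binary_erosion

    interior = binary_erosion(g.mask)
    edge = g.mask & ~interior
    out = []
    for k in range(g.K):
        supra = (g.maps[k] > 2.0) & g.mask
        if supra.sum() == 0:
            out.append(NOISE)
            continue
        frac = (supra & edge).sum() / supra.sum()
        out.append(NOISE if frac > edge_fraction_thr else SIGNAL)
    return out


def match_maps(maps_a: np.ndarray, maps_b: np.ndarray,
               mask: Optional[np.ndarray] = None):
    """Hungarian assignment of components in ``maps_a`` to maps in
    ``maps_b`` maximising |spatial correlation|.

    Returns ``(pairs, corrs)`` where ``pairs[i] = (ia, ib)`` and ``corrs[i]``
    is the signed correlation of that pair. Useful for recovery tests and
    for matching ICA output to generator ground truth.
    """
    from scipy.optimize import linear_sum_assignment

    def flat(m):
        return m[mask] if mask is not None else m.ravel()

    A = np.stack([flat(m) for m in maps_a])
    B = np.stack([flat(m) for m in maps_b])
    A = A - A.mean(axis=1, keepdims=True)
    B = B - B.mean(axis=1, keepdims=True)
    A /= np.linalg.norm(A, axis=1, keepdims=True)
    B /= np.linalg.norm(B, axis=1, keepdims=True)
    corr = A @ B.T
    rows, cols = linear_sum_assignment(-np.abs(corr))
    pairs = list(zip(rows.tolist(), cols.tolist()))
    corrs = np.array([corr[i, j] for i, j in pairs])
    return pairs, corrs


def write_group_maps(g: GroupMapSet, path, labels_path=None):
    """Write maps as a single 4D NIfTI (component as 4th axis) plus a
    labels TSV."""
    import nibabel as nib

    affine = np.diag(list(g.voxel_size) + [1.0])
    nib.save(nib.Nifti1Image(np.moveaxis(g.maps, 0, -1), affine), str(path))
    if labels_path is not None:
        pd.DataFrame({
            "component": np.arange(1, g.K + 1),
            "name": g.names,
            "label": g.labels,
            "var_explained": g.var_explained,
        }).to_csv(labels_path, sep="\t", index=False)
    return Path(path)


def read_group_maps(path, labels_path=None,
                    mask: Optional[np.ndarray] = None) -> GroupMapSet:
    import nibabel as nib

    img = nib.load(str(path))
    maps = np.moveaxis(np.asarray(img.get_fdata()), -1, 0)
    K = maps.shape[0]
    if mask is None:
        mask = np.ones(maps.shape[1:], dtype=bool)
    labels = [SIGNAL] * K
    names = [f"IC{k + 1:02d}" for k in range(K)]
    var = np.full(K, np.nan)
    g = GroupMapSet(maps=maps, labels=labels, names=names, var_explained=var,
                    mask=mask, voxel_size=tuple(float(z) for z in
                                                img.header.get_zooms()[:3]))
    if labels_path is not None:
        g = label_components(g, labels_path)
    return g
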