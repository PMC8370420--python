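"""Cross-subject voxelwise inference on dual-regression beta maps.

The cross-subject model is an ordinary GLM per voxel with a single contrast
of interest. Inference is nonparametric: Freedman-Lane permutation of the
nuisance-residualised data, threshold-free cluster enhancement (TFCE) of
the resulting t-maps, and max-statistic family-wise error correction per
direction. Contrasts are two-tailed by convention: two one-sided
max-statistic tests, each judged at alpha = 0.025 (optionally Bonferroni
corrected across networks).

Model vocabulary (covariates follow the study's analysis plan):

* ``age``           -- effect of PMA at scan in term-born infants,
                       covariates sex + motion;
* ``sex``           -- effect of sex, covariates PMA at scan, GA at birth
                       and motion;
* ``preterm_group`` -- term vs preterm birth, covariates PMA at scan,
                       sex and motion;
* ``ga_continuous`` -- GA at birth as a continuous exposure, covariates
                       PMA at scan, sex and motion;
* ``group_mean``    -- mean connectivity (weekly-bin maps), covariates
                       sex and motion.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .io import SubjectMeta

MODELS = ("age", "sex", "preterm_group", "ga_continuous", "group_mean")

#: weekly PMA-at-scan bins (half-open [lo, hi)) for the group-average maps
DEFAULT_WEEKLY_BINS = (
    (37.5, 38.5), (38.5, 39.5), (39.5, 40.5), (40.5, 41.5), (41.5, 42.5),
)


@dataclass
class Design:
    """Cross-subject design matrix, contrast and permutation scheme."""

    matrix: np.ndarray  # n x p
    column_names: list
    contrast: np.ndarray  # length p
    nuisance_columns: list  # indices with zero contrast weight
    n_perm: int = 5000
    seed: int = 0

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.contrast = np.asarray(self.contrast, dtype=float)
        n, p = self.matrix.shape
        if self.contrast.shape != (p,):
            raise ValueError("contrast length must match design columns")
        if not self.contrast.any():
            raise ValueError("contrast must be non-zero")
        if np.linalg.matrix_rank(self.matrix) < p:
            raise ValueError("design matrix is rank deficient")
        if not any(np.allclose(self.matrix[:, j], 1.0) for j in range(p)):
            raise ValueError("design must contain an intercept column")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def p(self) -> int:
        return self.matrix.shape[1]


@dataclass
class TFCEParams:
    """Threshold-free cluster enhancement settings (volumetric defaults)."""

    E: float = 0.5
    H: float = 2.0
    n_steps: int = 100
    connectivity: int = 26

    def __post_init__(self):
        if self.E <= 0 or self.H < 0:
            raise ValueError("need E > 0 and H >= 0")
        if self.n_steps < 10:
            raise ValueError("need at least 10 integration steps")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")

    @property
    def structure(self) -> np.ndarray:
        level = {6: 1, 18: 2, 26: 3}[self.connectivity]
        return ndimage.generate_binary_structure(3, level)


@dataclass
class StatResult:
    """Observed statistics and the permutation null for one contrast."""

    t_map: np.ndarray
    tfce_map_pos: np.ndarray
    tfce_map_neg: np.ndarray
    p_fwe_pos: np.ndarray
    p_fwe_neg: np.ndarray
    null_max_pos: np.ndarray
    null_max_neg: np.ndarray
    n_perm_used: int
    exhaustive: bool = False


def _centre(x: np.ndarray) -> np.ndarray:
    return x - x.mean()


def _require_motion(metas: Sequence[SubjectMeta]):
    missing = [m.subject_id for m in metas if m.motion_outliers is None]
    if missing:
        raise ValueError(
            f"motion_outliers not set for subjects {missing}; run motion QC first"
        )


def build_design(metas: Sequence[SubjectMeta], model: str,
                 n_perm: int = 5000, seed: int = 0) -> Design:
    """Build the design matrix and contrast for one of the study models.

    Continuous covariates (PMA, GA, motion count) are mean-centred; sex and
    group are coded 0/1 (male = 1, preterm = 1). The ``age`` model is only
    valid for term-born subjects.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model '{model}'; choose from {MODELS}")
    if not metas:
        raise ValueError("no subjects supplied")
    _require_motion(metas)
    pma = np.array([m.pma_scan for m in metas])
    ga = np.array([m.ga_birth for m in metas])
    sex = np.array([1.0 if m.sex == "male" else 0.0 for m in metas])
    grp = np.array([1.0 if m.group == "preterm" else 0.0 for m in metas])
    motion = np.array([float(m.motion_outliers) for m in metas])
    ones = np.ones(len(metas))

    if model == "age":
        if grp.any():
            raise ValueError("the age model is restricted to term-born subjects")
        cols = [ones, _centre(pma), sex, _centre(motion)]
        names = ["intercept", "pma_scan", "sex", "motion"]
        contrast = [0.0, 1.0, 0.0, 0.0]
    elif model == "sex":
        cols = [ones, sex, _centre(pma), _centre(ga), _centre(motion)]
        names = ["intercept", "sex", "pma_scan", "ga_birth", "motion"]
        contrast = [0.0, 1.0, 0.0, 0.0, 0.0]
    elif model == "preterm_group":
        cols = [ones, grp, _centre(pma), sex, _centre(motion)]
        names = ["intercept", "group", "pma_scan", "sex", "motion"]
        contrast = [0.0, 1.0, 0.0, 0.0, 0.0]
    elif model == "ga_continuous":
        cols = [ones, _centre(ga), _centre(pma), sex, _centre(motion)]
        names = ["intercept", "ga_birth", "pma_scan", "sex", "motion"]
        contrast = [0.0, 1.0, 0.0, 0.0, 0.0]
    else:  # group_mean
        cols = [ones, sex, _centre(motion)]
        names = ["intercept", "sex", "motion"]
        contrast = [1.0, 0.0, 0.0]

    X = np.column_stack(cols)
    for j, name in enumerate(names):
        if name != "intercept" and np.ptp(X[:, j]) == 0:
            raise ValueError(f"column '{name}' is constant; degenerate design")
    contrast = np.asarray(contrast)
    nuisance = [j for j in range(X.shape[1]) if contrast[j] == 0]
    return Design(matrix=X, column_names=names, contrast=contrast,
                  nuisance_columns=nuisance, n_perm=n_perm, seed=seed)


def _tstats(Y: np.ndarray, X: np.ndarray, pinvX: np.ndarray,
            contrast: np.ndarray, cvar: float) -> np.ndarray:
    """Vectorised contrast t-statistics across voxels (Y is n x V)."""
    n, p = X.shape
    b = pinvX @ Y
    resid = Y - X @ b
    dof = n - p
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(sigma2 * cvar)
    num = contrast @ b
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, num / np.where(se > 0, se, 1.0),
                     np.sign(num) * 1e12)
    t[np.isnan(t)] = 0.0
    return t


def fit_glm_voxelwise(betas: np.ndarray, d: Design,
                      mask: Optional[np.ndarray] = None) -> np.ndarray:
    """Per-voxel OLS contrast t-map for an n-subject stack of beta maps."""
    betas = np.asarray(betas, dtype=float)
    n = betas.shape[0]
    if n != d.n:
        raise ValueError("subject count does not match the design")
    if n <= d.p:
        raise ValueError(f"need n > p (n={n}, p={d.p})")
    shape = betas.shape[1:]
    Y = betas.reshape(n, -1)
    if mask is not None:
        Y = Y[:, mask.ravel()]
    X = d.matrix
    pinvX = np.linalg.pinv(X)
    cvar = float(d.contrast @ np.linalg.inv(X.T @ X) @ d.contrast)
    t = _tstats(Y, X, pinvX, d.contrast, cvar)
    if mask is not None:
        out = np.zeros(shape)
        out[mask] = t
        return out
    return t.reshape(shape)


def tfce_enhance(stat: np.ndarray, params: TFCEParams = TFCEParams()) -> np.ndarray:
    """Threshold-free cluster enhancement of the positive part of a 3D map.

    TFCE(v) = sum over h = dh, 2dh, ..., max (dh = max / n_steps) of
    extent(v, h)^E * h^H * dh, where extent(v, h) is the size of the
    connected component containing v after thresholding at h (>= h).
    Negative effects are handled by enhancing the negated map.
    """
    stat = np.asarray(stat, dtype=float)
    if stat.ndim != 3:
        raise ValueError("TFCE expects a 3D map")
    if not np.isfinite(stat).all():
        raise ValueError("non-finite values in statistic map")
    from ._tfce_fast import tfce_transform

    return tfce_transform(stat, params.E, params.H, params.n_steps,
                          params.connectivity)


def _draw_permutations(n: int, n_perm: int, seed: int):
    """Distinct non-identity row permutations (exhaustive when feasible).

    Returns ``(perms, exhaustive)``; with exhaustive enumeration all
    n! - 1 non-identity permutations are returned so that, together with
    the always-counted identity, p-values are exact multiples of 1/n!.
    """
    total = math.factorial(n)
    identity = tuple(range(n))
    if total - 1 <= n_perm:
        perms = [np.array(p) for p in itertools.permutations(range(n))
                 if p != identity]
        return perms, True
    rng = np.random.default_rng(seed)
    seen = {identity}
    perms = []
    while len(perms) < n_perm:
        p = tuple(rng.permutation(n))
        if p not in seen:
            seen.add(p)
            perms.append(np.array(p))
    return perms, False


def permutation_fwe(
    betas: np.ndarray,
    d: Design,
    params: TFCEParams = TFCEParams(),
    mask: Optional[np.ndarray] = None,
    n_perm: Optional[int] = None,
    seed: Optional[int] = None,
) -> StatResult:
    """Freedman-Lane permutation inference with TFCE and max-statistic FWE.

    The data are residualised against the nuisance columns; permuted
    residuals plus the nuisance fit are refit under the full model, and the
    spatial maximum of each permutation's TFCE map (per direction) forms
    the null. The identity permutation is always counted, so
    ``p >= 1 / (n_perm + 1)`` and, under exhaustive enumeration, p-values
    are exact multiples of 1 / n!.
    """
    if n_perm is None:
        n_perm = d.n_perm
    if seed is None:
        seed = d.seed
    betas = np.asarray(betas, dtype=float)
    n = betas.shape[0]
    shape = betas.shape[1:]
    if n != d.n:
        raise ValueError("subject count does not match the design")
    if n <= d.p:
        raise ValueError(f"need n > p (n={n}, p={d.p})")
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    Y = betas.reshape(n, -1)[:, mask.ravel()]

    X = d.matrix
    pinvX = np.linalg.pinv(X)
    cvar = float(d.contrast @ np.linalg.inv(X.T @ X) @ d.contrast)

    def tfce_pair(tvec):
        tmap = np.zeros(shape)
        tmap[mask] = tvec
        return (tfce_enhance(tmap, params), tfce_enhance(-tmap, params))

    t_obs = _tstats(Y, X, pinvX, d.contrast, cvar)
    tfce_pos, tfce_neg = tfce_pair(t_obs)

    Z = X[:, d.nuisance_columns]
    if Z.size:
        Hz = Z @ np.linalg.pinv(Z)
        fit = Hz @ Y
        resid = Y - fit
    else:
        fit = np.zeros_like(Y)
        resid = Y
    perms, exhaustive = _draw_permutations(n, n_perm, seed)
    null_pos = np.empty(len(perms))
    null_neg = np.empty(len(perms))
    for i, perm in enumerate(perms):
        Yp = resid[perm] + fit
        tp = _tstats(Yp, X, pinvX, d.contrast, cvar)
        ep, en = tfce_pair(tp)
        null_pos[i] = ep.max()
        null_neg[i] = en.max()

    def pvals(obs, null):
        sorted_null = np.sort(null)
        counts = len(null) - np.searchsorted(sorted_null, obs[mask],
                                             side="left")
        p = np.ones(shape)
        p[mask] = (1.0 + counts) / (1.0 + len(null))
        return p

    t_map = np.zeros(shape)
    t_map[mask] = t_obs
    return StatResult(
        t_map=t_map, tfce_map_pos=tfce_pos, tfce_map_neg=tfce_neg,
        p_fwe_pos=pvals(tfce_pos, null_pos), p_fwe_neg=pvals(tfce_neg, null_neg),
        null_max_pos=null_pos, null_max_neg=null_neg,
        n_perm_used=len(perms), exhaustive=exhaustive,
    )


def threshold_results(r: StatResult, alpha: float = 0.025,
                      n_networks: int = 1, bonferroni: bool = False):
    """Significance masks per direction at strict ``p < alpha`` (optionally
    Bonferroni corrected across the networks tested)."""
    if not (0 < alpha <= 0.5):
        raise ValueError("alpha must lie in (0, 0.5]")
    cut = alpha / n_networks if bonferroni else alpha
    return r.p_fwe_pos < cut, r.p_fwe_neg < cut


def select_weekly_bins(
    metas: Sequence[SubjectMeta],
    bins: Sequence = DEFAULT_WEEKLY_BINS,
    n_per_bin: int = 20,
):
    """Assign term-born subjects to half-open weekly PMA bins and keep, per
    bin, the ``n_per_bin`` subjects with the lowest postnatal age (ties by
    subject_id). Returns a list of per-bin index lists into ``metas``."""
    selected = []
    for lo, hi in bins:
        cand = [i for i, m in enumerate(metas)
                if m.group == "term" and lo <= m.pma_scan < hi]
        if len(cand) < n_per_bin:
            raise ValueError(
                f"bin [{lo}, {hi}) has only {len(cand)} term subjects, "
                f"need {n_per_bin}"
            )
        cand.sort(key=lambda i: (metas[i].postnatal_days, metas[i].subject_id))
        selected.append(cand[:n_per_bin])
    return selected


def weekly_bin_maps(
    metas: Sequence[SubjectMeta],
    betas: np.ndarray,
    bins: Sequence = DEFAULT_WEEKLY_BINS,
    n_per_bin: int = 20,
    params: TFCEParams = TFCEParams(),
    mask: Optional[np.ndarray] = None,
    n_perm: int = 5000,
    seed: int = 0,
    alpha: float = 0.05,
):
    """Group-average connectivity maps in weekly PMA bins.

    Fits the group-mean design (covariates sex and motion) to each bin's
    subjects and runs the same TFCE/FWE machinery, thresholded at
    ``p < alpha``. Returns ``[(bin, StatResult, sig_mask_pos), ...]``.
    """
    _require_motion(metas)
    out = []
    for (lo, hi), idx in zip(bins, select_weekly_bins(metas, bins, n_per_bin)):
        sub_metas = [metas[i] for i in idx]
        d = build_design(sub_metas, "group_mean", n_perm=n_perm, seed=seed)
        r = permutation_fwe(betas[idx], d, params=params, mask=mask)
        sig_pos, _ = threshold_results(r, alpha=alpha)
        out.append(((lo, hi), r, sig_pos))
    return out
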