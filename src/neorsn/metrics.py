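"""Core network strength and its inferential analyses.

Core network strength is the mean dual-regression beta within the group
template of the same network thresholded at Z > 3: a single per-subject,
per-network summary of within-network connectivity. It is analysed three
ways, mirroring the study design:

* partial Spearman correlation with PMA at scan in term-born infants,
  controlling for sex and motion;
* a GLM for term vs preterm group differences controlling for PMA at scan,
  sex and motion; and
* the raw (uncorrected) percent reduction of preterm relative to term group
  means, with an unpaired t-test per network.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dualreg import SubjectDR
from .ica import SIGNAL, GroupMapSet
from .io import SubjectMeta

DEFAULT_Z_THRESHOLD = 3.0


@dataclass
class CoreStrengthRecord:
    subject_id: str
    network: str
    strength: float


@dataclass
class PartialAssocResult:
    network: str
    rho: float
    p: float
    n: int
    covariates: list


def core_mask(g: GroupMapSet, network_index: int,
              z_thr: float = DEFAULT_Z_THRESHOLD) -> np.ndarray:
    """Boolean template mask: group Z-map strictly above ``z_thr``."""
    m = (g.maps[network_index] > z_thr) & g.mask
    if not m.any():
        raise ValueError(
            f"empty core mask for component {network_index} at Z > {z_thr}"
        )
    return m


def core_network_strength(
    dr: SubjectDR, g: GroupMapSet, network_index: int,
    z_thr: float = DEFAULT_Z_THRESHOLD,
) -> CoreStrengthRecord:
    """Mean beta of the subject's map for one network within that
    network's Z > z_thr group template."""
    if g.labels[network_index] != SIGNAL:
        raise ValueError(f"component {network_index} is not labelled signal")
    m = core_mask(g, network_index, z_thr)
    strength = float(dr.beta_maps[network_index][m].mean())
    return CoreStrengthRecord(subject_id=dr.subject_id,
                              network=g.names[network_index],
                              strength=strength)


def strength_table(
    drs: Sequence[SubjectDR], g: GroupMapSet,
    z_thr: float = DEFAULT_Z_THRESHOLD,
) -> pd.DataFrame:
    """Subjects x signal-networks table of core network strengths."""
    idx = g.signal_indices
    rows = {}
    for dr in drs:
        rows[dr.subject_id] = {
            g.names[k]: core_network_strength(dr, g, k, z_thr).strength
            for k in idx
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "subject_id"
    return df[[g.names[k] for k in idx]]


def partial_spearman(
    x: np.ndarray, y: np.ndarray,
    covariates: Optional[np.ndarray] = None,
    network: str = "",
) -> PartialAssocResult:
    """Partial Spearman correlation of x and y given covariates.

    All variables are rank-transformed (average ranks for ties); ranked x
    and y are residualised on the ranked covariates plus an intercept, and
    rho is the Pearson correlation of the residuals. The p-value uses the
    t approximation with n - c - 2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if len(y) != n:
        raise ValueError("x and y must have the same length")
    if covariates is None:
        C = np.empty((n, 0))
    else:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
    c = C.shape[1]
    if n <= c + 2:
        raise ValueError(f"need n > c + 2 (n={n}, c={c})")
    for name, v in [("x", x), ("y", y)] + [(f"covariate {j}", C[:, j])
                                           for j in range(c)]:
        if np.ptp(v) == 0:
            raise ValueError(f"{name} is constant; correlation undefined")

    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    Z = np.column_stack([np.ones(n)] +
                        [stats.rankdata(C[:, j]) for j in range(c)])
    coef_x, *_ = np.linalg.lstsq(Z, rx, rcond=None)
    coef_y, *_ = np.linalg.lstsq(Z, ry, rcond=None)
    ex = rx - Z @ coef_x
    ey = ry - Z @ coef_y
    # a variable fully explained by the covariates has no residual variance
    # left to correlate: the partial association is zero by convention
    tiny = 1e-12 * n**3
    if np.dot(ex, ex) < tiny or np.dot(ey, ey) < tiny:
        return PartialAssocResult(network=network, rho=0.0, p=1.0, n=n,
                                  covariates=[f"c{j}" for j in range(c)])
    rho = float(np.dot(ex, ey) / np.sqrt(np.dot(ex, ex) * np.dot(ey, ey)))
    dof = n - c - 2
    rho_c = np.clip(rho, -1 + 1e-15, 1 - 1e-15)
    tstat = rho_c * np.sqrt(dof / (1 - rho_c**2))
    p = float(2 * stats.t.sf(abs(tstat), dof))
    return PartialAssocResult(network=network, rho=rho, p=p, n=n,
                              covariates=[f"c{j}" for j in range(c)])


def age_association(
    strengths: pd.DataFrame, metas: Sequence[SubjectMeta]
) -> pd.DataFrame:
    """Partial Spearman of core strength vs PMA at scan in term-born
    infants, controlling for sex and motion, one row per network."""
    metas = [m for m in metas if m.subject_id in strengths.index]
    term = [m for m in metas if m.group == "term"]
    if not term:
        raise ValueError("no term-born subjects available")
    pma = np.array([m.pma_scan for m in term])
    cov = np.column_stack([
        [1.0 if m.sex == "male" else 0.0 for m in term],
        [float(m.motion_outliers) for m in term],
    ])
    ids = [m.subject_id for m in term]
    rows = []
    for net in strengths.columns:
        r = partial_spearman(strengths.loc[ids, net].to_numpy(), pma,
                             covariates=cov, network=net)
        rows.append({"network": net, "rho": r.rho, "p": r.p, "n": r.n})
    return pd.DataFrame(rows)


def strength_group_glm(
    strengths: pd.DataFrame, metas: Sequence[SubjectMeta]
) -> tuple:
    """Term vs preterm GLM on core strength per network.

    OLS of strength on [intercept, group, PMA, sex, motion]; returns a
    result table (group coefficient, t, two-sided p per network) and a
    table of covariate-adjusted strengths (nuisance effects removed) for
    plotting group differences.
    """
    import statsmodels.api as sm

    metas = [m for m in metas if m.subject_id in strengths.index]
    groups = {m.group for m in metas}
    if len(groups) < 2:
        raise ValueError("need both term and preterm subjects")
    ids = [m.subject_id for m in metas]
    grp = np.array([1.0 if m.group == "preterm" else 0.0 for m in metas])
    pma = np.array([m.pma_scan for m in metas])
    sex = np.array([1.0 if m.sex == "male" else 0.0 for m in metas])
    motion = np.array([float(m.motion_outliers) for m in metas])
    X = np.column_stack([np.ones(len(ids)), grp, pma - pma.mean(), sex,
                         motion - motion.mean()])
    rows, adjusted = [], {}
    for net in strengths.columns:
        y = strengths.loc[ids, net].to_numpy()
        fit = sm.OLS(y, X).fit()
        rows.append({
            "network": net,
            "group_coef": fit.params[1],
            "t": fit.tvalues[1],
            "p": fit.pvalues[1],
            "n_term": int((grp == 0).sum()),
            "n_preterm": int((grp == 1).sum()),
        })
        # strip nuisance (PMA, sex, motion) effects, keep intercept + group
        adjusted[net] = y - X[:, 2:] @ fit.params[2:]
    adj = pd.DataFrame(adjusted, index=pd.Index(ids, name="subject_id"))
    adj["group"] = ["preterm" if v else "term" for v in grp.astype(bool)]
    return pd.DataFrame(rows), adj


def percent_reduction(
    strengths: pd.DataFrame, metas: Sequence[SubjectMeta]
) -> pd.DataFrame:
    """Uncorrected preterm strength reduction, percent of the term mean.

    100 * (mean_term - mean_preterm) / mean_term per network, on raw
    strengths, with an unpaired t-test. A non-positive term mean is
    reported with ``warning=True`` rather than raising.
    """
    metas = [m for m in metas if m.subject_id in strengths.index]
    term_ids = [m.subject_id for m in metas if m.group == "term"]
    pre_ids = [m.subject_id for m in metas if m.group == "preterm"]
    if not term_ids or not pre_ids:
        raise ValueError("need both term and preterm subjects")
    rows = []
    for net in strengths.columns:
        st = strengths.loc[term_ids, net].to_numpy()
        sp = strengths.loc[pre_ids, net].to_numpy()
        mt, mp = st.mean(), sp.mean()
        tstat, p = stats.ttest_ind(st, sp)
        rows.append({
            "network": net,
            "mean_term": mt,
            "mean_preterm": mp,
            "percent_reduction": 100.0 * (mt - mp) / mt if mt != 0 else np.nan,
            "t": tstat,
            "p": p,
            "warning": bool(mt <= 0),
        })
    return pd.DataFrame(rows)
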