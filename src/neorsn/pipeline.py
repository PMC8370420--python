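"""End-to-end in-memory analysis of a synthetic cohort.

Chains the stages the way the on-disk CLI does -- motion QC, group ICA,
component-to-truth matching, dual regression, core network strength -- but
keeps everything in memory, which is how the recovery experiments and the
worked examples drive the package.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .dualreg import dual_regress
from .ica import NOISE, SIGNAL, GroupMapSet, group_ica, label_components, match_maps
from .metrics import strength_table
from .qc import run_qc
from .simulate import Cohort, SynthConfig, simulate_cohort


@dataclass
class RecoveryResult:
    """Outcome of one seeded effect-recovery experiment."""

    seed: int
    match_corr: np.ndarray  # ICA-template vs truth |correlation| per network
    n_analysis: int
    n_excluded: int
    age_localised: list  # per slope network: significant voxels inside support
    age_n_sig: list
    percent_reduction: np.ndarray  # per network
    group_coef: np.ndarray
    group_p: np.ndarray
    age_rho: np.ndarray  # partial Spearman of strength vs PMA, per network


@dataclass
class CohortAnalysis:
    """Everything the in-memory pipeline produces for one cohort."""

    cohort: Cohort
    metas: list  # retained (non-excluded) subjects, motion counts filled
    group_maps: GroupMapSet  # labelled: matched-to-truth components = signal
    matched: list  # component index matched to each true network
    match_corr: np.ndarray  # |spatial correlation| of each match
    drs: list  # SubjectDR per retained subject
    betas: np.ndarray  # n_subjects x K x grid stack of beta maps
    strengths: pd.DataFrame  # subjects x signal networks
    n_excluded: int


def analyse_cohort(
    cfg: SynthConfig,
    ica_seed: int = 0,
    ica_K: Optional[int] = None,
    variance_normalise: bool = False,
) -> CohortAnalysis:
    """Simulate a cohort and run QC -> group ICA -> dual regression.

    ICA components are labelled by matching against the generator's true
    maps (the stand-in for manual labelling on synthetic data): the
    component Hungarian-matched to each true network is labelled signal and
    named after that network; the rest are noise regressors.
    """
    cohort = simulate_cohort(cfg)
    cropped, metas = [], []
    n_excluded = 0
    for bold, meta in zip(cohort.bolds, cohort.metas):
        _, _, cb = run_qc(bold, meta)
        if cb is None:
            n_excluded += 1
            continue
        cropped.append(cb)
        metas.append(meta)

    K = ica_K if ica_K is not None else cfg.K_signal + cfg.K_artifact
    g = group_ica(cropped, K=K, seed=ica_seed)
    pairs, corrs = match_maps(g.maps, cohort.truth.true_maps)
    comp_of_net = {ib: ia for ia, ib in pairs}
    corr_of_net = {ib: c for (ia, ib), c in zip(pairs, corrs)}
    matched = [comp_of_net[k] for k in range(cfg.K_signal)]
    labels = [NOISE] * g.K
    names = list(g.names)
    for k, comp in enumerate(matched):
        labels[comp] = SIGNAL
        names[comp] = f"net{k}"
        if corr_of_net[k] < 0:  # orient the template to the network
            g.maps[comp] *= -1.0
    g = label_components(g, labels)
    g.names = names

    drs = [dual_regress(b, g, variance_normalise=variance_normalise)
           for b in cropped]
    betas = np.stack([dr.beta_maps for dr in drs])
    strengths = strength_table(drs, g)
    return CohortAnalysis(
        cohort=cohort, metas=metas, group_maps=g, matched=matched,
        match_corr=np.array([abs(corr_of_net[k])
                             for k in range(cfg.K_signal)]),
        drs=drs, betas=betas, strengths=strengths, n_excluded=n_excluded,
    )


def recovery_config(seed: int, n_term: int = 84, n_preterm: int = 40,
                    T: int = 1000) -> SynthConfig:
    """Desk-scale study analogue: 4 networks (age slope 0.07/week on two),
    30% preterm attenuation, 2 artifact components, ~3% spiked volumes.

    ``n_term`` includes the 24 held-out template subjects, leaving 60
    term-born subjects for analysis alongside the 40 preterm-born.
    """
    return SynthConfig(
        grid=(16, 16, 10), T=T, K_signal=4, K_artifact=2, blob_sigma=1.5,
        n_term=n_term, n_preterm=n_preterm,
        age_slope=[0.07, 0.07, 0.0, 0.0], preterm_attenuation=0.30,
        sex_effect=None,
        seed=seed,
    )


def effect_recovery_experiment(
    seed: int,
    cfg: Optional[SynthConfig] = None,
    n_template: int = 24,
    n_perm: int = 500,
    alpha: float = 0.025,
) -> RecoveryResult:
    """One seeded run of the full analysis against known ground truth.

    Mirrors the study design: the last ``n_template`` term-born subjects
    are held out as the template group that defines the networks by group
    ICA; everyone else is analysed by dual regression against those
    templates. Measures (i) whether the PMA-at-scan contrast localises
    FWE-significant voxels inside each true age-effect support, (ii) the
    estimated percent preterm reduction per network, (iii) the group GLM
    coefficient on core network strength and (iv) the partial Spearman
    age association.
    """
    from .glm import build_design, permutation_fwe, threshold_results
    from .metrics import age_association, percent_reduction, strength_group_glm

    if cfg is None:
        cfg = recovery_config(seed)
    cohort = simulate_cohort(cfg)

    cropped, metas = [], []
    n_excluded = 0
    for bold, meta in zip(cohort.bolds, cohort.metas):
        _, _, cb = run_qc(bold, meta)
        if cb is None:
            n_excluded += 1
            continue
        cropped.append(cb)
        metas.append(meta)

    term_pos = [i for i, m in enumerate(metas) if m.group == "term"]
    template_pos = set(term_pos[-n_template:])
    analysis_pos = [i for i in range(len(metas)) if i not in template_pos]

    template = [cropped[i] for i in template_pos]
    g = None
    for attempt in range(3):  # ICA restart guidance: retry on a new seed
        try:
            g = group_ica(template, K=cfg.K_signal + cfg.K_artifact,
                          seed=seed + 1000 * attempt)
            break
        except RuntimeError:
            continue
    if g is None:
        raise RuntimeError("group ICA failed to converge after 3 restarts")
    pairs, corrs = match_maps(g.maps, cohort.truth.true_maps)
    comp_of_net = {ib: ia for ia, ib in pairs}
    corr_of_net = {ib: c for (ia, ib), c in zip(pairs, corrs)}
    matched = [comp_of_net[k] for k in range(cfg.K_signal)]
    labels = [NOISE] * g.K
    names = list(g.names)
    for k, comp in enumerate(matched):
        labels[comp] = SIGNAL
        names[comp] = f"net{k}"
        if corr_of_net[k] < 0:
            g.maps[comp] *= -1.0
    g = label_components(g, labels)
    g.names = names

    drs = [dual_regress(cropped[i], g, variance_normalise=True)
           for i in analysis_pos]
    ana_metas = [metas[i] for i in analysis_pos]
    strengths = strength_table(drs, g)

    # voxelwise age contrast in term-born analysis subjects
    term_idx = [j for j, m in enumerate(ana_metas) if m.group == "term"]
    d = build_design([ana_metas[j] for j in term_idx], "age",
                     n_perm=n_perm, seed=seed)
    slope_nets = [k for k in range(cfg.K_signal) if cfg.age_slopes[k] > 0]
    age_localised, age_n_sig = [], []
    for k in slope_nets:
        betas = np.stack([drs[j].beta_maps[matched[k]] for j in term_idx])
        r = permutation_fwe(betas, d)
        sig_pos, _ = threshold_results(r, alpha=alpha)
        support = cohort.truth.true_maps[k] > 0
        age_n_sig.append(int(sig_pos.sum()))
        # pass = at least one FWE-significant voxel inside the true support
        age_localised.append(bool((sig_pos & support).any()))

    pr = percent_reduction(strengths, ana_metas)
    res, _ = strength_group_glm(strengths, ana_metas)
    assoc = age_association(strengths, ana_metas)
    net_order = [f"net{k}" for k in range(cfg.K_signal)]
    pr = pr.set_index("network").loc[net_order]
    res = res.set_index("network").loc[net_order]
    assoc = assoc.set_index("network").loc[net_order]
    return RecoveryResult(
        seed=seed,
        match_corr=np.array([abs(corr_of_net[k])
                             for k in range(cfg.K_signal)]),
        n_analysis=len(analysis_pos), n_excluded=n_excluded,
        age_localised=age_localised, age_n_sig=age_n_sig,
        percent_reduction=pr["percent_reduction"].to_numpy(),
        group_coef=res["group_coef"].to_numpy(),
        group_p=res["p"].to_numpy(),
        age_rho=assoc["rho"].to_numpy(),
    )
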