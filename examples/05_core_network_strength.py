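"""Core network strength: per-subject within-network connectivity summaries.

Core network strength is the mean dual-regression beta inside the group
template thresholded at Z > 3. On a synthetic cohort with a 30% preterm
amplitude attenuation and a positive age slope, the full pipeline should
recover: a positive partial Spearman correlation of strength with PMA at
scan (term infants, controlling sex + motion), a negative term-vs-preterm
group coefficient, and a raw percent reduction near 30%.
"""
import numpy as np

from neorsn.pipeline import effect_recovery_experiment, recovery_config

cfg = recovery_config(seed=5)
print(f"cohort: {cfg.n_term} term + {cfg.n_preterm} preterm, grid {cfg.grid}, "
      f"T={cfg.T}; age slope {[float(s) for s in cfg.age_slopes]} per week; "
      f"preterm attenuation {cfg.preterm_attenuation}")

res = effect_recovery_experiment(seed=5, n_perm=300)
print(f"ICA template match to truth: {np.round(res.match_corr, 3)}")
print(f"analysis subjects: {res.n_analysis} ({res.n_excluded} excluded by QC)")
print(f"percent preterm reduction per network: "
      f"{np.round(res.percent_reduction, 1)} (generated: 30%)")
print(f"group GLM coefficient (preterm vs term): "
      f"{np.round(res.group_coef, 3)}, p = {res.group_p}")
print(f"partial Spearman rho (strength vs PMA, term only): "
      f"{np.round(res.age_rho, 2)} "
      f"(networks 0 and 1 carry the age effect)")
print(f"age contrast localised inside the true support: {res.age_localised}")
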