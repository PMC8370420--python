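"""DVARS motion QC on a full-length (2300-volume) acquisition.

DVARS is the root-mean-square intensity difference between successive
volumes. Volumes above Q3 + 1.5*IQR of the subject's own DVARS series are
motion outliers; the contiguous 1600-volume window with the fewest
outliers is retained, and a subject with more than 160 retained outliers
(10% of the window) would be excluded entirely.
"""
from neorsn import SynthConfig, compute_dvars, flag_outliers, run_qc, simulate_subject
from neorsn.io import SubjectMeta
from neorsn.simulate import make_ground_truth_maps

cfg = SynthConfig(grid=(10, 10, 6), T=2300, K_signal=2, K_artifact=1,
                  blob_sigma=1.2, spike_rate=0.03, seed=7)
maps = make_ground_truth_maps(cfg)
meta = SubjectMeta("sub-T001", ga_birth=40.0, pma_scan=41.2, sex="female",
                   postnatal_days=8)
bold, truth = simulate_subject(cfg, meta, maps, seed=123)

dvars = compute_dvars(bold)
outliers = flag_outliers(dvars)
crop, _, cropped = run_qc(bold, meta)

print(f"acquisition: {bold.n_volumes} volumes at TR {bold.tr}s")
print(f"DVARS outlier threshold: {outliers.threshold:.3f} "
      f"(Q3 + 1.5*IQR of this subject's own series)")
print(f"flagged outlier volumes: {int(outliers.flags.sum())} "
      f"(truly spiked: {len(truth.spiked_volumes)}; a spike also raises "
      f"DVARS at the following volume)")
print(f"retained window: {crop.length} volumes starting at {crop.start}")
print(f"outliers inside the window: {crop.outlier_count} "
      f"-> excluded: {crop.excluded} (rule: more than 160)")
print(f"motion covariate recorded for the GLMs: {meta.motion_outliers}")
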