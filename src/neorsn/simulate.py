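"""Synthetic multi-subject BOLD cohorts with known ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes in real neonatal resting-state data:

* K spatially fixed, smooth, midline-symmetric network maps shared across
  subjects (disjoint blob pairs mirrored across the x midline);
* per-subject band-limited (< 0.1 Hz) unit-variance network time courses;
* covariate-linked network amplitudes -- a linear effect of postmenstrual
  age at scan, a multiplicative attenuation for preterm-born subjects and a
  region-specific additive sex effect;
* structured artifact components (edge-localised rings with broadband time
  courses) so that component labelling has genuine negatives;
* iid Gaussian sensor noise; and
* motion spikes: whole volumes receiving an additive global intensity jump
  large enough to be flagged by the DVARS outlier rule.

Every quantity the generator draws is recorded in a :class:`CohortTruth`
so downstream stages can be tested by parameter recovery.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .io import Bold4D, SubjectMeta, write_bold, write_covariates

#: GA-at-birth ranges (weeks) for the two groups
TERM_GA_RANGE = (37.0, 42.3)
PRETERM_GA_RANGE = (24.3, 36.9)
#: PMA-at-scan range (weeks) for the analysis cohort
PMA_SCAN_RANGE = (37.0, 43.5)
#: network fluctuations are band-limited below this frequency (Hz)
LOWFREQ_CUTOFF_HZ = 0.1


@dataclass
class SexEffect:
    """Additive amplitude delta for female subjects on a subregion of one
    network (the half of the network's support with lower y index).
    Negative ``network`` indexes from the end (default: last network)."""

    network: int = -1
    delta: float = 0.2


@dataclass
class SynthConfig:
    """Generative settings for a synthetic cohort.

    Defaults mirror the study conditions: a 15-minute acquisition of 2300
    volumes at TR 0.392 s, 248 term and 65 preterm subjects, 11 signal
    networks, ~3% motion-spiked volumes, a 30% multiplicative preterm
    attenuation and a linear age effect of 0.07 amplitude units per week.
    The spatial grid is a desk-scale stand-in (registration and real
    geometry are outside this package's scope).
    """

    grid: tuple = (24, 24, 14)
    T: int = 2300
    tr: float = 0.392
    K_signal: int = 11
    K_artifact: int = 4
    n_term: int = 248
    n_preterm: int = 65
    base_amplitude: float = 1.0
    age_slope: Union[float, Sequence[float]] = 0.07
    preterm_attenuation: float = 0.30
    sex_effect: Optional[SexEffect] = field(default_factory=SexEffect)
    artifact_amplitude: float = 1.0
    spike_rate: float = 0.03
    spike_amplitude: Optional[float] = None
    noise_sd: float = 1.0
    voxel_size: tuple = (2.15, 2.15, 2.15)
    blob_sigma: float = 1.6
    seed: int = 0

    def validate(self):
        if self.K_signal < 1:
            raise ValueError("K_signal must be >= 1")
        if not (0 <= self.preterm_attenuation < 1):
            raise ValueError("preterm_attenuation must be in [0, 1)")
        if not (0 <= self.spike_rate < 0.3):
            raise ValueError("spike_rate must be in [0, 0.3)")
        for name in ("T", "n_term", "n_preterm"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.K_artifact < 0:
            raise ValueError("K_artifact must be >= 0")
        if self.sex_effect is not None and not (
            -self.K_signal <= self.sex_effect.network < self.K_signal
        ):
            raise ValueError("sex_effect.network out of range")

    @property
    def age_slopes(self) -> np.ndarray:
        """Per-network age slope vector (scalar broadcast to all networks)."""
        s = np.asarray(self.age_slope, dtype=float)
        if s.ndim == 0:
            return np.full(self.K_signal, float(s))
        if len(s) != self.K_signal:
            raise ValueError("age_slope vector length must equal K_signal")
        return s


@dataclass
class SubjectTruth:
    """Generative record for one subject."""

    subject_id: str
    amplitudes: np.ndarray  # K_signal network amplitudes a_k
    sex_delta: float  # extra amplitude on the sex subregion (0 if none)
    spiked_volumes: np.ndarray  # indices of spiked volumes
    seed: int


@dataclass
class CohortTruth:
    """Everything the generator drew, for recovery tests."""

    true_maps: np.ndarray  # K_signal x grid
    artifact_maps: np.ndarray  # K_artifact x grid
    sex_subregion: Optional[np.ndarray]  # boolean grid or None
    age_slopes: np.ndarray
    metas: list
    subjects: list  # SubjectTruth per subject

    @property
    def true_amplitudes(self) -> np.ndarray:
        return np.stack([s.amplitudes for s in self.subjects])

    @property
    def spiked_volumes(self) -> list:
        return [s.spiked_volumes for s in self.subjects]


@dataclass
class Cohort:
    """A simulated cohort: metadata, truth, and data in memory or on disk."""

    metas: list
    truth: CohortTruth
    bolds: Optional[list] = None  # in-memory Bold4D list
    paths: Optional[list] = None  # per-subject NIfTI paths
    covariates_path: Optional[Path] = None


def _gaussian_blob(grid, center, sigma):
    coords = np.meshgrid(*[np.arange(n, dtype=float) for n in grid], indexing="ij")
    d2 = sum((c - mu) ** 2 for c, mu in zip(coords, center))
    return np.exp(-d2 / (2.0 * sigma**2))


def make_ground_truth_maps(cfg: SynthConfig, rng=None) -> np.ndarray:
    """K_signal smooth, non-negative, midline-symmetric network maps.

    Each map is a pair of Gaussian blobs mirrored across the x midline,
    truncated to compact support and max-normalised to 1. Centres are
    rejection-sampled until all pairwise spatial correlations are < 0.2.
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    X, Y, Z = cfg.grid
    sigma = cfg.blob_sigma
    want = max(1, int(np.ceil(sigma)))
    mx = min(want, max(0, int(np.floor(X / 2 - 1))))
    my = min(want, (Y - 1) // 2)
    mz = min(want, (Z - 1) // 2)
    if X < 4 or Y < 3 or Z < 3:
        raise ValueError(f"grid {cfg.grid} too small for blobs of sigma {sigma}")
    d_min = 3.2 * sigma  # centre separation keeping blob overlap low

    def mirror(c):
        return (X - 1 - c[0], c[1], c[2])

    def build(c):
        m = _gaussian_blob(cfg.grid, c, sigma)
        m = m + _gaussian_blob(cfg.grid, mirror(c), sigma)
        m[m < 0.01 * m.max()] = 0.0
        return m / m.max()

    for _restart in range(50):
        centres: list = []
        placed = True
        for _k in range(cfg.K_signal):
            for _attempt in range(2000):
                c = (rng.uniform(mx, X / 2 - 0.5),
                     rng.uniform(my, Y - 1 - my),
                     rng.uniform(mz, Z - 1 - mz))
                others = centres + [mirror(p) for p in centres]
                if all(np.linalg.norm(np.subtract(c, p)) >= d_min
                       for p in others):
                    centres.append(c)
                    break
            else:
                placed = False
                break
        if not placed:
            continue
        maps = np.stack([build(c) for c in centres])
        if cfg.K_signal == 1:
            return maps
        corr = np.corrcoef(maps.reshape(cfg.K_signal, -1))
        np.fill_diagonal(corr, 0.0)
        if np.abs(corr).max() < 0.2:
            return maps
    raise ValueError(
        f"grid {cfg.grid} too small to place {cfg.K_signal} "
        "sufficiently uncorrelated networks"
    )


def make_artifact_maps(cfg: SynthConfig, rng=None) -> np.ndarray:
    """Edge-localised ring artifacts with smooth random weights."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    if cfg.K_artifact == 0:
        return np.zeros((0,) + tuple(cfg.grid))
    from scipy.ndimage import gaussian_filter

    shell = np.zeros(cfg.grid, dtype=bool)
    shell[0, :, :] = shell[-1, :, :] = True
    shell[:, 0, :] = shell[:, -1, :] = True
    shell[:, :, 0] = shell[:, :, -1] = True
    maps = []
    for _ in range(cfg.K_artifact):
        w = gaussian_filter(rng.standard_normal(cfg.grid), 1.5)
        m = np.abs(w) * shell
        maps.append(m / m.max())
    return np.stack(maps)


def lowfreq_timecourse(rng, T: int, tr: float,
                       cutoff_hz: float = LOWFREQ_CUTOFF_HZ) -> np.ndarray:
    """Zero-mean, unit-variance time course band-limited below ``cutoff_hz``.

    White noise is hard-limited in the frequency domain (all components
    above the cutoff zeroed); if the series is too short for any nonzero
    frequency under the cutoff the lowest available frequency is kept.
    """
    white = rng.standard_normal(T)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(T, d=tr)
    keep = freqs <= cutoff_hz
    keep[0] = False  # mean removed below anyway
    if not keep[1:].any():
        keep[1] = True
    spec[~keep] = 0.0
    s = np.fft.irfft(spec, n=T)
    s -= s.mean()
    sd = s.std()
    if sd == 0:
        raise RuntimeError("degenerate time course")
    return s / sd


def _sex_subregion(cfg: SynthConfig, true_maps: np.ndarray) -> Optional[np.ndarray]:
    if cfg.sex_effect is None:
        return None
    m = true_maps[cfg.sex_effect.network % cfg.K_signal]
    support = m > 0
    ys = np.where(support.any(axis=(0, 2)))[0]
    ymid = (ys.min() + ys.max() + 1) / 2.0
    sub = support.copy()
    sub[:, int(np.ceil(ymid)):, :] = False
    if not sub.any():
        sub = support
    return sub


def subject_amplitudes(cfg: SynthConfig, meta: SubjectMeta) -> np.ndarray:
    """Deterministic amplitude law: a_k = (base + slope_k*(PMA-40)),
    multiplied by (1 - attenuation) for preterm-born subjects."""
    a = cfg.base_amplitude + cfg.age_slopes * (meta.pma_scan - 40.0)
    if meta.group == "preterm":
        a = a * (1.0 - cfg.preterm_attenuation)
    return a


def default_spike_amplitude(cfg: SynthConfig) -> float:
    """A global jump comfortably above the DVARS baseline.

    Baseline DVARS is ~sqrt(2)*noise_sd plus a signal term; a jump of
    3*(noise_sd + base_amplitude) lands far above the Q3 + 1.5*IQR cut
    while staying in a realistic intensity range.
    """
    return 3.0 * (cfg.noise_sd + cfg.base_amplitude)


def simulate_subject(
    cfg: SynthConfig,
    meta: SubjectMeta,
    true_maps: np.ndarray,
    artifact_maps: Optional[np.ndarray] = None,
    seed: int = 0,
):
    """Generate one subject's 4D data and its truth record.

    data = sum_k a_k map_k s_k(t) + sex term + sum_j artifact_j u_j(t)
           + Gaussian noise + volume spikes.
    """
    rng = np.random.default_rng(seed)
    K = cfg.K_signal
    T = cfg.T
    a = subject_amplitudes(cfg, meta)

    tcs = np.stack([lowfreq_timecourse(rng, T, cfg.tr) for _ in range(K)])
    data = np.tensordot(a[:, None, None, None] * true_maps, tcs, axes=(0, 0))

    sex_delta = 0.0
    if cfg.sex_effect is not None and meta.sex == "female":
        sub = _sex_subregion(cfg, true_maps)
        k = cfg.sex_effect.network % cfg.K_signal
        sex_delta = cfg.sex_effect.delta
        data += sex_delta * np.multiply.outer(true_maps[k] * sub, tcs[k])

    if artifact_maps is not None and len(artifact_maps):
        for art in artifact_maps:
            u = rng.standard_normal(T)
            u = (u - u.mean()) / u.std()
            data += cfg.artifact_amplitude * np.multiply.outer(art, u)

    if cfg.noise_sd > 0:
        data += rng.normal(0.0, cfg.noise_sd, size=data.shape)

    spiked = np.array([], dtype=int)
    if cfg.spike_rate > 0:
        amp = (cfg.spike_amplitude if cfg.spike_amplitude is not None
               else default_spike_amplitude(cfg))
        spiked = 1 + np.where(rng.random(T - 1) < cfg.spike_rate)[0]
        data[..., spiked] += amp

    bold = Bold4D(data=data, voxel_size=cfg.voxel_size, tr=cfg.tr,
                  subject_id=meta.subject_id)
    truth = SubjectTruth(subject_id=meta.subject_id, amplitudes=a,
                         sex_delta=sex_delta, spiked_volumes=spiked, seed=seed)
    return bold, truth


def draw_metas(cfg: SynthConfig, rng) -> list:
    """Draw a cohort's covariates: GA at birth uniform on the group-specific
    range, PMA at scan uniform on [max(37, GA), 43.5], sex Bernoulli(1/2)."""
    metas = []
    specs = [("term", cfg.n_term, TERM_GA_RANGE), ("preterm", cfg.n_preterm,
                                                   PRETERM_GA_RANGE)]
    for group, n, (lo, hi) in specs:
        for i in range(n):
            ga = rng.uniform(lo, hi)
            pma = rng.uniform(max(PMA_SCAN_RANGE[0], ga), PMA_SCAN_RANGE[1])
            sex = "female" if rng.random() < 0.5 else "male"
            sid = f"sub-{'T' if group == 'term' else 'P'}{i + 1:03d}"
            metas.append(SubjectMeta(
                subject_id=sid, ga_birth=round(ga, 3), pma_scan=round(pma, 3),
                sex=sex, group=group,
                postnatal_days=float(int(round((pma - ga) * 7))),
            ))
    return metas


def simulate_cohort(cfg: SynthConfig, outdir=None) -> Cohort:
    """Simulate a full cohort.

    With ``outdir`` set, one NIfTI file per subject plus the covariate TSV,
    the true-map volumes and a JSON truth record are written there;
    otherwise the subject volumes are kept in memory (``cohort.bolds``).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    true_maps = make_ground_truth_maps(cfg, rng)
    artifact_maps = make_artifact_maps(cfg, rng)
    metas = draw_metas(cfg, rng)
    seeds = rng.integers(0, 2**31 - 1, size=len(metas))

    bolds, paths, subjects = [], [], []
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
    for meta, s in zip(metas, seeds):
        bold, struth = simulate_subject(cfg, meta, true_maps, artifact_maps,
                                        seed=int(s))
        subjects.append(struth)
        if outdir is not None:
            p = write_bold(bold, outdir / f"{meta.subject_id}_bold.nii.gz")
            paths.append(p)
        else:
            bolds.append(bold)

    truth = CohortTruth(
        true_maps=true_maps, artifact_maps=artifact_maps,
        sex_subregion=_sex_subregion(cfg, true_maps),
        age_slopes=cfg.age_slopes, metas=metas, subjects=subjects,
    )
    cohort = Cohort(metas=metas, truth=truth,
                    bolds=bolds if outdir is None else None,
                    paths=paths or None)
    if outdir is not None:
        cohort.covariates_path = write_covariates(metas, outdir / "covariates.tsv")
        _write_truth(cfg, truth, outdir)
    return cohort


def _write_truth(cfg: SynthConfig, truth: CohortTruth, outdir: Path):
    import nibabel as nib

    affine = np.diag(list(cfg.voxel_size) + [1.0])
    nib.save(nib.Nifti1Image(np.moveaxis(truth.true_maps, 0, -1), affine),
             str(outdir / "true_maps.nii.gz"))
    record = {
        "config": {k: (list(v) if isinstance(v, tuple) else
                       dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v)
                   for k, v in dataclasses.asdict(cfg).items()},
        "age_slopes": truth.age_slopes.tolist(),
        "subjects": [
            {
                "subject_id": s.subject_id,
                "amplitudes": np.round(s.amplitudes, 10).tolist(),
                "sex_delta": s.sex_delta,
                "spiked_volumes": s.spiked_volumes.tolist(),
                "seed": s.seed,
            }
            for s in truth.subjects
        ],
    }
    (outdir / "truth.json").write_text(json.dumps(record, indent=1))
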