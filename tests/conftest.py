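import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from neorsn import Bold4D, GroupMapSet, SubjectMeta, SynthConfig, simulate_cohort

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """A small in-memory cohort shared by several tests."""
    cfg = SynthConfig(
        grid=(16, 16, 10), T=120, K_signal=4, K_artifact=2,
        n_term=8, n_preterm=4, seed=7,
    )
    return cfg, simulate_cohort(cfg)


@pytest.fixture
def term_meta():
    return SubjectMeta(subject_id="sub-T001", ga_birth=40.0, pma_scan=41.0,
                       sex="female", postnatal_days=7, motion_outliers=5)


def make_mapset(maps, mask=None, labels=None):
    """Wrap raw 3D maps (K x grid) into a GroupMapSet for tests."""
    maps = np.asarray(maps, dtype=float)
    K = maps.shape[0]
    if mask is None:
        mask = np.ones(maps.shape[1:], dtype=bool)
    return GroupMapSet(
        maps=maps,
        labels=list(labels) if labels is not None else ["signal"] * K,
        names=[f"IC{k + 1:02d}" for k in range(K)],
        var_explained=np.full(K, np.nan),
        mask=mask,
        voxel_size=(1.0, 1.0, 1.0),
    )


def disjoint_sources(rng, shape, K, voxels_per_source=30):
    """Disjoint super-Gaussian (sparse plateau) spatial sources."""
    V = int(np.prod(shape))
    S = np.zeros((K, V))
    idx = rng.permutation(V)
    for k in range(K):
        S[k, idx[k * voxels_per_source:(k + 1) * voxels_per_source]] = 1.0
    return S.reshape((K,) + tuple(shape))


def mixture_subjects(rng, true_maps, n_subjects=3, T=40):
    """Noise-free 4D mixtures of the given spatial sources."""
    K = true_maps.shape[0]
    shape = true_maps.shape[1:]
    S = true_maps.reshape(K, -1)
    subs = []
    for i in range(n_subjects):
        A = rng.standard_normal((T, K))
        X = (A @ S).T.reshape(shape + (T,))
        subs.append(Bold4D(X, voxel_size=(1, 1, 1), tr=0.392,
                           subject_id=f"mix{i}"))
    return subs
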