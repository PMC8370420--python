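"""Core network strength, partial Spearman and group analyses."""
import numpy as np
import pytest
from scipy import stats

from neorsn import (
    SubjectMeta,
    core_network_strength,
    partial_spearman,
    percent_reduction,
    strength_group_glm,
    strength_table,
)
from neorsn.dualreg import SubjectDR
from neorsn.metrics import core_mask
from conftest import make_mapset


def _dr(betas, sid="s"):
    K = betas.shape[0]
    return SubjectDR(timecourses=np.zeros((2, K)), beta_maps=betas,
                     subject_id=sid)


def _mapset_with_core():
    maps = np.zeros((1, 4, 4, 2))
    maps[0, 1:3, 1:3, 0] = 5.0  # core: 4 voxels above Z>3
    maps[0, 0, 0, 1] = 2.0  # below threshold
    return make_mapset(maps)


class TestCoreStrength:
    def test_constant_beta_inside_mask(self):
        g = _mapset_with_core()
        betas = np.full((1, 4, 4, 2), 7.5)
        rec = core_network_strength(_dr(betas), g, 0)
        assert rec.strength == pytest.approx(7.5)

    def test_mean_of_toy_values(self):
        maps = np.zeros((1, 3, 1, 1))
        maps[0, :, 0, 0] = 5.0  # 3-voxel core
        g = make_mapset(maps)
        betas = np.array([1.0, 2.0, 6.0]).reshape(1, 3, 1, 1)
        assert core_network_strength(_dr(betas), g, 0).strength == \
            pytest.approx(3.0)

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(0)
        maps = 4 * rng.random((1, 6, 6, 3))
        g = make_mapset(maps)
        m1 = core_mask(g, 0, z_thr=1.0)
        m2 = core_mask(g, 0, z_thr=2.5)
        assert (m2 <= m1).all()

    def test_linear_in_beta(self):
        g = _mapset_with_core()
        rng = np.random.default_rng(1)
        betas = rng.standard_normal((1, 4, 4, 2))
        s1 = core_network_strength(_dr(betas), g, 0).strength
        s2 = core_network_strength(_dr(3.0 * betas), g, 0).strength
        assert s2 == pytest.approx(3.0 * s1)

    def test_empty_mask_and_noise_component_rejected(self):
        maps = np.full((1, 3, 3, 2), 1.0)  # never above Z>3
        g = make_mapset(maps)
        with pytest.raises(ValueError, match="empty core mask"):
            core_network_strength(_dr(np.zeros((1, 3, 3, 2))), g, 0)
        g2 = make_mapset(_mapset_with_core().maps, labels=["noise"])
        with pytest.raises(ValueError, match="not labelled signal"):
            core_network_strength(_dr(np.zeros((1, 4, 4, 2))), g2, 0)


class TestPartialSpearman:
    def test_monotone_without_covariates_is_one(self):
        x = np.array([1.0, 2, 3, 4, 5, 6])
        y = x**3  # strictly increasing
        r = partial_spearman(x, y)
        assert r.rho == pytest.approx(1.0)

    def test_matches_residual_rank_oracle(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(8)
        y = rng.standard_normal(8)
        C = rng.standard_normal((8, 2))
        r = partial_spearman(x, y, C)

        def rank(v):  # independent average-rank implementation
            order = np.argsort(v, kind="stable")
            ranks = np.empty(len(v))
            sv = v[order]
            i = 0
            while i < len(v):
                j = i
                while j + 1 < len(v) and sv[j + 1] == sv[i]:
                    j += 1
                ranks[order[i:j + 1]] = (i + j) / 2 + 1
                i = j + 1
            return ranks

        Z = np.column_stack([np.ones(8), rank(C[:, 0]), rank(C[:, 1])])
        ex = rank(x) - Z @ np.linalg.solve(Z.T @ Z, Z.T @ rank(x))
        ey = rank(y) - Z @ np.linalg.solve(Z.T @ Z, Z.T @ rank(y))
        rho = (ex @ ey) / np.sqrt((ex @ ex) * (ey @ ey))
        assert r.rho == pytest.approx(rho, abs=1e-10)

    def test_matches_pingouin(self):
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(3)
        df = pd.DataFrame({
            "x": rng.standard_normal(25),
            "y": rng.standard_normal(25),
            "c1": rng.standard_normal(25),
            "c2": rng.standard_normal(25),
        })
        df["y"] += 0.5 * df["x"]
        got = partial_spearman(df["x"].to_numpy(), df["y"].to_numpy(),
                               df[["c1", "c2"]].to_numpy())
        want = pg.partial_corr(df, x="x", y="y", covar=["c1", "c2"],
                               method="spearman")
        assert got.rho == pytest.approx(float(want["r"].iloc[0]), abs=1e-10)
        assert got.p == pytest.approx(float(want["p_val"].iloc[0]), rel=1e-6)

    def test_reduces_to_plain_spearman_without_covariates(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(30)
        y = x + rng.standard_normal(30)
        r = partial_spearman(x, y)
        rho, _ = stats.spearmanr(x, y)
        assert r.rho == pytest.approx(rho, abs=1e-10)

    def test_covariate_equal_to_x_kills_the_association(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(20)
        y = 2 * x + 0.01 * rng.standard_normal(20)
        r = partial_spearman(x, y, x[:, None])
        assert abs(r.rho) < 0.5  # x fully explained by the covariate

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            partial_spearman(np.ones(10), np.arange(10.0))


def _cohort_metas_and_strengths(rng, n_term=8, n_preterm=6, ratio=0.7,
                                noise=0.0):
    metas, rows = [], {}
    for i in range(n_term + n_preterm):
        group = "term" if i < n_term else "preterm"
        ga = 40.0 if group == "term" else 30.0
        pma = rng.uniform(40.5, 43)
        m = SubjectMeta(f"s{i:02d}", ga, pma, "male" if i % 2 else "female",
                        postnatal_days=float(int((pma - ga) * 7)),
                        motion_outliers=int(rng.integers(0, 10)))
        metas.append(m)
        base = 10.0 if group == "term" else 10.0 * ratio
        rows[m.subject_id] = {"net": base + noise * rng.standard_normal()}
    import pandas as pd

    return metas, pd.DataFrame.from_dict(rows, orient="index")


class TestGroupAnalyses:
    def test_null_group_difference_gives_small_t(self):
        rng = np.random.default_rng(6)
        metas, table = _cohort_metas_and_strengths(rng, ratio=1.0, noise=0.5)
        res, _ = strength_group_glm(table, metas)
        assert abs(res["t"].iloc[0]) < 3.0
        assert res["p"].iloc[0] > 0.01

    def test_six_row_toy_matches_scalar_ols(self):
        rng = np.random.default_rng(7)
        metas, table = _cohort_metas_and_strengths(rng, n_term=3, n_preterm=3,
                                                   noise=1.0)
        res, _ = strength_group_glm(table, metas)
        grp = np.array([0.0, 0, 0, 1, 1, 1])
        pma = np.array([m.pma_scan for m in metas])
        sex = np.array([1.0 if m.sex == "male" else 0.0 for m in metas])
        mot = np.array([float(m.motion_outliers) for m in metas])
        X = np.column_stack([np.ones(6), grp, pma - pma.mean(), sex,
                             mot - mot.mean()])
        y = table["net"].to_numpy()
        b = np.linalg.solve(X.T @ X, X.T @ y)
        assert res["group_coef"].iloc[0] == pytest.approx(b[1], abs=1e-10)

    def test_percent_reduction_arithmetic(self):
        rng = np.random.default_rng(8)
        metas, table = _cohort_metas_and_strengths(rng, ratio=0.7)
        pr = percent_reduction(table, metas)
        assert pr["percent_reduction"].iloc[0] == pytest.approx(30.0)
        assert not pr["warning"].iloc[0]

    def test_equal_means_give_zero_reduction(self):
        rng = np.random.default_rng(9)
        metas, table = _cohort_metas_and_strengths(rng, ratio=1.0)
        pr = percent_reduction(table, metas)
        assert pr["percent_reduction"].iloc[0] == pytest.approx(0.0)

    def test_nonpositive_term_mean_flags_warning(self):
        rng = np.random.default_rng(10)
        metas, table = _cohort_metas_and_strengths(rng)
        table["net"] = -table["net"]
        pr = percent_reduction(table, metas)
        assert pr["warning"].iloc[0]

    def test_single_group_rejected(self):
        rng = np.random.default_rng(11)
        metas, table = _cohort_metas_and_strengths(rng)
        term_only = [m for m in metas if m.group == "term"]
        with pytest.raises(ValueError, match="both"):
            strength_group_glm(table.loc[[m.subject_id for m in term_only]],
                               term_only)
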