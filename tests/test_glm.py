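"""Design building, voxelwise GLM, TFCE and permutation-FWE behaviour."""
import math

import numpy as np
import pytest
from scipy import stats

from neorsn import (
    SubjectMeta,
    TFCEParams,
    build_design,
    fit_glm_voxelwise,
    permutation_fwe,
    tfce_enhance,
    threshold_results,
)
from neorsn.glm import select_weekly_bins, weekly_bin_maps


def _metas(n, group="term", rng=None, motion=True):
    rng = rng or np.random.default_rng(0)
    out = []
    for i in range(n):
        ga = rng.uniform(37.5, 42.0) if group == "term" else rng.uniform(25, 36.5)
        pma = rng.uniform(max(37.0, ga), 43.4)
        out.append(SubjectMeta(
            subject_id=f"{group[0]}{i:03d}", ga_birth=ga, pma_scan=pma,
            sex="female" if i % 2 else "male", group=group,
            postnatal_days=float(int((pma - ga) * 7)),
            motion_outliers=int(rng.integers(0, 20)) if motion else None,
        ))
    return out


class TestBuildDesign:
    def test_age_model_columns_and_contrast(self):
        d = build_design(_metas(5), "age")
        assert d.column_names == ["intercept", "pma_scan", "sex", "motion"]
        assert list(d.contrast) == [0, 1, 0, 0]
        assert d.nuisance_columns == [0, 2, 3]

    def test_age_model_rejects_preterm(self):
        with pytest.raises(ValueError, match="term-born"):
            build_design(_metas(3) + _metas(2, "preterm"), "age")

    def test_group_model_requires_both_groups(self):
        with pytest.raises(ValueError, match="constant"):
            build_design(_metas(6), "preterm_group")

    def test_continuous_columns_are_centred(self):
        d = build_design(_metas(8) + _metas(4, "preterm"), "preterm_group")
        for name in ("pma_scan", "motion"):
            j = d.column_names.index(name)
            assert abs(d.matrix[:, j].mean()) < 1e-12

    def test_model_covariate_sets_follow_study_plan(self):
        metas = _metas(8) + _metas(4, "preterm")
        assert build_design(metas, "sex").column_names == [
            "intercept", "sex", "pma_scan", "ga_birth", "motion"]
        assert build_design(metas, "ga_continuous").column_names == [
            "intercept", "ga_birth", "pma_scan", "sex", "motion"]
        assert build_design(metas, "group_mean").column_names == [
            "intercept", "sex", "motion"]

    def test_missing_motion_covariate_raises(self):
        with pytest.raises(ValueError, match="motion"):
            build_design(_metas(5, motion=False), "age")


class TestVoxelwiseGLM:
    def test_matches_scalar_regression_oracle(self):
        rng = np.random.default_rng(1)
        metas = _metas(6, rng=rng)
        d = build_design(metas, "age")
        y = rng.standard_normal(6)
        t_map = fit_glm_voxelwise(y.reshape(6, 1, 1, 1), d)
        X = d.matrix
        b = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ b
        s2 = resid @ resid / (6 - X.shape[1])
        se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
        assert t_map[0, 0, 0] == pytest.approx(b[1] / se, abs=1e-10)

    def test_perfect_signal_gives_huge_t(self):
        metas = _metas(10)
        d = build_design(metas, "age")
        pma = np.array([m.pma_scan for m in metas])
        betas = (-3.0 * (pma - pma.mean())).reshape(10, 1, 1, 1)
        t = fit_glm_voxelwise(betas, d)[0, 0, 0]
        assert t < -1e6  # sign follows the (negative) coefficient

    def test_joint_row_permutation_invariance(self):
        rng = np.random.default_rng(2)
        metas = _metas(12, rng=rng)
        betas = rng.standard_normal((12, 4, 4, 2))
        d = build_design(metas, "age")
        t1 = fit_glm_voxelwise(betas, d)
        perm = rng.permutation(12)
        d2 = build_design([metas[i] for i in perm], "age")
        t2 = fit_glm_voxelwise(betas[perm], d2)
        assert np.abs(t1 - t2).max() < 1e-8

    def test_n_must_exceed_p(self):
        metas = _metas(4)
        d = build_design(metas, "age")
        with pytest.raises(ValueError, match="n > p"):
            fit_glm_voxelwise(np.zeros((4, 2, 2, 1)), d)


def tfce_oracle(stat, E=0.5, H=2.0, n_steps=100, conn=26):
    """Independent per-threshold flood-fill TFCE (pure python BFS)."""
    shape = stat.shape
    hmax = stat.max()
    out = np.zeros(shape)
    if hmax <= 0:
        return out
    if conn == 26:
        offs = [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1)
                for k in (-1, 0, 1) if (i, j, k) != (0, 0, 0)]
    elif conn == 6:
        offs = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                (0, 0, 1), (0, 0, -1)]
    else:
        raise ValueError(conn)
    dh = hmax / n_steps
    for i in range(1, n_steps + 1):
        h = i * dh
        mask = stat >= h
        seen = np.zeros(shape, dtype=bool)
        for idx in zip(*np.nonzero(mask)):
            if seen[idx]:
                continue
            comp = [idx]
            seen[idx] = True
            queue = [idx]
            while queue:
                cur = queue.pop()
                for o in offs:
                    nb = tuple(np.add(cur, o))
                    if all(0 <= nb[d] < shape[d] for d in range(3)) \
                            and mask[nb] and not seen[nb]:
                        seen[nb] = True
                        comp.append(nb)
                        queue.append(nb)
            contrib = (len(comp) ** E) * (h ** H) * dh
            for v in comp:
                out[v] += contrib
    return out


class TestTFCE:
    def test_all_zero_map(self):
        assert tfce_enhance(np.zeros((4, 4, 4))).max() == 0.0

    def test_single_voxel_riemann_sum(self):
        """An isolated unit-height voxel integrates to sum h^2 dh over the
        100 steps (-> 1/3 as the step count grows)."""
        stat = np.zeros((5, 5, 5))
        stat[2, 2, 2] = 1.0
        got = tfce_enhance(stat, TFCEParams())[2, 2, 2]
        dh = 1.0 / 100
        expect = sum((i * dh) ** 2 * dh for i in range(1, 101))
        assert got == pytest.approx(expect, abs=1e-12)
        assert expect == pytest.approx(1 / 3, abs=0.01)

    def test_two_plateaus_match_oracle(self):
        stat = np.zeros((8, 8, 8))
        stat[1:3, 1:3, 1:3] = 1.0
        stat[5:8, 5:8, 5:7] = 2.5
        got = tfce_enhance(stat)
        assert np.abs(got - tfce_oracle(stat)).max() < 1e-6

    def test_random_maps_match_oracle(self):
        rng = np.random.default_rng(3)
        for conn in (6, 26):
            stat = rng.standard_normal((6, 6, 6))
            stat = np.where(stat > 0.8, stat, 0.0)
            got = tfce_enhance(stat, TFCEParams(connectivity=conn, n_steps=30))
            want = tfce_oracle(stat, n_steps=30, conn=conn)
            assert np.abs(got - want).max() < 1e-6

    def test_monotone_in_the_stat_map(self):
        rng = np.random.default_rng(4)
        a = np.abs(rng.standard_normal((6, 6, 6)))
        b = a + np.abs(rng.standard_normal((6, 6, 6)))
        # evaluate both at the same thresholds for comparability
        pa = TFCEParams(n_steps=50)
        ta = tfce_enhance(a, pa)
        tb = tfce_enhance(b, pa)
        # coarse check: enhanced values cannot globally shrink
        assert tb.sum() >= ta.sum()
        assert tb.max() >= ta.max()


class TestPermutationFWE:
    def test_exhaustive_enumeration_p_multiples(self):
        """n=5 two-group toy: all 5! permutations are enumerated and p-values
        are exact multiples of 1/120."""
        from neorsn.glm import Design

        rng = np.random.default_rng(5)
        grp = np.array([0.0, 0, 0, 1, 1])
        d = Design(matrix=np.column_stack([np.ones(5), grp]),
                   column_names=["intercept", "group"],
                   contrast=np.array([0.0, 1.0]), nuisance_columns=[0],
                   n_perm=5000, seed=0)
        betas = rng.standard_normal((5, 3, 3, 2))
        r = permutation_fwe(betas, d)
        assert r.exhaustive and r.n_perm_used == math.factorial(5) - 1
        for p in (r.p_fwe_pos, r.p_fwe_neg):
            mult = p * 120
            assert np.abs(mult - np.round(mult)).max() < 1e-9

    def test_minimum_attainable_p(self):
        rng = np.random.default_rng(6)
        metas = _metas(12, rng=rng)
        pma = np.array([m.pma_scan for m in metas])
        d = build_design(metas, "age", n_perm=99, seed=1)
        betas = np.einsum("n,xyz->nxyz", pma - pma.mean(),
                          np.ones((3, 3, 2)))
        betas += 0.001 * rng.standard_normal(betas.shape)
        r = permutation_fwe(betas, d)
        assert r.p_fwe_pos.min() == pytest.approx(1 / 100)

    def test_freedman_lane_without_nuisance_is_plain_permutation(self):
        """With only the tested column + intercept-as-nuisance removed,
        residualising is an exact mean-shift: permuted statistics equal
        those from directly permuting the data rows."""
        rng = np.random.default_rng(7)
        n = 8
        x = rng.standard_normal(n)
        from neorsn.glm import Design, _tstats, _draw_permutations

        X = np.column_stack([np.ones(n), x])
        d = Design(matrix=X, column_names=["intercept", "x"],
                   contrast=np.array([0.0, 1.0]), nuisance_columns=[0],
                   n_perm=20, seed=3)
        Y = rng.standard_normal((n, 10))
        pinvX = np.linalg.pinv(X)
        cvar = float(d.contrast @ np.linalg.inv(X.T @ X) @ d.contrast)
        perms, _ = _draw_permutations(n, 20, 3)
        Z = X[:, [0]]
        Hz = Z @ np.linalg.pinv(Z)
        resid = Y - Hz @ Y
        for perm in perms[:5]:
            t_fl = _tstats(resid[perm] + Hz @ Y, X, pinvX, d.contrast, cvar)
            t_direct = _tstats(Y[perm], X, pinvX, d.contrast, cvar)
            assert np.abs(t_fl - t_direct).max() < 1e-10

    def test_thresholding_is_strict_and_bonferroni_divides(self):
        from neorsn.glm import StatResult

        p = np.full((2, 2, 1), 0.025)
        p[0, 0, 0] = 0.024
        p[1, 1, 0] = 0.002
        r = StatResult(t_map=np.zeros((2, 2, 1)),
                       tfce_map_pos=np.zeros((2, 2, 1)),
                       tfce_map_neg=np.zeros((2, 2, 1)),
                       p_fwe_pos=p, p_fwe_neg=np.ones((2, 2, 1)),
                       null_max_pos=np.zeros(10), null_max_neg=np.zeros(10),
                       n_perm_used=10)
        pos, neg = threshold_results(r, alpha=0.025)
        assert pos.sum() == 2 and not neg.any()  # 0.025 itself excluded
        pos_b, _ = threshold_results(r, alpha=0.025, n_networks=11,
                                     bonferroni=True)
        assert pos_b.sum() == 1  # only p=0.002 < 0.025/11


class TestWeeklyBins:
    def _term_metas(self):
        rng = np.random.default_rng(8)
        metas = []
        i = 0
        for lo in (37.5, 38.5, 39.5, 40.5, 41.5):
            for _ in range(7):
                pma = rng.uniform(lo, lo + 1.0)
                ga = min(pma, rng.uniform(37.0, 41.5))
                metas.append(SubjectMeta(
                    subject_id=f"t{i:03d}", ga_birth=ga, pma_scan=pma,
                    sex="male" if i % 2 else "female", group="term",
                    postnatal_days=float(int((pma - ga) * 7)),
                    motion_outliers=int(rng.integers(0, 10))))
                i += 1
        return metas

    def test_half_open_bin_edges(self):
        m = SubjectMeta("edge", 38.0, 38.5, "male", postnatal_days=3,
                        motion_outliers=0)
        sel = select_weekly_bins([m] + self._term_metas(),
                                 bins=[(37.5, 38.5), (38.5, 39.5)],
                                 n_per_bin=5)
        # pma exactly 38.5 falls in the second bin
        assert 0 not in sel[0] and 0 in sel[1]

    def test_lowest_postnatal_days_selected(self):
        metas = self._term_metas()
        sel = select_weekly_bins(metas, bins=[(37.5, 38.5)], n_per_bin=5)[0]
        cand = [i for i, m in enumerate(metas)
                if 37.5 <= m.pma_scan < 38.5]
        dropped = set(cand) - set(sel)
        worst_kept = max(metas[i].postnatal_days for i in sel)
        assert all(metas[i].postnatal_days >= worst_kept for i in dropped)

    def test_underfilled_bin_raises(self):
        with pytest.raises(ValueError, match=r"bin \[37.5, 38.5\)"):
            select_weekly_bins(self._term_metas(), n_per_bin=20)

    def test_bin_mean_maps_recover_support(self):
        """With a constant network amplitude, each bin's group t-map peaks
        inside the true map support."""
        rng = np.random.default_rng(9)
        metas = self._term_metas()
        support = np.zeros((6, 6, 4), dtype=bool)
        support[1:3, 1:4, 1:3] = True
        betas = np.stack([
            2.0 * support + 0.3 * rng.standard_normal(support.shape)
            for _ in metas
        ])
        out = weekly_bin_maps(metas, betas, n_per_bin=7, n_perm=30, seed=0)
        assert len(out) == 5
        for (_, r, _sig) in out:
            peak = np.unravel_index(np.argmax(r.t_map), r.t_map.shape)
            assert support[peak]
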