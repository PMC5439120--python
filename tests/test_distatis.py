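"""Joint DISTATIS tests, including an independent dense-algebra oracle."""

import numpy as np
import pytest

from mmrtf import distatis
from mmrtf.mmr import MMRSurface


def surface(p, subject="s", condition="c"):
    p = np.asarray(p, dtype=float)
    return MMRSurface(
        p=p,
        scale_freqs_hz=np.geomspace(2, 48, p.shape[0]),
        time_ms=np.linspace(-100, 700, p.shape[1]),
        subject=subject,
        condition=condition,
    )


def random_surfaces(rng, n=6, shape=(5, 5), conditions=("a", "b", "c")):
    out = []
    for i in range(n):
        out.append(
            surface(rng.random(shape), subject=f"s{i}", condition=conditions[i % len(conditions)])
        )
    return out


# ---------------------------------------------------------------------------
# independent naive oracle (plain loops, no shared code paths)

def oracle_center_normalize(cp):
    n = cp.shape[0]
    m = np.full(n, 1.0 / n)
    xi = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            xi[i, j] = (1.0 if i == j else 0.0) - m[j]
    s0 = -0.5 * xi @ cp @ xi.T
    evals = np.linalg.eigvalsh(s0)
    lam1 = evals[int(np.argmax(np.abs(evals)))]
    return 0.5 * ((s0 / lam1) + (s0 / lam1).T)


def oracle_chain(surfaces, pvaf_min=0.01):
    by_cond_f, by_cond_t = {}, {}
    for s in surfaces:
        p = s.p
        sf = oracle_center_normalize(p @ p.T)
        st = oracle_center_normalize(p.T @ p)
        by_cond_f.setdefault(s.condition, []).append(sf)
        by_cond_t.setdefault(s.condition, []).append(st)
    cond_f = {d: sum(v) / len(v) for d, v in by_cond_f.items()}
    cond_t = {d: sum(v) / len(v) for d, v in by_cond_t.items()}
    grand_f = sum(cond_f.values()) / len(cond_f)
    grand_t = sum(cond_t.values()) / len(cond_t)

    def weights(mat):
        evals, evecs = np.linalg.eigh(mat)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        roots = np.sqrt(np.clip(evals, 0, None))
        pvaf = roots / roots.sum()
        keep = pvaf >= pvaf_min
        if not keep.any():
            keep[0] = True
        w = evecs[:, keep]
        return w / np.linalg.norm(w, axis=0, keepdims=True), float(evals[0])

    w_f, lam_f = weights(grand_f)
    w_t, lam_t = weights(grand_t)
    rc_f = lam_f / (lam_f + lam_t)
    rc_t = lam_t / (lam_f + lam_t)
    projections = []
    for s in surfaces:
        p = s.p
        proj = rc_f * (w_f @ w_f.T @ p) + (rc_t * (w_t @ w_t.T @ p.T)).T
        projections.append((s.subject, s.condition, proj))
    by_cond = {}
    for _, c, pm in projections:
        by_cond.setdefault(c, []).append(pm)
    g = {c: sum(v) / len(v) for c, v in by_cond.items()}
    grand = sum(g.values()) / len(g)
    pool = np.concatenate([grand.ravel()] + [v.ravel() for v in g.values()])
    lo, hi = pool.min(), pool.max()
    g = {c: (v - lo) / (hi - lo) for c, v in g.items()}
    grand = (grand - lo) / (hi - lo)
    return grand, g, rc_f, rc_t


# ---------------------------------------------------------------------------


class TestCrossProducts:
    def test_shared_nonzero_eigenvalues(self, rng):
        s = surface(rng.random((6, 9)))
        cp = distatis.cross_products(s)
        ef = np.sort(np.linalg.eigvalsh(cp.cp_f))[::-1]
        et = np.sort(np.linalg.eigvalsh(cp.cp_t))[::-1]
        assert np.allclose(ef[:6], et[:6], atol=1e-8)

    def test_rank_one_surface(self):
        u, v = np.arange(1.0, 5.0), np.arange(1.0, 7.0)
        s = surface(np.outer(u, v))
        cp = distatis.cross_products(s)
        assert np.allclose(cp.cp_f, np.outer(u, u) * (v @ v))

    def test_toy_integers_hand_computed(self):
        p = np.array([[1.0, 2.0, 0.0, 1.0], [0.0, 1.0, 1.0, 0.0], [2.0, 0.0, 1.0, 1.0]])
        cp = distatis.cross_products(surface(p))
        assert cp.cp_f[0, 1] == pytest.approx(1 * 0 + 2 * 1 + 0 * 1 + 1 * 0)
        assert cp.cp_f[0, 2] == pytest.approx(1 * 2 + 0 + 0 + 1 * 1)
        assert cp.cp_t[0, 3] == pytest.approx(1 * 1 + 0 + 2 * 1)


class TestCenterAndNormalize:
    def test_row_column_means_zero_and_unit_top_eigenvalue(self, rng):
        s = surface(rng.random((7, 7)))
        cp = distatis.center_and_normalize(distatis.cross_products(s))
        for mat in (cp.s_f, cp.s_t):
            assert np.allclose(mat.mean(axis=0), 0.0, atol=1e-10)
            assert np.allclose(mat.mean(axis=1), 0.0, atol=1e-10)
            evals = np.linalg.eigvalsh(mat)
            assert np.isclose(evals.max(), 1.0, atol=1e-10)

    def test_matches_textbook_double_centering(self, rng):
        p = rng.random((4, 4))
        cp = distatis.center_and_normalize(distatis.cross_products(surface(p)))
        assert np.allclose(cp.s_f, oracle_center_normalize(p @ p.T), atol=1e-12)

    def test_degenerate_surface_raises(self):
        s = surface(np.ones((4, 4)))  # centered Gram is exactly zero
        with pytest.raises(ValueError, match="degenerate"):
            distatis.center_and_normalize(distatis.cross_products(s))


class TestBuildCompromise:
    def test_identical_inputs_reproduced(self, rng):
        p = rng.random((5, 5))
        surfs = [surface(p, subject=f"s{i}", condition="abc"[i % 3]) for i in range(6)]
        cps = [distatis.center_and_normalize(distatis.cross_products(s)) for s in surfs]
        cs = distatis.build_compromise(cps)
        assert np.allclose(cs.grand_f, cps[0].s_f, atol=1e-12)

    def test_conditions_equally_weighted_despite_sizes(self, rng):
        # unbalanced condition sizes with distinct per-condition surfaces:
        # the grand compromise is the mean of condition means, not the pooled mean
        base = {c: rng.random((5, 5)) for c in "abc"}
        surfs = []
        for c, n in zip("abc", (1, 2, 8)):
            surfs += [surface(base[c], subject=f"{c}{i}", condition=c) for i in range(n)]
        cps = [distatis.center_and_normalize(distatis.cross_products(s)) for s in surfs]
        cs = distatis.build_compromise(cps)
        expected = np.mean(
            [distatis.center_and_normalize(distatis.cross_products(surface(base[c]))).s_f
             for c in "abc"], axis=0)
        assert np.allclose(cs.grand_f, expected, atol=1e-12)

    def test_compromise_psd(self, rng):
        surfs = random_surfaces(rng)
        cps = [distatis.center_and_normalize(distatis.cross_products(s)) for s in surfs]
        cs = distatis.build_compromise(cps)
        assert np.linalg.eigvalsh(cs.grand_f).min() > -1e-10


class TestSelectWeights:
    def test_pvaf_from_eigenvalue_roots(self):
        cs = distatis.CompromiseSet(
            condition_f={}, condition_t={},
            grand_f=np.diag([4.0, 1.0]), grand_t=np.diag([4.0, 1.0]),
            evals_f=np.array([4.0, 1.0]), evecs_f=np.eye(2),
            evals_t=np.array([4.0, 1.0]), evecs_t=np.eye(2),
        )
        cs = distatis.select_weights(cs)
        assert np.allclose(cs.pvaf_f, [2 / 3, 1 / 3])

    def test_rc_sums_to_one_and_symmetric_case(self, rng):
        surfs = random_surfaces(rng)
        cps = [distatis.center_and_normalize(distatis.cross_products(s)) for s in surfs]
        cs = distatis.select_weights(distatis.build_compromise(cps))
        assert cs.rc_f + cs.rc_t == pytest.approx(1.0, abs=1e-12)
        # retained weight vectors unit norm
        assert np.allclose(np.linalg.norm(cs.w_f, axis=0), 1.0, atol=1e-12)
        assert np.allclose(np.linalg.norm(cs.w_t, axis=0), 1.0, atol=1e-12)


class TestProject:
    def full_rank_cs(self, rng, shape=(5, 5)):
        surfs = random_surfaces(rng, shape=shape)
        cps = [distatis.center_and_normalize(distatis.cross_products(s)) for s in surfs]
        return surfs, distatis.select_weights(distatis.build_compromise(cps), pvaf_min=0.0)

    def test_full_basis_identity_with_equal_rc(self, rng):
        surfs, cs = self.full_rank_cs(rng)
        if cs.w_f.shape[1] == 5 and cs.w_t.shape[1] == 5:
            cs.rc_f = cs.rc_t = 0.5
            p = surfs[0].p
            assert np.allclose(distatis.project(surfs[0], cs), p, atol=1e-8)

    def test_projection_idempotent_per_dimension(self, rng):
        surfs = random_surfaces(rng)
        cps = [distatis.center_and_normalize(distatis.cross_products(s)) for s in surfs]
        cs = distatis.select_weights(distatis.build_compromise(cps))
        p = surfs[0].p
        once = cs.w_f @ (cs.w_f.T @ p)
        twice = cs.w_f @ (cs.w_f.T @ once)
        assert np.allclose(once, twice, atol=1e-10)

    def test_orthogonal_surface_projects_to_zero(self, rng):
        surfs = random_surfaces(rng)
        cps = [distatis.center_and_normalize(distatis.cross_products(s)) for s in surfs]
        cs = distatis.select_weights(distatis.build_compromise(cps))
        if cs.w_f.shape[1] < 5 and cs.w_t.shape[1] < 5:
            # build a surface inside the discarded subspaces
            null_f = np.eye(5) - cs.w_f @ cs.w_f.T
            null_t = np.eye(5) - cs.w_t @ cs.w_t.T
            vec_f = null_f @ np.ones(5)
            vec_t = null_t @ np.arange(5.0)
            s = surface(np.outer(vec_f, vec_t))
            assert np.abs(distatis.project(s, cs)).max() < 1e-8

    def test_truncated_projection_never_increases_norm(self, rng):
        surfs = random_surfaces(rng, n=9, shape=(6, 8))
        cps = [distatis.center_and_normalize(distatis.cross_products(s)) for s in surfs]
        cs = distatis.select_weights(distatis.build_compromise(cps))
        for s in surfs:
            p_f = cs.w_f @ (cs.w_f.T @ s.p)
            assert np.linalg.norm(p_f) <= np.linalg.norm(s.p) + 1e-10

    def test_shape_mismatch_raises(self, rng):
        surfs = random_surfaces(rng)
        cps = [distatis.center_and_normalize(distatis.cross_products(s)) for s in surfs]
        cs = distatis.select_weights(distatis.build_compromise(cps))
        with pytest.raises(ValueError, match="shape"):
            distatis.project(surface(np.ones((3, 3)) + np.eye(3)), cs)


class TestAggregate:
    def test_single_member_condition_mean_is_member(self, rng):
        pmats = [("s0", "a", rng.random((4, 4))), ("s1", "b", rng.random((4, 4)))]
        ps = distatis.aggregate(pmats)
        assert np.allclose(ps.raw_condition_means["a"], pmats[0][2])

    def test_all_equal_grand_is_that_surface(self, rng):
        p = rng.random((4, 4))
        ps = distatis.aggregate([("s0", "a", p), ("s1", "b", p.copy())])
        assert np.allclose(ps.raw_grand_mean, p)

    def test_rescaled_range(self, rng):
        pmats = [(f"s{i}", "ab"[i % 2], rng.standard_normal((4, 4))) for i in range(6)]
        ps = distatis.aggregate(pmats)
        pool = np.concatenate(
            [ps.grand_mean.ravel()] + [v.ravel() for v in ps.condition_means.values()]
        )
        assert pool.min() == pytest.approx(0.0, abs=1e-12)
        assert pool.max() == pytest.approx(1.0, abs=1e-12)

    def test_duplicating_condition_members_leaves_grand_unchanged(self, rng):
        pmats = [(f"s{i}", "abc"[i % 3], rng.random((4, 4))) for i in range(6)]
        doubled = pmats + [(s + "_dup", c, p) for s, c, p in pmats if c == "a"]
        g1 = distatis.aggregate(pmats).raw_grand_mean
        g2 = distatis.aggregate(doubled).raw_grand_mean
        assert np.allclose(g1, g2, atol=1e-12)


class TestFullChainOracle:
    def test_matches_naive_dense_implementation(self, rng):
        surfs = random_surfaces(rng, n=9, shape=(5, 5))
        cs, ps = distatis.group_analysis(surfs)
        grand_o, g_o, rc_f_o, rc_t_o = oracle_chain(surfs)
        assert cs.rc_f == pytest.approx(rc_f_o, abs=1e-10)
        assert np.max(np.abs(ps.grand_mean - grand_o)) < 1e-8
        for c in g_o:
            assert np.max(np.abs(ps.condition_means[c] - g_o[c])) < 1e-8
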