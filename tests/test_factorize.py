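"""Clone-mixture factorization: forward model, solver, model selection."""

import itertools

import numpy as np
import pytest

from hapclone.factorize import (CloneMixture, CloneMixtureSolver,
                                _simplex_lsq, enumerate_states,
                                expected_observables, label_events,
                                model_select, solve_fixed)
from hapclone.factorize import profiles_match as match_profiles
from hapclone.simulate import random_clone_mixture


def mixture(a, b, u, **kw):
    return CloneMixture(cn_a=np.asarray(a), cn_b=np.asarray(b),
                        u=np.asarray(u, dtype=float), **kw)


class TestExpectedObservables:
    def test_pure_normal(self):
        mix = mixture([[1, 1]], [[1, 1]], [[1.0]])
        r, b = expected_observables(mix, [1, 1])
        assert r == pytest.approx(np.ones((2, 1)))
        assert b == pytest.approx(np.full((2, 1), 0.5))

    def test_purity_one_single_clone(self):
        mix = mixture([[1, 1], [1, 1]], [[1, 1], [1, 0]], [[0.0], [1.0]])
        r, b = expected_observables(mix, [1, 1])
        assert r.ravel() == pytest.approx([4 / 3, 2 / 3])
        assert b.ravel() == pytest.approx([0.5, 0.0])

    def test_half_tumor_loh_and_neutral(self):
        mix = mixture([[1, 1], [2, 1]], [[1, 1], [0, 1]], [[0.5], [0.5]])
        r, b = expected_observables(mix, [1, 1])
        assert r.ravel() == pytest.approx([1.0, 1.0])
        assert b.ravel() == pytest.approx([0.25, 0.5])

    def test_weighted_mean_rdr_is_one(self, rng):
        for seed in range(5):
            mix, R, B, w = random_clone_mixture(seed)
            assert (w[:, None] * R).sum(axis=0) / w.sum() == pytest.approx(
                np.ones(R.shape[1]), abs=1e-10)
            assert (B >= 0).all() and (B <= 1).all()


class TestSimplexLSQ:
    def test_matches_scipy_on_random_instances(self, rng):
        from scipy.optimize import minimize

        for _ in range(25):
            n = int(rng.integers(2, 6))
            M = rng.normal(0, 1, (8, n))
            y = rng.normal(0, 1, 8)
            H, g = M.T @ M, M.T @ y
            u = _simplex_lsq(H, g)
            assert u.sum() == pytest.approx(1.0, abs=1e-9)
            assert (u >= -1e-12).all()
            ref = minimize(lambda v: 0.5 * v @ H @ v - g @ v,
                           np.full(n, 1 / n), method="SLSQP",
                           bounds=[(0, 1)] * n,
                           constraints={"type": "eq",
                                        "fun": lambda v: v.sum() - 1})
            obj = 0.5 * u @ H @ u - g @ u
            assert obj <= ref.fun + 1e-7


class TestSolveFixed:
    def test_pure_normal_zero_objective(self):
        mix, obj = solve_fixed(1, np.ones((2, 1)), np.full((2, 1), 0.5),
                               weights=[1, 1], seed=0)
        assert obj < 1e-12

    def test_inverse_of_forward_loh_example(self):
        mix, obj = solve_fixed(1, [[4 / 3], [2 / 3]], [[0.5], [0.0]],
                               weights=[1, 1], seed=0)
        assert obj < 1e-10
        assert mix.u[1, 0] == pytest.approx(1.0, abs=1e-6)
        states = sorted(zip(mix.cn_a[1], mix.cn_b[1]))
        assert states == [(1, 0), (1, 1)]

    def test_inverse_of_half_tumor_example(self):
        mix, obj = solve_fixed(1, [[1.0], [1.0]], [[0.25], [0.5]],
                               weights=[1, 1], seed=0)
        assert obj < 1e-10
        assert mix.u[1, 0] == pytest.approx(0.5, abs=1e-6)
        assert (mix.cn_a[1, 0], mix.cn_b[1, 0]) == (2, 0)
        assert (mix.cn_a[1, 1], mix.cn_b[1, 1]) == (1, 1)

    def test_proportions_on_simplex_always(self):
        for seed in range(5):
            mix, R, B, w = random_clone_mixture(seed + 100)
            got, obj = solve_fixed(mix.n_clones, R, B, weights=w, seed=seed)
            assert got.u.sum(axis=0) == pytest.approx(
                np.ones(got.u.shape[1]), abs=1e-8)
            assert (got.u >= -1e-10).all()
            got.validate(c_max=4)

    def test_enumeration_budget_error(self):
        with pytest.raises(ValueError, match="budget"):
            solve_fixed(5, np.ones((20, 1)), np.full((20, 1), 0.5),
                        c_max=8, enum_budget=1000)

    @pytest.mark.parametrize("m,n_seg", [(1, 3), (2, 2)])
    def test_matches_exhaustive_oracle_small(self, rng, m, n_seg):
        """On tiny instances, coordinate descent reaches the exhaustive
        optimum over all anchored state assignments with the proportions
        refit per assignment (c_max = 3)."""
        c_max = 3
        S = enumerate_states(c_max)
        # truth: segment 0 dominant and diploid (the anchor), others random
        a = np.ones((m + 1, n_seg), dtype=np.int64)
        b = np.ones_like(a)
        for i in range(1, m + 1):
            for s in range(1, n_seg):
                k = rng.integers(len(S))
                a[i, s], b[i, s] = S[k]
        P = 2
        u = rng.dirichlet(np.ones(m + 1), size=P).T
        w = np.concatenate([[10.0], rng.uniform(1, 3, n_seg - 1)])
        truth = mixture(a, b, u)
        R, B = expected_observables(truth, w)
        got, obj = solve_fixed(m, R, B, weights=w, c_max=c_max, seed=1)

        solver = CloneMixtureSolver(n_clones=m, c_max=c_max)
        kappa = 4 * float(R.mean()) ** 2
        combos = list(itertools.product(range(len(S)), repeat=m))
        best = np.inf
        for assign in itertools.product(range(len(combos)), repeat=n_seg):
            ca = np.ones((m + 1, n_seg), dtype=np.int64)
            cb = np.ones_like(ca)
            for s, ci in enumerate(assign):
                tpl = combos[ci]
                ca[1:, s] = S[list(tpl), 0]
                cb[1:, s] = S[list(tpl), 1]
            # same model assumption as the solver: diploid anchor is modal
            skip = False
            for i in range(1, m + 1):
                aber = (ca[i] != 1) | (cb[i] != 1)
                if w[aber].sum() > w[~aber].sum():
                    skip = True
            if skip:
                continue
            cand = CloneMixture(cn_a=ca, cn_b=cb,
                                u=np.full((m + 1, P), 1 / (m + 1)))
            o, _ = solver._refit_u_lam(R, B, w, kappa, cand,
                                       np.full(P, 2.0))
            best = min(best, o)
        assert obj <= best + 1e-8
        assert obj < 1e-8  # truth is feasible, so the optimum is exact


class TestModelSelect:
    def test_noiseless_two_clone_recovery(self):
        found = 0
        seed = 0
        while found < 2:
            mix, R, B, w = random_clone_mixture(seed, m_max=2)
            seed += 1
            if mix.n_clones != 2:
                continue
            found += 1
            got, report = model_select(R, B, weights=w, m_grid=(1, 2, 3),
                                       n_restarts=30, n_kicks=25, n_polish=4,
                                       state_penalty=1e-6, seed=0)
            assert report["m"] == 2
            assert not report["wgd"]
            assert match_profiles(mix, got)

    def test_flat_genome_prefers_diploid(self):
        got, report = model_select(np.ones((3, 2)), np.full((3, 2), 0.5),
                                   weights=[1, 1, 1], m_grid=(1, 2), seed=0)
        assert not report["wgd"]
        r, b = expected_observables(got, np.ones(3))
        assert r == pytest.approx(np.ones((3, 2)), abs=1e-6)
        assert b == pytest.approx(np.full((3, 2), 0.5), abs=1e-6)

    def test_single_sample_clonal_loh_purity(self):
        # one clone, genome (1,1) except a clonal LOH segment, purity 0.6
        u0 = 0.4
        truth = mixture([[1, 1], [1, 1]], [[1, 1], [1, 0]],
                        [[u0], [1 - u0]])
        R, B = expected_observables(truth, [3, 1])
        got, report = model_select(R, B, weights=[3, 1], m_grid=(1, 2),
                                   seed=0)
        assert report["m"] == 1
        assert got.u[1, 0] == pytest.approx(1 - u0, abs=1e-6)
        assert (got.cn_a[1, 1], got.cn_b[1, 1]) == (1, 0)


class TestRoundTrip:
    def test_exact_recovery_random_tree_mixtures(self):
        """Noiseless observables from random tree-consistent mixtures are
        recovered exactly (objective ~0, profiles equal up to permutation
        and orientation) -- a fast 10-instance version of the 50-instance
        benchmark in the acceptance suite."""
        fails = []
        for seed in range(10):
            mix, R, B, w = random_clone_mixture(seed)
            got, obj = solve_fixed(mix.n_clones, R, B, weights=w, seed=seed,
                                   n_restarts=30, n_kicks=25, n_polish=4,
                                   state_penalty=1e-6)
            if obj > 1e-8 or not match_profiles(mix, got):
                fails.append(seed)
        assert not fails

    def test_objective_monotone_descent(self):
        mix, R, B, w = random_clone_mixture(55)
        m = mix.n_clones
        solver = CloneMixtureSolver(n_clones=m, random_state=0)
        kappa = 4 * float(np.asarray(R).mean()) ** 2
        S = enumerate_states(4)
        combos = np.array(list(itertools.product(range(len(S)), repeat=m)))
        solver._A_t, solver._B_t = S[combos, 0], S[combos, 1]
        cand = CloneMixture(
            cn_a=np.ones_like(mix.cn_a), cn_b=np.ones_like(mix.cn_b),
            u=np.full_like(mix.u, 1 / (m + 1)))
        lam = np.full(R.shape[1], 2.0)
        objs = []
        idx = None
        for _ in range(15):
            idx, _ = solver._best_states(np.asarray(R, float),
                                         np.asarray(B, float), w, kappa,
                                         cand.u, lam, solver._A_t,
                                         solver._B_t, prev_idx=idx)
            cand.cn_a[1:] = solver._A_t[idx].T
            cand.cn_b[1:] = solver._B_t[idx].T
            o, lam = solver._refit_u_lam(np.asarray(R, float),
                                         np.asarray(B, float), w, kappa,
                                         cand, lam)
            objs.append(o)
        assert (np.diff(objs) <= 1e-12).all()


class TestLabelEvents:
    def test_mirrored_flag(self):
        mix = mixture([[1], [2], [1]], [[1], [1], [2]],
                      [[0.2], [0.4], [0.4]])
        ev = label_events(mix)
        assert ev[0]["mirrored_subclonal"]
        assert ev[0]["clones_major_a"] == [0]
        assert ev[0]["clones_major_b"] == [1]

    def test_all_neutral_unflagged(self):
        mix = mixture([[1], [1], [1]], [[1], [1], [1]],
                      [[0.2], [0.4], [0.4]])
        ev = label_events(mix)
        assert not ev[0]["mirrored_subclonal"]
        assert not ev[0]["loh"]
        assert ev[0]["clonal"]

    def test_loh_not_mirrored(self):
        mix = mixture([[1], [2], [2]], [[1], [0], [1]],
                      [[0.2], [0.4], [0.4]])
        ev = label_events(mix)
        assert ev[0]["loh"]
        assert not ev[0]["mirrored_subclonal"]
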