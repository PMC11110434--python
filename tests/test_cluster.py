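"""Local-global HMM: Baum-Welch, decoding, and K selection."""

import itertools

import numpy as np
import pytest

from hapclone.cluster import (LocalGlobalHMM, decode_map, fit_hmm,
                              merge_complement_clusters, select_K)


def simulate_chain(rng, means, tau, run_sd, n, D=None):
    """Markov-chain labels with Gaussian emissions around given means."""
    K = len(means)
    labels = np.zeros(n, dtype=int)
    labels[0] = rng.integers(K)
    for t in range(1, n):
        if rng.random() < tau:
            labels[t] = rng.choice([k for k in range(K) if k != labels[t - 1]])
        else:
            labels[t] = labels[t - 1]
    X = np.asarray(means)[labels] + rng.normal(0, run_sd,
                                               (n, len(means[0])))
    return X, labels


def brute_force_posteriors(logB, tau):
    """Posterior marginals by explicit enumeration of all K^T paths."""
    T, K = logB.shape
    A = np.full((K, K), tau / (K - 1))
    np.fill_diagonal(A, 1 - tau)
    post = np.zeros((T, K))
    total = 0.0
    for path in itertools.product(range(K), repeat=T):
        lp = -np.log(K) + logB[0, path[0]]
        for t in range(1, T):
            lp += np.log(A[path[t - 1], path[t]]) + logB[t, path[t]]
        p = np.exp(lp)
        total += p
        for t in range(T):
            post[t, path[t]] += p
    return post / total


class TestFitHMM:
    def test_parameter_recovery_two_states(self, rng):
        means = [[-1.0, -1.0], [1.0, 1.0]]
        X, lab = simulate_chain(rng, means, tau=0.05, run_sd=0.3, n=600)
        model, ll = fit_hmm(X, K=2, seed=0)
        got = model.means_[np.argsort(model.means_[:, 0])]
        assert got == pytest.approx(np.array(means), abs=0.1)
        assert model.tau_ == pytest.approx(0.05, abs=0.03)

    def test_K1_degenerate_iid_gaussian(self, rng):
        X = rng.normal(0, 1, (100, 2))
        model, ll = fit_hmm(X, K=1, seed=0, standardize=False)
        assert model.means_[0] == pytest.approx(X.mean(axis=0), abs=1e-6)
        v = X.var(axis=0)
        expect = -0.5 * (np.log(2 * np.pi * v).sum() * len(X)
                         + ((X - X.mean(0)) ** 2 / v).sum())
        assert ll == pytest.approx(expect, rel=1e-6)

    def test_loglik_monotone(self, rng):
        X, _ = simulate_chain(rng, [[-1, 0], [1, 0], [0, 2]], 0.1, 0.5, 300)
        model, _ = fit_hmm(X, K=3, seed=1)
        assert (np.diff(model.loglik_trace_) >= -1e-6).all()

    def test_posteriors_normalized_transitions_stochastic(self, rng):
        X, _ = simulate_chain(rng, [[-1.0], [1.0]], 0.1, 0.4, 200)
        model, _ = fit_hmm(X, K=2, seed=0)
        gamma = model.predict_proba(X)
        assert gamma.sum(axis=1) == pytest.approx(np.ones(len(X)), abs=1e-9)
        A = model._transmat(model.tau_, 2)
        assert A.sum(axis=1) == pytest.approx(np.ones(2))


class TestDecode:
    @pytest.mark.parametrize("T,K", [(3, 2), (5, 2), (4, 3), (8, 2)])
    def test_posterior_matches_path_enumeration(self, rng, T, K):
        model = LocalGlobalHMM(n_states=K, standardize=False)
        model._means = rng.normal(0, 1, (K, 2))
        model._vars = rng.uniform(0.3, 1.0, (K, 2))
        model.offset_ = np.zeros(2)
        model.scale_ = np.ones(2)
        model.tau_ = 0.13
        X = rng.normal(0, 1.2, (T, 2))
        logB = model._log_emission(X)
        gamma = model.predict_proba(X)
        expect = brute_force_posteriors(logB, model.tau_)
        assert gamma == pytest.approx(expect, abs=1e-10)

    def test_identical_emissions_tie_to_first_state(self):
        model = LocalGlobalHMM(n_states=2, standardize=False)
        model._means = np.zeros((2, 1))
        model._vars = np.ones((2, 1))
        model.offset_, model.scale_ = np.zeros(1), np.ones(1)
        model.tau_ = 0.2
        z = model.predict(np.zeros((4, 1)))
        assert (z == 0).all()

    def test_single_bin_posterior_is_start_times_emission(self, rng):
        model = LocalGlobalHMM(n_states=3, standardize=False)
        model._means = np.array([[-1.0], [0.0], [1.0]])
        model._vars = np.ones((3, 1))
        model.offset_, model.scale_ = np.zeros(1), np.ones(1)
        model.tau_ = 0.1
        x = np.array([[0.4]])
        gamma = model.predict_proba(x)
        e = np.exp(model._log_emission(x))[0]
        assert gamma[0] == pytest.approx(e / e.sum(), abs=1e-12)

    def test_uniform_tau_equals_mixture_responsibilities(self, rng):
        K = 3
        model = LocalGlobalHMM(n_states=K, standardize=False)
        model._means = rng.normal(0, 1, (K, 2))
        model._vars = np.full((K, 2), 0.5)
        model.offset_, model.scale_ = np.zeros(2), np.ones(2)
        model.tau_ = (K - 1) / K  # all transition rows uniform
        X = rng.normal(0, 1, (30, 2))
        gamma = model.predict_proba(X)
        logB = model._log_emission(X)
        resp = np.exp(logB - logB.max(axis=1, keepdims=True))
        resp /= resp.sum(axis=1, keepdims=True)
        assert gamma == pytest.approx(resp, abs=1e-10)


class TestSelectK:
    @pytest.mark.parametrize("true_K", [2, 3])
    def test_recovers_separable_blob_count(self, rng, true_K):
        centers = np.array([[i * 4.0, -i * 4.0] for i in range(true_K)])
        X, _ = simulate_chain(rng, centers.tolist(), 0.08, 0.4, 400)
        K, model, labels = select_K(X, K_grid=range(2, 7), seeds=(0, 1))
        assert K == true_K

    def test_constant_features_error(self):
        X = np.ones((50, 2))
        with pytest.raises(ValueError, match="no valid clustering"):
            select_K(X, K_grid=range(2, 5), seeds=(0,))


class TestLocalAdvantage:
    def test_hmm_beats_frozen_uniform_tau_on_runs(self, rng):
        """Two states with overlapping marginals but long runs: transition
        information must yield strictly higher mean label accuracy (ARI)."""
        from sklearn.metrics import adjusted_rand_score

        adv = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            X, lab = simulate_chain(r, [[-0.8, 0.0], [0.8, 0.0]],
                                    tau=0.03, run_sd=0.75, n=400)
            hmm, _ = fit_hmm(X, K=2, seed=0)
            base = LocalGlobalHMM(n_states=2, tau_init=0.5, learn_tau=False,
                                  random_state=0).fit(X)
            adv.append(adjusted_rand_score(lab, hmm.labels_)
                       - adjusted_rand_score(lab, base.labels_))
        assert np.mean(adv) > 0


class TestMergeComplement:
    def test_mirror_image_clusters_merge(self, rng):
        import pandas as pd

        from hapclone.binning import BinMatrix

        n = 60
        baf = np.vstack([np.tile([0.45, 0.55], (30, 1)),
                         np.tile([0.55, 0.45], (30, 1))])
        baf += rng.normal(0, 0.005, baf.shape)
        bins = pd.DataFrame({"CHROM": "chr1", "ARM": "p",
                             "START": np.arange(n), "END": np.arange(n) + 1,
                             "META_FIRST": 0, "META_LAST": 0,
                             "FALLBACK": False})
        bm = BinMatrix(bins=bins, snp_reads=np.ones((n, 3), int),
                       total_reads=np.ones((n, 3), int),
                       samples=["n", "t1", "t2"],
                       rdr=np.ones((n, 2)) + rng.normal(0, 0.01, (n, 2)),
                       baf=baf)
        labels = np.repeat([0, 1], 30)
        merged = merge_complement_clusters(bm, labels)
        assert len(np.unique(merged)) == 1
        # all bins now share one orientation
        side = bm.baf[:, 0] < 0.5
        assert side.all() or (~side).all()
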