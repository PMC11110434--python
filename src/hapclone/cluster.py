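"""Local-global clustering of genomic bins with a constrained Gaussian HMM.

Bins with the same copy-number state in every clone share one (RDR, mhBAF)
signature across all samples; a purely global mixture ignores that CNAs span
runs of adjacent bins, while purely local segmentation ignores recurrence of
the same state across the genome and across samples.  The model here is a
K-state hidden Markov model over each chromosome arm whose emissions are the
concatenated per-sample (RDR, mhBAF) vectors (multivariate Gaussian, diagonal
covariance by default) and whose transition matrix is maximally simple: a
single self-transition parameter, diagonal 1 - tau and off-diagonal
tau / (K - 1).  All arms share one parameter set; transitions never cross arm
boundaries.  Freezing tau at (K - 1) / K makes every transition row uniform
and the model collapses to an order-0 Gaussian mixture -- the purely global
baseline.

Parameters are fit by Baum-Welch and bins are labeled by MAP posterior
decoding.  The number of states K is chosen by silhouette score over a grid.
"""

from __future__ import annotations

import logging

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

logger = logging.getLogger(__name__)

__all__ = ["LocalGlobalHMM", "fit_hmm", "decode_map", "select_K"]


def _sequence_slices(n: int, lengths) -> list[slice]:
    if lengths is None:
        return [slice(0, n)]
    lengths = np.asarray(lengths, dtype=int)
    if lengths.sum() != n:
        raise ValueError("lengths must sum to the number of rows in X")
    bounds = np.concatenate([[0], np.cumsum(lengths)])
    return [slice(int(a), int(b)) for a, b in zip(bounds[:-1], bounds[1:])]


class LocalGlobalHMM(BaseEstimator):
    """Tied-transition Gaussian HMM over chromosome-arm sequences.

    Parameters
    ----------
    n_states : number of hidden states (clusters) K.
    tau_init : initial off-diagonal transition mass, in (0, 1).
    learn_tau : if False, tau stays frozen at ``tau_init`` (setting it to
        (K-1)/K yields the order-0 mixture baseline).
    covariance : "diag" (default) or "full".
    standardize : z-score each feature dimension before fitting; fitted means
        are reported back on the original scale in ``means_``.
    max_iter, tol : Baum-Welch stopping rule on |delta loglik|.
    random_state : seed for k-means++ mean initialization.

    Attributes (after fit)
    ----------------------
    means_, covars_ : per-state emission parameters on the original scale.
    tau_ : fitted off-diagonal transition mass.
    loglik_ : final log-likelihood; ``loglik_trace_`` the per-iteration values.
    labels_ : MAP state per training bin.
    """

    def __init__(self, n_states: int = 5, tau_init: float = 0.1,
                 learn_tau: bool = True, covariance: str = "diag",
                 standardize: bool = True, max_iter: int = 200,
                 tol: float = 1e-4, var_floor: float = 1e-6,
                 tau_floor: float = 1e-6, random_state: int | None = 0):
        self.n_states = n_states
        self.tau_init = tau_init
        self.learn_tau = learn_tau
        self.covariance = covariance
        self.standardize = standardize
        self.max_iter = max_iter
        self.tol = tol
        self.var_floor = var_floor
        self.tau_floor = tau_floor
        self.random_state = random_state

    # -- internals ---------------------------------------------------------

    def _transmat(self, tau: float, K: int) -> np.ndarray:
        if K == 1:
            return np.ones((1, 1))
        A = np.full((K, K), tau / (K - 1))
        np.fill_diagonal(A, 1 - tau)
        return A

    def _log_emission(self, Xz: np.ndarray) -> np.ndarray:
        K = self.n_states
        n, D = Xz.shape
        logB = np.empty((n, K))
        if self.covariance == "diag":
            for k in range(K):
                v = self._vars[k]
                logB[:, k] = -0.5 * (
                    np.log(2 * np.pi * v).sum()
                    + ((Xz - self._means[k]) ** 2 / v).sum(axis=1)
                )
        else:
            for k in range(K):
                cov = self._vars[k]
                L = np.linalg.cholesky(cov)
                sol = np.linalg.solve(L, (Xz - self._means[k]).T)
                logB[:, k] = -0.5 * (
                    D * np.log(2 * np.pi) + 2 * np.log(np.diag(L)).sum()
                    + (sol ** 2).sum(axis=0)
                )
        return logB

    def _forward_backward(self, logB: np.ndarray, tau: float):
        """Forward-backward in log space for one sequence.

        Returns (loglik, gamma, trans_diag_mass, trans_total_mass).
        """
        K = self.n_states
        T = logB.shape[0]
        A = self._transmat(tau, K)
        logA = np.log(np.maximum(A, 1e-300))

        def lse(M, axis):  # small-K logsumexp without scipy overhead
            mx = M.max(axis=axis, keepdims=True)
            return (mx + np.log(np.exp(M - mx).sum(axis=axis, keepdims=True))) \
                .squeeze(axis)

        la = np.empty((T, K))
        la[0] = -np.log(K) + logB[0]
        for t in range(1, T):
            la[t] = logB[t] + lse(la[t - 1][:, None] + logA, 0)
        ll = float(lse(la[-1], 0))
        lb = np.empty((T, K))
        lb[-1] = 0.0
        for t in range(T - 2, -1, -1):
            lb[t] = lse(logA + (logB[t + 1] + lb[t + 1])[None, :], 1)
        lg = la + lb - ll
        gamma = np.exp(lg - lse(lg, 1)[:, None])
        if T > 1:
            # all pairwise transition posteriors in one vectorized block
            lxi = (la[:-1, :, None] + logA[None, :, :]
                   + (logB[1:] + lb[1:])[:, None, :]) - ll
            xi = np.exp(lxi)
            diag_mass = float(xi[:, np.arange(K), np.arange(K)].sum())
            total_mass = float(xi.sum())
        else:
            diag_mass = total_mass = 0.0
        return ll, gamma, diag_mass, total_mass

    # -- sklearn API -------------------------------------------------------

    def fit(self, X: np.ndarray, lengths=None):
        X = np.asarray(X, dtype=float)
        n, D = X.shape
        K = self.n_states
        if n < K:
            raise ValueError("need at least n_states bins")
        if self.standardize:
            self.offset_ = X.mean(axis=0)
            sd = X.std(axis=0)
            self.scale_ = np.where(sd > 0, sd, 1.0)
        else:
            self.offset_ = np.zeros(D)
            self.scale_ = np.ones(D)
        Xz = (X - self.offset_) / self.scale_
        slices = _sequence_slices(n, lengths)

        rng = np.random.default_rng(self.random_state)
        if K == 1:
            means = Xz.mean(axis=0, keepdims=True)
        else:
            km = KMeans(n_clusters=K, n_init=4,
                        random_state=int(rng.integers(2**31 - 1))).fit(Xz)
            means = km.cluster_centers_.copy()
        gvar = np.maximum(Xz.var(axis=0), self.var_floor)
        if self.covariance == "diag":
            self._vars = np.tile(gvar, (K, 1))
        else:
            self._vars = np.tile(np.diag(gvar), (K, 1, 1))
        self._means = means
        tau = self.tau_init if K > 1 else 0.0

        trace = []
        prev_ll = -np.inf
        converged = False
        for it in range(1, self.max_iter + 1):
            logB = self._log_emission(Xz)
            ll = 0.0
            gam = np.zeros((n, K))
            diag_mass = total_mass = 0.0
            for sl in slices:
                l, g, dm, tm = self._forward_backward(logB[sl], tau)
                ll += l
                gam[sl] = g
                diag_mass += dm
                total_mass += tm
            trace.append(ll)
            # M-step
            w = gam.sum(axis=0)
            dead = np.nonzero(w < 1e-8)[0]
            for k in dead:
                worst = int(np.argmin(logB.max(axis=1)))
                self._means[k] = Xz[worst]
                if self.covariance == "diag":
                    self._vars[k] = gvar
                else:
                    self._vars[k] = np.diag(gvar)
                gam[:, k] = 1.0 / n
                logger.debug("re-seeded empty state %d at bin %d", k, worst)
            if dead.size:
                w = gam.sum(axis=0)
            self._means = (gam.T @ Xz) / w[:, None]
            if self.covariance == "diag":
                for k in range(K):
                    dev = Xz - self._means[k]
                    self._vars[k] = np.maximum(
                        (gam[:, k][:, None] * dev**2).sum(axis=0) / w[k],
                        self.var_floor,
                    )
            else:
                for k in range(K):
                    dev = Xz - self._means[k]
                    cov = (gam[:, k][:, None] * dev).T @ dev / w[k]
                    cov[np.diag_indices_from(cov)] = np.maximum(
                        np.diag(cov), self.var_floor
                    )
                    self._vars[k] = cov
            if self.learn_tau and K > 1 and total_mass > 0:
                tau = 1.0 - diag_mass / total_mass
                tau = float(np.clip(tau, self.tau_floor, 1 - self.tau_floor))
            if abs(ll - prev_ll) < self.tol:
                converged = True
                break
            prev_ll = ll

        self.tau_ = tau
        self.loglik_ = trace[-1]
        self.loglik_trace_ = np.array(trace)
        self.n_iter_ = it
        self.converged_ = converged
        self.means_ = self._means * self.scale_ + self.offset_
        if self.covariance == "diag":
            self.covars_ = self._vars * self.scale_**2
        else:
            self.covars_ = self._vars * np.outer(self.scale_, self.scale_)
        self.posteriors_ = self.predict_proba(X, lengths)
        self.labels_ = np.argmax(self.posteriors_, axis=1)
        return self

    def predict_proba(self, X: np.ndarray, lengths=None) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        Xz = (X - self.offset_) / self.scale_
        logB = self._log_emission(Xz)
        out = np.zeros((len(X), self.n_states))
        for sl in _sequence_slices(len(X), lengths):
            _, g, _, _ = self._forward_backward(logB[sl], self.tau_)
            out[sl] = g
        return out

    def predict(self, X: np.ndarray, lengths=None) -> np.ndarray:
        """MAP posterior decoding; ties resolve to the lower state index."""
        return np.argmax(self.predict_proba(X, lengths), axis=1)

    def score(self, X: np.ndarray, lengths=None) -> float:
        X = np.asarray(X, dtype=float)
        Xz = (X - self.offset_) / self.scale_
        logB = self._log_emission(Xz)
        return float(
            sum(self._forward_backward(logB[sl], self.tau_)[0]
                for sl in _sequence_slices(len(X), lengths))
        )


def fit_hmm(X: np.ndarray, lengths=None, K: int = 5, tau_init: float = 0.1,
            max_iter: int = 200, tol: float = 1e-4, seed: int | None = 0,
            **kw) -> tuple[LocalGlobalHMM, float]:
    """Fit a :class:`LocalGlobalHMM`; returns (model, log-likelihood)."""
    model = LocalGlobalHMM(n_states=K, tau_init=tau_init, max_iter=max_iter,
                           tol=tol, random_state=seed, **kw)
    model.fit(X, lengths)
    return model, model.loglik_


def decode_map(model: LocalGlobalHMM, X: np.ndarray, lengths=None):
    """Posterior marginals and MAP labels for new (or training) data."""
    gamma = model.predict_proba(X, lengths)
    return gamma, np.argmax(gamma, axis=1)


def merge_complement_clusters(binmat, labels: np.ndarray,
                              max_z: float = 4.0) -> np.ndarray:
    """Merge clusters that are mirror images of each other in mhBAF.

    The per-bin haplotype orientation is arbitrary wherever both haplotypes
    have similar mean frequency, so one copy-number state can surface as two
    clusters with equal RDR and complementary BAF.  Cluster pairs whose means
    match under the BAF complement within ``max_z`` standard errors are
    merged; the smaller cluster's bins have their BAF flipped to the larger
    cluster's orientation.  Returns the updated labels (``binmat.baf`` is
    modified in place).
    """
    labels = labels.copy()
    while True:
        ids, counts = np.unique(labels, return_counts=True)
        if len(ids) < 2:
            return labels
        mu_r = np.vstack([binmat.rdr[labels == k].mean(axis=0) for k in ids])
        mu_b = np.vstack([binmat.baf[labels == k].mean(axis=0) for k in ids])
        var_r = np.vstack([binmat.rdr[labels == k].var(axis=0) + 1e-6
                           for k in ids])
        var_b = np.vstack([binmat.baf[labels == k].var(axis=0) + 1e-6
                           for k in ids])
        best = None
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                se2_r = var_r[i] / counts[i] + var_r[j] / counts[j]
                se2_b = var_b[i] / counts[i] + var_b[j] / counts[j]
                z = max(
                    np.max(np.abs(mu_r[i] - mu_r[j]) / np.sqrt(se2_r)),
                    np.max(np.abs(mu_b[i] - (1 - mu_b[j])) / np.sqrt(se2_b)),
                )
                if z < max_z and (best is None or z < best[0]):
                    best = (z, i, j)
        if best is None:
            return labels
        _, i, j = best
        keep, drop = (i, j) if counts[i] >= counts[j] else (j, i)
        sel = labels == ids[drop]
        binmat.baf[sel] = 1 - binmat.baf[sel]
        labels[sel] = ids[keep]
        logger.info("merged mirror-image clusters %s -> %s", ids[drop],
                    ids[keep])


def select_K(X: np.ndarray, lengths=None, K_grid=range(2, 16), seeds=(0, 1, 2),
             max_silhouette_bins: int = 10_000, subsample_seed: int = 0,
             sil_margin: float = 0.03,
             **kw) -> tuple[int, LocalGlobalHMM, np.ndarray]:
    """Silhouette-based model selection over a grid of state counts.

    Each K is fit with every seed and the best fit by log-likelihood kept;
    the silhouette score of the MAP labels in the (standardized) feature space
    decides the winner.  Among K whose silhouette is within ``sil_margin`` of
    the best, the largest K wins: downstream steps can assign one state to
    two clusters, but a merge of two genuine states is unrecoverable.  K
    values yielding fewer than two non-empty clusters are skipped.
    """
    X = np.asarray(X, dtype=float)
    scored = []
    for K in K_grid:
        if len(X) < K + 1:
            continue
        fits = []
        for s in seeds:
            try:
                m, ll = fit_hmm(X, lengths, K=K, seed=s, **kw)
            except np.linalg.LinAlgError:
                continue
            fits.append((ll, s, m))
        if not fits:
            continue
        _, _, model = max(fits, key=lambda f: (f[0], -f[1]))
        labels = model.labels_
        if len(np.unique(labels)) < 2:
            continue
        Z = (X - model.offset_) / model.scale_
        if len(Z) > max_silhouette_bins:
            rng = np.random.default_rng(subsample_seed)
            idx = rng.choice(len(Z), max_silhouette_bins, replace=False)
            if len(np.unique(labels[idx])) < 2:
                continue
            sil = silhouette_score(Z[idx], labels[idx], metric="euclidean")
        else:
            sil = silhouette_score(Z, labels, metric="euclidean")
        scored.append((sil, K, model))
    if not scored:
        raise ValueError("no valid clustering for any K in the grid")
    best_sil = max(s for s, _, _ in scored)
    _, K, model = max((km for km in scored if km[0] >= best_sil - sil_margin),
                      key=lambda km: km[1])
    return K, model, model.labels_
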