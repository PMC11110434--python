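"""Deconvolution of cluster-level RDR/mhBAF into integer clone profiles.

A tumor sample is a mixture of a diploid normal clone (copy numbers (1,1)
everywhere) and m tumor clones with integer haplotype-specific copy numbers
(a_i, b_i) per segment.  With clone proportions u_{i,p} the fractional total
and minor copy numbers of segment s in sample p are

    F_{s,p} = sum_i u_{i,p} (a_{i,s} + b_{i,s}),   G_{s,p} = sum_i u_{i,p} b_{i,s}

and the model predicts mhBAF = G / F and RDR = F / lambda_p, with
lambda_p = sum_s w_s F_{s,p} / sum_s w_s so that the weight-averaged expected
RDR is 1, mirroring the library-size normalization of the observed RDR.

The solver minimizes the weighted squared residual of RDR and mhBAF jointly by
block coordinate descent: exhaustive enumeration of per-segment state tuples
given (U, lambda); simplex-constrained least squares for each sample's
proportions given the states; and the definitional lambda update -- each step
guarded so the exact objective never increases.  A "clonal balanced" anchor
pins every tumor clone's weight-modal state to (1,1), or (2,2) under a
whole-genome duplication, which resolves the scale degeneracies between
diploid and doubled solutions (including per-clone doubling).  Model selection over the number of clones (elbow on
the objective) and WGD status (objective plus a penalty on the subclonal
genome fraction, ties resolved in favor of no WGD) picks the reported mixture.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

__all__ = ["CloneMixture", "enumerate_states", "expected_observables",
           "CloneMixtureSolver", "solve_fixed", "model_select", "label_events",
           "profiles_match", "assign_states"]


@dataclass
class CloneMixture:
    """Integer haplotype-specific profiles and clone proportions.

    Row 0 of ``cn_a``/``cn_b``/``u`` is the normal clone, fixed at (1,1).
    """

    cn_a: np.ndarray  # (m+1, n_seg) int
    cn_b: np.ndarray
    u: np.ndarray  # (m+1, P), columns on the simplex
    wgd: bool = False
    lam: np.ndarray | None = None  # (P,) RDR scale

    @property
    def n_clones(self) -> int:
        return self.cn_a.shape[0] - 1

    @property
    def n_segments(self) -> int:
        return self.cn_a.shape[1]

    @property
    def purity(self) -> np.ndarray:
        return 1.0 - self.u[0]

    def validate(self, c_max: int | None = None) -> None:
        if (self.cn_a < 0).any() or (self.cn_b < 0).any():
            raise ValueError("negative copy numbers")
        if not np.allclose(self.u.sum(axis=0), 1.0, atol=1e-8) or (self.u < -1e-12).any():
            raise ValueError("clone proportions must lie on the simplex")
        if not ((self.cn_a[0] == 1).all() and (self.cn_b[0] == 1).all()):
            raise ValueError("normal clone must be (1,1) everywhere")
        if c_max is not None and (self.cn_a + self.cn_b > c_max).any():
            raise ValueError("copy-number state exceeds c_max")


def enumerate_states(c_max: int) -> np.ndarray:
    """All (a, b) integer states with a, b >= 0 and a + b <= c_max."""
    return np.array([(a, b) for a in range(c_max + 1) for b in range(c_max + 1 - a)],
                    dtype=np.int64)


def _fractional(mix: CloneMixture):
    ctot = mix.cn_a + mix.cn_b
    F = ctot.T @ mix.u  # (n_seg, P)
    G = mix.cn_b.T @ mix.u
    return F, G


def expected_observables(mix: CloneMixture, weights: np.ndarray):
    """Expected (RDR, mhBAF) per segment and sample under the forward model.

    RDR is normalized so its weight-averaged value over segments is 1;
    mhBAF = G / F (0.5 where F = 0, which requires G = 0).
    """
    w = np.asarray(weights, dtype=float)
    F, G = _fractional(mix)
    if ((F <= 0) & (G > 0)).any():
        raise ValueError("invalid state: zero total with positive minor copies")
    lam = (w[:, None] * F).sum(axis=0) / w.sum()
    if (lam <= 0).any():
        raise ValueError("all segments have zero fractional copy number")
    rdr = F / lam
    with np.errstate(invalid="ignore", divide="ignore"):
        baf = np.where(F > 0, G / np.maximum(F, 1e-300), 0.5)
    mix.lam = lam
    return rdr, baf


def _objective(r, f, w, kappa, mix: CloneMixture, lam=None, pen: float = 0.0):
    """Exact weighted objective at the given mixture (lambda optionally fixed).

    ``pen`` adds a parsimony term: pen * proportion-weighted copy-number
    event load (deviation from the baseline state), used to break ties among
    near-equivalent fits in favor of the least-aberrant explanation."""
    F, G = _fractional(mix)
    if lam is None:
        lam = (w[:, None] * F).sum(axis=0) / w.sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        eb = np.where(F > 0, G / np.maximum(F, 1e-300), 0.5)
    er = F / np.maximum(lam, 1e-300)
    res = (r - er) ** 2 + kappa * (f - eb) ** 2
    obj = float((w[:, None] * res).sum() / w.sum())
    if pen > 0.0:
        obj += pen * _event_load(mix, w)
    return obj


def _event_load(mix: CloneMixture, w) -> float:
    """Proportion-weighted mean copy-number deviation from the baseline."""
    base = 2 if mix.wgd else 1
    ubar = mix.u[1:].mean(axis=1)  # (m,)
    dev = (np.abs(mix.cn_a[1:] - base) + np.abs(mix.cn_b[1:] - base)).astype(float)
    return float((ubar @ dev @ w) / w.sum())


def _simplex_lsq(H: np.ndarray, g: np.ndarray) -> np.ndarray:
    """min 0.5 u' H u - g' u  s.t.  u >= 0, sum(u) = 1 (small active-set QP)."""
    n = len(g)
    active = np.zeros(n, dtype=bool)
    u = np.full(n, 1.0 / n)
    for _ in range(4 * n + 20):
        free = np.nonzero(~active)[0]
        k = len(free)
        KKT = np.zeros((k + 1, k + 1))
        KKT[:k, :k] = H[np.ix_(free, free)]
        KKT[:k, k] = 1.0
        KKT[k, :k] = 1.0
        rhs = np.concatenate([g[free], [1.0]])
        try:
            sol = np.linalg.solve(KKT, rhs)
        except np.linalg.LinAlgError:
            sol = np.linalg.lstsq(KKT, rhs, rcond=None)[0]
        u_free, lam = sol[:k], sol[k]
        if (u_free < -1e-10).any():
            j = free[int(np.argmin(u_free))]
            if active.sum() == n - 1:
                break
            active[j] = True
            continue
        u = np.zeros(n)
        u[free] = np.maximum(u_free, 0.0)
        mu = H @ u - g + lam  # multipliers for clamped coordinates
        viol = active & (mu < -1e-10)
        if viol.any():
            j = int(np.argmin(np.where(viol, mu, np.inf)))
            active[j] = False
            continue
        return u
    u = np.maximum(u, 0.0)
    s = u.sum()
    return u / s if s > 0 else np.full(n, 1.0 / n)


class CloneMixtureSolver(BaseEstimator):
    """Coordinate-descent solver for a fixed number of clones and WGD status.

    Parameters
    ----------
    n_clones : number m of tumor clones.
    c_max : maximum total copy number a + b per clone and segment.
    wgd : if True, clone modal states are anchored at (2,2) instead of
        (1,1).
    kappa : BAF/RDR balance weight; default ``4 * mean(R)**2`` so both residual
        terms have comparable scale.
    n_restarts : multi-start count; restart 0 is uniform proportions at
        lambda = 2 (diploid), the rest draw Dirichlet proportions and
        per-sample lambda anchors uniformly from ``lambda_range`` (or from
        ``lambda_grid`` anchors when given).
    n_polish : how many of the best fixed points get the local-search and
        clone-kick polish.
    n_kicks : clone-level perturbations (role swaps, partial diploid resets,
        proportion jitter) with re-descent, applied during polish.
    enum_budget : cap on (#state tuples x #segments) for the enumeration step.

    Attributes (after fit): ``mixture_``, ``objective_``, ``n_iter_``.
    """

    def __init__(self, n_clones: int = 2, c_max: int = 4, wgd: bool = False,
                 kappa: float | None = None, n_restarts: int = 20,
                 lambda_range=(1.2, 3.6), lambda_grid=None,
                 max_iter: int = 60, tol: float = 1e-9,
                 n_polish: int = 3, n_kicks: int = 12,
                 state_penalty: float = 0.0,
                 enum_budget: int = 5_000_000, random_state: int | None = 0):
        self.n_clones = n_clones
        self.c_max = c_max
        self.wgd = wgd
        self.kappa = kappa
        self.n_restarts = n_restarts
        self.lambda_range = lambda_range
        self.lambda_grid = lambda_grid
        self.max_iter = max_iter
        self.tol = tol
        self.n_polish = n_polish
        self.n_kicks = n_kicks
        self.state_penalty = state_penalty
        self.enum_budget = enum_budget
        self.random_state = random_state

    # -- coordinate steps --------------------------------------------------

    def _best_states(self, r, f, w, kappa, u, lam, A_t, B_t, prev_idx=None):
        """Per-segment enumeration of clone-state tuples, with the clonal
        anchor enforced on the most-abundant clone's modal state."""
        m = self.n_clones
        C_t = A_t + B_t  # (T, m)
        F = 2 * u[0] + C_t @ u[1:]  # (T, P)
        G = u[0] + B_t @ u[1:]
        er = F / lam[None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            eb = np.where(F > 0, G / np.maximum(F, 1e-300), 0.5)
        # cost[t, s] = sum_p (r_sp - er_tp)^2 + kappa (f_sp - eb_tp)^2,
        # expanded into matrix products to avoid a (T, n_seg, P) temporary
        cost = (
            ((er ** 2).sum(axis=1) + kappa * (eb ** 2).sum(axis=1))[:, None]
            + ((r ** 2).sum(axis=1) + kappa * (f ** 2).sum(axis=1))[None, :]
            - 2.0 * (er @ r.T + kappa * (eb @ f.T))
        )
        if self.state_penalty > 0.0:
            base = 2 if self.wgd else 1
            lv = (np.abs(A_t - base) + np.abs(B_t - base)) @ u[1:].mean(axis=1)
            cost = cost + self.state_penalty * lv[:, None]
        idx = np.argmin(cost, axis=0)

        # anchor: the baseline state must stay weight-modal for every
        # tumor clone (most abundant first) -- the scale anchor of the model
        anchor = (2, 2) if self.wgd else (1, 1)
        order = np.argsort(-u[1:].sum(axis=1), kind="stable")
        for i_star in order:
            anchor_mask = (A_t[:, i_star] == anchor[0]) \
                & (B_t[:, i_star] == anchor[1])
            idx = self._enforce_anchor(idx, cost, w, A_t, B_t, int(i_star),
                                       anchor, anchor_mask)
        if prev_idx is not None:
            new_obj = cost[idx, np.arange(len(idx))] @ w
            old_obj = cost[prev_idx, np.arange(len(idx))] @ w
            if old_obj < new_obj:
                idx = prev_idx
        return idx, cost

    def _enforce_anchor(self, idx, cost, w, A_t, B_t, i_star, anchor, mask):
        n_seg = len(idx)
        states = np.stack([A_t[idx, i_star], B_t[idx, i_star]], axis=1)

        def modal_ok(st):
            keys = {}
            for s in range(n_seg):
                keys.setdefault(tuple(st[s]), 0.0)
                keys[tuple(st[s])] += w[s]
            aw = keys.get(anchor, 0.0)
            return all(aw >= v for k, v in keys.items() if k != anchor)

        if modal_ok(states):
            return idx
        sub = np.nonzero(mask)[0]
        best_anchor = sub[np.argmin(cost[sub], axis=0)]  # per segment
        delta = cost[best_anchor, np.arange(n_seg)] - cost[idx, np.arange(n_seg)]
        order = np.argsort(delta, kind="stable")
        idx = idx.copy()
        for s in order:
            if (states[s] == anchor).all():
                continue
            idx[s] = best_anchor[s]
            states[s] = anchor
            if modal_ok(states):
                break
        return idx

    def _update_u(self, r, f, w, kappa, mix: CloneMixture, lam):
        """Simplex-constrained least squares per sample.

        The BAF residual f - G/F is non-linear in u through the denominator;
        it is linearized at the current F and re-linearized a few times
        (iteratively reweighted), then the exact objective decides between the
        old point, the new point and backtracked blends (safeguard keeps the
        descent monotone)."""
        ctot = (mix.cn_a + mix.cn_b).astype(float)  # (m+1, n_seg)
        sw = np.sqrt(w)
        obj0 = _objective(r, f, w, kappa, mix, lam, self.state_penalty)
        for p in range(mix.u.shape[1]):
            u_old = mix.u[:, p].copy()
            u_new = u_old.copy()
            for _ in range(3):
                Ft = np.maximum(ctot.T @ u_new, 1e-6)
                M1 = (ctot / lam[p]).T * sw[:, None]  # (n_seg, m+1)
                y1 = r[:, p] * sw
                M2 = (mix.cn_b / Ft[None, :]).T * (sw * np.sqrt(kappa))[:, None]
                y2 = f[:, p] * sw * np.sqrt(kappa)
                M = np.vstack([M1, M2])
                y = np.concatenate([y1, y2])
                u_next = _simplex_lsq(M.T @ M, M.T @ y)
                if np.abs(u_next - u_new).max() < 1e-12:
                    u_new = u_next
                    break
                u_new = u_next
            for tstep in (1.0, 0.5, 0.25, 0.1):
                mix.u[:, p] = (1 - tstep) * u_old + tstep * u_new
                if _objective(r, f, w, kappa, mix, lam, self.state_penalty) <= obj0 + 1e-15:
                    break
            else:
                mix.u[:, p] = u_old
            obj0 = _objective(r, f, w, kappa, mix, lam, self.state_penalty)
        return obj0

    def _descend(self, r, f, w, kappa, mix, lam, max_iter, idx=None):
        """Hard coordinate descent to a fixed point (monotone by guards)."""
        prev_obj = np.inf
        obj = np.inf
        it = 0
        for it in range(1, max_iter + 1):
            idx, _ = self._best_states(r, f, w, kappa, mix.u, lam,
                                       self._A_t, self._B_t, prev_idx=idx)
            mix.cn_a[1:] = self._A_t[idx].T
            mix.cn_b[1:] = self._B_t[idx].T
            obj, lam = self._refit_u_lam(r, f, w, kappa, mix, lam)
            mix.lam = lam.copy()
            if prev_obj - obj < self.tol * max(prev_obj, 1e-12):
                break
            prev_obj = obj
        return obj, lam, idx, it

    def _kick_search(self, r, f, w, kappa, mix, lam, idx, rng):
        """Clone-level basin hopping from a converged fixed point.

        Local optima of the factorization typically mix up clone *roles*
        (which clone carries which events), which no single-segment move can
        repair.  Kicks therefore act on whole clones: swapping two clones'
        states on a random segment subset, resetting part of a clone to the
        baseline state, or jittering the proportion matrix; each kick is
        followed by a short re-descent and kept only if it improves.
        """
        m = self.n_clones
        base = 2 if self.wgd else 1
        best = (_objective(r, f, w, kappa, mix, lam, self.state_penalty), mix, lam, idx)
        n_seg = r.shape[0]
        stall = 0
        for _ in range(self.n_kicks):
            if stall >= 8:
                break
            mix2 = CloneMixture(cn_a=best[1].cn_a.copy(),
                                cn_b=best[1].cn_b.copy(),
                                u=best[1].u.copy(), wgd=self.wgd)
            lam2 = best[2].copy()
            kind = int(rng.integers(3 if m > 1 else 2))
            if kind == 0:  # proportion jitter
                mix2.u = 0.6 * mix2.u + 0.4 * rng.dirichlet(
                    np.ones(m + 1), size=mix2.u.shape[1]).T
            elif kind == 1:  # partial reset of one clone to the baseline
                i = 1 + int(rng.integers(m))
                mask = rng.random(n_seg) < 0.4
                mix2.cn_a[i, mask] = base
                mix2.cn_b[i, mask] = base
            else:  # swap two clones' states on a random subset
                i, j = 1 + rng.choice(m, 2, replace=False)
                mask = rng.random(n_seg) < 0.5
                ai = mix2.cn_a[i, mask].copy()
                bi = mix2.cn_b[i, mask].copy()
                mix2.cn_a[i, mask] = mix2.cn_a[j, mask]
                mix2.cn_b[i, mask] = mix2.cn_b[j, mask]
                mix2.cn_a[j, mask] = ai
                mix2.cn_b[j, mask] = bi
            self._refit_u_lam(r, f, w, kappa, mix2, lam2)
            obj2, lam2, idx2, _ = self._descend(r, f, w, kappa, mix2, lam2, 15)
            if obj2 < best[0] - 1e-14:
                best = (obj2, mix2, lam2, idx2)
                stall = 0
                if obj2 <= 1e-14:
                    break
            else:
                stall += 1
        return best

    def _refit_u_lam(self, r, f, w, kappa, mix, lam):
        obj = self._update_u(r, f, w, kappa, mix, lam)
        F, _ = _fractional(mix)
        lam_def = (w[:, None] * F).sum(axis=0) / w.sum()
        num = (w[:, None] * r * F).sum(axis=0)
        den = (w[:, None] * F * F).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            lam_ls = np.where((num > 0) & (den > 0),
                              den / np.maximum(num, 1e-300), 0.0)
        best_lam = lam
        for cand in (lam_def, lam_ls):
            if (cand > 0).all() and _objective(r, f, w, kappa, mix, cand, self.state_penalty) < \
                    _objective(r, f, w, kappa, mix, best_lam, self.state_penalty) - 1e-18:
                best_lam = cand
        obj = _objective(r, f, w, kappa, mix, best_lam, self.state_penalty)
        return obj, best_lam

    def _local_search(self, r, f, w, kappa, mix, lam, idx, A_t, B_t,
                      top_k: int = 8, max_sweeps: int = 3):
        """Escape coordinate-descent fixed points: per segment, try the
        best alternative state tuples and refit (U, lambda) after each move.
        """
        m = self.n_clones
        anchor = (2, 2) if self.wgd else (1, 1)
        obj = _objective(r, f, w, kappa, mix, lam, self.state_penalty)
        n_seg = r.shape[0]
        for _ in range(max_sweeps):
            improved = False
            for s in range(n_seg):
                u_keep = mix.u.copy()
                lam_keep = lam.copy()
                a_keep = mix.cn_a[:, s].copy()
                b_keep = mix.cn_b[:, s].copy()
                # rank tuples for this segment under the current (U, lambda)
                C_t = A_t + B_t
                F = 2 * mix.u[0] + C_t @ mix.u[1:]
                G = mix.u[0] + B_t @ mix.u[1:]
                er = F / lam[None, :]
                with np.errstate(invalid="ignore", divide="ignore"):
                    eb = np.where(F > 0, G / np.maximum(F, 1e-300), 0.5)
                cost_s = ((r[s] - er) ** 2 + kappa * (f[s] - eb) ** 2).sum(axis=1)
                if self.state_penalty > 0.0:
                    base = 2 if self.wgd else 1
                    cost_s = cost_s + self.state_penalty * (
                        (np.abs(A_t - base) + np.abs(B_t - base))
                        @ mix.u[1:].mean(axis=1))
                order = np.argsort(cost_s, kind="stable")[: top_k + 1]
                found = False
                for t in order:
                    if (A_t[t] == a_keep[1:]).all() and (B_t[t] == b_keep[1:]).all():
                        continue
                    mix.cn_a[1:, s] = A_t[t]
                    mix.cn_b[1:, s] = B_t[t]
                    if not all(self._anchor_ok(mix, w, i, anchor)
                               for i in range(m)):
                        mix.cn_a[:, s] = a_keep
                        mix.cn_b[:, s] = b_keep
                        continue
                    new_obj, new_lam = self._refit_u_lam(r, f, w, kappa, mix, lam)
                    if new_obj < obj - 1e-14:
                        obj, lam = new_obj, new_lam
                        idx[s] = t
                        improved = found = True
                        break
                    mix.cn_a[:, s] = a_keep
                    mix.cn_b[:, s] = b_keep
                    mix.u = u_keep.copy()
                    lam = lam_keep
                if not found:
                    mix.u = u_keep
                    lam = lam_keep
            if not improved:
                break
        mix.lam = lam.copy()
        return obj, lam, idx

    @staticmethod
    def _anchor_ok(mix, w, i_star, anchor):
        """Whether ``anchor`` is a weight-modal state of clone ``i_star``."""
        acc: dict = {}
        a = mix.cn_a[1 + i_star]
        b = mix.cn_b[1 + i_star]
        for s in range(mix.n_segments):
            k = (int(a[s]), int(b[s]))
            acc[k] = acc.get(k, 0.0) + w[s]
        aw = acc.get(anchor, 0.0)
        return all(aw >= v - 1e-12 for k, v in acc.items() if k != anchor)

    # -- fitting -----------------------------------------------------------

    def fit(self, R: np.ndarray, B: np.ndarray, sample_weight=None):
        r = np.asarray(R, dtype=float)
        f = np.asarray(B, dtype=float)
        if r.shape != f.shape or r.ndim != 2:
            raise ValueError("R and B must be matching (n_segments, P) arrays")
        n_seg, P = r.shape
        m = self.n_clones
        if m < 1:
            raise ValueError("need at least one tumor clone")
        if self.c_max < 2 or (self.wgd and self.c_max < 4):
            raise ValueError("c_max must be >= 2 (>= 4 with wgd)")
        w = (np.ones(n_seg) if sample_weight is None
             else np.asarray(sample_weight, dtype=float))
        kappa = self.kappa if self.kappa is not None else 4.0 * float(r.mean()) ** 2

        S = enumerate_states(self.c_max)
        T = len(S) ** m
        if T * n_seg > self.enum_budget:
            raise ValueError(
                f"state enumeration ({T} tuples x {n_seg} segments) exceeds the "
                f"budget; lower c_max or n_clones")
        combos = np.array(list(itertools.product(range(len(S)), repeat=m)))
        A_t = S[combos, 0]  # (T, m)
        B_t = S[combos, 1]
        self._A_t, self._B_t = A_t, B_t

        rng = np.random.default_rng(self.random_state)
        lo, hi = self.lambda_range
        candidates = []
        for start in range(self.n_restarts):
            if start == 0:
                u = np.full((m + 1, P), 1.0 / (m + 1))
                lam = np.full(P, 2.0)
            else:
                alpha = rng.choice([0.6, 1.0, 2.0])
                u = rng.dirichlet(np.full(m + 1, alpha), size=P).T
                if self.lambda_grid is not None:
                    lam = np.full(P, float(rng.choice(self.lambda_grid)))
                else:
                    lam = rng.uniform(lo, hi, P)
            mix = CloneMixture(
                cn_a=np.ones((m + 1, n_seg), dtype=np.int64),
                cn_b=np.ones((m + 1, n_seg), dtype=np.int64),
                u=u, wgd=self.wgd, lam=lam.copy(),
            )
            obj, lam, idx, it = self._descend(r, f, w, kappa, mix, lam,
                                              self.max_iter)
            candidates.append((obj, len(candidates), mix, lam, idx, it))
            if obj <= 1e-14:
                break
        # polish the best coordinate-descent fixed points: greedy
        # segment-reassignment local search, then clone-level kicks
        # (swapping clone roles on random segment subsets) with re-descent
        candidates.sort(key=lambda c: c[:2])
        best = None
        for obj, _, mix, lam, idx, it in candidates[: self.n_polish]:
            if obj > 1e-14:
                obj, lam, idx = self._local_search(r, f, w, kappa, mix, lam,
                                                  idx, A_t, B_t)
            if best is None or obj < best[0] - 1e-15:
                best = (obj, mix, lam, idx, it)
            if obj <= 1e-14:
                break
        # clone-level kicks only from the overall best fixed point
        obj, mix, lam, idx, n_iter = best
        if obj > 1e-14:
            obj, mix, lam, idx = self._kick_search(
                r, f, w, kappa, mix, lam, idx, rng)
        # the reported objective is the pure residual at the fitted
        # orientation; the parsimony term only arbitrates between
        # near-equivalent fits during the search, and the canonical
        # orientation below is a reporting convention (observed mhBAF
        # orientation is itself arbitrary per segment)
        self.objective_ = _objective(r, f, w, kappa, mix, lam)
        self.objective_penalized_ = obj
        _canonicalize(mix)
        self.mixture_ = mix
        self.n_iter_ = n_iter
        self.kappa_ = kappa
        return self


def _canonicalize(mix: CloneMixture) -> CloneMixture:
    """Sort tumor clones by descending total proportion and orient each
    segment so the mean expected mhBAF across samples is <= 0.5."""
    order = np.argsort(-mix.u[1:].sum(axis=1), kind="stable") + 1
    perm = np.concatenate([[0], order])
    mix.cn_a = mix.cn_a[perm]
    mix.cn_b = mix.cn_b[perm]
    mix.u = mix.u[perm]
    F, G = _fractional(mix)
    with np.errstate(invalid="ignore", divide="ignore"):
        eb = np.where(F > 0, G / np.maximum(F, 1e-300), 0.5)
    mean_b = eb.mean(axis=1)
    swap = (mean_b > 0.5) | ((np.abs(mean_b - 0.5) < 1e-12) & (eb[:, 0] > 0.5))
    if swap.any():
        a = mix.cn_a.copy()
        mix.cn_a[:, swap] = mix.cn_b[:, swap]
        mix.cn_b[:, swap] = a[:, swap]
    return mix


def solve_fixed(m: int, R, B, weights=None, c_max: int = 4, wgd: bool = False,
                n_restarts: int = 20, lambda_grid=None,
                seed: int | None = 0, **kw) -> tuple[CloneMixture, float]:
    """Functional wrapper over :class:`CloneMixtureSolver`."""
    solver = CloneMixtureSolver(n_clones=m, c_max=c_max, wgd=wgd,
                                lambda_grid=lambda_grid, n_restarts=n_restarts,
                                random_state=seed, **kw)
    solver.fit(R, B, sample_weight=weights)
    return solver.mixture_, solver.objective_


def assign_states(mix: CloneMixture, R, B, c_max: int = 4,
                  kappa: float | None = None):
    """Best per-segment state tuples for extra observations, holding the
    fitted proportions and scale fixed (used for clusters too small to enter
    the deconvolution).  Returns (cn_a, cn_b) with the normal clone row."""
    r = np.atleast_2d(np.asarray(R, dtype=float))
    f = np.atleast_2d(np.asarray(B, dtype=float))
    m = mix.n_clones
    if kappa is None:
        kappa = 4.0 * float(r.mean()) ** 2
    S = enumerate_states(c_max)
    combos = np.array(list(itertools.product(range(len(S)), repeat=m)))
    A_t = S[combos, 0]
    B_t = S[combos, 1]
    C_t = A_t + B_t
    F = 2 * mix.u[0] + C_t @ mix.u[1:]
    G = mix.u[0] + B_t @ mix.u[1:]
    lam = mix.lam if mix.lam is not None else np.full(mix.u.shape[1], 2.0)
    er = F / lam[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        eb = np.where(F > 0, G / np.maximum(F, 1e-300), 0.5)
    cn_a = np.ones((m + 1, len(r)), dtype=np.int64)
    cn_b = np.ones((m + 1, len(r)), dtype=np.int64)
    for s in range(len(r)):
        cost = ((r[s] - er) ** 2 + kappa * (f[s] - eb) ** 2).sum(axis=1)
        t = int(np.argmin(cost))
        a, b = A_t[t], B_t[t]
        if eb[t].mean() > 0.5:  # canonical haplotype orientation
            a, b = b, a
        cn_a[1:, s] = a
        cn_b[1:, s] = b
    return cn_a, cn_b


def profiles_match(mix1: CloneMixture, mix2: CloneMixture) -> bool:
    """Whether two mixtures share the same integer profiles up to clone
    permutation and per-segment haplotype orientation."""
    m = mix1.n_clones
    if m != mix2.n_clones or mix1.n_segments != mix2.n_segments:
        return False
    for perm in itertools.permutations(range(1, m + 1)):
        p = np.array((0,) + perm)
        a2, b2 = mix2.cn_a[p], mix2.cn_b[p]
        ok = True
        for s in range(mix1.n_segments):
            same = (mix1.cn_a[:, s] == a2[:, s]).all() and \
                   (mix1.cn_b[:, s] == b2[:, s]).all()
            swap = (mix1.cn_a[:, s] == b2[:, s]).all() and \
                   (mix1.cn_b[:, s] == a2[:, s]).all()
            if not (same or swap):
                ok = False
                break
        if ok:
            return True
    return False


def subclonal_fraction(mix: CloneMixture, weights: np.ndarray) -> float:
    """Weighted fraction of the genome where tumor clones disagree."""
    w = np.asarray(weights, dtype=float)
    a, b = mix.cn_a[1:], mix.cn_b[1:]
    sub = (a != a[0]).any(axis=0) | (b != b[0]).any(axis=0)
    return float(w[sub].sum() / w.sum())


def model_select(R, B, weights=None, m_grid=(1, 2, 3, 4, 5),
                 c_max_map={False: 4, True: 8}, elbow: float = 0.05,
                 subclonal_penalty: float = 0.1, wgd_branches=(False, True),
                 abs_tol: float = 1e-10, tie_margin: float = 0.05,
                 min_clone_prop: float = 0.05, se_R=None, se_B=None,
                 floor_mult: float = 2.0, seed: int | None = 0, **kw):
    """Select the number of clones and WGD status.

    Within each WGD branch the chosen m is the smallest adequate one.  When
    the squared standard errors ``se_R``/``se_B`` of the segment observations
    are supplied, "adequate" means the objective is within ``floor_mult``
    times the sampling-noise floor they imply -- larger m only chases noise.
    Otherwise (or when no m reaches the floor) an elbow rule applies: stop at
    the smallest m whose objective is ~0, whose improvement on moving to m+1
    falls below ``elbow`` relative to the smallest-m objective, or where the
    (m+1)-fit contains a spurious clone (no sample with proportion >=
    ``min_clone_prop``).  Between branches the score is objective +
    ``subclonal_penalty`` * subclonal genome fraction; scores within a
    relative ``tie_margin`` are tied and resolved in favor of no WGD
    (parsimony).  Returns (mixture, report dict).
    """
    R = np.asarray(R, dtype=float)
    w = np.ones(R.shape[0]) if weights is None else np.asarray(weights, float)
    floor = None
    if se_R is not None and se_B is not None:
        kappa = kw.get("kappa") or 4.0 * float(R.mean()) ** 2
        per_seg = (np.asarray(se_R) + kappa * np.asarray(se_B)).sum(axis=1)
        floor = float((w * per_seg).sum() / w.sum())
        # parsimony tie-break among fits that are equivalent within noise
        kw = dict(kw, state_penalty=kw.get("state_penalty", 0.25 * floor))
    report = {"branches": {}, "noise_floor": floor}
    candidates = {}
    # diploid branch first: if it already fits within the noise floor, the
    # WGD branch cannot win (its score is bounded below by its objective,
    # which exceeds the floor whenever the data are genuinely diploid, and
    # ties resolve to no-WGD) -- so it need not be solved at all
    for wgd in sorted(wgd_branches):
        objs = {}
        mixes = {}
        for m in sorted(m_grid):
            mix, obj = solve_fixed(m, R, B, weights=w, c_max=c_max_map[wgd],
                                   wgd=wgd, seed=seed, **kw)
            objs[m] = obj
            mixes[m] = mix
            # once a fit is within sampling noise, more clones only chase it
            if floor is not None and obj <= floor_mult * floor:
                break
        ms = sorted(objs)
        scale = max(objs[ms[0]], 1e-300)
        floor_choice = None
        if floor is not None:
            for m in ms:
                if objs[m] <= floor_mult * floor:
                    floor_choice = m
                    break
        elbow_choice = ms[-1]
        for i, m in enumerate(ms):
            if objs[m] <= abs_tol:
                elbow_choice = m
                break
            if i + 1 < len(ms):
                nxt = mixes[ms[i + 1]]
                rel = (objs[m] - objs[ms[i + 1]]) / scale
                spurious = nxt.u[1:].max(axis=1).min() < min_clone_prop
                if rel < elbow or spurious:
                    elbow_choice = m
                    break
        # both rules are parsimony-first: take the smaller adequate m
        chosen = elbow_choice if floor_choice is None \
            else min(floor_choice, elbow_choice)
        candidates[wgd] = (objs[chosen], mixes[chosen], chosen,
                           subclonal_fraction(mixes[chosen], w))
        report["branches"][wgd] = {"objectives": objs, "chosen_m": chosen}
        if (not wgd and floor is not None
                and objs[chosen] <= floor_mult * floor):
            break
    # Branch comparison: objective plus the subclonal-fraction penalty, the
    # latter scaled by the larger branch objective so it arbitrates ties at
    # the fit's own scale instead of overriding a clearly better fit.
    if False in candidates and True in candidates \
            and candidates[True][0] < candidates[False][0]:
        # a WGD fit with all-even tumor states is a doubled diploid fit in
        # disguise: its halved version is a (usually better-searched)
        # diploid candidate the multistart may have missed
        mixT = candidates[True][1]
        aT, bT = mixT.cn_a[1:], mixT.cn_b[1:]
        if (aT % 2 == 0).all() and (bT % 2 == 0).all():
            # halving the states requires the matching Moebius rescale of
            # the proportions: v_i = 2 u_i / (1 + U), v_0 = (1 - U)/(1 + U),
            # which leaves both expected observables unchanged
            U = mixT.u[1:].sum(axis=0)
            v = np.vstack([(1 - U) / (1 + U), 2 * mixT.u[1:] / (1 + U)])
            half = CloneMixture(
                cn_a=np.vstack([mixT.cn_a[:1], aT // 2]),
                cn_b=np.vstack([mixT.cn_b[:1], bT // 2]),
                u=v, wgd=False)
            kappa_h = kw.get("kappa") or 4.0 * float(R.mean()) ** 2
            # orientation per segment is arbitrary: score the halved
            # candidate at its best per-segment haplotype orientation
            F_h, G_h = _fractional(half)
            lam_h = (w[:, None] * F_h).sum(axis=0) / w.sum()
            er = F_h / np.maximum(lam_h, 1e-300)
            with np.errstate(invalid="ignore", divide="ignore"):
                eb = np.where(F_h > 0, G_h / np.maximum(F_h, 1e-300), 0.5)
            Bf = np.asarray(B, float)
            res_keep = ((np.asarray(R, float) - er) ** 2
                        + kappa_h * (Bf - eb) ** 2).sum(axis=1)
            res_swap = ((np.asarray(R, float) - er) ** 2
                        + kappa_h * (Bf - (1 - eb)) ** 2).sum(axis=1)
            swap = res_swap < res_keep
            a_h = half.cn_a.copy()
            half.cn_a[:, swap] = half.cn_b[:, swap]
            half.cn_b[:, swap] = a_h[:, swap]
            obj_h = _objective(np.asarray(R, float), Bf, w, kappa_h, half)
            if obj_h < candidates[False][0]:
                m_h = candidates[True][2]
                candidates[False] = (obj_h, half, m_h,
                                     subclonal_fraction(half, w))
                report["branches"][False]["halved_from_wgd"] = True
    if len(candidates) == 1:
        wgd = next(iter(candidates))
    elif all(c[0] <= (floor_mult * floor if floor is not None else abs_tol)
             for c in candidates.values()):
        # both branches fit within sampling noise (or exactly): the data
        # cannot distinguish a doubled genome from a diploid one -- diploid
        wgd = False
    else:
        ref = max(candidates[False][0], candidates[True][0], abs_tol)
        scores = {g: candidates[g][0] + subclonal_penalty * ref * candidates[g][3]
                  for g in candidates}
        for g in candidates:
            report["branches"][g]["score"] = scores[g]
        wgd = bool(scores[True] < scores[False] - tie_margin * max(scores[False], abs_tol))
    report["wgd"] = wgd
    report["m"] = candidates[wgd][2]
    return candidates[wgd][1], report


def label_events(mix: CloneMixture, min_clone_prop: float = 0.0):
    """Per-segment event annotations.

    Returns a list of dicts with keys ``mirrored_subclonal`` (some clone has
    a > b while another has b > a), ``loh`` (some clone lost one haplotype
    entirely), ``clonal`` (all tumor clones share one state), and the clone
    indices carrying each mirrored side.
    """
    a, b = mix.cn_a[1:], mix.cn_b[1:]
    keep = mix.u[1:].max(axis=1) >= min_clone_prop
    out = []
    for s in range(mix.n_segments):
        asr, bsr = a[keep, s], b[keep, s]
        major_a = np.nonzero(asr > bsr)[0]
        major_b = np.nonzero(bsr > asr)[0]
        out.append({
            "mirrored_subclonal": bool(len(major_a) and len(major_b)),
            "loh": bool((np.minimum(asr, bsr) == 0).any()),
            "clonal": bool(len(set(zip(asr, bsr))) <= 1),
            "clones_major_a": major_a.tolist(),
            "clones_major_b": major_b.tolist(),
        })
    return out
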