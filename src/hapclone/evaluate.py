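"""Scoring inferred clone mixtures against simulator ground truth.

Since clone labels and the two parental haplotypes are not identifiable, all
metrics compare state *multisets* on the common refinement of the true and
inferred segmentations, allowing a joint haplotype swap per segment; clone
proportions are matched by assignment before averaging errors.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import adjusted_rand_score

__all__ = ["EvalReport", "accuracy", "aasapgp", "mirrored_eval",
           "proportion_error", "common_refinement"]


@dataclass
class EvalReport:
    accuracy: float
    aasapgp: float
    mirrored_recall: float
    mirrored_precision: float
    proportion_error: float
    ari: float | None = None
    notes: str = ""

    def to_dict(self):
        return asdict(self)


def _clone_states(seg_df: pd.DataFrame, row) -> tuple[np.ndarray, np.ndarray]:
    m = sum(1 for c in seg_df.columns if c.startswith("A_")) - 1
    a = np.array([row[f"A_{i}"] for i in range(m + 1)])
    b = np.array([row[f"B_{i}"] for i in range(m + 1)])
    return a, b


def common_refinement(truth: pd.DataFrame, pred: pd.DataFrame) -> pd.DataFrame:
    """Intersect the two segmentations per (CHROM, ARM).

    Both inputs need CHROM ARM START END columns; raises if either leaves part
    of the other's covered interval uncovered.
    """
    pieces = []
    keys = sorted(set(zip(truth.CHROM, truth.ARM)) | set(zip(pred.CHROM, pred.ARM)))
    for chrom, arm in keys:
        t = truth[(truth.CHROM == chrom) & (truth.ARM == arm)].sort_values("START")
        p = pred[(pred.CHROM == chrom) & (pred.ARM == arm)].sort_values("START")
        if len(t) == 0 or len(p) == 0:
            raise ValueError(f"{chrom}{arm} covered by only one segmentation")
        lo = max(t.START.min(), p.START.min())
        hi = min(t.END.max(), p.END.max())
        uncovered = []
        for df in (t, p):
            ends = df.END.to_numpy()
            starts = df.START.to_numpy()
            gaps = starts[1:] > ends[:-1]
            if gaps.any():
                g = int(np.nonzero(gaps)[0][0])
                uncovered.append((chrom, arm, int(ends[g]), int(starts[g + 1])))
        if uncovered:
            raise ValueError(f"uncovered intervals: {uncovered}")
        bounds = np.unique(np.concatenate([
            t.START.to_numpy(), t.END.to_numpy(),
            p.START.to_numpy(), p.END.to_numpy()]))
        bounds = bounds[(bounds >= lo) & (bounds <= hi)]
        for s0, s1 in zip(bounds[:-1], bounds[1:]):
            ti = t[(t.START <= s0) & (t.END >= s1)].iloc[0]
            pi = p[(p.START <= s0) & (p.END >= s1)].iloc[0]
            pieces.append((chrom, arm, int(s0), int(s1), ti.name, pi.name))
    return pd.DataFrame(pieces, columns=["CHROM", "ARM", "START", "END",
                                         "TRUTH_ROW", "PRED_ROW"])


def _tumor_multiset(a, b, swap=False):
    if swap:
        a, b = b, a
    return tuple(sorted(zip(a[1:].tolist(), b[1:].tolist())))


def accuracy(truth: pd.DataFrame, pred: pd.DataFrame) -> float:
    """Length-weighted agreement of per-segment tumor state multisets.

    A refined segment scores 1 iff the multiset of inferred tumor-clone
    (a, b) states equals the true multiset under either joint haplotype
    orientation, else 0.
    """
    ref = common_refinement(truth, pred)
    w = (ref.END - ref.START).to_numpy(dtype=float)
    score = np.zeros(len(ref))
    for i, row in ref.iterrows():
        ta, tb = _clone_states(truth, truth.loc[row.TRUTH_ROW])
        pa, pb = _clone_states(pred, pred.loc[row.PRED_ROW])
        t_ms = _tumor_multiset(ta, tb)
        score[i] = float(_tumor_multiset(pa, pb) == t_ms
                         or _tumor_multiset(pa, pb, swap=True) == t_ms)
    return float((w * score).sum() / w.sum())


def _state_proportions(a, b, u_col, swap=False):
    out = {}
    for i in range(len(a)):
        st = (b[i], a[i]) if swap else (a[i], b[i])
        out[st] = out.get(st, 0.0) + float(u_col[i])
    return out


def aasapgp(truth: pd.DataFrame, truth_u: np.ndarray,
            pred: pd.DataFrame, pred_u: np.ndarray) -> float:
    """Clone-proportion-weighted allele-specific agreement per genome position.

    Per refined segment and sample, overlap = sum over distinct states of
    min(true proportion carrying the state, inferred proportion carrying it),
    maximized over the joint haplotype orientation of the inferred states;
    length-weighted over segments, then averaged over samples.
    """
    ref = common_refinement(truth, pred)
    w = (ref.END - ref.START).to_numpy(dtype=float)
    P = truth_u.shape[1]
    per_sample = np.zeros(P)
    for p in range(P):
        vals = np.zeros(len(ref))
        for i, row in ref.iterrows():
            ta, tb = _clone_states(truth, truth.loc[row.TRUTH_ROW])
            pa, pb = _clone_states(pred, pred.loc[row.PRED_ROW])
            t_prop = _state_proportions(ta, tb, truth_u[:, p])
            best = 0.0
            for swap in (False, True):
                p_prop = _state_proportions(pa, pb, pred_u[:, p], swap=swap)
                ov = sum(min(v, p_prop.get(k, 0.0)) for k, v in t_prop.items())
                best = max(best, ov)
            vals[i] = best
        per_sample[p] = (w * vals).sum() / w.sum()
    return float(per_sample.mean())


def _merge_flagged(df: pd.DataFrame, col: str) -> list[tuple]:
    out = []
    for (chrom, arm), sub in df.groupby(["CHROM", "ARM"], sort=False):
        sub = sub.sort_values("START")
        cur = None  # [chrom, arm, start, end]
        for _, row in sub.iterrows():
            if not row[col]:
                if cur is not None:
                    out.append(tuple(cur))
                    cur = None
                continue
            if cur is not None and cur[3] == row.START:
                cur[3] = row.END
            else:
                if cur is not None:
                    out.append(tuple(cur))
                cur = [chrom, arm, int(row.START), int(row.END)]
        if cur is not None:
            out.append(tuple(cur))
    return out


def mirrored_eval(truth: pd.DataFrame, pred: pd.DataFrame,
                  min_reciprocal_overlap: float = 0.5):
    """Interval-level recall/precision of mirrored-subclonal calls.

    Adjacent flagged segments are merged; intervals match when their overlap
    is at least ``min_reciprocal_overlap`` of *both* lengths.  With no
    inferred mirrored interval, precision is reported as 1.0 with a note.
    """
    t_iv = _merge_flagged(truth, "MIRRORED")
    p_iv = _merge_flagged(pred, "MIRRORED")

    def reciprocal(iv1, iv2):
        if iv1[0] != iv2[0] or iv1[1] != iv2[1]:
            return False
        ov = min(iv1[3], iv2[3]) - max(iv1[2], iv2[2])
        if ov <= 0:
            return False
        return (ov >= min_reciprocal_overlap * (iv1[3] - iv1[2])
                and ov >= min_reciprocal_overlap * (iv2[3] - iv2[2]))

    matched_t = sum(1 for t in t_iv if any(reciprocal(t, q) for q in p_iv))
    matched_p = sum(1 for q in p_iv if any(reciprocal(q, t) for t in t_iv))
    recall = matched_t / len(t_iv) if t_iv else 1.0
    note = ""
    if p_iv:
        precision = matched_p / len(p_iv)
    else:
        precision = 1.0
        note = "no inferred mirrored segments (zero denominator)"
    return recall, precision, note


def match_clones(truth_u: np.ndarray, pred_u: np.ndarray):
    """Assign inferred tumor clones to true ones by proportion similarity.

    Pads the smaller side with zero-proportion clones; the normal clone (row
    0) is matched to itself.  Returns (truth_idx, pred_idx) over tumor rows of
    the padded matrices and the padded matrices themselves.
    """
    mt, mp = truth_u.shape[0] - 1, pred_u.shape[0] - 1
    m = max(mt, mp)
    P = truth_u.shape[1]
    tu = np.vstack([truth_u, np.zeros((m - mt, P))])
    pu = np.vstack([pred_u, np.zeros((m - mp, P))])
    cost = np.zeros((m, m))
    for i in range(m):
        for j in range(m):
            cost[i, j] = np.abs(tu[1 + i] - pu[1 + j]).sum()
    ti, pi = linear_sum_assignment(cost)
    return ti + 1, pi + 1, tu, pu


def proportion_error(truth_u: np.ndarray, pred_u: np.ndarray) -> float:
    """Mean absolute difference of matched clone proportions (normal incl.)."""
    ti, pi, tu, pu = match_clones(truth_u, pred_u)
    diffs = [np.abs(tu[0] - pu[0])]
    for i, j in zip(ti, pi):
        diffs.append(np.abs(tu[i] - pu[j]))
    return float(np.mean(np.concatenate(diffs)))


def clustering_ari(true_labels, pred_labels) -> float:
    return float(adjusted_rand_score(true_labels, pred_labels))
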