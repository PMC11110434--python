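"""Haplotype blocks and meta-SNPs from reference-phased germline SNP counts.

Reference-based phasing assigns each heterozygous SNP's alternate allele to one
of two haplotypes ("0"/"1") within a phase set, but switch errors -- spurious
flips of the phase between adjacent SNPs -- occur at appreciable rates.  Before
aggregating SNP read counts into haplotype blocks, this module (i) splits phase
sets into candidate blocks no longer than a maximum span, and (ii) applies an
exact statistical test between each pair of adjacent SNPs: if the phased allele
fraction x_i/(x_i+y_i) differs significantly from x_j/(x_j+y_j) in any sample,
the counts are not combined.  Surviving runs of SNPs are aggregated into
"meta-SNPs" with summed haplotype-"1" counts ``x_Q`` and totals ``t_Q``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

__all__ = [
    "fisher_exact_two_sided",
    "split_blocks",
    "switch_test",
    "build_metasnps",
    "hap1_counts",
]

#: columns required in a SNP table, followed by ALT_<s>/TOT_<s> pairs
SNP_FIXED_COLUMNS = ["CHROM", "POS", "PHASE_SET", "REF_PHASE"]


def fisher_exact_two_sided(a, b, c, d):
    """Vectorized two-sided Fisher exact p-values for 2x2 tables [[a, b], [c, d]].

    Uses the standard two-sided rule (sum of hypergeometric point masses not
    exceeding that of the observed table).  Equivalent to
    ``scipy.stats.fisher_exact(..., alternative="two-sided")`` but operates on
    arrays of tables at once.
    """
    a = np.atleast_1d(np.asarray(a, dtype=np.int64))
    b = np.atleast_1d(np.asarray(b, dtype=np.int64))
    c = np.atleast_1d(np.asarray(c, dtype=np.int64))
    d = np.atleast_1d(np.asarray(d, dtype=np.int64))
    M = a + b + c + d
    n = a + b
    N = a + c
    kmin = np.maximum(0, N - (M - n))
    kmax = np.minimum(n, N)
    width = int((kmax - kmin).max(initial=0))
    ks = kmin[:, None] + np.arange(width + 1)[None, :]
    valid = ks <= kmax[:, None]
    pmf = hypergeom.pmf(np.where(valid, ks, 0), M[:, None], n[:, None], N[:, None])
    pmf = np.where(valid, pmf, 0.0)
    obs = hypergeom.pmf(a, M, n, N)
    # relative tolerance matches scipy's handling of floating-point ties
    take = pmf <= obs[:, None] * (1.0 + 1e-7)
    p = np.where(take, pmf, 0.0).sum(axis=1)
    p = np.where(M == 0, 1.0, p)  # empty table carries no evidence
    return np.minimum(p, 1.0)


def hap1_counts(alt, tot, ref_phase):
    """Reads assigned to haplotype "1": alt reads if the alternate allele is
    phased to haplotype 1, otherwise the reference reads."""
    alt = np.asarray(alt)
    tot = np.asarray(tot)
    h = np.asarray(ref_phase)
    if h.ndim < alt.ndim:
        h = h[..., None]
    return np.where(h == 1, alt, tot - alt)


def _validate_sorted(pos):
    pos = np.asarray(pos)
    bad = np.nonzero(np.diff(pos) <= 0)[0]
    if bad.size:
        raise ValueError(
            f"SNP positions must be strictly increasing; first violation after "
            f"position {int(pos[bad[0]])}"
        )


def split_blocks(snps: pd.DataFrame, max_block_length: int = 25_000) -> list[np.ndarray]:
    """Split one chromosome's SNPs into candidate haplotype blocks.

    A candidate block is a maximal run of consecutive SNPs sharing a phase set
    whose genomic span (end - start + 1) does not exceed ``max_block_length``.
    Unphased SNPs (missing PHASE_SET) become singleton blocks.

    Returns a list of integer index arrays into ``snps`` (positional indices),
    in genome order.
    """
    if max_block_length <= 0:
        raise ValueError("max_block_length must be positive")
    pos = snps["POS"].to_numpy()
    _validate_sorted(pos)
    ps = snps["PHASE_SET"].to_numpy(dtype=object)
    phased = pd.notna(ps) & (ps != ".")
    blocks: list[np.ndarray] = []
    i = 0
    n = len(snps)
    while i < n:
        if not phased[i]:
            blocks.append(np.array([i]))
            i += 1
            continue
        j = i + 1
        while (
            j < n
            and phased[j]
            and ps[j] == ps[i]
            and pos[j] - pos[i] + 1 <= max_block_length
        ):
            j += 1
        blocks.append(np.arange(i, j))
        i = j
    return blocks


def switch_test(x1_i, t_i, x1_j, t_j, alpha: float = 0.01,
                sample_policy: str = "any") -> bool:
    """Decide whether two adjacent SNPs' counts may be combined.

    ``x1_*`` are per-sample haplotype-"1" read counts and ``t_*`` totals.
    Returns True (keep together) unless the phased allele fractions differ
    significantly (two-sided Fisher exact test at ``alpha``).  Samples with a
    zero total at either SNP are skipped.  With ``sample_policy="any"`` a
    significant difference in any sample blocks the merge; with ``"pooled"``
    counts are summed across samples before a single test.
    """
    x1_i = np.atleast_1d(np.asarray(x1_i, dtype=np.int64))
    t_i = np.atleast_1d(np.asarray(t_i, dtype=np.int64))
    x1_j = np.atleast_1d(np.asarray(x1_j, dtype=np.int64))
    t_j = np.atleast_1d(np.asarray(t_j, dtype=np.int64))
    use = (t_i > 0) & (t_j > 0)
    if not use.any():
        return True
    if sample_policy == "pooled":
        a, b = int(x1_i[use].sum()), int((t_i - x1_i)[use].sum())
        c, d = int(x1_j[use].sum()), int((t_j - x1_j)[use].sum())
        p = fisher_exact_two_sided(a, b, c, d)[0]
        return bool(p >= alpha)
    if sample_policy != "any":
        raise ValueError(f"unknown sample_policy {sample_policy!r}")
    p = fisher_exact_two_sided(
        x1_i[use], (t_i - x1_i)[use], x1_j[use], (t_j - x1_j)[use]
    )
    return bool((p >= alpha).all())


def _adjacent_split_flags(x1, t, alpha, sample_policy):
    """Vectorized switch tests between consecutive rows of (x1, t).

    Returns a boolean array of length n-1; True means *do not* merge the pair.
    """
    n = x1.shape[0]
    if n <= 1:
        return np.zeros(0, dtype=bool)
    xi, ti = x1[:-1], t[:-1]
    xj, tj = x1[1:], t[1:]
    use = (ti > 0) & (tj > 0)
    if sample_policy == "pooled":
        a = np.where(use, xi, 0).sum(axis=1)
        b = np.where(use, ti - xi, 0).sum(axis=1)
        c = np.where(use, xj, 0).sum(axis=1)
        d = np.where(use, tj - xj, 0).sum(axis=1)
        p = fisher_exact_two_sided(a, b, c, d)
        return p < alpha
    split = np.zeros(n - 1, dtype=bool)
    for s in range(x1.shape[1]):
        m = use[:, s]
        if not m.any():
            continue
        p = fisher_exact_two_sided(xi[m, s], (ti - xi)[m, s], xj[m, s], (tj - xj)[m, s])
        sub = np.zeros(n - 1, dtype=bool)
        sub[m] = p < alpha
        split |= sub
    return split


def build_metasnps(snps: pd.DataFrame, samples: list[str],
                   max_block_length: int = 25_000, alpha: float = 0.01,
                   sample_policy: str = "any") -> pd.DataFrame:
    """Aggregate phased SNPs into meta-SNPs, guarding against switch errors.

    Within each candidate block from :func:`split_blocks`, a meta-SNP is grown
    left-to-right and cut whenever the switch test fails between the incoming
    SNP and the last accepted SNP.  Counts are aggregated onto haplotype "1":
    ``x_Q = sum_j [h_j x_j + (1-h_j)(t_j - x_j)]``, ``t_Q = sum_j t_j``.

    Parameters
    ----------
    snps : DataFrame with columns CHROM POS PHASE_SET REF_PHASE and, per sample
        name ``s`` in ``samples``, ALT_<s> and TOT_<s>.
    samples : sample names, matched normal first by convention.

    Returns a DataFrame with columns CHROM START END N_SNPS and per-sample
    X_<s> T_<s>, plus FIRST/LAST positional indices of member SNPs.
    """
    alt = np.column_stack([snps[f"ALT_{s}"].to_numpy(dtype=np.int64) for s in samples])
    tot = np.column_stack([snps[f"TOT_{s}"].to_numpy(dtype=np.int64) for s in samples])
    if (alt < 0).any() or (alt > tot).any():
        raise ValueError("require 0 <= ALT <= TOT for every SNP and sample")
    ref_phase = snps["REF_PHASE"].fillna(1).to_numpy(dtype=np.int64)
    x1 = hap1_counts(alt, tot, ref_phase)
    pos = snps["POS"].to_numpy(dtype=np.int64)

    rows = []
    for chrom, idx in snps.groupby("CHROM", sort=False).indices.items():
        idx = np.sort(idx)
        sub = snps.iloc[idx]
        # one vectorized pass over all adjacent pairs of the chromosome;
        # blocks then reuse the per-pair verdicts
        flags = _adjacent_split_flags(x1[idx], tot[idx], alpha, sample_policy)
        for block in split_blocks(sub, max_block_length):
            g = idx[block]  # global positional indices
            split = flags[block[:-1]] if len(block) > 1 else np.zeros(0, bool)
            cut_after = np.nonzero(split)[0]
            starts = np.concatenate([[0], cut_after + 1])
            ends = np.concatenate([cut_after, [len(g) - 1]])
            for s0, e0 in zip(starts, ends):
                members = g[s0 : e0 + 1]
                rows.append(
                    (chrom, int(pos[members[0]]), int(pos[members[-1]]),
                     len(members), int(members[0]), int(members[-1]),
                     *x1[members].sum(axis=0), *tot[members].sum(axis=0))
                )
    cols = (["CHROM", "START", "END", "N_SNPS", "FIRST", "LAST"]
            + [f"X_{s}" for s in samples] + [f"T_{s}" for s in samples])
    return pd.DataFrame(rows, columns=cols)
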