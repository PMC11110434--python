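"""End-to-end inference: phased SNP counts + depths -> clone mixture.

Stages run in dependency order -- phase -> bin -> mhbaf -> cluster -> solve --
each a pure function of its inputs, parameters and seed.  ``infer`` runs them
in memory; the CLI wraps the same functions around TSV artifacts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phasing import build_metasnps
from .binning import BinMatrix, build_bin_matrix
from .baf import estimate_bin_baf, resolve_bin_switches
from .cluster import LocalGlobalHMM, fit_hmm, merge_complement_clusters, select_K
from .factorize import CloneMixture, assign_states, label_events, model_select

logger = logging.getLogger(__name__)

__all__ = ["PipelineParams", "PipelineResult", "infer", "cluster_observations",
           "segments_from_result"]


@dataclass
class PipelineParams:
    """Per-stage tunables; defaults are the pipeline's study conditions."""

    normal: str = "normal"
    max_block_length: int = 25_000
    alpha: float = 0.01
    k_snp: int = 1000
    k_total: int = 5000
    switch_window: int = 5
    balance_eps: float = 0.1
    switch_density_thresh: float = 0.2
    K_grid: tuple = (2, 3, 4, 5, 6)
    cluster_seeds: tuple = (0, 1)
    tau_init: float = 0.1
    m_grid: tuple = (1, 2, 3)
    c_max_no_wgd: int = 4
    c_max_wgd: int = 8
    elbow: float = 0.05
    subclonal_penalty: float = 0.1
    em_restarts: int = 5
    min_cluster_frac: float = 0.02
    solver_restarts: int = 12
    solver_kicks: int = 8
    seed: int = 0


@dataclass
class PipelineResult:
    meta: pd.DataFrame
    binmat: BinMatrix
    labels: np.ndarray
    model: LocalGlobalHMM
    cluster_R: np.ndarray  # per-cluster mean RDR (cluster x sample)
    cluster_B: np.ndarray
    cluster_w: np.ndarray
    cluster_ids: np.ndarray  # cluster label value per row of cluster_R
    mixture: CloneMixture
    report: dict
    segments: pd.DataFrame  # inferred clone profiles mapped back to the genome


def cluster_observations(binmat: BinMatrix, labels: np.ndarray):
    """Bin-count-weighted cluster means of RDR and mhBAF, with the squared
    standard errors of those means (pooled within-cluster variance / n_k),
    which downstream model selection uses as the fit's noise floor."""
    ids = np.unique(labels)
    R = np.vstack([binmat.rdr[labels == k].mean(axis=0) for k in ids])
    B = np.vstack([binmat.baf[labels == k].mean(axis=0) for k in ids])
    w = np.array([(labels == k).sum() for k in ids], dtype=float)
    n = len(labels)
    dof = max(n - len(ids), 1)
    var_r = np.zeros(binmat.rdr.shape[1])
    var_b = np.zeros(binmat.baf.shape[1])
    for j, k in enumerate(ids):
        sel = labels == k
        var_r += ((binmat.rdr[sel] - R[j]) ** 2).sum(axis=0)
        var_b += ((binmat.baf[sel] - B[j]) ** 2).sum(axis=0)
    se2_R = var_r[None, :] / dof / w[:, None]
    se2_B = var_b[None, :] / dof / w[:, None]
    # The per-bin minor-haplotype orientation cannot exceed 0.5 on average,
    # so a truly balanced cluster's mean BAF sits one estimator-noise unit
    # below 0.5 -- a known one-sided bias, not a signal.  For clusters whose
    # deviation is consistent with balance (within 2.5 binomial SEs of the
    # member bins' SNP-covering reads), that squared deviation is part of
    # the noise floor rather than model misfit.
    sig2 = 0.25 / np.maximum(binmat.snp_reads[:, 1:], 1)
    for j, k in enumerate(ids):
        sig2_k = sig2[labels == k].mean(axis=0)
        dev = np.abs(B[j] - 0.5)
        bal = dev <= 2.5 * np.sqrt(sig2_k)
        se2_B[j] = se2_B[j] + np.where(bal, dev ** 2, 0.0)
    return R, B, w, ids, se2_R, se2_B


def segments_from_result(binmat: BinMatrix, labels: np.ndarray,
                         cluster_ids: np.ndarray, mixture: CloneMixture):
    """Map cluster-level clone states back onto the genome.

    Adjacent bins with the same cluster merge into one segment; each segment
    carries the per-clone (a, b) of its cluster plus mirrored/LOH flags.
    """
    pos = {k: i for i, k in enumerate(cluster_ids)}
    events = label_events(mixture)
    m = mixture.n_clones
    rows = []
    bins = binmat.bins
    for i in range(binmat.n_bins):
        k = labels[i]
        s = pos[k]
        prev = rows[-1] if rows else None
        if (prev is not None and prev["CHROM"] == bins.CHROM.iloc[i]
                and prev["ARM"] == bins.ARM.iloc[i]
                and prev["END"] == bins.START.iloc[i]
                and prev["CLUSTER"] == k):
            prev["END"] = int(bins.END.iloc[i])
            prev["N_BINS"] += 1
            continue
        row = {"CHROM": bins.CHROM.iloc[i], "ARM": bins.ARM.iloc[i],
               "START": int(bins.START.iloc[i]), "END": int(bins.END.iloc[i]),
               "CLUSTER": int(k), "N_BINS": 1,
               "MIRRORED": events[s]["mirrored_subclonal"],
               "LOH": events[s]["loh"], "CLONAL": events[s]["clonal"]}
        for c in range(m + 1):
            row[f"A_{c}"] = int(mixture.cn_a[c, s])
            row[f"B_{c}"] = int(mixture.cn_b[c, s])
        rows.append(row)
    return pd.DataFrame(rows)


def infer(snp_df: pd.DataFrame, depth_df: pd.DataFrame,
          arm_table: pd.DataFrame, samples: list[str] | None = None,
          params: PipelineParams | None = None) -> PipelineResult:
    """Run phase -> bin -> mhbaf -> cluster -> solve on in-memory tables."""
    params = params or PipelineParams()
    if samples is None:
        from .io import samples_from_columns

        samples = samples_from_columns(snp_df)
        if params.normal in samples:
            samples = [params.normal] + [s for s in samples if s != params.normal]
    ss = np.random.SeedSequence(params.seed)
    s_baf, s_cluster, s_solve = [int(c.generate_state(1)[0] % (2**31 - 1))
                                 for c in ss.spawn(3)]

    meta = build_metasnps(snp_df, samples,
                          max_block_length=params.max_block_length,
                          alpha=params.alpha)
    binmat = build_bin_matrix(meta, depth_df, arm_table, samples,
                              k_snp=params.k_snp, k_total=params.k_total)
    estimate_bin_baf(binmat, meta, n_restarts=params.em_restarts, seed=s_baf)
    resolve_bin_switches(binmat, window=params.switch_window,
                         balance_eps=params.balance_eps,
                         switch_density_thresh=params.switch_density_thresh)

    X = binmat.features()
    lengths = binmat.arm_lengths()
    K, model, labels = select_K(X, lengths, K_grid=params.K_grid,
                                seeds=params.cluster_seeds,
                                tau_init=params.tau_init)
    labels = merge_complement_clusters(binmat, labels)
    logger.info("selected K=%d clusters (%d after mirror merge)", K,
                len(np.unique(labels)))

    R, B, w, ids, se2_R, se2_B = cluster_observations(binmat, labels)
    # clusters too small to carry a reliable mean are excluded from the
    # deconvolution and get their states assigned post hoc
    min_w = max(2.0, params.min_cluster_frac * binmat.n_bins)
    big = w >= min_w
    if not big.any():
        big = w == w.max()
    mixture, report = model_select(
        R[big], B[big], weights=w[big], m_grid=params.m_grid,
        c_max_map={False: params.c_max_no_wgd, True: params.c_max_wgd},
        elbow=params.elbow, subclonal_penalty=params.subclonal_penalty,
        se_R=se2_R[big], se_B=se2_B[big], seed=s_solve,
        n_restarts=params.solver_restarts, n_kicks=params.solver_kicks)
    logger.info("selected m=%d clones, wgd=%s", report["m"], report["wgd"])
    c_max = params.c_max_wgd if report["wgd"] else params.c_max_no_wgd
    full_a = np.ones((mixture.n_clones + 1, len(ids)), dtype=np.int64)
    full_b = np.ones_like(full_a)
    full_a[:, big] = mixture.cn_a
    full_b[:, big] = mixture.cn_b
    if (~big).any():
        ea, eb = assign_states(mixture, R[~big], B[~big], c_max=c_max)
        full_a[:, ~big] = ea
        full_b[:, ~big] = eb
    mixture = CloneMixture(cn_a=full_a, cn_b=full_b, u=mixture.u,
                           wgd=mixture.wgd, lam=mixture.lam)
    segments = segments_from_result(binmat, labels, ids, mixture)
    return PipelineResult(meta=meta, binmat=binmat, labels=labels, model=model,
                          cluster_R=R, cluster_B=B, cluster_w=w,
                          cluster_ids=ids, mixture=mixture, report=report,
                          segments=segments)
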