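"""Variable-width binning of chromosome arms and read-depth ratios.

Heterozygous SNPs are unevenly spread along the genome, so fixed-width bins
carry wildly different numbers of SNP-covering reads and hence unequal variance
in the allelic-imbalance signal.  Bins here are instead grown greedily along
each arm until they hold at least ``k_snp`` SNP-covering reads and ``k_total``
total reads in *every* sample (matched normal included), which stabilizes the
variance of both the B-allele frequency and the read-depth ratio (RDR).

Coordinates: meta-SNP tables are 1-based inclusive (VCF convention); emitted
bins are 0-based half-open (BED convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["GenomicBin", "BinMatrix", "partition_arm", "compute_raw_rdr",
           "normalize_rdr", "assign_arms", "load_arm_table"]


@dataclass
class GenomicBin:
    chrom: str
    arm: str
    start: int  # 0-based half-open
    end: int
    meta_first: int  # positional index range into the meta-SNP table
    meta_last: int
    snp_reads: np.ndarray  # per sample, normal first
    total_reads: np.ndarray
    fallback: bool = False


@dataclass
class BinMatrix:
    """Ordered genomic bins with per-tumor-sample RDR and (later) mhBAF."""

    bins: pd.DataFrame  # CHROM ARM START END META_FIRST META_LAST FALLBACK
    snp_reads: np.ndarray  # (n_bins, n_samples) incl. normal at column 0
    total_reads: np.ndarray
    samples: list[str]  # all sample names, normal first
    rdr: np.ndarray | None = None  # (n_bins, P) tumor samples only
    baf: np.ndarray | None = None
    baf_flags: np.ndarray | None = None  # bins with imputed/missing samples
    n_switched: np.ndarray | None = None

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    @property
    def tumor_samples(self) -> list[str]:
        return self.samples[1:]

    def arm_ids(self) -> np.ndarray:
        keys = self.bins["CHROM"].astype(str) + ":" + self.bins["ARM"].astype(str)
        _, ids = np.unique(keys.to_numpy(), return_inverse=True)
        return ids

    def arm_lengths(self) -> np.ndarray:
        """Number of consecutive bins per arm, in table order."""
        keys = (self.bins["CHROM"].astype(str) + ":" + self.bins["ARM"].astype(str)).to_numpy()
        change = np.nonzero(keys[1:] != keys[:-1])[0] + 1
        bounds = np.concatenate([[0], change, [len(keys)]])
        return np.diff(bounds)

    def features(self) -> np.ndarray:
        """Concatenated (RDR, mhBAF) per bin across tumor samples."""
        if self.rdr is None or self.baf is None:
            raise ValueError("features require both rdr and baf")
        return np.hstack([self.rdr, self.baf])

    def widths(self) -> np.ndarray:
        return (self.bins["END"] - self.bins["START"]).to_numpy()


def partition_arm(meta: pd.DataFrame, depth_pos: np.ndarray,
                  depth_counts: np.ndarray, samples: list[str],
                  arm_start: int, arm_end: int,
                  k_snp: int = 1000, k_total: int = 5000) -> list[GenomicBin]:
    """Greedy variable-width partition of one chromosome arm.

    Walks meta-SNPs left to right accumulating SNP-covering reads (T columns)
    and total reads (``depth_counts`` rows whose ``depth_pos`` start falls in
    the growing bin); a boundary is placed at the midpoint after the meta-SNP
    at which both accumulated counts reach their floors in all samples.  If the
    trailing residual violates either floor in any sample, the last boundary is
    removed, merging the residual into the previous bin.  An arm that cannot
    satisfy the floors at all becomes a single bin flagged ``fallback``.

    ``meta`` must contain only this arm's meta-SNPs, ordered; empty arms yield
    an empty list with a warning.
    """
    if k_snp < 1 and k_total < 1:
        raise ValueError("at least one of k_snp, k_total must be >= 1")
    if len(meta) == 0:
        logger.warning("arm %s-%s has no meta-SNPs; omitted", arm_start, arm_end)
        return []
    chrom = meta["CHROM"].iloc[0]
    arm = meta["ARM"].iloc[0] if "ARM" in meta else "p"
    T = meta[[f"T_{s}" for s in samples]].to_numpy(dtype=np.int64)
    starts = meta["START"].to_numpy()
    ends = meta["END"].to_numpy()
    order = np.argsort(depth_pos, kind="stable")
    depth_pos = np.asarray(depth_pos)[order]
    depth_counts = np.asarray(depth_counts)[order]
    n = len(meta)

    def depth_in(a: int, b: int) -> np.ndarray:
        lo, hi = np.searchsorted(depth_pos, [a, b], side="left")
        return depth_counts[lo:hi].sum(axis=0)

    bins: list[GenomicBin] = []
    prev_b = arm_start
    first_meta = 0
    cum_snp = np.zeros(len(samples), dtype=np.int64)
    for i in range(n):
        cum_snp = cum_snp + T[i]
        if i == n - 1:
            break
        # candidate boundary midway between this meta-SNP and the next
        b = int((ends[i] + starts[i + 1]) // 2)
        cum_tot = depth_in(prev_b, b)
        if (cum_snp >= k_snp).all() and (cum_tot >= k_total).all():
            bins.append(GenomicBin(chrom, arm, prev_b, b, first_meta, i,
                                   cum_snp.copy(), cum_tot))
            prev_b, first_meta = b, i + 1
            cum_snp = np.zeros(len(samples), dtype=np.int64)
    # trailing residual
    res_tot = depth_in(prev_b, arm_end)
    residual = GenomicBin(chrom, arm, prev_b, arm_end, first_meta, n - 1,
                          cum_snp.copy(), res_tot)
    ok = (cum_snp >= k_snp).all() and (res_tot >= k_total).all()
    if ok or not bins:
        residual.fallback = not ok
        bins.append(residual)
    else:
        last = bins.pop()
        merged = GenomicBin(chrom, arm, last.start, arm_end, last.meta_first,
                            n - 1, last.snp_reads + cum_snp,
                            last.total_reads + res_tot)
        bins.append(merged)
    return bins


def compute_raw_rdr(total_reads: np.ndarray, normal_col: int = 0) -> np.ndarray:
    """Raw read-depth ratio d_{s,p} / d_{s,0} per bin and tumor sample.

    Bins with zero normal reads must have been dropped beforehand.
    """
    d = np.asarray(total_reads, dtype=float)
    d0 = d[:, normal_col]
    if (d0 <= 0).any():
        raise ValueError("bins with zero matched-normal reads must be filtered "
                         "before computing RDR")
    tumor = np.delete(d, normal_col, axis=1)
    return tumor / d0[:, None]


def normalize_rdr(raw_rdr: np.ndarray) -> np.ndarray:
    """Library-size normalization: r = r~ * (sum_s r~_{s,0} / sum_s r~_{s,p}).

    The matched normal's raw RDR is identically 1, so post-normalization the
    per-sample mean RDR over bins is exactly 1.
    """
    rt = np.asarray(raw_rdr, dtype=float)
    if rt.shape[0] == 0:
        raise ValueError("need at least one bin")
    col = rt.sum(axis=0)
    if (col <= 0).any():
        bad = int(np.nonzero(col <= 0)[0][0])
        raise ValueError(f"sample column {bad} has no reads")
    return rt * (rt.shape[0] / col)


def load_arm_table(path=None) -> pd.DataFrame:
    """Chromosome-arm intervals (CHROM ARM START END, 0-based half-open).

    With no path, loads the packaged hg38 arm table derived from centromere
    midpoints; otherwise reads a user BED-like TSV.
    """
    if path is None:
        from importlib.resources import files

        path = files("hapclone.data").joinpath("hg38_arms.tsv")
    df = pd.read_csv(path, sep="\t", comment="#",
                     names=["CHROM", "START", "END", "ARM"], dtype={"CHROM": str})
    return df


def assign_arms(positions: np.ndarray, chroms: np.ndarray,
                arm_table: pd.DataFrame) -> np.ndarray:
    """Arm label ("p"/"q") per position; positions outside any arm get ""."""
    out = np.full(len(positions), "", dtype=object)
    for _, row in arm_table.iterrows():
        m = (chroms == row["CHROM"]) & (positions >= row["START"]) & (positions < row["END"])
        out[m] = row["ARM"]
    return out


def build_bin_matrix(meta: pd.DataFrame, depth: pd.DataFrame,
                     arm_table: pd.DataFrame, samples: list[str],
                     k_snp: int = 1000, k_total: int = 5000) -> BinMatrix:
    """Partition every arm and assemble a :class:`BinMatrix` with RDR.

    ``meta`` is a meta-SNP table (with CHROM/START/END and per-sample X/T);
    ``depth`` has columns CHROM POS and per-sample D_<s> read-start counts;
    ``arm_table`` defines arm intervals.  Bins with zero matched-normal reads
    are dropped with a warning before RDR computation.
    """
    meta = meta.copy()
    all_bins: list[GenomicBin] = []
    for _, armrow in arm_table.iterrows():
        chrom, arm = armrow["CHROM"], armrow["ARM"]
        sel = ((meta["CHROM"] == chrom) & (meta["START"] >= armrow["START"])
               & (meta["END"] <= armrow["END"]))
        sub = meta.loc[sel].copy()
        sub["ARM"] = arm
        dsel = (depth["CHROM"] == chrom) & (depth["POS"] >= armrow["START"]) \
            & (depth["POS"] < armrow["END"])
        dpos = depth.loc[dsel, "POS"].to_numpy()
        dcnt = depth.loc[dsel, [f"D_{s}" for s in samples]].to_numpy(dtype=np.int64)
        bins = partition_arm(sub, dpos, dcnt, samples,
                             int(armrow["START"]), int(armrow["END"]),
                             k_snp=k_snp, k_total=k_total)
        # remap meta indices to global positions
        base = np.nonzero(sel.to_numpy())[0]
        for b in bins:
            b.meta_first = int(base[b.meta_first])
            b.meta_last = int(base[b.meta_last])
        all_bins.extend(bins)

    keep = [b for b in all_bins if b.total_reads[0] > 0]
    if len(keep) < len(all_bins):
        logger.warning("dropped %d bins with zero matched-normal reads",
                       len(all_bins) - len(keep))
    if not keep:
        raise ValueError("no bins with matched-normal coverage")
    bins_df = pd.DataFrame(
        [(b.chrom, b.arm, b.start, b.end, b.meta_first, b.meta_last, b.fallback)
         for b in keep],
        columns=["CHROM", "ARM", "START", "END", "META_FIRST", "META_LAST", "FALLBACK"],
    )
    snp_reads = np.vstack([b.snp_reads for b in keep])
    total_reads = np.vstack([b.total_reads for b in keep])
    bm = BinMatrix(bins=bins_df, snp_reads=snp_reads, total_reads=total_reads,
                   samples=list(samples))
    bm.rdr = normalize_rdr(compute_raw_rdr(total_reads))
    return bm
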