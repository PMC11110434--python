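"""TSV readers/writers for the pipeline's on-disk dialects."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .binning import BinMatrix


def samples_from_columns(df: pd.DataFrame, prefix: str = "ALT_") -> list[str]:
    return [c[len(prefix):] for c in df.columns if c.startswith(prefix)]


def read_snp_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"CHROM", "POS", "PHASE_SET", "REF_PHASE"}
    if not need.issubset(df.columns):
        raise ValueError(f"SNP table missing columns {sorted(need - set(df.columns))}")
    return df


def read_depth_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_meta_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_meta_table(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def write_bin_table(binmat: BinMatrix, path, bed_path=None) -> None:
    """One row per bin x tumor sample:
    #CHR START END ARM SAMPLE RD BAF TOTAL_READS SNP_READS NORMAL_READS."""
    rows = []
    for i in range(binmat.n_bins):
        b = binmat.bins.iloc[i]
        for p, s in enumerate(binmat.tumor_samples):
            rows.append((
                b.CHROM, b.START, b.END, b.ARM, s,
                binmat.rdr[i, p] if binmat.rdr is not None else np.nan,
                binmat.baf[i, p] if binmat.baf is not None else np.nan,
                binmat.total_reads[i, p + 1], binmat.snp_reads[i, p + 1],
                binmat.total_reads[i, 0],
                int(binmat.n_switched[i]) if binmat.n_switched is not None else 0,
            ))
    out = pd.DataFrame(rows, columns=["#CHR", "START", "END", "ARM", "SAMPLE",
                                      "RD", "BAF", "TOTAL_READS", "SNP_READS",
                                      "NORMAL_READS", "N_SWITCHED"])
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")
    if bed_path:
        binmat.bins[["CHROM", "START", "END", "ARM"]].to_csv(
            bed_path, sep="\t", index=False, header=False)


def read_bin_table(path, samples: list[str]) -> BinMatrix:
    """Rebuild a BinMatrix (without meta-SNP links) from a bin table TSV."""
    df = pd.read_csv(path, sep="\t")
    tumor = samples[1:]
    first = df[df.SAMPLE == tumor[0]].reset_index(drop=True)
    bins = first[["#CHR", "START", "END", "ARM"]].rename(columns={"#CHR": "CHROM"})
    bins["META_FIRST"] = -1
    bins["META_LAST"] = -1
    bins["FALLBACK"] = False
    n = len(bins)
    rdr = np.zeros((n, len(tumor)))
    baf = np.zeros((n, len(tumor)))
    snp = np.zeros((n, len(samples)), dtype=np.int64)
    tot = np.zeros((n, len(samples)), dtype=np.int64)
    for p, s in enumerate(tumor):
        sub = df[df.SAMPLE == s].reset_index(drop=True)
        rdr[:, p] = sub.RD
        baf[:, p] = sub.BAF
        snp[:, p + 1] = sub.SNP_READS
        tot[:, p + 1] = sub.TOTAL_READS
        tot[:, 0] = sub.NORMAL_READS
    return BinMatrix(bins=bins, snp_reads=snp, total_reads=tot,
                     samples=list(samples), rdr=rdr, baf=baf)


def write_cluster_summary(R, B, w, labels_order, path, samples) -> None:
    rows = []
    for k, cid in enumerate(labels_order):
        for p, s in enumerate(samples):
            rows.append((cid, s, int(w[k]), R[k, p], B[k, p]))
    pd.DataFrame(rows, columns=["#ID", "SAMPLE", "#BINS", "RD", "BAF"]).to_csv(
        path, sep="\t", index=False, float_format="%.6g")


def write_segments(segments: pd.DataFrame, u: np.ndarray, path,
                   bed_path=None) -> None:
    """Clone-profile segment table plus a BED of mirrored/LOH annotations."""
    df = segments.copy()
    m = u.shape[0] - 1
    for i in range(m + 1):
        for p in range(u.shape[1]):
            df[f"U_{i}_S{p+1}"] = u[i, p]
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    if bed_path:
        rows = []
        for _, r in segments.iterrows():
            name = []
            if r.get("MIRRORED", False):
                name.append("mirrored")
            if r.get("LOH", False):
                name.append("loh")
            if name:
                rows.append((r.CHROM, r.START, r.END, ",".join(name)))
        pd.DataFrame(rows, columns=["CHROM", "START", "END", "NAME"]).to_csv(
            bed_path, sep="\t", index=False, header=False)


def read_segments(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_proportions(path) -> np.ndarray:
    return pd.read_csv(path, sep="\t", index_col=0).to_numpy()
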