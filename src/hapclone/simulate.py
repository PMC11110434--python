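"""Seeded synthetic clone mixtures: SNP counts, depths, and ground truth.

The generator emulates the statistical structure the inference pipeline
assumes: a clone tree whose tumor clones inherit ancestral copy-number events
and add their own (arm-level, focal, mirrored-subclonal pairs, optional WGD);
per-sample clone proportions; heterozygous SNPs placed by a Poisson process
with configurable density; SNP totals Poisson around coverage scaled by the
local fractional copy number; alt counts binomial with success probability
given by the haplotype carrying the alternate allele; reference phasing
emitted per phase set with independent per-SNP switch errors.

Per-sample depths are scaled by F / lambda_p with lambda_p the genome-wide
length-weighted mean fractional copy number, so that simulated RDR follows
the pipeline's mean-1 library-size convention without circularity.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = ["CNAEvent", "SimConfig", "GroundTruth", "simulate_genome",
           "simulate_counts", "write_fixture", "run_simulation",
           "mirrored_scenario", "focal_scenario", "random_clone_mixture"]


@dataclass
class CNAEvent:
    clone: int  # tumor clone index, 1-based
    chrom: str
    arm: str
    start: int  # 0-based half-open within the arm's coordinates
    end: int
    allele: str  # "A" or "B"
    delta: int  # copy-number change of that allele


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset.  ``seed`` is mandatory."""

    seed: int
    arms: list = field(default_factory=lambda: [("chr1", "p", 12_000_000),
                                                ("chr1", "q", 12_000_000),
                                                ("chr2", "p", 12_000_000)])
    snp_density: float = 0.4  # mean heterozygous SNPs per kb
    n_samples: int = 2
    n_clones: int = 2
    clone_tree: list = field(default_factory=list)  # (parent, child); 0 = normal
    events: list = field(default_factory=list)  # CNAEvent list
    wgd: bool = False
    u: list | None = None  # (m+1, P) proportions; None -> Dirichlet draw
    dirichlet_alpha: float = 1.5
    snp_coverage: float = 30.0  # mean reads over a SNP, per sample
    reads_per_kb: float = 60.0  # read starts per kb, per sample
    depth_grid: int = 1000  # bp between depth-table positions
    phase_set_mean_length: float = 40_000.0
    switch_error_rate: float = 0.02
    overdispersion: float = 0.0  # extra-Poisson variance: var = mu + od*mu^2

    def arm_key(self, chrom, arm):
        return f"{chrom}:{arm}"

    def arm_offsets(self) -> dict:
        """Global start coordinate of each arm: arms of one chromosome are
        laid out consecutively so their coordinate ranges never overlap."""
        out = {}
        cursor: dict[str, int] = {}
        for chrom, arm, length in self.arms:
            off = cursor.get(chrom, 0)
            out[self.arm_key(chrom, arm)] = off
            cursor[chrom] = off + length
        return out


@dataclass
class GroundTruth:
    segments: pd.DataFrame  # CHROM ARM START END + A_i/B_i per clone + MIRRORED
    u: np.ndarray  # (m+1, P)
    wgd: bool
    snp_pos: dict  # arm key -> positions (1-based)
    snp_on_b: dict  # arm key -> bool, alt allele on the B (minor) haplotype
    config: SimConfig

    def clone_columns(self):
        m = self.u.shape[0] - 1
        return [(f"A_{i}", f"B_{i}") for i in range(m + 1)]

    def states(self, chrom, arm, pos):
        """(a_i, b_i) per clone for the segment containing 0-based ``pos``."""
        seg = self.segments
        row = seg[(seg.CHROM == chrom) & (seg.ARM == arm)
                  & (seg.START <= pos) & (seg.END > pos)].iloc[0]
        m = self.u.shape[0] - 1
        a = np.array([row[f"A_{i}"] for i in range(m + 1)])
        b = np.array([row[f"B_{i}"] for i in range(m + 1)])
        return a, b

    def bin_state_labels(self, bins: pd.DataFrame) -> np.ndarray:
        """True cluster id per bin: distinct across-clone state combinations."""
        labels = []
        for _, b in bins.iterrows():
            mid = (b.START + b.END) // 2
            a, bb = self.states(b.CHROM, b.ARM, mid)
            labels.append(list(a) + list(bb))
        _, ids = np.unique(np.asarray(labels, dtype=np.int64), axis=0,
                           return_inverse=True)
        return ids


def _clone_profiles(cfg: SimConfig):
    """Per-arm segment boundaries and per-clone (a, b) states from events."""
    m = cfg.n_clones
    tree = cfg.clone_tree or [(0, i) for i in range(1, m + 1)]
    children = {}
    for p, c in tree:
        children.setdefault(p, []).append(c)

    events_by_clone = {}
    for ev in cfg.events:
        events_by_clone.setdefault(ev.clone, []).append(ev)
    # reject overlapping events within one clone on the same arm
    for clone, evs in events_by_clone.items():
        by_arm = {}
        for ev in evs:
            by_arm.setdefault((ev.chrom, ev.arm), []).append(ev)
        for (chrom, arm), lst in by_arm.items():
            lst = sorted(lst, key=lambda e: e.start)
            for e1, e2 in zip(lst, lst[1:]):
                if e2.start < e1.end and e1.allele == e2.allele:
                    raise ValueError(
                        f"overlapping events on clone {clone} {chrom}{arm} "
                        f"[{e2.start}, {min(e1.end, e2.end)})")

    segments = []
    offsets = cfg.arm_offsets()
    for chrom, arm, length in cfg.arms:
        off = offsets[cfg.arm_key(chrom, arm)]
        bounds = {0, length}
        for ev in cfg.events:
            if (ev.chrom, ev.arm) == (chrom, arm):
                if not (0 <= ev.start < ev.end <= length):
                    raise ValueError(f"event interval outside arm: {ev}")
                bounds.update((ev.start, ev.end))
        bounds = sorted(bounds)
        for s0, s1 in zip(bounds[:-1], bounds[1:]):
            a = np.ones(m + 1, dtype=np.int64)
            b = np.ones(m + 1, dtype=np.int64)
            if cfg.wgd:
                a[1:] = 2
                b[1:] = 2
            # accumulate events down the tree (BFS from normal root)
            deltas = {}
            for ev in cfg.events:
                if (ev.chrom, ev.arm) == (chrom, arm) and ev.start <= s0 < ev.end:
                    deltas.setdefault(ev.clone, []).append(ev)
            order = [0]
            queue = [0]
            while queue:
                p = queue.pop(0)
                for c in children.get(p, []):
                    order.append(c)
                    queue.append(c)
            inherited_a = {0: 1}
            inherited_b = {0: 1}
            for c in order[1:]:
                parent = next(p for p, ch in tree if ch == c)
                base_a = inherited_a[parent] if parent != 0 else a[c]
                base_b = inherited_b[parent] if parent != 0 else b[c]
                for ev in deltas.get(c, []):
                    if ev.allele == "A":
                        base_a += ev.delta
                    else:
                        base_b += ev.delta
                if base_a < 0 or base_b < 0:
                    raise ValueError(
                        f"negative copy number on clone {c} at {chrom}{arm}:{s0}")
                inherited_a[c] = base_a
                inherited_b[c] = base_b
                a[c] = base_a
                b[c] = base_b
            mirrored = bool((a[1:] > b[1:]).any() and (b[1:] > a[1:]).any())
            segments.append((chrom, arm, off + s0, off + s1, *a, *b, mirrored))
    cols = (["CHROM", "ARM", "START", "END"]
            + [f"A_{i}" for i in range(m + 1)] + [f"B_{i}" for i in range(m + 1)]
            + ["MIRRORED"])
    return pd.DataFrame(segments, columns=cols)


def simulate_genome(cfg: SimConfig) -> GroundTruth:
    """Place SNPs, apply events along the clone tree, draw clone proportions."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 11]))
    segments = _clone_profiles(cfg)
    m = cfg.n_clones
    if cfg.u is not None:
        u = np.asarray(cfg.u, dtype=float)
        if u.shape != (m + 1, cfg.n_samples) or (u < 0).any() \
                or not np.allclose(u.sum(axis=0), 1.0):
            raise ValueError("u must be a valid (m+1, P) simplex matrix")
    else:
        u = rng.dirichlet(np.full(m + 1, cfg.dirichlet_alpha),
                          size=cfg.n_samples).T
    snp_pos = {}
    snp_on_b = {}
    offsets = cfg.arm_offsets()
    for chrom, arm, length in cfg.arms:
        density_bp = cfg.snp_density / 1000.0
        n = rng.poisson(density_bp * length)
        key = cfg.arm_key(chrom, arm)
        pos = np.sort(rng.choice(length, size=n, replace=False)) + 1 + offsets[key]
        snp_pos[key] = pos
        snp_on_b[key] = rng.random(n) < 0.5
    return GroundTruth(segments=segments, u=u, wgd=cfg.wgd, snp_pos=snp_pos,
                       snp_on_b=snp_on_b, config=cfg)


def _draw_counts(rng, mu, overdispersion: float):
    """Poisson by default; gamma-Poisson (negative binomial) when
    overdispersion > 0, with variance mu + overdispersion * mu^2."""
    mu = np.asarray(mu, dtype=float)
    if overdispersion <= 0:
        return rng.poisson(mu)
    shape = 1.0 / overdispersion
    rate = rng.gamma(shape, np.maximum(mu, 1e-12) * overdispersion)
    return rng.poisson(rate)


def _segment_FG(truth: GroundTruth):
    """Fractional total/minor copy numbers per segment row and sample."""
    m = truth.u.shape[0] - 1
    a = truth.segments[[f"A_{i}" for i in range(m + 1)]].to_numpy()
    b = truth.segments[[f"B_{i}" for i in range(m + 1)]].to_numpy()
    F = (a + b) @ truth.u
    G = b @ truth.u
    return F, G


def genome_lambda(truth: GroundTruth) -> np.ndarray:
    """Length-weighted mean fractional copy number per sample."""
    F, _ = _segment_FG(truth)
    L = (truth.segments.END - truth.segments.START).to_numpy(dtype=float)
    return (L[:, None] * F).sum(axis=0) / L.sum()


def simulate_counts(truth: GroundTruth, cfg: SimConfig | None = None):
    """Draw the SNP table and the depth table for all samples + matched normal.

    Returns (snp_df, depth_df) in the TSV dialects the pipeline consumes:
    SNP table CHROM POS PHASE_SET REF_PHASE ALT_<s> TOT_<s>; depth table
    CHROM POS D_<s>; sample names are "normal", "tumor1", "tumor2", ...
    """
    cfg = cfg or truth.config
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 23]))
    P = cfg.n_samples
    samples = ["normal"] + [f"tumor{i+1}" for i in range(P)]
    lam = genome_lambda(truth)
    F_seg, G_seg = _segment_FG(truth)

    snp_rows = []
    depth_rows = []
    ps_counter = 0
    offsets = cfg.arm_offsets()
    for chrom, arm, length in cfg.arms:
        key = cfg.arm_key(chrom, arm)
        pos = truth.snp_pos[key]
        on_b = truth.snp_on_b[key]
        seg = truth.segments[(truth.segments.CHROM == chrom)
                             & (truth.segments.ARM == arm)]
        seg_start = seg.START.to_numpy()
        seg_idx_global = seg.index.to_numpy()
        which = np.searchsorted(seg_start, pos - 1, side="right") - 1
        gidx = seg_idx_global[which]
        F = F_seg[gidx]  # (n_snp, P)
        G = G_seg[gidx]

        n = len(pos)
        alt = np.zeros((n, P + 1), dtype=np.int64)
        tot = np.zeros((n, P + 1), dtype=np.int64)
        tot[:, 0] = _draw_counts(rng, np.full(n, cfg.snp_coverage),
                                 cfg.overdispersion)
        alt[:, 0] = rng.binomial(tot[:, 0], 0.5)
        for p in range(P):
            mean_t = cfg.snp_coverage * F[:, p] / lam[p]
            tot[:, p + 1] = _draw_counts(rng, mean_t, cfg.overdispersion)
            with np.errstate(invalid="ignore", divide="ignore"):
                q_b = np.where(F[:, p] > 0, G[:, p] / np.maximum(F[:, p], 1e-300), 0.5)
            q = np.where(on_b, q_b, 1 - q_b)
            alt[:, p + 1] = rng.binomial(tot[:, p + 1], q)

        # phase sets and reference phasing with switch errors
        ps_ids = np.empty(n, dtype=np.int64)
        ref_phase = np.empty(n, dtype=np.int64)
        i = 0
        while i < n:
            ps_len = rng.exponential(cfg.phase_set_mean_length)
            j = i
            while j < n and pos[j] - pos[i] <= ps_len:
                j += 1
            ps_counter += 1
            ps_ids[i:j] = ps_counter
            # haplotype "1" tracks the B haplotype up to switch errors
            state = 0
            for k in range(i, j):
                if k > i and rng.random() < cfg.switch_error_rate:
                    state ^= 1
                true_h = 1 if on_b[k] else 0
                ref_phase[k] = true_h ^ state
            i = j
        for k in range(n):
            snp_rows.append((chrom, arm, int(pos[k]), int(ps_ids[k]),
                             int(ref_phase[k]), *alt[k], *tot[k]))

        grid = offsets[key] + np.arange(0, length, cfg.depth_grid)
        gwhich = np.searchsorted(seg_start, grid, side="right") - 1
        gF = F_seg[seg_idx_global[gwhich]]
        base = cfg.reads_per_kb * cfg.depth_grid / 1000.0
        d = np.zeros((len(grid), P + 1), dtype=np.int64)
        d[:, 0] = _draw_counts(rng, np.full(len(grid), base),
                               cfg.overdispersion)
        for p in range(P):
            d[:, p + 1] = _draw_counts(rng, base * gF[:, p] / lam[p],
                                       cfg.overdispersion)
        for g in range(len(grid)):
            depth_rows.append((chrom, arm, int(grid[g]), *d[g]))

    snp_df = pd.DataFrame(
        snp_rows,
        columns=["CHROM", "ARM", "POS", "PHASE_SET", "REF_PHASE"]
        + [f"ALT_{s}" for s in samples] + [f"TOT_{s}" for s in samples],
    )
    # column order: interleave per-sample ALT/TOT pairs is not required; keep blocks
    depth_df = pd.DataFrame(
        depth_rows, columns=["CHROM", "ARM", "POS"] + [f"D_{s}" for s in samples]
    )
    return snp_df, depth_df


def run_simulation(cfg: SimConfig):
    """Convenience: (snp_df, depth_df, truth, arm_table)."""
    truth = simulate_genome(cfg)
    snp_df, depth_df = simulate_counts(truth, cfg)
    arm_table = arm_table_from_config(cfg)
    return snp_df, depth_df, truth, arm_table


def arm_table_from_config(cfg: SimConfig) -> pd.DataFrame:
    offsets = cfg.arm_offsets()
    rows = []
    for chrom, arm, length in cfg.arms:
        off = offsets[cfg.arm_key(chrom, arm)]
        rows.append((chrom, off, off + length, arm))
    return pd.DataFrame(rows, columns=["CHROM", "START", "END", "ARM"])


def mirrored_scenario(seed: int, u=None) -> SimConfig:
    """Two-sample, two-clone study with a (2,1)/(1,2) mirrored-subclonal CNA.

    The mirrored pair sits on chr1q; each clone additionally carries two
    private events (a one-copy loss and a one-copy gain) so that the clone
    proportions are identifiable from the cluster pattern -- a clone with no
    private event cannot be separated from its sibling by any method.  Clone
    proportions default to (0.5, 0.3) and (0.25, 0.55) with 20% normal
    contamination, so both clones exceed 20% in at least one sample and their
    proportions differ between samples.  Coverage gives bins of >= 2000
    SNP-covering reads per sample.
    """
    arms = [("chr1", "p", 8_000_000), ("chr1", "q", 8_000_000),
            ("chr2", "p", 8_000_000), ("chr2", "q", 8_000_000)]
    events = [
        # mirrored-subclonal pair
        CNAEvent(clone=1, chrom="chr1", arm="q", start=0, end=4_000_000,
                 allele="A", delta=1),
        CNAEvent(clone=2, chrom="chr1", arm="q", start=0, end=4_000_000,
                 allele="B", delta=1),
        # clone-1 private events
        CNAEvent(clone=1, chrom="chr2", arm="p", start=0, end=3_500_000,
                 allele="B", delta=-1),
        CNAEvent(clone=1, chrom="chr1", arm="p", start=4_500_000,
                 end=8_000_000, allele="A", delta=1),
        # clone-2 private events
        CNAEvent(clone=2, chrom="chr2", arm="q", start=0, end=3_500_000,
                 allele="A", delta=1),
        CNAEvent(clone=2, chrom="chr2", arm="q", start=4_800_000,
                 end=8_000_000, allele="B", delta=-1),
    ]
    return SimConfig(
        seed=seed, arms=arms, snp_density=0.2, n_samples=2, n_clones=2,
        events=events,
        u=u if u is not None else [[0.2, 0.2], [0.5, 0.25], [0.3, 0.55]],
        snp_coverage=50.0, reads_per_kb=80.0)


def random_clone_mixture(seed: int, m_max: int = 3, c_max: int = 4,
                         max_segments: int = 12,
                         ensure_identifiable: bool = True):
    """Random tree-consistent clone mixture with noiseless observables.

    Draws the clone count, a clone tree (star or chain), one to two focal or
    larger events per clone, and Dirichlet clone proportions, subject to the
    factorization model's identifiability requirements: at least as many
    samples as clones, every clone above 10% somewhere, the diploid state
    weight-modal for every clone, and total copy number within ``c_max``.
    Returns (CloneMixture, RDR, mhBAF, segment weights); the observables are
    the exact forward-model values, for solver recovery benchmarks.
    """
    from .factorize import CloneMixture, expected_observables

    rng = np.random.default_rng(seed)
    while True:
        m = int(rng.integers(1, m_max + 1))
        P = int(rng.integers(max(m, 2) if m > 1 else 1, 4))
        arms = [("chr1", "p", 10_000_000), ("chr1", "q", 10_000_000),
                ("chr2", "p", 10_000_000)]
        # star tree with private events only: under a chain tree the trunk
        # events shared by nested clones admit an exactly equivalent
        # star-shaped re-decomposition with shifted proportions, so exact
        # profile recovery from bulk data would be ill-posed
        tree = [(0, i) for i in range(1, m + 1)]
        events = []
        for clone in range(1, m + 1):
            # every clone carries at least one loss: a clone with only gains
            # admits a halved-proportion / doubled-gain re-description, so
            # exact recovery would be ill-posed
            deltas = [-1, int(rng.choice([-1, 1, 1]))]
            for delta in deltas:
                chrom, arm, L = arms[rng.integers(len(arms))]
                width = int(rng.integers(1_500_000, 4_000_000))
                s0 = int(rng.integers(0, L - width))
                events.append(CNAEvent(
                    clone=clone, chrom=chrom, arm=arm, start=s0,
                    end=s0 + width,
                    allele="A" if rng.random() < 0.5 else "B",
                    delta=delta))
        u = rng.dirichlet(np.ones(m + 1) * 1.2, size=P).T
        # identifiability: every clone detectable, clone proportion columns
        # pairwise well separated (else distinct integer decompositions of
        # the same fractional copy numbers exist and exact recovery is not
        # a meaningful benchmark)
        if (u[1:].max(axis=1) < 0.15).any():
            continue
        rows = u[1:]
        sep = min((np.abs(rows[i] - rows[j]).max()
                   for i in range(len(rows)) for j in range(i + 1, len(rows))),
                  default=1.0)
        if sep < 0.15 or np.abs(rows - u[0]).max(axis=1).min() < 0.1:
            continue
        cfg = SimConfig(seed=int(rng.integers(2**31)), arms=arms, n_clones=m,
                        n_samples=P, clone_tree=tree, events=events,
                        u=u.tolist())
        try:
            truth = simulate_genome(cfg)
        except ValueError:
            continue
        seg = truth.segments
        if len(seg) > max_segments:
            continue
        a = seg[[f"A_{i}" for i in range(m + 1)]].to_numpy().T
        b = seg[[f"B_{i}" for i in range(m + 1)]].to_numpy().T
        if (a + b).max() > c_max:
            continue
        w = (seg.END - seg.START).to_numpy(dtype=float) / 1e6
        bad = False
        for i in range(1, m + 1):
            if w[(a[i] != 1) | (b[i] != 1)].sum() >= w.sum() / 2:
                bad = True
        if bad:
            continue
        mix = CloneMixture(cn_a=a, cn_b=b, u=u)
        R, B = expected_observables(mix, w)
        if ensure_identifiable:
            # certificate screen: if another exact decomposition exists the
            # instance is ill-posed for exact recovery and is redrawn
            from .factorize import profiles_match, solve_fixed

            ambiguous = False
            for probe in (0, 137):
                alt, obj = solve_fixed(m, R, B, weights=w, seed=probe,
                                       n_restarts=14, n_kicks=10,
                                       state_penalty=1e-6)
                if obj < 1e-10 and not profiles_match(mix, alt):
                    ambiguous = True
                    break
            if ambiguous:
                continue
        return mix, R, B, w


def focal_scenario(seed: int, purity: float = 0.25) -> SimConfig:
    """Single long neutral arm with one focal single-copy gain, one clone.

    The focal event spans ~10 bins at the default binning floors; the rest of
    the arm is copy-neutral, so per-bin features of the two states overlap in
    the marginal distribution while the event forms one contiguous run --
    the regime where transition information should pay off over a purely
    global mixture.
    """
    arm_len = 40_000_000
    events = [CNAEvent(clone=1, chrom="chr1", arm="q", start=18_000_000,
                       end=21_300_000, allele="A", delta=1)]
    return SimConfig(
        seed=seed, arms=[("chr1", "q", arm_len)], snp_density=0.2,
        n_samples=1, n_clones=1, events=events,
        u=[[1.0 - purity], [purity]],
        snp_coverage=12.0, reads_per_kb=60.0, overdispersion=0.004)


def write_fixture(snp_df: pd.DataFrame, depth_df: pd.DataFrame,
                  truth: GroundTruth, out_dir: str, force: bool = False) -> None:
    """Write the TSV fixture bundle; byte-identical across runs at fixed seed."""
    if os.path.isdir(out_dir) and os.listdir(out_dir) and not force:
        raise FileExistsError(f"{out_dir} exists and is not empty (use force)")
    os.makedirs(out_dir, exist_ok=True)
    os.makedirs(os.path.join(out_dir, "truth"), exist_ok=True)
    snp_df.to_csv(os.path.join(out_dir, "snps.tsv"), sep="\t", index=False)
    depth_df.to_csv(os.path.join(out_dir, "depths.tsv"), sep="\t", index=False)
    arm_table_from_config(truth.config).to_csv(
        os.path.join(out_dir, "arms.bed"), sep="\t", index=False, header=False,
        columns=["CHROM", "START", "END", "ARM"])
    truth.segments.to_csv(os.path.join(out_dir, "truth", "segments.tsv"),
                          sep="\t", index=False)
    m = truth.u.shape[0] - 1
    pd.DataFrame(truth.u,
                 index=[f"clone{i}" if i else "normal" for i in range(m + 1)],
                 columns=[f"tumor{p+1}" for p in range(truth.u.shape[1])]
                 ).to_csv(os.path.join(out_dir, "truth", "proportions.tsv"),
                          sep="\t")
    phases = []
    for key in sorted(truth.snp_pos):
        chrom, arm = key.split(":")
        for p, hb in zip(truth.snp_pos[key], truth.snp_on_b[key]):
            phases.append((chrom, arm, int(p), int(hb)))
    pd.DataFrame(phases, columns=["CHROM", "ARM", "POS", "ALT_ON_B"]).to_csv(
        os.path.join(out_dir, "truth", "phases.tsv"), sep="\t", index=False)
    cfg = asdict(truth.config)
    cfg["events"] = [asdict(e) if not isinstance(e, dict) else e
                     for e in cfg.get("events", [])]
    with open(os.path.join(out_dir, "config.json"), "w") as fh:
        json.dump(cfg, fh, indent=1, sort_keys=True)
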