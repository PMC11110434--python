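"""Synthetic clone-mixture generator: truth construction and count laws."""

import numpy as np
import pytest

from hapclone.factorize import CloneMixture, expected_observables
from hapclone.simulate import (CNAEvent, SimConfig, genome_lambda,
                               mirrored_scenario, run_simulation,
                               simulate_counts, simulate_genome, write_fixture)


def base_config(seed=1, **kw):
    args = dict(seed=seed, arms=[("chr1", "p", 2_000_000)], snp_density=0.3,
                n_samples=1, n_clones=1, snp_coverage=30.0, reads_per_kb=40.0)
    args.update(kw)
    return SimConfig(**args)


class TestSimulateGenome:
    def test_no_events_all_diploid(self):
        truth = simulate_genome(base_config())
        seg = truth.segments
        assert len(seg) == 1
        assert (seg[["A_0", "A_1", "B_0", "B_1"]] == 1).all().all()
        assert not seg.MIRRORED.any()

    def test_wgd_doubles_tumor_baseline(self):
        truth = simulate_genome(base_config(wgd=True))
        seg = truth.segments.iloc[0]
        assert (seg.A_1, seg.B_1) == (2, 2)
        assert (seg.A_0, seg.B_0) == (1, 1)

    def test_mirrored_pair_flagged_exactly(self):
        events = [
            CNAEvent(1, "chr1", "p", 100_000, 900_000, "A", 1),
            CNAEvent(2, "chr1", "p", 100_000, 900_000, "B", 1),
        ]
        cfg = base_config(n_clones=2, n_samples=2, events=events)
        truth = simulate_genome(cfg)
        seg = truth.segments
        flagged = seg[seg.MIRRORED]
        assert len(flagged) == 1
        assert (flagged.START.iloc[0], flagged.END.iloc[0]) == (100_000, 900_000)

    def test_descendants_inherit_events(self):
        events = [CNAEvent(1, "chr1", "p", 0, 1_000_000, "A", 1)]
        cfg = base_config(n_clones=2, n_samples=2, events=events,
                          clone_tree=[(0, 1), (1, 2)])
        truth = simulate_genome(cfg)
        seg = truth.segments.iloc[0]
        assert seg.A_1 == 2 and seg.A_2 == 2  # clone 2 inherits from clone 1

    def test_overlapping_same_allele_events_rejected(self):
        events = [
            CNAEvent(1, "chr1", "p", 0, 1_000_000, "A", 1),
            CNAEvent(1, "chr1", "p", 500_000, 1_500_000, "A", 1),
        ]
        with pytest.raises(ValueError, match="overlap"):
            simulate_genome(base_config(events=events))

    def test_negative_copy_rejected(self):
        events = [CNAEvent(1, "chr1", "p", 0, 1_000_000, "A", -2)]
        with pytest.raises(ValueError, match="negative"):
            simulate_genome(base_config(events=events))


class TestSimulateCounts:
    def test_normal_sample_balanced_unit_rdr(self):
        cfg = base_config(seed=3, u=[[1.0], [0.0]])
        truth = simulate_genome(cfg)
        snp, depth = simulate_counts(truth, cfg)
        baf = snp.ALT_tumor1.sum() / snp.TOT_tumor1.sum()
        assert baf == pytest.approx(0.5, abs=0.01)
        rdr = depth.D_tumor1.sum() / depth.D_normal.sum()
        assert rdr == pytest.approx(1.0, abs=0.02)

    def test_clonal_loh_alt_fractions_extreme(self):
        events = [CNAEvent(1, "chr1", "p", 0, 2_000_000, "B", -1)]
        cfg = base_config(seed=4, events=events, u=[[0.0], [1.0]],
                          snp_coverage=60.0)
        truth = simulate_genome(cfg)
        snp, _ = simulate_counts(truth, cfg)
        frac = snp.ALT_tumor1 / snp.TOT_tumor1.clip(lower=1)
        assert ((frac < 0.05) | (frac > 0.95)).mean() > 0.95

    def test_expectation_matches_forward_model(self):
        """Empirical per-segment alt fraction and RDR converge to the
        expected observables at high coverage."""
        events = [
            CNAEvent(1, "chr1", "p", 0, 1_000_000, "A", 1),
            CNAEvent(2, "chr1", "p", 1_000_000, 2_000_000, "B", -1),
        ]
        cfg = base_config(seed=5, n_clones=2, n_samples=2, events=events,
                          u=[[0.2, 0.4], [0.5, 0.1], [0.3, 0.5]],
                          snp_coverage=400.0, reads_per_kb=400.0)
        truth = simulate_genome(cfg)
        snp, depth = simulate_counts(truth, cfg)
        m = 2
        seg = truth.segments
        a = seg[[f"A_{i}" for i in range(m + 1)]].to_numpy().T
        b = seg[[f"B_{i}" for i in range(m + 1)]].to_numpy().T
        mix = CloneMixture(cn_a=a, cn_b=b, u=truth.u)
        w = (seg.END - seg.START).to_numpy(dtype=float)
        er, eb = expected_observables(mix, w)
        for si, row in seg.iterrows():
            sel = (snp.POS - 1 >= row.START) & (snp.POS - 1 < row.END)
            dsel = (depth.POS >= row.START) & (depth.POS < row.END)
            for p, s in enumerate(["tumor1", "tumor2"]):
                # minor-haplotype fraction via the true phases
                key = f"{row.CHROM}:{row.ARM}"
                onb = dict(zip(truth.snp_pos[key], truth.snp_on_b[key]))
                sub = snp[sel]
                is_b = np.array([onb[p_] for p_ in sub.POS])
                x_b = np.where(is_b, sub[f"ALT_{s}"], sub[f"TOT_{s}"] - sub[f"ALT_{s}"])
                emp_b = x_b.sum() / sub[f"TOT_{s}"].sum()
                assert emp_b == pytest.approx(eb[si, p], abs=0.01)
                # raw tumor/normal depth ratio has expectation F / lambda,
                # which is exactly the forward model's expected RDR
                emp_r = depth[dsel][f"D_{s}"].sum() / depth[dsel].D_normal.sum()
                assert emp_r == pytest.approx(er[si, p], abs=0.02)

    def test_switch_error_calibration(self):
        cfg = base_config(seed=6, snp_density=1.0, switch_error_rate=0.05,
                          phase_set_mean_length=200_000.0)
        truth = simulate_genome(cfg)
        snp, _ = simulate_counts(truth, cfg)
        key = "chr1:p"
        true_h = truth.snp_on_b[key].astype(int)
        emitted = snp.REF_PHASE.to_numpy()
        same_ps = snp.PHASE_SET.to_numpy()[1:] == snp.PHASE_SET.to_numpy()[:-1]
        flips = (emitted ^ true_h)[1:] != (emitted ^ true_h)[:-1]
        rate = flips[same_ps].mean()
        n = same_ps.sum()
        assert rate == pytest.approx(0.05, abs=3 * np.sqrt(0.05 * 0.95 / n))


class TestWriteFixture:
    def test_deterministic_and_round_trips(self, tmp_path):
        import hashlib

        def checksums(outdir):
            out = {}
            for f in sorted(outdir.rglob("*")):
                if f.is_file():
                    out[f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
            return out

        cfg = mirrored_scenario(2)
        snp, depth, truth, _ = run_simulation(cfg)
        write_fixture(snp, depth, truth, tmp_path / "a")
        snp2, depth2, truth2, _ = run_simulation(mirrored_scenario(2))
        write_fixture(snp2, depth2, truth2, tmp_path / "b")
        assert checksums(tmp_path / "a") == checksums(tmp_path / "b")

        snp3, depth3, truth3, _ = run_simulation(mirrored_scenario(3))
        write_fixture(snp3, depth3, truth3, tmp_path / "c")
        assert checksums(tmp_path / "a") != checksums(tmp_path / "c")

        with pytest.raises(FileExistsError):
            write_fixture(snp, depth, truth, tmp_path / "a")

        # files parse back losslessly through the readers
        from hapclone import io as hio

        back = hio.read_snp_table(tmp_path / "a" / "snps.tsv")
        assert len(back) == len(snp)
        assert (back.POS.to_numpy() == snp.POS.to_numpy()).all()
        dback = hio.read_depth_table(tmp_path / "a" / "depths.tsv")
        assert (dback.D_normal.to_numpy() == depth.D_normal.to_numpy()).all()
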