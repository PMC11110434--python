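import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_snp_table(pos, phase_set, ref_phase, alt, tot, samples, chrom="chr1"):
    """Assemble a SNP table in the pipeline's dialect.

    ``alt``/``tot`` are (n_snps, n_samples) arrays; samples includes the
    matched normal first.
    """
    alt = np.atleast_2d(np.asarray(alt))
    tot = np.atleast_2d(np.asarray(tot))
    df = pd.DataFrame({"CHROM": chrom, "POS": pos, "PHASE_SET": phase_set,
                       "REF_PHASE": ref_phase})
    for j, s in enumerate(samples):
        df[f"ALT_{s}"] = alt[:, j]
        df[f"TOT_{s}"] = tot[:, j]
    return df


@pytest.fixture
def small_mirrored_run():
    """One small end-to-end simulation, shared across integration tests."""
    from hapclone.simulate import mirrored_scenario, run_simulation

    cfg = mirrored_scenario(4)
    snp, depth, truth, arm_table = run_simulation(cfg)
    return cfg, snp, depth, truth, arm_table
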