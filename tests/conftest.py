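import numpy as np
import pandas as pd
import pytest

from snprecall.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """Desk-scale dilution grid: 8 individuals x 6 inputs x 800 SNPs."""
    return SimConfig(n_snps=800, seed=11)


@pytest.fixture(scope="session")
def sim_data(small_cfg):
    """(records, truth, manifest) for the small simulated cohort."""
    return simulate_dataset(small_cfg)


@pytest.fixture()
def tiny_records() -> pd.DataFrame:
    """Six hand-written intensity records across two samples."""
    rows = [
        # sample, individual, ng, snp, chrom, pos, x, y, gencall, call
        ("s1", "i1", 50.0, "rs1", "1", 100, 1.0, 0.02, 0.90, "AA"),
        ("s1", "i1", 50.0, "rs2", "2", 200, 0.51, 0.49, 0.80, "AB"),
        ("s1", "i1", 50.0, "rs3", "X", 300, 0.02, 1.10, 0.95, "BB"),
        ("s2", "i2", 1.0, "rs1", "1", 100, 0.90, 0.05, 0.10, "AA"),
        ("s2", "i2", 1.0, "rs2", "2", 200, 0.05, 0.85, 0.70, "BB"),
        ("s2", "i2", 1.0, "rs4", "0", 400, 0.40, 0.40, 0.60, "AB"),
    ]
    df = pd.DataFrame(rows, columns=[
        "sample_id", "individual_id", "dna_input_ng", "snp_id", "chrom",
        "pos", "x", "y", "gencall", "gs_call"])
    df["r"] = df["x"] + df["y"]
    df["theta_norm"] = (2 / np.pi) * np.arctan2(df["y"], df["x"])
    df["gentrain"] = 0.8
    df["cluster_sep"] = 0.7
    df["allele_a"] = "A"
    df["allele_b"] = "C"
    return df
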