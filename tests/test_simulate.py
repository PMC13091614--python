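import numpy as np
import pandas as pd
import pytest
from scipy import stats

from snprecall.genotypes import NC
from snprecall.simulate import (DEFAULT_PEDIGREE, SimConfig, SimTruth,
                                simulate_dataset, simulate_genotypes,
                                simulate_intensities,
                                surrogate_platform_calls, write_fixture)

HALF_PI = np.pi / 2


class TestSimulateGenotypes:
    def test_founders_are_hwe(self):
        cfg = SimConfig(n_snps=100_000, seed=1,
                        pedigree=(("A", None, None),),
                        allele_freq_range=(0.5, 0.5))
        g = simulate_genotypes(cfg).genotypes["A"].to_numpy()
        freqs = np.bincount(g, minlength=3) / g.size
        assert np.allclose(freqs, [0.25, 0.5, 0.25], atol=0.01)

    def test_mendelian_consistency(self):
        cfg = SimConfig(n_snps=5000, seed=2)
        gt = simulate_genotypes(cfg).genotypes
        for child, mother, father in DEFAULT_PEDIGREE:
            if mother is None:
                continue
            for parent in (mother, father):
                # child never opposite-homozygous to a parent
                opp = ((gt[child] == 0) & (gt[parent] == 2)) | \
                      ((gt[child] == 2) & (gt[parent] == 0))
                assert not opp.any()

    def test_homozygous_parents_fix_offspring(self):
        cfg = SimConfig(n_snps=1000, seed=3,
                        pedigree=(("M", None, None), ("F", None, None),
                                  ("K", "M", "F")),
                        allele_freq_range=(0.0001, 0.0001))
        gt = simulate_genotypes(cfg).genotypes
        fixed = (gt["M"] == 0) & (gt["F"] == 0)
        assert fixed.sum() > 900
        assert (gt.loc[fixed, "K"] == 0).all()

    def test_cyclic_pedigree_rejected(self):
        cfg = SimConfig(pedigree=(("A", "B", "B"), ("B", "A", "A")))
        with pytest.raises(ValueError, match="cycle"):
            simulate_genotypes(cfg)

    def test_deterministic_under_seed(self):
        a = simulate_genotypes(SimConfig(n_snps=500, seed=9)).genotypes
        b = simulate_genotypes(SimConfig(n_snps=500, seed=9)).genotypes
        pd.testing.assert_frame_equal(a, b)


class TestSimulateIntensities:
    def test_noiseless_limit_recovers_cluster_centers(self):
        cfg = SimConfig(n_snps=500, seed=4, theta_sd_base=1e-6,
                        theta_sd_slope=0.0, dropout_pmax=0.0)
        truth = simulate_genotypes(cfg)
        rec = simulate_intensities(truth, 50.0, cfg)
        centers = np.clip(
            truth.genotypes.to_numpy().T.ravel() * np.pi / 4
            + np.tile(truth.snps["probe_offset"], len(truth.genotypes.columns)),
            0, HALF_PI)
        theta = rec["theta_norm"].to_numpy() * HALF_PI
        assert np.allclose(theta, centers, atol=1e-4)

    def test_degradation_directions(self, sim_data):
        """Mean r falls and theta residual spread grows as input falls."""
        records, truth, _ = sim_data
        offsets = truth.snps.set_index("snp_id")["probe_offset"]
        by_level_mean, by_level_resid = {}, {}
        for ng, sub in records.groupby("dna_input_ng"):
            keep = ~sub["dropout"]
            sub = sub.loc[keep]
            center = (sub["snp_id"].map(offsets).to_numpy()
                      + sub["true_genotype"].map({"AA": 0, "AB": np.pi / 4,
                                                  "BB": HALF_PI}).to_numpy())
            resid = sub["theta_norm"].to_numpy() * HALF_PI - np.clip(center, 0, HALF_PI)
            by_level_mean[ng] = sub["r"].mean()
            by_level_resid[ng] = resid.var()
        levels = sorted(by_level_mean)  # ascending DNA input
        means = [by_level_mean[l] for l in levels]
        resids = [by_level_resid[l] for l in levels]
        assert means == sorted(means)                  # r grows with input
        assert resids == sorted(resids, reverse=True)  # noise shrinks with input
        # sign match: input vs mean r positive, input vs theta variance negative
        assert stats.pearsonr(np.log(levels), means).statistic > 0
        assert stats.pearsonr(np.log(levels), resids).statistic < 0

    def test_dropout_only_hits_heterozygotes(self, sim_data):
        records, _, _ = sim_data
        assert (records.loc[records["dropout"], "true_genotype"] == "AB").all()

    def test_channel_split_consistent(self, sim_data):
        records, _, _ = sim_data
        sub = records.sample(2000, random_state=0)
        assert np.allclose(sub["x"] + sub["y"], sub["r"])
        theta = np.arctan2(sub["y"], sub["x"])
        assert np.allclose(theta, sub["theta_norm"] * HALF_PI, atol=1e-9)

    def test_unknown_level_rejected(self):
        cfg = SimConfig(n_snps=10, seed=0)
        truth = simulate_genotypes(cfg)
        with pytest.raises(ValueError, match="dilution"):
            simulate_intensities(truth, 2.0, cfg)


class TestSurrogateCaller:
    def test_noiseless_het_called_ab_with_high_score(self):
        cfg = SimConfig(n_snps=300, seed=5, theta_sd_base=1e-6,
                        theta_sd_slope=0.0, dropout_pmax=0.0,
                        probe_offset_sd=0.0)
        truth = simulate_genotypes(cfg)
        rec = surrogate_platform_calls(
            simulate_intensities(truth, 50.0, cfg), truth, cfg)
        het = rec.loc[rec["true_genotype"] == "AB"]
        assert (het["gs_call"] == "AB").all()
        assert (het["gencall"] > 0.9).all()

    def test_midpoint_record_scores_zero_and_nc(self, sim_data):
        records, truth, _ = sim_data
        cfg = SimConfig(n_snps=10, seed=0)
        rec = records.iloc[:1].copy()
        offset = truth.snps.set_index("snp_id").loc[rec["snp_id"].iloc[0],
                                                    "probe_offset"]
        rec["theta_norm"] = (np.pi / 8 + offset) / HALF_PI  # midway AA-AB
        rec["r"] = 2.0
        out = surrogate_platform_calls(rec, truth, cfg)
        assert out["gencall"].iloc[0] < 1e-9
        assert out["gs_call"].iloc[0] == NC

    def test_call_rate_declines_with_input(self, sim_data):
        records, _, _ = sim_data
        rate = records.groupby("dna_input_ng")["gs_call"].apply(
            lambda s: (s != NC).mean())
        assert rate.loc[0.01] < rate.loc[50.0]


class TestWriteFixture:
    def test_truth_rows_and_byte_determinism(self, tmp_path):
        cfg = SimConfig(n_snps=120, seed=21)
        records, truth, manifest = simulate_dataset(cfg)
        p1 = write_fixture(records, truth, manifest, tmp_path / "a")
        p2 = write_fixture(records, truth, manifest, tmp_path / "b")
        truth_df = pd.read_csv(p1["truth"], sep="\t")
        assert len(truth_df) == 120 * len(truth.genotypes.columns)
        for key in ("report", "manifest", "truth"):
            assert p1[key].read_bytes() == p2[key].read_bytes()

    def test_regenerated_fixture_is_byte_identical(self, tmp_path):
        for sub in ("a", "b"):
            cfg = SimConfig(n_snps=60, seed=8)
            records, truth, manifest = simulate_dataset(cfg)
            write_fixture(records, truth, manifest, tmp_path / sub)
        assert ((tmp_path / "a" / "final_report.tsv").read_bytes()
                == (tmp_path / "b" / "final_report.tsv").read_bytes())


def test_truth_long_format_roundtrip():
    cfg = SimConfig(n_snps=50, seed=6)
    truth = simulate_genotypes(cfg)
    long = truth.to_long()
    assert set(long.columns) == {"individual_id", "snp_id", "truth_genotype"}
    assert len(long) == 50 * len(truth.genotypes.columns)
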