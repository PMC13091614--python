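"""Synthetic two-channel array data with dilution-series degradation.

The generator produces everything the pipeline consumes, with the
statistical structure the method assumes:

* **pedigree genotypes** — founders drawn from Hardy-Weinberg equilibrium at
  per-SNP allele frequencies, offspring by uniform Mendelian transmission;
* **genotype-dependent intensity clusters** — cluster angles 0 (AA), pi/4
  (AB), pi/2 (BB) plus a small per-SNP probe offset; observed theta is
  truncated-normal around the cluster center, total intensity r is
  log-normal;
* **dilution-dependent degradation** — the mean of r declines log-linearly
  with DNA input while theta noise and the r dispersion grow, matching the
  observed signs (less DNA: less signal, more variability);
* **heterozygote dropout** — at low input a true AB record's signal collapses
  most of the way toward one homozygote cluster (fair coin) with reduced r,
  the dominant genotype-dependent error mode of degraded samples;
* **surrogate platform calls** — a stand-in scorer (synthetic, not the
  proprietary clustering algorithm): nearest-cluster call with a confidence
  score that decays with angular distance and low intensity, no-call below
  the conventional 0.15 threshold.

Everything is deterministic under ``SimConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .array_io import DEFAULT_COLUMN_MAP
from .genotypes import GENOTYPES, NC, decode_codes

_HALF_PI = np.pi / 2
_QUARTER_PI = np.pi / 4

#: 8 individuals: two founder pairs, three offspring, one half-sib — yielding
#: duplicate, first-degree, second-degree and unrelated comparisons.
DEFAULT_PEDIGREE: tuple[tuple[str, str | None, str | None], ...] = (
    ("F1", None, None), ("F2", None, None),
    ("F3", None, None), ("F4", None, None),
    ("C1", "F1", "F2"), ("C2", "F1", "F2"),
    ("C3", "F3", "F4"),
    ("H1", "F1", "F3"),  # half-sib of C1/C2 (via F1) and of C3 (via F3)
)


@dataclass
class SimConfig:
    n_snps: int = 20_000
    allele_freq_range: tuple[float, float] = (0.05, 0.95)
    pedigree: tuple = DEFAULT_PEDIGREE
    dilution_levels_ng: tuple = (50.0, 1.0, 0.5, 0.1, 0.05, 0.01)
    nc_score_threshold: float = 0.15
    seed: int = 0

    # intensity laws (units: r in normalized intensity, theta in radians)
    r_mean_50ng: float = 1.5          # median r at the 50 ng reference input
    r_decay_exp: float = 0.12         # median r scales as (ng/50)^exp
    r_sigma_base: float = 0.25        # log-sd of r at 50 ng
    r_sigma_slope: float = 0.05       # log-sd growth per decade below 50 ng
    sample_effect_sd: float = 0.05    # per-sample log-normal intensity effect
    theta_sd_base: float = 0.035      # theta noise (rad) at 50 ng
    theta_sd_slope: float = 0.055     # theta noise growth per decade below 50 ng
    probe_offset_sd: float = 0.02     # per-SNP cluster-angle offset (rad)

    # heterozygote dropout: p(ng) = pmax / (1 + (ng / k)^s)
    dropout_pmax: float = 0.75
    dropout_half_ng: float = 0.03
    dropout_shape: float = 0.8
    dropout_shift_range: tuple[float, float] = (0.4, 1.0)
    dropout_r_range: tuple[float, float] = (0.45, 0.7)

    def __post_init__(self) -> None:
        levels = tuple(self.dilution_levels_ng)
        if len(set(levels)) != len(levels) or any(l <= 0 for l in levels):
            raise ValueError("dilution levels must be positive and distinct")
        if not 0 <= self.nc_score_threshold <= 1:
            raise ValueError("nc_score_threshold must be in [0,1]")

    # --- degradation laws -------------------------------------------------
    def r_log_mean(self, ng: float) -> float:
        return float(np.log(self.r_mean_50ng)
                     + self.r_decay_exp * np.log(ng / 50.0))

    def r_log_sd(self, ng: float) -> float:
        return self.r_sigma_base + self.r_sigma_slope * max(0.0, np.log10(50.0 / ng))

    def theta_sd(self, ng: float) -> float:
        return self.theta_sd_base + self.theta_sd_slope * max(0.0, np.log10(50.0 / ng))

    def het_dropout(self, ng: float) -> float:
        return self.dropout_pmax / (1.0 + (ng / self.dropout_half_ng) ** self.dropout_shape)


@dataclass
class SimTruth:
    """Ground truth of a simulated cohort: SNP table and genotype codes."""

    snps: pd.DataFrame          # snp_id, chrom, pos, alleles, freq_b, probe stats
    genotypes: pd.DataFrame     # rows = snp_id, columns = individual_id, codes 0/1/2

    def to_long(self) -> pd.DataFrame:
        """Long-format (individual_id, snp_id, truth_genotype) label table."""
        long = (self.genotypes.reset_index()
                .melt(id_vars="snp_id", var_name="individual_id",
                      value_name="code"))
        long["truth_genotype"] = decode_codes(long["code"].to_numpy())
        return long[["individual_id", "snp_id", "truth_genotype"]]


def _pedigree_order(pedigree) -> list[tuple[str, str | None, str | None]]:
    """Topological order of the pedigree; raises on cycles/unknown parents."""
    entries = {ind: (m, f) for ind, m, f in pedigree}
    order, state = [], {}

    def visit(ind: str) -> None:
        if state.get(ind) == 1:
            raise ValueError(f"pedigree cycle involving {ind!r}")
        if state.get(ind) == 2:
            return
        state[ind] = 1
        for parent in entries[ind]:
            if parent is not None:
                if parent not in entries:
                    raise ValueError(f"unknown parent {parent!r} of {ind!r}")
                visit(parent)
        state[ind] = 2
        order.append(ind)

    for ind in entries:
        visit(ind)
    return [(ind, *entries[ind]) for ind in order]


_BASES = np.array(list("ACGT"))


def simulate_genotypes(cfg: SimConfig, rng: np.random.Generator | None = None
                       ) -> SimTruth:
    """Draw SNP metadata and pedigree-structured genotypes.

    Founders are HWE draws at each SNP's B-allele frequency (uniform over
    ``cfg.allele_freq_range``); non-founders receive one allele from each
    parent, chosen uniformly.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    n = cfg.n_snps
    lo, hi = cfg.allele_freq_range
    freq_b = rng.uniform(lo, hi, size=n)
    offsets = rng.normal(0.0, cfg.probe_offset_sd, size=n)
    gentrain = np.clip(0.95 - 1.5 * np.abs(offsets) + rng.normal(0, 0.03, n), 0, 1)
    cluster_sep = np.clip(0.85 - 2.0 * np.abs(offsets) + rng.normal(0, 0.05, n), 0, 1)
    ref_idx = rng.integers(0, 4, size=n)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4
    snps = pd.DataFrame({
        "snp_id": [f"snp{i:06d}" for i in range(n)],
        "chrom": [str(i % 22 + 1) for i in range(n)],
        "pos": np.arange(1, n + 1) * 1000,
        "allele_a": _BASES[ref_idx],
        "allele_b": _BASES[alt_idx],
        "freq_b": freq_b,
        "probe_offset": offsets,
        "gentrain": gentrain,
        "cluster_sep": cluster_sep,
    })

    geno: dict[str, np.ndarray] = {}
    for ind, mother, father in _pedigree_order(cfg.pedigree):
        if mother is None and father is None:
            geno[ind] = rng.binomial(2, freq_b).astype(np.int8)
        elif mother is not None and father is not None:
            a_m = rng.random(n) < geno[mother] / 2.0
            a_f = rng.random(n) < geno[father] / 2.0
            geno[ind] = (a_m.astype(np.int8) + a_f.astype(np.int8))
        else:
            raise ValueError(f"individual {ind!r} must have zero or two parents")

    order = [ind for ind, _, _ in cfg.pedigree]
    gt = pd.DataFrame(geno, index=snps["snp_id"])[order]
    return SimTruth(snps=snps, genotypes=gt)


def _truncnorm_theta(centers: np.ndarray, sd: float,
                     rng: np.random.Generator) -> np.ndarray:
    a = (0.0 - centers) / sd
    b = (_HALF_PI - centers) / sd
    return stats.truncnorm.rvs(a, b, loc=centers, scale=sd, random_state=rng)


def simulate_intensities(truth: SimTruth, input_ng: float, cfg: SimConfig,
                         rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Intensity records for every individual at one dilution level.

    Returns canonical record columns plus the bookkeeping columns
    ``true_genotype`` and ``dropout`` (dropout implies true AB).
    Platform-call columns are filled by :func:`surrogate_platform_calls`.
    """
    levels = tuple(cfg.dilution_levels_ng)
    if input_ng not in levels:
        raise ValueError(f"unknown dilution level {input_ng}; configured {levels}")
    if rng is None:
        rng = np.random.default_rng([cfg.seed, 1 + levels.index(input_ng)])

    n = cfg.n_snps
    theta_sd = cfg.theta_sd(input_ng)
    mu_r, sd_r = cfg.r_log_mean(input_ng), cfg.r_log_sd(input_ng)
    p_drop = cfg.het_dropout(input_ng)
    offsets = truth.snps["probe_offset"].to_numpy()

    frames = []
    for ind in truth.genotypes.columns:
        g = truth.genotypes[ind].to_numpy()
        centers = np.clip(g * _QUARTER_PI + offsets, 0.0, _HALF_PI)

        dropout = (g == 1) & (rng.random(n) < p_drop)
        n_drop = int(dropout.sum())
        if n_drop:
            lo, hi = cfg.dropout_shift_range
            delta = rng.uniform(lo, hi, n_drop) * _QUARTER_PI
            toward_bb = rng.random(n_drop) < 0.5
            collapsed = np.where(toward_bb, _QUARTER_PI + delta, _QUARTER_PI - delta)
            centers = centers.copy()
            centers[dropout] = np.clip(collapsed + offsets[dropout], 0.0, _HALF_PI)

        theta = _truncnorm_theta(centers, theta_sd, rng)
        sample_effect = rng.normal(0.0, cfg.sample_effect_sd)
        r = rng.lognormal(mu_r + sample_effect, sd_r, size=n)
        if n_drop:
            rlo, rhi = cfg.dropout_r_range
            r[dropout] *= rng.uniform(rlo, rhi, n_drop)

        denom = np.cos(theta) + np.sin(theta)
        x = r * np.cos(theta) / denom
        y = r - x
        frames.append(pd.DataFrame({
            "sample_id": f"{ind}_{input_ng:g}ng",
            "individual_id": ind,
            "dna_input_ng": input_ng,
            "snp_id": truth.snps["snp_id"].to_numpy(),
            "chrom": truth.snps["chrom"].to_numpy(),
            "pos": truth.snps["pos"].to_numpy(),
            "allele_a": truth.snps["allele_a"].to_numpy(),
            "allele_b": truth.snps["allele_b"].to_numpy(),
            "x": x, "y": y, "r": r,
            "theta_norm": theta / _HALF_PI,
            "true_genotype": decode_codes(g),
            "dropout": dropout,
        }))
    return pd.concat(frames, ignore_index=True)


def surrogate_platform_calls(records: pd.DataFrame, truth: SimTruth,
                             cfg: SimConfig) -> pd.DataFrame:
    """Fill gs_call/gencall/gentrain/cluster_sep with the surrogate scorer.

    The call is the nearest cluster center in theta; the score decays
    linearly with angular distance (zero midway between adjacent centers,
    i.e. at pi/8) and is damped for weak total intensity; scores below
    ``cfg.nc_score_threshold`` become no-calls.  Per-SNP gentrain and
    cluster-separation scores come from the SNP table (anti-correlated with
    probe offset magnitude).
    """
    out = records.copy()
    snp_info = truth.snps.set_index("snp_id")
    offsets = snp_info["probe_offset"].reindex(out["snp_id"]).to_numpy()
    theta = out["theta_norm"].to_numpy() * _HALF_PI
    centers = np.clip(
        np.array([0.0, _QUARTER_PI, _HALF_PI])[None, :] + offsets[:, None],
        0.0, _HALF_PI)
    dist = np.abs(theta[:, None] - centers)
    nearest = dist.argmin(axis=1)
    d = dist[np.arange(len(out)), nearest]

    intensity_factor = np.clip(out["r"].to_numpy() / 0.6, 0.0, 1.0) ** 0.5
    gencall = np.clip(1.0 - d / (np.pi / 8), 0.0, 1.0) * intensity_factor
    call = np.array(GENOTYPES, dtype=object)[nearest]
    call[gencall < cfg.nc_score_threshold] = NC

    out["gs_call"] = call
    out["gencall"] = gencall
    out["gentrain"] = snp_info["gentrain"].reindex(out["snp_id"]).to_numpy()
    out["cluster_sep"] = snp_info["cluster_sep"].reindex(out["snp_id"]).to_numpy()
    return out


def simulate_dataset(cfg: SimConfig) -> tuple[pd.DataFrame, SimTruth, pd.DataFrame]:
    """Full dilution grid: (records, truth, manifest), deterministic under seed.

    The manifest designates each individual's highest-input run as the
    ground-truth run.
    """
    truth = simulate_genotypes(cfg)
    frames = []
    for level in cfg.dilution_levels_ng:
        rec = simulate_intensities(truth, level, cfg)
        frames.append(surrogate_platform_calls(rec, truth, cfg))
    records = pd.concat(frames, ignore_index=True)
    top = max(cfg.dilution_levels_ng)
    manifest = (records[["sample_id", "individual_id", "dna_input_ng"]]
                .drop_duplicates().reset_index(drop=True))
    manifest["is_truth"] = manifest["dna_input_ng"] == top
    return records, truth, manifest


# ---------------------------------------------------------------------------
# fixture writing

_REPORT_FLOAT_COLS = ("x", "y", "r", "theta_norm", "gencall", "gentrain",
                      "cluster_sep")


def write_fixture(records: pd.DataFrame, truth: SimTruth, manifest: pd.DataFrame,
                  outdir: str | Path) -> dict[str, Path]:
    """Write a final-report TSV + manifest CSV + truth TSV fixture directory.

    Floats are written with 6 decimals, so reading the fixture back
    reproduces every field exactly for the rounded values.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = outdir / "final_report.tsv"
    manifest_path = outdir / "manifest.csv"
    truth_path = outdir / "truth_genotypes.tsv"

    cols = {v: records[k] for k, v in DEFAULT_COLUMN_MAP.items()
            if k in records.columns}
    df = pd.DataFrame(cols)
    for k, v in DEFAULT_COLUMN_MAP.items():
        if k in _REPORT_FLOAT_COLS and v in df.columns:
            df[v] = df[v].map(lambda f: f"{f:.6f}")
    df.to_csv(report, sep="\t", index=False)

    manifest.to_csv(manifest_path, index=False)

    long_truth = (truth.genotypes.reset_index()
                  .melt(id_vars="snp_id", var_name="individual_id",
                        value_name="code"))
    long_truth["genotype"] = decode_codes(long_truth["code"].to_numpy())
    long_truth[["individual_id", "snp_id", "genotype"]].to_csv(
        truth_path, sep="\t", index=False)
    return {"report": report, "manifest": manifest_path, "truth": truth_path}
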