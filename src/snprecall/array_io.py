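"""Reading GenomeStudio-style final-report tables and writing calls as VCF.

A *final report* here is a plain tab-separated table with one row per
sample x SNP and a single header line.  Column names follow the
GenomeStudio export dialect by default but are remappable via
``column_map`` (internal name -> file column name).

Records are held as a :class:`pandas.DataFrame` with the canonical columns
in :data:`RECORD_COLUMNS`; intensities are the two-channel summaries
(x, y, r = x + y, theta_norm in [0, 1] per the Illumina convention
theta_norm = (2/pi) * atan2(y, x)).
"""

from __future__ import annotations

import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import CALLS, GENOTYPE_CODE, NC

log = logging.getLogger(__name__)

#: canonical internal column order for intensity records
RECORD_COLUMNS = [
    "sample_id", "individual_id", "dna_input_ng", "snp_id", "chrom", "pos",
    "allele_a", "allele_b", "x", "y", "r", "theta_norm",
    "gencall", "gentrain", "cluster_sep", "gs_call",
]

#: default final-report header names (GenomeStudio dialect)
DEFAULT_COLUMN_MAP = {
    "sample_id": "Sample ID",
    "snp_id": "SNP Name",
    "chrom": "Chr",
    "pos": "Position",
    "allele_a": "Allele A",
    "allele_b": "Allele B",
    "x": "X",
    "y": "Y",
    "r": "R",
    "theta_norm": "Theta",
    "gencall": "GC Score",
    "gentrain": "GT Score",
    "cluster_sep": "Cluster Sep",
    "gs_call": "GType",
}

# columns that must exist in the file; R is recomputed from X+Y when absent,
# X/Y are tolerated missing when R and Theta are present
_MANDATORY = ["sample_id", "snp_id", "chrom", "pos", "theta_norm",
              "gencall", "gentrain", "cluster_sep", "gs_call"]
_NUMERIC = ["pos", "x", "y", "r", "theta_norm", "gencall", "gentrain", "cluster_sep"]


class FinalReportError(ValueError):
    """Malformed final report or manifest."""


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read the sample manifest CSV (sample_id, individual_id, dna_input_ng, is_truth)."""
    mf = pd.read_csv(path, dtype={"sample_id": str, "individual_id": str})
    required = {"sample_id", "individual_id", "dna_input_ng", "is_truth"}
    missing = required - set(mf.columns)
    if missing:
        raise FinalReportError(f"manifest missing columns: {sorted(missing)}")
    mf["is_truth"] = mf["is_truth"].astype(bool)
    validate_manifest(mf)
    return mf


def validate_manifest(manifest: pd.DataFrame) -> None:
    if (manifest["dna_input_ng"] <= 0).any():
        bad = manifest.loc[manifest["dna_input_ng"] <= 0, "sample_id"].tolist()
        raise FinalReportError(f"non-positive dna_input_ng for samples {bad}")
    truth_counts = manifest.loc[manifest["is_truth"]].groupby("individual_id").size()
    multi = truth_counts[truth_counts > 1]
    if len(multi):
        raise FinalReportError(
            f"more than one truth run for individuals {multi.index.tolist()}")
    if manifest["sample_id"].duplicated().any():
        dups = manifest.loc[manifest["sample_id"].duplicated(), "sample_id"].tolist()
        raise FinalReportError(f"duplicate sample_id in manifest: {dups}")


def read_final_report(
    path: str | Path,
    manifest: pd.DataFrame,
    column_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Parse a final-report table into canonical intensity records.

    Rows with unparseable numeric fields are dropped and counted
    (``result.attrs["n_dropped_unparseable"]`` and the log).  A missing R
    column is recomputed as x + y; missing X/Y columns are tolerated when
    R and Theta are present (x, y left NaN).

    Raises
    ------
    FinalReportError
        if a mandatory column is absent, or a sample_id is not in the manifest.
    """
    colmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        colmap.update(column_map)

    df = pd.read_csv(path, sep="\t", dtype=str)
    present = {k: v for k, v in colmap.items() if v in df.columns}
    for key in _MANDATORY:
        if key not in present:
            raise FinalReportError(
                f"final report is missing mandatory column {colmap[key]!r} ({key})")
    have_xy = "x" in present and "y" in present
    if not have_xy and "r" not in present:
        raise FinalReportError(
            "final report must provide X and Y, or R (with Theta)")

    rec = pd.DataFrame({k: df[v] for k, v in present.items()})
    for k in ("allele_a", "allele_b"):
        if k not in rec.columns:
            rec[k] = "A" if k == "allele_a" else "B"

    n_in = len(rec)
    for k in _NUMERIC:
        if k in rec.columns:
            rec[k] = pd.to_numeric(rec[k], errors="coerce")
    required_numeric = [k for k in _NUMERIC if k in rec.columns and k not in ("x", "y", "r")]
    if have_xy:
        required_numeric += ["x", "y"]
    elif "r" in rec.columns:
        required_numeric += ["r"]
    ok = rec[required_numeric].notna().all(axis=1)
    n_dropped = int((~ok).sum())
    if n_dropped:
        log.warning("dropped %d final-report rows with unparseable numeric fields", n_dropped)
    rec = rec.loc[ok].copy()

    if "r" not in rec.columns:
        rec["r"] = rec["x"] + rec["y"]
    else:
        rec["r"] = rec["r"].fillna(rec.get("x", np.nan) + rec.get("y", np.nan))
    for k in ("x", "y"):
        if k not in rec.columns:
            rec[k] = np.nan

    rec["pos"] = rec["pos"].astype(np.int64)
    rec["gs_call"] = rec["gs_call"].replace({"--": NC})
    bad_calls = ~rec["gs_call"].isin(CALLS)
    if bad_calls.any():
        raise FinalReportError(
            f"unrecognized genotype calls: {sorted(rec.loc[bad_calls, 'gs_call'].unique())}")

    unknown = sorted(set(rec["sample_id"]) - set(manifest["sample_id"]))
    if unknown:
        raise FinalReportError(f"sample IDs absent from manifest: {unknown}")
    rec = rec.merge(
        manifest[["sample_id", "individual_id", "dna_input_ng"]],
        on="sample_id", how="left")

    rec = rec[RECORD_COLUMNS].reset_index(drop=True)
    rec.attrs["n_input_rows"] = n_in
    rec.attrs["n_dropped_unparseable"] = n_dropped
    return rec


# ---------------------------------------------------------------------------
# VCF writing

_PL_FLOOR = 1e-99  # probability floor before Phred scaling
GQ_CAP = 99

_GT_FIELD = {"AA": "0/0", "AB": "0/1", "BB": "1/1"}


def _pl_from_probs(p: np.ndarray) -> np.ndarray:
    pl = -10.0 * np.log10(np.maximum(p, _PL_FLOOR))
    pl = pl - pl.min()
    return np.rint(pl).astype(int)


def _chrom_sort_key(chrom: str):
    c = str(chrom)
    return (0, int(c), "") if c.isdigit() else (1, 0, c)


def write_vcf(calls: pd.DataFrame, sites: pd.DataFrame, path: str | Path,
              source: str = "snprecall") -> None:
    """Write probabilistic genotype calls as a multi-sample VCF 4.2.

    Parameters
    ----------
    calls
        One row per sample x site: sample_id, snp_id, call (AA/AB/BB/NC),
        p_aa, p_ab, p_bb, q (Phred genotype quality).  NC or filtered calls
        are emitted as ``./.`` with GQ/PL missing.
    sites
        Site metadata: snp_id, chrom, pos, allele_a, allele_b.  REF is the
        A allele, ALT the B allele.
    """
    site_idx = sites.set_index("snp_id")
    unknown = sorted(set(calls["snp_id"]) - set(site_idx.index))
    if unknown:
        raise FinalReportError(f"calls reference unknown sites: {unknown[:10]}")

    samples = sorted(calls["sample_id"].unique())
    by_key: dict[tuple[str, str], str] = {}
    for row in calls.itertuples(index=False):
        if row.call in _GT_FIELD:
            probs = np.array([row.p_aa, row.p_ab, row.p_bb], dtype=float)
            pl = _pl_from_probs(probs)
            gq = int(min(GQ_CAP, math.floor(row.q))) if np.isfinite(row.q) else GQ_CAP
            field = f"{_GT_FIELD[row.call]}:{gq}:{pl[0]},{pl[1]},{pl[2]}"
        else:
            field = "./.:.:."
        by_key[(row.snp_id, row.sample_id)] = field

    used = site_idx.loc[sorted(set(calls["snp_id"]))].reset_index()
    used = used.sort_values(
        by=["chrom", "pos"],
        key=lambda s: s.map(_chrom_sort_key) if s.name == "chrom" else s,
        kind="mergesort",
    )

    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source={source}\n")
        for chrom in dict.fromkeys(used["chrom"].astype(str)):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,'
                 'Description="Phred-scaled genotype quality">\n')
        fh.write('##FORMAT=<ID=PL,Number=G,Type=Integer,'
                 'Description="Phred-scaled genotype likelihoods (AA,AB,BB)">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for row in used.itertuples(index=False):
            fields = [by_key.get((row.snp_id, s), "./.:.:.") for s in samples]
            fh.write(f"{row.chrom}\t{row.pos}\t{row.snp_id}\t{row.allele_a}\t"
                     f"{row.allele_b}\t.\t.\t.\tGT:GQ:PL\t" + "\t".join(fields) + "\n")
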