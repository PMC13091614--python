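"""Record-level quality control applied before feature engineering.

Filters, in fixed order:

1. drop non-autosomal markers (chromosomes X, Y, MT and the indeterminate "0");
2. drop markers with invalid identifiers (empty, ".", or containing a dash);
3. within each sample, drop *all* copies of any duplicated SNP name;
4. mark calls below the GenCall threshold (default 0.15) as no-calls —
   or drop the records outright in strict mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .genotypes import NC

NON_AUTOSOMAL = frozenset({"X", "Y", "MT", "0"})


@dataclass
class QcConfig:
    autosomes_only: bool = True
    drop_invalid_ids: bool = True
    dedupe_snp_names: bool = True
    gencall_min: float = 0.15
    #: strict mode deletes sub-threshold records instead of NC-converting them
    drop_low_gencall: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.gencall_min <= 1.0:
            raise ValueError(f"gencall_min must be in [0,1], got {self.gencall_min}")


def qc_filter(records: pd.DataFrame, cfg: QcConfig | None = None
              ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply record-level QC; returns (kept records, per-rule removal counts).

    The GenCall rule converts calls to NC by default (counted under
    ``low_gencall_nc``) so that the recaller can still be evaluated at sites
    the platform declined; with ``cfg.drop_low_gencall`` records are removed
    (counted under ``low_gencall_removed``).
    """
    cfg = cfg or QcConfig()
    report = {"non_autosomal": 0, "invalid_snp_id": 0, "duplicate_snp_id": 0,
              "low_gencall_nc": 0, "low_gencall_removed": 0}
    out = records

    if cfg.autosomes_only:
        keep = ~out["chrom"].astype(str).isin(NON_AUTOSOMAL)
        report["non_autosomal"] = int((~keep).sum())
        out = out.loc[keep]

    if cfg.drop_invalid_ids:
        ids = out["snp_id"].astype(str)
        keep = ~(ids.eq("") | ids.eq(".") | ids.str.contains("-", regex=False)
                 | out["snp_id"].isna())
        report["invalid_snp_id"] = int((~keep).sum())
        out = out.loc[keep]

    if cfg.dedupe_snp_names:
        dup = out.duplicated(subset=["sample_id", "snp_id"], keep=False)
        report["duplicate_snp_id"] = int(dup.sum())
        out = out.loc[~dup]

    out = out.copy()
    low = (out["gencall"] < cfg.gencall_min) & (out["gs_call"] != NC)
    if cfg.drop_low_gencall:
        report["low_gencall_removed"] = int(low.sum())
        out = out.loc[~low].copy()
    else:
        report["low_gencall_nc"] = int(low.sum())
        out.loc[low, "gs_call"] = NC

    return out.reset_index(drop=True), report
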