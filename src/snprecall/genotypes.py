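"""Genotype call conventions shared across the package.

Biallelic array sites carry two probe-targeted alleles, A and B.  Calls are
the three diploid genotypes plus the platform no-call sentinel.  Numeric
codes count copies of the B allele; ``MISSING_CODE`` stands for NC/filtered.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Fixed class order used everywhere (argmax tie-breaks, VCF GT, confusion axes).
GENOTYPES: tuple[str, str, str] = ("AA", "AB", "BB")
NC = "NC"
CALLS = GENOTYPES + (NC,)

GENOTYPE_CODE = {"AA": 0, "AB": 1, "BB": 2}
MISSING_CODE = -1
CODE_GENOTYPE = {v: k for k, v in GENOTYPE_CODE.items()}


def encode_calls(calls) -> np.ndarray:
    """Map call strings to B-allele dosage codes; NC (or anything else) -> -1."""
    s = pd.Series(calls, dtype="object")
    return s.map(GENOTYPE_CODE).fillna(MISSING_CODE).to_numpy(dtype=np.int8)


def decode_codes(codes) -> np.ndarray:
    codes = np.asarray(codes)
    out = np.full(codes.shape, NC, dtype=object)
    for code, g in CODE_GENOTYPE.items():
        out[codes == code] = g
    return out.astype(str)
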