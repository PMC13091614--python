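"""Pairwise relatedness from hard genotype calls (KING-robust estimator).

For individuals i, j over the sites called in both, let N_Aa,Aa be the count
of sites heterozygous in both, N_AA,aa the count of opposite homozygotes,
and N_Aa^i, N_Aa^j the per-individual heterozygote counts.  With
m = min(N_Aa^i, N_Aa^j) the between-family robust kinship estimate is

    phi = (N_Aa,Aa - 2 * N_AA,aa) / (2 m) + 1/2 - (N_Aa^i + N_Aa^j) / (4 m).

Expected values: 0.5 for duplicates/identity, 0.25 for first-degree pairs,
0.125 for second-degree, ~0 for unrelated (negative values are possible and
reported unclamped).  The estimator is undefined when either individual has
no heterozygote among shared sites.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .genotypes import MISSING_CODE


@dataclass
class KinshipResult:
    id_i: str
    id_j: str
    n_shared: int
    n_het_i: int
    n_het_j: int
    n_both_het: int
    n_opp_hom: int
    phi: float


def king_robust(gt_i, gt_j, id_i: str = "i", id_j: str = "j") -> KinshipResult:
    """KING-robust kinship from two genotype code vectors (0/1/2, -1 missing).

    Sites missing in either individual are excluded pairwise.
    """
    a = np.asarray(gt_i)
    b = np.asarray(gt_j)
    if a.shape != b.shape:
        raise ValueError("genotype vectors must have equal length")
    shared = (a != MISSING_CODE) & (b != MISSING_CODE)
    a, b = a[shared], b[shared]
    n_shared = int(shared.sum())
    if n_shared == 0:
        raise ValueError(f"no shared called sites for pair ({id_i}, {id_j})")
    het_i = int((a == 1).sum())
    het_j = int((b == 1).sum())
    m = min(het_i, het_j)
    if m == 0:
        raise ValueError(
            f"KING-robust undefined: zero heterozygotes for pair ({id_i}, {id_j})")
    both_het = int(((a == 1) & (b == 1)).sum())
    opp_hom = int((((a == 0) & (b == 2)) | ((a == 2) & (b == 0))).sum())
    phi = (both_het - 2 * opp_hom) / (2 * m) + 0.5 - (het_i + het_j) / (4 * m)
    return KinshipResult(id_i, id_j, n_shared, het_i, het_j, both_het,
                         opp_hom, float(phi))


def kinship_matrix(genotypes: pd.DataFrame, min_sites: int = 100
                   ) -> pd.DataFrame:
    """All-pairs KING-robust kinship from a sites x individuals code table.

    ``genotypes``: rows are sites, columns individuals, entries 0/1/2 or -1
    for missing/no-call.  Pairs sharing fewer than ``min_sites`` called sites
    (or with an undefined estimator) get phi = NaN.  Returns the long-format
    pair table.
    """
    ids = list(genotypes.columns)
    if len(ids) < 2:
        raise ValueError("kinship needs at least 2 individuals")
    rows = []
    for i, j in combinations(ids, 2):
        try:
            res = king_robust(genotypes[i].to_numpy(), genotypes[j].to_numpy(),
                              str(i), str(j))
        except ValueError:
            rows.append(dict(id_i=i, id_j=j, n_shared=0, n_het_i=0, n_het_j=0,
                             n_both_het=0, n_opp_hom=0, phi=np.nan))
            continue
        d = res.__dict__.copy()
        if res.n_shared < min_sites:
            d["phi"] = np.nan
        rows.append(d)
    return pd.DataFrame(rows)


def square_matrix(pairs: pd.DataFrame) -> pd.DataFrame:
    """Symmetric individuals x individuals phi matrix (diagonal = 0.5)."""
    ids = sorted(set(pairs["id_i"]) | set(pairs["id_j"]))
    M = pd.DataFrame(np.nan, index=ids, columns=ids)
    np.fill_diagonal(M.values, 0.5)
    for row in pairs.itertuples(index=False):
        M.loc[row.id_i, row.id_j] = row.phi
        M.loc[row.id_j, row.id_i] = row.phi
    return M
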