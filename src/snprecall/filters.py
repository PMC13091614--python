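"""Phred-scaled genotype quality and the call-retention filters.

The error probability of a call is P = 1 - max posterior; its Phred quality
is Q = -10 * log10(P), capped at 99.  Three retention filters follow:

* **Phred threshold** — keep calls with Q >= t, t in {0, 10, 20, 30};
* **rank-matched GenCall** — for a fair platform comparison, keep the k
  highest-GenCall platform calls where k is the size of the recaller's
  retained set, so both sets have equal cardinality;
* **concordance** — keep recalled genotypes only where they agree with the
  platform call (platform NC is never concordant).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genotypes import NC

Q_CAP = 99.0
_SIMPLEX_TOL = 1e-6


def phred_quality(probs) -> np.ndarray:
    """Phred genotype quality from posterior simplexes (rows AA, AB, BB)."""
    P = np.atleast_2d(np.asarray(probs, dtype=float))
    if np.any(P < -_SIMPLEX_TOL) or np.any(P > 1 + _SIMPLEX_TOL):
        raise ValueError("probabilities outside [0, 1]")
    sums = P.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > _SIMPLEX_TOL):
        raise ValueError("posterior rows must sum to 1")
    err = 1.0 - P.max(axis=1)
    with np.errstate(divide="ignore"):
        q = -10.0 * np.log10(np.maximum(err, 0.0))
    return np.minimum(q, Q_CAP)


def phred_filter(calls: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Retain calls with q >= threshold (threshold 0 keeps everything)."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    return calls.loc[calls["q"] >= threshold]


def rank_match_gencall(k: int, platform_calls: pd.DataFrame) -> pd.DataFrame:
    """The k platform calls with highest GenCall score.

    Boundary ties are broken by snp_id (then sample_id) lexicographic order,
    so the result is deterministic with exactly k rows.
    """
    if k > len(platform_calls):
        raise ValueError(f"k={k} exceeds {len(platform_calls)} platform calls")
    ordered = platform_calls.sort_values(
        by=["gencall", "snp_id", "sample_id"],
        ascending=[False, True, True], kind="mergesort")
    return ordered.head(k)


def concordance_filter(classifier_calls: pd.DataFrame,
                       platform_calls: pd.DataFrame) -> pd.DataFrame:
    """Retain recalled genotypes that match the platform call at the same
    sample x SNP; platform no-calls are treated as discordant."""
    plat = platform_calls[["sample_id", "snp_id", "gs_call"]]
    merged = classifier_calls.merge(plat, on=["sample_id", "snp_id"], how="left",
                                    suffixes=("", "_plat"))
    gs = merged["gs_call_plat"] if "gs_call_plat" in merged else merged["gs_call"]
    keep = (merged["call"] == gs) & (gs != NC) & gs.notna()
    return classifier_calls.loc[keep.to_numpy()]
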