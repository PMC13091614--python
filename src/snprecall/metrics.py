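"""Evaluation statistics for genotype call sets.

Call rates distinguish two denominators: the *absolute* rate divides called
sites by the full autosomal content of the chip, the *relative* rate by the
sites actually assayed for that DNA input, so absolute <= relative always.
Accuracy is computed over called sites only (uncalled sites drop out of both
numerator and denominator).  Per-class precision/recall/F1 are one-vs-rest;
method comparisons across strata use the exact two-sided paired sign test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GENOTYPES, NC

#: autosomal SNP content of the Omni5-4 chip, the default absolute-rate denominator
OMNI5_AUTOSOMAL_SITES = 4_198_873


def call_rates(n_called: int, n_chip_sites: int, n_input_sites: int
               ) -> tuple[float, float]:
    """(absolute, relative) call rates; denominators must be positive and nested."""
    if n_chip_sites <= 0 or n_input_sites <= 0:
        raise ValueError("call-rate denominators must be positive")
    if n_input_sites > n_chip_sites:
        raise ValueError("input sites cannot exceed chip sites")
    if n_called > n_input_sites:
        raise ValueError("called sites cannot exceed input sites")
    return n_called / n_chip_sites, n_called / n_input_sites


def genotype_accuracy(calls, truth) -> float:
    """Fraction of called sites (call != NC) whose call matches the truth.

    Returns NaN when no site is called.
    """
    calls = pd.Series(calls).reset_index(drop=True)
    truth = pd.Series(truth).reset_index(drop=True)
    called = calls != NC
    n_called = int(called.sum())
    if n_called == 0:
        return float("nan")
    return float((calls[called] == truth[called]).sum() / n_called)


def confusion_matrix(calls, truth) -> pd.DataFrame:
    """3x4 confusion table: rows = truth genotype, columns = call (incl. NC)."""
    calls = pd.Series(calls, dtype="object")
    truth = pd.Series(truth, dtype="object")
    tab = pd.crosstab(truth, calls)
    return tab.reindex(index=list(GENOTYPES), columns=list(GENOTYPES) + [NC],
                       fill_value=0).astype(int)


def per_class_f1(calls, truth) -> pd.DataFrame:
    """One-vs-rest precision/recall/F1 per genotype class over called sites.

    A class absent from both calls and truth gets NaN for all three.
    """
    calls = pd.Series(calls).reset_index(drop=True)
    truth = pd.Series(truth).reset_index(drop=True)
    called = calls != NC
    calls, truth = calls[called], truth[called]
    rows = {}
    for g in GENOTYPES:
        tp = int(((calls == g) & (truth == g)).sum())
        fp = int(((calls == g) & (truth != g)).sum())
        fn = int(((calls != g) & (truth == g)).sum())
        if tp + fp + fn == 0:  # class absent from calls and truth
            rows[g] = dict(precision=np.nan, recall=np.nan, f1=np.nan)
            continue
        prec = tp / (tp + fp) if tp + fp else np.nan
        rec = tp / (tp + fn) if tp + fn else np.nan
        f1 = 2 * tp / (2 * tp + fp + fn)
        rows[g] = dict(precision=prec, recall=rec, f1=f1)
    return pd.DataFrame(rows).T[["precision", "recall", "f1"]]


def paired_sign_test(differences) -> float:
    """Exact two-sided sign test on paired differences (zeros dropped).

    Returns NaN when every difference is zero.
    """
    d = np.asarray(differences, dtype=float)
    nonzero = d[d != 0]
    if nonzero.size == 0:
        return float("nan")
    k = int((nonzero > 0).sum())
    return float(stats.binomtest(k, nonzero.size, 0.5).pvalue)


@dataclass
class MetricsReport:
    """Bundle of the evaluation statistics for one call set vs truth."""

    n_total_sites: int
    n_uncalled: int
    n_wrong: int
    absolute_call_rate: float
    relative_call_rate: float
    accuracy: float
    per_class: pd.DataFrame
    confusion: pd.DataFrame

    def to_dict(self) -> dict:
        d = {
            "n_total_sites": self.n_total_sites,
            "n_uncalled": self.n_uncalled,
            "n_wrong": self.n_wrong,
            "absolute_call_rate": self.absolute_call_rate,
            "relative_call_rate": self.relative_call_rate,
            "accuracy": self.accuracy,
        }
        for g in GENOTYPES:
            for m in ("precision", "recall", "f1"):
                d[f"{m}_{g}"] = float(self.per_class.loc[g, m])
        return d


def evaluate_calls(calls, truth, n_chip_sites: int | None = None) -> MetricsReport:
    """Full evaluation of one call vector against truth labels.

    ``n_chip_sites`` defaults to the number of evaluated sites (absolute ==
    relative); pass the chip's autosomal content for the real-chip convention.
    """
    calls = pd.Series(calls).reset_index(drop=True)
    truth = pd.Series(truth).reset_index(drop=True)
    if len(calls) != len(truth):
        raise ValueError("calls and truth must align")
    n_total = len(calls)
    n_uncalled = int((calls == NC).sum())
    n_called = n_total - n_uncalled
    n_wrong = int(((calls != NC) & (calls != truth)).sum())
    absolute, relative = call_rates(
        n_called, n_chip_sites or n_total, n_total)
    return MetricsReport(
        n_total_sites=n_total, n_uncalled=n_uncalled, n_wrong=n_wrong,
        absolute_call_rate=absolute, relative_call_rate=relative,
        accuracy=genotype_accuracy(calls, truth),
        per_class=per_class_f1(calls, truth),
        confusion=confusion_matrix(calls, truth))
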