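"""Ground-truth labels, labeled training examples, and leakage-safe splits.

The highest-input run of each individual (flagged ``is_truth`` in the
manifest, 50 ng in the original design) supplies the reference genotype per
SNP; lower-input records of the same individual are labeled by joining on
(individual, SNP).  Partitioning is always by individual so that no
individual contributes to both training and evaluation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genotypes import GENOTYPES, NC


def build_truth(records: pd.DataFrame, manifest: pd.DataFrame) -> pd.DataFrame:
    """Reference genotypes from each individual's designated truth run.

    Returns one row per (individual_id, snp_id) with ``truth_genotype`` in
    {AA, AB, BB}; truth-run no-calls yield no label.  Every individual in the
    manifest must have exactly one truth run.
    """
    truth_samples = manifest.loc[manifest["is_truth"]]
    missing = set(manifest["individual_id"]) - set(truth_samples["individual_id"])
    if missing:
        raise ValueError(f"individuals without a truth run: {sorted(missing)}")
    if truth_samples["individual_id"].duplicated().any():
        dup = truth_samples.loc[truth_samples["individual_id"].duplicated(),
                                "individual_id"].tolist()
        raise ValueError(f"multiple truth runs for individuals: {dup}")

    rec = records.loc[records["sample_id"].isin(truth_samples["sample_id"])]
    rec = rec.loc[rec["gs_call"].isin(GENOTYPES)]
    truth = rec[["individual_id", "snp_id", "gs_call"]].rename(
        columns={"gs_call": "truth_genotype"}).reset_index(drop=True)
    if truth.duplicated(subset=["individual_id", "snp_id"]).any():
        raise ValueError("duplicate (individual, snp) truth labels; run QC first")
    return truth


def make_examples(records: pd.DataFrame, truth: pd.DataFrame,
                  strict: bool = False) -> pd.DataFrame:
    """Join lower-input records to truth labels (inner join on individual x SNP).

    Records with no truth label are dropped (count in
    ``attrs["n_without_truth"]``).  Records whose own platform call is NC are
    retained by default — they still carry informative features — and dropped
    in ``strict`` mode.
    """
    ex = records.merge(truth, on=["individual_id", "snp_id"], how="inner")
    n_dropped = len(records) - len(ex)
    if strict:
        ex = ex.loc[ex["gs_call"] != NC]
    ex = ex.reset_index(drop=True)
    ex.attrs["n_without_truth"] = int(n_dropped)
    return ex


def split_by_individual(examples: pd.DataFrame, test_individuals
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition examples so no individual appears in both train and test."""
    test_individuals = set(test_individuals)
    if not test_individuals:
        raise ValueError("test_individuals must be nonempty")
    known = set(examples["individual_id"])
    unknown = test_individuals - known
    if unknown:
        raise ValueError(f"unknown test individuals: {sorted(unknown)}")
    in_test = examples["individual_id"].isin(test_individuals)
    return (examples.loc[~in_test].reset_index(drop=True),
            examples.loc[in_test].reset_index(drop=True))


def downsample_balanced(examples: pd.DataFrame, seed: int,
                        mode: str = "binary") -> pd.DataFrame:
    """Down-sample to equal class counts for the model-selection phase.

    ``mode="binary"`` balances platform-correct vs platform-incorrect records
    (NC counts as incorrect); ``mode="genotype"`` balances the three true
    genotype classes.  Sampling is uniform without replacement under ``seed``.
    """
    rng = np.random.default_rng(seed)
    if mode == "binary":
        labels = (examples["gs_call"] == examples["truth_genotype"])
        classes = [True, False]
        keys = labels
    elif mode == "genotype":
        classes = list(GENOTYPES)
        keys = examples["truth_genotype"]
    else:
        raise ValueError(f"unknown mode {mode!r}")

    groups = {c: np.flatnonzero((keys == c).to_numpy()) for c in classes}
    sizes = {c: len(idx) for c, idx in groups.items()}
    if any(s == 0 for s in sizes.values()):
        raise ValueError(f"empty class in down-sampling: counts {sizes}")
    n = min(sizes.values())
    take = np.concatenate([
        np.sort(rng.choice(idx, size=n, replace=False)) for c, idx in groups.items()
    ])
    return examples.iloc[np.sort(take)].reset_index(drop=True)


def class_weights(labels) -> dict[str, float]:
    """Inverse-frequency weights w_c = N / (3 * N_c), a flat genotype prior."""
    counts = pd.Series(labels).value_counts()
    missing = set(GENOTYPES) - set(counts.index)
    if missing:
        raise ValueError(f"missing genotype classes: {sorted(missing)}")
    total = int(counts.sum())
    return {g: total / (len(GENOTYPES) * int(counts[g])) for g in GENOTYPES}
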