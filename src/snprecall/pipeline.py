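"""End-to-end workflows: train a recaller, recall genotypes, evaluate.

The flow mirrors the study design: record-level QC -> feature engineering ->
truth labeling from the designated high-input run -> two-phase training
(model selection on a correct/incorrect-balanced down-sample under
leave-individuals-out CV, then a final fit on all training data with class
reweighting) -> probabilistic recalling -> Phred / rank-matched / concordance
filtering -> metrics and kinship.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import filters as filt
from . import labeling, metrics
from .features import FEATURE_COLUMNS, Normalizer, compute_features
from .genotypes import GENOTYPES, NC, encode_calls
from .kinship import kinship_matrix
from .models import (ModelSpec, PROB_COLUMNS, TrainedModel, fit_final,
                     grid_search, predict_proba, save_model, train)
from .qc import QcConfig, qc_filter

log = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = (0, 10, 20, 30)

#: single-point default grids per family (expand via config for real tuning)
DEFAULT_GRIDS = {
    "gbt": {"n_estimators": [200], "max_depth": [6], "subsample": [0.8]},
    "rmlr": {"C": [0.01, 1.0, 100.0], "penalty": ["elasticnet"],
             "l1_ratio": [0.001]},
    "nn": {"learning_rate_init": [0.01]},
}

ID_COLUMNS = ["sample_id", "individual_id", "dna_input_ng", "snp_id",
              "gs_call", "gencall"]


def run_train(records: pd.DataFrame, manifest: pd.DataFrame, *,
              family: str = "gbt", grid: dict | None = None,
              test_individuals=(), seed: int = 0,
              qc_cfg: QcConfig | None = None,
              feature_names: list[str] | None = None,
              phase1_max_examples: int | None = None,
              outdir: str | Path | None = None) -> dict:
    """Two-phase training on a labeled dilution grid.

    Returns a dict with the fitted model (normalizer attached), the CV score
    table, the winning spec and a per-stage record-count report.
    """
    report: dict[str, object] = {"n_records_in": len(records)}
    kept, qc_report = qc_filter(records, qc_cfg)
    report["qc"] = qc_report
    feats = compute_features(kept)

    truth = labeling.build_truth(feats, manifest)
    report["n_truth_labels"] = len(truth)
    lower = feats.loc[~feats["sample_id"].isin(
        manifest.loc[manifest["is_truth"], "sample_id"])]
    examples = labeling.make_examples(lower, truth)
    report["n_examples"] = len(examples)

    test_individuals = set(test_individuals)
    if test_individuals:
        train_ex, _ = labeling.split_by_individual(examples, test_individuals)
    else:
        train_ex = examples
    report["n_train_examples"] = len(train_ex)
    names = list(feature_names or FEATURE_COLUMNS)
    normalizer = Normalizer.fit(train_ex, names)

    # phase 1: model selection on a correct/incorrect-balanced down-sample
    phase1 = labeling.downsample_balanced(train_ex, seed=seed)
    if phase1_max_examples and len(phase1) > phase1_max_examples:
        phase1 = phase1.sample(phase1_max_examples, random_state=seed)
    report["n_phase1_examples"] = len(phase1)
    n_folds = phase1["individual_id"].nunique()
    best, cv_scores = grid_search(
        family, grid or DEFAULT_GRIDS[family],
        normalizer.transform(phase1), phase1["truth_genotype"],
        phase1["individual_id"], n_folds=n_folds, seed=seed)

    # phase 2: final fit on all training data, class-reweighted
    weights = labeling.class_weights(train_ex["truth_genotype"])
    model = fit_final(family, best, normalizer.transform(train_ex),
                      train_ex["truth_genotype"], weights)
    model.normalizer = normalizer
    log.info("trained %s model on %d examples (phase-1 n=%d, %d-fold CV)",
             family, len(train_ex), len(phase1), n_folds)

    if outdir is not None:
        outdir = Path(outdir)
        save_model(model, outdir)
        cv_scores.to_csv(outdir / "cv_scores.tsv", sep="\t", index=False)
        (outdir / "train_report.json").write_text(json.dumps(report, indent=1))
    return {"model": model, "cv_scores": cv_scores, "best_spec": best,
            "report": report}


def recall_genotypes(model: TrainedModel, records: pd.DataFrame,
                     qc_cfg: QcConfig | None = None) -> pd.DataFrame:
    """QC + featurize + predict: one posterior call per surviving record."""
    if model.normalizer is None:
        raise ValueError("model has no attached normalizer")
    kept, _ = qc_filter(records, qc_cfg)
    feats = compute_features(kept)
    post = predict_proba(model, model.normalizer.transform(feats))
    keep_ids = [c for c in ID_COLUMNS if c in feats.columns]
    return pd.concat([feats[keep_ids].reset_index(drop=True),
                      post.reset_index(drop=True)], axis=1)


def apply_filters(calls: pd.DataFrame, threshold: float = 0.0,
                  concordance: bool = False) -> pd.DataFrame:
    """Phred-threshold (and optionally concordance-) filter a call table."""
    out = filt.phred_filter(calls, threshold)
    if concordance:
        out = filt.concordance_filter(out, calls)
    return out


def attach_truth(calls: pd.DataFrame, truth: pd.DataFrame) -> pd.DataFrame:
    """Inner-join recalled posteriors with truth genotype labels."""
    return calls.merge(truth, on=["individual_id", "snp_id"], how="inner")


def evaluation_grid(labeled_calls: pd.DataFrame,
                    thresholds=DEFAULT_THRESHOLDS,
                    concordance: bool = False) -> pd.DataFrame:
    """Per (DNA input x Phred threshold) metrics for recaller and platform.

    ``model_accuracy``/``model_f1_ab`` score the recaller's retained set.
    The head-to-head platform comparison uses equal-cardinality rank-matched
    sets: with k = min(recaller retained, platform called), the recaller's
    top-k calls by Phred quality are scored against the platform's top-k
    calls by GenCall (``model_accuracy_matched`` vs ``platform_accuracy``),
    so neither side is penalized for sites only the other declined.
    Input: recalled posteriors with truth labels attached.
    """
    rows = []
    for ng, stratum in labeled_calls.groupby("dna_input_ng"):
        n_input_sites = len(stratum)
        platform_called = stratum.loc[stratum["gs_call"] != NC]
        for t in thresholds:
            retained = apply_filters(stratum, t, concordance=concordance)
            k = min(len(retained), len(platform_called))
            model_matched = retained.sort_values(
                by=["q", "snp_id", "sample_id"],
                ascending=[False, True, True], kind="mergesort").head(k)
            plat_matched = filt.rank_match_gencall(k, platform_called)
            def _acc_f1(calls, truth):
                if len(calls) == 0:  # nothing retained in this cell
                    return float("nan"), float("nan")
                rep = metrics.evaluate_calls(calls, truth)
                return rep.accuracy, float(rep.per_class.loc["AB", "f1"])

            model_acc, model_f1 = _acc_f1(retained["call"],
                                          retained["truth_genotype"])
            model_acc_m, model_f1_m = _acc_f1(model_matched["call"],
                                              model_matched["truth_genotype"])
            plat_acc, plat_f1 = _acc_f1(plat_matched["gs_call"],
                                        plat_matched["truth_genotype"])
            rows.append({
                "dna_input_ng": ng, "threshold": t,
                "n_sites": n_input_sites,
                "model_called": len(retained),
                "model_relative_call_rate": len(retained) / n_input_sites,
                "model_accuracy": model_acc,
                "model_f1_ab": model_f1,
                "n_matched": k,
                "model_accuracy_matched": model_acc_m,
                "model_f1_ab_matched": model_f1_m,
                "platform_accuracy": plat_acc,
                "platform_f1_ab": plat_f1,
            })
    return pd.DataFrame(rows)


def _with_nc(all_calls: pd.DataFrame, retained: pd.DataFrame) -> pd.DataFrame:
    """Calls over all sites with filtered-out entries set to NC."""
    out = all_calls.copy()
    out["call"] = np.where(out.index.isin(retained.index), out["call"], NC)
    return out


def sign_test_vs_platform(grid: pd.DataFrame, column: str = "accuracy") -> float:
    """Paired sign test of recaller minus platform across strata
    (rank-matched equal-cardinality sets)."""
    diffs = grid[f"model_{column}_matched"] - grid[f"platform_{column}"]
    return metrics.paired_sign_test(diffs.to_numpy())


def calls_to_matrix(calls: pd.DataFrame, call_column: str = "call"
                    ) -> pd.DataFrame:
    """Pivot a long call table to a sites x individuals genotype-code matrix."""
    wide = calls.pivot_table(index="snp_id", columns="individual_id",
                             values=call_column, aggfunc="first")
    out = pd.DataFrame(index=wide.index)
    for c in wide.columns:
        out[c] = encode_calls(wide[c].fillna(NC))
    return out


def kinship_from_calls(calls: pd.DataFrame, call_column: str = "call",
                       min_sites: int = 100) -> pd.DataFrame:
    """KING-robust kinship pairs from hard calls (long table in, pairs out)."""
    return kinship_matrix(calls_to_matrix(calls, call_column), min_sites)
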