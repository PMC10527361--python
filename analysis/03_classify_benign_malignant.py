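#!/usr/bin/env python
"""Classify benign vs malignant basal profiles with PLS-DA: leave-one-out
signed prediction scores (score > 0 predicts benign), confusion metrics
with malignant as the positive class, and a 500-permutation null for the
cross-validated misclassification rate."""

import argparse
from pathlib import Path

import pandas as pd

from kinaprof import classify, io


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    args = ap.parse_args()

    matrix = io.read_signal_matrix(args.cohort / "signal_matrix.tsv")
    sheet = io.read_sample_sheet(args.data / "cohort_sample_sheet.tsv")
    labels = sheet.set_index("sample_id").loc[matrix.sample_ids, "class_label"]

    result = classify.loocv_scores(matrix.values, labels, n_components=2)
    io.write_tsv(result.table.reset_index(), args.cohort / "prediction_scores.tsv")
    metrics = classify.confusion_metrics(result)
    perm = classify.permutation_test(matrix.values, labels, B=500, folds="loo", seed=args.seed)
    metrics["permutation_p_value"] = perm.p_value
    metrics["observed_misclassification_rate"] = perm.observed_rate
    io.write_json(metrics, args.cohort / "classification_metrics.json")
    io.write_tsv(
        pd.DataFrame({"null_misclassification_rate": perm.null_rates}),
        args.cohort / "permutation_null.tsv",
    )
    print(
        f"LOOCV: {metrics['tp']}/{metrics['tp'] + metrics['fn']} malignant and "
        f"{metrics['tn']}/{metrics['tn'] + metrics['fp']} benign correct "
        f"(accuracy {metrics['accuracy']:.0%}); "
        f"permutation p = {perm.p_value:.4g} over 500 label permutations"
    )


if __name__ == "__main__":
    main()
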