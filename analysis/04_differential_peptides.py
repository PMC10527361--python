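#!/usr/bin/env python
"""Per-peptide benign vs malignant comparison of the basal signal: pooled
two-sample two-tailed t-tests with Benjamini-Hochberg adjustment, reported
in the study's style (count at p < 0.05 with the max q of that set as its
FDR figure)."""

import argparse
from pathlib import Path

from kinaprof import differential as diff
from kinaprof import io


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    args = ap.parse_args()

    matrix = io.read_signal_matrix(args.cohort / "signal_matrix.tsv")
    sheet = io.read_sample_sheet(args.data / "cohort_sample_sheet.tsv")
    labels = sheet.set_index("sample_id").loc[matrix.sample_ids, "class_label"]
    table = diff.differential_table(matrix.values, labels)
    io.write_tsv(table, args.cohort / "differential_basal.tsv")
    print(
        f"{table.attrs['n_pass_p']} of {len(table)} peptides differ at p < 0.05 "
        f"(FDR {100 * table.attrs['fdr_at_p_threshold']:.0f}%); "
        f"{table.attrs['n_pass_q']} at q < 0.05"
    )
    top = table.head(5)[["peptide_id", "delta", "p_value", "q_value"]]
    print(top.to_string(index=False))


if __name__ == "__main__":
    main()
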