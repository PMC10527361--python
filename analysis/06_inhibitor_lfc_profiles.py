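#!/usr/bin/env python
"""Ex vivo inhibitor profiling: per-strip log fold changes (inhibitor minus
control log2 signal, plate effects cancelling on the shared strip), then
per-peptide differential testing of the LFC profiles between
mutation-positive and negative samples and between recurrent and
non-recurrent samples."""

import argparse
from pathlib import Path

import numpy as np

from kinaprof import differential as diff
from kinaprof import io
from kinaprof import preprocess as pp


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results/inhibitor"))
    args = ap.parse_args()

    spot = io.read_spot_table(args.data / "inhibitor_spot_table.tsv")
    sheet = io.read_sample_sheet(args.data / "inhibitor_sample_sheet.tsv")
    kmap = io.read_kinase_map(args.data / "inhibitor_kinase_map.tsv")
    truth = io.read_ground_truth(args.data / "inhibitor_ground_truth.json")

    lfc = pp.compute_lfc(spot)
    io.write_lfc_matrix(lfc, args.out / "lfc_matrix.tsv")
    meta = sheet.set_index("sample_id").loc[lfc.values.index]
    subs = list(kmap.loc[kmap["kinase_id"].isin(truth.targeted_kinases), "peptide_id"])
    pos, neg = meta.index[meta["braf_v600e"]], meta.index[~meta["braf_v600e"]]
    print(
        f"{lfc.inhibitor}: median LFC on targeted substrates "
        f"{np.median(lfc.values.loc[pos, subs].to_numpy()):.2f} in mutation-positive vs "
        f"{np.median(lfc.values.loc[neg, subs].to_numpy()):.2f} in negative samples"
    )

    for column in ("braf_v600e", "recurrent"):
        labels = meta[column].map(lambda v: f"{column}={v}")
        table = diff.differential_table(lfc.values, labels)
        io.write_tsv(table, args.out / f"differential_lfc_{column}.tsv")
        print(
            f"  {column}: {table.attrs['n_pass_p']} peptides at p < 0.05 "
            f"(FDR {100 * table.attrs['fdr_at_p_threshold']:.0f}%)"
        )


if __name__ == "__main__":
    main()
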