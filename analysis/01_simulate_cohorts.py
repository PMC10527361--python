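#!/usr/bin/env python
"""Generate the synthetic study: a 55-sample basal cohort (21 benign + 34
malignant lysates on 240-peptide arrays, duplicate with-ATP plus one no-ATP
array per sample per plate, repeated on a second plate) and a 13-sample
paired inhibitor run (7 mutation-positive + 6 negative samples, control
and inhibitor arrays sharing a strip, on 140-peptide chips). Ground truth (planted kinase activities, targeted
kinases, true rates) is written alongside for the recovery analyses."""

import argparse
from pathlib import Path

from kinaprof import io
from kinaprof import simulate as sim


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/data"))
    args = ap.parse_args()

    cohort_cfg = sim.SimulationConfig(seed=args.seed)
    kmap = sim.simulate_kinase_map(
        cohort_cfg.n_kinases, cohort_cfg.n_peptides,
        cohort_cfg.substrates_per_kinase, cohort_cfg.seed,
    )
    spot, sheet, truth = sim.simulate_cohort(cohort_cfg, kmap)
    io.write_spot_table(spot, args.out / "cohort_spot_table.tsv")
    io.write_sample_sheet(sheet, args.out / "cohort_sample_sheet.tsv")
    io.write_kinase_map(kmap, args.out / "cohort_kinase_map.tsv")
    io.write_ground_truth(truth, args.out / "cohort_ground_truth.json")
    print(
        f"cohort: {len(sheet)} samples "
        f"({(sheet.class_label == 'benign').sum()} benign, "
        f"{(sheet.class_label == 'malignant').sum()} malignant), "
        f"{cohort_cfg.n_peptides} peptides, {spot.array_id.nunique()} arrays, "
        f"{len(spot)} spot rows; active kinases: {sorted(truth.active_kinases)}"
    )

    inh_cfg = sim.SimulationConfig.inhibitor_defaults(seed=args.seed + 1)
    ikmap = sim.simulate_kinase_map(
        inh_cfg.n_kinases, inh_cfg.n_peptides, inh_cfg.substrates_per_kinase, inh_cfg.seed
    )
    ispot, isheet, itruth = sim.simulate_inhibitor_run(inh_cfg, ikmap, specific=True)
    io.write_spot_table(ispot, args.out / "inhibitor_spot_table.tsv")
    io.write_sample_sheet(isheet, args.out / "inhibitor_sample_sheet.tsv")
    io.write_kinase_map(ikmap, args.out / "inhibitor_kinase_map.tsv")
    io.write_ground_truth(itruth, args.out / "inhibitor_ground_truth.json")
    print(
        f"inhibitor run: {len(isheet)} samples "
        f"({isheet.braf_v600e.sum()} mutation-positive), "
        f"paired control/{ispot.treatment.unique()[-1]} arrays per strip; "
        f"targeted kinases: {sorted(itruth.targeted_kinases)}"
    )


if __name__ == "__main__":
    main()
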