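"""End-to-end orchestration with a structured config and a run manifest.

Cohort mode: preprocess -> peptide filter -> PLS-DA LOOCV + permutation
test -> per-peptide differential table -> upstream kinase ranking.
Inhibitor mode: preprocess -> per-strip LFC -> differential table on LFC
between the groups named in the sample sheet (e.g. mutation-positive vs
negative, recurrent vs non-recurrent).

Every run writes a JSON manifest carrying the config, all seeds, package
and library versions, and row counts at each stage, sufficient to
reproduce it. All randomness flows from config seeds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, classify, differential, io, preprocess, simulate, upstream
from .errors import InvalidArgumentError

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    spot_table: str = ""
    sample_sheet: str = ""
    kinase_map: str = ""
    output_dir: str = "results"
    # preprocess
    threshold_fraction: float = preprocess.DEFAULT_THRESHOLD_FRACTION
    reference_exposure_ms: float = preprocess.REFERENCE_EXPOSURE_MS
    # classify
    n_components: int = 2
    folds: object = "loo"
    classify_B: int = 500
    classify_seed: int = 0
    # differential
    p_threshold: float = 0.05
    q_threshold: float = 0.05
    group_column: str = "class_label"  # used in inhibitor mode
    # upstream
    upstream_B: int = 500
    ladder: tuple[int, ...] = upstream.DEFAULT_LADDER
    min_substrates: int = upstream.DEFAULT_MIN_SUBSTRATES
    upstream_seed: int = 0
    # simulation (for the simulate command)
    simulate_overrides: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        flat = {}
        for section in ("paths", "preprocess", "classify", "differential", "upstream"):
            sub = dict(raw.get(section, {}) or {})
            # B and seed are section-qualified field names on the dataclass
            if section in ("classify", "upstream"):
                if "B" in sub:
                    flat[f"{section}_B"] = sub.pop("B")
                if "seed" in sub:
                    flat[f"{section}_seed"] = sub.pop("seed")
            flat.update(sub)
        flat["simulate_overrides"] = raw.get("simulate", {}) or {}
        if "ladder" in flat:
            flat["ladder"] = tuple(flat["ladder"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(flat) - known
        if unknown:
            raise InvalidArgumentError(f"unknown config keys: {sorted(unknown)}")
        return cls(**flat)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["ladder"] = list(self.ladder)
        return d


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _versions() -> dict:
    import scipy

    return {
        "kinaprof": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
    }


def simulate_command(config: PipelineConfig, mode: str = "cohort", seed: int | None = None) -> dict:
    """Write a complete synthetic cohort or inhibitor run ready for
    :func:`run_pipeline` into the configured output directory."""
    overrides = dict(config.simulate_overrides)
    if seed is not None:
        overrides["seed"] = seed
    if mode == "cohort":
        sim = simulate.SimulationConfig(**overrides)
    elif mode == "inhibitor":
        sim = simulate.SimulationConfig.inhibitor_defaults(**overrides)
    else:
        raise InvalidArgumentError(f"unknown simulate mode {mode!r}")
    kmap = simulate.simulate_kinase_map(
        sim.n_kinases, sim.n_peptides, sim.substrates_per_kinase, sim.seed
    )
    if mode == "cohort":
        spot, sheet, truth = simulate.simulate_cohort(sim, kmap)
    else:
        spot, sheet, truth = simulate.simulate_inhibitor_run(sim, kmap)
    out = Path(config.output_dir)
    io.write_spot_table(spot, out / "spot_table.tsv")
    io.write_sample_sheet(sheet, out / "sample_sheet.tsv")
    io.write_kinase_map(kmap, out / "kinase_map.tsv")
    io.write_ground_truth(truth, out / "ground_truth.json")
    manifest = {
        "mode": f"simulate-{mode}",
        "seed": sim.seed,
        "n_samples": int(sheet.shape[0]),
        "n_peptides": sim.n_peptides,
        "n_spot_rows": int(spot.shape[0]),
        "files": ["spot_table.tsv", "sample_sheet.tsv", "kinase_map.tsv", "ground_truth.json"],
    }
    io.write_json(manifest, out / "simulate_manifest.json")
    return manifest


def run_pipeline(config: PipelineConfig, mode: str = "cohort") -> dict:
    """Run all stages for one mode; returns (and writes) the run manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "mode": mode,
        "config_hash": _config_hash(config),
        "config": config.to_dict(),
        "versions": _versions(),
        "seeds": {"classify": config.classify_seed, "upstream": config.upstream_seed},
        "stages": {},
    }
    try:
        spot = io.read_spot_table(config.spot_table)
        sheet = io.read_sample_sheet(config.sample_sheet)
        manifest["stages"]["input"] = {
            "n_spot_rows": int(spot.shape[0]),
            "n_samples": int(sheet.shape[0]),
        }
        if mode == "cohort":
            _run_cohort(config, spot, sheet, out, manifest)
        elif mode == "inhibitor":
            _run_inhibitor(config, spot, sheet, out, manifest)
        else:
            raise InvalidArgumentError(f"unknown pipeline mode {mode!r}")
        manifest["status"] = "ok"
    except Exception as e:
        manifest["status"] = "failed"
        manifest["error"] = f"{type(e).__name__}: {e}"
        io.write_json(manifest, out / "manifest.json")
        raise
    io.write_json(manifest, out / "manifest.json")
    return manifest


def _run_cohort(config, spot, sheet, out: Path, manifest: dict) -> None:
    matrix, report = preprocess.process_cohort(
        spot,
        reference_exposure_ms=config.reference_exposure_ms,
        threshold_fraction=config.threshold_fraction,
    )
    io.write_signal_matrix(matrix, out / "signal_matrix.tsv")
    io.write_tsv(report, out / "filter_report.tsv")
    manifest["stages"]["preprocess"] = {
        "n_peptides_before_filter": int(report.shape[0]),
        "n_peptides_kept": int(report["kept"].sum()),
        "n_samples": int(matrix.values.shape[0]),
    }

    labels = sheet.set_index("sample_id").loc[matrix.sample_ids, "class_label"]
    result = classify.loocv_scores(matrix.values, labels, config.n_components)
    io.write_tsv(result.table.reset_index(), out / "prediction_scores.tsv")
    metrics = classify.confusion_metrics(result)
    perm = classify.permutation_test(
        matrix.values, labels, B=config.classify_B,
        folds=config.folds, seed=config.classify_seed,
        n_components=config.n_components,
    )
    io.write_tsv(
        pd.DataFrame({"null_misclassification_rate": perm.null_rates}),
        out / "permutation_null.tsv",
    )
    metrics.update(
        {"permutation_p_value": perm.p_value, "observed_misclassification_rate": perm.observed_rate}
    )
    io.write_json(metrics, out / "classification_metrics.json")
    manifest["stages"]["classify"] = {
        "loocv_accuracy": metrics["accuracy"],
        "permutation_p_value": perm.p_value,
    }

    table = differential.differential_table(
        matrix.values, labels,
        p_threshold=config.p_threshold, q_threshold=config.q_threshold,
    )
    io.write_tsv(table, out / "differential_basal.tsv")
    manifest["stages"]["differential"] = {
        "n_pass_p": table.attrs["n_pass_p"],
        "n_pass_q": table.attrs["n_pass_q"],
        "fdr_at_p_threshold": table.attrs["fdr_at_p_threshold"],
    }

    kmap = io.read_kinase_map(config.kinase_map)
    ranking = upstream.rank_kinases(
        matrix.values, labels, kmap,
        B=config.upstream_B, ladder=config.ladder,
        min_substrates=config.min_substrates, seed=config.upstream_seed,
    )
    io.write_tsv(ranking.table, out / "kinase_scores.tsv")
    io.write_tsv(upstream.emit_kinome_table(ranking.table), out / "kinome_annotation.tsv")
    manifest["stages"]["upstream"] = {
        "n_kinases_ranked": int(ranking.table.shape[0]),
        "n_kinases_skipped": len(ranking.skipped),
        "skipped": ranking.skipped,
    }


def _run_inhibitor(config, spot, sheet, out: Path, manifest: dict) -> None:
    lfc = preprocess.compute_lfc(spot, reference_exposure_ms=config.reference_exposure_ms)
    io.write_lfc_matrix(lfc, out / "lfc_matrix.tsv")
    manifest["stages"]["lfc"] = {
        "inhibitor": lfc.inhibitor,
        "n_samples": int(lfc.values.shape[0]),
        "n_peptides": int(lfc.values.shape[1]),
    }
    meta = sheet.set_index("sample_id").loc[lfc.values.index]
    if config.group_column not in meta.columns:
        raise InvalidArgumentError(
            f"group column {config.group_column!r} not in sample sheet"
        )
    raw = meta[config.group_column]
    labels = raw.map(lambda v: f"{config.group_column}={v}")
    table = differential.differential_table(
        lfc.values, labels,
        p_threshold=config.p_threshold, q_threshold=config.q_threshold,
    )
    io.write_tsv(table, out / f"differential_lfc_{config.group_column}.tsv")
    manifest["stages"]["differential"] = {
        "group_column": config.group_column,
        "groups": list(table.attrs["groups"]),
        "n_pass_p": table.attrs["n_pass_p"],
        "n_pass_q": table.attrs["n_pass_q"],
        "fdr_at_p_threshold": table.attrs["fdr_at_p_threshold"],
    }
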