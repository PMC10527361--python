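"""Stable on-disk schemas: TSV tables with UTF-8 and 9-significant-digit
floats (reproducible diffs), JSON for ground truth, metrics, and manifests."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import LfcMatrix, SignalMatrix
from .simulate import GroundTruth

FLOAT_FORMAT = "%.9g"

SPOT_COLUMNS = [
    "plate_id", "strip_id", "array_id", "sample_id", "atp_present",
    "treatment", "replicate_id", "peptide_id", "exposure_time_ms",
    "intensity", "local_background",
]


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_spot_table(spot: pd.DataFrame, path) -> None:
    write_tsv(spot[SPOT_COLUMNS], path)


def read_spot_table(path) -> pd.DataFrame:
    spot = read_tsv(path, dtype={"plate_id": str, "strip_id": str, "array_id": str,
                                 "sample_id": str, "peptide_id": str, "treatment": str})
    missing = set(SPOT_COLUMNS) - set(spot.columns)
    if missing:
        raise ValueError(f"spot table {path} lacks columns: {sorted(missing)}")
    spot["atp_present"] = spot["atp_present"].astype(bool)
    return spot


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    write_tsv(sheet, path)


def read_sample_sheet(path) -> pd.DataFrame:
    return read_tsv(path, dtype={"sample_id": str})


def write_kinase_map(kmap: pd.DataFrame, path) -> None:
    write_tsv(kmap, path)


def read_kinase_map(path) -> pd.DataFrame:
    return read_tsv(path, dtype={"kinase_id": str, "peptide_id": str})


def write_signal_matrix(matrix: SignalMatrix, path) -> None:
    """Matrix TSV (rows = samples) with a sidecar JSON of provenance."""
    path = Path(path)
    df = matrix.values.copy()
    df.index.name = "sample_id"
    write_tsv(df, path, index=True)
    sidecar = path.with_suffix(path.suffix + ".provenance.json")
    sidecar.write_text(json.dumps({"processing": matrix.provenance}, indent=2))


def read_signal_matrix(path) -> SignalMatrix:
    path = Path(path)
    df = read_tsv(path, index_col="sample_id")
    sidecar = path.with_suffix(path.suffix + ".provenance.json")
    provenance = (
        json.loads(sidecar.read_text())["processing"] if sidecar.exists() else []
    )
    return SignalMatrix(values=df, provenance=provenance)


def write_lfc_matrix(lfc: LfcMatrix, path) -> None:
    df = lfc.values.copy()
    df.index.name = "sample_id"
    write_tsv(df, path, index=True)


def read_lfc_matrix(path, inhibitor: str = "unknown") -> LfcMatrix:
    return LfcMatrix(values=read_tsv(path, index_col="sample_id"), inhibitor=inhibitor)


def _frame_to_json(df: pd.DataFrame) -> dict:
    return {
        "index": list(map(str, df.index)),
        "columns": list(map(str, df.columns)),
        "values": np.asarray(df, dtype=float).tolist(),
    }


def _frame_from_json(obj: dict) -> pd.DataFrame:
    return pd.DataFrame(obj["values"], index=obj["index"], columns=obj["columns"])


def write_ground_truth(truth: GroundTruth, path) -> None:
    payload = {
        "kinase_activity": _frame_to_json(truth.kinase_activity),
        "active_kinases": sorted(truth.active_kinases),
        "targeted_kinases": sorted(truth.targeted_kinases),
        "peptide_rates": _frame_to_json(truth.peptide_rates),
    }
    if truth.peptide_rates_inhibited is not None:
        payload["peptide_rates_inhibited"] = _frame_to_json(truth.peptide_rates_inhibited)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(payload))


def read_ground_truth(path) -> GroundTruth:
    obj = json.loads(Path(path).read_text())
    return GroundTruth(
        kinase_activity=_frame_from_json(obj["kinase_activity"]),
        active_kinases=set(obj["active_kinases"]),
        targeted_kinases=set(obj["targeted_kinases"]),
        peptide_rates=_frame_from_json(obj["peptide_rates"]),
        peptide_rates_inhibited=(
            _frame_from_json(obj["peptide_rates_inhibited"])
            if "peptide_rates_inhibited" in obj
            else None
        ),
    )


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonable))


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON-serializable: {type(x)}")
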