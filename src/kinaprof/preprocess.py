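"""Raw spot quantifications -> analysis-ready log2 signal and LFC matrices.

The processing order is fixed: local-background subtraction, integration of
the CCD exposure ladder into one value per spot (through-origin least-squares
slope scaled to a reference exposure), subtraction of the sample's no-ATP
signal on the same plate, averaging of the duplicate with-ATP arrays, log2
transform, per-plate median normalization, and finally averaging of the
replicate values obtained on different plates. Peptides enter the analysis
only if their ATP-corrected signal increases on more than 30% of the
with-ATP arrays.

Inhibitor runs are reduced to log fold changes (LFC) per strip: log2 signal
with inhibitor minus log2 signal without, computed on un-normalized values
because the paired arrays share a strip and hence a plate, so plate effects
cancel by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError, MissingControlError, PairingError

logger = logging.getLogger(__name__)

LOG_FLOOR = 1.0  # corrected intensities are floored here before log2
REFERENCE_EXPOSURE_MS = 100.0
DEFAULT_THRESHOLD_FRACTION = 0.30

_ARRAY_KEYS = [
    "plate_id",
    "strip_id",
    "array_id",
    "sample_id",
    "atp_present",
    "treatment",
    "replicate_id",
]


@dataclass
class SignalMatrix:
    """Samples x peptides matrix of processed log2 kinase-activity signal."""

    values: pd.DataFrame
    provenance: list[str] = field(default_factory=list)

    @property
    def sample_ids(self) -> list:
        return list(self.values.index)

    @property
    def peptide_ids(self) -> list:
        return list(self.values.columns)


@dataclass
class LfcMatrix:
    """Samples x peptides matrix of inhibitor-vs-control log fold changes."""

    values: pd.DataFrame
    inhibitor: str
    concentration: float | None = None


def net_signal(intensity, local_background, floor: float = LOG_FLOOR):
    """Background-corrected spot intensity, floored.

    Scalar or array-valued; both inputs must be nonnegative.
    """
    intensity = np.asarray(intensity, dtype=float)
    local_background = np.asarray(local_background, dtype=float)
    if np.any(intensity < 0) or np.any(local_background < 0):
        raise InvalidArgumentError("intensity and local_background must be >= 0")
    out = np.maximum(intensity - local_background, floor)
    return float(out) if out.ndim == 0 else out


def integrate_exposures(series, reference_exposure_ms: float = REFERENCE_EXPOSURE_MS) -> float:
    """Collapse a (exposure time, net signal) ladder into one value.

    Fits the through-origin least-squares slope of net signal versus
    exposure time and evaluates it at the reference exposure; exact for
    signals linear in exposure time.
    """
    pairs = [(float(t), float(y)) for t, y in series]
    times = np.array([t for t, _ in pairs])
    if len(set(times)) < 2:
        raise InvalidArgumentError("need >= 2 distinct exposure times to integrate")
    ys = np.array([y for _, y in pairs])
    slope = float(times @ ys) / float(times @ times)
    return slope * reference_exposure_ms


def integrate_spot_table(
    spot: pd.DataFrame, reference_exposure_ms: float = REFERENCE_EXPOSURE_MS
) -> pd.DataFrame:
    """Net + integrate every spot series: one row per (array, peptide).

    Vectorized equivalent of applying :func:`net_signal` and
    :func:`integrate_exposures` per spot.
    """
    d = spot.copy()
    net = net_signal(d["intensity"].to_numpy(), d["local_background"].to_numpy())
    t = d["exposure_time_ms"].to_numpy(dtype=float)
    d["_ty"] = net * t
    d["_t2"] = t * t
    d["_nt"] = d["exposure_time_ms"]
    keys = _ARRAY_KEYS + ["peptide_id"]
    g = d.groupby(keys, sort=False, observed=True).agg(
        _ty=("_ty", "sum"), _t2=("_t2", "sum"), _n=("_nt", "nunique")
    )
    if (g["_n"] < 2).any():
        bad = g.index[g["_n"] < 2][0]
        raise InvalidArgumentError(
            f"spot {bad} was imaged at fewer than 2 distinct exposure times"
        )
    out = (g["_ty"] / g["_t2"] * reference_exposure_ms).rename("value").reset_index()
    return out


def _pivot_arrays(integrated: pd.DataFrame) -> pd.DataFrame:
    """Long integrated table -> arrays x peptides wide table (meta in index)."""
    return integrated.set_index(_ARRAY_KEYS + ["peptide_id"])["value"].unstack("peptide_id")


def atp_corrected_arrays(plate_integrated: pd.DataFrame) -> pd.DataFrame:
    """Per with-ATP array on one plate: integrated value minus the mean of
    the same sample's no-ATP integrated values on that plate."""
    wide = _pivot_arrays(plate_integrated)
    atp = wide.index.get_level_values("atp_present").astype(bool)
    with_atp = wide[atp]
    no_atp = wide[~atp]
    no_atp_mean = no_atp.groupby(level="sample_id").mean()
    plate_id = wide.index.get_level_values("plate_id")[0]
    for sample in with_atp.index.get_level_values("sample_id").unique():
        if sample not in no_atp_mean.index:
            raise MissingControlError(str(sample), str(plate_id))
    corr = with_atp.to_numpy() - no_atp_mean.loc[
        with_atp.index.get_level_values("sample_id")
    ].to_numpy()
    return pd.DataFrame(corr, index=with_atp.index, columns=with_atp.columns)


def atp_correct_and_log(
    plate_slice: pd.DataFrame, reference_exposure_ms: float = REFERENCE_EXPOSURE_MS
) -> pd.DataFrame:
    """One plate's spots -> per-(sample, replicate) log2 values.

    ATP duplicates are averaged *after* the no-ATP correction, then floored
    at 1.0 and log2-transformed.
    """
    integrated = integrate_spot_table(plate_slice, reference_exposure_ms)
    corrected = atp_corrected_arrays(integrated)
    by_sample = corrected.groupby(level=["sample_id", "replicate_id"]).mean()
    return np.log2(np.maximum(by_sample, LOG_FLOOR))


def normalize_plates(values: pd.DataFrame, plate_labels: pd.Series) -> pd.DataFrame:
    """Equalize per-plate medians: subtract each plate's median over all of
    its cells and add back the grand median over all cells."""
    if values.size == 0:
        raise InvalidArgumentError("cannot normalize an empty matrix")
    plate_labels = pd.Series(np.asarray(plate_labels), index=values.index)
    grand = float(np.nanmedian(values.to_numpy()))
    out = values.copy()
    for plate, rows in values.groupby(plate_labels):
        med = float(np.nanmedian(rows.to_numpy()))
        out.loc[rows.index] = rows - med + grand
    return out


def average_replicates(values: pd.DataFrame) -> pd.DataFrame:
    """Average replicate rows (different plates) per biological sample.

    Expects a (sample_id, replicate_id) row MultiIndex; missing replicate
    cells are ignored, not imputed, and all-missing cells are logged.
    """
    out = values.groupby(level="sample_id", sort=False).mean()
    n_missing = int(out.isna().to_numpy().sum())
    if n_missing:
        logger.warning("%d sample/peptide cells have no non-missing replicate", n_missing)
    return out


def filter_peptides(
    corrected_arrays: pd.DataFrame,
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
) -> tuple[list, pd.DataFrame]:
    """Keep peptides whose ATP-corrected signal increases on strictly more
    than ``threshold_fraction`` of the with-ATP arrays.

    ``corrected_arrays`` is the arrays x peptides matrix of ATP-minus-no-ATP
    values across *all* plates. Returns the kept peptide ids and a per-
    peptide report.
    """
    if corrected_arrays.shape[0] == 0:
        raise InvalidArgumentError("no with-ATP arrays to filter on")
    frac = (corrected_arrays > 0).mean(axis=0)
    report = pd.DataFrame(
        {
            "peptide_id": corrected_arrays.columns,
            "fraction_increasing": frac.to_numpy(),
            "atp_dependent": (frac > 0).to_numpy(),
            "kept": (frac > threshold_fraction).to_numpy(),
        }
    )
    kept = list(report.loc[report["kept"], "peptide_id"])
    return kept, report


def process_cohort(
    spot: pd.DataFrame,
    reference_exposure_ms: float = REFERENCE_EXPOSURE_MS,
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
    apply_filter: bool = True,
) -> tuple[SignalMatrix, pd.DataFrame]:
    """Full basal-cohort pipeline: spots -> filtered log2 SignalMatrix.

    Returns the processed matrix (one row per sample, filtered columns if
    ``apply_filter``) and the peptide filter report.
    """
    integrated = integrate_spot_table(spot, reference_exposure_ms)
    per_plate_logs = []
    plate_of_row = []
    corrected_all = []
    for plate, sub in integrated.groupby("plate_id", sort=False):
        corrected = atp_corrected_arrays(sub)
        corrected_all.append(corrected.reset_index(drop=True))
        by_sample = corrected.groupby(level=["sample_id", "replicate_id"]).mean()
        logs = np.log2(np.maximum(by_sample, LOG_FLOOR))
        per_plate_logs.append(logs)
        plate_of_row.extend([plate] * len(logs))
    stacked = pd.concat(per_plate_logs)
    normalized = normalize_plates(stacked, pd.Series(plate_of_row, index=stacked.index))
    averaged = average_replicates(normalized)
    corrected_arrays = pd.concat(corrected_all, ignore_index=True)
    kept, report = filter_peptides(corrected_arrays, threshold_fraction)
    values = averaged[kept] if apply_filter else averaged
    provenance = [
        "net_signal: local background subtracted, floor 1.0",
        f"integrate_exposures: through-origin OLS slope at {reference_exposure_ms:g} ms",
        "atp_correct: minus same-plate no-ATP mean; duplicates averaged; log2(max(x, 1))",
        "normalize_plates: per-plate median equalized to grand median",
        "average_replicates: mean across plates per sample",
        f"filter_peptides: kept {len(kept)}/{report.shape[0]} at fraction > {threshold_fraction:g}",
    ]
    return SignalMatrix(values=values, provenance=provenance), report


def compute_lfc(
    spot: pd.DataFrame, reference_exposure_ms: float = REFERENCE_EXPOSURE_MS
) -> LfcMatrix:
    """Paired control/inhibitor strips -> per-sample LFC matrix.

    Per strip and peptide, LFC = log2(inhibitor net signal, floored) minus
    log2(control net signal, floored); technical-replicate strips of the
    same sample are averaged. Values are intentionally un-normalized: the
    paired arrays share a strip, so plate effects cancel.
    """
    integrated = integrate_spot_table(spot, reference_exposure_ms)
    wide = _pivot_arrays(integrated)
    logs = np.log2(np.maximum(wide, LOG_FLOOR))
    treatments = logs.index.get_level_values("treatment")
    inhibitors = sorted(set(treatments) - {"none"})
    if len(inhibitors) != 1:
        raise InvalidArgumentError(
            f"expected exactly one inhibitor treatment, found {inhibitors or 'none'}"
        )
    inhibitor = inhibitors[0]

    per_strip = []
    strip_samples = []
    for strip, sub in logs.groupby(level="strip_id", sort=False):
        treats = list(sub.index.get_level_values("treatment"))
        if sorted(treats) != sorted(["none", inhibitor]):
            raise PairingError(str(strip), f"treatments on strip: {treats}")
        ctl = sub.xs("none", level="treatment")
        inh = sub.xs(inhibitor, level="treatment")
        samples = set(sub.index.get_level_values("sample_id"))
        if len(samples) != 1:
            raise PairingError(str(strip), f"multiple samples on one strip: {sorted(samples)}")
        per_strip.append(inh.to_numpy()[0] - ctl.to_numpy()[0])
        strip_samples.append(samples.pop())
    lfc = pd.DataFrame(per_strip, index=strip_samples, columns=logs.columns)
    lfc.index.name = "sample_id"
    averaged = lfc.groupby(level="sample_id", sort=False).mean()
    return LfcMatrix(values=averaged, inhibitor=inhibitor)
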