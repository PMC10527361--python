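"""Synthetic peptide-microarray cohorts with known ground truth.

The generator emulates the structure of a flow-through peptide-array
(PamChip-style) kinase activity experiment: 96-array plates, each sample
incubated in duplicate with ATP plus once without ATP, the whole test
repeated on a second plate as an independent experiment, and inhibitor
runs in which control and treated incubations share a strip of adjacent
arrays so that plate effects cancel in their ratio.

Signal model
------------
The fluorescence of a spot imaged at CCD exposure time ``t`` is

    intensity = background + rate * t * plate_factor * noise_factor

where ``rate`` is the sample- and peptide-specific phosphorylation rate
(intensity units per ms), ``plate_factor = 2**N(0, plate_effect_sd)`` is a
single multiplicative plate effect, and ``noise_factor = 2**N(0, noise_sd)``
is a multiplicative log-normal spot noise shared across the exposure ladder
of one spot (the ladder re-images the same physical spot, so its kinetic
read stays exactly linear in ``t``).

A peptide mapped to kinases accrues rate ``baseline_rate * sum_k a[s, k]``
over its kinases' activities ``a[s, k]``; unmapped peptides carry a small
kinase-independent basal rate, a fraction of them none at all (these fail
the downstream ATP-dependence filter, as non-substrate peptides do on real
arrays). Malignant samples multiply the activity of the planted *active*
kinases by ``2**class_effect_size``; a specific inhibitor multiplies the
*targeted* kinases' activity by ``inhibitor_depth`` in mutation-positive
samples only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError

ARRAYS_PER_SAMPLE = 3  # duplicate with ATP + one no-ATP control
ARRAYS_PER_PLATE = 96
STRIP_SIZE = 4

# independent stream tags hung off the master seed
_TAG_MAP, _TAG_ACTIVITY, _TAG_BASAL, _TAG_PLATE, _TAG_NOISE, _TAG_META = range(6)


def _peptide_ids(n: int) -> list[str]:
    return [f"pep_{i:03d}" for i in range(1, n + 1)]


def _kinase_ids(n: int) -> list[str]:
    return [f"KIN_{i:02d}" for i in range(1, n + 1)]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a synthetic cohort or inhibitor run.

    Defaults mirror the study conditions: 21 benign + 34 malignant lysates
    on 240-peptide arrays for the basal cohort; use :meth:`inhibitor_defaults`
    for the 13-sample (7 mutation-positive + 6 negative) 140-peptide
    inhibitor experiment.
    """

    n_benign: int = 21
    n_malignant: int = 34
    n_peptides: int = 240
    n_kinases: int = 20
    substrates_per_kinase: int = 8
    exposure_times_ms: tuple[float, ...] = (10.0, 20.0, 50.0, 100.0, 200.0)
    n_plates: int = 2  # plates per replicate experiment; total plates = 2 * n_plates
    plate_effect_sd: float = 0.25  # log2 units
    baseline_rate: float = 3.0  # intensity units per ms per unit activity
    class_effect_size: float = 1.0  # log2 units on active kinases
    noise_sd: float = 0.25  # log2 units per spot
    nonspecific_fraction: float = 0.05  # residual no-ATP signal fraction
    inhibitor_depth: float = 0.5  # residual activity of targeted kinases
    seed: int = 0
    # secondary knobs
    background_level: float = 50.0  # intensity units
    kinase_activity_sd: float = 0.25  # log2 units, biological variability
    n_active_kinases: int = 3
    n_targeted_kinases: int = 1
    nonspecific_inhibitor_factor: float = 0.8  # mild generic inhibition
    inactive_peptide_fraction: float = 0.3  # of unmapped peptides, no signal at all
    basal_rate_range: tuple[float, float] = (0.05, 0.2)  # unmapped-peptide activity units
    n_braf_positive: int = 7
    n_braf_negative: int = 6
    n_inhibitor_replicates: int = 2  # technical replicate strips per sample

    def __post_init__(self):
        counts = {
            "n_benign": self.n_benign,
            "n_malignant": self.n_malignant,
            "n_peptides": self.n_peptides,
            "n_kinases": self.n_kinases,
            "substrates_per_kinase": self.substrates_per_kinase,
            "n_plates": self.n_plates,
        }
        for name, v in counts.items():
            if v < 1:
                raise InvalidArgumentError(f"{name} must be >= 1, got {v}")
        times = tuple(self.exposure_times_ms)
        if len(times) < 2 or any(t <= 0 for t in times):
            raise InvalidArgumentError("exposure_times_ms must hold >= 2 positive durations")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise InvalidArgumentError("exposure_times_ms must be strictly increasing")
        if not (0 < self.inhibitor_depth <= 1):
            raise InvalidArgumentError("inhibitor_depth must lie in (0, 1]")
        if self.noise_sd < 0:
            raise InvalidArgumentError("noise_sd must be >= 0")
        if not (0 <= self.nonspecific_fraction < 1):
            raise InvalidArgumentError("nonspecific_fraction must lie in [0, 1)")

    @classmethod
    def inhibitor_defaults(cls, **overrides) -> "SimulationConfig":
        """Study conditions of the ex vivo RAF-inhibitor experiment."""
        base = dict(n_peptides=140, n_kinases=12, n_plates=2)
        base.update(overrides)
        return cls(**base)

    def with_(self, **overrides) -> "SimulationConfig":
        return replace(self, **overrides)


@dataclass
class GroundTruth:
    """Planted values recorded for parameter-recovery tests.

    ``peptide_rates`` holds the true control-condition phosphorylation rate
    (intensity per ms) per sample and peptide, before plate effects and
    noise; ``peptide_rates_inhibited`` is present for inhibitor runs.
    """

    kinase_activity: pd.DataFrame  # samples x kinases, strictly positive
    active_kinases: set[str]
    targeted_kinases: set[str]
    peptide_rates: pd.DataFrame  # samples x peptides, >= 0
    peptide_rates_inhibited: pd.DataFrame | None = None


def simulate_kinase_map(
    n_kinases: int,
    n_peptides: int,
    substrates_per_kinase: int,
    seed: int,
) -> pd.DataFrame:
    """Draw a kinase -> substrate-peptide mapping with confidence ranks.

    Each kinase receives exactly ``substrates_per_kinase`` distinct peptides,
    ranked 1..k by decreasing mapping confidence. Peptides are dealt from a
    shuffled global pool without replacement while the pool lasts, so maps
    are disjoint whenever ``n_kinases * substrates_per_kinase <= n_peptides``;
    beyond that peptides serve multiple kinases, as shared phosphosites do.
    """
    if substrates_per_kinase > n_peptides:
        raise InvalidArgumentError(
            f"substrates_per_kinase ({substrates_per_kinase}) exceeds n_peptides ({n_peptides})"
        )
    rng = np.random.default_rng([seed, _TAG_MAP])
    peptides = _peptide_ids(n_peptides)
    deck: list[int] = list(rng.permutation(n_peptides))
    n_db = max(1, round(0.75 * substrates_per_kinase))
    rows = []
    for kin in _kinase_ids(n_kinases):
        subs: list[int] = []
        while len(subs) < substrates_per_kinase:
            if not deck:
                deck = list(rng.permutation(n_peptides))
            cand = deck.pop()
            if cand not in subs:
                subs.append(cand)
        for rank, p in enumerate(subs, start=1):
            rows.append(
                (kin, peptides[p], rank, "database" if rank <= n_db else "theoretical")
            )
    return pd.DataFrame(rows, columns=["kinase_id", "peptide_id", "rank", "source"])


def _check_map(config: SimulationConfig, kmap: pd.DataFrame) -> None:
    universe = set(_peptide_ids(config.n_peptides))
    extra = set(kmap["peptide_id"]) - universe
    if extra:
        raise InvalidArgumentError(
            f"kinase map references peptides outside the configured array: {sorted(extra)[:5]}"
        )


def _base_activities(
    config: SimulationConfig, sample_ids: Sequence[str], kinases: Sequence[str]
) -> pd.DataFrame:
    rng = np.random.default_rng([config.seed, _TAG_ACTIVITY])
    logs = rng.normal(0.0, config.kinase_activity_sd, size=(len(sample_ids), len(kinases)))
    return pd.DataFrame(2.0 ** logs, index=list(sample_ids), columns=list(kinases))


def _peptide_basal(config: SimulationConfig, mapped: set[str]) -> pd.Series:
    """Kinase-independent basal rate for unmapped peptides (0 for a fraction)."""
    rng = np.random.default_rng([config.seed, _TAG_BASAL])
    peptides = _peptide_ids(config.n_peptides)
    lo, hi = config.basal_rate_range
    basal = rng.uniform(lo, hi, size=config.n_peptides)
    dead = rng.random(config.n_peptides) < config.inactive_peptide_fraction
    basal[dead] = 0.0
    out = pd.Series(basal, index=peptides)
    out[out.index.isin(mapped)] = 0.0
    return out


def _rates_from_activity(
    config: SimulationConfig, kmap: pd.DataFrame, activity: pd.DataFrame
) -> pd.DataFrame:
    """True rate matrix (samples x peptides): kinase-driven plus basal."""
    peptides = _peptide_ids(config.n_peptides)
    weight = pd.DataFrame(
        0.0, index=activity.columns, columns=peptides
    )  # kinases x peptides
    for kin, pep in zip(kmap["kinase_id"], kmap["peptide_id"]):
        weight.loc[kin, pep] = 1.0
    basal = _peptide_basal(config, set(kmap["peptide_id"]))
    rates = activity.to_numpy() @ weight.to_numpy() + basal.to_numpy()[None, :]
    return pd.DataFrame(
        config.baseline_rate * rates, index=activity.index, columns=peptides
    )


def _noise_factor(
    config: SimulationConfig, plate_idx: int, array_idx: int
) -> np.ndarray:
    """Per-peptide multiplicative noise for one array, reproducible in isolation."""
    rng = np.random.default_rng([config.seed, _TAG_NOISE, plate_idx, array_idx])
    if config.noise_sd == 0:
        return np.ones(config.n_peptides)
    return 2.0 ** rng.normal(0.0, config.noise_sd, size=config.n_peptides)


def _plate_factors(config: SimulationConfig, n_total_plates: int) -> np.ndarray:
    rng = np.random.default_rng([config.seed, _TAG_PLATE])
    if config.plate_effect_sd == 0:
        return np.ones(n_total_plates)
    return 2.0 ** rng.normal(0.0, config.plate_effect_sd, size=n_total_plates)


def _emit_spots(
    config: SimulationConfig,
    arrays: pd.DataFrame,
    rates_per_array: np.ndarray,
    plate_factors: dict[str, float],
) -> pd.DataFrame:
    """Expand an array table into the long spot-quantification table.

    ``arrays`` carries one row per physical array with its metadata and a
    global ``plate_idx``/``array_idx`` used to key the noise stream;
    ``rates_per_array`` is (n_arrays, n_peptides).
    """
    peptides = _peptide_ids(config.n_peptides)
    times = np.asarray(config.exposure_times_ms, dtype=float)
    n_arr, n_pep, n_t = len(arrays), len(peptides), len(times)

    noise = np.stack(
        [
            _noise_factor(config, int(r.plate_idx), int(r.array_idx))
            for r in arrays.itertuples()
        ]
    )
    pf = np.array([plate_factors[p] for p in arrays["plate_id"]])
    slope = rates_per_array * pf[:, None] * noise  # (arrays, peptides)
    intensity = config.background_level + slope[:, :, None] * times[None, None, :]

    meta = arrays.drop(columns=["plate_idx", "array_idx"])
    out = meta.loc[meta.index.repeat(n_pep * n_t)].reset_index(drop=True)
    out["peptide_id"] = np.tile(np.repeat(peptides, n_t), n_arr)
    out["exposure_time_ms"] = np.tile(times, n_arr * n_pep)
    out["intensity"] = intensity.reshape(-1)
    out["local_background"] = config.background_level
    return out


def _cohort_layout(config: SimulationConfig, sample_ids: Sequence[str]) -> pd.DataFrame:
    """Assign each sample 2 with-ATP + 1 no-ATP array per plate, on two
    replicate plates, interleaving classes so plates stay balanced."""
    per_plate = ARRAYS_PER_PLATE // ARRAYS_PER_SAMPLE
    if config.n_plates * per_plate < len(sample_ids):
        raise InvalidArgumentError(
            f"{len(sample_ids)} samples need more than {config.n_plates} plates "
            f"({per_plate} samples per 96-array plate)"
        )
    rows = []
    for rep in (1, 2):
        for i, sample in enumerate(sample_ids):
            plate_no = (rep - 1) * config.n_plates + (i % config.n_plates) + 1
            slot = (i // config.n_plates) * ARRAYS_PER_SAMPLE
            plate_id = f"P{plate_no}"
            plate_idx = plate_no - 1
            for j, atp in enumerate((True, True, False)):
                pos = slot + j
                rows.append(
                    {
                        "plate_id": plate_id,
                        "strip_id": f"{plate_id}:S{pos // STRIP_SIZE + 1:02d}",
                        "array_id": f"{plate_id}:A{pos + 1:02d}",
                        "sample_id": sample,
                        "atp_present": atp,
                        "treatment": "none",
                        "replicate_id": rep,
                        "plate_idx": plate_idx,
                        "array_idx": pos,
                    }
                )
    return pd.DataFrame(rows)


def simulate_cohort(
    config: SimulationConfig, kmap: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate the basal benign/malignant cohort.

    Returns the long spot-quantification table, the sample sheet, and the
    planted ground truth. Deterministic for a fixed config (which includes
    the seed).
    """
    _check_map(config, kmap)
    kinases = _kinase_ids(config.n_kinases)
    if not set(kmap["kinase_id"]) <= set(kinases):
        raise InvalidArgumentError("kinase map references kinases outside the config")

    benign = [f"S{i:02d}" for i in range(1, config.n_benign + 1)]
    malignant = [
        f"S{i:02d}" for i in range(config.n_benign + 1, config.n_benign + config.n_malignant + 1)
    ]
    # interleave so "benign and malignant samples were equally distributed over the plates"
    order: list[str] = []
    for i in range(max(len(benign), len(malignant))):
        if i < len(benign):
            order.append(benign[i])
        if i < len(malignant):
            order.append(malignant[i])

    rng_meta = np.random.default_rng([config.seed, _TAG_META])
    active = {str(k) for k in rng_meta.choice(kinases, size=config.n_active_kinases, replace=False)}

    activity = _base_activities(config, order, kinases)
    for kin in sorted(active):
        activity.loc[malignant, kin] *= 2.0 ** config.class_effect_size
    rates = _rates_from_activity(config, kmap, activity)

    sheet = pd.DataFrame(
        {
            "sample_id": order,
            "class_label": ["benign" if s in benign else "malignant" for s in order],
        }
    )
    is_mal = (sheet["class_label"] == "malignant").to_numpy()
    sheet["braf_v600e"] = is_mal & (rng_meta.random(len(sheet)) < 0.3)
    sheet["recurrent"] = is_mal & (rng_meta.random(len(sheet)) < 0.25)

    arrays = _cohort_layout(config, order)
    rate_rows = rates.loc[arrays["sample_id"]].to_numpy()
    rate_rows = np.where(
        arrays["atp_present"].to_numpy()[:, None],
        rate_rows,
        config.nonspecific_fraction * rate_rows,
    )
    plate_factors = {
        f"P{i + 1}": f for i, f in enumerate(_plate_factors(config, 2 * config.n_plates))
    }
    spots = _emit_spots(config, arrays, rate_rows, plate_factors)
    truth = GroundTruth(
        kinase_activity=activity,
        active_kinases=active,
        targeted_kinases=set(),
        peptide_rates=rates,
    )
    return spots, sheet, truth


def simulate_inhibitor_run(
    config: SimulationConfig, kmap: pd.DataFrame, specific: bool = True
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate paired control/inhibitor incubations on shared strips.

    With ``specific`` set, the inhibitor multiplies the targeted kinases'
    activity by ``inhibitor_depth`` in mutation-positive samples only (the
    dabrafenib analogue); otherwise it multiplies every kinase's activity by
    ``nonspecific_inhibitor_factor`` in all samples (sorafenib/regorafenib
    analogue).
    """
    _check_map(config, kmap)
    kinases = _kinase_ids(config.n_kinases)
    n = config.n_braf_positive + config.n_braf_negative
    samples = [f"T{i:02d}" for i in range(1, n + 1)]
    positive = set(samples[: config.n_braf_positive])

    rng_meta = np.random.default_rng([config.seed, _TAG_META])
    targeted = {str(k) for k in rng_meta.choice(kinases, size=config.n_targeted_kinases, replace=False)}

    activity = _base_activities(config, samples, kinases)
    rates_ctl = _rates_from_activity(config, kmap, activity)
    if specific:
        inhibited = activity.copy()
        for kin in sorted(targeted):
            inhibited.loc[sorted(positive), kin] *= config.inhibitor_depth
        rates_inh = _rates_from_activity(config, kmap, inhibited)
        treatment_name = "dabrafenib"
    else:
        # a pan-kinase inhibitor also hits the unmodeled kinases behind the
        # basal rate of unmapped peptides, so the whole rate matrix scales
        inhibited = activity * config.nonspecific_inhibitor_factor
        rates_inh = rates_ctl * config.nonspecific_inhibitor_factor
        treatment_name = "sorafenib"

    sheet = pd.DataFrame(
        {
            "sample_id": samples,
            "class_label": "malignant",
            "braf_v600e": [s in positive for s in samples],
            "recurrent": rng_meta.random(n) < 0.5,
        }
    )

    strips_per_plate = ARRAYS_PER_PLATE // STRIP_SIZE
    rows = []
    strip_no = 0
    for rep in range(1, config.n_inhibitor_replicates + 1):
        for sample in samples:
            plate_no = strip_no // strips_per_plate + 1
            within = strip_no % strips_per_plate
            plate_id = f"P{plate_no}"
            strip_id = f"{plate_id}:S{within + 1:02d}"
            for j, treat in enumerate(("none", treatment_name)):
                pos = within * STRIP_SIZE + j
                rows.append(
                    {
                        "plate_id": plate_id,
                        "strip_id": strip_id,
                        "array_id": f"{plate_id}:A{pos + 1:02d}",
                        "sample_id": sample,
                        "atp_present": True,
                        "treatment": treat,
                        "replicate_id": rep,
                        "plate_idx": plate_no - 1,
                        "array_idx": pos,
                    }
                )
            strip_no += 1
    arrays = pd.DataFrame(rows)

    ctl = rates_ctl.loc[arrays["sample_id"]].to_numpy()
    inh = rates_inh.loc[arrays["sample_id"]].to_numpy()
    rate_rows = np.where((arrays["treatment"] == "none").to_numpy()[:, None], ctl, inh)
    n_plates_used = arrays["plate_idx"].max() + 1
    plate_factors = {
        f"P{i + 1}": f for i, f in enumerate(_plate_factors(config, int(n_plates_used)))
    }
    spots = _emit_spots(config, arrays, rate_rows, plate_factors)
    truth = GroundTruth(
        kinase_activity=activity,
        active_kinases=set(),
        targeted_kinases=targeted,
        peptide_rates=rates_ctl,
        peptide_rates_inhibited=rates_inh,
    )
    return spots, sheet, truth


def simulate_signal_matrix(
    n_group1: int,
    n_group2: int,
    n_peptides: int,
    informative_peptides: Iterable[int] | int = 0,
    shift: float = 0.0,
    noise_sd: float = 1.0,
    seed: int = 0,
    group_names: tuple[str, str] = ("benign", "malignant"),
) -> tuple[pd.DataFrame, pd.Series]:
    """Gaussian samples-x-peptides matrix with a planted group shift.

    A direct matrix-level generator for classifier and kinase-scoring tests:
    unit-variance noise means ``shift`` is the standardized effect size on
    the informative peptides (added to group 2). ``informative_peptides``
    is either a count (the first k columns) or explicit column indices.
    """
    rng = np.random.default_rng(seed)
    n = n_group1 + n_group2
    X = rng.normal(0.0, noise_sd, size=(n, n_peptides))
    if isinstance(informative_peptides, (int, np.integer)):
        idx = np.arange(int(informative_peptides))
    else:
        idx = np.asarray(list(informative_peptides), dtype=int)
    if idx.size:
        X[n_group1:, idx] += shift
    samples = [f"S{i:02d}" for i in range(1, n + 1)]
    values = pd.DataFrame(X, index=samples, columns=_peptide_ids(n_peptides))
    labels = pd.Series(
        [group_names[0]] * n_group1 + [group_names[1]] * n_group2,
        index=samples,
        name="class_label",
    )
    return values, labels
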