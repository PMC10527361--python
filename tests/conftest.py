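import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from kinaprof import simulate as sim

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_config():
    return sim.SimulationConfig(
        n_benign=6,
        n_malignant=6,
        n_peptides=40,
        n_kinases=4,
        substrates_per_kinase=5,
        n_plates=1,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_map(small_config):
    c = small_config
    return sim.simulate_kinase_map(c.n_kinases, c.n_peptides, c.substrates_per_kinase, c.seed)


@pytest.fixture(scope="session")
def small_cohort(small_config, small_map):
    spot, sheet, truth = sim.simulate_cohort(small_config, small_map)
    return spot, sheet, truth


def spot_rows(meta: dict, values: dict, times=(100.0, 200.0), background=10.0):
    """Hand-built spot series whose integrated value (through-origin slope
    at 100 ms) equals exactly the requested value, for values >= 1."""
    rows = []
    for pep, v in values.items():
        for t in times:
            rows.append(
                {
                    **meta,
                    "peptide_id": pep,
                    "exposure_time_ms": t,
                    "intensity": background + v * t / 100.0,
                    "local_background": background,
                }
            )
    return rows


def make_spot_table(arrays):
    """arrays: list of (meta dict, {peptide: integrated value}) pairs."""
    rows = []
    for meta, values in arrays:
        rows.extend(spot_rows(meta, values))
    return pd.DataFrame(rows)


def array_meta(
    plate="P1",
    strip="P1:S01",
    array="P1:A01",
    sample="S01",
    atp=True,
    treatment="none",
    replicate=1,
):
    return {
        "plate_id": plate,
        "strip_id": strip,
        "array_id": array,
        "sample_id": sample,
        "atp_present": atp,
        "treatment": treatment,
        "replicate_id": replicate,
    }
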