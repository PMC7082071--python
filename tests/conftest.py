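import numpy as np
import pandas as pd
import pytest

from homrec.datatypes import GenotypeMatrix, make_marker_map, make_sample_table
from homrec.simulate import SimulationConfig, simulate_breed_population


@pytest.fixture(scope="session")
def sim_default():
    """One default-condition simulated cohort shared across tests."""
    return simulate_breed_population(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def sim_discordant():
    """Cohort guaranteed to carry a risk-homozygous, causal-free control."""
    cfg = SimulationConfig(seed=5, recent_fraction=0.5, n_controls=80)
    return simulate_breed_population(cfg)


def build_gm(dosage, chroms=None, positions=None, sex=None, sample_ids=None):
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    chroms = chroms or ["1"] * m
    positions = positions or [100 * (j + 1) for j in range(m)]
    markers = make_marker_map([f"m{j + 1}" for j in range(m)], chroms, positions)
    sample_ids = sample_ids or [f"s{i + 1}" for i in range(n)]
    sex = sex or ["female"] * n
    return GenotypeMatrix(sample_ids, markers, dosage, np.array(sex, dtype=object))


def build_samples(gm, statuses, obligate=None):
    return make_sample_table(gm.samples, list(gm.sex), statuses, obligate)
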