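import numpy as np
import pandas as pd
import pytest

from acghcall import SimConfig, simulate_cohort
from acghcall.profiles import AcghProfileSet


def make_profileset(columns: dict[str, np.ndarray], chromosome: int = 1,
                    spacing: int = 1_000_000) -> AcghProfileSet:
    """Single-chromosome profile set from named value vectors."""
    n = len(next(iter(columns.values())))
    probes = pd.DataFrame(
        {"chromosome": [chromosome] * n, "position": (np.arange(n) + 1) * spacing},
        index=[f"p{i:05d}" for i in range(n)],
    )
    values = pd.DataFrame({k: np.asarray(v, dtype=float) for k, v in columns.items()},
                          index=probes.index)
    return AcghProfileSet(probes, values)


@pytest.fixture(scope="session")
def small_cohort():
    """Small noisy two-group cohort shared across tests."""
    return simulate_cohort(SimConfig(seed=11, n_per_group=6, n_chromosomes=3,
                                     probes_per_chromosome=80,
                                     n_candidate_aberrations=12))


@pytest.fixture(scope="session")
def clean_cohort():
    """Noise- and wave-free cohort with no 1-2 probe truth slivers and the
    copy-neutral state modal in every sample (so mode normalization is a
    no-op and recovery can be exact)."""
    return simulate_cohort(SimConfig(seed=0, noise_sd=0.0, wave_amplitude=0.0,
                                     n_per_group=3, n_chromosomes=3,
                                     n_candidate_aberrations=10))
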