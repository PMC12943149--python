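import hypothesis
import numpy as np
import pandas as pd
import pytest

from tdp.simulate import default_config, generate

hypothesis.settings.register_profile("deterministic", derandomize=True, deadline=None)
hypothesis.settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_cohort():
    """Default-noise cohort, n=300, fixed seed — shared across tests."""
    return generate(default_config(n_participants=300, seed=42))


@pytest.fixture(scope="session")
def low_noise_cohort():
    """Archetype-shape cohort for clustering-recovery tests."""
    return generate(default_config(n_participants=300, seed=7, low_noise=True))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def occasions_frame(rows):
    """rows: (person_id, type, minutes, kcal[, protein])"""
    recs = []
    for r in rows:
        pid, kind, minutes, kcal = r[:4]
        protein = r[4] if len(r) > 4 else kcal * 0.04
        recs.append({"person_id": pid, "occasion_type": kind,
                     "clock_min": minutes, "energy_kcal": kcal, "protein_g": protein})
    return pd.DataFrame(recs)
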