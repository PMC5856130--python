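import numpy as np
import pandas as pd
import pytest

from popkld.families import get_family


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_patient_table(family_name, latents, n_obs, lab_name="lab", seed=0):
    """Long-format table with one row per value, from per-patient params."""
    fam = get_family(family_name)
    rng = np.random.default_rng(seed)
    rows = []
    for i, params in enumerate(latents):
        vals = fam.sample(params, n_obs, rng)
        pid = f"p{i:04d}"
        rows.extend((pid, lab_name, v) for v in vals)
    return pd.DataFrame(rows, columns=["patient_id", "lab_name", "value"])


@pytest.fixture
def normal_patient_table():
    """200 patients x 30 draws from normal(mu_i, sigma_i), known latents."""
    rng = np.random.default_rng(7)
    mus = rng.normal(100.0, 15.0, size=200)
    sigmas = np.abs(rng.normal(12.0, 2.0, size=200)) + 1.0
    latents = list(zip(mus, sigmas))
    table = make_patient_table("normal", latents, n_obs=30, seed=11)
    return table, np.asarray(mus), np.asarray(sigmas)
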