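"""Shared fixtures: one synthetic world, reused across the suite.

The expensive objects (noise-free truth, a Zi-scale noisy realization, the
cold least-squares fits) are session-scoped so every test file can lean on
them without re-solving.
"""

import numpy as np
import pytest

from idminc import fit, generate_dataset, generate_truth
from idminc.synthetic import (
    DEFAULT_GOMPERTZ,
    DEFAULT_TRUE_INC,
    DEFAULT_TRUE_MRR,
    SyntheticConfig,
)


@pytest.fixture(scope="session")
def true_params():
    """Generating truths of the synthetic world (per-sex point estimates)."""
    return {
        sex: {
            "inc": DEFAULT_TRUE_INC[sex],
            "mrr": DEFAULT_TRUE_MRR[sex],
            "gompertz": DEFAULT_GOMPERTZ[sex],
        }
        for sex in ("male", "female")
    }


@pytest.fixture(scope="session")
def synth_truth():
    """(noise-free prevalence DataFrame, mortality table)."""
    return generate_truth(SyntheticConfig(noise="none"))


@pytest.fixture(scope="session")
def synth_noisy():
    """One binomial-noise realization at Zi-scale denominators, seed 1."""
    observed, table, manifest = generate_dataset(SyntheticConfig(seed=1))
    return observed, table


@pytest.fixture(scope="session")
def hazards(synth_truth):
    _, table = synth_truth
    return {sex: table.hazard(sex, 2013.5) for sex in ("male", "female")}


@pytest.fixture(scope="session")
def noisy_fits(synth_noisy, hazards):
    """Cold fits (with restarts) to the noisy data, per sex."""
    observed, _ = synth_noisy
    return {
        sex: fit(observed[observed["sex"] == sex], hazards[sex], seed=0)
        for sex in ("male", "female")
    }


@pytest.fixture(scope="session")
def noiseless_fits(synth_truth, hazards):
    """Cold fits to the noise-free truth, per sex (self-consistency)."""
    truth, _ = synth_truth
    return {
        sex: fit(truth[truth["sex"] == sex], hazards[sex], seed=0)
        for sex in ("male", "female")
    }
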