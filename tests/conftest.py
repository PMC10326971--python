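import numpy as np
import pandas as pd
import pytest

from erphagy import synthetic


@pytest.fixture(scope="session")
def paper_like():
    """One shared paper-like dataset, generated once per session."""
    return synthetic.paper_like_dataset(n_proteins=600, replicates=3, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_truth(protein_ids, baselines, steps, noise_sd=0.2):
    """Hand-built truth table for targeted scenarios (bypasses plant_effects,
    so noise_sd = 0 noiseless limits are expressible)."""
    steps = np.atleast_2d(np.asarray(steps, dtype=float))
    return pd.DataFrame(
        {
            "protein_id": list(protein_ids),
            "baseline_log2": np.asarray(baselines, dtype=float),
            "step1": steps[:, 0],
            "step2": steps[:, 1],
            "step3": steps[:, 2],
            "step4": steps[:, 3],
            "atg12_effect": steps.sum(axis=1),
            "noise_sd": noise_sd,
        }
    )
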