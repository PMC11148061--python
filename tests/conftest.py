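"""Shared fixtures: one small seeded screen reused across module tests."""

import numpy as np
import pandas as pd
import pytest

from epiperturb import mfa, perturbation, synthetic

SMALL_SEED = 5


@pytest.fixture(scope="session")
def small_screen():
    """400 CREs, 8 inhibitors, 4 programs — fast but structurally complete."""
    wiring = synthetic.generate_wiring(400, 8, 6, 4, seed=SMALL_SEED)
    mts, truth = synthetic.generate_counts(wiring, seed=SMALL_SEED)
    return wiring, mts, truth


@pytest.fixture(scope="session")
def small_std(small_screen):
    _, mts, _ = small_screen
    return mfa.standardize(mts, log2_transform=True)


@pytest.fixture(scope="session")
def small_mfa(small_std):
    res = mfa.mfa_fit(small_std)
    selected, pvals = mfa.select_dims(small_std, n_perm=100, seed=SMALL_SEED)
    res.selected_dims = selected or [0]
    res.perm_pvalues = pvals
    return res


@pytest.fixture(scope="session")
def small_scores(small_mfa, small_std):
    dist = perturbation.cre_distances(small_mfa)
    return perturbation.score_perturbations(dist, small_std)


@pytest.fixture(scope="session")
def noise_tables():
    """Pure i.i.d. noise multi-table set (no kinetic structure)."""
    rng = np.random.default_rng(0)
    return {f"T{i}": pd.DataFrame(rng.normal(size=(200, 5))) for i in range(6)}
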