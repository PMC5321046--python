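import numpy as np
import pytest

import splinepriors as sp

# fast constraints used where the defaults' sample-count minima would be
# overkill for a 60-subject phantom
FAST = sp.FitConstraints(penalty=1.0, cubic=False)


@pytest.fixture(scope="session")
def phantom():
    """Small frozen phantom cohort shared across the suite."""
    spec = sp.PhantomSpec(grid_size=10, n_subjects=60, sigma0=0.03, rng_seed=7)
    return sp.generate_cohort(spec)


@pytest.fixture(scope="session")
def design(phantom):
    table, _, _ = phantom
    return sp.build_design_matrix(table)


@pytest.fixture(scope="session")
def gm_global(phantom, design):
    _, stacks, _ = phantom
    return sp.fit_global_model(sp.compute_globals(stacks["GM"]), design, FAST)


@pytest.fixture(scope="session")
def fitted_all(phantom, design):
    """Option-2 model sets for all six classes (linear mode, fixed penalty)."""
    _, stacks, _ = phantom
    models = {}
    for lb in sp.TISSUE_CLASSES:
        g = sp.fit_global_model(sp.compute_globals(stacks[lb]), design, FAST)
        models[lb] = sp.fit_voxelwise(stacks[lb], design, FAST, option=2,
                                      global_models=g)
    return models
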