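import numpy as np
import pytest

import hemigrad as hg


@pytest.fixture(scope="session")
def small_parcellation():
    """16 regions (8 per hemisphere), 2 networks."""
    return hg.generate_parcellation(n_per_hemi=8, n_networks=2, seed=0)


@pytest.fixture(scope="session")
def seven_net_parcellation():
    return hg.generate_parcellation(n_per_hemi=32, n_networks=7, seed=0)


@pytest.fixture(scope="session")
def null_study():
    """Hemispherically symmetric cohort: no planted effects."""
    return hg.simulate_study(n_hc=12, n_sz=12, n_sites=2, n_per_hemi=8,
                             n_networks=2, n_timepoints=200, seed=5)


@pytest.fixture(scope="session")
def planted_study():
    """Cohort with a rightward DAN intra-G1 shift."""
    effects = [hg.EffectSpec("DAN", 1, "intra", -0.5)]
    return hg.simulate_study(n_hc=30, n_sz=30, n_sites=2, n_per_hemi=16,
                             n_timepoints=300, effects=effects, seed=7)


@pytest.fixture(scope="session")
def planted_results(planted_study):
    return hg.GradientAsymmetryAnalysis.from_study(planted_study).fit()


def random_affinity(n, rng):
    """Random symmetric affinity with unit diagonal, entries in (0, 1]."""
    A = rng.uniform(0.05, 1.0, size=(n, n))
    A = 0.5 * (A + A.T)
    np.fill_diagonal(A, 1.0)
    return A
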