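import numpy as np
import pytest

import protectomap as pm


@pytest.fixture(scope="session")
def geom60():
    """Small left-hemisphere geometry shared across tests."""
    return pm.generate_geometry(60, seed=7)


@pytest.fixture(scope="session")
def geom120():
    return pm.generate_geometry(120, seed=11)


@pytest.fixture(scope="session")
def small_cohort(geom60):
    """Balanced two-site cohort with a planted uniform sex-by-group effect."""
    cfg = pm.CohortConfig(
        n_patients_f=25, n_patients_m=25, n_controls_f=25, n_controls_m=25,
        n_regions=60, n_sites=2, site_shift=0.05, site_scale=1.1,
        atrophy_regions=frozenset(range(1, 16)), atrophy_gradient=(1.0, 1.0),
        atrophy_male=-0.3, atrophy_female=-0.1, noise_sd=0.1, seed=21)
    participants, thickness = pm.generate_cohort(cfg, geom60)
    return cfg, participants, thickness


def two_sample_t_p(a, b):
    from scipy import stats
    return stats.ttest_ind(a, b).pvalue


@pytest.fixture(scope="session")
def planted_pls_data(geom120):
    """Expression matrix with a planted set coupled to an interaction map."""
    ccfg = pm.CohortConfig(n_regions=120, atrophy_regions=frozenset(range(1, 31)),
                           seed=5)
    interaction = pm.true_interaction_map(ccfg, geom120)
    ecfg = pm.ExpressionConfig(n_genes=300, planted_set_size=20,
                               planted_coupling=0.8, seed=5)
    expr, planted = pm.generate_expression(ecfg, geom120, interaction)
    return expr, planted, interaction.to_numpy()
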