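import numpy as np
import pytest

from metsrisk.synthetic_cohort import SimulationConfig, simulate_cohort

ZERO_EXCLUSIONS = {
    "other_race": 0.0,
    "baseline_t2dm": 0.0,
    "baseline_chd": 0.0,
    "baseline_stroke": 0.0,
    "missing_components": 0.0,
    "non_fasting": 0.0,
    "no_followup": 0.0,
}


def clean_config(**overrides) -> SimulationConfig:
    """Default study conditions but without baseline exclusions."""
    cfg = SimulationConfig(exclusion_prevalences=dict(ZERO_EXCLUSIONS))
    for key, val in overrides.items():
        setattr(cfg, key, val)
    return cfg


@pytest.fixture(scope="session")
def big_cohort():
    """One large clean cohort shared by the marginal/recovery checks."""
    return simulate_cohort(clean_config(n_participants=20000, seed=101))


@pytest.fixture(scope="session")
def independent_cohort():
    """Cohort generated with all factor loadings zero (components independent),
    no covariate effects on CHD, and no random censoring; the Weibull scale is
    set so true 10-year survival is exactly 0.9."""
    cfg = clean_config(n_participants=20000, seed=202)
    cfg.latent_loadings = {
        g: {c: 0.0 for c in cfg.latent_loadings[g]} for g in cfg.latent_loadings
    }
    cfg.chd_hazard.beta_score = 0.0
    cfg.chd_hazard.beta_mets = 0.0
    cfg.chd_hazard.beta_interaction = 0.0
    cfg.chd_hazard.shape = 1.2
    cfg.chd_hazard.scale_years = 10.0 / (-np.log(0.9)) ** (1.0 / 1.2)
    cfg.censoring.dropout_rate_per_year = 0.0
    cfg.censoring.death_rate_per_year = 0.0
    return cfg, simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_default_cohort():
    """Default study conditions (exclusions included) at modest size."""
    return simulate_cohort(SimulationConfig(n_participants=3000, seed=5))
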