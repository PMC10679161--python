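import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from esmvar import (
    EsmDataset,
    SamplerSettings,
    build_time_grid,
    exclusion_filter,
    fit,
    simulate_study,
    specify_model,
    trivariate_study_params,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

VARIABLES2 = ("social_anxiety", "paranoia")

#: reduced sampler for test fits: 125 retained draws per chain
TEST_SAMPLER = SamplerSettings(chains=2, iterations=250, thin=1, burn_frac=0.5)


def make_panel(n_persons, n_cells, phi, sigma_w, mu, seed, keep_prob=1.0,
               variables=VARIABLES2):
    """Complete or randomly thinned equally spaced panel as an EsmDataset."""
    rng = np.random.default_rng(seed)
    k = len(mu)
    phi = np.asarray(phi, float)
    chol = np.linalg.cholesky(np.asarray(sigma_w, float))
    from esmvar.postprocess import stationary_cov

    v0 = np.linalg.cholesky(stationary_cov(phi, np.asarray(sigma_w, float)))
    rows = []
    for i in range(n_persons):
        w = np.empty((n_cells, k))
        w[0] = v0 @ rng.standard_normal(k)
        for t in range(1, n_cells):
            w[t] = phi @ w[t - 1] + chol @ rng.standard_normal(k)
        keep = rng.random(n_cells) < keep_prob
        keep[0] = keep[-1] = True
        for t in np.where(keep)[0]:
            rows.append((i, 0, t, t * 60.0, t * 60.0, *(np.asarray(mu) + w[t])))
    df = pd.DataFrame(rows, columns=["person_id", "day", "prompt_index",
                                     "scheduled_minute", "timestamp_minute",
                                     *variables])
    sched = pd.Series(n_cells, index=pd.Index(range(n_persons),
                                              name="person_id"))
    return EsmDataset(df, variables, sched)


@pytest.fixture(scope="session")
def study_fit():
    """Small synthetic three-variable study fitted with schema covariates."""
    params = trivariate_study_params()
    data, effects = simulate_study(params, n_persons=25, seed=901)
    kept, _ = exclusion_filter(data)
    grid = build_time_grid(kept)
    spec = specify_model(params.variables, covariates=("schemas",),
                         settings=TEST_SAMPLER)
    post = fit(grid, spec, baseline=effects.baseline_table(), seed=17)
    return {"params": params, "data": kept, "effects": effects,
            "grid": grid, "spec": spec, "post": post}


@pytest.fixture(scope="session")
def bivariate_fit():
    """Complete-panel two-variable fit with homogeneous truth."""
    phi = np.array([[0.5, 0.2], [0.1, 0.4]])
    sw = 0.75 * np.array([[1.0, 0.3], [0.3, 1.0]])
    data = make_panel(30, 70, phi, sw, mu=[2.0, 3.0], seed=42)
    grid = build_time_grid(data)
    spec = specify_model(VARIABLES2, settings=TEST_SAMPLER)
    post = fit(grid, spec, seed=5)
    return {"phi": phi, "sigma_w": sw, "grid": grid, "spec": spec,
            "post": post}
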