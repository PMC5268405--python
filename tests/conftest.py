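import numpy as np
import pytest

from nivalis import (
    AnimalModel,
    MCMCSettings,
    ModelSpec,
    SimulationConfig,
    simulate_dataset,
)
from nivalis.selection import relativize_fitness


def small_config(seed=11, **kw):
    """Reduced-scale study world reused across the suite."""
    base = dict(n_founders=40, n_years=5, seed=seed)
    base.update(kw)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def small_dataset():
    return simulate_dataset(small_config())


@pytest.fixture(scope="session")
def rel_fitness(small_dataset):
    fit = small_dataset.fitness.drop_duplicates("id")
    return relativize_fitness(fit, "lrs", by=("sex", "cohort"))


@pytest.fixture(scope="session")
def bivariate_posterior(small_dataset, rel_fitness):
    """Mass x relative-fitness animal model on the small world."""
    model = AnimalModel(
        spec=ModelSpec.multivariate(traits=("mass",), fitness="omega"),
        mcmc=MCMCSettings(iterations=1600, burnin=400, thin=4, seed=2),
    )
    model.fit(small_dataset.phenotypes, small_dataset.pedigree, fitness=rel_fitness)
    return model.posterior_


@pytest.fixture(scope="session")
def growth_fit():
    """Growth/survival model fitted to a compact synthetic world."""
    from nivalis import GrowthMCMC, GrowthSurvivalModel

    ds = simulate_dataset(small_config(seed=7, n_founders=30, n_years=4))
    surv = ds.truth.growth[["id", "sex", "survived"]]
    model = GrowthSurvivalModel(
        mcmc=GrowthMCMC(iterations=3000, burnin=1200, thin=6, n_chains=1, seed=3)
    )
    model.fit(ds.captures, ds.snow, surv)
    return ds, model.posterior_


def fake_vcv_posterior(G, pe=None, R=None, maternal=None, traits=None,
                       n_samples=400, jitter=0.0, bv=None, ids=None, seed=0):
    """Posterior stub with (optionally jittered) constant covariance draws."""
    from nivalis.animal import VarCompPosterior

    G = np.atleast_2d(np.asarray(G, dtype=float))
    k = G.shape[0]
    traits = list(traits) if traits else [f"t{i}" for i in range(k)]
    rng = np.random.default_rng(seed)

    def draws(M):
        M = np.eye(k) * 0.0 if M is None else np.atleast_2d(np.asarray(M, float))
        out = np.repeat(M[None], n_samples, axis=0)
        if jitter:
            noise = rng.normal(0, jitter, size=(n_samples, k, k))
            out = out + (noise + noise.transpose(0, 2, 1)) / 2
        return out

    samples = {
        "G": draws(G),
        "pe": draws(pe),
        "maternal": draws(maternal),
        "R": draws(R),
        "year": draws(None),
        "fixed": np.zeros((n_samples, 1)),
    }
    return VarCompPosterior(traits, samples, bv, ids, ["t0:1"], {})
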