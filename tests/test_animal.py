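import numpy as np
import pandas as pd
import pytest

from nivalis import (
    AnimalModel,
    MCMCSettings,
    ModelSpec,
    TraitDef,
    genetic_correlation,
    heritability,
    simulate_dataset,
)
from nivalis.animal import VarCompPosterior, _rinvwishart
from nivalis.stats import (
    hpd_interval,
    lag1_autocorr,
    pmcmc,
    posterior_mode,
    split_rhat,
)
from tests.conftest import fake_vcv_posterior, small_config


# ------------------------------------------------------------- summary stats
class TestPosteriorSummaries:
    def test_mode_of_symmetric_sample_near_mean(self):
        x = np.random.default_rng(0).normal(3.0, 1.0, 20000)
        assert posterior_mode(x) == pytest.approx(3.0, abs=0.25)

    def test_mode_of_point_mass(self):
        assert posterior_mode(np.full(500, 2.5)) == 2.5

    def test_mode_of_gamma_matches_analytic(self):
        x = np.random.default_rng(1).gamma(2.0, 1.0, 10000)
        assert posterior_mode(x) == pytest.approx(1.0, abs=0.15)  # (k-1)*theta

    def test_mode_warns_below_100_draws(self):
        with pytest.warns(UserWarning, match="only 50 draws"):
            posterior_mode(np.random.default_rng(2).normal(size=50))
        with pytest.raises(ValueError):
            posterior_mode(np.random.default_rng(2).normal(size=50), strict=True)

    def test_hpd_narrower_than_equal_tailed_for_skewed(self):
        x = np.random.default_rng(3).gamma(2.0, 1.0, 20000)
        lo, hi = hpd_interval(x, 0.95)
        q = np.percentile(x, [2.5, 97.5])
        assert (hi - lo) <= (q[1] - q[0])
        assert np.mean((x >= lo) & (x <= hi)) == pytest.approx(0.95, abs=0.01)

    def test_pmcmc_bounds(self):
        x = np.concatenate([np.full(99, 1.0), [-1.0]])
        assert pmcmc(x, 0.0) == pytest.approx(0.02)
        assert pmcmc(np.full(100, 1.0), 0.0) == pytest.approx(1 / 100)

    def test_split_rhat_detects_disagreement(self):
        rng = np.random.default_rng(4)
        good = rng.normal(size=(2, 500))
        bad = np.stack([rng.normal(0, 1, 500), rng.normal(3, 1, 500)])
        assert split_rhat(good) < 1.05
        assert split_rhat(bad) > 1.5

    def test_lag1_autocorr_of_white_noise(self):
        x = np.random.default_rng(5).normal(size=5000)
        assert abs(lag1_autocorr(x)) < 0.05

    def test_invwishart_moments(self):
        # mean of IW(Psi, df) is Psi / (df - k - 1)
        rng = np.random.default_rng(6)
        Psi = np.array([[4.0, 1.0], [1.0, 2.0]])
        df = 12.0
        draws = np.mean([_rinvwishart(rng, df, Psi) for _ in range(4000)], axis=0)
        assert np.allclose(draws, Psi / (df - 3), rtol=0.1)


# ------------------------------------------------------ derived-quantity math
class TestDerivedQuantities:
    def test_heritability_equal_va_vr(self):
        post = fake_vcv_posterior(G=[[1.0]], R=[[1.0]], traits=["mass"])
        assert np.allclose(heritability(post, "mass"), 0.5)

    def test_heritability_year_toggle(self):
        post = fake_vcv_posterior(G=[[2.0]], R=[[1.0]], traits=["mass"])
        post.samples["year"][:] = 1.0 * np.eye(1)
        with_year = heritability(post, "mass", include_year=True)
        without = heritability(post, "mass", include_year=False)
        assert np.allclose(with_year, 0.5)
        assert np.allclose(without, 2.0 / 3.0)

    def test_genetic_correlation_diagonal_G_is_zero(self):
        post = fake_vcv_posterior(G=np.eye(2), traits=["mass", "omega"])
        assert genetic_correlation(post, ("mass", "omega"))["mode"] == pytest.approx(
            0.0, abs=1e-9
        )

    def test_genetic_correlation_skips_zero_variance_draws(self):
        post = fake_vcv_posterior(G=np.eye(2), traits=["a", "b"], n_samples=100)
        post.samples["G"][:10, 1, 1] = 0.0
        res = genetic_correlation(post, ("a", "b"))
        assert res["n_skipped"] == 10
        assert len(res["samples"]) == 90


# ---------------------------------------------------------- sampler behaviour
def _one_way_data(seed=0, n_groups=40, per=6, mu=5.0, vg=2.0, ve=1.0):
    rng = np.random.default_rng(seed)
    g = np.repeat(np.arange(n_groups), per)
    eff = rng.normal(0, np.sqrt(vg), n_groups)
    y = mu + eff[g] + rng.normal(0, np.sqrt(ve), len(g))
    return g, y


def _reference_one_way_gibbs(g, y, iters=6000, burn=1000, seed=1, nu=0.002):
    """Independent scalar Gibbs sampler for y = mu + u_g + e."""
    rng = np.random.default_rng(seed)
    n_groups = g.max() + 1
    n = len(y)
    counts = np.bincount(g)
    mu, u = 0.0, np.zeros(n_groups)
    vg, ve = 1.0, 1.0
    keep = {"vg": [], "ve": [], "mu": []}
    for it in range(iters):
        # mu | rest (flat prior)
        resid = y - u[g]
        mu = rng.normal(resid.mean(), np.sqrt(ve / n))
        # u | rest
        ssum = np.bincount(g, weights=y - mu)
        prec = counts / ve + 1.0 / vg
        u = rng.normal(ssum / ve / prec, 1.0 / np.sqrt(prec))
        # variances | rest  (IW == scaled inv-chi2 in 1-D)
        ssq_u = np.sum(u**2)
        vg = (nu * 1.0 + ssq_u) / rng.chisquare(nu + n_groups)
        e = y - mu - u[g]
        ve = (nu * 1.0 + np.sum(e**2)) / rng.chisquare(nu + n)
        if it >= burn:
            keep["vg"].append(vg)
            keep["ve"].append(ve)
            keep["mu"].append(mu)
    return {k: np.asarray(v) for k, v in keep.items()}


class TestSamplerCorrectness:
    def test_conjugate_limit_matches_reference_gibbs(self):
        """On a pedigree-free one-way layout, the animal-model engine and an
        independent scalar Gibbs sampler agree on the posterior."""
        g, y = _one_way_data(seed=10)
        # dress the data as repeated phenotype records per individual
        phe = pd.DataFrame(
            {
                "id": [f"i{k}" for k in g],
                "sex": "F",
                "age_class": "adult",
                "date": 190,
                "year": 2000,
                "mass": y,
            }
        )
        ped = pd.DataFrame(
            {
                "id": [f"i{k}" for k in range(g.max() + 1)],
                "sire": "",
                "dam": "",
                "sex": "F",
                "cohort": 2000,
            }
        )
        from nivalis.pedigree import validate_pedigree

        spec = ModelSpec(
            traits=[TraitDef("mass", fixed_effects=("1",))], random_terms=("pe",)
        )
        model = AnimalModel(
            spec=spec, mcmc=MCMCSettings(iterations=6000, burnin=1000, thin=2, seed=3)
        )
        model.fit(phe, validate_pedigree(ped))
        post = model.posterior_
        ref = _reference_one_way_gibbs(g, y)

        for ours, theirs in [
            (post.samples["pe"][:, 0, 0], ref["vg"]),
            (post.samples["R"][:, 0, 0], ref["ve"]),
            (post.samples["fixed"][:, 0], ref["mu"]),
        ]:
            # generous Monte-Carlo tolerance: 4 x combined chain SE
            se = np.sqrt(np.var(ours) / 200 + np.var(theirs) / 200)
            assert abs(ours.mean() - theirs.mean()) < 4 * se + 0.02 * abs(theirs.mean())

    def test_null_additive_variance_shrinks_h2(self):
        G = np.diag([0.0, 8.0, 5.0, 0.1])
        ds = simulate_dataset(small_config(seed=13, G=G))
        model = AnimalModel(
            spec=ModelSpec.univariate("mass"),
            mcmc=MCMCSettings(iterations=1500, burnin=400, thin=3, seed=4),
        )
        model.fit(ds.phenotypes, ds.pedigree)
        h2 = heritability(model.posterior_, "mass")
        assert posterior_mode(h2) < 0.05
        assert hpd_interval(h2)[0] < 0.02  # lower bound at the boundary

    def test_row_order_invariance(self, small_dataset):
        """Permuting input rows leaves the posterior unchanged (same seed)."""
        mc = MCMCSettings(iterations=300, burnin=50, thin=2, seed=5)
        m1 = AnimalModel(spec=ModelSpec.univariate("mass"), mcmc=mc)
        m1.fit(small_dataset.phenotypes, small_dataset.pedigree)
        shuffled = small_dataset.phenotypes.sample(frac=1.0, random_state=0)
        m2 = AnimalModel(spec=ModelSpec.univariate("mass"), mcmc=mc)
        m2.fit(shuffled, small_dataset.pedigree)
        assert np.array_equal(
            m1.posterior_.samples["G"], m2.posterior_.samples["G"]
        )
        assert np.array_equal(
            m1.posterior_.samples["fixed"], m2.posterior_.samples["fixed"]
        )

    def test_univariate_recovery_covers_truth(self, small_dataset):
        model = AnimalModel(
            spec=ModelSpec.univariate("mass"),
            mcmc=MCMCSettings(iterations=2000, burnin=500, thin=3, seed=6),
        )
        model.fit(small_dataset.phenotypes, small_dataset.pedigree)
        va = model.posterior_.samples["G"][:, 0, 0]
        lo, hi = hpd_interval(va)
        assert lo < 4.34 < hi
        # all stored covariance draws PSD
        for level in ("G", "pe", "maternal", "year", "R"):
            arr = model.posterior_.samples[level]
            assert (arr[:, 0, 0] >= 0).all()

    def test_bivariate_psd_and_fixed_omega_residual(self, bivariate_posterior):
        post = bivariate_posterior
        w = post.trait_index("omega")
        R = post.samples["R"]
        assert R[:, w, w].max() < 1e-6  # residual variance pinned near zero
        assert np.allclose(R[:, 0, w], 0.0)
        for level in ("G", "pe"):
            eigs = np.linalg.eigvalsh(post.samples[level])
            assert eigs.min() > -1e-8

    def test_identifiability_error_names_aliased_column(self, small_dataset):
        phe = small_dataset.phenotypes.copy()
        phe["sex"] = "F"  # constant column aliases the intercept
        model = AnimalModel(
            spec=ModelSpec.univariate("mass"),
            mcmc=MCMCSettings(iterations=100, burnin=10, thin=1),
        )
        with pytest.raises(ValueError, match="aliased.*sex"):
            model.fit(phe, small_dataset.pedigree)

    def test_trait_without_observations_raises(self, small_dataset):
        model = AnimalModel(spec=ModelSpec.univariate("wingspan"))
        with pytest.raises(ValueError, match="wingspan"):
            model.fit(small_dataset.phenotypes, small_dataset.pedigree)

    def test_get_set_params_roundtrip(self):
        m = AnimalModel()
        m.set_params(mcmc=MCMCSettings(iterations=10))
        assert m.get_params()["mcmc"].iterations == 10
        with pytest.raises(ValueError):
            m.set_params(bogus=1)


def test_posterior_save_load_roundtrip(tmp_path, bivariate_posterior):
    bivariate_posterior.save(tmp_path / "post")
    back = VarCompPosterior.load(tmp_path / "post")
    assert back.traits == bivariate_posterior.traits
    assert np.allclose(back.samples["G"], bivariate_posterior.samples["G"])
    assert np.allclose(back.samples["R"], bivariate_posterior.samples["R"])
    assert np.allclose(back.bv, bivariate_posterior.bv)
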