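import numpy as np
import pandas as pd
import pytest

from nivalis import (
    SimulationConfig,
    SyntheticTruth,
    simulate_breeding_values,
    simulate_dataset,
    simulate_pedigree,
)
from nivalis.pedigree import additive_relationship, validate_pedigree
from nivalis.simulate import SimulationExtinctError
from tests.conftest import small_config


ZERO4 = np.zeros((4, 4))


class TestConfig:
    def test_covariances_must_be_psd(self):
        G = np.eye(4)
        G[0, 1] = G[1, 0] = 5.0  # breaks PSD
        with pytest.raises(ValueError, match="positive semi-definite"):
            SimulationConfig(G=G)

    def test_omega_residual_must_be_zero(self):
        R = np.eye(4)
        with pytest.raises(ValueError, match="omega residual"):
            SimulationConfig(residual_cov=R)

    def test_snowfall_before_snowmelt_rejected(self):
        with pytest.raises(ValueError, match="snowfall before snowmelt"):
            SimulationConfig(
                n_years=2, snowmelt_days=(120, 280), snowfall_days=(260, 130)
            )

    def test_sessions_outside_season_rejected(self):
        with pytest.raises(ValueError, match="outside the snow-free season"):
            SimulationConfig(session_days=(100, 200))

    def test_roundtrip_dict(self):
        cfg = small_config(seed=4)
        back = SimulationConfig.from_dict(cfg.to_dict())
        assert back.to_dict() == cfg.to_dict()


class TestPedigreeSimulation:
    def test_no_recruitment_gives_founders_only(self):
        cfg = small_config(litter_probs=(1.0,), adult_survival=0.99, n_years=3)
        ped, truth = simulate_pedigree(cfg)
        assert len(ped) == cfg.n_founders
        assert ped.founders.all()

    def test_determinism_same_seed(self):
        d1 = simulate_dataset(small_config(seed=5))
        d2 = simulate_dataset(small_config(seed=5))
        assert d1.pedigree.ids == d2.pedigree.ids
        pd.testing.assert_frame_equal(d1.phenotypes, d2.phenotypes)
        pd.testing.assert_frame_equal(d1.captures, d2.captures)
        pd.testing.assert_frame_equal(d1.fitness, d2.fitness)

    def test_byte_identical_output_files(self, tmp_path):
        for sub in ("a", "b"):
            simulate_dataset(small_config(seed=9)).write(tmp_path / sub)
        for f in (tmp_path / "a").iterdir():
            assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes(), f.name

    def test_litter_spacing_respected_exhaustively(self, small_dataset):
        litters = small_dataset.truth.litters
        for (_, _), grp in litters.groupby(["mother", "year"]):
            t0 = np.sort(grp["t0"].to_numpy())
            assert len(t0) <= 5
            if len(t0) > 1:
                assert np.diff(t0).min() >= 20.0

    def test_extinction_raises(self):
        cfg = small_config(n_founders=4, adult_survival=0.01, litter_probs=(1.0,))
        with pytest.raises(SimulationExtinctError):
            simulate_pedigree(cfg)

    def test_generated_pedigree_revalidates(self, small_dataset):
        frame = small_dataset.pedigree.to_frame()
        assert len(validate_pedigree(frame)) == len(small_dataset.pedigree)


class TestBreedingValues:
    def test_zero_G_gives_zero_bv(self, small_dataset):
        bv = simulate_breeding_values(small_dataset.pedigree, np.zeros((2, 2)), seed=1)
        assert np.all(bv == 0)

    def test_founder_variance_matches_G(self):
        cfg = small_config(litter_probs=(1.0,), adult_survival=0.99,
                           n_founders=2000, n_years=1)
        ped, _ = simulate_pedigree(cfg)
        bv = simulate_breeding_values(ped, np.array([[4.0]]), seed=2)
        var = bv.var()
        se = 4.0 * np.sqrt(2.0 / (len(ped) - 1))  # SE of a chi-square variance
        assert abs(var - 4.0) < 3 * se

    def test_bv_covariance_tracks_relatedness(self):
        """cov(BV_i, BV_j) across replicate drops equals A_ij * V_A."""
        rows = pd.DataFrame(
            [("s", "", "", "M", 0), ("d", "", "", "F", 0), ("o", "s", "d", "M", 1)],
            columns=["id", "sire", "dam", "sex", "cohort"],
        )
        ped = validate_pedigree(rows)
        A = additive_relationship(ped)
        rng = np.random.default_rng(3)
        reps = 5000
        draws = np.stack(
            [simulate_breeding_values(ped, np.array([[2.0]]), seed=rng)[:, 0]
             for _ in range(reps)]
        )
        C = np.cov(draws.T)
        assert np.allclose(C, 2.0 * A, atol=3 * 2.0 / np.sqrt(reps) * 2)

    def test_non_psd_G_rejected(self, small_dataset):
        G = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError, match="positive semi-definite"):
            simulate_breeding_values(small_dataset.pedigree, G)


class TestPhenotypesAndFitness:
    def test_degenerate_config_gives_pure_intercept(self):
        cfg = small_config(
            G=ZERO4, maternal_cov=ZERO4, pe_cov=ZERO4, year_cov=ZERO4,
            residual_cov=ZERO4, sex_effects=(0, 0, 0), juvenile_offsets=(0, 0, 0),
            date_lin=(0, 0, 0), date_quad=(0, 0, 0), year_trend_mass=0.0,
        )
        ds = simulate_dataset(cfg)
        assert np.allclose(ds.phenotypes["mass"], cfg.intercepts[0])
        assert np.allclose(ds.phenotypes["body_length"], cfg.intercepts[1])

    def test_sex_effect_recovered_in_records(self):
        cfg = small_config(seed=21, sex_effects=(4.0, 0.0, 0.0))
        ds = simulate_dataset(cfg)
        adults = ds.phenotypes[ds.phenotypes["age_class"] == "adult"]
        diff = (
            adults[adults.sex == "M"]["mass"].mean()
            - adults[adults.sex == "F"]["mass"].mean()
        )
        sd = adults["mass"].std()
        se = sd * np.sqrt(1 / (adults.sex == "M").sum() + 1 / (adults.sex == "F").sum())
        assert abs(diff - 4.0) < 4 * se

    def test_generating_trait_fitness_covariances(self):
        """Realized cov(BV_mass, omega) and cov(PE_mass, omega) match config."""
        cfg = small_config(litter_probs=(1.0,), adult_survival=0.99,
                           n_founders=4000, n_years=1)
        ped, truth = simulate_pedigree(cfg)
        n = len(ped)
        cov_a = np.cov(truth.bv[:, 0], truth.omega)[0, 1]
        cov_e = np.cov(truth.pe[:, 0], truth.omega)[0, 1]
        se = np.sqrt((cfg.G[0, 0] * truth.omega.var() + cfg.G[0, 3] ** 2) / n)
        assert abs(cov_a - cfg.G[0, 3]) < 4 * se
        se_e = np.sqrt((cfg.pe_cov[0, 0] * truth.omega.var() + cfg.pe_cov[0, 3] ** 2) / n)
        assert abs(cov_e - cfg.pe_cov[0, 3]) < 4 * se_e

    def test_fitness_cells_cover_every_individual_year(self, small_dataset):
        fit = small_dataset.fitness
        assert {"id", "sex", "cohort", "lrs", "year", "ars", "survived"} <= set(
            fit.columns
        )
        assert fit["survived"].isin((0, 1)).all()


class TestGrowthHistories:
    def test_zero_error_fast_growth_hits_asymptote(self):
        cfg = small_config(
            seed=2, measurement_error_sd=0.0, growth_rate_log_mean=np.log(1.0),
            growth_rate_log_sd=0.0,
        )
        ds = simulate_dataset(cfg)
        tr = ds.truth.growth.set_index("id")
        a = tr.loc[ds.captures["id"], "a"].to_numpy()
        assert np.allclose(ds.captures["mass"], a, rtol=1e-6)

    def test_neutral_survival_world_shows_no_mass_effect(self):
        """With b_mass = b_interaction = 0 survival is independent of a."""
        import statsmodels.api as sm

        cfg = small_config(seed=31, n_founders=60, surv_mass=0.0,
                           surv_interaction=0.0, surv_intercept=0.0,
                           surv_days=0.0, surv_sex_male=0.0)
        _, truth = simulate_pedigree(cfg)
        g = truth.growth
        X = sm.add_constant(g["a"].to_numpy())
        fit = sm.GLM(g["survived"], X, family=sm.families.Binomial()).fit()
        lo, hi = np.asarray(fit.conf_int())[1]
        assert lo < 0 < hi

    def test_default_world_selects_against_mass_in_short_seasons(self):
        neg = 0
        for seed in (1, 2, 3):
            _, truth = simulate_pedigree(small_config(seed=seed, n_founders=60))
            g = truth.growth[truth.growth["year"] >= small_config().start_year + 2]
            neg += np.cov(g["a"], g["survived"])[0, 1] < 0
        assert neg == 3

    def test_captures_within_season_and_after_emergence(self, small_dataset):
        caps = small_dataset.captures.merge(small_dataset.snow, on="year")
        assert (caps["julian_day"] >= caps["snowmelt_day"]).all()
        tr = small_dataset.truth.growth.set_index("id")
        age = caps["julian_day"].to_numpy() - tr.loc[caps["id"], "t0"].to_numpy()
        assert age.min() >= 25.0


def test_truth_roundtrips_to_json(tmp_path, small_dataset):
    path = tmp_path / "truth.json"
    small_dataset.truth.to_json(path)
    back = SyntheticTruth.from_json(path)
    assert back.ids == small_dataset.truth.ids
    assert np.allclose(back.bv, small_dataset.truth.bv)
    assert back.survived == small_dataset.truth.survived
    assert back.config.to_dict() == small_dataset.truth.config.to_dict()
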